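# histocbir

Content-based image retrieval (CBIR) for H&E histopathology patches using
deep features from intermediate layers of pre-trained convolutional networks.

Pathologists reviewing a whole-slide image routinely want to see *similar*
cases: given a query patch, retrieve the most visually similar patches from
an archive, together with their known diagnoses. `histocbir` implements the
retrieval pipeline and its full evaluation framework for this task:

1. **Offline indexing** — every archive patch is resized and normalised for a
   chosen CNN backbone, forwarded to a chosen intermediate layer, and the
   3-D activation map (H×W×C) is reduced to a 1-D descriptor by global
   average pooling (GAP), global max pooling (GMP) or flattening. Vectors,
   labels, ids and extraction provenance are persisted in an HDF5 feature
   bank.
2. **Online retrieval** — a query patch goes through the same pipeline and
   is scored against every stored vector with cosine similarity
   s(u, v) = ⟨u, v⟩ / (‖u‖‖v‖); results are ranked descending, ties broken
   deterministically by item id.
3. **Evaluation** — leave-one-out query-by-example: each of the N bank items
   queries the other N − 1. Per query, precision at k is P@k = I_r / k (the
   fraction of the k top-ranked items sharing the query's class); MAP@k is
   the mean of P@k over queries (*not* interpolated average precision);
   per-class confusion matrices at k show which classes are confused; and
   GLP_m@k = P_avg@k − P_m@k quantifies the gain (positive) or loss of GAP
   over an alternative configuration m. Selection procedures pick the best
   reduction, the best layer per backbone (minimum total precision deficit
   across k when no layer dominates at every k), and rank backbones.

A versioned registry catalogues nine ImageNet-pretrained backbones (VGG16,
InceptionV3, ResNet152V2, InceptionResNetV2, MobileNetV2, DenseNet201,
Xception, NASNetLarge, EfficientNetV2L) with their extraction layers, output
shapes, input sizes and pixel-normalisation modes; every backend output is
validated against it. The extraction backend is pluggable: a deterministic
seeded random-projection backend runs everywhere with no weight downloads
(and powers the whole test suite), while an optional `tensorflow.keras`
backend (`pip install 'histocbir[pretrained]'`) forwards through the real
pretrained networks.

## Worked example

Generate a 4-class synthetic patch collection (100 patches, weak class
signal), index it with VGG16/block5_pool/GAP features from the seeded
backend, and evaluate leave-one-out retrieval:

```bash
histocbir synth demo/patches --per-class 25 --patch-size 32 \
    --separation 0.4 --noise-sd 1.5 --seed 7
histocbir index demo/patches --backbone VGG16 --layer block5_pool \
    --reduction gap --backend seeded --seed 7 --out demo/bank.h5
histocbir evaluate demo/bank.h5 --ks 5,10 --out demo/report
```

which prints

```
wrote 100 patches under demo/patches (manifest: demo/patches/manifest.csv)
indexed 100 items (512-d) into demo/bank.h5
MAP@5 = 0.9280
MAP@10 = 0.9250
```

MAP@5 = 0.928 means that, averaged over all 100 leave-one-out queries, 92.8%
of each query's five nearest neighbours share its class (chance level here is
24/99 ≈ 0.24). The per-class confusion matrix at k = 5
(`demo/report/confusion_k5.csv`) shows *which* classes absorb the errors —
rows are query classes, columns retrieved classes, rows sum to 1, and the
diagonal is the class-conditional mean P@5:

```
          benign  insitu  invasive  normal
benign     0.928   0.000     0.000   0.072
insitu     0.000   0.936     0.064   0.000
invasive   0.000   0.056     0.944   0.000
normal     0.088   0.000     0.008   0.904
```

`histocbir sweep` evaluates a layers × reductions grid in one pass and runs
the reduction/layer selection procedures; `histocbir query` ranks the bank
against a single image and writes a top-k CSV.

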