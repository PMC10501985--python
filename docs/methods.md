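# Methods

## The retrieval model

`histocbir` treats patch retrieval as nearest-neighbour search in a deep
feature space. A pre-trained convolutional network is used purely as a fixed
feature extractor: the activation of a chosen intermediate layer, an H×W×C
map, is collapsed to a 1-D descriptor and patches are compared by cosine
similarity. Nothing is trained or fine-tuned; the method's degrees of
freedom are *which backbone*, *which layer* and *which reduction*, and the
evaluation framework exists to choose among them.

Three reductions are supported:

* **GAP** — per-channel spatial mean, output length C. Summarises how much
  of each learned pattern is present anywhere in the patch.
* **GMP** — per-channel spatial max, length C. Sensitive to the strongest
  local response only.
* **FLATTEN** — row-major linearisation (channels fastest-varying), length
  H·W·C. Keeps spatial layout but is huge (up to ~1.8M dimensions for early
  EfficientNetV2L layers) and brittle to translation.

Cosine similarity is scale-invariant, so descriptors are deliberately *not*
L2-normalised at extraction time; normalisation happens implicitly in the
similarity. Zero-norm descriptors are treated as errors rather than scored
0 — a dead (all-zero) pooled feature indicates a broken layer or backend and
silently scoring it would corrupt rankings.

## Registry as data

The backbone/layer catalogue (input size, preprocessing mode, layer names
and output shapes) is a versioned JSON document shipped with the package,
not code. Every backend forward pass is validated against it and a shape
mismatch is a hard error. The rationale is that silent shape drift across
deep-learning framework versions is the main failure mode of "extract layer
X" pipelines; pinning shapes as data makes it detectable. The Xception
entry exposes three curated layers by default, with the seven additional
middle-flow outputs (`add_3`…`add_9`, all 19×19×728) behind an
`extended=True` flag.

## Preprocessing

Patches are resized (bilinear by default; configurable, since the choice is
a convention rather than part of the method) to the backbone's square input
side, then pixel-normalised per the backbone's mode: symmetric scaling
x/127.5 − 1 onto [−1, 1]; unit scaling plus ImageNet channel
standardisation; BGR channel swap with ImageNet mean subtraction; or
identity. The ImageNet channel statistics are configurable defaults shipped
in `data/channel_stats.json` (they are conventions of the pretrained
weights, not constants of the method). No stain normalisation is applied
anywhere in the default pipeline.

## Evaluation framework

* **P@k = I_r / k** per query; evaluated by default at k ∈ {5, 10, 50, 100},
  the regime where a pathologist inspects the first page(s) of results.
* **MAP@k** is the arithmetic mean of P@k over all queries. This is *not*
  the IR literature's interpolated mean average precision; the simpler
  statistic is used throughout and named consistently.
* **Leave-one-out protocol:** each bank item queries the bank with itself
  excluded, so N items yield N queries over N − 1 candidates each.
* **Confusion at k** is macro-averaged over queries: cell (i, j) is the mean
  over class-i queries of the fraction of class-j items in the top k. Rows
  sum to 1 and the class-count-weighted diagonal equals MAP@k; both
  identities are property-tested.
* **GLP_m@k = P_avg@k − P_m@k** measures the gain (positive) or loss of the
  global-average-pooling side of a comparison. Per-backbone summaries
  average GLP@k over layers with equal weights.

### Selection procedures

* **Reduction:** the reduction with the highest grand-mean P@k over all
  layers and k wins; exact ties fall back to GAP > GMP > FLATTEN and are
  flagged. The per-backbone GLP table is attached for auditing.
* **Layer (per backbone):** if one layer attains the per-k maximum at every
  k it is chosen. Otherwise the candidates are the per-k winners and the
  choice minimises the total deficit Σ_k (max_layer P@k − P_candidate@k);
  this formalises "pick the layer that loses least precision overall" as a
  single number. Residual ties prefer the smaller descriptor, then the
  lexicographically smaller name. The pairwise per-k gain/loss table against
  every rival candidate is always emitted. On the bundled BACH reference
  cells this rule selects block_14_add (MobileNetV2), normal_concat_12
  (NASNetLarge) and block5_pool (VGG16), matching the published choices.
* **Backbone:** one (best-layer, GAP) row per backbone, sorted by P@5
  descending with ties broken at P@10 then by name.

## Extraction backends

The backend is an injected interface (backbone, layer, batch of S×S×3
inputs → batch of H×W×C maps). The default **seeded random-projection
backend** bilinearly pools the normalised input onto the layer's H×W grid
and mixes the three colour channels into C channels with a fixed Gaussian
matrix derived from (seed, backbone, layer). It is deterministic, needs no
framework or downloads, and preserves chromatic/texture structure, which is
exactly what the synthetic datasets encode — so end-to-end pipeline tests
have signal to find. It is *not* a semantic feature extractor; retrieval
quality numbers obtained with it say nothing about histology. The optional
Keras backend forwards through the real pretrained networks for production
use.

## Synthetic data

The generators emulate the shape of the 400-patch, 4-class breast-histology
benchmark (default 4 × 100, class names benign / insitu / invasive /
normal), not its content.

* **Feature banks:** class c draws items as separation·μ_c + σ·ε with
  orthonormal centroids μ_c and isotropic Gaussian noise. Two regimes are
  exactly analyzable and used as oracles: at separation 0 items are
  exchangeable, so E[P@k] = (m − 1)/(N − 1) for balanced classes of size m;
  at separation ≫ σ every class collapses onto its centroid and MAP@k = 1
  for k ≤ m − 1.
* **Patch images:** each class carries a distinct hue direction (equally
  spaced hues, centered to perturb chroma rather than brightness) applied as
  a DC shift plus a class-specific-frequency sinusoidal texture, both scaled
  by `separation`, over Gaussian pixel noise scaled by `noise_sd`. The
  pixel-domain amplitudes (base gray 120; 10, 15 and 12 intensity levels per
  unit of separation/noise) were chosen once so that separations of order 1
  give partial class overlap — neither trivial nor hopeless for the
  end-to-end pipeline. Default separation 4.0 gives clearly separable
  classes for fixture use.
* One seed in the spec drives every draw; identical specs produce
  byte-identical images and manifests.

What passing tests on these fixtures shows: the plumbing (shapes,
provenance, ranking, metric arithmetic, selection logic) is correct and
deterministic. What it does not show: anything about retrieval quality on
real H&E tissue, stain variability, or ImageNet feature transfer.

## Numerical choices

* Bank matrices are stored float32 (storage/precision balance at up to
  400 × 1.8M); all similarity arithmetic is float64.
* Ranking sorts by similarity descending with ties broken by ascending item
  id. Similarities are computed with one dot product per row rather than a
  single matrix–vector BLAS call: BLAS kernels can round bit-identical rows
  differently depending on their position in the matrix, which would make
  tie ordering (duplicated patches) nondeterministic.
* Flatten order is fixed (row-major, channels fastest). Cosine ranking is
  invariant to any fixed permutation, so only consistency matters.
* k beyond the candidate count is an explicit error everywhere (P@k divides
  by k; silent truncation would bias it).

## Bundled reference cells

`histocbir.reference` ships the per-layer mean-P@k cells reported for the
BACH benchmark with ImageNet-pretrained backbones and GAP reduction
(400 leave-one-out queries per cell). They serve as fixtures for the GLP
arithmetic and the layer-selection procedure — including reconstructing
rival layers' absolute cells from the chosen layer's row and the published
per-k gain/loss values — and as the inputs to `scripts/acceptance.py`.

## Known limitations

* Exhaustive O(N·D) scoring per query; no approximate-nearest-neighbour
  index. Fine at archive sizes of 10³–10⁴; not designed beyond that.
* No stain colour normalisation, no WSI tiling, no data augmentation: the
  unit of work is a pre-extracted patch.
* The pretrained backend requires tensorflow and weight downloads and is
  exercised only by its name/registry validation logic in the offline test
  suite.
* Evaluation reports raw precision differences only; no significance
  machinery is attached to the selection procedures.
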