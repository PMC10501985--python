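{
  "description": "Conventional ImageNet channel statistics used by the pixel-normalisation modes. Values are configurable defaults, not constants of the method: pass explicit stats to normalize() to override. imagenet_bgr_mean is in B,G,R order (raw 0-255 scale); imagenet_unit_mean/std are in R,G,B order on the 0-1 scale.",
  "imagenet_bgr_mean": [103.939, 116.779, 123.68],
  "imagenet_unit_mean": [0.485, 0.456, 0.406],
  "imagenet_unit_std": [0.229, 0.224, 0.225]
}
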