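{
  "schema_version": "1.0",
  "description": "Backbone/layer catalogue: nine ImageNet-pretrained CNN feature extractors, the intermediate layers exposed for deep-feature extraction, their feature-map output shapes (H, W, C), square input size in pixels, and pixel-normalisation mode. The registry validates backend outputs against these shapes at extraction time.",
  "backbones": {
    "VGG16": {
      "input_size": 224,
      "preprocess": "bgr_zero_center",
      "layers": [
        {"name": "block1_pool", "h": 112, "w": 112, "c": 64},
        {"name": "block2_pool", "h": 56, "w": 56, "c": 128},
        {"name": "block3_pool", "h": 28, "w": 28, "c": 256},
        {"name": "block4_pool", "h": 14, "w": 14, "c": 512},
        {"name": "block5_pool", "h": 7, "w": 7, "c": 512}
      ]
    },
    "InceptionV3": {
      "input_size": 299,
      "preprocess": "scale_symmetric",
      "layers": [
        {"name": "mixed0", "h": 35, "w": 35, "c": 256},
        {"name": "mixed1", "h": 35, "w": 35, "c": 288},
        {"name": "mixed2", "h": 35, "w": 35, "c": 288},
        {"name": "mixed3", "h": 17, "w": 17, "c": 768},
        {"name": "mixed4", "h": 17, "w": 17, "c": 768},
        {"name": "mixed5", "h": 17, "w": 17, "c": 768},
        {"name": "mixed6", "h": 17, "w": 17, "c": 768},
        {"name": "mixed7", "h": 17, "w": 17, "c": 768},
        {"name": "mixed8", "h": 8, "w": 8, "c": 1280},
        {"name": "mixed9", "h": 8, "w": 8, "c": 2048},
        {"name": "mixed10", "h": 8, "w": 8, "c": 2048}
      ]
    },
    "ResNet152V2": {
      "input_size": 224,
      "preprocess": "scale_symmetric",
      "layers": [
        {"name": "conv2_block3_out", "h": 28, "w": 28, "c": 256},
        {"name": "conv3_block8_out", "h": 14, "w": 14, "c": 512},
        {"name": "conv4_block36_out", "h": 7, "w": 7, "c": 1024},
        {"name": "conv5_block3_out", "h": 7, "w": 7, "c": 2048}
      ]
    },
    "InceptionResNetV2": {
      "input_size": 299,
      "preprocess": "scale_symmetric",
      "layers": [
        {"name": "mixed_5b", "h": 35, "w": 35, "c": 320},
        {"name": "mixed_6a", "h": 17, "w": 17, "c": 1088},
        {"name": "mixed_7a", "h": 8, "w": 8, "c": 2080},
        {"name": "conv_7b", "h": 8, "w": 8, "c": 1536}
      ]
    },
    "Xception": {
      "input_size": 299,
      "preprocess": "scale_symmetric",
      "layers": [
        {"name": "add_2", "h": 19, "w": 19, "c": 728},
        {"name": "add_10", "h": 19, "w": 19, "c": 728},
        {"name": "block14_sepconv2", "h": 10, "w": 10, "c": 2048}
      ],
      "extended_layers": [
        {"name": "add_3", "h": 19, "w": 19, "c": 728},
        {"name": "add_4", "h": 19, "w": 19, "c": 728},
        {"name": "add_5", "h": 19, "w": 19, "c": 728},
        {"name": "add_6", "h": 19, "w": 19, "c": 728},
        {"name": "add_7", "h": 19, "w": 19, "c": 728},
        {"name": "add_8", "h": 19, "w": 19, "c": 728},
        {"name": "add_9", "h": 19, "w": 19, "c": 728}
      ]
    },
    "DenseNet201": {
      "input_size": 224,
      "preprocess": "scale_unit_imagenet",
      "layers": [
        {"name": "pool2_pool", "h": 28, "w": 28, "c": 128},
        {"name": "pool3_pool", "h": 14, "w": 14, "c": 256},
        {"name": "pool4_pool", "h": 7, "w": 7, "c": 896},
        {"name": "conv5_block32_concat", "h": 7, "w": 7, "c": 1920}
      ]
    },
    "NASNetLarge": {
      "input_size": 331,
      "preprocess": "scale_symmetric",
      "layers": [
        {"name": "normal_concat_5", "h": 42, "w": 42, "c": 1008},
        {"name": "reduction_concat_reduce_6", "h": 21, "w": 21, "c": 1344},
        {"name": "normal_concat_12", "h": 21, "w": 21, "c": 2016},
        {"name": "reduction_concat_reduce_12", "h": 11, "w": 11, "c": 2688},
        {"name": "normal_concat_18", "h": 11, "w": 11, "c": 4032}
      ]
    },
    "MobileNetV2": {
      "input_size": 224,
      "preprocess": "scale_symmetric",
      "layers": [
        {"name": "block_1_project_BN", "h": 56, "w": 56, "c": 24},
        {"name": "block_2_add", "h": 56, "w": 56, "c": 24},
        {"name": "block_3_project_BN", "h": 28, "w": 28, "c": 32},
        {"name": "block_4_add", "h": 28, "w": 28, "c": 32},
        {"name": "block_5_add", "h": 28, "w": 28, "c": 32},
        {"name": "block_6_project_BN", "h": 14, "w": 14, "c": 64},
        {"name": "block_7_add", "h": 14, "w": 14, "c": 64},
        {"name": "block_8_add", "h": 14, "w": 14, "c": 64},
        {"name": "block_9_add", "h": 14, "w": 14, "c": 64},
        {"name": "block_10_project_BN", "h": 14, "w": 14, "c": 96},
        {"name": "block_11_add", "h": 14, "w": 14, "c": 96},
        {"name": "block_12_add", "h": 14, "w": 14, "c": 96},
        {"name": "block_13_project_BN", "h": 7, "w": 7, "c": 160},
        {"name": "block_14_add", "h": 7, "w": 7, "c": 160},
        {"name": "block_15_add", "h": 7, "w": 7, "c": 160},
        {"name": "block_16_project_BN", "h": 7, "w": 7, "c": 320},
        {"name": "out_relu", "h": 7, "w": 7, "c": 1280}
      ]
    },
    "EfficientNetV2L": {
      "input_size": 480,
      "preprocess": "identity",
      "layers": [
        {"name": "block1d_add", "h": 240, "w": 240, "c": 32},
        {"name": "block2g_add", "h": 120, "w": 120, "c": 64},
        {"name": "block3g_add", "h": 60, "w": 60, "c": 96},
        {"name": "block4j_add", "h": 30, "w": 30, "c": 192},
        {"name": "block5s_add", "h": 30, "w": 30, "c": 224},
        {"name": "block6y_add", "h": 15, "w": 15, "c": 384},
        {"name": "block7g_add", "h": 15, "w": 15, "c": 640},
        {"name": "top_activation", "h": 15, "w": 15, "c": 1280}
      ]
    }
  }
}
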