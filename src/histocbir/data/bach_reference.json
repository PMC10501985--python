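{
  "schema_version": "1.0",
  "description": "Reference mean-P@k values for leave-one-out retrieval on the BACH breast-histology benchmark (400 H&E patches, 4 classes) with ImageNet-pretrained backbones and global-average-pooling reduction. Shipped so the layer-selection and gain/loss (GLP) machinery can be audited against known benchmark cells without downloading the dataset or pretrained weights.",
  "ks": [5, 10, 50, 100],
  "best_layer_per_k": {
    "DenseNet201": {
      "5": ["conv5_block32_concat", 0.67],
      "10": ["conv5_block32_concat", 0.626],
      "50": ["conv5_block32_concat", 0.4839],
      "100": ["conv5_block32_concat", 0.4123]
    },
    "EfficientNetV2L": {
      "5": ["block6y_add", 0.7365],
      "10": ["block6y_add", 0.671],
      "50": ["block6y_add", 0.4998],
      "100": ["block6y_add", 0.4192]
    },
    "InceptionResNetV2": {
      "5": ["mixed_7a", 0.68],
      "10": ["mixed_7a", 0.6325],
      "50": ["mixed_7a", 0.495],
      "100": ["mixed_7a", 0.4177]
    },
    "InceptionV3": {
      "5": ["mixed6", 0.693],
      "10": ["mixed6", 0.6298],
      "50": ["mixed6", 0.4864],
      "100": ["mixed6", 0.411]
    },
    "MobileNetV2": {
      "5": ["block_13_project_BN", 0.6655],
      "10": ["block_13_project_BN", 0.604],
      "50": ["block_14_add", 0.471],
      "100": ["out_relu", 0.4025]
    },
    "NASNetLarge": {
      "5": ["normal_concat_12", 0.695],
      "10": ["normal_concat_12", 0.6295],
      "50": ["normal_concat_12", 0.4988],
      "100": ["reduction_concat_reduce_12", 0.4197]
    },
    "ResNet152V2": {
      "5": ["conv4_block36_out", 0.6475],
      "10": ["conv4_block36_out", 0.5923],
      "50": ["conv4_block36_out", 0.4586],
      "100": ["conv4_block36_out", 0.3902]
    },
    "VGG16": {
      "5": ["block4_pool", 0.6125],
      "10": ["block5_pool", 0.562],
      "50": ["block5_pool", 0.4532],
      "100": ["block5_pool", 0.3871]
    },
    "Xception": {
      "5": ["add_10", 0.671],
      "10": ["add_10", 0.6185],
      "50": ["add_10", 0.4771],
      "100": ["add_10", 0.4051]
    }
  },
  "chosen_layer_pk": {
    "VGG16": {"layer": "block5_pool", "pk": {"5": 0.5995, "10": 0.562, "50": 0.4532, "100": 0.387075}},
    "ResNet152V2": {"layer": "conv4_block36_out", "pk": {"5": 0.6475, "10": 0.59225, "50": 0.45855, "100": 0.390225}},
    "DenseNet201": {"layer": "conv5_block32_concat", "pk": {"5": 0.67, "10": 0.626, "50": 0.4839, "100": 0.412325}},
    "InceptionV3": {"layer": "mixed6", "pk": {"5": 0.693, "10": 0.62975, "50": 0.48635, "100": 0.411025}},
    "Xception": {"layer": "add_10", "pk": {"5": 0.671, "10": 0.6185, "50": 0.4771, "100": 0.4051}},
    "InceptionResNetV2": {"layer": "mixed_7a", "pk": {"5": 0.68, "10": 0.6325, "50": 0.495, "100": 0.4177}},
    "MobileNetV2": {"layer": "block_14_add", "pk": {"5": 0.6605, "10": 0.6, "50": 0.471, "100": 0.398575}},
    "NASNetLarge": {"layer": "normal_concat_12", "pk": {"5": 0.695, "10": 0.6295, "50": 0.49885, "100": 0.419425}},
    "EfficientNetV2L": {"layer": "block6y_add", "pk": {"5": 0.7365, "10": 0.671, "50": 0.4998, "100": 0.41915}}
  },
  "layer_gain_loss": {
    "MobileNetV2": {
      "reference": "block_14_add",
      "others": {
        "block_13_project_BN": {"5": -0.005, "10": -0.004, "50": 0.01255, "100": 0.007475},
        "out_relu": {"5": 0.027, "10": 0.0085, "50": 0.0014, "100": -0.003925}
      }
    },
    "NASNetLarge": {
      "reference": "normal_concat_12",
      "others": {
        "reduction_concat_reduce_12": {"5": 0.0295, "10": 0.009, "50": 0.00535, "100": -0.000275}
      }
    },
    "VGG16": {
      "reference": "block5_pool",
      "others": {
        "block4_pool": {"5": -0.013, "10": 0.01575, "50": 0.0343, "100": 0.0246}
      }
    }
  }
}
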