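"""Independently transcribed feature-size tables used as a registry oracle.

Each row: (layer name, (H, W, C) output shape, Max/Avg-pooled size,
flattened size) as printed in the published per-backbone tables.  Kept as a
separate transcription (not derived from the package's catalogue) so the
registry test is a genuine cross-check.
"""

PRINTED_FEATURE_SIZES = {
    "VGG16": [
        ("block1_pool", (112, 112, 64), 64, 802816),
        ("block2_pool", (56, 56, 128), 128, 401408),
        ("block3_pool", (28, 28, 256), 256, 200704),
        ("block4_pool", (14, 14, 512), 512, 100352),
        ("block5_pool", (7, 7, 512), 512, 25088),
    ],
    "InceptionV3": [
        ("mixed0", (35, 35, 256), 256, 313600),
        ("mixed1", (35, 35, 288), 288, 352800),
        ("mixed2", (35, 35, 288), 288, 352800),
        ("mixed3", (17, 17, 768), 768, 221952),
        ("mixed4", (17, 17, 768), 768, 221952),
        ("mixed5", (17, 17, 768), 768, 221952),
        ("mixed6", (17, 17, 768), 768, 221952),
        ("mixed7", (17, 17, 768), 768, 221952),
        ("mixed8", (8, 8, 1280), 1280, 81920),
        ("mixed9", (8, 8, 2048), 2048, 131072),
        ("mixed10", (8, 8, 2048), 2048, 131072),
    ],
    "ResNet152V2": [
        ("conv2_block3_out", (28, 28, 256), 256, 200704),
        ("conv3_block8_out", (14, 14, 512), 512, 100352),
        ("conv4_block36_out", (7, 7, 1024), 1024, 50176),
        ("conv5_block3_out", (7, 7, 2048), 2048, 100352),
    ],
    "InceptionResNetV2": [
        ("mixed_5b", (35, 35, 320), 320, 392000),
        ("mixed_6a", (17, 17, 1088), 1088, 314432),
        ("mixed_7a", (8, 8, 2080), 2080, 133120),
        ("conv_7b", (8, 8, 1536), 1536, 98304),
    ],
    "Xception": [
        ("add_2", (19, 19, 728), 728, 262808),
        ("add_10", (19, 19, 728), 728, 262808),
        ("block14_sepconv2", (10, 10, 2048), 2048, 204800),
    ],
    "DenseNet201": [
        ("pool2_pool", (28, 28, 128), 128, 100352),
        ("pool3_pool", (14, 14, 256), 256, 50176),
        ("pool4_pool", (7, 7, 896), 896, 43904),
        ("conv5_block32_concat", (7, 7, 1920), 1920, 94080),
    ],
    "NASNetLarge": [
        ("normal_concat_5", (42, 42, 1008), 1008, 1778112),
        ("reduction_concat_reduce_6", (21, 21, 1344), 1344, 592704),
        ("normal_concat_12", (21, 21, 2016), 2016, 889056),
        ("reduction_concat_reduce_12", (11, 11, 2688), 2688, 325248),
        ("normal_concat_18", (11, 11, 4032), 4032, 487872),
    ],
    "MobileNetV2": [
        ("block_1_project_BN", (56, 56, 24), 24, 75264),
        ("block_2_add", (56, 56, 24), 24, 75264),
        ("block_3_project_BN", (28, 28, 32), 32, 25088),
        ("block_4_add", (28, 28, 32), 32, 25088),
        ("block_5_add", (28, 28, 32), 32, 25088),
        ("block_6_project_BN", (14, 14, 64), 64, 12544),
        ("block_7_add", (14, 14, 64), 64, 12544),
        ("block_8_add", (14, 14, 64), 64, 12544),
        ("block_9_add", (14, 14, 64), 64, 12544),
        ("block_10_project_BN", (14, 14, 96), 96, 18816),
        ("block_11_add", (14, 14, 96), 96, 18816),
        ("block_12_add", (14, 14, 96), 96, 18816),
        ("block_13_project_BN", (7, 7, 160), 160, 7840),
        ("block_14_add", (7, 7, 160), 160, 7840),
        ("block_15_add", (7, 7, 160), 160, 7840),
        ("block_16_project_BN", (7, 7, 320), 320, 15680),
        ("out_relu", (7, 7, 1280), 1280, 62720),
    ],
    "EfficientNetV2L": [
        ("block1d_add", (240, 240, 32), 32, 1843200),
        ("block2g_add", (120, 120, 64), 64, 921600),
        ("block3g_add", (60, 60, 96), 96, 345600),
        ("block4j_add", (30, 30, 192), 192, 172800),
        ("block5s_add", (30, 30, 224), 224, 201600),
        ("block6y_add", (15, 15, 384), 384, 86400),
        ("block7g_add", (15, 15, 640), 640, 144000),
        ("top_activation", (15, 15, 1280), 1280, 288000),
    ],
}

PRINTED_INPUT_SIZES = {
    "VGG16": 224,
    "InceptionV3": 299,
    "ResNet152V2": 224,
    "InceptionResNetV2": 299,
    "MobileNetV2": 224,
    "DenseNet201": 224,
    "Xception": 299,
    "NASNetLarge": 331,
    "EfficientNetV2L": 480,
}
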