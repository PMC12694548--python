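# Published budget table for the audit CLI.
# params_M: trainable parameters in millions, rounded to params_decimals.
# macs_G: multiply-accumulates at 224x224x3 in G, 2 decimals (the
# lightweight-CNN literature prints this column as "FLOPs(G)").
# Rows whose printed figures are not reconstructible from standard layer
# definitions are omitted (see docs/methods.md).
targets:
  - {name: MS, params_M: 1.53, macs_G: 0.06}
  - {name: MS-CBAM, params_M: 1.52}
  - {name: MS-CA, params_M: 1.37}
  - {name: MS-CA-I, params_M: 1.07}
  - {name: ICS-MS-CE, params_M: 1.12}
  - {name: ICS-MS, params_M: 1.17, macs_G: 0.21}
  - {name: resnet50, params_M: 23.53}
  - {name: mobilenet_v2, params_M: 2.24}
  - {name: mobilenet_v3_large, params_M: 4.2, params_decimals: 1, macs_G: 0.22}
  - {name: shufflenet_v2_x1_0, params_M: 1.26}
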