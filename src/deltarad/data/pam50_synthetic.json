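{
 "centroids": {
  "Basal": [
   -0.7452,
   1.2673,
   -1.1576,
   0.326,
   -0.7875,
   0.5386,
   0.0744,
   0.4642,
   -0.9206,
   0.2103,
   0.1803,
   -1.3098,
   0.3862,
   0.4793,
   1.781,
   1.0601,
   -0.0165,
   -2.8031,
   -1.538,
   -0.7799,
   -0.4281,
   0.13,
   0.916,
   0.3819,
   -0.4028,
   -0.5818,
   1.0033,
   0.9056,
   -0.0688,
   -0.0639,
   -1.6939,
   0.1305,
   -0.2302,
   -0.8143,
   0.0206,
   1.4681,
   0.7809,
   -2.1782,
   -2.2442,
   0.2723,
   0.0866,
   0.701,
   1.0523,
   -0.9833,
   -0.7616,
   -1.301,
   -0.0033,
   0.5196,
   0.4692,
   0.9043
  ],
  "Her2": [
   -0.4164,
   -0.9543,
   -1.3929,
   0.0624,
   0.8782,
   -0.8334,
   0.3281,
   1.126,
   0.6037,
   -0.4147,
   2.0952,
   -0.4689,
   0.9161,
   0.9389,
   0.7647,
   0.5666,
   0.9054,
   -0.654,
   -0.5111,
   1.8993,
   0.6363,
   0.5158,
   0.6244,
   0.5761,
   -1.0088,
   -0.3954,
   0.7947,
   0.0025,
   2.203,
   0.2703,
   2.1422,
   -0.0494,
   0.1195,
   -1.0138,
   1.2194,
   2.079,
   0.5527,
   -1.1467,
   0.7682,
   -0.2773,
   -0.5781,
   1.4132,
   -1.5897,
   -1.1652,
   0.7111,
   -0.4954,
   0.1402,
   0.3581,
   1.4518,
   -0.9779
  ],
  "LumA": [
   -0.7336,
   0.0744,
   -0.6645,
   -0.5898,
   -1.4559,
   -2.3299,
   -0.8112,
   0.5187,
   2.185,
   -0.4265,
   0.3094,
   0.8792,
   -0.9758,
   -2.4439,
   -1.1573,
   0.4685,
   -0.1576,
   0.6735,
   -0.3171,
   -0.4494,
   2.2174,
   0.205,
   0.3449,
   -2.0086,
   0.5447,
   -0.3856,
   -0.3015,
   1.9169,
   0.7133,
   -1.7668,
   -0.5356,
   -0.3088,
   -1.6117,
   0.9902,
   0.2969,
   -0.0439,
   0.6306,
   0.3209,
   -0.104,
   -1.3005,
   -0.0339,
   -0.0373,
   -0.0479,
   -0.1653,
   -2.1641,
   -0.7255,
   0.3919,
   1.1191,
   1.3627,
   -1.3439
  ],
  "LumB": [
   0.4789,
   1.256,
   0.552,
   -0.6494,
   -1.3211,
   -0.2568,
   -0.9027,
   -1.2091,
   -1.4906,
   -0.2954,
   1.1663,
   0.7546,
   -1.3773,
   -2.0076,
   1.2693,
   -0.3293,
   0.344,
   1.0324,
   -0.8033,
   -0.6891,
   1.3264,
   -0.5416,
   -0.1691,
   0.67,
   1.5577,
   0.695,
   0.4196,
   0.1965,
   1.266,
   -0.7452,
   -1.1753,
   -0.8511,
   0.6286,
   -1.7993,
   1.8166,
   1.9987,
   0.5087,
   0.194,
   1.7985,
   0.2513,
   0.5791,
   -1.0277,
   -0.1514,
   0.5273,
   0.0152,
   -0.6336,
   -0.0002,
   1.1849,
   -1.1164,
   0.0258
  ],
  "Normal": [
   -0.4833,
   -0.6411,
   -0.5767,
   0.0539,
   -1.5534,
   0.8638,
   -0.505,
   -0.0691,
   0.0472,
   -1.1569,
   0.1698,
   -0.1896,
   0.1724,
   0.3208,
   -0.1153,
   1.9384,
   -0.1746,
   -0.0375,
   0.3099,
   1.0677,
   -0.02,
   -1.4808,
   -0.0259,
   0.0142,
   0.156,
   -1.3195,
   0.597,
   -1.4127,
   1.1078,
   1.4299,
   -0.8477,
   -0.3841,
   0.1342,
   -1.3124,
   -1.2629,
   -0.873,
   0.0221,
   -0.7101,
   0.0599,
   -0.1609,
   1.5523,
   -0.0895,
   -0.1701,
   0.2012,
   -0.7872,
   1.6748,
   0.3645,
   -0.3699,
   1.106,
   -0.5519
  ]
 },
 "class_centroid_map": {
  "high risk": "LumB",
  "intermediate risk": "Her2",
  "low risk": "LumA"
 },
 "correlation": "spearman",
 "genes": [
  "PAMSYN001",
  "PAMSYN002",
  "PAMSYN003",
  "PAMSYN004",
  "PAMSYN005",
  "PAMSYN006",
  "PAMSYN007",
  "PAMSYN008",
  "PAMSYN009",
  "PAMSYN010",
  "PAMSYN011",
  "PAMSYN012",
  "PAMSYN013",
  "PAMSYN014",
  "PAMSYN015",
  "PAMSYN016",
  "PAMSYN017",
  "PAMSYN018",
  "PAMSYN019",
  "PAMSYN020",
  "PAMSYN021",
  "PAMSYN022",
  "PAMSYN023",
  "PAMSYN024",
  "PAMSYN025",
  "PAMSYN026",
  "PAMSYN027",
  "PAMSYN028",
  "PAMSYN029",
  "PAMSYN030",
  "PAMSYN031",
  "PAMSYN032",
  "PAMSYN033",
  "PAMSYN034",
  "PAMSYN035",
  "PAMSYN036",
  "PAMSYN037",
  "PAMSYN038",
  "PAMSYN039",
  "PAMSYN040",
  "PAMSYN041",
  "PAMSYN042",
  "PAMSYN043",
  "PAMSYN044",
  "PAMSYN045",
  "PAMSYN046",
  "PAMSYN047",
  "PAMSYN048",
  "PAMSYN049",
  "PAMSYN050"
 ],
 "name": "pam50_ror_s_synthetic",
 "schema_version": 1,
 "thresholds": {
  "intermediate_max": 0.1225,
  "low_max": -0.0958
 },
 "weights": {
  "Basal": 0.05,
  "Her2": 0.12,
  "LumA": -0.34,
  "LumB": 0.23
 }
}
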