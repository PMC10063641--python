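{
 "centroids": {
  "good_prognosis": [
   -0.8657,
   0.4233,
   -0.6363,
   -1.7952,
   0.3939,
   -0.0317,
   -0.7641,
   -1.0877,
   -1.0995,
   -0.7103,
   -1.965,
   -0.8175,
   0.0982,
   -1.221,
   1.0962,
   -0.5987,
   -1.3528,
   -0.09,
   0.5284,
   -0.2151,
   0.6544,
   -0.5218,
   0.8141,
   0.1204,
   0.0374,
   1.3229,
   0.0452,
   -0.3506,
   -0.8638,
   1.0919,
   -0.6022,
   0.8971,
   -0.2464,
   1.3079,
   -0.3334,
   0.9166,
   0.3627,
   -0.1425,
   1.1552,
   -0.0543,
   -1.3509,
   0.6462,
   0.2996,
   -0.6284,
   0.4047,
   0.8511,
   0.9591,
   -1.3491,
   -0.1467,
   1.1895,
   -0.3404,
   -0.6321,
   -0.3663,
   -0.6343,
   -1.4067,
   -0.0798,
   -1.2407,
   0.633,
   0.3129,
   -0.2874,
   -0.0844,
   -0.6914,
   -0.117,
   -1.8844,
   2.1131,
   -0.608,
   -0.5786,
   0.3075,
   1.5879,
   1.1388
  ],
  "poor_prognosis": [
   0.8657,
   -0.4233,
   0.6363,
   1.7952,
   -0.3939,
   0.0317,
   0.7641,
   1.0877,
   1.0995,
   0.7103,
   1.965,
   0.8175,
   -0.0982,
   1.221,
   -1.0962,
   0.5987,
   1.3528,
   0.09,
   -0.5284,
   0.2151,
   -0.6544,
   0.5218,
   -0.8141,
   -0.1204,
   -0.0374,
   -1.3229,
   -0.0452,
   0.3506,
   0.8638,
   -1.0919,
   0.6022,
   -0.8971,
   0.2464,
   -1.3079,
   0.3334,
   -0.9166,
   -0.3627,
   0.1425,
   -1.1552,
   0.0543,
   1.3509,
   -0.6462,
   -0.2996,
   0.6284,
   -0.4047,
   -0.8511,
   -0.9591,
   1.3491,
   0.1467,
   -1.1895,
   0.3404,
   0.6321,
   0.3663,
   0.6343,
   1.4067,
   0.0798,
   1.2407,
   -0.633,
   -0.3129,
   0.2874,
   0.0844,
   0.6914,
   0.117,
   1.8844,
   -2.1131,
   0.608,
   0.5786,
   -0.3075,
   -1.5879,
   -1.1388
  ]
 },
 "class_centroid_map": {
  "high risk": "poor_prognosis",
  "low risk": "good_prognosis"
 },
 "correlation": "cosine",
 "genes": [
  "MPSYN0001",
  "MPSYN0002",
  "MPSYN0003",
  "MPSYN0004",
  "MPSYN0005",
  "MPSYN0006",
  "MPSYN0007",
  "MPSYN0008",
  "MPSYN0009",
  "MPSYN0010",
  "MPSYN0011",
  "MPSYN0012",
  "MPSYN0013",
  "MPSYN0014",
  "MPSYN0015",
  "MPSYN0016",
  "MPSYN0017",
  "MPSYN0018",
  "MPSYN0019",
  "MPSYN0020",
  "MPSYN0021",
  "MPSYN0022",
  "MPSYN0023",
  "MPSYN0024",
  "MPSYN0025",
  "MPSYN0026",
  "MPSYN0027",
  "MPSYN0028",
  "MPSYN0029",
  "MPSYN0030",
  "MPSYN0031",
  "MPSYN0032",
  "MPSYN0033",
  "MPSYN0034",
  "MPSYN0035",
  "MPSYN0036",
  "MPSYN0037",
  "MPSYN0038",
  "MPSYN0039",
  "MPSYN0040",
  "MPSYN0041",
  "MPSYN0042",
  "MPSYN0043",
  "MPSYN0044",
  "MPSYN0045",
  "MPSYN0046",
  "MPSYN0047",
  "MPSYN0048",
  "MPSYN0049",
  "MPSYN0050",
  "MPSYN0051",
  "MPSYN0052",
  "MPSYN0053",
  "MPSYN0054",
  "MPSYN0055",
  "MPSYN0056",
  "MPSYN0057",
  "MPSYN0058",
  "MPSYN0059",
  "MPSYN0060",
  "MPSYN0061",
  "MPSYN0062",
  "MPSYN0063",
  "MPSYN0064",
  "MPSYN0065",
  "MPSYN0066",
  "MPSYN0067",
  "MPSYN0068",
  "MPSYN0069",
  "MPSYN0070"
 ],
 "name": "mammaprint_synthetic",
 "schema_version": 1,
 "thresholds": {
  "low_risk_min": 0.4
 },
 "weights": {}
}
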