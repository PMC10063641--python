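{
 "centroids": {
  "mutant": [
   0.0619,
   -0.0126,
   3.5207,
   -0.9042,
   -0.6774,
   0.6296,
   -0.5637,
   -0.7007,
   1.6211,
   -0.1116,
   -0.5933,
   0.4588,
   -0.3636,
   -0.4159,
   0.0642,
   -0.1827,
   -0.2624,
   1.2814,
   -1.2134,
   -1.0036,
   0.0285,
   0.1278,
   0.6443,
   -0.6456,
   -0.6535,
   0.1178,
   1.3838,
   -0.5325,
   0.1669,
   0.1082,
   0.741,
   -1.0724
  ],
  "wildtype": [
   -1.3173,
   -1.99,
   0.7663,
   0.5685,
   0.5696,
   1.7697,
   0.8322,
   -2.1057,
   -0.0119,
   0.3918,
   -0.2408,
   0.4664,
   0.2391,
   -1.1494,
   -0.3444,
   0.2054,
   0.5972,
   1.3527,
   -0.2013,
   0.4458,
   -1.4402,
   -0.6772,
   1.8007,
   -0.0729,
   -1.5992,
   -0.0968,
   -1.6692,
   -0.5301,
   -0.2473,
   2.1232,
   -1.0289,
   0.6355
  ]
 },
 "class_centroid_map": {
  "mutant": "mutant",
  "wildtype": "wildtype"
 },
 "correlation": "spearman",
 "genes": [
  "P53SYN001",
  "P53SYN002",
  "P53SYN003",
  "P53SYN004",
  "P53SYN005",
  "P53SYN006",
  "P53SYN007",
  "P53SYN008",
  "P53SYN009",
  "P53SYN010",
  "P53SYN011",
  "P53SYN012",
  "P53SYN013",
  "P53SYN014",
  "P53SYN015",
  "P53SYN016",
  "P53SYN017",
  "P53SYN018",
  "P53SYN019",
  "P53SYN020",
  "P53SYN021",
  "P53SYN022",
  "P53SYN023",
  "P53SYN024",
  "P53SYN025",
  "P53SYN026",
  "P53SYN027",
  "P53SYN028",
  "P53SYN029",
  "P53SYN030",
  "P53SYN031",
  "P53SYN032"
 ],
 "name": "p53_synthetic",
 "schema_version": 1,
 "thresholds": {},
 "weights": {}
}
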