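{
 "units": "mm",
 "plane": "coronal_AP+1.2",
 "note": "synthetic approximate NAc-shell outline for simulation/testing; not digitized atlas data",
 "outer": [
  [
   2.1865,
   -7.4
  ],
  [
   2.2008,
   -7.315
  ],
  [
   2.1986,
   -7.2289
  ],
  [
   2.179,
   -7.1443
  ],
  [
   2.1418,
   -7.0636
  ],
  [
   2.0877,
   -6.9894
  ],
  [
   2.0184,
   -6.924
  ],
  [
   1.9365,
   -6.8691
  ],
  [
   1.845,
   -6.826
  ],
  [
   1.7473,
   -6.795
  ],
  [
   1.6471,
   -6.7757
  ],
  [
   1.5475,
   -6.767
  ],
  [
   1.4515,
   -6.7669
  ],
  [
   1.361,
   -6.7732
  ],
  [
   1.2773,
   -6.7833
  ],
  [
   1.2004,
   -6.7944
  ],
  [
   1.1297,
   -6.8044
  ],
  [
   1.0636,
   -6.8111
  ],
  [
   1.0,
   -6.8135
  ],
  [
   0.9364,
   -6.8111
  ],
  [
   0.8703,
   -6.8044
  ],
  [
   0.7996,
   -6.7944
  ],
  [
   0.7227,
   -6.7833
  ],
  [
   0.639,
   -6.7732
  ],
  [
   0.5485,
   -6.7669
  ],
  [
   0.4525,
   -6.767
  ],
  [
   0.3529,
   -6.7757
  ],
  [
   0.2527,
   -6.795
  ],
  [
   0.155,
   -6.826
  ],
  [
   0.0635,
   -6.8691
  ],
  [
   -0.0184,
   -6.924
  ],
  [
   -0.0877,
   -6.9894
  ],
  [
   -0.1418,
   -7.0636
  ],
  [
   -0.179,
   -7.1443
  ],
  [
   -0.1986,
   -7.2289
  ],
  [
   -0.2008,
   -7.315
  ],
  [
   -0.1865,
   -7.4
  ],
  [
   -0.1575,
   -7.482
  ],
  [
   -0.1159,
   -7.5593
  ],
  [
   -0.0642,
   -7.6308
  ],
  [
   -0.005,
   -7.6961
  ],
  [
   0.0594,
   -7.7551
  ],
  [
   0.127,
   -7.808
  ],
  [
   0.1964,
   -7.8555
  ],
  [
   0.2665,
   -7.8983
  ],
  [
   0.3367,
   -7.937
  ],
  [
   0.4069,
   -7.9722
  ],
  [
   0.4774,
   -8.0042
  ],
  [
   0.5485,
   -8.0331
  ],
  [
   0.6206,
   -8.0587
  ],
  [
   0.694,
   -8.0806
  ],
  [
   0.7688,
   -8.0984
  ],
  [
   0.845,
   -8.1116
  ],
  [
   0.9222,
   -8.1198
  ],
  [
   1.0,
   -8.1225
  ],
  [
   1.0778,
   -8.1198
  ],
  [
   1.155,
   -8.1116
  ],
  [
   1.2312,
   -8.0984
  ],
  [
   1.306,
   -8.0806
  ],
  [
   1.3794,
   -8.0587
  ],
  [
   1.4515,
   -8.0331
  ],
  [
   1.5226,
   -8.0042
  ],
  [
   1.5931,
   -7.9722
  ],
  [
   1.6633,
   -7.937
  ],
  [
   1.7335,
   -7.8983
  ],
  [
   1.8036,
   -7.8555
  ],
  [
   1.873,
   -7.808
  ],
  [
   1.9406,
   -7.7551
  ],
  [
   2.005,
   -7.6961
  ],
  [
   2.0642,
   -7.6308
  ],
  [
   2.1159,
   -7.5593
  ],
  [
   2.1575,
   -7.482
  ]
 ],
 "electrode": [
  [
   0.925,
   -7.6
  ],
  [
   0.9207,
   -7.5676
  ],
  [
   0.9083,
   -7.5375
  ],
  [
   0.8884,
   -7.5116
  ],
  [
   0.8625,
   -7.4917
  ],
  [
   0.8324,
   -7.4793
  ],
  [
   0.8,
   -7.475
  ],
  [
   0.7676,
   -7.4793
  ],
  [
   0.7375,
   -7.4917
  ],
  [
   0.7116,
   -7.5116
  ],
  [
   0.6917,
   -7.5375
  ],
  [
   0.6793,
   -7.5676
  ],
  [
   0.675,
   -7.6
  ],
  [
   0.6793,
   -7.6324
  ],
  [
   0.6917,
   -7.6625
  ],
  [
   0.7116,
   -7.6884
  ],
  [
   0.7375,
   -7.7083
  ],
  [
   0.7676,
   -7.7207
  ],
  [
   0.8,
   -7.725
  ],
  [
   0.8324,
   -7.7207
  ],
  [
   0.8625,
   -7.7083
  ],
  [
   0.8884,
   -7.6884
  ],
  [
   0.9083,
   -7.6625
  ],
  [
   0.9207,
   -7.6324
  ]
 ]
}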