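{
 "transcript": "synthetic-ABCA4-like (6822 nt CDS, 50 exons; coordinates are synthetic, not the reference transcript)",
 "exons": [
  {
   "index": 1,
   "cdna_start": 1,
   "cdna_end": 136
  },
  {
   "index": 2,
   "cdna_start": 137,
   "cdna_end": 272
  },
  {
   "index": 3,
   "cdna_start": 273,
   "cdna_end": 408
  },
  {
   "index": 4,
   "cdna_start": 409,
   "cdna_end": 544
  },
  {
   "index": 5,
   "cdna_start": 545,
   "cdna_end": 680
  },
  {
   "index": 6,
   "cdna_start": 681,
   "cdna_end": 816
  },
  {
   "index": 7,
   "cdna_start": 817,
   "cdna_end": 952
  },
  {
   "index": 8,
   "cdna_start": 953,
   "cdna_end": 1088
  },
  {
   "index": 9,
   "cdna_start": 1089,
   "cdna_end": 1224
  },
  {
   "index": 10,
   "cdna_start": 1225,
   "cdna_end": 1360
  },
  {
   "index": 11,
   "cdna_start": 1361,
   "cdna_end": 1496
  },
  {
   "index": 12,
   "cdna_start": 1497,
   "cdna_end": 1632
  },
  {
   "index": 13,
   "cdna_start": 1633,
   "cdna_end": 1768
  },
  {
   "index": 14,
   "cdna_start": 1769,
   "cdna_end": 1904
  },
  {
   "index": 15,
   "cdna_start": 1905,
   "cdna_end": 2040
  },
  {
   "index": 16,
   "cdna_start": 2041,
   "cdna_end": 2176
  },
  {
   "index": 17,
   "cdna_start": 2177,
   "cdna_end": 2312
  },
  {
   "index": 18,
   "cdna_start": 2313,
   "cdna_end": 2448
  },
  {
   "index": 19,
   "cdna_start": 2449,
   "cdna_end": 2584
  },
  {
   "index": 20,
   "cdna_start": 2585,
   "cdna_end": 2720
  },
  {
   "index": 21,
   "cdna_start": 2721,
   "cdna_end": 2856
  },
  {
   "index": 22,
   "cdna_start": 2857,
   "cdna_end": 2992
  },
  {
   "index": 23,
   "cdna_start": 2993,
   "cdna_end": 3128
  },
  {
   "index": 24,
   "cdna_start": 3129,
   "cdna_end": 3264
  },
  {
   "index": 25,
   "cdna_start": 3265,
   "cdna_end": 3400
  },
  {
   "index": 26,
   "cdna_start": 3401,
   "cdna_end": 3536
  },
  {
   "index": 27,
   "cdna_start": 3537,
   "cdna_end": 3672
  },
  {
   "index": 28,
   "cdna_start": 3673,
   "cdna_end": 3808
  },
  {
   "index": 29,
   "cdna_start": 3809,
   "cdna_end": 3944
  },
  {
   "index": 30,
   "cdna_start": 3945,
   "cdna_end": 4080
  },
  {
   "index": 31,
   "cdna_start": 4081,
   "cdna_end": 4216
  },
  {
   "index": 32,
   "cdna_start": 4217,
   "cdna_end": 4352
  },
  {
   "index": 33,
   "cdna_start": 4353,
   "cdna_end": 4488
  },
  {
   "index": 34,
   "cdna_start": 4489,
   "cdna_end": 4624
  },
  {
   "index": 35,
   "cdna_start": 4625,
   "cdna_end": 4760
  },
  {
   "index": 36,
   "cdna_start": 4761,
   "cdna_end": 4896
  },
  {
   "index": 37,
   "cdna_start": 4897,
   "cdna_end": 5032
  },
  {
   "index": 38,
   "cdna_start": 5033,
   "cdna_end": 5168
  },
  {
   "index": 39,
   "cdna_start": 5169,
   "cdna_end": 5304
  },
  {
   "index": 40,
   "cdna_start": 5305,
   "cdna_end": 5440
  },
  {
   "index": 41,
   "cdna_start": 5441,
   "cdna_end": 5576
  },
  {
   "index": 42,
   "cdna_start": 5577,
   "cdna_end": 5712
  },
  {
   "index": 43,
   "cdna_start": 5713,
   "cdna_end": 5848
  },
  {
   "index": 44,
   "cdna_start": 5849,
   "cdna_end": 5984
  },
  {
   "index": 45,
   "cdna_start": 5985,
   "cdna_end": 6120
  },
  {
   "index": 46,
   "cdna_start": 6121,
   "cdna_end": 6256
  },
  {
   "index": 47,
   "cdna_start": 6257,
   "cdna_end": 6392
  },
  {
   "index": 48,
   "cdna_start": 6393,
   "cdna_end": 6528
  },
  {
   "index": 49,
   "cdna_start": 6529,
   "cdna_end": 6664
  },
  {
   "index": 50,
   "cdna_start": 6665,
   "cdna_end": 6822
  }
 ],
 "domains": [
  {
   "name": "TMD1",
   "aa_start": 1,
   "aa_end": 650
  },
  {
   "name": "NBD1",
   "aa_start": 651,
   "aa_end": 1100
  },
  {
   "name": "ECD1",
   "aa_start": 1101,
   "aa_end": 1350
  },
  {
   "name": "TMD2",
   "aa_start": 1351,
   "aa_end": 1900
  },
  {
   "name": "NBD2",
   "aa_start": 1901,
   "aa_end": 2150
  },
  {
   "name": "ECD2",
   "aa_start": 2151,
   "aa_end": 2273
  }
 ]
}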