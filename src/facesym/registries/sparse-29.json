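{
 "name": "sparse-29",
 "n_landmarks": 68,
 "midline_indices": [
  8,
  27,
  28,
  29,
  30,
  33
 ],
 "pairs": [
  {
   "left": 17,
   "right": 26,
   "region": "eye"
  },
  {
   "left": 18,
   "right": 25,
   "region": "eye"
  },
  {
   "left": 19,
   "right": 24,
   "region": "eye"
  },
  {
   "left": 20,
   "right": 23,
   "region": "eye"
  },
  {
   "left": 21,
   "right": 22,
   "region": "eye"
  },
  {
   "left": 36,
   "right": 45,
   "region": "eye"
  },
  {
   "left": 37,
   "right": 44,
   "region": "eye"
  },
  {
   "left": 38,
   "right": 43,
   "region": "eye"
  },
  {
   "left": 39,
   "right": 42,
   "region": "eye"
  },
  {
   "left": 41,
   "right": 46,
   "region": "eye"
  },
  {
   "left": 40,
   "right": 47,
   "region": "eye"
  },
  {
   "left": 31,
   "right": 35,
   "region": "nose"
  },
  {
   "left": 32,
   "right": 34,
   "region": "nose"
  },
  {
   "left": 48,
   "right": 54,
   "region": "mouth"
  },
  {
   "left": 49,
   "right": 53,
   "region": "mouth"
  },
  {
   "left": 50,
   "right": 52,
   "region": "mouth"
  },
  {
   "left": 59,
   "right": 55,
   "region": "mouth"
  },
  {
   "left": 58,
   "right": 56,
   "region": "mouth"
  },
  {
   "left": 60,
   "right": 64,
   "region": "mouth"
  },
  {
   "left": 61,
   "right": 63,
   "region": "mouth"
  },
  {
   "left": 67,
   "right": 65,
   "region": "mouth"
  },
  {
   "left": 0,
   "right": 16,
   "region": "other"
  },
  {
   "left": 1,
   "right": 15,
   "region": "other"
  },
  {
   "left": 2,
   "right": 14,
   "region": "other"
  },
  {
   "left": 3,
   "right": 13,
   "region": "other"
  },
  {
   "left": 4,
   "right": 12,
   "region": "other"
  },
  {
   "left": 5,
   "right": 11,
   "region": "other"
  },
  {
   "left": 6,
   "right": 10,
   "region": "other"
  },
  {
   "left": 7,
   "right": 9,
   "region": "other"
  }
 ],
 "subsets": {
  "21": [
   0,
   1,
   2,
   3,
   4,
   5,
   6,
   7,
   8,
   9,
   10,
   11,
   12,
   13,
   14,
   15,
   16,
   17,
   18,
   19,
   20
  ]
 }
}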