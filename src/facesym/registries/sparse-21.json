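{
 "name": "sparse-21",
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
  }
 ],
 "subsets": {}
}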