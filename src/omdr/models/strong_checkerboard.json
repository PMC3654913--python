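{
 "classes": 3,
 "prevalences": [
  0.3,
  0.4,
  0.3
 ],
 "mafs": [
  0.5,
  0.5
 ],
 "pattern_id": "checkerboard-strong",
 "genotype_rows": [
  {
   "genotype": [
    0,
    0
   ],
   "or": [
    1.0,
    2.0,
    6.0
   ]
  },
  {
   "genotype": [
    0,
    1
   ],
   "or": [
    1.0,
    0.6,
    0.2
   ]
  },
  {
   "genotype": [
    0,
    2
   ],
   "or": [
    1.0,
    2.0,
    6.0
   ]
  },
  {
   "genotype": [
    1,
    0
   ],
   "or": [
    1.0,
    0.6,
    0.2
   ]
  },
  {
   "genotype": [
    1,
    1
   ],
   "or": [
    1.0,
    2.0,
    6.0
   ]
  },
  {
   "genotype": [
    1,
    2
   ],
   "or": [
    1.0,
    0.6,
    0.2
   ]
  },
  {
   "genotype": [
    2,
    0
   ],
   "or": [
    1.0,
    2.0,
    6.0
   ]
  },
  {
   "genotype": [
    2,
    1
   ],
   "or": [
    1.0,
    0.6,
    0.2
   ]
  },
  {
   "genotype": [
    2,
    2
   ],
   "or": [
    1.0,
    2.0,
    6.0
   ]
  }
 ]
}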