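{
 "categories": [
  {
   "id": "i",
   "label": "dishwashing detergents",
   "samples": [
    1,
    2,
    3,
    4,
    5,
    6
   ]
  },
  {
   "id": "ii",
   "label": "antifreeze and dish-rinsing agents",
   "samples": [
    7,
    8,
    9,
    10
   ]
  },
  {
   "id": "iii",
   "label": "mouthwash products",
   "samples": [
    11,
    12,
    13,
    14,
    15,
    16
   ]
  },
  {
   "id": "iv",
   "label": "kitchen and bathroom sanitary cleaning products",
   "samples": [
    17,
    18,
    19,
    20,
    21,
    22,
    23
   ]
  },
  {
   "id": "v",
   "label": "shampoos",
   "samples": [
    24,
    25,
    26,
    27,
    28,
    29
   ]
  },
  {
   "id": "vi",
   "label": "shower gels and liquid soap products",
   "samples": [
    30,
    31,
    32,
    33,
    34,
    35,
    36
   ]
  }
 ]
}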