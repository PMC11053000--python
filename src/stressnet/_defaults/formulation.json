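{
 "name": "daily_plus",
 "combination_rule": "multiplicative",
 "ingredients": [
  {
   "name": "gotukola",
   "class": "botanical",
   "targets": [
    [
     "nfkb",
     "down",
     0.12192911726643246
    ],
    [
     "nrf2",
     "up",
     0.1
    ],
    [
     "keap1",
     "down",
     0.019292894163896256
    ],
    [
     "pakt",
     "down",
     0.27
    ],
    [
     "ampk",
     "up",
     0.1
    ]
   ]
  },
  {
   "name": "acerola",
   "class": "botanical",
   "targets": [
    [
     "ros",
     "down",
     0.1327714035072383
    ],
    [
     "crh",
     "down",
     0.11253590016789888
    ],
    [
     "tnfa",
     "down",
     0.1
    ],
    [
     "pakt",
     "down",
     0.27
    ],
    [
     "ampk",
     "up",
     0.1
    ]
   ]
  },
  {
   "name": "elderberry",
   "class": "botanical",
   "targets": [
    [
     "ros",
     "down",
     0.1169609466698571
    ],
    [
     "keap1",
     "down",
     0.02658203333405843
    ],
    [
     "nfkb",
     "down",
     0.22858291631874175
    ]
   ]
  },
  {
   "name": "purple_carrot",
   "class": "botanical",
   "targets": [
    [
     "tnfa",
     "down",
     0.4571658326374835
    ],
    [
     "nfkb",
     "down",
     0.1828663330549934
    ]
   ]
  },
  {
   "name": "vitamin_a",
   "class": "vitamin",
   "targets": [
    [
     "nfkb",
     "down",
     0.22306733684722682
    ],
    [
     "tnfa",
     "down",
     0.11153366842361341
    ]
   ]
  },
  {
   "name": "vitamin_c",
   "class": "vitamin",
   "targets": [
    [
     "ros",
     "down",
     0.06954692569894311
    ],
    [
     "il6",
     "down",
     0.11429145815937088
    ]
   ]
  },
  {
   "name": "vitamin_d",
   "class": "vitamin",
   "targets": [
    [
     "nfkb",
     "down",
     0.1828663330549934
    ],
    [
     "tnfa",
     "down",
     0.1828663330549934
    ],
    [
     "il6",
     "down",
     0.13714974979124503
    ]
   ]
  },
  {
   "name": "vitamin_e",
   "class": "vitamin",
   "targets": [
    [
     "ros",
     "down",
     0.021265626667246743
    ],
    [
     "nfkb",
     "down",
     0.1828663330549934
    ],
    [
     "tnfa",
     "down",
     0.1828663330549934
    ]
   ]
  },
  {
   "name": "vitamin_k",
   "class": "vitamin",
   "targets": [
    [
     "nfkb",
     "down",
     0.1828663330549934
    ],
    [
     "tnfa",
     "down",
     0.1828663330549934
    ],
    [
     "il6",
     "down",
     0.13714974979124503
    ]
   ]
  },
  {
   "name": "zinc",
   "class": "mineral",
   "targets": [
    [
     "ros",
     "down",
     0.06954692569894311
    ],
    [
     "nfkb",
     "down",
     0.05
    ],
    [
     "pakt",
     "down",
     0.15
    ]
   ]
  },
  {
   "name": "vitamin_b1",
   "class": "vitamin",
   "targets": [
    [
     "cortisol",
     "down",
     0.006865384620818187
    ],
    [
     "sod",
     "up",
     0.01594922000043506
    ],
    [
     "nfkb",
     "down",
     0.04571658326374835
    ]
   ]
  },
  {
   "name": "vitamin_b2",
   "class": "vitamin",
   "targets": [
    [
     "cortisol",
     "down",
     0.006865384620818187
    ],
    [
     "sod",
     "up",
     0.01594922000043506
    ],
    [
     "nfkb",
     "down",
     0.04571658326374835
    ]
   ]
  },
  {
   "name": "vitamin_b3",
   "class": "vitamin",
   "targets": [
    [
     "cortisol",
     "down",
     0.006865384620818187
    ],
    [
     "sod",
     "up",
     0.01594922000043506
    ],
    [
     "nfkb",
     "down",
     0.04571658326374835
    ]
   ]
  },
  {
   "name": "vitamin_b5",
   "class": "vitamin",
   "targets": [
    [
     "cortisol",
     "down",
     0.006865384620818187
    ],
    [
     "sod",
     "up",
     0.01594922000043506
    ],
    [
     "nfkb",
     "down",
     0.04571658326374835
    ]
   ]
  },
  {
   "name": "vitamin_b6",
   "class": "vitamin",
   "targets": [
    [
     "cortisol",
     "down",
     0.006865384620818187
    ],
    [
     "sod",
     "up",
     0.01594922000043506
    ],
    [
     "nfkb",
     "down",
     0.04571658326374835
    ],
    [
     "pakt",
     "down",
     0.2
    ]
   ]
  },
  {
   "name": "vitamin_b7",
   "class": "vitamin",
   "targets": [
    [
     "cortisol",
     "down",
     0.006865384620818187
    ],
    [
     "sod",
     "up",
     0.01594922000043506
    ],
    [
     "nfkb",
     "down",
     0.04571658326374835
    ]
   ]
  },
  {
   "name": "vitamin_b9",
   "class": "vitamin",
   "targets": [
    [
     "cortisol",
     "down",
     0.006865384620818187
    ],
    [
     "sod",
     "up",
     0.01594922000043506
    ],
    [
     "nfkb",
     "down",
     0.04571658326374835
    ]
   ]
  },
  {
   "name": "vitamin_b12",
   "class": "vitamin",
   "targets": [
    [
     "cortisol",
     "down",
     0.006865384620818187
    ],
    [
     "sod",
     "up",
     0.01594922000043506
    ],
    [
     "nfkb",
     "down",
     0.04571658326374835
    ],
    [
     "pakt",
     "down",
     0.2
    ]
   ]
  },
  {
   "name": "magnesium",
   "class": "mineral",
   "targets": [
    [
     "acth",
     "down",
     0.013730769241636374
    ],
    [
     "il6",
     "down",
     0.11429145815937088
    ],
    [
     "cortisol",
     "down",
     0.006865384620818187
    ],
    [
     "pakt",
     "down",
     0.2
    ]
   ]
  },
  {
   "name": "copper",
   "class": "mineral",
   "targets": [
    [
     "cortisol",
     "down",
     0.008238461544981824
    ]
   ]
  },
  {
   "name": "molybdenum",
   "class": "mineral",
   "targets": [
    [
     "cortisol",
     "down",
     0.006865384620818187
    ]
   ]
  },
  {
   "name": "iodine",
   "class": "mineral",
   "targets": [
    [
     "gpx",
     "up",
     0.03189844000087012
    ],
    [
     "sod",
     "up",
     0.023923830000652586
    ],
    [
     "cat",
     "up",
     0.021265626667246743
    ],
    [
     "il6",
     "down",
     0.0914331665274967
    ]
   ]
  },
  {
   "name": "selenium",
   "class": "mineral",
   "targets": [
    [
     "gpx",
     "up",
     0.03189844000087012
    ],
    [
     "ros",
     "down",
     0.018607423333840904
    ]
   ]
  },
  {
   "name": "manganese",
   "class": "mineral",
   "targets": [
    [
     "sod",
     "up",
     0.03189844000087012
    ]
   ]
  },
  {
   "name": "chromium",
   "class": "mineral",
   "targets": [
    [
     "ros",
     "down",
     0.01594922000043506
    ],
    [
     "pakt",
     "down",
     0.25
    ]
   ]
  },
  {
   "name": "iron",
   "class": "mineral",
   "targets": [
    [
     "ros",
     "down",
     0.010632813333623372
    ]
   ]
  },
  {
   "name": "calcium",
   "class": "mineral",
   "targets": [
    [
     "il6",
     "down",
     0.06857487489562251
    ]
   ]
  },
  {
   "name": "phosphorus",
   "class": "mineral",
   "targets": [
    [
     "ros",
     "down",
     0.00797461000021753
    ]
   ]
  }
 ]
}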