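{
 "nfkb": 1.0,
 "tnfa": 0.0001,
 "il6": 1.0,
 "il10": 1.0,
 "lps": 1.0,
 "stat3": 1.0,
 "jak1": 1.0,
 "mapk": 1.0,
 "nrf2": 1.0,
 "keap1": 1.0,
 "ros": 1.0,
 "sod": 1.0,
 "cat": 1.0,
 "gpx": 1.0,
 "gsh": 1.0,
 "mda": 1.0,
 "irs": 0.8,
 "pirs": 0.2,
 "akt": 0.8,
 "pakt": 0.2,
 "pi3k": 1.0,
 "mtor": 1.0,
 "ampk": 1.0,
 "foxo1_cyt": 1.0,
 "hif1a": 1.0,
 "crh": 1.0,
 "acth": 1.0,
 "cortisol": 10.0,
 "renin": 1.0,
 "ang2": 1.0,
 "aldosterone": 1.0,
 "insulin": 1.0,
 "glucagon": 1.0,
 "glucose": 5.0
}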