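{
 "edges": {
  "acth->cortisol": {
   "K": 15.487887178145021,
   "n": 2.0,
   "sign": "activate",
   "w": 1011.6735268203852
  },
  "ampk->mtor": {
   "K": 2.0,
   "n": 1.0,
   "sign": "inhibit",
   "w": 0.0
  },
  "ang2->aldosterone": {
   "K": 10.0,
   "n": 1.0,
   "sign": "activate",
   "w": 8.8
  },
  "cortisol->renin": {
   "K": 40.0,
   "n": 2.0,
   "sign": "activate",
   "w": 3.74
  },
  "crh->acth": {
   "K": 25.44235361305316,
   "n": 1.0,
   "sign": "activate",
   "w": 23.798118251747844
  },
  "foxo1_cyt->lps": {
   "K": 5.946199832572786,
   "n": 1.0,
   "sign": "activate",
   "w": 5.55695986605823
  },
  "gsh->ros": {
   "K": 1.0,
   "n": 1.0,
   "sign": "inhibit",
   "w": 0.0
  },
  "hif1a->crh": {
   "K": 4.531567904183546,
   "n": 2.1045246245278952,
   "sign": "activate",
   "w": 16.28163724963617
  },
  "il10->nfkb": {
   "K": 3.0,
   "n": 1.0,
   "sign": "inhibit",
   "w": 0.0
  },
  "il6->crh": {
   "K": 155.8195560003795,
   "n": 1.0,
   "sign": "activate",
   "w": 39.20488900009487
  },
  "il6->jak1": {
   "K": 40.0,
   "n": 1.0,
   "sign": "activate",
   "w": 32.8
  },
  "insulin->pi3k": {
   "K": 1.0,
   "n": 1.0,
   "sign": "activate",
   "w": 1.0
  },
  "jak1->stat3": {
   "K": 20.0,
   "n": 1.0,
   "sign": "activate",
   "w": 16.8
  },
  "keap1->nrf2": {
   "K": 1.0,
   "n": 2.0,
   "sign": "inhibit",
   "w": 0.0
  },
  "lps->nfkb": {
   "K": 2.0,
   "n": 4.0,
   "sign": "activate",
   "w": 19.266666666666666
  },
  "mapk->il6": {
   "K": 50.0,
   "n": 1.0,
   "sign": "activate",
   "w": 5.1000000000000005
  },
  "nfkb->il6": {
   "K": 100.0,
   "n": 1.0,
   "sign": "activate",
   "w": 70.69999999999999
  },
  "nfkb->mapk": {
   "K": 50.0,
   "n": 1.0,
   "sign": "activate",
   "w": 30.599999999999998
  },
  "nfkb->tnfa": {
   "K": 100.0,
   "n": 1.0,
   "sign": "activate",
   "w": 0.00808
  },
  "nrf2->cat": {
   "K": 1.0,
   "n": 1.0,
   "sign": "activate",
   "w": 1.2
  },
  "nrf2->gpx": {
   "K": 1.0,
   "n": 1.0,
   "sign": "activate",
   "w": 1.2
  },
  "nrf2->gsh": {
   "K": 1.0,
   "n": 1.0,
   "sign": "activate",
   "w": 1.0
  },
  "nrf2->sod": {
   "K": 1.0,
   "n": 2.0,
   "sign": "activate",
   "w": 1.4
  },
  "pakt->foxo1_cyt": {
   "K": 1.0,
   "n": 2.0,
   "sign": "activate",
   "w": 20.799999999999997
  },
  "pakt->mtor": {
   "K": 1.0,
   "n": 1.0,
   "sign": "activate",
   "w": 4.499999999999999
  },
  "renin->ang2": {
   "K": 20.0,
   "n": 1.0,
   "sign": "activate",
   "w": 16.8
  },
  "ros->hif1a": {
   "K": 5.0,
   "n": 1.0,
   "sign": "activate",
   "w": 4.8
  },
  "ros->mda": {
   "K": 5.0,
   "n": 1.0,
   "sign": "activate",
   "w": 4.8
  },
  "sod->ros": {
   "K": 0.5,
   "n": 2.0,
   "sign": "inhibit",
   "w": 0.0
  },
  "stat3->il10": {
   "K": 20.0,
   "n": 1.0,
   "sign": "activate",
   "w": 12.6
  },
  "tnfa->renin": {
   "K": 0.0019529645071828527,
   "n": 3.0,
   "sign": "activate",
   "w": 7.449744053312975
  }
 },
 "pools": {
  "akt": {
   "K": 1.0,
   "driver": "pi3k",
   "kdeph": 1.0,
   "kph": 0.5,
   "n": 1.0,
   "total": 1.0
  },
  "irs": {
   "K": 1.0,
   "driver": "insulin",
   "kdeph": 1.0,
   "kph": 0.5,
   "n": 1.0,
   "total": 1.0
  }
 },
 "species": {
  "acth": {
   "basal": 0.09999999999999998,
   "deg": 1.0
  },
  "aldosterone": {
   "basal": 0.19999999999999996,
   "deg": 1.0
  },
  "ampk": {
   "basal": 1.0,
   "deg": 1.0
  },
  "ang2": {
   "basal": 0.19999999999999996,
   "deg": 1.0
  },
  "cat": {
   "basal": 0.4,
   "deg": 1.0
  },
  "cortisol": {
   "basal": 5.800000000000001,
   "deg": 1.0
  },
  "crh": {
   "basal": 0.09999999999999998,
   "deg": 1.0
  },
  "foxo1_cyt": {
   "basal": 0.19999999999999996,
   "deg": 1.0
  },
  "glucagon": {
   "basal": 1.0,
   "deg": 1.0
  },
  "glucose": {
   "basal": 5.0,
   "deg": 1.0
  },
  "gpx": {
   "basal": 0.4,
   "deg": 1.0
  },
  "gsh": {
   "basal": 0.5,
   "deg": 1.0
  },
  "hif1a": {
   "basal": 0.19999999999999996,
   "deg": 1.0
  },
  "il10": {
   "basal": 0.4,
   "deg": 1.0
  },
  "il6": {
   "basal": 0.20000000000000007,
   "deg": 1.0
  },
  "insulin": {
   "basal": 1.0,
   "deg": 1.0
  },
  "jak1": {
   "basal": 0.19999999999999996,
   "deg": 1.0
  },
  "keap1": {
   "basal": 1.0,
   "deg": 1.0
  },
  "lps": {
   "basal": 0.19999999999999996,
   "deg": 1.0
  },
  "mapk": {
   "basal": 0.4,
   "deg": 1.0
  },
  "mda": {
   "basal": 0.19999999999999996,
   "deg": 1.0
  },
  "mtor": {
   "basal": 0.75,
   "deg": 1.0
  },
  "nfkb": {
   "basal": 0.2,
   "deg": 1.0
  },
  "nrf2": {
   "basal": 2.0,
   "deg": 1.0
  },
  "pi3k": {
   "basal": 0.5,
   "deg": 1.0
  },
  "renin": {
   "basal": 0.779,
   "deg": 1.0
  },
  "ros": {
   "basal": 10.0,
   "deg": 1.0
  },
  "sod": {
   "basal": 0.30000000000000004,
   "deg": 1.0
  },
  "stat3": {
   "basal": 0.19999999999999996,
   "deg": 1.0
  },
  "tnfa": {
   "basal": 1.9999999999999995e-05,
   "deg": 1.0
  }
 },
 "stress_gains": {
  "alpha_inf": 3.7445651285830017,
  "beta_keap1": 0.3981168915070826,
  "beta_ros": 0.18181074613346035,
  "beta_sod": 1.3720670049820585,
  "gamma_akt": 7.3594517309289555,
  "gamma_irs": 7.3594517309289555
 }
}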