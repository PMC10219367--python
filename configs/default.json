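{
 "seed": 0,
 "profiles": [
  {
   "name": "grade1-2",
   "n": 43,
   "means": {
    "k_true": 2.0,
    "g_old": 0.3,
    "b_wm": 0.45,
    "d_novel": 0.8,
    "tau_ltm": 0.45,
    "b_ltm": 0.55,
    "g_old_ltm": 0.13,
    "beta_same": 0.7
   },
   "sds": {
    "k_true": 0.55,
    "g_old": 0.08,
    "beta_same": 0.06,
    "b_wm": 0.08,
    "d_novel": 0.05,
    "tau_ltm": 0.1,
    "b_ltm": 0.08,
    "g_old_ltm": 0.08
   }
  },
  {
   "name": "grade5-7",
   "n": 39,
   "means": {
    "k_true": 3.0,
    "g_old": 0.33,
    "b_wm": 0.65,
    "d_novel": 0.85,
    "tau_ltm": 0.55,
    "b_ltm": 0.55,
    "g_old_ltm": 0.29,
    "beta_same": 0.7
   },
   "sds": {
    "k_true": 0.5,
    "g_old": 0.08,
    "beta_same": 0.06,
    "b_wm": 0.08,
    "d_novel": 0.05,
    "tau_ltm": 0.1,
    "b_ltm": 0.08,
    "g_old_ltm": 0.08
   }
  },
  {
   "name": "adult",
   "n": 42,
   "means": {
    "k_true": 3.6,
    "g_old": 0.35,
    "b_wm": 0.75,
    "d_novel": 0.9,
    "tau_ltm": 0.55,
    "b_ltm": 0.55,
    "g_old_ltm": 0.32,
    "beta_same": 0.7
   },
   "sds": {
    "k_true": 0.45,
    "g_old": 0.08,
    "beta_same": 0.06,
    "b_wm": 0.08,
    "d_novel": 0.05,
    "tau_ltm": 0.1,
    "b_ltm": 0.08,
    "g_old_ltm": 0.08
   }
  }
 ],
 "pool_wm_lures": false,
 "binding_include_all": false,
 "adjust_mode": "k_floor",
 "prior_width": 1.0
}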