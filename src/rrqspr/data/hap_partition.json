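{
 "labeling": "reduced_reverse",
 "classes": [
  {"a": 5, "b": 4, "slope": 1, "intercept": 1},
  {"a": 5, "b": 3, "slope": 16, "intercept": 0},
  {"a": 5, "b": 2, "slope": 4, "intercept": 0},
  {"a": 4, "b": 4, "slope": 13, "intercept": 1},
  {"a": 4, "b": 3, "slope": 32, "intercept": -1},
  {"a": 4, "b": 2, "slope": 3, "intercept": 0},
  {"a": 3, "b": 3, "slope": 19, "intercept": -1},
  {"a": 3, "b": 2, "slope": 7, "intercept": 0},
  {"a": 2, "b": 2, "slope": 1, "intercept": 0}
 ]
}
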