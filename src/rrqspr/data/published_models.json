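{
 "chi2_critical": 37.652,
 "linear": {
  "BP":   {"index": "RRR_-1",   "alpha1": 129,      "gamma": -75.26},
  "LogP": {"index": "RRR_-1",   "alpha1": 1.228,    "gamma": 0.296},
  "CT":   {"index": "RRGA",     "alpha1": 16.62,    "gamma": 291.4},
  "GE":   {"index": "RRHM1",    "alpha1": 0.9654,   "gamma": 26.46},
  "PI":   {"index": "RRABC",    "alpha1": 1.63,     "gamma": 1.197},
  "HL":   {"index": "RRF",      "alpha1": 0.01448,  "gamma": -0.03858},
  "CP":   {"index": "RRR_-1",   "alpha1": -6.6085,  "gamma": 54.162},
  "CV":   {"index": "RRR_-1/2", "alpha1": 73.21,    "gamma": 46.92},
  "EM":   {"index": "RRR_-1/2", "alpha1": 25.23,    "gamma": 3.109},
  "HAC":  {"index": "RRR_-1/2", "alpha1": 2.024,    "gamma": -0.022},
  "MR":   {"index": "RRR_-1/2", "alpha1": 8.699,    "gamma": -0.6273},
  "MW":   {"index": "RRR_-1/2", "alpha1": 25.25,    "gamma": 3.143}
 },
 "quadratic": {
  "BP":   {"index": "RRR_-1",   "alpha1": -10.47,    "alpha2": 202.4,   "gamma": -192.6},
  "LogP": {"index": "RRR_-1",   "alpha1": -0.0407,   "alpha2": 1.513,   "gamma": -0.1598},
  "CT":   {"index": "RRGA",     "alpha1": -0.3939,   "alpha2": 31.57,   "gamma": -166.2},
  "GE":   {"index": "RRHM1",    "alpha1": 0.000047,  "alpha2": 0.9208,  "gamma": 35.4},
  "PI":   {"index": "RRABC",    "alpha1": -0.004891, "alpha2": 1.761,   "gamma": 0.4245},
  "HL":   {"index": "RRF",      "alpha1": 8.815e-08, "alpha2": 0.01444, "gamma": -0.03427},
  "CP":   {"index": "RRR_-1/2", "alpha1": 0.1774,    "alpha2": -5.46,   "gamma": 62.12},
  "CV":   {"index": "RRR_-1/2", "alpha1": -0.2004,   "alpha2": 76.46,   "gamma": 35.08},
  "EM":   {"index": "RRR_-1/2", "alpha1": -0.05377,  "alpha2": 26.1,    "gamma": -0.06767},
  "HAC":  {"index": "RRR_-1/2", "alpha1": -0.003732, "alpha2": 2.084,   "gamma": -0.2424},
  "MR":   {"index": "RRR_-1/2", "alpha1": -0.0148,   "alpha2": 8.939,   "gamma": -1.503},
  "MW":   {"index": "RRR_-1/2", "alpha1": -0.0085,   "alpha2": 3.042,   "gamma": -1.157}
 }
}
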