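{
 "T0": 0.0,
 "V0": 50.0,
 "W0": 100.0,
 "alphas": [
  0.5,
  0.7,
  0.9
 ],
 "base": {
  "I_baseline": 90.0,
  "K": 10000.0,
  "alpha": 0.7,
  "beta1": 0.01,
  "beta2": 0.01,
  "beta3": 0.04,
  "delta": 0.001,
  "gamma": 0.07,
  "lam": 0.3,
  "mu": 0.01,
  "phi1": 0.03,
  "phi2": 0.04,
  "phi3": 0.01
 },
 "control_phis": [
  0.9,
  0.458,
  0.8,
  0.45,
  0.5,
  0.6,
  0.5,
  0.6,
  0.9,
  0.5
 ],
 "eta": 0.7,
 "h": 0.015625,
 "initial_state": [
  3000.0,
  90.0,
  20.0
 ],
 "k_initial": [
  100.0,
  0.0,
  100.0,
  0.0,
  10.0,
  0.0
 ],
 "kparams": {
  "alpha": 0.8,
  "k1": 0.35,
  "k10": 0.1,
  "k11": 1.0,
  "k12": 0.1,
  "k13": 0.1,
  "k14": 0.1,
  "k2": 0.2,
  "k3": 0.1,
  "k4": 0.1,
  "k5": 0.2,
  "k6": 0.1,
  "k7": 0.1,
  "k8": 0.05,
  "k9": 0.1
 },
 "name": "paper2023",
 "t0": 0.0,
 "t_final": 400.0,
 "therapy": {
  "base": {
   "I_baseline": 90.0,
   "K": 10000.0,
   "alpha": 0.7,
   "beta1": 0.01,
   "beta2": 0.01,
   "beta3": 0.04,
   "delta": 0.001,
   "gamma": 0.07,
   "lam": 0.3,
   "mu": 0.01,
   "phi1": 0.03,
   "phi2": 0.04,
   "phi3": 0.01
  },
  "eps1": 0.5,
  "eps2": 0.5,
  "eps3": 0.7,
  "eps4": 0.5,
  "tau": 5.0
 },
 "theta_scalar": 0.5
}
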