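# Michaelis-Menten, saturating dataset (A), vague uniform priors.
model: michaelis_menten
data:
  generator:
    kind: heteroscedastic
    eps: 0.25
    seed: 1
    x: [20000, 30000, 40000, 50000, 60000]
prior:
  - {name: k_cat, dist: uniform, lo: 1.0, hi: 10000.0}
  - {name: E_T, dist: uniform, lo: 0.01, hi: 100.0}
  - {name: K_M, dist: uniform, lo: 1.0, hi: 1000.0}
  - {name: eps, dist: uniform, lo: 0.01, hi: 0.6}
smc: {M: 1000, seed: 2}
fd: {delta: 0.001}
matrices: [H, L, P, G, K]
nuisance: [eps]
output_dir: scratch/mm_scenario1_out
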