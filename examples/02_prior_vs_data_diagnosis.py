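"""Where does the information come from: prior or data?

Runs the full Bayesian sloppiness pipeline (SMC posterior, posterior-mean-
initialised MLE, sensitivity matrices H/L at the MLE plus posterior-based P
and likelihood-informed G) for three Michaelis-Menten prior scenarios and
prints the stiffest eigenparameter of each matrix with the resulting
diagnosis:

1. vague uniform priors, saturating data   -> all matrices agree on
   k_cat*E_T: the data dominate (data_dominated);
2. a tight, badly placed K_M prior         -> P picks K_M (it reflects
   prior information) while H/L and G still pick k_cat*E_T
   (P_prior_influenced);
3. first-order-regime data with informative E_T and K_M priors -> H/L see
   k_cat*E_T/K_M, P sees K_M, G sees k_cat alone: the prior influences the
   fit itself (prior_influences_fit).

Takes ~10 s (1000 SMC particles per scenario).
"""

from sloppykit.scenarios import run_mm_scenario

for scenario in (1, 2, 3):
    res = run_mm_scenario(scenario, data_seed=1)
    print(f"scenario {scenario}: diagnosis = {res.diagnosis}")
    for kind in ("H", "L", "P", "G"):
        print(f"    {kind}: {res.stiffest_string(kind)}")
    print("    similarities:", {k: round(v, 3) for k, v in res.similarities.items()})
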