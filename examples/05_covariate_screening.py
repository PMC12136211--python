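"""Screen residualization covariates for association with ancestry groups.

If batch or cell-type composition is confounded with ancestry, residualizing
against them removes ancestry signal too. This screening tests each
control-probe PC against the grouping with a random-intercept mixed model
(repeated samples per individual) compared by likelihood-ratio test.
"""

from methylancestry import (SimConfig, control_probe_pcs,
                            mixed_model_group_lrt, simulate_cohort)

for confounded in (False, True):
    cohort = simulate_cohort(SimConfig(seed=1, confounded=confounded))
    ctrl_pcs = control_probe_pcs(cohort.control_probes, n_pcs=3)
    group = cohort.truth["group"].to_numpy()
    individual = cohort.sheet["individual_id"].to_numpy()
    print(f"\nconfounded design: {confounded}")
    for col in ctrl_pcs.columns:
        res = mixed_model_group_lrt(ctrl_pcs[col].to_numpy(), group, individual)
        print(f"  {col}: LRT = {res.statistic:8.2f}, p = {res.p_value:.3g}")
# In the randomized design the control-probe PCs are unrelated to ancestry
# (large p); under confounding they associate strongly, the situation in
# which residualization trades away part of the ancestry signal.
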