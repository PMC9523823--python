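"""A miniature simulation study: bias of both estimators under
exposure-induced confounding.

Scenario L6 lets the exposure raise a time-varying confounder that lowers
the mediator and raises the hazard.  The g-formula adjusts for it; the
path-analysis estimator can only use baseline covariates and misattributes
part of the direct effect to the mediator pathway.
"""

import survmediate as sm
from survmediate.evaluation import (
    percentile_event_times,
    run_replications,
    summarize_performance,
)

cfg = sm.get_scenario("L6", n=2000, seed=0)
big = sm.simulate_cohort(sm.get_scenario("L6", n=100_000, seed=1))
times = percentile_event_times(big)
truth = sm.true_effects(cfg, times, n_truth=300_000, seed=2)

est = run_replications(cfg, ("aalen", "vansteelandt"), nsim=40, times=times,
                       master_seed=3)
perf = summarize_performance(est, truth, scenario="L6", sub_scenario="DE+IE")
cols = ["method", "estimand", "time", "truth", "bias", "mcse"]
print(perf[cols].round(3).to_string(index=False))
# Expect the path-analysis IE bias to grow positive with time (toward +0.1
# at the 80% event time) with a mirror-image DE bias, while the g-formula
# rows stay within Monte Carlo error of zero.
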