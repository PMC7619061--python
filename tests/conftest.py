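import numpy as np
import pytest

from clonedrift import attrition, clonesim, synth


@pytest.fixture(scope="session")
def km_cohort_36():
    """36-mouse survival table generated at the fitted operating point."""
    params = attrition.AttritionParams(n0=100, delta=1 / 3, xi=0.6)
    return synth.gen_km_cohort(params, 36, seed=1)


@pytest.fixture(scope="session")
def neutral_vaf_dataset():
    """One neutral-homeostasis VAF dataset (N_ss=1500, lambda_ss=1.5/wk,
    mu=1, age 35 wk, 90x depth)."""
    scen = synth.SynthScenario(
        tag="neutral_drift",
        params={"n_ss": 1500, "lambda_ss": 1.5, "mu": 1.0, "age": 35.0},
        depth=90,
        seed=1,
    )
    table, truth = synth.gen_vaf_dataset(scen)
    return table, truth


@pytest.fixture(scope="session")
def filter_fixture():
    return synth.gen_filter_fixture(seed=42)


@pytest.fixture(scope="session")
def homeostasis_mean_sfs():
    """Monte-Carlo mean S_1..S_10 over 2000 replicate homeostatic runs
    (N_ss=50, lambda_ss=1, mu=2, sampled 30 weeks after birth).

    Per-replicate spread is large (the critical pool drifts and ~19% of
    runs are extinct, counted as zero), so 2000 replicates keep the
    standard error near 2% of the mean.
    """
    reps = 2000
    acc = np.zeros(11)
    for i in range(reps):
        rng = np.random.default_rng(40_000 + i)
        cfg = clonesim.SimConfig(
            n_target=50, regime="homeostasis", lam=1.0, checkpoints=(30.0,)
        )
        pop = clonesim.expand_population(cfg, rng)
        clonesim.evolve(pop, 1.0, 1.0, pop.t_birth + 30.0 - pop.time, rng)
        if pop.extinct:
            continue
        for n, c in clonesim.sfs(pop).counts.items():
            if n <= 10:
                acc[n] += c
    return acc[1:] / reps


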