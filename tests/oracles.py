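"""Independent brute-force oracles shared by the test modules."""

import numpy as np

from fmdd.inner import evaluate_levels


def grid_oracle_1d(problem, target, resolution=200):
    """Dense 1-D scan over one target's activity range: best min-grade."""
    net = problem.network
    basal = net.alpha_basal[net.reaction_index(target)]
    lo, hi = problem.bounds.activity_range(target, basal)
    best = -1.0
    for level in np.geomspace(lo, hi, resolution):
        dp = evaluate_levels(problem, (target,), {target: level})
        if dp.feasible and dp.report.lam > best:
            best = dp.report.lam
    return best


def grid_oracle_2d(problem, t1, t2, resolution=60):
    """Dense 2-D scan over two targets' ranges."""
    net = problem.network
    rng1 = problem.bounds.activity_range(t1, net.alpha_basal[net.reaction_index(t1)])
    rng2 = problem.bounds.activity_range(t2, net.alpha_basal[net.reaction_index(t2)])
    best = -1.0
    for a in np.geomspace(*rng1, resolution):
        for b in np.geomspace(*rng2, resolution):
            dp = evaluate_levels(problem, (t1, t2), {t1: a, t2: b})
            if dp.feasible and dp.report.lam > best:
                best = dp.report.lam
    return best
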