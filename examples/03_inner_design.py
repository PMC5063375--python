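"""Optimal regulation of a fixed target subset (the inner max-min solve).

For a chosen enzyme target the solver maximizes lambda = the minimum
satisfaction grade over all objectives, adjusting only that enzyme's
activity within fold bounds [0.1, 10] of basal.  Here: a random synthetic
network with a 60% deficiency of its first chain reaction.
"""

from fmdd import solve_fixed_targets
from fmdd.fixtures import FixtureSpec, generate_random_gma, synthetic_problem

net = generate_random_gma(FixtureSpec(n_species=5, n_reactions=8,
                                      n_controls=1, seed=7))
problem = synthetic_problem(net, disease={"v1_in": 60})
print("disease:", problem.scenario.disease)
print("therapeutic species:", problem.sets.te, " adverse:", problem.sets.ae)

for target in problem.sets.ve_activities[:3]:
    dp = solve_fixed_targets(problem, (target,), n_starts=4, seed=0)
    basal = net.alpha_basal[net.reaction_index(target)]
    print(f"target {target:14s} lambda={dp.lam:.3f} "
          f"T={dp.report.T:.3f} A={dp.report.A:.3f} V={dp.report.V:.3f} "
          f"activity fold={dp.levels[target]/basal:.2f}")

# lambda is the worst satisfied objective; a target with lambda = 1 fully
# compensates the deficiency without violating adverse or variation goals.
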