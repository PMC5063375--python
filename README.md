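# fmdd — fuzzy multiobjective enzyme-target discovery on GMA kinetic models

`fmdd` is a Python library for model-based drug-target screening in
metabolic disorders.  It answers the question: *which enzymes (and external
inputs) should be regulated, and by how much, to best compensate a disease
while limiting side effects and keeping interventions small?*  Its intended
users are computational systems biologists working with power-law kinetic
models of human metabolism.

## The model and the decision problem

Pathways are represented as **generalized mass action (GMA)** networks: each
reaction rate is a power law

$$v_k = \alpha_k \prod_l x_l^{g_{kl}},$$

with enzyme activity $\alpha_k$ and real-valued kinetic orders $g_{kl}$, and
species follow the material balance $\dot x = N v(x, \alpha) + B u$ with
external controls $u$.  A disease is a **deficiency**: the affected enzyme is
fixed at $\alpha^{DS} = (1 - \delta/100)\,\alpha^{basal}$ and removed from
the regulable set.

Design goals are expressed as **fuzzy objectives** with membership functions
$\eta(\cdot) \in [0,1]$:

* *therapeutic* — keep key metabolites (e.g. extracellular dopamine) at
  their healthy level (fuzzy-equal: grade 1 at basal, 0 beyond fold bounds);
* *adverse* — keep toxic metabolites low (fuzzy-minimize: grade 1 at or
  below basal, 0 at an upper fold bound);
* *variation* — perturb the chosen targets as little as possible
  (fuzzy-equal on activities and controls), the kinetic analogue of a
  minimum effective dose.

A design selecting targets $z$ (binary) and levels $(\hat\alpha, u)$ is
scored by the **max–min decision problem**

$$\max\; \frac{Z^{UB} - \sum_j z_j}{Z^{UB} - 1}\;\lambda
\quad\text{s.t.}\quad \eta_i \ge \lambda \;\forall i,\;
(x,\hat\alpha,u,z) \in \Psi,$$

where $\lambda$ is the worst satisfied objective and the leading factor
penalises the number of targets.  The mixed-integer problem is solved by a
**nested hybrid differential evolution (NHDE)**: an outer integer-coded
evolutionary search over target subsets (mutation, crossover, two-step
selection, migration, acceleration, memoization) where every candidate
subset is evaluated by an inner continuous max–min solve (multistart SLSQP
on log-activities with an explicit $\lambda$).

The package ships a presynaptic **dopamine metabolism case study**
(VMAT2/tyrosine-hydroxylase deficiency scenarios, clinical treatment presets
for L-DOPA, dopamine agonists, MAO and COMT inhibitors).  The packaged
network is a clearly-labelled *synthetic stand-in*: it reproduces the
published dimensions (34 species, 68 reactions, 3 controls), species
identities, healthy-state concentrations (DA-e = 400 relative units) and
named enzyme roles, but not the unpublished kinetic parameters — see
`docs/methods.md`.

## Worked example

```python
from fmdd import NHDEConfig, nhde_search
from fmdd.fixtures import FixtureSpec, generate_random_gma, synthetic_problem

net = generate_random_gma(FixtureSpec(n_species=5, n_reactions=8,
                                      n_controls=1, seed=7))
problem = synthetic_problem(net, disease={"v1_in": 60})   # 60% deficiency
result = nhde_search(problem, NHDEConfig(population_size=8,
                                         max_generations=8,
                                         cardinality=1, seed=3))
print(result.best.targets, round(result.best_fitness, 3))
```

prints

```
('v4_X3_X4',) 0.593
```

— under a 60% deficiency of the head influx, the best single target is the
efflux of the therapeutic species (downregulating it props the depleted pool
back up), and the best achievable overall satisfaction grade is 0.593: the
worst objective (here the therapeutic one) can be satisfied to 59%, times a
target-count factor of 1 for a single target.  The untreated scenario grades
only 0.236.  Running `python examples/05_dopamine_case.py` prints the same
kind of analysis on the dopamine network, e.g. the VMAT2-deficiency series
DA-e folds 0.559 / 0.330 / 0.086 / 0.033 for 50–95% severity and a
fold/grade table for the reported metabolites.

The `examples/` directory holds one short script per capability (steady
states, membership grading, inner design, target search, the dopamine case);
a thin CLI (`fmdd simulate|grade|optimize|treat|fixtures`) wraps the same
functions for shell use.

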