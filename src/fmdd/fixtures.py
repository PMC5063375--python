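"""Synthetic GMA fixtures: a closed-form toy network and random generators.

These networks make every stage of the pipeline testable without any
transcribed pathway model.  The toy network has an analytic steady state;
the random generator draws a topology and kinetic orders, designates a
target steady state, and back-solves the rate constants so the designated
state balances exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import GMANetwork

__all__ = ["FixtureSpec", "toy_network", "toy_steady_state", "generate_random_gma"]


def toy_network() -> GMANetwork:
    """Two-species, three-reaction linear chain with closed-form steady state.

    Constant influx ``v1 = a1`` into X1, transfer ``v2 = a2 * x1**0.5`` from
    X1 to X2, efflux ``v3 = a3 * x2**0.5``.  At steady state
    ``x1 = (a1/a2)**2`` and ``x2 = (a1/a3)**2``; with the default activities
    (1, 1, 2) the state is (1, 0.25).
    """
    alpha = np.array([1.0, 1.0, 2.0])
    N = np.array(
        [
            [1.0, -1.0, 0.0],
            [0.0, 1.0, -1.0],
        ]
    )
    G = np.array(
        [
            [0.0, 0.0],
            [0.5, 0.0],
            [0.0, 0.5],
        ]
    )
    x_basal = np.array([(alpha[0] / alpha[1]) ** 2, (alpha[0] / alpha[2]) ** 2])
    return GMANetwork(
        species_names=["X1", "X2"],
        reaction_names=["v1", "v2", "v3"],
        control_names=[],
        N=N,
        B=np.zeros((2, 0)),
        G=G,
        alpha_basal=alpha,
        u_basal=np.zeros(0),
        x_basal=x_basal,
        meta={"kind": "toy"},
    )


def toy_steady_state(alpha1: float = 1.0, alpha2: float = 1.0, alpha3: float = 2.0):
    """Closed-form steady state of the toy chain for arbitrary activities."""
    return np.array([(alpha1 / alpha2) ** 2, (alpha1 / alpha3) ** 2])


@dataclass
class FixtureSpec:
    """Dimensions and kinetic ranges for a random consistent GMA network."""

    n_species: int = 6
    n_reactions: int = 10
    n_controls: int = 1
    order_low: float = -1.0
    order_high: float = 1.0
    min_order_magnitude: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_reactions < self.n_species + 1:
            raise ValueError("need an influx, a chain and a terminal efflux")
        if self.n_controls < 0:
            raise ValueError("n_controls must be nonnegative")


def _draw_order(rng: np.random.Generator, spec: FixtureSpec) -> float:
    """Kinetic order in [low, high] with tiny magnitudes excluded."""
    for _ in range(100):
        g = rng.uniform(spec.order_low, spec.order_high)
        if abs(g) >= spec.min_order_magnitude:
            return float(g)
    return spec.min_order_magnitude


def generate_random_gma(spec: FixtureSpec, _retries: int = 10) -> GMANetwork:
    """Random consistent GMA network, reproducible by seed.

    Construction: a main chain X1 -> X2 -> ... -> Xn with a constant influx
    into X1 and a terminal efflux from Xn (the last species doubles as the
    downstream "toxic byproduct" exercised by adverse-effect objectives);
    extra reactions are random effluxes or transfers, some modulated by an
    off-path species through a fractional or negative kinetic order.  A
    target steady state is drawn, steady fluxes are assigned by sweeping the
    chain so every species balances exactly (controls included), and each
    rate constant is back-solved as ``alpha_k = v_k / prod x**g``.
    """
    rng = np.random.default_rng(spec.seed)
    n, r, m = spec.n_species, spec.n_reactions, spec.n_controls
    species = [f"X{i+1}" for i in range(n)]
    x_target = rng.uniform(0.5, 5.0, size=n)

    N = np.zeros((n, r))
    G = np.zeros((r, n))
    reactions: list[str] = []
    k = 0
    # constant influx into the head of the chain
    N[0, k] = 1.0
    reactions.append("v1_in")
    k += 1
    # chain transfers with substrate dependence; record the outgoing reaction
    # of every species for the balancing sweep below
    outgoing = np.empty(n, dtype=int)
    for i in range(n - 1):
        N[i, k] = -1.0
        N[i + 1, k] = 1.0
        G[k, i] = abs(_draw_order(rng, spec))
        outgoing[i] = k
        reactions.append(f"v{k+1}_X{i+1}_X{i+2}")
        k += 1
    # terminal efflux from the last species
    N[n - 1, k] = -1.0
    G[k, n - 1] = abs(_draw_order(rng, spec))
    outgoing[n - 1] = k
    reactions.append(f"v{k+1}_X{n}_out")
    k += 1
    # remaining reactions: random effluxes or transfers with a modulator
    while k < r:
        if rng.random() < 0.5:
            i = int(rng.integers(0, n))
            N[i, k] = -1.0
            G[k, i] = abs(_draw_order(rng, spec))
            reactions.append(f"v{k+1}_X{i+1}_out")
        else:
            i, j = (int(a) for a in rng.choice(n, size=2, replace=False))
            N[i, k] = -1.0
            N[j, k] = 1.0
            G[k, i] = abs(_draw_order(rng, spec))
            mod = int(rng.integers(0, n))
            if mod not in (i, j):
                G[k, mod] = _draw_order(rng, spec)
            reactions.append(f"v{k+1}_X{i+1}_X{j+1}")
        k += 1

    # controls feed random species
    B = np.zeros((n, m))
    u = np.zeros(m)
    controls = [f"u{j+1}" for j in range(m)]
    for j in range(m):
        B[int(rng.integers(0, n)), j] = 1.0
        u[j] = float(rng.uniform(0.1, 1.0))

    # designate steady fluxes: draw all, then sweep down the chain adjusting
    # each species' outgoing flux so its balance (incl. controls) closes;
    # chain order makes each correction final.
    # extras drain little relative to the head influx, so the sweep leaves
    # every chain flux positive
    v = rng.uniform(0.05, 0.2, size=r)
    v[0] = float(n)
    rhs = -(B @ u)
    for i in range(n):
        res_i = float(N[i, :] @ v - rhs[i])
        v[outgoing[i]] += res_i  # N[i, outgoing[i]] == -1
    if np.min(v) <= 1e-3 or np.max(np.abs(N @ v - rhs)) > 1e-9:
        if _retries <= 0:
            raise RuntimeError("could not draw a positive steady flux vector")
        retry = FixtureSpec(
            n_species=n,
            n_reactions=r,
            n_controls=m,
            order_low=spec.order_low,
            order_high=spec.order_high,
            min_order_magnitude=spec.min_order_magnitude,
            seed=spec.seed + 100_003,
        )
        net = generate_random_gma(retry, _retries - 1)
        net.meta["seed"] = spec.seed  # reproducibility: same spec, same net
        return net

    # back-solve rate constants so x_target is an exact steady state
    prod = np.prod(np.where(G == 0.0, 1.0, x_target[np.newaxis, :] ** G), axis=1)
    alpha = v / prod

    net = GMANetwork(
        species_names=species,
        reaction_names=reactions,
        control_names=controls,
        N=N,
        B=B,
        G=G,
        alpha_basal=alpha,
        u_basal=u,
        x_basal=x_target,
        meta={"kind": "random", "seed": spec.seed},
    )
    assert net.is_consistent(1e-10), "constructed network failed consistency"
    return net


def synthetic_problem(
    network: GMANetwork,
    *,
    therapeutic: str | None = None,
    adverse: str | None = None,
    z_ub: int = 6,
    targets: list[str] | None = None,
    disease: dict[str, float] | None = None,
):
    """Wrap a fixture network into a small decision problem.

    The therapeutic species defaults to the middle of the chain and the
    adverse species to the terminal byproduct; regulable targets default to
    every reaction except the head influx, plus any controls.  ``disease``
    maps reaction name -> percent deficiency, applied as the scenario.
    """
    from .inner import DecisionProblem, TargetBounds
    from .membership import ObjectiveSets, build_default_memberships
    from .steady_state import Perturbation, apply_deficiency

    n = network.n_species
    te = [therapeutic or network.species_names[n // 2]]
    ae = [adverse or network.species_names[-1]]
    scenario = Perturbation()
    for rxn, delta in (disease or {}).items():
        scenario = scenario.merged(apply_deficiency(network, rxn, delta))
    if targets is None:
        targets = [
            r for r in network.reaction_names[1:] if r not in scenario.disease_set
        ]
    sets = ObjectiveSets(
        te=te,
        ae=ae,
        ve_activities=[t for t in targets if t in network.reaction_names],
        ve_controls_equal=[t for t in targets if t in network.control_names],
        ds=sorted(scenario.disease_set),
        z_ub=z_ub,
    )
    specs = build_default_memberships(network, sets)
    return DecisionProblem(
        network=network, sets=sets, specs=specs,
        bounds=TargetBounds(), scenario=scenario,
    )
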