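"""Inner continuous problem: optimal regulation for a fixed target subset.

Given a binary selection of regulable targets (enzyme activities and external
controls), the inner problem maximizes the overall satisfaction grade lambda
subject to the kinetic steady-state equalities, switched box bounds on the
selected targets, and every membership grade >= lambda.

The solver uses a reduced-space formulation: the decision variables are the
selected targets' log-activities / control levels (unselected handles are
pinned at basal by the bound-switching construction) plus an explicit lambda;
the steady state is solved as an inner equation at each trial point, so the
equality constraints are always satisfied exactly and only the grade
inequalities remain.  SLSQP with multistart does the search, with a
derivative-free fallback on the max-min composite when SLSQP stalls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .membership import (
    GradeReport,
    MembershipSpec,
    ObjectiveSets,
    grade_design,
)
from .network import GMANetwork
from .steady_state import Perturbation, SteadyState, solve_steady_state

__all__ = [
    "DecisionProblem",
    "DesignPoint",
    "TargetBounds",
    "solve_fixed_targets",
    "evaluate_treatment",
]


@dataclass
class TargetBounds:
    """Per-target regulation range.

    Activities are bounded as folds of basal (default [0.1, 10], i.e. +-ln 10
    in log space); controls by absolute values (default [0, 10 x basal-or-1]).
    """

    activity_fold: tuple[float, float] = (0.1, 10.0)
    control_abs: dict[str, tuple[float, float]] = field(default_factory=dict)
    activity_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)

    def activity_range(self, name: str, basal: float) -> tuple[float, float]:
        lo, hi = self.activity_overrides.get(name, self.activity_fold)
        return lo * basal, hi * basal

    def control_range(self, name: str, basal: float) -> tuple[float, float]:
        if name in self.control_abs:
            return self.control_abs[name]
        scale = basal if basal > 0 else 1.0
        return 0.0, 10.0 * scale


@dataclass
class DecisionProblem:
    """Everything the inner and outer searches need.

    ``scenario`` carries the disease restriction (and any pre-fixed
    treatment overrides); diseased reactions are excluded from the decision
    variables by construction.
    """

    network: GMANetwork
    sets: ObjectiveSets
    specs: dict[str, MembershipSpec]
    bounds: TargetBounds = field(default_factory=TargetBounds)
    scenario: Perturbation = field(default_factory=Perturbation)

    def __post_init__(self):
        sick = self.scenario.disease_set & set(self.sets.ve_activities)
        if sick:
            raise ValueError(
                f"diseased reactions cannot be regulable targets: {sorted(sick)}"
            )

    @property
    def regulable_targets(self) -> list[str]:
        return self.sets.regulable_targets

    def is_control(self, name: str) -> bool:
        return name in self.network.control_names


@dataclass
class DesignPoint:
    """A candidate design: selected targets, their levels, state and grades."""

    targets: tuple[str, ...]
    levels: dict[str, float]  # absolute activity / control values
    state: SteadyState
    report: GradeReport
    feasible: bool

    @property
    def lam(self) -> float:
        return self.report.lam if self.feasible else 0.0

    @property
    def overall(self) -> float:
        return self.report.overall if self.feasible else 0.0

    def as_dict(self) -> dict:
        return {
            "targets": list(self.targets),
            "levels": self.levels,
            "feasible": self.feasible,
            "lambda": self.lam,
            "overall": self.overall,
            "grades": self.report.as_dict(),
        }


def _target_space(problem: DecisionProblem, targets: tuple[str, ...]):
    """Per-target (is_control, basal, lo, hi, log_space) tuples."""
    net = problem.network
    space = []
    for t in targets:
        if problem.is_control(t):
            basal = net.u_basal[net.control_index(t)]
            lo, hi = problem.bounds.control_range(t, basal)
            space.append((t, True, basal, lo, hi, False))
        else:
            basal = net.alpha_basal[net.reaction_index(t)]
            lo, hi = problem.bounds.activity_range(t, basal)
            space.append((t, False, basal, lo, hi, True))
    return space


def _perturbation_for(problem, space, theta):
    """Build the full perturbation (scenario + regulated levels) at theta."""
    act: dict[str, float] = {}
    ctl: dict[str, float] = {}
    for (name, is_ctl, _basal, _lo, _hi, logsp), val in zip(space, theta):
        level = math.exp(val) if logsp else float(val)
        if is_ctl:
            ctl[name] = level
        else:
            act[name] = level
    trial = Perturbation(activity_values=act, control_values=ctl)
    return problem.scenario.merged(trial), act, ctl


def evaluate_levels(
    problem: DecisionProblem, targets: tuple[str, ...], levels: dict[str, float]
) -> DesignPoint:
    """Grade a design with explicit absolute levels for the selected targets."""
    net = problem.network
    act = {t: levels[t] for t in targets if not problem.is_control(t)}
    ctl = {t: levels[t] for t in targets if problem.is_control(t)}
    pert = problem.scenario.merged(
        Perturbation(activity_values=act, control_values=ctl)
    )
    state = solve_steady_state(net, pert)
    alpha, u = pert.apply(net)
    report = grade_design(
        state, net, problem.sets, problem.specs,
        alpha=alpha, u=u, n_targets=len(targets),
    )
    return DesignPoint(
        targets=tuple(targets),
        levels=dict(levels),
        state=state,
        report=report,
        feasible=state.converged,
    )


def solve_fixed_targets(
    problem: DecisionProblem,
    targets,
    *,
    n_starts: int = 8,
    seed: int = 0,
    maxiter: int = 120,
) -> DesignPoint:
    """Maximize lambda over the levels of a fixed target subset.

    Decision variables are the selected targets' log-activities (controls in
    linear space) plus an explicit lambda; constraints are grade_k >= lambda.
    Multistart initial points are the basal point plus uniform draws within
    bounds; the best SLSQP result is polished and, if SLSQP stalls, a
    derivative-free Powell pass on the max-min composite is used instead.
    Deterministic for a fixed seed.  With no targets the scenario is simply
    graded as-is.
    """
    targets = tuple(targets)
    if len(set(targets)) != len(targets):
        raise ValueError("duplicate targets in subset")
    bad = set(targets) & problem.scenario.disease_set
    if bad:
        raise ValueError(f"diseased reactions are not regulable: {sorted(bad)}")
    if len(targets) > problem.sets.z_ub:
        raise ValueError("subset exceeds Z_UB")
    net = problem.network

    if not targets:
        state = solve_steady_state(net, problem.scenario)
        alpha, u = problem.scenario.apply(net)
        report = grade_design(
            state, net, problem.sets, problem.specs, alpha=alpha, u=u, n_targets=0
        )
        return DesignPoint(
            targets=(), levels={}, state=state, report=report,
            feasible=state.converged,
        )

    space = _target_space(problem, targets)
    lo = np.array([math.log(s[3]) if s[5] else s[3] for s in space])
    hi = np.array([math.log(s[4]) if s[5] else s[4] for s in space])
    basal_theta = np.array(
        [
            math.log(s[2]) if s[5] else s[2]
            for s in space
        ]
    )
    basal_theta = np.clip(basal_theta, lo, hi)

    # warm start: successive trial points are close, so reuse the last
    # converged concentrations as the Newton initial guess
    warm = {"x0": None}
    eval_cache: dict[tuple, tuple[float, DesignPoint | None]] = {}

    def grades_at(theta) -> tuple[float, DesignPoint | None]:
        key = tuple(np.round(np.asarray(theta, dtype=float), 12))
        if key in eval_cache:
            return eval_cache[key]
        pert, act, ctl = _perturbation_for(problem, space, theta)
        state = solve_steady_state(net, pert, x0=warm["x0"])
        if not state.converged:
            state = solve_steady_state(net, pert)  # retry cold from basal
        if not state.converged:
            eval_cache[key] = (-1.0, None)
            return -1.0, None
        warm["x0"] = state.x
        alpha, u = pert.apply(net)
        report = grade_design(
            state, net, problem.sets, problem.specs,
            alpha=alpha, u=u, n_targets=len(targets),
        )
        levels = {**act, **ctl}
        dp = DesignPoint(
            targets=targets, levels=levels, state=state, report=report, feasible=True
        )
        eval_cache[key] = (report.lam, dp)
        return report.lam, dp

    def neg_mingrade(theta):
        lam, _ = grades_at(theta)
        return -lam

    rng = np.random.default_rng(seed)
    starts = [basal_theta]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(rng.uniform(lo, hi))

    best_lam, best_dp, best_theta = -1.0, None, None

    def consider(theta):
        nonlocal best_lam, best_dp, best_theta
        lam, dp = grades_at(theta)
        if dp is not None and lam > best_lam:
            best_lam, best_dp, best_theta = lam, dp, np.array(theta, dtype=float)
        return lam

    # coarse seeding scan along each axis (cheap, catches the right basin)
    for axis in range(len(targets)):
        for t in np.linspace(0.0, 1.0, 9):
            theta = basal_theta.copy()
            theta[axis] = lo[axis] + t * (hi[axis] - lo[axis])
            consider(theta)

    for theta0 in starts:
        lam0 = consider(theta0)
        # explicit-lambda SLSQP: variables (theta, lam), maximize lam
        z0 = np.append(theta0, max(lam0, 0.0))

        def neg_lambda(z):
            return -z[-1]

        def cons_f(z):
            lam, _ = grades_at(z[:-1])
            return lam - z[-1]

        try:
            res = minimize(
                neg_lambda,
                z0,
                method="SLSQP",
                bounds=[(a, b) for a, b in zip(lo, hi)] + [(0.0, 1.0)],
                constraints=[{"type": "ineq", "fun": cons_f}],
                options={"maxiter": maxiter, "ftol": 1e-7},
            )
            consider(np.clip(res.x[:-1], lo, hi))
        except (ValueError, np.linalg.LinAlgError):
            pass

    # derivative-free polish on the max-min composite from the best point
    if best_theta is not None:
        try:
            res = minimize(
                neg_mingrade,
                best_theta,
                method="Powell",
                bounds=list(zip(lo, hi)),
                options={"maxfev": 80 * len(targets), "xtol": 1e-5, "ftol": 1e-7},
            )
            consider(np.clip(res.x, lo, hi))
        except (ValueError, np.linalg.LinAlgError):
            pass

    if best_dp is None:
        # every trial point failed to converge: report an infeasible design
        state = solve_steady_state(net, problem.scenario)
        alpha, u = problem.scenario.apply(net)
        report = grade_design(
            state, net, problem.sets, problem.specs,
            alpha=alpha, u=u, n_targets=len(targets),
        )
        return DesignPoint(
            targets=targets, levels={}, state=state, report=report, feasible=False
        )

    # tie-break refinement: among equal-lambda optima prefer smaller total
    # deviation from basal (variation-effect intent) by nudging each
    # coordinate toward basal while lambda is preserved
    theta = best_theta.copy()
    for idx in range(len(theta)):
        for frac in (1.0, 0.5, 0.25):
            cand = theta.copy()
            cand[idx] = theta[idx] + frac * (basal_theta[idx] - theta[idx])
            lam_c, dp_c = grades_at(cand)
            if dp_c is not None and lam_c >= best_lam - 1e-10:
                theta, best_lam, best_dp = cand, max(best_lam, lam_c), dp_c
                break
    return best_dp


def evaluate_treatment(
    problem: DecisionProblem,
    fixed_overrides: dict[str, float] | None = None,
    *,
    optimize_targets=None,
    n_starts: int = 8,
    seed: int = 0,
) -> DesignPoint:
    """Evaluate a treatment preset.

    ``fixed_overrides`` pins named activities/controls at explicit absolute
    levels ("fixed-dose" mode); ``optimize_targets`` instead lets the inner
    solver choose the levels of the named targets within bounds.  Grades are
    reported per effect class (T, A, V) in the design's report.
    """
    if optimize_targets:
        return solve_fixed_targets(
            problem, tuple(optimize_targets), n_starts=n_starts, seed=seed
        )
    fixed_overrides = fixed_overrides or {}
    return evaluate_levels(problem, tuple(fixed_overrides), fixed_overrides)
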