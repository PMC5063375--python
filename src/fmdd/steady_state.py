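"""Steady-state solving, perturbations and fold-change reporting.

The solver works in logarithmic coordinates (damped Newton on ``y = log x``),
where the GMA equality constraints are well conditioned, and falls back to
stiff time integration of the material balance when Newton does not converge
(e.g. when a knockout pushes a pool to the zero boundary, which log
coordinates cannot represent).  Concentrations that converge below a small
floor are flagged "effectively zero" rather than reported as exact zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .network import GMANetwork, evaluate_rates

__all__ = [
    "Perturbation",
    "SteadyState",
    "SteadyStateError",
    "apply_deficiency",
    "solve_steady_state",
    "fold_changes",
]

#: concentrations below this (relative units) are reported as effectively zero
ZERO_FLOOR = 1e-9


class SteadyStateError(RuntimeError):
    """Raised when no steady state could be found within tolerance."""


@dataclass
class Perturbation:
    """A modification of the basal model.

    ``activity_values`` fixes reactions at absolute activities;
    ``activity_folds`` fixes them at a multiple of basal.  ``control_values``
    fixes external controls.  ``disease`` holds the disease restriction: a map
    reaction -> absolute activity alpha^DS, and those reactions are excluded
    from the regulable set downstream.
    """

    activity_values: dict[str, float] = field(default_factory=dict)
    activity_folds: dict[str, float] = field(default_factory=dict)
    control_values: dict[str, float] = field(default_factory=dict)
    disease: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        overlap = set(self.activity_values) & set(self.activity_folds)
        if overlap:
            raise ValueError(f"reactions overridden twice: {sorted(overlap)}")
        for d in (self.activity_values, self.activity_folds, self.disease):
            for name, val in d.items():
                if val < 0:
                    raise ValueError(f"negative activity override for {name!r}")

    @property
    def disease_set(self) -> set[str]:
        return set(self.disease)

    def merged(self, other: "Perturbation") -> "Perturbation":
        """Combine two perturbations; ``other`` wins on conflicts."""
        return Perturbation(
            activity_values={**self.activity_values, **other.activity_values},
            activity_folds={**self.activity_folds, **other.activity_folds},
            control_values={**self.control_values, **other.control_values},
            disease={**self.disease, **other.disease},
        )

    def apply(self, network: GMANetwork) -> tuple[np.ndarray, np.ndarray]:
        """Return (alpha, u) vectors with the overrides applied to basal."""
        alpha = network.alpha_basal.copy()
        for name, val in self.activity_values.items():
            alpha[network.reaction_index(name)] = val
        for name, f in self.activity_folds.items():
            alpha[network.reaction_index(name)] = f * network.alpha_basal[
                network.reaction_index(name)
            ]
        for name, val in self.disease.items():
            alpha[network.reaction_index(name)] = val
        u = network.u_basal.copy()
        for name, val in self.control_values.items():
            u[network.control_index(name)] = val
        return alpha, u


def apply_deficiency(
    network: GMANetwork, reaction: str, delta_percent: float
) -> Perturbation:
    """Disease restriction for a deficient enzyme.

    The diseased activity is ``alpha_DS = (1 - delta/100) * alpha_basal``;
    the reaction joins the disease set and is no longer a regulable target.
    ``delta_percent = 100`` silences the reaction completely.
    """
    if not 0.0 <= delta_percent <= 100.0:
        raise ValueError("deficiency must be between 0 and 100 percent")
    k = network.reaction_index(reaction)
    alpha_ds = (1.0 - delta_percent / 100.0) * network.alpha_basal[k]
    return Perturbation(disease={reaction: float(alpha_ds)})


@dataclass
class SteadyState:
    """A solved steady state: concentrations, rates and diagnostics."""

    x: np.ndarray
    v: np.ndarray
    converged: bool
    residual_norm: float
    effectively_zero: np.ndarray  # boolean mask over species
    method: str = ""

    def concentration(self, network: GMANetwork, species: str) -> float:
        return float(self.x[network.species_index(species)])


def _newton_log(network, alpha, u, x0, tol, max_iter):
    """Damped Newton on y = log x.  Rates evaluated as alpha*exp(G y) so
    zero activities (knockouts) are handled without -inf log activities."""
    y = np.log(np.maximum(x0, ZERO_FLOOR))
    G, N, B = network.G, network.N, network.B
    bu = B @ u
    scale = max(np.max(np.abs(evaluate_rates(network.x_basal, network.alpha_basal, G))), 1.0)

    def F(yv):
        v = alpha * np.exp(np.clip(G @ yv, -500, 500))
        return N @ v + bu, v

    f, v = F(y)
    fnorm = np.max(np.abs(f))
    for _ in range(max_iter):
        if fnorm <= tol * scale:
            x = np.exp(y)
            return SteadyState(
                x=x,
                v=v,
                converged=True,
                residual_norm=fnorm,
                effectively_zero=x < ZERO_FLOOR,
                method="newton-log",
            )
        J = N @ (v[:, None] * G)  # d residual / d y
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            step, *_ = np.linalg.lstsq(J, -f, rcond=None)
        # trust-region style cap on the log step, then backtracking
        mx = np.max(np.abs(step))
        if mx > 5.0:
            step *= 5.0 / mx
        lam, improved = 1.0, False
        for _ in range(30):
            y_try = y + lam * step
            f_try, v_try = F(y_try)
            fn_try = np.max(np.abs(f_try))
            if fn_try < fnorm:
                y, f, v, fnorm = y_try, f_try, v_try, fn_try
                improved = True
                break
            lam *= 0.5
        if not improved:
            break
    x = np.exp(y)
    return SteadyState(
        x=x,
        v=v,
        converged=fnorm <= tol * scale,
        residual_norm=fnorm,
        effectively_zero=x < ZERO_FLOOR,
        method="newton-log",
    )


def _integrate(network, alpha, u, x0, tol, t_max=1e7):
    """Stiff integration of dx/dt = N v + B u until the derivative settles."""
    N, B, G = network.N, network.B, network.G
    bu = B @ u
    scale = max(np.max(np.abs(evaluate_rates(network.x_basal, network.alpha_basal, G))), 1.0)

    def rhs(_t, x):
        v = evaluate_rates(np.maximum(x, 0.0), alpha, G)
        return N @ v + bu

    sol = solve_ivp(
        rhs,
        (0.0, t_max),
        np.maximum(x0, 0.0),
        method="BDF",
        rtol=1e-10,
        atol=1e-12,
    )
    x = np.maximum(sol.y[:, -1], 0.0)
    v = evaluate_rates(x, alpha, G)
    res = N @ v + bu
    fnorm = float(np.max(np.abs(res)))
    return SteadyState(
        x=x,
        v=v,
        converged=bool(sol.success and fnorm <= max(tol * scale, 1e2 * tol)),
        residual_norm=fnorm,
        effectively_zero=x < ZERO_FLOOR,
        method="ode-bdf",
    )


def solve_steady_state(
    network: GMANetwork,
    perturbation: Perturbation | None = None,
    *,
    tol: float = 1e-10,
    max_iter: int = 200,
    x0: np.ndarray | None = None,
    raise_on_failure: bool = False,
) -> SteadyState:
    """Solve ``N v(x, alpha) + B u = 0`` for the perturbed model.

    Strategy: damped Newton on log-concentrations starting from the basal
    state, with a fallback to stiff time integration (BDF) from basal when
    Newton fails — e.g. when a complete knockout drives a pool to the zero
    boundary.  A non-converged result is returned (or raised) explicitly,
    never as silent NaNs.
    """
    if perturbation is None:
        perturbation = Perturbation()
    alpha, u = perturbation.apply(network)
    start = network.x_basal if x0 is None else np.asarray(x0, dtype=float)
    state = _newton_log(network, alpha, u, start, tol, max_iter)
    if not state.converged or np.any(~np.isfinite(state.x)):
        ode_state = _integrate(network, alpha, u, start, tol)
        if ode_state.converged:
            # polish with Newton from the integrated point when possible
            polished = _newton_log(
                network, alpha, u, np.maximum(ode_state.x, ZERO_FLOOR), tol, max_iter
            )
            state = polished if polished.converged else ode_state
        elif ode_state.residual_norm < state.residual_norm:
            state = ode_state
    if raise_on_failure and not state.converged:
        raise SteadyStateError(
            f"no steady state found (residual max-norm {state.residual_norm:.3e})"
        )
    return state


def fold_changes(state: SteadyState, reference: SteadyState):
    """Per-species and per-flux fold changes relative to a reference state.

    Fold change is the value in ``state`` divided by the value in
    ``reference``; entries whose reference is zero (or effectively zero,
    below the solver floor) are undefined (NaN), never infinity.
    """
    x_ok = reference.x > ZERO_FLOOR
    v_ok = reference.v > ZERO_FLOOR
    xf = np.where(x_ok, state.x / np.where(x_ok, reference.x, 1.0), np.nan)
    vf = np.where(v_ok, state.v / np.where(v_ok, reference.v, 1.0), np.nan)
    return xf, vf
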