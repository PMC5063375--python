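"""Generalized mass action (GMA) kinetic networks.

A GMA network is the standard Biochemical Systems Theory representation of a
metabolic pathway: every reaction rate is a power law

    v_k = alpha_k * prod_l x_l ** g_kl

with rate constant (enzyme activity) ``alpha_k`` and real-valued kinetic
orders ``g_kl`` (negative orders encode inhibition, fractional orders encode
saturation-like behaviour).  Species dynamics follow the material balance

    dx/dt = N v(x, alpha) + B u

where ``N`` is the stoichiometric matrix, ``u`` a vector of external controls
(regulable independent inputs) and ``B`` the connectivity matrix coupling
controls to species.

All concentrations and activities are in relative units; no unit conversion
layer is provided.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GMANetwork",
    "evaluate_rates",
    "steady_state_residual",
    "log_transform_constraints",
    "load_network",
    "save_network",
]

#: exponent clip used by the log-space evaluation to guard against overflow
EXP_CLIP = 500.0


def evaluate_rates(x, alpha, G):
    """Power-law reaction rates ``v_k = alpha_k * prod_l x_l**g_kl``.

    ``0**0`` is taken as 1 (a species with zero kinetic order does not enter
    the rate, even at zero concentration).  Zero activities are allowed and
    yield zero rates, which is how complete enzyme deficiencies are encoded.

    Parameters
    ----------
    x : (n,) array_like
        Nonnegative concentrations.
    alpha : (r,) array_like
        Nonnegative activities (zero only for knocked-out reactions).
    G : (r, n) array_like
        Kinetic orders.

    Returns
    -------
    (r,) ndarray of rates.
    """
    x = np.asarray(x, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    G = np.atleast_2d(np.asarray(G, dtype=float))
    if np.any(x < 0):
        raise ValueError("negative concentration in power-law rate evaluation")
    if np.any(alpha < 0):
        raise ValueError("negative activity in power-law rate evaluation")
    # x**g with the 0**0 := 1 convention; 0**negative is a genuine domain
    # error surfaced as inf by numpy, handled by the floor in the solvers.
    with np.errstate(divide="ignore"):
        terms = np.where(G == 0.0, 1.0, x[np.newaxis, :] ** G)
    return alpha * np.prod(terms, axis=1)


@dataclass
class GMANetwork:
    """Full GMA model: structure, kinetics, and a basal (healthy) state.

    Attributes
    ----------
    species_names, reaction_names, control_names : lists of identifiers.
    N : (n, r) stoichiometric matrix.
    B : (n, m) connectivity matrix for external controls.
    G : (r, n) kinetic orders.
    alpha_basal : (r,) basal activities, positive.
    u_basal : (m,) basal control values, nonnegative.
    x_basal : (n,) basal concentrations, positive.
    """

    species_names: list[str]
    reaction_names: list[str]
    control_names: list[str]
    N: np.ndarray
    B: np.ndarray
    G: np.ndarray
    alpha_basal: np.ndarray
    u_basal: np.ndarray
    x_basal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.N = np.asarray(self.N, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        self.alpha_basal = np.asarray(self.alpha_basal, dtype=float)
        self.u_basal = np.asarray(self.u_basal, dtype=float)
        self.x_basal = np.asarray(self.x_basal, dtype=float)
        n, r, m = self.n_species, self.n_reactions, self.n_controls
        if self.N.shape != (n, r):
            raise ValueError(f"N has shape {self.N.shape}, expected {(n, r)}")
        if self.B.shape != (n, m):
            raise ValueError(f"B has shape {self.B.shape}, expected {(n, m)}")
        if self.G.shape != (r, n):
            raise ValueError(f"G has shape {self.G.shape}, expected {(r, n)}")
        if self.alpha_basal.shape != (r,):
            raise ValueError("alpha_basal length mismatch")
        if self.u_basal.shape != (m,):
            raise ValueError("u_basal length mismatch")
        if self.x_basal.shape != (n,):
            raise ValueError("x_basal length mismatch")
        if np.any(self.alpha_basal <= 0):
            raise ValueError("basal activities must be positive")
        if np.any(self.x_basal <= 0):
            raise ValueError("basal concentrations must be positive")
        if np.any(self.u_basal < 0):
            raise ValueError("basal controls must be nonnegative")

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_names)

    @property
    def n_controls(self) -> int:
        return len(self.control_names)

    # -- index helpers -------------------------------------------------
    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    def reaction_index(self, name: str) -> int:
        try:
            return self.reaction_names.index(name)
        except ValueError:
            raise KeyError(f"unknown reaction {name!r}") from None

    def control_index(self, name: str) -> int:
        try:
            return self.control_names.index(name)
        except ValueError:
            raise KeyError(f"unknown control {name!r}") from None

    def rates(self, x, alpha=None):
        """Reaction rates at concentrations ``x`` (basal activities by default)."""
        if alpha is None:
            alpha = self.alpha_basal
        return evaluate_rates(x, alpha, self.G)

    def residual(self, x, alpha=None, u=None):
        """Material-balance residual ``N v(x, alpha) + B u``."""
        if alpha is None:
            alpha = self.alpha_basal
        if u is None:
            u = self.u_basal
        return steady_state_residual(self, x, alpha, u)

    def is_consistent(self, tol: float = 1e-8) -> bool:
        """Whether the basal state is a steady state of the model.

        The residual is compared in max-norm against ``tol`` times the flux
        scale (the largest basal rate), so consistency is scale invariant.
        """
        res = self.residual(self.x_basal)
        scale = max(np.max(np.abs(self.rates(self.x_basal))), 1.0)
        return bool(np.max(np.abs(res)) <= tol * scale)


def steady_state_residual(network: GMANetwork, x, alpha, u):
    """One material-balance residual entry per species: ``N v + B u``."""
    v = evaluate_rates(x, alpha, network.G)
    return network.N @ v + network.B @ np.asarray(u, dtype=float)


def log_transform_constraints(network: GMANetwork, y, alpha_hat, u):
    """Evaluate the kinetic model in logarithmic coordinates.

    With ``y = log x`` and ``alpha_hat = log alpha`` the power law becomes
    linear: ``w_j = alpha_hat_j + sum_k g_jk y_k`` and ``v_j = exp(w_j)``.
    This is the transformation under which the model's equality constraints
    define a convex feasible region, and is the parameterisation used by the
    steady-state Newton solver and the inner optimizer.

    Returns
    -------
    (w, v, x, residual) : log-rates, rates, concentrations, and the
    material-balance residual ``N v + B u``.
    """
    y = np.asarray(y, dtype=float)
    alpha_hat = np.asarray(alpha_hat, dtype=float)
    w = alpha_hat + network.G @ y
    w_clipped = np.clip(w, -EXP_CLIP, EXP_CLIP)
    v = np.exp(w_clipped)
    x = np.exp(np.clip(y, -EXP_CLIP, EXP_CLIP))
    residual = network.N @ v + network.B @ np.asarray(u, dtype=float)
    return w, v, x, residual


# ----------------------------------------------------------------------
# model file format: JSON with species / reactions / controls blocks
# ----------------------------------------------------------------------

def network_to_dict(network: GMANetwork) -> dict:
    """Serializable dict in the package model-file convention."""
    species = [
        {"name": s, "basal": float(b)}
        for s, b in zip(network.species_names, network.x_basal)
    ]
    reactions = []
    for k, rname in enumerate(network.reaction_names):
        orders = {
            network.species_names[l]: float(network.G[k, l])
            for l in range(network.n_species)
            if network.G[k, l] != 0.0
        }
        stoich = {
            network.species_names[i]: float(network.N[i, k])
            for i in range(network.n_species)
            if network.N[i, k] != 0.0
        }
        reactions.append(
            {
                "name": rname,
                "alpha": float(network.alpha_basal[k]),
                "orders": orders,
                "stoichiometry": stoich,
            }
        )
    controls = []
    for j, cname in enumerate(network.control_names):
        coeff = {
            network.species_names[i]: float(network.B[i, j])
            for i in range(network.n_species)
            if network.B[i, j] != 0.0
        }
        controls.append({"name": cname, "basal": float(network.u_basal[j]), "B": coeff})
    out = {"species": species, "reactions": reactions, "controls": controls}
    if network.meta:
        out["meta"] = network.meta
    return out


def network_from_dict(d: dict) -> GMANetwork:
    species_names = [s["name"] for s in d["species"]]
    x_basal = np.array([s["basal"] for s in d["species"]], dtype=float)
    reaction_names = [r["name"] for r in d["reactions"]]
    control_names = [c["name"] for c in d.get("controls", [])]
    n, r, m = len(species_names), len(reaction_names), len(control_names)
    sidx = {s: i for i, s in enumerate(species_names)}
    N = np.zeros((n, r))
    G = np.zeros((r, n))
    alpha = np.zeros(r)
    for k, rec in enumerate(d["reactions"]):
        alpha[k] = rec["alpha"]
        for s, g in rec.get("orders", {}).items():
            G[k, sidx[s]] = g
        for s, c in rec.get("stoichiometry", {}).items():
            N[sidx[s], k] = c
    B = np.zeros((n, m))
    u = np.zeros(m)
    for j, rec in enumerate(d.get("controls", [])):
        u[j] = rec["basal"]
        for s, c in rec.get("B", {}).items():
            B[sidx[s], j] = c
    return GMANetwork(
        species_names=species_names,
        reaction_names=reaction_names,
        control_names=control_names,
        N=N,
        B=B,
        G=G,
        alpha_basal=alpha,
        u_basal=u,
        x_basal=x_basal,
        meta=d.get("meta", {}),
    )


def save_network(network: GMANetwork, path) -> None:
    Path(path).write_text(json.dumps(network_to_dict(network), indent=1))


def load_network(path) -> GMANetwork:
    return network_from_dict(json.loads(Path(path).read_text()))


def export_matrices(network: GMANetwork, directory) -> None:
    """Write the N, B and G matrices as TSV files for audit."""
    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        network.N, index=network.species_names, columns=network.reaction_names
    ).to_csv(directory / "N.tsv", sep="\t")
    pd.DataFrame(
        network.B, index=network.species_names, columns=network.control_names
    ).to_csv(directory / "B.tsv", sep="\t")
    pd.DataFrame(
        network.G, index=network.reaction_names, columns=network.species_names
    ).to_csv(directory / "G.tsv", sep="\t")
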