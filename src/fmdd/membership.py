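"""Fuzzy membership functions and the max-min decision objective.

Each design objective is expressed as a fuzzy goal with a membership function
mapping a quantity (a concentration, an activity, a control level) to a
satisfaction grade in [0, 1]:

* **fuzzy-equal** — keep the quantity close to its basal value: grade 1 on a
  plateau around basal, falling to 0 at designer-supplied lower/upper bounds
  (strictly monotone on each side).
* **fuzzy-minimize** — keep the quantity low: grade 1 at or below basal,
  falling monotonically to 0 at the upper bound.

The overall satisfaction grade of a design is the *minimum* grade over all
objectives (the fuzzy intersection), lambda.  The number of regulated targets
enters as a normalised crisp factor (Z_UB - sum z) / (Z_UB - 1) multiplying
lambda, so designs with fewer targets are preferred among equally satisfying
ones.

Five monotone shape families are available (linear, exponential, hyperbolic,
inverse, piecewise-linear); the linear shape is the calibrated default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import GMANetwork

__all__ = [
    "MembershipSpec",
    "ObjectiveSets",
    "GradeReport",
    "fuzzy_equal_grade",
    "fuzzy_min_grade",
    "target_count_factor",
    "grade_design",
    "build_default_memberships",
]


# ----------------------------------------------------------------------
# shape families: strictly increasing maps [0,1] -> [0,1] applied to the
# normalised coordinate t of the rising (or mirrored falling) branch
# ----------------------------------------------------------------------

def _shape_map(t: np.ndarray, shape: str, s: float, points) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    if shape == "linear":
        return t
    if shape == "exponential":
        return (1.0 - np.exp(-s * t)) / (1.0 - np.exp(-s))
    if shape == "hyperbolic":
        h = np.tanh(s / 2.0)
        return (np.tanh(s * (t - 0.5)) + h) / (2.0 * h)
    if shape == "inverse":
        return t / (t + s * (1.0 - t))
    if shape == "piecewise-linear":
        if not points:
            return t
        xs = [0.0] + [p[0] for p in points] + [1.0]
        ys = [0.0] + [p[1] for p in points] + [1.0]
        if any(b <= a for a, b in zip(xs, xs[1:])) or any(
            b <= a for a, b in zip(ys, ys[1:])
        ):
            raise ValueError("piecewise-linear points must be strictly increasing")
        return np.interp(t, xs, ys)
    raise ValueError(f"unknown membership shape {shape!r}")


@dataclass
class MembershipSpec:
    """Breakpoints and shape of one fuzzy objective's membership function.

    For ``kind='equal'`` all four breakpoints are used:
    ``x_lb <= x_basal_lb <= x_basal_ub <= x_ub``, grade 1 on the central
    plateau.  For ``kind='minimize'`` only the plateau end ``x_basal_ub``
    (grade 1 at or below) and ``x_ub`` (grade 0 at or above) matter; ``x_lb``
    and ``x_basal_lb`` are ignored.
    """

    kind: str  # "equal" | "minimize"
    x_lb: float = float("-inf")
    x_basal_lb: float = float("nan")
    x_basal_ub: float = float("nan")
    x_ub: float = float("nan")
    shape: str = "linear"
    shape_param: float = 2.0
    shape_points: tuple = ()
    name: str = ""

    def __post_init__(self):
        if self.kind not in ("equal", "minimize"):
            raise ValueError(f"unknown membership kind {self.kind!r}")
        if self.kind == "equal":
            seq = (self.x_lb, self.x_basal_lb, self.x_basal_ub, self.x_ub)
            if any(np.isnan(seq)):
                raise ValueError("fuzzy-equal spec requires all four breakpoints")
            if not (seq[0] <= seq[1] <= seq[2] <= seq[3]):
                raise ValueError(f"breakpoints out of order: {seq}")
        else:
            if np.isnan(self.x_basal_ub) or np.isnan(self.x_ub):
                raise ValueError("fuzzy-minimize spec requires plateau end and upper bound")
            if not self.x_basal_ub <= self.x_ub:
                raise ValueError("plateau end must not exceed the upper bound")

    def grade(self, value: float) -> float:
        if self.kind == "equal":
            return fuzzy_equal_grade(value, self)
        return fuzzy_min_grade(value, self)

    @classmethod
    def equal_around(cls, basal: float, lb_fold: float = 0.1, ub_fold: float = 10.0,
                     shape: str = "linear", name: str = "") -> "MembershipSpec":
        """Fuzzy-equal with a degenerate plateau at ``basal`` and fold bounds."""
        return cls(
            kind="equal",
            x_lb=lb_fold * basal,
            x_basal_lb=basal,
            x_basal_ub=basal,
            x_ub=ub_fold * basal,
            shape=shape,
            name=name,
        )

    @classmethod
    def minimize_above(cls, basal: float, ub_fold: float = 10.0,
                       shape: str = "linear", name: str = "") -> "MembershipSpec":
        """Fuzzy-minimize with grade 1 at or below ``basal``, 0 at ``ub_fold*basal``."""
        return cls(
            kind="minimize",
            x_basal_ub=basal,
            x_ub=ub_fold * basal,
            shape=shape,
            name=name,
        )


def fuzzy_equal_grade(value: float, spec: MembershipSpec) -> float:
    """Unimodal satisfaction grade: 1 on the basal plateau, 0 outside bounds.

    The rising left branch and falling right branch are strictly monotone
    under every shape family.
    """
    if spec.kind != "equal":
        raise ValueError("spec is not a fuzzy-equal membership")
    v = float(value)
    if v <= spec.x_lb or v >= spec.x_ub:
        # boundary values grade 0 except when the boundary touches the plateau
        if spec.x_basal_lb <= v <= spec.x_basal_ub:
            return 1.0
        return 0.0
    if spec.x_basal_lb <= v <= spec.x_basal_ub:
        return 1.0
    if v < spec.x_basal_lb:
        t = (v - spec.x_lb) / (spec.x_basal_lb - spec.x_lb)
    else:
        t = (spec.x_ub - v) / (spec.x_ub - spec.x_basal_ub)
    return float(_shape_map(np.asarray(t), spec.shape, spec.shape_param, spec.shape_points))


def fuzzy_min_grade(value: float, spec: MembershipSpec) -> float:
    """Monotone non-increasing grade: 1 at or below basal, 0 at or above x_ub."""
    if spec.kind != "minimize":
        raise ValueError("spec is not a fuzzy-minimize membership")
    v = float(value)
    if v <= spec.x_basal_ub:
        return 1.0
    if v >= spec.x_ub:
        return 0.0
    t = (spec.x_ub - v) / (spec.x_ub - spec.x_basal_ub)
    return float(_shape_map(np.asarray(t), spec.shape, spec.shape_param, spec.shape_points))


def target_count_factor(n_targets: int, z_ub: int) -> float:
    """Normalised crisp penalty on the number of regulated targets.

    ``(Z_UB - sum z) / (Z_UB - 1)``: equals 1 for a single target and
    decreases linearly as targets are added.
    """
    if z_ub < 2:
        raise ValueError("Z_UB must be at least 2")
    if n_targets > z_ub:
        raise ValueError(f"{n_targets} targets exceed the upper bound Z_UB={z_ub}")
    return (z_ub - n_targets) / (z_ub - 1)


@dataclass
class ObjectiveSets:
    """Index sets of the multiobjective design problem.

    ``te`` — therapeutic species (fuzzy-equal to basal);
    ``ae`` — adverse species (fuzzy-minimize);
    ``ve_activities`` — regulable enzyme activities (fuzzy-equal to basal);
    ``ve_controls_equal`` / ``ve_controls_min`` — external controls graded
    fuzzy-equal or fuzzy-minimize (the split is designer configuration);
    ``ds`` — disease reactions, excluded from the regulable set;
    ``z_ub`` — upper bound on the number of regulated targets.
    """

    te: list[str] = field(default_factory=list)
    ae: list[str] = field(default_factory=list)
    ve_activities: list[str] = field(default_factory=list)
    ve_controls_equal: list[str] = field(default_factory=list)
    ve_controls_min: list[str] = field(default_factory=list)
    ds: list[str] = field(default_factory=list)
    z_ub: int = 10

    def __post_init__(self):
        if self.z_ub < 2:
            raise ValueError("Z_UB must be at least 2")
        clash = set(self.ds) & set(self.ve_activities)
        if clash:
            raise ValueError(
                f"disease reactions cannot be variation-effect targets: {sorted(clash)}"
            )

    @property
    def regulable_targets(self) -> list[str]:
        """All decision handles: regulable activities then controls."""
        return (
            list(self.ve_activities)
            + list(self.ve_controls_equal)
            + list(self.ve_controls_min)
        )


@dataclass
class GradeReport:
    """Per-objective satisfaction grades and the aggregated objective."""

    te_grades: dict[str, float]
    ae_grades: dict[str, float]
    ve_grades: dict[str, float]
    count_factor: float
    n_targets: int

    @property
    def T(self) -> float:
        return min(self.te_grades.values(), default=1.0)

    @property
    def A(self) -> float:
        return min(self.ae_grades.values(), default=1.0)

    @property
    def V(self) -> float:
        return min(self.ve_grades.values(), default=1.0)

    @property
    def lam(self) -> float:
        return min(self.T, self.A, self.V)

    @property
    def overall(self) -> float:
        return self.count_factor * self.lam

    def as_dict(self) -> dict:
        return {
            "T": self.T,
            "A": self.A,
            "V": self.V,
            "lambda": self.lam,
            "count_factor": self.count_factor,
            "n_targets": self.n_targets,
            "overall": self.overall,
            "te_grades": self.te_grades,
            "ae_grades": self.ae_grades,
            "ve_grades": self.ve_grades,
        }


def build_default_memberships(
    network: GMANetwork,
    sets: ObjectiveSets,
    *,
    te_lb_fold: float = 0.1,
    te_ub_fold: float = 10.0,
    ae_ub_fold: float = 10.0,
    ve_lb_fold: float = 0.1,
    ve_ub_fold: float = 10.0,
    overrides: dict[str, MembershipSpec] | None = None,
) -> dict[str, MembershipSpec]:
    """Default membership specs for every objective member.

    Therapeutic species get a fuzzy-equal membership with a degenerate plateau
    at basal and fold bounds [0.1, 10]; adverse species a fuzzy-minimize with
    grade 0 at 10x basal; variation-effect activities/controls a fuzzy-equal
    on their basal level with the same fold bounds (fuzzy-minimize for
    controls designated so).  These fold bounds are a calibration choice;
    every spec can be overridden per objective.
    """
    specs: dict[str, MembershipSpec] = {}
    for s in sets.te:
        basal = network.x_basal[network.species_index(s)]
        specs[s] = MembershipSpec.equal_around(
            basal, lb_fold=te_lb_fold, ub_fold=te_ub_fold, name=s
        )
    for s in sets.ae:
        basal = network.x_basal[network.species_index(s)]
        specs[s] = MembershipSpec.minimize_above(basal, ub_fold=ae_ub_fold, name=s)
    for r in sets.ve_activities:
        basal = network.alpha_basal[network.reaction_index(r)]
        specs[r] = MembershipSpec.equal_around(
            basal, lb_fold=ve_lb_fold, ub_fold=ve_ub_fold, name=r
        )
    for c in sets.ve_controls_equal:
        basal = network.u_basal[network.control_index(c)]
        if basal <= 0:
            # zero-basal control: grade on absolute level, plateau at 0
            specs[c] = MembershipSpec(
                kind="equal", x_lb=-1.0, x_basal_lb=0.0, x_basal_ub=0.0, x_ub=1.0, name=c
            )
        else:
            specs[c] = MembershipSpec.equal_around(
                basal, lb_fold=ve_lb_fold, ub_fold=ve_ub_fold, name=c
            )
    for c in sets.ve_controls_min:
        basal = network.u_basal[network.control_index(c)]
        scale = basal if basal > 0 else 1.0
        specs[c] = MembershipSpec.minimize_above(basal, ub_fold=ve_ub_fold, name=c)
        if basal <= 0:
            specs[c] = MembershipSpec(
                kind="minimize", x_basal_ub=0.0, x_ub=10.0 * scale, name=c
            )
    if overrides:
        specs.update(overrides)
    return specs


def grade_design(
    state,
    network: GMANetwork,
    sets: ObjectiveSets,
    specs: dict[str, MembershipSpec],
    *,
    alpha: np.ndarray | None = None,
    u: np.ndarray | None = None,
    n_targets: int = 0,
) -> GradeReport:
    """Grade a steady state plus its regulated activities/controls.

    Therapeutic and adverse grades are evaluated on steady-state
    concentrations; variation grades on the regulated activity and control
    levels (untouched handles sit on their basal plateau and grade 1).  The
    minimum grade is lambda; the overall objective multiplies lambda by the
    target-count factor.
    """
    if alpha is None:
        alpha = network.alpha_basal
    if u is None:
        u = network.u_basal

    def _spec(name):
        try:
            return specs[name]
        except KeyError:
            raise KeyError(f"no membership spec for objective member {name!r}") from None

    te = {s: _spec(s).grade(state.x[network.species_index(s)]) for s in sets.te}
    ae = {s: _spec(s).grade(state.x[network.species_index(s)]) for s in sets.ae}
    ve: dict[str, float] = {}
    for r in sets.ve_activities:
        ve[r] = _spec(r).grade(alpha[network.reaction_index(r)])
    for c in sets.ve_controls_equal + sets.ve_controls_min:
        ve[c] = _spec(c).grade(u[network.control_index(c)])
    return GradeReport(
        te_grades=te,
        ae_grades=ae,
        ve_grades=ve,
        count_factor=target_count_factor(max(n_targets, 1), sets.z_ub),
        n_targets=n_targets,
    )


def membership_specs_from_records(records, network: GMANetwork | None = None):
    """Build membership specs from a list of plain records (JSON/YAML).

    Each record: ``{name, kind, shape?, breakpoints}`` where breakpoints are
    either absolute ``[x_lb, x_basal_lb, x_basal_ub, x_ub]`` (``[plateau,
    upper]`` for minimize) or folds of the named quantity's basal value when
    ``fold: true`` and a network is given.
    """
    specs: dict[str, MembershipSpec] = {}
    for rec in records:
        name, kind = rec["name"], rec["kind"]
        bp = [float(b) for b in rec["breakpoints"]]
        if rec.get("fold"):
            if network is None:
                raise ValueError("fold breakpoints require a network")
            if name in network.species_names:
                basal = network.x_basal[network.species_index(name)]
            elif name in network.reaction_names:
                basal = network.alpha_basal[network.reaction_index(name)]
            else:
                basal = network.u_basal[network.control_index(name)]
            bp = [b * basal for b in bp]
        shape = rec.get("shape", "linear")
        if kind == "equal":
            if len(bp) != 4:
                raise ValueError(f"{name}: fuzzy-equal needs 4 breakpoints")
            specs[name] = MembershipSpec(
                kind="equal", x_lb=bp[0], x_basal_lb=bp[1], x_basal_ub=bp[2],
                x_ub=bp[3], shape=shape, name=name,
            )
        else:
            if len(bp) != 2:
                raise ValueError(f"{name}: fuzzy-minimize needs 2 breakpoints")
            specs[name] = MembershipSpec(
                kind="minimize", x_basal_ub=bp[0], x_ub=bp[1], shape=shape,
                name=name,
            )
    return specs


def load_membership_specs(path, network: GMANetwork | None = None):
    """Load membership overrides from a JSON or YAML file."""
    import json
    from pathlib import Path

    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        records = yaml.safe_load(text)
    else:
        records = json.loads(text)
    return membership_specs_from_records(records, network)
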