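"""Property-class binding model for anti-peptide antibodies.

An antibody raised against a linear consensus epitope tolerates
substitutions in a species' epitope according to how much the replacement
residue changes side-chain chemistry: an identical residue costs nothing,
a replacement within the same physicochemical class (e.g. Lys->Arg, both
polar basic) costs little, a cross-class replacement (e.g. Ala->Arg,
nonpolar -> polar basic) costs a lot, and an indel in a linear epitope is
worst of all.  Core positions weigh more than flank positions.  The
antibody is predicted to bind when the weighted penalty sum stays at or
below a threshold.

Scores are dimensionless; the model quantifies a qualitative structural
argument, it is not an affinity predictor.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .panel import GAP
from .regions import EpitopeWindow

NONPOLAR = "nonpolar"
POLAR_UNCHARGED = "polar_uncharged"
POLAR_BASIC = "polar_basic"
POLAR_ACIDIC = "polar_acidic"

#: Fixed residue -> side-chain property class map.  Histidine sits with the
#: polar basic residues by standard convention.
PROPERTY_CLASSES: Mapping[str, str] = {
    **{aa: NONPOLAR for aa in "GAVLIMFWP"},
    **{aa: POLAR_UNCHARGED for aa in "STCYNQ"},
    **{aa: POLAR_BASIC for aa in "KRH"},
    **{aa: POLAR_ACIDIC for aa in "DE"},
}


def class_of(residue: str) -> str:
    """Side-chain property class of a standard residue."""
    try:
        return PROPERTY_CLASSES[residue]
    except KeyError:
        raise ValueError(f"nonstandard residue {residue!r}") from None


@dataclass(frozen=True)
class BindingModelParams:
    """Penalties, weights, and threshold of the binding model.

    Defaults make the documented reference behavior hold: a single
    same-class core substitution (penalty 1) binds, while one cross-class
    plus two same-class core substitutions (penalty 5) does not, and two
    cross-class flank substitutions (0.5 * 6 = 3) alone are enough to
    abolish binding.
    """

    penalty_identity: float = 0.0
    penalty_same_class: float = 1.0
    penalty_cross_class: float = 3.0
    penalty_gap: float = 4.0
    core_weight: float = 1.0
    flank_weight: float = 0.5
    binding_threshold: float = 2.5

    def __post_init__(self) -> None:
        if not (
            0.0
            <= self.penalty_identity
            <= self.penalty_same_class
            <= self.penalty_cross_class
            <= self.penalty_gap
        ):
            raise ValueError(
                "penalties must satisfy 0 <= identity <= same_class <= cross_class <= gap"
            )
        if self.core_weight <= 0 or self.flank_weight < 0:
            raise ValueError("core_weight must be > 0 and flank_weight >= 0")
        if self.binding_threshold < 0:
            raise ValueError("binding_threshold must be nonnegative")


@dataclass(frozen=True)
class BindingScore:
    """Weighted mismatch penalty of a species window against an epitope."""

    core_penalty: float
    flank_penalty: float
    total: float
    binds: bool


def substitution_penalty(a: str, b: str, params: BindingModelParams) -> float:
    """Penalty for one aligned column (residues or '-'); symmetric in a, b."""
    if a == GAP or b == GAP:
        return params.penalty_gap
    class_a = class_of(a)
    class_b = class_of(b)
    if a == b:
        return params.penalty_identity
    if class_a == class_b:
        return params.penalty_same_class
    return params.penalty_cross_class


def binding_score(
    epitope_consensus: EpitopeWindow,
    species_window: EpitopeWindow,
    params: BindingModelParams,
) -> BindingScore:
    """Score a species window against the consensus epitope the antibody saw.

    Core penalty sums over core columns, flank penalty over both flanks;
    total = core_weight * core + flank_weight * flank, and the antibody
    binds when total <= binding_threshold.
    """
    e, w = epitope_consensus, species_window
    if e.region.index != w.region.index:
        raise ValueError(
            f"windows come from different regions ({e.region.index} vs {w.region.index})"
        )
    if len(e.core_residues) != len(w.core_residues) or len(e.left_flank) != len(
        w.left_flank
    ) or len(e.right_flank) != len(w.right_flank):
        raise ValueError("epitope and species windows must have equal core/flank lengths")

    core = sum(
        substitution_penalty(x, y, params)
        for x, y in zip(e.core_residues, w.core_residues)
    )
    flank = sum(
        substitution_penalty(x, y, params)
        for x, y in zip(e.left_flank + e.right_flank, w.left_flank + w.right_flank)
    )
    total = params.core_weight * core + params.flank_weight * flank
    return BindingScore(
        core_penalty=core,
        flank_penalty=flank,
        total=total,
        binds=total <= params.binding_threshold,
    )


# ---------------------------------------------------------------------------
# Calibration against an observed reactivity profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BindingConstraint:
    """One observed reactivity fact: this window must (not) bind this epitope."""

    epitope: EpitopeWindow
    species_window: EpitopeWindow
    must_bind: bool
    label: str = ""


#: Deterministic default search grid, iterated in field order
#: (same_class, cross_class, gap, core_weight, flank_weight, threshold),
#: rightmost field fastest (itertools.product order).
DEFAULT_PARAM_GRID: Mapping[str, Sequence[float]] = {
    "penalty_same_class": (0.5, 1.0, 2.0),
    "penalty_cross_class": (2.0, 3.0, 4.0),
    "penalty_gap": (4.0, 6.0),
    "core_weight": (1.0,),
    "flank_weight": (0.0, 0.5, 1.0),
    "binding_threshold": (1.5, 2.0, 2.5, 3.0),
}

_GRID_FIELDS = (
    "penalty_same_class",
    "penalty_cross_class",
    "penalty_gap",
    "core_weight",
    "flank_weight",
    "binding_threshold",
)


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of a grid calibration.

    When infeasible, ``violated`` lists the constraint labels unsatisfied
    at the best grid point (the one violating fewest constraints).
    """

    feasible: bool
    params: BindingModelParams | None
    n_evaluated: int
    violated: tuple[str, ...] = ()


def _constraint_label(c: BindingConstraint, i: int) -> str:
    if c.label:
        return c.label
    want = "bind" if c.must_bind else "not-bind"
    return f"constraint[{i}] {c.species_window.source_id} {want} region {c.epitope.region.index}"


def calibrate_params(
    constraints: Iterable[BindingConstraint],
    search_grid: Mapping[str, Sequence[float]] | None = None,
) -> CalibrationResult:
    """First grid point (deterministic grid order) satisfying all constraints.

    Grid points violating the parameter invariants are skipped.  An
    infeasible grid is reported, not raised.
    """
    constraints = tuple(constraints)
    if not constraints:
        raise ValueError("calibrate_params needs at least one constraint")
    grid = dict(DEFAULT_PARAM_GRID)
    if search_grid:
        grid.update(search_grid)

    n_evaluated = 0
    best_violations: tuple[str, ...] | None = None
    for values in itertools.product(*(grid[f] for f in _GRID_FIELDS)):
        kwargs = dict(zip(_GRID_FIELDS, values))
        try:
            params = BindingModelParams(**kwargs)
        except ValueError:
            continue
        n_evaluated += 1
        violated = tuple(
            _constraint_label(c, i)
            for i, c in enumerate(constraints)
            if binding_score(c.epitope, c.species_window, params).binds != c.must_bind
        )
        if not violated:
            return CalibrationResult(feasible=True, params=params, n_evaluated=n_evaluated)
        if best_violations is None or len(violated) < len(best_violations):
            best_violations = violated
    return CalibrationResult(
        feasible=False,
        params=None,
        n_evaluated=n_evaluated,
        violated=best_violations or (),
    )


# ---------------------------------------------------------------------------
# Parameter file I/O
# ---------------------------------------------------------------------------

def params_to_file(params: BindingModelParams, path) -> None:
    data = {
        "penalty_identity": params.penalty_identity,
        "penalty_same_class": params.penalty_same_class,
        "penalty_cross_class": params.penalty_cross_class,
        "penalty_gap": params.penalty_gap,
        "core_weight": params.core_weight,
        "flank_weight": params.flank_weight,
        "binding_threshold": params.binding_threshold,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def params_from_file(path) -> BindingModelParams:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"parameter file {path} must contain a mapping")
    return BindingModelParams(**data)
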