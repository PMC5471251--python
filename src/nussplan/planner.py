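"""Operative-plan enumeration, evaluation and selection.

A candidate plan is (intercostal space, sternal elevation).  Each plan is
simulated, the post-operative Haller index is measured at the four standard
cross sections, and the plan passes only if every section reaches the
corrective criterion (H <= 2.68, the mean post-operative index of a large
clinical series) without hypercorrecting any section beyond the patient's
healthy reference profile.  Among the surviving plans the one with the
lowest maximum equivalent stress is selected.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

from . import fem, haller
from .errors import NoFeasiblePlanError, ParameterError
from .geometry import (SECTION_LABELS, SPACE_TO_SECTION, ThoraxModel,
                       extract_cross_section)

#: elevation grid explored per intercostal space, mm
DEFAULT_ELEVATIONS = (15.0, 20.0, 25.0, 30.0, 35.0)
#: candidate intercostal spaces
DEFAULT_SPACES = (2, 3, 4, 5)


@dataclass(frozen=True, order=True)
class OperativePlan:
    """One candidate bar placement."""

    space: int
    elevation: float


@dataclass(frozen=True)
class Criterion:
    """Plan-acceptance thresholds."""

    haller_threshold: float = 2.68  # corrective Haller index, inclusive
    hyper_tolerance: float = 2.0  # mm beyond the reference B that counts
    #                               as hypercorrection

    def __post_init__(self):
        if self.haller_threshold <= 1.0:
            raise ParameterError("haller_threshold must exceed 1")


@dataclass
class PlanEvaluation:
    """Everything measured for one candidate plan."""

    plan: OperativePlan
    haller_post: dict[str, float]
    meets_criterion: bool
    hypercorrected: bool
    max_stress: float  # Pa

    @property
    def feasible(self) -> bool:
        return self.meets_criterion and not self.hypercorrected

    def rejection_reason(self, criterion: Criterion) -> str | None:
        if self.feasible:
            return None
        reasons = []
        if not self.meets_criterion:
            worst = max(self.haller_post.items(), key=lambda kv: kv[1])
            reasons.append(f"Haller {worst[1]:.3f} at section {worst[0]} "
                           f"> {criterion.haller_threshold}")
        if self.hypercorrected:
            reasons.append("hypercorrection beyond the reference profile")
        return "; ".join(reasons)


def enumerate_plans(spaces=DEFAULT_SPACES,
                    elevations=DEFAULT_ELEVATIONS) -> list[OperativePlan]:
    """Cartesian product of spaces and elevations, deterministically ordered
    (space ascending, then elevation ascending)."""
    if not spaces or not elevations:
        raise ParameterError("spaces and elevations must be non-empty")
    return [OperativePlan(s, float(e))
            for s, e in product(sorted(spaces), sorted(elevations))]


def meets_haller_criterion(haller_post: dict[str, float] | list[float],
                           threshold: float = 2.68) -> bool:
    """True iff every section index is at or below the threshold."""
    values = (list(haller_post.values())
              if isinstance(haller_post, dict) else list(haller_post))
    return max(values) <= threshold


def detect_hypercorrection(deformed: ThoraxModel, reference: ThoraxModel,
                           tolerance: float = 2.0) -> bool:
    """True iff any section's anteroposterior distance exceeds the healthy
    reference's by more than ``tolerance`` mm."""
    for level in deformed.section_levels:
        if level not in reference.section_levels:
            raise KeyError(f"reference has no section {level!r}")
        b_def = haller.anteroposterior_distance(
            extract_cross_section(deformed, level))
        b_ref = haller.anteroposterior_distance(
            extract_cross_section(reference, level))
        if b_def > b_ref + tolerance:
            return True
    return False


def evaluate_plan(thorax: ThoraxModel, plan: OperativePlan,
                  criterion: Criterion, reference: ThoraxModel,
                  section_props=None, materials=None) -> PlanEvaluation:
    """Simulate one plan and measure its outcome.

    Runs the elevation simulation, extracts the four deformed cross
    sections, and records per-section Haller indices, the criterion and
    hypercorrection flags, and the maximum equivalent stress.
    """
    try:
        deformed, result = fem.simulate_elevation(
            thorax, plan.space, plan.elevation,
            section_props=section_props, materials=materials)
        haller_post = {}
        for level in SECTION_LABELS:
            if level not in deformed.section_levels:
                continue
            m = haller.measure(extract_cross_section(deformed, level))
            haller_post[level] = m.H
        return PlanEvaluation(
            plan=plan,
            haller_post=haller_post,
            meets_criterion=meets_haller_criterion(
                haller_post, criterion.haller_threshold),
            hypercorrected=detect_hypercorrection(
                deformed, reference, criterion.hyper_tolerance),
            max_stress=result.max_equivalent_stress,
        )
    except Exception as exc:
        exc.add_note(f"while evaluating plan space={plan.space}, "
                     f"elevation={plan.elevation} mm")
        raise


def select_plan(evaluations: list[PlanEvaluation],
                criterion: Criterion = Criterion()) -> OperativePlan:
    """Select the optimal plan.

    Filter to plans that meet the Haller criterion and are not
    hypercorrected; among survivors return the minimum maximum-stress plan,
    breaking ties by lower elevation, then lower space.  The result is
    independent of the order of ``evaluations``.
    """
    if not evaluations:
        raise ParameterError("no evaluations given")
    survivors = [e for e in evaluations if e.feasible]
    if not survivors:
        failures = {(e.plan.space, e.plan.elevation):
                    e.rejection_reason(criterion) for e in evaluations}
        lines = "; ".join(
            f"space {s}/{int(el)} mm: {why}"
            for (s, el), why in sorted(failures.items()))
        raise NoFeasiblePlanError(
            f"no operative plan passes both gates ({lines})", failures)
    best = min(survivors,
               key=lambda e: (e.max_stress, e.plan.elevation, e.plan.space))
    return best.plan
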