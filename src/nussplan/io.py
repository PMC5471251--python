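"""File formats, run configuration, and the end-to-end pipeline.

Interchange formats are deliberately lowest-common-denominator: JSON for
thorax models and planning reports, CSV for contours, YAML for solver/plan
configuration, and legacy-ASCII VTK for mesh visualization.  Reading is
fail-loud: malformed rows are reported with line numbers and nothing is
silently defaulted.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import barshape, fem, haller, planner
from .errors import FormatError, ParameterError
from .geometry import (SECTION_LABELS, SPACE_TO_SECTION, CrossSectionContour,
                       Segment, ThoraxModel, anterior_boundary,
                       extract_cross_section)

log = logging.getLogger("nussplan")

_LANDMARKS = {"": None, "vertebra_anterior": "vertebra",
              "sternum_posterior": "sternum"}


# ---------------------------------------------------------------------------
# thorax model JSON
# ---------------------------------------------------------------------------

def thorax_to_dict(model: ThoraxModel) -> dict:
    return {
        "nodes": model.nodes.tolist(),
        "segments": [s.as_tuple() for s in model.segments],
        "spine_nodes": list(model.spine_nodes),
        "sternum_nodes": list(model.sternum_nodes),
        "intercostal_anchor": {str(k): v
                               for k, v in model.intercostal_anchor.items()},
        "section_levels": dict(model.section_levels),
        "rib_rings": [list(r) for r in model.rib_rings],
        "meta": model.meta,
    }


def thorax_from_dict(d: dict) -> ThoraxModel:
    try:
        return ThoraxModel(
            nodes=np.asarray(d["nodes"], dtype=float),
            segments=[Segment(*s) for s in d["segments"]],
            spine_nodes=list(d["spine_nodes"]),
            sternum_nodes=list(d["sternum_nodes"]),
            intercostal_anchor={int(k): v
                                for k, v in d["intercostal_anchor"].items()},
            section_levels={k: float(v)
                            for k, v in d["section_levels"].items()},
            rib_rings=[list(r) for r in d["rib_rings"]],
            meta=d.get("meta", {}),
        )
    except (KeyError, TypeError) as exc:
        raise FormatError(f"malformed thorax model: {exc}") from exc


def save_thorax(model: ThoraxModel, path) -> None:
    Path(path).write_text(json.dumps(thorax_to_dict(model), indent=1))


def load_thorax(path) -> ThoraxModel:
    try:
        return thorax_from_dict(json.loads(Path(path).read_text()))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc


# ---------------------------------------------------------------------------
# contour CSV
# ---------------------------------------------------------------------------

CONTOUR_HEADER = ["level", "x_mm", "y_mm", "landmark"]


def write_contours(contours, path) -> None:
    """Write contours as CSV with header ``level,x_mm,y_mm,landmark``."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CONTOUR_HEADER)
        for c in contours:
            for i, (x, y) in enumerate(c.points):
                mark = ""
                if i == c.vertebra_anterior_idx:
                    mark = "vertebra_anterior"
                elif i == c.sternum_posterior_idx:
                    mark = "sternum_posterior"
                w.writerow([c.level, repr(float(x)), repr(float(y)), mark])


def read_contours(path) -> list[CrossSectionContour]:
    """Read contours grouped by level; malformed rows fail with their line
    number, a missing landmark or unknown level label is an error."""
    groups: dict[str, dict] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty contour file") from None
        if [h.strip() for h in header] != CONTOUR_HEADER:
            raise FormatError(f"{path}: bad header {header!r}; expected "
                              f"{','.join(CONTOUR_HEADER)}")
        for ln, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise FormatError(f"{path}:{ln}: expected 4 fields, "
                                  f"got {len(row)}")
            level, xs, ys, mark = (f.strip() for f in row)
            if level not in SECTION_LABELS:
                raise FormatError(f"{path}:{ln}: unknown level label "
                                  f"{level!r} (expected one of "
                                  f"{', '.join(SECTION_LABELS)})")
            if mark not in _LANDMARKS:
                raise FormatError(f"{path}:{ln}: unknown landmark {mark!r}")
            try:
                x, y = float(xs), float(ys)
            except ValueError:
                raise FormatError(
                    f"{path}:{ln}: non-numeric coordinate") from None
            g = groups.setdefault(level, {"pts": [], "vert": None,
                                          "stern": None})
            if level not in order:
                order.append(level)
            idx = len(g["pts"])
            g["pts"].append((x, y))
            if _LANDMARKS[mark] == "vertebra":
                g["vert"] = idx
            elif _LANDMARKS[mark] == "sternum":
                g["stern"] = idx
    if not groups:
        raise FormatError(f"{path}: contour file has a header but no rows")
    out = []
    for level in order:
        g = groups[level]
        if g["vert"] is None or g["stern"] is None:
            raise FormatError(f"{path}: level {level!r} is missing a "
                              f"landmark row")
        out.append(CrossSectionContour(
            level=level, points=np.array(g["pts"]),
            vertebra_anterior_idx=g["vert"],
            sternum_posterior_idx=g["stern"]))
    return out


# ---------------------------------------------------------------------------
# VTK legacy ASCII export
# ---------------------------------------------------------------------------

def write_vtk(path, nodes: np.ndarray, lines: list[tuple[int, int]],
              point_vectors: np.ndarray | None = None,
              cell_scalars: np.ndarray | None = None,
              vector_name: str = "displacement",
              scalar_name: str = "equivalent_stress") -> None:
    """Write a line mesh as legacy-ASCII VTK with optional nodal vectors
    (e.g. displacements) and per-cell scalars (e.g. stresses)."""
    nodes = np.asarray(nodes, dtype=float)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nnussplan frame mesh\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(nodes)} double\n")
        for p in nodes:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        fh.write(f"LINES {len(lines)} {3 * len(lines)}\n")
        for i, j in lines:
            fh.write(f"2 {i} {j}\n")
        if point_vectors is not None:
            fh.write(f"POINT_DATA {len(nodes)}\n")
            fh.write(f"VECTORS {vector_name} double\n")
            for v in np.asarray(point_vectors, dtype=float):
                fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        if cell_scalars is not None:
            fh.write(f"CELL_DATA {len(lines)}\n")
            fh.write(f"SCALARS {scalar_name} double 1\nLOOKUP_TABLE default\n")
            for s in np.asarray(cell_scalars, dtype=float):
                fh.write(f"{s:.9g}\n")


def export_thorax_vtk(model: ThoraxModel, path,
                      result: "fem.SolveResult | None" = None) -> None:
    lines = [(s.i, s.j) for s in model.segments]
    write_vtk(path, model.nodes, lines,
              point_vectors=None if result is None else result.displacements,
              cell_scalars=None if result is None else result.element_stress)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything a planning run needs besides the two thorax models."""

    spaces: tuple = planner.DEFAULT_SPACES
    elevations: tuple = planner.DEFAULT_ELEVATIONS
    criterion: planner.Criterion = field(default_factory=planner.Criterion)
    section_radii: dict = field(default_factory=lambda: {
        "rib": 5.0, "cartilage": 5.0, "sternum": 9.0, "spine": 15.0})
    materials: dict = field(default_factory=lambda: dict(
        fem.DEFAULT_MATERIALS))
    catalogue: tuple = barshape.DEFAULT_CATALOGUE
    span_fraction: float = 0.9  # bar span as a fraction of the boundary chord
    seed: int = 0

    def __post_init__(self):
        if not self.spaces or not self.elevations:
            raise ParameterError("spaces and elevations must be non-empty")
        if not self.catalogue:
            raise ParameterError("catalogue must be non-empty")
        for key in ("rib", "cartilage", "sternum", "spine"):
            if key not in self.section_radii:
                raise ParameterError(f"section_radii missing {key!r}")
        for tissue in ("bone", "cartilage"):
            if tissue not in self.materials:
                raise ParameterError(f"materials missing {tissue!r}")

    @property
    def section_props(self) -> dict[str, fem.SectionProperties]:
        return {k: fem.SectionProperties.circular(r)
                for k, r in self.section_radii.items()}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise FormatError(f"{path}: config must be a mapping")
        kw: dict = {}
        if "spaces" in raw:
            kw["spaces"] = tuple(int(s) for s in raw["spaces"])
        if "elevations" in raw:
            kw["elevations"] = tuple(float(e) for e in raw["elevations"])
        if "criterion" in raw:
            kw["criterion"] = planner.Criterion(**raw["criterion"])
        if "section_radii" in raw:
            base = {"rib": 5.0, "cartilage": 5.0, "sternum": 9.0,
                    "spine": 15.0}
            base.update({k: float(v) for k, v in raw["section_radii"].items()})
            kw["section_radii"] = base
        if "materials" in raw:
            mats = dict(fem.DEFAULT_MATERIALS)
            for name, m in raw["materials"].items():
                mats[name] = fem.Material(
                    name=m.get("name", name), density=float(m["density"]),
                    youngs_modulus=float(m["youngs_modulus"]),
                    poisson_ratio=float(m["poisson_ratio"]))
            kw["materials"] = mats
        if "catalogue" in raw:
            kw["catalogue"] = tuple(float(c) for c in raw["catalogue"])
        if "span_fraction" in raw:
            kw["span_fraction"] = float(raw["span_fraction"])
        if "seed" in raw:
            kw["seed"] = int(raw["seed"])
        unknown = set(raw) - {"spaces", "elevations", "criterion",
                              "section_radii", "materials", "catalogue",
                              "span_fraction", "seed"}
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**kw)

    def digest(self) -> str:
        """Stable hash of the configuration, for run logs and reports."""
        blob = json.dumps({
            "spaces": list(self.spaces),
            "elevations": list(self.elevations),
            "criterion": [self.criterion.haller_threshold,
                          self.criterion.hyper_tolerance],
            "section_radii": dict(sorted(self.section_radii.items())),
            "materials": {k: [m.density, m.youngs_modulus, m.poisson_ratio]
                          for k, m in sorted(self.materials.items())},
            "catalogue": list(self.catalogue),
            "span_fraction": self.span_fraction,
            "seed": self.seed,
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# the end-to-end pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, pex_thorax: ThoraxModel,
                 reference: ThoraxModel) -> dict:
    """Evaluate every plan, select the optimum, and design the bar.

    Returns a JSON-serializable report: the decision trace of every
    candidate plan, the selected plan, the orthopedic distance it realizes
    at its anchor section, and the designed (and catalogue-rounded) bar
    curve.
    """
    log.info("pipeline start: config %s, seed %d", config.digest(),
             config.seed)
    plans = planner.enumerate_plans(config.spaces, config.elevations)
    evaluations = []
    for plan in plans:
        ev = planner.evaluate_plan(
            pex_thorax, plan, config.criterion, reference,
            section_props=config.section_props, materials=config.materials)
        log.info("plan space %d / %.0f mm: H=%s meets=%s hyper=%s "
                 "stress=%.3g Pa", plan.space, plan.elevation,
                 {k: round(v, 3) for k, v in ev.haller_post.items()},
                 ev.meets_criterion, ev.hypercorrected, ev.max_stress)
        evaluations.append(ev)
    selected = planner.select_plan(evaluations, config.criterion)
    log.info("selected plan: space %d, elevation %.0f mm",
             selected.space, selected.elevation)

    deformed, result = fem.simulate_elevation(
        pex_thorax, selected.space, selected.elevation,
        section_props=config.section_props, materials=config.materials)
    section = SPACE_TO_SECTION[selected.space]
    b_pre = haller.anteroposterior_distance(
        extract_cross_section(pex_thorax, section))
    b_post = haller.anteroposterior_distance(
        extract_cross_section(deformed, section))
    delta = haller.orthopedic_distance(b_pre, b_post)

    boundary = anterior_boundary(extract_cross_section(reference, section))
    chord = float(np.linalg.norm(boundary[-1] - boundary[0]))
    span = config.span_fraction * chord
    bar = barshape.design_bar_curve(boundary, delta=max(delta, 0.0),
                                    span=span)
    bar = barshape.round_to_standard_length(bar, config.catalogue)
    log.info("bar: span %.1f mm -> standard %.1f mm, apex %.1f mm, "
             "min curvature %.2e 1/mm", span, bar.standard_length,
             bar.apex_height, bar.min_curvature())

    return {
        "config": config.digest(),
        "seed": config.seed,
        "plans": [{
            "space": e.plan.space,
            "elevation_mm": e.plan.elevation,
            "haller_post": {k: round(v, 4)
                            for k, v in e.haller_post.items()},
            "meets_criterion": e.meets_criterion,
            "hypercorrected": e.hypercorrected,
            "max_stress_pa": e.max_stress,
            "rejected_because": e.rejection_reason(config.criterion),
        } for e in evaluations],
        "selected": {"space": selected.space,
                     "elevation_mm": selected.elevation},
        "orthopedic_distance_mm": delta,
        "bar": {
            "control_points_mm": bar.control_points.tolist(),
            "span_mm": bar.span,
            "standard_length_mm": bar.standard_length,
            "apex_height_mm": bar.apex_height,
            "min_curvature_per_mm": bar.min_curvature(),
        },
    }
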