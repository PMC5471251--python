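"""Bundled clinical case-study measurements.

A published worked example used as fixture data throughout the package:
twelve pre-/post-operative transverse-diameter pairs from Nuss patients
(the source of the ~95% shrinkage-rate prior), and the complete simulated
operative-plan study of one patient ("patient A") — Haller measurements at
four axial cross sections (a-d = intercostal spaces 2-5) before surgery and
after simulated bar placement at each space/elevation combination.

Distances are mm; Haller indices are reproduced at the precision of the
original report (2 decimals pre-operative, 3 post-operative).  One printed
post-operative row — 5th space / 20 mm, section b — is internally
inconsistent (242.07/95.603 = 2.532, printed 2.666) and is flagged so
arithmetic checks can exclude it.
"""

from __future__ import annotations

#: (A_pre, A_post) transverse diameters of 12 patients, mm
SHRINKAGE_TABLE: list[tuple[float, float]] = [
    (268.05, 253.98),
    (223.31, 210.83),
    (264.35, 250.56),
    (222.76, 217.92),
    (254.97, 242.77),
    (249.98, 243.46),
    (204.51, 194.73),
    (212.23, 203.29),
    (245.81, 232.09),
    (240.91, 235.48),
    (232.30, 211.71),
    (250.38, 228.63),
]

#: printed shrinkage rates (2 dp) of the same 12 patients
SHRINKAGE_PRINTED: list[float] = [
    0.95, 0.94, 0.95, 0.98, 0.95, 0.97, 0.95, 0.96, 0.94, 0.98, 0.91, 0.91,
]

#: patient A pre-operative: section -> (B, A, printed H at 2 dp)
PREOP: dict[str, tuple[float, float, float]] = {
    "a": (72.10, 246.23, 3.42),
    "b": (74.01, 251.64, 3.40),
    "c": (74.76, 254.72, 3.41),
    "d": (68.18, 253.98, 3.73),
}

#: patient A post-operative simulations:
#: (intercostal space, elevation mm) -> {section: (B, A, printed H at 3 dp)}
POSTOP: dict[tuple[int, int], dict[str, tuple[float, float, float]]] = {
    (2, 15): {"a": (87.21, 234.23, 2.686), "b": (89.12, 241.47, 2.709),
              "c": (89.87, 248.73, 2.768), "d": (83.29, 250.68, 3.010)},
    (2, 20): {"a": (92.246, 229.28, 2.486), "b": (94.156, 238.34, 2.531),
              "c": (94.906, 245.29, 2.585), "d": (88.326, 248.78, 2.817)},
    (2, 25): {"a": (97.21, 225.98, 2.325), "b": (99.12, 234.59, 2.367),
              "c": (99.87, 243.28, 2.436), "d": (93.29, 245.92, 2.636)},
    (3, 15): {"a": (86.329, 235.63, 2.729), "b": (89.076, 240.64, 2.702),
              "c": (89.826, 247.72, 2.758), "d": (83.246, 250.48, 3.009)},
    (3, 20): {"a": (91.072, 231.23, 2.539), "b": (94.098, 236.64, 2.515),
              "c": (94.848, 243.72, 2.570), "d": (88.268, 247.98, 2.809)},
    (3, 25): {"a": (95.760, 227.83, 2.379), "b": (99.120, 231.72, 2.338),
              "c": (99.870, 239.98, 2.403), "d": (93.290, 244.38, 2.620)},
    (3, 30): {"a": (100.508, 224.58, 2.234), "b": (104.142, 228.14, 2.191),
              "c": (104.892, 237.32, 2.263), "d": (98.312, 242.13, 2.463)},
    (4, 15): {"a": (85.485, 239.05, 2.796), "b": (89.068, 241.34, 2.710),
              "c": (89.818, 242.72, 2.702), "d": (83.238, 250.02, 3.004)},
    (4, 20): {"a": (89.947, 237.12, 2.636), "b": (94.088, 237.98, 2.529),
              "c": (94.838, 239.32, 2.523), "d": (88.258, 246.12, 2.789)},
    (4, 25): {"a": (94.409, 234.58, 2.485), "b": (99.107, 233.54, 2.356),
              "c": (99.857, 235.09, 2.354), "d": (93.277, 241.23, 2.586)},
    (4, 30): {"a": (98.871, 231.62, 2.343), "b": (104.127, 229.97, 2.209),
              "c": (104.877, 229.11, 2.184), "d": (98.297, 237.11, 2.412)},
    (5, 20): {"a": (86.495, 242.86, 2.808), "b": (95.603, 242.07, 2.666),
              "c": (96.353, 241.83, 2.510), "d": (89.773, 244.92, 2.728)},
    (5, 25): {"a": (90.094, 239.16, 2.655), "b": (95.005, 237.81, 2.503),
              "c": (101.751, 238.23, 2.341), "d": (95.171, 240.25, 2.524)},
    (5, 30): {"a": (93.693, 239.16, 2.553), "b": (99.201, 232.81, 2.347),
              "c": (107.149, 234.97, 2.193), "d": (100.569, 235.02, 2.337)},
}

#: rows whose printed index disagrees with its own B and A beyond rounding;
#: excluded from arithmetic-reproduction checks
INCONSISTENT_ROWS: set[tuple[int, int, str]] = {(5, 20, "b")}

#: plans the study judged hypercorrected (over-elevated beyond the normal
#: profile) from sectional views; stated in the report's text only
HYPERCORRECTED_PLANS: set[tuple[int, int]] = {(2, 25), (3, 30), (4, 35), (5, 30)}

#: plans judged to meet the corrective criterion in the text without a
#: printed measurement table
TEXT_ONLY_MEETS: set[tuple[int, int]] = {(4, 35)}

#: corrective Haller-index criterion: mean post-operative index of a
#: 252-patient series, used as the acceptance threshold
HALLER_CRITERION = 2.68

#: the plan the study finally selected (minimum stress among survivors)
SELECTED_PLAN: tuple[int, int] = (4, 30)


def iter_rows():
    """Yield (space, elevation, section, B, A, printed_H, consistent)."""
    for (space, elev), rows in sorted(POSTOP.items()):
        for section, (B, A, H) in sorted(rows.items()):
            ok = (space, elev, section) not in INCONSISTENT_ROWS
            yield space, elev, section, B, A, H, ok
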