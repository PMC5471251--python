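"""Linear-elastic 3-D frame solver for sternal-elevation simulation.

The simplified thorax is solved as a space frame of Euler-Bernoulli beam
elements (6 degrees of freedom per node) by the direct stiffness method:
the spine is fixed, the Nuss bar acts as a prescribed purely anterior
displacement at one sternal anchor node, and every other node is free.
Materials are isotropic, homogeneous, linearly elastic; the analysis is
static and geometrically linear.

Internally forces are N, lengths mm, hence moduli N/mm^2 (MPa); material
moduli are supplied and stresses reported in Pa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve

from .errors import ParameterError, RigidBodyModeError, TopologyError
from .geometry import ThoraxModel

_PA_TO_MPA = 1e-6
_MPA_TO_PA = 1e6


@dataclass(frozen=True)
class Material:
    """Isotropic linear-elastic material (SI units)."""

    name: str
    density: float  # kg m^-3 (stored for completeness; unused in statics)
    youngs_modulus: float  # Pa
    poisson_ratio: float

    def __post_init__(self):
        if self.youngs_modulus <= 0:
            raise ParameterError("youngs_modulus must be positive")
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise ParameterError("poisson_ratio must lie in [0, 0.5)")

    @property
    def shear_modulus(self) -> float:
        return self.youngs_modulus / (2.0 * (1.0 + self.poisson_ratio))


#: the two tissue classes of the simplified model.  The densities are kept
#: exactly as tabulated in the source FE study although their magnitudes
#: (1e5 kg/m^3) are physically implausible; they play no role in a static
#: solve.
DEFAULT_MATERIALS: dict[str, Material] = {
    "bone": Material("cancellous bone", 1.67e5, 4.55e8, 0.3),
    "cartilage": Material("costal cartilage", 1.17e5, 3.75e7, 0.3),
}


@dataclass(frozen=True)
class SectionProperties:
    """Beam cross-section constants (mm units)."""

    area: float  # mm^2
    second_moment: float  # I about either bending axis, mm^4
    torsion_constant: float  # J, mm^4
    fiber_distance: float  # extreme-fiber distance c, mm

    @classmethod
    def circular(cls, radius: float) -> "SectionProperties":
        r = float(radius)
        if r <= 0:
            raise ParameterError("section radius must be positive")
        return cls(area=np.pi * r ** 2,
                   second_moment=np.pi * r ** 4 / 4.0,
                   torsion_constant=np.pi * r ** 4 / 2.0,
                   fiber_distance=r)


#: default circular sections, mm radius.  Ribs and cartilage 5 mm; the
#: sternum 9 mm, a circle with bending stiffness comparable to the sternal
#: plate (~25 x 12 mm), which is what lets an elevation at one intercostal
#: space carry along the whole sternal bar as observed clinically; the
#: spine section is irrelevant (its nodes are all fixed).
DEFAULT_SECTIONS: dict[str, SectionProperties] = {
    "rib": SectionProperties.circular(5.0),
    "cartilage": SectionProperties.circular(5.0),
    "sternum": SectionProperties.circular(9.0),
    "spine": SectionProperties.circular(15.0),
}


@dataclass
class Element:
    i: int
    j: int
    material: str
    section: SectionProperties


@dataclass
class FrameMesh:
    """Assembled frame model: geometry, sections, and boundary conditions."""

    nodes: np.ndarray  # (n, 3), mm
    elements: list[Element]
    materials: dict[str, Material]
    fixed_nodes: list[int]
    #: node id -> imposed translation vector (mm); rotations stay free
    prescribed: dict[int, np.ndarray] = field(default_factory=dict)
    #: node id -> applied force vector (N)
    loads: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        n = len(self.nodes)
        for e in self.elements:
            if np.linalg.norm(self.nodes[e.j] - self.nodes[e.i]) < 1e-9:
                raise TopologyError(f"zero-length element {e.i}-{e.j}")
            if e.material not in self.materials:
                raise TopologyError(f"undefined material {e.material!r}")
        for nid in list(self.fixed_nodes) + list(self.prescribed):
            if not 0 <= nid < n:
                raise TopologyError(f"constrained node {nid} does not exist")


@dataclass
class SolveResult:
    """Outcome of one static solve."""

    displacements: np.ndarray  # (n, 3) translations, mm
    rotations: np.ndarray  # (n, 3), rad
    element_stress: np.ndarray  # per-element von Mises equivalent stress, Pa
    reactions: dict[int, np.ndarray]  # constrained node -> force (N)

    @property
    def max_equivalent_stress(self) -> float:
        return float(np.max(self.element_stress)) if len(
            self.element_stress) else 0.0


def build_frame_mesh(thorax: ThoraxModel,
                     section_props: dict[str, SectionProperties] | None = None,
                     materials: dict[str, Material] | None = None
                     ) -> FrameMesh:
    """One beam element per thorax segment; spine nodes fixed."""
    props = dict(DEFAULT_SECTIONS)
    if section_props:
        props.update(section_props)
    mats = dict(materials or DEFAULT_MATERIALS)
    elements = []
    n = thorax.n_nodes
    rows, cols = [], []
    for seg in thorax.segments:
        if seg.prop_id not in props:
            raise TopologyError(f"no section properties for {seg.prop_id!r}")
        elements.append(Element(seg.i, seg.j, seg.tissue, props[seg.prop_id]))
        rows.append(seg.i)
        cols.append(seg.j)
    adj = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp != 1:
        raise TopologyError(f"mesh is disconnected ({n_comp} components)")
    return FrameMesh(nodes=thorax.nodes.copy(), elements=elements,
                     materials=mats, fixed_nodes=list(thorax.spine_nodes))


# ---------------------------------------------------------------------------
# element matrices
# ---------------------------------------------------------------------------

def _element_frames(mesh: FrameMesh):
    """Yield (element, length, rotation matrix R, local stiffness k_local)."""
    for e in mesh.elements:
        dvec = mesh.nodes[e.j] - mesh.nodes[e.i]
        L = float(np.linalg.norm(dvec))
        ex = dvec / L
        ref = np.array([0.0, 1.0, 0.0]) if abs(ex[2]) > 0.9 \
            else np.array([0.0, 0.0, 1.0])
        ez = np.cross(ex, ref)
        ez /= np.linalg.norm(ez)
        ey = np.cross(ez, ex)
        R = np.vstack([ex, ey, ez])
        mat = mesh.materials[e.material]
        E = mat.youngs_modulus * _PA_TO_MPA  # N/mm^2
        G = mat.shear_modulus * _PA_TO_MPA
        yield e, L, R, _local_stiffness(E, G, e.section, L)


def _local_stiffness(E: float, G: float, sec: SectionProperties,
                     L: float) -> np.ndarray:
    """12x12 Euler-Bernoulli space-frame stiffness in local coordinates."""
    A, I, J = sec.area, sec.second_moment, sec.torsion_constant
    k = np.zeros((12, 12))
    ax, tr = E * A / L, G * J / L
    a = 12.0 * E * I / L ** 3
    b = 6.0 * E * I / L ** 2
    c = 4.0 * E * I / L
    d = 2.0 * E * I / L
    k[0, 0] = k[6, 6] = ax
    k[0, 6] = k[6, 0] = -ax
    k[3, 3] = k[9, 9] = tr
    k[3, 9] = k[9, 3] = -tr
    # bending in the local x-y plane (deflection uy, rotation rz)
    for (p, q), v in {(1, 1): a, (1, 5): b, (1, 7): -a, (1, 11): b,
                      (5, 5): c, (5, 7): -b, (5, 11): d,
                      (7, 7): a, (7, 11): -b, (11, 11): c}.items():
        k[p, q] = k[q, p] = v
    # bending in the local x-z plane (deflection uz, rotation ry)
    for (p, q), v in {(2, 2): a, (2, 4): -b, (2, 8): -a, (2, 10): -b,
                      (4, 4): c, (4, 8): b, (4, 10): d,
                      (8, 8): a, (8, 10): b, (10, 10): c}.items():
        k[p, q] = k[q, p] = v
    return k


def _transform(R: np.ndarray) -> np.ndarray:
    T = np.zeros((12, 12))
    for blk in range(4):
        T[3 * blk:3 * blk + 3, 3 * blk:3 * blk + 3] = R
    return T


def assemble_stiffness(mesh: FrameMesh) -> sp.csr_matrix:
    """Global stiffness matrix (N/mm units), 6 dof per node."""
    n_dof = 6 * len(mesh.nodes)
    rows, cols, vals = [], [], []
    for e, L, R, k_l in _element_frames(mesh):
        T = _transform(R)
        k_g = T.T @ k_l @ T
        dofs = np.concatenate([6 * e.i + np.arange(6), 6 * e.j + np.arange(6)])
        rr, cc = np.meshgrid(dofs, dofs, indexing="ij")
        rows.append(rr.ravel())
        cols.append(cc.ravel())
        vals.append(k_g.ravel())
    K = sp.coo_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(n_dof, n_dof)).tocsr()
    return K


# ---------------------------------------------------------------------------
# solve
# ---------------------------------------------------------------------------

def solve_static(mesh: FrameMesh) -> SolveResult:
    """Direct-stiffness static solve with exact imposition of prescribed
    displacements; returns displacements, equivalent stresses and reactions.
    """
    n = len(mesh.nodes)
    n_dof = 6 * n
    K = assemble_stiffness(mesh)

    u = np.zeros(n_dof)
    constrained = np.zeros(n_dof, dtype=bool)
    for nid in mesh.fixed_nodes:
        constrained[6 * nid:6 * nid + 6] = True
    for nid, vec in mesh.prescribed.items():
        vec = np.asarray(vec, dtype=float)
        u[6 * nid:6 * nid + 3] = vec
        constrained[6 * nid:6 * nid + 3] = True

    f = np.zeros(n_dof)
    for nid, force in mesh.loads.items():
        f[6 * nid:6 * nid + 3] = np.asarray(force, dtype=float)

    free = ~constrained
    if free.any():
        K_ff = K[free][:, free].tocsc()
        rhs = f[free] - K[free][:, constrained] @ u[constrained]
        with warnings.catch_warnings():
            warnings.simplefilter("error", sp.linalg.MatrixRankWarning)
            try:
                u_f = spsolve(K_ff, rhs)
            except sp.linalg.MatrixRankWarning:
                raise _rigid_body_error(K_ff, np.flatnonzero(free))
        if not np.all(np.isfinite(u_f)):
            raise _rigid_body_error(K_ff, np.flatnonzero(free))
        res = np.linalg.norm(K_ff @ u_f - rhs)
        scale = max(np.linalg.norm(rhs), 1e-30)
        if res > 1e-6 * scale + 1e-9:
            raise _rigid_body_error(K_ff, np.flatnonzero(free))
        u[free] = u_f

    r_full = K @ u - f
    reactions = {}
    for nid in list(mesh.fixed_nodes) + list(mesh.prescribed):
        reactions[nid] = r_full[6 * nid:6 * nid + 3].copy()

    u_nodes = u.reshape(n, 6)
    result = SolveResult(
        displacements=u_nodes[:, :3].copy(),
        rotations=u_nodes[:, 3:].copy(),
        element_stress=np.zeros(len(mesh.elements)),
        reactions=reactions,
    )
    result.element_stress = equivalent_stress(result, mesh)
    return result


def _rigid_body_error(K_ff, free_idx) -> RigidBodyModeError:
    """Identify the dominant unconstrained mode for the error message."""
    dof_names = ("ux", "uy", "uz", "rx", "ry", "rz")
    try:
        dense = K_ff.toarray()
        w, v = np.linalg.eigh(dense)
        mode = v[:, int(np.argmin(np.abs(w)))]
        k = int(np.argmax(np.abs(mode)))
        dof = int(free_idx[k])
        name = f"node {dof // 6}, dof {dof_names[dof % 6]}"
    except Exception:  # pragma: no cover - diagnostics only
        name = "unidentified"
    return RigidBodyModeError(
        f"constrained stiffness is singular; dominant free mode at {name}")


def equivalent_stress(result: SolveResult, mesh: FrameMesh) -> np.ndarray:
    """Per-element von Mises equivalent stress, Pa.

    Normal stress combines the axial force with the extreme-fiber bending
    stress (larger end moment); shear comes from torsion alone, transverse
    shear being negligible for slender members.
    """
    u = np.hstack([result.displacements, result.rotations]).ravel()
    out = np.zeros(len(mesh.elements))
    for idx, (e, L, R, k_l) in enumerate(_element_frames(mesh)):
        dofs = np.concatenate([6 * e.i + np.arange(6), 6 * e.j + np.arange(6)])
        T = _transform(R)
        f_local = k_l @ (T @ u[dofs])
        N = f_local[6]  # axial force at end j, N
        Tx = f_local[9]  # torsion, N mm
        M_i = float(np.hypot(f_local[4], f_local[5]))
        M_j = float(np.hypot(f_local[10], f_local[11]))
        sec = e.section
        sigma = abs(N) / sec.area \
            + max(M_i, M_j) * sec.fiber_distance / sec.second_moment
        tau = abs(Tx) * sec.fiber_distance / sec.torsion_constant
        out[idx] = np.sqrt(sigma ** 2 + 3.0 * tau ** 2) * _MPA_TO_PA
    return out


# ---------------------------------------------------------------------------
# sternal elevation
# ---------------------------------------------------------------------------

#: element strain beyond which the linear small-deformation assumption is
#: flagged as doubtful
STRAIN_WARNING_LIMIT = 0.20


def simulate_elevation(thorax: ThoraxModel, space: int, elevation: float,
                       section_props: dict[str, SectionProperties] | None = None,
                       materials: dict[str, Material] | None = None
                       ) -> tuple[ThoraxModel, SolveResult]:
    """Simulate elevating the sternum at one intercostal space.

    A purely anterior displacement of magnitude ``elevation`` (mm) is
    prescribed at the sternal anchor node of the chosen space (the bar's
    point of action); the spine is fixed.  Returns the deformed model and
    the solve result.
    """
    if space not in thorax.intercostal_anchor:
        raise ParameterError(f"intercostal space {space} has no anchor; "
                             f"have {sorted(thorax.intercostal_anchor)}")
    if elevation < 0:
        raise ParameterError("elevation must be >= 0")
    mesh = build_frame_mesh(thorax, section_props, materials)
    anchor = thorax.intercostal_anchor[space]
    mesh.prescribed = {anchor: np.array([0.0, elevation, 0.0])}
    result = solve_static(mesh)

    # linear-model validity check
    for e in mesh.elements:
        p0 = mesh.nodes[e.i], mesh.nodes[e.j]
        L0 = np.linalg.norm(p0[1] - p0[0])
        p1 = (mesh.nodes[e.i] + result.displacements[e.i],
              mesh.nodes[e.j] + result.displacements[e.j])
        L1 = np.linalg.norm(p1[1] - p1[0])
        if abs(L1 - L0) / L0 > STRAIN_WARNING_LIMIT:
            warnings.warn(
                f"element {e.i}-{e.j} strain {abs(L1 - L0) / L0:.2f} exceeds "
                f"{STRAIN_WARNING_LIMIT:.0%}: linear model validity doubtful",
                UserWarning, stacklevel=2)
            break

    deformed = thorax.copy()
    deformed.nodes = thorax.nodes + result.displacements
    deformed.meta = dict(thorax.meta)
    deformed.meta["elevation"] = {"space": space, "mm": elevation}
    return deformed, result
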