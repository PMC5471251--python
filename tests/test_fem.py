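"""Frame solver verification against beam-theory closed forms and
structural invariants."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from nussplan.errors import (ParameterError, RigidBodyModeError,
                             TopologyError)
from nussplan.fem import (DEFAULT_MATERIALS, Element, FrameMesh, Material,
                          SectionProperties, assemble_stiffness,
                          build_frame_mesh, simulate_elevation, solve_static)

BONE = DEFAULT_MATERIALS["bone"]
SEC = SectionProperties.circular(5.0)


def _cantilever(L=200.0, n=4, tip_disp=(0.0, 2.0, 0.0)):
    nodes = np.column_stack([np.linspace(0, L, n + 1),
                             np.zeros(n + 1), np.zeros(n + 1)])
    elements = [Element(i, i + 1, "bone", SEC) for i in range(n)]
    return FrameMesh(nodes, elements, dict(DEFAULT_MATERIALS),
                     fixed_nodes=[0],
                     prescribed={n: np.asarray(tip_disp, float)})


class TestClosedForms:
    def test_prescribed_tip_deflection_reaction(self):
        """Tip reaction of a cantilever with prescribed transverse tip
        displacement equals 3*E*I*delta/L^3 (Euler-Bernoulli)."""
        L, delta = 200.0, 2.0
        res = solve_static(_cantilever(L, tip_disp=(0, delta, 0)))
        E = BONE.youngs_modulus * 1e-6  # N/mm^2
        expected = 3.0 * E * SEC.second_moment * delta / L ** 3
        assert res.reactions[4][1] == pytest.approx(expected, rel=1e-6)

    def test_extreme_fiber_bending_stress(self):
        """Base stress of the same cantilever equals M*c/I with M = F*L."""
        L, delta = 200.0, 2.0
        res = solve_static(_cantilever(L, tip_disp=(0, delta, 0)))
        E = BONE.youngs_modulus * 1e-6
        F = 3.0 * E * SEC.second_moment * delta / L ** 3
        expected = F * L * SEC.fiber_distance / SEC.second_moment * 1e6
        assert res.max_equivalent_stress == pytest.approx(expected, rel=1e-6)

    def test_pure_axial_extension_stress_is_hookean(self):
        """A bar stretched by strain eps carries stress E*eps."""
        L, eps = 100.0, 1e-3
        mesh = _cantilever(L, n=2, tip_disp=(eps * L, 0.0, 0.0))
        res = solve_static(mesh)
        assert res.max_equivalent_stress == pytest.approx(
            BONE.youngs_modulus * eps, rel=1e-9)

    def test_no_load_no_displacement(self):
        mesh = _cantilever()
        mesh.prescribed = {}
        res = solve_static(mesh)
        assert np.all(res.displacements == 0.0)
        assert res.max_equivalent_stress == 0.0


class TestInvariants:
    def test_stiffness_matrix_symmetric(self, patient):
        pex, _ = patient
        K = assemble_stiffness(build_frame_mesh(pex))
        asym = abs(K - K.T).max()
        assert asym <= 1e-12 * abs(K).max()

    def test_linearity_in_prescribed_elevation(self, patient):
        pex, _ = patient
        _, r1 = simulate_elevation(pex, 3, 10.0)
        _, r2 = simulate_elevation(pex, 3, 20.0)
        assert np.allclose(r2.displacements, 2.0 * r1.displacements,
                           rtol=1e-9, atol=1e-12)
        assert np.allclose(r2.element_stress, 2.0 * r1.element_stress,
                           rtol=1e-9, atol=1e-6)

    def test_reactions_balance_on_thorax_solve(self, patient):
        pex, _ = patient
        _, res = simulate_elevation(pex, 4, 25.0)
        total = sum(res.reactions.values())
        scale = max(np.abs(np.concatenate(list(res.reactions.values()))))
        assert np.abs(total).max() <= 1e-6 * scale

    def test_mirror_symmetric_displacement_field(self, patient):
        """A mid-sagittal elevation of a bilaterally symmetric thorax gives
        an x-mirror-symmetric displacement field."""
        pex, _ = patient
        _, res = simulate_elevation(pex, 3, 25.0)
        _, idx = cKDTree(pex.nodes).query(
            pex.nodes * np.array([-1.0, 1.0, 1.0]))
        u = res.displacements
        mirrored = u[idx] * np.array([-1.0, 1.0, 1.0])
        assert np.abs(u - mirrored).max() <= 1e-9 * np.abs(u).max()

    def test_stiffer_cartilage_raises_max_stress(self, patient):
        """Replacing cartilage by bone (12x stiffer) increases the maximum
        equivalent stress at fixed elevation."""
        pex, _ = patient
        _, soft = simulate_elevation(pex, 4, 25.0)
        all_bone = {"bone": BONE,
                    "cartilage": Material("bone-as-cartilage", BONE.density,
                                          BONE.youngs_modulus,
                                          BONE.poisson_ratio)}
        _, hard = simulate_elevation(pex, 4, 25.0, materials=all_bone)
        assert hard.max_equivalent_stress > soft.max_equivalent_stress


class TestMeshAndErrors:
    def test_build_mesh_mirrors_thorax(self, patient):
        pex, _ = patient
        mesh = build_frame_mesh(pex)
        assert len(mesh.elements) == len(pex.segments)
        assert set(mesh.fixed_nodes) == set(pex.spine_nodes)
        assert {e.material for e in mesh.elements} == {"bone", "cartilage"}

    def test_disconnected_mesh_rejected(self, healthy):
        broken = healthy.copy()
        iso = set(broken.rib_rings[-1])
        broken.segments = [s for s in broken.segments
                           if not (s.i in iso or s.j in iso)]
        with pytest.raises(TopologyError):
            build_frame_mesh(broken)

    def test_floating_component_is_rigid_body_mode(self):
        nodes = np.array([[0, 0, 0], [100, 0, 0], [0, 200, 0],
                          [100, 200, 0]], float)
        elements = [Element(0, 1, "bone", SEC), Element(2, 3, "bone", SEC)]
        mesh = FrameMesh(nodes, elements, dict(DEFAULT_MATERIALS),
                         fixed_nodes=[0])
        with pytest.raises(RigidBodyModeError, match="node"):
            solve_static(mesh)

    def test_zero_length_element_rejected(self):
        nodes = np.zeros((2, 3))
        with pytest.raises(TopologyError):
            FrameMesh(nodes, [Element(0, 1, "bone", SEC)],
                      dict(DEFAULT_MATERIALS), fixed_nodes=[0])

    def test_material_validation(self):
        with pytest.raises(ParameterError):
            Material("bad", 1000.0, -1.0, 0.3)
        with pytest.raises(ParameterError):
            Material("bad", 1000.0, 1e9, 0.6)


class TestElevation:
    def test_anchor_displacement_is_exactly_prescribed(self, patient):
        pex, _ = patient
        deformed, res = simulate_elevation(pex, 3, 25.0)
        anchor = pex.intercostal_anchor[3]
        assert res.displacements[anchor, 1] == 25.0
        assert res.displacements[anchor, 0] == 0.0

    def test_zero_elevation_is_identity(self, patient):
        pex, _ = patient
        deformed, res = simulate_elevation(pex, 4, 0.0)
        assert np.array_equal(deformed.nodes, pex.nodes)
        assert np.all(res.displacements == 0.0)

    def test_unknown_space_rejected(self, patient):
        pex, _ = patient
        with pytest.raises(ParameterError):
            simulate_elevation(pex, 7, 20.0)

    def test_extreme_elevation_warns_about_linearity(self, patient):
        pex, _ = patient
        with pytest.warns(UserWarning, match="strain"):
            simulate_elevation(pex, 2, 100.0)

    def test_table_material_constants(self):
        """The two tissue materials carry the tabulated constants."""
        bone, cart = DEFAULT_MATERIALS["bone"], DEFAULT_MATERIALS["cartilage"]
        assert (bone.youngs_modulus, bone.poisson_ratio) == (4.55e8, 0.3)
        assert (cart.youngs_modulus, cart.poisson_ratio) == (3.75e7, 0.3)
        assert bone.density == 1.67e5 and cart.density == 1.17e5
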