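import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import femstrength as fs
from femstrength.voxel_fe import (
    DEFAULT_LOAD_DIRECTIONS, MaterialCurve, MeshConstructionError,
    SolveConfig, assemble_global_stiffness, build_mesh, effective_strain,
    elastic_modulus, element_strains, mesh_from_mask, solve_load_capacity,
    uniaxial_stress, yield_stress,
)
from conftest import make_bar_mesh


class TestUniaxialStress:
    def test_zero_strain_zero_stress(self, linear_curve):
        assert uniaxial_stress(linear_curve, 0.0, 1.0) == 0.0

    def test_half_yield_strain_in_elastic_region(self, linear_curve):
        rho = 0.8
        E = elastic_modulus(linear_curve, rho)
        sy = yield_stress(linear_curve, rho)
        assert uniaxial_stress(linear_curve, 0.5 * sy / E, rho) == (
            pytest.approx(0.5 * sy, rel=1e-12))

    def test_residual_plateau_exact(self, linear_curve):
        rho = 1.0
        sy = yield_stress(linear_curve, rho)
        assert uniaxial_stress(linear_curve, 1.0, rho) == pytest.approx(
            linear_curve.residual_fraction * sy, rel=1e-12)

    @given(rho=st.floats(0.05, 1.5), eps=st.floats(0.0, 0.5))
    @settings(max_examples=200, deadline=None)
    def test_curve_continuous_nonnegative_bounded(self, rho, eps):
        curve = MaterialCurve()
        s = float(uniaxial_stress(curve, eps, rho))
        sy = float(yield_stress(curve, rho))
        assert 0.0 <= s <= sy + 1e-9
        # continuity: small strain perturbation -> small stress change
        s2 = float(uniaxial_stress(curve, eps + 1e-9, rho))
        E = float(elastic_modulus(curve, rho))
        assert abs(s2 - s) <= 2e-9 * E

    def test_region_joins_are_continuous(self, linear_curve):
        rho = 1.0
        E = elastic_modulus(linear_curve, rho)
        sy = yield_stress(linear_curve, rho)
        eps_y = sy / E
        eps1 = eps_y + linear_curve.plateau_strain
        eps2 = eps1 + (1 - linear_curve.residual_fraction) * sy / \
            linear_curve.softening_modulus
        for e in (eps_y, eps1, eps2):
            lo = uniaxial_stress(linear_curve, e - 1e-10, rho)
            hi = uniaxial_stress(linear_curve, e + 1e-10, rho)
            assert hi == pytest.approx(lo, abs=1e-5)


class TestBuildMesh:
    def test_solid_block_counts(self):
        n = 4
        grid = np.zeros((n + 2, n + 2, n + 2))
        grid[1:-1, 1:-1, 1:-1] = 500.0
        # head "centre" low in the block so the superior surface is the cap
        vol = fs.QCTVolume(grid=grid, spacing=(2, 2, 2), calibrated=True,
                           meta={"head_center_mm": (6.0, 6.0, 2.0),
                                 "head_radius_mm": 8.0})
        mesh = build_mesh(vol, bone_threshold=100.0, configuration="NLS")
        assert mesh.n_elements == n ** 3
        assert len(mesh.nodes) == (n + 1) ** 3

    def test_all_below_threshold_raises(self):
        vol = fs.QCTVolume(grid=np.full((4, 4, 4), 10.0), spacing=(1, 1, 1),
                           calibrated=True)
        with pytest.raises(MeshConstructionError):
            build_mesh(vol, bone_threshold=100.0)

    def test_edge_touching_component_dropped(self):
        # two blocks touching only along an edge: flood fill with face
        # connectivity must keep only the larger one
        grid = np.zeros((6, 6, 3))
        grid[0:3, 0:3, :] = 500.0     # 27 voxels
        grid[3:5, 3:5, :] = 500.0     # 12 voxels, edge contact at (3,3)
        vol = fs.QCTVolume(grid=grid, spacing=(2, 2, 2), calibrated=True,
                           meta={"head_center_mm": (3.0, 3.0, 0.0),
                                 "head_radius_mm": 6.0})
        mesh = build_mesh(vol, bone_threshold=100.0)
        assert mesh.n_elements == 27

    def test_femur_mesh_node_sets(self, calibrated_volume):
        mesh = build_mesh(calibrated_volume, 100.0, "NLS")
        head = mesh.node_sets["head_surface"]
        distal = mesh.node_sets["distal_face"]
        assert len(head) > 0 and len(distal) > 0
        assert np.intersect1d(head, distal).size == 0
        # distal nodes all share the inferior z coordinate
        assert np.ptp(mesh.nodes[distal][:, 2]) == 0
        # head nodes sit near the head sphere surface
        c = np.asarray(calibrated_volume.meta["head_center_mm"])
        r = np.linalg.norm(mesh.nodes[head] - c, axis=1)
        assert (r > 0.6 * calibrated_volume.meta["head_radius_mm"]).all()


class TestElasticBehaviour:
    def test_patch_test_uniform_strain(self):
        """A homogeneous elastic block under a prescribed linear displacement
        field reproduces the uniform strain exactly (conforming trilinear
        elements pass the patch test)."""
        mask = np.ones((3, 3, 3), bool)
        dens = np.ones(mask.shape)
        nzp = 4
        nodes_flat = np.arange(nzp ** 3)
        mesh = mesh_from_mask(mask, (2.0, 2.0, 2.0), dens,
                              head_nodes=nodes_flat[-4:],
                              distal_nodes=nodes_flat[:4],
                              load_direction=(0, 0, -1))
        E = np.full(mesh.n_elements, 5000.0)
        nu = 0.3
        K = assemble_global_stiffness(mesh, E, nu)
        # linear field u = A x with symmetric-gradient strain eps0
        A = np.array([[1e-3, 2e-4, 0.0],
                      [2e-4, -5e-4, 1e-4],
                      [0.0, 1e-4, 8e-4]])
        u = (mesh.nodes @ A.T).ravel()
        eps = element_strains(mesh, u)
        eps0 = np.array([A[0, 0], A[1, 1], A[2, 2],
                         A[0, 1] + A[1, 0], A[1, 2] + A[2, 1],
                         A[0, 2] + A[2, 0]])
        assert np.allclose(eps, eps0[None, :], atol=1e-15)
        # interior residual forces vanish: K u has support only on boundary
        f = (K @ u).reshape(-1, 3)
        interior = np.all((mesh.nodes > 0) & (mesh.nodes < 6.0), axis=1)
        assert np.abs(f[interior]).max() < 1e-8 * np.abs(f).max()

    def test_energy_consistency_elastic(self, linear_curve):
        """External work equals stored strain energy in the elastic regime."""
        mesh = make_bar_mesh(2)
        cfg = SolveConfig(displacement_increment=0.004, max_steps=1)
        res = solve_load_capacity(mesh, linear_curve, cfg)
        # linear ramp: W = 1/2 F u;  U = 1/2 u^T K u
        F, delta = res.reaction_forces[0], res.displacements[0]
        E = elastic_modulus(linear_curve, mesh.element_density)
        K = assemble_global_stiffness(mesh, E, linear_curve.poisson)
        # rebuild the converged displacement field
        u = np.zeros(3 * len(mesh.nodes))
        top = mesh.node_sets["head_surface"]
        u[(top[:, None] * 3 + np.arange(3)).ravel()] = np.tile(
            delta * mesh.load_direction, len(top))
        # solve interior dofs elastically
        from scipy.sparse.linalg import spsolve
        presc = np.concatenate([
            (top[:, None] * 3 + np.arange(3)).ravel(),
            (mesh.node_sets["distal_face"][:, None] * 3
             + np.arange(3)).ravel()])
        free = np.setdiff1d(np.arange(3 * len(mesh.nodes)), presc)
        u[free] = spsolve(K[free][:, free].tocsc(),
                          -K[free][:, presc] @ u[presc])
        U = 0.5 * float(u @ (K @ u))
        W = 0.5 * F * delta
        assert U == pytest.approx(W, rel=1e-6)

    def test_mesh_refinement_elastic_bar(self, linear_curve):
        """Halving the voxel size changes the elastic bar stiffness < 2%."""
        caps = []
        for nz, side in ((2, 10.0), (4, 5.0)):
            mask = np.ones((1, 1, nz), bool) if side == 10.0 else \
                np.ones((2, 2, nz), bool)
            dens = np.ones(mask.shape)
            nx, ny = mask.shape[0] + 1, mask.shape[1] + 1
            nzp = nz + 1
            flat = np.arange(nx * ny * nzp).reshape(nx, ny, nzp)
            mesh = mesh_from_mask(mask, (side,) * 3, dens,
                                  head_nodes=flat[:, :, -1].ravel(),
                                  distal_nodes=flat[:, :, 0].ravel(),
                                  load_direction=(0, 0, -1))
            cfg = SolveConfig(displacement_increment=0.02, max_steps=1)
            res = solve_load_capacity(mesh, linear_curve, cfg)
            caps.append(res.reaction_forces[0])
        assert abs(caps[1] - caps[0]) / caps[0] < 0.02


class TestSolveLoadCapacity:
    def test_single_element_elastic_plastic_oracle(self, linear_curve):
        import dataclasses
        curve = dataclasses.replace(linear_curve, residual_fraction=1.0)
        mesh = make_bar_mesh(1)
        E, sy, A, h = 10000.0, 100.0, 100.0, 10.0
        cfg = SolveConfig(displacement_increment=0.002 * h, max_steps=12)
        res = solve_load_capacity(mesh, curve, cfg)
        eps = res.displacements / h
        expected = np.minimum(E * eps, sy) * A
        assert np.allclose(res.reaction_forces, expected, rtol=1e-9)
        assert res.load_capacity == pytest.approx(sy * A, rel=1e-6)

    def test_single_element_softening_drops_and_stops(self, linear_curve):
        mesh = make_bar_mesh(1)
        cfg = SolveConfig(displacement_increment=0.02, max_steps=30)
        res = solve_load_capacity(mesh, linear_curve, cfg)
        assert res.stopped_reason == "force_drop"
        assert res.load_capacity == pytest.approx(100.0 * 100.0, rel=1e-6)
        assert res.reaction_forces[-1] < res.load_capacity

    def test_two_element_series_same_capacity(self, linear_curve):
        one = make_bar_mesh(1)
        two = make_bar_mesh(2)
        cfg1 = SolveConfig(displacement_increment=0.02, max_steps=30)
        cfg2 = SolveConfig(displacement_increment=0.04, max_steps=30)
        r1 = solve_load_capacity(one, linear_curve, cfg1)
        r2 = solve_load_capacity(two, linear_curve, cfg2)
        assert r2.load_capacity == pytest.approx(r1.load_capacity, rel=1e-6)
        # strain halves per increment relative to the applied head motion
        u = np.zeros(3 * len(two.nodes))
        eps2 = element_strains(two, u)  # shape check only
        assert eps2.shape == (2, 6)

    def test_determinism_bit_identical(self, linear_curve):
        mesh = make_bar_mesh(2)
        cfg = SolveConfig(displacement_increment=0.02, max_steps=10)
        a = solve_load_capacity(mesh, linear_curve, cfg)
        b = solve_load_capacity(mesh, linear_curve, cfg)
        assert np.array_equal(a.reaction_forces, b.reaction_forces)
        assert a.load_capacity == b.load_capacity

    def test_rigid_translation_invariance(self, linear_curve):
        mesh = make_bar_mesh(2)
        shifted = make_bar_mesh(2)
        shifted.nodes = shifted.nodes + np.array([100.0, -50.0, 30.0])
        cfg = SolveConfig(displacement_increment=0.02, max_steps=10)
        a = solve_load_capacity(mesh, linear_curve, cfg)
        b = solve_load_capacity(shifted, linear_curve, cfg)
        assert a.load_capacity == pytest.approx(b.load_capacity, rel=1e-12)

    def test_node_permutation_invariance(self, linear_curve):
        mesh = make_bar_mesh(2)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(mesh.nodes))
        inv = np.argsort(perm)
        from femstrength.voxel_fe import HexMesh
        permuted = HexMesh(
            nodes=mesh.nodes[perm],
            elements=inv[mesh.elements],
            element_density=mesh.element_density,
            node_sets={k: inv[v] for k, v in mesh.node_sets.items()},
            load_direction=mesh.load_direction, spacing=mesh.spacing)
        cfg = SolveConfig(displacement_increment=0.02, max_steps=10)
        a = solve_load_capacity(mesh, linear_curve, cfg)
        b = solve_load_capacity(permuted, linear_curve, cfg)
        assert a.load_capacity == pytest.approx(b.load_capacity, rel=1e-9)


class TestEffectiveStrain:
    def test_uniaxial_stress_state_recovers_axial_strain(self):
        nu = 0.3
        eps = np.array([[1e-3, -nu * 1e-3, -nu * 1e-3, 0, 0, 0]])
        assert effective_strain(eps, nu)[0] == pytest.approx(1e-3, rel=1e-12)

    def test_hydrostatic_strain_has_zero_effective(self):
        eps = np.array([[1e-3, 1e-3, 1e-3, 0, 0, 0]])
        assert effective_strain(eps, 0.3)[0] == pytest.approx(0.0, abs=1e-15)


class TestRunConfiguration:
    def test_nlf_weaker_than_nls_on_default_femur(self, calibrated_volume):
        nls = fs.run_configuration(calibrated_volume, "NLS")
        nlf = fs.run_configuration(calibrated_volume, "NLF")
        assert nlf.load_capacity < nls.load_capacity
        assert nls.label == "F_NLS" and nlf.label == "F_NLF"

    def test_zero_density_volume_errors(self):
        vol = fs.QCTVolume(grid=np.zeros((5, 5, 5)), spacing=(2, 2, 2),
                           calibrated=True)
        with pytest.raises(MeshConstructionError):
            fs.run_configuration(vol, "NLS")

    def test_default_directions_unit_norm(self):
        for d in DEFAULT_LOAD_DIRECTIONS.values():
            assert np.linalg.norm(d) == pytest.approx(1.0, rel=1e-9)
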