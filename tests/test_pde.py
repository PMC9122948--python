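import numpy as np
import pytest
from scipy.spatial import cKDTree

from colonycomp import (
    DomainGeometry,
    DomainTooSmallError,
    FieldState,
    ModelParams,
    SolverSettings,
    build_disk_mesh,
    competitive_outcome,
    homogeneous_ic,
    initial_state_from_config,
    mass_totals,
    overlap_fraction,
    place_founders,
    rhs,
    solve,
)
from colonycomp.pde import SolverError


# ----------------------------------------------------------------------
# independent oracles

def dense_rhs_oracle(mesh, B1, B2, params):
    """Loop-based re-derivation of the semi-discrete operator.

    Assembles the full stiffness matrix and lumped mass vector element by
    element using the cotangent-free gradient formula, evaluates the
    clamped mean mobility per element and applies reaction terms; shares
    no code with the vectorised implementation.
    """
    n = mesh.n_nodes
    lumped = np.zeros(n)
    out1 = np.zeros(n)
    out2 = np.zeros(n)
    tot = B1 + B2
    for tri in mesh.triangles:
        p = mesh.node_coords[tri]
        mat = np.column_stack([np.ones(3), p])
        area = 0.5 * abs(np.linalg.det(mat))
        # basis phi_i = a + b x + c y with phi_i(p_j) = delta_ij, so the
        # coefficient matrix is inv(mat) and grad(phi_i) is its rows 1:3
        G = np.linalg.inv(mat)[1:, :]  # (2, 3): column i = grad(phi_i)
        Ke = area * (G.T @ G)
        mob = max(float(np.mean(1.0 - tot[tri] / params.k)), 0.0)
        out1[tri] -= mob * (Ke @ B1[tri])
        out2[tri] -= params.d * mob * (Ke @ B2[tri])
        lumped[tri] += area / 3.0
    out1 /= lumped
    out2 /= lumped
    g = 1.0 - tot / params.k
    out1 += B1 * g
    out2 += params.r * B2 * g
    if params.antagonistic:
        out1 -= B1 * B2
        out2 -= params.c * B1 * B2
    return out1, out2


def radial_reference(R, h_hat, T, dr=0.02, k=1.0):
    """1-D radially symmetric finite-difference solve of the single-strain
    model, u_t = (1/r)(r m(u) u_r)_r + u(1-u/k), from a cone of height 1
    and radius ``h_hat`` at the origin."""
    r = np.arange(0.0, R + dr, dr)
    u = np.clip(1.0 - r / h_hat, 0.0, 1.0)
    dt = 0.2 * dr * dr
    n = int(np.ceil(T / dt))
    dt = T / n
    rf = r[:-1] + dr / 2
    for _ in range(n):
        m = np.clip(1.0 - u / k, 0.0, None)
        mf = 0.5 * (m[:-1] + m[1:])
        flux = rf * mf * (u[1:] - u[:-1]) / dr
        div = np.zeros_like(u)
        div[1:-1] = (flux[1:] - flux[:-1]) / (r[1:-1] * dr)
        div[0] = 2.0 * (m[0] + m[1]) * (u[1] - u[0]) / dr**2
        u = u + dt * (div + u * (1.0 - u / k))
        np.clip(u, 0.0, None, out=u)
    return r, u


# ----------------------------------------------------------------------

class TestModelParams:
    def test_isogenic_constraints(self):
        with pytest.raises(ValueError):
            ModelParams(mode="isogenic", r=2.0)
        with pytest.raises(ValueError):
            ModelParams(mode="antagonistic", c=-0.1)

    def test_label_swap_transform_involution(self):
        p = ModelParams.antagonism(r=1.3, d=0.7, c=0.2, k=1.0)
        q = p.swapped().swapped()
        assert np.allclose([q.r, q.d, q.c, q.k], [p.r, p.d, p.c, p.k])


class TestInitialStates:
    def test_homogeneous_levels_on_footprint(self, small_mesh):
        st = homogeneous_ic(small_mesh, 0.5, 0.3)
        ids = small_mesh.inoculum_node_ids
        assert (st.B1[ids] == 0.5).all() and (st.B2[ids] == 0.3).all()
        outside = np.setdiff1d(np.arange(small_mesh.n_nodes), ids)
        assert (st.B1[outside] == 0).all()

    def test_homogeneous_mass_matches_disk_area(self, default_mesh):
        # the P1 ramp at the footprint edge costs O(h/R0) mass, so the
        # closed-form comparison is a production-geometry check
        st = homogeneous_ic(default_mesh, 0.5, 0.5)
        m1, m2 = mass_totals(st)
        exact = 0.5 * np.pi * default_mesh.geometry.R0**2
        assert abs(m1 - exact) / exact < 0.02
        assert m1 == m2

    def test_homogeneous_level_validation(self, small_mesh):
        with pytest.raises(ValueError):
            homogeneous_ic(small_mesh, 0.7, 0.7)
        with pytest.raises(ValueError):
            homogeneous_ic(small_mesh, -0.1, 0.2)

    def test_zero_levels_zero_field(self, small_mesh):
        st = homogeneous_ic(small_mesh, 0.0, 0.0)
        assert mass_totals(st) == (0.0, 0.0)

    def test_founder_state_equal_strain_masses(self, small_mesh):
        cfg = place_founders(small_mesh, 6, seed=12)
        st = initial_state_from_config(cfg, small_mesh)
        m1, m2 = mass_totals(st)
        # interior hex-lattice nodes share one patch area
        assert m1 == pytest.approx(m2, rel=1e-9)

    def test_single_strain_config_leaves_other_empty(self, small_mesh):
        cfg = place_founders(small_mesh, 4, seed=1)
        cfg.strains[:] = 1
        st = initial_state_from_config(cfg, small_mesh)
        assert mass_totals(st)[1] == 0.0

    def test_empty_config_zero_state(self, small_mesh, config_factory):
        cfg = config_factory(np.empty((0, 2)), [])
        st = initial_state_from_config(cfg, small_mesh)
        assert mass_totals(st) == (0.0, 0.0)

    def test_off_mesh_positions_rejected(self, small_mesh, config_factory):
        cfg = config_factory([[0.123, 0.456]], [1])
        with pytest.raises(ValueError):
            initial_state_from_config(cfg, small_mesh)


class TestRhs:
    def test_matches_independent_dense_assembly(self):
        mesh = build_disk_mesh(DomainGeometry(R=5.0, R0=2.0, target_element_area=0.5))
        rng = np.random.default_rng(2)
        x, y = mesh.node_coords.T
        B1 = 0.8 * np.exp(-((x - 0.5) ** 2 + y**2))  # Gaussian bump
        B2 = 0.15 * np.ones(mesh.n_nodes)
        for params in (ModelParams.isogenic(), ModelParams.antagonism(r=1.2, d=0.8, c=0.3)):
            got1, got2 = rhs(FieldState(mesh, B1, B2), params)
            exp1, exp2 = dense_rhs_oracle(mesh, B1, B2, params)
            assert np.abs(got1 - exp1).max() < 1e-6
            assert np.abs(got2 - exp2).max() < 1e-6

    def test_capacity_equilibrium_is_stationary(self, small_mesh):
        B1 = np.full(small_mesh.n_nodes, 0.4)
        B2 = np.full(small_mesh.n_nodes, 0.6)
        d1, d2 = rhs(FieldState(small_mesh, B1, B2), ModelParams.isogenic())
        assert np.abs(d1).max() < 1e-12
        assert np.abs(d2).max() < 1e-12

    def test_isogenic_swap_symmetry(self, small_mesh):
        rng = np.random.default_rng(8)
        B1 = rng.uniform(0, 0.5, small_mesh.n_nodes)
        B2 = rng.uniform(0, 0.5, small_mesh.n_nodes)
        d1, d2 = rhs(FieldState(small_mesh, B1, B2), ModelParams.isogenic())
        s2, s1 = rhs(FieldState(small_mesh, B2, B1), ModelParams.isogenic())
        assert np.array_equal(d1, s1)
        assert np.array_equal(d2, s2)

    def test_invalid_states_rejected(self, small_mesh):
        bad = np.zeros(small_mesh.n_nodes)
        nan = bad.copy()
        nan[0] = np.nan
        with pytest.raises(SolverError):
            rhs(FieldState(small_mesh, nan, bad), ModelParams.isogenic())
        neg = bad.copy()
        neg[0] = -0.5
        with pytest.raises(SolverError):
            rhs(FieldState(small_mesh, neg, bad), ModelParams.isogenic())


class TestSolve:
    def test_zero_ic_stays_zero(self, small_mesh):
        st = homogeneous_ic(small_mesh, 0.0, 0.0)
        fin = solve(st, settings=SolverSettings(end_time=2.0))
        assert mass_totals(fin) == (0.0, 0.0)

    def test_homogeneous_half_half_stays_symmetric(self, small_mesh):
        st = homogeneous_ic(small_mesh, 0.5, 0.5)
        fin = solve(st, settings=SolverSettings(end_time=5.0))
        assert np.abs(fin.B1 - fin.B2).max() < 1e-12
        assert competitive_outcome(fin) == 0.5

    def test_boundedness_invariant(self, small_mesh):
        cfg = place_founders(small_mesh, 6, seed=3)
        fin = solve(initial_state_from_config(cfg, small_mesh),
                    settings=SolverSettings(end_time=6.0))
        assert fin.B1.min() >= 0 and fin.B2.min() >= 0
        assert (fin.B1 + fin.B2).max() <= 1.0 + 1e-6

    def test_label_swap_equivariance(self, small_mesh):
        cfg = place_founders(small_mesh, 6, seed=4)
        settings = SolverSettings(end_time=6.0)
        s = competitive_outcome(solve(initial_state_from_config(cfg, small_mesh),
                                      settings=settings))
        sw = competitive_outcome(solve(
            initial_state_from_config(cfg.swap_labels(), small_mesh), settings=settings))
        assert sw == pytest.approx(1.0 - s, abs=1e-12)

    def test_front_hitting_boundary_raises(self):
        mesh = build_disk_mesh(DomainGeometry(R=12.0, R0=10.0, target_element_area=0.72))
        st = homogeneous_ic(mesh, 0.5, 0.5)
        with pytest.raises(DomainTooSmallError):
            solve(st, settings=SolverSettings(end_time=10.0))

    def test_wellmixed_consistency(self, small_mesh):
        """Uniform fields have no gradients, so the PDE trajectory must track
        the well-mixed ODE even with diffusion active."""
        from colonycomp import WellMixedState, integrate_wellmixed

        params = ModelParams.antagonism(r=1.1, d=0.9, c=0.3)
        n = small_mesh.n_nodes
        st = FieldState(small_mesh, np.full(n, 0.2), np.full(n, 0.1))
        fin = solve(st, params, SolverSettings(end_time=5.0, check_front=False, max_dt=0.02))
        _t, b1, b2 = integrate_wellmixed(WellMixedState(0.2, 0.1), params, 5.0)
        assert np.abs(fin.B1 - b1[-1]).max() < 1e-4
        assert np.abs(fin.B2 - b2[-1]).max() < 1e-4

    def test_radial_symmetry_against_1d_reference(self):
        """A single centred microcolony grows into a radially symmetric
        colony consistent with a 1-D radial solve of matched initial mass."""
        geo = DomainGeometry(R=20.0, R0=5.0, target_element_area=0.36)
        mesh = build_disk_mesh(geo)
        i0 = cKDTree(mesh.node_coords).query([0.0, 0.0])[1]
        B1 = np.zeros(mesh.n_nodes)
        B1[i0] = 1.0
        st = FieldState(mesh, B1, np.zeros(mesh.n_nodes))
        h_eq = np.sqrt(3.0 * mass_totals(st)[0] / np.pi)
        fin = solve(st, settings=SolverSettings(end_time=6.0))
        r1, u1 = radial_reference(geo.R, h_eq, 6.0)

        m2d = mass_totals(fin)[0]
        m1d = 2 * np.pi * np.trapezoid(u1 * r1, r1)
        assert abs(m2d / m1d - 1.0) < 0.08
        f2d = fin.front_radius(0.5)
        assert abs(f2d - r1[u1 > 0.5].max()) < 0.6
        # angular variation within radius bins well behind the front
        rr = mesh.node_radii
        h = geo.spacing
        bins = np.floor(rr / h).astype(int)
        worst = max(
            fin.B1[bins == b].std()
            for b in np.unique(bins)
            if (bins == b).sum() > 3 and rr[bins == b].mean() < f2d - 3 * h
        )
        assert worst < 0.03

    def test_two_colonies_abut_overlap_small_and_decreasing(self, small_mesh):
        """Separated colonies meet along a sharp interface: the co-located
        mass is a small fraction of the total and shrinks with separation."""
        tree = cKDTree(small_mesh.node_coords)

        def run(sep):
            B1 = np.zeros(small_mesh.n_nodes)
            B2 = np.zeros(small_mesh.n_nodes)
            B1[tree.query([-sep / 2, 0])[1]] = 1.0
            B2[tree.query([sep / 2, 0])[1]] = 1.0
            fin = solve(FieldState(small_mesh, B1, B2),
                        settings=SolverSettings(end_time=8.0))
            return overlap_fraction(fin)

        near, far = run(6.0), run(14.0)
        assert far < near < 0.15

    def test_mass_quadrature_linearity(self, small_mesh):
        st = homogeneous_ic(small_mesh, 0.25, 0.1)
        st2 = FieldState(small_mesh, 2 * st.B1, 2 * st.B2)
        m = mass_totals(st)
        m2 = mass_totals(st2)
        assert m2[0] == pytest.approx(2 * m[0], rel=1e-14)
        assert m2[1] == pytest.approx(2 * m[1], rel=1e-14)

    def test_outcome_degenerate_cases(self, small_mesh):
        st = homogeneous_ic(small_mesh, 0.5, 0.0)
        assert competitive_outcome(st) == 1.0
        with pytest.raises(ValueError):
            competitive_outcome(homogeneous_ic(small_mesh, 0.0, 0.0))

    def test_mesh_and_step_refinement_convergence(self, coarse_mesh, default_mesh):
        """Halving the element size (and hence the CFL step) moves the
        outcome of a fixed founder layout by less than 0.01."""
        cfg = place_founders(coarse_mesh, 6, seed=17)
        s_coarse = competitive_outcome(solve(
            initial_state_from_config(cfg, coarse_mesh), settings=SolverSettings()))
        # same physical layout on the refined mesh
        ids = cKDTree(default_mesh.node_coords).query(cfg.positions)[1]
        from colonycomp import FounderConfiguration

        fine_cfg = FounderConfiguration(default_mesh.node_coords[ids], cfg.strains,
                                        node_ids=ids)
        s_fine = competitive_outcome(solve(
            initial_state_from_config(fine_cfg, default_mesh), settings=SolverSettings()))
        assert abs(s_fine - s_coarse) < 0.01
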