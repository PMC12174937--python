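"""Macroscale dispersion step: probabilities, partition, update, ledger."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hexsca import (
    DensityField,
    GridSpec,
    ParamField,
    RandomDraws,
    apply_dispersion,
    find_interaction_neighbourhoods,
    inclusion_probability,
    inclusion_weights,
    macro_step,
    partition_and_pool,
    sample_inclusion,
    survival_probability,
    transition_matrix,
)

from conftest import random_field


def forced_example(grid, field, params):
    """The single-affected-cell update with forced draws: the affected cell
    and four halo cells included, survival failing at exactly one."""
    nbhd = find_interaction_neighbourhoods(field, grid)[0]
    centre = next(iter(nbhd.affected))
    halo = sorted(nbhd.halo)
    included = [centre] + halo[:4]
    failed = halo[0]
    incl = {c: int(c in included) for c in nbhd.members}
    surv = {c: int(c != failed) for c in included if c != centre}
    return nbhd, RandomDraws(inclusion=incl, survival=surv), failed


class TestInclusionProbability:
    def test_isolated_affected_cell_probability_is_half_the_density(self):
        # w = 1, d = pi: p = (1/2) * pi
        for pi in np.arange(0.1, 1.05, 0.1):
            assert inclusion_probability(1, pi) == pytest.approx(pi / 2, abs=1e-15)

    def test_zero_weight_gives_zero(self):
        assert inclusion_probability(0, 0.9) == 0.0

    def test_general_form_with_emphasis_exponents(self):
        # w = 3, d = 0.6, alpha = beta = 2: ((9/10) * 0.6)^2
        assert inclusion_probability(3, 0.6, 2, 2) == pytest.approx(0.2916)

    def test_nonpositive_exponents_rejected(self):
        with pytest.raises(ValueError):
            inclusion_probability(1, 0.5, alpha=0.0)
        with pytest.raises(ValueError):
            inclusion_probability(1, 0.5, beta=-1.0)

    @settings(max_examples=200, derandomize=True)
    @given(
        w=st.integers(min_value=0, max_value=7),
        d=st.floats(min_value=0, max_value=1),
        alpha=st.floats(min_value=0.1, max_value=4),
        beta=st.floats(min_value=0.1, max_value=4),
    )
    def test_always_a_probability_and_monotone(self, w, d, alpha, beta):
        p = inclusion_probability(w, d, alpha, beta)
        assert 0.0 <= p <= 1.0
        assert inclusion_probability(w + 1, d, alpha, beta) >= p
        assert inclusion_probability(w, min(1.0, d + 0.1), alpha, beta) >= p


class TestSurvivalProbability:
    def test_empty_cell_gets_baseline(self):
        assert survival_probability(0.0, 0.25, 0.9) == pytest.approx(0.25)

    def test_boundary_case_of_the_parameter_constraint(self):
        # phi = rho = 1/3, pi = 1: 1/3 + (1/3)(pi/4)
        assert survival_probability(1.0, 1 / 3, 1 / 3) == pytest.approx(
            1 / 3 + (1 / 3) * (np.pi / 4)
        )

    @settings(max_examples=100, derandomize=True)
    @given(
        pi=st.floats(min_value=0, max_value=0.95),
        phi=st.floats(min_value=0, max_value=0.5),
        rho=st.floats(min_value=0, max_value=0.6),
        xi=st.floats(min_value=0.2, max_value=3),
    )
    def test_probability_range_and_monotonicity(self, pi, phi, rho, xi):
        if phi + rho * np.arctan(xi) > 1:
            rho = (1 - phi) / np.arctan(xi)
        p = survival_probability(pi, phi, rho, xi)
        assert 0.0 <= p <= 1.0 + 1e-12
        assert survival_probability(min(1.0, pi + 0.05), phi, rho, xi) >= p

    def test_constraint_checked_at_construction(self):
        with pytest.raises(ValueError):
            ParamField(phi=0.9, rho=0.5)


class TestPartitionAndPool:
    def test_single_contributor_with_four_empty_recipients(self, grid5):
        # mean is pi/5 and the pool is 4*gamma1*pi/5
        cells = [grid5.cell(0, k) for k in range(5)]
        dens = {cells[0]: 1.0, **{c: 0.0 for c in cells[1:]}}
        pi_bar, contrib, noncontrib, pool = partition_and_pool(dens, 0.8)
        assert pi_bar == pytest.approx(0.2)
        assert contrib == {cells[0]}
        assert pool == pytest.approx(4 * 0.8 / 5)

    def test_equal_densities_all_contribute_nothing(self, grid5):
        cells = [grid5.cell(0, k) for k in range(4)]
        pi_bar, contrib, noncontrib, pool = partition_and_pool(
            {c: 0.4 for c in cells}, 0.8
        )
        assert pi_bar == pytest.approx(0.4)
        assert contrib == set(cells)
        assert pool == pytest.approx(0.0)

    def test_hand_worked_mixed_densities(self, grid5):
        cells = [grid5.cell(0, k) for k in range(4)]
        dens = dict(zip(cells, [0.9, 0.3, 0.0, 0.0]))
        pi_bar, contrib, noncontrib, pool = partition_and_pool(dens, 0.8)
        assert pi_bar == pytest.approx(0.3)
        assert contrib == {cells[0], cells[1]}
        assert pool == pytest.approx(0.8 * 0.6)

    def test_empty_inclusion_returns_sentinel(self):
        assert partition_and_pool({}, 0.8) is None


class TestApplyDispersion:
    def test_worked_single_cell_update_is_exact(
        self, single_cell_field, base_params
    ):
        grid = GridSpec(4, 4)
        nbhd, draws, failed = forced_example(grid, single_cell_field, base_params)
        out = apply_dispersion(nbhd, draws, base_params, single_cell_field, grid)
        nf = out.next_field.values
        centre = next(iter(nbhd.affected))
        assert nf[centre.i, centre.j] == pytest.approx(0.4624, abs=1e-15)
        recipients = [
            c for c in out.included if c != centre and c != failed
        ]
        assert len(recipients) == 3
        for c in recipients:
            assert nf[c.i, c.j] == pytest.approx(0.1024, abs=1e-15)
        assert nf[failed.i, failed.j] == 0.0
        # all other cells unchanged
        touched = {(c.i, c.j) for c in out.included}
        for i in range(4):
            for j in range(4):
                if (i, j) not in touched:
                    assert nf[i, j] == single_cell_field.values[i, j]
        assert out.pool == pytest.approx(0.64)
        assert out.mean_density == pytest.approx(0.2)

    def test_transition_matrix_reproduces_update_exactly(
        self, single_cell_field, base_params
    ):
        grid = GridSpec(4, 4)
        nbhd, draws, failed = forced_example(grid, single_cell_field, base_params)
        out = apply_dispersion(nbhd, draws, base_params, single_cell_field, grid)
        T, cells = transition_matrix(nbhd, draws, base_params, single_cell_field, grid)
        state = np.array([single_cell_field.values[c.i, c.j] for c in cells])
        nxt = np.array([out.next_field.values[c.i, c.j] for c in cells])
        np.testing.assert_allclose(T @ state, nxt, rtol=0, atol=1e-15)
        # printed symbolic entries of the affected cell's column:
        # recipients 4*g1*g2/25, contributor 1 - 4*g1/5 + 4*g1*g2/25, failed 0
        centre = next(iter(nbhd.affected))
        col = T[:, cells.index(centre)]
        g1 = g2 = 0.8
        vals = sorted(np.round(col, 12))
        assert vals.count(pytest.approx(4 * g1 * g2 / 25)) == 3
        assert max(vals) == pytest.approx(1 - 4 * g1 / 5 + 4 * g1 * g2 / 25)
        assert col[cells.index(failed)] == 0.0

    def test_zero_gamma1_only_zeroing_can_change_state(self, grid8):
        rng = np.random.default_rng(5)
        field = random_field(rng, 8, 8)
        params = ParamField(gamma1=0.0, gamma2=0.8, phi=1 / 3, rho=1 / 3)
        new, outcomes = macro_step(field, params, grid8, seed=9)
        changed = np.nonzero(new.values != field.values)
        zeroed = {
            (c.i, c.j) for o in outcomes for c in o.zeroed
        }
        assert {(int(a), int(b)) for a, b in zip(*changed)} <= zeroed
        assert all(new.values[i, j] == 0.0 for i, j in zeroed)

    def test_full_survival_and_gamma2_one_conserves_mass(self, grid8):
        rng = np.random.default_rng(6)
        # interior blob so no auxiliary recipient exists
        v = np.zeros((8, 8))
        v[3:5, 3:5] = rng.uniform(0.3, 0.9, (2, 2))
        field = DensityField(v)
        params = ParamField(gamma1=0.8, gamma2=1.0, phi=1.0, rho=0.0)
        new, outcomes = macro_step(field, params, grid8, seed=2)
        assert not any(o.zeroed for o in outcomes)
        assert new.values.sum() == pytest.approx(field.values.sum(), abs=1e-12)

    def test_missing_draws_raise_contract_error(
        self, single_cell_field, base_params
    ):
        grid = GridSpec(4, 4)
        nbhd, draws, _ = forced_example(grid, single_cell_field, base_params)
        del draws.inclusion[sorted(nbhd.members)[0]]
        with pytest.raises(ValueError):
            apply_dispersion(nbhd, draws, base_params, single_cell_field, grid)


class TestSampleInclusion:
    def test_zero_probability_includes_nothing(self, grid5):
        v = np.zeros((5, 5))
        v[2, 2] = 0.4
        field = DensityField(v)
        nbhd = find_interaction_neighbourhoods(field, grid5)[0]
        w = inclusion_weights(nbhd, field, grid5)
        for c in w.d:
            w.d[c] = 0.0  # force p_I = 0 everywhere
        draws = sample_inclusion(nbhd, w, ParamField(), 123, grid5)
        assert not any(draws.inclusion.values())

    def test_reproducible_given_seed(self, grid5):
        v = np.zeros((5, 5))
        v[2, 2] = 0.9
        field = DensityField(v)
        nbhd = find_interaction_neighbourhoods(field, grid5)[0]
        w = inclusion_weights(nbhd, field, grid5)
        a = sample_inclusion(nbhd, w, ParamField(), 77, grid5)
        b = sample_inclusion(nbhd, w, ParamField(), 77, grid5)
        assert a.inclusion == b.inclusion

    def test_empirical_inclusion_frequency_matches_probability(self, grid5):
        # p_I = 0.4 for an isolated cell of density 0.8
        n = 100_000
        rng = np.random.default_rng(0)
        hits = (rng.random(n) < 0.4).sum()  # binomial reference band
        v = np.zeros((5, 5))
        v[2, 2] = 0.8
        field = DensityField(v)
        nbhd = find_interaction_neighbourhoods(field, grid5)[0]
        w = inclusion_weights(nbhd, field, grid5)
        centre = grid5.cell(2, 2)
        gen = np.random.default_rng(42)
        count = sum(
            sample_inclusion(nbhd, w, ParamField(), gen, grid5).inclusion[centre]
            for _ in range(2000)
        )
        p_hat = count / 2000
        sigma = np.sqrt(0.4 * 0.6 / 2000)
        assert abs(p_hat - 0.4) < 3 * sigma


class TestMacroStep:
    def test_mass_ledger_balances_on_random_configurations(self, grid8):
        rng = np.random.default_rng(13)
        for k in range(200):
            field = random_field(rng, 8, 8)
            new, outcomes = macro_step(field, ParamField(), grid8, seed=k)
            delta = new.values.sum() - field.values.sum()
            ledger = sum(
                o.lost_in_transit + o.zeroed_mass + o.absorbed_mass
                for o in outcomes
            )
            assert delta + ledger == pytest.approx(0.0, abs=1e-12)
            assert new.values.min() >= 0.0
            assert new.values.max() <= 1.0

    def test_neighbourhood_independence_block_diagonal(self):
        grid = GridSpec(12, 12)
        v = np.zeros((12, 12))
        v[2, 2] = 0.9
        v[9, 9] = 0.7
        field = DensityField(v)
        joint, _ = macro_step(field, ParamField(), grid, seed=31)
        merged = np.zeros((12, 12))
        for cell in [(2, 2, 0.9), (9, 9, 0.7)]:
            alone = np.zeros((12, 12))
            alone[cell[0], cell[1]] = cell[2]
            res, _ = macro_step(DensityField(alone), ParamField(), grid, seed=31)
            merged += res.values
        assert np.array_equal(joint.values, merged)

    def test_empty_field_is_a_fixed_point(self, grid5):
        field = DensityField(np.zeros((5, 5)))
        new, outcomes = macro_step(field, ParamField(), grid5, seed=1)
        assert np.array_equal(new.values, field.values)
        assert outcomes == []

    def test_barrier_cells_never_become_affected(self):
        grid = GridSpec(10, 10)
        barrier = np.zeros((10, 10), dtype=bool)
        barrier[:, 5] = True
        barrier[4, 5] = False  # narrow corridor
        v = np.zeros((10, 10))
        v[4, 2] = 0.9
        field = DensityField(v)
        params = ParamField(gamma1=0.9, gamma2=0.9, phi=0.5, rho=0.3)
        for t in range(60):
            field, _ = macro_step(field, params, grid, seed=8, barrier=barrier, t=t)
            assert not np.any(field.values[barrier] > 0)

    def test_retention_factor_scales_instead_of_zeroing(self):
        grid = GridSpec(5, 5)
        params = ParamField(
            gamma1=0.8, gamma2=0.8, phi=1 / 3, rho=1 / 3, retention=0.5
        )
        centre = grid.cell(2, 2)
        from hexsca import moore_neighbors

        low = moore_neighbors(centre, grid)[0]
        v = np.zeros((5, 5))
        v[centre.i, centre.j] = 1.0
        v[low.i, low.j] = 0.1  # below the included-cell mean: non-contributor
        field = DensityField(v)
        nbhd = find_interaction_neighbourhoods(field, grid)[0]
        incl = {c: int(c in (centre, low)) for c in nbhd.members}
        draws = RandomDraws(inclusion=incl, survival={low: 0})
        out = apply_dispersion(nbhd, draws, params, field, grid)
        assert out.next_field.values[low.i, low.j] == pytest.approx(0.5 * 0.1)
        assert out.zeroed == {low}

    def test_time_varying_parameters_are_resolved_per_step(self, grid5):
        v = np.zeros((5, 5))
        v[2, 2] = 0.8
        field = DensityField(v)
        params = ParamField(gamma1=lambda t: 0.0 if t == 0 else 0.8, phi=1.0, rho=0.0)
        new0, _ = macro_step(field, params, grid5, seed=4, t=0)
        # gamma1 = 0 at t = 0: nothing disperses (survival always succeeds)
        assert np.array_equal(new0.values, field.values)


class TestInhomogeneousConditions:
    def test_eastward_wind_field_biases_the_centre_of_mass(self):
        """A per-cell exponent raster favouring inclusion east of the seed
        shifts the density-weighted centre of mass eastward relative to an
        isotropic run."""
        from hexsca import BirthDeathSpec, equal_area_radius_and_com, run_multiscale
        from hexsca.stats import affected_set

        grid = GridSpec(30, 30)
        beta = np.ones((30, 30))
        beta[:, :15] = 2.0  # suppress inclusion upwind (west)
        beta[:, 15:] = 0.6  # favour inclusion downwind (east)
        bd = BirthDeathSpec()
        v0 = np.zeros((30, 30))
        v0[15, 15] = 0.8
        com_x = {}
        for name, b in (("wind", beta), ("calm", 1.0)):
            xs = []
            for seed in range(4):
                params = ParamField(gamma1=0.8, gamma2=0.8, phi=1 / 3, rho=1 / 3, beta=b)
                snaps = run_multiscale(
                    DensityField(v0.copy()), params, grid, bd, 25, seed=40 + seed
                )
                _, com = equal_area_radius_and_com(
                    affected_set(snaps[-1]), snaps[-1], grid
                )
                xs.append(com[0])
            com_x[name] = np.mean(xs)
        from hexsca import centroid_xy

        seed_x = centroid_xy(grid.cell(15, 15), grid)[0]
        assert com_x["wind"] > com_x["calm"]
        assert com_x["wind"] > seed_x


class TestBoundaryAbsorption:
    def test_corner_cell_dispersion_loses_mass_to_auxiliary_cells(self):
        # phi = 1, rho = 0: survival never zeroes, so any deficit in the
        # mass balance beyond transit loss is boundary absorption
        grid = GridSpec(6, 6)
        v = np.zeros((6, 6))
        v[0, 0] = 1.0
        field = DensityField(v)
        params = ParamField(gamma1=0.9, gamma2=1.0, phi=1.0, rho=0.0)
        absorbed = 0.0
        for seed in range(30):
            _, outcomes = macro_step(field, params, grid, seed=seed)
            absorbed += sum(o.absorbed_mass for o in outcomes)
            for o in outcomes:
                assert not o.zeroed
        assert absorbed > 0.0
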