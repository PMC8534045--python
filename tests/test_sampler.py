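"""Distribution construction, mixing and roulette-wheel draws."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coilgen import ndrd
from coilgen.ndrd import N_BINS, N_CELLS, RamachandranGrid, ResidueKey
from coilgen.sampler import (
    BiasSpec,
    CumulativeSampler,
    GridMissingError,
    Mode,
    ModeContext,
    assign_torsions,
    bias_grid,
    mix_distributions,
    read_bias_file,
    triplet_grid,
)

from conftest import oracle_triplet_ratio, oracle_wrapped_gaussian, random_grid


class TestTripletGrid:
    def test_marginal_equals_neighbor_gives_exact_uniform(self, rng):
        g = random_grid(rng)
        h = random_grid(rng)
        result = triplet_grid(g, h, g, h)
        np.testing.assert_array_equal(result.bins, np.full((72, 72), 1.0 / N_CELLS))

    def test_two_bin_conditional_ratio(self):
        # two distinguished bins carry (0.8, 0.2) vs flat marginals (0.5, 0.5);
        # the combination must keep the 0.8/0.2 odds between those bins
        scale = 0.5
        rest = (1.0 - scale) / (N_CELLS - 2)
        def make(p0, p1):
            bins = np.full((72, 72), rest)
            bins[0, 0] = p0 * scale
            bins[0, 1] = p1 * scale
            return RamachandranGrid(bins)
        result = triplet_grid(make(0.8, 0.2), make(0.5, 0.5),
                              make(0.5, 0.5), make(0.5, 0.5))
        odds = result.bins[0, 0] / (result.bins[0, 0] + result.bins[0, 1])
        assert odds == pytest.approx(0.8, abs=1e-12)

    def test_matches_direct_ratio_oracle(self, rng):
        for _ in range(20):
            grids = [random_grid(rng) for _ in range(4)]
            result = triplet_grid(*grids)
            expected = oracle_triplet_ratio(*(g.bins for g in grids))
            rel = np.abs(result.bins - expected) / expected
            assert rel.max() < 1e-10

    def test_shape_mismatch_rejected(self, rng):
        g = random_grid(rng)
        bad = RamachandranGrid(g.bins.copy())
        bad.bins = bad.bins[:10]
        with pytest.raises(ValueError, match="shape"):
            triplet_grid(g, g, g, bad)


class TestBiasGrid:
    @pytest.mark.parametrize(
        "phi0,psi0,argmax",
        [(-58.0, -47.0, (-60.0, -50.0)), (-120.0, 120.0, (-120.0, 120.0))],
    )
    def test_argmax_bin_contains_center(self, phi0, psi0, argmax):
        grid = bias_grid(BiasSpec(1, phi0, psi0, 10.0, 0.5))
        assert grid.argmax_edges == argmax

    def test_huge_sigma_is_near_uniform(self):
        grid = bias_grid(BiasSpec(1, 0.0, 0.0, 180.0, 0.5))
        assert grid.bins.max() / grid.bins.min() < 1.5
        expected = oracle_wrapped_gaussian(0.0, 0.0, 180.0)
        np.testing.assert_allclose(grid.bins, expected, rtol=1e-9)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            BiasSpec(1, 0.0, 0.0, -5.0, 0.5)
        with pytest.raises(ValueError):
            BiasSpec(1, 0.0, 0.0, 10.0, 1.5)
        with pytest.raises(ValueError):
            BiasSpec(0, 0.0, 0.0, 10.0, 0.5)


class TestMixing:
    def test_weight_zero_is_data_only(self, rng):
        user, data = random_grid(rng), random_grid(rng)
        mixed = mix_distributions(user, data, 0.0)
        np.testing.assert_array_equal(
            mixed.cumulative, CumulativeSampler.from_grid(data).cumulative
        )

    def test_weight_one_is_user_only(self, rng):
        user, data = random_grid(rng), random_grid(rng)
        mixed = mix_distributions(user, data, 1.0)
        np.testing.assert_array_equal(
            mixed.cumulative, CumulativeSampler.from_grid(user).cumulative
        )

    def test_mixing_commutes_with_cumulation(self, rng):
        user, data = random_grid(rng), random_grid(rng)
        mixed = mix_distributions(user, data, 0.5)
        mean_of_cumulatives = 0.5 * (
            CumulativeSampler.from_grid(user).cumulative
            + CumulativeSampler.from_grid(data).cumulative
        )
        assert np.max(np.abs(mixed.cumulative - mean_of_cumulatives)) < 1e-12

    @pytest.mark.parametrize("w", [-0.1, 1.01])
    def test_weight_out_of_range(self, rng, w):
        g = random_grid(rng)
        with pytest.raises(ValueError):
            mix_distributions(g, g, w)


class TestCumulativeSampler:
    def test_u_zero_returns_first_nonzero_bin(self):
        bins = np.zeros((72, 72))
        bins[0, 3] = 0.4
        bins[10, 10] = 0.6
        sampler = CumulativeSampler.from_probs(bins)
        assert sampler.draw(0.0) == (-180.0, -165.0)

    def test_upper_boundary_returns_last_bin(self):
        bins = np.full((72, 72), 1.0)
        sampler = CumulativeSampler.from_probs(bins)
        assert sampler.draw(0.999999) == (175.0, 175.0)

    def test_draw_is_deterministic_in_u(self, rng):
        sampler = CumulativeSampler.from_grid(random_grid(rng))
        us = rng.random(100)
        first = [sampler.draw(u) for u in us]
        second = [sampler.draw(u) for u in us]
        assert first == second
        np.testing.assert_array_equal(sampler.draw_many(us), np.array(first))

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_cumulative_contract(self, seed):
        # monotone non-decreasing, starts >= 0, ends at exactly 1
        grid = random_grid(np.random.default_rng(seed))
        cum = CumulativeSampler.from_grid(grid).cumulative
        assert cum[0] >= 0.0
        assert np.all(np.diff(cum) >= 0)
        assert cum[-1] == 1.0


class TestAssignTorsions:
    def make_context(self, sequence, mode, grids=None, biases=None, rng=None):
        if grids is None:
            gen = np.random.default_rng(0)
            grids = {
                key: random_grid(gen) for key in ndrd.keys_for_sequence(sequence)
            }
        return ModeContext(Mode(mode), grids, biases)

    def test_single_residue_uses_terminal_fallback(self):
        context = self.make_context("A", Mode.LEFT)
        torsions = assign_torsions("A", context, np.random.default_rng(1))
        assert len(torsions) == 1

    def test_triplet_needs_exactly_the_interior_keys(self):
        # residue 2 of "ACG" draws from the combination of the CYS tables
        # with ALA on the left and GLY on the right, plus the CYS marginals
        needed = {
            ResidueKey("CYS", "left", "ALA"),
            ResidueKey("CYS", "right", "GLY"),
            ResidueKey("CYS", "left", "ALL"),
            ResidueKey("CYS", "right", "ALL"),
            # terminal residues degrade to RIGHT / LEFT mode
            ResidueKey("ALA", "right", "CYS"),
            ResidueKey("GLY", "left", "CYS"),
        }
        gen = np.random.default_rng(2)
        grids = {key: random_grid(gen) for key in needed}
        context = ModeContext(Mode.TRIPLET, grids)
        torsions = assign_torsions("ACG", context, np.random.default_rng(3))
        assert len(torsions) == 3

    def test_missing_grid_error_names_key(self):
        context = ModeContext(Mode.LEFT, {})
        with pytest.raises(GridMissingError, match="ALA left ALL"):
            assign_torsions("A", context, np.random.default_rng(0))

    def test_same_seed_reproduces_torsions(self, seq55_grids):
        from conftest import SEQ55

        context = ModeContext(Mode.TRIPLET, seq55_grids)
        a = assign_torsions(SEQ55, context, np.random.default_rng(42))
        b = assign_torsions(SEQ55, context, np.random.default_rng(42))
        assert a == b

    def test_angles_are_grid_multiples(self, seq55_grids):
        from conftest import SEQ55

        context = ModeContext(Mode.TRIPLET, seq55_grids)
        torsions = np.array(
            assign_torsions(SEQ55, context, np.random.default_rng(7))
        )
        assert np.all(torsions % 5.0 == 0.0)
        assert torsions.min() >= -180.0 and torsions.max() <= 175.0

    def test_weighted_mode_requires_bias_table(self, seq55_grids):
        with pytest.raises(ValueError, match="bias"):
            ModeContext(Mode.WEIGHTED_TRIPLET, seq55_grids, None)

    def test_full_weight_bias_pins_residue_to_gaussian(self, seq55_grids):
        from conftest import SEQ55

        # weight-1 helical bias with tiny sigma: residue 10 must land in
        # the bin containing (-58, -47)
        biases = {10: BiasSpec(10, -58.0, -47.0, 1.0, 1.0)}
        context = ModeContext(Mode.WEIGHTED_TRIPLET, seq55_grids, biases)
        for seed in range(5):
            torsions = assign_torsions(SEQ55, context, np.random.default_rng(seed))
            assert torsions[9] == (-60.0, -50.0)


def test_read_bias_file(tmp_path):
    path = tmp_path / "bias.txt"
    path.write_text(
        "# index phi0 psi0 sigma weight\n"
        "1 -58 -47 10 0.99\n"
        "56 -58 -47 10 0.80  # C-terminal taper\n"
    )
    biases = read_bias_file(path)
    assert set(biases) == {1, 56}
    assert biases[56].weight == 0.80
    bad = tmp_path / "bad.txt"
    bad.write_text("1 2 3\n")
    with pytest.raises(ValueError, match="5 columns"):
        read_bias_file(bad)
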