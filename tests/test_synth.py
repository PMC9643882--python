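"""Simulator: endmember structure, convex mixing, artifacts, Table-1 design."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bloodspec as bs
from bloodspec.errors import InvalidCompositionError
from bloodspec.synth import KEY_WAVENUMBERS, SPECIES, classify_fractions


class TestEndmembers:
    def test_twelve_key_band_centers(self, endmembers):
        for sp in SPECIES:
            centers = [c for c, _, _ in endmembers[sp].bands]
            assert centers == list(KEY_WAVENUMBERS)
            assert len(centers) == 12

    def test_amplitude_tables_pairwise_distinct(self, endmembers):
        amps = {sp: np.array([a for _, _, a in endmembers[sp].bands]) for sp in SPECIES}
        for a in SPECIES:
            for b in SPECIES:
                if a < b:
                    # separability needs at least 6 differing amplitudes
                    assert np.sum(amps[a] != amps[b]) >= 6

    def test_pure_spectra_strictly_positive(self, endmembers, grid):
        for sp in SPECIES:
            assert np.all(endmembers[sp].evaluate(grid) > 0)

    def test_invalid_band_parameters_rejected(self):
        with pytest.raises(ValueError):
            bs.EndmemberSet("DBT", bands=((5000.0, -1.0, 0.5),), baseline_level=0.1)
        with pytest.raises(ValueError):
            bs.EndmemberSet("DBT", bands=((3000.0, 50.0, 0.5),), baseline_level=0.1)


class TestMixing:
    def test_pure_fraction_returns_endmember(self, endmembers, grid):
        mixed = bs.mix_spectrum(endmembers, np.array([1.0, 0.0, 0.0]), grid)
        np.testing.assert_array_equal(mixed, endmembers["DBT"].evaluate(grid))

    def test_linearity_in_fractions(self, endmembers, grid):
        a = bs.mix_spectrum(endmembers, np.array([1.0, 0.0, 0.0]), grid)
        b = bs.mix_spectrum(endmembers, np.array([0.0, 0.5, 0.5]), grid)
        mid = bs.mix_spectrum(endmembers, np.array([0.5, 0.25, 0.25]), grid)
        np.testing.assert_allclose(mid, (a + b) / 2, rtol=0, atol=1e-12)

    def test_ternary_ten_percent_composition_accepted(self, endmembers, grid):
        out = bs.mix_spectrum(endmembers, np.array([0.9, 0.05, 0.05]), grid)
        assert out.shape == grid.shape

    def test_invalid_composition_rejected(self, endmembers, grid):
        with pytest.raises(InvalidCompositionError):
            bs.mix_spectrum(endmembers, np.array([0.5, 0.5, 0.5]), grid)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_mixture_between_endmember_envelopes(self, endmembers, grid, u, v):
        f = np.array([u, (1 - u) * v, (1 - u) * (1 - v)])
        f = f / f.sum() if f.sum() > 0 else np.array([1.0, 0.0, 0.0])
        if abs(f.sum() - 1) > 1e-9:
            return
        mixed = bs.mix_spectrum(endmembers, f, grid)
        pures = np.vstack([endmembers[sp].evaluate(grid) for sp in SPECIES])
        assert np.all(mixed >= pures.min(axis=0) - 1e-12)
        assert np.all(mixed <= pures.max(axis=0) + 1e-12)


class TestArtifacts:
    def test_zero_noise_is_identity(self, grid):
        params = bs.ArtifactParams(0.0, 0.0, 0.0, 0.0, n_replicates=3)
        spec = np.linspace(0.2, 1.0, grid.size)
        out = bs.apply_artifacts(spec, grid, params, np.random.default_rng(0))
        np.testing.assert_array_equal(out, spec)

    def test_same_seed_reproducible(self, grid):
        params = bs.ArtifactParams()
        spec = np.linspace(0.2, 1.0, grid.size)
        a = bs.apply_artifacts(spec, grid, params, np.random.default_rng(42))
        b = bs.apply_artifacts(spec, grid, params, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_replicate_averaging_shrinks_noise_variance(self):
        # white noise only: averaging 3 replicates leaves variance sd^2/3
        sd, n_rep, n_draws = 0.01, 3, 10_000
        params = bs.ArtifactParams(0.0, 0.0, 0.0, noise_sd=sd, n_replicates=n_rep)
        grid = np.linspace(4000, 10000, 4)
        rng = np.random.default_rng(7)
        draws = np.array(
            [bs.apply_artifacts(np.zeros(4), grid, params, rng) for _ in range(n_draws)]
        )
        observed = draws.var()
        expected = sd**2 / n_rep
        assert abs(observed - expected) < 4 * expected / np.sqrt(n_draws)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            bs.ArtifactParams(noise_sd=-1.0)


class TestDesign:
    def test_table_counts(self, design):
        assert design.n_samples == 540
        counts = {c: int(np.sum(design.class_labels == c)) for c in set(design.class_labels)}
        assert counts == {
            "raw_dbt": 30, "pure_cbg": 30, "pure_pbg": 30,
            "dbt_cbg": 150, "dbt_pbg": 150, "ternary": 150,
        }

    def test_grid_is_instrument_grid(self, design):
        assert design.n_variables == 1557
        assert design.wavenumbers[0] == 4000.0
        assert design.wavenumbers[-1] == 10000.0
        assert np.all(np.diff(design.wavenumbers) > 0)

    def test_fraction_simplex(self, design):
        np.testing.assert_allclose(design.fractions.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(design.fractions >= 0)

    def test_ternary_equal_adulterant_split(self, design):
        tern = design.fractions[design.class_labels == "ternary"]
        np.testing.assert_array_equal(tern[:, 1], tern[:, 2])

    def test_binary_levels_are_ten_to_fifty(self, design):
        cbg = design.fractions[design.class_labels == "dbt_cbg"][:, 1]
        assert set(np.round(cbg * 100).astype(int)) == {10, 20, 30, 40, 50}

    def test_labels_consistent_with_fractions(self, design):
        for f, lab in zip(design.fractions, design.class_labels):
            assert classify_fractions(f) == lab

    def test_seeded_design_bit_reproducible(self):
        a = bs.generate_design(seed=3)
        b = bs.generate_design(seed=3)
        np.testing.assert_array_equal(a.absorbance, b.absorbance)

    def test_per_sample_substreams_stable_under_subsetting(self, design):
        # sample spectra don't depend on how many other cells were generated
        again = bs.generate_design(seed=1)
        np.testing.assert_array_equal(design.absorbance[100], again.absorbance[100])

    def test_pure_class_means_pairwise_distinct(self, clean_design):
        means = {
            c: clean_design.absorbance[clean_design.class_labels == c].mean(axis=0)
            for c in ("raw_dbt", "pure_cbg", "pure_pbg")
        }
        default_noise = bs.ArtifactParams().noise_sd
        for a in means:
            for b in means:
                if a < b:
                    assert np.abs(means[a] - means[b]).max() > 10 * default_noise

    def test_fractions_recoverable_by_regression_on_endmembers(
        self, clean_design, endmembers, grid
    ):
        # linearity oracle: zero-artifact spectra are exact endmember mixes
        E = np.vstack([endmembers[sp].evaluate(grid) for sp in SPECIES]).T
        coef, *_ = np.linalg.lstsq(E, clean_design.absorbance.T, rcond=None)
        np.testing.assert_allclose(coef.T, clean_design.fractions, atol=1e-8)
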