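"""Synthetic-cohort generator: determinism, calibration, couplings."""

import numpy as np
import pytest
from scipy import stats as sps

from boneqol.cohort import (
    Couplings,
    MixtureParams,
    default_spec,
    gen_cohort,
    gen_responses,
    gen_utilities,
)
from boneqol.io import write_cohort
from boneqol.stats import fit_linear


class TestUtilityMixture:
    def test_values_respect_truncation_bounds(self, rng):
        mix = MixtureParams()
        u = gen_utilities(5000, mix, rng)
        assert u.min() >= mix.bounds[0]
        assert u.max() <= mix.bounds[1]

    def test_determinism_given_seed(self):
        a = gen_utilities(100, seed=42)
        b = gen_utilities(100, seed=42)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, gen_utilities(100, seed=43))

    def test_degenerate_sd_rejected(self):
        with pytest.raises(ValueError, match="SD"):
            MixtureParams(sds=(0.0, 0.12))

    def test_large_sample_mean_matches_quadrature_oracle(self):
        """Sample mean of the default mixture vs numerical integration
        of the truncated components."""
        mix = MixtureParams()
        # oracle: weighted truncated-normal means, computed independently
        expected = 0.0
        for w, m, s in zip(mix.weights, mix.means, mix.sds):
            a, b = (mix.bounds[0] - m) / s, (mix.bounds[1] - m) / s
            expected += w * sps.truncnorm.mean(a, b, loc=m, scale=s)
        u = gen_utilities(1_000_000, mix, seed=7)
        assert u.mean() == pytest.approx(expected, abs=0.01)
        assert expected == pytest.approx(0.65, abs=0.01)

    def test_lowest_fifteen_of_43_calibration(self):
        """Expected mean of the 15 lowest utilities in a 43-draw sample
        is ~0.339, the moment the economic simulation depends on."""
        rng = np.random.default_rng(11)
        mix = MixtureParams()
        lows = []
        for _ in range(600):
            u = gen_utilities(43, mix, rng)
            lows.append(np.sort(u)[:15].mean())
        assert np.mean(lows) == pytest.approx(0.339, abs=0.01)

    def test_ppf_inverts_cdf(self):
        mix = MixtureParams()
        q = np.linspace(0.01, 0.99, 25)
        x = mix.ppf(q)
        assert np.allclose(mix.cdf(x), q, atol=1e-9)


class TestResponses:
    def test_point_mass_yields_all_threes(self):
        probs = {d: np.eye(5)[2] for d in ("MO", "SC", "UA", "PD", "AD")}
        states = gen_responses(50, probs, seed=0)
        assert all(s.levels == (3, 3, 3, 3, 3) for s in states)

    def test_same_seed_identical_output(self):
        probs = {d: np.full(5, 0.2) for d in ("MO", "SC", "UA", "PD", "AD")}
        a = gen_responses(200, probs, seed=5)
        b = gen_responses(200, probs, seed=5)
        assert a == b

    def test_empirical_frequencies_converge_to_oi_pain_probs(self):
        """At n = 1e5 the pain/discomfort level frequencies match the
        published OI distribution (3,14,19,4,3)/43 within +-0.01."""
        target = np.array([3, 14, 19, 4, 3]) / 43
        probs = {d: (target if d == "PD" else np.full(5, 0.2))
                 for d in ("MO", "SC", "UA", "PD", "AD")}
        states = gen_responses(100_000, probs, seed=3)
        pd_levels = np.array([s.pd for s in states])
        freq = np.bincount(pd_levels, minlength=6)[1:] / len(states)
        assert np.allclose(freq, target, atol=0.01)

    def test_invalid_probabilities_rejected(self):
        probs = {d: np.full(5, 0.25) for d in ("MO", "SC", "UA", "PD", "AD")}
        with pytest.raises(ValueError, match="sum to 1"):
            gen_responses(10, probs, seed=0)


class TestCohortAssembly:
    def test_default_spec_sizes(self):
        cohort = gen_cohort(default_spec(seed=0))
        assert len(cohort) == 109
        sizes = cohort.df.disease.value_counts().to_dict()
        assert sizes == {"OI": 43, "FD": 42, "XLH": 24}

    def test_byte_identical_serialization_under_fixed_seed(self, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cohort(gen_cohort(default_spec(seed=9)), p1)
        write_cohort(gen_cohort(default_spec(seed=9)), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_ages_within_configured_ranges(self):
        cohort = gen_cohort(default_spec(seed=4))
        for disease, params in default_spec().age_params.items():
            ages = cohort.df.loc[cohort.df.disease == disease, "age"]
            assert ages.between(params.low, params.high).all()

    def test_utilities_within_value_set_range(self):
        cohort = gen_cohort(default_spec(seed=4))
        assert cohort.df.utility.between(-0.285, 1.0).all()

    def test_zero_coupling_gives_uncorrelated_age_and_vas(self):
        spec = default_spec(
            seed=21,
            n_by_disease={"OI": 10_000},
            couplings={"OI": Couplings()},
        )
        df = gen_cohort(spec).df
        r = sps.pearsonr(df.age, df.vas)[0]
        assert abs(r) < 0.05

    def test_injected_utility_age_slope_recovered(self):
        """OLS on a large generated OI sample recovers the configured
        -0.005/year utility-on-age slope within +-0.002."""
        spec = default_spec(seed=13, n_by_disease={"OI": 10_000})
        df = gen_cohort(spec).df
        slope, _, _, _ = fit_linear(df.age, df.utility)
        assert slope == pytest.approx(-0.005, abs=0.002)

    def test_age_couplings_hit_targets(self):
        spec = default_spec(seed=17, n_by_disease={"OI": 10_000})
        df = gen_cohort(spec).df
        assert sps.pearsonr(df.age, df.ua)[0] == pytest.approx(0.39, abs=0.1)
        assert sps.pearsonr(df.age, df.vas)[0] == pytest.approx(-0.42, abs=0.1)

    def test_infeasible_coupling_raises(self):
        spec = default_spec(seed=0)
        spec.couplings["OI"] = Couplings(age_usual_activity=0.999)
        with pytest.raises(ValueError, match="infeasible coupling"):
            gen_cohort(spec)

    def test_valueset_mode_recomputes_utilities_from_states(self, england_vs):
        spec = default_spec(seed=6, utility_mode="valueset")
        cohort = gen_cohort(spec, value_set=england_vs)
        for p in list(cohort.patients())[:20]:
            assert p.utility == pytest.approx(england_vs.utility(p.state))

    def test_adding_a_disease_does_not_perturb_existing_streams(self):
        """Child-seed derivation isolates per-disease streams."""
        full = gen_cohort(default_spec(seed=30)).df
        oi_only = gen_cohort(default_spec(seed=30, n_by_disease={"OI": 43})).df
        assert np.array_equal(
            full[full.disease == "OI"].utility.to_numpy(),
            oi_only.utility.to_numpy(),
        )

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            default_spec(n_by_disease={"OI": 2})
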