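"""Generator invariants: social structure, convergence mechanics, call
synthesis determinism and the dyadic beta simulator's distribution."""

import numpy as np
import pytest
from scipy.special import expit

from callsim import synth
from callsim.synth import ConvergenceSpec


class TestMakePopulation:
    def test_rejects_single_bat(self):
        with pytest.raises(ValueError):
            synth.make_population(1, 1)

    def test_cohoused_cross_site_pairs_are_introduced(self):
        profiles, social = synth.make_population(
            12, 2, seed=0, colonies=[[0, 1]]
        )
        for i, j in social.pair_index():
            si, sj = profiles[i].site, profiles[j].site
            if si != sj:
                assert social.familiarity_class[i, j] == "introduced-cohoused"
            else:
                assert social.familiarity_class[i, j] == "same-site-cohoused"

    def test_never_met_pair_has_zero_interaction(self):
        _, social = synth.make_population(2, 2, seed=0, colonies=[[0], [1]])
        assert social.familiarity_class[0, 1] == "never-met"
        assert social.groom_seconds[0, 1] == 0
        assert social.share_seconds[0, 1] == 0

    def test_call_count_median_matches_target(self):
        # across 200 draws the per-bat call-count median should sit near 2500
        counts = []
        for s in range(3):
            profiles, _ = synth.make_population(95, 4, seed=s)
            counts.extend(p.n_calls for p in profiles)
        counts = np.asarray(counts[:200])
        med = np.median(counts)
        assert 1700 < med < 3700
        # heavy tail: mean well above median
        assert counts.mean() > 1.5 * med

    def test_deterministic_given_seed(self):
        a, _ = synth.make_population(8, 2, seed=42)
        b, _ = synth.make_population(8, 2, seed=42)
        for pa, pb in zip(a, b):
            assert pa.contour_params == pb.contour_params
            assert pa.n_calls == pb.n_calls


class TestApplyConvergence:
    def test_identity_when_deltas_zero(self, small_population):
        profiles, social = small_population
        out = synth.apply_convergence(profiles, social, ConvergenceSpec(0, 0))
        for p, q in zip(profiles, out):
            assert p.contour_params == q.contour_params

    def test_full_shrinkage_collapses_colony(self, small_population):
        profiles, social = small_population
        out = synth.apply_convergence(profiles, social, ConvergenceSpec(1.0, 0))
        cohoused = np.nonzero(social.cohoused[0])[0]
        ref = out[0].contour_params
        for j in cohoused:
            assert out[j].contour_params == pytest.approx(ref)

    def test_half_shrinkage_moves_means_halfway(self):
        # two co-housed bats with duration means 20 and 40 -> 25 and 35
        profiles, social = synth.make_population(2, 1, seed=0)
        for p, d in zip(profiles, (20.0, 40.0)):
            p.contour_params["duration_ms"] = d
        out = synth.apply_convergence(profiles, social, ConvergenceSpec(0.5, 0))
        assert out[0].contour_params["duration_ms"] == pytest.approx(25.0)
        assert out[1].contour_params["duration_ms"] == pytest.approx(35.0)

    def test_bat_without_cagemates_unchanged(self):
        # 3 bats, 2 sites, each site its own colony: bat 1 is alone at site 1
        profiles, social = synth.make_population(3, 2, seed=2, colonies=[[0], [1]])
        lonely = [i for i in range(3) if not social.cohoused[i].any()]
        assert lonely == [1]
        out = synth.apply_convergence(profiles, social, ConvergenceSpec(0.7, 0.1))
        assert out[1].contour_params == profiles[1].contour_params

    def test_pairwise_distance_monotone_in_delta(self):
        rng_seeds = range(3)
        grid = [0.0, 0.25, 0.5, 0.75, 1.0]
        for s in rng_seeds:
            profiles, social = synth.make_population(8, 2, seed=s, colonies=[[0, 1]])
            dists = []
            for d in grid:
                out = synth.apply_convergence(profiles, social, ConvergenceSpec(d, 0))
                theta = np.array(
                    [[p.contour_params[k] for k in synth.CONTOUR_PARAMS] for p in out]
                )
                dd = [
                    np.linalg.norm(theta[i] - theta[j])
                    for i, j in social.pair_index()
                    if social.cohoused[i, j]
                ]
                dists.append(np.mean(dd))
            assert all(a >= b - 1e-12 for a, b in zip(dists, dists[1:]))

    def test_dimension_mismatch_rejected(self, small_population):
        profiles, social = small_population
        with pytest.raises(ValueError):
            synth.apply_convergence(profiles[:5], social, ConvergenceSpec(0.5, 0))


class TestSynthesizeCall:
    def test_unsupported_rate_rejected(self, small_population):
        with pytest.raises(ValueError):
            synth.synthesize_call(small_population[0][0], rate=44_100)

    def test_same_seed_bit_identical(self, small_population):
        p = small_population[0][0]
        a = synth.synthesize_call(p, 250_000, 20.0, seed=9)
        b = synth.synthesize_call(p, 250_000, 20.0, seed=9)
        assert np.array_equal(a, b)

    def test_clean_sweep_contour_tracks_profile(self):
        from callsim.detect import CallSegment
        from callsim.features import fundamental_contour

        p = synth.BatProfile(
            "x", "s", "F", "adult",
            {"f_start_khz": 80.0, "f_end_khz": 20.0, "duration_ms": 10.0,
             "curvature": 3.0},
            within_bat_sd={k: 1e-9 for k in synth.DEFAULT_WITHIN_SD},
        )
        x = synth.synthesize_call(p, 250_000, np.inf, seed=0)
        seg = CallSegment("x", 0.0, len(x) / 250e3, x, 250_000)
        c = fundamental_contour(seg)
        voiced = ~np.isnan(c.freq_khz)
        assert voiced.mean() > 0.8
        # analytic contour f(t) = f_end + (f_start - f_end) e^{-c t/T} at the
        # first/last frame centers (~0.5 ms inside each edge)
        T = 10.0
        t0, t1 = c.times_ms[voiced][0], c.times_ms[voiced][-1]
        f = lambda t: 20.0 + 60.0 * np.exp(-3.0 * t / T)
        assert c.freq_khz[voiced][0] == pytest.approx(f(t0), abs=4.0)
        assert c.freq_khz[voiced][-1] == pytest.approx(f(t1), abs=4.0)

    def test_duration_within_contract(self, small_population):
        p = small_population[0][0]
        for s in range(10):
            x = synth.synthesize_call(p, 250_000, np.inf, seed=s)
            assert 3e-3 <= len(x) / 250e3 <= 50e-3


class TestRecordingSession:
    def test_zero_calls_pure_noise(self, small_population):
        wav, truth = synth.generate_recording_session(
            small_population[0][0], 0, seed=0
        )
        assert truth.empty
        assert np.abs(wav).max() < 0.1

    def test_truth_segments_disjoint(self, small_population):
        _, truth = synth.generate_recording_session(small_population[0][0], 5, seed=1)
        assert len(truth) == 5
        assert (truth["offset_s"].to_numpy()[:-1] <= truth["onset_s"].to_numpy()[1:]).all()


class TestDyadicGenerator:
    def test_rejects_nonpositive_phi(self):
        with pytest.raises(ValueError):
            synth.generate_dyadic_dataset(10, {}, phi=0.0, sigma_bat=0.1)

    def test_null_model_centered_at_half(self):
        table, _ = synth.generate_dyadic_dataset(40, {}, phi=20, sigma_bat=0.0, seed=0)
        assert table["similarity"].mean() == pytest.approx(0.5, abs=0.02)

    def test_large_phi_concentrates_at_inverse_logit(self):
        table, _ = synth.generate_dyadic_dataset(
            30, {"cohoused": 1.0}, phi=5e4, sigma_bat=0.0, seed=1, alpha=-0.5
        )
        mu = expit(-0.5 + table["cohoused"].to_numpy())
        assert np.abs(table["similarity"].to_numpy() - mu).max() < 0.02

    def test_moments_match_beta_distribution(self):
        # empirical mean/variance vs Beta(mu*phi, (1-mu)*phi) at n = 10 000
        phi, alpha = 25.0, 0.4
        table, _ = synth.generate_dyadic_dataset(
            142, {}, phi=phi, sigma_bat=0.0, seed=3, alpha=alpha
        )
        y = table["similarity"].to_numpy()[:10_000]
        mu = expit(alpha)
        var = mu * (1 - mu) / (1 + phi)
        assert y.mean() == pytest.approx(mu, abs=4 * np.sqrt(var / len(y)))
        assert y.var() == pytest.approx(var, rel=0.1)

    def test_deterministic_given_seed(self):
        a, _ = synth.generate_dyadic_dataset(12, {"kinship": 1.0}, 20, 0.2, seed=5)
        b, _ = synth.generate_dyadic_dataset(12, {"kinship": 1.0}, 20, 0.2, seed=5)
        assert a.equals(b)
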