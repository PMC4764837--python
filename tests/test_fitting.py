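import numpy as np
import pytest
from scipy import stats

from consensusconf.cmaes import cma_minimize
from consensusconf.fitting import (
    BehavioralDataset,
    MeritConfig,
    TargetMeanDistribution,
    confidence_merit,
    decision_merit,
    fit_stage,
    generate_synthetic_subject,
    pearson_chi2,
    sample_confidence_counts,
    simulate_behavioral_trials,
)
from consensusconf.params import ModelParams
from consensusconf.readout import ConfidenceMap
from consensusconf.stimulus import LuminanceTransform

TINY = ModelParams(n_modules=9)
G0 = LuminanceTransform().g
B0 = LuminanceTransform().b


class TestPearsonChi2:
    def test_perfect_agreement_is_zero(self):
        assert pearson_chi2([50, 50], [0.5, 0.5]) == 0.0

    def test_hand_computed_value(self):
        assert pearson_chi2([60, 40], [0.5, 0.5]) == pytest.approx(4.0)

    def test_doubling_counts_doubles_statistic(self):
        x1 = pearson_chi2([30, 50, 20], [0.3, 0.5, 0.2])
        x2 = pearson_chi2([60, 100, 40], [0.3, 0.5, 0.2])
        assert x2 == pytest.approx(2 * x1)
        # and is invariant when observed == expected exactly
        assert pearson_chi2([30, 50, 20], [0.3, 0.5, 0.2]) == pytest.approx(0.0)

    def test_zero_expected_count_suggests_pooling(self):
        with pytest.raises(ValueError, match="pool"):
            pearson_chi2([10, 0], [1.0, 0.0])

    def test_unnormalized_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            pearson_chi2([10, 10], [0.5, 0.6])

    def test_matches_textbook_implementation_on_random_tables(self, rng):
        # independent oracle: scipy.stats.chisquare
        for _ in range(50):
            k = int(rng.integers(2, 6))
            obs = rng.integers(1, 100, size=k)
            p = rng.dirichlet(np.ones(k) * 2) + 0.01
            p = p / p.sum()
            ours = pearson_chi2(obs, p)
            ref = stats.chisquare(obs, f_exp=obs.sum() * p).statistic
            assert ours == pytest.approx(ref, abs=1e-10)


class TestCmaes:
    def test_sphere_recovered(self):
        rng = np.random.default_rng(0)
        res = cma_minimize(
            lambda x: float(np.sum((x - [0.4, -0.2]) ** 2)),
            [0.0, 0.0],
            0.3,
            rng=rng,
            max_iter=200,
        )
        np.testing.assert_allclose(res.x, [0.4, -0.2], atol=1e-3)

    def test_bounds_respected(self):
        rng = np.random.default_rng(1)
        res = cma_minimize(
            lambda x: float(np.sum((x - 2.0) ** 2)),
            [0.0],
            0.5,
            bounds=[(-1.0, 1.0)],
            rng=rng,
            max_iter=100,
        )
        assert -1.0 <= res.x[0] <= 1.0
        assert res.x[0] == pytest.approx(1.0, abs=1e-3)

    def test_non_finite_objective_raises(self):
        rng = np.random.default_rng(2)
        with pytest.raises(FloatingPointError):
            cma_minimize(lambda x: np.nan, [0.0], 0.5, rng=rng)


@pytest.fixture(scope="module")
def tiny_subject():
    rng = np.random.default_rng(42)
    return generate_synthetic_subject(
        G0, B0, 0.06, 0.39, 300, rng, params=TINY, wait=0.2, max_t=1.0
    )


class TestSyntheticSubject:
    def test_same_seed_same_dataset(self):
        d1 = generate_synthetic_subject(
            G0, B0, 0.06, 0.39, 40, np.random.default_rng(5), params=TINY,
            wait=0.2, max_t=1.0,
        )
        d2 = generate_synthetic_subject(
            G0, B0, 0.06, 0.39, 40, np.random.default_rng(5), params=TINY,
            wait=0.2, max_t=1.0,
        )
        np.testing.assert_array_equal(d1.lum, d2.lum)
        np.testing.assert_array_equal(d1.choice, d2.choice)
        np.testing.assert_array_equal(d1.rt, d2.rt)
        np.testing.assert_array_equal(
            np.nan_to_num(d1.confidence), np.nan_to_num(d2.confidence)
        )

    def test_accuracy_increases_with_target_offset(self):
        accs = []
        for hi_lo in ((51.0, 53.0), (62.0, 70.0)):
            dist = TargetMeanDistribution(loc=np.mean(hi_lo), scale=1.0, lo=hi_lo[0], hi=hi_lo[1])
            ds = generate_synthetic_subject(
                G0, B0, 0.06, 0.39, 150, np.random.default_rng(8),
                params=TINY, target_dist=dist, wait=0.2, max_t=1.0,
            )
            accs.append(ds.correct[ds.decided].mean())
        assert accs[1] > accs[0]

    def test_four_way_counts_partition_decided_trials(self, tiny_subject):
        ds = tiny_subject
        reported = ds.decided & ~np.isnan(np.asarray(ds.confidence))
        assert ds.counts_4way().sum() == int(reported.sum())
        assert ds.counts_2way().sum() == int(ds.decided.sum())

    def test_save_load_round_trip(self, tiny_subject, tmp_path):
        ds = tiny_subject
        ds.save(tmp_path / "subj")
        back = BehavioralDataset.load(tmp_path / "subj")
        np.testing.assert_allclose(back.lum, ds.lum)
        np.testing.assert_array_equal(back.choice, ds.choice)
        np.testing.assert_allclose(back.nominal_means, ds.nominal_means)
        np.testing.assert_array_equal(back.counts_4way(), ds.counts_4way())


class TestDecisionMerit:
    def test_components_sum_to_total(self, tiny_subject):
        cfg = MeritConfig(n_sim=60, wait=0.2, deadline=1.0)
        merit, comps = decision_merit(
            G0, B0, tiny_subject, cfg, TINY, np.random.default_rng(0),
            return_components=True,
        )
        assert merit == pytest.approx(sum(comps.values()))
        assert set(comps) == {"lsq", "chi2", "early", "undecided"}

    def test_blind_network_is_worse_than_truth(self, tiny_subject):
        cfg = MeritConfig(n_sim=150, wait=0.2, deadline=1.0)
        m_true = decision_merit(
            G0, B0, tiny_subject, cfg, TINY, np.random.default_rng(1)
        )
        m_blind = decision_merit(
            0.0, B0, tiny_subject, cfg, TINY, np.random.default_rng(1)
        )
        assert m_blind > m_true

    def test_undecided_penalty_is_linear(self, tiny_subject):
        rng_seed = 3
        merits = []
        for pen in (1.0, 5.0):
            cfg = MeritConfig(
                n_sim=80, wait=0.2, deadline=0.4, pen_undecided=pen
            )
            m, comps = decision_merit(
                G0, B0, tiny_subject, cfg, TINY,
                np.random.default_rng(rng_seed), return_components=True,
            )
            merits.append((m, comps))
        (m1, c1), (m5, c5) = merits
        assert c1["undecided"] > 0  # short deadline leaves undecided trials
        assert c5["undecided"] == pytest.approx(5 * c1["undecided"])
        assert m5 > m1


class TestConfidenceMerit:
    def test_self_fit_is_near_sampling_floor(self, tiny_subject):
        cfg = MeritConfig(n_sim=300, wait=0.2, deadline=1.0)
        sim = simulate_behavioral_trials(
            G0, B0, TINY, cfg.n_sim, np.random.default_rng(11),
            wait=0.2, deadline=1.0,
        )
        chi2 = confidence_merit(
            0.06, 0.39, tiny_subject, (G0, B0), cfg, TINY,
            np.random.default_rng(12), sim=sim,
        )
        # 4 categories, 3 df: under the null chi2 is rarely above ~15
        assert chi2 < 25.0

    def test_degenerate_center_maximizes_chi2(self, tiny_subject):
        cfg = MeritConfig(n_sim=300, wait=0.2, deadline=1.0)
        sim = simulate_behavioral_trials(
            G0, B0, TINY, cfg.n_sim, np.random.default_rng(13),
            wait=0.2, deadline=1.0,
        )
        values = {
            c: confidence_merit(
                0.06, c, tiny_subject, (G0, B0), cfg, TINY,
                np.random.default_rng(14), sim=sim,
            )
            for c in (0.39, 5.0)  # c=5 pushes every report to "low"
        }
        assert values[5.0] > values[0.39]

    def test_statistic_matches_independent_recomputation(self, tiny_subject):
        cfg = MeritConfig(n_sim=200, wait=0.2, deadline=1.0)
        sim = simulate_behavioral_trials(
            G0, B0, TINY, cfg.n_sim, np.random.default_rng(15),
            wait=0.2, deadline=1.0,
        )
        conf_map = ConfidenceMap(slope_a=0.05, center_c=0.25)
        counts = sample_confidence_counts(sim, conf_map, np.random.default_rng(16))
        chi2 = confidence_merit(
            0.05, 0.25, tiny_subject, (G0, B0), cfg, TINY,
            np.random.default_rng(16), sim=sim,
        )
        p = np.clip(counts / counts.sum(), 1e-6, None)
        p = p / p.sum()
        assert chi2 == pytest.approx(
            pearson_chi2(tiny_subject.counts_4way(), p)
        )


class TestFitStage:
    def test_optimizer_sanity_on_quadratic(self):
        res = fit_stage(
            lambda x: float((x[0] - 0.3) ** 2 + (x[1] + 0.1) ** 2),
            [(-1, 1), (-1, 1)],
            np.random.default_rng(0),
            max_iter=150,
        )
        np.testing.assert_allclose(res.x, [0.3, -0.1], atol=1e-3)

    def test_common_random_numbers_make_objective_deterministic(self, tiny_subject):
        cfg = MeritConfig(n_sim=50, wait=0.2, deadline=1.0)

        def objective(x):
            return decision_merit(
                x[0], x[1], tiny_subject, cfg, TINY, np.random.default_rng(77)
            )

        x = np.array([G0, B0])
        assert objective(x) == objective(x)
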