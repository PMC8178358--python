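import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from feverscreen import screening as scr
from feverscreen.synth import CohortGenSpec, generate_reference_cohort, simulate_ncit
from feverscreen.types import OffsetModel


MODEL = OffsetModel(delta_mu=-6.15, rho=1.45)


def brute_force_confusion(ref, test, t_star, t_star_ir):
    """Independent oracle: per-record enumeration with explicit branches."""
    tp = fp = tn = fn = 0
    for r, t in zip(ref, test):
        if r >= t_star and t >= t_star_ir:
            tp += 1
        elif r >= t_star:
            fn += 1
        elif t >= t_star_ir:
            fp += 1
        else:
            tn += 1
    return tp, fp, tn, fn


class TestThreshold:
    def test_published_threshold_construction(self):
        mid = scr.screening_threshold(100.0, MODEL, 0.0)
        assert mid.t_star_ir == pytest.approx(93.85)
        assert mid.display == 93.9
        upper = scr.screening_threshold(100.0, MODEL, 2.84)
        assert upper.t_star_ir == pytest.approx(96.69)
        assert upper.display == 96.7

    def test_identity_model(self):
        thr = scr.screening_threshold(100.0, OffsetModel(delta_mu=0.0, rho=0.0), 0.0)
        assert thr.t_star_ir == 100.0

    def test_delta_t_outside_loa_rejected(self):
        with pytest.raises(ValueError, match="envelope"):
            scr.screening_threshold(100.0, MODEL, 5.0)
        # but permissive mode allows exploration outside the envelope
        thr = scr.screening_threshold(100.0, MODEL, 5.0, strict=False)
        assert thr.t_star_ir == pytest.approx(98.85)


class TestClassify:
    def test_perfect_test(self):
        m = scr.classify([99.0, 101.0], [99.0, 101.0], 100.0, 100.0)
        assert (m.tp, m.fp, m.tn, m.fn) == (1, 0, 1, 0)
        assert m.sensitivity == 100.0 and m.specificity == 100.0

    def test_four_point_hand_count(self):
        m = scr.classify([99, 99, 101, 101], [94, 92, 94, 92], 100.0, 93.9)
        assert (m.tp, m.fn, m.fp, m.tn) == (1, 1, 1, 1)

    def test_healthy_sample_at_upper_threshold_fully_specific(self, rng):
        # afebrile subjects whose readings never reach the upper threshold
        test = rng.uniform(88.9, 95.3, size=51)
        ref = rng.uniform(97.1, 99.6, size=51)
        m = scr.classify(ref, test, 100.0, 96.7)
        assert m.fp == 0 and m.specificity == 100.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="lengths differ"):
            scr.classify([99.0], [94.0, 95.0], 100.0, 93.9)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        data=st.lists(
            st.tuples(
                st.floats(min_value=95.0, max_value=104.0),
                st.floats(min_value=85.0, max_value=100.0),
            ),
            min_size=1,
            max_size=40,
        ),
        t_star=st.floats(min_value=99.0, max_value=101.0),
        t_ir=st.floats(min_value=88.0, max_value=97.0),
    )
    def test_matches_brute_force_oracle(self, data, t_star, t_ir):
        ref, test = zip(*data)
        m = scr.classify(ref, test, t_star, t_ir)
        assert (m.tp, m.fp, m.tn, m.fn) == brute_force_confusion(ref, test, t_star, t_ir)
        # rate identities hold exactly whenever both classes are present
        if m.tp + m.fn > 0:
            assert m.sensitivity + m.fnr == pytest.approx(100.0)
        if m.tn + m.fp > 0:
            assert m.specificity + m.fpr == pytest.approx(100.0)

    def test_bayes_prevalence_identity(self, rng):
        ref = rng.normal(98.8, 0.7, size=20_000)
        test = simulate_ncit(ref, MODEL, seed=3)
        m = scr.classify(ref, test, 100.0, 93.9)
        n = m.n
        prev = (m.tp + m.fn) / n
        se, sp = m.sensitivity / 100, m.specificity / 100
        ppv = 100 * se * prev / (se * prev + (1 - sp) * (1 - prev))
        npv = 100 * sp * (1 - prev) / (sp * (1 - prev) + (1 - se) * prev)
        assert m.ppv == pytest.approx(ppv, rel=1e-9)
        assert m.npv == pytest.approx(npv, rel=1e-9)

    def test_joint_permutation_invariance(self, rng):
        ref = rng.normal(98.8, 0.7, size=500)
        test = simulate_ncit(ref, MODEL, seed=4)
        perm = rng.permutation(500)
        assert scr.classify(ref, test, 100.0, 93.9) == scr.classify(
            ref[perm], test[perm], 100.0, 93.9
        )

    def test_monotone_in_threshold(self, rng):
        ref = rng.normal(98.8, 0.7, size=2000)
        test = simulate_ncit(ref, MODEL, seed=5)
        grid = np.arange(88.0, 98.0, 0.25)
        ms = [scr.classify(ref, test, 100.0, t) for t in grid]
        se = [m.sensitivity for m in ms]
        sp = [m.specificity for m in ms]
        assert all(a >= b for a, b in zip(se, se[1:]))
        assert all(a <= b for a, b in zip(sp, sp[1:]))


class TestSpecificitySweep:
    def test_extreme_thresholds(self, rng):
        temps = rng.uniform(88.9, 95.3, size=51)
        sweep = scr.specificity_sweep(temps, [80.0, 99.0])
        assert sweep[0][1] == 0.0  # below the minimum: everyone screens positive
        assert sweep[1][1] == 100.0

    def test_monotone_nondecreasing(self, rng):
        temps = rng.normal(92.2, 1.5, size=200)
        grid = np.arange(87.0, 98.0, 0.1)
        sweep = scr.specificity_sweep(temps, grid)
        sps = [sp for _, sp in sweep]
        assert all(a <= b for a, b in zip(sps, sps[1:]))
        # oracle: direct counting at each grid point
        for t, sp in sweep[::10]:
            assert sp == pytest.approx(100.0 * np.mean(temps < t))

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            scr.specificity_sweep([92.0], [])


class TestRoc:
    def test_perfect_discrimination(self, rng):
        ref = rng.normal(98.8, 0.7, size=4000)
        curve = scr.roc_curve(ref, ref, 100.0, grid=np.arange(96.0, 102.0, 0.1))
        assert curve.auc >= 0.99
        assert any(se == 100.0 and sp == pytest.approx(100.0, abs=0.2)
                   for _, se, sp in curve.points)

    def test_shuffled_test_is_nondiscriminatory(self, rng):
        ref = rng.normal(98.8, 0.7, size=20_000)
        test = simulate_ncit(ref, MODEL, seed=6)
        aucs = []
        for _ in range(5):
            shuffled = rng.permutation(test)
            aucs.append(scr.roc_curve(ref, shuffled, 100.0).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)

    def test_four_point_toy_matches_enumeration(self):
        ref = [99, 99, 101, 101]
        test = [94, 92, 94, 92]
        curve = scr.roc_curve(ref, test, 100.0, grid=[91.0, 93.9, 97.0])
        for (thr, se, sp) in curve.points:
            tp, fp, tn, fn = brute_force_confusion(ref, test, 100.0, thr)
            assert se == pytest.approx(100.0 * tp / (tp + fn))
            assert sp == pytest.approx(100.0 * tn / (tn + fp))

    def test_monotone_curve_invariant(self, rng):
        ref = rng.normal(98.8, 0.7, size=5000)
        test = simulate_ncit(ref, MODEL, seed=7)
        curve = scr.roc_curve(ref, test, 100.0)
        se = [p[1] for p in curve.points]
        fpr = [100.0 - p[2] for p in curve.points]
        assert all(a >= b for a, b in zip(se, se[1:]))
        assert all(a >= b for a, b in zip(fpr, fpr[1:]))
        assert 0.0 <= curve.auc <= 1.0

    def test_single_class_cohort_rejected(self):
        with pytest.raises(scr.DegenerateRocError, match="positive"):
            scr.roc_curve([98.0, 98.5], [92.0, 92.5], 100.0)


class TestEqualError:
    def test_perfect_test_rate_100(self, rng):
        ref = rng.normal(98.8, 0.7, size=4000)
        curve = scr.roc_curve(ref, ref, 100.0, grid=np.arange(96.0, 102.0, 0.05))
        thr, rate = scr.equal_error_threshold(curve)
        assert rate == pytest.approx(100.0, abs=0.5)

    def test_symmetric_overlap_crosses_at_50(self, rng):
        # test values independent of condition: SE(t) ~ SP(t) mirror around
        # the common median, so the crossing rate is ~50%
        ref = rng.normal(98.8, 0.7, size=30_000)
        test = rng.permutation(simulate_ncit(ref, MODEL, seed=8))
        curve = scr.roc_curve(ref, test, 100.0)
        _, rate = scr.equal_error_threshold(curve)
        assert rate == pytest.approx(50.0, abs=2.0)

    def test_no_crossing_raises(self):
        curve = scr.RocCurve(points=((90.0, 100.0, 10.0), (91.0, 99.0, 20.0)), auc=0.9)
        with pytest.raises(scr.NoCrossingError):
            scr.equal_error_threshold(curve)

    def test_default_cohort_equal_error_envelope(self):
        """Across seeds, the simulated-screening equal-error point stays in a
        narrow band around 93.4-93.9 F at a rate in the high 60s."""
        thrs, rates = [], []
        for seed in range(20):
            cohort = generate_reference_cohort(CohortGenSpec(n=60_000, seed=seed))
            ref = np.asarray(cohort.temps)
            sim = simulate_ncit(ref, MODEL, seed=1000 + seed)
            curve = scr.roc_curve(ref, sim, 100.0)
            t, r = scr.equal_error_threshold(curve)
            thrs.append(t)
            rates.append(r)
        assert 93.3 <= np.mean(thrs) <= 94.1
        assert 65.0 <= np.mean(rates) <= 73.0
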