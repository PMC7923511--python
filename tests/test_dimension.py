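import math

import numpy as np
import pytest

from cytopattern.dimension import (AuerGerviniDimension, EigenSpectrum, Step,
                                   StepFunction, ThresherFilter, ThresherParams,
                                   auer_gervini, broken_stick,
                                   broken_stick_thresholds, eigen_spectrum,
                                   select_dimension, thresher_filter)
from cytopattern.exceptions import ValidationError
from cytopattern.synthetic import default_spec, simulate
from conftest import make_matrix
from oracles import broken_stick_threshold, grid_argmax_dimension


def spectrum(eigs, n=50):
    return EigenSpectrum(eigenvalues=np.asarray(eigs, float), n=n)


class TestEigenSpectrum:
    def test_matches_covariance_eigendecomposition(self, rng):
        m = make_matrix(rng.integers(0, 2, (30, 10)))
        s = eigen_spectrum(m)
        ref = np.linalg.eigvalsh(np.cov(m.values.T.astype(float)))[::-1]
        assert np.allclose(s.eigenvalues, np.clip(ref, 0, None), atol=1e-10)

    def test_duplicated_column_rank_one(self):
        c = np.array([1, 0, 1, 0, 1])
        m = make_matrix(np.column_stack([c, c]))
        s = eigen_spectrum(m)
        assert s.eigenvalues[1] == 0.0 and s.eigenvalues[0] > 0

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValidationError):
            eigen_spectrum(make_matrix(np.ones((4, 3), dtype=int)))

    def test_spectrum_sums_to_total_variance(self, rng):
        m = make_matrix(rng.integers(0, 2, (25, 8)))
        s = eigen_spectrum(m)
        total = np.var(m.values.astype(float), axis=0, ddof=1).sum()
        assert s.eigenvalues.sum() == pytest.approx(total)


class TestBrokenStick:
    def test_closed_form_thresholds_d3(self):
        b = broken_stick_thresholds(3)
        assert np.allclose(b, [11 / 18, 5 / 18, 1 / 9])

    @pytest.mark.parametrize("d", [2, 5, 17, 50])
    def test_thresholds_match_harmonic_transcription(self, d):
        b = broken_stick_thresholds(d)
        for k in range(1, d + 1):
            assert b[k - 1] == pytest.approx(broken_stick_threshold(k, d), abs=1e-14)

    def test_rule_on_printed_proportions(self):
        assert broken_stick(spectrum([0.7, 0.2, 0.1])) == 1

    def test_uniform_proportions_give_zero(self):
        assert broken_stick(spectrum([1.0, 1.0, 1.0, 1.0])) == 0

    def test_invariant_to_uniform_rescale(self, rng):
        eigs = np.sort(rng.exponential(1, 12))[::-1]
        assert broken_stick(spectrum(eigs)) == broken_stick(spectrum(eigs * 37.0))


class TestAuerGervini:
    def test_hull_equals_grid_oracle(self, rng):
        for _ in range(20):
            d = int(rng.integers(4, 20))
            eigs = np.sort(rng.exponential(1.0, d))[::-1] + 1e-6
            s = spectrum(eigs, n=int(rng.integers(10, 200)))
            sf = auer_gervini(s)
            thetas = np.linspace(1e-6, 1.2 * max(st.theta_lo for st in sf.steps[-1:])
                                 + 5.0, 200)
            expected = grid_argmax_dimension(list(eigs), s.n, list(thetas))
            got = [sf.q_at(t) for t in thetas]
            assert got == expected

    def test_limits(self, rng):
        eigs = np.sort(rng.exponential(1.0, 10))[::-1] + 1e-6
        sf = auer_gervini(spectrum(eigs))
        qs = [st.q for st in sf.steps]
        assert qs[-1] == 0                      # theta -> infinity
        assert qs[0] == max(qs)                 # theta -> 0+ gives max hull q
        assert all(a > b for a, b in zip(qs, qs[1:]))  # strictly decreasing

    def test_non_increasing_in_theta(self, rng):
        eigs = np.sort(rng.uniform(0.01, 5, 15))[::-1]
        sf = auer_gervini(spectrum(eigs))
        thetas = np.linspace(0.01, 50, 300)
        vals = [sf.q_at(t) for t in thetas]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_step_ordering_preserved_under_rescale(self, rng):
        eigs = np.sort(rng.exponential(1.0, 10))[::-1] + 1e-6
        sf1 = auer_gervini(spectrum(eigs))
        sf2 = auer_gervini(spectrum(eigs * 4.2))
        assert [st.q for st in sf1.steps] == [st.q for st in sf2.steps]

    def test_degenerate_single_positive_eigenvalue(self):
        sf = auer_gervini(spectrum([2.0, 0.0, 0.0]))
        assert [st.q for st in sf.steps] == [1]

    def test_intervals_tile_without_overlap(self, rng):
        eigs = np.sort(rng.exponential(1.0, 12))[::-1] + 1e-6
        sf = auer_gervini(spectrum(eigs))
        for a, b in zip(sf.steps, sf.steps[1:]):
            assert a.theta_hi == pytest.approx(b.theta_lo)
        assert sf.steps[0].theta_lo == 0.0
        assert math.isinf(sf.steps[-1].theta_hi)


class TestSelectDimension:
    @staticmethod
    def _sf(qs, lengths):
        steps, lo = [], 0.0
        for q, ln in zip(reversed(qs), reversed(lengths)):
            steps.append(Step(q=q, theta_lo=lo, theta_hi=lo + ln))
            lo += ln
        steps.append(Step(q=0, theta_lo=lo, theta_hi=math.inf))
        steps.sort(key=lambda st: st.theta_lo)
        return StepFunction(steps=steps)

    def test_twice_mean_rule_example(self):
        sf = self._sf(qs=[2, 5, 8, 9, 11], lengths=[10, 1, 1, 1, 1])
        est = select_dimension(sf, spectrum([5, 3, 1, 0.5, 0.2]))
        assert est.long_step_candidates == [2]
        assert est.chosen_q == 2 and est.criterion == "twice-mean"

    def test_equal_steps_fall_back_to_longest(self):
        sf = self._sf(qs=[2, 5, 8], lengths=[1.0, 1.0, 1.0])
        est = select_dimension(sf, spectrum([5, 3, 1]))
        assert est.long_step_candidates == []
        assert est.criterion == "longest-step"
        assert est.chosen_q == 8  # tie on length -> larger q

    def test_manual_override(self):
        sf = self._sf(qs=[2, 5], lengths=[3.0, 1.0])
        s = spectrum(np.linspace(10, 0.1, 200))
        est = select_dimension(sf, s, manual_q=134)
        assert est.chosen_q == 134 and est.criterion == "manual"

    def test_manual_out_of_range_rejected(self):
        sf = self._sf(qs=[2], lengths=[1.0])
        with pytest.raises(ValidationError):
            select_dimension(sf, spectrum([3, 1, 0.5]), manual_q=3)

    def test_estimator_interface(self, rng):
        m, _ = simulate(default_spec(), seed=7)
        est = AuerGerviniDimension().fit(m.values)
        assert est.n_components_ >= 1
        assert est.n_components_ in est.candidates_ or not est.candidates_
        assert est.get_params()["criterion"] == "twice-mean"


class TestThresherFilter:
    def test_delta_zero_drops_nothing(self, rng):
        m = make_matrix(rng.integers(0, 2, (20, 8)))
        kept, dropped, lengths = thresher_filter(m, ThresherParams(delta=0.0))
        assert dropped == [] and len(kept) == 8
        assert lengths.shape == (8,)

    def test_outlier_features_dropped_structural_kept(self):
        """Over 50 seeds, pure-noise columns fall below delta=0.3 while planted
        event-block members stay, in at least 90% of draws."""
        ok_out = ok_block = 0
        trials = 50
        for seed in range(trials):
            m, truth = simulate(default_spec(), seed=3000 + seed)
            kept, dropped, _ = thresher_filter(m)
            dropped_raws = {f.raw for f in dropped}
            kept_raws = {f.raw for f in kept}
            outliers = {r for r, e in truth.feature_to_event.items() if e == "outlier"}
            blocks = {r for r, e in truth.feature_to_event.items() if e != "outlier"}
            ok_out += outliers <= dropped_raws
            ok_block += blocks <= kept_raws
        assert ok_out >= 0.9 * trials
        assert ok_block >= 0.9 * trials

    def test_all_dropped_advises_lower_delta(self, rng):
        m = make_matrix(rng.integers(0, 2, (10, 4)))
        with pytest.raises(ValidationError, match="delta"):
            thresher_filter(m, ThresherParams(delta=0.999999))

    def test_kept_and_dropped_partition_features(self, rng):
        m = make_matrix(rng.integers(0, 2, (30, 12)))
        kept, dropped, _ = thresher_filter(m, ThresherParams(delta=0.3))
        assert sorted(f.raw for f in kept + dropped) == sorted(m.raw_names)

    def test_transformer_interface(self, rng):
        X = rng.integers(0, 2, (25, 10))
        filt = ThresherFilter(delta=0.0).fit(X)
        assert filt.transform(X).shape == X.shape
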