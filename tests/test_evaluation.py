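"""Qualification statistics, PK metrics and the elementary-effects screen."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gestpbpk as g
from gestpbpk.errors import DomainError, UsageError
from gestpbpk.evaluation import morris_screening, verification_report


def _profile(times, conc):
    return g.ConcentrationProfile(times=np.asarray(times, float),
                                  maternal_plasma=np.asarray(conc, float))


class TestPKMetrics:
    def test_constant_profile(self):
        t = np.linspace(0, 24, 241)
        m = g.compute_pk_metrics(_profile(t, np.full_like(t, 10.0)), 24.0)
        assert m.c_max == m.c_min_ss == m.c_avg_ss == 10.0
        assert m.auc == pytest.approx(240.0)

    def test_triangular_pulse(self):
        t = np.linspace(0, 24, 2401)
        c = np.interp(t, [0, 4, 24], [0, 10, 0])
        m = g.compute_pk_metrics(_profile(t, c), 24.0)
        assert m.c_max == pytest.approx(10.0, abs=0.01)
        assert m.t_max == pytest.approx(4.0, abs=0.02)

    def test_auc_linearity_between_doses(self, escitalopram, phys0, profile10_gw0):
        p20 = g.simulate_individual(escitalopram, phys0, g.DoseRegimen(20.0, 24.0, 10))
        m10 = g.compute_pk_metrics(profile10_gw0, 24.0)
        m20 = g.compute_pk_metrics(p20, 24.0)
        assert m20.auc == pytest.approx(2 * m10.auc, rel=1e-9)

    def test_metric_ordering_invariant(self, profile10_gw0):
        m = g.compute_pk_metrics(profile10_gw0, 24.0)
        assert m.c_min_ss <= m.c_avg_ss <= m.c_max_ss

    def test_short_profile_rejected(self):
        t = np.linspace(0, 5, 50)
        with pytest.raises(UsageError):
            g.compute_pk_metrics(_profile(t, np.ones_like(t)), 24.0)


class TestPredictionRatio:
    @pytest.mark.parametrize("pred,obs,ratio,ok", [
        (5.0, 5.0, 1.0, True),
        (0.7, 1.0, 0.7, True),     # boundary of the acceptance band
        (2.0, 1.0, 2.0, False),
    ])
    def test_values_and_flags(self, pred, obs, ratio, ok):
        r, flag = g.prediction_ratio(pred, obs)
        assert r == pytest.approx(ratio)
        assert flag is ok

    def test_nonpositive_observed_rejected(self):
        with pytest.raises(DomainError):
            g.prediction_ratio(1.0, 0.0)

    @given(a=st.floats(0.01, 100), b=st.floats(0.01, 100))
    @settings(max_examples=50, deadline=None)
    def test_reciprocal_identity(self, a, b):
        assert g.prediction_ratio(a, b)[0] * g.prediction_ratio(b, a)[0] == pytest.approx(1.0)


class TestAAFE:
    def test_perfect_agreement(self):
        assert g.aafe([(3.0, 3.0), (7.0, 7.0)]) == pytest.approx(1.0)

    def test_placental_clearance_pair(self):
        # model placental clearance vs ex vivo cotyledon clearance index
        assert g.aafe([(0.80902, 1.03)]) == pytest.approx(1.27, abs=0.005)

    def test_symmetric_folds(self):
        assert g.aafe([(2.0, 1.0), (1.0, 2.0)]) == pytest.approx(2.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            g.aafe([(0.0, 1.0)])
        with pytest.raises(DomainError):
            g.aafe([])

    @given(pairs=st.lists(
        st.tuples(st.floats(0.01, 100), st.floats(0.01, 100)), min_size=1, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_at_least_one_and_inversion_symmetric(self, pairs):
        val = g.aafe(pairs)
        assert val >= 1.0 - 1e-12
        flipped = [(o, p) for p, o in pairs]
        assert g.aafe(flipped) == pytest.approx(val, rel=1e-9)

    def test_report_flags(self):
        rep = verification_report({"cmax": (8.0, 10.0), "auc": (300.0, 290.0)})
        assert rep.ratio_acceptable["cmax"] is True
        assert rep.aafe < 2 and rep.aafe_acceptable
        assert rep.n_pairs == 2


class TestCoverage:
    def _band(self):
        class Band:
            times = np.linspace(0.0, 24.0, 25)
            p5 = np.full(25, 1.0)
            p95 = np.full(25, 3.0)
            mean = np.full(25, 2.0)
        return Band()

    def test_points_on_mean_covered(self):
        import pandas as pd
        obs = pd.DataFrame({"time_h": [2.0, 10.0], "conc_ng_per_ml": [2.0, 2.0]})
        assert g.coverage_check(obs, self._band()) == 1.0

    def test_half_covered(self):
        import pandas as pd
        obs = pd.DataFrame({"time_h": [2.0, 10.0], "conc_ng_per_ml": [2.0, 4.0]})
        assert g.coverage_check(obs, self._band()) == 0.5

    def test_all_above_band(self):
        import pandas as pd
        obs = pd.DataFrame({"time_h": [2.0, 10.0], "conc_ng_per_ml": [5.0, 9.0]})
        assert g.coverage_check(obs, self._band()) == 0.0

    def test_empty_rejected(self):
        import pandas as pd
        with pytest.raises(UsageError):
            g.coverage_check(pd.DataFrame({"time_h": [], "conc_ng_per_ml": []}), self._band())

    def test_out_of_range_times_rejected(self):
        import pandas as pd
        obs = pd.DataFrame({"time_h": [30.0], "conc_ng_per_ml": [2.0]})
        with pytest.raises(UsageError):
            g.coverage_check(obs, self._band())


class TestMorris:
    def test_linear_function_recovers_coefficients(self):
        def model(p):
            return {"y": 3.0 * p["a"] - 2.0 * p["b"] + 0.0 * p["c"]}

        res = morris_screening(model, {"a": (0, 1), "b": (0, 1), "c": (0, 1)},
                               r=8, seed=0)
        mu = dict(zip(res.parameters, res.mu_star["y"]))
        assert mu["a"] == pytest.approx(3.0, rel=1e-9)
        assert mu["b"] == pytest.approx(2.0, rel=1e-9)
        assert mu["c"] == 0.0
        assert res.ranking("y") == ["a", "b", "c"]

    def test_deterministic_given_seed(self):
        def model(p):
            return {"y": p["a"] ** 2 + p["b"]}

        r1 = morris_screening(model, {"a": (0, 1), "b": (0, 1)}, r=6, seed=3)
        r2 = morris_screening(model, {"a": (0, 1), "b": (0, 1)}, r=6, seed=3)
        np.testing.assert_array_equal(r1.mu_star["y"], r2.mu_star["y"])

    def test_too_few_trajectories_rejected(self):
        with pytest.raises(DomainError):
            morris_screening(lambda p: {"y": 0.0}, {"a": (0, 1)}, r=2)
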