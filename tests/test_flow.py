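"""Gating, mixture fitting, assignment, fractions, CV and sensor ratios."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from phenopop import flow
from phenopop.synthetic import (HIGH_SUBPOP, LOW_SUBPOP,
                                simulate_flow_events)


def _events(fsc_h, fsc_a, **extra):
    df = pd.DataFrame({"FSC-H": fsc_h, "FSC-A": fsc_a, **extra})
    df.insert(0, "event_id", np.arange(len(df)))
    return df


class TestExcludeDoublets:
    def test_perfectly_collinear_events_all_kept(self):
        h = np.linspace(100, 1000, 50)
        res = flow.exclude_doublets(_events(h, 1.5 * h))
        assert res.n_doublets_removed == 0
        assert len(res.events) == 50

    def test_order_of_survivors_preserved(self, rng):
        h = rng.lognormal(10, 0.3, 200)
        a = 1.5 * h * (1 + 0.01 * rng.standard_normal(200))
        res = flow.exclude_doublets(_events(h, a))
        assert list(res.events["event_id"]) == sorted(res.events["event_id"])

    def test_synthetic_doublets_removed(self):
        ev = simulate_flow_events([LOW_SUBPOP, HIGH_SUBPOP], 1100,
                                  doublet_rate=100 / 1100, seed=3)
        res = flow.exclude_doublets(ev, k_mad=3.0)
        removed = ev.loc[~ev.index.isin(res.events.index)]
        assert int(removed["truth_doublet"].sum()) >= 95
        assert not res.events["truth_doublet"].any() or \
            res.events["truth_doublet"].sum() <= 5

    def test_nonpositive_events_counted_separately(self):
        h = np.r_[np.linspace(100, 1000, 20), -5.0]
        a = 1.5 * h
        res = flow.exclude_doublets(_events(h, a))
        assert res.n_nonpositive_dropped == 1

    def test_too_few_events_error(self):
        with pytest.raises(ValueError, match="fewer than 10"):
            flow.exclude_doublets(_events(np.ones(3), np.ones(3)))


class TestNormalizeBySize:
    def test_elementwise_ratio(self):
        ev = _events([50.0, 10.0], [75.0, 15.0])
        ev["BL1-H"] = [100.0, 10.0]
        out = flow.normalize_by_size(ev)
        assert out == pytest.approx([2.0, 1.0])

    def test_identity_when_channels_equal(self):
        ev = _events([3.0, 7.0], [4.5, 10.5])
        ev["BL1-H"] = ev["FSC-H"]
        assert flow.normalize_by_size(ev) == pytest.approx([1.0, 1.0])

    def test_nonpositive_size_error_names_events(self):
        ev = _events([50.0, 0.0], [75.0, 0.0])
        ev["BL1-H"] = [1.0, 1.0]
        with pytest.raises(ValueError, match="rows \\[1\\]"):
            flow.normalize_by_size(ev)

    def test_matches_truth_table_arithmetic(self):
        # marker scales linearly with size plus offset; the normalised
        # low-vs-high gap must equal direct arithmetic on the truth table
        ev = simulate_flow_events([LOW_SUBPOP, HIGH_SUBPOP], 4000, seed=9)
        ev["BL1-H"] = 2.0 * ev["FSC-H"] + 100.0
        norm = flow.normalize_by_size(ev)
        by_pop = pd.Series(norm).groupby(ev["truth_subpop"].values).mean()
        size_means = ev.groupby("truth_subpop")["FSC-H"].apply(
            lambda s: np.mean((2.0 * s + 100.0) / s))
        assert by_pop["low"] - by_pop["high"] == pytest.approx(
            size_means["low"] - size_means["high"], rel=1e-12)


class TestMixture:
    def test_k1_closed_form(self, rng):
        X = rng.normal(size=(500, 2)) @ np.array([[1.0, 0.3], [0.0, 0.7]])
        fit = flow.fit_gaussian_mixture(X, K=1)
        assert fit.means[0] == pytest.approx(X.mean(axis=0), abs=1e-9)
        diff = X - X.mean(axis=0)
        assert fit.covariances[0] == pytest.approx(diff.T @ diff / len(X),
                                                   abs=1e-9)

    def test_two_component_recovery(self, rng):
        X = np.vstack([rng.normal([0, 0], 1, (5000, 2)),
                       rng.normal([5, 5], 1, (5000, 2))])
        fit = flow.fit_gaussian_mixture(X, K=2, seed=0)
        assert fit.weights == pytest.approx([0.5, 0.5], abs=0.02)
        assert fit.means[0] == pytest.approx([0, 0], abs=0.1)
        assert fit.means[1] == pytest.approx([5, 5], abs=0.1)
        assert fit.converged

    def test_agrees_with_sklearn(self, rng):
        """Independent EM cross-check on well-separated data."""
        from sklearn.mixture import GaussianMixture

        X = np.vstack([rng.normal(-4, 1, (2000, 1)),
                       rng.normal(4, 1.5, (3000, 1))])
        fit = flow.fit_gaussian_mixture(X, K=2, seed=1)
        sk = GaussianMixture(2, random_state=0, n_init=3).fit(X)
        order = np.argsort(sk.means_[:, 0])
        assert fit.means[:, 0] == pytest.approx(sk.means_[order, 0],
                                                rel=0.01)
        assert fit.weights == pytest.approx(sk.weights_[order], abs=0.01)

    def test_shared_spherical_lambda_recovery(self, rng):
        X = np.vstack([rng.normal([-4, 0], 1.0, (4000, 2)),
                       rng.normal([4, 2], 1.0, (4000, 2))])
        fit = flow.fit_gaussian_mixture(X, K=2, family="shared_spherical",
                                        seed=0)
        lam = fit.covariances[0, 0, 0]
        assert np.allclose(fit.covariances,
                           lam * np.eye(2)[None].repeat(2, 0))
        assert lam == pytest.approx(1.0, rel=0.05)

    def test_low_label_has_smaller_size_mean(self, rng):
        X = np.vstack([rng.normal(10, 1, (500, 1)),
                       rng.normal(0, 1, (500, 1))])
        fit = flow.fit_gaussian_mixture(X, K=2, seed=0)
        low = fit.component_order["low"]
        high = fit.component_order["high"]
        assert fit.means[low, 0] < fit.means[high, 0]

    def test_single_component_data_not_split(self, rng):
        """K=2 on truly unimodal data: tiny weight or overlapping means."""
        X = rng.normal(0, 1, (3000, 1))
        fit = flow.fit_gaussian_mixture(X, K=2, seed=0)
        sep = abs(fit.means[1, 0] - fit.means[0, 0])
        pooled_sd = np.sqrt(np.mean([fit.covariances[k, 0, 0]
                                     for k in range(2)]))
        assert fit.weights.min() < 0.02 or sep < 2 * pooled_sd

    def test_preconditions(self, rng):
        with pytest.raises(ValueError):
            flow.fit_gaussian_mixture(rng.normal(size=(30, 3)), K=2)
        with pytest.raises(ValueError):
            flow.fit_gaussian_mixture(rng.normal(size=(10, 2)), K=2)

    def test_json_round_trip(self, rng, tmp_path):
        X = rng.normal(size=(200, 2))
        fit = flow.fit_gaussian_mixture(X, K=2, seed=0)
        path = tmp_path / "fit.json"
        fit.to_json(path)
        back = flow.MixtureFit.from_json(path)
        assert np.allclose(back.means, fit.means)
        assert np.allclose(back.covariances, fit.covariances)
        assert back.component_order == fit.component_order


class TestAssignment:
    def _fit(self):
        return flow.MixtureFit(
            K=2, family="full", weights=np.array([0.5, 0.5]),
            means=np.array([[0.0], [10.0]]),
            covariances=np.array([[[1.0]], [[1.0]]]),
            log_likelihood=0.0, n_iter=1, converged=True,
            component_order={"low": 0, "high": 1})

    def test_point_at_component_mean(self):
        out = flow.assign_subpopulations(self._fit(), np.array([[0.0]]))
        assert out.loc[0, "hard_label"] == "low"
        assert out.loc[0, "confidence"] > 0.999

    def test_posteriors_sum_to_one(self, rng):
        X = rng.normal(5, 3, (500, 1))
        out = flow.assign_subpopulations(self._fit(), X)
        total = out["posterior_low"] + out["posterior_high"]
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_confidence_threshold_unassigns(self):
        # a point with posteriors (0.6, 0.4) at threshold 0.85
        fit = self._fit()
        x = 5.0 + np.log(0.6 / 0.4) / 10.0  # logit spacing for unit sds
        out = flow.assign_subpopulations(fit, np.array([[x]]),
                                         mode="confidence", threshold=0.85)
        assert abs(out.loc[0, "posterior_high"] - 0.6) < 1e-6
        assert out.loc[0, "hard_label"] == "unassigned"

    def test_transfer_fit_labels_match_truth(self):
        ref = simulate_flow_events([LOW_SUBPOP, HIGH_SUBPOP], 5000, seed=0)
        other = simulate_flow_events([replace(LOW_SUBPOP, weight=0.5),
                                      replace(HIGH_SUBPOP, weight=0.5)],
                                     5000, seed=1)
        cols = [np.log(ref["FSC-H"]), np.log(ref["BL1-H"])]
        fit = flow.fit_gaussian_mixture(np.column_stack(cols), K=2, seed=0)
        Xo = np.column_stack([np.log(other["FSC-H"]),
                              np.log(other["BL1-H"])])
        out = flow.assign_subpopulations(fit, Xo, mode="hard")
        acc = (out["hard_label"].to_numpy()
               == other["truth_subpop"].to_numpy()).mean()
        assert acc >= 0.99

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="d=2"):
            flow.assign_subpopulations(self._fit(), np.ones((5, 2)))


class TestFractions:
    def _assignments(self, labels, reps):
        return pd.DataFrame({"hard_label": labels, "replicate": reps})

    def test_all_low_gives_one(self):
        out = flow.subpopulation_fractions(
            self._assignments(["low"] * 5, ["a"] * 5))
        assert out.fraction_mean == 1.0

    def test_closed_form_mean_sem(self):
        labels, reps = [], []
        for rep, frac in zip("abc", [0.2, 0.3, 0.4]):
            labels += ["low"] * int(frac * 10) + \
                      ["high"] * (10 - int(frac * 10))
            reps += [rep] * 10
        out = flow.subpopulation_fractions(self._assignments(labels, reps))
        assert out.fraction_mean == pytest.approx(0.3)
        assert out.fraction_sem == pytest.approx(0.1 / np.sqrt(3))

    def test_unassigned_excluded_from_denominator(self):
        out = flow.subpopulation_fractions(self._assignments(
            ["low", "high", "unassigned", "unassigned"], ["a"] * 4))
        assert out.per_replicate.loc[0, "frac_low"] == 0.5
        assert out.per_replicate.loc[0, "frac_unassigned"] == 0.5

    def test_recovers_generator_weight(self):
        ev = simulate_flow_events([LOW_SUBPOP, HIGH_SUBPOP], 10000, seed=4)
        X = np.column_stack([np.log(ev["FSC-H"]), np.log(ev["BL1-H"])])
        fit = flow.fit_gaussian_mixture(X, K=2, seed=0)
        asg = flow.assign_subpopulations(fit, X, mode="hard")
        asg["replicate"] = "r1"
        out = flow.subpopulation_fractions(asg)
        assert out.fraction_mean == pytest.approx(0.30, abs=0.01)

    def test_fraction_error_shrinks_with_n(self):
        errs = []
        for n in (1000, 100000):
            ev = simulate_flow_events([LOW_SUBPOP, HIGH_SUBPOP], n, seed=11)
            X = np.column_stack([np.log(ev["FSC-H"]), np.log(ev["BL1-H"])])
            fit = flow.fit_gaussian_mixture(X, K=2, seed=0)
            asg = flow.assign_subpopulations(fit, X, mode="hard")
            frac = (asg["hard_label"] == "low").mean()
            errs.append(abs(frac - 0.3))
        assert errs[1] <= errs[0] + 1e-3


class TestCvAndSensor:
    def test_cv_closed_form(self):
        assert flow.cell_size_cv([1.0, 2.0, 3.0]) == pytest.approx(0.5)
        assert flow.cell_size_cv([5.0, 5.0, 5.0]) == 0.0

    def test_cv_matches_two_pass_formula(self, rng):
        x = rng.lognormal(1, 0.4, 1000)
        mean = sum(x) / len(x)
        var = sum((v - mean) ** 2 for v in x) / (len(x) - 1)
        assert flow.cell_size_cv(x) == pytest.approx(var**0.5 / mean,
                                                     abs=1e-12)

    def test_cv_errors(self):
        with pytest.raises(ValueError):
            flow.cell_size_cv([1.0])
        with pytest.raises(ValueError):
            flow.cell_size_cv([-1.0, -2.0])

    def test_sensor_ratio_and_invert(self):
        ev = pd.DataFrame({"VL2-H": [200.0], "VL1-H": [100.0]})
        assert flow.sensor_ratio(ev, "VL2-H", "VL1-H").iloc[0] == 2.0
        assert flow.sensor_ratio(ev, "VL2-H", "VL1-H",
                                 invert=True).iloc[0] == 0.5

    def test_sensor_gap_recovered_by_grouped_medians(self, rng):
        # designed 2x ratio gap between subpopulations
        n = 4000
        subpop = np.r_[np.zeros(n // 2, bool), np.ones(n // 2, bool)]
        vl1 = rng.lognormal(4, 0.2, n)
        ratio_true = np.where(subpop, 2.0, 1.0)
        ev = pd.DataFrame({"VL1-H": vl1,
                           "VL2-H": vl1 * ratio_true
                           * rng.lognormal(0, 0.05, n)})
        r = flow.sensor_ratio(ev, "VL2-H", "VL1-H")
        gap = (np.median(r[subpop]) / np.median(r[~subpop]))
        assert gap == pytest.approx(2.0, rel=0.05)
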