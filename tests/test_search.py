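"""Specification enumeration, loss evaluation, MCS, bridge selection."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

import smokecast as sc


def _loss_frame(rng, n_states=20, years=(2007, 2008, 2009, 2010), cols=("a", "b", "c")):
    idx = pd.MultiIndex.from_product(
        [[f"s{i:02d}" for i in range(n_states)], years], names=["state", "target"])
    return pd.DataFrame(rng.chisquare(1, (len(idx), len(cols))) * 1e-3,
                        index=idx, columns=list(cols))


class TestEnumerate:
    def test_seven_candidates_give_128_specs(self, default_spec):
        specs = sc.enumerate_cs_specs(list(sc.CS_CANDIDATES), default_spec)
        assert len(specs) == 128
        subsets = {s.cs_averages for s in specs}
        assert len(subsets) == 128

    def test_zero_candidates_give_single_empty_spec(self, default_spec):
        specs = sc.enumerate_cs_specs([], default_spec)
        assert len(specs) == 1
        assert specs[0].cs_averages == ()

    def test_three_candidates_each_subset_once(self, default_spec):
        specs = sc.enumerate_cs_specs(["elderly", "hexp", "prev"], default_spec)
        assert len(specs) == 8
        assert specs[0].cs_averages == ()        # binary-counter order: empty first
        assert specs[-1].cs_averages == ("elderly", "hexp", "prev")

    def test_duplicate_candidates_rejected(self, default_spec):
        with pytest.raises(ValueError, match="duplicate"):
            sc.enumerate_cs_specs(["hexp", "hexp"], default_spec)

    def test_non_cs_fields_copied_from_base(self, default_spec):
        base = default_spec.with_(lag=1, bridge_mode="intercept_shift")
        specs = sc.enumerate_cs_specs(["hexp"], base)
        assert all(s.bridge_mode == "intercept_shift" for s in specs)


class TestEvaluateSpecs:
    def test_identical_specs_rejected_as_duplicates(self, small_panel, default_spec):
        with pytest.raises(ValueError, match="duplicate"):
            sc.evaluate_specs(small_panel, [default_spec, default_spec],
                              2006, 2007, 2008)

    def test_common_cells_and_cross_module_consistency(self, small_panel, default_spec):
        specs = [default_spec.with_(cs_averages=()), default_spec]
        lt = sc.evaluate_specs(small_panel, specs, 2006, 2007, 2010)
        assert lt.losses.notna().all().all()
        # spot-check one spec against a standalone forecasting recomputation
        fits = sc.recursive_fit(small_panel, default_spec, 2006, 2009)
        sq = sc.one_step_forecasts(fits, small_panel).squared_log_errors()
        col = lt.losses[default_spec.spec_id]
        pd.testing.assert_series_equal(col, sq.loc[col.index], check_names=False)

    def test_failing_spec_excluded_with_warning(self, small_panel, default_spec):
        bad = default_spec.with_(sample_start=2005)   # window too short to estimate
        with pytest.warns(UserWarning, match="excluded"):
            lt = sc.evaluate_specs(small_panel, [default_spec, bad], 2006, 2007, 2008)
        assert bad.spec_id in lt.failed
        assert list(lt.losses.columns) == [default_spec.spec_id]


class TestModelConfidenceSet:
    def test_single_candidate_survives_with_p_one(self):
        rng = np.random.default_rng(0)
        frame = _loss_frame(rng, cols=("only",))
        m = sc.model_confidence_set(frame, reps=200, seed=0)
        assert m.survivors == ["only"]
        assert m.pvalues["only"] == 1.0

    def test_dominated_candidate_eliminated(self):
        hits = 0
        runs = 30
        for s in range(runs):
            rng = np.random.default_rng(s)
            frame = _loss_frame(rng)
            frame["c"] *= 10.0
            m = sc.model_confidence_set(frame, reps=500, seed=s)
            hits += ("c" not in m.survivors) and (m.pvalues["c"] <= 0.05)
        assert hits / runs >= 0.95

    def test_exact_ties_all_survive(self):
        rng = np.random.default_rng(1)
        frame = _loss_frame(rng)
        frame["b"] = frame["a"]
        frame["c"] = frame["a"]
        m = sc.model_confidence_set(frame, reps=200, seed=1)
        assert sorted(m.survivors) == ["a", "b", "c"]

    def test_survivor_sets_nested_in_alpha(self):
        rng = np.random.default_rng(2)
        frame = _loss_frame(rng, cols=("a", "b", "c", "d"))
        frame["d"] *= 3.0
        tight = sc.model_confidence_set(frame, alpha=0.01, reps=500, seed=3)
        loose = sc.model_confidence_set(frame, alpha=0.10, reps=500, seed=3)
        assert set(loose.survivors) <= set(tight.survivors)

    def test_survivors_match_pvalue_rule(self):
        rng = np.random.default_rng(5)
        frame = _loss_frame(rng)
        m = sc.model_confidence_set(frame, alpha=0.05, reps=300, seed=5)
        assert set(m.survivors) == {c for c in frame.columns if m.pvalues[c] > 0.05}
        assert len(m.survivors) >= 1

    def test_too_few_reps_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError, match="reps"):
            sc.model_confidence_set(_loss_frame(rng), reps=10)


class TestSelectBest:
    @staticmethod
    def _table(mean_losses, specs):
        idx = pd.MultiIndex.from_product([["s1", "s2"], [2007, 2008]],
                                         names=["state", "target"])
        frame = pd.DataFrame({sid: [m] * 4 for sid, m in mean_losses.items()}, index=idx)
        return sc.LossTable(losses=frame, specs=specs)

    def test_single_survivor_returned(self, default_spec):
        spec = default_spec.with_(cs_averages=("hexp",))
        lt = self._table({spec.spec_id: 1.0}, {spec.spec_id: spec})
        mcs = sc.MCSResult(survivors=[spec.spec_id], elimination_order=[],
                           pvalues=pd.Series({spec.spec_id: 1.0}),
                           alpha=0.05, reps=100, block=2, seed=0)
        assert sc.select_best(mcs, lt) == spec

    def test_tie_broken_toward_fewer_averages(self, default_spec):
        s2 = default_spec.with_(cs_averages=("hexp", "elderly"))
        s3 = default_spec.with_(cs_averages=("hexp", "elderly", "prev"))
        lt = self._table({s2.spec_id: 1.0, s3.spec_id: 1.0},
                         {s2.spec_id: s2, s3.spec_id: s3})
        mcs = sc.MCSResult(survivors=[s3.spec_id, s2.spec_id], elimination_order=[],
                           pvalues=pd.Series({s2.spec_id: 1.0, s3.spec_id: 1.0}),
                           alpha=0.05, reps=100, block=2, seed=0)
        assert sc.select_best(mcs, lt) == s2

    def test_generating_subset_outforecasts_empty_subset(self):
        """Active national-trend averages are recovered as better forecasters."""
        wins = 0
        reps = 8
        base = sc.ModelSpec()
        gen_id = base.spec_id
        empty_id = base.with_(cs_averages=()).spec_id
        for s in range(reps):
            _, measured, _ = sc.generate_panel(sc.SynthConfig(seed=500 + s))
            lt = sc.evaluate_specs(
                measured, [base.with_(cs_averages=()), base], 2006, 2007, 2010)
            wins += lt.mean_loss[gen_id] < lt.mean_loss[empty_id]
        assert wins / reps >= 0.75


class TestSelectBridge:
    def test_returns_argmin_and_reports_collinearity(self, small_panel, default_spec):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = sc.select_bridge(small_panel, default_spec,
                                   eval_start=2011, eval_end=2014)
        assert sel.best_mode == min(sel.rmsfe, key=sel.rmsfe.get)
        assert set(sel.collinearity) == set(sel.rmsfe)
        assert not sel.failed

    def test_no_break_modes_indistinguishable(self, default_spec):
        cfg = dataclasses.replace(
            sc.SynthConfig(seed=123),
            break_means={v: 0.0 for v in sc.SURVEY_VARS},
            break_sds={v: 0.0 for v in sc.SURVEY_VARS},
        )
        _, measured, _ = sc.generate_panel(cfg)
        sel = sc.select_bridge(measured, default_spec,
                               modes=("none", "intercept_shift"),
                               eval_start=2011, eval_end=2014)
        ratio = sel.rmsfe["intercept_shift"] / sel.rmsfe["none"]
        assert 0.9 <= ratio <= 1.1

    def test_heterogeneous_level_shift_selects_a_bridge(self, default_spec):
        z = {v: 0.0 for v in sc.SURVEY_VARS}
        cfg = dataclasses.replace(
            sc.SynthConfig(seed=9),
            break_means={**z, "prev": 2.0}, break_sds={**z, "prev": 3.0},
        )
        _, measured, _ = sc.generate_panel(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = sc.select_bridge(measured, default_spec,
                                   eval_start=2011, eval_end=2014)
        assert sel.best_mode != "none"

    def test_window_validation(self, small_panel, default_spec):
        with pytest.raises(ValueError, match="break_year"):
            sc.select_bridge(small_panel, default_spec, eval_start=2009, eval_end=2010)
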