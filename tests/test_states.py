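"""Classification of visits from test scores, norms, and clinical flags."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import mcistates as m
from mcistates.states import (
    AllScoresMissingError,
    DegenerateTestError,
    UnknownTestError,
    State,
)


class TestFitNorms:
    def test_recovers_age_slope_and_residual_sd(self):
        # score = 50 - 0.5 (age - 75) + N(0, 4); OLS must recover both pieces
        rng = np.random.default_rng(3)
        age = rng.uniform(60, 90, 200)
        score = 50.0 - 0.5 * (age - 75.0) + rng.normal(0, 4.0, 200)
        df = pd.DataFrame({"age": age, "recall": score})
        norms = m.fit_norms(df, {"recall": m.TestSpec("memory")})
        assert norms.table.loc["recall", "slope"] == pytest.approx(-0.5, abs=0.1)
        assert norms.table.loc["recall", "sd"] == pytest.approx(4.0, abs=0.5)

    def test_matches_independent_ols(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(9)
        age = rng.uniform(62, 88, 120)
        score = 30.0 - 0.3 * age + rng.normal(0, 2.5, 120)
        df = pd.DataFrame({"age": age, "recall": score})
        norms = m.fit_norms(df, {"recall": m.TestSpec("memory")})
        ols = sm.OLS(score, sm.add_constant(age)).fit()
        assert norms.table.loc["recall", "intercept"] == pytest.approx(ols.params[0], abs=1e-8)
        assert norms.table.loc["recall", "slope"] == pytest.approx(ols.params[1], abs=1e-8)
        assert norms.table.loc["recall", "sd"] == pytest.approx(np.sqrt(ols.mse_resid), abs=1e-8)

    def test_collinear_scores_raise_degenerate_error(self):
        df = pd.DataFrame({"age": [70.0, 75.0, 80.0], "recall": [70.0, 80.0, 90.0]})
        with pytest.raises(DegenerateTestError, match="recall"):
            m.fit_norms(df, {"recall": m.TestSpec("memory")})

    def test_single_age_falls_back_to_sample_mean_and_sd(self):
        scores = np.array([10.0, 12.0, 14.0, 16.0])
        df = pd.DataFrame({"age": [75.0] * 4, "recall": scores})
        norms = m.fit_norms(df, {"recall": m.TestSpec("memory")})
        assert norms.table.loc["recall", "slope"] == 0.0
        assert norms.adjusted_mean("recall", 99.0) == pytest.approx(scores.mean())
        assert norms.table.loc["recall", "sd"] == pytest.approx(scores.std(ddof=1))

    def test_too_few_scores_raise(self):
        df = pd.DataFrame({"age": [70.0, 80.0], "recall": [10.0, 12.0]})
        with pytest.raises(ValueError, match="recall"):
            m.fit_norms(df, {"recall": m.TestSpec("memory")})


class TestPoorScore:
    def test_exact_cutoff_is_poor(self, simple_norms, simple_battery):
        # "at least 1.5 SD below": the boundary itself counts
        mu = simple_norms.adjusted_mean("recall", 80.0)
        sd = simple_norms.sd("recall")
        assert m.poor_score(mu - 1.5 * sd, "recall", 80.0, simple_norms, simple_battery)
        assert not m.poor_score(mu - 1.49 * sd, "recall", 80.0, simple_norms, simple_battery)

    def test_mean_is_not_poor(self, simple_norms, simple_battery):
        mu = simple_norms.adjusted_mean("recall", 70.0)
        assert not m.poor_score(mu, "recall", 70.0, simple_norms, simple_battery)

    def test_error_count_direction_flips_inequality(self, simple_norms, simple_battery):
        mu = simple_norms.adjusted_mean("errors", 75.0)
        sd = simple_norms.sd("errors")
        assert m.poor_score(mu + 1.6 * sd, "errors", 75.0, simple_norms, simple_battery)
        assert not m.poor_score(mu - 1.6 * sd, "errors", 75.0, simple_norms, simple_battery)

    def test_unknown_test_raises(self, simple_norms, simple_battery):
        with pytest.raises(UnknownTestError):
            m.poor_score(1.0, "nosuch", 75.0, simple_norms, simple_battery)

    def test_missing_score_is_never_poor(self, simple_norms, simple_battery):
        assert not m.poor_score(float("nan"), "recall", 75.0, simple_norms, simple_battery)


class TestClassifyVisit:
    def _mu(self, norms, test, age):
        return norms.adjusted_mean(test, age)

    def test_clinical_mci_supersedes_normal_scores(self, simple_norms, simple_battery):
        panel = {"recall": self._mu(simple_norms, "recall", 80.0)}
        state = m.classify_visit(panel, m.ClinicalFlags(mci_cc=True), 80.0, simple_norms, simple_battery)
        assert state is State.MCI_CC

    def test_death_and_dementia_precedence(self, simple_norms, simple_battery):
        assert m.classify_visit({}, m.ClinicalFlags(death=True), 80.0, simple_norms, simple_battery) is State.DEATH
        assert (
            m.classify_visit({}, m.ClinicalFlags(dementia=True, mci_cc=True), 80.0, simple_norms, simple_battery)
            is State.DEMENTIA
        )

    def test_conflicting_flags_raise(self):
        with pytest.raises(ValueError):
            m.ClinicalFlags(dementia=True, death=True)

    def test_mixed_takes_precedence_over_amnestic(self, simple_norms, simple_battery):
        age = 75.0
        panel = {
            "recall": self._mu(simple_norms, "recall", age) - 2.0 * simple_norms.sd("recall"),
            "errors": self._mu(simple_norms, "errors", age) + 2.0 * simple_norms.sd("errors"),
        }
        state = m.classify_visit(panel, m.ClinicalFlags(), age, simple_norms, simple_battery)
        assert state is State.MMCI_TB

    def test_poor_memory_only_is_amnestic(self, simple_norms, simple_battery):
        age = 75.0
        panel = {
            "recall": self._mu(simple_norms, "recall", age) - 2.0 * simple_norms.sd("recall"),
            "errors": self._mu(simple_norms, "errors", age),
        }
        assert m.classify_visit(panel, m.ClinicalFlags(), age, simple_norms, simple_battery) is State.AMCI_TB

    def test_no_poor_scores_is_normal(self, simple_norms, simple_battery):
        age = 75.0
        panel = {"recall": self._mu(simple_norms, "recall", age), "errors": float("nan")}
        assert m.classify_visit(panel, m.ClinicalFlags(), age, simple_norms, simple_battery) is State.NORMAL

    def test_all_missing_without_flag_raises(self, simple_norms, simple_battery):
        with pytest.raises(AllScoresMissingError):
            m.classify_visit({"recall": float("nan")}, m.ClinicalFlags(), 75.0, simple_norms, simple_battery)

    @given(
        z_recall=st.floats(-4, 4),
        z_errors=st.floats(-4, 4),
        age=st.floats(65, 90),
    )
    def test_improving_scores_never_worsens_classification(
        self, z_recall, z_errors, age, simple_norms, simple_battery
    ):
        """Monotonicity: +10 SD in the good direction never moves toward MCI."""
        mu_r, sd_r = simple_norms.adjusted_mean("recall", age), simple_norms.sd("recall")
        mu_e, sd_e = simple_norms.adjusted_mean("errors", age), simple_norms.sd("errors")
        panel = {"recall": mu_r + z_recall * sd_r, "errors": mu_e - z_errors * sd_e}
        severity = {State.NORMAL: 0, State.AMCI_TB: 1, State.MMCI_TB: 2}
        before = m.classify_visit(panel, m.ClinicalFlags(), age, simple_norms, simple_battery)
        for test, sign in (("recall", +1), ("errors", -1)):
            better = dict(panel)
            better[test] += sign * 10.0 * simple_norms.sd(test)
            after = m.classify_visit(better, m.ClinicalFlags(), age, simple_norms, simple_battery)
            assert severity[after] <= severity[before]
        all_better = {"recall": panel["recall"] + 10 * sd_r, "errors": panel["errors"] - 10 * sd_e}
        assert m.classify_visit(all_better, m.ClinicalFlags(), age, simple_norms, simple_battery) is State.NORMAL

    def test_exactly_k_planted_subjects_are_amnestic(self, simple_norms, simple_battery):
        k, n, age = 7, 40, 75.0
        mu_r, sd_r = simple_norms.adjusted_mean("recall", age), simple_norms.sd("recall")
        mu_e = simple_norms.adjusted_mean("errors", age)
        df = pd.DataFrame(
            {
                "age": age,
                "recall": [mu_r - 2.0 * sd_r] * k + [mu_r] * (n - k),
                "errors": mu_e,
            }
        )
        out = m.classify_table(df, simple_norms, simple_battery)
        assert (out["state"] == State.AMCI_TB).sum() == k
        assert (out["state"] == State.NORMAL).sum() == n - k


class TestClassifyTable:
    def test_matches_per_visit_classification(self, simple_norms, simple_battery):
        rng = np.random.default_rng(12)
        n = 60
        df = pd.DataFrame(
            {
                "age": rng.uniform(65, 90, n),
                "recall": rng.normal(0, 1, n),
                "errors": rng.normal(0, 1, n),
                "mci_cc": rng.random(n) < 0.1,
                "dementia": 0,
                "death": 0,
            }
        )
        df["recall"] = simple_norms.adjusted_mean("recall", 75) + rng.normal(0, 2, n) * 4
        df["errors"] = rng.normal(-2 + 0.1 * 75, 4, n)
        out = m.classify_table(df, simple_norms, simple_battery)
        for i in out.index:
            expected = m.classify_visit(
                {"recall": out.loc[i, "recall"], "errors": out.loc[i, "errors"]},
                m.ClinicalFlags(mci_cc=bool(out.loc[i, "mci_cc"])),
                out.loc[i, "age"],
                simple_norms,
                simple_battery,
            )
            assert out.loc[i, "state"] is expected

    def test_determinism(self, simple_norms, simple_battery):
        df = pd.DataFrame({"age": [70.0, 80.0], "recall": [40.0, 20.0], "errors": [5.0, 9.0]})
        a = m.classify_table(df, simple_norms, simple_battery)
        b = m.classify_table(df, simple_norms, simple_battery)
        assert list(a["state"]) == list(b["state"])
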