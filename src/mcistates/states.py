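"""Cognitive-state classification from neuropsychological scores and clinical flags.

Each annual visit is assigned exactly one of six states:

* ``NORMAL`` — no poor test score, no clinical diagnosis;
* ``AMCI_TB`` — test-based amnestic MCI: at least one poor episodic-memory score;
* ``MMCI_TB`` — test-based mixed MCI: at least one poor language/executive score,
  regardless of memory performance (mixed takes precedence over amnestic);
* ``MCI_CC`` — clinical-consensus MCI, taken from a diagnosis flag;
* ``DEMENTIA`` and ``DEATH`` — absorbing clinical outcomes, also flag-driven.

A *poor* score lies at least ``threshold`` (default 1.5) residual standard
deviations on the impaired side of an age-adjusted normative mean.  Norms are
fitted once on the baseline visits of a cognitively normal cohort — by default a
per-test linear regression of score on age, whose residual SD serves as the
normative SD — and are frozen thereafter; classification never refits them.

Clinical diagnoses supersede test-based classification: death > dementia >
clinical MCI > test-based states.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "State",
    "TRANSIENT_STATES",
    "ABSORBING_STATES",
    "TestSpec",
    "DEFAULT_BATTERY",
    "ClinicalFlags",
    "NormTable",
    "fit_norms",
    "poor_score",
    "classify_visit",
    "classify_table",
    "DegenerateTestError",
    "UnknownTestError",
    "AllScoresMissingError",
]


class State(enum.IntEnum):
    """Cognitive state at a single assessment."""

    NORMAL = 0
    AMCI_TB = 1
    MMCI_TB = 2
    MCI_CC = 3
    DEMENTIA = 4
    DEATH = 5

    @property
    def is_transient(self) -> bool:
        return self in TRANSIENT_STATES

    @property
    def is_absorbing(self) -> bool:
        return self in ABSORBING_STATES

    @property
    def is_test_based(self) -> bool:
        return self in (State.AMCI_TB, State.MMCI_TB)


#: States a subject can leave freely (normal cognition and the test-based MCIs).
TRANSIENT_STATES = (State.NORMAL, State.AMCI_TB, State.MMCI_TB)
#: States with no outgoing transitions.
ABSORBING_STATES = (State.DEMENTIA, State.DEATH)

MEMORY = "memory"
NONMEMORY = "nonmemory"


class DegenerateTestError(ValueError):
    """A test has (near-)zero residual variance in the normative fit."""


class UnknownTestError(KeyError):
    """A score refers to a test absent from the norms or battery."""


class AllScoresMissingError(ValueError):
    """A visit carries no clinical flag and no non-missing test score."""


@dataclass(frozen=True)
class TestSpec:
    """Cognitive domain and scoring direction of one test.

    ``higher_is_worse`` marks error-count or completion-time scores (e.g. Benton
    errors, Trail Making seconds) where large raw values indicate impairment.
    """

    domain: str
    higher_is_worse: bool = False

    def __post_init__(self) -> None:
        if self.domain not in (MEMORY, NONMEMORY):
            raise ValueError(f"domain must be {MEMORY!r} or {NONMEMORY!r}, got {self.domain!r}")


#: Default battery: episodic-memory measures define the amnestic domain,
#: language/executive measures the mixed domain.  Users may register any battery
#: by passing their own mapping.
DEFAULT_BATTERY: dict[str, TestSpec] = {
    "logical_memory": TestSpec(MEMORY),
    "benton_correct": TestSpec(MEMORY),
    "benton_errors": TestSpec(MEMORY, higher_is_worse=True),
    "wordlist_learning": TestSpec(MEMORY),
    "wordlist_delayed": TestSpec(MEMORY),
    "wordlist_savings": TestSpec(MEMORY),
    "wordlist_forgetting": TestSpec(MEMORY, higher_is_worse=True),
    "fluency_phonemic": TestSpec(NONMEMORY),
    "fluency_category": TestSpec(NONMEMORY),
    "boston_naming": TestSpec(NONMEMORY),
    "trails_a_seconds": TestSpec(NONMEMORY, higher_is_worse=True),
    "trails_b_seconds": TestSpec(NONMEMORY, higher_is_worse=True),
}


@dataclass(frozen=True)
class ClinicalFlags:
    """Consensus-team diagnoses attached to a visit."""

    mci_cc: bool = False
    dementia: bool = False
    death: bool = False

    def __post_init__(self) -> None:
        if self.dementia and self.death:
            raise ValueError("a visit cannot carry both a dementia and a death flag")

    @property
    def any(self) -> bool:
        return self.mci_cc or self.dementia or self.death


class NormTable:
    """Frozen age-adjustment norms: per test an age-linear mean and residual SD."""

    COLUMNS = ("intercept", "slope", "sd", "n")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.COLUMNS[:3] if c not in table.columns]
        if missing:
            raise ValueError(f"norms table lacks columns {missing}")
        if (table["sd"] <= 0).any():
            bad = table.index[table["sd"] <= 0].tolist()
            raise DegenerateTestError(f"non-positive residual SD for tests {bad}")
        self.table = table.copy()

    def __contains__(self, test: str) -> bool:
        return test in self.table.index

    def tests(self) -> list[str]:
        return list(self.table.index)

    def adjusted_mean(self, test: str, age: float) -> float:
        if test not in self:
            raise UnknownTestError(test)
        row = self.table.loc[test]
        return float(row["intercept"] + row["slope"] * age)

    def sd(self, test: str) -> float:
        if test not in self:
            raise UnknownTestError(test)
        return float(self.table.loc[test, "sd"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="test")

    @classmethod
    def from_csv(cls, path) -> "NormTable":
        return cls(pd.read_csv(path, index_col="test"))

    def __repr__(self) -> str:  # pragma: no cover
        return f"NormTable({len(self.table)} tests)"


def fit_norms(
    baseline_visits: pd.DataFrame,
    battery: Mapping[str, TestSpec] = DEFAULT_BATTERY,
    *,
    age_col: str = "age",
    min_scores: int = 3,
) -> NormTable:
    """Fit age-adjustment norms on the baseline visits of the normal cohort.

    For every battery test present in ``baseline_visits``, regress the score on
    age by ordinary least squares and take the residual SD as the normative SD.
    When all contributing ages coincide the fit degenerates gracefully to the
    sample mean and sample SD.

    Raises
    ------
    DegenerateTestError
        If a test's residual variance is (numerically) zero — such a test cannot
        define a 1.5-SD impairment cut-off.
    ValueError
        If a test has fewer than ``min_scores`` non-missing baseline scores.
    """
    if age_col not in baseline_visits.columns:
        raise ValueError(f"baseline table lacks age column {age_col!r}")
    rows = {}
    for test in battery:
        if test not in baseline_visits.columns:
            continue
        sub = baseline_visits[[age_col, test]].dropna()
        n = len(sub)
        if n < min_scores:
            raise ValueError(f"test {test!r} has only {n} non-missing baseline scores (need >= {min_scores})")
        age = sub[age_col].to_numpy(float)
        y = sub[test].to_numpy(float)
        if np.ptp(age) == 0.0:
            slope, intercept = 0.0, float(y.mean())
            resid = y - intercept
            dof = n - 1
        else:
            slope, intercept = np.polyfit(age, y, 1)
            resid = y - (intercept + slope * age)
            dof = n - 2
        sd = float(np.sqrt(resid @ resid / dof))
        if sd <= 1e-9 * max(1.0, float(np.abs(y).max())):
            raise DegenerateTestError(
                f"test {test!r} has zero residual variance in the normative fit"
            )
        rows[test] = (float(intercept), float(slope), sd, n)
    if not rows:
        raise ValueError("no battery test found in the baseline table")
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(NormTable.COLUMNS))
    table.index.name = "test"
    return NormTable(table)


def poor_score(
    score: float,
    test: str,
    age: float,
    norms: NormTable,
    battery: Mapping[str, TestSpec] = DEFAULT_BATTERY,
    threshold: float = 1.5,
) -> bool:
    """True iff ``score`` is at least ``threshold`` SDs worse than the age-adjusted mean.

    The comparison is inclusive ("at least 1.5 SD") and respects the test's
    scoring direction.  A missing (NaN) score is never poor: absence of evidence
    must not create impairment.
    """
    if test not in battery:
        raise UnknownTestError(test)
    if score is None or (isinstance(score, float) and np.isnan(score)):
        return False
    mu = norms.adjusted_mean(test, age)
    sd = norms.sd(test)
    if battery[test].higher_is_worse:
        return bool(score >= mu + threshold * sd)
    return bool(score <= mu - threshold * sd)


def _test_based_state(
    panel: Mapping[str, float],
    age: float,
    norms: NormTable,
    battery: Mapping[str, TestSpec],
    threshold: float,
) -> State:
    """Classification from scores alone; raises if every score is missing."""
    any_score = False
    poor_memory = False
    poor_nonmemory = False
    for test, score in panel.items():
        if test not in battery:
            raise UnknownTestError(test)
        if score is None or (isinstance(score, float) and np.isnan(score)):
            continue
        any_score = True
        if poor_score(score, test, age, norms, battery, threshold):
            if battery[test].domain == NONMEMORY:
                poor_nonmemory = True
            else:
                poor_memory = True
    if not any_score:
        raise AllScoresMissingError("all test scores missing and no clinical flag set")
    if poor_nonmemory:  # mixed MCI regardless of memory status
        return State.MMCI_TB
    if poor_memory:
        return State.AMCI_TB
    return State.NORMAL


def classify_visit(
    panel: Mapping[str, float],
    flags: ClinicalFlags,
    age: float,
    norms: NormTable,
    battery: Mapping[str, TestSpec] = DEFAULT_BATTERY,
    threshold: float = 1.5,
) -> State:
    """Assign the visit state with precedence death > dementia > clinical MCI > test-based."""
    if flags.death:
        return State.DEATH
    if flags.dementia:
        return State.DEMENTIA
    if flags.mci_cc:
        return State.MCI_CC
    return _test_based_state(panel, age, norms, battery, threshold)


def classify_table(
    visits: pd.DataFrame,
    norms: NormTable,
    battery: Mapping[str, TestSpec] = DEFAULT_BATTERY,
    *,
    age_col: str = "age",
    mci_cc_col: str = "mci_cc",
    dementia_col: str = "dementia",
    death_col: str = "death",
    threshold: float = 1.5,
) -> pd.DataFrame:
    """Classify every row of a long-format visit table.

    Returns a copy with two appended columns: ``state`` (final classification,
    clinical flags superseding) and ``state_test_based`` (classification from
    scores alone, pandas NA where no score is available).  The test-based column
    is what trajectory cleaning falls back on when demoting an isolated clinical
    MCI diagnosis.
    """
    tests = [t for t in battery if t in visits.columns]
    if not tests:
        raise ValueError("no battery test column present in the visit table")
    age = visits[age_col].to_numpy(float)
    n = len(visits)

    poor_mem = np.zeros(n, bool)
    poor_nonmem = np.zeros(n, bool)
    any_score = np.zeros(n, bool)
    for test in tests:
        score = visits[test].to_numpy(float)
        ok = ~np.isnan(score)
        any_score |= ok
        mu = norms.table.loc[test, "intercept"] + norms.table.loc[test, "slope"] * age
        sd = norms.table.loc[test, "sd"]
        if battery[test].higher_is_worse:
            poor = ok & (score >= mu + threshold * sd)
        else:
            poor = ok & (score <= mu - threshold * sd)
        if battery[test].domain == NONMEMORY:
            poor_nonmem |= poor
        else:
            poor_mem |= poor

    tb = np.where(poor_nonmem, State.MMCI_TB, np.where(poor_mem, State.AMCI_TB, State.NORMAL))

    def _flag(col: str) -> np.ndarray:
        if col in visits.columns:
            return visits[col].fillna(0).to_numpy(float).astype(bool)
        return np.zeros(n, bool)

    f_cc, f_dem, f_death = _flag(mci_cc_col), _flag(dementia_col), _flag(death_col)
    if (f_dem & f_death).any():
        raise ValueError("rows with both dementia and death flags set")

    flagged = f_cc | f_dem | f_death
    missing = ~any_score & ~flagged
    if missing.any():
        idx = visits.index[missing].tolist()[:5]
        raise AllScoresMissingError(
            f"{int(missing.sum())} visits have no score and no clinical flag (first rows: {idx})"
        )

    state = tb.copy()
    state[f_cc] = State.MCI_CC
    state[f_dem] = State.DEMENTIA
    state[f_death] = State.DEATH

    out = visits.copy()
    # object dtype keeps State enums intact (pandas would downcast IntEnum to int64)
    out["state"] = pd.Series([State(int(s)) for s in state], index=out.index, dtype=object)
    out["state_test_based"] = pd.Series(
        [State(int(s)) if ok else pd.NA for s, ok in zip(tb, any_score)],
        index=out.index,
        dtype=object,
    )
    return out
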