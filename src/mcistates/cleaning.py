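"""Trajectory container and enforcement of the quasi-absorbing clinical-MCI state.

Clinical-consensus MCI (``MCI_CC``) is quasi-absorbing: a subject may progress to
dementia or death but never reverts to a transient state.  Raw longitudinal
classifications occasionally violate this — in the motivating cohort, chart
review traced every apparent reversion to medical comorbidity, conflicting
informant data, or misclassification.  This module replaces that human
adjudication with two deterministic patterns plus an audit trail:

* **Pattern A** — the reversion is followed by a later ``MCI_CC`` or dementia:
  every transient visit after the first ``MCI_CC`` is reclassified as ``MCI_CC``.
* **Pattern B** — the ``MCI_CC`` visits are followed only by transient states to
  the end of follow-up: those diagnoses are demoted to the visit's test-based
  classification (such subjects may still be aMCI_TB or mMCI_TB on scores;
  ``NORMAL`` when no fallback classification is available).  ``B_initial`` marks
  the sub-case where the demoted diagnosis sat at the very first visit,
  ``B_mid`` the isolated-diagnosis-with-normals-on-either-side case.

Users can override individual visits before the pattern rules run via a manual
edit mapping (e.g. loaded from YAML), mirroring record-level adjudication.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .states import ABSORBING_STATES, State

__all__ = [
    "Trajectory",
    "Edit",
    "ValidationReport",
    "clean_trajectory",
    "clean_cohort",
    "validate_trajectories",
    "audit_frame",
]

#: Baseline covariates a trajectory is expected to carry for modelling.
BASELINE_COVARIATES = ("female", "famhx", "apoe4", "low_educ", "htn")


@dataclass
class Trajectory:
    """Ordered per-subject sequence of classified states.

    ``times`` are years since study entry (strictly increasing, first element
    0); ``covariates`` holds the baseline risk factors; ``test_based`` optionally
    carries the score-only classification per visit, used when demoting an
    unsupported clinical-MCI diagnosis.
    """

    subject_id: Hashable
    times: np.ndarray
    states: list[State]
    age_at_entry: float
    covariates: dict = field(default_factory=dict)
    test_based: list | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.states = [State(s) for s in self.states]
        if len(self.times) != len(self.states):
            raise ValueError("times and states differ in length")
        if self.test_based is not None and len(self.test_based) != len(self.states):
            raise ValueError("test_based and states differ in length")

    @property
    def n_visits(self) -> int:
        return len(self.states)

    @property
    def ages(self) -> np.ndarray:
        return self.age_at_entry + self.times

    def violations(self) -> Counter:
        """Count invariant violations (never mutates)."""
        c: Counter = Counter()
        if np.any(np.diff(self.times) <= 0):
            c["nonmonotone_times"] += 1
        seen_death = seen_dementia = False
        seen_cc = False
        n_death = self.states.count(State.DEATH)
        if n_death > 1:
            c["multiple_death"] += 1
        for s in self.states:
            if seen_death:
                c["visit_after_death"] += 1
            if seen_dementia:
                c["visit_after_dementia"] += 1
            if seen_cc and s.is_transient:
                c["transient_after_mci_cc"] += 1
            seen_death |= s is State.DEATH
            seen_dementia |= s is State.DEMENTIA
            seen_cc |= s is State.MCI_CC
        return c


@dataclass(frozen=True)
class Edit:
    """One reclassified visit in the cleaning audit trail."""

    subject_id: Hashable
    visit: int
    old: State
    new: State
    pattern: str


def _check_orderly(traj: Trajectory) -> None:
    v = traj.violations()
    for key in ("nonmonotone_times", "visit_after_death", "visit_after_dementia", "multiple_death"):
        if v[key]:
            raise ValueError(f"trajectory {traj.subject_id!r}: invariant violation {key!r}")


def clean_trajectory(
    raw: Trajectory,
    manual_edits: Mapping[int, State] | None = None,
) -> tuple[Trajectory, list[Edit]]:
    """Apply the back-transition reclassification patterns to one trajectory.

    Returns a new trajectory satisfying the quasi-absorbing invariant together
    with the list of per-visit edits.  Idempotent: cleaning a clean trajectory
    returns it unchanged with an empty audit.  Dementia and death visits, visit
    count and visit times are never altered.
    """
    _check_orderly(raw)
    states = list(raw.states)
    edits: list[Edit] = []

    if manual_edits:
        for visit, new in sorted(manual_edits.items()):
            new = State(new)
            if states[visit] is not new:
                edits.append(Edit(raw.subject_id, visit, states[visit], new, "manual"))
                states[visit] = new

    cc_idx = [i for i, s in enumerate(states) if s is State.MCI_CC]
    if cc_idx:
        i0 = cc_idx[0]
        trans_after = [i for i in range(i0 + 1, len(states)) if states[i].is_transient]
        if trans_after:
            later_progression = any(
                states[j] in (State.MCI_CC, State.DEMENTIA) for j in range(trans_after[0] + 1, len(states))
            )
            if later_progression:
                # Pattern A: MCI_CC held at every assessment after the first diagnosis.
                for i in trans_after:
                    edits.append(Edit(raw.subject_id, i, states[i], State.MCI_CC, "A"))
                    states[i] = State.MCI_CC
            else:
                # Pattern B: unsupported diagnoses demoted to the test-based state.
                pattern = "B_initial" if i0 == 0 else "B_mid"
                for i in cc_idx:
                    fallback = State.NORMAL
                    if raw.test_based is not None and raw.test_based[i] is not None and not pd.isna(raw.test_based[i]):
                        fallback = State(raw.test_based[i])
                    edits.append(Edit(raw.subject_id, i, states[i], fallback, pattern))
                    states[i] = fallback

    cleaned = replace(raw, states=states, times=raw.times.copy())
    assert cleaned.violations()["transient_after_mci_cc"] == 0
    return cleaned, edits


def clean_cohort(
    trajs: Iterable[Trajectory],
    manual_edits: Mapping[Hashable, Mapping[int, State]] | None = None,
) -> tuple[list[Trajectory], list[Edit]]:
    """Clean every trajectory; returns cleaned cohort and pooled audit."""
    cleaned, audit = [], []
    for traj in trajs:
        per_subject = (manual_edits or {}).get(traj.subject_id)
        t, e = clean_trajectory(traj, per_subject)
        cleaned.append(t)
        audit.extend(e)
    return cleaned, audit


def audit_frame(edits: Sequence[Edit]) -> pd.DataFrame:
    """Audit trail as a table (subject, visit, old state, new state, pattern)."""
    return pd.DataFrame(
        [(e.subject_id, e.visit, e.old.name, e.new.name, e.pattern) for e in edits],
        columns=["subject_id", "visit", "old_state", "new_state", "pattern"],
    )


@dataclass
class ValidationReport:
    """Invariant-violation counts over a cohort; reporting only, never mutates."""

    n_trajectories: int
    counts: Counter

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def ok(self) -> bool:
        return self.total == 0

    def __repr__(self) -> str:
        body = ", ".join(f"{k}={v}" for k, v in sorted(self.counts.items())) or "no violations"
        return f"ValidationReport({self.n_trajectories} trajectories: {body})"


def validate_trajectories(trajs: Iterable[Trajectory]) -> ValidationReport:
    """Tally invariant violations (ordering, absorbing, quasi-absorbing) by type."""
    counts: Counter = Counter()
    n = 0
    for traj in trajs:
        n += 1
        counts.update(traj.violations())
    return ValidationReport(n, counts)
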