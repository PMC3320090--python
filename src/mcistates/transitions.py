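"""One-step transition pairs and the transition count/percentage matrix.

Every couple of temporally adjacent assessments forms a pair (prior state,
current state).  The *base state* of a pair — the reference category of the
polytomous regression — is normal cognition while the prior state is transient
and clinical-consensus MCI afterwards.  Absorbing states (dementia, death)
terminate a subject's contribution; transitions among transient states between
scheduled assessments are not modelled.  Death, when supplied with its own
date, is mapped to the assessment slot following the last visit, matching the
discrete-time chain.
"""

from __future__ import annotations

from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import model
from .cleaning import Trajectory
from .states import ABSORBING_STATES, State

__all__ = [
    "TransitionPair",
    "TransitionMatrix",
    "build_pairs",
    "tabulate",
    "aggregate_rates",
    "PAIR_COLUMNS",
]

#: Prior-state rows of the transition matrix (absorbing states have no row).
PRIOR_ORDER = (State.NORMAL, State.AMCI_TB, State.MMCI_TB, State.MCI_CC)
CURRENT_ORDER = tuple(State)

PAIR_COLUMNS = (
    "subject",
    "prior",
    "current",
    "base",
    "interval",
) + model.NORMAL_COVARIATES


class TransitionPair(NamedTuple):
    """One likelihood contribution: a prior/current state couple with covariates."""

    subject: object
    prior: State
    current: State
    base: State
    covariates: dict
    interval: float


def _as_state(value) -> State:
    if isinstance(value, State):
        return value
    if isinstance(value, str):
        try:
            return State[value]
        except KeyError as exc:
            raise KeyError(f"unknown state name {value!r}") from exc
    return State(value)


def build_pairs(trajs: Iterable[Trajectory], *, log=None) -> pd.DataFrame:
    """Decompose cleaned trajectories into one-step transition pairs.

    A subject with *k* visits and no absorbing endpoint contributes *k - 1*
    pairs; an absorbing state ends the contribution.  Pairs with missing
    baseline covariates are excluded complete-case and counted via ``log``
    (a callable receiving one message), never silently.

    Raises on uncleaned input (a transient state following MCI_CC, or any state
    after an absorbing one).
    """
    rows = []
    n_excluded = 0
    for traj in trajs:
        v = traj.violations()
        if v["transient_after_mci_cc"]:
            raise ValueError(
                f"trajectory {traj.subject_id!r} has a back-transition from MCI_CC; clean first"
            )
        if v["visit_after_death"] or v["visit_after_dementia"] or v["nonmonotone_times"]:
            raise ValueError(f"trajectory {traj.subject_id!r} violates ordering invariants")
        ages = traj.ages
        for i in range(traj.n_visits - 1):
            prior = traj.states[i]
            if prior in ABSORBING_STATES:
                break
            base = State.MCI_CC if prior is State.MCI_CC else State.NORMAL
            cov = model.build_covariates(prior, float(ages[i]), traj.covariates, base)
            if cov is None:
                n_excluded += 1
                continue
            rows.append(
                (
                    traj.subject_id,
                    prior,
                    traj.states[i + 1],
                    base,
                    float(traj.times[i + 1] - traj.times[i]),
                )
                + tuple(cov[c] for c in model.NORMAL_COVARIATES)
            )
    if n_excluded and log is not None:
        log(f"excluded {n_excluded} pairs with missing baseline covariates")
    df = pd.DataFrame(rows, columns=list(PAIR_COLUMNS))
    df.attrs["n_excluded"] = n_excluded
    return df


def _round_half_up(x, decimals: int = 1):
    factor = 10.0**decimals
    return np.floor(np.asarray(x, float) * factor + 0.5) / factor


class TransitionMatrix:
    """Counts and row percentages of one-step transitions (4 prior rows x 6 columns).

    Structurally impossible cells (MCI_CC row to transient columns) are zero and
    rendered blank.  Percentages are reported to one decimal with half-up
    rounding.
    """

    def __init__(self, counts: pd.DataFrame):
        counts = counts.reindex(
            index=[s.name for s in PRIOR_ORDER], columns=[s.name for s in CURRENT_ORDER]
        ).fillna(0)
        if (counts.to_numpy() < 0).any():
            raise ValueError("negative transition counts")
        impossible = counts.loc["MCI_CC", [s.name for s in State if s.is_transient]]
        if (impossible != 0).any():
            raise ValueError("nonzero counts in structurally impossible MCI_CC-row cells")
        self.counts = counts.astype(int)

    @classmethod
    def from_pairs(cls, pairs: pd.DataFrame) -> "TransitionMatrix":
        if len(pairs) == 0:
            raise ValueError("no transition pairs")
        tab = pd.crosstab(
            pairs["prior"].map(lambda s: State(s).name),
            pairs["current"].map(lambda s: State(s).name),
        )
        return cls(tab)

    @classmethod
    def from_counts(cls, counts: Mapping[State, Mapping[State, float]] | pd.DataFrame | np.ndarray) -> "TransitionMatrix":
        """Build from an explicit count table (e.g. a published transition matrix)."""
        if isinstance(counts, pd.DataFrame):
            df = counts.copy()
            df.index = [_as_state(i).name for i in df.index]
            df.columns = [_as_state(c).name for c in df.columns]
        elif isinstance(counts, Mapping):
            df = pd.DataFrame(
                {
                    _as_state(prior).name: {_as_state(cur).name: v for cur, v in row.items()}
                    for prior, row in counts.items()
                }
            ).T
        else:
            df = pd.DataFrame(
                np.asarray(counts),
                index=[s.name for s in PRIOR_ORDER],
                columns=[s.name for s in CURRENT_ORDER],
            )
        return cls(df)

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def row_percent(self) -> pd.DataFrame:
        """Unrounded row-conditional percentages."""
        return 100.0 * self.counts.div(self.row_totals.replace(0, np.nan), axis=0)

    def rounded_percent(self, decimals: int = 1) -> pd.DataFrame:
        return self.row_percent.apply(lambda col: _round_half_up(col, decimals))

    def pooled_rate(self, prior, currents: Sequence, decimals: int | None = None) -> float:
        """Percentage of a prior row falling in a union of current-state columns."""
        prior = _as_state(prior).name
        cols = [_as_state(c).name for c in currents]
        value = 100.0 * self.counts.loc[prior, cols].sum() / self.counts.loc[prior].sum()
        return float(_round_half_up(value, decimals)) if decimals is not None else float(value)

    def to_csv(self, path) -> None:
        self.counts.to_csv(path, index_label="prior")

    def to_text(self) -> str:
        """Formatted count (percent) table; impossible cells left blank."""
        pct = self.rounded_percent()
        width = 16
        lines = ["prior".ljust(10) + "".join(s.name.ljust(width) for s in CURRENT_ORDER)]
        for prior in PRIOR_ORDER:
            cells = []
            for cur in CURRENT_ORDER:
                if prior is State.MCI_CC and cur.is_transient:
                    cells.append("".ljust(width))
                    continue
                c = self.counts.loc[prior.name, cur.name]
                p = pct.loc[prior.name, cur.name]
                cells.append(f"{c} ({p:.1f})".ljust(width))
            lines.append(prior.name.ljust(10) + "".join(cells))
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"TransitionMatrix(total={self.total})"


def tabulate(pairs: pd.DataFrame) -> TransitionMatrix:
    """Tabulate transition pairs into the count/percentage matrix."""
    return TransitionMatrix.from_pairs(pairs)


def aggregate_rates(
    source: pd.DataFrame | TransitionMatrix,
    groupings: Iterable[tuple[object, Sequence]],
) -> pd.DataFrame:
    """Pooled percentages for arbitrary unions of current-state columns within a row.

    ``groupings`` is an iterable of ``(prior_state, currents)``; unknown state
    names raise ``KeyError``.
    """
    matrix = source if isinstance(source, TransitionMatrix) else tabulate(source)
    rows = []
    for prior, currents in groupings:
        p = _as_state(prior)
        cols = [_as_state(c) for c in currents]
        count = int(matrix.counts.loc[p.name, [c.name for c in cols]].sum())
        total = int(matrix.counts.loc[p.name].sum())
        rows.append(
            {
                "prior": p.name,
                "currents": "+".join(c.name for c in cols),
                "count": count,
                "total": total,
                "percent": 100.0 * count / total if total else np.nan,
            }
        )
    return pd.DataFrame(rows)
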