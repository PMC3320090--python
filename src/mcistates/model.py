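"""Shared-random-effect polytomous logistic Markov model of one-step transitions.

The chain has three transient states (normal cognition, aMCI_TB, mMCI_TB), one
quasi-absorbing state (clinical-consensus MCI) and two absorbing states
(dementia, death).  Between two adjacent assessments the log-odds of moving to
each competing outcome versus remaining in (or returning to) a *base state* are
linear in covariates:

    logit_k = alpha_k + x' beta_k + u,        u ~ N(0, sigma_u^2),

where the base state — the reference category with logit 0 — is normal cognition
until the subject enters clinical MCI, and clinical MCI afterwards.  The model
is additive: covariate effects do not interact with the prior state, so a single
6-category block (with prior-state indicator covariates) covers all transient
prior states, and a 3-category block covers the clinical-MCI base.  A scalar
subject-level random effect ``u`` is shared across every non-reference logit of
both blocks, inducing within-subject correlation.

The marginal likelihood integrates ``u`` by Gauss–Hermite quadrature, either
centred at zero (non-adaptive) or recentred and rescaled at each subject's
posterior mode (adaptive; with one point this is the Laplace approximation,
the default).  Maximisation is quasi-Newton (BFGS).  Exact analytic gradients
are implemented for the fixed-effects, Laplace, and non-adaptive rules; adaptive
rules with more than one point fall back on finite differences.  Standard
errors come from the inverse observed information (numerically differentiated
score), and "relative risks" are exponentiated coefficients with Wald intervals
— odds-ratio-type quantities, labelled RR to mirror conventional reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp, roots_hermite
from scipy.stats import norm

from .states import State

__all__ = [
    "AGE_CENTER",
    "NORMAL_COVARIATES",
    "CC_COVARIATES",
    "NORMAL_OUTCOMES",
    "CC_OUTCOMES",
    "ModelParams",
    "QuadratureRule",
    "PairData",
    "FitConfig",
    "FitResult",
    "build_covariates",
    "linear_predictors",
    "transition_probs",
    "subject_loglik",
    "marginal_loglik",
    "fit",
    "relative_risks",
    "format_relative_risks",
    "InestimableCategoryError",
    "LikelihoodError",
]

#: Age is centred at the sample median of the motivating cohort.
AGE_CENTER = 78.0

#: Covariates of the normal-base block, in reporting order.  Prior-state
#: indicators encode the transient prior state (normal cognition is reference).
NORMAL_COVARIATES = ("age_c", "female", "famhx", "apoe4", "low_educ", "htn", "prior_amci", "prior_mmci")
#: The clinical-MCI base block drops the prior-state indicators.
CC_COVARIATES = NORMAL_COVARIATES[:6]

#: Competing outcomes per base state (the base itself is the reference).
NORMAL_OUTCOMES = (State.AMCI_TB, State.MMCI_TB, State.MCI_CC, State.DEMENTIA, State.DEATH)
CC_OUTCOMES = (State.DEMENTIA, State.DEATH)

_LOG_2PI = math.log(2.0 * math.pi)


class InestimableCategoryError(ValueError):
    """An outcome category has no observed transition; its coefficients are inestimable."""


class LikelihoodError(FloatingPointError):
    """Non-finite likelihood contribution, annotated with the subject id."""


# ---------------------------------------------------------------------------
# Parameters


@dataclass
class ModelParams:
    """Regression coefficients per (base state, outcome) plus the random-effect SD.

    ``beta_normal`` has shape ``(1 + len(covariates_normal), 5)`` — an intercept
    row followed by one row per covariate, one column per competing outcome in
    ``NORMAL_OUTCOMES`` order.  ``beta_cc`` is ``(1 + len(covariates_cc), 2)``
    for ``CC_OUTCOMES``.  The base category has all-zero coefficients by
    construction and is not stored.
    """

    beta_normal: np.ndarray
    beta_cc: np.ndarray
    sigma_u: float = 0.0
    covariates_normal: tuple = NORMAL_COVARIATES
    covariates_cc: tuple = CC_COVARIATES

    def __post_init__(self) -> None:
        self.beta_normal = np.asarray(self.beta_normal, float)
        self.beta_cc = np.asarray(self.beta_cc, float)
        if self.beta_normal.shape != (1 + len(self.covariates_normal), len(NORMAL_OUTCOMES)):
            raise ValueError(f"beta_normal has shape {self.beta_normal.shape}")
        if self.beta_cc.shape != (1 + len(self.covariates_cc), len(CC_OUTCOMES)):
            raise ValueError(f"beta_cc has shape {self.beta_cc.shape}")
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be >= 0")

    @classmethod
    def zeros(
        cls,
        covariates_normal: tuple = NORMAL_COVARIATES,
        covariates_cc: tuple = CC_COVARIATES,
        sigma_u: float = 0.0,
    ) -> "ModelParams":
        return cls(
            np.zeros((1 + len(covariates_normal), len(NORMAL_OUTCOMES))),
            np.zeros((1 + len(covariates_cc), len(CC_OUTCOMES))),
            sigma_u,
            covariates_normal,
            covariates_cc,
        )

    def copy(self) -> "ModelParams":
        return replace(self, beta_normal=self.beta_normal.copy(), beta_cc=self.beta_cc.copy())

    def labels(self) -> list[tuple[str, str, str]]:
        """(base, term, outcome) label per packed coefficient, matching ``pack`` order."""
        out = []
        for term in ("intercept",) + tuple(self.covariates_normal):
            for outcome in NORMAL_OUTCOMES:
                out.append(("NORMAL", term, outcome.name))
        for term in ("intercept",) + tuple(self.covariates_cc):
            for outcome in CC_OUTCOMES:
                out.append(("MCI_CC", term, outcome.name))
        return out

    def pack(self, with_sigma: bool) -> np.ndarray:
        theta = np.concatenate([self.beta_normal.ravel(), self.beta_cc.ravel()])
        if with_sigma:
            theta = np.append(theta, math.log(self.sigma_u))
        return theta

    def unpack(self, theta: np.ndarray, with_sigma: bool) -> "ModelParams":
        n_n = self.beta_normal.size
        n_c = self.beta_cc.size
        bn = np.asarray(theta[:n_n], float).reshape(self.beta_normal.shape)
        bc = np.asarray(theta[n_n : n_n + n_c], float).reshape(self.beta_cc.shape)
        sigma = math.exp(float(theta[n_n + n_c])) if with_sigma else self.sigma_u
        return ModelParams(bn, bc, sigma, self.covariates_normal, self.covariates_cc)

    def to_frame(self) -> pd.DataFrame:
        labels = self.labels()
        values = self.pack(with_sigma=False)
        df = pd.DataFrame(labels, columns=["base", "term", "outcome"])
        df["estimate"] = values
        return df


@dataclass(frozen=True)
class QuadratureRule:
    """Gauss–Hermite integration rule for the random effect.

    ``adaptive`` recentres/rescales the nodes at the per-subject posterior mode;
    one adaptive point coincides with the Laplace approximation.  With
    ``sigma_u == 0`` every rule collapses to the fixed-effects likelihood.
    """

    n_points: int = 1
    adaptive: bool = True

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")


# ---------------------------------------------------------------------------
# Covariates


def build_covariates(
    prior_state: State,
    prior_age: float,
    baseline: Mapping[str, float],
    base: State | None = None,
) -> dict | None:
    """Covariate vector for one transition; ``None`` when a baseline field is missing.

    Age comes from the prior visit of the pair and is centred at ``AGE_CENTER``;
    binary codings: female 1/0, family history 1/0, any APOE-4 allele 1/0,
    education <=12 years 1/0, baseline hypertension 1/0.  Prior-state indicators
    are set from the prior state only when the base is normal cognition.
    Missing-covariate pairs are excluded (complete case) by the caller, which
    logs the count rather than raising.
    """
    prior_state = State(prior_state)
    if base is None:
        base = State.MCI_CC if prior_state is State.MCI_CC else State.NORMAL
    fields = {}
    for name in CC_COVARIATES[1:]:  # all binary baseline covariates
        value = baseline.get(name)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return None
        fields[name] = float(value)
    if prior_age is None or (isinstance(prior_age, float) and np.isnan(prior_age)):
        return None
    fields["age_c"] = float(prior_age) - AGE_CENTER
    is_normal_base = base is State.NORMAL
    fields["prior_amci"] = float(is_normal_base and prior_state is State.AMCI_TB)
    fields["prior_mmci"] = float(is_normal_base and prior_state is State.MMCI_TB)
    return fields


# ---------------------------------------------------------------------------
# Pair container

_N_CODE = {State.NORMAL: 0, **{s: i + 1 for i, s in enumerate(NORMAL_OUTCOMES)}}
_CC_CODE = {State.MCI_CC: 0, **{s: i + 1 for i, s in enumerate(CC_OUTCOMES)}}


@dataclass
class PairData:
    """Transition pairs arranged for vectorised likelihood evaluation.

    Pairs are split by base state; within each block ``X`` is the design matrix
    (leading intercept column), ``y`` the outcome code (0 = remained in /
    returned to the base state) and ``subj`` the 0-based subject index, sorted.
    """

    X_n: np.ndarray
    y_n: np.ndarray
    subj_n: np.ndarray
    X_c: np.ndarray
    y_c: np.ndarray
    subj_c: np.ndarray
    subject_ids: pd.Index
    covariates_normal: tuple = NORMAL_COVARIATES
    covariates_cc: tuple = CC_COVARIATES

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_pairs(self) -> int:
        return len(self.y_n) + len(self.y_c)

    @classmethod
    def from_pairs(
        cls,
        pairs: pd.DataFrame,
        covariates_normal: Sequence[str] = NORMAL_COVARIATES,
        covariates_cc: Sequence[str] = CC_COVARIATES,
    ) -> "PairData":
        pairs = pairs.sort_values("subject", kind="stable").reset_index(drop=True)
        subject_ids = pd.Index(pairs["subject"].unique(), name="subject")
        subj_code = pairs["subject"].map({s: i for i, s in enumerate(subject_ids)}).to_numpy()

        base = pairs["base"].map(State).to_numpy()
        current = pairs["current"].map(State).to_numpy()
        is_n = base == State.NORMAL

        bad = [
            (b, c)
            for b, c in zip(base[~is_n], current[~is_n])
            if State(c) not in _CC_CODE
        ]
        if bad:
            raise ValueError(f"structurally impossible transition(s) from MCI_CC base: {bad[:3]}")

        def _design(df: pd.DataFrame, covs: Sequence[str]) -> np.ndarray:
            X = np.empty((len(df), 1 + len(covs)))
            X[:, 0] = 1.0
            for j, c in enumerate(covs):
                X[:, 1 + j] = df[c].to_numpy(float)
            return X

        df_n = pairs[is_n]
        df_c = pairs[~is_n]
        return cls(
            X_n=_design(df_n, covariates_normal),
            y_n=np.array([_N_CODE[State(c)] for c in current[is_n]], dtype=np.int64),
            subj_n=subj_code[is_n],
            X_c=_design(df_c, covariates_cc),
            y_c=np.array([_CC_CODE[State(c)] for c in current[~is_n]], dtype=np.int64),
            subj_c=subj_code[~is_n],
            subject_ids=subject_ids,
            covariates_normal=tuple(covariates_normal),
            covariates_cc=tuple(covariates_cc),
        )


def _segment_sum(values: np.ndarray, subj: np.ndarray, n: int) -> np.ndarray:
    """Sum ``values`` (first axis = pairs, subject-sorted) per subject."""
    out_shape = (n,) + values.shape[1:]
    out = np.zeros(out_shape)
    if len(subj) == 0:
        return out
    starts = np.flatnonzero(np.diff(subj, prepend=-1))
    sums = np.add.reduceat(values, starts, axis=0)
    out[subj[starts]] = sums
    return out


# ---------------------------------------------------------------------------
# Single-pair API


def linear_predictors(
    x: Mapping[str, float],
    base: State,
    params: ModelParams,
    u: float = 0.0,
) -> pd.Series:
    """Logits over outcome categories for one transition; the base category is 0.

    The shared random effect ``u`` shifts every non-reference logit by the same
    amount.
    """
    base = State(base)
    if base is State.NORMAL:
        covs, B, outcomes = params.covariates_normal, params.beta_normal, NORMAL_OUTCOMES
    elif base is State.MCI_CC:
        covs, B, outcomes = params.covariates_cc, params.beta_cc, CC_OUTCOMES
    else:
        raise ValueError(f"base must be NORMAL or MCI_CC, got {base}")
    missing = [c for c in covs if c not in x]
    if missing:
        raise ValueError(f"covariate vector lacks {missing}")
    xv = np.concatenate([[1.0], [float(x[c]) for c in covs]])
    eta = xv @ B + u
    index = [base] + list(outcomes)
    return pd.Series(np.concatenate([[0.0], eta]), index=index, name="logit")


def transition_probs(
    x: Mapping[str, float],
    base: State,
    params: ModelParams,
    u: float = 0.0,
) -> pd.Series:
    """Multinomial-logit transition probabilities; structurally excluded outcomes absent."""
    eta = linear_predictors(x, base, params, u)
    p = np.exp(eta.to_numpy() - logsumexp(eta.to_numpy()))
    return pd.Series(p, index=eta.index, name="prob")


# ---------------------------------------------------------------------------
# Vectorised likelihood internals


def _block_eta(X: np.ndarray, B: np.ndarray, u_rows: np.ndarray) -> np.ndarray:
    return X @ B + u_rows[:, None]


def _block_ll(eta: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair log-likelihood and log(1 + sum exp eta)."""
    lse = np.logaddexp(0.0, logsumexp(eta, axis=1)) if eta.shape[1] else np.zeros(len(eta))
    chosen = np.zeros(len(eta))
    nz = y > 0
    if nz.any():
        chosen[nz] = eta[nz, y[nz] - 1]
    return chosen - lse, lse


def _loglik_by_subject(data: PairData, params: ModelParams, u: np.ndarray) -> np.ndarray:
    """Conditional log-likelihood per subject at random-effect values ``u``."""
    n = data.n_subjects
    total = np.zeros(n)
    for X, y, subj, B in (
        (data.X_n, data.y_n, data.subj_n, params.beta_normal),
        (data.X_c, data.y_c, data.subj_c, params.beta_cc),
    ):
        if len(y) == 0:
            continue
        ll, _ = _block_ll(_block_eta(X, B, u[subj]), y)
        total += _segment_sum(ll, subj, n)
    return total


def _block_q(eta: np.ndarray) -> np.ndarray:
    """Per-pair probability of leaving the base state, q = 1 - p_base."""
    lse = np.logaddexp(0.0, logsumexp(eta, axis=1))
    return np.exp(logsumexp(eta, axis=1) - lse)


def _posterior_modes(
    data: PairData,
    params: ModelParams,
    u0: np.ndarray | None = None,
    tol: float = 1e-11,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject mode of loglik(u) + log-prior and the negated curvature there.

    The objective is strictly concave in ``u`` (multinomial log-likelihood plus a
    Gaussian log-prior), so damped Newton converges quickly; iterations run
    vectorised across subjects.
    """
    n = data.n_subjects
    sigma2 = params.sigma_u**2
    u = np.zeros(n) if u0 is None else u0.copy()
    for _ in range(max_iter):
        score = -u / sigma2
        curv = np.full(n, 1.0 / sigma2)
        for X, y, subj, B in (
            (data.X_n, data.y_n, data.subj_n, params.beta_normal),
            (data.X_c, data.y_c, data.subj_c, params.beta_cc),
        ):
            if len(y) == 0:
                continue
            q = _block_q(_block_eta(X, B, u[subj]))
            score += _segment_sum((y > 0).astype(float) - q, subj, n)
            curv += _segment_sum(q * (1.0 - q), subj, n)
        step = score / curv
        np.clip(step, -4.0, 4.0, out=step)
        u += step
        if np.max(np.abs(step)) < tol:
            break
    return u, curv


def _log_prior(u: np.ndarray, sigma: float) -> np.ndarray:
    return -0.5 * (u / sigma) ** 2 - math.log(sigma) - 0.5 * _LOG_2PI


def _marginal_by_subject(
    data: PairData,
    params: ModelParams,
    rule: QuadratureRule,
    u0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-subject marginal log-likelihood; also returns the modes when adaptive."""
    if params.sigma_u == 0.0:
        return _loglik_by_subject(data, params, np.zeros(data.n_subjects)), None
    z, w = roots_hermite(rule.n_points)
    if rule.adaptive:
        u_hat, curv = _posterior_modes(data, params, u0)
        tau = 1.0 / np.sqrt(curv)
        # log integral = log(sqrt(2) tau) + logsumexp_q [log w_q + z_q^2 + h(u_hat + sqrt(2) tau z_q)]
        terms = np.empty((data.n_subjects, rule.n_points))
        for qi, (zq, wq) in enumerate(zip(z, w)):
            uq = u_hat + math.sqrt(2.0) * tau * zq
            h = _loglik_by_subject(data, params, uq) + _log_prior(uq, params.sigma_u)
            terms[:, qi] = math.log(wq) + zq**2 + h
        per = np.log(math.sqrt(2.0) * tau) + logsumexp(terms, axis=1)
        return per, u_hat
    # non-adaptive: nodes fixed at sqrt(2) sigma z_q, weights integrate the prior exactly
    terms = np.empty((data.n_subjects, rule.n_points))
    for qi, (zq, wq) in enumerate(zip(z, w)):
        uq = math.sqrt(2.0) * params.sigma_u * zq
        terms[:, qi] = math.log(wq / math.sqrt(math.pi)) + _loglik_by_subject(
            data, params, np.full(data.n_subjects, uq)
        )
    return logsumexp(terms, axis=1), None


# ---------------------------------------------------------------------------
# Public likelihood API


def subject_loglik(pairs: pd.DataFrame, params: ModelParams, u: float) -> float:
    """Conditional log-likelihood of one subject's transition pairs given ``u``.

    Under the Markov assumption this is the sum of per-pair log transition
    probabilities.  Raises :class:`LikelihoodError` when a pair's current state
    is impossible under the parameters (log-probability ``-inf``).
    """
    if pairs["subject"].nunique() > 1:
        raise ValueError("subject_loglik expects the pairs of a single subject")
    data = PairData.from_pairs(pairs, params.covariates_normal, params.covariates_cc)
    value = float(_loglik_by_subject(data, params, np.full(1, float(u)))[0])
    if not np.isfinite(value):
        raise LikelihoodError(f"non-finite log-likelihood for subject {data.subject_ids[0]!r}")
    return value


def marginal_loglik(
    source: pd.DataFrame | PairData,
    params: ModelParams,
    rule: QuadratureRule = QuadratureRule(),
) -> float:
    """Marginal log-likelihood of the cohort, integrating the shared random effect.

    With ``sigma_u == 0`` the integral collapses to the fixed-effects likelihood
    for any rule.
    """
    data = source if isinstance(source, PairData) else PairData.from_pairs(
        source, params.covariates_normal, params.covariates_cc
    )
    per, _ = _marginal_by_subject(data, params, rule)
    bad = ~np.isfinite(per)
    if bad.any():
        sid = data.subject_ids[int(np.flatnonzero(bad)[0])]
        raise LikelihoodError(f"non-finite marginal likelihood for subject {sid!r}")
    return float(per.sum())


# ---------------------------------------------------------------------------
# Analytic gradients


def _fe_nll_grad(theta: np.ndarray, data: PairData, template: ModelParams) -> tuple[float, np.ndarray]:
    """Fixed-effects (sigma_u = 0) negative log-likelihood and gradient."""
    params = template.unpack(theta, with_sigma=False)
    nll = 0.0
    grads = []
    for X, y, subj, B in (
        (data.X_n, data.y_n, data.subj_n, params.beta_normal),
        (data.X_c, data.y_c, data.subj_c, params.beta_cc),
    ):
        K = B.shape[1]
        if len(y) == 0:
            grads.append(np.zeros(B.size))
            continue
        eta = X @ B
        ll, lse = _block_ll(eta, y)
        nll -= ll.sum()
        P = np.exp(eta - lse[:, None])
        R = -P
        nz = y > 0
        R[nz, y[nz] - 1] += 1.0
        grads.append(-(X.T @ R).ravel())
    return float(nll), np.concatenate(grads)


def _laplace_nll_grad(theta: np.ndarray, data: PairData, template: ModelParams, cache: dict) -> tuple[float, np.ndarray]:
    """Exact negative log-likelihood and gradient of the Laplace (1-point adaptive) objective.

    Differentiates through the per-subject mode via the implicit-function
    theorem; verified against finite differences in the test suite.
    """
    params = template.unpack(theta, with_sigma=True)
    sigma = params.sigma_u
    n = data.n_subjects
    u_hat, H = _posterior_modes(data, params, cache.get("u0"))
    cache["u0"] = u_hat

    n_beta = params.beta_normal.size + params.beta_cc.size
    S = np.zeros((n, n_beta))   # d loglik / d beta at the mode
    A = np.zeros((n, n_beta))   # d loglik'(u) / d beta
    C = np.zeros((n, n_beta))   # d loglik''(u) / d beta
    l3 = np.zeros(n)            # third derivative of loglik in u
    loglik = np.zeros(n)

    offset = 0
    for X, y, subj, B in (
        (data.X_n, data.y_n, data.subj_n, params.beta_normal),
        (data.X_c, data.y_c, data.subj_c, params.beta_cc),
    ):
        size = B.size
        if len(y):
            eta = _block_eta(X, B, u_hat[subj])
            ll, lse = _block_ll(eta, y)
            loglik += _segment_sum(ll, subj, n)
            P = np.exp(eta - lse[:, None])       # non-base outcome probs
            q = P.sum(axis=1)                    # prob of leaving base
            p0 = 1.0 - q
            R = -P
            nz = y > 0
            R[nz, y[nz] - 1] += 1.0
            # per-pair outer products x (x) categories, flattened to match pack order
            S[:, offset : offset + size] += _segment_sum(
                (X[:, :, None] * R[:, None, :]).reshape(len(y), size), subj, n
            )
            Pp0 = P * p0[:, None]
            A[:, offset : offset + size] += _segment_sum(
                (-X[:, :, None] * Pp0[:, None, :]).reshape(len(y), size), subj, n
            )
            C[:, offset : offset + size] += _segment_sum(
                (-X[:, :, None] * (Pp0 * (1.0 - 2.0 * q)[:, None])[:, None, :]).reshape(len(y), size),
                subj,
                n,
            )
            l3 += _segment_sum(-(1.0 - 2.0 * q) * q * p0, subj, n)
        offset += size

    sigma2 = sigma * sigma
    per = loglik + _log_prior(u_hat, sigma) + 0.5 * _LOG_2PI - 0.5 * np.log(H)
    nll = -float(per.sum())

    inv_H = 1.0 / H
    du_dbeta = A * inv_H[:, None]
    dH_dbeta = -C - l3[:, None] * du_dbeta
    g_beta = (S - 0.5 * dH_dbeta * inv_H[:, None]).sum(axis=0)

    dh_dsigma = u_hat**2 / sigma**3 - 1.0 / sigma
    du_dsigma = (2.0 * u_hat / sigma**3) * inv_H
    dH_dsigma = -l3 * du_dsigma - 2.0 / sigma**3
    g_sigma = (dh_dsigma - 0.5 * dH_dsigma * inv_H).sum()
    g_logsigma = sigma * g_sigma

    return nll, -np.append(g_beta, g_logsigma)


def _gh_nll_grad(
    theta: np.ndarray, data: PairData, template: ModelParams, rule: QuadratureRule
) -> tuple[float, np.ndarray]:
    """Negative log-likelihood and exact gradient of the non-adaptive Gauss–Hermite objective."""
    params = template.unpack(theta, with_sigma=True)
    sigma = params.sigma_u
    n = data.n_subjects
    z, w = roots_hermite(rule.n_points)
    Q = rule.n_points

    terms = np.empty((n, Q))
    for qi in range(Q):
        uq = math.sqrt(2.0) * sigma * z[qi]
        terms[:, qi] = math.log(w[qi] / math.sqrt(math.pi)) + _loglik_by_subject(
            data, params, np.full(n, uq)
        )
    per = logsumexp(terms, axis=1)
    omega = np.exp(terms - per[:, None])  # posterior node weights per subject

    n_beta = params.beta_normal.size + params.beta_cc.size
    g_beta = np.zeros(n_beta)
    g_sigma = 0.0
    for qi in range(Q):
        uq = math.sqrt(2.0) * sigma * z[qi]
        offset = 0
        lprime = np.zeros(n)
        for X, y, subj, B in (
            (data.X_n, data.y_n, data.subj_n, params.beta_normal),
            (data.X_c, data.y_c, data.subj_c, params.beta_cc),
        ):
            size = B.size
            if len(y):
                eta = _block_eta(X, B, np.full(len(y), uq))
                lse = np.logaddexp(0.0, logsumexp(eta, axis=1))
                P = np.exp(eta - lse[:, None])
                R = -P
                nz = y > 0
                R[nz, y[nz] - 1] += 1.0
                wrow = omega[subj, qi]
                g_beta[offset : offset + size] += (
                    (X * wrow[:, None]).T @ R
                ).ravel()
                lprime += _segment_sum((y > 0).astype(float) - P.sum(axis=1), subj, n)
            offset += size
        g_sigma += float(omega[:, qi] @ lprime) * math.sqrt(2.0) * z[qi]

    return -float(per.sum()), -np.append(g_beta, sigma * g_sigma)


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class FitConfig:
    """Options for maximum-likelihood estimation.

    ``quadrature`` defaults to one adaptive point (Laplace).  ``random_effects
    = False`` fixes ``sigma_u`` at zero and fits the plain polytomous logistic
    model.  ``n_starts > 1`` adds jittered restarts (seeded) as a guard against
    local optima.  ``sigma_u`` is estimated on the log scale internally.
    """

    quadrature: QuadratureRule = field(default_factory=QuadratureRule)
    random_effects: bool = True
    covariates_normal: tuple = NORMAL_COVARIATES
    covariates_cc: tuple = CC_COVARIATES
    start: ModelParams | None = None
    sigma_start: float = 0.3
    gtol: float = 1e-6
    max_iter: int = 500
    n_starts: int = 1
    start_jitter: float = 0.3
    start_seed: int = 0
    compute_se: bool = True
    separation_threshold: float = 15.0


@dataclass
class FitResult:
    """Maximum-likelihood estimates with uncertainty and convergence metadata."""

    params: ModelParams
    se: ModelParams | None
    cov: pd.DataFrame | None
    loglik: float
    converged: bool
    n_iter: int
    message: str
    n_pairs: int
    n_subjects: int
    config: FitConfig
    warnings: list = field(default_factory=list)
    se_sigma_u: float | None = None

    def param_table(self) -> pd.DataFrame:
        df = self.params.to_frame()
        if self.se is not None:
            df["se"] = self.se.pack(with_sigma=False)
        return df

    def to_json_dict(self) -> dict:
        d = {
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "message": self.message,
            "n_pairs": self.n_pairs,
            "n_subjects": self.n_subjects,
            "sigma_u": self.params.sigma_u,
            "se_sigma_u": self.se_sigma_u,
            "warnings": list(self.warnings),
            "covariates_normal": list(self.params.covariates_normal),
            "covariates_cc": list(self.params.covariates_cc),
            "beta_normal": self.params.beta_normal.tolist(),
            "beta_cc": self.params.beta_cc.tolist(),
        }
        if self.se is not None:
            d["se_beta_normal"] = self.se.beta_normal.tolist()
            d["se_beta_cc"] = self.se.beta_cc.tolist()
        return d


def _check_estimable(data: PairData) -> None:
    if len(data.y_n):
        seen = set(np.unique(data.y_n))
        required = set(range(len(NORMAL_OUTCOMES) + 1))
        missing = sorted(required - seen)
        if missing:
            names = [("NORMAL" if c == 0 else NORMAL_OUTCOMES[c - 1].name) for c in missing]
            raise InestimableCategoryError(
                f"no observed transition into {names} from the normal-base block"
            )
    if len(data.y_c):
        seen = set(np.unique(data.y_c))
        missing = sorted(set(range(len(CC_OUTCOMES) + 1)) - seen)
        if missing:
            names = [("MCI_CC" if c == 0 else CC_OUTCOMES[c - 1].name) for c in missing]
            raise InestimableCategoryError(
                f"no observed transition into {names} from the MCI_CC-base block"
            )


def _numeric_hessian(grad_fn, theta: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Observed information via central differences of the score."""
    p = len(theta)
    H = np.empty((p, p))
    for j in range(p):
        h = rel_step * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        H[:, j] = (grad_fn(tp) - grad_fn(tm)) / (2.0 * h)
    return 0.5 * (H + H.T)


def fit(pairs: pd.DataFrame, config: FitConfig | None = None) -> FitResult:
    """Maximise the marginal likelihood by quasi-Newton (BFGS) ascent.

    Fixed-effects estimates (``sigma_u = 0``) are obtained first and seed the
    random-effects fit.  Standard errors come from the inverse observed
    information; the covariance is reported on the internal scale (log
    ``sigma_u``), with the ``sigma_u`` SE mapped back by the delta method.
    """
    config = config or FitConfig()
    data = PairData.from_pairs(pairs, config.covariates_normal, config.covariates_cc)
    _check_estimable(data)
    template = ModelParams.zeros(config.covariates_normal, config.covariates_cc)
    warnings: list[str] = []

    # --- stage 1: fixed effects ---------------------------------------------
    theta0 = (
        config.start.pack(with_sigma=False)
        if config.start is not None
        else template.pack(with_sigma=False)
    )
    fe = minimize(
        _fe_nll_grad,
        theta0,
        args=(data, template),
        jac=True,
        method="BFGS",
        options={"gtol": config.gtol, "maxiter": config.max_iter},
    )

    estimate_sigma = config.random_effects
    if not estimate_sigma:
        best, with_sigma, nll_fn = fe, False, lambda t: _fe_nll_grad(t, data, template)
    else:
        rule = config.quadrature
        cache: dict = {}
        if rule.adaptive and rule.n_points == 1:
            def nll_fn(t, _cache=cache):
                return _laplace_nll_grad(t, data, template, _cache)

            use_jac = True
        elif not rule.adaptive:
            def nll_fn(t):
                return _gh_nll_grad(t, data, template, rule)

            use_jac = True
        else:
            def nll_fn(t):  # adaptive, >1 point: objective only, numeric gradient
                params = template.unpack(t, with_sigma=True)
                per, _ = _marginal_by_subject(data, params, rule)
                return -float(per.sum())

            use_jac = False

        sigma0 = config.start.sigma_u if (config.start is not None and config.start.sigma_u > 0) else config.sigma_start
        start_theta = np.append(fe.x, math.log(sigma0))
        starts = [start_theta]
        if config.n_starts > 1:
            rng = np.random.default_rng(config.start_seed)
            starts += [
                start_theta + rng.normal(0.0, config.start_jitter, len(start_theta))
                for _ in range(config.n_starts - 1)
            ]
        best = None
        for s in starts:
            res = minimize(
                nll_fn,
                s,
                jac=use_jac if use_jac else None,
                method="BFGS",
                options={"gtol": config.gtol, "maxiter": config.max_iter},
            )
            if best is None or res.fun < best.fun:
                best = res
        with_sigma = True

    params = template.unpack(best.x, with_sigma=with_sigma)
    converged = bool(best.success) or "precision loss" in str(best.message).lower()
    if not bool(best.success):
        warnings.append(f"optimizer message: {best.message}")

    max_beta = max(np.abs(params.beta_normal).max(), np.abs(params.beta_cc).max())
    if max_beta > config.separation_threshold:
        warnings.append(
            f"possible separation: |beta| up to {max_beta:.1f} exceeds {config.separation_threshold}"
        )

    se = cov_df = None
    se_sigma = None
    if config.compute_se:
        if not with_sigma:
            def grad_only(t):
                return _fe_nll_grad(t, data, template)[1]
        elif use_jac:
            def grad_only(t):
                return nll_fn(t)[1]
        else:
            def grad_only(t, _h=1e-6):  # numeric score for adaptive multi-point rules
                f0 = nll_fn(t)
                g = np.empty(len(t))
                for j in range(len(t)):
                    tp = t.copy()
                    tp[j] += _h * max(1.0, abs(t[j]))
                    g[j] = (nll_fn(tp) - f0) / (_h * max(1.0, abs(t[j])))
                return g
        try:
            H = _numeric_hessian(grad_only, best.x)
            try:
                cov = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                cov = np.linalg.pinv(H)
                warnings.append("observed information singular; pseudo-inverse used")
            d = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            labels = [f"{b}:{t}:{o}" for b, t, o in template.labels()]
            if with_sigma:
                labels.append("log_sigma_u")
            cov_df = pd.DataFrame(cov, index=labels, columns=labels)
            n_beta = template.beta_normal.size + template.beta_cc.size
            se = template.unpack(d[:n_beta], with_sigma=False)
            se.sigma_u = 0.0
            if with_sigma:
                se_sigma = float(params.sigma_u * d[n_beta])  # delta method from log scale
        except Exception as exc:  # pragma: no cover - defensive
            warnings.append(f"standard errors unavailable: {exc}")

    return FitResult(
        params=params,
        se=se,
        cov=cov_df,
        loglik=-float(best.fun),
        converged=converged,
        n_iter=int(best.get("nit", 0)),
        message=str(best.message),
        n_pairs=data.n_pairs,
        n_subjects=data.n_subjects,
        config=config,
        warnings=warnings,
        se_sigma_u=se_sigma,
    )


# ---------------------------------------------------------------------------
# Reporting

#: Two-sided 95% normal quantile used for Wald intervals.
Z_95 = float(norm.ppf(0.975))


def relative_risks(result: FitResult, level: float = 0.95) -> pd.DataFrame:
    """Exponentiated coefficients with Wald confidence intervals.

    One row per (base state, outcome, covariate); ``significant`` marks
    intervals excluding 1.  Intercepts are omitted (they are baseline log-odds,
    not risk ratios).  These are odds-ratio-type quantities from a polytomous
    logistic model, labelled RR by convention.
    """
    if result.se is None:
        raise ValueError("fit carries no standard errors")
    z = float(norm.ppf(0.5 + level / 2.0))
    df = result.param_table()
    df = df[df["term"] != "intercept"].copy()
    df["rr"] = np.exp(df["estimate"])
    df["lo"] = np.exp(df["estimate"] - z * df["se"])
    df["hi"] = np.exp(df["estimate"] + z * df["se"])
    df["significant"] = (df["lo"] > 1.0) | (df["hi"] < 1.0)
    return df.reset_index(drop=True)


def format_relative_risks(rr: pd.DataFrame, base: str = "NORMAL") -> str:
    """Text table (covariate rows x outcome columns) of RR (lo-hi), '*' = significant."""
    sub = rr[rr["base"] == base]
    outcomes = [o.name for o in (NORMAL_OUTCOMES if base == "NORMAL" else CC_OUTCOMES) if o.name in set(sub["outcome"])]
    terms = list(dict.fromkeys(sub["term"]))
    width = 24
    lines = [f"Base state: {base}", "risk factor".ljust(16) + "".join(o.ljust(width) for o in outcomes)]
    for term in terms:
        cells = []
        for o in outcomes:
            row = sub[(sub["term"] == term) & (sub["outcome"] == o)]
            if row.empty:
                cells.append("".ljust(width))
                continue
            r = row.iloc[0]
            star = "*" if r["significant"] else " "
            cells.append(f"{r['rr']:.2f} ({r['lo']:.2f}-{r['hi']:.2f}){star}".ljust(width))
        lines.append(term.ljust(16) + "".join(cells))
    return "\n".join(lines)
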