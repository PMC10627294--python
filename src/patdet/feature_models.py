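"""Feature-based observer models.

Two families of models describe an observer who uses only summary
features of the sequence rather than the whole sequence:

* **Ideal single-feature observers** — for a feature ``phi`` the exact
  distributions of ``phi(S)`` under both generators are computed by full
  enumeration, and the observer applies the likelihood-ratio rule
  "respond DMS iff P[phi(S)=v | DMS] > P[phi(S)=v | RANDOM]" (ties to
  RANDOM).  For a feature with monotone likelihood ratio this reduces to
  a fixed threshold on the feature value.

* **GLM feature-combination observers** — a logistic regression of the
  per-trial binary response on a subset of the (signed) features,

      E[P[DMS-response | S]] = psi(beta_0 + sum_k beta_k phi_k(S)),

  fitted by maximum likelihood.  Weights are also reported in Menard's
  fully standardized form so that features on different scales are
  comparable:

      beta*_k = beta_k * s_k * R / s_eta,

  with ``s_k`` the sample SD of feature k, ``s_eta`` the sample SD of
  the fitted linear predictor (the logit of the fitted probability) and
  ``R`` the correlation between fitted probabilities and responses.
  An observer's *dominant feature* is the feature with the largest
  standardized coefficient in the all-features fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .features import FEATURE_IDS, FEATURE_NAMES, signed_feature_batch
from .generators import GeneratorParams
from .ideal_observer import _exact_grid
from .model_selection import aicc as _aicc
from .sdt import SDTEstimate, sdt_from_rates

#: Cap (absolute value) on standardized-scale coefficients when a fit is
#: refitted under complete separation.
SEPARATION_CAP = 15.0

#: Below this largest |standardized coefficient| a dominance call is
#: flagged unreliable (the observer is statistically indistinguishable
#: from guessing at typical session sizes).
DOMINANCE_RELIABLE_MIN = 0.1


@dataclass(frozen=True)
class FeatureDistribution:
    """Exact distribution of one (signed) feature under both generators."""

    feature_id: int
    support: np.ndarray
    p_random: np.ndarray
    p_dms: np.ndarray
    params: GeneratorParams


def exact_feature_distribution(
    feature_id: int, params: GeneratorParams
) -> FeatureDistribution:
    """Exact feature distribution by summing over all 2^n sequences.

    ``p_random(v)`` sums ``2**-n`` and ``p_dms(v)`` sums ``P[S|DMS]``
    over the sequences with feature value ``v``.  Feature values use the
    signed convention (F2 negated).
    """
    if feature_id not in FEATURE_IDS:
        raise ValueError(f"unknown feature id {feature_id}; expected 1..4")
    seqs, log_dms = _exact_grid(params)
    vals = signed_feature_batch(feature_id, seqs)
    support, idx = np.unique(vals, return_inverse=True)
    p_random = np.bincount(idx, minlength=support.size) / seqs.shape[0]
    p_dms = np.bincount(idx, weights=np.exp(log_dms), minlength=support.size)
    return FeatureDistribution(
        feature_id=feature_id,
        support=support,
        p_random=p_random,
        p_dms=p_dms,
        params=params,
    )


@dataclass(frozen=True)
class SingleFeatureClassifier:
    """Ideal observer that sees only one feature of the sequence."""

    dist: FeatureDistribution
    #: per-support-value decision (True = respond DMS); LR rule, ties to RANDOM
    decision: np.ndarray

    @property
    def feature_id(self) -> int:
        return self.dist.feature_id

    def _lookup(self, vals: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.dist.support, vals)
        in_support = (idx < self.dist.support.size) & (
            self.dist.support[np.minimum(idx, self.dist.support.size - 1)] == vals
        )
        if not in_support.all():
            bad = np.asarray(vals)[~in_support][:5]
            raise ValueError(
                f"feature value(s) {bad.tolist()} outside the support of "
                f"feature {self.feature_id} at n={self.dist.params.n}"
            )
        return idx

    def decide_batch(self, seqs) -> np.ndarray:
        """Boolean array: True where the decision is DMS."""
        vals = signed_feature_batch(self.feature_id, seqs)
        return self.decision[self._lookup(vals)]

    def decide(self, seq) -> str:
        from .generators import as_sequence

        return "DMS" if self.decide_batch(as_sequence(seq)[None, :])[0] else "RANDOM"

    def exact_performance(self) -> SDTEstimate:
        """Exact hit/false-alarm rates of the feature rule by summation."""
        hit = float(self.dist.p_dms[self.decision].sum())
        fa = float(self.dist.p_random[self.decision].sum())
        return sdt_from_rates(hit, fa)


def single_feature_classifier(dist: FeatureDistribution) -> SingleFeatureClassifier:
    """Build the likelihood-ratio rule on a feature's exact distribution.

    Probabilities equal within relative tolerance 1e-9 count as ties
    (and go to RANDOM): the exact masses are sums of many floating-point
    terms, so a strict comparison would turn round-off into decisions in
    the degenerate p_d = 0.5 case.
    """
    tied = np.isclose(dist.p_dms, dist.p_random, rtol=1e-9, atol=1e-15)
    decision = (dist.p_dms > dist.p_random) & ~tied
    return SingleFeatureClassifier(dist=dist, decision=decision)


@dataclass
class GLMFit:
    """A maximum-likelihood logistic fit of responses on a feature subset."""

    subset: tuple[int, ...]
    beta0: float
    beta: np.ndarray
    loglik: float
    k_params: int
    n_obs: int
    aicc: float
    converged: bool
    separation: bool
    beta_std: np.ndarray | None = None
    beta_se: np.ndarray | None = field(default=None, repr=False)

    @property
    def feature_names(self) -> list[str]:
        return [FEATURE_NAMES[i] for i in self.subset]

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        x = X[self.feature_names].to_numpy(dtype=float)
        return self.beta0 + x @ self.beta


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _bounded_ml_fit(x: np.ndarray, y: np.ndarray, cap: float) -> tuple[float, np.ndarray]:
    """ML logistic fit with coefficients capped on the standardized scale.

    Used when the data are completely separated, where unbounded ML
    diverges.  Features are z-scored internally; standardized-scale
    slopes are bounded at +-cap and mapped back to raw scale.
    """
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    z = (x - mu) / sd
    k = x.shape[1]

    def neg_ll(theta):
        eta = theta[0] + z @ theta[1:]
        p = expit(eta)
        grad_eta = p - y
        grad = np.concatenate([[grad_eta.sum()], z.T @ grad_eta])
        return -_bernoulli_loglik(eta, y), grad

    bounds = [(-2 * cap, 2 * cap)] + [(-cap, cap)] * k
    res = minimize(
        neg_ll, np.zeros(k + 1), jac=True, method="L-BFGS-B", bounds=bounds
    )
    theta = res.x
    beta = theta[1:] / sd
    beta0 = theta[0] - float(np.sum(theta[1:] * mu / sd))
    return beta0, beta


def glm_fit(X: pd.DataFrame, responses, subset=FEATURE_IDS) -> GLMFit:
    """Fit the logistic feature-combination model by maximum likelihood.

    Parameters
    ----------
    X : DataFrame
        Per-trial signed feature values (columns named as in
        :data:`patdet.features.FEATURE_NAMES`).
    responses : array-like
        Per-trial binary judgments; 1 / "DMS" codes a pattern response.
    subset : iterable of int
        Feature ids to include (non-empty subset of {1, 2, 3, 4}).

    Complete separation is detected (the fitted predictor perfectly
    splits the two response classes); the fit is then redone with capped
    coefficients and flagged, keeping the comparison on an ML footing
    without penalization.
    """
    subset = tuple(sorted(set(subset)))
    if not subset or not set(subset) <= set(FEATURE_IDS):
        raise ValueError(f"subset must be a non-empty subset of {FEATURE_IDS}")
    y = np.asarray(
        [1 if r in (1, True, "DMS") else 0 for r in np.asarray(responses).ravel()],
        dtype=float,
    )
    cols = [FEATURE_NAMES[i] for i in subset]
    missing = [c for c in cols if c not in X.columns]
    if missing:
        raise ValueError(f"feature matrix lacks columns {missing}")
    x = X[cols].to_numpy(dtype=float)
    if x.shape[0] != y.size:
        raise ValueError("features and responses disagree on trial count")
    if y.size < 2 or y.min() == y.max():
        raise ValueError("need at least one trial in each response class")
    if np.any(x.std(axis=0) == 0.0):
        flat = [c for c, s in zip(cols, x.std(axis=0)) if s == 0.0]
        raise ValueError(f"degenerate (constant) feature column(s): {flat}")

    design = sm.add_constant(x)
    converged = False
    separation = False
    params = None
    bse = None
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", False))
            params = np.asarray(res.params, dtype=float)
            bse = np.asarray(res.bse, dtype=float)
        except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
            separation = True

    if params is not None and not separation:
        # quasi-separation check: fitted predictor perfectly splits classes
        eta = design @ params
        if eta[y == 1].min() > eta[y == 0].max():
            separation = True
    if separation or params is None or not converged:
        beta0, beta = _bounded_ml_fit(x, y, SEPARATION_CAP)
        separation = True
        converged = True
        bse = None
    else:
        beta0, beta = float(params[0]), params[1:]

    eta = beta0 + x @ beta
    ll = _bernoulli_loglik(eta, y)
    k = len(subset) + 1
    fit = GLMFit(
        subset=subset,
        beta0=float(beta0),
        beta=np.asarray(beta, dtype=float),
        loglik=ll,
        k_params=k,
        n_obs=int(y.size),
        aicc=_aicc(ll, k, int(y.size)),
        converged=converged,
        separation=separation,
        beta_se=bse,
    )
    standardize_menard(fit, X, y)
    return fit


def standardize_menard(fit: GLMFit, X: pd.DataFrame, responses) -> np.ndarray:
    """Menard's fully standardized logistic-regression coefficients.

    ``beta*_k = beta_k * s_k * R / s_eta`` with ``s_k`` the sample SD of
    feature k, ``s_eta`` the sample SD of the fitted linear predictor
    and ``R`` the correlation between fitted probabilities and observed
    responses.  One SD of feature k then moves logit(Y-hat) by
    ``beta*_k`` standardized units.  Stored on the fit and returned.

    A fit whose slopes are all zero has a zero-variance predictor; the
    standardized weights are then all zero (and any dominance call on
    them is flagged unreliable).
    """
    y = np.asarray(
        [1 if r in (1, True, "DMS") else 0 for r in np.asarray(responses).ravel()],
        dtype=float,
    )
    x = X[fit.feature_names].to_numpy(dtype=float)
    s_x = x.std(axis=0, ddof=1)
    if np.any(s_x == 0.0):
        raise ValueError("standardization undefined for a zero-variance feature")
    eta = fit.beta0 + x @ fit.beta
    s_eta = eta.std(ddof=1)
    if s_eta == 0.0:
        fit.beta_std = np.zeros_like(fit.beta)
        return fit.beta_std
    p = expit(eta)
    r = float(np.corrcoef(p, y)[0, 1])
    fit.beta_std = fit.beta * s_x * r / s_eta
    return fit.beta_std


@dataclass(frozen=True)
class DominanceResult:
    """Which feature carries the largest standardized weight for a fit."""

    feature_id: int
    tied: bool
    reliable: bool
    coefficients: dict[int, float]


def dominant_feature(fit: GLMFit) -> DominanceResult:
    """Identify the dominant feature of an all-features fit.

    Returns the feature with the greatest standardized coefficient
    (signed argmax; F2 is already sign-flipped so all expected signs are
    positive).  Exact ties resolve to the lowest feature index and are
    flagged.  A call where every |beta*| is below
    :data:`DOMINANCE_RELIABLE_MIN` is flagged unreliable.
    """
    if fit.subset != FEATURE_IDS:
        raise ValueError("dominance is defined on the all-features fit (subset 1234)")
    if fit.beta_std is None:
        raise ValueError("fit has no standardized coefficients")
    coefs = dict(zip(fit.subset, (float(b) for b in fit.beta_std)))
    best_val = max(coefs.values())
    winners = [fid for fid, v in coefs.items() if v == best_val]
    return DominanceResult(
        feature_id=min(winners),
        tied=len(winners) > 1,
        reliable=bool(np.max(np.abs(fit.beta_std)) >= DOMINANCE_RELIABLE_MIN),
        coefficients=coefs,
    )


def fit_all_subsets(X: pd.DataFrame, responses) -> dict[str, GLMFit]:
    """Fit the logistic model for every non-empty feature subset (15 fits)."""
    from .model_selection import enumerate_subsets, subset_name

    return {
        subset_name(s): glm_fit(X, responses, s) for s in enumerate_subsets(4)
    }
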