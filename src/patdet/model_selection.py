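"""AICc model comparison over all feature subsets.

Fifteen candidate observer models arise from the non-empty subsets of
the four features; each is a logistic regression of the observer's
responses on the chosen features.  Models are compared by the
small-sample-corrected Akaike information criterion

    AICc = -2 loglik + 2k + 2k(k+1) / (n - k - 1)

and the relative support of two fitted models is the evidence ratio
``exp(dAICc / 2)``.  Jeffreys-style benchmarks: > 3 substantial,
> 10 strong, > 30 very strong, > 100 decisive.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd

#: Jeffreys-style evidence-ratio benchmarks selectable as support cutoffs.
EVIDENCE_LEVELS = (3.0, 10.0, 30.0, 100.0)


def aicc(loglik: float, k_params: int, n_obs: int) -> float:
    """Small-sample-corrected AIC.

    Parameters
    ----------
    loglik : float
        Maximized log-likelihood of the fitted model.
    k_params : int
        Number of free parameters (intercept + slopes for a GLM).
    n_obs : int
        Number of observations; must exceed ``k_params + 1`` or the
        correction term is undefined.
    """
    if n_obs <= k_params + 1:
        raise ValueError(
            f"AICc undefined for n_obs={n_obs} <= k_params+1={k_params + 1}"
        )
    return -2.0 * loglik + 2.0 * k_params + 2.0 * k_params * (k_params + 1) / (
        n_obs - k_params - 1
    )


def evidence_ratio(delta_aicc: float) -> float:
    """Relative support exp(dAICc / 2) of the lower-AICc model of a pair.

    Signed input is allowed: a negative delta returns the reciprocal.
    """
    return math.exp(delta_aicc / 2.0)


def subset_name(subset) -> str:
    """Canonical model name: concatenated sorted feature indices ('13')."""
    return "".join(str(i) for i in sorted(subset))


def enumerate_subsets(n_features: int = 4) -> list[tuple[int, ...]]:
    """All non-empty feature subsets, ordered by (size, lexicographic).

    For four features this yields 15 models: four single-feature, six
    two-feature, four three-feature and one four-feature model.
    """
    if n_features < 1:
        raise ValueError(f"n_features must be >= 1, got {n_features}")
    ids = range(1, n_features + 1)
    out: list[tuple[int, ...]] = []
    for size in range(1, n_features + 1):
        out.extend(combinations(ids, size))
    return out


def multimodel_table(
    fits, criterion: float = 10.0, n_features: int = 4
) -> tuple[pd.DataFrame, dict]:
    """Rank a complete set of subset fits by AICc.

    Parameters
    ----------
    fits : mapping or iterable
        One :class:`~patdet.feature_models.GLMFit` per subset, keyed (or
        named) by the canonical subset name; all ``2**n_features - 1``
        subsets must be present.
    criterion : float
        Evidence-ratio cutoff for the supported set; a model is marked
        supported when its evidence ratio against the best model is
        strictly below the cutoff (default 10, "strong evidence").

    Returns
    -------
    table : DataFrame
        Columns model, k, loglik, aicc, delta_aicc, evidence_ratio,
        supported; rows in canonical subset order.
    summary : dict
        ``best`` (overall best model name), ``best_by_size`` (best model
        per feature count) and ``step_evidence_ratios`` mapping
        ``"k->k+1"`` to exp((AICc best k-feature - AICc best
        (k+1)-feature)/2) — the parsimony comparison of adding one
        feature (> 1 favours the larger model).
    """
    if criterion <= 1.0:
        raise ValueError(f"evidence-ratio cutoff must exceed 1, got {criterion}")
    if hasattr(fits, "values"):
        fit_map = {subset_name(f.subset): f for f in fits.values()}
    else:
        fit_map = {subset_name(f.subset): f for f in fits}
    wanted = [subset_name(s) for s in enumerate_subsets(n_features)]
    missing = [name for name in wanted if name not in fit_map]
    if missing:
        raise ValueError(f"incomplete model table; missing subsets {missing}")

    rows = []
    for name in wanted:
        f = fit_map[name]
        rows.append(
            {
                "model": name,
                "k": len(f.subset),
                "loglik": f.loglik,
                "aicc": f.aicc,
            }
        )
    table = pd.DataFrame(rows)
    best_aicc = table["aicc"].min()
    table["delta_aicc"] = table["aicc"] - best_aicc
    table["evidence_ratio"] = np.exp(table["delta_aicc"] / 2.0)
    table["supported"] = table["evidence_ratio"] < criterion

    best = table.loc[table["aicc"].idxmin(), "model"]
    best_by_size = {
        int(k): g.loc[g["aicc"].idxmin(), "model"] for k, g in table.groupby("k")
    }
    step_er = {}
    for k in sorted(best_by_size)[:-1]:
        a_small = table.loc[table["model"] == best_by_size[k], "aicc"].item()
        a_large = table.loc[table["model"] == best_by_size[k + 1], "aicc"].item()
        step_er[f"{k}->{k + 1}"] = evidence_ratio(a_small - a_large)
    summary = {
        "best": best,
        "best_by_size": best_by_size,
        "step_evidence_ratios": step_er,
        "criterion": criterion,
    }
    return table, summary


def average_aicc_table(tables) -> pd.DataFrame:
    """Average AICc (and deltas) across observers' model tables.

    Mirrors reporting AICc per model averaged over a population of
    observers.  Input: iterable of per-observer tables from
    :func:`multimodel_table`.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("need at least one model table")
    stacked = pd.concat(tables, ignore_index=True)
    out = (
        stacked.groupby(["model", "k"], as_index=False)["aicc"]
        .mean()
        .sort_values(["k", "model"], ignore_index=True)
    )
    out["delta_aicc"] = out["aicc"] - out["aicc"].min()
    return out
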