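"""Synthetic observers: noisy weighted-feature responders with lapses.

A synthetic observer mirrors the logistic feature-combination model so
that every fitting stage of the analysis has a known ground truth.  On
each trial the probability of a "pattern" (DMS) response is

    P(respond DMS | S) = lapse/2 + (1 - lapse) * psi(beta_0 + sum_k beta_k phi_k(S) + e),

where ``psi`` is the logistic function, ``phi_k`` are the signed
features, ``e`` is zero-mean Gaussian decision noise and ``lapse`` is
the probability of an attention lapse resolved by a fair guess.

Cohorts default to the study's group sizes (33 / 19 / 40 observers in
the low / medium / high disruption conditions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .feature_models import exact_feature_distribution
from .features import FEATURE_IDS, feature_matrix
from .generators import (
    DMS,
    RANDOM,
    GeneratorParams,
    Session,
    build_session,
    resolve_params,
)

#: Default observers per condition, echoing the study design.
DEFAULT_COHORT_SIZES = {"LD": 33, "MD": 19, "HD": 40}


@dataclass(frozen=True)
class ObserverSpec:
    """Generative description of one synthetic observer.

    ``betas`` are the weights on the four signed features (f1, -f2, f3,
    f4) in that order; a zero weight means the feature is ignored.
    """

    beta0: float
    betas: tuple[float, float, float, float]
    lapse: float = 0.0
    noise_sd: float = 0.0
    label: str | None = None

    def __post_init__(self) -> None:
        if len(self.betas) != len(FEATURE_IDS):
            raise ValueError(f"betas must have {len(FEATURE_IDS)} entries")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError(f"lapse must be in [0, 1], got {self.lapse}")
        if self.noise_sd < 0.0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


def pooled_feature_moments(
    feature_id: int, params: GeneratorParams
) -> tuple[float, float]:
    """Mean and SD of a signed feature under the 50/50 session mixture.

    Computed from the exact feature distributions under both generators.
    """
    dist = exact_feature_distribution(feature_id, params)
    p_mix = 0.5 * (dist.p_random + dist.p_dms)
    mean = float(np.sum(dist.support * p_mix))
    var = float(np.sum(dist.support**2 * p_mix) - mean**2)
    return mean, np.sqrt(var)


def single_feature_spec(
    feature_id: int,
    params: GeneratorParams,
    strength: float = 2.0,
    lapse: float = 0.02,
    noise_sd: float = 0.0,
    label: str | None = None,
) -> ObserverSpec:
    """An observer who consults exactly one feature.

    The slope is ``strength`` logits per pooled-SD of the feature and
    the intercept centres the rule at the pooled feature mean, so
    ``strength`` is a scale-free commitment level (2.0 = a committed but
    imperfect feature user; very large values approach a deterministic
    threshold rule on the feature).
    """
    if feature_id not in FEATURE_IDS:
        raise ValueError(f"unknown feature id {feature_id}; expected 1..4")
    mean, sd = pooled_feature_moments(feature_id, params)
    slope = strength / sd
    betas = [0.0] * len(FEATURE_IDS)
    betas[feature_id - 1] = slope
    return ObserverSpec(
        beta0=-slope * mean,
        betas=tuple(betas),
        lapse=lapse,
        noise_sd=noise_sd,
        label=label or f"F{feature_id}-only",
    )


def simulate_observer(
    spec: ObserverSpec, session: Session, rng: np.random.Generator
) -> pd.DataFrame:
    """One stochastic response per trial of a session.

    Returns a DataFrame with columns ``trial`` and ``response``
    ('RANDOM'/'DMS'), aligned with the session's trial order.
    """
    X = feature_matrix(session.sequences())
    eta = spec.beta0 + X.to_numpy(dtype=float) @ np.asarray(spec.betas, dtype=float)
    if spec.noise_sd > 0.0:
        eta = eta + spec.noise_sd * rng.standard_normal(eta.size)
    p_dms = spec.lapse / 2.0 + (1.0 - spec.lapse) * expit(eta)
    resp = np.where(rng.random(eta.size) < p_dms, DMS, RANDOM)
    return pd.DataFrame(
        {"trial": [t.index for t in session.trials], "response": resp}
    )


def simulate_cohort(
    specs,
    condition: str | None = None,
    *,
    params: GeneratorParams | None = None,
    n_trials: int = 100,
    seed: int = 0,
) -> list[tuple[Session, pd.DataFrame]]:
    """Fresh session plus responses for each observer in a cohort.

    Every observer gets a newly generated session (sequences drawn anew,
    as in the study) and an independent response stream, all derived
    deterministically from ``seed``.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("cohort needs at least one observer spec")
    p = resolve_params(condition, params)
    out = []
    for i, spec in enumerate(specs):
        # two deterministic substreams per observer: session and responses
        session = build_session(
            condition=condition if params is None else None,
            params=p,
            n_trials=n_trials,
            seed=int(np.random.SeedSequence([seed, i, 0]).generate_state(1)[0] % 2**31),
        )
        resp_rng = np.random.default_rng(np.random.SeedSequence([seed, i, 1]))
        out.append((session, simulate_observer(spec, session, resp_rng)))
    return out


def heterogeneous_cohort_specs(
    n_observers: int,
    params: GeneratorParams,
    rng: np.random.Generator,
    strength_range: tuple[float, float] = (0.3, 2.5),
    lapse_range: tuple[float, float] = (0.0, 0.15),
) -> list[ObserverSpec]:
    """A varied cohort for end-to-end exercises.

    Each observer draws a random commitment strength, splits it across a
    random non-empty subset of features (in pooled-SD units) and draws a
    lapse rate; this spans observers from near-guessers to committed
    multi-feature users.
    """
    if n_observers < 1:
        raise ValueError("n_observers must be >= 1")
    moments = {fid: pooled_feature_moments(fid, params) for fid in FEATURE_IDS}
    specs = []
    for i in range(n_observers):
        strength = rng.uniform(*strength_range)
        lapse = rng.uniform(*lapse_range)
        k = int(rng.integers(1, len(FEATURE_IDS) + 1))
        used = rng.choice(FEATURE_IDS, size=k, replace=False)
        weights = rng.dirichlet(np.ones(k)) * strength
        betas = [0.0] * len(FEATURE_IDS)
        beta0 = 0.0
        for fid, w in zip(used, weights):
            mean, sd = moments[int(fid)]
            betas[int(fid) - 1] = w / sd
            beta0 -= w / sd * mean
        specs.append(
            ObserverSpec(
                beta0=beta0,
                betas=tuple(betas),
                lapse=lapse,
                label=f"obs{i + 1:02d}",
            )
        )
    return specs
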