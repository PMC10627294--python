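"""Equal-variance Gaussian signal-detection metrics.

Sensitivity is ``d' = z(H) - z(F)`` and the criterion is
``c = -(z(H) + z(F)) / 2`` where ``H`` is the hit rate (DMS trials
answered DMS), ``F`` the false-alarm rate (random trials answered DMS)
and ``z`` the standard normal quantile.  Positive ``c`` is a
conservative bias toward answering "random".

Empirical rates of exactly 0 or 1 are corrected by the standard
``1/(2N)`` rule before the z-transform (0 -> 1/(2N), 1 -> 1 - 1/(2N),
with N the trial count in that margin); corrected estimates carry a
flag so downstream analyses can exclude them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from scipy.stats import norm


@dataclass(frozen=True)
class SDTEstimate:
    """Hit/false-alarm rates with derived sensitivity and criterion."""

    hit_rate: float
    fa_rate: float
    d_prime: float
    criterion_c: float
    n_signal: int | None = None
    n_noise: int | None = None
    corrected: bool = False


def sdt_from_rates(
    hit_rate: float,
    fa_rate: float,
    *,
    n_signal: int | None = None,
    n_noise: int | None = None,
    corrected: bool = False,
) -> SDTEstimate:
    """Build an estimate from (possibly exact) rates.

    Equal rates give d' = 0 by symmetry, covering the degenerate case
    where a classifier never (or always) responds DMS under both
    generators; the criterion is undefined (NaN) at boundary rates.
    """
    for name, r in (("hit_rate", hit_rate), ("fa_rate", fa_rate)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {r}")
    if hit_rate == fa_rate:
        d = 0.0
        c = -norm.ppf(hit_rate) if 0.0 < hit_rate < 1.0 else math.nan
    else:
        zh = norm.ppf(hit_rate)
        zf = norm.ppf(fa_rate)
        d = zh - zf
        c = -(zh + zf) / 2.0
    return SDTEstimate(
        hit_rate=float(hit_rate),
        fa_rate=float(fa_rate),
        d_prime=float(d),
        criterion_c=float(c),
        n_signal=n_signal,
        n_noise=n_noise,
        corrected=corrected,
    )


def sdt_from_counts(hits: int, misses: int, fas: int, crs: int) -> SDTEstimate:
    """Estimate d' and c from the four outcome counts of a session.

    ``hits``/``misses`` partition the signal (DMS) trials and
    ``fas``/``crs`` the noise (random) trials.  Extreme rates are
    corrected by the 1/(2N) rule and flagged.
    """
    counts = (hits, misses, fas, crs)
    if any(int(x) != x or x < 0 for x in counts):
        raise ValueError(f"outcome counts must be non-negative integers, got {counts}")
    n_signal = hits + misses
    n_noise = fas + crs
    if n_signal < 1 or n_noise < 1:
        raise ValueError("need at least one signal trial and one noise trial")
    hit_rate = hits / n_signal
    fa_rate = fas / n_noise
    corrected = False
    if hit_rate == 0.0 or hit_rate == 1.0:
        hit_rate = 1 / (2 * n_signal) if hit_rate == 0.0 else 1 - 1 / (2 * n_signal)
        corrected = True
    if fa_rate == 0.0 or fa_rate == 1.0:
        fa_rate = 1 / (2 * n_noise) if fa_rate == 0.0 else 1 - 1 / (2 * n_noise)
        corrected = True
    return sdt_from_rates(
        hit_rate, fa_rate, n_signal=n_signal, n_noise=n_noise, corrected=corrected
    )


def dprime_se(est: SDTEstimate) -> float:
    """Delta-method standard error of d' from binomial rate variability.

    Requires the estimate to carry trial counts and interior rates.
    """
    if est.n_signal is None or est.n_noise is None:
        raise ValueError("standard error needs trial counts (n_signal, n_noise)")
    h, f = est.hit_rate, est.fa_rate
    if not (0.0 < h < 1.0 and 0.0 < f < 1.0):
        raise ValueError("standard error needs interior rates")
    var_h = h * (1 - h) / est.n_signal / norm.pdf(norm.ppf(h)) ** 2
    var_f = f * (1 - f) / est.n_noise / norm.pdf(norm.ppf(f)) ** 2
    return math.sqrt(var_h + var_f)


@dataclass(frozen=True)
class EfficiencyRecord:
    """An observer's d' relative to the full Bayesian model's d'."""

    observer_dprime: float
    model_dprime: float
    efficiency: float


@lru_cache(maxsize=32)
def _full_model_dprime(p_r: float, p_d: float, n: int, threshold: float) -> float:
    from .generators import GeneratorParams
    from .ideal_observer import exact_performance

    return exact_performance(
        GeneratorParams(p_r=p_r, p_d=p_d, n=n), threshold=threshold
    ).d_prime


def efficiency(observer_dprime: float, params, threshold: float = 1.0) -> EfficiencyRecord:
    """Ratio of an observer's d' to the exact full-model d' at ``params``.

    The full-model d' comes from exact enumeration (cached per condition).
    Raises if the full model itself has non-positive d' (the ratio is
    then undefined, e.g. at p_d = 0.5).
    """
    model_d = _full_model_dprime(params.p_r, params.p_d, params.n, threshold)
    if model_d <= 0.0:
        raise ValueError(
            f"full-model d' is {model_d:.4g} at p_r={params.p_r}, p_d={params.p_d}; "
            "efficiency is undefined"
        )
    return EfficiencyRecord(
        observer_dprime=float(observer_dprime),
        model_dprime=float(model_d),
        efficiency=float(observer_dprime) / model_d,
    )
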