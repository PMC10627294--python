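"""The full Bayesian ideal observer for the random-vs-DMS task.

The observer computes the posterior odds that a sequence ``S`` came from
the DMS generator rather than the random generator,

    lambda = P[S | DMS] / P[S | RANDOM]

(prior odds are 1 by design), and responds DMS exactly when
``lambda > L`` with criterion ``L = 1`` for the accuracy-maximizing
rule.  Ties (``lambda == L``) resolve to RANDOM.

``P[S | RANDOM]`` is ``0.5**n``.  ``P[S | DMS]`` marginalizes over the
undisrupted Markov sequence: a two-state hidden Markov chain with a fair
initial state and stick probability ``p_r``, emitting the observed token
with probability ``1 - p_d`` (flipped otherwise).  The scalar routine
runs a forward recursion in log space; the batch routine runs a scaled
linear-space forward pass over whole sequence arrays, which makes exact
enumeration of all 2^20 length-20 sequences take seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import logsumexp

from .generators import GeneratorParams, as_sequence
from .sdt import SDTEstimate, sdt_from_counts, sdt_from_rates

LOG_HALF = math.log(0.5)

#: Largest n for which full 2^n enumeration is allowed.
ENUMERATION_CAP = 24


def likelihood_random(seq_or_n) -> float:
    """log P[S | RANDOM] = n * log(1/2); accepts a sequence or a length."""
    if isinstance(seq_or_n, (int, np.integer)):
        n = int(seq_or_n)
        if n < 1:
            raise ValueError(f"sequence length must be >= 1, got {n}")
    else:
        n = as_sequence(seq_or_n).size
    return n * LOG_HALF


def likelihood_dms(seq, params: GeneratorParams) -> float:
    """log P[S | DMS] by a two-state forward recursion in log space."""
    s = as_sequence(seq)
    with np.errstate(divide="ignore"):
        log_t = np.log(
            [[params.p_r, 1.0 - params.p_r], [1.0 - params.p_r, params.p_r]]
        )
        log_e = np.log([1.0 - params.p_d, params.p_d])  # [match, mismatch]
    # emission log-probs for hidden states (0, 1) given observed token
    def emit(tok: int) -> np.ndarray:
        return np.array([log_e[0], log_e[1]] if tok == 0 else [log_e[1], log_e[0]])

    alpha = LOG_HALF + emit(int(s[0]))
    for tok in s[1:]:
        alpha = logsumexp(alpha[:, None] + log_t, axis=0) + emit(int(tok))
    return float(logsumexp(alpha))


def likelihood_dms_batch(seqs, params: GeneratorParams) -> np.ndarray:
    """log P[S | DMS] for each row of an (N, n) sequence array.

    Scaled linear-space forward pass; numerically equivalent to the
    scalar log-space recursion (relative error at machine precision).
    """
    arr = np.asarray(seqs, dtype=np.uint8)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] != params.n:
        raise ValueError(
            f"sequence length {arr.shape[1]} does not match params.n={params.n}"
        )
    p_r, p_d = params.p_r, params.p_d
    e_match, e_mis = 1.0 - p_d, p_d
    obs0 = arr == 0
    a0 = 0.5 * np.where(obs0[:, 0], e_match, e_mis)
    a1 = 0.5 * np.where(obs0[:, 0], e_mis, e_match)
    logp = np.zeros(arr.shape[0])

    def rescale(a0, a1, logp):
        s = a0 + a1
        dead = s == 0.0  # impossible sequences (only at p_r or p_d in {0,1})
        s_safe = np.where(dead, 1.0, s)
        with np.errstate(divide="ignore"):
            logp = logp + np.where(dead, -np.inf, np.log(s_safe))
        return a0 / s_safe, a1 / s_safe, logp

    a0, a1, logp = rescale(a0, a1, logp)
    for t in range(1, arr.shape[1]):
        b0 = a0 * p_r + a1 * (1.0 - p_r)
        b1 = a0 * (1.0 - p_r) + a1 * p_r
        a0 = b0 * np.where(obs0[:, t], e_match, e_mis)
        a1 = b1 * np.where(obs0[:, t], e_mis, e_match)
        a0, a1, logp = rescale(a0, a1, logp)
    return logp


@dataclass(frozen=True)
class OddsResult:
    """Posterior odds and the induced classification of one sequence."""

    log_p_dms: float
    log_p_random: float
    lam: float
    decision: str


def posterior_odds(
    seq, params: GeneratorParams, threshold: float = 1.0
) -> OddsResult:
    """Compute lambda = P[S|DMS] / P[S|RANDOM] and classify the sequence.

    Prior odds are 1 (equiprobable generators), so lambda equals the
    likelihood ratio exactly.  Decision is DMS iff ``lambda > threshold``;
    a tie resolves to RANDOM.
    """
    if threshold <= 0.0:
        raise ValueError(f"threshold L must be positive, got {threshold}")
    log_dms = likelihood_dms(seq, params)
    log_rand = likelihood_random(seq)
    lam = math.exp(log_dms - log_rand)
    decision = "DMS" if lam > threshold else "RANDOM"
    return OddsResult(
        log_p_dms=log_dms, log_p_random=log_rand, lam=lam, decision=decision
    )


@dataclass(frozen=True)
class FullBayesClassifier:
    """The full-model decision rule: respond DMS iff lambda > threshold."""

    params: GeneratorParams
    threshold: float = 1.0

    def decide_batch(self, seqs) -> np.ndarray:
        """Boolean array: True where the decision is DMS."""
        log_dms = likelihood_dms_batch(seqs, self.params)
        llr = log_dms - self.params.n * LOG_HALF
        return llr > math.log(self.threshold)

    def decide(self, seq) -> str:
        return "DMS" if self.decide_batch(as_sequence(seq)[None, :])[0] else "RANDOM"


def enumerate_sequences(n: int) -> np.ndarray:
    """All 2^n binary sequences as a (2^n, n) uint8 array (read-only use)."""
    if n < 1:
        raise ValueError(f"sequence length must be >= 1, got {n}")
    if n > ENUMERATION_CAP:
        raise ValueError(
            f"enumeration of 2^{n} sequences exceeds the cap n <= {ENUMERATION_CAP}"
        )
    codes = np.arange(2**n, dtype=np.uint32)
    return ((codes[:, None] >> np.arange(n, dtype=np.uint32)) & 1).astype(np.uint8)


@lru_cache(maxsize=8)
def _exact_grid(params: GeneratorParams) -> tuple[np.ndarray, np.ndarray]:
    """Cached (sequences, log P[S|DMS]) over all 2^n sequences."""
    seqs = enumerate_sequences(params.n)
    return seqs, likelihood_dms_batch(seqs, params)


def exact_performance(
    params: GeneratorParams, threshold: float = 1.0
) -> SDTEstimate:
    """Exact hit/false-alarm rates and d' of the full model by enumeration.

    Sums the generator probabilities of every sequence the rule calls
    DMS: hit rate = sum P[S|DMS], false-alarm rate = sum P[S|RANDOM].
    Requires ``params.n`` at or below the enumeration cap.
    """
    if threshold <= 0.0:
        raise ValueError(f"threshold L must be positive, got {threshold}")
    seqs, log_dms = _exact_grid(params)
    llr = log_dms - params.n * LOG_HALF
    dms_region = llr > math.log(threshold)
    hit = float(np.exp(log_dms[dms_region]).sum())
    fa = float(dms_region.mean())
    return sdt_from_rates(hit, fa)


def mc_performance(
    classifier,
    params: GeneratorParams,
    n_reps: int = 5000,
    rng: np.random.Generator | None = None,
) -> SDTEstimate:
    """Monte-Carlo hit/false-alarm rates and d' of any classifier.

    Simulates ``n_reps`` fresh sequences per generator, applies the
    classifier's ``decide_batch`` and estimates rates empirically (with
    the 1/(2N) boundary correction of :func:`patdet.sdt.sdt_from_counts`).
    """
    from .generators import generate_dms_batch, generate_random_batch

    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    if rng is None:
        rng = np.random.default_rng()
    dms_seqs = generate_dms_batch(params, n_reps, rng)
    rand_seqs = generate_random_batch(n_reps, params.n, rng)
    hits = int(classifier.decide_batch(dms_seqs).sum())
    fas = int(classifier.decide_batch(rand_seqs).sum())
    return sdt_from_counts(hits, n_reps - hits, fas, n_reps - fas)
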