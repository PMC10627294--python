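"""Stimulus generators for the binary-texture signal-detection task.

Stimuli are sequences of ``n`` binary tokens (1 = blue, 0 = yellow) read
left to right.  Two stochastic generators define the task:

* the **random** generator draws each token as an independent fair
  Bernoulli variable;
* the **DMS** (disrupted Markov sequence) generator first draws a Markov
  chain whose first token is fair and whose every later token repeats its
  left neighbour with probability ``p_r``, then independently flips each
  token with the disruption probability ``p_d``.

A session interleaves equal numbers of trials from both generators in a
random order; the observer's task is to identify, per trial, which
generator produced the sequence.

Sequences are stored as 1-D ``numpy`` ``uint8`` arrays and serialized as
``'0'``/``'1'`` character strings.  Positions are described 1-based
(leftmost token = position 1) in documentation and error messages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RANDOM = "RANDOM"
DMS = "DMS"

#: Named study conditions: low/medium/high disruption, all at p_r = 0.9.
CONDITIONS: dict[str, "GeneratorParams"]


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the DMS generator.

    Parameters
    ----------
    p_r : float
        Repetition probability of the underlying Markov chain, in [0, 1].
    p_d : float
        Disruption (per-token flip) probability, in [0, 1].
    n : int
        Sequence length in tokens (20 in the study conditions).
    """

    p_r: float
    p_d: float
    n: int = 20

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_r <= 1.0:
            raise ValueError(f"p_r must be in [0, 1], got {self.p_r}")
        if not 0.0 <= self.p_d <= 1.0:
            raise ValueError(f"p_d must be in [0, 1], got {self.p_d}")
        if self.n < 1:
            raise ValueError(f"sequence length n must be >= 1, got {self.n}")


CONDITIONS = {
    "LD": GeneratorParams(p_r=0.9, p_d=0.1, n=20),
    "MD": GeneratorParams(p_r=0.9, p_d=0.2, n=20),
    "HD": GeneratorParams(p_r=0.9, p_d=0.3, n=20),
}


def resolve_params(
    condition: str | None = None, params: GeneratorParams | None = None
) -> GeneratorParams:
    """Resolve a condition name (LD/MD/HD) or explicit params to params.

    Explicit ``params`` take precedence over the named condition.
    """
    if params is not None:
        return params
    if condition is None:
        raise ValueError("either a condition name or explicit params is required")
    try:
        return CONDITIONS[condition]
    except KeyError:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {sorted(CONDITIONS)}"
        ) from None


def as_sequence(tokens) -> np.ndarray:
    """Coerce a token container ('0101...' string, list, array) to uint8.

    Raises ``ValueError`` for empty input or tokens outside {0, 1}.
    """
    if isinstance(tokens, str):
        if not tokens:
            raise ValueError("empty token string")
        if set(tokens) - {"0", "1"}:
            raise ValueError(f"token string must contain only '0'/'1': {tokens!r}")
        return np.frombuffer(tokens.encode("ascii"), dtype=np.uint8) - ord("0")
    arr = np.asarray(tokens)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("a token sequence must be a non-empty 1-D vector")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("every token must be 0 or 1")
    return arr.astype(np.uint8)


def seq_to_str(seq) -> str:
    """Render a token sequence as a left-to-right '0'/'1' string."""
    return "".join("1" if t else "0" for t in as_sequence(seq))


def complement(seq) -> np.ndarray:
    """Flip every token (blue <-> yellow)."""
    return (1 - as_sequence(seq)).astype(np.uint8)


def generate_random(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw a length-``n`` sequence of independent fair tokens."""
    if n < 1:
        raise ValueError(f"sequence length n must be >= 1, got {n}")
    return rng.integers(0, 2, size=n, dtype=np.uint8)


def generate_markov(params: GeneratorParams, rng: np.random.Generator) -> np.ndarray:
    """Draw a Markov sequence: fair first token, repeat-left with prob p_r."""
    return generate_markov_batch(params, 1, rng)[0]


def disrupt(seq, p_d: float, rng: np.random.Generator) -> np.ndarray:
    """Independently flip each token with probability ``p_d``."""
    if not 0.0 <= p_d <= 1.0:
        raise ValueError(f"p_d must be in [0, 1], got {p_d}")
    s = as_sequence(seq)
    flips = (rng.random(s.size) < p_d).astype(np.uint8)
    return s ^ flips


def generate_dms(params: GeneratorParams, rng: np.random.Generator) -> np.ndarray:
    """Draw a disrupted Markov sequence: Markov draw, then disruption."""
    return disrupt(generate_markov(params, rng), params.p_d, rng)


def generate_random_batch(
    n_reps: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n_reps`` random sequences as an (n_reps, n) uint8 array."""
    if n < 1:
        raise ValueError(f"sequence length n must be >= 1, got {n}")
    return rng.integers(0, 2, size=(n_reps, n), dtype=np.uint8)


def generate_markov_batch(
    params: GeneratorParams, n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n_reps`` Markov sequences as an (n_reps, n) uint8 array."""
    n = params.n
    first = rng.integers(0, 2, size=(n_reps, 1), dtype=np.uint8)
    if n == 1:
        return first
    # token_t = token_1 XOR (number of colour switches up to t, mod 2)
    switches = (rng.random((n_reps, n - 1)) >= params.p_r).astype(np.uint8)
    parity = np.cumsum(switches, axis=1, dtype=np.int64) % 2
    return np.concatenate([first, first ^ parity.astype(np.uint8)], axis=1)


def generate_dms_batch(
    params: GeneratorParams, n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n_reps`` DMS sequences as an (n_reps, n) uint8 array."""
    markov = generate_markov_batch(params, n_reps, rng)
    flips = (rng.random(markov.shape) < params.p_d).astype(np.uint8)
    return markov ^ flips


@dataclass
class TrialRecord:
    """One trial: 1-based index, stimulus sequence, generating label."""

    index: int
    sequence: np.ndarray
    true_label: str

    def __post_init__(self) -> None:
        if self.true_label not in (RANDOM, DMS):
            raise ValueError(f"true_label must be RANDOM or DMS, got {self.true_label!r}")


@dataclass
class Session:
    """An ordered list of trials drawn under one condition.

    ``seed`` is the master seed; each trial's sequence is drawn from a
    deterministic per-trial substream so single trials are reproducible
    in isolation.
    """

    params: GeneratorParams
    seed: int
    trials: list[TrialRecord] = field(default_factory=list)
    condition: str | None = None

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def sequences(self) -> np.ndarray:
        """Stack the trial sequences into an (n_trials, n) uint8 array."""
        return np.stack([t.sequence for t in self.trials])

    def labels(self) -> np.ndarray:
        """Return the true labels as an array of 'RANDOM'/'DMS' strings."""
        return np.array([t.true_label for t in self.trials])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": [t.index for t in self.trials],
                "sequence": [seq_to_str(t.sequence) for t in self.trials],
                "true_label": [t.true_label for t in self.trials],
            }
        )


def build_session(
    condition: str | None = None,
    *,
    params: GeneratorParams | None = None,
    n_trials: int = 100,
    seed: int = 0,
    exact_balance: bool = True,
) -> Session:
    """Build one experimental session.

    With ``exact_balance`` (the study design) exactly half the trials are
    DMS and half random, presented in a uniformly random order.  With
    ``exact_balance=False`` each trial's generator is an independent fair
    coin flip instead (the alternative reading of "chosen at random").

    Parameters
    ----------
    condition : str, optional
        One of 'LD', 'MD', 'HD'; or pass explicit ``params``.
    n_trials : int
        Number of trials; must be even when ``exact_balance`` is set.
    seed : int
        Master seed; all randomness in the session derives from it.
    """
    p = resolve_params(condition, params)
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    if exact_balance and n_trials % 2:
        raise ValueError(
            f"a balanced session needs an even trial count, got {n_trials}"
        )
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_trials + 1)
    design_rng = np.random.default_rng(children[0])
    if exact_balance:
        labels = np.array([DMS] * (n_trials // 2) + [RANDOM] * (n_trials - n_trials // 2))
        design_rng.shuffle(labels)
    else:
        labels = np.where(design_rng.random(n_trials) < 0.5, DMS, RANDOM)
    trials = []
    for i, label in enumerate(labels):
        trial_rng = np.random.default_rng(children[i + 1])
        if label == DMS:
            seq = generate_dms(p, trial_rng)
        else:
            seq = generate_random(p.n, trial_rng)
        trials.append(TrialRecord(index=i + 1, sequence=seq, true_label=str(label)))
    return Session(params=p, seed=seed, trials=trials, condition=condition)
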