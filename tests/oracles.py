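"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's likelihood/feature code paths:
the DMS likelihood is an explicit sum over every hidden Markov sequence,
and the feature oracles are exhaustive scans over contiguous blocks.
"""

import numpy as np


def enumerate_bits(n: int) -> np.ndarray:
    codes = np.arange(2**n, dtype=np.uint32)
    return ((codes[:, None] >> np.arange(n, dtype=np.uint32)) & 1).astype(np.uint8)


def brute_force_dms_probability(seqs: np.ndarray, p_r: float, p_d: float) -> np.ndarray:
    """P[S | DMS] as an explicit sum over all 2^n hidden Markov sequences.

    P[S|DMS] = sum_h 0.5 * p_r^{reps(h)} * (1-p_r)^{n-1-reps(h)}
                     * p_d^{hamming(S,h)} * (1-p_d)^{n-hamming(S,h)}
    """
    seqs = np.atleast_2d(np.asarray(seqs, dtype=np.uint8))
    n = seqs.shape[1]
    hidden_codes = np.arange(2**n, dtype=np.uint64)
    hidden = ((hidden_codes[:, None] >> np.arange(n, dtype=np.uint64)) & 1).astype(
        np.uint8
    )
    if n > 1:
        reps = (hidden[:, 1:] == hidden[:, :-1]).sum(axis=1)
    else:
        reps = np.zeros(hidden.shape[0], dtype=np.int64)
    p_hidden = 0.5 * p_r**reps * (1.0 - p_r) ** (n - 1 - reps)
    seq_codes = seqs.astype(np.uint64) @ (np.uint64(1) << np.arange(n, dtype=np.uint64))
    out = np.empty(seqs.shape[0])
    for i, code in enumerate(seq_codes):
        dist = np.bitwise_count(code ^ hidden_codes)
        out[i] = (p_d**dist * (1.0 - p_d) ** (n - dist)) @ p_hidden
    return out


def longest_monochromatic_block(seq) -> int:
    """Max length over all contiguous blocks of a single token value."""
    s = list(seq)
    best = 0
    for i in range(len(s)):
        for j in range(i, len(s)):
            block = s[i : j + 1]
            if len(set(block)) == 1:
                best = max(best, len(block))
    return best


def longest_alternating_block(seq) -> int:
    """Max length over all contiguous strictly alternating blocks."""
    s = list(seq)
    best = 0
    for i in range(len(s)):
        for j in range(i, len(s)):
            block = s[i : j + 1]
            if all(block[t] != block[t - 1] for t in range(1, len(block))):
                best = max(best, len(block))
    return best
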