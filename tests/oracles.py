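"""Independent oracles used by the test suite.

The numeric oracles (series matrix exponential, quadrature gamma rates,
closed-form JC quantities, exhaustive-enumeration site likelihoods) live
in :mod:`plastosig.validation` and are re-exported here; the inverted-
repeat brute force below is test-only.
"""

from __future__ import annotations

import numpy as np

from plastosig.validation import (enumeration_site_loglik,  # noqa: F401
                                  gamma_rates_by_quadrature, jc_distance,
                                  jc_site_loglik,
                                  series_matrix_exponential)


def longest_inverted_repeat_bruteforce(seq: str):
    """Longest pair of reverse-complement substrings by anti-diagonal scan.

    O(n^2) over all anti-diagonals of the seq-vs-revcomp(seq) match
    matrix; returns ``(length, start_a, start_b)`` with start_a < start_b
    (0 if nothing found).  Linear (non-wrapping) semantics.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    b = np.frombuffer("".join(comp[c] for c in seq).encode(), dtype=np.uint8)
    n = len(seq)
    best = (0, 0, 0)
    # match matrix M[i, j] = (seq[i] == comp(seq[j])); an inverted repeat
    # of length L shows up as a run of L ones along an anti-diagonal
    for d in range(2 * n - 1):
        i0 = max(0, d - n + 1)
        j = d - np.arange(i0, min(d + 1, n))
        i = np.arange(i0, min(d + 1, n))
        eq = a[i] == b[j]
        if not eq.any():
            continue
        padded = np.concatenate([[0], eq.view(np.int8), [0]])
        diff = np.diff(padded)
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        for s, e in zip(starts, ends):
            run = e - s
            ia = i0 + s
            ja = d - (i0 + e - 1)  # left end of the partner interval
            if ja <= ia:
                continue  # same copy or overlapping; count each pair once
            if ja < ia + run:
                continue  # arms overlap
            if run > best[0]:
                best = (int(run), int(ia), int(ja))
    return best
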