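"""Global (Needleman-Wunsch) alignment identity.

Used to report percent identity of duplicated gene pairs at the protein and
nucleotide level. Scoring is the classic unit scheme: match = 1, mismatch =
0, and a linear per-gap-symbol penalty (default 1). Identity is the fraction
of identical columns over all alignment columns; gap columns count toward
the denominator by default (configurable).

Traceback ties are resolved deterministically: diagonal is preferred over a
gap in the second sequence, which is preferred over a gap in the first.
"""

from __future__ import annotations

import numpy as np

from .errors import SequenceError


def nw_align(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap: float = 1.0,
) -> tuple[str, str, float]:
    """Optimal global alignment; returns (aligned_a, aligned_b, score).

    ``gap`` is the penalty subtracted per gap symbol (linear gap cost).
    """
    if not seq_a or not seq_b:
        raise SequenceError("cannot align an empty sequence")
    a, b = seq_a.upper(), seq_b.upper()
    n, m = len(a), len(b)
    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    score = np.empty((n + 1, m + 1))
    score[0, :] = -gap * np.arange(m + 1)
    score[:, 0] = -gap * np.arange(n + 1)
    sub = np.where(arr_a[:, None] == arr_b[None, :], match, mismatch)
    for i in range(1, n + 1):
        diag = score[i - 1, :-1] + sub[i - 1]
        up = score[i - 1, 1:] - gap
        row = score[i]
        prev = row[0]
        best = np.maximum(diag, up)
        for j in range(1, m + 1):
            prev = max(best[j - 1], prev - gap)
            row[j] = prev
    # traceback (diag > up > left on ties)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        here = score[i, j]
        if i > 0 and j > 0 and np.isclose(here, score[i - 1, j - 1] + sub[i - 1, j - 1]):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and np.isclose(here, score[i - 1, j] - gap):
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(score[n, m])


def global_identity(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap: float = 1.0,
    count_gap_columns: bool = True,
) -> tuple[float, int]:
    """Percent identity over an optimal global alignment.

    Returns ``(identity_pct, alignment_columns)``. With
    ``count_gap_columns=False`` the denominator excludes gap columns.
    Symmetric in its arguments: the pair is put in canonical order before
    aligning, so tie-broken optimal alignments cannot depend on argument
    order.
    """
    if (len(seq_b), seq_b.upper()) < (len(seq_a), seq_a.upper()):
        seq_a, seq_b = seq_b, seq_a
    ali_a, ali_b, _ = nw_align(seq_a, seq_b, match, mismatch, gap)
    cols = len(ali_a)
    ident = sum(x == y for x, y in zip(ali_a, ali_b))
    if count_gap_columns:
        denom = cols
    else:
        denom = sum(x != "-" and y != "-" for x, y in zip(ali_a, ali_b))
    if denom == 0:
        return 0.0, cols
    return 100.0 * ident / denom, cols
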