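"""Global pairwise alignment with linear gap costs.

A small Needleman-Wunsch implementation with a fixed, documented tie-break
(diagonal on a match, then up, then diagonal on a mismatch, then left) so that
alignments — and everything built on them, IMGT number transfer in
particular — are deterministic. The matrix fill
is vectorized over anti-diagonals, which keeps alignment of ~130-residue
variable domains in the low milliseconds.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import AA_SET

DEFAULT_MATCH = 2.0
DEFAULT_MISMATCH = -1.0
DEFAULT_GAP = -2.0


@dataclasses.dataclass
class Alignment:
    """A global alignment: gapped strings of equal length plus the score."""

    aligned_a: str
    aligned_b: str
    score: float

    def columns(self) -> list[tuple[str, str]]:
        return list(zip(self.aligned_a, self.aligned_b))

    @property
    def n_matches(self) -> int:
        return sum(x == y and x != "-" for x, y in zip(self.aligned_a, self.aligned_b))

    @property
    def length(self) -> int:
        return len(self.aligned_a)

    def identity(self) -> float:
        """Matched columns divided by alignment length."""
        return self.n_matches / self.length


def _check(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name} sequence is empty")
    bad = sorted(set(seq) - AA_SET)
    if bad:
        raise ValueError(f"non-canonical residues {bad} in {name} sequence")


def global_align(a: str, b: str, match: float = DEFAULT_MATCH,
                 mismatch: float = DEFAULT_MISMATCH,
                 gap: float = DEFAULT_GAP) -> Alignment:
    """Optimal global alignment of ``a`` against ``b`` under linear gap costs.

    Ties during traceback are broken diagonal-on-match > up (gap in ``b``) >
    diagonal-on-mismatch > left (gap in ``a``), making the returned alignment
    deterministic and keeping substituted residues paired adjacent to their
    match runs.
    """
    _check(a, "query")
    _check(b, "reference")
    n, m = len(a), len(b)
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    S = np.where(av[:, None] == bv[None, :], match, mismatch)

    H = np.empty((n + 1, m + 1), dtype=np.float64)
    H[0, :] = gap * np.arange(m + 1)
    H[:, 0] = gap * np.arange(n + 1)
    for d in range(2, n + m + 1):
        lo = max(1, d - m)
        hi = min(n, d - 1)
        if lo > hi:
            continue
        ii = np.arange(lo, hi + 1)
        jj = d - ii
        diag = H[ii - 1, jj - 1] + S[ii - 1, jj - 1]
        up = H[ii - 1, jj] + gap
        left = H[ii, jj - 1] + gap
        H[ii, jj] = np.maximum(diag, np.maximum(up, left))

    # traceback with fixed preference order: diagonal on a match, then gap in
    # the reference (up), then diagonal on a mismatch, then gap in the query.
    # Preferring insertions over mismatch columns keeps a substituted residue
    # paired with the column adjacent to its match run rather than a distant
    # tied column, which matters when numbering is transferred through columns.
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        h = H[i, j]
        diag_ok = i > 0 and j > 0 and h == H[i - 1, j - 1] + S[i - 1, j - 1]
        if diag_ok and a[i - 1] == b[j - 1]:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and h == H[i - 1, j] + gap:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        elif diag_ok:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return Alignment("".join(reversed(out_a)), "".join(reversed(out_b)),
                     float(H[n, m]))


def pairwise_identity(a: str, b: str, match: float = DEFAULT_MATCH,
                      mismatch: float = DEFAULT_MISMATCH,
                      gap: float = DEFAULT_GAP) -> float:
    """Sequence identity = matched columns / global-alignment length."""
    return global_align(a, b, match, mismatch, gap).identity()
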