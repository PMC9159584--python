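"""Kozak similarity scoring of flanked codons.

The Kozak similarity score (KSS) of a codon is the sum of the logo
heights of the ten bases on each side of it, divided by the maximum
attainable height sum.  Bases that fall outside the sequence (missing,
marked ``-``) contribute zero, so scores always lie in [0, 1].  The
codon's own three bases do not enter the score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .logo import LETTERS, LogoMatrix
from .sequence import MISSING, clean_sequence

FLANK_LEN = 10

_LETTER_INDEX = {letter: i for i, letter in enumerate(LETTERS)}


class ContextError(ValueError):
    pass


@dataclass(frozen=True)
class FlankedCodon:
    """A 3-base codon with its 10-base left and right flanks.

    Flanks are stored left-to-right; slots beyond the ends of the source
    sequence hold the missing marker ``-``.  The left flank is padded on
    its left, the right flank on its right, so base adjacency to the
    codon is preserved.
    """

    codon: str
    left: str
    right: str

    def __post_init__(self) -> None:
        codon = clean_sequence(self.codon, allow_missing=False)
        if len(codon) != 3:
            raise ContextError(f"codon must have 3 bases, got {self.codon!r}")
        left = clean_sequence(self.left)
        right = clean_sequence(self.right)
        if len(left) != FLANK_LEN or len(right) != FLANK_LEN:
            raise ContextError("flanks must each have exactly 10 slots")
        object.__setattr__(self, "codon", codon)
        object.__setattr__(self, "left", left)
        object.__setattr__(self, "right", right)

    @property
    def flanks(self) -> str:
        """The 20 scored slots, left flank then right flank."""
        return self.left + self.right

    @property
    def is_complete(self) -> bool:
        return MISSING not in self.flanks


def extract_context(seq: str, codon_start: int) -> FlankedCodon:
    """Extract the flanked codon at ``codon_start`` (0-based) from ``seq``.

    Slots that would fall before the start or past the end of the
    sequence are marked missing.
    """
    s = clean_sequence(seq)
    if not 0 <= codon_start <= len(s) - 3:
        raise IndexError(
            f"codon_start {codon_start} out of range for sequence of length {len(s)}"
        )
    left_lo = max(codon_start - FLANK_LEN, 0)
    left = s[left_lo:codon_start].rjust(FLANK_LEN, MISSING)
    right = s[codon_start + 3 : codon_start + 3 + FLANK_LEN].ljust(FLANK_LEN, MISSING)
    return FlankedCodon(codon=s[codon_start : codon_start + 3], left=left, right=right)


def kss(fc: FlankedCodon, logo: LogoMatrix) -> float:
    """Kozak similarity score of a flanked codon under a logo.

    Sums the height of the observed letter at each of the 20 flank
    positions (zero for missing slots) and divides by the logo's maximum
    attainable sum.  The codon identity itself is ignored.
    """
    norm = logo.max_total_bits
    if norm <= 0:
        raise ValueError("logo normaliser must be positive")
    total = 0.0
    for p, base in enumerate(fc.flanks):
        if base != MISSING:
            total += logo.heights[p, _LETTER_INDEX[base]]
    return total / norm


def kss_many(contexts: np.ndarray, logo: LogoMatrix) -> np.ndarray:
    """Vectorised scoring of encoded contexts.

    ``contexts`` is an integer array of shape (n, 20) with values 0..3
    indexing A, C, G, T and 4 marking a missing slot.
    """
    ctx = np.asarray(contexts)
    if ctx.ndim != 2 or ctx.shape[1] != 2 * FLANK_LEN:
        raise ValueError("contexts must have shape (n, 20)")
    # pad a zero-height 'missing' column onto each position's heights
    padded = np.concatenate([logo.heights, np.zeros((2 * FLANK_LEN, 1))], axis=1)
    totals = padded[np.arange(2 * FLANK_LEN)[None, :], ctx].sum(axis=1)
    return totals / logo.max_total_bits


def encode_flanks(fc: FlankedCodon) -> np.ndarray:
    """Integer-encode the 20 flank slots (A,C,G,T -> 0..3, missing -> 4)."""
    return np.array(
        [_LETTER_INDEX.get(b, 4) for b in fc.flanks], dtype=np.int64
    )


def sample_random_scores(
    logo: LogoMatrix, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Scores of ``n`` complete contexts with uniformly random flank bases.

    This is the dummy-codon baseline: every one of the 20 flank slots is
    drawn independently and uniformly from {A, C, G, T}.
    """
    ctx = rng.integers(0, 4, size=(n, 2 * FLANK_LEN))
    return kss_many(ctx, logo)


def score_table(table: pd.DataFrame, logo: LogoMatrix) -> pd.DataFrame:
    """Append a ``kss`` column to a training-style table.

    Expects columns ``codon``, ``left_flank`` and ``right_flank`` (10
    characters each, ``-`` padded).
    """
    scores = [
        kss(FlankedCodon(row.codon, row.left_flank, row.right_flank), logo)
        for row in table.itertuples(index=False)
    ]
    out = table.copy()
    out["kss"] = scores
    return out
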