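"""Kozak-consensus sequence logo built by the Shannon method.

The logo assigns every nucleotide at every flank position a height in
bits.  For a position with letter frequencies ``f(p, l)`` the information
content is ``R(p) = 2 - H(p)`` with ``H`` the Shannon entropy in bits, and
the height of letter ``l`` is ``f(p, l) * R(p)``.  The sum over positions
of the tallest letter's height is the normaliser that maps raw context
scores onto [0, 1].

Twenty flank positions are modelled: the ten bases preceding a codon
(labelled -10..-1) and the ten following it (+4..+13, numbered as if the
codon occupied +1..+3).  The codon's own bases carry no height.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

LETTERS = ("A", "C", "G", "T")
N_POSITIONS = 20
POSITION_LABELS = tuple(f"-{i}" for i in range(10, 0, -1)) + tuple(
    f"+{i}" for i in range(4, 14)
)

_DEFAULT_MATRIX_RESOURCE = "kozak_context_synthetic.csv"

_ROW_TOL = 1e-9


class MatrixValidationError(ValueError):
    """Raised when a frequency matrix violates its invariants."""


@dataclass(frozen=True)
class FrequencyMatrix:
    """Per-position nucleotide frequencies over the 20 flank slots.

    ``freqs`` is a (20, 4) array in position-major order (p = 1..20,
    i.e. -10..-1 then +4..+13) with columns A, C, G, T.  Every row must
    be a probability vector.
    """

    freqs: np.ndarray
    labels: tuple[str, ...] = POSITION_LABELS

    def __post_init__(self) -> None:
        arr = np.asarray(self.freqs, dtype=float)
        if arr.shape != (N_POSITIONS, 4):
            raise MatrixValidationError(
                f"frequency matrix must be {N_POSITIONS}x4, got {arr.shape}"
            )
        if (arr < 0).any():
            raise MatrixValidationError("frequencies must be non-negative")
        rowsums = arr.sum(axis=1)
        if np.abs(rowsums - 1.0).max() > _ROW_TOL:
            worst = int(np.abs(rowsums - 1.0).argmax())
            raise MatrixValidationError(
                f"row {self.labels[worst]} sums to {rowsums[worst]:.12f}, not 1"
            )
        object.__setattr__(self, "freqs", arr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.freqs, index=list(self.labels), columns=LETTERS)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FrequencyMatrix":
        missing = [c for c in LETTERS if c not in df.columns]
        if missing:
            raise MatrixValidationError(f"missing letter columns: {missing}")
        return cls(df[list(LETTERS)].to_numpy(dtype=float), tuple(map(str, df.index)))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FrequencyMatrix":
        # keep position labels like "+4" as text
        df = pd.read_csv(path, converters={"position": str})
        if "position" in df.columns:
            df = df.set_index("position")
        return cls.from_frame(df)

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "position"
        df.to_csv(path)


@dataclass(frozen=True)
class LogoMatrix:
    """Per-position per-letter heights in bits, plus the score normaliser."""

    heights: np.ndarray  # (20, 4) bits
    information: np.ndarray = field(repr=False, default=None)  # R(p), bits
    labels: tuple[str, ...] = POSITION_LABELS

    def __post_init__(self) -> None:
        h = np.asarray(self.heights, dtype=float)
        if h.shape != (N_POSITIONS, 4):
            raise MatrixValidationError(f"logo must be {N_POSITIONS}x4, got {h.shape}")
        if (h < -1e-12).any() or (h > 2 + 1e-12).any():
            raise MatrixValidationError("heights must lie in [0, 2] bits")
        info = self.information
        if info is None:
            info = h.sum(axis=1)
        object.__setattr__(self, "heights", h)
        object.__setattr__(self, "information", np.asarray(info, dtype=float))

    @property
    def max_total_bits(self) -> float:
        """Sum over positions of the tallest letter's height (the KSS normaliser)."""
        return float(self.heights.max(axis=1).sum())

    def argmax_letters(self) -> str:
        """The consensus string: the tallest letter at each of the 20 positions."""
        return "".join(LETTERS[i] for i in self.heights.argmax(axis=1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.heights, index=list(self.labels), columns=LETTERS)


def build_logo(freq: FrequencyMatrix) -> LogoMatrix:
    """Build the Shannon-method logo from a frequency matrix.

    ``R(p) = 2 - H(p)``; zero frequencies contribute zero entropy terms.
    """
    f = freq.freqs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log2(np.where(f > 0, f, 1.0)), 0.0)
    entropy = -terms.sum(axis=1)
    information = 2.0 - entropy
    heights = f * information[:, None]
    return LogoMatrix(heights=heights, information=information, labels=freq.labels)


def max_bits(logo: LogoMatrix) -> float:
    """The maximum attainable bit sum over a complete 20-base context."""
    return logo.max_total_bits


def expected_random_kss(logo: LogoMatrix) -> float:
    """Closed-form mean score of a uniformly random complete context.

    Each position contributes a mean height of ``R(p) / 4`` (the four
    letters are equally likely and their heights sum to ``R(p)``), so the
    expectation is ``(sum_p R(p) / 4) / max_total_bits``.
    """
    return float(logo.information.sum() / 4.0 / logo.max_total_bits)


def shrink_toward_uniform(freq: FrequencyMatrix, weight: float) -> FrequencyMatrix:
    """Linearly mix a matrix with the uniform matrix.

    ``weight = 1`` returns the matrix unchanged; ``weight = 0`` is fully
    uniform.  Weights slightly above 1 sharpen, subject to positivity.
    """
    mixed = weight * freq.freqs + (1.0 - weight) * 0.25
    return FrequencyMatrix(mixed, freq.labels)


def calibrate_matrix(raw: FrequencyMatrix, target_max_bits: float) -> FrequencyMatrix:
    """Rescale a matrix toward/away from uniform to hit a target normaliser.

    Solves for the mixing weight such that the Shannon logo built from the
    rescaled matrix has ``max_total_bits == target_max_bits``.
    """

    def gap(weight: float) -> float:
        return build_logo(shrink_toward_uniform(raw, weight)).max_total_bits - target_max_bits

    hi = 1.0
    while gap(hi) < 0 and hi < 8.0:
        hi *= 1.25
    weight = brentq(gap, 1e-6, hi)
    return shrink_toward_uniform(raw, weight)


def default_frequency_matrix() -> FrequencyMatrix:
    """The shipped Kozak flanking-context matrix.

    A synthetic reconstruction: vertebrate Kozak-style context frequencies
    (C-rich upstream, A favoured at -3, G at +4) uniformly rescaled so the
    logo normaliser matches the published pre-normalisation maximum of
    ~0.5990 bits.  Users may substitute their own matrix file.
    """
    ref = resources.files("tisscan.data").joinpath(_DEFAULT_MATRIX_RESOURCE)
    with resources.as_file(ref) as path:
        return FrequencyMatrix.from_csv(path)


_default_logo_cache: LogoMatrix | None = None


def default_logo() -> LogoMatrix:
    """The logo built from the shipped default matrix (cached)."""
    global _default_logo_cache
    if _default_logo_cache is None:
        _default_logo_cache = build_logo(default_frequency_matrix())
    return _default_logo_cache
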