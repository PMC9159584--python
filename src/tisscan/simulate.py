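"""Synthetic labelled contexts and toy repeat loci.

The classifiers in this package assume positionally independent flank
composition: initiating codons sit in Kozak-enriched context, while
non-initiating codons sit in background context.  The generator draws
each of the 20 flank bases independently from a per-position
composition, which matches the scoring model's own independence
assumption exactly.

Default compositions are calibrated by exponential tilting of the
uniform background along the logo heights so that the expected KSS of
the positive class is 0.73 and of the negative class 0.52 — the centres
of the published score histograms for initiating and non-initiating ATG
contexts.  The positive tilt additionally exchanges the two tallest
letters at the three most informative positions (for instance the other
purine at -3): a reference logo compiled from one sequence collection
captures the context preferences of any particular dataset only
imperfectly, and this mismatch is what lets a trained classifier
outperform a fixed similarity score.  A configurable fraction of
examples has one flank truncated at a uniform depth, emulating codons
near transcript ends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .forest import (
    CANONICAL_CODON,
    LabeledExample,
    TRAINED_NEAR_COGNATE,
)
from .logo import FrequencyMatrix, LogoMatrix, default_logo
from .scan import RepeatLocus, has_upstream_stop
from .scoring import FLANK_LEN, FlankedCodon
from .sequence import MISSING, STOP_CODONS

LETTERS = "ACGT"

#: published centres of the ATG score histograms (initiating / non-initiating)
DEFAULT_POSITIVE_MEAN_KSS = 0.73
DEFAULT_NEGATIVE_MEAN_KSS = 0.52


class ConstructionError(ValueError):
    pass


def expected_kss_under(matrix: FrequencyMatrix, logo: LogoMatrix) -> float:
    """Closed-form expected KSS of complete contexts drawn from ``matrix``."""
    return float((matrix.freqs * logo.heights).sum() / logo.max_total_bits)


def composition_matrix(base_freqs) -> FrequencyMatrix:
    """A position-independent composition (same base frequencies at every slot)."""
    row = np.asarray(base_freqs, dtype=float)
    row = row / row.sum()
    return FrequencyMatrix(np.tile(row, (2 * FLANK_LEN, 1)))


def tilted_context_matrix(logo: LogoMatrix, target_mean_kss: float) -> FrequencyMatrix:
    """Exponentially tilt the uniform background to a target expected KSS.

    Each position's composition is ``c(p, l) ∝ exp(tau * height(p, l))``;
    positive ``tau`` enriches toward the consensus, negative ``tau``
    depletes it.  ``tau`` is solved so the closed-form expectation equals
    the target.
    """

    return _tilt_along(logo.heights, logo, target_mean_kss)


def _tilt_along(
    directions: np.ndarray, logo: LogoMatrix, target_mean_kss: float
) -> FrequencyMatrix:
    def matrix_at(tau: float) -> FrequencyMatrix:
        w = np.exp(tau * directions)
        return FrequencyMatrix(w / w.sum(axis=1, keepdims=True))

    def gap(tau: float) -> float:
        return expected_kss_under(matrix_at(tau), logo) - target_mean_kss

    lo, hi = -1.0, 1.0
    while gap(lo) > 0:
        lo *= 2
        if lo < -2**12:
            raise ConstructionError("target expected KSS unreachable (too low)")
    while gap(hi) < 0:
        hi *= 2
        if hi > 2**12:
            raise ConstructionError("target expected KSS unreachable (too high)")
    return matrix_at(brentq(gap, lo, hi))


def shifted_consensus_matrix(
    logo: LogoMatrix, target_mean_kss: float, n_shifted: int = 3
) -> FrequencyMatrix:
    """A Kozak-enriched composition whose preferences differ from the logo.

    Tilts along the logo heights, but with the two tallest letters
    exchanged at the ``n_shifted`` most informative positions.  The
    resulting contexts still score high under the logo (the calibration
    fixes the expected KSS at ``target_mean_kss``) yet carry
    dataset-specific letter preferences a fixed score cannot represent.
    """
    h = logo.heights.copy()
    for p in np.argsort(logo.information)[::-1][:n_shifted]:
        order = np.argsort(h[p])[::-1]
        h[p, order[0]], h[p, order[1]] = h[p, order[1]], h[p, order[0]]
    return _tilt_along(h, logo, target_mean_kss)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a labelled flank-context dataset.

    ``positive_matrix`` / ``negative_matrix`` default to the tilted
    compositions described in the module docstring.  ``codon_mix`` maps
    codons to sampling weights; it defaults to pure ATG for the
    canonical class and uniform CTG/GTG/TTG for the near-cognate class.
    """

    n_pos: int = 500
    n_neg: int = 800
    missing_fraction: float = 0.2
    codon_class: str = "ATG"  # "ATG" or "near-cognate"
    positive_matrix: FrequencyMatrix | None = None
    negative_matrix: FrequencyMatrix | None = None
    codon_mix: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.missing_fraction <= 1.0:
            raise ValueError("missing_fraction must lie in [0, 1]")
        if self.codon_class not in ("ATG", "near-cognate"):
            raise ValueError("codon_class must be 'ATG' or 'near-cognate'")


def _resolve_codon_mix(spec: SyntheticSpec) -> tuple[list[str], np.ndarray]:
    if spec.codon_mix is not None:
        codons = list(spec.codon_mix)
        weights = np.array([spec.codon_mix[c] for c in codons], dtype=float)
        if (weights < 0).any() or weights.sum() <= 0:
            raise ValueError("codon mix weights must be non-negative and sum > 0")
        return codons, weights / weights.sum()
    if spec.codon_class == "ATG":
        return [CANONICAL_CODON], np.array([1.0])
    codons = list(TRAINED_NEAR_COGNATE)
    return codons, np.full(len(codons), 1.0 / len(codons))


def _draw_flank_blocks(
    matrix: FrequencyMatrix, n: int, rng: np.random.Generator
) -> np.ndarray:
    """(n, 20) array of letter indices, column p drawn from matrix row p."""
    out = np.empty((n, 2 * FLANK_LEN), dtype=np.int64)
    u = rng.random((n, 2 * FLANK_LEN))
    cdf = np.cumsum(matrix.freqs, axis=1)
    for p in range(2 * FLANK_LEN):
        out[:, p] = np.searchsorted(cdf[p], u[:, p], side="right")
    return np.clip(out, 0, 3)


def _truncate(left: str, right: str, rng: np.random.Generator) -> tuple[str, str]:
    depth = int(rng.integers(1, FLANK_LEN + 1))
    if rng.integers(0, 2) == 0:
        return MISSING * depth + left[depth:], right
    return left, right[: FLANK_LEN - depth] + MISSING * depth


def generate_labeled_dataset(
    spec: SyntheticSpec, logo: LogoMatrix | None = None
) -> list[LabeledExample]:
    """Draw a labelled dataset reproducibly from a spec.

    Positives take their flank bases from the positive matrix, negatives
    from the negative matrix; a ``missing_fraction`` subset has one
    flank truncated at a depth uniform on 1..10.
    """
    logo = logo or default_logo()
    pos_matrix = spec.positive_matrix or shifted_consensus_matrix(
        logo, DEFAULT_POSITIVE_MEAN_KSS
    )
    neg_matrix = spec.negative_matrix or tilted_context_matrix(
        logo, DEFAULT_NEGATIVE_MEAN_KSS
    )
    rng = np.random.default_rng(spec.seed)
    codons, codon_probs = _resolve_codon_mix(spec)

    examples: list[LabeledExample] = []
    for label, matrix, count in ((1, pos_matrix, spec.n_pos), (0, neg_matrix, spec.n_neg)):
        blocks = _draw_flank_blocks(matrix, count, rng)
        codon_idx = rng.choice(len(codons), size=count, p=codon_probs)
        truncate_mask = rng.random(count) < spec.missing_fraction
        for i in range(count):
            row = blocks[i]
            left = "".join(LETTERS[j] for j in row[:FLANK_LEN])
            right = "".join(LETTERS[j] for j in row[FLANK_LEN:])
            if truncate_mask[i]:
                left, right = _truncate(left, right, rng)
            examples.append(
                LabeledExample(
                    context=FlankedCodon(codons[codon_idx[i]], left, right),
                    label=label,
                    codon_class=spec.codon_class,
                    source="synthetic",
                )
            )
    return examples


# ---------------------------------------------------------------------------
# toy repeat loci


@dataclass(frozen=True)
class PlantedCodon:
    """A codon planted upstream of the repeat with consensus (argmax) flanks.

    ``offset`` follows the scanner's convention (bases upstream of the
    repeat start).  ``blocked`` plants an in-frame stop codon directly
    after the codon, so the stop filter must remove it.
    """

    codon: str
    offset: int
    blocked: bool = False


def generate_toy_locus(
    upstream_length: int,
    planted: list[PlantedCodon],
    repeat_unit: str,
    copies: int = 10,
    seed: int = 0,
    logo: LogoMatrix | None = None,
    label: str | None = None,
) -> RepeatLocus:
    """Uniform background upstream with maximally scoring planted codons.

    Planted codons are written with the logo's argmax letters in all 20
    flank slots, so they score KSS = 1.0 and present the strongest
    possible context to a trained classifier.  Unintended in-frame stop
    codons between an (unblocked) planted codon and the repeat are
    scrubbed from the background.  Plant windows (codon plus flanks,
    23 bases) must not overlap each other or the repeat.
    """
    logo = logo or default_logo()
    rng = np.random.default_rng(seed)
    consensus = logo.argmax_letters()
    seq = list(rng.choice(list(LETTERS), size=upstream_length))
    repeat_start = upstream_length

    windows: list[tuple[int, int]] = []
    for plant in planted:
        start = repeat_start - plant.offset
        lo, hi = start - FLANK_LEN, start + 3 + FLANK_LEN
        if lo < 0 or hi > repeat_start:
            raise ConstructionError(
                f"plant {plant.codon}@{plant.offset} does not fit with full flanks"
            )
        for wlo, whi in windows:
            if lo < whi and wlo < hi:
                raise ConstructionError("planted codons collide")
        windows.append((lo, hi))
        seq[lo:start] = list(consensus[:FLANK_LEN])
        seq[start : start + 3] = list(plant.codon)
        seq[start + 3 : hi] = list(consensus[FLANK_LEN:])
        if plant.blocked:
            seq[start + 3 : start + 6] = list("TAA")

    # scrub accidental in-frame stops between unblocked plants and the repeat,
    # including codons straddling the junction into the repeat
    in_window = set()
    for lo, hi in windows:
        in_window.update(range(lo, hi))
    repeat_tail = (repeat_unit * copies)[:2]
    full = seq + list(repeat_tail)
    for plant in planted:
        if plant.blocked:
            continue
        start = repeat_start - plant.offset
        for i in range(start + 3, repeat_start, 3):
            if "".join(full[i : i + 3]) in STOP_CODONS:
                mutable = [
                    j
                    for j in range(i, min(i + 3, repeat_start))
                    if j not in in_window
                ]
                if not mutable:
                    raise ConstructionError(
                        "cannot scrub a stop codon without disturbing a planted window"
                    )
                full[mutable[0]] = "C"  # no stop codon contains C
    upstream = "".join(full[:repeat_start])
    for plant in planted:
        if plant.blocked:
            continue
        full = upstream + repeat_unit * copies
        if has_upstream_stop(full, repeat_start - plant.offset, repeat_start):
            raise ConstructionError("stop scrub failed")  # pragma: no cover
    return RepeatLocus(
        label=label or f"toy-locus-seed{seed}",
        upstream=upstream,
        repeat_unit=repeat_unit,
        copies=copies,
    )
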