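"""Repeat-locus scanning for candidate translation initiation sites.

A repeat locus is modelled as an upstream region followed by ten copies
of the repeat unit (ten copies are at least thirty bases, enough to
saturate the ten-base flank window of every codon at or near the
junction).  Every ATG and near-cognate codon in the assembled sequence
is scored by the matching forest; candidates whose simulated translation
would hit an in-frame stop codon before reaching the repeat are dropped,
and the surviving predictions are annotated with the repeat polypeptide
their reading frame would produce.

Offset convention: ``offset = repeat_start - codon_start`` in bases, so
offset 0 means the codon begins exactly at the repeat and negative
offsets place it inside the repeat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .forest import (
    CANDIDATE_CODONS,
    CANONICAL_CODON,
    TISModel,
    TRAINED_CODONS,
    encode,
)
from .logo import LogoMatrix
from .scoring import extract_context, kss
from .sequence import clean_sequence, is_stop, translate_codon

import numpy as np


@dataclass(frozen=True)
class RepeatLocus:
    """An upstream region plus a repeat unit expanded to ``copies`` copies."""

    label: str
    upstream: str
    repeat_unit: str
    copies: int = 10
    strand: str = "sense"  # informational tag only

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "upstream", clean_sequence(self.upstream, allow_missing=False)
        )
        unit = clean_sequence(self.repeat_unit, allow_missing=False)
        if not unit:
            raise ValueError("repeat unit must be non-empty")
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        object.__setattr__(self, "repeat_unit", unit)


@dataclass(frozen=True)
class Prediction:
    """A candidate initiation codon at a repeat locus."""

    codon: str
    codon_start: int
    offset: int  # repeat_start - codon_start; negative = inside the repeat
    frame: int  # codon_start mod 3 of the assembled sequence
    probability: float  # forest vote fraction
    kss: float
    trained_codon: bool
    peptide_unit: str = ""
    peptide_truncated: bool = False  # a stop occurs within the repeat cycle
    category: int | None = None


def assemble_locus(locus: RepeatLocus) -> tuple[str, int]:
    """Concatenate upstream and expanded repeat; return (sequence, repeat_start)."""
    return locus.upstream + locus.repeat_unit * locus.copies, len(locus.upstream)


def candidate_positions(seq: str) -> list[tuple[int, str]]:
    """All (start, codon) whose 3-mer is a candidate initiation codon."""
    members = set(CANDIDATE_CODONS)
    return [
        (i, seq[i : i + 3]) for i in range(len(seq) - 2) if seq[i : i + 3] in members
    ]


def scan_locus(
    locus: RepeatLocus,
    atg_model: TISModel,
    nc_model: TISModel,
    logo: LogoMatrix,
) -> list[Prediction]:
    """Score every candidate codon in the assembled locus (pre-filter).

    ATG codons are dispatched to the canonical model, all near-cognate
    codons to the near-cognate model (with first-base features).  Every
    candidate is returned with its vote probability and KSS; thresholding
    and the stop filter are applied downstream.
    """
    seq, repeat_start = assemble_locus(locus)
    positions = candidate_positions(seq)
    predictions: list[Prediction] = []
    if not positions:
        return predictions

    contexts = [extract_context(seq, i) for i, _ in positions]
    atg_rows = [k for k, (_, c) in enumerate(positions) if c == CANONICAL_CODON]
    nc_rows = [k for k, (_, c) in enumerate(positions) if c != CANONICAL_CODON]
    proba = np.empty(len(positions))
    if atg_rows:
        X = np.stack([encode(contexts[k], atg_model.schema) for k in atg_rows])
        proba[atg_rows] = atg_model.predict_proba_matrix(X)
    if nc_rows:
        X = np.stack([encode(contexts[k], nc_model.schema) for k in nc_rows])
        proba[nc_rows] = nc_model.predict_proba_matrix(X)

    for k, (start, codon) in enumerate(positions):
        predictions.append(
            Prediction(
                codon=codon,
                codon_start=start,
                offset=repeat_start - start,
                frame=start % 3,
                probability=float(proba[k]),
                kss=kss(contexts[k], logo),
                trained_codon=codon in TRAINED_CODONS,
            )
        )
    return predictions


def has_upstream_stop(seq: str, codon_start: int, repeat_start: int) -> bool:
    """Whether translation from ``codon_start`` hits a stop before the repeat.

    Checks the in-frame codons starting at ``codon_start + 3, + 6, ...``
    with start strictly below ``repeat_start``.
    """
    for i in range(codon_start + 3, repeat_start, 3):
        if is_stop(seq[i : i + 3]):
            return True
    return False


def stop_filter(
    candidates: list[Prediction], seq: str, repeat_start: int
) -> list[Prediction]:
    """Drop upstream candidates blocked by an in-frame stop codon.

    A candidate starting before the repeat is removed if simulated
    translation encounters a stop codon before reaching the repeat;
    candidates at or inside the repeat are never filtered by this rule.
    """
    kept = []
    for p in candidates:
        if p.codon_start < repeat_start and has_upstream_stop(
            seq, p.codon_start, repeat_start
        ):
            continue
        kept.append(p)
    return kept


def peptide_repeat(
    repeat_unit: str, codon_start: int, repeat_start: int
) -> tuple[str, bool]:
    """The repeat polypeptide unit read in the frame set by ``codon_start``.

    Translation proceeds in steps of three from the initiation codon; the
    first in-frame position at or past the repeat start fixes the phase
    within the length-k repeat cycle, and one full cycle of lcm(3, k)
    bases is translated (lcm(3, k) / 3 residues).  If a stop codon occurs
    within the cycle the unit is truncated there and flagged.
    """
    unit = clean_sequence(repeat_unit, allow_missing=False)
    k = len(unit)
    anchor = max(codon_start, repeat_start)
    q = codon_start + 3 * math.ceil((anchor - codon_start) / 3)
    phase = (q - repeat_start) % k
    cycle_len = math.lcm(3, k)
    reps = (cycle_len + phase) // k + 2
    stretch = (unit * reps)[phase : phase + cycle_len]
    peptide = []
    for i in range(0, cycle_len, 3):
        aa = translate_codon(stretch[i : i + 3])
        if aa == "*":
            return "".join(peptide), True
        peptide.append(aa)
    return "".join(peptide), False


def predict_locus(
    locus: RepeatLocus,
    atg_model: TISModel,
    nc_model: TISModel,
    logo: LogoMatrix,
    min_probability: float = 0.5,
) -> list[Prediction]:
    """Full pipeline: scan, threshold votes, stop-filter, infer peptides.

    Returns predictions sorted by position, each carrying its repeat
    polypeptide unit.  Ranking into categories is a separate step (see
    :mod:`tisscan.ranking`).
    """
    seq, repeat_start = assemble_locus(locus)
    candidates = [
        p
        for p in scan_locus(locus, atg_model, nc_model, logo)
        if p.probability >= min_probability
    ]
    retained = stop_filter(candidates, seq, repeat_start)
    out = []
    for p in retained:
        unit, truncated = peptide_repeat(locus.repeat_unit, p.codon_start, repeat_start)
        out.append(replace(p, peptide_unit=unit, peptide_truncated=truncated))
    return sorted(out, key=lambda p: p.codon_start)


# ---------------------------------------------------------------------------
# report rendering

#: one colour per reading frame of the assembled sequence
_FRAME_ANSI = {0: "31", 1: "32", 2: "34"}  # red, green, blue
_FRAME_HTML = {0: "#c0392b", 1: "#1e8449", 2: "#1f618d"}


class ReportFormatError(ValueError):
    pass


def predictions_table(predictions: list[Prediction]) -> "pd.DataFrame":
    """Machine-readable table; KSS is reported to two decimal places."""
    import pandas as pd

    return pd.DataFrame(
        {
            "offset": [p.offset for p in predictions],
            "codon": [p.codon for p in predictions],
            "frame": [p.frame for p in predictions],
            "probability": [p.probability for p in predictions],
            "kss": [f"{p.kss:.2f}" for p in predictions],
            "peptide_unit": [p.peptide_unit for p in predictions],
            "trained": [p.trained_codon for p in predictions],
            "category": [p.category for p in predictions],
        }
    )


def _base_styles(
    predictions: list[Prediction], seq_len: int
) -> list[tuple[int, bool] | None]:
    """Per-base (frame, bold) annotation.

    Later (downstream) codons overwrite earlier ones on overlap, so a
    shared base takes the colour of the next predicted codon; it is bold
    only if that codon's model was trained on it.
    """
    styles: list[tuple[int, bool] | None] = [None] * seq_len
    for p in sorted(predictions, key=lambda p: p.codon_start):
        for i in range(p.codon_start, min(p.codon_start + 3, seq_len)):
            styles[i] = (p.frame, p.trained_codon)
    return styles


def render_report(
    predictions: list[Prediction],
    locus: RepeatLocus,
    format: str = "text",
    color: bool = True,
    width: int = 60,
) -> str:
    """Render the annotated sequence view plus the prediction table.

    Formats: ``tsv`` (table only), ``text`` (marked-up sequence, ANSI
    colour optional, bold for codons the models were trained on) and
    ``html``.
    """
    seq, _ = assemble_locus(locus)
    preds = sorted(predictions, key=lambda p: p.codon_start)
    table = predictions_table(preds)

    if format == "tsv":
        return table.to_csv(sep="\t", index=False)

    styles = _base_styles(preds, len(seq))
    if format == "text":
        pieces = []
        for i, base in enumerate(seq):
            st = styles[i]
            if st is None or not color:
                pieces.append(base)
            else:
                frame, bold = st
                codes = ("1;" if bold else "") + _FRAME_ANSI[frame]
                pieces.append(f"\x1b[{codes}m{base}\x1b[0m")
            if (i + 1) % width == 0:
                pieces.append("\n")
        body = "".join(pieces).rstrip("\n")
        return f"> {locus.label} ({locus.strand})\n{body}\n\n{table.to_string(index=False)}\n"

    if format == "html":
        spans = []
        for i, base in enumerate(seq):
            st = styles[i]
            if st is None:
                spans.append(base)
            else:
                frame, bold = st
                weight = "bold" if bold else "normal"
                spans.append(
                    f'<span style="color:{_FRAME_HTML[frame]};font-weight:{weight}">{base}</span>'
                )
            if (i + 1) % width == 0:
                spans.append("<br/>")
        rows = table.to_html(index=False)
        return (
            f"<html><body><h3>{locus.label} ({locus.strand})</h3>"
            f'<p style="font-family:monospace">{"".join(spans)}</p>{rows}</body></html>'
        )

    raise ReportFormatError(f"unknown report format: {format!r}")
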