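"""Category ranking of predicted initiation codons.

Predictions are placed into five categories, 1 most preferred: the
canonical ATG first, then the trained near-cognate codons in order of
their observed initiation tendency, and finally the extrapolated
near-cognate codons, which the models never saw in training and which
are therefore split by whether their Kozak similarity score clears the
display threshold.  Within a category, predictions are ordered by KSS
(default) or by forest vote probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .forest import CANDIDATE_CODONS
from .scan import Prediction


class CategoryError(ValueError):
    pass


@dataclass(frozen=True)
class CategoryTable:
    """Mapping from codon identity (plus KSS for extrapolations) to category."""

    codon_categories: dict = field(
        default_factory=lambda: {"ATG": 1, "CTG": 2, "GTG": 3, "TTG": 3}
    )
    extrapolated_high: int = 4
    extrapolated_low: int = 5
    kss_threshold: float = 0.70

    def category_for(self, codon: str, kss: float) -> int:
        if codon in self.codon_categories:
            return int(self.codon_categories[codon])
        if codon not in CANDIDATE_CODONS:
            raise CategoryError(f"{codon!r} is not a candidate initiation codon")
        return self.extrapolated_high if kss >= self.kss_threshold else self.extrapolated_low

    @classmethod
    def from_file(cls, path: str | Path) -> "CategoryTable":
        """Load a user-edited table from a small JSON config."""
        cfg = json.loads(Path(path).read_text())
        return cls(
            codon_categories={str(k): int(v) for k, v in cfg.get("codon_categories", {}).items()},
            extrapolated_high=int(cfg.get("extrapolated_high", 4)),
            extrapolated_low=int(cfg.get("extrapolated_low", 5)),
            kss_threshold=float(cfg.get("kss_threshold", 0.70)),
        )

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "codon_categories": self.codon_categories,
                    "extrapolated_high": self.extrapolated_high,
                    "extrapolated_low": self.extrapolated_low,
                    "kss_threshold": self.kss_threshold,
                },
                indent=2,
            )
        )


DEFAULT_CATEGORY_TABLE = CategoryTable()


def categorize(prediction: Prediction, table: CategoryTable | None = None) -> int:
    """Deterministic category lookup for one prediction."""
    table = table or DEFAULT_CATEGORY_TABLE
    return table.category_for(prediction.codon, prediction.kss)


def rank_predictions(
    predictions: list[Prediction],
    table: CategoryTable | None = None,
    sort_key: str = "kss",
) -> list[Prediction]:
    """Order predictions by (category asc, sort key desc, offset asc).

    ``sort_key`` is ``"kss"`` or ``"probability"``.  The result is a
    total order independent of input order; each returned prediction
    carries its assigned category.
    """
    if sort_key not in ("kss", "probability"):
        raise CategoryError(f"sort_key must be 'kss' or 'probability', got {sort_key!r}")
    table = table or DEFAULT_CATEGORY_TABLE
    from dataclasses import replace

    annotated = [replace(p, category=categorize(p, table)) for p in predictions]
    return sorted(
        annotated,
        key=lambda p: (p.category, -getattr(p, sort_key), p.offset, p.codon),
    )
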