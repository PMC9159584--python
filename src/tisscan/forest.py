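"""Random-forest classifiers over one-hot flank features.

Two classifiers are trained: one for the canonical ATG start codon and
one for the near-cognate codons CTG/GTG/TTG.  Each of the 20 flank
positions is encoded as five indicators (A, C, G, T, missing); the
near-cognate schema appends five more indicators for the codon's first
base, the position that distinguishes CTG from GTG from TTG.

Class imbalance is handled at the tree level rather than by reweighting:
every tree is grown on the full set of training negatives plus an equal
number of positives sampled without replacement, so each tree sees a
balanced sample while the forest as a whole sees every positive.  The
reported probability for a codon is the fraction of trees voting that it
initiates translation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .scoring import FLANK_LEN, FlankedCodon
from .threshold import RocSummary, roc_auroc

MODEL_FORMAT_VERSION = 1

CANONICAL_CODON = "ATG"
TRAINED_NEAR_COGNATE = ("CTG", "GTG", "TTG")
EXTRAPOLATED_NEAR_COGNATE = ("ACG", "AAG", "AGG", "ATA", "ATC", "ATT")
NEAR_COGNATE_CODONS = TRAINED_NEAR_COGNATE + EXTRAPOLATED_NEAR_COGNATE
CANDIDATE_CODONS = (CANONICAL_CODON,) + NEAR_COGNATE_CODONS
TRAINED_CODONS = (CANONICAL_CODON,) + TRAINED_NEAR_COGNATE

STATES = "ACGT-"
_STATE_INDEX = {s: i for i, s in enumerate(STATES)}


class SchemaError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureSchema:
    """Feature layout for one codon class."""

    name: str
    codon_class: str  # "ATG" or "near-cognate"
    include_first_base: bool

    @property
    def n_features(self) -> int:
        return 5 * (2 * FLANK_LEN) + (5 if self.include_first_base else 0)

    def checksum(self) -> str:
        payload = f"{self.name}:{self.codon_class}:{self.n_features}:{STATES}"
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


ATG_SCHEMA = FeatureSchema("atg-v1", "ATG", include_first_base=False)
NEAR_COGNATE_SCHEMA = FeatureSchema("nc-v1", "near-cognate", include_first_base=True)


def schema_for_codon(codon: str) -> FeatureSchema:
    if codon == CANONICAL_CODON:
        return ATG_SCHEMA
    if codon in NEAR_COGNATE_CODONS:
        return NEAR_COGNATE_SCHEMA
    raise SchemaError(f"{codon!r} is not a candidate initiation codon")


@dataclass(frozen=True)
class LabeledExample:
    """A flanked codon with its initiation label."""

    context: FlankedCodon
    label: int  # 1 = initiates, 0 = does not
    codon_class: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


def encode(fc: FlankedCodon, schema: FeatureSchema) -> np.ndarray:
    """One-hot encode a flanked codon under a schema.

    Position-major: five indicators per flank slot, in A, C, G, T,
    missing order; the near-cognate schema appends the codon's
    first-base indicators (missing never set for a valid codon).
    """
    if schema.include_first_base:
        if fc.codon not in NEAR_COGNATE_CODONS:
            raise SchemaError(
                f"codon {fc.codon} does not match the near-cognate schema"
            )
    elif fc.codon != CANONICAL_CODON:
        raise SchemaError(f"codon {fc.codon} does not match the ATG schema")
    vec = np.zeros(schema.n_features, dtype=np.uint8)
    for p, base in enumerate(fc.flanks):
        vec[5 * p + _STATE_INDEX[base]] = 1
    if schema.include_first_base:
        vec[5 * 2 * FLANK_LEN + _STATE_INDEX[fc.codon[0]]] = 1
    return vec


def decode_flanks(vec: np.ndarray) -> str:
    """Recover the 20 flank characters from an encoded vector."""
    chars = []
    for p in range(2 * FLANK_LEN):
        block = vec[5 * p : 5 * p + 5]
        (idx,) = np.nonzero(block)
        chars.append(STATES[int(idx[0])])
    return "".join(chars)


def encode_examples(
    examples: list[LabeledExample], schema: FeatureSchema
) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([encode(ex.context, schema) for ex in examples])
    y = np.array([ex.label for ex in examples], dtype=int)
    return X, y


@dataclass(frozen=True)
class TrainTestSplit:
    train_pos: list[LabeledExample]
    train_neg: list[LabeledExample]
    test: list[LabeledExample]  # balanced holdout


def prepare_training_sets(
    pos: list[LabeledExample],
    neg: list[LabeledExample],
    holdout_fraction: float = 0.05,
    missing_ratio: float = 0.9,
    n_missing: int | None = None,
    rng_seed: np.random.Generator | int | None = None,
) -> TrainTestSplit:
    """Build the negative pool and carve out a balanced holdout.

    The negative pool keeps every complete-flank negative and adds
    ``floor(missing_ratio * n_complete)`` negatives sampled without
    replacement from those with missing flank bases (``n_missing``
    overrides the computed count).  This tilts the pool toward complete
    contexts, which dominate real scanning input.  The holdout is
    ``round(holdout_fraction * pool)`` negatives plus the same number of
    positives, excluded from training.
    """
    if not pos or not neg:
        raise ValueError("both classes must be non-empty")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)

    complete = [ex for ex in neg if ex.context.is_complete]
    incomplete = [ex for ex in neg if not ex.context.is_complete]
    want_missing = int(missing_ratio * len(complete)) if n_missing is None else n_missing
    want_missing = min(want_missing, len(incomplete))
    picked = (
        [incomplete[i] for i in rng.choice(len(incomplete), size=want_missing, replace=False)]
        if want_missing
        else []
    )
    pool = complete + picked

    n_hold = int(round(holdout_fraction * len(pool)))
    if n_hold > len(pool) or n_hold > len(pos):
        raise ValueError("negative pool or positive set too small for holdout")
    if n_hold == 0:
        return TrainTestSplit(list(pos), pool, [])

    neg_hold_idx = rng.choice(len(pool), size=n_hold, replace=False)
    pos_hold_idx = rng.choice(len(pos), size=n_hold, replace=False)
    neg_hold = set(neg_hold_idx.tolist())
    pos_hold = set(pos_hold_idx.tolist())
    test = [pool[i] for i in sorted(neg_hold)] + [pos[i] for i in sorted(pos_hold)]
    train_neg = [ex for i, ex in enumerate(pool) if i not in neg_hold]
    train_pos = [ex for i, ex in enumerate(pos) if i not in pos_hold]
    return TrainTestSplit(train_pos, train_neg, test)


@dataclass
class TISModel:
    """A trained forest with its feature schema and training metadata."""

    trees: list[DecisionTreeClassifier]
    schema: FeatureSchema
    codon_class: str
    n_trees: int
    seed: int | None
    config: dict = field(default_factory=dict)
    format_version: int = MODEL_FORMAT_VERSION

    def predict_proba_matrix(self, X: np.ndarray) -> np.ndarray:
        """Vote fractions for encoded rows, at resolution 1 / n_trees."""
        if X.shape[1] != self.schema.n_features:
            raise SchemaError(
                f"feature count {X.shape[1]} does not match schema "
                f"{self.schema.name} ({self.schema.n_features})"
            )
        votes = np.zeros(len(X))
        for tree in self.trees:
            votes += tree.predict(X)
        return votes / self.n_trees


def train_forest(
    train_pos: list[LabeledExample],
    train_neg: list[LabeledExample],
    schema: FeatureSchema,
    n_trees: int = 1000,
    min_samples_leaf: int = 2,
    max_features: str | int = "sqrt",
    n_tree_negatives: int | None = None,
    rng_seed: int | None = None,
) -> TISModel:
    """Grow a forest of per-tree-balanced decision trees.

    Each tree trains on ``n_tree_negatives`` negatives (default: all of
    them) plus an equal number of positives sampled without replacement,
    with sqrt(n_features) candidate features per split and a minimum
    leaf size of two codon instances.
    """
    if not train_pos or not train_neg:
        raise ValueError("training set must contain both labels")
    Xp, _ = encode_examples(train_pos, schema)
    Xn, _ = encode_examples(train_neg, schema)
    rng = np.random.default_rng(rng_seed)

    n_neg = len(Xn) if n_tree_negatives is None else min(n_tree_negatives, len(Xn))
    # every tree sees equal label counts, whichever class is scarcer
    n_bal = min(n_neg, len(Xp))
    trees: list[DecisionTreeClassifier] = []
    for _ in range(n_trees):
        ni = rng.choice(len(Xn), size=n_bal, replace=False) if n_bal < len(Xn) else np.arange(len(Xn))
        pi = rng.choice(len(Xp), size=n_bal, replace=False) if n_bal < len(Xp) else np.arange(len(Xp))
        X = np.concatenate([Xn[ni], Xp[pi]])
        y = np.concatenate([np.zeros(n_bal, dtype=int), np.ones(n_bal, dtype=int)])
        tree = DecisionTreeClassifier(
            max_features=max_features,
            min_samples_leaf=min_samples_leaf,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X, y)
        trees.append(tree)
    return TISModel(
        trees=trees,
        schema=schema,
        codon_class=schema.codon_class,
        n_trees=n_trees,
        seed=rng_seed,
        config={
            "min_samples_leaf": min_samples_leaf,
            "max_features": max_features,
            "n_tree_negatives": n_bal,
            "n_train_pos": len(train_pos),
            "n_train_neg": len(train_neg),
            "schema_checksum": schema.checksum(),
        },
    )


def predict_proba(model: TISModel, fc: FlankedCodon) -> float:
    """Vote fraction for a single flanked codon; >= 0.5 classifies as initiating."""
    X = encode(fc, model.schema)[None, :]
    return float(model.predict_proba_matrix(X)[0])


def evaluate_balanced(
    model: TISModel, test: list[LabeledExample], force: bool = False
) -> tuple[float, RocSummary]:
    """Accuracy at the 0.5 vote threshold and ROC on a balanced holdout."""
    y = np.array([ex.label for ex in test], dtype=int)
    if y.sum() * 2 != len(y) and not force:
        raise ValueError(
            "test set is not balanced; pass force=True to evaluate anyway"
        )
    X, _ = encode_examples(test, model.schema)
    proba = model.predict_proba_matrix(X)
    accuracy = float(((proba >= 0.5).astype(int) == y).mean())
    return accuracy, roc_auroc(proba, y)


def sample_near_cognate_test(
    examples: list[LabeledExample],
    per_codon: int = 20,
    rng_seed: np.random.Generator | int | None = None,
) -> tuple[list[LabeledExample], list[LabeledExample]]:
    """Set aside a balanced near-cognate holdout before training.

    For each trained near-cognate codon, ``per_codon`` positives and
    ``per_codon`` negatives are isolated (20 each by default, 120 total
    over CTG/GTG/TTG).  Returns ``(test, remainder)``.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    test: list[LabeledExample] = []
    held: set[int] = set()
    for codon in TRAINED_NEAR_COGNATE:
        for label in (1, 0):
            idx = [
                i
                for i, ex in enumerate(examples)
                if ex.context.codon == codon and ex.label == label
            ]
            if len(idx) < per_codon:
                raise ValueError(f"not enough {codon} examples with label {label}")
            chosen = rng.choice(len(idx), size=per_codon, replace=False)
            for j in chosen:
                held.add(idx[j])
                test.append(examples[idx[j]])
    remainder = [ex for i, ex in enumerate(examples) if i not in held]
    return test, remainder


def save_model(model: TISModel, path) -> None:
    joblib.dump(
        {
            "format_version": model.format_version,
            "schema_name": model.schema.name,
            "schema_checksum": model.schema.checksum(),
            "model": model,
        },
        path,
    )


def load_model(path) -> TISModel:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {payload.get('format_version')} is not supported"
        )
    model: TISModel = payload["model"]
    if payload.get("schema_checksum") != model.schema.checksum():
        raise SchemaError("model schema checksum mismatch; refusing to predict")
    return model


# ---------------------------------------------------------------------------
# training-table I/O

TABLE_COLUMNS = ["codon", "left_flank", "right_flank", "label", "source"]


def examples_to_frame(examples: list[LabeledExample]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "codon": [ex.context.codon for ex in examples],
            "left_flank": [ex.context.left for ex in examples],
            "right_flank": [ex.context.right for ex in examples],
            "label": [ex.label for ex in examples],
            "source": [ex.source for ex in examples],
        }
    )


def frame_to_examples(df: pd.DataFrame) -> list[LabeledExample]:
    missing = [c for c in TABLE_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"training table missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        codon = str(row.codon)
        out.append(
            LabeledExample(
                context=FlankedCodon(codon, str(row.left_flank), str(row.right_flank)),
                label=int(row.label),
                codon_class="ATG" if codon == CANONICAL_CODON else "near-cognate",
                source=str(getattr(row, "source", "")),
            )
        )
    return out


def read_training_table(path) -> list[LabeledExample]:
    return frame_to_examples(pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False))


def write_training_table(examples: list[LabeledExample], path) -> None:
    examples_to_frame(examples).to_csv(path, sep="\t", index=False)
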