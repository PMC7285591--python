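"""End-to-end workflows: train/predict for pair-interaction and aptamer
modes, configuration, and run logging.

A pair is featurized as the concatenation of its protein encoding and its
aptamer encoding.  SMOTE balancing is applied to training partitions only
— the API provides no way to balance a test partition, and evaluation
helpers refuse datasets containing synthetic rows.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from aptapred.ensemble import (
    APTAMER_THRESHOLD,
    PAIR_THRESHOLD,
    BoostedForestModel,
    BoostParams,
    classify,
    fit_boosted_forest,
)
from aptapred.evaluation import evaluate_scores
from aptapred.features import FeatureVector, feature_frame
from aptapred.imbalance import REAL, LabeledDataset, smote
from aptapred.nucleotide_encoders import NucleotideEncoderConfig, encode_nucleotide
from aptapred.protein_encoders import ProteinEncoderConfig, encode_protein
from aptapred.seqio import PairRecord, SequenceRecord

log = logging.getLogger("aptapred")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[aptapred] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


@dataclass(frozen=True)
class PipelineConfig:
    """Every knob of the end-to-end pipeline, with published defaults.

    Defaults: forests of 10 trees with max depth 150, 300 boosting rounds
    at learning rate 0.75, decision thresholds 0.44 (pair mode) and 0.48
    (aptamer mode), SMOTE with 5 neighbors balancing the training
    partition to the majority count.
    """

    protein: ProteinEncoderConfig = field(default_factory=ProteinEncoderConfig)
    nucleotide: NucleotideEncoderConfig = field(default_factory=NucleotideEncoderConfig)
    boost: BoostParams = field(default_factory=BoostParams)
    smote_enabled: bool = True
    smote_k_neighbors: int = 5
    balance_test: bool = False  # must stay False; validated below
    pair_threshold: float = PAIR_THRESHOLD
    aptamer_threshold: float = APTAMER_THRESHOLD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.balance_test:
            raise ValueError(
                "balancing a test partition is not permitted: independent "
                "test sets must consist solely of real samples"
            )

    # -- flat key=value serialization ------------------------------------
    def to_text(self) -> str:
        lines = [
            f"protein.encoders = {','.join(self.protein.encoders)}",
            f"protein.paac_lam = {self.protein.paac_lam}",
            f"protein.paac_w = {self.protein.paac_w}",
            f"protein.socn_lam = {self.protein.socn_lam}",
            f"nucleotide.encoders = {','.join(self.nucleotide.encoders)}",
            f"nucleotide.molecule = {self.nucleotide.molecule}",
            f"nucleotide.pseknc_k = {self.nucleotide.pseknc_k}",
            f"nucleotide.pseknc_lam = {self.nucleotide.pseknc_lam}",
            f"nucleotide.pseknc_w = {self.nucleotide.pseknc_w}",
            f"nucleotide.nmbac_max_lag = {self.nucleotide.nmbac_max_lag}",
            f"boost.n_trees = {self.boost.n_trees}",
            f"boost.max_depth = {self.boost.max_depth}",
            f"boost.n_rounds = {self.boost.n_rounds}",
            f"boost.learning_rate = {self.boost.learning_rate}",
            f"smote_enabled = {self.smote_enabled}",
            f"smote_k_neighbors = {self.smote_k_neighbors}",
            f"pair_threshold = {self.pair_threshold}",
            f"aptamer_threshold = {self.aptamer_threshold}",
            f"seed = {self.seed}",
        ]
        return "\n".join(lines) + "\n"

    @staticmethod
    def from_text(text: str) -> "PipelineConfig":
        kv: dict[str, str] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()

        def get(key, cast, default):
            return cast(kv[key]) if key in kv else default

        as_bool = lambda s: s.lower() in ("1", "true", "yes")
        protein = ProteinEncoderConfig(
            encoders=tuple(get("protein.encoders", lambda s: s.split(","), ProteinEncoderConfig().encoders)),
            paac_lam=get("protein.paac_lam", int, 30),
            paac_w=get("protein.paac_w", float, 0.05),
            socn_lam=get("protein.socn_lam", int, 30),
        )
        nucleotide = NucleotideEncoderConfig(
            encoders=tuple(get("nucleotide.encoders", lambda s: s.split(","), NucleotideEncoderConfig().encoders)),
            molecule=get("nucleotide.molecule", str, "DNA"),
            pseknc_k=get("nucleotide.pseknc_k", int, 2),
            pseknc_lam=get("nucleotide.pseknc_lam", int, 10),
            pseknc_w=get("nucleotide.pseknc_w", float, 0.05),
            nmbac_max_lag=get("nucleotide.nmbac_max_lag", int, 10),
        )
        boost = BoostParams(
            n_trees=get("boost.n_trees", int, 10),
            max_depth=get("boost.max_depth", int, 150),
            n_rounds=get("boost.n_rounds", int, 300),
            learning_rate=get("boost.learning_rate", float, 0.75),
        )
        return PipelineConfig(
            protein=protein,
            nucleotide=nucleotide,
            boost=boost,
            smote_enabled=get("smote_enabled", as_bool, True),
            smote_k_neighbors=get("smote_k_neighbors", int, 5),
            balance_test=get("balance_test", as_bool, False),
            pair_threshold=get("pair_threshold", float, PAIR_THRESHOLD),
            aptamer_threshold=get("aptamer_threshold", float, APTAMER_THRESHOLD),
            seed=get("seed", int, 0),
        )


class _EncoderCache:
    """Per-unique-sequence feature cache (pair tables reuse sequences)."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self._protein: dict[str, FeatureVector] = {}
        self._nucleotide: dict[str, FeatureVector] = {}

    def protein(self, rec: SequenceRecord) -> FeatureVector:
        if rec.residues not in self._protein:
            self._protein[rec.residues] = encode_protein(rec, self.config.protein)
        return self._protein[rec.residues]

    def nucleotide(self, rec: SequenceRecord) -> FeatureVector:
        if rec.residues not in self._nucleotide:
            self._nucleotide[rec.residues] = encode_nucleotide(rec, self.config.nucleotide)
        return self._nucleotide[rec.residues]


def encode_pairs(
    pairs: Sequence[PairRecord], config: PipelineConfig
) -> LabeledDataset:
    """Featurize pairs: protein encoding ++ aptamer encoding, with labels."""
    if not pairs:
        raise ValueError("no pairs to encode")
    cache = _EncoderCache(config)
    rows = [
        FeatureVector.concat([cache.protein(p.protein), cache.nucleotide(p.aptamer)])
        for p in pairs
    ]
    names = [f"{p.protein.name}|{p.aptamer.name}" for p in pairs]
    features = feature_frame(names, rows).reset_index(drop=True)
    labels = np.array([p.label for p in pairs])
    return LabeledDataset.from_real(features, labels)


def encode_sequences(
    records: Sequence[SequenceRecord], config: PipelineConfig, labels=None
) -> LabeledDataset | pd.DataFrame:
    """Featurize nucleotide records; with labels returns a LabeledDataset."""
    cache = _EncoderCache(config)
    rows = [cache.nucleotide(r) for r in records]
    features = feature_frame([r.name for r in records], rows).reset_index(drop=True)
    if labels is None:
        return features
    return LabeledDataset.from_real(features, np.asarray(labels, dtype=int))


def _balance(train: LabeledDataset, config: PipelineConfig) -> LabeledDataset:
    if not config.smote_enabled:
        return train
    before = train.class_counts()
    balanced = smote(train, k_neighbors=config.smote_k_neighbors, seed=config.seed)
    after = balanced.class_counts()
    log.info("SMOTE balancing: %s -> %s", before, after)
    return balanced


def train_pairs(
    pairs_train: Sequence[PairRecord], config: PipelineConfig | None = None
) -> tuple[BoostedForestModel, dict]:
    """Encode, balance (training partition only) and fit the pair model."""
    config = config or PipelineConfig()
    labels = np.array([p.label for p in pairs_train])
    if len(np.unique(labels)) < 2:
        raise ValueError("pair training data contains a single class")
    dataset = encode_pairs(pairs_train, config)
    counts_before = dataset.class_counts()
    dataset = _balance(dataset, config)
    model = fit_boosted_forest(
        dataset, config.boost, seed=config.seed, threshold=config.pair_threshold
    )
    run_log = {
        "n_pairs": len(pairs_train),
        "counts_before_balancing": counts_before,
        "counts_after_balancing": dataset.class_counts(),
        "rounds_fitted": model.n_rounds,
        "stopped_early_at": model.stopped_early_at,
    }
    log.info("pair model: %s", run_log)
    return model, run_log


def predict_pairs(
    model: BoostedForestModel,
    proteins: Sequence[SequenceRecord],
    aptamers: Sequence[SequenceRecord],
    config: PipelineConfig | None = None,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Score every aptamer x protein combination.

    Output columns: aptamer, protein, result ("yes"/"no"), score.  All
    aptamers must share one molecule kind (DNA and RNA pairs are predicted
    separately).
    """
    config = config or PipelineConfig()
    if not proteins:
        raise ValueError("empty protein list")
    if not aptamers:
        raise ValueError("empty aptamer list")
    kinds = {a.molecule for a in aptamers}
    if len(kinds) > 1:
        raise ValueError(
            "aptamer file mixes DNA and RNA; predictions for DNA-protein and "
            "RNA-protein pairs must be run separately"
        )
    threshold = model.threshold if threshold is None else threshold
    cache = _EncoderCache(config)
    rows, apt_names, prot_names = [], [], []
    for apt in aptamers:
        for prot in proteins:
            rows.append(
                FeatureVector.concat([cache.protein(prot), cache.nucleotide(apt)])
            )
            apt_names.append(apt.name)
            prot_names.append(prot.name)
    features = feature_frame(range(len(rows)), rows)
    scores = model.predict_score(
        features if tuple(features.columns) == model.feature_names else features.to_numpy()
    )
    labels = classify(scores, threshold)
    return pd.DataFrame(
        {
            "aptamer": apt_names,
            "protein": prot_names,
            "result": ["yes" if v else "no" for v in labels],
            "score": scores,
        }
    )


def train_aptamer(
    positives: Sequence[SequenceRecord],
    negatives: Sequence[SequenceRecord],
    config: PipelineConfig | None = None,
) -> tuple[BoostedForestModel, dict]:
    """Fit the aptamer-vs-non-aptamer model from positive/negative records.

    All records must share the molecule kind declared in the nucleotide
    encoder config; DNA and RNA get separate models.
    """
    config = config or PipelineConfig()
    records = list(positives) + list(negatives)
    kinds = {r.molecule for r in records}
    if len(kinds) > 1:
        raise ValueError(
            "aptamer training set mixes DNA and RNA; train separate models"
        )
    if kinds != {config.nucleotide.molecule}:
        raise ValueError(
            f"records are {kinds.pop()} but the nucleotide encoder config is "
            f"for {config.nucleotide.molecule}"
        )
    labels = np.array([1] * len(positives) + [0] * len(negatives))
    dataset = encode_sequences(records, config, labels)
    counts_before = dataset.class_counts()
    dataset = _balance(dataset, config)
    model = fit_boosted_forest(
        dataset, config.boost, seed=config.seed, threshold=config.aptamer_threshold
    )
    run_log = {
        "n_records": len(records),
        "counts_before_balancing": counts_before,
        "counts_after_balancing": dataset.class_counts(),
        "rounds_fitted": model.n_rounds,
        "stopped_early_at": model.stopped_early_at,
    }
    log.info("aptamer model: %s", run_log)
    return model, run_log


def predict_aptamer(
    model: BoostedForestModel,
    records: Sequence[SequenceRecord],
    config: PipelineConfig | None = None,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Score sequences for aptamer-ness: columns name, result, score."""
    config = config or PipelineConfig()
    if not records:
        raise ValueError("empty sequence list")
    threshold = model.threshold if threshold is None else threshold
    features = encode_sequences(records, config)
    scores = model.predict_score(features)
    labels = classify(scores, threshold)
    return pd.DataFrame(
        {
            "name": [r.name for r in records],
            "result": ["yes" if v else "no" for v in labels],
            "score": scores,
        }
    )


def evaluate_model(
    model: BoostedForestModel, test: LabeledDataset, threshold: float | None = None
) -> dict[str, float]:
    """Evaluate on a strictly-real test partition (synthetic rows refused)."""
    if np.any(test.provenance != REAL):
        raise ValueError(
            "test partition contains synthetic rows; evaluation is only "
            "defined on real samples"
        )
    threshold = model.threshold if threshold is None else threshold
    scores = model.predict_score(test.features)
    return evaluate_scores(test.labels, scores, threshold)


def tune_threshold(
    labels, scores, grid: np.ndarray | None = None
) -> tuple[float, pd.DataFrame]:
    """Grid-search the decision threshold maximizing balanced Sn/Sp
    (Youden's J) on a validation split's scores."""
    grid = np.round(np.arange(0.05, 0.96, 0.01), 2) if grid is None else grid
    rows = []
    for t in grid:
        rep = evaluate_scores(labels, scores, float(t))
        rows.append({"threshold": float(t), **rep})
    table = pd.DataFrame(rows)
    j = (table["Sn"] + table["Sp"] - 1.0).to_numpy()
    # midpoint of the optimal plateau, not its edge
    tied = np.flatnonzero(j >= j.max() - 1e-12)
    best = float(table["threshold"].iloc[tied[len(tied) // 2]])
    return best, table


def lookup(
    table: pd.DataFrame, query: str, columns: tuple[str, str] = ("name", "sequence")
) -> pd.DataFrame:
    """Convenience search of a user-supplied table by exact name or sequence."""
    name_col, seq_col = columns
    mask = (table[name_col].astype(str) == query) | (
        table[seq_col].astype(str).str.upper() == query.upper()
    )
    return table.loc[mask].reset_index(drop=True)
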