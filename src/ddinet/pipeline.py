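"""End-to-end orchestration: dataset -> embeddings -> classifier -> network.

This is the glue the command-line interface and the evaluation scripts
call; each step simply delegates to the stage modules with the protocol
order fixed: the Pfam2Vec corpus and the DDI weight table are built from
the *training* positives only, the decision threshold is tuned on
validation, and the final forest is refit on train+validation before it
ever sees the test records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ddinet.classifier import (
    ClassifierConfig,
    EvalReport,
    TrainedClassifier,
    fit_forest,
    grid_search,
    retrain_and_test,
    tune_threshold,
)
from ddinet.core import PPIRecord, ProteinCatalog
from ddinet.dataset import DatasetSplit, LabeledDataset, split_dataset
from ddinet.embedding import (
    DDIWeightTable,
    EmbeddingModel,
    build_corpus,
    build_ddi_weights,
    canonical_pair_order,
    pair_vector,
    train_embeddings,
)
from ddinet.network import InteractionNetwork, build_network, score_all_pairs

logger = logging.getLogger(__name__)

DEFAULT_TREE_GRID = [50, 100, 150, 200]
DEFAULT_FEATURE_RULES = ["sqrt", "log2"]


def featurize(
    records: list[PPIRecord],
    catalog: ProteinCatalog,
    model: EmbeddingModel,
    weights: DDIWeightTable,
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]]]:
    """Pair vectors, 0/1 labels and pair keys for a list of labeled records."""
    X, y, keys = [], [], []
    for rec in records:
        first, second = canonical_pair_order(catalog[rec.a], catalog[rec.b])
        X.append(pair_vector(first, second, model, weights))
        y.append(1 if rec.label == "positive" else 0)
        keys.append(rec.key)
    return np.vstack(X), np.asarray(y), keys


@dataclass
class TrainingResult:
    split: DatasetSplit
    embeddings: EmbeddingModel
    weights: DDIWeightTable
    config: ClassifierConfig
    decision_threshold: float
    classifier: TrainedClassifier
    report: EvalReport


def train_pipeline(
    dataset: LabeledDataset,
    catalog: ProteinCatalog,
    seed: int,
    fractions: tuple[float, float, float] = (0.70, 0.11, 0.19),
    dim: int = 100,
    window: int = 1,
    epochs: int = 10,
    tree_grid: list[int] | None = None,
    feature_rules: list[str] | None = None,
    dt_metric: str = "f1",
    skip_grid_search: bool = False,
) -> TrainingResult:
    """Split, embed, tune and evaluate; fully reproducible from ``seed``.

    With ``skip_grid_search`` the forest uses the first grid entry
    directly (useful when the grid has already been explored).
    """
    rng = np.random.default_rng(seed)
    split = split_dataset(dataset, fractions, seed=int(rng.integers(2**31)),
                          catalog=catalog)
    corpus = build_corpus(split.train.positives(), catalog)
    embeddings = train_embeddings(
        corpus, dim=dim, window=window, epochs=epochs,
        seed=int(rng.integers(2**31)),
    )
    weights = build_ddi_weights(split.train.positives(), catalog)

    X_tr, y_tr, k_tr = featurize(split.train.records, catalog, embeddings, weights)
    X_val, y_val, k_val = featurize(split.validation.records, catalog, embeddings, weights)
    X_te, y_te, k_te = featurize(split.test.records, catalog, embeddings, weights)

    grid = tree_grid or DEFAULT_TREE_GRID
    rules = feature_rules or DEFAULT_FEATURE_RULES
    forest_seed = int(rng.integers(2**31))
    if skip_grid_search:
        config = ClassifierConfig(n_trees=grid[0], max_features_rule=rules[0],
                                  seed=forest_seed)
    else:
        config = grid_search((X_tr, y_tr), (X_val, y_val), grid, rules,
                             seed=forest_seed)
    model = fit_forest(X_tr, y_tr, config)
    threshold = tune_threshold(
        TrainedClassifier(model, config).predict_proba(X_val), y_val,
        metric=dt_metric,
    )
    classifier, report = retrain_and_test(
        (np.vstack([X_tr, X_val]), np.concatenate([y_tr, y_val])),
        (X_te, y_te),
        config, threshold,
        merged_keys=k_tr + k_val, test_keys=k_te,
    )
    logger.info("test evaluation: %s", report.as_dict())
    return TrainingResult(
        split=split, embeddings=embeddings, weights=weights, config=config,
        decision_threshold=threshold, classifier=classifier, report=report,
    )


def predict_network(
    result: TrainingResult,
    catalog: ProteinCatalog,
    cutoff: float = 0.99,
    batch_size: int = 2048,
) -> InteractionNetwork:
    """Score all host x bacterial pairs and keep the high-confidence edges."""
    scored = score_all_pairs(
        catalog.humans(), catalog.bacteria(), result.classifier,
        result.embeddings, result.weights, batch_size=batch_size,
    )
    return build_network(scored, catalog, cutoff=cutoff)
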