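"""Construction of the labeled learning dataset.

Three steps with non-obvious rules live here:

* **DDI inference** — every positive protein pair contributes the full
  cross product of its two domain sets as candidate domain-domain
  interactions (DDIs), accumulated with multiplicity.
* **Negative sampling** — non-interacting pairs are human-human pairs
  expressed in strictly disjoint organ/tissue sets whose domain cross
  product avoids the golden-standard DDI set, and which appear neither
  among the positives nor in the known human interactome.
* **Splitting** — a random train/validation/test partition followed by a
  repair pass that moves any held-out positive whose inferred DDIs are
  not all covered by the training partition into training. The model is
  therefore never asked to rank a domain pair it could not have seen.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from ddinet.core import DDISet, PPIRecord, ProteinCatalog, pair_key

logger = logging.getLogger(__name__)


@dataclass
class LabeledDataset:
    """Positive/negative protein-pair records with provenance counts."""

    records: list[PPIRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_key: dict[tuple[str, str], str] = {}
        for r in self.records:
            if r.label not in ("positive", "negative"):
                raise ValueError(f"labeled dataset requires +/- labels, got {r.label!r}")
            prev = by_key.get(r.key)
            if prev is not None and prev != r.label:
                raise ValueError(f"pair {r.key} appears with both labels")
            by_key[r.key] = r.label

    @property
    def provenance(self) -> Counter:
        return Counter(r.source for r in self.records)

    def positives(self) -> list[PPIRecord]:
        return [r for r in self.records if r.label == "positive"]

    def negatives(self) -> list[PPIRecord]:
        return [r for r in self.records if r.label == "negative"]

    def keys(self) -> set[tuple[str, str]]:
        return {r.key for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __add__(self, other: "LabeledDataset") -> "LabeledDataset":
        return LabeledDataset(self.records + other.records)


@dataclass
class DatasetSplit:
    train: LabeledDataset
    validation: LabeledDataset
    test: LabeledDataset
    coverage_report: dict[str, DDISet] = field(default_factory=dict)


def infer_ddis(ppis: list[PPIRecord], catalog: ProteinCatalog) -> DDISet:
    """Accumulate the domain cross product of every pair into a DDI multiset.

    Each observing pair increments the count of every one of its candidate
    DDIs by one; a domain shared by both endpoints yields a self-pair.
    """
    ddis = DDISet()
    for rec in ppis:
        for pid in (rec.a, rec.b):
            if pid not in catalog or not catalog[pid].embeddable:
                raise ValueError(f"protein {pid} has no Pfam domains; cannot infer DDIs")
        for da, db in product(catalog[rec.a].pfam_ids, catalog[rec.b].pfam_ids):
            ddis.add(da, db)
    return ddis


def negative_pair_qualifies(
    a_id: str,
    b_id: str,
    catalog: ProteinCatalog,
    golden_ddis: DDISet,
    excluded_keys: set[tuple[str, str]],
) -> bool:
    """The three exclusion rules for a candidate non-interacting pair."""
    a, b = catalog[a_id], catalog[b_id]
    if not a.tissues or not b.tissues or (a.tissues & b.tissues):
        return False
    if any((da, db) in golden_ddis for da, db in product(a.pfam_ids, b.pfam_ids)):
        return False
    if pair_key(a_id, b_id) in excluded_keys:
        return False
    return True


def sample_negatives(
    catalog: ProteinCatalog,
    positives: LabeledDataset,
    known_interactome: list[PPIRecord],
    golden_ddis: DDISet,
    n: int,
    seed: int,
    cross_species: bool = False,
) -> list[PPIRecord]:
    """Uniformly sample ``n`` qualifying non-interacting pairs.

    Qualifying pairs have disjoint nonempty tissue sets, no golden-standard
    DDI in their domain cross product, and are absent from both the positive
    set and the known interactome. By default only human-human pairs are
    considered, mirroring the tissue-based definition of non-interaction;
    ``cross_species=True`` widens the pool (bacterial proteins then fail the
    tissue rule unless they carry tissue labels).
    """
    rng = np.random.default_rng(seed)
    pool = [p.id for p in catalog if p.embeddable and (cross_species or p.is_human)]
    pool.sort()
    excluded = positives.keys() | {r.key for r in known_interactome}

    qualifying = [
        (a, b)
        for i, a in enumerate(pool)
        for b in pool[i + 1:]
        if negative_pair_qualifies(a, b, catalog, golden_ddis, excluded)
    ]
    if len(qualifying) < n:
        warnings.warn(
            f"only {len(qualifying)} qualifying negative pairs available "
            f"(requested {n}); returning all"
        )
        chosen = qualifying
    else:
        idx = rng.choice(len(qualifying), size=n, replace=False)
        chosen = [qualifying[i] for i in sorted(idx)]
    return [PPIRecord(a, b, label="negative", source="sampled") for a, b in chosen]


def split_dataset(
    dataset: LabeledDataset,
    fractions: tuple[float, float, float],
    seed: int,
    catalog: ProteinCatalog | None = None,
) -> DatasetSplit:
    """Random train/val/test partition with a DDI-coverage repair pass.

    After the random assignment, every validation/test *positive* whose
    inferred DDI set is not fully contained in the train-inferred DDI set
    is moved into training; the pass iterates to a fixed point (moves only
    grow the training DDI set, so convergence is guaranteed). Negatives are
    split purely at random — the coverage constraint is defined on DDIs
    inferred from interacting pairs.
    """
    if not dataset.records:
        raise ValueError("cannot split an empty dataset")
    f_train, f_val, f_test = fractions
    if any(f < 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must be nonnegative and sum to 1, got {fractions}")
    if catalog is None:
        raise ValueError("split_dataset requires the catalog to infer DDIs")

    rng = np.random.default_rng(seed)
    records = list(dataset.records)
    order = rng.permutation(len(records))
    n = len(records)
    n_train = int(round(f_train * n))
    n_val = int(round(f_val * n))
    buckets = {"train": [], "validation": [], "test": []}
    for rank, i in enumerate(order):
        if rank < n_train:
            buckets["train"].append(records[i])
        elif rank < n_train + n_val:
            buckets["validation"].append(records[i])
        else:
            buckets["test"].append(records[i])

    moved = -1
    while moved != 0:
        moved = 0
        train_ddis = infer_ddis(
            [r for r in buckets["train"] if r.label == "positive"], catalog
        )
        for part in ("validation", "test"):
            keep = []
            for rec in buckets[part]:
                if rec.label == "positive":
                    rec_ddis = infer_ddis([rec], catalog)
                    if not rec_ddis.issubset(train_ddis):
                        buckets["train"].append(rec)
                        train_ddis = train_ddis.union(rec_ddis)
                        moved += 1
                        continue
                keep.append(rec)
            buckets[part] = keep
    if moved:
        logger.info("coverage repair moved %d records to train", moved)

    for part, frac in (("validation", f_val), ("test", f_test)):
        if frac > 0 and not buckets[part]:
            raise ValueError(
                f"dataset too small to keep a nonempty {part} partition under "
                f"the DDI-coverage constraint (deficit: all {part} positives "
                f"carried uncovered DDIs)"
            )

    split = DatasetSplit(
        train=LabeledDataset(buckets["train"]),
        validation=LabeledDataset(buckets["validation"]),
        test=LabeledDataset(buckets["test"]),
    )
    split.coverage_report = {
        part: infer_ddis(
            [r for r in getattr(split, attr).records if r.label == "positive"], catalog
        )
        for part, attr in (
            ("train", "train"), ("validation", "validation"), ("test", "test"),
        )
    }
    return split
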