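"""Synthetic worlds with planted domain-interaction structure.

The generator emulates every input the pipeline reads: a protein catalog
(human proteins with tissue labels, bacterial proteins grouped into
strains), a set of *planted* domain-domain interaction rules that drive
which protein pairs interact, labeled positive/negative pair sets, a
golden-standard DDI subset, strain abundances, per-protein disorder
fractions, and a known human interactome.

Interaction model: a candidate pair that shares at least one planted DDI
in its domain cross product is a true interaction with probability beta;
any other pair interacts with background probability epsilon << beta.
Gene names follow a root+suffix scheme (e.g. "qrt" -> "qrtA", "qrtB") so
that fuzzy gene-name clustering has planted, recoverable structure.
"""

from __future__ import annotations

import hashlib
import json
import string
from dataclasses import dataclass, field
from itertools import combinations, product
from pathlib import Path

import numpy as np

from ddinet import io as dio
from ddinet.core import DDISet, PPIRecord, Protein, ProteinCatalog, pair_key
from ddinet.dataset import LabeledDataset, sample_negatives


@dataclass
class WorldConfig:
    """Study conditions of the default synthetic world.

    The defaults are the conditions under which the pipeline's recovery
    behaviour is assessed: 150 human and 5 x 40 bacterial proteins over a
    60-domain vocabulary, 5% of domain pairs planted as interaction
    rules, interaction probability beta = 0.9 given a shared planted DDI
    against epsilon = 0.02 background, and 1500 positive pairs.
    """

    n_domains: int = 60
    domains_per_protein: tuple[int, int] = (1, 4)
    n_human: int = 150
    n_strains: int = 5
    proteins_per_strain: int = 40
    n_tissues: int = 6
    planted_ddi_density: float = 0.05
    interaction_prob_given_ddi: float = 0.9
    background_noise: float = 0.02
    n_positive_ppis: int = 1500
    n_negative_ppis: int = 1500
    n_interactome_pairs: int = 300
    golden_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.interaction_prob_given_ddi <= 1.0:
            raise ValueError("interaction_prob_given_ddi must be in (0, 1]")
        if not 0.0 <= self.background_noise < self.interaction_prob_given_ddi:
            raise ValueError("background_noise must be < interaction_prob_given_ddi")
        lo, hi = self.domains_per_protein
        if lo < 1 or hi < lo:
            raise ValueError("invalid domains_per_protein range")
        for name in ("n_domains", "n_human", "n_strains", "proteins_per_strain",
                     "n_tissues", "n_positive_ppis"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class SyntheticWorld:
    config: WorldConfig
    catalog: ProteinCatalog
    planted_ddis: DDISet
    golden_ddis: DDISet
    positives: LabeledDataset
    negatives: LabeledDataset
    known_interactome: list[PPIRecord]
    abundances: dict[str, float]
    disorder: dict[str, float]
    gene_roots: dict[str, list[str]] = field(default_factory=dict)  # root -> protein ids

    def dataset(self) -> LabeledDataset:
        return self.positives + self.negatives


def _gene_roots(rng: np.random.Generator, n: int) -> list[str]:
    """Random 3-letter roots kept pairwise >= 2 edits apart, so names built
    from different roots can never reach the 0.70 fuzzy-merge similarity."""
    import edlib

    letters = list(string.ascii_lowercase)
    roots: list[str] = []
    attempts = 0
    while len(roots) < n and attempts < 10**6:
        attempts += 1
        cand = "".join(rng.choice(letters, size=3))
        if all(edlib.align(cand, r)["editDistance"] >= 2 for r in roots):
            roots.append(cand)
    if len(roots) < n:
        raise ValueError(f"could not build {n} well-separated gene roots")
    return sorted(roots)


def _shares_planted(a: Protein, b: Protein, planted: DDISet) -> bool:
    return any((da, db) in planted for da, db in product(a.pfam_ids, b.pfam_ids))


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Build a complete, reproducible synthetic world from its seed."""
    rng = np.random.default_rng(config.seed)
    domains = [f"PF{i + 1:05d}" for i in range(config.n_domains)]
    tissues = [f"tissue_{i + 1}" for i in range(config.n_tissues)]
    strains = [f"strain_{i + 1:02d}" for i in range(config.n_strains)]

    # planted DDI rules over distinct domain pairs, golden = random subset
    all_pairs = list(combinations(domains, 2))
    n_planted = max(1, round(config.planted_ddi_density * len(all_pairs)))
    planted_idx = rng.choice(len(all_pairs), size=n_planted, replace=False)
    planted = DDISet(all_pairs[i] for i in sorted(planted_idx))
    n_golden = max(1, round(config.golden_fraction * n_planted))
    golden_idx = rng.choice(n_planted, size=n_golden, replace=False)
    planted_list = sorted(planted.pairs())
    golden = DDISet(planted_list[i] for i in sorted(golden_idx))

    # proteins: shared gene-name roots plant fuzzy-cluster structure
    n_prot = config.n_human + config.n_strains * config.proteins_per_strain
    roots = _gene_roots(rng, max(1, n_prot // 3))
    suffixes = list(string.ascii_uppercase)
    root_members: dict[str, list[str]] = {r: [] for r in roots}
    lo, hi = config.domains_per_protein

    catalog = ProteinCatalog()
    root_domain: dict[str, str] = {
        r: domains[rng.integers(0, len(domains))] for r in roots
    }

    def make_protein(pid: str, organism: str, with_tissues: bool) -> Protein:
        root = roots[rng.integers(0, len(roots))]
        name = root + suffixes[len(root_members[root]) % len(suffixes)]
        root_members[root].append(pid)
        k = int(rng.integers(lo, hi + 1))
        # one domain is tied to the gene root so planted fuzzy clusters
        # share a Pfam ID; the rest are uniform over the vocabulary
        own = rng.choice(len(domains), size=k, replace=False)
        pfams = tuple(dict.fromkeys([root_domain[root]] + [domains[i] for i in own]))[:k] \
            if k > 0 else (root_domain[root],)
        tiss = frozenset()
        if with_tissues:
            n_t = int(rng.integers(1, 3))
            tiss = frozenset(tissues[i] for i in rng.choice(len(tissues), size=n_t, replace=False))
        return Protein(id=pid, organism=organism, pfam_ids=pfams,
                       gene_name=name, tissues=tiss)

    for i in range(config.n_human):
        catalog.add(make_protein(f"HP{i + 1:04d}", "human", with_tissues=True))
    b = 0
    for strain in strains:
        for _ in range(config.proteins_per_strain):
            b += 1
            catalog.add(make_protein(f"BP{b:04d}", strain, with_tissues=False))

    # positives: rejection sampling over random distinct pairs
    ids = catalog.ids
    beta = config.interaction_prob_given_ddi
    eps = config.background_noise
    chosen: dict[tuple[str, str], str] = {}
    max_attempts = 2000 * config.n_positive_ppis
    attempts = 0
    while len(chosen) < config.n_positive_ppis:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not draw {config.n_positive_ppis} positives in "
                f"{max_attempts} attempts; the planted-DDI density or noise "
                "level makes the request infeasible at this catalog size"
            )
        i, j = rng.integers(0, len(ids), size=2)
        if i == j:
            continue
        key = pair_key(ids[i], ids[j])
        if key in chosen:
            continue
        pa, pb = catalog[key[0]], catalog[key[1]]
        if _shares_planted(pa, pb, planted):
            if rng.random() < beta:
                chosen[key] = "planted"
        elif eps > 0 and rng.random() < eps:
            chosen[key] = "noise"
    positives = LabeledDataset([
        PPIRecord(a, b, label="positive", source=src)
        for (a, b), src in chosen.items()
    ])

    # known human interactome: random human-human pairs (unlabeled provenance)
    human_ids = sorted(p.id for p in catalog.humans())
    interactome: list[PPIRecord] = []
    seen = set(chosen)
    attempts = 0
    while len(interactome) < config.n_interactome_pairs and attempts < 10**6:
        attempts += 1
        i, j = rng.integers(0, len(human_ids), size=2)
        if i == j:
            continue
        key = pair_key(human_ids[i], human_ids[j])
        if key in seen:
            continue
        seen.add(key)
        interactome.append(PPIRecord(*key, label="unlabeled", source="interactome"))

    negatives = LabeledDataset(
        sample_negatives(
            catalog, positives, interactome, golden,
            n=config.n_negative_ppis,
            seed=int(rng.integers(0, 2**31)),
        )
    )

    # strain abundances: lognormal weights normalized to fractions
    weights = rng.lognormal(mean=0.0, sigma=1.0, size=len(strains))
    weights /= weights.sum()
    abundances = dict(zip(strains, map(float, weights)))

    # intrinsic disorder: ~25% of human and ~2% of bacterial proteins nonzero
    disorder: dict[str, float] = {}
    for p in catalog:
        p_nonzero = 0.25 if p.is_human else 0.02
        disorder[p.id] = float(rng.beta(2, 4)) if rng.random() < p_nonzero else 0.0

    return SyntheticWorld(
        config=config, catalog=catalog, planted_ddis=planted, golden_ddis=golden,
        positives=positives, negatives=negatives, known_interactome=interactome,
        abundances=abundances, disorder=disorder,
        gene_roots={r: m for r, m in root_members.items() if m},
    )


WORLD_FILES = {
    "catalog": "catalog.tsv",
    "ppis": "ppis.tsv",
    "golden_ddis": "golden_ddis.tsv",
    "interactome": "interactome.tsv",
    "abundances": "abundances.tsv",
    "disorder": "disorder.tsv",
}


def world_to_files(world: SyntheticWorld, directory: str | Path) -> dict:
    """Write every input table the pipeline consumes; return a hash manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dio.write_protein_catalog(world.catalog, directory / WORLD_FILES["catalog"])
    dio.write_ppi_table(world.dataset().records, directory / WORLD_FILES["ppis"])
    dio.write_ddi_table(world.golden_ddis, directory / WORLD_FILES["golden_ddis"])
    dio.write_ppi_table(world.known_interactome, directory / WORLD_FILES["interactome"])
    dio.write_strain_abundances(world.abundances, directory / WORLD_FILES["abundances"])
    dio.write_disorder_table(world.disorder, directory / WORLD_FILES["disorder"])

    manifest = {"files": {}}
    for key, fname in WORLD_FILES.items():
        digest = hashlib.sha256((directory / fname).read_bytes()).hexdigest()
        manifest["files"][fname] = digest
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
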