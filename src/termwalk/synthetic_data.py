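"""Seeded generators for planted-module gene-set collections.

Real curated collections are modular: groups of related terms draw their
members from shared gene pools.  The generator plants ``n_modules``
disjoint pools; each term samples ``genes_per_term`` genes from its
module's pool plus ``noise_genes_per_term`` genes from one global
background pool shared by all modules.  Within-module term pairs
therefore overlap much more than between-module pairs (whose only overlap
comes through the background), which makes module recovery from
embeddings a well-posed check.  A matching ortholog table (prefixed 1:1
aliases) and duplicated "foreign" terms drive the cross-species stages
without any download.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .gmt_io import GeneSetCollection, OrthologMap, TermRecord

__all__ = [
    "SyntheticSpec",
    "generate_collection",
    "generate_ortholog_map",
    "generate_duplicated_foreign_terms",
    "foreign_alias",
]

FOREIGN_PREFIX = "MM_"


def foreign_alias(gene: str) -> str:
    """The 'foreign species' alias of a host gene symbol."""
    return FOREIGN_PREFIX + gene


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-module generator.

    Defaults are the package's standard test scale: 4 modules of 15 terms,
    50-gene pools, 20 module genes + 3 background genes per term over a
    200-gene background — small enough for minute-scale runs while leaving
    clear within/between structure.
    """

    n_modules: int = 4
    terms_per_module: int = 15
    pool_size: int = 50
    genes_per_term: int = 20
    noise_genes_per_term: int = 3
    background_pool_size: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_modules, self.terms_per_module, self.pool_size,
               self.genes_per_term, self.background_pool_size) < 1:
            raise ValueError("all counts must be >= 1 (noise may be 0)")
        if self.noise_genes_per_term < 0:
            raise ValueError("noise_genes_per_term must be >= 0")
        if self.genes_per_term > self.pool_size:
            raise ValueError("genes_per_term cannot exceed pool_size")
        if self.noise_genes_per_term > self.background_pool_size:
            raise ValueError("noise draw exceeds background pool")


def generate_collection(
    spec: SyntheticSpec,
) -> Tuple[GeneSetCollection, Dict[str, int]]:
    """Sample a collection; returns it with hidden term -> module labels.

    The labels are for evaluation only and are never consumed by the
    pipeline itself.
    """
    rng = np.random.default_rng(spec.seed)
    pools = [
        [f"MOD{m}_G{i}" for i in range(spec.pool_size)]
        for m in range(spec.n_modules)
    ]
    background = [f"BG_G{i}" for i in range(spec.background_pool_size)]
    records: List[TermRecord] = []
    labels: Dict[str, int] = {}
    for m in range(spec.n_modules):
        pool = pools[m]
        for t in range(spec.terms_per_module):
            picked = rng.choice(len(pool), size=spec.genes_per_term,
                                replace=False)
            genes = {pool[i] for i in picked}
            if spec.noise_genes_per_term:
                noise = rng.choice(len(background),
                                   size=spec.noise_genes_per_term,
                                   replace=False)
                genes |= {background[i] for i in noise}
            term_id = f"M{m}_T{t}"
            records.append(TermRecord(term_id, f"module {m} term {t}",
                                      frozenset(genes)))
            labels[term_id] = m
    return GeneSetCollection(records, species_label="synthetic"), labels


def generate_ortholog_map(
    collection: GeneSetCollection, mapped_fraction: float, seed: int = 0
) -> OrthologMap:
    """Give a ``mapped_fraction`` subset of genes a 1:1 prefixed alias.

    Exactly ``floor(mapped_fraction * n_genes)`` genes are mapped (all of
    them at fraction 1).  The alias is ``MM_<symbol>``, emulating a
    foreign-species symbol that converts back to the host symbol.
    """
    if not (0.0 < mapped_fraction <= 1.0):
        raise ValueError("mapped_fraction must be in (0, 1]")
    genes = sorted(collection.all_genes())
    n_mapped = int(np.floor(mapped_fraction * len(genes)))
    if mapped_fraction == 1.0:
        n_mapped = len(genes)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(genes), size=n_mapped, replace=False)
    pairs = frozenset(
        (foreign_alias(genes[i]), genes[i]) for i in chosen
    )
    return OrthologMap(pairs)


def generate_duplicated_foreign_terms(
    collection: GeneSetCollection, k_terms: int, seed: int = 0
) -> GeneSetCollection:
    """Foreign terms that are exact aliased duplicates of host terms.

    Picks ``k_terms`` host terms and emits, for each, a foreign term whose
    gene set is the host set with every symbol aliased; converting through
    a full ortholog map recovers the host set exactly.  Drives the
    duplicate-recovery check of the cross-species projection.
    """
    if k_terms > len(collection):
        raise ValueError("k_terms exceeds number of terms")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(collection), size=k_terms, replace=False)
    records = [
        TermRecord(
            f"FOREIGN_{collection[i].term_id}",
            f"aliased duplicate of {collection[i].term_id}",
            frozenset(foreign_alias(g) for g in collection[i].genes),
        )
        for i in sorted(chosen)
    ]
    return GeneSetCollection(records, species_label="synthetic-foreign")
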