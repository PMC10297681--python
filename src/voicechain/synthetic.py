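"""Seeded synthetic generators and brute-force oracles.

Everything here is a pure function of its spec and seed: pathway ensembles
with tunable pairwise overlap density, terminal regions planted with known
ground-truth chainlink genes, CMP samples drawn by inverse CDF, and a
brute-force chain enumerator used as the independent oracle for the
breadth-first search.

The generated ensembles emulate the structure that matters for chain
search — gene sharing between pathways, a unique head-gene pathway by
default — not the size distribution of any real pathway collection.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .chain_search import ChainlinkReport, LevelResult
from .dispersion import CMPParams, CountSet, cmp_log_pmf
from .pathway_io import Pathway, PathwayEnsemble, TerminalSet

__all__ = [
    "EnsembleSpec",
    "generate_ensemble",
    "plant_region",
    "PlantedTruth",
    "brute_force_chainlinks",
    "sample_cmp",
]

#: Brute-force oracle refuses instances larger than this.
ORACLE_MAX_PATHWAYS = 50


@dataclass(frozen=True)
class EnsembleSpec:
    """Specification of a synthetic pathway ensemble.

    ``overlap_density`` is the probability that any given ordered pathway
    pair is forced to share at least one gene; 0 yields pairwise-disjoint
    pathways, 1 links every pair.
    """

    n_pathways: int = 20
    gene_universe_size: int = 400
    pathway_size_min: int = 5
    pathway_size_max: int = 15
    overlap_density: float = 0.1
    head_gene: str = "FOXP2"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pathways < 1 or self.gene_universe_size < 1:
            raise ValueError("sizes must be positive")
        if not 1 <= self.pathway_size_min <= self.pathway_size_max:
            raise ValueError("invalid pathway size range")
        if not 0.0 <= self.overlap_density <= 1.0:
            raise ValueError("overlap_density must be in [0, 1]")


def generate_ensemble(spec: EnsembleSpec) -> PathwayEnsemble:
    """Generate a reproducible ensemble matching the spec.

    Pathway P0 receives the head gene; every later pathway shares one
    uniformly chosen gene with each earlier pathway independently with
    probability ``overlap_density``, and is filled to its drawn size with
    previously unused universe genes. Raises if the gene universe cannot
    supply enough fresh genes.
    """
    rng = np.random.default_rng(spec.seed)
    pool = [f"G{i:05d}" for i in range(spec.gene_universe_size)]
    next_fresh = 0
    pathways: list[Pathway] = []
    gene_lists: list[list[str]] = []
    for i in range(spec.n_pathways):
        size = int(rng.integers(spec.pathway_size_min, spec.pathway_size_max + 1))
        genes: set[str] = set()
        if i == 0:
            genes.add(spec.head_gene)
        else:
            for j in range(i):
                if rng.random() < spec.overlap_density:
                    shared = gene_lists[j][int(rng.integers(len(gene_lists[j])))]
                    genes.add(shared)
        while len(genes) < size:
            if next_fresh >= len(pool):
                raise ValueError(
                    f"infeasible spec: gene universe of {spec.gene_universe_size} "
                    f"exhausted while building pathway {i}"
                )
            genes.add(pool[next_fresh])
            next_fresh += 1
        ordered = sorted(genes)
        gene_lists.append(ordered)
        pathways.append(Pathway(id=f"P{i:03d}", name=f"P{i:03d}", genes=frozenset(ordered)))
    return PathwayEnsemble.from_pathways(pathways)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth chainlink labels of a planted region (exclusive levels)."""

    level1: frozenset[str]
    level2: frozenset[str]
    background: frozenset[str]


def plant_region(
    ensemble: PathwayEnsemble,
    head_gene: str,
    n_level1: int,
    n_level2: int,
    n_background: int,
    seed: int = 0,
    name: str = "planted",
) -> tuple[TerminalSet, PlantedTruth]:
    """Plant a terminal region with known chainlink composition.

    Samples ``n_level1`` genes from head pathways, ``n_level2`` genes lying
    on head-linked pathways but not on any head pathway (exclusive-level
    truth), and ``n_background`` genes lying only on pathways that are
    neither head nor linked (hence inert up to level 2). Errors name the
    class that cannot be satisfied.
    """
    from .chain_search import head_pathways, linked_pathways  # local: avoid cycle at import

    rng = np.random.default_rng(seed)
    heads = head_pathways(ensemble, head_gene)
    if not heads:
        raise ValueError(f"head gene {head_gene!r} absent from ensemble")
    head_genes: set[str] = set()
    for pid in heads:
        head_genes |= ensemble.pathways[pid].genes
    linked_genes: set[str] = set()
    for pid in linked_pathways(ensemble, head_gene):
        linked_genes |= ensemble.pathways[pid].genes
    pools = {
        "level1": sorted(head_genes - {head_gene}),
        "level2": sorted(linked_genes - head_genes),
        "background": sorted(ensemble.genes - head_genes - linked_genes),
    }
    wanted = {"level1": n_level1, "level2": n_level2, "background": n_background}
    picks: dict[str, frozenset[str]] = {}
    for cls, n in wanted.items():
        if n > len(pools[cls]):
            raise ValueError(
                f"insufficient {cls} genes: requested {n}, ensemble offers "
                f"{len(pools[cls])}"
            )
        chosen = rng.choice(pools[cls], size=n, replace=False) if n else []
        picks[cls] = frozenset(str(g) for g in chosen)
    genes = picks["level1"] | picks["level2"] | picks["background"]
    if not genes:
        raise ValueError("planted region would be empty")
    region = TerminalSet(name=name, genes=genes)
    return region, PlantedTruth(picks["level1"], picks["level2"], picks["background"])


def brute_force_chainlinks(
    ensemble: PathwayEnsemble,
    terminal: TerminalSet,
    head_gene: str,
    max_level: int = 2,
    inclusive: bool = False,
    connectivity_mode: str = "union",
    exclude_head: bool = False,
) -> ChainlinkReport:
    """Chainlink sets by literal enumeration of all pathway chains.

    Test-only oracle: enumerates every non-repeating pathway sequence of
    length <= ``max_level`` whose head (and head alone) contains the head
    gene and whose adjacent pathways intersect, then collects the terminal
    genes each chain reaches. Independent of the breadth-first
    implementation in :mod:`voicechain.chain_search`.
    """
    if len(ensemble) > ORACLE_MAX_PATHWAYS:
        raise ValueError(
            f"oracle limited to {ORACLE_MAX_PATHWAYS} pathways, got {len(ensemble)}"
        )
    if not 1 <= max_level <= 2:
        raise ValueError("oracle supports levels 1 and 2 only")
    all_p = list(ensemble.pathways.values())
    heads = [p for p in all_p if head_gene in p.genes]
    if not heads:
        raise ValueError(f"no head pathway for {head_gene!r}")
    non_heads = [p for p in all_p if head_gene not in p.genes]

    level_sets: dict[int, set[str]] = {1: set()}
    for bv in heads:
        for g in terminal.genes:
            if g in bv.genes:
                level_sets[1].add(g)
    if max_level >= 2:
        level_sets[2] = set()
        for bv in heads:
            for b1 in non_heads:
                if not (bv.genes & b1.genes):
                    continue
                for g in terminal.genes:
                    if g in b1.genes:
                        level_sets[2].add(g)
        if not inclusive:
            level_sets[2] -= level_sets[1]

    excl = {p.id for p in heads} if exclude_head else set()
    results: dict[int, LevelResult] = {}
    counts: dict[str, int] = {}
    for lvl, genes in level_sets.items():
        if connectivity_mode == "union":
            hit = {p.id for p in all_p if p.genes & genes} - excl
            conn = len(hit)
        else:
            conn = sum(1 for p in all_p for g in genes
                       if g in p.genes and p.id not in excl)
        results[lvl] = LevelResult(genes=tuple(sorted(genes)), connectivity=conn)
        for g in genes:
            counts[g] = sum(1 for p in all_p if g in p.genes)
    return ChainlinkReport(terminal=terminal.name, levels=results,
                           per_gene_pathway_counts=counts)


def sample_cmp(params: CMPParams, n: int, seed: int = 0) -> CountSet:
    """Draw ``n`` CMP variates by inverse CDF over the truncated support."""
    if n < 1:
        raise ValueError("n must be >= 1")
    support = np.arange(0, max(params.truncation_n, 1) + 1)
    pmf = np.exp(np.asarray(cmp_log_pmf(support, params)))
    cdf = np.cumsum(pmf)
    # extend support until essentially all mass is covered
    while cdf[-1] < 1.0 - 1e-12 and len(support) < 10**6:
        extra = np.arange(support[-1] + 1, support[-1] + 1 + len(support))
        pmf_extra = np.exp(np.asarray(cmp_log_pmf(extra, params)))
        support = np.concatenate([support, extra])
        cdf = np.concatenate([cdf, cdf[-1] + np.cumsum(pmf_extra)])
    rng = np.random.default_rng(seed)
    u = rng.random(n) * cdf[-1]
    draws = support[np.searchsorted(cdf, u, side="right")]
    label = f"cmp(lam={params.lam:g},nu={params.nu:g})"
    return CountSet(label=label, values=tuple(int(d) for d in draws))
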