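"""Closed-form chance model for voice-chain occurrence.

Because the head pathway is densely linked within any realistic pathway
collection, even a small random gene set is very likely to contain a
level-2 chainlink gene. The null model assumes the genes of a region are
drawn independently and uniformly from the gene universe:

* a single random gene is a level-2 chainlink gene with probability
  ``p = n_linked_genes / n_universe``, where ``n_linked_genes`` counts the
  distinct genes on pathways linked to the head pathway(s);
* a region of ``k`` random genes then has a level-2 voice chain with
  probability ``1 - (1 - p)^k``.

In the motivating study 1205 of 4319 pathways are linked to the unique
FOXP2-containing pathway and collectively contain 11,746 genes out of a
42,764-symbol universe, giving p = 27.5% and region probabilities of 94.44%
(k = 9, the shortest region) and 99.98% (k = 26).
"""
from __future__ import annotations

from dataclasses import dataclass

from .chain_search import ChainlinkReport, head_pathways, linked_pathways
from .pathway_io import PathwayEnsemble, TerminalSet

__all__ = [
    "HGNC_UNIVERSE_SIZE",
    "ChanceInputs",
    "per_gene_probability",
    "region_chain_probability",
    "linked_gene_census",
    "chain_fraction",
]

#: Default gene-symbol universe: the HGNC human-genome symbol count used in
#: the motivating study.
HGNC_UNIVERSE_SIZE = 42_764


@dataclass(frozen=True)
class ChanceInputs:
    """Census inputs for the chance model."""

    n_linked_genes: int
    n_universe: int
    n_linked_pathways: int | None = None

    def __post_init__(self) -> None:
        if self.n_universe <= 0:
            raise ValueError("universe size must be positive")
        if not 0 <= self.n_linked_genes <= self.n_universe:
            raise ValueError(
                f"n_linked_genes={self.n_linked_genes} outside "
                f"[0, n_universe={self.n_universe}]"
            )


def per_gene_probability(inputs: ChanceInputs) -> float:
    """Probability that one random gene is a level-2 chainlink gene."""
    return inputs.n_linked_genes / inputs.n_universe


def region_chain_probability(p: float, k: int) -> float:
    """Probability that a k-gene random region has at least one level-2 chain.

    Independence across genes gives ``1 - (1 - p)^k``; monotone
    non-decreasing in both arguments.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p={p} is not a probability")
    if k < 0:
        raise ValueError("region size must be non-negative")
    return 1.0 - (1.0 - p) ** k


def linked_gene_census(
    ensemble: PathwayEnsemble,
    head_gene: str,
    universe_size: int = HGNC_UNIVERSE_SIZE,
    include_head_genes: bool = False,
) -> ChanceInputs:
    """Count pathways linked to the head pathway(s) and their distinct genes.

    Head pathways themselves are excluded from the linked-pathway count. By
    default the gene census is the union of genes over linked pathways only;
    genes occurring solely in head pathways are level-1 (not level-2)
    material and are excluded unless ``include_head_genes`` is set.
    """
    heads = head_pathways(ensemble, head_gene)
    if not heads:
        raise ValueError(f"head gene {head_gene!r} absent from the ensemble")
    linked = linked_pathways(ensemble, head_gene)
    genes: set[str] = set()
    for pid in linked:
        genes |= ensemble.pathways[pid].genes
    if include_head_genes:
        for pid in heads:
            genes |= ensemble.pathways[pid].genes
    return ChanceInputs(
        n_linked_genes=len(genes),
        n_universe=universe_size,
        n_linked_pathways=len(linked),
    )


def chain_fraction(report: ChainlinkReport, region: TerminalSet) -> float:
    """Fraction of a region's genes that appear in any voice chain."""
    if not region.genes:
        raise ValueError(f"region {region.name!r} is empty")
    return len(report.all_chainlink_genes) / len(region.genes)
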