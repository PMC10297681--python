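"""Voice-chain search over a pathway-overlap graph.

A *pathway chain* is a non-repeating sequence of pathways in which every
adjacent pair shares at least one gene. A *voice chain* is a pathway chain
whose head node — and the head node alone — contains a designated
voice-related gene (FOXP2 in the motivating study) and whose terminus is a
terminal gene set ``S`` (e.g. a microdeletion region). The chain's *level*
is the number of pathway nodes, the terminus excluded.

The genes of ``S`` through which level-``a`` chains reach it form the
chainlink set ``V^a``:

* level 1 — genes of ``S`` lying directly on a head pathway;
* level 2 — genes of ``S`` lying on a non-head pathway that shares at least
  one gene with a head pathway.

Levels deeper than 2 are rejected: at greater lengths the chained influences
can no longer be disambiguated, and overlap density makes chains ubiquitous.

Under the default *exclusive* convention a level-1 gene is not re-reported
at level 2 (the two levels partition the chainlink genes); the *inclusive*
convention reports each level independently.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .pathway_io import PathwayEnsemble, TerminalSet

__all__ = [
    "MAX_CHAIN_LEVEL",
    "NoHeadPathwayError",
    "VoiceChain",
    "LevelResult",
    "ChainlinkReport",
    "head_pathways",
    "linked_pathways",
    "connectivity",
    "find_chainlinks",
    "chain_witnesses",
]

#: Hard cap on chain level.
MAX_CHAIN_LEVEL = 2


class NoHeadPathwayError(ValueError):
    """The head gene is not a member of any ensemble pathway."""


@dataclass(frozen=True)
class VoiceChain:
    """One witness chain: head pathway, optional intermediates, terminal name."""

    head_pathway: str
    intermediates: tuple[str, ...]
    terminal: str

    @property
    def level(self) -> int:
        return 1 + len(self.intermediates)


@dataclass(frozen=True)
class LevelResult:
    """Chainlink genes and their collective pathway connectivity at one level."""

    genes: tuple[str, ...]
    connectivity: int


@dataclass(frozen=True)
class ChainlinkReport:
    """Per-level chainlink sets for one terminal set.

    ``per_gene_pathway_counts`` maps every chainlink gene to the number of
    ensemble pathways containing it.
    """

    terminal: str
    levels: dict[int, LevelResult]
    per_gene_pathway_counts: dict[str, int]

    def genes(self, level: int) -> tuple[str, ...]:
        return self.levels[level].genes

    def count(self, level: int) -> int:
        return len(self.levels[level].genes)

    def connectivity(self, level: int) -> int:
        return self.levels[level].connectivity

    @property
    def all_chainlink_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for res in self.levels.values():
            out.update(res.genes)
        return frozenset(out)


def head_pathways(ensemble: PathwayEnsemble, head_gene: str) -> frozenset[str]:
    """Ids of the pathways containing the head gene (may be empty)."""
    return ensemble.pathways_containing(head_gene)


def linked_pathways(ensemble: PathwayEnsemble, head_gene: str) -> frozenset[str]:
    """Non-head pathways sharing at least one gene with some head pathway."""
    heads = head_pathways(ensemble, head_gene)
    linked: set[str] = set()
    for hid in heads:
        for g in ensemble.pathways[hid].genes:
            linked.update(ensemble.pathways_containing(g))
    return frozenset(linked - heads)


def connectivity(
    ensemble: PathwayEnsemble,
    genes: frozenset[str] | set[str] | tuple[str, ...],
    mode: Literal["union", "sum"] = "union",
    exclude: frozenset[str] = frozenset(),
) -> int:
    """Number of ensemble pathways that include the given genes.

    ``union`` (default) counts the distinct pathways containing at least one
    of the genes — the pathways the genes *collectively* influence; ``sum``
    adds the per-gene pathway counts. Head pathways are counted unless their
    ids are passed in ``exclude``.
    """
    if mode not in ("union", "sum"):
        raise ValueError(f"unknown connectivity mode {mode!r}")
    if mode == "union":
        hit: set[str] = set()
        for g in genes:
            hit.update(ensemble.pathways_containing(g))
        return len(hit - exclude)
    return sum(len(ensemble.pathways_containing(g) - exclude) for g in genes)


def find_chainlinks(
    ensemble: PathwayEnsemble,
    terminal: TerminalSet,
    head_gene: str,
    max_level: int = MAX_CHAIN_LEVEL,
    inclusive: bool = False,
    connectivity_mode: Literal["union", "sum"] = "union",
    exclude_head: bool = False,
) -> ChainlinkReport:
    """Breadth-first extraction of the level-1 and level-2 chainlink sets.

    Parameters
    ----------
    inclusive:
        If True, a level-1 gene may also appear at level 2; by default the
        levels are exclusive.
    connectivity_mode, exclude_head:
        Passed through to :func:`connectivity` for the per-level numbers.
    """
    if not 1 <= max_level <= MAX_CHAIN_LEVEL:
        raise ValueError(
            f"max_level must be in 1..{MAX_CHAIN_LEVEL}: deeper chains are not "
            "supported because chained influences cannot be disambiguated "
            "beyond two pathway hops"
        )
    if not terminal.genes:
        raise ValueError(f"terminal set {terminal.name!r} is empty")
    heads = head_pathways(ensemble, head_gene)
    if not heads:
        raise NoHeadPathwayError(
            f"no head pathway: gene {head_gene!r} is absent from the ensemble"
        )

    head_genes: set[str] = set()
    for hid in heads:
        head_genes |= ensemble.pathways[hid].genes
    level1 = frozenset(terminal.genes & head_genes)

    levels: dict[int, frozenset[str]] = {1: level1}
    if max_level >= 2:
        linked_genes: set[str] = set()
        for pid in linked_pathways(ensemble, head_gene):
            linked_genes |= ensemble.pathways[pid].genes
        level2 = terminal.genes & linked_genes
        if not inclusive:
            level2 -= level1
        levels[2] = frozenset(level2)

    excl = heads if exclude_head else frozenset()
    results: dict[int, LevelResult] = {}
    counts: dict[str, int] = {}
    for lvl, genes in levels.items():
        conn = connectivity(ensemble, genes, mode=connectivity_mode, exclude=excl)
        results[lvl] = LevelResult(genes=tuple(sorted(genes)), connectivity=conn)
        for g in genes:
            counts[g] = len(ensemble.pathways_containing(g))
    return ChainlinkReport(terminal=terminal.name, levels=results,
                           per_gene_pathway_counts=counts)


def chain_witnesses(
    ensemble: PathwayEnsemble,
    terminal: TerminalSet,
    head_gene: str,
    gene: str,
    level: int,
) -> list[VoiceChain]:
    """All distinct voice chains of the given level passing through ``gene``.

    Level 1: one chain per head pathway containing the gene. Level 2: one
    chain per (head, intermediate) pair where the intermediate is a non-head
    pathway containing the gene and sharing a gene with the head. Returns an
    empty list when the gene is not a chainlink gene at that level. Ordered
    by (head id, intermediate id).
    """
    if not 1 <= level <= MAX_CHAIN_LEVEL:
        raise ValueError(f"level must be in 1..{MAX_CHAIN_LEVEL}")
    if gene not in terminal.genes:
        return []
    heads = head_pathways(ensemble, head_gene)
    chains: list[VoiceChain] = []
    if level == 1:
        for hid in sorted(heads & ensemble.pathways_containing(gene)):
            chains.append(VoiceChain(hid, (), terminal.name))
        return chains
    for mid in sorted(ensemble.pathways_containing(gene) - heads):
        mid_genes = ensemble.pathways[mid].genes
        for hid in sorted(heads):
            if ensemble.pathways[hid].genes & mid_genes:
                chains.append(VoiceChain(hid, (mid,), terminal.name))
    chains.sort(key=lambda c: (c.head_pathway, c.intermediates))
    return chains
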