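"""Voice-chain extraction: definitions, conventions, connectivity, witnesses."""
import numpy as np
import pytest

from voicechain import (
    EnsembleSpec,
    NoHeadPathwayError,
    TerminalSet,
    chain_witnesses,
    connectivity,
    find_chainlinks,
    generate_ensemble,
    head_pathways,
)
from voicechain.chain_search import linked_pathways
from voicechain.pathway_io import Pathway, PathwayEnsemble

from conftest import make_ensemble


class TestHeadPathways:
    def test_acc_fixture_single_head(self, acc_ensemble):
        assert head_pathways(acc_ensemble, "FOXP2") == {"ACC"}

    def test_absent_head_gene_is_empty(self, acc_ensemble):
        assert head_pathways(acc_ensemble, "NOSUCH") == frozenset()

    def test_membership_scan(self):
        ens = make_ensemble({"FOXP2", "A"}, {"B"}, {"FOXP2", "C"},
                            {"D"}, {"FOXP2"})
        assert head_pathways(ens, "FOXP2") == {"B0", "B2", "B4"}


class TestFindChainlinks:
    def test_level2_through_linked_pathway(self, two_hop_ensemble, region):
        rep = find_chainlinks(two_hop_ensemble, region({"G1", "G3"}), "FOXP2")
        assert rep.genes(1) == ()
        assert rep.genes(2) == ("G3",)

    def test_level1_same_pathway(self, region):
        ens = make_ensemble({"FOXP2", "G1"})
        rep = find_chainlinks(ens, region({"G1"}), "FOXP2")
        assert rep.genes(1) == ("G1",)
        assert rep.genes(2) == ()

    def test_disjoint_region_all_empty(self, two_hop_ensemble, region):
        rep = find_chainlinks(two_hop_ensemble, region({"X", "Y"}), "FOXP2")
        assert rep.genes(1) == () and rep.genes(2) == ()
        assert rep.connectivity(1) == 0 and rep.connectivity(2) == 0

    def test_exclusive_vs_inclusive_levels(self, region):
        # G2 is on the head pathway AND on a linked pathway
        ens = make_ensemble({"FOXP2", "G2"}, {"G2", "G3"})
        excl = find_chainlinks(ens, region({"G2"}), "FOXP2")
        incl = find_chainlinks(ens, region({"G2"}), "FOXP2", inclusive=True)
        assert excl.genes(1) == ("G2",) and excl.genes(2) == ()
        assert incl.genes(1) == ("G2",) and incl.genes(2) == ("G2",)

    def test_no_head_pathway_error(self, two_hop_ensemble, region):
        with pytest.raises(NoHeadPathwayError):
            find_chainlinks(two_hop_ensemble, region({"G3"}), "NOSUCH")

    def test_level_cap(self, two_hop_ensemble, region):
        with pytest.raises(ValueError, match="max_level"):
            find_chainlinks(two_hop_ensemble, region({"G3"}), "FOXP2", max_level=3)

    def test_level1_characterization(self, dense_ensemble):
        """V^1 is exactly S intersected with the union of head pathways."""
        rng = np.random.default_rng(42)
        genes = sorted(dense_ensemble.genes)
        head_genes = set()
        for pid in head_pathways(dense_ensemble, "FOXP2"):
            head_genes |= dense_ensemble.pathways[pid].genes
        for _ in range(25):
            s = frozenset(str(g) for g in rng.choice(genes, size=8, replace=False))
            rep = find_chainlinks(dense_ensemble, TerminalSet("s", s), "FOXP2")
            assert set(rep.genes(1)) == s & head_genes

    def test_monotone_under_pathway_addition(self, region):
        """Adding a pathway never shrinks the inclusive chainlink union."""
        rng = np.random.default_rng(7)
        base = generate_ensemble(EnsembleSpec(
            n_pathways=10, gene_universe_size=200, overlap_density=0.3, seed=3))
        genes = sorted(base.genes)
        s = region(set(str(g) for g in rng.choice(genes, size=10, replace=False)))
        before = find_chainlinks(base, s, "FOXP2", inclusive=True)
        for extra_genes in ({"G00000", "G00003"}, {"FOXP2", "G00050"}, {"ZZZ"}):
            bigger = PathwayEnsemble.from_pathways(
                list(base) + [Pathway("EXTRA", "EXTRA", frozenset(extra_genes))])
            after = find_chainlinks(bigger, s, "FOXP2", inclusive=True)
            assert set(before.genes(1)) | set(before.genes(2)) <= \
                set(after.genes(1)) | set(after.genes(2))


class TestConnectivity:
    def test_empty_gene_set_is_zero(self, acc_ensemble):
        assert connectivity(acc_ensemble, frozenset()) == 0

    def test_union_vs_sum(self):
        # two genes appearing in the same 3 pathways
        ens = make_ensemble({"A", "B"}, {"A", "B"}, {"A", "B"}, {"C"})
        assert connectivity(ens, {"A", "B"}, mode="union") == 3
        assert connectivity(ens, {"A", "B"}, mode="sum") == 6

    def test_single_gene_membership_scan(self):
        ens = make_ensemble({"A"}, {"A"}, {"A"}, {"A"}, {"A"}, {"B"}, {"C"})
        assert connectivity(ens, {"A"}, mode="union") == 5

    def test_exclude_pathways(self):
        ens = make_ensemble({"FOXP2", "A"}, {"A", "B"})
        assert connectivity(ens, {"A"}, exclude=frozenset({"B0"})) == 1

    def test_bounds(self, dense_ensemble):
        rng = np.random.default_rng(0)
        genes = set(str(g) for g in rng.choice(sorted(dense_ensemble.genes),
                                               size=12, replace=False))
        u = connectivity(dense_ensemble, genes, mode="union")
        s = connectivity(dense_ensemble, genes, mode="sum")
        assert u <= s <= len(genes) * len(dense_ensemble)

    def test_bad_mode(self, acc_ensemble):
        with pytest.raises(ValueError):
            connectivity(acc_ensemble, {"TP53"}, mode="max")


class TestChainWitnesses:
    def test_level1_one_chain_per_head(self, region):
        ens = make_ensemble({"FOXP2", "G"}, {"FOXP2", "G"}, {"X"})
        chains = chain_witnesses(ens, region({"G"}), "FOXP2", "G", level=1)
        assert [(c.head_pathway, c.intermediates) for c in chains] == \
            [("B0", ()), ("B1", ())]
        assert all(c.level == 1 for c in chains)

    def test_fig_2c_topology_single_level1_chain(self, region):
        ens = make_ensemble({"FOXP2", "G1"}, {"G1", "G3"})
        chains = chain_witnesses(ens, region({"G1"}), "FOXP2", "G1", level=1)
        assert len(chains) == 1 and chains[0].head_pathway == "B0"

    def test_level2_head_intermediate_pairs(self, two_hop_ensemble, region):
        chains = chain_witnesses(two_hop_ensemble, region({"G3"}), "FOXP2",
                                 "G3", level=2)
        assert [(c.head_pathway, c.intermediates) for c in chains] == [("B0", ("B1",))]
        assert chains[0].level == 2

    def test_non_chainlink_gene_empty(self, two_hop_ensemble, region):
        assert chain_witnesses(two_hop_ensemble, region({"X"}), "FOXP2",
                               "X", level=1) == []


def test_linked_pathways_excludes_heads():
    ens = make_ensemble({"FOXP2", "A"}, {"A", "B"}, {"C"}, {"FOXP2", "C"})
    assert linked_pathways(ens, "FOXP2") == {"B1", "B2"}
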