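"""LCA taxonomy, peptide-taxon index, GO slims, and group statistics."""

import math
from collections import Counter

import numpy as np
import pytest

from conftest import lca_oracle, random_tree
from protsip.digestion import DigestionParams
from protsip.taxonomy import (
    GoOntology,
    GroupedRia,
    PeptideAssignment,
    TaxonNode,
    TaxonomyTree,
    assign_peptide,
    build_index,
    collapse_il,
    compare_groups,
    goslim_rollup,
    group_filter,
    significance_stars,
    summarize_taxa,
)


class TestLca:
    def test_singleton(self, toy_tree):
        assert toy_tree.lca({"ecoli"}) == "ecoli"

    def test_sister_species_resolve_to_family(self, toy_tree):
        # the two enteric species are the only members of their family
        assert toy_tree.lca({"ecoli", "senterica"}) == "enterobacteriaceae"

    def test_cross_phylum_resolves_to_domain(self, toy_tree):
        assert toy_tree.lca({"ecoli", "lacidophilus"}) == "root"

    def test_empty_set_is_unassigned(self, toy_tree):
        assert toy_tree.lca(set()) is None

    def test_unknown_taxon_rejected(self, toy_tree):
        with pytest.raises(KeyError):
            toy_tree.lca({"ecoli", "nope"})

    def test_agrees_with_root_path_intersection_oracle(self):
        tree = random_tree(n_nodes=200, seed=4)
        ids = list(tree.nodes)
        rng = np.random.default_rng(99)
        for _ in range(1000):
            k = int(rng.integers(1, 6))
            subset = [ids[i] for i in rng.integers(0, len(ids), size=k)]
            assert tree.lca(subset) == lca_oracle(tree, subset)


class TestTreeStructure:
    def test_two_roots_rejected(self):
        with pytest.raises(ValueError, match="root"):
            TaxonomyTree(
                [
                    TaxonNode("a", "a", "domain", None),
                    TaxonNode("b", "b", "domain", None),
                ]
            )

    def test_rank_order_enforced(self):
        with pytest.raises(ValueError, match="rank"):
            TaxonomyTree(
                [
                    TaxonNode("r", "r", "species", None),
                    TaxonNode("c", "c", "domain", "r"),
                ]
            )

    def test_ancestor_at_rank(self, toy_tree):
        assert toy_tree.ancestor_at_rank("ecoli", "family") == "enterobacteriaceae"
        assert toy_tree.ancestor_at_rank("enterobacteriaceae", "species") is None

    def test_lineage_runs_domain_to_species(self, toy_tree):
        ranks = [r for r, _ in toy_tree.lineage("ecoli")]
        assert ranks == ["domain", "phylum", "class", "order", "family", "genus", "species"]


PROTEINS = [
    # shared peptide between the sister species plus species-specific ones
    ("eco1", "ecoli", "MAAAGGGELVISKSHAREDPEPK"),
    ("sen1", "senterica", "MTTTGGGWLVISKSHAREDPEPK"),
    ("lac1", "lacidophilus", "MYYYYYKFFFFFFK"),
]
GO = {"eco1": ["GO:1"], "sen1": ["GO:1", "GO:2"], "lac1": ["GO:3"]}


@pytest.fixture
def index(toy_tree):
    return build_index(
        PROTEINS,
        toy_tree,
        go_annotations=GO,
        digestion=DigestionParams(missed_cleavages=1, min_length=5, max_length=50),
    )


class TestIndex:
    def test_shared_peptide_maps_to_both_taxa(self, index):
        assert index.taxa[collapse_il("SHAREDPEPK")] == {"ecoli", "senterica"}

    def test_il_collapse_key(self, index, toy_tree):
        taxon_i, _ = assign_peptide("MAAAGGGELVISK", index, toy_tree)
        taxon_l, _ = assign_peptide("MAAAGGGELVLSK", index, toy_tree)
        assert taxon_l == taxon_i == "ecoli"

    def test_missing_taxon_id_rejected(self, toy_tree):
        with pytest.raises(ValueError):
            build_index([("x", "", "MKKK")], toy_tree)
        with pytest.raises(KeyError):
            build_index([("x", "unknown", "MKKK")], toy_tree)

    def test_go_terms_propagate_to_peptides(self, index, toy_tree):
        _, go = assign_peptide("SHAREDPEPK", index, toy_tree)
        assert go["GO:1"] == 2
        assert go["GO:2"] == 1


class TestAssignPeptide:
    def test_species_specific_peptide(self, index, toy_tree):
        taxon, _ = assign_peptide("MAAAGGGELVISK", index, toy_tree)
        assert taxon == "ecoli"

    def test_replacing_i_with_l_never_changes_assignment(self, index, toy_tree):
        pep = "MAAAGGGELVISK"
        base, _ = assign_peptide(pep, index, toy_tree)
        variant, _ = assign_peptide(pep.replace("I", "L"), index, toy_tree)
        assert base == variant

    def test_missed_cleavage_split_resolves(self, index, toy_tree):
        # both tryptic halves map only to E. coli's protein
        pep = "MAAAGGGELVISKSHAREDPEPK"
        taxon, _ = assign_peptide(pep, index, toy_tree)
        assert taxon == "ecoli"

    def test_absent_peptide_unassigned(self, index, toy_tree):
        taxon, go = assign_peptide("WWWWWWWWK", index, toy_tree)
        assert taxon is None
        assert not go


class TestGoSlim:
    @pytest.fixture
    def ontology(self):
        #      top
        #     /   \
        #   s1     s2      (slim terms)
        #   |     /  \
        #   a    b    c     ; d is child of both s1 and s2
        parents = {
            "top": set(),
            "s1": {"top"},
            "s2": {"top"},
            "a": {"s1"},
            "b": {"s2"},
            "c": {"s2"},
            "d": {"s1", "s2"},
            "orphan": {"top"},
        }
        return GoOntology(parents, slim={"s1", "s2"})

    def test_slim_term_maps_to_itself(self, ontology):
        assert goslim_rollup(["s1"], ontology) == Counter({"s1": 1})

    def test_single_slim_ancestor(self, ontology):
        assert goslim_rollup(["a"], ontology) == Counter({"s1": 1})

    def test_two_slim_ancestors_give_multiset(self, ontology):
        assert goslim_rollup(["d"], ontology) == Counter({"s1": 1, "s2": 1})

    def test_no_slim_ancestor_dropped(self, ontology):
        assert goslim_rollup(["orphan"], ontology) == Counter()

    def test_unknown_term_skipped(self, ontology):
        assert goslim_rollup(["GO:404"], ontology) == Counter()

    def test_never_emits_non_slim_and_idempotent(self, ontology):
        rolled = goslim_rollup(["a", "b", "c", "d"], ontology)
        assert set(rolled) <= ontology.slim
        again = goslim_rollup(list(rolled.elements()), ontology)
        assert again == rolled

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            GoOntology({"a": {"b"}, "b": {"a"}}, slim=set())

    def test_load_from_obo_file(self, tmp_path):
        obo = tmp_path / "mini.obo"
        obo.write_text(
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:0008150\nname: biological_process\n\n"
            "[Term]\nid: GO:0008152\nname: metabolic process\n"
            "is_a: GO:0008150 ! biological_process\n\n"
            "[Term]\nid: GO:0005975\nname: carbohydrate metabolic process\n"
            "is_a: GO:0008152 ! metabolic process\n"
        )
        ontology = GoOntology.from_obo(obo, slim={"GO:0008152"})
        assert goslim_rollup(["GO:0005975"], ontology) == Counter({"GO:0008152": 1})


class TestHelpers:
    def test_benjamini_hochberg_monotone_and_bounded(self):
        from protsip.taxonomy import adjust_pvalues

        raw = [0.001, 0.01, 0.02, 0.5]
        adjusted = adjust_pvalues(raw)
        assert all(a >= r for a, r in zip(adjusted, raw))
        assert all(0 <= a <= 1 for a in adjusted)
        assert adjust_pvalues([]) == []

    def test_unipept_csv_adapter(self, tmp_path):
        from protsip.taxonomy import read_unipept_csv

        path = tmp_path / "unipept.csv"
        path.write_text(
            "peptide,lca,phylum,species\n"
            "ELVISLIVESK,Escherichia coli,Pseudomonadota,Escherichia coli\n"
        )
        df = read_unipept_csv(path)
        assert list(df.columns) == ["peptide", "lca", "phylum", "species"]
        assert df.iloc[0].lca == "Escherichia coli"
        bad = tmp_path / "bad.csv"
        bad.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError):
            read_unipept_csv(bad)


class TestGroupFilter:
    def _group(self, n, counts=None):
        return GroupedRia("taxon", "cond", [5.0] * n, counts or [])

    def test_small_group_dropped(self):
        assert group_filter([self._group(2)], min_peptides=3) == []

    def test_group_at_threshold_kept(self):
        assert len(group_filter([self._group(3)], min_peptides=3)) == 1

    def test_min_one_is_identity(self):
        groups = [self._group(1), self._group(2)]
        assert len(group_filter(groups, min_peptides=1)) == 2

    def test_min_samples_applies_per_peptide(self):
        g = GroupedRia("t", "c", [5.0, 6.0, 7.0], [1, 2, 3])
        out = group_filter([g], min_peptides=2, min_samples=2)
        assert out[0].values == [6.0, 7.0]


class TestCompareGroups:
    def test_identical_groups(self):
        a = GroupedRia("x", "c1", [1.0, 2.0, 3.0])
        b = GroupedRia("x", "c2", [1.0, 2.0, 3.0])
        res = compare_groups(a, b)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.stars == ""

    def test_separated_groups_highly_significant(self):
        rng = np.random.default_rng(7)
        a = GroupedRia("x", "c1", list(np.clip(rng.normal(1.07, 0.5, 30), 0, 100)))
        b = GroupedRia("x", "c2", list(np.clip(rng.normal(50, 0.5, 30), 0, 100)))
        res = compare_groups(a, b)
        assert res.p_value < 0.001
        assert res.stars == "***"

    def test_matches_closed_form_pooled_t(self):
        a = GroupedRia("x", "c1", [1.0, 2.0, 4.0, 3.0])
        b = GroupedRia("x", "c2", [2.0, 5.0, 6.0, 7.0])
        res = compare_groups(a, b)
        na, nb = 4, 4
        ma, mb = np.mean(a.values), np.mean(b.values)
        sp2 = (
            (na - 1) * np.var(a.values, ddof=1) + (nb - 1) * np.var(b.values, ddof=1)
        ) / (na + nb - 2)
        t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
        assert res.statistic == pytest.approx(t)

    def test_undefined_for_tiny_or_degenerate_groups(self):
        a = GroupedRia("x", "c1", [1.0])
        b = GroupedRia("x", "c2", [1.0, 2.0])
        assert not compare_groups(a, b).valid
        c = GroupedRia("x", "c1", [1.0, 1.0])
        d = GroupedRia("x", "c2", [2.0, 2.0])
        assert not compare_groups(c, d).valid

    def test_star_thresholds(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.0009) == "***"
        assert significance_stars(0.06) == ""


class TestSummarizeTaxa:
    def _assignments(self):
        return [
            PeptideAssignment("p1", "ecoli", 8.0, True),
            PeptideAssignment("p2", "ecoli", 9.0, True),
            PeptideAssignment("p3", "ecoli", 10.0, False),
            PeptideAssignment("p4", "enterobacteriaceae", 1.07, False),
            PeptideAssignment("p5", "senterica", 1.1, False),
            PeptideAssignment("p6", None, 5.0, True),
        ]

    def test_species_rollup(self, toy_tree):
        table = summarize_taxa(self._assignments(), toy_tree, "species")
        ecoli = table[table.taxon_id == "ecoli"].iloc[0]
        assert ecoli.n_peptides == 3
        assert ecoli.median_ria == pytest.approx(9.0)
        assert ecoli.labeled_count == 2
        # family-level peptide excluded from the species table
        assert "enterobacteriaceae" not in set(table.taxon_id)

    def test_family_rollup_includes_shallow_lca(self, toy_tree):
        table = summarize_taxa(self._assignments(), toy_tree, "family")
        fam = table[table.taxon_id == "enterobacteriaceae"].iloc[0]
        assert fam.n_peptides == 5  # 3 ecoli + 1 family-level + 1 senterica

    def test_counts_match_brute_force_rollup(self, toy_tree):
        # oracle: count assignments whose root path passes each rank node
        assignments = self._assignments()
        for rank in ("species", "genus", "family", "order"):
            table = summarize_taxa(assignments, toy_tree, rank)
            for _, row in table.iterrows():
                expected = sum(
                    1
                    for a in assignments
                    if a.taxon is not None
                    and row.taxon_id in toy_tree.path_to_root(a.taxon)
                )
                assert row.n_peptides == expected

    def test_unknown_rank_rejected(self, toy_tree):
        with pytest.raises(ValueError):
            summarize_taxa([], toy_tree, "tribe")
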