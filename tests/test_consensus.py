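"""Set arithmetic: overlaps, ortholog translation, k-of-n consensus, categories."""

import numpy as np
import pandas as pd
import pytest

from sensome import (
    ConfigError,
    ValidationError,
    categorize,
    core_sensome,
    ligand_group_profile,
    map_orthologs,
    overlap,
    shared_ligand_groups,
)
from sensome.io import OrthologMap

from conftest import make_annotation, make_set


def symbols(prefix, n, start=0):
    return [f"{prefix}{i:03d}" for i in range(start, start + n)]


class TestOverlap:
    def test_two_hundred_gene_sets_sharing_73_give_union_127(self):
        shared = symbols("S", 73)
        a = make_set(shared + symbols("A", 27), label="a", target_size=100)
        b = make_set(shared + symbols("B", 27), label="b", target_size=100)
        res = overlap(a, b)
        assert len(res.intersection) == 73
        assert len(res.union) == 127
        assert res.percent_overlap == pytest.approx(73.0)

    def test_identical_sets_overlap_completely(self):
        a = make_set(symbols("G", 50))
        b = make_set(symbols("G", 50), label="other")
        res = overlap(a, b)
        assert res.percent_overlap == pytest.approx(100.0)
        assert res.union == a.genes

    def test_disjoint_sets_do_not_overlap(self):
        res = overlap(make_set(symbols("A", 100)), make_set(symbols("B", 100)))
        assert res.percent_overlap == 0.0
        assert len(res.union) == 200

    def test_symmetric_in_its_arguments(self):
        rng = np.random.default_rng(59)
        universe = symbols("U", 300)
        a = make_set(list(rng.choice(universe, 100, replace=False)))
        b = make_set(list(rng.choice(universe, 100, replace=False)), label="b")
        ab, ba = overlap(a, b), overlap(b, a)
        assert {g.casefold() for g in ab.intersection} == {g.casefold() for g in ba.intersection}
        assert {g.casefold() for g in ab.union} == {g.casefold() for g in ba.union}
        assert ab.percent_overlap == ba.percent_overlap

    def test_case_insensitive_matching(self):
        a = make_set(["Trem2", "Cx3cr1"], species="mouse")
        b = make_set(["TREM2", "P2RY12"], species="human")
        res = overlap(a, b)
        assert res.intersection == ["Trem2"]

    def test_intersection_plus_union_conserves_sizes(self):
        a = make_set(symbols("S", 40) + symbols("A", 60))
        b = make_set(symbols("S", 40) + symbols("B", 60), label="b")
        res = overlap(a, b)
        assert len(res.intersection) + len(res.union) == len(a.genes) + len(b.genes)

    def test_empty_set_rejected(self):
        import sensome.io as sio
        empty = sio.SensomeSet(species="mouse", source_label="e", genes=[],
                               target_size=0, partial=True)
        with pytest.raises(ValidationError):
            overlap(empty, make_set(["A"]))


class TestMapOrthologs:
    def test_identity_map_keeps_set_unchanged(self):
        genes = symbols("Gm", 10)
        m = OrthologMap(pairs={(g, g) for g in genes})
        out, unmapped = map_orthologs(make_set(genes), m, "mouse")
        assert out.genes == genes and unmapped == []

    def test_missing_symbol_is_reported_not_dropped_silently(self):
        genes = symbols("Gm", 5)
        m = OrthologMap(pairs={(g, g.upper()) for g in genes[:-1]})
        out, unmapped = map_orthologs(make_set(genes), m, "human")
        assert len(out.genes) == 4
        assert unmapped == [genes[-1]]

    def test_matches_naive_dictionary_translation(self):
        rng = np.random.default_rng(61)
        mouse = symbols("Mm", 40)
        human = [s.upper() for s in symbols("Hs", 40)]
        mapped_idx = rng.choice(40, 30, replace=False)
        m = OrthologMap(pairs={(mouse[i], human[i]) for i in mapped_idx})
        picked = list(rng.choice(mouse, 20, replace=False))
        out, unmapped = map_orthologs(make_set(picked), m, "human")
        naive = {mouse[i]: human[i] for i in mapped_idx}
        expected = [naive[g] for g in picked if g in naive]
        assert out.genes == expected
        assert unmapped == [g for g in picked if g not in naive]

    def test_one_to_many_expands_and_preserves_rank(self):
        m = OrthologMap(pairs={("Ga", "HA1"), ("Ga", "HA2"), ("Gb", "HB")})
        out, _ = map_orthologs(make_set(["Ga", "Gb"]), m, "human")
        assert out.genes == ["HA1", "HA2", "HB"]

    def test_many_to_one_collapses_once(self):
        m = OrthologMap(pairs={("Ga", "H"), ("Gb", "H")})
        out, _ = map_orthologs(make_set(["Ga", "Gb"]), m, "human")
        assert out.genes == ["H"]

    def test_translation_then_overlap_consistency(self):
        """Translating two sets independently then overlapping equals
        overlapping pre-translated sets."""
        mouse = symbols("Mm", 60)
        human = [f"HS{i:03d}" for i in range(60)]
        m = OrthologMap(pairs=set(zip(mouse, human)))
        rng = np.random.default_rng(67)
        a = make_set(list(rng.choice(mouse, 30, replace=False)))
        b = make_set(list(rng.choice(mouse, 30, replace=False)), label="b")
        ta, _ = map_orthologs(a, m, "human")
        tb, _ = map_orthologs(b, m, "human")
        res_native = overlap(a, b)
        res_translated = overlap(ta, tb)
        assert len(res_translated.intersection) == len(res_native.intersection)
        assert len(res_translated.union) == len(res_native.union)


class TestCoreSensome:
    def test_identical_sets_with_k_equal_n(self):
        sets = [make_set(symbols("G", 20), label=f"s{i}") for i in range(3)]
        res = core_sensome(sets, k=3)
        assert set(res.core_genes) == set(symbols("G", 20))

    def test_k_one_is_union_and_k_n_is_intersection(self):
        rng = np.random.default_rng(71)
        universe = symbols("U", 500)
        sets = [
            make_set(list(rng.choice(universe, 100, replace=False)), label=f"s{i}")
            for i in range(4)
        ]
        union = set().union(*(set(s.genes) for s in sets))
        inter = set(sets[0].genes)
        for s in sets[1:]:
            inter &= set(s.genes)
        assert set(core_sensome(sets, k=1).core_genes) == union
        assert set(core_sensome(sets, k=4).core_genes) == inter

    def test_matches_exhaustive_membership_counting(self):
        rng = np.random.default_rng(73)
        universe = symbols("U", 500)
        sets = [
            make_set(list(rng.choice(universe, 100, replace=False)), label=f"s{i}")
            for i in range(4)
        ]
        res = core_sensome(sets, k=3)
        # brute force: count per gene over the raw lists
        expected = set()
        for g in universe:
            n = sum(g in s.genes for s in sets)
            if n >= 3:
                expected.add(g)
        assert set(res.core_genes) == expected
        for g in res.table.index:
            assert res.table.at[g, "n_present"] == sum(g in s.genes for s in sets)

    def test_increasing_k_never_adds_genes(self):
        rng = np.random.default_rng(79)
        universe = symbols("U", 200)
        sets = [
            make_set(list(rng.choice(universe, 80, replace=False)), label=f"s{i}")
            for i in range(4)
        ]
        prev = None
        for k in range(1, 5):
            core = set(core_sensome(sets, k=k).core_genes)
            if prev is not None:
                assert core <= prev
            prev = core

    def test_output_ordered_by_presence_then_symbol(self):
        sets = [
            make_set(["B", "A", "C"], label="s0"),
            make_set(["A", "C", "D"], label="s1"),
        ]
        res = core_sensome(sets, k=2)
        assert list(res.table.index) == ["A", "C", "B", "D"]

    def test_invalid_k_rejected(self):
        sets = [make_set(["A"]), make_set(["A"], label="b")]
        with pytest.raises(ConfigError):
            core_sensome(sets, k=3)


class TestCategorize:
    def test_single_group_counts_all_genes(self):
        annot = make_annotation(
            {f"g{i}": (f"G{i}", {"plasma membrane"}, "verified",
                       "purinergic receptors") for i in range(5)}
        )
        summary = categorize([f"G{i}" for i in range(5)], annot)
        assert summary.group_counts == {"purinergic receptors": 5}
        assert summary.modal_group == "purinergic receptors"

    def test_counts_match_construction(self):
        groups = ["Fc receptors"] * 4 + ["cytokine receptors"] * 2 + [None]
        annot = make_annotation(
            {f"g{i}": (f"G{i}", set(), "verified", grp) for i, grp in enumerate(groups)}
        )
        summary = categorize([f"G{i}" for i in range(7)], annot)
        assert summary.group_counts == {
            "Fc receptors": 4,
            "cytokine receptors": 2,
            "uncategorized": 1,
        }
        assert summary.modal_group == "Fc receptors"
        assert sum(summary.group_counts.values()) == 7

    def test_ordering_follows_log2fc_when_enrichment_given(self):
        from sensome.enrichment import EnrichmentResult
        annot = make_annotation(
            {f"g{i}": (f"G{i}", set(), "verified", "ECM receptors") for i in range(3)}
        )
        enr = EnrichmentResult(
            table=pd.DataFrame(
                {"log2fc": [1.0, 5.0, 3.0], "p_value": [0.1] * 3, "padj": [0.1] * 3,
                 "mean_microglia_expression": [1.0] * 3},
                index=["g0", "g1", "g2"],
            ),
            size_factors={},
        )
        summary = categorize(["G0", "G1", "G2"], annot, enr)
        assert list(summary.per_gene.index) == ["G1", "G2", "G0"]


class TestLigandProfile:
    def test_empty_ligand_annotation_counts_nothing(self):
        annot = make_annotation({"g0": ("G0", set(), "verified", None, set())})
        assert ligand_group_profile(["G0"], annot) == {}

    def test_counts_match_construction(self):
        annot = make_annotation(
            {
                "g0": ("G0", set(), "verified", None, {"cytokines", "lipids"}),
                "g1": ("G1", set(), "verified", None, {"cytokines"}),
                "g2": ("G2", set(), "verified", None, set()),
            }
        )
        assert ligand_group_profile(["G0", "G1", "G2"], annot) == {
            "cytokines": 2,
            "lipids": 1,
        }

    def test_identically_annotated_lists_share_all_groups(self):
        annot = make_annotation(
            {
                "g0": ("G0", set(), "verified", None, {"cytokines", "lipids"}),
                "g1": ("G1", set(), "verified", None, {"cytokines", "lipids"}),
            }
        )
        assert shared_ligand_groups(["G0"], ["G1"], annot) == {"cytokines", "lipids"}
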