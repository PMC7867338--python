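"""QC boundaries, size factors, BH adjustment, and the NB enrichment test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sensome import (
    QCError,
    SimConfig,
    ValidationError,
    bh_adjust,
    candidate_enriched,
    enrichment_test,
    generate_counts,
    sample_qc,
    size_factors,
)

from conftest import make_matrix


def brute_force_bh(p):
    """Step-up rule computed literally, one gene at a time."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = min(running_min, 1.0)
    return adj


class TestSampleQC:
    def _matrix_with_detected(self, n_detected_per_sample, min_reads=5):
        """One column per entry; each sample detects exactly that many genes."""
        n_genes = max(n_detected_per_sample)
        cols = []
        for nd in n_detected_per_sample:
            col = np.zeros(n_genes, dtype=np.int64)
            col[:nd] = min_reads
            cols.append(col)
        return make_matrix(np.stack(cols, axis=1), n_microglia=1)

    def test_sample_below_threshold_is_excluded(self):
        m = self._matrix_with_detected([6000, 5999, 6001], min_reads=5)
        kept, report = sample_qc(m, min_genes=6000, min_reads=5)
        assert report.passed == {"s0": True, "s1": False, "s2": True}
        assert kept.sample_ids == ["s0", "s2"]

    def test_sample_exactly_at_threshold_is_retained(self):
        m = self._matrix_with_detected([6000, 6000])
        kept, _ = sample_qc(m, min_genes=6000)
        assert kept.sample_ids == ["s0", "s1"]

    def test_generous_depth_excludes_no_sample(self):
        cfg = SimConfig(n_genes=8000, n_planted_sensome=0, seed=13)
        m, _, _ = generate_counts(cfg)
        kept, report = sample_qc(m, min_genes=6000, min_reads=5)
        assert report.failed_samples() == []
        assert kept.sample_ids == m.sample_ids

    def test_all_samples_failing_is_a_hard_error(self):
        m = self._matrix_with_detected([10, 12])
        with pytest.raises(QCError):
            sample_qc(m, min_genes=6000)

    def test_emptied_group_is_a_hard_error_naming_the_group(self):
        m = self._matrix_with_detected([10, 7000])  # microglia sample fails
        with pytest.raises(QCError, match="microglia"):
            sample_qc(m, min_genes=6000)


class TestSizeFactors:
    def test_identical_samples_get_equal_factors(self):
        col = np.array([5, 10, 80, 3])
        m = make_matrix(np.stack([col, col], axis=1))
        f = size_factors(m)
        assert f["s0"] == pytest.approx(f["s1"])

    def test_doubled_sample_gets_doubled_factor(self):
        col = np.array([5, 10, 80, 3])
        m = make_matrix(np.stack([col, 2 * col], axis=1))
        f = size_factors(m)
        assert f["s1"] / f["s0"] == pytest.approx(2.0)

    def test_matches_independent_median_of_ratios(self):
        rng = np.random.default_rng(17)
        counts = rng.poisson(30, size=(50, 6)) + 1
        m = make_matrix(counts)
        f = size_factors(m)
        # independent re-derivation, scalar loops only
        logs = np.log(counts.astype(float))
        for j, s in enumerate(m.sample_ids):
            ratios = []
            for g in range(50):
                gm = np.exp(np.mean(logs[g]))
                ratios.append(counts[g, j] / gm)
            assert f[s] == pytest.approx(float(np.median(ratios)))

    def test_no_all_positive_gene_advises_pseudocount(self):
        counts = np.array([[0, 5], [5, 0]])
        m = make_matrix(counts)
        with pytest.raises(ValidationError, match="pseudocount"):
            size_factors(m)
        f = size_factors(m, pseudocount=1.0)
        assert all(v > 0 for v in f.values())


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_ties_all_equal(self):
        out = bh_adjust([0.01] * 10)
        assert np.allclose(out, 0.01)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])

    def test_equals_brute_force_on_many_random_vectors(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), brute_force_bh(p))

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(29)
        p = rng.uniform(size=500)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_adjust(p), ref)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_step_up_properties_hold(self, p):
        adj = bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-12).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestEnrichmentTest:
    def test_identical_groups_give_null_statistics(self):
        col = np.array([10, 40, 7, 100, 3])
        counts = np.stack([col, col + 1, col, col + 1], axis=1)
        m = make_matrix(counts)
        enr = enrichment_test(m)
        assert np.allclose(enr.table["log2fc"], 0.0, atol=0.05)
        assert (enr.table["p_value"] > 0.5).all()

    def test_group_with_one_sample_is_rejected(self):
        counts = np.array([[5, 5, 5], [9, 9, 9]])
        m = make_matrix(counts, n_microglia=1)
        with pytest.raises(ValidationError):
            enrichment_test(m)

    def test_label_symmetry_negates_log2fc_and_keeps_p(self):
        cfg = SimConfig(n_genes=400, n_planted_sensome=20, seed=31)
        m, _, _ = generate_counts(cfg)
        enr = enrichment_test(m)
        flipped_groups = {
            s: ("tissue" if g == "microglia" else "microglia")
            for s, g in m.sample_group.items()
        }
        from sensome import CountMatrix
        m_flipped = CountMatrix(counts=m.counts, sample_group=flipped_groups,
                                species=m.species)
        enr_f = enrichment_test(m_flipped)
        assert np.allclose(enr.table["log2fc"], -enr_f.table["log2fc"])
        assert np.allclose(enr.table["p_value"], enr_f.table["p_value"])

    def test_padj_never_below_p(self, sim_dataset):
        m, _, _ = sim_dataset
        enr = enrichment_test(m)
        assert (enr.table["padj"] >= enr.table["p_value"] - 1e-12).all()

    def test_type_one_error_controlled_under_null(self):
        """No planted genes: the fraction of p < 0.05 stays near nominal."""
        cfg = SimConfig(n_genes=5000, n_planted_sensome=0, seed=37)
        m, _, _ = generate_counts(cfg)
        enr = enrichment_test(m)
        frac = float((enr.table["p_value"] < 0.05).mean())
        bound = 1.5 * 0.05
        se = np.sqrt(bound * (1 - bound) / len(enr.table))
        assert frac <= bound + 3 * se

    def test_planted_effect_recovered_with_significance(self):
        """A strongly enriched gene is estimated near truth and significant."""
        hits = 0
        errs = []
        for seed in range(30):
            cfg = SimConfig(
                n_genes=300, n_planted_sensome=1,
                planted_log2fc_range=(4.0, 4.0), dispersion=0.1, seed=1000 + seed,
            )
            m, _, truth = generate_counts(cfg)
            (gene,) = truth.planted_genes
            enr = enrichment_test(m)
            row = enr.table.loc[gene]
            errs.append(abs(row["log2fc"] - 4.0))
            hits += row["padj"] < 0.05
        assert hits >= 0.95 * 30
        assert np.median(errs) < 1.0


class TestCandidateSelection:
    def _enr(self, lfc, padj):
        import pandas as pd

        from sensome.enrichment import EnrichmentResult
        table = pd.DataFrame(
            {"log2fc": lfc, "p_value": padj, "padj": padj,
             "mean_microglia_expression": np.ones(len(lfc))},
            index=[f"g{i}" for i in range(len(lfc))],
        )
        return EnrichmentResult(table=table, size_factors={})

    def test_thresholds_are_strict(self):
        enr = self._enr([2.0, 5.0, 2.1], [0.01, 0.049, 0.05])
        assert candidate_enriched(enr) == {"g1"}

    def test_monotone_in_both_thresholds(self):
        rng = np.random.default_rng(41)
        enr = self._enr(rng.normal(2, 1, 100), rng.uniform(0, 0.1, 100))
        base = candidate_enriched(enr, lfc_min=2.0, fdr=0.05)
        assert base <= candidate_enriched(enr, lfc_min=1.5, fdr=0.05)
        assert base <= candidate_enriched(enr, lfc_min=2.0, fdr=0.08)

    def test_planted_genes_recovered_across_seeds(self):
        recalls = []
        for seed in range(20):
            cfg = SimConfig(seed=seed)
            m, _, truth = generate_counts(cfg)
            enr = enrichment_test(m)
            cands = candidate_enriched(enr)
            recalls.append(len(cands & truth.planted_genes) / len(truth.planted_genes))
        assert min(recalls) >= 0.9
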