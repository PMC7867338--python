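"""Sample QC and the microglia-vs-tissue negative-binomial enrichment test.

The test defines sensome candidacy: a gene is a candidate when its
microglia/tissue log2 fold change exceeds 2 with a BH-adjusted p-value below
0.05.  Counts are normalised by median-of-ratios size factors; per-gene
dispersion is estimated by the method of moments under the NB variance
function var = mu + phi * mu^2; the two-sided test on the log-mean difference
uses a Student-t reference with n1 + n2 - 2 degrees of freedom, which keeps
the test close to nominal at the small group sizes typical of these designs.
No dispersion shrinkage, covariates, or batch correction are applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import QCError, ValidationError
from .io import CountMatrix

logger = logging.getLogger("sensome")

__all__ = [
    "QCReport",
    "EnrichmentResult",
    "sample_qc",
    "size_factors",
    "enrichment_test",
    "bh_adjust",
    "candidate_enriched",
    "expression_summary",
]

DISPERSION_FLOOR = 1e-8
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class QCReport:
    """Per-sample detected-gene counts and pass/fail verdicts."""

    n_genes_detected: dict[str, int]
    passed: dict[str, bool]
    min_genes: int
    min_reads: int

    def failed_samples(self) -> list[str]:
        return [s for s, ok in self.passed.items() if not ok]


@dataclass
class EnrichmentResult:
    """Per-gene enrichment statistics (microglia over tissue).

    ``table`` is indexed by gene id with columns ``log2fc``, ``p_value``,
    ``padj``, ``mean_microglia_expression``; ``size_factors`` maps sample id
    to its normalisation constant.
    """

    table: pd.DataFrame
    size_factors: dict[str, float]

    def __post_init__(self) -> None:
        if (self.table["padj"] + 1e-12 < self.table["p_value"]).any():
            raise ValidationError("padj below p_value violates the BH property")


def sample_qc(
    m: CountMatrix, min_genes: int = 6000, min_reads: int = 5
) -> tuple[CountMatrix, QCReport]:
    """Exclude samples detecting fewer than ``min_genes`` genes.

    A gene counts as detected in a sample when it has at least ``min_reads``
    mapped reads there.  Samples with fewer than ``min_genes`` detected genes
    are excluded (strictly-less-than rule, so a sample at exactly the
    threshold is retained).
    """
    detected = (m.counts >= min_reads).sum(axis=0)
    n_detected = {s: int(detected[s]) for s in m.sample_ids}
    passed = {s: n_detected[s] >= min_genes for s in m.sample_ids}
    keep = [s for s in m.sample_ids if passed[s]]
    report = QCReport(
        n_genes_detected=n_detected, passed=passed,
        min_genes=min_genes, min_reads=min_reads,
    )
    if not keep:
        raise QCError("all samples failed QC; analysis undefined")
    for s in m.sample_ids:
        if not passed[s]:
            logger.info(
                "QC: sample %s excluded (%d genes detected < %d)",
                s, n_detected[s], min_genes,
            )
    groups_before = {m.sample_group[s] for s in m.sample_ids}
    kept = m.subset_samples(keep)
    groups_after = {kept.sample_group[s] for s in kept.sample_ids}
    emptied = groups_before - groups_after
    if emptied:
        raise QCError(f"QC emptied sample group {sorted(emptied)[0]!r}")
    return kept, report


def size_factors(m: CountMatrix, pseudocount: float = 0.0) -> dict[str, float]:
    """Median-of-ratios size factors.

    For each sample s, the factor is the median over genes g of
    counts[g, s] / geometric-mean-over-samples(counts[g, .]), computed over
    genes with strictly positive counts in every sample.  A ``pseudocount``
    may be added to all counts when no gene is positive everywhere.
    """
    k = m.counts.to_numpy(dtype=float) + pseudocount
    positive = (k > 0).all(axis=1)
    if not positive.any():
        raise ValidationError(
            "no gene with positive counts in all samples; "
            "retry with the pseudocount option"
        )
    kp = k[positive]
    log_gm = np.mean(np.log(kp), axis=1, keepdims=True)
    ratios = np.exp(np.log(kp) - log_gm)
    factors = np.median(ratios, axis=0)
    return {s: float(f) for s, f in zip(m.sample_ids, factors)}


def bh_adjust(p: "list[float] | np.ndarray") -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved.

    padj_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def _group_moments(
    q: np.ndarray, cols: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    """Mean and sample variance of normalised counts within one group."""
    sub = q[:, cols]
    n = sub.shape[1]
    mean = sub.mean(axis=1)
    var = sub.var(axis=1, ddof=1)
    return mean, var, n


def enrichment_test(
    m: CountMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> EnrichmentResult:
    """Per-gene microglia-vs-tissue NB Wald test on normalised counts.

    Returns log2 fold changes (microglia over tissue, with ``pseudocount``
    added to both group means), two-sided p-values, BH-adjusted p-values and
    the mean normalised microglial expression.  Genes with zero counts in
    every sample are dropped and logged.
    """
    mg = m.samples_in_group("microglia")
    ts = m.samples_in_group("tissue")
    if len(mg) < 2 or len(ts) < 2:
        raise ValidationError(
            "each group needs at least 2 samples for dispersion estimation "
            f"(microglia={len(mg)}, tissue={len(ts)})"
        )
    sf = size_factors(m)
    sf_vec = np.array([sf[s] for s in m.sample_ids])
    q = m.counts.to_numpy(dtype=float) / sf_vec[None, :]

    nonzero = m.counts.to_numpy().sum(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("enrichment: dropping %d genes with all-zero counts", n_dropped)
    genes = np.array(m.gene_ids)[nonzero]
    q = q[nonzero]

    cols = np.array(m.sample_ids)
    mg_idx = np.flatnonzero(np.isin(cols, mg))
    ts_idx = np.flatnonzero(np.isin(cols, ts))
    m1, v1, n1 = _group_moments(q, mg_idx)
    m2, v2, n2 = _group_moments(q, ts_idx)

    # Method-of-moments dispersion under var = mu + phi mu^2, pooled across
    # groups and floored: noisy per-group estimates are averaged weighted by
    # their degrees of freedom.
    with np.errstate(divide="ignore", invalid="ignore"):
        phi1 = (v1 - m1) / np.square(m1)
        phi2 = (v2 - m2) / np.square(m2)
    phi1 = np.where(np.isfinite(phi1), phi1, 0.0)
    phi2 = np.where(np.isfinite(phi2), phi2, 0.0)
    phi = ((n1 - 1) * phi1 + (n2 - 1) * phi2) / (n1 + n2 - 2)
    phi = np.maximum(phi, DISPERSION_FLOOR)

    c = pseudocount
    log2fc = np.log2(m1 + c) - np.log2(m2 + c)

    # Delta-method variance of log(mean + c); the NB variance of each
    # normalised count is mu/sf + phi mu^2.
    inv_sf_mean_mg = np.mean(1.0 / sf_vec[mg_idx])
    inv_sf_mean_ts = np.mean(1.0 / sf_vec[ts_idx])
    var_m1 = (m1 * inv_sf_mean_mg + phi * np.square(m1)) / n1
    var_m2 = (m2 * inv_sf_mean_ts + phi * np.square(m2)) / n2
    se2 = var_m1 / np.square(m1 + c) + var_m2 / np.square(m2 + c)
    se = np.sqrt(np.maximum(se2, 1e-300))
    z = (np.log(m1 + c) - np.log(m2 + c)) / se
    df = n1 + n2 - 2
    p = 2.0 * sps.t.sf(np.abs(z), df=df)
    p = np.clip(p, 0.0, 1.0)
    padj = bh_adjust(p)

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": p,
            "padj": padj,
            "mean_microglia_expression": m1,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return EnrichmentResult(table=table, size_factors=sf)


def expression_summary(m: CountMatrix) -> EnrichmentResult:
    """Expression-only summary for designs without a tissue comparator.

    Produces an :class:`EnrichmentResult` whose fold changes and p-values are
    neutral (0 and 1): downstream stages that rank by mean microglial
    expression work unchanged, while the enrichment gate has nothing to act
    on.  Used for single-cell-derived microglia-only matrices.
    """
    mg = m.samples_in_group("microglia")
    if not mg:
        raise ValidationError("no microglia samples present")
    sub = m.subset_samples(mg)
    sf = size_factors(sub)
    sf_vec = np.array([sf[s] for s in sub.sample_ids])
    q = sub.counts.to_numpy(dtype=float) / sf_vec[None, :]
    nonzero = sub.counts.to_numpy().sum(axis=1) > 0
    genes = np.array(sub.gene_ids)[nonzero]
    mean = q[nonzero].mean(axis=1)
    table = pd.DataFrame(
        {
            "log2fc": np.zeros(len(genes)),
            "p_value": np.ones(len(genes)),
            "padj": np.ones(len(genes)),
            "mean_microglia_expression": mean,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return EnrichmentResult(table=table, size_factors=sf)


def candidate_enriched(
    enr: EnrichmentResult, lfc_min: float = 2.0, fdr: float = 0.05
) -> set[str]:
    """Genes with log2fc strictly above ``lfc_min`` and padj strictly below ``fdr``."""
    t = enr.table
    keep = t.index[(t["log2fc"] > lfc_min) & (t["padj"] < fdr)]
    result = set(keep)
    if not result:
        logger.warning("candidate_enriched: no genes pass lfc>%.3g, fdr<%.3g", lfc_min, fdr)
    return result
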