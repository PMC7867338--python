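# Methods

## The problem

Microglia, the innate immune cells of the central nervous system, survey
their environment through a set of highly expressed plasma-membrane
receptors — their *sensome*. Given bulk RNA-seq count matrices from sorted
microglia and matched whole-tissue samples, this package extracts a curated
fixed-size sensome per dataset, compares sensomes within and across species,
distils a cross-species *core sensome* (genes present in at least k of n
independently extracted sensomes), and applies that core to published
disease differential-expression tables to ask which sensing genes move, and
in which direction, across conditions.

## Extraction pipeline

Stages, applied in order to one dataset:

1. **Sample QC.** A gene is *detected* in a sample when it has ≥ `min_reads`
   (default 5) mapped reads. Samples detecting fewer than `min_genes`
   (default 6,000) genes are excluded; exclusion is strictly-less-than, so a
   sample at exactly the threshold stays. Emptying either group, or all
   samples failing, is a hard error. The 6,000-gene default assumes a full
   mammalian transcriptome; analyses on the 5,000-gene synthetic universe use
   a bar of 3,000.
2. **Enrichment gate.** Counts are normalised by median-of-ratios size
   factors (factor_s = median over all-positive genes of count/geometric-mean
   reference). Per gene, log2FC = log2((mean microglia + c)/(mean tissue + c))
   with pseudocount c = 0.5 for stability. The per-gene NB dispersion φ in
   var = μ + φμ² is estimated by the method of moments on normalised counts,
   pooled across the two groups by degrees of freedom and floored at 1e-8;
   there is no shrinkage, no covariates. The two-sided test on the log-mean
   difference uses the delta-method standard error and a Student-t reference
   with n₁+n₂−2 degrees of freedom — at the typical group size of 5, the
   plug-in dispersion makes a normal reference anticonservative, and the t
   reference brings the null rejection rate back to ≈ nominal (measured at
   0.043–0.050 for α = 0.05 on 5,000 null genes). P-values are BH-adjusted
   (step-up, running-minimum, capped at 1; implemented directly and checked
   against a literal step-up oracle and statsmodels). Candidates are genes
   with log2FC strictly > 2 and adjusted p strictly < 0.05.
3. **Membrane GO filter.** Candidates keep their place if annotated with at
   least one of: *plasma membrane*, *integral component of membrane*,
   *integral component of plasma membrane*, *transmembrane signaling
   receptor activity*. Genes with **no** GO annotation are not discarded —
   they are routed onward to curation, mirroring the manual screen such genes
   receive in practice. Genes carrying only other terms are excluded. Terms
   are matched by name, not identifier, because curated sensome annotation
   tables circulate that way.
4. **Top-expression bar.** The (1 − `top_fraction`) quantile (default top
   25%) of mean size-factor-normalised microglial expression is computed over
   *all tested genes* and candidates at or above the cut survive (ties at the
   cut included). The transcriptome-wide universe is the default reading of
   "top 25% expressed microglial genes"; a candidates-only universe is
   available via `quantile_universe="candidates"` for the alternative
   reading. Whether the expression bar precedes or follows the GO filter is
   ambiguous in the source descriptions; the default follows the flow-chart
   order (GO first). Both stages are intersective filters on the same
   candidate set, so the composition — though not each stage's audit count —
   is order-independent.
5. **Curation.** Curation is a human verdict supplied as an input column
   (verified / rejected / unknown), never computed: the rubric is that the
   encoded protein sits in the cell membrane (not secreted) and transduces an
   extracellular signal. Verified candidates are ranked by mean microglial
   expression (ties broken by symbol, for determinism) and cut at
   `target_size` (default 100). Unknown-status genes are excluded with a
   logged list for the curator; a shortfall is an error unless
   `allow_partial` is set.

**Expression-only mode** (`use_enrichment=False`) serves microglia-only
designs such as single-cell-derived pseudobulk, where no tissue comparator
exists: the enrichment gate is skipped and ranking is purely by mean
microglial expression among GO-qualified, verified genes.

## Consensus and cross-species comparison

Symbol matching is case-insensitive everywhere (mouse `Trem2` equals human
`TREM2`); output casing follows the first set in which a gene appears.
`overlap` returns the intersection ("core") and union ("extended") of two
sensomes with percent overlap relative to the shared target size — two
100-gene sets sharing 73 genes give 73% and a 127-gene extended set.
`map_orthologs` translates a sensome through an ortholog-pair table
preserving rank; one-to-many orthologs expand to all targets, many-to-one
collapse to the first occurrence, and unmapped symbols are reported, never
silently dropped. `core_sensome` counts per-gene membership across n sets in
one namespace and flags genes present in ≥ k (default 3); k = 1 yields the
union and k = n the intersection. The consensus namespace is mouse symbols
(human sensomes are translated into murine orthologs before counting).

Functional categorisation uses an eight-label vocabulary (purinergic,
cytokine, chemokine-and-related, Fc, pattern-recognition-and-related, and
ECM receptors; cell-cell interactions; sensors or transporters). Published
descriptions of this partition fluctuate between eight and nine labels, so
the vocabulary ships as data and is caller-replaceable. Ligand groups
(16 labels, from glycoproteins to phospholipids, with "hormones and
steroids" as a single label) are many-per-gene.

## Disease application

Disease datasets enter as published DE summaries (gene, log2FC, adjusted p);
raw reads are never reprocessed. Per condition each core gene is called
**up** (padj < α and log2FC > 0), **down** (padj < α and log2FC < 0), **ns**
(padj ≥ α; strict inequalities, so padj exactly α is ns) or **absent** (not
in the table — never imputed). The cross-condition consistency set contains
genes present in every condition with one identical non-ns direction
throughout. Heatmap export uses log2(normalised count + 1) in place of a
regularised-log transform; the quantities this package reports — direction
calls and set arithmetic — do not depend on that visual transform. Heatmap
size factors are rescaled to geometric mean 1, which makes the matrix
invariant (up to a single global scalar inherent to any cross-sample
reference) under rescaling one sample's library.

## Synthetic data: what it emulates, and what it does not

`generate_counts` draws per-gene baseline means from a log-normal
(log-mean 4.0, log-sd 1.5 — median ≈ 55 counts, a realistic bulk depth at
5,000 genes and ~1–3 M reads per sample), applies per-sample library factors
uniform on [0.7, 1.3], and samples NB counts with a single global dispersion
φ = 0.05 (per-gene dispersion available as an option; a global value keeps
moment estimates well-conditioned at n = 5). A planted subset of 100 genes
receives microglia-group means equal to tissue means × 2^lfc with lfc
uniform on [2.5, 6] — floored above the 2.0 gate so recovery is not
threshold-boundary-sensitive — plus a membrane GO term, verified curation
status, a functional group and ligand groups. Planted baselines are drawn
from the upper half of the baseline distribution, making the planted genes
high-expressed by construction, as true sensome genes are. Background genes
carry a membrane term with probability 0.3 and, if so, verified status with
probability 0.5; 5% of the remainder have no GO annotation at all
(exercising the unmapped-to-curation route). Everything is deterministic
under the seed.

The generator does **not** emulate read-level structure, UMIs, single-cell
dropout, batch effects, or correlated genes. Passing recovery tests
therefore demonstrate that the pipeline's set logic and statistics behave
as specified under the assumed NB model — not that any particular published
gene list would be reproduced, which additionally depends on the source
data and on human curation.

The four-dataset study (`sensome.study`) plants each dataset's 100 genes as
a seeded random subset of a shared 130-gene per-species sensing pool, so
independently extracted sensomes overlap strongly but imperfectly
(expected pairwise overlap 100²/130 ≈ 77 genes), and pool genes are
orthologous one-to-one across species with 90% of filler genes mapped.
The 3-of-4 consensus size is then itself a random variable (expected
≈ 100 under these conditions), reported as computed, never asserted.

## Numerical choices and degenerate inputs

- Size factors require at least one gene positive in every sample; otherwise
  the error advises the pseudocount option. Raw factors follow the
  median-of-ratios definition exactly (no rescaling), so they satisfy
  scale-equivariance per sample.
- Genes with zero counts in every sample are dropped from testing, logged.
- BH is vectorised with a stable sort; ties are handled by the
  running-minimum, matching the literal step-up rule exactly.
- A group with fewer than two samples cannot support a dispersion estimate
  and is rejected.
- Sensome ranking ties are broken lexicographically by symbol and logged —
  determinism over silent arbitrariness.

## Command-line interface

A thin `sensome` CLI wraps the library (`simulate`, `enrich`, `extract`,
`overlap`, `core`, `categorize`, `apply`, `validate`). There is no
`convert` subcommand: every artifact already uses the one TSV dialect.
Venn counts and circ-plot tables are exported as TSV; no figure rendering.

## Known limitations

- The enrichment test is a moment-based NB Wald test, not a full GLM fit
  with dispersion shrinkage; at very small counts it is conservative, and
  candidate counts will differ from shrinkage-based analyses of the same
  data.
- Curation quality is entirely inherited from the input annotation.
- Ortholog handling assumes the supplied pair table is correct; one-to-many
  expansion can inflate a translated set's length relative to its source.
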