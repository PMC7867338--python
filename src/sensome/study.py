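"""The four-dataset consensus study, end to end, on synthetic data.

This module wires the primary components into the full comparative design:
two mouse and two human microglia-vs-tissue datasets sharing a planted pool
of true sensing genes, per-dataset extraction of a curated 100-gene sensome,
within-species core/extended overlaps, ortholog translation of the human
sensomes into the mouse symbol namespace, the 3-of-4 consensus core sensome,
and the application of that core to synthetic disease tables.  The numbered
scripts under ``analysis/`` and ``scripts/acceptance.py`` are thin drivers
over these functions.

Study conditions: each dataset has 5 microglia and 5 tissue samples and a
5,000-gene transcriptome; each plants 100 sensome genes drawn from a shared
species pool of 130 true sensing genes, so the four extracted sensomes
overlap strongly but not perfectly, as independent datasets do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .consensus import ConsensusResult, OverlapResult, core_sensome, map_orthologs, overlap
from .disease import DiseaseChangeTable, core_changes, cross_condition_consistency
from .extraction import ExtractionConfig, extract_sensome
from .io import CountMatrix, GeneAnnotationTable, OrthologMap, SensomeSet
from .simulate import GroundTruth, SimConfig, generate_counts, generate_disease_table

POOL_SIZE = 130
SENSOME_SIZE = 100
N_GENES = 5000
N_PER_GROUP = 5
# the 6,000-detected-genes QC bar assumes a full transcriptome; scaled to the
# 5,000-gene synthetic universe
QC_MIN_GENES = 3000

DATASET_NAMES = ("mouse_a", "mouse_b", "human_a", "human_b")


def _symbols(species: str) -> tuple[list[str], list[str]]:
    """(sensing pool, filler) symbol lists for one species, species-cased."""
    if species == "human":
        pool = [f"SENS{i:03d}" for i in range(1, POOL_SIZE + 1)]
        filler = [f"HG{i:04d}" for i in range(1, N_GENES - POOL_SIZE + 1)]
    else:
        pool = [f"Sens{i:03d}" for i in range(1, POOL_SIZE + 1)]
        filler = [f"Mg{i:04d}" for i in range(1, N_GENES - POOL_SIZE + 1)]
    return pool, filler


@dataclass
class StudyDataset:
    name: str
    species: str
    matrix: CountMatrix
    annotation: GeneAnnotationTable
    truth: GroundTruth


@dataclass
class StudyInputs:
    datasets: dict[str, StudyDataset]
    ortholog_map: OrthologMap
    pools: dict[str, list[str]] = field(default_factory=dict)


def simulate_study(seed: int) -> StudyInputs:
    """Simulate the four datasets and the mouse<->human ortholog map.

    Each dataset plants a seeded random 100-gene subset of its species'
    130-gene sensing pool; pool genes are orthologous one-to-one across
    species, filler genes map for 90% of the genome (orthology is incomplete
    in practice).
    """
    import numpy as np

    datasets: dict[str, StudyDataset] = {}
    pools: dict[str, list[str]] = {}
    for i, name in enumerate(DATASET_NAMES):
        species = "human" if name.startswith("human") else "mouse"
        pool, filler = _symbols(species)
        pools[species] = pool
        rng = np.random.default_rng(seed + 101 + i)
        planted = sorted(rng.choice(pool, size=SENSOME_SIZE, replace=False))
        cfg = SimConfig(
            n_genes=N_GENES,
            n_microglia_samples=N_PER_GROUP,
            n_tissue_samples=N_PER_GROUP,
            n_planted_sensome=SENSOME_SIZE,
            seed=seed + 201 + i,
            species=species,
            gene_symbols=pool + filler,
            planted_gene_ids=planted,
        )
        matrix, annot, truth = generate_counts(cfg)
        datasets[name] = StudyDataset(name, species, matrix, annot, truth)

    from .simulate import generate_ortholog_map

    mouse_pool, mouse_filler = _symbols("mouse")
    human_pool, human_filler = _symbols("human")
    pool_map = OrthologMap(pairs=set(zip(mouse_pool, human_pool)))
    filler_map = generate_ortholog_map(mouse_filler, human_filler, 0.9, seed + 301)
    orth = OrthologMap(pairs=pool_map.pairs | filler_map.pairs)
    return StudyInputs(datasets=datasets, ortholog_map=orth, pools=pools)


def extract_study_sensomes(
    inputs: StudyInputs,
) -> tuple[dict[str, SensomeSet], dict[str, dict[str, int]]]:
    """Extract one curated 100-gene sensome per dataset, with audits."""
    sensomes: dict[str, SensomeSet] = {}
    audits: dict[str, dict[str, int]] = {}
    for name, ds in inputs.datasets.items():
        cfg = ExtractionConfig(
            target_size=SENSOME_SIZE, species=ds.species, source_label=name
        )
        s, audit = extract_sensome(
            ds.matrix, ds.annotation, cfg,
            min_genes=QC_MIN_GENES, allow_partial=True,
        )
        sensomes[name] = s
        audits[name] = audit
    return sensomes, audits


@dataclass
class ConsensusOutputs:
    mouse_overlap: OverlapResult
    human_overlap: OverlapResult
    cross_species: ConsensusResult
    unmapped_human: dict[str, list[str]]


def run_consensus(
    sensomes: dict[str, SensomeSet], orth: OrthologMap, k: int = 3
) -> ConsensusOutputs:
    """Within-species overlaps and the k-of-4 consensus in mouse namespace."""
    mouse_overlap = overlap(sensomes["mouse_a"], sensomes["mouse_b"])
    human_overlap = overlap(sensomes["human_a"], sensomes["human_b"])
    unmapped: dict[str, list[str]] = {}
    translated = []
    for name in ("human_a", "human_b"):
        t, um = map_orthologs(sensomes[name], orth, "mouse")
        translated.append(t)
        unmapped[name] = um
    consensus = core_sensome(
        [sensomes["mouse_a"], sensomes["mouse_b"], *translated], k=k
    )
    return ConsensusOutputs(
        mouse_overlap=mouse_overlap,
        human_overlap=human_overlap,
        cross_species=consensus,
        unmapped_human=unmapped,
    )


@dataclass
class DiseaseOutputs:
    tables: list[DiseaseChangeTable]
    consistent: set[str]
    truths: dict[str, GroundTruth]


def run_disease_application(
    core_genes: list[str], seed: int, conditions=("aging", "als", "ad")
) -> DiseaseOutputs:
    """Planted disease tables for each condition, direction calls, consistency.

    One core gene (the alphabetically first) is planted "up" in every
    condition, mirroring the uniformly induced sensing genes seen across
    neurodegeneration models; the remaining up/down genes differ per
    condition.
    """
    import numpy as np

    always_up = sorted(core_genes)[0]
    tables: list[DiseaseChangeTable] = []
    truths: dict[str, GroundTruth] = {}
    for i, cond in enumerate(conditions):
        others = [g for g in core_genes if g != always_up]
        de_base, truth = generate_disease_table(
            others, n_up=4, n_down=3, seed=seed + 401 + i, condition_label=cond
        )
        rng = np.random.default_rng(seed + 501 + i)
        de_base.table.loc[always_up] = (
            float(rng.uniform(0.5, 3.0)),
            float(rng.uniform(1e-6, 0.01)),
        )
        truth.planted_genes.add(always_up)
        truth.planted_disease_direction[always_up] = "up"
        tables.append(core_changes(core_genes, de_base))
        truths[cond] = truth
    _, consistent = cross_condition_consistency(tables)
    return DiseaseOutputs(tables=tables, consistent=consistent, truths=truths)
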