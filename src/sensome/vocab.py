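"""Controlled vocabularies: GO filter terms, functional groups, ligand groups.

The functional-group partition of sensome genes is not fully standardised in
the literature (published descriptions enumerate between eight and nine
labels); the eight-label set below is the default and callers may supply their
own vocabulary wherever a ``groups=`` argument is accepted.
"""

from __future__ import annotations

# GO terms that admit a gene into the membrane/receptor candidate pool.
# Stored by name, not identifier, because that is how curated sensome
# annotation tables circulate.
MEMBRANE_GO_TERMS: frozenset[str] = frozenset(
    {
        "plasma membrane",
        "integral component of membrane",
        "integral component of plasma membrane",
        "transmembrane signaling receptor activity",
    }
)

# Functional subgroups of sensome genes (circ-plot categories).
FUNCTIONAL_GROUPS: tuple[str, ...] = (
    "purinergic receptors",
    "cytokine receptors",
    "chemokine and related receptors",
    "Fc receptors",
    "pattern recognition and related receptors",
    "ECM receptors",
    "cell-cell interactions",
    "sensors or transporters",
)

UNCATEGORIZED = "uncategorized"

# Ligand classes recognised by sensome receptors.
LIGAND_GROUPS: tuple[str, ...] = (
    "glycoproteins",
    "cytokines",
    "immunoglobulin",
    "amino acids",
    "carbohydrates",
    "electrolytes",
    "lipopeptides",
    "chemokines",
    "neuraminic acids",
    "nucleic acids",
    "receptors",
    "lipids",
    "fatty acids",
    "leukotrienes",
    "hormones and steroids",
    "phospholipids",
)

CURATION_STATUSES: frozenset[str] = frozenset({"verified", "rejected", "unknown"})
SAMPLE_GROUPS: frozenset[str] = frozenset({"microglia", "tissue"})
SPECIES: frozenset[str] = frozenset({"mouse", "human"})
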