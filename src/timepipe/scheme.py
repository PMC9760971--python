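"""Phenotype scheme and shared constants.

The classification is hierarchical: three broad classes (Tumor, Stroma,
Immune), with the Immune class resolved into eight named immune phenotypes
plus an UnclassifiedImmune catch-all — ten assignable phenotypes in total,
eleven scheme classes counting the catch-all separately from the named ones.
"""

from __future__ import annotations

TUMOR = "Tumor"
STROMA = "Stroma"
IMMUNE = "Immune"  # broad class only, never a per-cell phenotype
UNASSIGNED = "Unassigned"

#: Fine-grained immune phenotypes (tier-2 classifier targets).
IMMUNE_CLASSES: tuple[str, ...] = (
    "BCell",
    "CytotoxicT",
    "HelperT",
    "Treg",
    "Neutrophil",
    "Monocyte",
    "Macrophage",
    "Dendritic",
    "UnclassifiedImmune",
)

#: Every assignable phenotype.
ALL_CLASSES: tuple[str, ...] = (TUMOR, STROMA) + IMMUNE_CLASSES

#: Broad (tier-1) classes.
BROAD_CLASSES: tuple[str, ...] = (TUMOR, STROMA, IMMUNE)

#: Tumor-infiltrating lymphocyte subset — the classes scored for PD1 positivity.
TIL_CLASSES: tuple[str, ...] = ("BCell", "CytotoxicT", "HelperT", "Treg")

#: Square field-of-view side, pixels (~1 mm^2 at ~0.49 um/px).
DEFAULT_FOV_SIZE = 2040.0

#: Diameter of an index-cell-centric neighborhood, pixels.
DEFAULT_NEIGHBORHOOD_DIAMETER = 57.0

#: Neighbors per cell for community composition vectors.
DEFAULT_COMMUNITY_K = 75

#: Default number of community clusters.
DEFAULT_COMMUNITY_C = 11

_BROAD_OF = {c: IMMUNE for c in IMMUNE_CLASSES}
_BROAD_OF[TUMOR] = TUMOR
_BROAD_OF[STROMA] = STROMA


def broad_class(phenotype: str) -> str:
    """Collapse a phenotype to its broad class (Tumor / Stroma / Immune).

    Unknown strings (including UNASSIGNED) raise KeyError.
    """
    return _BROAD_OF[phenotype]


def is_immune(phenotype: str) -> bool:
    return phenotype in IMMUNE_CLASSES


def coerce_phenotype(label: str) -> str:
    """Map arbitrary phenotype strings onto the scheme.

    Known class names pass through; anything else becomes UNASSIGNED so that
    classification can be (re)run inside the pipeline.
    """
    return label if label in ALL_CLASSES else UNASSIGNED
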