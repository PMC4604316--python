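"""Bundled summary data for the 19-isolate study panel.

These are published per-genome statistics and panel-level counts for the
19 *Pseudomonas fluorescens* isolates the package was built around
(4 rhizosphere, 15 endosphere). They serve as ready-made inputs for the
summary operations and as planting targets for the exact-recovery mode
of the synthetic generators.
"""

from __future__ import annotations

import pandas as pd

from .io_cli.types import ENDOSPHERE, RHIZOSPHERE

_GENOME_STATS_ROWS = [
    # isolate, compartment, size_mb, scaffolds, gc, genes, coding,
    # functional_prediction, kegg, similarity
    ("GM25", RHIZOSPHERE, 6.37, 186, 61, 5836, 90.3, 81.2, 28.1, 99.5),
    ("GM48", RHIZOSPHERE, 6.46, 272, 59, 5977, 87.7, 81.1, 29.1, 99.6),
    ("GM49", RHIZOSPHERE, 6.60, 370, 60, 6340, 88.1, 80.6, 28.3, 99.6),
    ("GM74", RHIZOSPHERE, 6.12, 219, 60, 5649, 88.2, 81.4, 29.8, 99.6),
    ("GM16", ENDOSPHERE, 6.56, 155, 59, 5981, 88.6, 79.6, 26.9, 98.9),
    ("GM18", ENDOSPHERE, 6.31, 178, 60, 5797, 89.2, 80.5, 28.8, 99.3),
    ("GM21", ENDOSPHERE, 6.62, 258, 58, 6154, 88.0, 79.1, 27.9, 99.4),
    ("GM24", ENDOSPHERE, 6.54, 476, 59, 5974, 88.8, 79.3, 27.0, 99.3),
    ("GM30", ENDOSPHERE, 6.15, 215, 60, 5696, 88.3, 79.6, 26.9, 99.4),
    ("GM33", ENDOSPHERE, 6.74, 245, 60, 6177, 88.3, 82.0, 28.6, 99.3),
    ("GM41", ENDOSPHERE, 6.63, 230, 59, 6150, 88.6, 80.9, 28.6, 99.4),
    ("GM50", ENDOSPHERE, 6.70, 202, 59, 6151, 88.1, 79.9, 27.5, 99.2),
    ("GM55", ENDOSPHERE, 6.50, 217, 60, 6068, 87.9, 81.1, 28.7, 99.5),
    ("GM60", ENDOSPHERE, 6.44, 230, 60, 5991, 88.2, 80.9, 28.5, 99.6),
    ("GM67", ENDOSPHERE, 6.52, 254, 60, 6086, 88.4, 79.3, 27.8, 99.6),
    ("GM78", ENDOSPHERE, 7.30, 291, 60, 6804, 88.8, 81.0, 27.7, 99.6),
    ("GM79", ENDOSPHERE, 6.72, 166, 59, 6146, 87.6, 79.7, 28.0, 99.1),
    ("GM80", ENDOSPHERE, 6.81, 368, 59, 6334, 88.2, 77.2, 25.8, 99.4),
    ("GM102", ENDOSPHERE, 6.67, 207, 59, 6126, 88.1, 79.8, 27.9, 99.1),
]

_COLUMNS = [
    "isolate", "compartment", "size_mb", "scaffolds", "gc_percent", "genes",
    "coding_percent", "functional_prediction_percent", "kegg_percent",
    "similarity",
]


def genome_stats() -> pd.DataFrame:
    """Per-genome statistics table for the 19-isolate panel."""
    return pd.DataFrame(_GENOME_STATS_ROWS, columns=_COLUMNS)


def panel_labels() -> dict[str, str]:
    """isolate -> compartment map for the panel (4 R, 15 E)."""
    return {row[0]: row[1] for row in _GENOME_STATS_ROWS}


N_RHIZOSPHERE = 4
N_ENDOSPHERE = 15
N_COMPOUNDS = 190

#: Published compartment Venn decomposition of the panel's pan-genome,
#: keyed by (rhizosphere occupancy, endosphere occupancy).
PANGENOME_VENN_COUNTS: dict[tuple[str, str], int] = {
    ("all", "all"): 3255,
    ("all", "some"): 731,
    ("some", "all"): 52,
    ("some", "some"): 3157,
    ("some", "none"): 268,
    ("none", "some"): 3212,
    ("all", "none"): 0,
    ("none", "all"): 0,
}

#: Published metabolic-model reaction categories for the panel.
REACTION_CATEGORIES = {
    "core": 1151,
    "shared_non_core": 175,
    "rhizosphere_only": 1,
    "endosphere_only": 105,
}

#: Published all/none/differential utilization partition of the
#: endosphere group over the 190-compound panel.
ENDOSPHERE_UTILIZATION_PARTITION = (51, 71, 68)

#: Same for the rhizosphere group.
RHIZOSPHERE_UTILIZATION_PARTITION = (62, 95, 33)
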