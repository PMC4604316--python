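"""Core/pan-genome decomposition with compartment-labelled occupancy.

Each ortholog cluster is classified by its occupancy in each isolation
compartment: ``all`` (present in every member genome), ``none`` (absent
from every member genome) or ``some`` (in between). The 3x3 occupancy
grid minus the structurally empty (none, none) cell is the compartment
Venn decomposition of the pan-genome; (all, all) is the core.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConsistencyError
from .io_cli.types import (
    ClusterSet,
    CompartmentLabels,
    ENDOSPHERE,
    PresenceMatrix,
    RHIZOSPHERE,
)

OCCUPANCIES = ("all", "some", "none")

#: Admissible cells in canonical order; (none, none) is excluded because a
#: cluster absent from every genome cannot exist.
VENN_CELLS: tuple[tuple[str, str], ...] = tuple(
    (r, e) for r in OCCUPANCIES for e in OCCUPANCIES if (r, e) != ("none", "none")
)


@dataclass(frozen=True)
class PangenomeVenn:
    """Counts of clusters per (rhizosphere occupancy, endosphere occupancy)."""

    counts: dict[tuple[str, str], int]
    n_rhizosphere: int
    n_endosphere: int
    total_clusters: int

    def __post_init__(self):
        filled = {cell: int(self.counts.get(cell, 0)) for cell in VENN_CELLS}
        unknown = set(self.counts) - set(VENN_CELLS)
        if unknown:
            raise ValueError(f"inadmissible Venn cell(s): {sorted(unknown)}")
        if any(v < 0 for v in filled.values()):
            raise ValueError("negative Venn cell count")
        if sum(filled.values()) != self.total_clusters:
            raise ValueError(
                f"Venn cells sum to {sum(filled.values())}, "
                f"expected total_clusters={self.total_clusters}"
            )
        object.__setattr__(self, "counts", filled)

    def __getitem__(self, cell: tuple[str, str]) -> int:
        return self.counts[cell]

    @property
    def core(self) -> int:
        """Clusters present in every genome of both compartments."""
        return self.counts[("all", "all")]

    @property
    def rhizosphere_exclusive(self) -> int:
        """Clusters found only in rhizosphere genomes (in some, not all)."""
        return self.counts[("some", "none")]

    @property
    def endosphere_exclusive(self) -> int:
        return self.counts[("none", "some")]

    def exclusive(self, compartment: str) -> int:
        if compartment == RHIZOSPHERE:
            return self.rhizosphere_exclusive
        if compartment == ENDOSPHERE:
            return self.endosphere_exclusive
        raise ValueError(f"unknown compartment {compartment!r}")

    def group_size(self, compartment: str) -> int:
        if compartment == RHIZOSPHERE:
            return self.n_rhizosphere
        if compartment == ENDOSPHERE:
            return self.n_endosphere
        raise ValueError(f"unknown compartment {compartment!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"occupancy_rhizosphere": r, "occupancy_endosphere": e,
             "clusters": self.counts[(r, e)]}
            for r, e in VENN_CELLS
        ]
        return pd.DataFrame(rows)


def presence_from_clusters(
    clusters: ClusterSet, genomes: Iterable[str]
) -> PresenceMatrix:
    """Collapse a cluster set into a binary genomes x clusters matrix.

    Cell (g, c) is 1 iff cluster c has at least one member gene from
    genome g (paralogs collapse). Genomes listed but never seen in any
    cluster get all-zero rows; a cluster naming a genome outside the
    list is an error.
    """
    genomes = list(genomes)
    if not genomes:
        raise ValueError("empty genome list")
    if len(set(genomes)) != len(genomes):
        raise ValueError("duplicate genome ids in genome list")
    index = {g: i for i, g in enumerate(genomes)}
    values = np.zeros((len(genomes), len(clusters)), dtype=np.int8)
    for j, cl in enumerate(clusters):
        for g in cl.genomes:
            if g not in index:
                raise ConsistencyError(
                    f"cluster {cl.id!r} names genome {g!r} which is not in "
                    "the genome list"
                )
            values[index[g], j] = 1
    return PresenceMatrix.from_arrays(
        genomes, [cl.id for cl in clusters], values, kind="presence"
    )


def _occupancy(present: int, size: int) -> str:
    if present == size:
        return "all"
    if present == 0:
        return "none"
    return "some"


def partition_compartments(
    presence: PresenceMatrix, labels: CompartmentLabels
) -> PangenomeVenn:
    """Classify every feature column into the compartment Venn grid."""
    labels.require_cover(presence.strains)
    labels.require_both_compartments(presence.strains)
    r_strains, e_strains = labels.split(presence.strains)
    vals = presence.data
    r_counts = vals.loc[r_strains].sum(axis=0).to_numpy()
    e_counts = vals.loc[e_strains].sum(axis=0).to_numpy()
    counts: dict[tuple[str, str], int] = {cell: 0 for cell in VENN_CELLS}
    for feature, rc, ec in zip(presence.features, r_counts, e_counts):
        cell = (_occupancy(int(rc), len(r_strains)),
                _occupancy(int(ec), len(e_strains)))
        if cell == ("none", "none"):
            raise ValueError(
                f"feature {feature!r} is absent from every strain; the "
                "(none, none) cell is structurally empty"
            )
        counts[cell] += 1
    return PangenomeVenn(
        counts=counts,
        n_rhizosphere=len(r_strains),
        n_endosphere=len(e_strains),
        total_clusters=len(presence.features),
    )


def accessory_average(exclusive_count: int, group_size: int) -> int:
    """Exclusive pan-gene count per genome, rounded half away from zero."""
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    if exclusive_count < 0:
        raise ValueError("exclusive_count must be >= 0")
    return int(math.floor(exclusive_count / group_size + 0.5))


@dataclass(frozen=True)
class GenomeSummary:
    mean_genes: int
    size_range_mb: tuple[float, float]
    min_similarity: float


def summarize_genome_stats(stats: pd.DataFrame) -> GenomeSummary:
    """Panel-level summary of a per-genome statistics table.

    ``stats`` must carry columns ``size_mb`` (genome size, Mb), ``genes``
    (gene count) and ``similarity`` (percent identity to the marker-gene
    consensus). Returns the mean gene count (nearest integer), the size
    range rounded to one decimal, and the minimum similarity as given.
    """
    required = {"size_mb", "genes", "similarity"}
    missing = required - set(stats.columns)
    if missing:
        raise ValueError(f"missing column(s): {sorted(missing)}")
    if len(stats) == 0:
        raise ValueError("empty genome statistics table")
    return GenomeSummary(
        mean_genes=int(math.floor(float(stats["genes"].mean()) + 0.5)),
        size_range_mb=(
            round(float(stats["size_mb"].min()), 1),
            round(float(stats["size_mb"].max()), 1),
        ),
        min_similarity=float(stats["similarity"].min()),
    )


def venn_report(venn: PangenomeVenn) -> pd.DataFrame:
    """Venn cell table plus exclusive-pan per-genome average summary rows."""
    df = venn.to_frame()
    extra = pd.DataFrame(
        [
            {
                "occupancy_rhizosphere": "exclusive_avg",
                "occupancy_endosphere": comp,
                "clusters": accessory_average(
                    venn.exclusive(comp), venn.group_size(comp)
                ),
            }
            for comp in (RHIZOSPHERE, ENDOSPHERE)
        ]
    )
    return pd.concat([df, extra], ignore_index=True)
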