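"""Scoring of metabolic-model growth predictions against observations.

Predictions and observations are binary strains x compounds matrices;
only the strain/compound intersection is scored. Per strain the report
carries a full confusion count (TP/TN/FP/FN) and accuracy; per compound
it counts how many strains were mispredicted in each direction, which
surfaces systematic model gaps (a compound every strain grows on but no
model predicts shows up as an all-strain false negative).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_cli.types import CompartmentLabels, PresenceMatrix
from .pangenome import PangenomeVenn, partition_compartments

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StrainConfusion:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n_compounds(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n_compounds


@dataclass(frozen=True)
class ValidationReport:
    per_strain: dict[str, StrainConfusion]
    shared_compounds: tuple[str, ...]
    predicted_core: frozenset[str]
    observed_core: frozenset[str]
    false_negative_strains: pd.Series  # per compound: strains predicted 0, observed 1
    false_positive_strains: pd.Series
    skipped_strains: tuple[str, ...]
    skipped_compounds: tuple[str, ...]

    @property
    def overall_accuracy(self) -> float:
        tp = sum(c.tp for c in self.per_strain.values())
        tn = sum(c.tn for c in self.per_strain.values())
        total = sum(c.n_compounds for c in self.per_strain.values())
        return 100.0 * (tp + tn) / total

    @property
    def mean_strain_accuracy(self) -> float:
        accs = [c.accuracy for c in self.per_strain.values()]
        return float(np.mean(accs))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "strain": s,
                "tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn,
                "n_compounds": c.n_compounds,
                "accuracy_percent": round(c.accuracy, 1),
            }
            for s, c in self.per_strain.items()
        ]
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        """JSON-ready summary; accuracies to the nearest whole percent."""
        return {
            "overall_accuracy_percent": int(math.floor(self.overall_accuracy + 0.5)),
            "mean_strain_accuracy_percent": int(
                math.floor(self.mean_strain_accuracy + 0.5)
            ),
            "n_strains": len(self.per_strain),
            "n_shared_compounds": len(self.shared_compounds),
            "n_predicted_core": len(self.predicted_core),
            "n_observed_core": len(self.observed_core),
            "skipped_strains": sorted(self.skipped_strains),
            "skipped_compounds": sorted(self.skipped_compounds),
            "systematic_false_negatives": sorted(
                self.false_negative_strains[
                    self.false_negative_strains == len(self.per_strain)
                ].index
            ),
        }


def validate_predictions(
    pred: PresenceMatrix, obs: PresenceMatrix
) -> ValidationReport:
    """Confusion counts and accuracy of predictions against observations."""
    shared_strains = [s for s in pred.strains if s in set(obs.strains)]
    shared_compounds = [c for c in pred.features if c in set(obs.features)]
    if not shared_strains or not shared_compounds:
        raise ValueError(
            "prediction and observation matrices share no "
            + ("strains" if not shared_strains else "compounds")
        )
    skipped_strains = tuple(
        sorted(
            (set(pred.strains) | set(obs.strains)) - set(shared_strains)
        )
    )
    skipped_compounds = tuple(
        sorted(
            (set(pred.features) | set(obs.features)) - set(shared_compounds)
        )
    )
    if skipped_strains:
        logger.info("strains excluded from scoring: %s", list(skipped_strains))
    if skipped_compounds:
        logger.info(
            "%d compound(s) excluded from scoring (present in only one matrix)",
            len(skipped_compounds),
        )
    p = pred.restrict(strains=shared_strains, features=shared_compounds).values
    o = obs.restrict(strains=shared_strains, features=shared_compounds).values
    per_strain = {}
    for i, strain in enumerate(shared_strains):
        tp = int(((p[i] == 1) & (o[i] == 1)).sum())
        tn = int(((p[i] == 0) & (o[i] == 0)).sum())
        fp = int(((p[i] == 1) & (o[i] == 0)).sum())
        fn = int(((p[i] == 0) & (o[i] == 1)).sum())
        per_strain[strain] = StrainConfusion(tp, tn, fp, fn)
    fn_counts = pd.Series(
        ((p == 0) & (o == 1)).sum(axis=0), index=shared_compounds,
        name="false_negative_strains",
    )
    fp_counts = pd.Series(
        ((p == 1) & (o == 0)).sum(axis=0), index=shared_compounds,
        name="false_positive_strains",
    )
    return ValidationReport(
        per_strain=per_strain,
        shared_compounds=tuple(shared_compounds),
        predicted_core=frozenset(
            core_compound_sets(pred.restrict(strains=shared_strains,
                                             features=shared_compounds))
        ),
        observed_core=frozenset(
            core_compound_sets(obs.restrict(strains=shared_strains,
                                            features=shared_compounds))
        ),
        false_negative_strains=fn_counts,
        false_positive_strains=fp_counts,
        skipped_strains=skipped_strains,
        skipped_compounds=skipped_compounds,
    )


def core_compound_sets(matrix: PresenceMatrix) -> set[str]:
    """Compounds positive in every strain (column-wise AND)."""
    if not matrix.strains:
        raise ValueError("empty matrix")
    col_all = matrix.data.all(axis=0)
    return set(matrix.data.columns[col_all])


@dataclass(frozen=True)
class ReactionVenn:
    """Compartment bookkeeping of model reactions."""

    venn: PangenomeVenn

    @property
    def total(self) -> int:
        return self.venn.total_clusters

    @property
    def core(self) -> int:
        return self.venn.core

    @property
    def differential(self) -> int:
        """Reactions not common to every model."""
        return self.total - self.core

    @property
    def rhizosphere_only(self) -> int:
        """Reactions found exclusively in rhizosphere models."""
        c = self.venn.counts
        return c[("some", "none")] + c[("all", "none")]

    @property
    def endosphere_only(self) -> int:
        c = self.venn.counts
        return c[("none", "some")] + c[("none", "all")]

    @property
    def shared_non_core(self) -> int:
        """Non-core reactions present in both compartments."""
        c = self.venn.counts
        return c[("all", "some")] + c[("some", "all")] + c[("some", "some")]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"category": "core", "reactions": self.core},
            {"category": "shared_non_core", "reactions": self.shared_non_core},
            {"category": "rhizosphere_only", "reactions": self.rhizosphere_only},
            {"category": "endosphere_only", "reactions": self.endosphere_only},
            {"category": "differential", "reactions": self.differential},
            {"category": "total", "reactions": self.total},
        ]
        return pd.DataFrame(rows)


def reaction_venn(
    reaction_presence: PresenceMatrix, labels: CompartmentLabels
) -> ReactionVenn:
    """Classify model reactions by compartment occupancy.

    Delegates to the same partition used for gene clusters, so both
    analyses are guaranteed to agree on identical matrices.
    """
    return ReactionVenn(partition_compartments(reaction_presence, labels))
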