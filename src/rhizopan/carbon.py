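"""Per-strain and per-class analysis of sole-carbon-source utilization.

The utilization matrix records, per strain and compound, whether the
strain oxidized the compound. Compounds carry a user-supplied class map
(carboxylic acids, amino acids, ...). Class-level bias tests pool the
strain x compound calls of a class into one (compartment) x (positive,
negative) table; the pooled cells are not independent across strains,
so the strain-label permutation p is offered as the robust alternative
to the asymptotic chi-square reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .enrichment import (
    ContingencyTable,
    EnrichmentResult,
    _degenerate_result,
    _permutation_p_2x2,
    chi_square,
)
from .errors import ConsistencyError, DegenerateTableError
from .io_cli.types import (
    CompartmentLabels,
    COMPARTMENTS,
    ENDOSPHERE,
    PresenceMatrix,
    RHIZOSPHERE,
)

logger = logging.getLogger(__name__)

#: Compound -> class name map; every compound in the matrix must appear.
CompoundClassification = Mapping[str, str]


class GroupPartition(NamedTuple):
    """All/none/differential compound counts for one strain group."""

    n_all: int
    n_none: int
    n_differential: int

    @property
    def total(self) -> int:
        return self.n_all + self.n_none + self.n_differential


@dataclass(frozen=True)
class GroupBiasResult:
    """Bias verdict for one compound class."""

    class_name: str
    n_compounds: int
    frac_rhizosphere: float
    frac_endosphere: float
    enrichment: EnrichmentResult
    bias_call: str  # rhizosphere | endosphere | none


def strain_substrate_counts(util: PresenceMatrix) -> pd.Series:
    """Number of compounds each strain utilizes (row sums)."""
    counts = util.data.sum(axis=1).astype(int)
    counts.name = "compounds_utilized"
    return counts


def group_count_ranges(
    util: PresenceMatrix, labels: CompartmentLabels
) -> dict[str, tuple[int, int]]:
    """Per-compartment (min, max) of the per-strain substrate counts."""
    labels.require_cover(util.strains)
    counts = strain_substrate_counts(util)
    out = {}
    for comp in COMPARTMENTS:
        members = [s for s in util.strains if labels[s] == comp]
        if members:
            sub = counts.loc[members]
            out[comp] = (int(sub.min()), int(sub.max()))
    return out


def group_partition(util: PresenceMatrix, strains: Iterable[str]) -> GroupPartition:
    """Partition compounds by their occupancy in a strain subset:
    used by all of them, by none, or differentially."""
    strains = list(strains)
    if not strains:
        raise ValueError("empty strain subset")
    sub = util.restrict(strains=strains)
    col_sums = sub.data.sum(axis=0).to_numpy()
    n = len(strains)
    n_all = int((col_sums == n).sum())
    n_none = int((col_sums == 0).sum())
    n_diff = int(((col_sums > 0) & (col_sums < n)).sum())
    return GroupPartition(n_all, n_none, n_diff)


def _classes_in_matrix(
    util: PresenceMatrix, classes: CompoundClassification
) -> dict[str, list[str]]:
    """class -> compounds present in the matrix, with coverage checks."""
    unclassified = [c for c in util.features if c not in classes]
    if unclassified:
        raise ConsistencyError(
            "compound(s) missing from the classification map: "
            + ", ".join(sorted(unclassified))
        )
    by_class: dict[str, list[str]] = {}
    for compound in util.features:
        by_class.setdefault(classes[compound], []).append(compound)
    for cls in set(classes.values()) - set(by_class):
        raise ConsistencyError(
            f"class {cls!r} has no compounds in the utilization matrix"
        )
    return by_class


def classify_group_bias(
    util: PresenceMatrix,
    labels: CompartmentLabels,
    classes: CompoundClassification,
    alpha: float = 0.01,
    n_perm: int = 0,
    seed: int | None = None,
) -> list[GroupBiasResult]:
    """Test every compound class for compartment-biased utilization.

    Per class, strain x compound calls are pooled into a 2x2
    (compartment) x (positive, negative) table and tested; a class is
    called biased toward the compartment with the larger pooled positive
    fraction when the test is significant at ``alpha``. A class whose
    pooled table is degenerate (all calls positive or all negative) is
    homogeneous by construction: chi2 0, no bias.
    """
    labels.require_cover(util.strains)
    labels.require_both_compartments(util.strains)
    by_class = _classes_in_matrix(util, classes)
    r_strains, e_strains = labels.split(util.strains)
    n_r, n_e = len(r_strains), len(e_strains)
    rng = np.random.default_rng(seed)
    results = []
    for cls in sorted(by_class):
        compounds = by_class[cls]
        m = len(compounds)
        sub = util.restrict(features=compounds)
        pos_per_strain = sub.data.sum(axis=1)
        pos_r = int(pos_per_strain.loc[r_strains].sum())
        pos_e = int(pos_per_strain.loc[e_strains].sum())
        frac_r = pos_r / (n_r * m)
        frac_e = pos_e / (n_e * m)
        counts = np.array(
            [[pos_r, n_r * m - pos_r], [pos_e, n_e * m - pos_e]]
        )
        try:
            table = ContingencyTable(
                counts, (RHIZOSPHERE, ENDOSPHERE), ("positive", "negative")
            )
            res = chi_square(table, alpha=alpha)
            if n_perm > 0:
                pos_vec = pos_per_strain.loc[util.strains].to_numpy(np.int64)
                tot_vec = np.full_like(pos_vec, m)
                # reorder so the first n_r entries are not special: masks are
                # uniform subsets, strain order is irrelevant
                p_perm = _permutation_p_2x2(
                    pos_vec, tot_vec, n_r, res.chi2, n_perm, rng
                )
                res = replace(res, p_permutation=p_perm,
                              significant=p_perm < alpha)
        except DegenerateTableError:
            # all calls positive or all negative: perfectly homogeneous
            res = replace(
                _degenerate_result(alpha), chi2=0.0, p_asymptotic=1.0
            )
        bias = "none"
        if res.significant and frac_r != frac_e:
            bias = RHIZOSPHERE if frac_r > frac_e else ENDOSPHERE
        results.append(
            GroupBiasResult(
                class_name=cls,
                n_compounds=m,
                frac_rhizosphere=frac_r,
                frac_endosphere=frac_e,
                enrichment=res,
                bias_call=bias,
            )
        )
    return results


def group_bias_table(results: Iterable[GroupBiasResult]) -> pd.DataFrame:
    rows = [
        {
            "class": r.class_name,
            "n_compounds": r.n_compounds,
            "frac_rhizosphere": r.frac_rhizosphere,
            "frac_endosphere": r.frac_endosphere,
            "chi2": r.enrichment.chi2,
            "p_asymptotic": r.enrichment.p_asymptotic,
            "p_permutation": r.enrichment.p_permutation,
            "bias_call": r.bias_call,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def top_biased_compounds(
    util: PresenceMatrix,
    labels: CompartmentLabels,
    k: int,
    direction: str,
) -> pd.DataFrame:
    """Top-k compounds ranked by compartment utilization-fraction gap.

    Score per compound = fraction of ``direction`` strains using it minus
    the fraction of the other compartment's strains; descending order,
    ties broken by compound id.
    """
    if direction not in COMPARTMENTS:
        raise ValueError(f"unknown compartment {direction!r}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(util.features):
        raise ValueError(
            f"k={k} exceeds the {len(util.features)} compounds in the matrix"
        )
    labels.require_cover(util.strains)
    labels.require_both_compartments(util.strains)
    r_strains, e_strains = labels.split(util.strains)
    frac_r = util.data.loc[r_strains].mean(axis=0)
    frac_e = util.data.loc[e_strains].mean(axis=0)
    score = (frac_r - frac_e) if direction == RHIZOSPHERE else (frac_e - frac_r)
    df = pd.DataFrame(
        {"compound": util.features, "bias_score": score.to_numpy()}
    )
    df = df.sort_values(
        ["bias_score", "compound"], ascending=[False, True], kind="mergesort"
    ).head(k)
    return df.reset_index(drop=True)
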