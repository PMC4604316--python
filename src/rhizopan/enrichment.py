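"""Contingency chi-square tests for compartment bias in binary traits.

Two inferential routes are offered for every test: the asymptotic
Pearson chi-square p-value (no continuity correction) and a label-
permutation p-value that shuffles strains across compartments while
preserving group sizes. With a handful of strains per compartment the
expected cell counts are small and the asymptotic reference is
unreliable, so the permutation p is the recommended result whenever
``min_expected`` dips below 5 (a warning is logged in that case).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateTableError
from .io_cli.types import (
    CompartmentLabels,
    ENDOSPHERE,
    PresenceMatrix,
    RHIZOSPHERE,
)

logger = logging.getLogger(__name__)

#: Tolerance used when comparing permuted statistics to the observed one.
_TIE_EPS = 1e-12


@dataclass(frozen=True)
class ContingencyTable:
    """A 2 x K table of non-negative counts with labelled margins."""

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != 2:
            raise ValueError(f"expected a 2 x K table, got shape {counts.shape}")
        if (counts < 0).any():
            raise ValueError("negative count in contingency table")
        if counts.sum() < 1:
            raise ValueError("contingency table grand total must be >= 1")
        if len(self.row_labels) != 2 or len(self.col_labels) != counts.shape[1]:
            raise ValueError("margin labels do not match table shape")
        object.__setattr__(self, "counts", counts)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass(frozen=True)
class EnrichmentResult:
    """Outcome of one non-homogeneity test."""

    chi2: float
    df: int
    p_asymptotic: float
    min_expected: float
    direction: str | None
    significant: bool
    alpha: float
    p_permutation: float | None = None

    @property
    def p_value(self) -> float:
        """Permutation p when available, asymptotic otherwise."""
        return self.p_asymptotic if self.p_permutation is None else self.p_permutation


# ---------------------------------------------------------------------------
# table construction
# ---------------------------------------------------------------------------

def build_trait_table(
    traits: PresenceMatrix, labels: CompartmentLabels, trait_id: str
) -> ContingencyTable:
    """2x2 table of (compartment) x (positive, negative) strain counts."""
    labels.require_cover(traits.strains)
    labels.require_both_compartments(traits.strains)
    x = traits.feature_vector(trait_id)
    r_strains, e_strains = labels.split(traits.strains)
    pos = pd.Series(x, index=traits.strains)
    pos_r = int(pos.loc[r_strains].sum())
    pos_e = int(pos.loc[e_strains].sum())
    counts = np.array(
        [[pos_r, len(r_strains) - pos_r], [pos_e, len(e_strains) - pos_e]]
    )
    return ContingencyTable(
        counts, (RHIZOSPHERE, ENDOSPHERE), ("positive", "negative")
    )


# ---------------------------------------------------------------------------
# chi-square machinery
# ---------------------------------------------------------------------------

def _pearson_chi2(tables: np.ndarray) -> np.ndarray:
    """Pearson chi-square of one or many 2 x K tables (last two axes).

    Cells with zero expectation contribute zero (their observed count is
    necessarily zero too when the zero comes from a margin).
    """
    tables = np.asarray(tables, dtype=np.float64)
    rows = tables.sum(axis=-1, keepdims=True)
    cols = tables.sum(axis=-2, keepdims=True)
    total = tables.sum(axis=(-1, -2), keepdims=True)
    expected = rows * cols / total
    contrib = np.divide(
        (tables - expected) ** 2,
        expected,
        out=np.zeros_like(expected),
        where=expected > 0,
    )
    return contrib.sum(axis=(-1, -2))


def chi_square(table: ContingencyTable, alpha: float = 0.05) -> EnrichmentResult:
    """Pearson chi-square test of homogeneity, no continuity correction."""
    counts = table.counts
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    for margin, labels_, name in (
        (row_sums, table.row_labels, "row"),
        (col_sums, table.col_labels, "column"),
    ):
        zero = [labels_[i] for i in np.nonzero(margin == 0)[0]]
        if zero:
            raise DegenerateTableError(
                f"all-zero {name} margin for {zero}; chi-square undefined"
            )
    expected = np.outer(row_sums, col_sums) / counts.sum()
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    if df == 0:
        raise DegenerateTableError("single-column table has zero degrees of freedom")
    p = float(stats.chi2.sf(chi2, df))
    min_expected = float(expected.min())
    if min_expected < 5:
        logger.warning(
            "minimum expected cell count %.2f < 5; asymptotic p unreliable, "
            "prefer the permutation p", min_expected,
        )
    direction = None
    if table.shape == (2, 2) and table.col_labels == ("positive", "negative"):
        frac = counts[:, 0] / row_sums
        if frac[0] != frac[1]:
            direction = table.row_labels[int(np.argmax(frac))]
    return EnrichmentResult(
        chi2=chi2,
        df=df,
        p_asymptotic=p,
        min_expected=min_expected,
        direction=direction,
        significant=p < alpha,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

def _random_group_masks(
    n: int, n_group: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_perm, n) boolean masks, each a uniform random n_group-subset."""
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    masks = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(masks, order[:, :n_group], True, axis=1)
    return masks


def _permutation_p_2x2(
    pos: np.ndarray,
    tot: np.ndarray,
    n_r: int,
    chi2_obs: float,
    n_perm: int,
    rng: np.random.Generator,
) -> float:
    """Permutation p for a pooled 2x2 (positive/negative) table.

    ``pos``/``tot`` give each strain's positive and total call counts
    (both 1s and a 1 for a plain binary trait); strains are reassigned to
    a random ``n_r``-sized rhizosphere group each round.
    """
    masks = _random_group_masks(len(pos), n_r, n_perm, rng)
    pos_r = masks @ pos
    tot_r = masks @ tot
    pos_all, tot_all = pos.sum(), tot.sum()
    tables = np.empty((n_perm, 2, 2), dtype=np.float64)
    tables[:, 0, 0] = pos_r
    tables[:, 0, 1] = tot_r - pos_r
    tables[:, 1, 0] = pos_all - pos_r
    tables[:, 1, 1] = (tot_all - tot_r) - (pos_all - pos_r)
    chi2_perm = _pearson_chi2(tables)
    exceed = int((chi2_perm >= chi2_obs - _TIE_EPS).sum())
    return (1 + exceed) / (n_perm + 1)


def _permutation_p_stacked(
    pos_matrix: np.ndarray,
    n_r: int,
    chi2_obs: float,
    n_perm: int,
    rng: np.random.Generator,
) -> float:
    """Permutation p for the stacked 2 x 2K (positive, negative per trait)
    table; ``pos_matrix`` is the strains x traits binary matrix."""
    n, k = pos_matrix.shape
    n_e = n - n_r
    masks = _random_group_masks(n, n_r, n_perm, rng)
    pos_r = masks.astype(np.int64) @ pos_matrix  # (n_perm, K)
    col_tot = pos_matrix.sum(axis=0)
    tables = np.empty((n_perm, 2, 2 * k), dtype=np.float64)
    tables[:, 0, 0::2] = pos_r
    tables[:, 0, 1::2] = n_r - pos_r
    tables[:, 1, 0::2] = col_tot[None, :] - pos_r
    tables[:, 1, 1::2] = n_e - (col_tot[None, :] - pos_r)
    chi2_perm = _pearson_chi2(tables)
    exceed = int((chi2_perm >= chi2_obs - _TIE_EPS).sum())
    return (1 + exceed) / (n_perm + 1)


def permutation_chi_square(
    traits: PresenceMatrix,
    labels: CompartmentLabels,
    trait_id: str,
    n_perm: int,
    seed: int | np.random.Generator | None,
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Chi-square test with a label-shuffling permutation p-value.

    ``p_permutation = (1 + #{chi2_perm >= chi2_obs}) / (n_perm + 1)``;
    compartment sizes are preserved by every shuffle, and the whole
    procedure is deterministic given a seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    table = build_trait_table(traits, labels, trait_id)
    result = chi_square(table, alpha=alpha)
    rng = np.random.default_rng(seed)
    x = traits.feature_vector(trait_id).astype(np.int64)
    n_r = len(labels.split(traits.strains)[0])
    p_perm = _permutation_p_2x2(
        x, np.ones_like(x), n_r, result.chi2, n_perm, rng
    )
    return replace(result, p_permutation=p_perm, significant=p_perm < alpha)


# ---------------------------------------------------------------------------
# multivariate (stacked) test and per-trait tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MultivariateEnrichment:
    overall: EnrichmentResult
    per_trait: dict[str, EnrichmentResult]
    table: ContingencyTable


def multivariate_enrichment(
    traits: PresenceMatrix,
    labels: CompartmentLabels,
    trait_ids: Sequence[str] | None = None,
    alpha: float = 0.05,
    n_perm: int = 0,
    seed: int | None = None,
) -> MultivariateEnrichment:
    """Joint non-homogeneity test across several traits.

    Stacks every trait's (positive, negative) compartment counts side by
    side into one 2 x 2K table and applies the chi-square test: equal
    per-trait fractions across compartments make the rows proportional
    (chi2 = 0), while compartment-aligned traits inflate the statistic.
    Per-trait 2x2 results are returned alongside; ``n_perm > 0`` adds a
    permutation p-value to the overall test.
    """
    if trait_ids is None:
        trait_ids = traits.features
    trait_ids = list(trait_ids)
    if len(trait_ids) < 2:
        raise ValueError("multivariate test needs at least two traits")
    labels.require_cover(traits.strains)
    labels.require_both_compartments(traits.strains)
    r_strains, e_strains = labels.split(traits.strains)
    sub = traits.restrict(features=trait_ids)
    pos_r = sub.data.loc[r_strains].sum(axis=0).to_numpy()
    pos_e = sub.data.loc[e_strains].sum(axis=0).to_numpy()
    k = len(trait_ids)
    counts = np.empty((2, 2 * k), dtype=np.int64)
    counts[0, 0::2] = pos_r
    counts[0, 1::2] = len(r_strains) - pos_r
    counts[1, 0::2] = pos_e
    counts[1, 1::2] = len(e_strains) - pos_e
    col_labels = tuple(
        f"{tid}:{cat}" for tid in trait_ids for cat in ("positive", "negative")
    )
    table = ContingencyTable(
        counts, (RHIZOSPHERE, ENDOSPHERE), col_labels
    )
    overall = chi_square(table, alpha=alpha)
    # direction: compartment with the higher mean positive fraction
    frac_r = float(pos_r.sum()) / (len(r_strains) * len(trait_ids))
    frac_e = float(pos_e.sum()) / (len(e_strains) * len(trait_ids))
    if frac_r != frac_e:
        direction = RHIZOSPHERE if frac_r > frac_e else ENDOSPHERE
        overall = replace(overall, direction=direction)
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        p_perm = _permutation_p_stacked(
            sub.values.astype(np.int64), len(r_strains),
            overall.chi2, n_perm, rng,
        )
        overall = replace(
            overall, p_permutation=p_perm, significant=p_perm < alpha
        )
    per_trait: dict[str, EnrichmentResult] = {}
    rng = np.random.default_rng(seed)
    for tid in trait_ids:
        try:
            if n_perm > 0:
                per_trait[tid] = permutation_chi_square(
                    traits, labels, tid, n_perm, rng, alpha=alpha
                )
            else:
                per_trait[tid] = chi_square(
                    build_trait_table(traits, labels, tid), alpha=alpha
                )
        except DegenerateTableError:
            per_trait[tid] = _degenerate_result(alpha)
    return MultivariateEnrichment(overall=overall, per_trait=per_trait,
                                  table=table)


def _degenerate_result(alpha: float) -> EnrichmentResult:
    """Placeholder for a trait whose table has a zero margin (constant
    trait): no evidence of non-homogeneity, statistic undefined."""
    return EnrichmentResult(
        chi2=float("nan"), df=1, p_asymptotic=float("nan"),
        min_expected=float("nan"), direction=None, significant=False,
        alpha=alpha,
    )


def enrichment_table(
    traits: PresenceMatrix,
    labels: CompartmentLabels,
    alpha: float = 0.05,
    n_perm: int = 0,
    seed: int | None = None,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-trait test table ready for TSV export.

    Columns: trait_id, chi2, df, p_asymptotic, p_permutation,
    min_expected, direction, significant (+ p_bh when requested).
    Constant traits are reported with NaN statistics rather than
    aborting the whole table.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for tid in traits.features:
        try:
            if n_perm > 0:
                res = permutation_chi_square(
                    traits, labels, tid, n_perm, rng, alpha=alpha
                )
            else:
                res = chi_square(build_trait_table(traits, labels, tid),
                                 alpha=alpha)
        except DegenerateTableError:
            logger.warning("trait %r is constant; statistic undefined", tid)
            res = _degenerate_result(alpha)
        rows.append(
            {
                "trait_id": tid,
                "chi2": res.chi2,
                "df": res.df,
                "p_asymptotic": res.p_asymptotic,
                "p_permutation": res.p_permutation,
                "min_expected": res.min_expected,
                "direction": res.direction or "none",
                "significant": res.significant,
            }
        )
    df = pd.DataFrame(rows)
    if bh_correct and len(df):
        from statsmodels.stats.multitest import multipletests

        pcol = "p_permutation" if n_perm > 0 else "p_asymptotic"
        pvals = df[pcol].to_numpy(dtype=float)
        ok = ~np.isnan(pvals)
        adjusted = np.full_like(pvals, np.nan)
        if ok.any():
            adjusted[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
        df["p_bh"] = adjusted
        df["significant"] = (df["p_bh"] < alpha).fillna(False)
    return df
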