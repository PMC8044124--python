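"""Association of genomic alterations and basal expression with co-resistance cases.

A "case" is one co-resistant drug pair (its co-resistant cell-line set).  For
each case and feature kind (copy-number amplification or deletion of recurrent
segments, driver-gene mutation, CpG hypermethylation) the per-feature
alteration fraction among the case's co-resistant lines is computed; cases are
then compared by correlating these frequency vectors over shared features.
Expression analyses stratify cell lines by a marker gene's raw intensity
(default EGFR at a baseline of 4) and rank a receptor-tyrosine-kinase list by
standardized mean expression within each case/stratum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coresistance import CoResistancePair
from .errors import (
    EmptyProfileError,
    GeneLookupError,
    InsufficientDataError,
)

MUTATION_TYPES = ("missense", "nonsense", "essential_splicing", "frameshift")

STRATUM_LOW = "low"
STRATUM_HIGH = "high"

DEFAULT_EXPRESSION_CUTOFF = 4.0


@dataclass
class AlterationProfile:
    """Per-feature alteration frequencies among one case's co-resistant lines."""

    case_id: str
    feature_kind: str
    frequencies: pd.Series  # feature -> fraction altered, NaN-free
    denominators: pd.Series  # feature -> number of lines with data


@dataclass
class AssociationMatrix:
    """Case × case correlation matrix of alteration-frequency vectors."""

    feature_kind: str
    method: str
    matrix: pd.DataFrame  # symmetric, unit diagonal, entries in [-1, 1] or NaN


@dataclass
class MutationTypeProfile:
    """Mutation-type composition among a case's co-resistant lines."""

    case_id: str
    counts: dict[str, int]
    proportions: dict[str, float]


@dataclass
class ExpressionStrata:
    """Cell lines split by a stratifier gene's expression at a raw-intensity cutoff.

    ``high`` holds lines with value >= cutoff (boundary inclusive), ``low``
    the rest; lines with missing expression belong to neither stratum.
    """

    gene: str
    cutoff: float
    low: frozenset[str]
    high: frozenset[str]


def case_alteration_frequency(
    features: pd.DataFrame,
    case: CoResistancePair,
    feature_kind: str,
) -> AlterationProfile:
    """Per-feature altered fraction among the case's co-resistant lines.

    ``features`` is a cell-line × feature 0/1 matrix (NaN = no data).  The
    denominator for each feature is the number of co-resistant lines with
    data for that feature; features with no data in any case line are omitted
    (missing is not absence).
    """
    lines = sorted(case.co_resistant_lines & set(features.index))
    if not lines:
        raise EmptyProfileError(
            f"case {case.case_id} has no co-resistant line with {feature_kind} data"
        )
    sub = features.loc[lines].astype(float)
    denom = sub.notna().sum()
    keep = denom > 0
    freq = sub.mean(skipna=True)[keep]
    return AlterationProfile(
        case_id=case.case_id,
        feature_kind=feature_kind,
        frequencies=freq,
        denominators=denom[keep].astype(int),
    )


def association_matrix(
    profiles: Sequence[AlterationProfile],
    method: str = "pearson",
    min_shared: int = 3,
) -> AssociationMatrix:
    """Pairwise correlation of case frequency vectors over shared features.

    ``method`` is ``"pearson"`` (default), ``"spearman"``, or ``"jaccard"``
    (on profiles binarized at frequency > 0).  Entries with fewer than
    ``min_shared`` shared features, or a zero-variance vector, are NaN.
    """
    if len(profiles) < 2:
        raise InsufficientDataError("association matrix needs at least 2 profiles")
    ids = [p.case_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate case ids among profiles")
    m = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for i, pi in enumerate(profiles):
        for j in range(i + 1, len(profiles)):
            pj = profiles[j]
            shared = pi.frequencies.index.intersection(pj.frequencies.index)
            val = np.nan
            if len(shared) >= min_shared:
                a = pi.frequencies[shared].to_numpy()
                b = pj.frequencies[shared].to_numpy()
                if method == "jaccard":
                    xa, xb = a > 0, b > 0
                    union = (xa | xb).sum()
                    val = (xa & xb).sum() / union if union else np.nan
                elif np.ptp(a) > 0 and np.ptp(b) > 0:
                    if method == "pearson":
                        val = stats.pearsonr(a, b).statistic
                    elif method == "spearman":
                        val = stats.spearmanr(a, b).statistic
                    else:
                        raise ValueError(f"unknown association method {method!r}")
                elif method not in ("pearson", "spearman"):
                    raise ValueError(f"unknown association method {method!r}")
            m.iloc[i, j] = m.iloc[j, i] = val
    return AssociationMatrix(
        feature_kind=profiles[0].feature_kind, method=method, matrix=m
    )


def mutation_type_profile(
    mutations: pd.DataFrame, case: CoResistancePair
) -> MutationTypeProfile:
    """Mutation-type proportions among the case's co-resistant lines.

    ``mutations`` is a long table with columns ``cell_line``, ``gene``,
    ``mutation_type``; proportions are over the four canonical types and sum
    to 1.
    """
    _check_mutation_table(mutations)
    sub = mutations[mutations["cell_line"].isin(case.co_resistant_lines)]
    if sub.empty:
        raise EmptyProfileError(
            f"no mutation record among co-resistant lines of case {case.case_id}"
        )
    counts = {t: int((sub["mutation_type"] == t).sum()) for t in MUTATION_TYPES}
    total = sum(counts.values())
    proportions = {t: c / total for t, c in counts.items()}
    return MutationTypeProfile(case_id=case.case_id, counts=counts, proportions=proportions)


def _check_mutation_table(mutations: pd.DataFrame) -> None:
    required = {"cell_line", "gene", "mutation_type"}
    missing = required - set(mutations.columns)
    if missing:
        raise ValueError(f"mutation table missing columns: {sorted(missing)}")
    bad = set(mutations["mutation_type"]) - set(MUTATION_TYPES)
    if bad:
        raise ValueError(f"unknown mutation types: {sorted(bad)}")


def mutation_frequency_table(
    mutations: pd.DataFrame,
    lines: Sequence[str],
    genes: Sequence[str],
    by: str = "mutation_type",
) -> pd.DataFrame:
    """Gene × bin mutation-frequency table over a set of cell lines.

    With ``by="mutation_type"`` each bin is a mutation type and the value is
    the fraction of the given lines carrying that gene/type; a (gene, type)
    combination with no record anywhere in the table is NaN (no input data,
    as opposed to an observed zero).  With ``by="cell_line"`` each bin is a
    line and the value is a 0/1 mutated indicator for the gene.
    """
    _check_mutation_table(mutations)
    lines = list(lines)
    sub = mutations[mutations["cell_line"].isin(lines) & mutations["gene"].isin(genes)]
    if by == "mutation_type":
        out = pd.DataFrame(np.nan, index=list(genes), columns=list(MUTATION_TYPES))
        any_record = mutations.groupby(["gene", "mutation_type"]).size()
        for g in genes:
            for t in MUTATION_TYPES:
                if (g, t) not in any_record.index:
                    continue  # no input data for this gene/type at all
                carriers = sub[(sub["gene"] == g) & (sub["mutation_type"] == t)][
                    "cell_line"
                ].nunique()
                out.loc[g, t] = carriers / len(lines) if lines else np.nan
        return out
    if by == "cell_line":
        out = pd.DataFrame(0.0, index=list(genes), columns=lines)
        for g in genes:
            carriers = set(sub[sub["gene"] == g]["cell_line"])
            out.loc[g] = [1.0 if cl in carriers else 0.0 for cl in lines]
        return out
    raise ValueError(f"by must be 'mutation_type' or 'cell_line', got {by!r}")


def rtk_mutation_correlation(
    freq_table: pd.DataFrame, gene_a: str, gene_b: str
) -> tuple[float, int, float]:
    """Pearson correlation between two genes' mutation-frequency vectors.

    Bins where either gene has no data are dropped pairwise; fewer than 3
    remaining paired bins is an error.  Returns (r, n, two-sided p).
    """
    for g in (gene_a, gene_b):
        if g not in freq_table.index:
            raise GeneLookupError(g)
    a = freq_table.loc[gene_a]
    b = freq_table.loc[gene_b]
    mask = a.notna() & b.notna()
    n = int(mask.sum())
    if n < 3:
        raise InsufficientDataError(
            f"only {n} paired bins between {gene_a} and {gene_b}; need >= 3"
        )
    av, bv = a[mask].to_numpy(), b[mask].to_numpy()
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        raise InsufficientDataError("zero-variance frequency vector; correlation undefined")
    res = stats.pearsonr(av, bv)
    return float(res.statistic), n, float(res.pvalue)


def stratify_by_expression(
    expression: pd.DataFrame,
    gene: str = "EGFR",
    cutoff: float = DEFAULT_EXPRESSION_CUTOFF,
) -> ExpressionStrata:
    """Split cell lines into low/high strata by one gene's raw intensity."""
    if gene not in expression.columns:
        raise GeneLookupError(gene)
    col = expression[gene]
    present = col.dropna()
    high = frozenset(present.index[present >= cutoff])
    low = frozenset(present.index[present < cutoff])
    return ExpressionStrata(gene=gene, cutoff=float(cutoff), low=low, high=high)


def rank_rtks(
    expression: pd.DataFrame,
    cases: Sequence[CoResistancePair],
    strata: ExpressionStrata,
    rtk_list: Sequence[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardized RTK expression per case/stratum and a cross-case ranking.

    For each (case, stratum) cell the mean expression of every RTK over that
    case's co-resistant lines in the stratum is z-scored across the RTK list
    within the cell (so cases on different intensity baselines are
    comparable); the overall ranking is the descending cross-case mean of the
    z-scores.  Cells with no line are flagged missing (NaN rows).

    Returns
    -------
    long : tidy frame (case_id, stratum, gene, n_lines, mean_expression, z_score)
    ranking : frame (gene, mean_z, rank) sorted by rank
    """
    missing = [g for g in rtk_list if g not in expression.columns]
    if missing:
        raise GeneLookupError(f"RTK genes absent from expression matrix: {missing}")
    rtk_list = list(rtk_list)
    rows = []
    for case in cases:
        for stratum_name, stratum_lines in ((STRATUM_LOW, strata.low), (STRATUM_HIGH, strata.high)):
            lines = sorted(case.co_resistant_lines & stratum_lines & set(expression.index))
            if lines:
                means = expression.loc[lines, rtk_list].mean()
                sd = means.std(ddof=0)
                z = (means - means.mean()) / sd if sd > 0 else means * 0.0
            else:
                means = pd.Series(np.nan, index=rtk_list)
                z = pd.Series(np.nan, index=rtk_list)
            for g in rtk_list:
                rows.append(
                    {
                        "case_id": case.case_id,
                        "stratum": stratum_name,
                        "gene": g,
                        "n_lines": len(lines),
                        "mean_expression": means[g],
                        "z_score": z[g],
                    }
                )
    long = pd.DataFrame(rows)
    mean_z = long.groupby("gene")["z_score"].mean()
    ranking = (
        mean_z.rename("mean_z")
        .reset_index()
        .sort_values(["mean_z", "gene"], ascending=[False, True])
        .reset_index(drop=True)
    )
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    return long, ranking
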