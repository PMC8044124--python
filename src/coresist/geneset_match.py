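"""Case-specific top upregulated genes matched against annotated gene sets.

The question answered here: of the genes annotated to a phenotype program
(epithelial–mesenchymal transition, cancer stemness, or any custom list), what
fraction also appears among the top-k genes upregulated in a co-resistance
case's cell lines relative to the remaining evaluable lines?
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .coresistance import CoResistancePair
from .errors import InsufficientDataError

DEFAULT_TOP_K = 1000  # top upregulated genes retained per case

UPREGULATION_STATISTICS = ("mean_difference", "standardized_difference")


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (e.g. EMT, CSC) read from a one-gene-per-line file."""

    label: str
    members: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.label!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class TopGeneResult:
    """Ranked top-k upregulated genes for one co-resistance case."""

    case_id: str
    k: int
    statistic: str
    table: pd.DataFrame  # columns gene, score; scores non-increasing

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])


@dataclass
class MatchResult:
    """Overlap between a top-gene list and an annotated gene set."""

    case_id: str
    set_label: str
    proportion: float  # |top ∩ annotated| / |annotated|
    proportion_of_top: float  # |top ∩ annotated| / k, reported for transparency
    intersection: tuple[str, ...]
    n_annotated: int
    k: int


def top_upregulated(
    expression: pd.DataFrame,
    case: CoResistancePair,
    k: int = DEFAULT_TOP_K,
    statistic: str = "mean_difference",
) -> TopGeneResult:
    """Top-k genes upregulated in the case's co-resistant lines vs. the rest.

    The rest group is all *evaluable* lines of the case that are not
    co-resistant.  The default statistic is the difference of group means on
    the log-intensity scale; ``"standardized_difference"`` divides by the
    pooled standard deviation.  Ties are broken lexicographically by gene id.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if statistic not in UPREGULATION_STATISTICS:
        raise ValueError(f"statistic must be one of {UPREGULATION_STATISTICS}")
    case_lines = sorted(case.co_resistant_lines & set(expression.index))
    rest_lines = sorted(
        (case.evaluable_lines - case.co_resistant_lines) & set(expression.index)
    )
    if len(case_lines) < 2 or len(rest_lines) < 2:
        raise InsufficientDataError(
            f"case {case.case_id}: need >= 2 co-resistant and >= 2 other lines "
            f"with expression (got {len(case_lines)} and {len(rest_lines)})"
        )
    n_genes = expression.shape[1]
    if k > n_genes:
        warnings.warn(
            f"k={k} exceeds the {n_genes}-gene universe; truncating", stacklevel=2
        )
        k = n_genes
    case_mean = expression.loc[case_lines].mean()
    rest_mean = expression.loc[rest_lines].mean()
    score = case_mean - rest_mean
    if statistic == "standardized_difference":
        n1, n2 = len(case_lines), len(rest_lines)
        v1 = expression.loc[case_lines].var(ddof=1)
        v2 = expression.loc[rest_lines].var(ddof=1)
        pooled = (((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)) ** 0.5
        score = score / pooled.replace(0.0, float("nan"))
    table = (
        score.rename("score")
        .rename_axis("gene")
        .reset_index()
        .dropna(subset=["score"])
        .sort_values(["score", "gene"], ascending=[False, True])
        .head(k)
        .reset_index(drop=True)
    )
    return TopGeneResult(case_id=case.case_id, k=k, statistic=statistic, table=table)


def match_proportion(top: TopGeneResult, annotated: GeneSet) -> MatchResult:
    """Fraction of an annotated gene set present among the case's top genes."""
    top_genes = set(top.genes)
    inter = tuple(sorted(top_genes & annotated.members))
    return MatchResult(
        case_id=top.case_id,
        set_label=annotated.label,
        proportion=len(inter) / len(annotated),
        proportion_of_top=len(inter) / len(top_genes) if top_genes else 0.0,
        intersection=inter,
        n_annotated=len(annotated),
        k=len(top_genes),
    )


def match_table(
    tops: Iterable[TopGeneResult], gene_sets: Sequence[GeneSet]
) -> pd.DataFrame:
    """Per-case × per-set overlap table (tidy)."""
    rows = []
    for top in tops:
        for gs in gene_sets:
            m = match_proportion(top, gs)
            rows.append(
                {
                    "case_id": m.case_id,
                    "gene_set": m.set_label,
                    "n_annotated": m.n_annotated,
                    "k": m.k,
                    "n_matched": len(m.intersection),
                    "proportion_of_set": m.proportion,
                    "proportion_of_top": m.proportion_of_top,
                }
            )
    return pd.DataFrame(rows)
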