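"""Pairwise co-resistance: counting, normalization, binning, ranking, networks.

Two frequency notions coexist and are labelled throughout:

* network edges carry the min–max-normalized joint co-resistance count over a
  pair set (``normalized_frequency``);
* panel rankings use the conditional co-resistance fraction among the lines
  resistant to a panel drug (``RankTable.scores``), the quantity under which
  "rank of drug X among lines resistant to drug Y" is well defined.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .binarize import RESISTANT, SensitivityCalls
from .errors import (
    ConfigurationError,
    DegenerateDataError,
    DrugLookupError,
    EmptyPanelError,
)

DEGREE_LOW = "low"
DEGREE_MID = "mid"
DEGREE_HIGH = "high"

#: Degree-bin boundaries on the normalized-frequency scale: low = [0, 0.10),
#: mid = [0.10, 0.60), high = [0.60, 1].
DEGREE_BIN_EDGES = (0.10, 0.60)


@dataclass(frozen=True)
class CoResistancePair:
    """A drug pair with its co-resistant cell-line set.

    Symmetric in (drug_a, drug_b).  ``normalized_frequency`` and
    ``degree_bin`` are filled by :func:`normalize_frequencies`.
    """

    drug_a: str
    drug_b: str
    co_resistant_lines: frozenset[str]
    evaluable_lines: frozenset[str]
    count: int
    normalized_frequency: float | None = None
    degree_bin: str | None = None

    @property
    def case_id(self) -> str:
        return f"{self.drug_a}<->{self.drug_b}"


@dataclass(frozen=True)
class RankTable:
    """Conditional co-resistance ranking of drugs within a resistant-line panel."""

    panel_drug: str
    panel_size: int
    focal_drug: str
    scores: dict[str, float]
    evaluable: dict[str, int]
    order: tuple[str, ...]
    rank: int
    n_ranked: int
    exclusions: frozenset[str]


@dataclass
class LineageProfile:
    """Per-lineage co-resistance frequencies for one drug pair, relative to pan-cancer."""

    drug_a: str
    drug_b: str
    pan_cancer_frequency: float
    table: pd.DataFrame  # lineage, n_evaluable, n_co_resistant, frequency, relative, flagged


def coresistance_count(
    calls: SensitivityCalls, drug_a: str, drug_b: str
) -> CoResistancePair:
    """Count cell lines resistant to both drugs.

    Evaluable lines are those with a non-missing call for *both* drugs; lines
    missing either call are excluded entirely.
    """
    for d in (drug_a, drug_b):
        if d not in calls.calls.columns:
            raise DrugLookupError(d)
    a = calls.calls[drug_a]
    b = calls.calls[drug_b]
    evaluable = a.notna() & b.notna()
    both_resistant = evaluable & (a == RESISTANT) & (b == RESISTANT)
    co = frozenset(a.index[both_resistant])
    ev = frozenset(a.index[evaluable])
    return CoResistancePair(
        drug_a=drug_a,
        drug_b=drug_b,
        co_resistant_lines=co,
        evaluable_lines=ev,
        count=len(co),
    )


def enumerate_pairs(
    calls: SensitivityCalls,
    drugs_a: Sequence[str] | None = None,
    drugs_b: Sequence[str] | None = None,
) -> list[CoResistancePair]:
    """All co-resistance pairs between two drug families (or all unordered pairs).

    With both families given, pairs are the cross product (minus self-pairs,
    deduplicated); with neither, all unordered pairs of drugs in the calls.
    """
    if drugs_a is None and drugs_b is None:
        combos: Iterable[tuple[str, str]] = itertools.combinations(calls.drug_ids, 2)
    else:
        da = list(drugs_a or calls.drug_ids)
        db = list(drugs_b or calls.drug_ids)
        seen: set[frozenset[str]] = set()
        combos = []
        for a, b in itertools.product(da, db):
            if a == b:
                continue
            key = frozenset((a, b))
            if key in seen:
                continue
            seen.add(key)
            combos.append((a, b))
    return [coresistance_count(calls, a, b) for a, b in combos]


def normalize_frequencies(pairs: Sequence[CoResistancePair]) -> list[CoResistancePair]:
    """Min–max rescale the raw co-resistance counts of a pair set to [0, 1].

    The degree bin is assigned from the normalized value.  Raises
    :class:`DegenerateDataError` when all counts are equal (zero range);
    callers may then fall back to raw fractions.
    """
    if len(pairs) < 2:
        raise DegenerateDataError("min–max scaling needs at least 2 pairs")
    counts = [p.count for p in pairs]
    lo, hi = min(counts), max(counts)
    if lo == hi:
        raise DegenerateDataError(
            f"all co-resistance counts equal ({lo}); min–max scaling undefined"
        )
    out = []
    for p in pairs:
        f = (p.count - lo) / (hi - lo)
        out.append(replace(p, normalized_frequency=f, degree_bin=bin_degree(f)))
    return out


def bin_degree(normalized_frequency: float) -> str:
    """Bin a normalized co-resistance frequency: [0,.1) low, [.1,.6) mid, [.6,1] high."""
    f = float(normalized_frequency)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"normalized frequency must lie in [0, 1], got {f}")
    lo_edge, hi_edge = DEGREE_BIN_EDGES
    if f < lo_edge:
        return DEGREE_LOW
    if f < hi_edge:
        return DEGREE_MID
    return DEGREE_HIGH


def rank_drug_in_panel(
    calls: SensitivityCalls,
    panel_drug: str,
    focal_drug: str,
    exclusions: Iterable[str] = (),
    similarity_groups: Mapping[str, str] | None = None,
    exclude_similar: bool = False,
) -> RankTable:
    """Rank all drugs by conditional co-resistance frequency in a resistant panel.

    The panel is the set of cell lines called resistant to ``panel_drug``.
    Every other non-excluded drug d gets
    ``score(d) = (# panel lines resistant to d) / (# panel lines non-missing for d)``.
    Drugs are sorted by descending score, ties broken by higher evaluable
    count then lexicographic drug id.  With ``exclude_similar`` and a
    similarity-group map, drugs sharing the focal drug's group (other than the
    focal drug itself) are removed before ranking — the "chemically similar
    drugs removed" re-ranking.
    """
    if focal_drug == panel_drug:
        raise ConfigurationError("focal drug must differ from the panel drug")
    exclusions = set(exclusions)
    if focal_drug in exclusions:
        raise ConfigurationError(f"focal drug {focal_drug!r} is excluded from ranking")
    panel = calls.resistant_lines(panel_drug)
    if not panel:
        raise EmptyPanelError(f"no cell line is resistant to {panel_drug!r}")
    if focal_drug not in calls.calls.columns:
        raise DrugLookupError(focal_drug)

    if exclude_similar and similarity_groups is not None:
        focal_group = similarity_groups.get(focal_drug)
        if focal_group is not None:
            exclusions |= {
                d
                for d, g in similarity_groups.items()
                if g == focal_group and d != focal_drug
            }
    if focal_drug in exclusions:
        raise ConfigurationError("exclusion rules removed the focal drug itself")

    panel_idx = sorted(panel)
    sub = calls.calls.loc[panel_idx]
    scores: dict[str, float] = {}
    evaluable: dict[str, int] = {}
    for d in calls.drug_ids:
        if d == panel_drug or d in exclusions:
            continue
        col = sub[d]
        n_eval = int(col.notna().sum())
        n_res = int((col == RESISTANT).sum())
        evaluable[d] = n_eval
        scores[d] = n_res / n_eval if n_eval else 0.0

    order = tuple(sorted(scores, key=lambda d: (-scores[d], -evaluable[d], d)))
    rank = order.index(focal_drug) + 1
    return RankTable(
        panel_drug=panel_drug,
        panel_size=len(panel),
        focal_drug=focal_drug,
        scores=scores,
        evaluable=evaluable,
        order=order,
        rank=rank,
        n_ranked=len(order),
        exclusions=frozenset(exclusions),
    )


def lineage_relative_frequencies(
    calls: SensitivityCalls,
    lineage_map: Mapping[str, str],
    drug_a: str,
    drug_b: str,
    min_evaluable: int = 3,
) -> LineageProfile:
    """Per-lineage co-resistance frequency for a pair, relative to pan-cancer.

    The pan-cancer frequency is co-resistant / evaluable over all lineages;
    each lineage's relative value is its own frequency divided by that.
    Lineages with fewer than ``min_evaluable`` evaluable lines (or an
    undefined ratio) are flagged; a zero pan-cancer frequency yields missing
    relative values rather than an error.
    """
    pair = coresistance_count(calls, drug_a, drug_b)
    missing_lineage = [cl for cl in pair.evaluable_lines if cl not in lineage_map]
    if missing_lineage:
        raise ConfigurationError(
            f"{len(missing_lineage)} evaluable cell lines lack a lineage label "
            f"(e.g. {sorted(missing_lineage)[:3]})"
        )
    pan = pair.count / len(pair.evaluable_lines) if pair.evaluable_lines else 0.0

    rows = []
    lineages = sorted({lineage_map[cl] for cl in pair.evaluable_lines} | set(lineage_map.values()))
    for lineage in lineages:
        ev = {cl for cl in pair.evaluable_lines if lineage_map[cl] == lineage}
        co = pair.co_resistant_lines & ev
        freq = len(co) / len(ev) if ev else float("nan")
        rel = freq / pan if ev and pan > 0 else float("nan")
        rows.append(
            {
                "lineage": lineage,
                "n_evaluable": len(ev),
                "n_co_resistant": len(co),
                "frequency": freq,
                "relative": rel,
                "flagged": len(ev) < min_evaluable or not (pan > 0),
            }
        )
    table = pd.DataFrame(rows)
    return LineageProfile(
        drug_a=drug_a, drug_b=drug_b, pan_cancer_frequency=pan, table=table
    )


def build_network(
    pairs: Sequence[CoResistancePair],
    calls: SensitivityCalls,
    drug_classes: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Build a drug co-resistance graph.

    Nodes are the drugs appearing in ``pairs`` with attributes ``drug_class``
    and ``resistant_count`` (node weight: number of resistant lines); edges
    carry ``count``, ``normalized_frequency`` and ``degree_bin``.  Pairs must
    have been through :func:`normalize_frequencies`.
    """
    g = nx.Graph()
    for p in pairs:
        if p.normalized_frequency is None:
            raise ValueError(
                f"pair {p.case_id} has no normalized frequency; "
                "run normalize_frequencies first"
            )
    drugs = sorted({d for p in pairs for d in (p.drug_a, p.drug_b)})
    for d in drugs:
        g.add_node(
            d,
            drug_class=(drug_classes or {}).get(d, "other"),
            resistant_count=len(calls.resistant_lines(d)),
        )
    for p in pairs:
        g.add_edge(
            p.drug_a,
            p.drug_b,
            count=p.count,
            normalized_frequency=float(p.normalized_frequency),
            degree_bin=p.degree_bin,
        )
    return g


def aggregate_partner_frequencies(
    pairs: Sequence[CoResistancePair],
    drugs: Sequence[str],
) -> pd.DataFrame:
    """Per-drug mean and sum of normalized co-resistance frequencies with its partners.

    The frequency-based drug ranking (e.g. RTK inhibitors against all
    antimitotics) is ambiguous between mean and sum aggregation, so both are
    reported, sorted by the mean.
    """
    rows = []
    for d in drugs:
        fs = [
            p.normalized_frequency
            for p in pairs
            if d in (p.drug_a, p.drug_b) and p.normalized_frequency is not None
        ]
        rows.append(
            {
                "drug": d,
                "n_partners": len(fs),
                "mean_normalized_frequency": sum(fs) / len(fs) if fs else float("nan"),
                "sum_normalized_frequency": sum(fs) if fs else float("nan"),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["mean_normalized_frequency", "drug"], ascending=[False, True]
    )
    return df.reset_index(drop=True)


def panel_coresistance_status(
    calls: SensitivityCalls,
    panel_drugs: Sequence[str],
    focal_drug: str,
) -> float:
    """Fraction of resistant-line panels in which the focal drug is co-resistant.

    A panel (one per panel drug) counts as co-resistant when at least one of
    its resistant lines is also resistant to the focal drug.  Panels with no
    resistant line are skipped.
    """
    hits = 0
    n = 0
    for pd_ in panel_drugs:
        if pd_ == focal_drug:
            continue
        pair = coresistance_count(calls, pd_, focal_drug)
        panel = calls.resistant_lines(pd_)
        if not panel:
            continue
        n += 1
        if pair.count > 0:
            hits += 1
    if n == 0:
        raise EmptyPanelError("no panel drug has any resistant line")
    return hits / n
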