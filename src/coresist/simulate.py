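"""Synthetic pharmacogenomic bundles with known ground truth.

The generator emulates the shape and statistical structure of a large public
cell-line drug-sensitivity resource: a cell-line × drug summary-response
matrix (per drug a two-component Gaussian mixture on the log-IC50 scale, one
component per latent sensitive/resistant state), drug and cell-line
annotations, long-format mutation calls, binary copy-number and
hypermethylation matrices, and a basal expression matrix.  Ground truth —
latent resistance states, planted co-resistant drug pairs, planted
upregulated gene sets, the planted AXL–EGFR expression correlation — is
returned alongside, so every downstream stage can be tested against a known
answer without downloads.

Randomness is hierarchical: one global seed, with an independent substream
per drug / gene / feature, so enlarging the panel does not perturb columns
that already existed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binarize import LOW_IS_SENSITIVE, ResponseMatrix
from .errors import ConfigurationError
from .geneset_match import GeneSet

# substream domains (second entry of the seed key)
_D_LATENT, _D_PAIR, _D_VALUES, _D_MISSING, _D_LINEAGE = 1, 2, 3, 4, 5
_D_MUT, _D_AMP, _D_DEL, _D_ICPG = 6, 7, 8, 9
_D_EXPR, _D_EXPR_JOINT, _D_PLANT, _D_SETS = 10, 11, 12, 13

#: 22 receptor tyrosine kinases, AXL and EGFR included.
DEFAULT_RTK_GENES = (
    "AXL", "EGFR", "ERBB2", "ERBB3", "ERBB4", "MET", "IGF1R", "INSR",
    "FGFR1", "FGFR2", "FGFR3", "FGFR4", "PDGFRA", "PDGFRB", "KIT", "FLT3",
    "RET", "ALK", "ROS1", "NTRK1", "DDR1", "EPHA2",
)

DEFAULT_MUTATION_TYPE_PROBS = {
    # missense dominates (> 45% of calls); essential splicing is rarest (> 2%)
    "missense": 0.47,
    "nonsense": 0.25,
    "essential_splicing": 0.03,
    "frameshift": 0.25,
}


def _rng(seed: int, domain: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed), domain, index])


@dataclass
class SimulationConfig:
    """Stated world of the generator.

    Defaults mirror the screened panel the pipeline targets: 1001 cell lines,
    265 drugs across 23 cancer lineages, a >17k-gene expression/mutation
    universe with a 22-member RTK list.  The response mixture places the
    resistant component 4σ above the sensitive one on the log-IC50 scale
    (resistant = high IC50), which is the separation regime the waterfall
    discretization is designed to split.
    """

    n_cell_lines: int = 1001
    n_drugs: int = 265
    drug_classes: Mapping[str, str] | None = None
    similarity_groups: Mapping[str, str] | None = None
    resistant_fraction: float | Mapping[str, float] = 0.3
    planted_pairs: Sequence[tuple[str, str, float]] | None = None
    sensitive_mean: float = -2.0
    resistant_mean: float = 2.0
    response_scale: float = 1.0
    missing_rate: float = 0.05
    n_genes: int = 17000
    rtk_genes: Sequence[str] = DEFAULT_RTK_GENES
    expression_coupling: float = 0.8  # AXL–EGFR correlation rho
    expression_loc: float = 5.0  # log-intensity baseline, spans the cutoff of 4
    expression_scale: float = 1.0
    axl_coresistance_shift: float = 3.0  # sigmas added to AXL in co-resistant lines
    upregulation_shift: float = 2.0  # sigmas added to planted genes in case lines
    upregulated_set_size: int = 50
    mutation_rate: float = 0.02
    mutation_type_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MUTATION_TYPE_PROBS)
    )
    alteration_base_rate: float = 0.1
    alteration_enrichment: float = 0.3  # delta added in co-resistant lines
    n_racs_amp: int = 200
    n_racs_del: int = 200
    n_icpg: int = 300
    emt_set_size: int = 342
    csc_set_size: int = 1782
    geneset_planted_fraction: float = 0.5
    n_lineages: int = 23
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cell_lines <= 0 or self.n_drugs <= 0 or self.n_genes <= 0:
            raise ConfigurationError("n_cell_lines, n_drugs and n_genes must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if not self.resistant_mean > self.sensitive_mean:
            raise ConfigurationError(
                "resistant-state response location must exceed the sensitive one "
                "(log-IC50 polarity is explicit)"
            )
        if self.response_scale <= 0:
            raise ConfigurationError("response_scale must be positive")
        if abs(self.expression_coupling) > 1.0:
            raise ConfigurationError("|expression_coupling| must not exceed 1")
        probs = self.mutation_type_probs
        if abs(sum(probs.values()) - 1.0) > 1e-9 or any(p < 0 for p in probs.values()):
            raise ConfigurationError("mutation_type_probs must be a distribution")
        if len(self.rtk_genes) != len(set(self.rtk_genes)):
            raise ConfigurationError("rtk_genes contains duplicates")
        if len(self.rtk_genes) > self.n_genes:
            raise ConfigurationError("rtk_genes larger than the gene universe")

        if self.drug_classes is None:
            self.drug_classes = default_drug_classes(self.drug_ids)
        unknown = set(self.drug_classes) - set(self.drug_ids)
        if unknown:
            raise ConfigurationError(f"drug_classes references unknown drugs: {sorted(unknown)}")
        if self.similarity_groups is None:
            self.similarity_groups = {d: d for d in self.drug_ids}
        if self.planted_pairs is None:
            self.planted_pairs = default_planted_pairs(self.drug_classes)
        seen_dependent: set[str] = set()
        for a, b, kappa in self.planted_pairs:
            for d in (a, b):
                if d not in set(self.drug_ids):
                    raise ConfigurationError(f"planted pair references unknown drug {d!r}")
            if a == b:
                raise ConfigurationError("planted pair must involve two distinct drugs")
            if not 0.0 <= kappa <= 1.0:
                raise ConfigurationError("coupling kappa must lie in [0, 1]")
            if b in seen_dependent:
                raise ConfigurationError(
                    f"drug {b!r} is the dependent member of more than one planted pair"
                )
            seen_dependent.add(b)
        for d in self.drug_ids:
            f = self.resistant_fraction_of(d)
            if not 0.0 < f < 1.0:
                raise ConfigurationError(
                    f"resistant fraction for {d!r} must lie in (0, 1), got {f}"
                )

    @property
    def drug_ids(self) -> list[str]:
        if self.drug_classes is not None:
            return list(self.drug_classes)
        return [f"drug_{j + 1:03d}" for j in range(self.n_drugs)]

    @property
    def cell_line_ids(self) -> list[str]:
        return [f"CL_{i + 1:04d}" for i in range(self.n_cell_lines)]

    @property
    def gene_ids(self) -> list[str]:
        extra = self.n_genes - len(self.rtk_genes)
        return list(self.rtk_genes) + [f"GENE_{g + 1:05d}" for g in range(extra)]

    def resistant_fraction_of(self, drug_id: str) -> float:
        if isinstance(self.resistant_fraction, Mapping):
            return float(self.resistant_fraction[drug_id])
        return float(self.resistant_fraction)


def default_drug_classes(drug_ids: Sequence[str]) -> dict[str, str]:
    """Class labels emulating the screened panel: 11 CTDs, a few further
    antimitotics, a block of RTK inhibitors, remainder unclassified.  Small
    panels keep the same proportions so at least one CTD and one RTK
    inhibitor always exist."""
    n = len(drug_ids)
    if n >= 32:
        b_ctd, b_anti, b_rtki = 11, 16, 32
    else:
        n_ctd = max(1, round(n * 11 / 32))
        n_anti = round(n * 5 / 32)
        n_rtki = max(1, round(n * 16 / 32))
        b_ctd = n_ctd
        b_anti = n_ctd + n_anti
        b_rtki = min(n, b_anti + n_rtki)
    classes = {}
    for j, d in enumerate(drug_ids):
        if j < b_ctd:
            classes[d] = "CTD"
        elif j < b_anti:
            classes[d] = "antimitotic"
        elif j < b_rtki:
            classes[d] = "RTK inhibitor"
        else:
            classes[d] = "other"
    return classes


def default_planted_pairs(
    drug_classes: Mapping[str, str], kappa: float = 0.9
) -> tuple[tuple[str, str, float], ...]:
    """Three strongly coupled pairs: the first RTK inhibitor against the
    first three CTDs (the gefitinib ↔ CTD motif)."""
    ctds = [d for d, c in drug_classes.items() if c == "CTD"]
    rtkis = [d for d, c in drug_classes.items() if c == "RTK inhibitor"]
    if not ctds or not rtkis:
        return ()
    anchor = rtkis[0]
    return tuple((anchor, c, kappa) for c in ctds[:3])


@dataclass
class SyntheticTruth:
    """Ground truth for one generated bundle."""

    latent_state: pd.DataFrame  # cell-line × drug bool; True = resistant
    true_threshold: dict[str, float]
    planted_pairs: tuple[tuple[str, str, float], ...]
    planted_upregulated_genes: dict[str, tuple[str, ...]] = field(default_factory=dict)
    planted_expression_correlation: float = 0.0

    def coresistant_lines(self, drug_a: str, drug_b: str) -> frozenset[str]:
        both = self.latent_state[drug_a] & self.latent_state[drug_b]
        return frozenset(self.latent_state.index[both])

    def any_planted_coresistant_lines(self) -> frozenset[str]:
        """Lines co-resistant (in truth) to at least one planted pair."""
        out: set[str] = set()
        for a, b, _ in self.planted_pairs:
            out |= self.coresistant_lines(a, b)
        return frozenset(out)


def generate_response_matrix(config: SimulationConfig) -> tuple[ResponseMatrix, SyntheticTruth]:
    """Draw latent resistance states and the response matrix they generate.

    Each drug's latent states are i.i.d. Bernoulli draws at its resistant
    fraction; for a planted pair (a, b, κ) the state of b is replaced by a's
    state with probability κ per line and redrawn independently otherwise.
    Responses are Gaussian around the state-conditional mean; missing entries
    are inserted uniformly at random.
    """
    drugs = config.drug_ids
    lines = config.cell_line_ids
    n = config.n_cell_lines
    seed = config.seed

    latent = {}
    for j, d in enumerate(drugs):
        latent[d] = _rng(seed, _D_LATENT, j).random(n) < config.resistant_fraction_of(d)
    col_index = {d: j for j, d in enumerate(drugs)}
    for a, b, kappa in config.planted_pairs:
        rng = _rng(seed, _D_PAIR, col_index[b])
        copy_mask = rng.random(n) < kappa
        redraw = rng.random(n) < config.resistant_fraction_of(b)
        latent[b] = np.where(copy_mask, latent[a], redraw)

    values = np.empty((n, len(drugs)))
    for j, d in enumerate(drugs):
        rng = _rng(seed, _D_VALUES, j)
        noise = rng.normal(0.0, config.response_scale, n)
        loc = np.where(latent[d], config.resistant_mean, config.sensitive_mean)
        values[:, j] = loc + noise
        miss = _rng(seed, _D_MISSING, j).random(n) < config.missing_rate
        values[miss, j] = np.nan

    matrix = ResponseMatrix(
        values=pd.DataFrame(values, index=lines, columns=drugs),
        polarity=LOW_IS_SENSITIVE,
        scale_label="log IC50 (µM)",
    )
    midpoint = (config.sensitive_mean + config.resistant_mean) / 2.0
    truth = SyntheticTruth(
        latent_state=pd.DataFrame(
            {d: latent[d] for d in drugs}, index=lines, columns=drugs
        ).astype(bool),
        true_threshold={d: midpoint for d in drugs},
        planted_pairs=tuple(config.planted_pairs),
        planted_expression_correlation=config.expression_coupling,
    )
    return matrix, truth


@dataclass
class GenomicFeatures:
    """Mutation long table plus binary alteration matrices."""

    mutations: pd.DataFrame  # columns cell_line, gene, mutation_type
    racs_amp: pd.DataFrame
    racs_del: pd.DataFrame
    icpg: pd.DataFrame


def _binary_feature_matrix(
    config: SimulationConfig,
    domain: int,
    prefix: str,
    n_features: int,
    enriched: np.ndarray,
) -> pd.DataFrame:
    p_base = config.alteration_base_rate
    p_hot = p_base + config.alteration_enrichment
    cols = {}
    for f in range(n_features):
        rng = _rng(config.seed, domain, f)
        p = np.where(enriched, p_hot, p_base)
        cols[f"{prefix}_{f + 1:04d}"] = (rng.random(config.n_cell_lines) < p).astype(int)
    return pd.DataFrame(cols, index=config.cell_line_ids)


def generate_genomic_features(
    config: SimulationConfig, truth: SyntheticTruth
) -> GenomicFeatures:
    """Mutations and binary alteration matrices coupled to resistance status.

    Alteration (and mutation) probability is the base rate plus the
    enrichment δ in cell lines co-resistant to at least one planted pair.
    """
    delta = config.alteration_enrichment
    if config.alteration_base_rate + delta > 1.0 or config.mutation_rate + delta > 1.0:
        raise ConfigurationError(
            "alteration enrichment pushes a probability above 1"
        )
    lines = np.array(config.cell_line_ids)
    hot = np.isin(lines, sorted(truth.any_planted_coresistant_lines()))

    types = list(config.mutation_type_probs)
    type_p = np.array([config.mutation_type_probs[t] for t in types])
    recs: list[tuple[str, str, str]] = []
    p = np.where(hot, config.mutation_rate + delta, config.mutation_rate)
    for g, gene in enumerate(config.gene_ids):
        rng = _rng(config.seed, _D_MUT, g)
        mutated = rng.random(config.n_cell_lines) < p
        idx = np.nonzero(mutated)[0]
        if idx.size:
            chosen = rng.choice(len(types), size=idx.size, p=type_p)
            recs.extend((lines[i], gene, types[c]) for i, c in zip(idx, chosen))
    mutations = pd.DataFrame(recs, columns=["cell_line", "gene", "mutation_type"])

    return GenomicFeatures(
        mutations=mutations,
        racs_amp=_binary_feature_matrix(config, _D_AMP, "RACS_AMP", config.n_racs_amp, hot),
        racs_del=_binary_feature_matrix(config, _D_DEL, "RACS_DEL", config.n_racs_del, hot),
        icpg=_binary_feature_matrix(config, _D_ICPG, "ICPG", config.n_icpg, hot),
    )


def generate_expression(
    config: SimulationConfig, truth: SyntheticTruth
) -> pd.DataFrame:
    """Basal expression matrix with planted structure.

    AXL and EGFR are jointly Gaussian with the configured correlation ρ; AXL
    additionally gains ``axl_coresistance_shift`` σ in lines co-resistant to
    any planted pair.  Each planted pair (a case) receives a disjoint set of
    ``upregulated_set_size`` non-RTK genes shifted up by
    ``upregulation_shift`` σ in that case's co-resistant lines; these are
    recorded in ``truth.planted_upregulated_genes``.  All remaining genes are
    independent noise on a log-intensity scale spanning the stratification
    cutoff.
    """
    genes = config.gene_ids
    lines = config.cell_line_ids
    n = config.n_cell_lines
    loc, sc = config.expression_loc, config.expression_scale

    values = np.empty((n, len(genes)))
    gene_pos = {g: j for j, g in enumerate(genes)}
    joint = {}
    if "AXL" in gene_pos and "EGFR" in gene_pos:
        rho = config.expression_coupling
        z = _rng(config.seed, _D_EXPR_JOINT, 0).standard_normal((n, 2))
        joint["AXL"] = loc + sc * z[:, 0]
        joint["EGFR"] = loc + sc * (rho * z[:, 0] + np.sqrt(1.0 - rho**2) * z[:, 1])
    for j, g in enumerate(genes):
        if g in joint:
            values[:, j] = joint[g]
        else:
            values[:, j] = _rng(config.seed, _D_EXPR, j).normal(loc, sc, n)

    line_index = {cl: i for i, cl in enumerate(lines)}
    hot = sorted(truth.any_planted_coresistant_lines())
    if "AXL" in gene_pos and hot:
        rows = [line_index[cl] for cl in hot]
        values[rows, gene_pos["AXL"]] += config.axl_coresistance_shift * sc

    non_rtk = [g for g in genes if g not in set(config.rtk_genes)]
    order = _rng(config.seed, _D_PLANT, 0).permutation(len(non_rtk))
    cursor = 0
    truth.planted_upregulated_genes = {}
    for a, b, _ in truth.planted_pairs:
        size = min(config.upregulated_set_size, len(non_rtk) - cursor)
        chosen = tuple(sorted(non_rtk[k] for k in order[cursor : cursor + size]))
        cursor += size
        case_lines = sorted(truth.coresistant_lines(a, b))
        rows = [line_index[cl] for cl in case_lines]
        for g in chosen:
            values[rows, gene_pos[g]] += config.upregulation_shift * sc
        truth.planted_upregulated_genes[f"{a}<->{b}"] = chosen

    return pd.DataFrame(values, index=lines, columns=genes)


def _synthetic_gene_set(
    config: SimulationConfig,
    truth: SyntheticTruth,
    label: str,
    size: int,
    stream: int,
) -> GeneSet:
    """Synthetic annotated set: a slice of each case's planted genes plus
    random non-RTK fill, emulating a curated phenotype-program list."""
    rng = _rng(config.seed, _D_SETS, stream)
    members: set[str] = set()
    for genes in truth.planted_upregulated_genes.values():
        take = int(round(config.geneset_planted_fraction * len(genes)))
        members |= set(rng.choice(list(genes), size=take, replace=False))
    pool = [
        g
        for g in config.gene_ids
        if g not in members and g not in set(config.rtk_genes)
    ]
    size = min(size, len(members) + len(pool))
    fill = size - len(members)
    if fill > 0:
        members |= set(rng.choice(pool, size=fill, replace=False))
    return GeneSet(label=label, members=frozenset(members), source="synthetic")


@dataclass
class SyntheticBundle:
    """Everything one generated world contains."""

    config: SimulationConfig
    truth: SyntheticTruth
    response: ResponseMatrix
    drug_annotations: pd.DataFrame  # drug, drug_class, similarity_group
    lineages: pd.DataFrame  # cell_line, lineage
    features: GenomicFeatures
    expression: pd.DataFrame
    gene_sets: dict[str, GeneSet]

    @property
    def lineage_map(self) -> dict[str, str]:
        return dict(zip(self.lineages["cell_line"], self.lineages["lineage"]))


def generate_bundle(config: SimulationConfig) -> SyntheticBundle:
    """Generate a complete bundle: response, annotations, features, expression, sets."""
    response, truth = generate_response_matrix(config)
    features = generate_genomic_features(config, truth)
    expression = generate_expression(config, truth)

    lin_rng = _rng(config.seed, _D_LINEAGE, 0)
    lineage_ids = [f"lineage_{k + 1:02d}" for k in range(config.n_lineages)]
    lineages = pd.DataFrame(
        {
            "cell_line": config.cell_line_ids,
            "lineage": [
                lineage_ids[i]
                for i in lin_rng.integers(0, config.n_lineages, config.n_cell_lines)
            ],
        }
    )
    drug_annotations = pd.DataFrame(
        {
            "drug": config.drug_ids,
            "drug_class": [config.drug_classes[d] for d in config.drug_ids],
            "similarity_group": [config.similarity_groups[d] for d in config.drug_ids],
        }
    )
    gene_sets = {
        "EMT": _synthetic_gene_set(config, truth, "EMT", config.emt_set_size, 0),
        "CSC": _synthetic_gene_set(config, truth, "CSC", config.csc_set_size, 1),
        "RTK": GeneSet(label="RTK", members=frozenset(config.rtk_genes), source="config"),
    }
    return SyntheticBundle(
        config=config,
        truth=truth,
        response=response,
        drug_annotations=drug_annotations,
        lineages=lineages,
        features=features,
        expression=expression,
        gene_sets=gene_sets,
    )


# %.17g round-trips float64 exactly while keeping files byte-stable per seed.
_FLOAT_FMT = "%.17g"


def write_bundle(bundle: SyntheticBundle, directory) -> dict[str, str]:
    """Write all bundle tables plus truth and a manifest; returns name → path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _write(name: str, fn) -> None:
        p = directory / name
        fn(p)
        paths[name] = str(p)

    _write(
        "response.csv",
        lambda p: bundle.response.values.to_csv(
            p, index_label="cell_line", float_format=_FLOAT_FMT
        ),
    )
    _write("drugs.csv", lambda p: bundle.drug_annotations.to_csv(p, index=False))
    _write("cell_lines.csv", lambda p: bundle.lineages.to_csv(p, index=False))
    _write(
        "mutations.tsv",
        lambda p: bundle.features.mutations.to_csv(p, sep="\t", index=False),
    )
    for name, frame in (
        ("racs_amp.csv", bundle.features.racs_amp),
        ("racs_del.csv", bundle.features.racs_del),
        ("icpg.csv", bundle.features.icpg),
    ):
        _write(name, lambda p, f=frame: f.to_csv(p, index_label="cell_line"))
    _write(
        "expression.csv",
        lambda p: bundle.expression.to_csv(
            p, index_label="cell_line", float_format=_FLOAT_FMT
        ),
    )
    for label, gs in bundle.gene_sets.items():
        _write(
            f"geneset_{label.lower()}.txt",
            lambda p, g=gs: p.write_text("\n".join(sorted(g.members)) + "\n"),
        )
    _write(
        "truth_latent_state.csv",
        lambda p: bundle.truth.latent_state.astype(int).to_csv(p, index_label="cell_line"),
    )
    truth_doc = {
        "true_threshold": bundle.truth.true_threshold,
        "planted_pairs": [list(t) for t in bundle.truth.planted_pairs],
        "planted_upregulated_genes": {
            k: list(v) for k, v in bundle.truth.planted_upregulated_genes.items()
        },
        "planted_expression_correlation": bundle.truth.planted_expression_correlation,
    }
    _write(
        "truth.json",
        lambda p: p.write_text(json.dumps(truth_doc, indent=2, sort_keys=True) + "\n"),
    )

    manifest = {
        "seed": bundle.config.seed,
        "n_cell_lines": bundle.config.n_cell_lines,
        "n_drugs": bundle.config.n_drugs,
        "n_genes": bundle.config.n_genes,
        "files": {
            "response.csv": list(bundle.response.values.shape),
            "expression.csv": list(bundle.expression.shape),
            "mutations.tsv": [int(len(bundle.features.mutations)), 3],
            "racs_amp.csv": list(bundle.features.racs_amp.shape),
            "racs_del.csv": list(bundle.features.racs_del.shape),
            "icpg.csv": list(bundle.features.icpg.shape),
        },
    }
    _write(
        "manifest.json",
        lambda p: p.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n"),
    )
    return paths
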