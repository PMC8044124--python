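"""End-to-end pipeline driver: binarize → co-resistance → association → gene sets.

Mirrors the full analysis on user-supplied flat tables: discretize the
response matrix, build the pair network between two drug families, rank the
focal drug in each panel, profile genomic alterations per co-resistance case,
rank RTK expression under marker stratification, and match annotated gene
sets against each case's top upregulated genes.  A run manifest records tool
version, config echo, input checksums, per-stage row counts and timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__, io
from .binarize import binarize_response
from .coresistance import (
    aggregate_partner_frequencies,
    build_network,
    coresistance_count,
    enumerate_pairs,
    normalize_frequencies,
    rank_drug_in_panel,
)
from .errors import ConfigurationError, DegenerateDataError, EmptyPanelError
from .geneset_match import match_table, top_upregulated
from .genomic_assoc import (
    association_matrix,
    case_alteration_frequency,
    mutation_type_profile,
    rank_rtks,
    stratify_by_expression,
)

logger = logging.getLogger("coresist")


@dataclass
class PipelineConfig:
    """All inputs and settings for one pipeline run."""

    response: str
    out_dir: str
    drugs: str | None = None  # drug annotations (drug, drug_class, similarity_group)
    cell_lines: str | None = None  # cell-line annotations (cell_line, lineage)
    mutations: str | None = None
    racs_amp: str | None = None
    racs_del: str | None = None
    icpg: str | None = None
    expression: str | None = None
    gene_sets: list[str] = field(default_factory=list)
    rtk_list: str | None = None
    polarity: str = "high_is_sensitive"
    linearity_cutoff: float = 0.95
    class_a: str = "CTD"  # panel family
    focal_drug: str | None = None
    stratifier_gene: str = "EGFR"
    expression_cutoff: float = 4.0
    top_k: int = 1000
    min_coresistant_lines: int = 2
    exclude_similar: bool = False
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def config_hash(self) -> str:
        doc = dataclasses.asdict(self)
        doc.pop("out_dir")  # hash identifies the analysis, not where it lands
        return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:12]


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _validate_inputs(config: PipelineConfig) -> dict[str, str]:
    """Fail fast: every referenced input must exist before any compute."""
    paths = {
        "response": config.response,
        "drugs": config.drugs,
        "cell_lines": config.cell_lines,
        "mutations": config.mutations,
        "racs_amp": config.racs_amp,
        "racs_del": config.racs_del,
        "icpg": config.icpg,
        "expression": config.expression,
        "rtk_list": config.rtk_list,
    }
    for i, gs in enumerate(config.gene_sets):
        paths[f"gene_set_{i}"] = gs
    missing = [f"{k}: {v}" for k, v in paths.items() if v is not None and not Path(v).exists()]
    if missing:
        raise ConfigurationError("missing input files — " + "; ".join(missing))
    if config.gene_sets and config.expression is None:
        raise ConfigurationError("gene-set matching requested but no expression file given")
    return {k: _checksum(v) for k, v in paths.items() if v is not None}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order and write every declared output table.

    Returns the run manifest (also written to ``manifest.json``).
    """
    started = datetime.now(timezone.utc).isoformat()
    checksums = _validate_inputs(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    row_counts: dict[str, int] = {}

    def emit(name: str, df: pd.DataFrame, **kw) -> None:
        io.write_stage_table(df, out / name, config_hash=chash, **kw)
        row_counts[name] = len(df)

    # ---- stage: binarize -------------------------------------------------
    logger.info("stage binarize: %s", config.response)
    try:
        response = io.read_response(config.response, polarity=config.polarity)
        calls = binarize_response(response, linearity_cutoff=config.linearity_cutoff)
    except Exception as exc:
        raise RuntimeError(f"stage binarize failed on {config.response}: {exc}") from exc
    io.write_calls(calls, out / "calls.csv", thresholds_path=out / "thresholds.csv")
    row_counts["calls.csv"] = len(calls.calls)

    drug_classes = (
        io.read_annotations(config.drugs, "drug", "drug_class") if config.drugs else {}
    )
    similarity = (
        io.read_annotations(config.drugs, "drug", "similarity_group")
        if config.drugs
        else {}
    )
    focal = config.focal_drug
    panel_drugs = [d for d, c in drug_classes.items() if c == config.class_a]

    # ---- stage: coresistance --------------------------------------------
    logger.info("stage coresistance: %d panel drugs, focal=%s", len(panel_drugs), focal)
    try:
        if focal and panel_drugs:
            pairs = enumerate_pairs(calls, panel_drugs, [focal])
        else:
            pairs = enumerate_pairs(calls)
        try:
            pairs = normalize_frequencies(pairs)
            normalized = True
        except DegenerateDataError:
            logger.warning("all pair counts equal; skipping min–max normalization")
            normalized = False
        pair_rows = pd.DataFrame(
            {
                "drug_a": [p.drug_a for p in pairs],
                "drug_b": [p.drug_b for p in pairs],
                "count": [p.count for p in pairs],
                "n_evaluable": [len(p.evaluable_lines) for p in pairs],
                "normalized_frequency": [p.normalized_frequency for p in pairs],
                "degree_bin": [p.degree_bin for p in pairs],
            }
        )
        emit("pairs.tsv", pair_rows, sep="\t", index=False)
        if normalized:
            net = build_network(pairs, calls, drug_classes)
            io.write_network(net, out / "network.graphml", out / "network_edges.tsv")
            row_counts["network_edges.tsv"] = net.number_of_edges()
            drugs_in = sorted({d for p in pairs for d in (p.drug_a, p.drug_b)})
            emit(
                "partner_frequencies.tsv",
                aggregate_partner_frequencies(pairs, drugs_in),
                sep="\t",
                index=False,
            )
        if focal:
            rank_rows = []
            for panel in panel_drugs:
                try:
                    rt = rank_drug_in_panel(
                        calls,
                        panel,
                        focal,
                        similarity_groups=similarity or None,
                        exclude_similar=config.exclude_similar,
                    )
                except EmptyPanelError:
                    continue
                rank_rows.append(
                    {
                        "panel_drug": panel,
                        "panel_size": rt.panel_size,
                        "focal_drug": focal,
                        "rank": rt.rank,
                        "n_ranked": rt.n_ranked,
                        "focal_score": rt.scores[focal],
                    }
                )
            emit("ranks.tsv", pd.DataFrame(rank_rows), sep="\t", index=False)
    except RuntimeError:
        raise
    except Exception as exc:
        raise RuntimeError(f"stage coresistance failed: {exc}") from exc

    # cases: focal drug against each panel drug, by co-resistant line count
    cases = []
    if focal:
        for panel in panel_drugs:
            pair = coresistance_count(calls, panel, focal)
            if pair.count >= config.min_coresistant_lines:
                cases.append(pair)

    # ---- stage: assoc ----------------------------------------------------
    try:
        feature_tables = {
            "RACS_amp": config.racs_amp,
            "RACS_del": config.racs_del,
            "iCpG_hypermethylation": config.icpg,
        }
        for kind, path in feature_tables.items():
            if path is None or len(cases) < 2:
                continue
            features = io.read_matrix(path)
            profiles = [case_alteration_frequency(features, c, kind) for c in cases]
            assoc = association_matrix(profiles)
            emit(f"assoc_{kind}.csv", assoc.matrix, index_label="case_id")
        if config.mutations and cases:
            mut = io.read_mutations(config.mutations)
            rows = []
            for c in cases:
                prof = mutation_type_profile(mut, c)
                for t, p in prof.proportions.items():
                    rows.append(
                        {
                            "case_id": c.case_id,
                            "mutation_type": t,
                            "count": prof.counts[t],
                            "proportion": p,
                        }
                    )
            emit("mutation_types.tsv", pd.DataFrame(rows), sep="\t", index=False)
        if config.expression and config.rtk_list and cases:
            expr = io.read_matrix(config.expression)
            rtks = sorted(io.read_gene_set(config.rtk_list, label="RTK").members)
            strata = stratify_by_expression(
                expr, config.stratifier_gene, config.expression_cutoff
            )
            long, ranking = rank_rtks(expr, cases, strata, rtks)
            emit("rtk_expression.tsv", long, sep="\t", index=False)
            emit("rtk_ranking.tsv", ranking, sep="\t", index=False)
    except RuntimeError:
        raise
    except Exception as exc:
        raise RuntimeError(f"stage assoc failed: {exc}") from exc

    # ---- stage: genesets -------------------------------------------------
    try:
        if config.expression and config.gene_sets and cases:
            expr = io.read_matrix(config.expression)
            gene_sets = [io.read_gene_set(p) for p in config.gene_sets]
            tops = [top_upregulated(expr, c, k=config.top_k) for c in cases]
            emit("geneset_matches.tsv", match_table(tops, gene_sets), sep="\t", index=False)
    except RuntimeError:
        raise
    except Exception as exc:
        raise RuntimeError(f"stage genesets failed: {exc}") from exc

    manifest = {
        "tool_version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": chash,
        "input_checksums": checksums,
        "row_counts": row_counts,
        "started": started,
        "finished": datetime.now(timezone.utc).isoformat(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
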