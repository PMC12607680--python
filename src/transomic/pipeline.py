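"""End-to-end orchestration from one validated config to Table-style reports.

Stages: diff -> enrich -> cma -> master -> drugs.  Up- and downregulated
gene sets are processed as two independent runs sharing one No set (the
unchanged genes' promoters).  Every report is TSV with a commented
provenance header (package version, config hash, seed); identical
config+seed yields byte-identical output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping, Sequence

from . import __version__
from ._util import report_header, stable_hash
from . import diff_integration as di
from . import composite_module as cm
from . import druggability as dg
from . import master_regulator as mr
from . import motif_enrichment as me
from .io_formats import (
    DiffTable,
    FormatError,
    read_compound_table,
    read_diff_table,
    read_drug_table,
    read_network,
    read_promoters_fasta,
    read_pwm_library,
)

logger = logging.getLogger(__name__)

STAGES = ("diff", "enrich", "cma", "master", "drugs")


class ConfigError(ValueError):
    """Raised for invalid pipeline configuration."""


@dataclass
class InputPaths:
    transcriptome: str = ""
    proteome: str = ""
    promoters: str = ""
    pwms: str = ""
    network_edges: str = ""
    network_nodes: str = ""
    drug_targets: str = ""
    compound_activities: str = ""
    gene_weights: str = ""


@dataclass
class SignificanceConfig:
    alpha: float = 0.05
    lfc_min: float = 0.0
    top_n: int = 300


@dataclass
class EnrichmentConfig:
    alpha: float = 0.01
    cutoff: float | None = None
    method: str = "fisher"


@dataclass
class CmaConfig:
    population_size: int = 100
    n_generations: int = 50
    mutation_prob: float = 0.2
    tournament_size: int = 3
    parsimony: float = 0.1
    stride: int = 10
    n_permutations: int = 0


@dataclass
class MasterConfig:
    radius: int = 12
    n_runs: int = 10_000
    fdr: float = 0.05


@dataclass
class DrugsConfig:
    tox_threshold: float = 0.5
    effect_threshold: float = 0.0
    target_threshold: float = 0.0
    w: float = 1.0
    diseases: list[str] = field(default_factory=lambda: ["DIS01"])


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "results"
    inputs: InputPaths = field(default_factory=InputPaths)
    significance: SignificanceConfig = field(default_factory=SignificanceConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    cma: CmaConfig = field(default_factory=CmaConfig)
    master: MasterConfig = field(default_factory=MasterConfig)
    drugs: DrugsConfig = field(default_factory=DrugsConfig)

    def config_hash(self) -> str:
        # out_dir does not affect the analysis, keep it out of the hash
        data = asdict(self)
        data.pop("out_dir")
        return stable_hash(data)


_SECTION_TYPES = {
    "inputs": InputPaths,
    "significance": SignificanceConfig,
    "enrichment": EnrichmentConfig,
    "cma": CmaConfig,
    "master": MasterConfig,
    "drugs": DrugsConfig,
}


def config_from_dict(data: Mapping[str, Any]) -> PipelineConfig:
    """Build a config from a nested mapping, rejecting unknown keys."""
    top_known = {"seed", "out_dir", *_SECTION_TYPES}
    unknown = sorted(set(data) - top_known)
    if unknown:
        raise ConfigError(f"unknown config keys: {unknown}")
    kwargs: dict[str, Any] = {}
    for key in ("seed", "out_dir"):
        if key in data:
            kwargs[key] = data[key]
    for section, cls in _SECTION_TYPES.items():
        if section in data:
            sub = data[section]
            known = set(cls.__dataclass_fields__)
            bad = sorted(set(sub) - known)
            if bad:
                raise ConfigError(f"unknown keys in section {section!r}: {bad}")
            kwargs[section] = cls(**sub)
    return PipelineConfig(**kwargs)


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML/JSON config file; defaults are filled and
    referenced input paths must exist."""
    import yaml

    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    config = config_from_dict(data)
    for name, value in asdict(config.inputs).items():
        if value and not Path(value).exists():
            raise ConfigError(f"input path for {name!r} does not exist: {value}")
    logger.info("config loaded: %s", json.dumps(asdict(config), sort_keys=True))
    return config


def config_to_dict(config: PipelineConfig) -> dict:
    return asdict(config)


# ---------------------------------------------------------------------------
# report writers
# ---------------------------------------------------------------------------


def _fmt(value: Any) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        if value != value:  # nan -> blank cell ('not applicable')
            return ""
        return f"{value:.6g}"
    return str(value)


def _write_tsv(path: Path, header: Sequence[str], rows: Sequence[Sequence[Any]],
               config_hash: str, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(report_header(config_hash, seed) + "\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def run_pipeline(
    config: PipelineConfig, from_stage: str | None = None, fast: bool = False
) -> dict[str, Path]:
    """Execute all stages, writing six reports plus a run manifest.

    ``from_stage`` resumes from previously written artifacts.  ``fast``
    shrinks GA and null-run sizes for smoke testing.  Returns a map of
    report name -> path.
    """
    if from_stage is not None and from_stage not in STAGES:
        raise ConfigError(f"unknown stage {from_stage!r}; expected one of {STAGES}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    seed = config.seed
    start = STAGES.index(from_stage) if from_stage else 0
    paths: dict[str, Path] = {}

    inp = config.inputs
    tx = read_diff_table(inp.transcriptome, "transcriptome")
    prot = read_diff_table(inp.proteome, "proteome")

    # ---- diff ----
    sig_path = {
        "transcriptome": out / "significance_transcriptome.tsv",
        "proteome": out / "significance_proteome.tsv",
    }
    conc_path = out / "concordance.tsv"
    if start <= STAGES.index("diff"):
        tx_calls = di.call_significance(tx, config.significance.alpha, config.significance.lfc_min)
        prot_calls = di.call_significance(
            prot, config.significance.alpha, config.significance.lfc_min
        )
        for layer, calls in (("transcriptome", tx_calls), ("proteome", prot_calls)):
            _write_tsv(
                sig_path[layer],
                ["feature_id", "direction", "significant", "log_fc", "p_value", "adj_p"],
                [
                    (c.feature_id, c.direction, int(c.significant), c.log_fc, c.p_value, c.adj_p)
                    for c in calls
                ],
                chash,
                seed,
            )
        records, summary = di.classify_concordance(tx_calls, prot_calls)
        _write_tsv(
            conc_path,
            ["feature_id", "class"],
            [(r.feature_id, r.concordance_class) for r in records],
            chash,
            seed,
        )
        with open(out / "concordance_summary.json", "w") as fh:
            json.dump(summary, fh, sort_keys=True, indent=1)
    else:
        tx_calls = _read_calls(sig_path["transcriptome"], "transcriptome")
        prot_calls = _read_calls(sig_path["proteome"], "proteome")
    paths["concordance"] = conc_path

    # gene sets per direction
    top_n = config.significance.top_n
    up_calls = [c for c in tx_calls if c.direction == "up"]
    down_calls = [c for c in tx_calls if c.direction == "down"]
    up_genes = di.top_n_by_significance(up_calls, top_n)
    down_genes = di.top_n_by_significance(down_calls, top_n)
    unchanged = [c.feature_id for c in tx_calls if not c.significant]

    library = read_pwm_library(inp.pwms)
    if config.enrichment.cutoff is not None:
        for mat in library:
            mat.cutoff = config.enrichment.cutoff

    import pandas as pd
    from Bio import SeqIO

    fasta_ids = {rec.id for rec in SeqIO.parse(inp.promoters, "fasta")}

    def promoter_set(yes_genes: list[str]):
        yes = [g for g in yes_genes if g in fasta_ids]
        no = [g for g in unchanged if g in fasta_ids]
        if not yes or not no:
            raise FormatError(
                "promoter FASTA does not cover both the significant and unchanged gene sets"
            )
        label_map = {g: "yes" for g in yes}
        label_map.update({g: "no" for g in no})
        return read_promoters_fasta(inp.promoters, label_map)

    directions = {"up": up_genes, "down": down_genes}
    cma_results: dict[str, cm.CMAResult] = {}
    enriched_tfs: dict[str, set[str]] = {}
    tf_reports: dict[str, Path] = {}

    for direction, genes in directions.items():
        promoters = promoter_set(genes)

        # ---- enrich ----
        enrich_file = out / f"enrichment_{direction}.tsv"
        if start <= STAGES.index("enrich"):
            rows = me.enrich_matrices(
                library,
                promoters,
                alpha=config.enrichment.alpha,
                method=config.enrichment.method,
            )
            _write_tsv(
                enrich_file,
                ["matrix_id", "tf_symbols", "yes_density", "no_density", "yes_no_ratio",
                 "p_value", "adj_p", "enriched"],
                [
                    (r.matrix_id, ",".join(r.tf_symbols), r.yes_site_density,
                     r.no_site_density, r.yes_no_ratio, r.p_value, r.adj_p, int(r.enriched))
                    for r in rows
                ],
                chash,
                seed,
            )

        # ---- cma ----
        module_file = out / f"module_{direction}.json"
        if start <= STAGES.index("cma"):
            cma_cfg = cm.GAConfig(
                population_size=min(config.cma.population_size, 24) if fast
                else config.cma.population_size,
                n_generations=min(config.cma.n_generations, 10) if fast
                else config.cma.n_generations,
                mutation_prob=config.cma.mutation_prob,
                tournament_size=config.cma.tournament_size,
                parsimony=config.cma.parsimony,
                stride=config.cma.stride,
                n_permutations=config.cma.n_permutations,
                seed=seed,
            )
            result = cm.fit_cma(library, promoters, cma_cfg)
            with open(module_file, "w") as fh:
                json.dump(
                    {
                        "module": cm.module_to_dict(result.module),
                        "wilcoxon_p": result.wilcoxon_p,
                        "tf_regulatory_scores": result.tf_regulatory_scores,
                        "seed": seed,
                    },
                    fh,
                    sort_keys=True,
                    indent=1,
                )
        else:
            result = _read_cma(module_file, library, promoters, config)
        cma_results[direction] = result

        # Table 1/2-shaped TF report
        enr_by_symbol: dict[str, float] = {}
        flagged: set[str] = set()
        if enrich_file.exists():
            enr = pd.read_csv(enrich_file, sep="\t", comment="#")
            for row in enr.itertuples(index=False):
                for sym in str(row.tf_symbols).split(","):
                    ratio = float(row.yes_no_ratio)
                    if sym not in enr_by_symbol or ratio > enr_by_symbol[sym]:
                        enr_by_symbol[sym] = ratio
                    if int(row.enriched):
                        flagged.add(sym)
        enriched_tfs[direction] = flagged
        tf_file = out / f"tf_report_{direction}.tsv"
        tf_rows = sorted(
            result.tf_regulatory_scores.items(), key=lambda kv: (-kv[1], kv[0])
        )
        _write_tsv(
            tf_file,
            ["gene_symbol", "regulatory_score", "yes_no_ratio"],
            [(sym, score, enr_by_symbol.get(sym)) for sym, score in tf_rows],
            chash,
            seed,
        )
        tf_reports[direction] = tf_file
        paths[f"tf_report_{direction}"] = tf_file

    # ---- master ----
    network = read_network(inp.network_edges, inp.network_nodes or None)
    node_genes = {n: list(a.gene_symbols) for n, a in network.node_annotations.items()}
    master_results: dict[str, list[mr.KeyNodeResult]] = {}
    for direction, result in cma_results.items():
        master_file = out / f"master_report_{direction}.tsv"
        if start <= STAGES.index("master"):
            module_tfs = {
                sym for mat in library for sym in mat.tf_symbols
                if mat.matrix_id in result.module.matrix_ids()
            }
            active_tfs = sorted(
                {t for t, s in result.tf_regulatory_scores.items() if s > 0}
                | module_tfs
                | enriched_tfs.get(direction, set())
            )
            tf_nodes = [
                n for n, syms in node_genes.items()
                if set(syms) & set(active_tfs)
                and network.node_annotations[n].is_transcription_factor
            ]
            n_runs = min(config.master.n_runs, 1000) if fast else config.master.n_runs
            scored = mr.empirical_null(
                network, tf_nodes, max_radius=config.master.radius,
                n_runs=n_runs, seed=seed,
            )
            candidates = mr.significant_candidates(scored, config.master.fdr)
            ranked = mr.total_rank(
                candidates, result.tf_regulatory_scores, tx, prot, node_genes
            )
            _write_tsv(
                master_file,
                ["master_molecule", "gene_symbols", "total_rank", "keynode_score",
                 "z_score", "fdr", "log_fc_transcriptome", "log_fc_proteome"],
                [
                    (
                        c.node,
                        ",".join(node_genes.get(c.node, [])),
                        c.total_rank,
                        c.keynode_score,
                        c.z_score,
                        c.fdr,
                        _best_lfc(c.node, node_genes, tx),
                        _best_lfc(c.node, node_genes, prot),
                    )
                    for c in ranked
                ],
                chash,
                seed,
            )
            master_results[direction] = ranked
        else:
            master_results[direction] = _read_master(master_file)
        paths[f"master_report_{direction}"] = master_file

    # ---- drugs ----
    if start <= STAGES.index("drugs"):
        drug_table = read_drug_table(inp.drug_targets)
        activity = read_compound_table(inp.compound_activities, inp.gene_weights)
        candidate_genes: dict[str, float] = {}
        gene_lfcs: dict[str, tuple[float | None, float | None]] = {}
        for ranked in master_results.values():
            for c in ranked:
                for gene in node_genes.get(c.node, []):
                    if gene not in candidate_genes or c.total_rank < candidate_genes[gene]:
                        candidate_genes[gene] = c.total_rank
                        gene_lfcs[gene] = (
                            _best_lfc(c.node, node_genes, tx),
                            _best_lfc(c.node, node_genes, prot),
                        )
        input_ranks = dict(candidate_genes)

        curated_file = out / "druggability_curated.tsv"
        curated_rows = []
        for gene in sorted(candidate_genes):
            score = dg.curated_druggability(gene, drug_table)
            if score > 0:
                lfc_tx, lfc_prot = gene_lfcs[gene]
                curated_rows.append(
                    (gene, score, candidate_genes[gene], lfc_tx, lfc_prot)
                )
        _write_tsv(
            curated_file,
            ["gene_symbol", "druggability_score", "total_rank",
             "log_fc_transcriptome", "log_fc_proteome"],
            curated_rows,
            chash,
            seed,
        )
        paths["druggability_curated"] = curated_file

        compound_file = out / "drug_rank_curated.tsv"
        scored = dg.score_curated(
            drug_table, input_ranks, config.drugs.diseases, w=config.drugs.w
        )
        _write_tsv(
            compound_file,
            ["compound_id", "t_score_psd", "d_score_psd", "clinical_validity", "drug_rank"],
            [
                (c.compound_id, c.t_score_psd, c.d_score_psd,
                 c.clinical_validity_score, c.drug_rank)
                for c in scored
            ],
            chash,
            seed,
        )

        predicted_file = out / "druggability_predicted.tsv"
        predicted = dg.predicted_druggability(
            sorted(candidate_genes),
            activity,
            tox_threshold=config.drugs.tox_threshold,
            effect_threshold=config.drugs.effect_threshold,
            target_threshold=config.drugs.target_threshold,
            diseases=config.drugs.diseases,
        )
        pred_rows = []
        for t in predicted:
            if t.druggability_score > 0:
                lfc_tx, lfc_prot = gene_lfcs[t.gene]
                pred_rows.append(
                    (t.gene, t.druggability_score, candidate_genes[t.gene], lfc_tx, lfc_prot)
                )
        _write_tsv(
            predicted_file,
            ["gene_symbol", "druggability_score", "total_rank",
             "log_fc_transcriptome", "log_fc_proteome"],
            pred_rows,
            chash,
            seed,
        )
        paths["druggability_predicted"] = predicted_file

    manifest = {
        "version": __version__,
        "seed": seed,
        "config_hash": chash,
        "config": asdict(config),
        "reports": {k: str(v) for k, v in sorted(paths.items())},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    paths["manifest"] = out / "manifest.json"
    return paths


def _best_lfc(node: str, node_genes: Mapping[str, Sequence[str]], table: DiffTable):
    best = None
    for gene in node_genes.get(node, ()):
        hit = table.lookup(gene)
        if hit is not None and (best is None or abs(hit[0]) > abs(best)):
            best = hit[0]
    return best


def _read_calls(path: Path, layer: str) -> list[di.SignificanceCall]:
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", comment="#")
    return [
        di.SignificanceCall(
            feature_id=str(r.feature_id),
            layer=layer,
            direction=str(r.direction),
            significant=bool(r.significant),
            log_fc=float(r.log_fc),
            p_value=float(r.p_value),
            adj_p=float(r.adj_p),
        )
        for r in frame.itertuples(index=False)
    ]


def _read_cma(module_file: Path, library, promoters, config: PipelineConfig) -> cm.CMAResult:
    with open(module_file) as fh:
        data = json.load(fh)
    module = cm.module_from_dict(data["module"])
    sequences = [r.sequence for r in promoters.yes_records + promoters.no_records]
    cache = cm.ScanCache(library, sequences, floor=0.0)
    n_yes = len(promoters.yes_records)
    import numpy as np

    scores = np.array(
        [cm._module_score_cached(module, cache, i, config.cma.stride)
         for i in range(len(sequences))]
    )
    return cm.CMAResult(
        module=module,
        wilcoxon_p=data["wilcoxon_p"],
        yes_scores=scores[:n_yes],
        no_scores=scores[n_yes:],
        tf_regulatory_scores=data["tf_regulatory_scores"],
        generations_run=0,
        seed=data["seed"],
        fitness=float("nan"),
    )


def _read_master(path: Path) -> list[mr.KeyNodeResult]:
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for r in frame.itertuples(index=False):
        out.append(
            mr.KeyNodeResult(
                node=str(r.master_molecule),
                keynode_score=float(r.keynode_score),
                reached_tfs=(),
                mean_distance=float("nan"),
                z_score=float(r.z_score),
                empirical_p=float("nan"),
                fdr=float(r.fdr),
                total_rank=float(r.total_rank),
            )
        )
    return out
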