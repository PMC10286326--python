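"""End-to-end pipeline driver: QC -> normalize -> DE -> rescue -> regulon -> scores -> correlation -> ORA.

The configuration maps arbitrary condition labels onto the three roles
(control, disease, treated) so the pipeline generalizes beyond any one
study's naming, validates before any compute, and produces deterministic
TSV outputs with provenance headers. Stages can be skipped independently;
a stage failure aborts with the stage name and a machine-readable code.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import pandas as pd
import yaml

from . import correlation, de, enrichment, io, qc, regulon, rescue
from .errors import ConfigurationError, ScRescueError

log = logging.getLogger(__name__)

STAGES = ("qc", "de", "rescue", "regulon", "score", "correlate", "ora")
ROLES = ("naive", "disease", "treated")


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    counts_path: str
    annotation_path: str
    out_dir: str
    groups: dict = field(default_factory=lambda: {r: r for r in ROLES})
    regulon_path: str | None = None
    gmt_path: str | None = None
    focal_tf: str | None = None
    focal_cluster: str | None = None
    focal_gene: str | None = None
    min_genes: int = 600
    max_mito: float = 0.15
    lfc_cut: float = 0.25
    p_cut: float = 0.05
    r_cut: float = 0.15
    corr_p_cut: float = 0.01
    top_n: int = 20
    top_k: int = 15
    min_cells: int = 3
    min_pct: float = 0.1
    score_seed: int | None = None
    mito_prefix: str = io.MITO_PREFIX
    skip: tuple = ()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.skip = tuple(cfg.skip or ())
        cfg.validate()
        return cfg

    def validate(self) -> None:
        missing_roles = [r for r in ROLES if r not in self.groups or not self.groups[r]]
        if missing_roles:
            raise ConfigurationError(f"group mapping must cover all roles; missing {missing_roles}")
        if not (0 <= self.max_mito <= 1):
            raise ConfigurationError("max_mito must be in [0, 1]")
        for name in ("min_genes", "min_cells", "top_n", "top_k"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name in ("p_cut", "corr_p_cut", "min_pct"):
            if not (0 <= getattr(self, name) <= 1):
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.lfc_cut < 0 or self.r_cut < -1:
            raise ConfigurationError("lfc_cut must be >= 0 and r_cut >= -1")
        bad = set(self.skip) - set(STAGES)
        if bad:
            raise ConfigurationError(f"unknown stages in skip: {sorted(bad)}")
        if "score" not in self.skip and self.regulon_path and self.score_seed is None:
            raise ConfigurationError(
                "score_seed is required when the score stage runs (seeds are mandatory)"
            )

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["skip"] = list(self.skip)  # YAML-safe
        return d


class _Stage:
    """Context that converts a stage failure into a labelled error."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and isinstance(exc, ScRescueError):
            exc.args = (f"[stage={self.name} code={type(exc).__name__}] {exc}",)
        return False


def run_pipeline(config: PipelineConfig, adata: ad.AnnData | None = None) -> dict:
    """Run every non-skipped stage; returns a dict of result objects.

    ``adata`` may be supplied directly (already annotated) to bypass file
    reading; otherwise the counts bundle and annotation TSV from the config
    are loaded. Outputs are written under ``config.out_dir``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.as_dict()
    results: dict = {}
    naive, disease, treated = (config.groups[r] for r in ROLES)

    if adata is None:
        with _Stage("load"):
            adata = io.read_counts(config.counts_path, mito_prefix=config.mito_prefix)
            ann = io.read_annotation(config.annotation_path)
            adata = io.attach_annotation(adata, ann)

    with _Stage("qc"):
        metrics = qc.compute_qc_metrics(adata)
        if "qc" in config.skip:
            kept = adata
        else:
            kept = qc.apply_qc(adata, min_genes=config.min_genes, max_mito=config.max_mito)
        io.write_tsv(metrics, out / "qc_metrics.tsv", cfg, index=True)
        norm = qc.normalize_cp10k(kept)
        results["adata"] = norm
        results["qc_metrics"] = metrics

    obs = norm.obs
    contrasts = {"EAU": (disease, naive), "PRG": (treated, disease)}
    if "de" not in config.skip:
        with _Stage("de"):
            deg_sets: dict[str, dict[str, de.DEGSet]] = {}
            tables: dict[tuple[str, str], pd.DataFrame] = {}
            for label, (ga, gb) in contrasts.items():
                celltypes = de.comparable_celltypes(obs, ga, gb, min_cells=config.min_cells)
                all_ct = sorted(obs["cluster"].astype(str).unique())
                log.info(
                    "contrast %s: %d cell types tested, %d skipped by the %d-cell rule",
                    label, len(celltypes), len(all_ct) - len(celltypes), config.min_cells,
                )
                deg_sets[label] = {}
                for ct in celltypes:
                    table = de.find_markers(
                        norm, ct, ga, gb, min_pct=config.min_pct, min_cells=config.min_cells
                    )
                    tables[(label, ct)] = table
                    io.write_tsv(table, out / f"de_{label}_{ct}.tsv", cfg)
                    deg_sets[label][ct] = de.threshold_degs(
                        table, config.lfc_cut, config.p_cut, contrast=label, cell_type=ct
                    )
            results["de_tables"] = tables
            results["deg_sets"] = deg_sets

    if "rescue" not in config.skip and "de" not in config.skip:
        with _Stage("rescue"):
            shared = sorted(set(results["deg_sets"]["EAU"]) & set(results["deg_sets"]["PRG"]))
            rescue_sets = {
                ct: rescue.derive_rescue_degs(
                    results["deg_sets"]["EAU"][ct], results["deg_sets"]["PRG"][ct]
                )
                for ct in shared
            }
            rows = [
                (ct, g, direction)
                for ct, rs in rescue_sets.items()
                for direction, genes in (("down", rs.down_rescue), ("up", rs.up_rescue))
                for g in sorted(genes)
            ]
            io.write_tsv(
                pd.DataFrame(rows, columns=["cell_type", "gene", "direction"]),
                out / "rescue_sets.tsv", cfg,
            )
            ratio_rows = []
            for ct, rs in rescue_sets.items():
                dr, ur = rescue.rescue_ratio(rs, results["deg_sets"]["EAU"][ct])
                ratio_rows.append((ct, dr, ur))
            io.write_tsv(
                pd.DataFrame(ratio_rows, columns=["cell_type", "down_ratio", "up_ratio"]),
                out / "rescue_ratios.tsv", cfg,
            )
            freq_frames = []
            for direction in ("down", "up", "both") if rescue_sets else ():
                freq, top = rescue.rescue_frequency(rescue_sets, direction, top_k=config.top_k)
                freq_frames.append(
                    pd.DataFrame({
                        "gene": freq.index, "direction": direction,
                        "n_cell_types": freq.values,
                        "in_top_k": [g in set(top) for g in freq.index],
                    })
                )
            if freq_frames:
                io.write_tsv(pd.concat(freq_frames), out / "rescue_frequency.tsv", cfg)
            comp = rescue.composition_table(obs)
            io.write_tsv(comp, out / "composition.tsv", cfg, index=True)
            lfc_rows = []
            for ct in comp.index:
                for label, (num, den) in {"disease_vs_naive": (disease, naive),
                                          "treated_vs_disease": (treated, disease)}.items():
                    lfc_rows.append(
                        (ct, label, rescue.proportion_log2fc(comp, ct, num, den))
                    )
            io.write_tsv(
                pd.DataFrame(lfc_rows, columns=["cluster", "comparison", "log2fc"]),
                out / "composition_log2fc.tsv", cfg,
            )
            results["rescue_sets"] = rescue_sets
            results["composition"] = comp

    if (
        "regulon" not in config.skip
        and config.regulon_path
        and results.get("rescue_sets")
    ):
        with _Stage("regulon"):
            reg = regulon.read_regulon_table(config.regulon_path)
            cluster = config.focal_cluster or sorted(results["rescue_sets"])[0]
            tf = config.focal_tf or sorted(reg["TF"].unique())[0]
            targets = regulon.rescue_target_genes(
                reg, tf, results["rescue_sets"][cluster].down_rescue, top_n=config.top_n
            )
            imp = reg[reg["TF"] == tf].set_index("target")["importance"]
            io.write_tsv(
                pd.DataFrame({"gene": targets, "importance": [imp[g] for g in targets],
                              "rank": range(1, len(targets) + 1)}),
                out / "rescue_target_genes.tsv", cfg,
            )
            results["rescue_target_genes"] = targets

            if "score" not in config.skip and targets:
                scores = regulon.module_score(
                    norm, targets, seed=config.score_seed, gene_set_id=f"{tf}_rescue_targets"
                )
                io.write_tsv(
                    scores.scores.rename("score").reset_index(),
                    out / "module_scores.tsv", cfg, seed=config.score_seed,
                )
                p_eau = regulon.score_group_test(scores, obs, disease, naive)
                p_prg = regulon.score_group_test(scores, obs, treated, disease)
                io.write_tsv(
                    pd.DataFrame({"comparison": ["disease_vs_naive", "treated_vs_disease"],
                                  "p": [p_eau, p_prg]}),
                    out / "module_score_tests.tsv", cfg, seed=config.score_seed,
                )
                results["module_scores"] = scores
                results["score_tests"] = {"disease_vs_naive": p_eau, "treated_vs_disease": p_prg}

    if (
        "correlate" not in config.skip
        and config.focal_gene
        and results.get("rescue_sets")
    ):
        with _Stage("correlate"):
            cluster = config.focal_cluster or sorted(results["rescue_sets"])[0]
            cells = (obs["cluster"].astype(str) == cluster).to_numpy()
            candidates = sorted(results["rescue_sets"][cluster].down_rescue - {config.focal_gene})
            if candidates:
                screened = correlation.screen_correlates(
                    norm, config.focal_gene, candidates, cells=cells,
                    r_cut=config.r_cut, p_cut=config.corr_p_cut,
                )
                io.write_tsv(screened, out / "correlation_screen.tsv", cfg)
                rho = correlation.spearman_matrix(
                    norm, [config.focal_gene] + candidates, cells=cells
                )
                io.write_tsv(rho, out / "correlation_matrix.tsv", cfg, index=True)
                results["correlation_screen"] = screened

    if "ora" not in config.skip and config.gmt_path and results.get("rescue_sets"):
        with _Stage("ora"):
            collection = io.read_gmt(config.gmt_path)
            universe = frozenset(norm.var_names)
            collection = enrichment.GeneSetCollection(
                sets=dict(collection.sets), universe=universe
            )
            frames = []
            for ct, rs in results["rescue_sets"].items():
                if rs.down_rescue:
                    tab = enrichment.run_ora(rs.down_rescue, collection)
                    tab.insert(0, "cell_type", ct)
                    frames.append(tab)
            if frames:
                io.write_tsv(pd.concat(frames), out / "ora.tsv", cfg)
                results["ora"] = pd.concat(frames)

    log.info("pipeline complete: outputs in %s", out)
    return results
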