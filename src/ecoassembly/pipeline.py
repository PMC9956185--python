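"""End-to-end orchestration: validate -> diversity -> spatial -> assembly -> report."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import (
    OTUTable,
    SampleMetadata,
    ValidationError,
    average_samples,
    dominant_taxa,
    filter_taxonomy,
    flag_hypoxia,
    read_otu_table,
    read_taxonomy,
    to_relative,
)
from .diversity import anova_shannon, bray_curtis, nmds, shannon_per_sample, spearman_env
from .spatial import distance_decay, haversine_matrix
from .assembly import (
    assembly_analysis,
    patristic_distances,
    per_site_fractions,
    read_tree,
    summarize_processes,
)

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_STAGE = 3

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """All inputs and knobs of a full run; mirrored by CLI flags."""

    otu: str
    tree: str
    meta: str
    out_dir: str
    taxonomy: str | None = None
    orientation: str = "auto"
    min_identity: float = 90.0
    min_coverage: float = 90.0
    dominance_threshold: float = 0.01
    hypoxia_mg_l: float = 2.0
    bnti_thresh: float = 2.0
    rc_thresh: float = 0.95
    reps: int = 999
    permutations: int = 999
    seed: int = 42
    nmds_restarts: int = 20
    average_replicates: bool = False
    n_jobs: int = 1

    def __post_init__(self) -> None:
        for name in ("min_identity", "min_coverage", "dominance_threshold",
                     "hypoxia_mg_l", "bnti_thresh", "rc_thresh"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_toml(cls, path, **overrides) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class ValidationReport:
    issues: list[str] = field(default_factory=list)
    pruned_tree_tips: list[str] = field(default_factory=list)
    dropped_table_taxa: list[str] = field(default_factory=list)
    dropped_samples: list[str] = field(default_factory=list)
    fatal: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def validate_inputs(table: OTUTable, tree, meta: SampleMetadata) -> ValidationReport:
    """Cross-check taxa between table and tree and samples between table and
    metadata.  Disjoint label sets are fatal; partial overlap is reported."""
    report = ValidationReport()
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    taxa = set(table.taxon_ids)
    report.pruned_tree_tips = sorted(tips - taxa)
    report.dropped_table_taxa = sorted(taxa - tips)
    if report.pruned_tree_tips:
        report.issues.append(
            f"{len(report.pruned_tree_tips)} tree tips absent from table (pruned)"
        )
    if report.dropped_table_taxa:
        report.issues.append(
            f"{len(report.dropped_table_taxa)} table taxa absent from tree (dropped for assembly)"
        )
    if not (tips & taxa):
        report.issues.append("no taxa shared between table and tree")
        report.fatal = True
    table_samples = set(table.sample_ids)
    meta_samples = set(meta.sample_ids)
    report.dropped_samples = sorted(table_samples ^ meta_samples)
    if report.dropped_samples:
        report.issues.append(
            f"{len(report.dropped_samples)} samples not shared between table and metadata"
        )
    if not (table_samples & meta_samples):
        report.issues.append("no samples shared between table and metadata")
        report.fatal = True
    return report


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path, index=False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def run_all(config: RunConfig) -> dict:
    """Execute every stage and write per-stage TSVs, a JSON manifest and a
    human-readable summary.  Deterministic for a given config + inputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stale_flag = out / "INCOMPLETE"
    stale_flag.write_text("run in progress; outputs may be stale\n")
    t0 = time.time()
    summary_lines: list[str] = []
    manifest: dict = {
        "tool": "ecoassembly",
        "version": __version__,
        "config": asdict(config),
        "inputs": {},
        "stages": {},
    }

    # timings go to the log only: every written output must be byte-identical
    # across reruns of the same config + inputs
    def stage(name):
        logger.info("stage %s starting (t=%.1fs)", name, time.time() - t0)
        manifest["stages"][name] = {}
        return name

    # -- load ---------------------------------------------------------------
    name = stage("load")
    try:
        for key in ("otu", "tree", "meta", "taxonomy"):
            path = getattr(config, key)
            if path is None:
                continue
            if not Path(path).exists():
                raise FileNotFoundError(f"{key} input does not exist: {path}")
            manifest["inputs"][key] = {"path": str(path), "sha256": _sha256(path)}
        table = read_otu_table(config.otu, orientation=config.orientation)
        tree = read_tree(config.tree)
        meta = SampleMetadata.read_csv(config.meta)
    except Exception as err:
        stale_flag.write_text(f"failed at stage load: {err}\n")
        raise StageError(name, err) from err

    # -- validate -----------------------------------------------------------
    name = stage("validate")
    report = validate_inputs(table, tree, meta)
    (out / "validation.json").write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    if report.fatal:
        stale_flag.write_text("failed at stage validate\n")
        raise ValidationError("; ".join(report.issues))

    shared_samples = [s for s in table.sample_ids if s in set(meta.sample_ids)]
    table = table.select_samples(shared_samples)
    meta = meta.subset(shared_samples)
    if config.average_replicates and "replicate" in meta.df.columns:
        groups = {s: f"{meta.df.loc[s, 'site_id']}|{meta.df.loc[s, 'layer']}" for s in meta.sample_ids}
        table = average_samples(table, groups)
        logger.info("averaged PCR replicates down to %d samples", table.n_samples)

    layer_of = {s: meta.layer_of(s) for s in meta.sample_ids}
    site_of = {s: str(meta.df.loc[s, "site_id"]) for s in meta.sample_ids}

    try:
        # -- diversity --------------------------------------------------------
        name = stage("diversity")
        rel = to_relative(table)
        alpha = shannon_per_sample(rel)
        alpha_df = alpha.rename_axis("sample_id").reset_index()
        alpha_df["layer"] = alpha_df["sample_id"].map(layer_of)
        _write_tsv(alpha_df, out / "alpha_diversity.tsv")
        groups = {
            layer: alpha[[s for s in alpha.index if layer_of[s] == layer]].to_numpy()
            for layer in ("surface", "bottom")
            if any(layer_of[s] == layer for s in alpha.index)
        }
        anova = None
        if len(groups) == 2 and all(len(v) >= 2 for v in groups.values()):
            try:
                anova = anova_shannon(groups)
            except ValueError as err:
                logger.warning("layer ANOVA skipped: %s", err)
        env_corr = spearman_env(alpha, meta)
        _write_tsv(env_corr, out / "alpha_env_spearman.tsv")
        hypoxia = flag_hypoxia(meta, config.hypoxia_mg_l) if "DO" in meta.df.columns else {}

        bc = bray_curtis(rel)
        bc.write_tsv(out / "bray_curtis.tsv")
        ord_res = nmds(bc, k=2, restarts=config.nmds_restarts, seed=config.seed)
        ord_df = ord_res.to_dataframe().rename_axis("sample_id").reset_index()
        _write_tsv(ord_df, out / "nmds.tsv")
        manifest["stages"][name]["nmds_stress"] = ord_res.stress
        manifest["stages"][name]["nmds_converged"] = ord_res.converged

        dominant = None
        if config.taxonomy:
            records = filter_taxonomy(
                read_taxonomy(config.taxonomy), config.min_identity, config.min_coverage
            )
            level_map = {r.taxon_id: r.lineage.split(";")[0] for r in records}
            dominant = {
                stratum: dominant_taxa(
                    rel,
                    level_map,
                    config.dominance_threshold,
                    samples=[s for s in rel.sample_ids if stratum == "all" or layer_of[s] == stratum],
                )
                for stratum in ("surface", "bottom", "all")
            }
            rows = [
                {"stratum": st, "group": g, "fraction": f}
                for st, d in dominant.items()
                for g, f in sorted(d.items())
            ]
            _write_tsv(pd.DataFrame(rows), out / "dominant_taxa.tsv")

        # -- spatial ----------------------------------------------------------
        name = stage("spatial")
        geo = haversine_matrix(meta)
        geo.write_tsv(out / "geographic_km.tsv")
        decay = {}
        for stratum in ("surface", "bottom", "all"):
            ids = meta.samples_in_layer(stratum)
            if len(ids) < 4:
                continue
            fit = distance_decay(
                bc.subset(ids), geo.subset(ids),
                permutations=config.permutations, seed=config.seed,
            )
            decay[stratum] = fit.to_dict()
        (out / "distance_decay.json").write_text(json.dumps(decay, indent=2, sort_keys=True))

        # -- assembly ---------------------------------------------------------
        name = stage("assembly")
        dists = patristic_distances(tree, [t for t in table.taxon_ids if t in
                                           {l.taxon.label for l in tree.leaf_node_iter()}])
        pairs_df = assembly_analysis(
            table,
            dists,
            meta=meta,
            reps=config.reps,
            seed=config.seed,
            bnti_thresh=config.bnti_thresh,
            rc_thresh=config.rc_thresh,
            strata="within-layer",
            n_jobs=config.n_jobs,
        )
        _write_tsv(pairs_df, out / "assembly_pairs.tsv")
        summaries = summarize_processes(pairs_df, layer_of=layer_of)
        summary_rows = [
            {"stratum": s.stratum, "process": p, "fraction": f, "n_pairs": s.n_pairs}
            for s in summaries
            for p, f in s.fractions.items()
        ]
        _write_tsv(pd.DataFrame(summary_rows), out / "process_summary.tsv")
        _write_tsv(per_site_fractions(pairs_df, site_of), out / "process_by_site.tsv")
    except StageError:
        raise
    except Exception as err:
        stale_flag.write_text(f"failed at stage {name}: {err}\n")
        raise StageError(name, err) from err

    # -- report -------------------------------------------------------------
    summary_lines.append(f"samples: {table.n_samples}; taxa: {table.n_taxa}")
    if hypoxia:
        hypoxic = sorted(s for s, v in hypoxia.items() if v)
        summary_lines.append(
            f"hypoxic samples (DO < {config.hypoxia_mg_l} mg/L): {', '.join(hypoxic) or 'none'}"
        )
    summary_lines.append(
        "Shannon range: "
        f"{alpha.min():.3f} ({alpha.idxmin()}) to {alpha.max():.3f} ({alpha.idxmax()})"
    )
    if anova is not None:
        summary_lines.append(f"surface vs bottom Shannon ANOVA: F={anova[0]:.4g}, p={anova[1]:.4g}")
    if dominant is not None:
        for st, d in dominant.items():
            top = sorted(d.items(), key=lambda kv: -kv[1])[:3]
            summary_lines.append(
                f"dominant groups ({st}): " + ", ".join(f"{g} {100 * f:.1f}%" for g, f in top)
            )
    summary_lines.append(f"NMDS stress: {ord_res.stress:.4f} (converged={ord_res.converged})")
    for st, fit in decay.items():
        summary_lines.append(
            f"distance-decay ({st}): rho={fit['rho']:.3f}, p={fit['p_value']:.4g}, "
            f"n_pairs={fit['n_pairs']}"
        )
    for s in summaries:
        top = sorted(s.fractions.items(), key=lambda kv: -kv[1])
        summary_lines.append(
            f"assembly ({s.stratum}, {s.n_pairs} pairs): "
            + ", ".join(f"{p} {100 * f:.2f}%" for p, f in top if f > 0)
        )
    (out / "summary.txt").write_text("\n".join(summary_lines) + "\n")

    logger.info("run complete in %.1fs", time.time() - t0)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    stale_flag.unlink(missing_ok=True)
    return {
        "out_dir": str(out),
        "summary": summary_lines,
        "nmds_stress": ord_res.stress,
        "decay": decay,
        "process_summaries": summaries,
        "pairs": pairs_df,
    }
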