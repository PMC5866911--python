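"""End-to-end orchestration: simulate/classify -> traits -> QC -> GWAS -> enrichment.

A single configuration mapping (usually loaded from YAML) drives every
stage.  For each trait the Bayes-Cpi stage estimates pi, which then flows
into the long Bayes-C chain for that trait; 1-Mb window decomposition,
adjacent-window pruning and (when gene coordinates and term annotations are
supplied) the binomial over-representation test follow.  A JSON manifest
records the seed, per-stage record counts, per-trait posterior summaries
and SHA-256 checksums of every output, so identical configurations yield
identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import enrichment as enrich_mod
from . import genoqc, io, phenotype, thi
from .gwas import ChainConfig, build_design, merge_adjacent, run_bayes_c, run_bayes_cpi, summarize_heritability, window_variance
from .simulate import SimConfig, simulate_all

logger = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    """Configuration invalid; nothing was run."""


class StageError(RuntimeError):
    """A pipeline stage failed."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


_DEFAULTS = {
    "thi_thresholds": list(thi.THRESHOLDS_C),
    "min_hours": 18,
    "maf_threshold": 0.05,
    "window_report_pct": 1.0,
    "window_top_pct": 3.0,
    "seed": 0,
}


def validate_config(config: dict) -> dict:
    cfg = {**_DEFAULTS, **(config or {})}
    th = cfg["thi_thresholds"]
    if list(th) != sorted(th) or len(set(th)) != len(th):
        raise PipelineConfigError("thi_thresholds must be strictly increasing")
    if not (0 <= cfg["maf_threshold"] < 0.5):
        raise PipelineConfigError("maf_threshold must lie in [0, 0.5)")
    if cfg["window_report_pct"] >= cfg["window_top_pct"]:
        raise PipelineConfigError("window_report_pct must be below window_top_pct")
    if "out_dir" not in cfg:
        raise PipelineConfigError("out_dir is required")
    if "simulate" not in cfg:
        for key in ("pings", "meta", "genotypes", "marker_map"):
            if key not in cfg:
                raise PipelineConfigError(f"{key!r} path required when not simulating")
            if not Path(cfg[key]).exists():
                raise PipelineConfigError(f"input path does not exist: {cfg[key]}")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _chain_cfg(section: dict | None, seed: int, **overrides) -> ChainConfig:
    kw = dict(section or {})
    kw.update(overrides)
    kw.setdefault("seed", seed)
    return ChainConfig(**kw)


def run_pipeline(config: dict) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    cfg = validate_config(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {"seed": seed, "stages": {}, "traits": {}, "outputs": {}}

    def record(stage: str, **counts):
        manifest["stages"][stage] = counts
        logger.info("stage %s: %s", stage, counts)

    # ---------------------------------------------------------------- inputs
    try:
        if "simulate" in cfg:
            sim_cfg = SimConfig(**{**(cfg["simulate"] or {}), "seed": seed})
            sim = simulate_all(sim_cfg, with_weather=True)
            io.write_weather(sim.weather, out / "weather.tsv")
            io.write_day_classes(sim.day_classes, out / "days.tsv")
            io.write_pings(sim.pings, out / "pings.tsv")
            io.write_meta(sim.meta, out / "meta.tsv")
            io.write_dosages(sim.dosages, out / "genotypes.tsv")
            io.write_marker_map(sim.marker_map, out / "marker_map.tsv")
            truth_df = pd.DataFrame({"qtl_id": sim.truth.qtl_ids,
                                     "effect": sim.truth.qtl_effects})
            truth_df.to_csv(out / "truth.tsv", sep="\t", index=False)
            pings, meta = sim.pings, sim.meta
            dosages, marker_map = sim.dosages, sim.marker_map
            days = sim.day_classes
            record("simulate", n_animals=len(meta), n_markers=dosages.shape[1],
                   n_days=len(days), realized_h2=sim.truth.realized_h2)
        else:
            pings = io.read_pings(cfg["pings"])
            meta = io.read_meta(cfg["meta"])
            dosages = io.read_dosages(cfg["genotypes"])
            marker_map = io.read_marker_map(cfg["marker_map"])
            if "days" in cfg:
                days = io.read_day_classes(cfg["days"])
            elif "weather" in cfg:
                weather = io.read_weather(cfg["weather"])
                days = thi.categorize_series(weather, min_hours=cfg["min_hours"],
                                             thresholds=tuple(cfg["thi_thresholds"]))
                io.write_day_classes(days, out / "days.tsv")
            else:
                raise PipelineConfigError("either 'days' or 'weather' is required")
            record("inputs", n_animals=len(meta), n_markers=dosages.shape[1],
                   n_days=len(days))
    except PipelineConfigError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("inputs", str(exc)) from exc

    # ---------------------------------------------------------------- phenotypes
    try:
        prof = phenotype.category_profile(pings, days)
        z = phenotype.standardize_deviations(prof, meta)
        traits = phenotype.pairwise_traits(z)
        corr = phenotype.trait_correlations(traits)
        io.write_traits(traits, out / "traits.tsv")
        corr.to_csv(out / "trait_correlations.tsv", sep="\t")
        record("phenotypes", n_animals=len(traits),
               n_traits=len([c for c in traits.columns if "-" in c]))
    except Exception as exc:  # noqa: BLE001
        raise StageError("phenotypes", str(exc)) from exc

    # ---------------------------------------------------------------- marker QC
    try:
        qc = genoqc.GenotypeQC(maf_threshold=cfg["maf_threshold"], marker_map=marker_map)
        clean = qc.fit_transform(dosages)
        kept_map = marker_map[marker_map["marker_id"].isin(qc.kept_markers_)]
        io.write_dosages(clean, out / "genotypes_qc.tsv")
        qc.report_.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        record("qc", n_markers_in=dosages.shape[1], n_markers_kept=clean.shape[1],
               n_animals=clean.shape[0])
    except Exception as exc:  # noqa: BLE001
        raise StageError("qc", str(exc)) from exc

    # ---------------------------------------------------------------- GWAS per trait
    trait_list = cfg.get("traits") or [
        t for t in phenotype.trait_names() if traits[t].notna().sum() >= 10
    ]
    chain_cfg = cfg.get("chain", {})
    all_windows = []
    for i, trait_name in enumerate(trait_list):
        try:
            design = build_design(traits, trait_name, meta, clean, kept_map)
            cpi = run_bayes_cpi(design, _chain_cfg(
                chain_cfg.get("cpi"), seed + 17 * i + 1,
                pi="estimate",
                **({} if chain_cfg.get("cpi") else
                   {"n_iter": 8100, "burn_in": 100, "thin": 1})))
            pi_hat = float(cpi.pi.mean())
            bc = run_bayes_c(design, _chain_cfg(
                chain_cfg.get("c"), seed + 17 * i + 2, pi=pi_hat))
            h2_mean, h2_sd = summarize_heritability(bc)
            windows = window_variance(bc, kept_map,
                                      threshold_report=cfg["window_report_pct"],
                                      threshold_top=cfg["window_top_pct"])
            windows.insert(0, "trait", trait_name)
            all_windows.append(windows)
            bc.to_frame().to_csv(out / f"samples_{trait_name}.tsv", sep="\t", index=False)
            bc.marker_summary().to_csv(out / f"markers_{trait_name}.tsv", sep="\t", index=False)
            pd.DataFrame({"iteration": range(1, len(cpi.pi_trace) + 1),
                          "pi": cpi.pi_trace}).to_csv(
                out / f"pi_trace_{trait_name}.tsv", sep="\t", index=False)
            manifest["traits"][trait_name] = {
                "n_animals": len(design.y), "pi": pi_hat,
                "h2_mean": h2_mean, "h2_sd_last100": h2_sd,
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"gwas:{trait_name}", str(exc)) from exc
    if all_windows:
        windows_df = pd.concat(all_windows, ignore_index=True)
        io.write_windows(windows_df, out / "windows.tsv")
        record("gwas", n_traits=len(trait_list),
               n_reported_windows=int(windows_df["reported"].sum()))

    # ---------------------------------------------------------------- enrichment
    if all_windows and "genes" in cfg and "terms" in cfg:
        try:
            genes = io.read_bed(cfg["genes"]) if str(cfg["genes"]).endswith(".bed") \
                else io.read_gff3(cfg["genes"])
            terms = io.read_terms(cfg["terms"])
            reported = windows_df.loc[windows_df["reported"],
                                      ["chromosome", "window_mb", "pct"]].drop_duplicates()
            top = merge_adjacent(
                windows_df.loc[windows_df["top"]].drop_duplicates(
                    subset=["chromosome", "window_mb"]),
                threshold=cfg["window_top_pct"])
            for label, wset in (("1pct", reported), ("3pct", top)):
                gene_list = enrich_mod.genes_in_windows(wset, genes)
                result = enrich_mod.binomial_enrichment(gene_list, terms)
                io.write_enrichment(result, out / f"enrichment_{label}.tsv")
                manifest["stages"][f"enrichment_{label}"] = {
                    "n_genes": len(gene_list),
                    "n_significant": int(result["significant"].sum()) if len(result) else 0,
                }
        except Exception as exc:  # noqa: BLE001
            raise StageError("enrichment", str(exc)) from exc

    for f in sorted(out.glob("*.tsv")):
        manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
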