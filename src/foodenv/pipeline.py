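"""End-to-end pipeline driver: simulate -> clean -> match -> categorize ->
summarize -> export, with a machine-readable run manifest.

Re-running with the same configuration reproduces identical outputs; the
manifest records the seed, a hash of the full configuration, and row counts
per stage (no timestamps, so manifests of identical runs are byte-identical).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

from . import io_export as io
from .categorize import CategoryLexicon, categorize_all
from .config import PipelineConfig, default_simulation_config
from .environments import EnvironmentAssembler, cuisine_frequencies, pct_change
from .linkage import audit_unmatched, run_cascade
from .normalize import normalize_dataset
from .synthetic import generate_universe, make_geography, render_local_view, render_online_view

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage, writing all outputs under ``outdir``.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - abort with stage context
                raise StageError(name, exc) from exc
            return result
        return deco

    # -- simulate -------------------------------------------------------------
    @stage("simulate")
    def _sim():
        geography = make_geography(config.geography)
        sim = config.simulation or default_simulation_config(
            dict(zip(geography["region"], geography["urban"])))
        noise = config.noise.model_copy(update={"seed": config.seed})
        universe = generate_universe(sim, geography, config.seed)
        local_rows, local_truth = render_local_view(
            universe, noise, config.normalization.centre_list)
        online_rows, online_truth = render_online_view(
            universe, geography, noise, config.normalization.centre_list)
        io.write_geography(geography, outdir / "geography.csv")
        io.write_raw_listings(local_rows, outdir / "local_view.csv")
        io.write_raw_listings(online_rows, outdir / "online_view.csv")
        io.write_truth_map(local_truth, outdir / "local_truth.csv")
        io.write_truth_map(online_truth, outdir / "online_truth.csv")
        return geography, universe, local_rows, online_rows

    geography, universe, local_rows, online_rows = _sim
    manifest["stages"]["simulate"] = {
        "universe": len(universe),
        "local_rows": len(local_rows),
        "online_rows": len(online_rows),
    }

    # -- clean ----------------------------------------------------------------
    @stage("clean")
    def _clean():
        norm_cfg = config.normalization.model_copy(
            update={"suburb_list": sorted(geography["suburb"].str.lower().unique())})
        online_norm, local_norm = normalize_dataset(online_rows, local_rows, norm_cfg)
        io.write_normalized(online_norm, outdir / "online_normalized.csv")
        io.write_normalized(local_norm, outdir / "local_normalized.csv")
        return online_norm, local_norm

    online_norm, local_norm = _clean
    manifest["stages"]["clean"] = {
        "online_unique": len(online_norm),
        "local_kept": len(local_norm),
    }

    # -- match ----------------------------------------------------------------
    @stage("match")
    def _match():
        matches, un_online, un_local = run_cascade(
            online_norm, local_norm, thresholds=config.thresholds)
        audit = audit_unmatched(un_online, local_norm,
                                config.normalization.centre_list)
        io.write_matches(matches, outdir / "matches.csv")
        io.write_normalized(un_online, outdir / "unmatched_online.csv")
        io.write_normalized(un_local, outdir / "unmatched_local.csv")
        io.write_audit(audit, outdir / "audit.csv")
        return matches, un_online, un_local

    matches, un_online, un_local = _match
    manifest["stages"]["match"] = {
        "matches": len(matches),
        "unmatched_online": len(un_online),
        "unmatched_local": len(un_local),
    }

    # -- categorize -----------------------------------------------------------
    @stage("categorize")
    def _cat():
        lexicon = CategoryLexicon()
        assignments, registry = categorize_all(
            online_norm, local_norm, matches, lexicon, lexicon,
            franchise_min_locations=config.franchise_min_locations)
        io.write_assignments(assignments, outdir / "assignments.csv")
        return assignments, registry

    assignments, registry = _cat
    manifest["stages"]["categorize"] = {
        "assignments": len(assignments),
        "franchise_brands": len(registry.brands),
    }

    # -- summarize ------------------------------------------------------------
    @stage("summarize")
    def _summ():
        delivery_rows = [
            (r.source_id, str(r.extra.get("delivery_suburb", "")).lower())
            for r in online_rows if r.extra.get("delivery_suburb")
        ]
        assembler = EnvironmentAssembler(
            local_norm, online_norm, delivery_rows, matches, geography,
            assignments)
        summaries = assembler.region_summaries()
        io.write_region_summaries(summaries, outdir / "region_summary.csv")
        assembler.category_table().to_csv(outdir / "category_table.csv",
                                          index=False, encoding="utf-8")
        totals = assembler.unique_totals()
        (outdir / "unique_totals.json").write_text(
            json.dumps(totals, indent=1), encoding="utf-8")
        return assembler, summaries, totals

    assembler, summaries, totals = _summ
    manifest["stages"]["summarize"] = {
        "regions": len(summaries),
        "unique_totals": totals,
    }

    # -- export ---------------------------------------------------------------
    @stage("export")
    def _exp():
        views = assembler.build_views()
        counts = {u: v["hybrid"].n_outlets for u, v in views.items()
                  if u != "unknown"}
        densities = assembler.densities("hybrid")
        pct_by_pc = {
            u: pct_change(v["local"].n_outlets, v["hybrid"].n_outlets)
            for u, v in views.items() if u != "unknown"
        }
        io.write_density_geojson(densities, counts, geography,
                                 outdir / "density.geojson", pct_by_pc)
        freqs = cuisine_frequencies(local_norm + online_norm)
        io.write_wordcloud_json(freqs, outdir / "wordcloud.json")
        return len(densities)

    n_densities = _exp
    manifest["stages"]["export"] = {"postcodes": n_densities}

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8")
    return manifest
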