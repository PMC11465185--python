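"""End-to-end pipeline orchestration and fixture management.

Stages: simulate (optional) -> screen -> dereplicate -> profile ->
classify -> report. Every stage reads and writes tab-separated tables so
each can be run and tested independently; a manifest records the seed and
every threshold so a run can be replayed exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abundance import bray_curtis_matrix, rpkm_table, within_layer_dispersion
from .config import LAYERS, CommunityConfig, PipelineConfig
from .dereplication import assign_serial_ids, cluster_species, \
    drep_quality_score
from .habitat import classify_community, persistence_cohort, summary_report
from .io import grid_to_long, long_to_grid, read_table, write_fasta, \
    write_table
from .ordination import nmds
from .screening import MagRecord, n50, quality_summary, screen_mag
from .synthetic import abundance_to_reads, generate_genomes, simulate_dynamics

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def make_fixtures(config: CommunityConfig, out_dir, force: bool = False,
                  with_sequences: bool = True) -> Path:
    """Write the full synthetic bundle (plus ground truth) to ``out_dir``."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists; pass force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)

    community = generate_genomes(config, with_sequences=with_sequences)
    if with_sequences:
        write_fasta(community.contigs, out / "contigs.fasta")
    write_table(community.markers, out / "markers.tsv")
    write_table(community.checkm, out / "checkm.tsv")
    write_table(community.truth, out / "truth.tsv")

    genome_df = pd.DataFrame(
        [(s.mag_id, s.length_bp, s.n_contigs, round(s.completeness_pct, 2))
         for s in community.specs],
        columns=["mag_id", "length_bp", "n_contigs", "completeness_pct"])
    write_table(genome_df, out / "genomes.tsv")

    abundance, sample_meta = simulate_dynamics(config)
    lengths = community.genome_lengths.loc[abundance.index]
    counts, depth, covfrac = abundance_to_reads(abundance, lengths, config)
    write_table(grid_to_long(abundance, "abundance"), out / "abundance.tsv")
    write_table(grid_to_long(counts, "count"), out / "counts.tsv")
    write_table(grid_to_long(depth, "depth"), out / "coverage.tsv")
    write_table(grid_to_long(covfrac, "covered_fraction"), out / "covfrac.tsv")
    write_table(sample_meta, out / "samples.tsv")
    return out


def run_pipeline(config: PipelineConfig, fixture_dir, out_dir) -> dict:
    """Run screen -> dereplicate -> profile -> classify -> report.

    Inputs are the tables produced by :func:`make_fixtures` (or real
    tables in the same formats). Returns the report dict; every stage
    writes its table under ``out_dir``.
    """
    fix = Path(fixture_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("markers.tsv", "checkm.tsv", "genomes.tsv", "counts.tsv",
                 "covfrac.tsv", "samples.tsv"):
        if not (fix / name).exists():
            raise PipelineError("input", f"missing input: {fix / name}")

    # --- screen -----------------------------------------------------------
    try:
        markers = read_table(fix / "markers.tsv")
        checkm = read_table(fix / "checkm.tsv").set_index("seq_id")
        genomes = read_table(fix / "genomes.tsv").set_index("mag_id")
        rows = []
        kept: list[str] = []
        for mag_id, g in genomes.iterrows():
            hits = [(r.gene, r.bit_score) for r in
                    markers[markers["seq_id"] == mag_id].itertuples()]
            ck = checkm.loc[mag_id] if mag_id in checkm.index else None
            # contig length detail is synthetic-side; approximate even split
            contig_lengths = _even_split(int(g["length_bp"]),
                                         int(g["n_contigs"]))
            mag = MagRecord(
                mag_id=mag_id, contig_lengths=contig_lengths,
                marker_hits=hits,
                completeness_pct=float(g.get("completeness_pct", 0.0)),
                bac_completeness=float(ck["bac_completeness"]) if ck is not None else 0.0,
                arc_completeness=float(ck["arc_completeness"]) if ck is not None else 0.0)
            keep, reason = screen_mag(
                mag, min_length_bp=config.min_length_bp,
                hk97_min_bitscore=config.hk97_min_bitscore,
                max_bac=config.max_bac_completeness,
                max_arc=config.max_arc_completeness)
            qs = quality_summary(
                mag, high_quality_completeness=config.high_quality_completeness)
            rows.append((mag_id, keep, reason, qs.n_contigs, qs.n50, qs.tier,
                         qs.marker_count_of_7))
            if keep:
                kept.append(mag_id)
        screened = pd.DataFrame(rows, columns=[
            "mag_id", "decision", "reason", "n_contigs", "n50", "tier",
            "marker_count"])
        write_table(screened, out / "mags_screened.tsv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("screen", str(exc)) from exc

    # --- profile ----------------------------------------------------------
    try:
        counts = long_to_grid(read_table(fix / "counts.tsv"), "count")
        covfrac = long_to_grid(read_table(fix / "covfrac.tsv"),
                               "covered_fraction")
        sample_meta = read_table(fix / "samples.tsv")
        gv_index = [m for m in counts.index if m in kept]
        counts = counts.loc[gv_index]
        covfrac = covfrac.loc[gv_index]
        lengths = genomes["length_bp"]
        rpkm_grid = rpkm_table(counts, lengths)
        write_table(grid_to_long(rpkm_grid, "rpkm"), out / "rpkm.tsv")

        beta = bray_curtis_matrix(rpkm_grid)
        beta_out = beta.copy()
        beta_out.index = [f"{m}_{l}" for m, l in beta.index]
        beta_out.columns = beta_out.index
        write_table(beta_out, out / "beta.tsv", index=True)

        ord_res = nmds(beta.values, k=2, seed=config.seed)
        nmds_df = pd.DataFrame(ord_res.coordinates,
                               columns=["dim1", "dim2"])
        nmds_df.insert(0, "sample", [f"{m}_{l}" for m, l in beta.index])
        nmds_df["stress"] = ord_res.stress
        write_table(nmds_df, out / "nmds.tsv")
        dispersion, disp_p = within_layer_dispersion(beta, sample_meta)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("profile", str(exc)) from exc

    # --- dereplicate ------------------------------------------------------
    try:
        screened_ix = screened.set_index("mag_id")
        scores = {m: drep_quality_score(
                      float(genomes.loc[m, "completeness_pct"]),
                      int(screened_ix.loc[m, "n50"])) for m in gv_index}
        ani_path = fix / "ani.tsv"
        ani = read_table(ani_path) if ani_path.exists() else \
            pd.DataFrame(columns=["query", "subject", "ani_pct"])
        clusters = cluster_species(ani, scores,
                                   ani_threshold=config.ani_species_threshold)
        depth_grid = (long_to_grid(read_table(fix / "coverage.tsv"), "depth")
                      if (fix / "coverage.tsv").exists()
                      else rpkm_grid).copy()
        depth_grid.columns = range(depth_grid.shape[1])
        clusters.serial_ids = assign_serial_ids(clusters.representatives,
                                                depth_grid)
        write_table(pd.DataFrame(
            [(rep, m) for rep, mem in clusters.clusters for m in mem],
            columns=["representative", "member"]), out / "clusters.tsv")
        write_table(pd.DataFrame(sorted(clusters.serial_ids.items()),
                                 columns=["mag_id", "serial_id"]),
                    out / "ids.tsv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("derep", str(exc)) from exc

    # --- classify + report ------------------------------------------------
    try:
        calls = classify_community(rpkm_grid, config.stratified_months,
                                   upper=config.p_epi_upper,
                                   lower=config.p_epi_lower)
        cohort = persistence_cohort(
            calls, covfrac, config.stratified_months,
            threshold=config.covered_fraction_threshold)
        write_table(pd.DataFrame(
            [(c.mag_id, c.p_epi, c.label, c.persistence_months)
             for c in calls],
            columns=["mag_id", "p_epi", "label", "persistence_months"]),
            out / "habitat_calls.tsv")

        quality_df = screened_ix.loc[gv_index, ["tier", "marker_count",
                                                "n_contigs"]]
        report = summary_report(calls, quality_df)
        report["persistence_median_epilimnion"] = cohort["medians"].get(
            "epilimnion-specific")
        report["persistence_median_hypolimnion"] = cohort["medians"].get(
            "hypolimnion-specific")
        report["persistence_welch_p"] = cohort["welch_p"]
        report["nmds_stress"] = ord_res.stress
        report["dispersion_mannwhitney_p"] = disp_p
        report["n_species_clusters"] = len(clusters.clusters)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("classify", str(exc)) from exc

    manifest = {"stratovir_version": __version__, "seed": config.seed,
                "thresholds": {k: v for k, v in config.to_dict().items()
                               if k not in ("paths", "community")}}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return report


def _even_split(total: int, n_parts: int) -> list[int]:
    base = total // n_parts
    parts = [base] * n_parts
    parts[0] += total - base * n_parts
    return parts
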