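"""End-to-end orchestration: simulate -> call TUs -> normalize -> half-life
-> decay patterns -> covariates, from one config, with a manifest.

Stage outputs are plain TSVs with '#'-prefixed headers (tool version,
config hash, seed), so intermediate results are diff-able and reruns with
the same config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .covariates import build_table, cyclic_anova, posthoc_class_test
from .halflife import estimate_all, records_to_frame, summarize
from .io import read_bedgraph, read_fasta, read_gff3, read_tsv, write_tsv
from .models import CoverageTrack, STATUS_OK
from .patterns import classify_direction, plot_profile, profile_operon, segmental_calls
from .quantify import (
    NormalizationFactors,
    anchor_factors,
    apply_normalization,
    expression_table,
    qpcr_halflife,
)
from .simulate import SimConfig, write_dataset
from .transcript_units import call_transcript_units, compute_utrs, tus_to_frame


@dataclass
class PipelineConfig:
    """All stage parameters, with the analysis defaults baked in."""

    outdir: str = "decaymap_out"
    # inputs: either simulate, or point at existing files
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    annotation: str | None = None
    fasta: str | None = None
    coverage_dir: str | None = None
    anchors_ct: str | None = None
    anchor_half_lives: str | None = None  # TSV gene_id, half_life_min
    # TU calling
    min_mean: float = 5.0
    merge_gap: int = 5
    kmer: int = 52
    use_kmer_fusing: bool = True
    # quantification / half-life
    read_length: int = 52
    cap: float = 15.0
    r2_min: float = 0.8
    rpk_min: float = 50.0
    # patterns
    min_t0_mean: float = 50.0
    rho_threshold: float = 0.3
    p_threshold: float = 0.0005
    plots: bool = False
    max_plots: int = 10
    # covariates
    posthoc_alpha: float = 0.005
    posthoc_min_n: int = 25
    seed: int = 0

    def config_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        d = self.to_dict()
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        cfg = cls(**raw)
        if sim_raw:
            sim_kwargs = dict(sim_raw)
            for key, conv in (("genes_per_operon", int), ("depth_factors", float),
                              ("direction_mix", str)):
                if key in sim_kwargs:
                    sim_kwargs[key] = {conv(k): v
                                       for k, v in sim_kwargs[key].items()}
            for key in ("timepoints", "half_life_bounds", "intra_operon_gap",
                        "intergenic_gap"):
                if key in sim_kwargs:
                    sim_kwargs[key] = tuple(sim_kwargs[key])
            cfg.sim = SimConfig(**sim_kwargs)
        return cfg


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _header(config: PipelineConfig) -> list[str]:
    return [f"decaymap {__version__}", f"config_hash: {config.config_hash()}",
            f"seed: {config.seed}"]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in dependency order; returns the manifest dict.

    The manifest records every artifact with its sha256, plus the config
    hash and seed, and is written to ``<outdir>/manifest.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = _header(config)
    artifacts: dict[str, str] = {}

    # ---- stage: inputs (simulate or load) -------------------------------
    if config.simulate:
        config.sim.seed = config.seed if config.sim.seed == 0 else config.sim.seed
        sim_manifest = write_dataset(outdir / "sim", config.sim)
        annotation_path = sim_manifest["files"]["annotation"]
        fasta_path = sim_manifest["files"]["fasta"]
        coverage_paths = sim_manifest["files"]["coverage"]
        anchors_ct_path = sim_manifest["files"]["anchors_ct"]
    else:
        if config.annotation is None or config.coverage_dir is None:
            raise StageError("inputs", "annotation and coverage_dir are required")
        if config.anchors_ct is None and config.anchor_half_lives is None:
            raise StageError("normalize",
                             "anchors_ct or anchor_half_lives is required")
        annotation_path = config.annotation
        fasta_path = config.fasta
        coverage_paths = sorted(str(p) for p in
                                Path(config.coverage_dir).glob("*.bedGraph"))
        if not coverage_paths:
            raise StageError("inputs", f"no bedGraph files in {config.coverage_dir}")
        anchors_ct_path = config.anchors_ct

    genes = read_gff3(annotation_path)
    sequences = read_fasta(fasta_path) if fasta_path else {}
    if sequences:
        lengths = {name: len(seq) for name, seq in sequences.items()}
    else:
        lengths = {}
        for g in genes:
            lengths[g.replicon] = max(lengths.get(g.replicon, 0), g.end + 1000)
    tracks: dict[tuple[str, float], list[CoverageTrack]] = {}
    for path in coverage_paths:
        # one file may cover only one replicon; read against each known length
        stem = Path(path).stem
        for replicon, length in lengths.items():
            track = read_bedgraph(path, length, replicon=replicon)
            if track.values.any() or len(lengths) == 1:
                tracks.setdefault((track.replicate, track.time_min), []).append(track)
    if not tracks:
        raise StageError("inputs", "no coverage loaded")

    # ---- stage: transcript units ----------------------------------------
    all_tus = []
    sequence_by_replicon = sequences if config.use_kmer_fusing else {}
    for replicon in lengths:
        rep_tracks = [t for ts in tracks.values() for t in ts
                      if t.replicon == replicon]
        all_tus.extend(call_transcript_units(
            rep_tracks, genes, sequence=sequence_by_replicon.get(replicon),
            min_mean=config.min_mean, merge_gap=config.merge_gap, k=config.kmer))
    tu_path = outdir / "transcript_units.tsv"
    write_tsv(tus_to_frame(all_tus), tu_path, header)
    utr_df, op_hist = compute_utrs(all_tus, genes)
    utr_path = outdir / "utr_lengths.tsv"
    write_tsv(utr_df, utr_path, header)
    hist_path = outdir / "operon_sizes.tsv"
    write_tsv(op_hist, hist_path, header)
    artifacts["transcript_units"] = str(tu_path)
    artifacts["utr_lengths"] = str(utr_path)
    artifacts["operon_sizes"] = str(hist_path)

    # ---- stage: quantify + normalize ------------------------------------
    expr = expression_table(tracks, genes, read_length=config.read_length)
    if config.anchor_half_lives is not None:
        anchors_df = read_tsv(config.anchor_half_lives)
        anchor_hl = dict(zip(anchors_df["gene_id"], anchors_df["half_life_min"]))
    else:
        qpcr_df = qpcr_halflife(read_tsv(anchors_ct_path))
        anchor_hl = dict(zip(qpcr_df["gene_id"], qpcr_df["half_life_min"]))
    # factors per replicate (library depth is a per-sample property)
    normed = []
    factor_rows = []
    for rep, sub in expr.groupby("replicate"):
        factors = anchor_factors(anchor_hl, sub)
        normed.append(apply_normalization(sub, factors))
        fdf = factors.to_frame()
        fdf.insert(0, "replicate", rep)
        factor_rows.append(fdf)
    expr_norm = pd.concat(normed, ignore_index=True)
    factors_df = pd.concat(factor_rows, ignore_index=True)
    expr_path = outdir / "expression.tsv"
    write_tsv(expr_norm, expr_path, header)
    factors_path = outdir / "factors.tsv"
    write_tsv(factors_df, factors_path, header)
    artifacts["expression"] = str(expr_path)
    artifacts["factors"] = str(factors_path)

    # ---- stage: half-life ------------------------------------------------
    records = estimate_all(expr_norm, cap=config.cap, r2_min=config.r2_min,
                           rpk_min=config.rpk_min)
    hl_df = records_to_frame(records)
    hl_path = outdir / "halflives.tsv"
    write_tsv(hl_df, hl_path, header)
    artifacts["halflives"] = str(hl_path)
    n_ok = int((hl_df["status"] == STATUS_OK).sum())
    summary = summarize(records) if n_ok else {}

    # ---- stage: decay patterns ------------------------------------------
    # per-time mean coverage across replicates, per replicon
    mean_tracks: dict[str, dict[float, CoverageTrack]] = {}
    times = sorted({t for (_, t) in tracks})
    for replicon, length in lengths.items():
        mean_tracks[replicon] = {}
        for t in times:
            stack = [tr.values for (rep, tt), ts in tracks.items()
                     for tr in ts if tt == t and tr.replicon == replicon]
            mean_tracks[replicon][t] = CoverageTrack(
                replicon=replicon, values=np.mean(stack, axis=0), time_min=t)
    # pooled factors for profiles: mean of per-replicate factors
    pooled_factors = NormalizationFactors(factors={
        t: float(factors_df.loc[factors_df["time_min"] == t, "factor"].mean())
        for t in times if t > 0})
    by_id = {g.gene_id: g for g in genes}
    direction_rows = []
    n_plotted = 0
    for tu in all_tus:
        if not tu.member_gene_ids:
            continue
        profile = profile_operon(mean_tracks[tu.replicon], pooled_factors, tu,
                                 min_t0_mean=config.min_t0_mean)
        if profile is None:
            continue
        if config.plots and n_plotted < config.max_plots:
            plot_dir = outdir / "plots"
            plot_dir.mkdir(exist_ok=True)
            plot_profile(profile, mean_tracks[tu.replicon],
                         str(plot_dir / f"{profile.tu_id}.png"),
                         factors=pooled_factors)
            n_plotted += 1
        for gid in tu.member_gene_ids:
            call = classify_direction(profile, by_id[gid],
                                      rho_threshold=config.rho_threshold,
                                      p_threshold=config.p_threshold)
            if call is None:
                continue
            row = {"gene_id": call.gene_id, "tu_id": tu.tu_id,
                   "direction": call.direction, "p_t10": call.p_value,
                   "n_bases": call.n_bases}
            for t, rho in call.rho_by_time.items():
                row[f"rho_t{t:g}"] = rho
            direction_rows.append(row)
    direction_df = pd.DataFrame(direction_rows)
    dir_path = outdir / "direction_calls.tsv"
    write_tsv(direction_df, dir_path, header)
    seg = segmental_calls(all_tus, records)
    seg_df = pd.DataFrame([
        {"tu_id": s.tu_id, "min_half_life": s.min_half_life,
         "max_half_life": s.max_half_life, "mean_half_life": s.mean_half_life,
         "relative_spread": s.relative_spread, "class": s.spread_class,
         "n_members": s.n_members}
        for s in seg])
    seg_path = outdir / "segmental_calls.tsv"
    write_tsv(seg_df, seg_path, header)
    artifacts["direction_calls"] = str(dir_path)
    artifacts["segmental_calls"] = str(seg_path)

    # ---- stage: covariates ----------------------------------------------
    cov_results = pd.DataFrame()
    posthoc = pd.DataFrame()
    if n_ok >= 30:
        table = build_table(genes, expr_norm, records, all_tus)
        cov_results = cyclic_anova(
            table, "log_half_life",
            ["log_expression", "gc_percent", "n_genes_in_operon", "cog_class"])
        posthoc = posthoc_class_test(table, "cog_class",
                                     min_n=config.posthoc_min_n,
                                     alpha=config.posthoc_alpha)
    cov_path = outdir / "covariate_results.tsv"
    write_tsv(cov_results, cov_path, header)
    posthoc_path = outdir / "posthoc_cog.tsv"
    write_tsv(posthoc, posthoc_path, header)
    artifacts["covariate_results"] = str(cov_path)
    artifacts["posthoc_cog"] = str(posthoc_path)

    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_genes": len(genes),
        "n_tus": len(all_tus),
        "n_half_lives": n_ok,
        "half_life_summary": summary,
        "artifacts": {k: {"path": v, "sha256": _sha256(v)}
                      for k, v in artifacts.items()},
    }
    with (outdir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
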