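"""End-to-end orchestration: simulate -> clean -> coverage -> metrics ->
stats -> report, from a single config with deterministic seeding.

A run produces per-gene metric tables (travelling ratio per condition,
antisense densities and fold change, upstream nucleosome occupancy change),
a DE table and gene-class table, class-stratified Welch contrasts
(bound vs unbound within each DE class, for antisense fold change and
upstream occupancy change), the bound-vs-unbound log-log slope comparison,
TSS metaprofiles, and a manifest echoing every parameter and seed. The same
config and seed reproduce the output byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .annotation import (
    GENE_BODY_OFFSETS,
    PROXIMAL_PROMOTER,
    effective_genome_size,
    filter_isolated_promoters,
)
from .coverage import (
    Metaprofile,
    anchor_matrix,
    build_fragment_track,
    build_stranded_tracks,
    metaprofile,
    normalize_rpgc,
    smooth,
    write_bedgraph,
)
from .metrics import (
    DEFAULT_ANTISENSE_PSEUDOCOUNT,
    antisense_table,
    class_contrast,
    classify_genes,
    occupancy_change_table,
    spike_filter,
    travelling_ratio_table,
)
from .readproc import dedup_tags, partition_fragments, remove_splicing_intermediates
from .simdata import (
    CONDITIONS,
    TruthConfig,
    simulate_counts,
    simulate_fragments,
    simulate_genome,
    simulate_netseq,
)
from .stats import de_call, loglog_fit, slope_z

logger = logging.getLogger(__name__)

# fixed per-stage seed streams derived from the run seed
_STAGE_STREAMS = {"genome": 1, "netseq": 2, "mnase": 3, "atac": 4, "counts": 5}


@dataclass
class RunConfig:
    truth: TruthConfig = field(default_factory=TruthConfig)
    seed: int = 0
    outdir: str | Path | None = None
    n_reps: int = 4
    proximal: tuple[int, int] = PROXIMAL_PROMOTER
    body_offsets: tuple[int, int] = GENE_BODY_OFFSETS
    antisense_window: int = 1000
    antisense_pseudocount: float = DEFAULT_ANTISENSE_PSEUDOCOUNT
    occupancy_window: tuple[int, int] = (-450, -30)
    netseq_flank: int = 2000
    mnase_flank: int = 1000
    smooth_window: int = 20
    spike_subwindow: int = 100
    spike_frac_threshold: float = 0.8
    make_profiles: bool = True
    write_tracks: bool = False

    def stage_seed(self, stage: str) -> int:
        return int((self.seed * 1_000_003 + _STAGE_STREAMS[stage]) % 2_147_483_647)


@dataclass
class PipelineResult:
    genes: list
    truth: pd.DataFrame
    class_table: pd.DataFrame
    de_table: pd.DataFrame
    tr_tables: dict[str, pd.DataFrame]
    antisense: pd.DataFrame
    occupancy: pd.DataFrame
    contrasts: pd.DataFrame
    slopes: pd.DataFrame
    profiles: dict[str, Metaprofile]
    manifest: dict[str, Any]


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Run the full synthetic-data analysis; write TSVs when outdir is set."""
    counts_filtered: dict[str, int] = {}

    genome, genes, truth = simulate_genome(cfg.truth, seed=cfg.stage_seed("genome"))
    egs = effective_genome_size(genome)
    chrom_sizes = {c: len(s) for c, s in genome.items()}

    kept = filter_isolated_promoters(genes)
    counts_filtered["genes_total"] = len(genes)
    counts_filtered["genes_isolated"] = len(kept)
    kept_ids = {g.gene_id for g in kept}

    # --- NET-seq per condition: clean tags, stranded 1x tracks -------------
    net_tracks: dict[str, tuple] = {}
    for i, cond in enumerate(CONDITIONS):
        raw = simulate_netseq(
            genes, truth, cond, cfg.truth, seed=cfg.stage_seed("netseq") + i
        )
        deduped = dedup_tags(raw)
        clean, removed = remove_splicing_intermediates(deduped, genes)
        counts_filtered[f"netseq_{cond}_raw"] = len(raw)
        counts_filtered[f"netseq_{cond}_duplicates_removed"] = len(raw) - len(deduped)
        counts_filtered[f"netseq_{cond}_intermediates_removed"] = len(removed)
        plus, minus = build_stranded_tracks(clean, chrom_sizes)
        net_tracks[cond] = (normalize_rpgc(plus, egs), normalize_rpgc(minus, egs))

    # --- MNase per condition: mononucleosome 1x smoothed occupancy --------
    mono_tracks: dict[str, object] = {}
    for i, cond in enumerate(CONDITIONS):
        fs = simulate_fragments(
            genes, truth, cond, "mnase", cfg.truth, seed=cfg.stage_seed("mnase") + i
        )
        mono = partition_fragments(fs)["mononucleosome"]
        counts_filtered[f"mnase_{cond}_fragments"] = len(fs)
        counts_filtered[f"mnase_{cond}_mononucleosome"] = len(mono)
        track = build_fragment_track(mono, chrom_sizes)
        mono_tracks[cond] = smooth(normalize_rpgc(track, egs), cfg.smooth_window)

    # --- spike row filter on the control sense matrix ----------------------
    anchors = [g.tss_anchor() for g in kept]
    plus_c, minus_c = net_tracks["control"]
    mat, used = anchor_matrix(
        plus_c, anchors, cfg.netseq_flank, minus_track=minus_c, anti_strand=False
    )
    keep_mask = spike_filter(mat, cfg.spike_subwindow, cfg.spike_frac_threshold)
    analysis_genes = [kept[used[i]] for i in np.flatnonzero(keep_mask)]
    counts_filtered["genes_after_spike_filter"] = len(analysis_genes)

    # --- RNA-seq DE and gene classes ---------------------------------------
    counts = simulate_counts(
        genes, truth, cfg.n_reps, cfg.truth, seed=cfg.stage_seed("counts")
    )
    de = de_call(counts)
    bound_ids = truth.loc[truth["bound"], "gene_id"]
    class_table = classify_genes(de, bound_ids)
    class_table = class_table.loc[
        class_table["gene_id"].isin({g.gene_id for g in analysis_genes})
    ]

    # --- per-gene promoter metrics -----------------------------------------
    tr_tables = {
        cond: travelling_ratio_table(
            *net_tracks[cond],
            analysis_genes,
            proximal=cfg.proximal,
            body_offsets=cfg.body_offsets,
        )
        for cond in CONDITIONS
    }
    antisense = antisense_table(
        net_tracks,
        analysis_genes,
        window=cfg.antisense_window,
        pseudocount=cfg.antisense_pseudocount,
    )
    occupancy = occupancy_change_table(
        mono_tracks,
        analysis_genes,
        window=cfg.occupancy_window,
        pseudocount=cfg.antisense_pseudocount,
    )

    # --- class-stratified Welch contrasts ----------------------------------
    contrasts = []
    for name, values in (
        ("antisense_log2fc", antisense["log2fc_antisense"]),
        ("occupancy_log2fc", occupancy["log2fc_occupancy"]),
    ):
        tab = class_contrast(values, class_table)
        tab.insert(0, "metric", name)
        contrasts.append(tab)
    contrasts = pd.concat(contrasts, ignore_index=True)

    # --- log-log slope comparison (bound vs unbound, control) --------------
    body_density = tr_tables["control"]["body_density"]
    mrna = 2.0 ** de["mean_log2cpm_control"]
    slopes = _slope_table(body_density, mrna, class_table)

    # --- metaprofiles -------------------------------------------------------
    profiles: dict[str, Metaprofile] = {}
    if cfg.make_profiles:
        up_ids = set(class_table.loc[class_table["de_class"] == "up", "gene_id"])
        for bound in (True, False):
            ids = up_ids & set(
                class_table.loc[class_table["bound"] == bound, "gene_id"]
            )
            sel = [g.tss_anchor() for g in analysis_genes if g.gene_id in ids]
            tag = "bound" if bound else "unbound"
            if len(sel) < 2:
                continue
            for cond in CONDITIONS:
                p, m = net_tracks[cond]
                profiles[f"netseq_sense_up_{tag}_{cond}"] = metaprofile(
                    p, sel, cfg.netseq_flank, minus_track=m
                )
                profiles[f"mnase_up_{tag}_{cond}"] = metaprofile(
                    mono_tracks[cond], sel, cfg.mnase_flank
                )

    cfg_echo = asdict(cfg)
    cfg_echo.pop("outdir")  # a location, not a parameter: keep runs comparable
    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": cfg.seed,
        "stage_seeds": {s: cfg.stage_seed(s) for s in _STAGE_STREAMS},
        "config": _jsonable(cfg_echo),
        "filter_counts": counts_filtered,
    }

    result = PipelineResult(
        genes=analysis_genes,
        truth=truth,
        class_table=class_table,
        de_table=de,
        tr_tables=tr_tables,
        antisense=antisense,
        occupancy=occupancy,
        contrasts=contrasts,
        slopes=slopes,
        profiles=profiles,
        manifest=manifest,
    )
    if cfg.outdir is not None:
        _write_bundle(result, Path(cfg.outdir), cfg, net_tracks, mono_tracks)
    return result


def _slope_table(body_density, mrna, class_table) -> pd.DataFrame:
    joined = pd.DataFrame({"y": body_density}).join(mrna.rename("x"), how="inner")
    joined = joined.join(class_table[["bound"]], how="inner").dropna()
    fits = {}
    for bound, grp in joined.groupby("bound"):
        if len(grp) >= 3:
            try:
                fits[bound] = loglog_fit(grp["x"], grp["y"])
            except ValueError:
                pass
    rows = []
    for bound, fit in fits.items():
        rows.append(
            {
                "group": "bound" if bound else "unbound",
                "beta": fit.beta,
                "se_beta": fit.se_beta,
                "intercept": fit.intercept,
                "n": fit.n,
            }
        )
    out = pd.DataFrame(rows)
    if len(fits) == 2:
        cmp = slope_z(fits[True], fits[False])
        out.attrs["slope_z"] = cmp.z
        out.attrs["slope_p"] = cmp.p
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _write_bundle(res: PipelineResult, outdir: Path, cfg: RunConfig, net_tracks, mono_tracks) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    res.de_table.to_csv(outdir / "de_table.tsv", sep="\t", index=False)
    res.class_table.to_csv(outdir / "gene_classes.tsv", sep="\t", index=False)
    res.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    for cond, tab in res.tr_tables.items():
        tab.to_csv(outdir / f"travelling_ratio_{cond}.tsv", sep="\t", index=False)
    res.antisense.to_csv(outdir / "antisense.tsv", sep="\t", index=False)
    res.occupancy.to_csv(outdir / "occupancy.tsv", sep="\t", index=False)
    res.contrasts.to_csv(outdir / "class_contrasts.tsv", sep="\t", index=False)
    slopes = res.slopes.copy()
    slopes.to_csv(outdir / "slopes.tsv", sep="\t", index=False)
    stats_extra = {
        "slope_z": res.slopes.attrs.get("slope_z"),
        "slope_p": res.slopes.attrs.get("slope_p"),
    }
    for name, prof in res.profiles.items():
        prof.to_frame().to_csv(outdir / f"profile_{name}.tsv", sep="\t", index=False)
    if cfg.write_tracks:
        for cond, (p, m) in net_tracks.items():
            write_bedgraph(p, outdir / f"netseq_{cond}.plus.bedgraph")
            write_bedgraph(m, outdir / f"netseq_{cond}.minus.bedgraph")
        for cond, t in mono_tracks.items():
            write_bedgraph(t, outdir / f"mnase_mono_{cond}.bedgraph")
    manifest = dict(res.manifest)
    manifest["slope_comparison"] = _jsonable(stats_extra)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
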