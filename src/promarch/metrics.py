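"""Promoter-level metrics: travelling ratio, antisense quantification,
expression summaries, region densities and co-occupancy, gene classification,
and the high-occupancy row filter.

Density everywhere means signal summed over a region divided by the region
length in bp, so ratios of densities (e.g. the travelling ratio) are
invariant to 1x normalization. The travelling ratio is the density over the
proximal promoter (-30/+250 around the TSS) divided by the density over the
gene body (+300 after the TSS to -200 before the TES); high values indicate
promoter-proximal Pol II pausing. Antisense transcription is quantified on
the opposite strand in the 1,000 bp upstream of the TSS, and its knockdown
vs. control change as log2((kd + eps)/(ctrl + eps)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    ANTISENSE_WINDOW,
    GENE_BODY_OFFSETS,
    PROXIMAL_PROMOTER,
    GeneModel,
    Region,
    ShortGeneError,
    derive_region,
    oriented_window,
)
from .coverage import TagTrack
from .stats import welch_t

logger = logging.getLogger(__name__)

QUANTILE_LABELS = ("very low", "low", "medium", "high")
DEFAULT_ANTISENSE_PSEUDOCOUNT = 0.1e-3  # 0.1 signal units per kb, per bp


@dataclass(frozen=True)
class TravellingRatio:
    gene_id: str
    proximal_density: float
    body_density: float
    tr: float
    usable: bool


def _sense_track(plus: TagTrack, minus: TagTrack, strand: str) -> TagTrack:
    return plus if strand == "+" else minus


def travelling_ratio(
    plus_track: TagTrack,
    minus_track: TagTrack,
    gene: GeneModel,
    *,
    proximal: tuple[int, int] = PROXIMAL_PROMOTER,
    body_offsets: tuple[int, int] = GENE_BODY_OFFSETS,
) -> TravellingRatio:
    """Pol II pause/release measure: proximal-promoter density over gene-body
    density of sense-strand signal. Genes that are too short or have zero
    body density are flagged unusable."""
    track = _sense_track(plus_track, minus_track, gene.strand)
    prox = derive_region(gene, "proximal_promoter", proximal=proximal)
    try:
        body = derive_region(gene, "gene_body", body_offsets=body_offsets)
    except ShortGeneError:
        logger.info("travelling_ratio: gene %s too short, unusable", gene.gene_id)
        return TravellingRatio(gene.gene_id, np.nan, np.nan, np.nan, False)
    pd_ = track.region_density(prox.chrom, prox.start, prox.end)
    bd = track.region_density(body.chrom, body.start, body.end)
    if bd == 0.0:
        logger.info("travelling_ratio: gene %s has empty body, unusable", gene.gene_id)
        return TravellingRatio(gene.gene_id, pd_, bd, np.nan, False)
    return TravellingRatio(gene.gene_id, pd_, bd, pd_ / bd, True)


def travelling_ratio_table(
    plus_track: TagTrack, minus_track: TagTrack, genes: Iterable[GeneModel], **kw
) -> pd.DataFrame:
    rows = [travelling_ratio(plus_track, minus_track, g, **kw) for g in genes]
    return pd.DataFrame([vars(r) for r in rows]).set_index("gene_id", drop=False)


# ---------------------------------------------------------------------------
# antisense transcription in the 1-kb upstream window
# ---------------------------------------------------------------------------

def antisense_density(
    plus_track: TagTrack,
    minus_track: TagTrack,
    gene: GeneModel,
    window: int = ANTISENSE_WINDOW,
) -> tuple[float, float]:
    """(antisense_density, sense_density) over the upstream antisense window:
    antisense reads the strand opposite to transcription."""
    region = derive_region(gene, "antisense_window", antisense_window=window)
    anti = _sense_track(plus_track, minus_track, region.strand)
    sense = _sense_track(plus_track, minus_track, gene.strand)
    return (
        anti.region_density(region.chrom, region.start, region.end),
        sense.region_density(region.chrom, region.start, region.end),
    )


def log2_fold_change(kd: float, ctrl: float, pseudocount: float) -> float:
    return float(np.log2((kd + pseudocount) / (ctrl + pseudocount)))


def antisense_table(
    tracks: Mapping[str, tuple[TagTrack, TagTrack]],
    genes: Iterable[GeneModel],
    window: int = ANTISENSE_WINDOW,
    pseudocount: float = DEFAULT_ANTISENSE_PSEUDOCOUNT,
    *,
    cond_test: str = "kd",
    cond_ref: str = "control",
) -> pd.DataFrame:
    """Per-gene antisense densities per condition and knockdown-vs-control
    log2 fold change. ``tracks`` maps condition -> (plus, minus) track pair;
    the pseudocount is in density units (signal per bp)."""
    rows = []
    for g in genes:
        rec = {"gene_id": g.gene_id}
        for cond, (p, m) in tracks.items():
            a, s = antisense_density(p, m, g, window)
            rec[f"antisense_density_{cond}"] = a
            rec[f"sense_density_{cond}"] = s
        rec["log2fc_antisense"] = log2_fold_change(
            rec[f"antisense_density_{cond_test}"],
            rec[f"antisense_density_{cond_ref}"],
            pseudocount,
        )
        rows.append(rec)
    return pd.DataFrame(rows).set_index("gene_id", drop=False)


def upstream_occupancy(
    track: TagTrack, gene: GeneModel, window: tuple[int, int] = (-450, -30)
) -> float:
    """Mean signal density in a strand-oriented window upstream of the TSS
    (default covers the -1/-2 nucleosome positions)."""
    start, end = oriented_window(gene.tss, gene.strand, *window)
    return track.region_density(gene.chrom, max(start, 0), end)


def occupancy_change_table(
    tracks: Mapping[str, TagTrack],
    genes: Iterable[GeneModel],
    window: tuple[int, int] = (-450, -30),
    pseudocount: float = DEFAULT_ANTISENSE_PSEUDOCOUNT,
    *,
    cond_test: str = "kd",
    cond_ref: str = "control",
) -> pd.DataFrame:
    """Per-gene upstream occupancy per condition and its log2 change."""
    rows = []
    for g in genes:
        rec = {"gene_id": g.gene_id}
        for cond, track in tracks.items():
            rec[f"occupancy_{cond}"] = upstream_occupancy(track, g, window)
        rec["log2fc_occupancy"] = log2_fold_change(
            rec[f"occupancy_{cond_test}"], rec[f"occupancy_{cond_ref}"], pseudocount
        )
        rows.append(rec)
    return pd.DataFrame(rows).set_index("gene_id", drop=False)


# ---------------------------------------------------------------------------
# expression summaries and gene classes
# ---------------------------------------------------------------------------

def expression_summary(
    counts: pd.Series, gene_lengths: pd.Series
) -> pd.DataFrame:
    """Per-gene CPM, RPKM and RPKM quartile class (high/medium/low/very low).

    Ties are broken by stable rank so the four classes always have equal
    counts (+/- 1). Scale-invariant: doubling all counts changes nothing.
    """
    if (gene_lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    lib = counts.sum()
    if lib <= 0:
        raise ValueError("zero library size")
    cpm = counts * 1e6 / lib
    rpkm = cpm * 1e3 / gene_lengths.loc[counts.index]
    ranks = rpkm.rank(method="first")
    quartile = pd.cut(ranks, bins=4, labels=QUANTILE_LABELS)
    return pd.DataFrame(
        {"gene_id": counts.index, "cpm": cpm, "rpkm": rpkm, "quantile_class": quartile}
    ).set_index("gene_id", drop=False)


def region_density_matrix(
    tracks: Mapping[str, TagTrack],
    regions: Sequence[Region],
    log: bool = False,
    pseudocount: float = DEFAULT_ANTISENSE_PSEUDOCOUNT,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(region x track density matrix, pairwise Pearson r of its columns).

    Zero-variance columns yield NaN correlations. With ``log=True`` the
    correlation is computed on log(density + pseudocount).
    """
    if len(regions) < 3:
        raise ValueError("need at least 3 regions for a correlation")
    dens = pd.DataFrame(
        {
            name: [t.region_density(r.chrom, r.start, r.end) for r in regions]
            for name, t in tracks.items()
        }
    )
    cols = np.log(dens + pseudocount) if log else dens
    return dens, cols.corr(method="pearson")


def classify_genes(
    de: pd.DataFrame,
    bound_ids: Iterable[str],
    *,
    logfc_min: float = 1.0,
    padj_max: float = 0.01,
    padj_unchanged: float = 0.05,
) -> pd.DataFrame:
    """Mutually exclusive DE classes joined with the factor-bound flag.

    up: logFC > 1 and adj p < 0.01; down: logFC < -1 and adj p < 0.01;
    unchanged: adj p > 0.05; other: the remainder. Bound gene ids absent from
    the DE table are dropped with a warning.
    """
    bound = set(bound_ids)
    missing = bound - set(de["gene_id"])
    if missing:
        logger.warning(
            "classify_genes: %d bound gene ids absent from the DE table", len(missing)
        )
    cls = np.where(
        (de["logfc"] > logfc_min) & (de["padj"] < padj_max),
        "up",
        np.where(
            (de["logfc"] < -logfc_min) & (de["padj"] < padj_max),
            "down",
            np.where(de["padj"] > padj_unchanged, "unchanged", "other"),
        ),
    )
    out = pd.DataFrame(
        {
            "gene_id": de["gene_id"],
            "de_class": cls,
            "bound": de["gene_id"].isin(bound),
        }
    ).set_index("gene_id", drop=False)
    out["label"] = out["de_class"] + ":" + np.where(out["bound"], "bound", "unbound")
    return out


# ---------------------------------------------------------------------------
# high-occupancy row filter (short ncRNA spikes)
# ---------------------------------------------------------------------------

def spike_filter(
    matrix: np.ndarray, subwindow: int = 100, frac_threshold: float = 0.8
) -> np.ndarray:
    """Boolean keep-mask over anchor rows of a 1-bp anchor x offset matrix.

    A row is removed iff some ``subwindow``-bp sliding window holds at least
    ``frac_threshold`` of the row's total signal (and the total is > 0):
    such rows are dominated by a short, unannotated high-occupancy unit
    rather than genic transcription. Deterministic surrogate for clustering-
    based row triage.
    """
    mat = np.asarray(matrix, dtype=float)
    totals = mat.sum(axis=1)
    cs = np.concatenate([np.zeros((mat.shape[0], 1)), np.cumsum(mat, axis=1)], axis=1)
    w = min(subwindow, mat.shape[1])
    win_max = (cs[:, w:] - cs[:, :-w]).max(axis=1) if mat.shape[1] > w else totals
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(totals > 0, win_max / totals, 0.0)
    keep = ~((totals > 0) & (share >= frac_threshold))
    logger.info("spike_filter: removed %d of %d rows", int((~keep).sum()), len(keep))
    return keep


def kmeans_spike_filter(
    matrix: np.ndarray,
    k: int = 6,
    rounds: int = 3,
    subwindow: int = 100,
    frac_threshold: float = 0.8,
    seed: int = 0,
) -> np.ndarray:
    """Clustering-based variant: k-means on row-normalized profiles, repeated
    ``rounds`` times, dropping clusters whose centroid violates the subwindow
    rule. Fixed seed; provided for fidelity to clustering-based triage."""
    from sklearn.cluster import KMeans

    mat = np.asarray(matrix, dtype=float)
    keep = np.ones(mat.shape[0], dtype=bool)
    for r in range(rounds):
        idx = np.flatnonzero(keep)
        if len(idx) <= k:
            break
        rows = mat[idx]
        totals = rows.sum(axis=1, keepdims=True)
        norm = np.divide(rows, totals, out=np.zeros_like(rows), where=totals > 0)
        km = KMeans(n_clusters=k, random_state=seed + r, n_init=5).fit(norm)
        bad_clusters = np.flatnonzero(~spike_filter(km.cluster_centers_, subwindow, frac_threshold))
        if len(bad_clusters) == 0:
            break
        keep[idx[np.isin(km.labels_, bad_clusters)]] = False
    return keep


# ---------------------------------------------------------------------------
# class contrasts (bound vs unbound within each DE class)
# ---------------------------------------------------------------------------

def class_contrast(
    values: pd.Series, classes: pd.DataFrame, min_n: int = 3
) -> pd.DataFrame:
    """Welch test of bound vs unbound genes within each DE class.

    ``values`` is a per-gene statistic (e.g. antisense log2 fold change),
    ``classes`` a table from :func:`classify_genes`. Returns one row per
    class with the Welch t, df, p and group means.
    """
    joined = classes.join(values.rename("value"), how="inner").dropna(subset=["value"])
    rows = []
    for de_class, grp in joined.groupby("de_class", sort=True):
        if de_class == "other":
            continue
        a = grp.loc[grp["bound"], "value"].to_numpy()
        b = grp.loc[~grp["bound"], "value"].to_numpy()
        if len(a) < min_n or len(b) < min_n:
            continue
        res = welch_t(a, b)
        rows.append(
            {
                "de_class": de_class,
                "n_bound": len(a),
                "n_unbound": len(b),
                "mean_bound": a.mean(),
                "mean_unbound": b.mean(),
                "t": res.t,
                "df": res.df,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)
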