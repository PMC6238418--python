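"""Strand-aware signal tracks, 1x normalization, smoothing, metaprofiles.

A :class:`TagTrack` holds per-bin signal arrays keyed by chromosome, together
with its normalization state. NET-seq tracks count +1 at each tag position on
the tag's strand; fragment tracks count either +1 per covered base (occupancy
mode, the default for depth-normalized plots) or +1 at the fragment midpoint
(dyad-resolution mode).

1x normalization (RPGC) scales a raw track so the genome-wide mean per-bp
signal equals 1, using the effective (non-N) genome size. Smoothing is a
centered moving average whose window shrinks at chromosome edges, so interior
signal is conserved.

Metaprofiles average anchor-centered windows: a minus-strand anchor at base
``p`` is orientation-flipped, so profile offset ``o`` reads base ``p - o``
(and sense/antisense swap tracks). Offsets run from ``-flank`` to ``+flank``
inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .readproc import FragmentSet

logger = logging.getLogger(__name__)


@dataclass
class TagTrack:
    """Per-chromosome binned signal with a normalization state machine."""

    data: dict[str, np.ndarray]
    binsize: int = 1
    strand: str = "."
    norm_state: str = "raw"
    smooth_window: int | None = None
    _cumsums: dict[str, np.ndarray] = field(
        default_factory=dict, repr=False, compare=False
    )

    @property
    def total_signal_bp(self) -> float:
        """Total signal integrated over base pairs."""
        return float(sum(arr.sum() for arr in self.data.values())) * self.binsize

    @property
    def genome_bins(self) -> int:
        return int(sum(arr.size for arr in self.data.values()))

    def region_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of signal over [start, end) in bp coordinates (cached cumsums)."""
        if chrom not in self._cumsums:
            self._cumsums[chrom] = np.concatenate(
                [[0.0], np.cumsum(self.data[chrom])]
            )
        cs = self._cumsums[chrom]
        a, b = start // self.binsize, -(-end // self.binsize)
        a, b = max(a, 0), min(b, len(cs) - 1)
        if a >= b:
            return 0.0
        return float(cs[b] - cs[a])

    def region_density(self, chrom: str, start: int, end: int) -> float:
        """Mean per-bp signal over [start, end)."""
        return self.region_sum(chrom, start, end) / (end - start)


def _new_data(chrom_sizes: Mapping[str, int], binsize: int) -> dict[str, np.ndarray]:
    return {
        chrom: np.zeros(-(-size // binsize), dtype=np.float64)
        for chrom, size in chrom_sizes.items()
    }


def build_tag_track(
    tags: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    strand: str,
    binsize: int = 1,
) -> TagTrack:
    """Single-strand NET-seq track: +1 at each tag position of that strand."""
    data = _new_data(chrom_sizes, binsize)
    sel = tags[tags["strand"] == strand] if len(tags) else tags
    for chrom, grp in sel.groupby("chrom", sort=True, observed=True):
        if chrom not in data:
            raise ValueError(f"tag on unknown chromosome {chrom!r}")
        pos = grp["pos"].to_numpy()
        bad = (pos < 0) | (pos >= chrom_sizes[chrom])
        if bad.any():
            i = grp.index[np.flatnonzero(bad)[0]]
            raise ValueError(f"tag record {i} at {chrom}:{pos[bad][0]} out of bounds")
        counts = np.bincount(pos // binsize, minlength=data[chrom].size)
        data[chrom] = data[chrom] + counts.astype(np.float64)
    return TagTrack(data, binsize=binsize, strand=strand)


def build_stranded_tracks(
    tags: pd.DataFrame, chrom_sizes: Mapping[str, int], binsize: int = 1
) -> tuple[TagTrack, TagTrack]:
    """(plus, minus) NET-seq track pair."""
    return (
        build_tag_track(tags, chrom_sizes, "+", binsize),
        build_tag_track(tags, chrom_sizes, "-", binsize),
    )


def build_fragment_track(
    fragments: FragmentSet | pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    binsize: int = 1,
    mode: str = "coverage",
) -> TagTrack:
    """Unstranded fragment track: per-base occupancy or midpoint counts."""
    frags = fragments.frags if isinstance(fragments, FragmentSet) else fragments
    if mode not in ("coverage", "midpoint"):
        raise ValueError(f"unknown fragment counting mode {mode!r}")
    data = _new_data(chrom_sizes, binsize)
    for chrom, grp in frags.groupby("chrom", sort=True, observed=True):
        if chrom not in data:
            raise ValueError(f"fragment on unknown chromosome {chrom!r}")
        size = chrom_sizes[chrom]
        start = np.clip(grp["start"].to_numpy(), 0, size)
        end = np.clip(grp["end"].to_numpy(), 0, size)
        if mode == "midpoint":
            mids = (start + end) // 2
            np.add.at(data[chrom], mids[mids < size] // binsize, 1.0)
        else:
            if binsize == 1:
                delta = np.zeros(size + 1, dtype=np.float64)
                np.add.at(delta, start, 1.0)
                np.add.at(delta, end, -1.0)
                data[chrom] = np.cumsum(delta[:-1])
            else:  # approximate: distribute coverage by overlapped bins
                for s, e in zip(start, end):
                    b0, b1 = s // binsize, -(-e // binsize)
                    data[chrom][b0:b1] += 1.0
    return TagTrack(data, binsize=binsize, strand=".")


def normalize_rpgc(track: TagTrack, effective_genome_size: int) -> TagTrack:
    """Scale a raw track to 1x depth: genome-wide mean per-bp signal = 1."""
    if track.norm_state != "raw":
        raise ValueError(f"track already normalized ({track.norm_state})")
    total = track.total_signal_bp
    if total <= 0:
        raise ValueError("cannot 1x-normalize a track with zero total signal")
    scale = effective_genome_size / total
    data = {c: arr * scale for c, arr in track.data.items()}
    return replace(track, data=data, norm_state="rpgc", _cumsums={})


def smooth(track: TagTrack, window: int = 20) -> TagTrack:
    """Centered moving average over ``2*(window//2)+1`` bins, window shrunk at
    chromosome edges (interior signal sum is conserved)."""
    if track.binsize != 1:
        raise ValueError("smoothing expects 1-bp bins")
    half = window // 2
    data = {}
    for chrom, arr in track.data.items():
        n = arr.size
        cs = np.concatenate([[0.0], np.cumsum(arr)])
        idx = np.arange(n)
        lo = np.maximum(idx - half, 0)
        hi = np.minimum(idx + half + 1, n)
        data[chrom] = (cs[hi] - cs[lo]) / (hi - lo)
    return replace(track, data=data, smooth_window=window, _cumsums={})


# ---------------------------------------------------------------------------
# metaprofiles
# ---------------------------------------------------------------------------

@dataclass
class Metaprofile:
    """Anchor-averaged profile; offsets are strand-oriented bp from the anchor."""

    offsets: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    n_anchors: int
    n_skipped: int = 0
    matrix: np.ndarray | None = None
    anchor_ids: list[str] | None = None

    @property
    def ci95(self) -> np.ndarray:
        return 1.96 * self.se

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset": self.offsets,
                "mean": self.mean,
                "se": self.se,
                "ci95": self.ci95,
                "n": self.n_anchors,
            }
        )


def anchor_matrix(
    track: TagTrack,
    anchors: Sequence[tuple[str, int, str]],
    flank: int,
    *,
    minus_track: TagTrack | None = None,
    anti_strand: bool = False,
) -> tuple[np.ndarray, list[int]]:
    """Anchor x offset matrix of signal around each anchor base.

    ``anchors`` are (chrom, base position, strand). For stranded data pass the
    plus-strand track as ``track`` and the minus-strand one as ``minus_track``;
    each anchor then reads the track matching its own strand (sense) or the
    opposite one (``anti_strand=True``). Minus-strand anchors are orientation-
    flipped. Returns the matrix and the indices of used anchors (out-of-bounds
    anchors are skipped and logged).
    """
    if track.binsize != 1:
        raise ValueError("metaprofiles expect 1-bp tracks")
    rows, used = [], []
    for i, (chrom, pos, strand) in enumerate(anchors):
        if minus_track is None:
            src = track
        else:
            want_plus = (strand == "+") != anti_strand
            src = track if want_plus else minus_track
        arr = src.data[chrom]
        lo, hi = pos - flank, pos + flank + 1
        if lo < 0 or hi > arr.size:
            logger.info("metaprofile: anchor %d (%s:%d) out of bounds, skipped", i, chrom, pos)
            continue
        window = arr[lo:hi]
        rows.append(window if strand == "+" else window[::-1])
        used.append(i)
    if not rows:
        raise ValueError("no anchor window fits inside the track")
    return np.vstack(rows), used


def metaprofile(
    track: TagTrack,
    anchors: Sequence[tuple[str, int, str]],
    flank: int,
    *,
    minus_track: TagTrack | None = None,
    anti_strand: bool = False,
    keep_matrix: bool = False,
) -> Metaprofile:
    """Mean/SE/95% CI of signal per strand-oriented offset in [-flank, flank]."""
    mat, used = anchor_matrix(
        track, anchors, flank, minus_track=minus_track, anti_strand=anti_strand
    )
    mean = mat.mean(axis=0)
    se = (
        mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
        if mat.shape[0] > 1
        else np.zeros_like(mean)
    )
    return Metaprofile(
        offsets=np.arange(-flank, flank + 1),
        mean=mean,
        se=se,
        n_anchors=mat.shape[0],
        n_skipped=len(anchors) - len(used),
        matrix=mat if keep_matrix else None,
    )


# ---------------------------------------------------------------------------
# bedGraph I/O
# ---------------------------------------------------------------------------

def write_bedgraph(track: TagTrack, path: str | Path) -> None:
    """Four-column bedGraph with run-length merging; zero runs are omitted."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            arr = track.data[chrom]
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [arr.size]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v == 0:
                    continue
                fh.write(
                    f"{chrom}\t{s * track.binsize}\t{e * track.binsize}\t{v:.6f}\n"
                )


def read_bedgraph(
    path: str | Path,
    chrom_sizes: Mapping[str, int],
    binsize: int = 1,
    strand: str = ".",
    norm_state: str = "raw",
) -> TagTrack:
    data = _new_data(chrom_sizes, binsize)
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"]
    )
    for chrom, grp in df.groupby("chrom", sort=False):
        arr = data[chrom]
        for s, e, v in zip(grp["start"], grp["end"], grp["value"]):
            arr[s // binsize : -(-e // binsize)] = v
    return TagTrack(data, binsize=binsize, strand=strand, norm_state=norm_state)
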