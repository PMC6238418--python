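"""NET-seq tag cleanup and MNase/ATAC fragment partitioning.

NET-seq tags are kept in a pandas DataFrame with columns ``chrom``, ``pos``
(0-based base position of the recorded Pol II / nascent-RNA 3' end), ``strand``
and ``umi`` (an opaque molecular-identifier label; extra columns such as
simulator provenance are carried through untouched). Paired-end fragments live
in a DataFrame with ``chrom``, ``start``, ``end`` (0-based half-open) wrapped
in a :class:`FragmentSet` that records the assay and condition.

The two NET-seq filters implemented here are the standard pre-analysis steps:
PCR-duplicate removal (UMI-aware positional dedup) and removal of splicing
intermediates, i.e. tags sitting exactly on the strand-oriented last base of
an annotated exon or intron.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel

logger = logging.getLogger(__name__)

TAG_KEY = ["chrom", "pos", "strand", "umi"]
TAG_COLUMNS = TAG_KEY

#: fragment-length classes, inclusive bounds: "<80 bp" TF-sized footprints and
#: "135-170 bp" mononucleosome fragments
MNASE_CLASSES: dict[str, tuple[int, int]] = {
    "subnucleosomal": (1, 79),
    "mononucleosome": (135, 170),
}


class ConfigError(ValueError):
    pass


def empty_tags() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=object),
            "pos": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=object),
            "umi": pd.Series(dtype=object),
        }
    )


@dataclass
class FragmentSet:
    """Homogeneous set of paired-end fragments from one assay/condition."""

    frags: pd.DataFrame
    assay: str
    condition: str = ""

    def __post_init__(self) -> None:
        if self.assay not in ("mnase", "atac"):
            raise ConfigError(f"unknown assay {self.assay!r}")
        f = self.frags
        if len(f) and "length" not in f.columns:
            f = f.assign(length=f["end"] - f["start"])
            self.frags = f
        if len(f) and (f["length"] < 1).any():
            raise ValueError("fragment with length < 1")

    def __len__(self) -> int:
        return len(self.frags)


# ---------------------------------------------------------------------------
# NET-seq tag filters
# ---------------------------------------------------------------------------

def dedup_tags(tags: pd.DataFrame) -> pd.DataFrame:
    """Collapse PCR duplicates: one tag per (chrom, pos, strand, umi).

    Idempotent; output is coordinate-sorted (stable within ties).
    """
    if len(tags) == 0:
        return tags.copy()
    out = tags.drop_duplicates(subset=TAG_KEY, keep="first")
    out = out.sort_values(["chrom", "pos", "strand"], kind="stable")
    n_removed = len(tags) - len(out)
    logger.info("dedup_tags: removed %d duplicate tags of %d", n_removed, len(tags))
    return out.reset_index(drop=True)


def splice_intermediate_sites(genes: Iterable[GeneModel]) -> pd.DataFrame:
    """Strand-oriented last bases of every exon and intron.

    For a ``+`` strand interval [a, b) the last transcribed base is ``b - 1``;
    for ``-`` strand it is ``a``. Genes without exons contribute no sites.
    """
    rows: list[tuple[str, str, int]] = []
    for g in genes:
        for a, b in list(g.exons) + list(g.introns):
            pos = b - 1 if g.strand == "+" else a
            rows.append((g.chrom, g.strand, pos))
    return pd.DataFrame(rows, columns=["chrom", "strand", "pos"]).drop_duplicates()


def remove_splicing_intermediates(
    tags: pd.DataFrame, genes: Sequence[GeneModel]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split tags into (kept, removed): removed iff the tag position equals a
    strand-oriented exon/intron last base of a same-strand gene."""
    sites = splice_intermediate_sites(genes)
    if len(tags) == 0 or len(sites) == 0:
        return tags.copy(), tags.iloc[0:0].copy()
    key = pd.MultiIndex.from_frame(tags[["chrom", "strand", "pos"]])
    site_key = pd.MultiIndex.from_frame(sites)
    is_si = key.isin(site_key)
    kept, removed = tags[~is_si].copy(), tags[is_si].copy()
    logger.info(
        "splicing-intermediate filter: removed %d of %d tags", len(removed), len(tags)
    )
    return kept, removed


# ---------------------------------------------------------------------------
# Fragment partitioning
# ---------------------------------------------------------------------------

def partition_fragments(
    fs: FragmentSet, classes: Mapping[str, tuple[int, int]] = MNASE_CLASSES
) -> dict[str, FragmentSet]:
    """Assign fragments to disjoint inclusive length classes; fragments that
    match no class are dropped (count logged)."""
    bounds = sorted(classes.items(), key=lambda kv: kv[1])
    for (na, (_, hi_a)), (nb, (lo_b, _)) in zip(bounds, bounds[1:]):
        if hi_a >= lo_b:
            raise ConfigError(f"length classes {na!r} and {nb!r} overlap")
    lengths = fs.frags["length"] if len(fs.frags) else pd.Series(dtype=np.int64)
    out = {}
    assigned = pd.Series(False, index=fs.frags.index)
    for name, (lo, hi) in classes.items():
        mask = (lengths >= lo) & (lengths <= hi)
        assigned |= mask
        out[name] = replace(fs, frags=fs.frags[mask].reset_index(drop=True))
    n_dropped = int((~assigned).sum())
    logger.info(
        "partition_fragments: %d of %d fragments matched no class and were dropped",
        n_dropped,
        len(fs.frags),
    )
    return out


def select_atac_nfr(fs: FragmentSet, max_len: int = 100) -> FragmentSet:
    """Nucleosome-free-region fragments: remove duplicated fragments (identical
    start/end), then keep fragments with length <= ``max_len``.

    A fragment-length threshold stands in for model-based NFR classification;
    short ATAC fragments are the canonical NFR signal.
    """
    if fs.assay != "atac":
        raise ConfigError("select_atac_nfr expects an ATAC FragmentSet")
    dedup = fs.frags.drop_duplicates(subset=["chrom", "start", "end"], keep="first")
    kept = dedup[dedup["length"] <= max_len].reset_index(drop=True)
    logger.info(
        "select_atac_nfr: %d duplicates removed, %d of %d fragments kept",
        len(fs.frags) - len(dedup),
        len(kept),
        len(fs.frags),
    )
    return replace(fs, frags=kept)


# ---------------------------------------------------------------------------
# I/O: BED6 tags, BEDPE fragments, SAM
# ---------------------------------------------------------------------------

def read_tags_bed(path: str | Path) -> pd.DataFrame:
    """BED6 NET-seq tags: one base per record, name field = UMI."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 3, 5],
        names=["chrom", "pos", "umi", "strand"],
        dtype={"chrom": str, "pos": np.int64, "umi": str, "strand": str},
    )
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"{path}: unknown strand on record {int(np.flatnonzero(bad)[0]) + 1}")
    return df[["chrom", "pos", "strand", "umi"]]


def write_tags_bed(tags: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "chrom": tags["chrom"],
            "start": tags["pos"],
            "end": tags["pos"] + 1,
            "name": tags["umi"].astype(str),
            "score": 0,
            "strand": tags["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_fragments_bedpe(
    path: str | Path, assay: str, condition: str = ""
) -> FragmentSet:
    """Three-column fragment BED / BEDPE-style TSV: chrom, start, end."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    return FragmentSet(df, assay=assay, condition=condition)


def write_fragments_bedpe(fs: FragmentSet, path: str | Path) -> None:
    fs.frags[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def read_sam(path: str | Path):
    """Read a SAM/BAM: paired proper pairs become fragments (keyed by assay
    'mnase'), single-end reads become NET-seq tags whose position is the 5'
    end of the read (reference_end - 1 on the reverse strand)."""
    import pysam

    tag_rows = []
    frag_rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.is_paired:
                if read.is_proper_pair and read.is_read1 and read.template_length > 0:
                    start = read.reference_start
                    frag_rows.append(
                        (read.reference_name, start, start + read.template_length)
                    )
            else:
                strand = "-" if read.is_reverse else "+"
                pos = read.reference_end - 1 if read.is_reverse else read.reference_start
                tag_rows.append((read.reference_name, pos, strand, read.query_name))
    tags = pd.DataFrame(tag_rows, columns=["chrom", "pos", "strand", "umi"])
    frags = pd.DataFrame(frag_rows, columns=["chrom", "start", "end"])
    return tags, frags
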