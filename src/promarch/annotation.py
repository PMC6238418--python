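"""Gene annotation, derived analysis regions, and GC profiles.

Coordinate conventions
----------------------
Everything internal is 0-based, half-open (BED-native); GTF input (1-based,
closed) is converted at the boundary. A :class:`GeneModel` stores its TSS and
TES as *boundary* coordinates: for a ``+`` strand gene the TSS is the leftmost
coordinate of the span (the first transcribed base is ``tss``); for a ``-``
strand gene the TSS is the rightmost coordinate (the first transcribed base is
``tss - 1``). A strand-oriented window ``[a, b)`` relative to the TSS (``a``
and ``b`` in transcript coordinates, negative = upstream) maps to genomic
``[tss + a, tss + b)`` on ``+`` genes and to the mirrored ``[tss - b, tss - a)``
on ``-`` genes, so region lengths are strand-independent.

Analysis windows (all tunable, defaults are the study definitions):

* proximal promoter: -30 / +250 around the TSS (280 bp),
* gene body: TSS+300 to TES-200,
* antisense window: the 1,000 bp upstream of the TSS, signal read on the
  strand opposite to transcription,
* TSS flank: symmetric +/- flank for metaprofiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")

#: strand-oriented window defaults, transcript coordinates relative to the TSS
PROXIMAL_PROMOTER = (-30, 250)
GENE_BODY_OFFSETS = (300, 200)  # downstream of TSS, upstream of TES
ANTISENSE_WINDOW = 1000
ISOLATION_MARGIN = 2500

REGION_ROLES = ("proximal_promoter", "gene_body", "antisense_window", "tss_flank")


class AnnotationError(ValueError):
    """Malformed annotation input."""


@dataclass(frozen=True)
class GeneModel:
    """A gene/transcript model anchored by boundary TSS/TES coordinates."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise AnnotationError(f"unknown strand {self.strand!r} for {self.gene_id}")
        if self.strand == "+" and not self.tss < self.tes:
            raise AnnotationError(f"+ strand gene {self.gene_id} needs tss < tes")
        if self.strand == "-" and not self.tes < self.tss:
            raise AnnotationError(f"- strand gene {self.gene_id} needs tes < tss")
        lo, hi = self.span
        prev_end = lo - 1
        for start, end in self.exons:
            if start >= end or start < lo or end > hi:
                raise AnnotationError(
                    f"exon [{start},{end}) of {self.gene_id} outside span [{lo},{hi})"
                )
            if start <= prev_end:
                raise AnnotationError(f"exons of {self.gene_id} unsorted or overlapping")
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        """Genomic [start, end) of the gene."""
        return (min(self.tss, self.tes), max(self.tss, self.tes))

    @property
    def length(self) -> int:
        return abs(self.tes - self.tss)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (a_end, b_start)
            for (_, a_end), (b_start, _) in zip(self.exons, self.exons[1:])
        )

    def tss_anchor(self) -> tuple[str, int, str]:
        """(chrom, base position of the first transcribed base, strand)."""
        pos = self.tss if self.strand == "+" else self.tss - 1
        return (self.chrom, pos, self.strand)


@dataclass(frozen=True)
class Region:
    """A derived analysis interval; ``strand`` is the strand whose signal the
    region is meant to be read on ('.' for unstranded)."""

    chrom: str
    start: int
    end: int
    strand: str
    role: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise AnnotationError(
                f"empty region [{self.start},{self.end}) for role {self.role}"
            )
        if self.role not in REGION_ROLES:
            raise AnnotationError(f"unknown region role {self.role!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


class ShortGeneError(AnnotationError):
    """Gene too short for the requested body offsets; flag it unusable."""


def oriented_window(tss: int, strand: str, a: int, b: int) -> tuple[int, int]:
    """Map transcript-coordinate window [a, b) at a boundary TSS to genomic."""
    if a >= b:
        raise AnnotationError(f"window [{a},{b}) is empty")
    if strand == "+":
        return (tss + a, tss + b)
    return (tss - b, tss - a)


def derive_region(
    gene: GeneModel,
    role: str,
    *,
    proximal: tuple[int, int] = PROXIMAL_PROMOTER,
    body_offsets: tuple[int, int] = GENE_BODY_OFFSETS,
    antisense_window: int = ANTISENSE_WINDOW,
    flank: int = 2000,
) -> Region:
    """Derive a standard analysis region from a gene model.

    Raises :class:`ShortGeneError` for ``gene_body`` when the gene is shorter
    than the sum of the two body offsets (such genes are unusable for the
    travelling ratio).
    """
    if role == "proximal_promoter":
        start, end = oriented_window(gene.tss, gene.strand, *proximal)
        strand = gene.strand
    elif role == "gene_body":
        down, up = body_offsets
        if gene.length <= down + up:
            raise ShortGeneError(
                f"gene {gene.gene_id} (length {gene.length}) shorter than "
                f"body offsets +{down}/-{up}"
            )
        if gene.strand == "+":
            start, end = gene.tss + down, gene.tes - up
        else:
            start, end = gene.tes + up, gene.tss - down
        strand = gene.strand
    elif role == "antisense_window":
        start, end = oriented_window(gene.tss, gene.strand, -antisense_window, 0)
        strand = "-" if gene.strand == "+" else "+"
    elif role == "tss_flank":
        start, end = oriented_window(gene.tss, gene.strand, -flank, flank)
        strand = gene.strand
    else:
        raise AnnotationError(f"unknown region role {role!r}")
    if start < 0:
        raise AnnotationError(
            f"region {role} of {gene.gene_id} extends past the chromosome start"
        )
    return Region(gene.chrom, start, end, strand, role)


def gene_body_usable(
    gene: GeneModel, body_offsets: tuple[int, int] = GENE_BODY_OFFSETS
) -> bool:
    return gene.length > sum(body_offsets)


def filter_isolated_promoters(
    genes: Sequence[GeneModel],
    upstream_margin: int = ISOLATION_MARGIN,
    *,
    include_promoters: bool = False,
) -> list[GeneModel]:
    """Keep genes whose strand-oriented ``[TSS - margin, TSS)`` upstream window
    does not intersect any other gene.

    By default the window is tested against other genes' full annotated spans.
    With ``include_promoters=True`` each other gene's span is extended by its
    own upstream margin, which additionally discards bidirectional pairs that
    share a promoter region. Deterministic and order-independent.
    """
    trees: dict[str, IntervalTree] = {}
    for i, g in enumerate(genes):
        lo, hi = g.span
        if include_promoters:
            a, b = oriented_window(g.tss, g.strand, -upstream_margin, 0)
            lo, hi = min(lo, max(a, 0)), max(hi, b)
        trees.setdefault(g.chrom, IntervalTree()).addi(lo, hi, i)

    kept = []
    for i, g in enumerate(genes):
        a, b = oriented_window(g.tss, g.strand, -upstream_margin, 0)
        a = max(a, 0)
        hits = trees[g.chrom].overlap(a, b) if a < b else set()
        if all(h.data == i for h in hits):
            kept.append(g)
    logger.info("isolation filter: kept %d of %d genes", len(kept), len(genes))
    return kept


# ---------------------------------------------------------------------------
# GC profiles
# ---------------------------------------------------------------------------

def gc_profile(
    seq: dict[str, str],
    anchors: Iterable[tuple[str, int, str]],
    flank: int,
    binsize: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean G/C fraction in [anchor - flank, anchor + flank), anchor-oriented.

    ``anchors`` are (chrom, base position, strand); minus-strand anchors are
    orientation-flipped (offset ``o`` reads base ``pos - o``). Ns are excluded
    from the mean; a bin that is all-N across all anchors is NaN. Returns
    ``(offsets, gc)`` where offsets are window-start offsets of each bin.
    """
    width = 2 * flank
    if width % binsize:
        raise ValueError("binsize must divide 2*flank")
    rows = []
    for chrom, pos, strand in anchors:
        s = seq[chrom]
        if strand == "+":
            lo, hi = pos - flank, pos + flank
            if lo < 0 or hi > len(s):
                continue
            window = s[lo:hi]
        else:
            lo, hi = pos - flank + 1, pos + flank + 1
            if lo < 0 or hi > len(s):
                continue
            window = s[lo:hi][::-1]
        arr = np.frombuffer(window.upper().encode("ascii"), dtype=np.uint8)
        gc = np.where(np.isin(arr, (ord("G"), ord("C"))), 1.0, 0.0)
        gc[arr == ord("N")] = np.nan
        rows.append(gc)
    if not rows:
        raise ValueError("no anchor window fits inside the sequence")
    mat = np.vstack(rows).reshape(len(rows), width // binsize, binsize)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-N bins -> NaN
        profile = np.nanmean(mat, axis=(0, 2))
    offsets = np.arange(-flank, flank, binsize)
    return offsets, profile


# ---------------------------------------------------------------------------
# File formats: BED6 / BED12, GTF, FASTA
# ---------------------------------------------------------------------------

def _parse_bed_line(fields: list[str], lineno: int, path: str) -> GeneModel:
    try:
        chrom = fields[0]
        start, end = int(fields[1]), int(fields[2])
        name = fields[3] if len(fields) > 3 else f"record{lineno}"
        strand = fields[5] if len(fields) > 5 else "+"
    except (IndexError, ValueError) as exc:
        raise AnnotationError(f"{path}: malformed BED line {lineno}: {exc}") from exc
    if strand not in STRANDS:
        raise AnnotationError(f"{path}: line {lineno}: unknown strand {strand!r}")
    if len(fields) >= 12:
        try:
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
        except ValueError as exc:
            raise AnnotationError(
                f"{path}: malformed BED12 blocks on line {lineno}"
            ) from exc
        exons = tuple((start + s, start + s + z) for s, z in zip(starts, sizes))
    else:
        exons = ()
    tss, tes = (start, end) if strand == "+" else (end, start)
    return GeneModel(name, chrom, strand, tss, tes, exons)


def read_bed(path: str | Path) -> list[GeneModel]:
    """Read BED6 or BED12 gene records (block fields become exons)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            genes.append(_parse_bed_line(line.split("\t"), lineno, str(path)))
    return genes


def write_bed(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as BED12 (BED6 when a gene carries no exons)."""
    with open(path, "w") as fh:
        for g in genes:
            lo, hi = g.span
            base = [g.chrom, lo, hi, g.gene_id, 0, g.strand]
            if g.exons:
                sizes = ",".join(str(e - s) for s, e in g.exons)
                starts = ",".join(str(s - lo) for s, _ in g.exons)
                base += [lo, hi, "0,0,0", len(g.exons), sizes, starts]
            fh.write("\t".join(map(str, base)) + "\n")


def write_regions_bed(regions: Iterable[Region], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.role}\t0\t{r.strand}\n")


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read an Ensembl-dialect GTF; one model per unique (chrom, strand, TSS,
    TES), exons taken from the transcript's exon children."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneModel] = []
    seen: set[tuple[str, str, int, int]] = set()
    featuretypes = set(db.featuretypes())
    parent_type = "transcript" if "transcript" in featuretypes else "gene"
    for t in db.features_of_type(parent_type):
        if t.strand not in STRANDS:
            raise AnnotationError(f"{path}: unknown strand {t.strand!r} for {t.id}")
        start, end = t.start - 1, t.end  # 1-based closed -> 0-based half-open
        tss, tes = (start, end) if t.strand == "+" else (end, start)
        key = (t.seqid, t.strand, tss, tes)
        if key in seen:
            continue
        seen.add(key)
        exons = tuple(
            sorted((e.start - 1, e.end) for e in db.children(t, featuretype="exon"))
        )
        name = t.attributes.get("gene_id", [t.id])[0]
        genes.append(GeneModel(name, t.seqid, t.strand, tss, tes, exons))
    return genes


def read_annotation(path: str | Path) -> list[GeneModel]:
    """Dispatch on extension: .bed -> BED6/BED12, .gtf/.gff -> GTF."""
    suffix = Path(path).suffix.lower()
    if suffix == ".bed":
        return read_bed(path)
    if suffix in (".gtf", ".gff"):
        return read_gtf(path)
    raise AnnotationError(f"cannot guess annotation dialect of {path}")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a (multi-record, wrapped) FASTA into a chrom -> sequence mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seq: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, s in seq.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def effective_genome_size(seq: dict[str, str]) -> int:
    """Total non-N genome length (used for 1x coverage normalization)."""
    return sum(len(s) - s.count("N") for s in seq.values())
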