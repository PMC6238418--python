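"""Synthetic genome, gene set and multi-assay data with ground-truth labels.

The generator emulates a two-condition (control vs. knockdown of a histone
chaperone) mouse-ES-cell-like experiment at desk scale:

* a genome with GC-rich promoters on a GC-poorer background,
* non-overlapping multi-exon genes with >= 2.5 kb upstream clearance by
  construction (the promoter-isolation filter is a no-op unless violations
  are planted),
* six gene classes: {up, down, unchanged} x {bound, unbound} by the factor,
* NET-seq tags: a Poisson gene-body rate coupled to expression level, a
  Gaussian promoter-proximal pause peak, strand-specific antisense tags in
  the 1-kb upstream window whose rate is multiplied by ``antisense_gain`` at
  bound-up genes in the knockdown, planted splicing intermediates exactly at
  exon/intron 3' ends, and planted PCR duplicates with shared UMIs,
* MNase fragments drawn around phased nucleosome dyads with Gaussian fuzz;
  upstream (-1, -2) dyad weight reduced by ``upstream_nucleosome_loss`` at
  bound-up genes in the knockdown,
* ATAC fragments as a mixture of short promoter NFR fragments (weight
  increased at bound-up genes in the knockdown) and mononucleosome-spanning
  fragments,
* a negative-binomial RNA-seq count matrix with planted log2 fold changes.

Every sampler is deterministic given its seed. Primary tags receive unique
UMI labels so that duplicate removal is exactly invertible, and clean tags
are shifted off exon/intron terminal bases so that the splicing-intermediate
filter recovers the planted intermediates exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .annotation import GeneModel, oriented_window
from .readproc import FragmentSet, splice_intermediate_sites

DE_CLASSES = ("up", "down", "unchanged")
CONDITIONS = ("control", "kd")


@dataclass
class TruthConfig:
    """Ground-truth configuration; defaults are the study conditions."""

    genes_per_class: int = 200
    class_counts: dict[str, int] | None = None  # keys "up:bound", ... override
    seed: int = 0
    chrom_name: str = "chrS"
    chrom_length: int | None = None  # None: auto-sized to fit the gene set

    # gene layout
    gene_length_range: tuple[int, int] = (2000, 6000)
    intergenic_gap_range: tuple[int, int] = (2600, 4000)
    exons_per_gene: tuple[int, int] = (2, 4)
    min_segment: int = 150

    # sequence composition
    gc_background: float = 0.42
    gc_promoter: float = 0.60
    promoter_gc_halfwidth: int = 250

    # expression / RNA-seq
    logfc_up: float = 2.0
    logfc_down: float = -2.0
    expr_mean: float = 150.0
    expr_sigma: float = 1.0
    dispersion: float = 0.05
    lib_factor_sigma: float = 0.1

    # NET-seq
    netseq_body_rate: float = 0.1  # tags/bp at the reference expression level
    body_noise_sigma: float = 0.3  # gene-level lognormal residual on the rate
    loglog_slope_bound: float = 1.2
    loglog_slope_unbound: float = 0.9
    pause_tags: float = 100.0
    pause_offset: int = 40
    pause_sd: float = 15.0
    antisense_rate: float = 0.02  # tags/bp in the 1-kb upstream window
    antisense_gain: float = 2.0  # applied at bound-up genes in the knockdown
    antisense_window: int = 1000
    splicing_intermediate_rate: float = 0.05  # per sense tag
    duplicate_rate: float = 0.1

    # MNase
    nucleosome_spacing: int = 180
    plus1_offset: int = 120
    n_down_nucleosomes: int = 4
    n_up_nucleosomes: int = 2
    dyad_fuzz: float = 20.0
    frags_per_dyad: float = 30.0
    mnase_len_mean: float = 147.0
    mnase_len_sd: float = 10.0
    mnase_len_range: tuple[int, int] = (120, 190)
    upstream_nucleosome_loss: float = 0.4  # bound-up genes in the knockdown
    tf_frags_per_gene: float = 5.0
    tf_len_range: tuple[int, int] = (30, 79)

    # ATAC
    atac_nfr_frags: float = 20.0
    atac_nfr_gain: float = 1.5  # bound-up genes in the knockdown
    atac_mono_frags: float = 20.0

    # planted pathologies
    spike_genes: int = 0  # snoRNA-like 50-bp occupancy spikes
    spike_tags: float = 3000.0
    spike_width: int = 50
    spike_offset: int = 600
    planted_upstream_violations: int = 0

    def __post_init__(self) -> None:
        for name in (
            "duplicate_rate",
            "splicing_intermediate_rate",
            "upstream_nucleosome_loss",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        if self.antisense_gain < 1.0:
            raise ValueError("antisense_gain must be >= 1")
        if any(n < 0 for n in self.counts().values()):
            raise ValueError("negative class count")

    def counts(self) -> dict[tuple[str, bool], int]:
        """Per (de_class, bound) gene counts; they sum to n_genes."""
        out = {
            (de, bound): self.genes_per_class
            for de in DE_CLASSES
            for bound in (True, False)
        }
        if self.class_counts:
            for key, n in self.class_counts.items():
                de, b = key.split(":")
                out[(de, b == "bound")] = int(n)
        return out

    @property
    def n_genes(self) -> int:
        # each planted violation adds a host gene and the violator itself
        return sum(self.counts().values()) + 2 * self.planted_upstream_violations

    def logfc(self, de_class: str) -> float:
        return {"up": self.logfc_up, "down": self.logfc_down, "unchanged": 0.0}[
            de_class
        ]


def _rng(seed: int | None, cfg: TruthConfig, stream: int) -> np.random.Generator:
    base = cfg.seed if seed is None else seed
    return np.random.default_rng(np.random.SeedSequence([int(base), stream]))


# ---------------------------------------------------------------------------
# genome + truth
# ---------------------------------------------------------------------------

def _make_exons(rng, lo: int, hi: int, cfg: TruthConfig) -> tuple[tuple[int, int], ...]:
    n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    n_seg = 2 * n_exons - 1
    total = hi - lo
    extra = total - n_seg * cfg.min_segment
    if extra < 0:
        n_exons, n_seg = 1, 1
        extra = total - cfg.min_segment
    parts = rng.multinomial(extra, np.full(n_seg, 1.0 / n_seg))
    lengths = parts + cfg.min_segment
    edges = lo + np.concatenate([[0], np.cumsum(lengths)])
    return tuple((int(edges[i]), int(edges[i + 1])) for i in range(0, n_seg, 2))


def simulate_genome(
    cfg: TruthConfig, seed: int | None = None
) -> tuple[dict[str, str], list[GeneModel], pd.DataFrame]:
    """Generate (genome sequence, gene models, truth table).

    The truth table has one row per gene: class label, bound flag, planted
    logFC, expression level, NET-seq body rate, per-condition antisense rates
    and upstream-nucleosome weights, spike/violation flags and dyad offsets.
    """
    rng = _rng(seed, cfg, 11)

    labels: list[tuple[str, bool]] = []
    for (de, bound), n in sorted(cfg.counts().items()):
        labels += [(de, bound)] * n
    rng.shuffle(labels)

    genes: list[GeneModel] = []
    rows: list[dict] = []
    cursor = 3000  # clearance at the chromosome start
    gi = 0

    def add_gene(de, bound, lo, hi, strand, *, spike=False, violation=False):
        nonlocal gi
        gid = f"g{gi:04d}"
        gi += 1
        tss, tes = (lo, hi) if strand == "+" else (hi, lo)
        exons = _make_exons(rng, lo, hi, cfg)
        genes.append(GeneModel(gid, cfg.chrom_name, strand, tss, tes, exons))
        expr = cfg.expr_mean * float(rng.lognormal(0.0, cfg.expr_sigma))
        slope = cfg.loglog_slope_bound if bound else cfg.loglog_slope_unbound
        factor = (expr / cfg.expr_mean) ** slope * float(
            rng.lognormal(0.0, cfg.body_noise_sigma)
        )
        body_rate = cfg.netseq_body_rate * min(factor, 20.0)
        gain = cfg.antisense_gain if (bound and de == "up") else 1.0
        loss = cfg.upstream_nucleosome_loss if (bound and de == "up") else 0.0
        down = [cfg.plus1_offset + k * cfg.nucleosome_spacing for k in range(cfg.n_down_nucleosomes)]
        up = [-cfg.nucleosome_spacing * (k + 1) for k in range(cfg.n_up_nucleosomes)]
        rows.append(
            dict(
                gene_id=gid,
                de_class=de,
                bound=bound,
                label=f"{de}:{'bound' if bound else 'unbound'}",
                logfc=cfg.logfc(de),
                expr_mean=expr,
                netseq_body_rate=body_rate,
                antisense_rate_control=cfg.antisense_rate,
                antisense_rate_kd=cfg.antisense_rate * gain,
                upstream_weight_control=1.0,
                upstream_weight_kd=1.0 - loss,
                nfr_weight_control=1.0,
                nfr_weight_kd=cfg.atac_nfr_gain if (bound and de == "up") else 1.0,
                dyad_offsets=";".join(map(str, down + up)),
                spike=spike,
                violation=violation,
            )
        )

    n_spikes_left = cfg.spike_genes
    for de, bound in labels:
        gap = int(rng.integers(*cfg.intergenic_gap_range))
        length = int(rng.integers(*cfg.gene_length_range))
        lo = cursor + gap
        hi = lo + length
        strand = "+" if rng.random() < 0.5 else "-"
        spike = False
        if n_spikes_left > 0 and de == "unchanged":
            spike, n_spikes_left = True, n_spikes_left - 1
        add_gene(de, bound, lo, hi, strand, spike=spike)
        cursor = hi

    # planted isolation violations: a dedicated + strand host gene followed
    # too closely by a + strand violator, so only the violator's upstream
    # window is dirty (the host's upstream side keeps normal clearance)
    for _ in range(cfg.planted_upstream_violations):
        gap = int(rng.integers(*cfg.intergenic_gap_range))
        length = int(rng.integers(*cfg.gene_length_range))
        lo = cursor + gap
        add_gene("unchanged", False, lo, lo + length, "+", violation=False)
        cursor = lo + length
        gap = int(rng.integers(200, 1000))
        length = int(rng.integers(*cfg.gene_length_range))
        lo = cursor + gap
        add_gene("unchanged", False, lo, lo + length, "+", violation=True)
        cursor = lo + length

    needed = cursor + 3000
    chrom_len = cfg.chrom_length or needed
    if chrom_len < needed:
        raise ValueError(
            f"chrom_length={chrom_len} too small for the gene set (needs {needed})"
        )

    base_probs = {
        "A": (1 - cfg.gc_background) / 2,
        "T": (1 - cfg.gc_background) / 2,
        "G": cfg.gc_background / 2,
        "C": cfg.gc_background / 2,
    }
    alphabet = np.frombuffer(b"ATGC", dtype=np.uint8)
    seq = rng.choice(alphabet, size=chrom_len, p=list(base_probs.values()))
    w = cfg.promoter_gc_halfwidth
    for g in genes:
        lo, hi = max(0, g.tss - w), min(chrom_len, g.tss + w)
        n = hi - lo
        p = cfg.gc_promoter
        seq[lo:hi] = rng.choice(
            alphabet, size=n, p=[(1 - p) / 2, (1 - p) / 2, p / 2, p / 2]
        )
    genome = {cfg.chrom_name: seq.tobytes().decode("ascii")}
    truth = pd.DataFrame(rows).set_index("gene_id", drop=False)
    return genome, genes, truth


# ---------------------------------------------------------------------------
# NET-seq
# ---------------------------------------------------------------------------

def simulate_netseq(
    genes: Iterable[GeneModel],
    truth: pd.DataFrame,
    condition: str,
    cfg: TruthConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """NET-seq tag table (chrom, pos, strand, umi, kind, gene_id).

    ``kind`` is simulator provenance: ``sense``/``antisense``/``spike`` are
    the clean planted tags, ``si`` are splicing intermediates, ``dup`` are PCR
    duplicates (copies of primary tags with the same UMI).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    rng = _rng(seed, cfg, 23 if condition == "control" else 29)
    truth_rows = truth.to_dict("index")

    chroms, poss, strands, kinds, gids = [], [], [], [], []

    def emit(gene, pos, strand, kind):
        n = len(pos)
        if n == 0:
            return
        chroms.append(np.full(n, gene.chrom, dtype=object))
        poss.append(pos.astype(np.int64))
        strands.append(np.full(n, strand, dtype=object))
        kinds.append(np.full(n, kind, dtype=object))
        gids.append(np.full(n, gene.gene_id, dtype=object))

    for gene in genes:
        row = truth_rows[gene.gene_id]
        anti_strand = "-" if gene.strand == "+" else "+"
        lo, hi = gene.span
        step = 1 if gene.strand == "+" else -1

        # genes have >= 2.5 kb clearance, so the only splicing-intermediate
        # sites a gene's own tags can hit are its own exon/intron last bases
        intervals = list(gene.exons) + list(gene.introns)
        own_sites = np.array(
            sorted((b - 1 if gene.strand == "+" else a) for a, b in intervals),
            dtype=np.int64,
        )

        def clean(pos: np.ndarray) -> np.ndarray:
            # shift clean tags off splicing-intermediate sites (downstream in
            # transcription direction; sites are isolated single bases)
            for _ in range(4):
                hit = np.zeros(len(pos), dtype=bool)
                for s in own_sites:
                    hit |= pos == s
                if not hit.any():
                    break
                pos = pos + np.where(hit, step, 0)
            return pos

        n_body = rng.poisson(row["netseq_body_rate"] * (hi - lo))
        body = clean(rng.integers(lo, hi, size=n_body))
        emit(gene, body, gene.strand, "sense")

        n_pause = rng.poisson(cfg.pause_tags)
        offs = np.clip(
            np.rint(rng.normal(cfg.pause_offset, cfg.pause_sd, size=n_pause)), 0, 249
        ).astype(np.int64)
        pause = gene.tss + offs if gene.strand == "+" else gene.tss - 1 - offs
        emit(gene, clean(pause), gene.strand, "sense")

        rate = row[f"antisense_rate_{condition}"]
        a, b = oriented_window(gene.tss, gene.strand, -cfg.antisense_window, 0)
        n_anti = rng.poisson(rate * (b - a))
        emit(gene, rng.integers(a, b, size=n_anti), anti_strand, "antisense")

        if bool(row["spike"]):
            n_spk = rng.poisson(cfg.spike_tags)
            so = cfg.spike_offset + rng.integers(0, cfg.spike_width, size=n_spk)
            spk = gene.tss + so if gene.strand == "+" else gene.tss - 1 - so
            emit(gene, clean(spk), gene.strand, "spike")

        if cfg.splicing_intermediate_rate > 0 and len(own_sites):
            n_si = rng.poisson(cfg.splicing_intermediate_rate * (n_body + n_pause))
            if n_si:
                emit(gene, rng.choice(own_sites, size=n_si), gene.strand, "si")

    if not chroms:
        tags = pd.DataFrame(
            columns=["chrom", "pos", "strand", "umi", "kind", "gene_id"]
        )
        return tags
    tags = pd.DataFrame(
        {
            "chrom": pd.Categorical(np.concatenate(chroms)),
            "pos": np.concatenate(poss),
            "strand": pd.Categorical(np.concatenate(strands), categories=["+", "-"]),
            "kind": pd.Categorical(np.concatenate(kinds)),
            "gene_id": pd.Categorical(np.concatenate(gids)),
        }
    )
    # unique integer UMI labels (opaque; exported as strings by the writers)
    tags["umi"] = np.arange(len(tags), dtype=np.int64)

    n_dup = rng.binomial(len(tags), cfg.duplicate_rate) if len(tags) else 0
    if n_dup:
        dup = tags.iloc[rng.integers(0, len(tags), size=n_dup)].copy()
        dup["kind"] = "dup"
        tags = pd.concat([tags, dup], ignore_index=True)
    return tags[["chrom", "pos", "strand", "umi", "kind", "gene_id"]]


# ---------------------------------------------------------------------------
# MNase / ATAC fragments
# ---------------------------------------------------------------------------

class _FragAccumulator:
    """Accumulates per-gene fragment arrays; one DataFrame at the end."""

    def __init__(self) -> None:
        self.chroms: list[np.ndarray] = []
        self.starts: list[np.ndarray] = []
        self.lengths: list[np.ndarray] = []
        self.kinds: list[np.ndarray] = []

    def add(self, chrom: str, mids: np.ndarray, lengths: np.ndarray, kind: str) -> None:
        n = len(mids)
        if n == 0:
            return
        self.chroms.append(np.full(n, chrom, dtype=object))
        self.starts.append(mids - lengths // 2)
        self.lengths.append(lengths.astype(np.int64))
        self.kinds.append(np.full(n, kind, dtype=object))

    def add_gaussian_lengths(self, rng, chrom, mids, mean, sd, lo, hi, kind) -> None:
        lengths = np.clip(np.rint(rng.normal(mean, sd, size=len(mids))), lo, hi)
        self.add(chrom, mids, lengths.astype(np.int64), kind)

    def frame(self) -> pd.DataFrame:
        if not self.chroms:
            return pd.DataFrame(columns=["chrom", "start", "end", "length", "kind"])
        starts = np.concatenate(self.starts)
        lengths = np.concatenate(self.lengths)
        return pd.DataFrame(
            {
                "chrom": np.concatenate(self.chroms),
                "start": starts,
                "end": starts + lengths,
                "length": lengths,
                "kind": np.concatenate(self.kinds),
            }
        )


def simulate_fragments(
    genes: Iterable[GeneModel],
    truth: pd.DataFrame,
    condition: str,
    assay: str,
    cfg: TruthConfig,
    seed: int | None = None,
) -> FragmentSet:
    """Paired-end fragments for one assay/condition (see module docstring)."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if assay not in ("mnase", "atac"):
        raise ValueError(f"unknown assay {assay!r}")
    stream = {"mnase": 41, "atac": 43}[assay] + (0 if condition == "control" else 2)
    rng = _rng(seed, cfg, stream)
    truth_rows = truth.to_dict("index")
    acc = _FragAccumulator()

    for gene in genes:
        row = truth_rows[gene.gene_id]
        sign = 1 if gene.strand == "+" else -1
        origin = gene.tss if gene.strand == "+" else gene.tss - 1

        if assay == "mnase":
            weight_up = row[f"upstream_weight_{condition}"]
            for off in map(int, row["dyad_offsets"].split(";")):
                w = weight_up if off < 0 else 1.0
                n = rng.poisson(cfg.frags_per_dyad * w)
                mids = origin + sign * off + np.rint(
                    rng.normal(0.0, cfg.dyad_fuzz, size=n)
                ).astype(np.int64)
                acc.add_gaussian_lengths(
                    rng,
                    gene.chrom,
                    mids,
                    cfg.mnase_len_mean,
                    cfg.mnase_len_sd,
                    *cfg.mnase_len_range,
                    "upstream_nuc" if off < 0 else "body_nuc",
                )
            n_tf = rng.poisson(cfg.tf_frags_per_gene)
            mids = origin + rng.integers(-50, 51, size=n_tf)
            lengths = rng.integers(
                cfg.tf_len_range[0], cfg.tf_len_range[1] + 1, size=n_tf
            )
            acc.add(gene.chrom, mids, lengths, "tf")
        else:  # atac
            n_nfr = rng.poisson(cfg.atac_nfr_frags * row[f"nfr_weight_{condition}"])
            mids = origin + sign * rng.integers(-100, 50, size=n_nfr)
            lengths = np.clip(
                np.rint(rng.normal(60.0, 15.0, size=n_nfr)), 30, 99
            ).astype(np.int64)
            acc.add(gene.chrom, mids, lengths, "nfr")
            n_mono = rng.poisson(cfg.atac_mono_frags)
            mids = origin + sign * cfg.plus1_offset + np.rint(
                rng.normal(0.0, 30.0, size=n_mono)
            ).astype(np.int64)
            acc.add_gaussian_lengths(
                rng, gene.chrom, mids, 195.0, 20.0, 150, 250, "mono"
            )

    return FragmentSet(acc.frame(), assay=assay, condition=condition)


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------

def simulate_counts(
    genes: Iterable[GeneModel],
    truth: pd.DataFrame,
    n_reps_per_condition: int = 4,
    cfg: TruthConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Negative-binomial count matrix, genes x (control_*, kd_*) samples."""
    cfg = cfg or TruthConfig()
    if n_reps_per_condition < 2:
        raise ValueError("need >= 2 replicates per condition")
    rng = _rng(seed, cfg, 57)
    gene_ids = [g.gene_id for g in genes]
    mu_ctrl = truth.loc[gene_ids, "expr_mean"].to_numpy()
    mu_kd = mu_ctrl * 2.0 ** truth.loc[gene_ids, "logfc"].to_numpy()
    r = 1.0 / cfg.dispersion
    cols = {}
    for cond, mu in (("control", mu_ctrl), ("kd", mu_kd)):
        for rep in range(1, n_reps_per_condition + 1):
            lib = float(rng.lognormal(0.0, cfg.lib_factor_sigma))
            m = mu * lib
            cols[f"{cond}_{rep}"] = rng.negative_binomial(r, r / (r + m))
    return pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))


# ---------------------------------------------------------------------------
# writers / config round-trip
# ---------------------------------------------------------------------------

def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")


def config_from_mapping(data: Mapping) -> TruthConfig:
    """Build a TruthConfig from a flat mapping (YAML/TOML), coercing lists."""
    kwargs = dict(data)
    for key in (
        "gene_length_range",
        "intergenic_gap_range",
        "exons_per_gene",
        "mnase_len_range",
        "tf_len_range",
    ):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    return TruthConfig(**kwargs)


def config_to_mapping(cfg: TruthConfig) -> dict:
    out = asdict(cfg)
    for key, val in out.items():
        if isinstance(val, tuple):
            out[key] = list(val)
    return out
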