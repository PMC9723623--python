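"""Miniature three-phenotype regulatory-landscape simulator with planted
ground truth.

The generator emulates the structure of a brain multiome across three
phenotypes (queen/worker/drone analogues, "Q"/"W"/"D") x 2 replicates:

* ATAC fragments with a tri-modal length mixture (nucleosome-free,
  mono-nucleosome, di-nucleosome) and NFR-class fragments concentrated on
  planted nucleosome-free regions;
* a well-positioned mono-nucleosome downstream of every TSS;
* Tn5 cut depletion across bound planted motif sites (footprints);
* four histone-mark peak sets per phenotype with replicate jitter and
  one-replicate-only false peaks;
* negative-binomial expression counts in which NFR-containing genes are
  up-shifted.

Everything planted is recorded in a :class:`TruthManifest` so downstream
stages can be scored against known truth. All stages are deterministic under
a fixed seed; per-stage substreams are derived from the root seed by name so
skipping one stage does not shift another's draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from regland.chromatin_states import MARKS
from regland.genome_io import (
    FragmentRecord,
    GenomeAnnotation,
    Interval,
    Motif,
    Peak,
    Transcript,
    write_fasta,
)

PHENOTYPES = ("Q", "W", "D")

# gene template (transcription order): exon/intron lengths in bp
_EXON_LENS = (250, 400, 350)
_INTRON_LENS = (900, 900)
_UTR5_LEN = 150
_UTR3_LEN = 200
_GENE_LEN = sum(_EXON_LENS) + sum(_INTRON_LENS)
_MARGIN = 2500  # free bp kept at chromosome edges
_MIN_GAP, _MAX_GAP = 3000, 6000
_STATE_FLANK = 300  # planted state = NFR extended this much on each side

# mark-subset frequencies by NFR location class
_STATE_CHOICES = {
    "tss": (
        (frozenset({"H3K4me3", "H3K27ac"}), 0.6),
        (frozenset({"H3K4me3"}), 0.1),
        (frozenset({"H3K27ac"}), 0.2),
        (frozenset(), 0.1),
    ),
    "intron": (
        (frozenset({"H3K27ac"}), 0.36),
        (frozenset({"H3K4me1", "H3K27ac"}), 0.18),
        (frozenset({"H3K27me3"}), 0.135),
        (frozenset({"H3K4me1"}), 0.135),
        (frozenset({"H3K4me1", "H3K27me3"}), 0.09),
        (frozenset(), 0.1),
    ),
    "intergenic": (
        (frozenset({"H3K27me3"}), 0.54),
        (frozenset({"H3K4me1"}), 0.18),
        (frozenset({"H3K27ac"}), 0.18),
        (frozenset(), 0.1),
    ),
}


def substream(seed: int, *names: str) -> np.random.Generator:
    """Named, order-independent random substream derived from a root seed."""
    keys = [zlib.crc32(n.encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *keys]))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic dataset.

    The fragment-length mixture (Normal(55,18) truncated positive,
    Normal(200,25), Normal(400,35); weights 0.5/0.35/0.15) reproduces the
    tri-modal ATAC size distribution with its nucleosomal periodicity.
    """

    genome_size: int = 2_000_000
    n_chromosomes: int = 4
    n_genes: int = 200
    n_motifs: int = 12
    motif_length: int = 10
    fragments_per_replicate: int = 400_000
    mixture_weights: tuple[float, float, float] = (0.5, 0.35, 0.15)
    mixture_means: tuple[float, float, float] = (55.0, 200.0, 400.0)
    mixture_sds: tuple[float, float, float] = (18.0, 25.0, 35.0)
    replicates: int = 2
    phenotypes: tuple[str, ...] = PHENOTYPES
    n_nfrs: int = 240
    nfr_width: int = 300
    frac_nfr_tss: float = 0.35
    intron_frac_of_non_tss: float = 0.64
    frac_shared: float = 0.8  # NFRs active in all phenotypes
    nfr_rate_ratio: float = 10.0  # NFR-class coverage enrichment on planted NFRs
    footprint_depletion: float = 0.25  # cut-rate factor over bound motif cores
    mono_phasing_offset: int = 250  # nucleosome center downstream of TSS
    mono_phased_fraction: float = 0.5
    chip_jitter: int = 50
    chip_false_rate: float = 0.1
    expression_effect: float = 1.0  # log2 shift for NFR-containing genes
    expression_dispersion: float = 0.1
    expression_base_mean: float = 150.0

    def __post_init__(self) -> None:
        if abs(sum(self.mixture_weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if not (self.mixture_means[0] < self.mixture_means[1] < self.mixture_means[2]):
            raise ValueError("mixture component means must be ordered NFR < mono < di")
        if self.genome_size <= 0 or self.n_chromosomes <= 0:
            raise ValueError("genome_size and n_chromosomes must be positive")

    def noiseless(self) -> "SimConfig":
        """The dial-to-zero configuration: no jitter, no false peaks, full
        footprint protection, all NFR-class fragments on planted NFRs."""
        return replace(
            self,
            chip_jitter=0,
            chip_false_rate=0.0,
            footprint_depletion=0.0,
            nfr_rate_ratio=float("inf"),
        )


@dataclass(frozen=True)
class PlantedSite:
    motif_id: str
    interval: Interval
    bound_in: frozenset[str]  # phenotypes in which the site is bound


@dataclass
class TruthManifest:
    """Everything the generator planted, for downstream scoring."""

    nfrs: list[tuple[Interval, frozenset[str]]]
    states: list[tuple[Interval, frozenset[str]]]
    sites: list[PlantedSite]
    edges: list[tuple[str, str, str, frozenset[str]]]  # source, target, class, phenotypes
    tf_gene_map: dict[str, str]
    expression_effect: float
    seed: int

    def nfrs_active_in(self, phenotype: str) -> list[Interval]:
        return [iv for iv, ph in self.nfrs if phenotype in ph]

    def bound_sites_in(self, phenotype: str) -> list[PlantedSite]:
        return [s for s in self.sites if phenotype in s.bound_in]


@dataclass
class SyntheticDataset:
    config: SimConfig
    seed: int
    sequences: dict[str, str]
    annotation: GenomeAnnotation
    motifs: list[Motif]
    manifest: TruthManifest


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------


def generate_genome(config: SimConfig, seed: int) -> SyntheticDataset:
    """Build the synthetic genome, gene annotation, motif set and manifest.

    Deterministic for a fixed (config, seed). At least 60% of non-TSS NFRs
    are placed in introns, mirroring the predominantly intronic location of
    accessible regions in this kind of data.
    """
    rng = substream(seed, "genome")
    sizes = _chrom_sizes(config)

    # gene capacity check
    per_chrom = _split_counts(config.n_genes, config.n_chromosomes)
    for (chrom, size), n_c in zip(sizes.items(), per_chrom):
        needed = 2 * _MARGIN + n_c * (_GENE_LEN + _MIN_GAP)
        if needed > size:
            raise ValueError(
                f"genome too small: chromosome {chrom} ({size} bp) needs >= "
                f"{needed} bp for {n_c} genes"
            )

    seqs = {c: _random_sequence(rng, n) for c, n in sizes.items()}
    genes, transcripts, utr5, utr3 = _place_genes(config, rng, sizes, per_chrom)
    annotation = GenomeAnnotation(
        genes=genes,
        transcripts=transcripts,
        chrom_sizes=dict(sizes),
        utr5=utr5,
        utr3=utr3,
    )

    nfrs, nfr_class = _place_nfrs(config, rng, annotation)
    states = _assign_states(config, rng, nfrs, nfr_class)
    motifs = _make_motifs(config, rng)
    sites = _plant_sites(config, rng, seqs, nfrs, motifs)
    tf_gene_map = _make_tf_gene_map(config, rng, annotation, motifs)
    edges = planted_edges(sites, annotation, tf_gene_map)

    manifest = TruthManifest(
        nfrs=nfrs,
        states=states,
        sites=sites,
        edges=edges,
        tf_gene_map=tf_gene_map,
        expression_effect=config.expression_effect,
        seed=seed,
    )
    _check_manifest(manifest, sizes)
    return SyntheticDataset(config, seed, seqs, annotation, motifs, manifest)


def _chrom_sizes(config: SimConfig) -> dict[str, int]:
    base = config.genome_size // config.n_chromosomes
    sizes = {}
    for i in range(config.n_chromosomes):
        extra = config.genome_size - base * config.n_chromosomes if i == config.n_chromosomes - 1 else 0
        sizes[f"chr{i + 1}"] = base + extra
    return sizes


def _split_counts(total: int, parts: int) -> list[int]:
    q, r = divmod(total, parts)
    return [q + (1 if i < r else 0) for i in range(parts)]


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def _place_genes(config, rng, sizes, per_chrom):
    genes: dict[str, Interval] = {}
    transcripts: dict[str, Transcript] = {}
    utr5: dict[str, tuple[Interval, ...]] = {}
    utr3: dict[str, tuple[Interval, ...]] = {}
    gi = 0
    for (chrom, size), n_c in zip(sizes.items(), per_chrom):
        pos = _MARGIN
        for _ in range(n_c):
            start = pos
            end = start + _GENE_LEN
            if end + _MARGIN > size:
                raise ValueError(f"genome too small on {chrom}: gene would end at {end}")
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"gene{gi:04d}"
            tid = f"{gid}.t1"
            genes[gid] = Interval(chrom, start, end, strand)

            lens = _EXON_LENS if strand == "+" else tuple(reversed(_EXON_LENS))
            exons = []
            p = start
            for j, el in enumerate(lens):
                exons.append(Interval(chrom, p, p + el, strand))
                p += el
                if j < len(_INTRON_LENS):
                    p += _INTRON_LENS[j]
            transcripts[tid] = Transcript(tid, gid, genes[gid], tuple(exons))
            if strand == "+":
                utr5[tid] = (Interval(chrom, start, start + _UTR5_LEN, strand),)
                utr3[tid] = (Interval(chrom, end - _UTR3_LEN, end, strand),)
            else:
                utr5[tid] = (Interval(chrom, end - _UTR5_LEN, end, strand),)
                utr3[tid] = (Interval(chrom, start, start + _UTR3_LEN, strand),)
            gi += 1
            pos = end + int(rng.integers(_MIN_GAP, _MAX_GAP + 1))
    return genes, transcripts, utr5, utr3


def _place_nfrs(config, rng, annotation):
    """Plant NFRs at TSSs, in first introns (transcription order) and in
    intergenic space; returns (list of (Interval, phenotype set), class list)."""
    gene_ids = sorted(annotation.genes)
    if gene_ids:
        n_tss = round(config.n_nfrs * config.frac_nfr_tss)
        n_non = config.n_nfrs - n_tss
        n_intron = round(n_non * config.intron_frac_of_non_tss)
    else:
        n_tss = n_intron = 0  # no genes: everything is intergenic
    n_inter = config.n_nfrs - n_tss - n_intron
    w = config.nfr_width

    if n_tss + n_intron > len(gene_ids):
        raise ValueError(
            f"genome too small: {n_tss + n_intron} host genes needed, "
            f"{len(gene_ids)} available (raise n_genes or lower n_nfrs)"
        )
    order = list(rng.permutation(gene_ids))
    tss_hosts = order[:n_tss]
    intron_hosts = order[n_tss : n_tss + n_intron]

    intervals: list[Interval] = []
    classes: list[str] = []
    for gid in tss_hosts:
        g = annotation.genes[gid]
        tss = annotation.tss(gid)
        intervals.append(Interval(g.chrom, tss - w // 2, tss - w // 2 + w))
        classes.append("tss")
    for gid in intron_hosts:
        g = annotation.genes[gid]
        tid = f"{gid}.t1"
        introns = annotation.transcripts[tid].introns
        intron = introns[0] if g.strand == "+" else introns[-1]
        lo = intron.start + 100
        hi = intron.end - 100 - w
        start = int(rng.integers(lo, hi + 1))
        intervals.append(Interval(g.chrom, start, start + w))
        classes.append("intron")

    # intergenic: away from every gene span +- 2.7 kb and from each other
    buffered: dict[str, list[tuple[int, int]]] = {c: [] for c in annotation.chrom_sizes}
    for g in annotation.genes.values():
        buffered[g.chrom].append((g.start - 2700, g.end + 2700))
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in annotation.chrom_sizes}
    chroms = sorted(annotation.chrom_sizes)
    sizes_arr = np.array([annotation.chrom_sizes[c] for c in chroms], dtype=float)
    for _ in range(n_inter):
        for _try in range(2000):
            c = chroms[int(rng.choice(len(chroms), p=sizes_arr / sizes_arr.sum()))]
            start = int(rng.integers(_MARGIN, annotation.chrom_sizes[c] - _MARGIN - w))
            span = (start - _STATE_FLANK - 100, start + w + _STATE_FLANK + 100)
            if any(s < span[1] and span[0] < e for s, e in buffered[c]):
                continue
            if any(s - 1000 < span[1] and span[0] < e + 1000 for s, e in placed[c]):
                continue
            placed[c].append((start, start + w))
            intervals.append(Interval(c, start, start + w))
            classes.append("intergenic")
            break
        else:
            raise ValueError("could not place intergenic NFR; genome too crowded")

    # phenotype activity: frac_shared active everywhere, rest cycled per phenotype
    n = len(intervals)
    idx = rng.permutation(n)
    n_shared = int(np.ceil(config.frac_shared * n))
    pheno_sets: list[frozenset[str]] = [frozenset()] * n
    for rank, i in enumerate(idx):
        if rank < n_shared:
            pheno_sets[i] = frozenset(config.phenotypes)
        else:
            pheno_sets[i] = frozenset({config.phenotypes[(rank - n_shared) % len(config.phenotypes)]})
    return list(zip(intervals, pheno_sets)), classes


def _assign_states(config, rng, nfrs, nfr_class):
    states: list[tuple[Interval, frozenset[str]]] = []
    for (iv, _ph), cls in zip(nfrs, nfr_class):
        choices = _STATE_CHOICES[cls]
        probs = np.array([p for _, p in choices])
        marks = choices[int(rng.choice(len(choices), p=probs / probs.sum()))][0]
        if not marks:
            continue
        states.append(
            (Interval(iv.chrom, iv.start - _STATE_FLANK, iv.end + _STATE_FLANK), marks)
        )
    return states


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _self_rc_overlap(cons: str, max_shift: int = 6) -> bool:
    """True when the consensus exactly matches its reverse complement under
    some small alignment shift (a near-palindrome). Such motifs produce
    ambiguous overlapping self-hits when their reverse strand is planted."""
    L = len(cons)
    rc = reverse_complement(cons)
    for s in range(-max_shift, max_shift + 1):
        span = range(max(0, s), min(L, L + s))
        if span and all(cons[i] == rc[i - s] for i in span):
            return True
    return False


def _make_motifs(config, rng) -> list[Motif]:
    """Sharply informative synthetic PFMs with pairwise-distinct consensi
    (also distinct under reverse complement, and free of near-palindromes)."""
    motifs: list[Motif] = []
    seen: set[str] = set()
    i = 0
    while len(motifs) < config.n_motifs:
        cons = "".join(np.array(list("ACGT"))[rng.integers(0, 4, config.motif_length)])
        if cons in seen or reverse_complement(cons) in seen or _self_rc_overlap(cons):
            continue
        seen.add(cons)
        pfm = np.ones((4, config.motif_length))
        for j, b in enumerate(cons):
            pfm["ACGT".index(b), j] = 97.0
        motifs.append(Motif(f"SYN{i + 1:04d}", f"synTF{i + 1:02d}", pfm))
        i += 1
    return motifs


def _plant_sites(config, rng, seqs, nfrs, motifs) -> list[PlantedSite]:
    """Write motif consensus sequences into shared NFRs and assign bound
    phenotypes per site.

    Motif roles: the first motif is the top-occupancy motif (bound
    everywhere with high probability); the last two are phenotype-specific
    (bound only in the first / second phenotype); the rest span a ladder of
    intermediate occupancies.
    """
    L = config.motif_length
    shared = [iv for iv, ph in nfrs if ph == frozenset(config.phenotypes)]
    slots = [(iv, off) for iv in shared for off in (70, 200)]
    order = rng.permutation(len(slots))

    n_m = config.n_motifs
    occ = np.empty(n_m)
    occ[0] = 0.95
    if n_m > 3:
        occ[1 : n_m - 2] = np.linspace(0.25, 0.55, n_m - 3)
    occ[n_m - 2 :] = 0.7  # phenotype-specific motifs
    specific = {n_m - 2: config.phenotypes[0], n_m - 1: config.phenotypes[1]}

    mutable = {c: list(s) for c, s in seqs.items()}
    sites: list[PlantedSite] = []
    for rank, slot_i in enumerate(order):
        iv, off = slots[slot_i]
        m_i = rank % n_m
        motif = motifs[m_i]
        strand = "+" if rng.random() < 0.5 else "-"
        seq = motif.consensus if strand == "+" else reverse_complement(motif.consensus)
        start = iv.start + off
        mutable[iv.chrom][start : start + L] = list(seq)
        if m_i in specific:
            bound = frozenset({specific[m_i]}) if rng.random() < occ[m_i] else frozenset()
        else:
            bound = frozenset(config.phenotypes) if rng.random() < occ[m_i] else frozenset()
        sites.append(
            PlantedSite(motif.id, Interval(iv.chrom, start, start + L, strand), bound)
        )
    for c in seqs:
        seqs[c] = "".join(mutable[c])
    sites.sort(key=lambda s: (s.interval.chrom, s.interval.start, s.motif_id))
    return sites


def _make_tf_gene_map(config, rng, annotation, motifs) -> dict[str, str]:
    gene_ids = sorted(annotation.genes)
    if not gene_ids:
        return {}
    chosen = list(rng.choice(gene_ids, size=min(config.n_motifs, len(gene_ids)), replace=False))
    return {m.id: g for m, g in zip(motifs, chosen)}


def planted_edges(
    sites: list[PlantedSite],
    annotation: GenomeAnnotation,
    tf_gene_map: dict[str, str],
    tss_window: tuple[int, int] = (-2000, 200),
) -> list[tuple[str, str, str, frozenset[str]]]:
    """Ground-truth TF->TF edges by a brute-force (site x gene) double loop.

    A bound site of motif A inside gene B's span or its strand-oriented TSS
    window yields edge A->B; class tss when all supporting sites fall in the
    window, non_tss when all fall elsewhere in the gene, both otherwise.
    """
    gene_to_tf = {g: m for m, g in tf_gene_map.items()}
    support: dict[tuple[str, str], dict[str, set]] = {}
    for site in sites:
        if not site.bound_in:
            continue
        mid = site.interval.midpoint
        for gid, g in annotation.genes.items():
            tf = gene_to_tf.get(gid)
            if tf is None or g.chrom != site.interval.chrom:
                continue
            tss = annotation.tss(gid)
            lo, hi = tss_window
            if g.strand == "-":
                w_start, w_end = tss - hi, tss - lo + 1
            else:
                w_start, w_end = tss + lo, tss + hi + 1
            in_window = w_start <= mid < w_end
            in_gene = g.start <= mid < g.end
            if not (in_window or in_gene):
                continue
            d = support.setdefault((site.motif_id, tf), {"cls": set(), "ph": set()})
            d["cls"].add("tss" if in_window else "non_tss")
            d["ph"].update(site.bound_in)
    edges = []
    for (src, tgt), d in sorted(support.items()):
        cls = "both" if len(d["cls"]) == 2 else next(iter(d["cls"]))
        edges.append((src, tgt, cls, frozenset(d["ph"])))
    return edges


def _check_manifest(manifest: TruthManifest, sizes: dict[str, int]) -> None:
    nfr_spans = [(iv.chrom, iv.start, iv.end) for iv, _ in manifest.nfrs]
    for iv, _ in manifest.nfrs + manifest.states:
        if iv.start < 0 or iv.end > sizes[iv.chrom]:
            raise AssertionError(f"planted interval {iv} outside genome")
    for s in manifest.sites:
        if s.bound_in and not any(
            c == s.interval.chrom and st <= s.interval.start and s.interval.end <= en
            for c, st, en in nfr_spans
        ):
            raise AssertionError(f"bound site {s} outside every planted NFR")


# ---------------------------------------------------------------------------
# Fragment simulation
# ---------------------------------------------------------------------------


def simulate_fragments(
    ds: SyntheticDataset,
    phenotype: str,
    replicate: int,
    seed: int | None = None,
    n_fragments: int | None = None,
) -> list[FragmentRecord]:
    """Draw one replicate's ATAC fragments for a phenotype.

    Lengths follow the configured tri-modal mixture. NFR-class fragments are
    concentrated on planted NFRs active in the phenotype at the configured
    coverage rate ratio; mono-class fragments are partially phased downstream
    of TSSs; cut sites over bound motif cores are depleted by rejection
    sampling at the configured depletion factor.
    """
    cfg = ds.config
    if phenotype not in cfg.phenotypes:
        raise ValueError(f"unknown phenotype {phenotype!r}; have {cfg.phenotypes}")
    rng = substream(seed if seed is not None else ds.seed, "fragments", phenotype, f"rep{replicate}")
    n = n_fragments if n_fragments is not None else cfg.fragments_per_replicate

    chroms = sorted(ds.sequences)
    sizes = np.array([len(ds.sequences[c]) for c in chroms], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    total = int(offsets[-1])
    chrom_index = {c: i for i, c in enumerate(chroms)}

    comp = rng.choice(3, size=n, p=np.asarray(cfg.mixture_weights))
    means = np.asarray(cfg.mixture_means)[comp]
    sds = np.asarray(cfg.mixture_sds)[comp]
    lengths = np.maximum(np.rint(np.abs(rng.normal(means, sds))), 1).astype(np.int64)

    starts = np.empty(n, dtype=np.int64)

    def uniform_start(sel: np.ndarray) -> None:
        k = int(sel.sum())
        ci = rng.choice(len(chroms), size=k, p=sizes / sizes.sum())
        span = np.maximum(sizes[ci] - lengths[sel], 1)
        starts[sel] = offsets[ci] + (rng.random(k) * span).astype(np.int64)

    # --- NFR-class placement -------------------------------------------------
    active = ds.manifest.nfrs_active_in(phenotype)
    is_nfr = comp == 0
    if active:
        nfr_lo = np.array([offsets[chrom_index[iv.chrom]] + iv.start for iv in active])
        nfr_hi = np.array([offsets[chrom_index[iv.chrom]] + iv.end for iv in active])
        widths = (nfr_hi - nfr_lo).astype(float)
        nfr_bp = float(widths.sum())
        R = cfg.nfr_rate_ratio
        if np.isinf(R):
            f_on = 1.0
        else:
            f_on = R * nfr_bp / (R * nfr_bp + (total - nfr_bp))
        on_nfr = is_nfr & (rng.random(n) < f_on)
        k = int(on_nfr.sum())
        which = rng.choice(len(active), size=k, p=widths / widths.sum())

        def sample_in_nfr(which_idx: np.ndarray, lens: np.ndarray) -> np.ndarray:
            lo = nfr_lo[which_idx]
            hi = nfr_hi[which_idx]
            span = hi - lo - lens
            u = rng.random(len(which_idx))
            s = np.where(span > 0, lo + (u * np.maximum(span, 1)).astype(np.int64),
                         (lo + hi) // 2 - lens // 2)
            return np.maximum(s, 0)

        starts[on_nfr] = sample_in_nfr(which, lengths[on_nfr])
        uniform_start(is_nfr & ~on_nfr)
    else:
        on_nfr = np.zeros(n, dtype=bool)
        which = np.empty(0, dtype=np.int64)
        uniform_start(is_nfr)

    # --- mono-class: partially phased downstream of TSSs ---------------------
    is_mono = comp == 1
    tss_list = ds.annotation.tss_positions()
    if tss_list:
        phased = is_mono & (rng.random(n) < cfg.mono_phased_fraction)
        k = int(phased.sum())
        gi = rng.integers(0, len(tss_list), size=k)
        centers = np.empty(k, dtype=np.int64)
        for j, g_idx in enumerate(gi):
            _gid, chrom, tss, strand = tss_list[g_idx]
            direction = 1 if strand == "+" else -1
            centers[j] = offsets[chrom_index[chrom]] + tss + direction * cfg.mono_phasing_offset
        centers = centers + rng.normal(0, 30, size=k).astype(np.int64)
        starts[phased] = centers - lengths[phased] // 2
        uniform_start(is_mono & ~phased)
    else:
        uniform_start(is_mono)

    uniform_start(comp == 2)

    # --- footprint depletion over bound motif cores ---------------------------
    bound = ds.manifest.bound_sites_in(phenotype)
    if bound and int(on_nfr.sum()):
        core_mask = np.zeros(total, dtype=bool)
        for s in bound:
            o = offsets[chrom_index[s.interval.chrom]]
            core_mask[o + s.interval.start : o + s.interval.end] = True
        sel = np.nonzero(on_nfr)[0]
        sel_which = which.copy()
        for _ in range(60):
            c1 = np.clip(starts[sel] + 4, 0, total - 1)
            c2 = np.clip(starts[sel] + lengths[sel] - 6, 0, total - 1)
            bad = core_mask[c1] | core_mask[c2]
            if cfg.footprint_depletion > 0:
                bad &= rng.random(len(sel)) >= cfg.footprint_depletion
            if not bad.any():
                break
            redo = bad
            starts_redo = sample_in_nfr(sel_which[redo], lengths[sel[redo]])
            starts[sel[redo]] = starts_redo
            sel = sel[redo]
            sel_which = sel_which[redo]

    # clip to chromosome bounds in virtual coordinates
    ci = np.searchsorted(offsets, starts, side="right") - 1
    ci = np.clip(ci, 0, len(chroms) - 1)
    lo_b = offsets[ci]
    hi_b = offsets[ci + 1]
    starts = np.clip(starts, lo_b, hi_b - lengths - 1)
    starts = np.maximum(starts, lo_b)
    ends = np.minimum(starts + lengths, hi_b)

    frags = [
        FragmentRecord(chroms[c], int(s - offsets[c]), int(e - offsets[c]))
        for c, s, e in zip(ci.tolist(), starts.tolist(), ends.tolist())
    ]
    frags.sort(key=lambda f: (f.chrom, f.start, f.end))
    return frags


def write_fragments(frags: list[FragmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in frags:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\n")


# ---------------------------------------------------------------------------
# ChIP peak and expression simulation
# ---------------------------------------------------------------------------


def simulate_chip_peaks(
    ds: SyntheticDataset, mark: str, phenotype: str, seed: int | None = None
) -> tuple[list[Peak], list[Peak]]:
    """Two replicate peak sets for one histone mark and phenotype.

    Every planted state interval carrying the mark emits a peak in both
    replicates with boundary jitter <= chip_jitter bp; false peaks (rate
    chip_false_rate per true peak) appear in exactly one replicate.
    """
    if mark not in MARKS:
        raise ValueError(f"unknown mark {mark!r}; expected one of {MARKS}")
    cfg = ds.config
    rng = substream(seed if seed is not None else ds.seed, "chip", mark, phenotype)
    true_ivs = [iv for iv, marks in ds.manifest.states if mark in marks]
    sizes = ds.annotation.chrom_sizes

    reps: list[list[Peak]] = [[], []]
    for r in range(2):
        for iv in true_ivs:
            j = cfg.chip_jitter
            js = int(rng.integers(-j, j + 1)) if j else 0
            je = int(rng.integers(-j, j + 1)) if j else 0
            s = max(iv.start + js, 0)
            e = min(iv.end + je, sizes[iv.chrom])
            if e <= s:
                s, e = iv.start, iv.end
            reps[r].append(Peak(Interval(iv.chrom, s, e), score=1.0))

    n_false = round(cfg.chip_false_rate * len(true_ivs))
    chroms = sorted(sizes)
    weights = np.array([sizes[c] for c in chroms], dtype=float)
    # false peaks avoid planted states and each other (also across replicates),
    # so the replicate-consensus step removes every one of them
    avoid = {c: [] for c in chroms}
    for iv, _m in ds.manifest.states:
        avoid[iv.chrom].append((iv.start - 200, iv.end + 200))
    for _ in range(n_false):
        rep = int(rng.integers(0, 2))
        for _try in range(500):
            c = chroms[int(rng.choice(len(chroms), p=weights / weights.sum()))]
            s = int(rng.integers(0, sizes[c] - 600))
            if any(a < s + 600 and s < b for a, b in avoid[c]):
                continue
            avoid[c].append((s, s + 600))
            reps[rep].append(Peak(Interval(c, s, s + 600), score=0.5))
            break
    for r in range(2):
        reps[r].sort(key=lambda p: (p.chrom, p.start))
    return reps[0], reps[1]


def simulate_expression(
    ds: SyntheticDataset, seed: int | None = None
) -> pd.DataFrame:
    """Negative-binomial counts (genes x phenotype.replicate samples).

    Genes overlapping a planted NFR (any phenotype; span plus the 200 bp
    promoter window) have their mean shifted by 2**expression_effect.
    """
    cfg = ds.config
    rng = substream(seed if seed is not None else ds.seed, "expression")
    gene_ids = sorted(ds.annotation.genes)
    base = cfg.expression_base_mean * np.exp(rng.normal(0.0, 0.6, size=len(gene_ids)))

    from regland.expression_link import gene_has_nfr

    nfr_peaks = [Peak(iv) for iv, _ph in ds.manifest.nfrs]
    has = gene_has_nfr(ds.annotation, nfr_peaks)
    mu = base * np.where([has[g] for g in gene_ids], 2.0**cfg.expression_effect, 1.0)

    disp = cfg.expression_dispersion
    nb_n = 1.0 / disp
    cols = {}
    for ph in cfg.phenotypes:
        for rep in range(1, cfg.replicates + 1):
            p = nb_n / (nb_n + mu)
            cols[f"{ph}_rep{rep}"] = rng.negative_binomial(nb_n, p)
    return pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene"))


# ---------------------------------------------------------------------------
# Dataset serialization (FASTA, GFF3, JASPAR, fragments, peaks, counts, manifest)
# ---------------------------------------------------------------------------


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(annotation.chrom_sizes):
            fh.write(f"##sequence-region {chrom} 1 {annotation.chrom_sizes[chrom]}\n")
        for gid in sorted(annotation.genes):
            g = annotation.genes[gid]
            fh.write(_gff_row(g, "gene", f"ID={gid}"))
            tid = None
            for t in annotation.transcripts.values():
                if t.gene_id == gid:
                    tid = t.id
                    fh.write(_gff_row(t.interval, "mRNA", f"ID={tid};Parent={gid}"))
                    for k, e in enumerate(t.exons):
                        fh.write(_gff_row(e, "exon", f"ID={tid}.e{k};Parent={tid}"))
            if tid:
                for iv in annotation.utr5.get(tid, ()):
                    fh.write(_gff_row(iv, "five_prime_UTR", f"ID={tid}.u5;Parent={tid}"))
                for iv in annotation.utr3.get(tid, ()):
                    fh.write(_gff_row(iv, "three_prime_UTR", f"ID={tid}.u3;Parent={tid}"))


def _gff_row(iv: Interval, ftype: str, attrs: str) -> str:
    return (
        f"{iv.chrom}\tregland\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t"
        f"{iv.strand}\t.\t{attrs}\n"
    )


def write_jaspar(motifs: list[Motif], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.id} {m.name}\n")
            for row, base in zip(m.pfm, "ACGT"):
                counts = " ".join(f"{int(v)}" if v == int(v) else f"{v}" for v in row)
                fh.write(f"{base} [ {counts} ]\n")


def write_manifest(manifest: TruthManifest, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# regland truth manifest\n")
        fh.write(f"seed\t{manifest.seed}\n")
        fh.write(f"expression_effect\t{manifest.expression_effect:g}\n")
        fh.write("[nfrs]\n")
        for iv, ph in manifest.nfrs:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{','.join(sorted(ph))}\n")
        fh.write("[states]\n")
        for iv, marks in manifest.states:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{','.join(sorted(marks))}\n")
        fh.write("[sites]\n")
        for s in manifest.sites:
            fh.write(
                f"{s.motif_id}\t{s.interval.chrom}\t{s.interval.start}\t"
                f"{s.interval.end}\t{s.interval.strand}\t{','.join(sorted(s.bound_in))}\n"
            )
        fh.write("[tf_gene_map]\n")
        for m in sorted(manifest.tf_gene_map):
            fh.write(f"{m}\t{manifest.tf_gene_map[m]}\n")
        fh.write("[edges]\n")
        for src, tgt, cls, ph in manifest.edges:
            fh.write(f"{src}\t{tgt}\t{cls}\t{','.join(sorted(ph))}\n")


def read_manifest(path: str | Path) -> TruthManifest:
    seed = 0
    effect = 0.0
    section = ""
    nfrs, states, sites, edges = [], [], [], []
    tf_map: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith("["):
                section = line.strip("[]")
                continue
            cols = line.split("\t")
            if not section:
                if cols[0] == "seed":
                    seed = int(cols[1])
                elif cols[0] == "expression_effect":
                    effect = float(cols[1])
            elif section == "nfrs":
                nfrs.append(
                    (Interval(cols[0], int(cols[1]), int(cols[2])),
                     frozenset(cols[3].split(",")) if cols[3] else frozenset())
                )
            elif section == "states":
                states.append(
                    (Interval(cols[0], int(cols[1]), int(cols[2])),
                     frozenset(cols[3].split(",")))
                )
            elif section == "sites":
                sites.append(
                    PlantedSite(
                        cols[0],
                        Interval(cols[1], int(cols[2]), int(cols[3]), cols[4]),
                        frozenset(cols[5].split(",")) if len(cols) > 5 and cols[5] else frozenset(),
                    )
                )
            elif section == "tf_gene_map":
                tf_map[cols[0]] = cols[1]
            elif section == "edges":
                edges.append(
                    (cols[0], cols[1], cols[2],
                     frozenset(cols[3].split(",")) if len(cols) > 3 and cols[3] else frozenset())
                )
    return TruthManifest(nfrs, states, sites, edges, tf_map, effect, seed)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Serialize the full dataset under one directory; returns path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["fasta"] = out / "genome.fa"
    write_fasta(ds.sequences, paths["fasta"])
    paths["gff3"] = out / "annotation.gff3"
    write_gff3(ds.annotation, paths["gff3"])
    paths["motifs"] = out / "motifs.jaspar"
    write_jaspar(ds.motifs, paths["motifs"])
    paths["manifest"] = out / "manifest.tsv"
    write_manifest(ds.manifest, paths["manifest"])

    from regland.genome_io import write_intervals

    for ph in ds.config.phenotypes:
        for rep in range(1, ds.config.replicates + 1):
            key = f"fragments_{ph}_rep{rep}"
            paths[key] = out / f"fragments_{ph}_rep{rep}.tsv"
            write_fragments(simulate_fragments(ds, ph, rep), paths[key])
        for mark in MARKS:
            r1, r2 = simulate_chip_peaks(ds, mark, ph)
            for rep, peaks in ((1, r1), (2, r2)):
                key = f"chip_{mark}_{ph}_rep{rep}"
                paths[key] = out / f"chip_{mark}_{ph}_rep{rep}.bed"
                write_intervals(peaks, paths[key], "bed3")

    paths["counts"] = out / "counts.tsv"
    simulate_expression(ds).to_csv(paths["counts"], sep="\t")
    return paths
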