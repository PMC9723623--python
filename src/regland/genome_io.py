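"""Readers/writers for the standard formats touched by the pipeline and the
core interval/annotation data model every other module consumes.

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive) is
converted at the boundary. narrowPeak -log10 p/q columns are converted to
linear probabilities on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

STRANDS = ("+", "-", ".")

FEATURE_PRIORITY = (
    "promoter",
    "five_prime_utr",
    "exon",
    "intron",
    "three_prime_utr",
    "intergenic",
)


class FileFormatError(ValueError):
    """Malformed input file; message carries the offending line number."""


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic range, the universal coordinate unit."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class Peak:
    """MACS2-style peak: an interval with enrichment score, p/q and summit.

    ``summit`` is an offset within the interval (or None). p/q are linear
    probabilities in [0, 1].
    """

    interval: Interval
    score: float = 0.0
    p_value: float = 1.0
    q_value: float = 1.0
    summit: int | None = None
    name: str = "."

    def __post_init__(self) -> None:
        if self.summit is not None and not (0 <= self.summit < len(self.interval)):
            raise ValueError(
                f"summit {self.summit} outside interval of length {len(self.interval)}"
            )
        if self.q_value < 0:
            raise ValueError("q_value must be >= 0")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def summit_pos(self) -> int:
        """Absolute summit coordinate (midpoint when no summit was called)."""
        if self.summit is None:
            return self.interval.midpoint
        return self.interval.start + self.summit


@dataclass(frozen=True)
class FragmentRecord:
    """One sequenced ATAC template (both Tn5 insertion points)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start <= 0:
            raise ValueError(
                f"fragment {self.chrom}:{self.start}-{self.end} has length <= 0"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Transcript:
    id: str
    gene_id: str
    interval: Interval
    exons: tuple[Interval, ...]

    @property
    def introns(self) -> tuple[Interval, ...]:
        """Gaps between sorted exons within the transcript span."""
        exons = sorted(self.exons, key=lambda e: e.start)
        out = []
        for a, b in zip(exons, exons[1:]):
            if b.start > a.end:
                out.append(
                    Interval(self.interval.chrom, a.end, b.start, self.interval.strand)
                )
        return tuple(out)


@dataclass
class GenomeAnnotation:
    """Gene models plus derived feature sets and strand-aware TSS positions.

    ``promoter_window`` bp upstream of each TSS are labeled "promoter"; every
    other genome bp maps to five_prime_utr/exon/intron/three_prime_utr or the
    intergenic fallback via :meth:`feature_at` (priority order
    ``FEATURE_PRIORITY``).
    """

    genes: dict[str, Interval]
    transcripts: dict[str, Transcript]
    chrom_sizes: dict[str, int]
    utr5: dict[str, tuple[Interval, ...]] = field(default_factory=dict)
    utr3: dict[str, tuple[Interval, ...]] = field(default_factory=dict)
    promoter_window: int = 200

    def tss(self, gene_id: str) -> int:
        """Strand-aware TSS: start for +, end-1 for -."""
        g = self.genes[gene_id]
        return g.start if g.strand != "-" else g.end - 1

    def tss_positions(self) -> list[tuple[str, str, int, str]]:
        """(gene_id, chrom, tss, strand) for every gene, in gene-id order."""
        out = []
        for gid in sorted(self.genes):
            g = self.genes[gid]
            out.append((gid, g.chrom, self.tss(gid), g.strand))
        return out

    def promoter_interval(self, gene_id: str, window: int | None = None) -> Interval | None:
        """Window bp strictly upstream of the TSS, clipped to the chromosome."""
        w = self.promoter_window if window is None else window
        g = self.genes[gene_id]
        size = self.chrom_sizes.get(g.chrom)
        tss = self.tss(gene_id)
        if g.strand == "-":
            start, end = tss + 1, tss + 1 + w
        else:
            start, end = tss - w, tss
        start = max(start, 0)
        if size is not None:
            end = min(end, size)
        if start >= end:
            return None
        return Interval(g.chrom, start, end, g.strand)

    def feature_intervals(self, feature: str) -> list[Interval]:
        """All raw (unmerged) intervals carrying the given feature label."""
        if feature == "promoter":
            out = []
            for gid in sorted(self.genes):
                p = self.promoter_interval(gid)
                if p is not None:
                    out.append(p)
            return out
        if feature == "five_prime_utr":
            return [iv for gid in sorted(self.utr5) for iv in self.utr5[gid]]
        if feature == "three_prime_utr":
            return [iv for gid in sorted(self.utr3) for iv in self.utr3[gid]]
        if feature == "exon":
            return [e for tid in sorted(self.transcripts) for e in self.transcripts[tid].exons]
        if feature == "intron":
            return [i for tid in sorted(self.transcripts) for i in self.transcripts[tid].introns]
        raise KeyError(f"unknown feature {feature!r}")

    @cached_property
    def _feature_index(self) -> dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]:
        idx: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
        for feat in FEATURE_PRIORITY[:-1]:
            per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            by_chrom: dict[str, list[tuple[int, int]]] = {}
            for iv in self.feature_intervals(feat):
                by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
            for chrom, pairs in by_chrom.items():
                merged = merge_pairs(pairs)
                starts = np.array([p[0] for p in merged], dtype=np.int64)
                ends = np.array([p[1] for p in merged], dtype=np.int64)
                per_chrom[chrom] = (starts, ends)
            idx[feat] = per_chrom
        return idx

    def feature_at(self, chrom: str, pos: int) -> str:
        """Highest-priority feature covering a position; intergenic fallback."""
        for feat in FEATURE_PRIORITY[:-1]:
            per_chrom = self._feature_index[feat]
            if chrom not in per_chrom:
                continue
            starts, ends = per_chrom[chrom]
            i = int(np.searchsorted(starts, pos, side="right")) - 1
            if i >= 0 and pos < ends[i]:
                return feat
        return "intergenic"

    def feature_bp(self, feature: str) -> int:
        """Genome bp assigned to the feature under the priority rule.

        Higher-priority features mask lower ones so that the six feature bp
        totals partition the genome exactly.
        """
        totals = self._priority_bp
        return totals[feature]

    @cached_property
    def _priority_bp(self) -> dict[str, int]:
        totals = {f: 0 for f in FEATURE_PRIORITY}
        total_bp = sum(self.chrom_sizes.values())
        covered: dict[str, list[tuple[int, int]]] = {c: [] for c in self.chrom_sizes}
        for feat in FEATURE_PRIORITY[:-1]:
            per_chrom = self._feature_index[feat]
            for chrom, (starts, ends) in per_chrom.items():
                pairs = list(zip(starts.tolist(), ends.tolist()))
                new_bp = 0
                for s, e in pairs:
                    new_bp += _uncovered_bp(s, e, covered[chrom])
                covered[chrom] = merge_pairs(covered[chrom] + pairs)
                totals[feat] += new_bp
        assigned = sum(totals.values())
        totals["intergenic"] = total_bp - assigned
        return totals


def _uncovered_bp(start: int, end: int, merged: list[tuple[int, int]]) -> int:
    """bp of [start, end) not covered by a merged, sorted pair list."""
    bp = end - start
    for s, e in merged:
        if s >= end:
            break
        if e <= start:
            continue
        bp -= min(e, end) - max(s, start)
    return bp


def merge_pairs(pairs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping-or-touching (start, end) pairs; returns sorted list."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(pairs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass(frozen=True)
class Motif:
    """JASPAR-style position frequency matrix with log-odds scoring.

    ``pfm`` rows are A, C, G, T counts per column. The PWM entry is
    log2(((count + pseudocount*bg) / (col_total + pseudocount)) / bg).
    """

    id: str
    name: str
    pfm: np.ndarray
    pseudocount: float = 0.8
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        pfm = np.asarray(self.pfm, dtype=float)
        if pfm.ndim != 2 or pfm.shape[0] != 4:
            raise ValueError("pfm must be a 4 x L matrix (rows A, C, G, T)")
        if pfm.shape[1] < 2:
            raise ValueError("motif length must be >= 2")
        if (pfm < 0).any():
            raise ValueError("pfm counts must be non-negative")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        bg = np.asarray(self.background, dtype=float)
        if not math.isclose(float(bg.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")
        object.__setattr__(self, "pfm", pfm)

    @property
    def length(self) -> int:
        return self.pfm.shape[1]

    @cached_property
    def pwm(self) -> np.ndarray:
        """4 x L log2-odds matrix with the JASPAR pseudocount scheme."""
        bg = np.asarray(self.background, dtype=float)[:, None]
        col_tot = self.pfm.sum(axis=0, keepdims=True)
        p = (self.pfm + self.pseudocount * bg) / (col_tot + self.pseudocount)
        return np.log2(p / bg)

    @property
    def max_score(self) -> float:
        return float(self.pwm.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.pfm.argmax(axis=0))


class SignalTrack:
    """Dense per-bp non-negative signal (cut counts or coverage) per chrom."""

    def __init__(self, chrom_sizes: dict[str, int], dtype=np.float64):
        self.data: dict[str, np.ndarray] = {
            c: np.zeros(n, dtype=dtype) for c, n in chrom_sizes.items()
        }
        self.n_clipped = 0

    @classmethod
    def from_arrays(cls, arrays: dict[str, np.ndarray]) -> "SignalTrack":
        t = cls({})
        t.data = {c: np.asarray(a, dtype=float) for c, a in arrays.items()}
        return t

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.data.items()}

    def total(self) -> float:
        return float(sum(a.sum() for a in self.data.values()))

    def add_at(self, chrom: str, positions: np.ndarray) -> None:
        """Increment the track at the given positions, clipping to bounds."""
        arr = self.data[chrom]
        pos = np.asarray(positions, dtype=np.int64)
        ok = (pos >= 0) & (pos < len(arr))
        self.n_clipped += int((~ok).sum())
        np.add.at(arr, pos[ok], 1.0)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_BED_COLUMN_COUNTS = {3, 4, 5, 6, 10}


def read_bed(path: str | Path) -> list[Peak]:
    """Read BED3/4/5/6 or 10-column narrowPeak into Peak records.

    narrowPeak -log10 p/q (columns 8/9) become linear probabilities; -1
    sentinel values map to 1.0. Input order is preserved.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) not in _BED_COLUMN_COUNTS:
                raise FileFormatError(
                    f"{path}: line {ln}: unsupported column count {len(cols)} "
                    "(expected 3, 4, 5, 6 or 10)"
                )
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FileFormatError(f"{path}: line {ln}: non-integer coordinate") from exc
            if start >= end:
                raise FileFormatError(
                    f"{path}: line {ln}: start {start} >= end {end}"
                )
            name = cols[3] if len(cols) >= 4 else "."
            strand = cols[5] if len(cols) >= 6 and cols[5] in STRANDS else "."
            if len(cols) == 10:
                score = float(cols[6])
                p = _neglog10_to_linear(float(cols[7]))
                q = _neglog10_to_linear(float(cols[8]))
                summit_off = int(cols[9])
                summit = summit_off if summit_off >= 0 else None
            else:
                score = float(cols[4]) if len(cols) >= 5 else 0.0
                p = q = 1.0
                summit = None
            peaks.append(
                Peak(Interval(cols[0], start, end, strand), score, p, q, summit, name)
            )
    return peaks


def _neglog10_to_linear(v: float) -> float:
    return 1.0 if v < 0 else 10.0 ** (-v)


def _linear_to_neglog10(p: float) -> float:
    return 0.0 if p >= 1.0 else (-math.log10(p) if p > 0 else 400.0)


def read_gff3(path: str | Path, promoter_window: int = 200) -> GenomeAnnotation:
    """Parse a GFF3 into a GenomeAnnotation (coordinates to 0-based half-open).

    Recognises gene / mRNA / exon / five_prime_UTR / three_prime_UTR rows and
    ``##sequence-region`` pragmas for chromosome sizes. Introns are derived
    per transcript as gaps between sorted exons.
    """
    genes: dict[str, Interval] = {}
    tx_meta: dict[str, tuple[str, Interval]] = {}
    tx_exons: dict[str, list[Interval]] = {}
    utr5: dict[str, list[Interval]] = {}
    utr3: dict[str, list[Interval]] = {}
    chrom_sizes: dict[str, int] = {}

    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    chrom_sizes[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FileFormatError(f"{path}: line {ln}: expected 9 columns")
            chrom, _src, ftype, start1, end1, _score, strand, _frame, attrs = cols
            start, end = int(start1) - 1, int(end1)  # 1-based inclusive -> half-open
            attr = _parse_attrs(attrs)
            if ftype == "gene":
                if strand not in ("+", "-"):
                    raise FileFormatError(
                        f"{path}: line {ln}: gene {attr.get('ID', '?')} lacks strand"
                    )
                genes[attr["ID"]] = Interval(chrom, start, end, strand)
            elif ftype in ("mRNA", "transcript"):
                tx_meta[attr["ID"]] = (attr.get("Parent", ""), Interval(chrom, start, end, strand))
            elif ftype == "exon":
                parent = attr["Parent"]
                tx_exons.setdefault(parent, []).append(Interval(chrom, start, end, strand))
            elif ftype == "five_prime_UTR":
                utr5.setdefault(attr.get("Parent", attr.get("ID", "?")), []).append(
                    Interval(chrom, start, end, strand)
                )
            elif ftype == "three_prime_UTR":
                utr3.setdefault(attr.get("Parent", attr.get("ID", "?")), []).append(
                    Interval(chrom, start, end, strand)
                )

    transcripts: dict[str, Transcript] = {}
    for tid, (gene_id, span) in tx_meta.items():
        exons = tuple(sorted(tx_exons.get(tid, []), key=lambda e: e.start))
        for e in exons:
            if e.start < span.start or e.end > span.end:
                raise FileFormatError(
                    f"{path}: exon {e.chrom}:{e.start}-{e.end} outside "
                    f"transcript {tid} span {span.start}-{span.end}"
                )
        transcripts[tid] = Transcript(tid, gene_id, span, exons)

    if not chrom_sizes:
        seen: dict[str, int] = {}
        for iv in list(genes.values()) + [t.interval for t in transcripts.values()]:
            seen[iv.chrom] = max(seen.get(iv.chrom, 0), iv.end)
        chrom_sizes = seen

    return GenomeAnnotation(
        genes=genes,
        transcripts=transcripts,
        chrom_sizes=chrom_sizes,
        utr5={k: tuple(v) for k, v in utr5.items()},
        utr3={k: tuple(v) for k, v in utr3.items()},
        promoter_window=promoter_window,
    )


def _parse_attrs(s: str) -> dict[str, str]:
    out = {}
    for kv in s.split(";"):
        kv = kv.strip()
        if kv and "=" in kv:
            k, v = kv.split("=", 1)
            out[k] = v
    return out


def read_fragments(path: str | Path) -> list[FragmentRecord]:
    """Read a fragment TSV (chrom, start, end, ...) or BEDPE file.

    BEDPE rows (>= 6 columns with a second chrom in column 4) collapse to the
    outermost mate span. Output is sorted by (chrom, start).
    """
    frags: list[FragmentRecord] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FileFormatError(f"{path}: line {ln}: fewer than 3 columns")
            is_bedpe = len(cols) >= 6 and not _is_int(cols[3]) and _is_int(cols[4])
            try:
                if is_bedpe:
                    c1, s1, e1, c2, s2, e2 = cols[0], int(cols[1]), int(cols[2]), cols[3], int(cols[4]), int(cols[5])
                    if c1 != c2:
                        raise FileFormatError(
                            f"{path}: line {ln}: BEDPE mates on different chromosomes"
                        )
                    chrom, start, end = c1, min(s1, s2), max(e1, e2)
                else:
                    chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FileFormatError(f"{path}: line {ln}: non-integer coordinate") from exc
            if end - start <= 0:
                raise FileFormatError(
                    f"{path}: line {ln}: non-positive fragment length {end - start}"
                )
            frags.append(FragmentRecord(chrom, start, end))
    frags.sort(key=lambda f: (f.chrom, f.start, f.end))
    return frags


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def read_jaspar_pfm(
    path: str | Path,
    pseudocount: float = 0.8,
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> list[Motif]:
    """Read motifs in JASPAR PFM text format.

    Each record is a ``>ID name`` header followed by four count rows (A, C,
    G, T), optionally row-labeled and bracketed.
    """
    motifs: list[Motif] = []
    header: tuple[str, str] | None = None
    rows: list[list[float]] = []

    def flush(ln: int) -> None:
        nonlocal header, rows
        if header is None:
            return
        if len(rows) != 4:
            raise FileFormatError(
                f"{path}: motif {header[0]}: expected 4 rows, got {len(rows)}"
            )
        lens = {len(r) for r in rows}
        if len(lens) != 1:
            raise FileFormatError(
                f"{path}: motif {header[0]}: rows of unequal length {sorted(lens)}"
            )
        motifs.append(
            Motif(header[0], header[1], np.array(rows), pseudocount, background)
        )
        header, rows = None, []

    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(ln)
                parts = line[1:].split(None, 1)
                header = (parts[0], parts[1].strip() if len(parts) > 1 else parts[0])
                rows = []
            else:
                body = line
                if body[:1].upper() in "ACGT" and (len(body) == 1 or not body[1].isdigit()):
                    body = body[1:]
                body = body.replace("[", " ").replace("]", " ")
                try:
                    rows.append([float(x) for x in body.split()])
                except ValueError as exc:
                    raise FileFormatError(
                        f"{path}: line {ln}: non-numeric count"
                    ) from exc
        flush(-1)
    return motifs


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

WRITE_DIALECTS = ("bed3", "narrowPeak", "tsv")


def write_intervals(items: Sequence[Peak | Interval], path: str | Path, dialect: str = "bed3") -> None:
    """Write peaks/intervals; read(write(x)) reproduces coordinates and labels.

    Dialects: ``bed3`` (coordinates only), ``narrowPeak`` (10 columns,
    -log10 p/q), ``tsv`` (6 BED-like columns).
    """
    if dialect not in WRITE_DIALECTS:
        raise ValueError(f"dialect must be one of {WRITE_DIALECTS}, got {dialect!r}")
    with open(path, "w") as fh:
        for item in items:
            pk = item if isinstance(item, Peak) else Peak(item)
            iv = pk.interval
            if dialect == "bed3":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            elif dialect == "tsv":
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{pk.name}\t"
                    f"{pk.score:g}\t{iv.strand}\n"
                )
            else:
                summit = pk.summit if pk.summit is not None else -1
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{pk.name}\t0\t{iv.strand}\t"
                    f"{pk.score:g}\t{_linear_to_neglog10(pk.p_value):g}\t"
                    f"{_linear_to_neglog10(pk.q_value):g}\t{summit}\n"
                )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA into an uppercase chrom -> sequence dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")
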