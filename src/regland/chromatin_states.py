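"""Combinatorial chromatin states from histone-mark consensus peak sets.

A chromatin state is the subset of the four marks (H3K4me1, H3K4me3,
H3K27ac, H3K27me3) covering a genomic segment. The decomposition unit is the
disjoint bp-resolved segment (the UpSet analogue of a Venn diagram); NFR-level
tables use a summit lookup into those segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from regland.genome_io import (
    FEATURE_PRIORITY,
    GenomeAnnotation,
    Interval,
    Peak,
    SignalTrack,
    merge_pairs,
)

MARKS = ("H3K4me1", "H3K4me3", "H3K27ac", "H3K27me3")


@dataclass(frozen=True)
class StateSegment:
    """Disjoint region labeled by the non-empty subset of marks covering it."""

    interval: Interval
    marks: frozenset[str]

    def __post_init__(self) -> None:
        if not self.marks:
            raise ValueError("state segment must carry >= 1 mark")

    @property
    def label(self) -> str:
        return state_label(self.marks)


def state_label(marks: frozenset[str] | set[str]) -> str:
    """Canonical state name: marks joined in fixed H3K4me1..H3K27me3 order."""
    ordered = [m for m in MARKS if m in marks]
    ordered += sorted(m for m in marks if m not in MARKS)
    return "+".join(ordered)


def flatten_state_segments(
    mark_peaks: Mapping[str, Sequence[Peak | Interval]],
) -> list[StateSegment]:
    """Decompose 1-4 mark peak sets into disjoint labeled segments.

    Segment boundaries fall at every peak start/end; each segment's label is
    exactly the set of marks covering every bp of it. Overlapping peaks
    within one mark set are auto-merged (with a warning). The union of the
    output equals the union of the inputs.
    """
    if not mark_peaks:
        return []
    merged: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for mark, peaks in mark_peaks.items():
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for p in peaks:
            iv = p.interval if isinstance(p, Peak) else p
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, pairs in by_chrom.items():
            m = merge_pairs(pairs)
            if len(m) < len(pairs):
                warnings.warn(
                    f"{mark}: overlapping peaks on {chrom} auto-merged"
                )
            merged.setdefault(chrom, {})[mark] = m

    segments: list[StateSegment] = []
    for chrom in sorted(merged):
        events: list[tuple[int, int, str]] = []  # (pos, +1/-1, mark)
        for mark, pairs in merged[chrom].items():
            for s, e in pairs:
                events.append((s, +1, mark))
                events.append((e, -1, mark))
        boundaries = sorted({pos for pos, _, _ in events})
        starts = {}
        ends = {}
        for pos, delta, mark in events:
            (starts if delta > 0 else ends).setdefault(pos, []).append(mark)
        active: set[str] = set()
        for i, pos in enumerate(boundaries):
            for m in ends.get(pos, []):
                active.discard(m)
            for m in starts.get(pos, []):
                active.add(m)
            if active and i + 1 < len(boundaries):
                segments.append(
                    StateSegment(
                        Interval(chrom, pos, boundaries[i + 1]), frozenset(active)
                    )
                )
    return segments


def state_upset_table(segments: Sequence[StateSegment]) -> pd.DataFrame:
    """Per-state counts and bp with percentages over both units.

    Both the segment-count and bp shares are reported since either can be the
    unit of an UpSet decomposition.
    """
    rows: dict[str, list[float]] = {}
    for seg in segments:
        n, bp = rows.setdefault(seg.label, [0, 0])
        rows[seg.label] = [n + 1, bp + len(seg.interval)]
    df = pd.DataFrame(
        [(k, int(v[0]), int(v[1])) for k, v in sorted(rows.items())],
        columns=["state", "n_segments", "bp"],
    )
    if len(df):
        df["pct_segments"] = 100 * df["n_segments"] / df["n_segments"].sum()
        df["pct_bp"] = 100 * df["bp"] / df["bp"].sum()
    return df.sort_values("bp", ascending=False, kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Feature annotation
# ---------------------------------------------------------------------------

FEATURE_CODES = {f: i for i, f in enumerate(FEATURE_PRIORITY)}


def build_feature_map(annotation: GenomeAnnotation) -> dict[str, np.ndarray]:
    """Per-bp feature codes per chromosome, painted in reverse priority so
    higher-priority features overwrite lower ones."""
    fmap = {
        c: np.full(n, FEATURE_CODES["intergenic"], dtype=np.int8)
        for c, n in annotation.chrom_sizes.items()
    }
    for feat in reversed(FEATURE_PRIORITY[:-1]):
        code = FEATURE_CODES[feat]
        for iv in annotation.feature_intervals(feat):
            if iv.chrom in fmap:
                arr = fmap[iv.chrom]
                arr[max(iv.start, 0) : min(iv.end, len(arr))] = code
    return fmap


def annotate_feature(interval: Interval, annotation: GenomeAnnotation) -> str:
    """Feature label of the interval's midpoint (priority: promoter >
    five_prime_utr > exon > intron > three_prime_utr > intergenic)."""
    return annotation.feature_at(interval.chrom, interval.midpoint)


def state_feature_enrichment(
    segments: Sequence[StateSegment],
    annotation: GenomeAnnotation,
    feature_map: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """log2 enrichment of each state's bp in each genomic feature.

    enrichment(state, feature) = log2((obs_bp/state_bp) / (feature_bp/genome_bp)),
    with a 1 bp pseudocount on zero observed overlap so the log is finite.
    """
    if not segments:
        raise ValueError("need >= 1 state segment")
    genome_bp = sum(annotation.chrom_sizes.values())
    if genome_bp == 0:
        raise ValueError("zero-length genome")
    if feature_map is None:
        feature_map = build_feature_map(annotation)

    feat_bp = np.zeros(len(FEATURE_PRIORITY), dtype=np.int64)
    for arr in feature_map.values():
        feat_bp += np.bincount(arr, minlength=len(FEATURE_PRIORITY))

    obs: dict[str, np.ndarray] = {}
    for seg in segments:
        arr = feature_map[seg.interval.chrom][seg.interval.start : seg.interval.end]
        counts = np.bincount(arr, minlength=len(FEATURE_PRIORITY))
        obs[seg.label] = obs.get(seg.label, 0) + counts

    rows = []
    for label in sorted(obs):
        counts = obs[label]
        state_bp = counts.sum()
        row = {"state": label}
        for feat, code in FEATURE_CODES.items():
            o = max(int(counts[code]), 1)  # 1 bp pseudocount for empty cells
            expected = feat_bp[code] / genome_bp
            row[feat] = float(np.log2((o / state_bp) / expected)) if expected > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("state")


# ---------------------------------------------------------------------------
# TSS / non-TSS NFR partition and state tables
# ---------------------------------------------------------------------------


def classify_nfr_tss(
    nfr_peaks: Sequence[Peak],
    annotation: GenomeAnnotation,
    window: int = 200,
) -> list[str]:
    """Label each NFR peak ``tss`` when it overlaps [TSS-window, TSS+window]
    of any gene by >= 1 bp, else ``non_tss``."""
    windows: dict[str, list[tuple[int, int]]] = {}
    for gid, chrom, tss, _strand in annotation.tss_positions():
        windows.setdefault(chrom, []).append((max(tss - window, 0), tss + window + 1))
    sorted_w = {
        c: (
            np.array([s for s, _ in sorted(v)], dtype=np.int64),
            np.array([e for _, e in sorted(v)], dtype=np.int64),
        )
        for c, v in windows.items()
    }
    labels = []
    for p in nfr_peaks:
        lab = "non_tss"
        if p.chrom in sorted_w:
            starts, ends = sorted_w[p.chrom]
            i = np.searchsorted(starts, p.end, side="left")
            if ((starts[:i] < p.end) & (ends[:i] > p.start)).any():
                lab = "tss"
        labels.append(lab)
    return labels


def state_at_point(
    segments: Sequence[StateSegment], chrom: str, pos: int
) -> frozenset[str]:
    """Mark subset covering a position (empty set when unmarked)."""
    for seg in segments:
        if seg.interval.contains_point(chrom, pos):
            return seg.marks
    return frozenset()


def nfr_state_overlap(
    nfrs: Sequence[Peak],
    labels: Sequence[str],
    segments: Sequence[StateSegment],
) -> pd.DataFrame:
    """Percentage of TSS and non-TSS NFRs per chromatin state.

    Each NFR takes the state at its summit (midpoint when no summit).
    Percentages within each class sum to 100; NFRs covered by no segment are
    counted as ``unmarked``.
    """
    seg_idx: dict[str, tuple[np.ndarray, np.ndarray, list[frozenset[str]]]] = {}
    by_chrom: dict[str, list[StateSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.interval.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.interval.start)
        seg_idx[chrom] = (
            np.array([s.interval.start for s in segs], dtype=np.int64),
            np.array([s.interval.end for s in segs], dtype=np.int64),
            [s.marks for s in segs],
        )

    counts: dict[tuple[str, str], int] = {}
    for p, cls in zip(nfrs, labels):
        pos = p.summit_pos
        state = "unmarked"
        if p.chrom in seg_idx:
            starts, ends, marks = seg_idx[p.chrom]
            i = int(np.searchsorted(starts, pos, side="right")) - 1
            if i >= 0 and pos < ends[i]:
                state = state_label(marks[i])
        counts[(cls, state)] = counts.get((cls, state), 0) + 1

    rows = []
    for cls in ("tss", "non_tss"):
        total = sum(n for (c, _), n in counts.items() if c == cls)
        for (c, state), n in sorted(counts.items()):
            if c == cls:
                rows.append(
                    {
                        "class": cls,
                        "state": state,
                        "n": n,
                        "pct": 100.0 * n / total if total else 0.0,
                    }
                )
    return pd.DataFrame(rows, columns=["class", "state", "n", "pct"])


def fisher_cooccurrence(
    n11: int, n10: int, n01: int, n00: int
) -> tuple[float, float]:
    """Odds ratio and two-sided Fisher exact p for a 2x2 co-occurrence table.

    OR = (n11*n00)/(n10*n01), with the infinity convention when a denominator
    cell is zero while the numerator cells are positive.
    """
    cells = (n11, n10, n01, n00)
    if any(c < 0 for c in cells):
        raise ValueError("cell counts must be non-negative")
    if all(c == 0 for c in cells):
        raise ValueError("all-zero contingency table")
    if n10 * n01 == 0:
        odds = float("inf") if n11 * n00 > 0 else float("nan")
    else:
        odds = (n11 * n00) / (n10 * n01)
    _, p = sps.fisher_exact([[n11, n10], [n01, n00]], alternative="two-sided")
    return odds, float(p)


def gene_mark_enrichment(
    ip_track: SignalTrack,
    input_track: SignalTrack,
    annotation: GenomeAnnotation,
    fold: float = 3.0,
) -> pd.DataFrame:
    """Per-gene IP/input mean-density ratio with an enrichment flag.

    ratio = (mean IP + eps)/(mean input + eps), eps = 0.5/gene_length; a gene
    is flagged when ratio > ``fold``. Genes on chromosomes missing from
    either track are skipped with a warning.
    """
    rows = []
    skipped = 0
    for gid in sorted(annotation.genes):
        g = annotation.genes[gid]
        if g.chrom not in ip_track.data or g.chrom not in input_track.data:
            skipped += 1
            continue
        eps = 0.5 / len(g)
        ip = float(ip_track[g.chrom][g.start : g.end].mean())
        inp = float(input_track[g.chrom][g.start : g.end].mean())
        ratio = (ip + eps) / (inp + eps)
        rows.append({"gene": gid, "ratio": ratio, "enriched": ratio > fold})
    if skipped:
        warnings.warn(f"{skipped} genes skipped (chromosome missing from a track)")
    return pd.DataFrame(rows, columns=["gene", "ratio", "enriched"])


def any_mark_enrichment(per_mark: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Combine per-mark gene enrichment tables into an any-of-marks flag."""
    combined: pd.DataFrame | None = None
    for mark, df in per_mark.items():
        cur = df.set_index("gene")["enriched"].rename(mark)
        combined = cur.to_frame() if combined is None else combined.join(cur, how="outer")
    if combined is None:
        raise ValueError("no mark tables supplied")
    combined = combined.fillna(False)
    combined["any_mark"] = combined.any(axis=1)
    return combined.reset_index()
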