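"""ATAC-seq core: fragment-length classification, Tn5 cut-site tracks, NFR
peak calling (windowed local-Poisson scan), replicate consensus, TSS
metaprofiles and differential accessibility.

Fragment classes follow the standard ATAC size bands: 0-100 bp nucleosome
free (NFR), 150-247 bp mono-nucleosome, 315-473 bp di-nucleosome; lengths in
the gaps are left unassigned rather than force-assigned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from regland.genome_io import (
    FragmentRecord,
    GenomeAnnotation,
    Interval,
    Peak,
    SignalTrack,
    merge_pairs,
)
from regland.stats import bh_adjust, median_of_ratios_size_factors

# Inclusive fragment-length bounds per class.
FRAGMENT_CLASS_BOUNDS: dict[str, tuple[int, int]] = {
    "nfr": (0, 100),
    "mono": (150, 247),
    "di": (315, 473),
}

FRAGMENT_CLASSES = ("nfr", "mono", "di", "unassigned")

TN5_SHIFT_PLUS = 4
TN5_SHIFT_MINUS = -5


def classify_fragment_length(length: int) -> str:
    for label, (lo, hi) in FRAGMENT_CLASS_BOUNDS.items():
        if lo <= length <= hi:
            return label
    return "unassigned"


def classify_fragments(
    fragments: Sequence[FragmentRecord],
) -> dict[str, list[FragmentRecord]]:
    """Partition fragments into {nfr, mono, di, unassigned} by length.

    The partition is total: every fragment lands in exactly one class.
    """
    out: dict[str, list[FragmentRecord]] = {c: [] for c in FRAGMENT_CLASSES}
    if not fragments:
        return out
    lengths = np.fromiter((f.length for f in fragments), dtype=np.int64, count=len(fragments))
    labels = np.full(len(lengths), 3, dtype=np.int8)
    for i, cls in enumerate(("nfr", "mono", "di")):
        lo, hi = FRAGMENT_CLASS_BOUNDS[cls]
        labels[(lengths >= lo) & (lengths <= hi)] = i
    for frag, lab in zip(fragments, labels):
        out[FRAGMENT_CLASSES[lab]].append(frag)
    return out


def cut_site_track(
    fragments: Iterable[FragmentRecord],
    chrom_sizes: Mapping[str, int],
    shift_plus: int = TN5_SHIFT_PLUS,
    shift_minus: int = TN5_SHIFT_MINUS,
) -> SignalTrack:
    """Per-bp Tn5 cut counts: each fragment cuts at start+shift_plus and
    end-1+shift_minus. Positions outside the chromosome are clipped and
    counted in ``track.n_clipped``.
    """
    track = SignalTrack(dict(chrom_sizes))
    by_chrom: dict[str, list[int]] = {}
    for f in fragments:
        by_chrom.setdefault(f.chrom, []).append(f.start + shift_plus)
        by_chrom[f.chrom].append(f.end - 1 + shift_minus)
    for chrom, positions in by_chrom.items():
        if chrom not in track.data:
            track.n_clipped += len(positions)
            continue
        track.add_at(chrom, np.array(positions, dtype=np.int64))
    return track


# ---------------------------------------------------------------------------
# Peak calling: windowed scan with tiered local Poisson background
# ---------------------------------------------------------------------------


def call_peaks(
    fragments: Sequence[FragmentRecord],
    effective_genome_size: float,
    chrom_sizes: Mapping[str, int],
    window: int = 200,
    step: int = 50,
    q_threshold: float = 0.05,
    local_spans: tuple[int, ...] = (1_000, 10_000),
) -> list[Peak]:
    """Call enriched regions from fragment midpoints.

    Each ``window``-bp window (stepped by ``step``) is tested against a
    Poisson background with lambda = max(genome-wide rate, 1 kb local rate,
    10 kb local rate) x window length; window p-values are BH-corrected
    genome-wide and significant overlapping/adjacent windows are merged.
    The peak summit is the maximum-fragment-coverage bp within the merged
    region.
    """
    if effective_genome_size <= 0:
        raise ValueError("effective_genome_size must be > 0")
    if not fragments:
        return []

    mids: dict[str, np.ndarray] = {}
    for f in fragments:
        mids.setdefault(f.chrom, [])
    for f in fragments:
        mids[f.chrom].append((f.start + f.end) // 2)  # type: ignore[attr-defined]
    mids = {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in mids.items()}

    n_total = len(fragments)
    bg_rate = n_total / effective_genome_size

    win_records: list[tuple[str, int, int]] = []
    pvals: list[float] = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        m = mids.get(chrom, np.empty(0, dtype=np.int64))
        starts = np.arange(0, max(size - 1, 1), step, dtype=np.int64)
        ends = np.minimum(starts + window, size)
        counts = np.searchsorted(m, ends) - np.searchsorted(m, starts)
        centers = (starts + ends) // 2
        lam = np.full(len(starts), bg_rate, dtype=float)
        for span in local_spans:
            lo = np.maximum(centers - span // 2, 0)
            hi = np.minimum(centers + span // 2, size)
            local = (np.searchsorted(m, hi) - np.searchsorted(m, lo)) / np.maximum(hi - lo, 1)
            lam = np.maximum(lam, local)
        lam_win = lam * (ends - starts)
        p = sps.poisson.sf(counts - 1, lam_win)
        for s, e, pv in zip(starts.tolist(), ends.tolist(), p.tolist()):
            win_records.append((chrom, s, e))
            pvals.append(pv)

    q = bh_adjust(pvals)
    sig_by_chrom: dict[str, list[tuple[int, int, float, float]]] = {}
    for (chrom, s, e), pv, qv in zip(win_records, pvals, q):
        if qv <= q_threshold:
            sig_by_chrom.setdefault(chrom, []).append((s, e, pv, qv))

    peaks: list[Peak] = []
    for chrom in sorted(sig_by_chrom):
        entries = sorted(sig_by_chrom[chrom])
        merged = merge_pairs([(s, e) for s, e, _, _ in entries])
        cov = _fragment_coverage(fragments, chrom, chrom_sizes[chrom])
        for ms, me in merged:
            members = [(p, qv) for s, e, p, qv in entries if s < me and ms < e]
            seg = cov[ms:me]
            summit = int(np.argmax(seg))
            peaks.append(
                Peak(
                    Interval(chrom, ms, me),
                    score=float(seg[summit]),
                    p_value=min(p for p, _ in members),
                    q_value=min(qv for _, qv in members),
                    summit=summit,
                    name=f"peak_{chrom}_{ms}",
                )
            )
    return peaks


def _fragment_coverage(
    fragments: Iterable[FragmentRecord], chrom: str, size: int
) -> np.ndarray:
    diff = np.zeros(size + 1, dtype=np.int64)
    for f in fragments:
        if f.chrom != chrom:
            continue
        s = max(f.start, 0)
        e = min(f.end, size)
        if s < e:
            diff[s] += 1
            diff[e] -= 1
    return np.cumsum(diff[:-1])


def consensus_peaks(rep_a: Sequence[Peak], rep_b: Sequence[Peak]) -> list[Peak]:
    """Replicate-consensus peaks: keep peaks overlapping (>= 1 bp) a peak in
    the other replicate, then merge each overlapping group into one interval
    spanning the union.
    """
    kept: list[Interval] = []
    for this, other in ((rep_a, rep_b), (rep_b, rep_a)):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for p in other:
            by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
        sorted_other = {
            c: (np.array(sorted(s for s, _ in v)), np.array([e for _, e in sorted(v)]))
            for c, v in by_chrom.items()
        }
        for p in this:
            if p.chrom not in sorted_other:
                continue
            starts, ends = sorted_other[p.chrom]
            i = np.searchsorted(starts, p.end, side="left")
            if ((starts[:i] < p.end) & (ends[:i] > p.start)).any():
                kept.append(p.interval)

    by_chrom2: dict[str, list[tuple[int, int]]] = {}
    for iv in kept:
        by_chrom2.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out: list[Peak] = []
    for chrom in sorted(by_chrom2):
        for s, e in merge_pairs(by_chrom2[chrom]):
            out.append(Peak(Interval(chrom, s, e), name=f"consensus_{chrom}_{s}"))
    return out


@dataclass(frozen=True)
class TssProfile:
    """Mean signal around TSSs; minus-strand genes are orientation-flipped."""

    values: np.ndarray  # length 2*halfwidth + 1
    n_used: int
    n_skipped: int


def tss_metaprofile(
    track: SignalTrack, annotation: GenomeAnnotation, halfwidth: int = 1000
) -> TssProfile:
    """Average signal in a +-halfwidth window around every usable TSS.

    Genes whose window crosses a chromosome edge are skipped (counted in
    ``n_skipped``); an error is raised when no TSS is usable.
    """
    acc = np.zeros(2 * halfwidth + 1, dtype=float)
    n_used = n_skipped = 0
    sizes = track.chrom_sizes()
    for gid, chrom, tss, strand in annotation.tss_positions():
        if chrom not in sizes or tss - halfwidth < 0 or tss + halfwidth + 1 > sizes[chrom]:
            n_skipped += 1
            continue
        seg = track[chrom][tss - halfwidth : tss + halfwidth + 1]
        acc += seg[::-1] if strand == "-" else seg
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable TSS within chromosome bounds")
    return TssProfile(acc / n_used, n_used, n_skipped)


# ---------------------------------------------------------------------------
# Differential accessibility
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiffResult:
    """Per-unit differential test result with BH q-value."""

    unit: str
    log2_fold_change: float
    statistic: float
    p_value: float
    q_value: float


def count_fragments_in_peaks(
    fragments: Sequence[FragmentRecord], peaks: Sequence[Peak]
) -> np.ndarray:
    """Fragment-midpoint counts per peak (one column of a count matrix)."""
    mids: dict[str, np.ndarray] = {}
    for f in fragments:
        mids.setdefault(f.chrom, []).append((f.start + f.end) // 2)  # type: ignore[attr-defined]
    mids = {c: np.sort(np.asarray(v)) for c, v in mids.items()}
    counts = np.zeros(len(peaks), dtype=np.int64)
    for i, p in enumerate(peaks):
        m = mids.get(p.chrom)
        if m is None:
            continue
        counts[i] = np.searchsorted(m, p.end) - np.searchsorted(m, p.start)
    return counts


def differential_accessibility(
    counts: np.ndarray,
    groups: Sequence[str],
    unit_ids: Sequence[str] | None = None,
    dispersion_floor: float = 0.01,
) -> list[DiffResult]:
    """Two-group differential test on a units x samples count matrix.

    Median-of-ratios normalization, then a per-unit z-test on normalized
    group means under a quadratic mean-variance model var = mu + phi*mu^2
    with a pooled dispersion floored at ``dispersion_floor``. The fold change
    is first group over second in sorted label order, so relabeling the
    groups negates every log2 fold change.
    """
    c = np.asarray(counts, dtype=float)
    labels = list(groups)
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {uniq}")
    idx_a = [i for i, g in enumerate(labels) if g == uniq[0]]
    idx_b = [i for i, g in enumerate(labels) if g == uniq[1]]
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("each group needs >= 2 replicates")
    if unit_ids is None:
        unit_ids = [f"unit_{i}" for i in range(c.shape[0])]

    try:
        sf = median_of_ratios_size_factors(c)
    except ValueError:
        totals = c.sum(axis=0)
        sf = totals / np.exp(np.mean(np.log(totals)))
        warnings.warn(
            "no all-positive row for median-of-ratios; using library-size factors"
        )
    norm = c / sf

    a, b = norm[:, idx_a], norm[:, idx_b]
    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    # method-of-moments dispersion pooled over units and groups
    phis = []
    for grp, mu in ((a, mu_a), (b, mu_b)):
        s2 = grp.var(axis=1, ddof=1)
        ok = mu > 0
        if ok.any():
            phis.append(np.median((s2[ok] - mu[ok]) / mu[ok] ** 2))
    phi = max(max(phis) if phis else 0.0, dispersion_floor)

    var_a = (mu_a + phi * mu_a**2) / len(idx_a)
    var_b = (mu_b + phi * mu_b**2) / len(idx_b)
    se = np.sqrt(var_a + var_b)
    diff = mu_a - mu_b
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
    p = np.where(diff == 0, 1.0, 2.0 * sps.norm.sf(np.abs(z)))
    q = bh_adjust(p)
    lfc = np.log2((mu_a + 0.5) / (mu_b + 0.5))

    return [
        DiffResult(uid, float(l), float(zz), float(pp), float(qq))
        for uid, l, zz, pp, qq in zip(unit_ids, lfc, z, p, q)
    ]
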