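"""TF footprinting: PWM motif scanning within accessible regions, k-mer cut
bias correction, flank-vs-core footprint scoring, bound/unbound calling,
occupancy ranking and phenotype-differential occupancy.

The footprint score is FS = log2((mean corrected cuts over the two flanks +
eps) / (mean over the motif core + eps)): a bound factor protects its core
from transposase insertion, so depletion inside the motif relative to the
flanks scores high.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from regland.genome_io import Interval, Motif, Peak, SignalTrack
from regland.stats import bh_adjust

BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

FS_EPS = 0.1
BIAS_EPS = 0.01
DEFAULT_FLANK = 20
MIN_SITES_FOR_TAU = 50


@dataclass(frozen=True)
class MotifSite:
    """A PWM match: motif id, location (strand in the interval), log2-odds bits."""

    motif_id: str
    interval: Interval
    score: float

    @property
    def key(self) -> tuple:
        return (
            self.motif_id,
            self.interval.chrom,
            self.interval.start,
            self.interval.end,
            self.interval.strand,
        )


@dataclass(frozen=True)
class FootprintCall:
    site: MotifSite
    fs: float
    bound: bool = False
    phenotype: str = ""


def encode_sequence(seq: str) -> np.ndarray:
    """ACGT -> 0..3, anything else -> -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def reverse_complement_pwm(pwm: np.ndarray) -> np.ndarray:
    # complement = reversed row order for (A,C,G,T); then reverse columns
    return pwm[::-1, ::-1]


def scan_motifs(
    genome: Mapping[str, str],
    motif: Motif,
    regions: Sequence[Interval | Peak],
    min_score_frac: float = 0.8,
    min_score_bits: float | None = None,
    dedupe: bool = True,
) -> list[MotifSite]:
    """Scan both strands of the given regions for PWM matches.

    The score threshold defaults to ``min_score_frac`` x the maximum
    attainable bits. Overlapping same-motif hits are deduplicated keeping the
    higher score (``dedupe=False`` returns every above-threshold window);
    output is sorted by coordinate. Regions shorter than the motif are
    skipped; regions outside the genome raise.
    """
    thr = motif.max_score * min_score_frac if min_score_bits is None else min_score_bits
    pwm_f = motif.pwm
    pwm_r = reverse_complement_pwm(pwm_f)
    L = motif.length

    hits: list[MotifSite] = []
    for region in regions:
        iv = region.interval if isinstance(region, Peak) else region
        if iv.chrom not in genome:
            raise ValueError(f"region chromosome {iv.chrom!r} not in genome")
        seq = genome[iv.chrom]
        if iv.start < 0 or iv.end > len(seq):
            raise ValueError(
                f"region {iv.chrom}:{iv.start}-{iv.end} outside genome bounds"
            )
        if len(iv) < L:
            continue
        enc = encode_sequence(seq[iv.start : iv.end])
        windows = np.lib.stride_tricks.sliding_window_view(enc, L)
        valid = (windows >= 0).all(axis=1)
        cols = np.arange(L)
        safe = np.where(windows >= 0, windows, 0)
        for strand, pwm in (("+", pwm_f), ("-", pwm_r)):
            scores = pwm[safe, cols].sum(axis=1)
            ok = valid & (scores >= thr)
            for off in np.nonzero(ok)[0]:
                hits.append(
                    MotifSite(
                        motif.id,
                        Interval(iv.chrom, iv.start + int(off), iv.start + int(off) + L, strand),
                        float(scores[off]),
                    )
                )

    if not dedupe:
        hits.sort(key=lambda h: (h.interval.chrom, h.interval.start, h.interval.strand))
        return hits

    # dedupe overlapping self-hits, keeping the higher score
    hits.sort(key=lambda h: (-h.score, h.interval.chrom, h.interval.start, h.interval.strand))
    kept: list[MotifSite] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        spans = occupied.setdefault(h.interval.chrom, [])
        if any(s < h.interval.end and h.interval.start < e for s, e in spans):
            continue
        spans.append((h.interval.start, h.interval.end))
        kept.append(h)
    kept.sort(key=lambda h: (h.interval.chrom, h.interval.start, h.interval.strand))
    return kept


def scan_all_motifs(
    genome: Mapping[str, str],
    motifs: Sequence[Motif],
    regions: Sequence[Interval | Peak],
    min_score_frac: float = 0.8,
) -> list[MotifSite]:
    sites: list[MotifSite] = []
    for m in motifs:
        sites.extend(scan_motifs(genome, m, regions, min_score_frac))
    sites.sort(key=lambda h: (h.interval.chrom, h.interval.start, h.motif_id))
    return sites


# ---------------------------------------------------------------------------
# Tn5 k-mer bias model
# ---------------------------------------------------------------------------


@dataclass
class BiasModel:
    """k-mer -> expected relative cut rate, normalized to mean 1 over
    genomic k-mer usage. The k-mer window is anchored k//2 bp left of the
    cut position."""

    k: int
    rates: np.ndarray  # length 4**k; 1.0 for k-mers never seen in the genome
    trained_on: str = ""


def _kmer_ids(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(ids, valid) per position; the window for position i is
    [i - k//2, i - k//2 + k). Positions with out-of-range windows or non-ACGT
    bases are invalid."""
    n = len(enc)
    ids = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    off0 = -(k // 2)
    for j in range(k):
        shift = off0 + j
        idx = np.arange(n) + shift
        inb = (idx >= 0) & (idx < n)
        base = np.where(inb, enc[np.clip(idx, 0, n - 1)], -1)
        valid &= base >= 0
        ids = ids * 4 + np.where(base >= 0, base, 0)
    return ids, valid


def fit_bias_model(
    cut_track: SignalTrack, genome: Mapping[str, str], k: int = 6
) -> BiasModel:
    """Estimate per-k-mer relative cut rates from observed cut counts.

    rate(kmer) = (cuts on positions carrying the k-mer / genomic frequency of
    the k-mer), scaled so the usage-weighted mean rate is 1.
    """
    nk = 4**k
    cut_sum = np.zeros(nk)
    pos_sum = np.zeros(nk)
    for chrom, seq in genome.items():
        if chrom not in cut_track.data:
            continue
        enc = encode_sequence(seq)
        ids, valid = _kmer_ids(enc, k)
        cuts = cut_track[chrom][: len(enc)]
        cut_sum += np.bincount(ids[valid], weights=cuts[valid], minlength=nk)
        pos_sum += np.bincount(ids[valid], minlength=nk)
    total_cuts = cut_sum.sum()
    total_pos = pos_sum.sum()
    if total_cuts == 0 or total_pos == 0:
        raise ValueError("no cuts or no valid positions to fit the bias model")
    rates = np.ones(nk)
    seen = pos_sum > 0
    rates[seen] = (cut_sum[seen] / pos_sum[seen]) / (total_cuts / total_pos)
    return BiasModel(k=k, rates=rates, trained_on=f"{int(total_cuts)} cuts")


def correct_cuts(
    cut_track: SignalTrack, model: BiasModel, genome: Mapping[str, str],
    eps: float = BIAS_EPS,
) -> SignalTrack:
    """Divide observed cuts by the expected k-mer rate: corrected =
    observed/(expected + eps). Positions with invalid k-mers pass through
    unchanged."""
    out: dict[str, np.ndarray] = {}
    for chrom, arr in cut_track.data.items():
        if chrom not in genome:
            out[chrom] = arr.astype(float).copy()
            continue
        enc = encode_sequence(genome[chrom])
        ids, valid = _kmer_ids(enc, model.k)
        expected = np.ones(len(arr))
        n = min(len(arr), len(enc))
        expected[:n] = np.where(valid[:n], model.rates[ids[:n]], 1.0)
        corrected = arr / (expected + eps)
        corrected[:n] = np.where(valid[:n], corrected[:n], arr[:n])
        out[chrom] = corrected
    return SignalTrack.from_arrays(out)


# ---------------------------------------------------------------------------
# Footprint scoring and bound calling
# ---------------------------------------------------------------------------


def footprint_score(
    track: SignalTrack,
    site: MotifSite | Interval,
    flank_bp: int = DEFAULT_FLANK,
    eps: float = FS_EPS,
) -> float:
    """log2((mean signal over both flanks + eps)/(mean over motif core + eps)).

    Returns NaN (with a warning at the caller's discretion) when a flank
    extends past the chromosome.
    """
    iv = site.interval if isinstance(site, MotifSite) else site
    arr = track[iv.chrom]
    if iv.start - flank_bp < 0 or iv.end + flank_bp > len(arr):
        return float("nan")
    core = arr[iv.start : iv.end].mean()
    flank = np.concatenate(
        [arr[iv.start - flank_bp : iv.start], arr[iv.end : iv.end + flank_bp]]
    ).mean()
    return float(np.log2((flank + eps) / (core + eps)))


def score_sites(
    track: SignalTrack,
    sites: Sequence[MotifSite],
    flank_bp: int = DEFAULT_FLANK,
    phenotype: str = "",
) -> list[FootprintCall]:
    """Footprint-score every site; sites whose flanks leave the chromosome
    are skipped with one summary warning."""
    calls: list[FootprintCall] = []
    skipped = 0
    for s in sites:
        fs = footprint_score(track, s, flank_bp)
        if np.isnan(fs):
            skipped += 1
            continue
        calls.append(FootprintCall(s, fs, phenotype=phenotype))
    if skipped:
        warnings.warn(f"{skipped} sites skipped: flank outside chromosome")
    return calls


def otsu_threshold(values: np.ndarray) -> float:
    """Exact Otsu threshold: the split of the sorted values maximizing the
    between-class variance; returns the midpoint of the boundary pair."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n < 2 or v[0] == v[-1]:
        raise ValueError("cannot threshold a constant score distribution")
    csum = np.cumsum(v)
    total = csum[-1]
    k = np.arange(1, n)  # split: first k values below, rest above
    mu0 = csum[:-1] / k
    mu1 = (total - csum[:-1]) / (n - k)
    w0 = k / n
    between = w0 * (1 - w0) * (mu0 - mu1) ** 2
    # only splits between distinct values are admissible
    distinct = v[1:] > v[:-1]
    between = np.where(distinct, between, -np.inf)
    i = int(np.argmax(between))
    return float((v[i] + v[i + 1]) / 2.0)


def call_bound(
    calls: Sequence[FootprintCall],
    method: str = "otsu",
    tau: float | None = None,
    quantile: float = 0.75,
    min_sites: int = MIN_SITES_FOR_TAU,
) -> tuple[list[FootprintCall], float]:
    """Set bound flags: bound <=> FS >= tau.

    tau is estimated by Otsu's between-class variance maximization on the FS
    distribution (or a quantile), unless given explicitly.
    """
    fs = np.array([c.fs for c in calls])
    if tau is None:
        if len(calls) < min_sites:
            raise ValueError(
                f"only {len(calls)} sites (< {min_sites}); pass an explicit tau"
            )
        if method == "otsu":
            tau = otsu_threshold(fs)
        elif method == "quantile":
            tau = float(np.quantile(fs, quantile))
        else:
            raise ValueError(f"unknown method {method!r}")
    out = [replace(c, bound=bool(c.fs >= tau)) for c in calls]
    return out, float(tau)


def occupancy_table(
    calls: Sequence[FootprintCall],
    nfr_peaks: Sequence[Peak] | None = None,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Per-motif occupancy: 100 * n_bound / n_sites, ranked descending.

    When ``nfr_peaks`` is given, only sites whose midpoint falls inside an
    NFR peak are counted.
    """
    if nfr_peaks is not None:
        idx: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for p in nfr_peaks:
            by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
        for c, v in by_chrom.items():
            sv = sorted(v)
            idx[c] = (
                np.array([s for s, _ in sv], dtype=np.int64),
                np.array([e for _, e in sv], dtype=np.int64),
            )

        def in_nfr(call: FootprintCall) -> bool:
            iv = call.site.interval
            if iv.chrom not in idx:
                return False
            starts, ends = idx[iv.chrom]
            i = int(np.searchsorted(starts, iv.midpoint, side="right")) - 1
            return i >= 0 and iv.midpoint < ends[i]

        calls = [c for c in calls if in_nfr(c)]

    agg: dict[str, list[int]] = {}
    for c in calls:
        n, b = agg.setdefault(c.site.motif_id, [0, 0])
        agg[c.site.motif_id] = [n + 1, b + int(c.bound)]
    rows = [
        {
            "motif": m,
            "n_sites": n,
            "n_bound": b,
            "occupancy_pct": 100.0 * b / n,
        }
        for m, (n, b) in agg.items()
    ]
    df = pd.DataFrame(rows, columns=["motif", "n_sites", "n_bound", "occupancy_pct"])
    df = df.sort_values(
        ["occupancy_pct", "motif"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df.head(top_k) if top_k else df


def differential_occupancy(
    calls_a: Sequence[FootprintCall],
    calls_b: Sequence[FootprintCall],
    n_background_draws: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-motif differential footprint scores between two phenotypes.

    Both call sets are matched on the shared site set; per motif, dFS = mean
    FS_a - mean FS_b over its shared sites. The null is built from
    ``n_background_draws`` motif-blind random site subsets of matching size;
    z = (dFS - null mean)/(null sd * sqrt(1 + 1/draws)) with a two-sided
    t(draws-1) p (the prediction-error scaling accounts for the null mean and
    sd being estimated from finitely many draws), BH q over motifs.
    """
    fs_a = {c.site.key: c.fs for c in calls_a}
    fs_b = {c.site.key: c.fs for c in calls_b}
    shared = sorted(set(fs_a) & set(fs_b))
    if not shared:
        raise ValueError("no shared sites between the two phenotypes")
    d = np.array([fs_a[k] - fs_b[k] for k in shared])
    motif_of = np.array([k[0] for k in shared])
    motifs = sorted(set(motif_of))
    only_a = set(k[0] for k in fs_a) - set(motifs)
    only_b = set(k[0] for k in fs_b) - set(motifs)
    if only_a or only_b:
        warnings.warn(
            f"motifs excluded (absent from one phenotype): {sorted(only_a | only_b)}"
        )

    rng = np.random.default_rng(seed)
    rows = []
    for m in motifs:
        sel = motif_of == m
        n_m = int(sel.sum())
        dfs = float(d[sel].mean())
        null = np.array(
            [d[rng.choice(len(d), size=n_m, replace=False)].mean()
             for _ in range(n_background_draws)]
        )
        sd = float(null.std(ddof=1))
        if sd == 0:
            z = 0.0
            p = 1.0 if dfs == float(null.mean()) else 0.0
        else:
            z = (dfs - float(null.mean())) / (sd * np.sqrt(1 + 1 / n_background_draws))
            p = float(2 * sps.t.sf(abs(z), df=n_background_draws - 1))
        rows.append({"motif": m, "n_sites": n_m, "delta_fs": dfs, "z": z, "p_value": p})
    df = pd.DataFrame(rows)
    df["q_value"] = bh_adjust(df["p_value"].values)
    return df.sort_values("p_value", kind="mergesort").reset_index(drop=True)
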