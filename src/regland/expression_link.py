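"""Expression-table handling and the NFR-expression contrast.

Counts are normalized with median-of-ratios size factors; the contrast
between genes that contain a nucleosome-free region and those that do not is
a one-sided Mann-Whitney U test on log(normalized+1) expression. Logs are
natural with a +1 pseudocount throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from regland.genome_io import GenomeAnnotation, Peak
from regland.stats import median_of_ratios_size_factors

EXACT_MW_MAX_N = 8  # exact enumeration up to this group size


@dataclass
class ExpressionMatrix:
    """Genes x samples non-negative values with a sample -> (phenotype,
    replicate) map and a normalized flag."""

    values: pd.DataFrame
    sample_map: dict[str, tuple[str, int]]
    normalized: bool = False

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if set(self.sample_map) != set(self.values.columns):
            raise ValueError("sample map must cover exactly the matrix columns")


def parse_sample_map(columns) -> dict[str, tuple[str, int]]:
    """Derive (phenotype, replicate) from 'PHENO_repN'-style column names."""
    out = {}
    for c in columns:
        parts = str(c).rsplit("_rep", 1)
        if len(parts) == 2 and parts[1].isdigit():
            out[c] = (parts[0], int(parts[1]))
        else:
            out[c] = (str(c), 1)
    return out


def read_counts_tsv(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, parse_sample_map(df.columns))


def normalize_counts(raw: ExpressionMatrix) -> ExpressionMatrix:
    """Median-of-ratios normalization; all-zero genes are retained but
    excluded from size-factor estimation."""
    if raw.normalized:
        return raw
    sf = median_of_ratios_size_factors(raw.values.values)
    norm = raw.values / sf
    return ExpressionMatrix(norm, dict(raw.sample_map), normalized=True)


def gene_has_nfr(
    annotation: GenomeAnnotation,
    nfr_peaks: list[Peak],
    promoter_window: int = 200,
) -> dict[str, bool]:
    """Flag genes whose span (plus the promoter window upstream) overlaps an
    NFR peak by >= 1 bp."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in nfr_peaks:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    idx = {
        c: (
            np.array([s for s, _ in sorted(v)], dtype=np.int64),
            np.array([e for _, e in sorted(v)], dtype=np.int64),
        )
        for c, v in by_chrom.items()
    }
    flags = {}
    for gid in sorted(annotation.genes):
        g = annotation.genes[gid]
        start, end = g.start, g.end
        if g.strand == "-":
            end = end + promoter_window
        else:
            start = max(start - promoter_window, 0)
        hit = False
        if g.chrom in idx:
            starts, ends = idx[g.chrom]
            i = np.searchsorted(starts, end, side="left")
            hit = bool(((starts[:i] < end) & (ends[:i] > start)).any())
        flags[gid] = hit
    return flags


def nfr_expression_test(
    expr: ExpressionMatrix | pd.DataFrame,
    has_nfr: dict[str, bool],
) -> tuple[float, float, dict[str, float]]:
    """One-sided Mann-Whitney U: NFR-containing genes express higher.

    Expression per gene is mean log(normalized+1) over samples. Exact p by
    enumeration when both groups are <= 8, normal approximation with
    continuity correction otherwise. Returns (U, p, group medians).
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    logx = np.log1p(values).mean(axis=1)
    grp_nfr = np.array([logx[g] for g in logx.index if has_nfr.get(g, False)])
    grp_other = np.array([logx[g] for g in logx.index if not has_nfr.get(g, False)])
    if len(grp_nfr) == 0 or len(grp_other) == 0:
        raise ValueError("both NFR and non-NFR gene groups must be non-empty")
    method = (
        "exact"
        if max(len(grp_nfr), len(grp_other)) <= EXACT_MW_MAX_N
        else "asymptotic"
    )
    res = sps.mannwhitneyu(
        grp_nfr, grp_other, alternative="greater", method=method, use_continuity=True
    )
    medians = {
        "nfr": float(np.median(grp_nfr)),
        "other": float(np.median(grp_other)),
    }
    return float(res.statistic), float(res.pvalue), medians


def replicate_correlation(x, y, qc_floor: float = 0.8) -> float:
    """Spearman rank correlation (average ranks on ties) between replicates.

    Emits a QC warning below ``qc_floor``, the weakest replicate-agreement
    tier accepted for this kind of data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    rho = float(sps.spearmanr(x, y).statistic)
    if rho < qc_floor:
        warnings.warn(f"replicate correlation rho={rho:.3f} below QC floor {qc_floor}")
    return rho


def row_zscore_log(
    expr: ExpressionMatrix | pd.DataFrame, genes: list[str]
) -> pd.DataFrame:
    """Per-row z-score of log(x+1) for the selected genes.

    Constant rows become all-zero rows (with a warning) rather than NaN.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    missing = [g for g in genes if g not in values.index]
    if missing:
        raise KeyError(f"genes not in matrix: {missing}")
    if values.shape[1] < 2:
        raise ValueError("need >= 2 samples for row z-scores")
    sub = np.log1p(values.loc[genes].astype(float))
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    const = sd <= 1e-12 * (mu.abs() + 1.0)  # constant up to float rounding
    if const.any():
        warnings.warn(f"{int(const.sum())} constant rows set to zero z-scores")
    z = (sub.sub(mu, axis=0)).div(sd.where(~const, 1.0), axis=0)
    z[const] = 0.0
    return z
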