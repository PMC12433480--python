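"""Count normalization and susceptibility-correlate analysis.

Bulk RNA-seq counts from the uninfected cell-line panel are normalized with
the median-of-ratios size-factor estimator, log2-transformed, and z-scored
per gene.  Per-line mean expression is then correlated (Spearman, optionally
Pearson) against the susceptibility ranking from the imaging screen, looking
for candidate viral-entry receptors and antiviral genes whose expression
tracks susceptibility.  Small panels get exact permutation inference.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "CountMatrix",
    "NormalizedExpression",
    "CorrelationRecord",
    "NormalizationError",
    "size_factors",
    "log_normalize",
    "scale_rows",
    "normalize_expression",
    "MedianOfRatiosNormalizer",
    "spearman_rho",
    "spearman_p",
    "pearson_r",
    "correlate_with_susceptibility",
]


class NormalizationError(ValueError):
    """Raised when the median-of-ratios reference cannot be formed."""


@dataclass
class CountMatrix:
    """Raw gene x sample counts plus the sample -> cell-line map."""

    counts: pd.DataFrame
    sample_to_line: Dict[str, str]

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene names: {dupes}")
        if df.columns.duplicated().any():
            raise ValueError("duplicate sample names")
        vals = df.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite counts")
        if np.any(vals < 0):
            raise ValueError("negative counts")
        if np.any(vals != np.round(vals)):
            raise ValueError("counts must be integral")
        unmapped = [s for s in df.columns if s not in self.sample_to_line]
        if unmapped:
            raise ValueError(f"samples without a cell-line mapping: {unmapped}")

    @property
    def genes(self) -> list:
        return self.counts.index.tolist()

    @property
    def samples(self) -> list:
        return self.counts.columns.tolist()


@dataclass
class NormalizedExpression:
    """Size factors plus log-normalized and per-gene z-scored matrices."""

    size_factors: pd.Series
    lognorm: pd.DataFrame
    scaled: pd.DataFrame
    sample_to_line: Dict[str, str] = field(default_factory=dict)


@dataclass
class CorrelationRecord:
    """One gene's correlation with the susceptibility ranking."""

    gene: str
    method: str
    estimate: float
    n: int
    sum_sq_rank_diff: Optional[int] = None
    p: float = math.nan
    p_method: Optional[str] = None
    degenerate: bool = False


# ---------------------------------------------------------------------------
# normalization


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    The reference is the per-gene geometric mean across samples, restricted
    to genes with strictly positive counts in every sample; each sample's
    factor is the median over those genes of count / reference.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    vals = counts.to_numpy(dtype=float)
    positive = np.all(vals > 0, axis=1)
    if not positive.any():
        raise NormalizationError(
            "no gene has strictly positive counts in all samples"
        )
    logs = np.log(vals[positive])
    log_ref = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_ref, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def log_normalize(
    counts: pd.DataFrame,
    factors: pd.Series,
    base: float = 2.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """log_base(count / size_factor + pseudocount), elementwise."""
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    f = np.asarray(factors, dtype=float)
    if np.any(f <= 0) or not np.all(np.isfinite(f)):
        raise ValueError("size factors must be positive and finite")
    return np.log(counts / f + pseudocount) / math.log(base)


def scale_rows(lognorm: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores (mean 0, sample SD 1); constant genes map to zeros."""
    if lognorm.shape[1] < 2:
        raise ValueError("scaling needs at least 2 samples")
    vals = lognorm.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    centered = vals - mean
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(sd > 0, centered / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(scaled, index=lognorm.index, columns=lognorm.columns)


def normalize_expression(
    cm: CountMatrix, base: float = 2.0, pseudocount: float = 1.0
) -> NormalizedExpression:
    """Full normalization: size factors, log transform, per-gene scaling."""
    factors = size_factors(cm.counts)
    lognorm = log_normalize(cm.counts, factors, base=base, pseudocount=pseudocount)
    return NormalizedExpression(
        size_factors=factors,
        lognorm=lognorm,
        scaled=scale_rows(lognorm),
        sample_to_line=dict(cm.sample_to_line),
    )


class MedianOfRatiosNormalizer(TransformerMixin, BaseEstimator):
    """Transformer wrapping median-of-ratios normalization.

    ``fit`` learns per-sample size factors from a gene x sample count frame;
    ``transform`` returns the log-normalized matrix on the same samples.
    """

    def __init__(self, base: float = 2.0, pseudocount: float = 1.0):
        self.base = base
        self.pseudocount = pseudocount

    def fit(self, X: pd.DataFrame, y=None) -> "MedianOfRatiosNormalizer":
        counts = X.counts if isinstance(X, CountMatrix) else X
        self.size_factors_ = size_factors(counts)
        self.n_features_in_ = counts.shape[0]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        counts = X.counts if isinstance(X, CountMatrix) else X
        factors = self.size_factors_.reindex(counts.columns)
        if factors.isna().any():
            raise ValueError("transform saw samples unseen at fit time")
        return log_normalize(
            counts, factors, base=self.base, pseudocount=self.pseudocount
        )


# ---------------------------------------------------------------------------
# correlation


def _is_untied(x: np.ndarray) -> bool:
    return np.unique(x).size == x.size


def spearman_rho(x: Sequence[float], y: Sequence[float], gene: str = "") -> CorrelationRecord:
    """Spearman rank correlation with midranks for ties.

    For untied inputs the record also carries the integer sum of squared rank
    differences and the estimate satisfies 1 - 6*sum_d2/(n(n^2-1)) exactly.
    Constant inputs yield an undefined (NaN) estimate flagged ``degenerate``.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = xa.size
    if n < 3:
        raise ValueError("need n >= 3")
    if np.unique(xa).size == 1 or np.unique(ya).size == 1:
        return CorrelationRecord(gene, "spearman", math.nan, n, degenerate=True)
    rx = stats.rankdata(xa)
    ry = stats.rankdata(ya)
    if _is_untied(xa) and _is_untied(ya):
        d2 = int(round(((rx - ry) ** 2).sum()))
        est = 1.0 - 6.0 * d2 / (n * (n * n - 1))
        return CorrelationRecord(gene, "spearman", float(est), n, sum_sq_rank_diff=d2)
    est = float(np.corrcoef(rx, ry)[0, 1])
    return CorrelationRecord(gene, "spearman", est, n)


class SpearmanP(NamedTuple):
    p: float
    p_method: str
    se: Optional[float] = None


_EXACT_MAX_N = 8


def _exact_null_rho(n: int) -> np.ndarray:
    """All n! Spearman statistics for untied ranks (permutation null)."""
    base = np.arange(1, n + 1)
    denom = n * (n * n - 1)
    rhos = np.empty(math.factorial(n))
    for i, perm in enumerate(itertools.permutations(base)):
        d2 = int(np.sum((np.array(perm) - base) ** 2))
        rhos[i] = 1.0 - 6.0 * d2 / denom
    return rhos


def spearman_p(
    estimate: float,
    n: int,
    method: str = "exact",
    n_draws: int = 20_000,
    seed: int = 0,
) -> SpearmanP:
    """Two-sided p-value for an observed Spearman statistic.

    ``exact``: full enumeration of the n! rank permutations (n <= 8);
    ``montecarlo``: seeded permutation sampling, reported with its standard
    error; ``t_approx``: t = r sqrt((n-2)/(1-r^2)) against df = n-2.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not np.isfinite(estimate):
        raise ValueError("estimate is not finite")
    r = abs(float(estimate))
    tol = 1e-12
    if method == "exact":
        if n > _EXACT_MAX_N:
            raise ValueError(
                f"exact enumeration limited to n <= {_EXACT_MAX_N}; "
                "use method='montecarlo'"
            )
        rhos = _exact_null_rho(n)
        p = float(np.mean(np.abs(rhos) >= r - tol))
        return SpearmanP(p, "exact")
    if method == "montecarlo":
        rng = np.random.default_rng(seed)
        base = np.arange(1, n + 1)
        denom = n * (n * n - 1)
        perms = rng.permuted(np.tile(base, (int(n_draws), 1)), axis=1)
        d2 = ((perms - base) ** 2).sum(axis=1)
        rhos = 1.0 - 6.0 * d2 / denom
        hits = int(np.sum(np.abs(rhos) >= r - tol))
        p = hits / n_draws
        se = math.sqrt(max(p * (1.0 - p), 1e-300) / n_draws)
        return SpearmanP(float(p), "montecarlo", se)
    if method == "t_approx":
        if r >= 1.0:
            return SpearmanP(0.0, "t_approx")
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        return SpearmanP(float(2.0 * stats.t.sf(t, n - 2)), "t_approx")
    raise ValueError(f"unknown method {method!r}")


def pearson_r(x: Sequence[float], y: Sequence[float], gene: str = "") -> CorrelationRecord:
    """Product-moment correlation; constant input is rejected."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if xa.size < 3:
        raise ValueError("need n >= 3")
    if np.unique(xa).size == 1 or np.unique(ya).size == 1:
        raise ValueError("constant vector has undefined correlation")
    est = float(np.corrcoef(xa, ya)[0, 1])
    return CorrelationRecord(gene, "pearson", est, xa.size)


def correlate_with_susceptibility(
    norm: NormalizedExpression,
    ranks: Mapping[str, int],
    gene_set: Optional[Sequence[str]] = None,
    p_method: str = "auto",
    n_draws: int = 20_000,
    seed: int = 0,
    include_pearson: bool = False,
    bh_adjust: bool = True,
) -> pd.DataFrame:
    """Correlate per-line mean expression with the susceptibility rank.

    Replicate samples are averaged (arithmetic mean of the log-normalized
    values) per cell line, then each gene is tested with Spearman against
    the integer rank (1 = most susceptible).  ``p_method='auto'`` picks exact
    enumeration for panels of up to 8 lines and the t approximation above.
    Output is sorted by estimate (strongest negative correlate first) and
    reports unadjusted p-values, optionally with a Benjamini-Hochberg column.
    """
    lognorm = norm.lognorm
    line_of = norm.sample_to_line
    lines = sorted(set(line_of.values()) & set(ranks))
    if len(lines) < 4:
        raise ValueError(f"need >= 4 cell lines with ranks, got {len(lines)}")
    for line in lines:
        if not any(line_of[s] == line for s in lognorm.columns):
            raise ValueError(f"cell line {line} has no expression sample")
    genes = list(gene_set) if gene_set is not None else lognorm.index.tolist()
    missing = [g for g in genes if g not in lognorm.index]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing}")

    cols_by_line = {
        line: [s for s in lognorm.columns if line_of[s] == line] for line in lines
    }
    per_line = pd.DataFrame(
        {line: lognorm.loc[genes, cols].mean(axis=1) for line, cols in cols_by_line.items()}
    )
    rank_vec = np.array([float(ranks[line]) for line in lines])

    if p_method == "auto":
        p_method = "exact" if len(lines) <= _EXACT_MAX_N else "t_approx"

    records = []
    for gene in genes:
        expr = per_line.loc[gene, lines].to_numpy(dtype=float)
        rec = spearman_rho(expr, rank_vec, gene=gene)
        if not rec.degenerate:
            pv = spearman_p(
                rec.estimate, rec.n, method=p_method, n_draws=n_draws, seed=seed
            )
            rec.p, rec.p_method = pv.p, pv.p_method
        row = {
            "gene": gene,
            "method": rec.method,
            "estimate": rec.estimate,
            "n": rec.n,
            "sum_sq_rank_diff": rec.sum_sq_rank_diff,
            "p": rec.p,
            "p_method": rec.p_method,
            "degenerate": rec.degenerate,
        }
        if include_pearson:
            try:
                row["pearson_r"] = pearson_r(expr, rank_vec).estimate
            except ValueError:
                row["pearson_r"] = math.nan
        records.append(row)
    out = pd.DataFrame(records)
    if bh_adjust:
        ok = out["p"].notna().to_numpy()
        adj = np.full(len(out), math.nan)
        if ok.any():
            adj[ok] = stats.false_discovery_control(out.loc[ok, "p"].to_numpy())
        out["p_bh"] = adj
    return out.sort_values("estimate", kind="mergesort").reset_index(drop=True)
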