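"""Dose-response inference and the composite susceptibility score.

The screen asks, per cell line: at which multiplicity of infection (MOI) does
the virus significantly slow growth?  Untreated-normalized AUCs at each MOI
are compared against the untreated condition with a many-to-one Dunnett test.
The line's *rank multiplier* encodes the lowest significant MOI (1 for the
lowest MOI on the grid up to 5 for the highest, 6 if nothing is significant),
and the composite susceptibility score is

    score = (sum of normalized AUCs across MOIs) x rank multiplier,

lowest for the most susceptible line.  Lines are then ranked 1..N by score.

Also provided: a classical one-way ANOVA, a type-III fixed-effects two-way
ANOVA (time x MOI factorial), and Sidak / Tukey / Fisher-LSD pairwise
adjustments used elsewhere in the study design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "AnovaResult",
    "DoseResponseResult",
    "one_way_anova",
    "dunnett_adjusted_p",
    "dunnett_max_abs_t_cdf",
    "lowest_significant_rank",
    "susceptibility_score",
    "rank_cell_lines",
    "two_way_anova_type3",
    "pairwise_adjust",
    "SusceptibilityScorer",
]


class AnovaResult(NamedTuple):
    F: float
    df1: int
    df2: int
    p: float


@dataclass
class DoseResponseResult:
    """Per-cell-line dose-response summary."""

    cell_line: str
    moi_grid: List[float]
    auc_norm_by_moi: Dict[float, float]
    p_adj_by_moi: Dict[float, float]
    rank_multiplier: int
    auc_sum: float
    score: float
    susceptibility_rank: Optional[int] = None


# ---------------------------------------------------------------------------
# one-way ANOVA


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical between/within one-way ANOVA.

    Convention for degenerate input: if both the between- and within-group
    sums of squares are zero (all values identical) the statistic is defined
    as F = 0 with p = 1.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    for g in arrs:
        if g.size < 2:
            raise ValueError("every group needs at least 2 values")
        if not np.all(np.isfinite(g)):
            raise ValueError("non-finite value in ANOVA input")
    all_vals = np.concatenate(arrs)
    grand = all_vals.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in arrs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in arrs)
    df1 = len(arrs) - 1
    df2 = all_vals.size - len(arrs)
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(0.0, df1, df2, 1.0)
        return AnovaResult(math.inf, df1, df2, 0.0)
    F = (ssb / df1) / (ssw / df2)
    return AnovaResult(float(F), df1, df2, float(stats.f.sf(F, df1, df2)))


# ---------------------------------------------------------------------------
# Dunnett many-to-one comparisons


def _chi_nodes(df: float, n_nodes: int = 128):
    """Nodes/weights for integrating against the density of sqrt(chi2_df/df)."""
    lo2, hi2 = stats.chi2.ppf([1e-13, 1.0 - 1e-13], df)
    lo, hi = math.sqrt(lo2 / df), math.sqrt(hi2 / df)
    x, w = leggauss(n_nodes)
    s = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
    # density of s: s^2*df ~ chi2_df  =>  f(s) = chi2.pdf(df s^2, df) * 2 df s
    dens = stats.chi2.pdf(df * s * s, df) * 2.0 * df * s
    return s, 0.5 * (hi - lo) * w * dens


def dunnett_max_abs_t_cdf(
    t: float,
    lambdas: np.ndarray,
    df: float,
    two_sided: bool = True,
    n_nodes_z: int = 96,
    n_nodes_s: int = 128,
) -> float:
    """P(max_j |T_j| <= t) under the joint Dunnett null.

    T_j are many-to-one t statistics sharing the control mean and the pooled
    scale; their correlation structure is rho_ij = lambda_i * lambda_j with
    lambda_j = sqrt(n_j / (n_j + n_0)).  Evaluated by Gauss-Legendre
    quadrature over the shared control variate (weighted by the standard
    normal density) nested in quadrature over the pooled-scale chi
    distribution; ``df=inf`` gives the known-variance (multivariate normal)
    limit.  Absolute accuracy is well below 1e-5 at the default node counts.
    """
    lam = np.asarray(lambdas, dtype=float)
    if t <= 0:
        return 0.0
    comp = np.sqrt(1.0 - lam**2)
    zx, zw = leggauss(n_nodes_z)
    z = 9.0 * zx
    zw = 9.0 * zw * stats.norm.pdf(z)

    def inner(s: np.ndarray) -> np.ndarray:
        # shape: (ns, nz, k)
        s_ = np.asarray(s, dtype=float).reshape(-1, 1, 1)
        z_ = z.reshape(1, -1, 1)
        hi = (t * s_ - lam * z_) / comp
        if two_sided:
            lo = (-t * s_ - lam * z_) / comp
            cell = stats.norm.cdf(hi) - stats.norm.cdf(lo)
        else:
            cell = stats.norm.cdf(hi)
        return (cell.prod(axis=2) * zw).sum(axis=1)

    if not np.isfinite(df):
        return float(np.clip(inner(np.array([1.0]))[0], 0.0, 1.0))
    s_nodes, s_w = _chi_nodes(df, n_nodes_s)
    return float(np.clip((inner(s_nodes) * s_w).sum(), 0.0, 1.0))


def dunnett_adjusted_p(
    control: Sequence[float],
    treatments: Sequence[Sequence[float]],
    two_sided: bool = True,
) -> np.ndarray:
    """Dunnett-adjusted p-value for each treatment versus the shared control.

    p_adj_i = P(max_j |T_j| >= |t_i|) under the joint multivariate-t null.
    With a single treatment this reduces exactly to the pooled two-sample
    t-test.  All groups enter the pooled variance; if that variance is zero
    the p-value is 1 where the observed difference is zero and 0 otherwise.
    """
    c = np.asarray(control, dtype=float)
    trts = [np.asarray(g, dtype=float) for g in treatments]
    if len(trts) == 0:
        raise ValueError("need at least one treatment group")
    groups = [c] + trts
    if any(not np.all(np.isfinite(g)) for g in groups):
        raise ValueError("non-finite value in Dunnett input")
    ns = np.array([g.size for g in groups])
    if np.any(ns < 1):
        raise ValueError("empty group")
    df = int(ns.sum() - len(groups))
    if df < 1:
        raise ValueError("pooled residual df must be >= 1")
    ss = sum(((g - g.mean()) ** 2).sum() for g in groups)
    s2 = ss / df
    diffs = np.array([g.mean() - c.mean() for g in trts])
    if s2 == 0.0:
        return np.where(diffs == 0.0, 1.0, 0.0)
    n0 = ns[0]
    ni = ns[1:]
    se = np.sqrt(s2 * (1.0 / ni + 1.0 / n0))
    tstats = diffs / se
    lam = np.sqrt(ni / (ni + n0))
    out = np.empty(len(trts))
    for i, t in enumerate(tstats):
        out[i] = 1.0 - dunnett_max_abs_t_cdf(
            abs(float(t)), lam, df, two_sided=two_sided
        )
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# scoring


def lowest_significant_rank(
    p_adj_by_moi: Mapping[float, float], alpha: float = 0.05
) -> int:
    """Rank of the lowest MOI with adjusted p <= alpha.

    Ranks run 1 (lowest MOI on the ascending grid) to k (highest, 5 on the
    study's five-MOI grid); k+1 (6) if no MOI is significant.  The threshold
    is inclusive, matching the '*p <= 0.05' convention.
    """
    if not p_adj_by_moi:
        raise ValueError("empty adjusted-p map")
    mois = sorted(float(m) for m in p_adj_by_moi)
    for rank, moi in enumerate(mois, start=1):
        p = float(p_adj_by_moi[moi])
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p value {p} outside [0, 1] at MOI {moi}")
        if p <= alpha:
            return rank
    return len(mois) + 1


def susceptibility_score(
    auc_norm_by_moi: Sequence[float], rank_multiplier: int
) -> float:
    """Composite score: sum of normalized AUCs times the rank multiplier."""
    aucs = np.asarray(auc_norm_by_moi, dtype=float)
    if aucs.size < 1:
        raise ValueError("need at least one AUC value")
    if np.any(aucs < 0):
        raise ValueError("negative normalized AUC")
    if not (isinstance(rank_multiplier, (int, np.integer)) and rank_multiplier >= 1):
        raise ValueError(f"rank multiplier must be a positive integer, got {rank_multiplier}")
    return float(aucs.sum() * rank_multiplier)


def rank_cell_lines(
    scores: Mapping[str, float], auc_sums: Optional[Mapping[str, float]] = None
) -> Dict[str, int]:
    """Rank lines 1..N ascending by score (1 = most susceptible).

    Ties broken by smaller AUC sum, then lexicographic name; the result does
    not depend on input order.
    """
    if not scores:
        raise ValueError("empty score map")
    if any(not np.isfinite(v) for v in scores.values()):
        raise ValueError("non-finite score")
    keys = sorted(
        scores,
        key=lambda k: (
            scores[k],
            auc_sums[k] if auc_sums is not None else 0.0,
            str(k),
        ),
    )
    return {k: i + 1 for i, k in enumerate(keys)}


# ---------------------------------------------------------------------------
# type-III factorial ANOVA


def _sum_to_zero(values: pd.Series, levels: Sequence) -> np.ndarray:
    """Sum-to-zero (deviation) coding: one column per non-reference level."""
    n = len(values)
    cols = np.zeros((n, len(levels) - 1))
    idx = {lev: j for j, lev in enumerate(levels)}
    last = len(levels) - 1
    for i, v in enumerate(values):
        j = idx[v]
        if j == last:
            cols[i, :] = -1.0
        else:
            cols[i, j] = 1.0
    return cols


def two_way_anova_type3(
    data: pd.DataFrame,
    value: str = "value",
    factor_a: str = "time",
    factor_b: str = "moi",
) -> pd.DataFrame:
    """Type-III F tests for two crossed fixed factors and their interaction.

    Fits the full sum-to-zero-contrast linear model and, per effect, compares
    against the model with that effect's columns removed (full-vs-reduced
    residual sums of squares, which with deviation coding yields type-III
    sums of squares).  For complete balanced data this equals the classical
    two-way decomposition.  Degenerate convention: a zero effect SS with zero
    residual variance reports F = 0, p = 1.
    """
    for col in (value, factor_a, factor_b):
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")
    y = data[value].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    la = sorted(data[factor_a].unique().tolist())
    lb = sorted(data[factor_b].unique().tolist())
    if len(la) < 2 or len(lb) < 2:
        raise ValueError("each factor needs at least 2 levels")
    cells = data.groupby([factor_a, factor_b]).size()
    if len(cells) < len(la) * len(lb):
        missing = sorted(
            set((a, b) for a in la for b in lb) - set(cells.index.tolist())
        )
        raise ValueError(f"empty design cells: {missing}")

    A = _sum_to_zero(data[factor_a], la)
    B = _sum_to_zero(data[factor_b], lb)
    AB = np.einsum("ni,nj->nij", A, B).reshape(len(y), -1)
    ones = np.ones((len(y), 1))
    blocks = {"intercept": ones, factor_a: A, factor_b: B, f"{factor_a}:{factor_b}": AB}

    def rss(mats: List[np.ndarray]) -> float:
        X = np.hstack(mats)
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        return float(resid @ resid)

    full_mats = list(blocks.values())
    rss_full = rss(full_mats)
    df_resid = len(y) - sum(m.shape[1] for m in full_mats)
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom (need replication)")
    mse = rss_full / df_resid

    rows = []
    effects = [
        (factor_a, len(la) - 1),
        (factor_b, len(lb) - 1),
        (f"{factor_a}:{factor_b}", (len(la) - 1) * (len(lb) - 1)),
    ]
    for name, df_eff in effects:
        reduced = [m for key, m in blocks.items() if key != name]
        ss = max(rss(reduced) - rss_full, 0.0)
        if mse == 0.0:
            F, p = (0.0, 1.0) if ss <= 1e-12 else (math.inf, 0.0)
        else:
            F = (ss / df_eff) / mse
            p = float(stats.f.sf(F, df_eff, df_resid))
        rows.append({"effect": name, "ss": ss, "df": df_eff, "F": F, "p": p})
    rows.append(
        {"effect": "residual", "ss": rss_full, "df": df_resid, "F": np.nan, "p": np.nan}
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pairwise adjustments


def pairwise_adjust(
    groups: Sequence[Sequence[float]], method: str, alpha: float = 0.05
) -> pd.DataFrame:
    """All-pairs comparisons with a single pooled variance.

    Methods: ``sidak`` (1-(1-p)^m over the m pairs), ``tukey`` (studentized
    range), ``fisher_lsd`` (unadjusted pairwise t).  Returns a tidy frame
    with group indices, the t statistic, raw p and adjusted p.
    """
    if method not in {"sidak", "tukey", "fisher_lsd"}:
        raise ValueError(f"unknown method {method!r}")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrs)
    if k < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([g.size for g in arrs])
    df = int(ns.sum() - k)
    if df < 1:
        raise ValueError("pooled residual df must be >= 1")
    s2 = sum(((g - g.mean()) ** 2).sum() for g in arrs) / df
    m = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = arrs[i].mean() - arrs[j].mean()
            if s2 == 0.0:
                t = 0.0 if diff == 0.0 else math.inf
                p_raw = 1.0 if diff == 0.0 else 0.0
            else:
                t = diff / math.sqrt(s2 * (1.0 / ns[i] + 1.0 / ns[j]))
                p_raw = float(2.0 * stats.t.sf(abs(t), df))
            if method == "sidak":
                p_adj = 1.0 - (1.0 - p_raw) ** m
            elif method == "tukey":
                p_adj = (
                    float(stats.studentized_range.sf(abs(t) * math.sqrt(2.0), k, df))
                    if np.isfinite(t)
                    else 0.0
                )
            else:  # fisher_lsd
                p_adj = p_raw
            rows.append(
                {
                    "group_i": i,
                    "group_j": j,
                    "t": t,
                    "p_raw": p_raw,
                    "p_adj": min(p_adj, 1.0),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# estimator


class SusceptibilityScorer(BaseEstimator):
    """Score and rank cell lines by susceptibility from a tidy AUC table.

    Parameters
    ----------
    alpha : float, default 0.05
        Inclusive significance threshold for the Dunnett-adjusted p-values.
    two_sided : bool, default True
        Sidedness of the many-to-one comparisons.

    ``fit`` expects the output of :func:`oncolysis.kinetics.auc_table`
    (columns cell_line, repeat, moi, auc_norm) with biological repeats as the
    replicate unit.  Fitted attributes:

    results_ : list of :class:`DoseResponseResult`
    scores_ : pandas.Series, score per cell line
    ranks_ : pandas.Series, susceptibility rank (1 = most susceptible)
    """

    def __init__(self, alpha: float = 0.05, two_sided: bool = True):
        self.alpha = alpha
        self.two_sided = two_sided

    def fit(self, auc_df: pd.DataFrame, y=None) -> "SusceptibilityScorer":
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        required = {"cell_line", "repeat", "moi", "auc_norm"}
        missing = required - set(auc_df.columns)
        if missing:
            raise ValueError(f"AUC table missing columns {sorted(missing)}")
        results: List[DoseResponseResult] = []
        for line, sub in auc_df.groupby("cell_line", sort=True):
            mois = sorted(sub["moi"].unique().tolist())
            if 0.0 not in mois:
                raise ValueError(f"{line}: no untreated condition in AUC table")
            treated = [m for m in mois if m > 0]
            if not treated:
                raise ValueError(f"{line}: no treated condition in AUC table")
            control = sub.loc[sub["moi"] == 0.0, "auc_norm"].to_numpy()
            groups = [
                sub.loc[sub["moi"] == m, "auc_norm"].to_numpy() for m in treated
            ]
            p_adj = dunnett_adjusted_p(control, groups, two_sided=self.two_sided)
            p_map = dict(zip(treated, (float(p) for p in p_adj)))
            multiplier = lowest_significant_rank(p_map, alpha=self.alpha)
            means = {m: float(g.mean()) for m, g in zip(treated, groups)}
            auc_sum = float(sum(means.values()))
            score = susceptibility_score(list(means.values()), multiplier)
            results.append(
                DoseResponseResult(
                    cell_line=str(line),
                    moi_grid=mois,
                    auc_norm_by_moi=means,
                    p_adj_by_moi=p_map,
                    rank_multiplier=multiplier,
                    auc_sum=auc_sum,
                    score=score,
                )
            )
        if len(results) < 1:
            raise ValueError("no cell lines in AUC table")
        scores = {r.cell_line: r.score for r in results}
        sums = {r.cell_line: r.auc_sum for r in results}
        ranks = (
            rank_cell_lines(scores, sums)
            if len(results) > 1
            else {results[0].cell_line: 1}
        )
        for r in results:
            r.susceptibility_rank = ranks[r.cell_line]
        self.results_ = results
        self.scores_ = pd.Series(scores, name="score").sort_index()
        self.ranks_ = pd.Series(ranks, name="susceptibility_rank").sort_index()
        return self

    def summary(self) -> pd.DataFrame:
        """Long-format per-line summary of the fitted screen."""
        if not hasattr(self, "results_"):
            raise AttributeError("scorer is not fitted")
        rows = []
        for r in sorted(self.results_, key=lambda r: r.susceptibility_rank):
            row = {
                "cell_line": r.cell_line,
                "susceptibility_rank": r.susceptibility_rank,
                "score": r.score,
                "auc_sum": r.auc_sum,
                "rank_multiplier": r.rank_multiplier,
            }
            for m in sorted(r.auc_norm_by_moi):
                row[f"auc_norm_moi_{m:g}"] = r.auc_norm_by_moi[m]
                row[f"p_adj_moi_{m:g}"] = r.p_adj_by_moi[m]
            rows.append(row)
        return pd.DataFrame(rows)
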