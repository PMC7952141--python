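"""Statistical battery over measurement-record tables.

Covers the three study questions: (1) clustered group comparisons of
signal quality across glottal-parameter levels (fixed GGI intervals or
exact 1-D k-means; Kruskal-Wallis followed by Bonferroni-corrected
Mann-Whitney U tests), (2) per-larynx Pearson correlation between
subglottal and acoustic parameters plus pooled simple linear
regression, and (3) stepwise multiple linear regression (forward entry
p < 0.05, backward removal p > 0.10) with collinearity and residual
diagnostics.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.base import BaseEstimator, ClusterMixin, RegressorMixin
from statsmodels.stats.diagnostic import het_breuschpagan, lilliefors
from statsmodels.stats.stattools import durbin_watson

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterAssignment",
    "GroupComparisonResult",
    "CorrelationSummary",
    "RegressionResult",
    "StepwiseStep",
    "StepwiseResult",
    "KMeans1D",
    "StepwiseOLS",
    "assign_ggi_groups",
    "cluster_1d",
    "normality_screen",
    "compare_groups",
    "correlate_by_larynx",
    "simple_linreg",
    "stepwise_regression",
    "diagnostics",
]

KW_ALPHA = 0.05
PAIRWISE_ALPHA = 0.05 / 3  # Bonferroni over the 3 pairs; reported rounded to 0.017
COLLINEARITY_ADVISORY = 0.65
GGI_INTERVAL_EDGES = (0.01, 0.4)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    """Per-record low/medium/high grouping of one parameter."""

    parameter: str
    labels: np.ndarray          # 1 = low, 2 = medium, 3 = high; -1 for missing
    centers: np.ndarray
    method: str                 # "fixed_ggi_intervals" | "kmeans_1d"

    def __post_init__(self) -> None:
        present = self.labels[self.labels > 0]
        if present.size and not set(np.unique(present)) <= {1, 2, 3}:
            raise ValueError("labels must be in {1, 2, 3}")


def assign_ggi_groups(ggi: Sequence[float], parameter: str = "ggi") -> ClusterAssignment:
    """Fixed GGI intervals: group 1 = [0, 0.01] (entire closure during
    vibration), group 2 = (0.01, 0.4) (partial closure), group 3 =
    [0.4, 1] (no vocal-fold contact).  NaN values get label -1."""
    v = np.asarray(ggi, dtype=float)
    finite = v[~np.isnan(v)]
    if np.any((finite < 0) | (finite > 1)):
        raise ValueError("GGI values must lie in [0, 1]")
    lo, hi = GGI_INTERVAL_EDGES
    labels = np.full(v.size, -1, dtype=int)
    ok = ~np.isnan(v)
    labels[ok & (v <= lo)] = 1
    labels[ok & (v > lo) & (v < hi)] = 2
    labels[ok & (v >= hi)] = 3
    centers = np.array(
        [v[labels == g].mean() if np.any(labels == g) else np.nan for g in (1, 2, 3)]
    )
    return ClusterAssignment(parameter=parameter, labels=labels, centers=centers,
                             method="fixed_ggi_intervals")


class KMeans1D(BaseEstimator, ClusterMixin):
    """Globally optimal 1-D k-means by dynamic programming.

    Optimal clusters of sorted scalars are contiguous, so the within-
    cluster sum of squares can be minimized exactly with a DP over
    prefix sums — no seeds, no restarts, fully reproducible.  Follows
    the scikit-learn clusterer protocol: ``fit(X)`` sets ``labels_``
    (0-based, ordered by center) and ``cluster_centers_``.
    """

    def __init__(self, n_clusters: int = 3):
        self.n_clusters = n_clusters

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        k = self.n_clusters
        if np.unique(x).size < k:
            raise ValueError(f"need at least {k} distinct values")
        order = np.argsort(x, kind="stable")
        xs = x[order]
        n = xs.size
        ps = np.concatenate(([0.0], np.cumsum(xs)))
        ps2 = np.concatenate(([0.0], np.cumsum(xs**2)))

        def sse(i: int, j: int) -> float:
            # within-cluster SS of xs[i:j]
            s, s2, m = ps[j] - ps[i], ps2[j] - ps2[i], j - i
            return s2 - s * s / m

        cost = np.full((k + 1, n + 1), np.inf)
        split = np.zeros((k + 1, n + 1), dtype=int)
        cost[0, 0] = 0.0
        for c in range(1, k + 1):
            for j in range(c, n + 1):
                best, arg = np.inf, c - 1
                for i in range(c - 1, j):
                    v = cost[c - 1, i] + sse(i, j)
                    if v < best - 1e-15:
                        best, arg = v, i
                cost[c, j] = best
                split[c, j] = arg
        bounds = [n]
        for c in range(k, 0, -1):
            bounds.append(split[c, bounds[-1]])
        bounds = bounds[::-1]
        labels_sorted = np.empty(n, dtype=int)
        centers = np.empty(k)
        for c in range(k):
            i, j = bounds[c], bounds[c + 1]
            labels_sorted[i:j] = c
            centers[c] = xs[i:j].mean()
        labels = np.empty(n, dtype=int)
        labels[order] = labels_sorted
        self.labels_ = labels
        self.cluster_centers_ = centers
        self.inertia_ = float(cost[k, n])
        return self

    def predict(self, X) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "cluster_centers_")
        x = np.asarray(X, dtype=float).ravel()
        return np.argmin(np.abs(x[:, None] - self.cluster_centers_[None, :]), axis=1)


def cluster_1d(values: Sequence[float], k: int = 3, parameter: str = "") -> ClusterAssignment:
    """Exact 1-D k-means grouping; labels 1..k ordered by center value
    (1 = low).  NaN values get label -1."""
    v = np.asarray(values, dtype=float)
    ok = ~np.isnan(v)
    km = KMeans1D(n_clusters=k).fit(v[ok])
    labels = np.full(v.size, -1, dtype=int)
    labels[ok] = km.labels_ + 1
    return ClusterAssignment(parameter=parameter, labels=labels,
                             centers=km.cluster_centers_, method="kmeans_1d")


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

@dataclass
class GroupComparisonResult:
    kw_h: float
    kw_p: float
    kw_significant: bool
    pairwise: Dict[Tuple[int, int], Tuple[float, float, bool]] = field(default_factory=dict)
    alpha_kw: float = KW_ALPHA
    alpha_pairwise: float = PAIRWISE_ALPHA


def normality_screen(values: Sequence[float]) -> Tuple[float, float, bool]:
    """Lilliefors-corrected Kolmogorov-Smirnov screen against a normal
    with estimated mean/sd.  Returns (statistic, p, normal?); a constant
    sample is flagged degenerate (not normal, p = 0)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 8:
        raise ValueError("normality screen needs n >= 8")
    if np.ptp(v) == 0:
        warnings.warn("constant sample: degenerate, flagged not normal")
        return math.nan, 0.0, False
    stat, p = lilliefors(v, dist="norm")
    return float(stat), float(p), bool(p > 0.05)


def _mwu(a: np.ndarray, b: np.ndarray) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U: exact distribution for small tie-free
    samples, normal approximation with tie correction otherwise."""
    exact = a.size <= 20 and b.size <= 20 and np.unique(np.concatenate([a, b])).size == a.size + b.size
    res = sstats.mannwhitneyu(a, b, alternative="two-sided",
                              method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)


def compare_groups(values: Sequence[float], groups: Sequence[int]) -> GroupComparisonResult:
    """Kruskal-Wallis over 3 groups at alpha = 0.05; when significant,
    all pairwise Mann-Whitney U tests flagged at the Bonferroni level
    0.05/3 (printed as 0.017)."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    ok = ~np.isnan(v) & (g > 0)
    v, g = v[ok], g[ok]
    ids = np.unique(g)
    if ids.size != 3:
        raise ValueError(f"expected 3 groups, got {ids.size}")
    samples = [v[g == i] for i in ids]
    if any(s.size < 2 for s in samples):
        raise ValueError("every group needs n >= 2")
    if all(np.ptp(np.concatenate(samples)) == 0 for _ in (0,)):
        h, p = 0.0, 1.0
    else:
        h, p = sstats.kruskal(*samples)
    result = GroupComparisonResult(kw_h=float(h), kw_p=float(p),
                                   kw_significant=bool(p < KW_ALPHA))
    if result.kw_significant:
        for i in range(3):
            for j in range(i + 1, 3):
                u, pu = _mwu(samples[i], samples[j])
                result.pairwise[(int(ids[i]), int(ids[j]))] = (u, pu, bool(pu < PAIRWISE_ALPHA))
    return result


# ---------------------------------------------------------------------------
# Correlation and regression
# ---------------------------------------------------------------------------

@dataclass
class CorrelationSummary:
    mean_r: float
    sd_r: float
    min_r: float
    max_r: float
    per_larynx_r: Dict[str, float]
    per_larynx_n: Dict[str, int]


def correlate_by_larynx(
    x: Sequence[float],
    y: Sequence[float],
    larynx: Sequence[str],
    fisher_z: bool = False,
) -> CorrelationSummary:
    """Pearson r per larynx, then averaged across larynges (unweighted;
    optionally via the Fisher z transform).  Zero-variance larynges are
    skipped with a warning."""
    df = pd.DataFrame({"x": x, "y": y, "lid": larynx}).dropna(subset=["x", "y"])
    per_r: Dict[str, float] = {}
    per_n: Dict[str, int] = {}
    for lid, sub in df.groupby("lid", sort=True):
        if len(sub) < 3:
            warnings.warn(f"larynx {lid}: n < 3, skipped")
            continue
        if sub["x"].std() == 0 or sub["y"].std() == 0:
            warnings.warn(f"larynx {lid}: zero variance, skipped")
            continue
        r, _ = sstats.pearsonr(sub["x"], sub["y"])
        per_r[str(lid)] = float(r)
        per_n[str(lid)] = int(len(sub))
    if not per_r:
        raise ValueError("no larynx had enough usable data")
    rs = np.array(list(per_r.values()))
    if fisher_z:
        mean_r = float(np.tanh(np.mean(np.arctanh(np.clip(rs, -0.999999, 0.999999)))))
    else:
        mean_r = float(np.mean(rs))
    sd = float(np.std(rs, ddof=1)) if rs.size > 1 else 0.0
    return CorrelationSummary(mean_r=mean_r, sd_r=sd, min_r=float(rs.min()),
                              max_r=float(rs.max()), per_larynx_r=per_r, per_larynx_n=per_n)


@dataclass
class RegressionResult:
    r2: float
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    f_stat: float
    df: Tuple[int, int]
    p_value: float
    n: int


def simple_linreg(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on a single predictor x."""
    import statsmodels.api as sm

    df = pd.DataFrame({"x": x, "y": y}).dropna()
    n = len(df)
    if n < 3:
        raise ValueError("simple regression needs n >= 3")
    if df["x"].std() == 0:
        raise ValueError("zero-variance predictor")
    model = sm.OLS(df["y"], sm.add_constant(df["x"])).fit()
    return RegressionResult(
        r2=float(model.rsquared),
        slope=float(model.params["x"]),
        intercept=float(model.params["const"]),
        slope_se=float(model.bse["x"]),
        intercept_se=float(model.bse["const"]),
        f_stat=float(model.fvalue),
        df=(int(model.df_model), int(model.df_resid)),
        p_value=float(model.f_pvalue),
        n=n,
    )


# ---------------------------------------------------------------------------
# Stepwise multiple regression
# ---------------------------------------------------------------------------

@dataclass
class StepwiseStep:
    action: str                  # "add" | "remove"
    variable: str
    adj_r2: float
    delta_adj_r2: float
    f_stat: float
    df: Tuple[int, int]
    p_value: float


@dataclass
class DiagnosticsReport:
    max_abs_corr: float
    collinearity_flag: bool
    corr_matrix: Optional[pd.DataFrame]
    resid_normal_p: float
    resid_normal: bool
    bp_p: float
    homoscedastic: bool
    durbin_watson: float


@dataclass
class StepwiseResult:
    steps: List[StepwiseStep]
    selected: List[str]
    adj_r2: float
    p_enter: float
    p_remove: float
    final_params: pd.Series
    final_pvalues: pd.Series
    diagnostics: Optional[DiagnosticsReport] = None


def _design(df: pd.DataFrame, variables: Sequence[str], blocks: Dict[str, List[str]]) -> np.ndarray:
    cols = [np.ones(len(df))]
    for v in variables:
        for c in blocks[v]:
            cols.append(df[c].to_numpy(float))
    return np.column_stack(cols)


def _rss(Xd: np.ndarray, y: np.ndarray) -> Tuple[float, int]:
    beta, res, rank, _ = np.linalg.lstsq(Xd, y, rcond=None)
    if rank < Xd.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design")
    resid = y - Xd @ beta
    return float(resid @ resid), rank


class StepwiseOLS(BaseEstimator, RegressorMixin):
    """Stepwise multiple linear regression (forward entry / backward
    removal by partial-F p-values).

    Candidates are columns of a DataFrame; categorical columns (e.g. the
    larynx identifier) enter and leave as a single indicator block, so a
    specimen label counts as one candidate.  Each iteration first adds
    the candidate with the smallest partial-F p below ``p_enter`` (ties
    broken by larger adjusted-R^2 gain, then lexicographic name), then
    removes included variables whose partial-F p exceeds ``p_remove``
    (largest first).  Selection stops when no change occurs.  Perfectly
    collinear candidates are skipped with a warning.
    """

    def __init__(self, p_enter: float = 0.05, p_remove: float = 0.10):
        self.p_enter = p_enter
        self.p_remove = p_remove

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X).reset_index(drop=True)
        y = np.asarray(y, dtype=float)
        ok = ~np.isnan(y) & ~X.isna().any(axis=1).to_numpy()
        X, y = X.loc[ok].reset_index(drop=True), y[ok]
        n = len(X)
        if n < 10 + X.shape[1]:
            raise ValueError("need n >= 10 + number of candidate variables")

        # expand categoricals into indicator blocks
        blocks: Dict[str, List[str]] = {}
        data = pd.DataFrame(index=X.index)
        for col in X.columns:
            if X[col].dtype == object or isinstance(X[col].dtype, pd.CategoricalDtype):
                dummies = pd.get_dummies(X[col], prefix=col, drop_first=True).astype(float)
                blocks[col] = list(dummies.columns)
                data = pd.concat([data, dummies], axis=1)
            else:
                blocks[col] = [col]
                data[col] = X[col].astype(float)

        included: List[str] = []
        steps: List[StepwiseStep] = []
        tss = float(np.sum((y - y.mean()) ** 2))

        def adj_r2_of(variables: Sequence[str]) -> float:
            Xd = _design(data, variables, blocks)
            rss, rank = _rss(Xd, y)
            dfr = n - rank
            if dfr <= 0 or tss == 0:
                return 1.0
            return 1.0 - (rss / dfr) / (tss / (n - 1))

        def partial_f(base: List[str], extra: str) -> Tuple[float, float, Tuple[int, int]]:
            """F test of adding ``extra`` to ``base``."""
            X0 = _design(data, base, blocks)
            rss0, rank0 = _rss(X0, y)
            X1 = _design(data, base + [extra], blocks)
            rss1, rank1 = _rss(X1, y)
            q = rank1 - rank0
            dfr = n - rank1
            if q <= 0 or dfr <= 0 or rss1 <= 0:
                return math.inf, 0.0, (max(q, 1), max(dfr, 1))
            f = ((rss0 - rss1) / q) / (rss1 / dfr)
            return f, float(sstats.f.sf(f, q, dfr)), (q, dfr)

        current_adj = 0.0
        while True:
            changed = False
            # forward step
            best = None
            for cand in sorted(set(X.columns) - set(included)):
                try:
                    f, p, dfs = partial_f(included, cand)
                    gain = adj_r2_of(included + [cand]) - current_adj
                except np.linalg.LinAlgError:
                    warnings.warn(f"candidate {cand!r} perfectly collinear; skipped")
                    continue
                if p < self.p_enter:
                    key = (p, -gain, cand)
                    if best is None or key < best[0]:
                        best = (key, cand, f, p, dfs, gain)
            if best is not None:
                _, cand, f, p, dfs, gain = best
                included.append(cand)
                current_adj += gain
                steps.append(StepwiseStep("add", cand, current_adj, gain, f, dfs, p))
                changed = True
            # backward step(s)
            while len(included) > 1 or (included and not changed):
                worst = None
                for v in included:
                    base = [w for w in included if w != v]
                    try:
                        f, p, dfs = partial_f(base, v)
                    except np.linalg.LinAlgError:
                        continue
                    if p > self.p_remove and (worst is None or p > worst[2]):
                        worst = (v, f, p, dfs)
                if worst is None:
                    break
                v, f, p, dfs = worst
                included.remove(v)
                new_adj = adj_r2_of(included) if included else 0.0
                steps.append(StepwiseStep("remove", v, new_adj, new_adj - current_adj, f, dfs, p))
                current_adj = new_adj
                changed = True
            if not changed:
                break

        self.steps_ = steps
        self.selected_ = list(included)
        self.blocks_ = blocks
        self._data = data
        self._y = y
        if included:
            import statsmodels.api as sm

            cols = [c for v in included for c in blocks[v]]
            final = sm.OLS(y, sm.add_constant(data[cols].to_numpy(float))).fit()
            names = ["const"] + cols
            self.model_ = final
            self.final_params_ = pd.Series(final.params, index=names)
            self.final_pvalues_ = pd.Series(final.pvalues, index=names)
            self.adj_r2_ = float(final.rsquared_adj)
        else:
            self.model_ = None
            self.final_params_ = pd.Series({"const": float(np.mean(y))})
            self.final_pvalues_ = pd.Series({"const": math.nan})
            self.adj_r2_ = 0.0
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "selected_")
        X = pd.DataFrame(X)
        out = np.full(len(X), float(self.final_params_["const"]))
        for v in self.selected_:
            for c in self.blocks_[v]:
                if c in X.columns:
                    col = X[c].to_numpy(float)
                else:  # rebuild indicator from the categorical source column
                    src, _, level = c.partition("_")
                    col = (X[src].astype(str) == level).to_numpy(float)
                out += self.final_params_[c] * col
        return out

    def result(self, with_diagnostics: bool = True) -> StepwiseResult:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "selected_")
        diag = None
        if with_diagnostics and self.model_ is not None:
            numeric = [c for v in self.selected_ for c in self.blocks_[v]]
            diag = diagnostics(self.model_, self._data[numeric])
        return StepwiseResult(
            steps=list(self.steps_), selected=list(self.selected_),
            adj_r2=self.adj_r2_, p_enter=self.p_enter, p_remove=self.p_remove,
            final_params=self.final_params_, final_pvalues=self.final_pvalues_,
            diagnostics=diag,
        )


def stepwise_regression(
    y: Sequence[float],
    X: pd.DataFrame,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    with_diagnostics: bool = True,
) -> StepwiseResult:
    """Functional wrapper over :class:`StepwiseOLS`."""
    est = StepwiseOLS(p_enter=p_enter, p_remove=p_remove).fit(X, y)
    return est.result(with_diagnostics=with_diagnostics)


def diagnostics(
    model,
    predictors: Optional[pd.DataFrame] = None,
    plot_path: Optional[str] = None,
) -> DiagnosticsReport:
    """Model-assumption checks for a fitted OLS model: max pairwise
    predictor |r| against a 0.65 advisory threshold, Lilliefors residual
    normality, Breusch-Pagan homoscedasticity, and the Durbin-Watson
    statistic for residual independence.  ``plot_path`` additionally
    writes residual-vs-fitted and QQ panels."""
    resid = np.asarray(model.resid, dtype=float)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from scipy import stats as _ss

        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3.2))
        ax1.scatter(model.fittedvalues, resid, s=8, alpha=0.6)
        ax1.axhline(0.0, color="k", lw=0.8)
        ax1.set_xlabel("fitted")
        ax1.set_ylabel("residual")
        _ss.probplot(resid, dist="norm", plot=ax2)
        ax2.set_title("residual QQ")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=110)
        plt.close(fig)
    exog = np.asarray(model.model.exog, dtype=float)
    max_r = 0.0
    corr = None
    if predictors is not None and predictors.shape[1] >= 2:
        corr = predictors.corr()
        off = corr.to_numpy().copy()
        np.fill_diagonal(off, 0.0)
        max_r = float(np.nanmax(np.abs(off)))
    if resid.size >= 8 and np.ptp(resid) > 0:
        _, pn = lilliefors(resid, dist="norm")
    else:
        pn = math.nan
    try:
        _, bp_p, _, _ = het_breuschpagan(resid, exog)
    except (np.linalg.LinAlgError, ValueError):
        bp_p = math.nan
    return DiagnosticsReport(
        max_abs_corr=max_r,
        collinearity_flag=bool(max_r > COLLINEARITY_ADVISORY),
        corr_matrix=corr,
        resid_normal_p=float(pn) if not math.isnan(pn) else math.nan,
        resid_normal=bool(pn > 0.05) if not math.isnan(pn) else False,
        bp_p=float(bp_p) if not math.isnan(bp_p) else math.nan,
        homoscedastic=bool(bp_p > 0.05) if not math.isnan(bp_p) else False,
        durbin_watson=float(durbin_watson(resid)),
    )
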