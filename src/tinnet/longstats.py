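"""Longitudinal statistics linking network measures to clinical scores.

Paired session t-tests on TFI, correlations of consecutive-session
changes in global graph measures with TFI changes (parametric and
subject-permutation p-values, Holm FWER across the density grid),
nodal two-sample comparisons with Benjamini-Hochberg control, OLS of
score changes on graph-measure changes, and kernel-density summaries of
sliding-window metric series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import SESSIONS, ScoreTable

_NORM_GUARD = 1e-8


@dataclass
class PairedTResult:
    t: float | None
    df: int
    p: float | None
    n_pairs: int
    mean_diff: float
    degenerate: bool = False


def paired_t(values_a: Sequence[float], values_b: Sequence[float]) -> PairedTResult:
    """Classical paired t on complete pairs (listwise deletion).

    Pairs with either side missing (NaN) are dropped; df = n_pairs - 1.
    Zero-variance differences are reported degenerate rather than as an
    infinite t.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    d = a[ok] - b[ok]
    n = d.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    sd = d.std(ddof=1)
    mean = float(d.mean())
    if sd == 0:
        if mean == 0:
            return PairedTResult(t=0.0, df=n - 1, p=1.0, n_pairs=n,
                                 mean_diff=0.0)
        return PairedTResult(t=None, df=n - 1, p=None, n_pairs=n,
                             mean_diff=mean, degenerate=True)
    t = mean / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    return PairedTResult(t=float(t), df=n - 1, p=float(p), n_pairs=n,
                         mean_diff=mean)


def build_delta_records(metrics: pd.DataFrame, scores: ScoreTable,
                        metric: str, density: float,
                        pairs: Sequence[tuple[str, str]] | None = None,
                        score: str = "TFI") -> pd.DataFrame:
    """Join per-subject consecutive-session changes of a graph metric
    with the matching score changes.

    ``metrics`` is the long-format table from the graph-metric stage
    (columns subject, session, density, metric, node, value). Default
    pairs are the consecutive transitions among sessions present,
    pooled. The normalized change (later - earlier)/|earlier| is
    included, guarded for |earlier| < 1e-8.
    """
    sub = metrics[(metrics.metric == metric)
                  & (np.isclose(metrics.density, density))
                  & ((metrics.node == "") | metrics.node.isna())]
    w = sub.pivot(index="subject", columns="session", values="value")
    present = [s for s in SESSIONS if s in w.columns]
    if pairs is None:
        pairs = list(zip(present[:-1], present[1:]))
    sd = scores.deltas(score=score, pairs=pairs)
    rows = []
    for earlier, later in pairs:
        if earlier not in w.columns or later not in w.columns:
            continue
        both = w[[earlier, later]].dropna()
        for subj, r in both.iterrows():
            match = sd[(sd.subject == subj) & (sd.earlier == earlier)
                       & (sd.later == later)]
            if match.empty:
                continue
            dm = r[later] - r[earlier]
            denom = abs(r[earlier])
            rows.append({
                "subject": subj, "earlier": earlier, "later": later,
                "delta_metric": dm,
                "delta_score": float(match.delta_score.iloc[0]),
                "normalized": dm / denom if denom > _NORM_GUARD else np.nan,
            })
    return pd.DataFrame(rows, columns=["subject", "earlier", "later",
                                       "delta_metric", "delta_score",
                                       "normalized"])


@dataclass
class DeltaCorrelationResult:
    r: float | None
    p_param: float | None
    p_perm: float | None
    n: int
    degenerate: bool = False


def delta_correlation(delta_metric: Sequence[float],
                      delta_score: Sequence[float],
                      n_perm: int = 9999, seed: int = 0,
                      method: str = "pearson") -> DeltaCorrelationResult:
    """Correlation between metric changes and score changes.

    Pearson by default (Spearman via ``method``); two-sided parametric
    p plus a subject-label permutation p (sampled, two-sided on |r|).
    """
    x = np.asarray(delta_metric, dtype=float)
    y = np.asarray(delta_score, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 complete delta pairs")
    if x.std() == 0 or y.std() == 0:
        return DeltaCorrelationResult(None, None, None, n, degenerate=True)
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ValueError("method must be 'pearson' or 'spearman'")
    r, p_param = stats.pearsonr(x, y)
    rng = np.random.default_rng(seed)
    xs = (x - x.mean()) / x.std()
    ys = (y - y.mean()) / y.std()
    perms = rng.permuted(np.tile(ys, (n_perm, 1)), axis=1)
    r_null = perms @ xs / n
    p_perm = (1 + np.sum(np.abs(r_null) >= abs(r) - 1e-12)) / (1 + n_perm)
    return DeltaCorrelationResult(float(r), float(p_param), float(p_perm), n)


def fwer_adjust(pvals: Sequence[float], method: str = "holm") -> np.ndarray:
    """Holm step-down familywise-error adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method != "holm":
        raise ValueError("only the holm method is supported")
    return multipletests(p, method="holm")[1]


def fdr_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def nodal_compare(metrics_a: pd.DataFrame, metrics_b: pd.DataFrame,
                  fdr_q: float = 0.05) -> pd.DataFrame:
    """Per-ROI Welch two-sample t between groups of subjects.

    Inputs are (subject x ROI) frames of a nodal measure. Returns per
    ROI: t, raw p, BH-adjusted p with flags at ``fdr_q``, Holm-adjusted
    p with FWER flags. ROIs with zero variance in both groups are
    reported degenerate (NaN statistics, never flagged).
    """
    rois = list(metrics_a.columns)
    if list(metrics_b.columns) != rois:
        raise ValueError("groups must share the ROI set")
    if len(metrics_a) < 3 or len(metrics_b) < 3:
        raise ValueError("need at least 3 subjects per group")
    t = np.full(len(rois), np.nan)
    p = np.full(len(rois), np.nan)
    degenerate = np.zeros(len(rois), bool)
    for i, roi in enumerate(rois):
        a = metrics_a[roi].dropna().to_numpy()
        b = metrics_b[roi].dropna().to_numpy()
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            degenerate[i] = True
            continue
        t[i], p[i] = stats.ttest_ind(a, b, equal_var=False)
    p_for_adjust = np.where(np.isnan(p), 1.0, p)
    p_bh = fdr_adjust(p_for_adjust)
    p_holm = fwer_adjust(p_for_adjust)
    return pd.DataFrame({
        "node": rois, "t": t, "p_raw": p, "p_bh": p_bh, "p_holm": p_holm,
        "flag_fdr": (p_bh <= fdr_q) & ~degenerate,
        "flag_fwer": (p_holm <= 0.05) & ~degenerate,
        "degenerate": degenerate,
    })


@dataclass
class DeltaRegressionResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    r_squared: float
    df_resid: int
    condition_number: float

    def summary(self) -> str:
        lines = ["OLS of delta score on delta graph measures",
                 f"  R^2 = {self.r_squared:.4f}   df_resid = {self.df_resid}"]
        for name in self.params.index:
            lines.append(f"  {name:>10s}: {self.params[name]: .4f} "
                         f"(SE {self.bse[name]:.4f}, p {self.pvalues[name]:.3g})")
        return "\n".join(lines)


def regress_delta_scores(deltas: pd.DataFrame,
                         predictors: Sequence[str] = ("dQ", "dE_glob",
                                                      "dC_glob")) -> DeltaRegressionResult:
    """OLS of the score change on graph-measure changes with intercept.

    ``deltas`` must contain ``delta_score`` and one column per
    predictor. Collinear designs trigger a condition-number warning and
    a pseudoinverse fit (statsmodels' default behaviour).
    """
    import statsmodels.api as sm

    cols = ["delta_score", *predictors]
    data = deltas[cols].dropna()
    if len(data) < len(predictors) + 2:
        raise ValueError("too few complete cases for the design")
    X = sm.add_constant(data[list(predictors)].to_numpy())
    cond = np.linalg.cond(X)
    if cond > 1e8:
        import warnings

        warnings.warn(f"ill-conditioned design (cond={cond:.3g}); "
                      "coefficients from pseudoinverse", UserWarning,
                      stacklevel=2)
    res = sm.OLS(data["delta_score"].to_numpy(), X).fit()
    names = ["const", *predictors]
    return DeltaRegressionResult(
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        r_squared=float(res.rsquared), df_resid=int(res.df_resid),
        condition_number=float(cond))


@dataclass
class KDEResult:
    grid: np.ndarray | None
    density: np.ndarray | None
    bandwidth: float
    degenerate: bool = False
    spike_at: float | None = None

    def modes(self) -> np.ndarray:
        """Locations of local maxima of the estimated density."""
        d = self.density
        ix = np.where((d[1:-1] > d[:-2]) & (d[1:-1] > d[2:]))[0] + 1
        return self.grid[ix]


def kde_summary(values: Sequence[float], n_grid: int = 256) -> KDEResult:
    """Gaussian KDE with Silverman bandwidth on a 256-point grid
    spanning the data +/- 3 bandwidths; integrates to 1 within 1e-3.

    Constant series are degenerate (a point mass); no KDE is returned.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 10:
        raise ValueError("need at least 10 values")
    if v.std() == 0:
        return KDEResult(None, None, bandwidth=0.0, degenerate=True,
                         spike_at=float(v[0]))
    kde = stats.gaussian_kde(v, bw_method="silverman")
    h = float(kde.factor * v.std(ddof=1))
    grid = np.linspace(v.min() - 3 * h, v.max() + 3 * h, n_grid)
    dens = kde(grid)
    return KDEResult(grid=grid, density=dens, bandwidth=h)


def delta_correlation_table(metrics: pd.DataFrame, scores: ScoreTable,
                            densities: Sequence[float],
                            metric_names: Sequence[str] = ("Q", "C_glob",
                                                           "E_glob"),
                            n_perm: int = 9999, seed: int = 0) -> pd.DataFrame:
    """Delta-correlation table across the density grid with Holm FWER
    applied per metric across densities (the multiplicity the study
    corrected for)."""
    rows = []
    for metric in metric_names:
        per_density = []
        for d in densities:
            rec = build_delta_records(metrics, scores, metric, d)
            res = delta_correlation(rec.delta_metric, rec.delta_score,
                                    n_perm=n_perm, seed=seed)
            per_density.append((d, res))
        raw = [r.p_perm if r.p_perm is not None else 1.0
               for _, r in per_density]
        holm = fwer_adjust(raw)
        for (d, res), ph in zip(per_density, holm):
            rows.append({"analysis": "delta_correlation", "metric": metric,
                         "density": d, "estimate": res.r,
                         "p_param": res.p_param, "p_perm": res.p_perm,
                         "p_holm": float(ph), "n": res.n})
    return pd.DataFrame(rows)
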