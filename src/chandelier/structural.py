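"""Structural-components analysis of perisomatic features.

Six perisomatic features per cell (depth, AIS radius, non-ChC AIS synapse
count, soma synapse density, soma area, soma synapse count) are screened for
pairwise correlation, decomposed into three independent components, and the
chandelier input target is regressed on the component scores with
standardized OLS. Because the scores are mutually uncorrelated, R^2 equals
the sum of squared standardized coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import FastICA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FEATURE_COLUMNS",
    "ComponentModel",
    "RegressionFit",
    "correlation_screen",
    "fit_components",
    "regress_on_components",
    "residual_bootstrap",
    "coefficient_of_variation",
]

FEATURE_COLUMNS = [
    "depth",
    "ais_radius",
    "nonchc_ais_syn_count",
    "soma_syn_density",
    "soma_area",
    "soma_syn_count",
]


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, float)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance column in z-scoring")
    return (x - x.mean(axis=0)) / sd


@dataclass
class ComponentModel:
    """ICA mixing and per-cell scores for the structural features."""

    mixing: np.ndarray  # (n_features, k) loadings on z-scored features
    scores: np.ndarray  # (n_cells, k), mutually uncorrelated
    feature_names: list
    labels: list  # one human-readable label per component

    def score_correlations(self) -> np.ndarray:
        return np.corrcoef(self.scores, rowvar=False)


@dataclass
class RegressionFit:
    """Standardized OLS of a target on component scores."""

    coef: np.ndarray
    conf_int: np.ndarray  # (k, 2) 95% interval per coefficient
    pvalues: np.ndarray
    pvalues_adjusted: np.ndarray  # Holm-Sidak over the k coefficients
    r_squared: float


def correlation_screen(features: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with Holm-Sidak-adjusted p-values.

    Returns (r, p_adjusted) as symmetric DataFrames with unit diagonal /
    zero diagonal. The multiple-testing family is the off-diagonal upper
    triangle of the matrix.
    """
    if len(features) < 3:
        raise ValueError("need n >= 3 rows")
    cols = list(features.columns)
    X = features.to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError(
            f"zero-variance feature(s): {[c for c, s in zip(cols, sd) if s == 0]}"
        )
    m = len(cols)
    r = np.eye(m)
    pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
    raw = []
    for i, j in pairs:
        res = stats.pearsonr(X[:, i], X[:, j])
        r[i, j] = r[j, i] = res.statistic
        raw.append(res.pvalue)
    adj = multipletests(raw, method="holm-sidak")[1] if pairs else []
    padj = np.zeros((m, m))
    for (i, j), p_a in zip(pairs, adj):
        padj[i, j] = padj[j, i] = p_a
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(padj, index=cols, columns=cols),
    )


def _match_components(ref: np.ndarray, other: np.ndarray) -> float:
    """Mean absolute loading difference after sign/permutation matching."""
    k = ref.shape[1]
    cost = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            cost[i, j] = min(
                np.abs(ref[:, i] - other[:, j]).mean(),
                np.abs(ref[:, i] + other[:, j]).mean(),
            )
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].mean())


def fit_components(
    features: pd.DataFrame,
    k: int = 3,
    restarts: int = 50,
    seed: int = 0,
    fun: str = "logcosh",
    max_iter: int = 1000,
    tol: float = 1e-4,
) -> ComponentModel:
    """Fit a k-component ICA to z-scored features, selecting a robust run.

    FastICA is stochastic, so it is restarted ``restarts`` times and the
    solution minimizing the mean pairwise dissimilarity to the other
    restarts is returned (dissimilarity = mean absolute loading difference
    after Hungarian sign/permutation matching). Each component is oriented
    so its largest-magnitude loading is positive.
    """
    if len(features) <= features.shape[1]:
        raise ValueError("need more observations than features")
    X = _zscore(features.to_numpy(float))
    rng = np.random.default_rng(seed)
    solutions = []
    for _ in range(restarts):
        ica = FastICA(
            n_components=k,
            whiten="unit-variance",
            fun=fun,
            max_iter=max_iter,
            tol=tol,
            random_state=int(rng.integers(2**31 - 1)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                scores = ica.fit_transform(X)
            except Exception:
                continue
        # keep oscillating (max-iter) runs too: the robustness selection
        # below is what picks the stable solution among restarts
        solutions.append((ica.mixing_.copy(), scores))
    if not solutions:
        raise RuntimeError("FastICA failed in every restart")
    if len(solutions) == 1:
        best = 0
    else:
        dissim = np.zeros(len(solutions))
        for i, (mix_i, _) in enumerate(solutions):
            d = [
                _match_components(mix_i, mix_j)
                for j, (mix_j, _) in enumerate(solutions)
                if j != i
            ]
            dissim[i] = np.mean(d)
        best = int(np.argmin(dissim))
    mixing, scores = solutions[best]
    # sign convention: largest-magnitude loading positive
    for j in range(k):
        top = np.argmax(np.abs(mixing[:, j]))
        if mixing[top, j] < 0:
            mixing[:, j] *= -1
            scores[:, j] *= -1
    labels = [
        f"component_{j}:{features.columns[np.argmax(np.abs(mixing[:, j]))]}"
        for j in range(k)
    ]
    return ComponentModel(mixing, scores, list(features.columns), labels)


def regress_on_components(target, scores) -> RegressionFit:
    """Standardized OLS of a target on (uncorrelated) component scores.

    Target and scores are z-scored before fitting, so coefficients are in
    SD units. 95% confidence intervals follow the usual OLS normal-theory
    formula; the k coefficient p-values are Holm-Sidak adjusted as one
    family.
    """
    y = _zscore(np.asarray(target, float).reshape(-1, 1)).ravel()
    S = _zscore(np.asarray(scores, float))
    if not np.all(np.isfinite(y)):
        raise ValueError("target contains non-finite values")
    if np.linalg.cond(S.T @ S) > 1e8:
        raise ValueError("component scores are collinear")
    model = sm.OLS(y, sm.add_constant(S)).fit()
    coef = model.params[1:]
    ci = model.conf_int(alpha=0.05)[1:]
    pvals = model.pvalues[1:]
    padj = multipletests(pvals, method="holm-sidak")[1]
    return RegressionFit(
        coef=np.asarray(coef),
        conf_int=np.asarray(ci),
        pvalues=np.asarray(pvals),
        pvalues_adjusted=padj,
        r_squared=float(model.rsquared),
    )


def residual_bootstrap(
    target,
    scores,
    focal: int,
    n_boot: int = 1000,
    seed: int = 0,
    grid_size: int = 50,
):
    """Residual scatter against one component with a bootstrap CI band.

    The target is regressed on the non-focal components; the residual is
    plotted against the focal component with a line fit. The 95% band is
    the percentile interval of line fits over ``n_boot`` resamples of cells.

    Returns a dict with keys ``x`` (focal scores), ``residual``, ``grid``,
    ``line`` (point-estimate fit on the grid), ``lo``/``hi`` (band).
    """
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable confidence bands")
    y = _zscore(np.asarray(target, float).reshape(-1, 1)).ravel()
    S = _zscore(np.asarray(scores, float))
    k = S.shape[1]
    others = [j for j in range(k) if j != focal]
    X_other = sm.add_constant(S[:, others])
    resid = sm.OLS(y, X_other).fit().resid
    x = S[:, focal]
    grid = np.linspace(x.min(), x.max(), grid_size)
    slope, intercept = np.polyfit(x, resid, 1)
    line = intercept + slope * grid
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, grid_size))
    n = len(y)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        yb, Sb = y[idx], S[idx]
        if np.ptp(Sb[:, focal]) == 0:
            boots[b] = line
            continue
        rb = sm.OLS(yb, sm.add_constant(Sb[:, others])).fit().resid
        sb, ib = np.polyfit(Sb[:, focal], rb, 1)
        boots[b] = ib + sb * grid
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    return {
        "x": x,
        "residual": resid,
        "grid": grid,
        "line": line,
        "lo": lo,
        "hi": hi,
        "slope": slope,
    }


def coefficient_of_variation(values) -> float:
    """Sample SD (n-1 denominator) over sample mean."""
    v = np.asarray(values, float)
    m = v.mean()
    if m == 0:
        raise ValueError("mean is zero; CV undefined")
    if len(v) < 2:
        return 0.0
    return float(v.std(ddof=1) / m)
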