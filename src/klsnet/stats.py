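"""Group-level inference for connectome features.

Covers the statistical layer of the pipeline:

* covariate-adjusted two-group comparison of metric AUCs (linear model
  ``y ~ group + sex + age + education``; the group coefficient's t test),
* Benjamini-Hochberg FDR correction,
* network-based statistics (NBS): edgewise t tests on covariate-residualised
  KLS weights, supra-threshold component formation, and a max-component-size
  permutation null for family-wise error control,
* partial correlation with clinical scores controlling for covariates,
* demographic table tests (Mann-Whitney U / chi-square), and
* the a-priori two-sample t-test power computation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GroupTestResult",
    "NBSComponent",
    "NBSResult",
    "adjusted_group_test",
    "fdr_correct",
    "nbs",
    "partial_correlation",
    "demographic_tests",
    "power_required_n",
    "covariate_design",
]

COVARIATE_COLUMNS = ("sex", "age", "education")


def covariate_design(cov: pd.DataFrame | np.ndarray | None, n: int) -> np.ndarray:
    """Intercept-plus-covariates design matrix; full-rank check is caller's."""
    if cov is None:
        return np.ones((n, 1))
    X = np.asarray(cov, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != n:
        raise ValueError("covariates and data disagree on subject count")
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates contain missing/non-finite values")
    return np.column_stack([np.ones(n), X])


@dataclass
class GroupTestResult:
    metric: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t: float
    p: float
    df: float
    p_fdr: float = float("nan")


def adjusted_group_test(
    y: np.ndarray,
    group: np.ndarray,
    cov: pd.DataFrame | np.ndarray | None = None,
    metric: str = "metric",
) -> GroupTestResult:
    """Two-group comparison of ``y`` adjusting for nuisance covariates.

    Fits ``y ~ 1 + group + cov`` by OLS and reports the group coefficient's
    t statistic and two-sided p value.  With no covariates this reduces to
    the ordinary equal-variance two-sample t test.  ``group`` is binary
    (1 = patients, 0 = controls); reported means/SDs are unadjusted.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(group).astype(float)
    n = y.size
    if g.shape != y.shape:
        raise ValueError("y and group must align")
    if min((g == 1).sum(), (g == 0).sum()) < 3:
        raise ValueError("need at least 3 subjects per group")
    base = covariate_design(cov, n)
    X = np.column_stack([base[:, :1], g, base[:, 1:]])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    import statsmodels.api as sm

    fit = sm.OLS(y, X).fit()
    t = float(fit.tvalues[1])
    p = float(fit.pvalues[1])
    ya, yb = y[g == 1], y[g == 0]
    return GroupTestResult(
        metric=metric,
        mean_a=float(ya.mean()), sd_a=float(ya.std(ddof=1)),
        mean_b=float(yb.mean()), sd_b=float(yb.std(ddof=1)),
        t=t, p=p, df=float(fit.df_resid),
    )


def fdr_correct(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p values must lie in [0, 1]")
    _, adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return adj


# ---------------------------------------------------------------------------
# network-based statistics
# ---------------------------------------------------------------------------

@dataclass
class NBSComponent:
    nodes: tuple[int, ...]
    edges: tuple[tuple[int, int], ...]
    size: int                    # number of edges (the component statistic)
    p_fwe: float


@dataclass
class NBSResult:
    edge_threshold_p: float
    tail: str
    n_perm: int
    components: list[NBSComponent]
    null_max_sizes: np.ndarray = field(repr=False, default=None)
    t_stats: np.ndarray = field(repr=False, default=None)
    seed: int | None = None

    @property
    def significant(self) -> list[NBSComponent]:
        return [c for c in self.components if c.p_fwe < 0.05]


def _edge_t(R: np.ndarray, mask1: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per column (group 1 minus group 0)."""
    n1 = int(mask1.sum())
    n2 = R.shape[0] - n1
    x1, x2 = R[mask1], R[~mask1]
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    ss = ((x1 - m1) ** 2).sum(axis=0) + ((x2 - m2) ** 2).sum(axis=0)
    pooled = ss / (n1 + n2 - 2)
    denom = np.sqrt(pooled * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / denom
    return np.where(denom > 0, t, 0.0)


def _perm_t(R: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Two-sample t for many permuted group assignments at once.

    ``masks`` is (P, S) boolean with a fixed number n1 of True per row.
    Returns (P, E).
    """
    S, _ = R.shape
    n1 = int(masks[0].sum())
    n2 = S - n1
    M = masks.astype(float)
    tot = R.sum(axis=0)
    tot_sq = (R**2).sum(axis=0)
    s1 = M @ R                     # (P, E)
    q1 = M @ (R**2)
    m1 = s1 / n1
    m2 = (tot - s1) / n2
    ss = (q1 - n1 * m1**2) + ((tot_sq - q1) - n2 * m2**2)
    pooled = ss / (S - 2)
    denom = np.sqrt(pooled * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / denom
    return np.where(denom > 0, t, 0.0)


def _components_from_edges(
    n: int, iu: np.ndarray, ju: np.ndarray, supra: np.ndarray
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Connected components of the supra-threshold edge graph.

    Returns a list of (node_index_array, edge_index_array) per component with
    at least one edge.
    """
    idx = np.flatnonzero(supra)
    if idx.size == 0:
        return []
    rows, cols = iu[idx], ju[idx]
    data = np.ones(idx.size)
    G = csr_matrix((data, (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(G, directed=False)
    out = []
    edge_labels = labels[rows]
    for c in range(n_comp):
        e_sel = idx[edge_labels == c]
        if e_sel.size == 0:
            continue
        nodes = np.unique(np.concatenate([iu[e_sel], ju[e_sel]]))
        out.append((nodes, e_sel))
    return out


def _max_component_size(n: int, iu: np.ndarray, ju: np.ndarray, supra: np.ndarray) -> int:
    comps = _components_from_edges(n, iu, ju, supra)
    return max((len(e) for _, e in comps), default=0)


def nbs(
    edge_stack: np.ndarray,
    group: np.ndarray,
    cov: pd.DataFrame | np.ndarray | None = None,
    edge_p: float = 0.001,
    n_perm: int = 5000,
    tail: str = "decrease",
    rng_seed: int = 0,
) -> NBSResult:
    """Network-based statistics on a subjects x n x n weight stack.

    Procedure: covariates are regressed out of every edge across subjects;
    edgewise two-sample t tests (patients minus controls) on the residuals
    form a supra-threshold graph of edges significant at ``edge_p`` in the
    requested tail (``decrease``: patients < controls, one-sided;
    ``increase``: one-sided the other way; ``both``: two-sided).  Connected
    components of that graph are scored by edge count, and family-wise error
    is controlled by comparing each observed component against the maximum
    component size over ``n_perm`` group-label permutations, with the
    (1 + b) / (1 + P) estimator so p is never zero.
    """
    E = np.asarray(edge_stack, dtype=float)
    if E.ndim != 3 or E.shape[1] != E.shape[2]:
        raise ValueError("edge_stack must be (subjects, n, n)")
    S, n, _ = E.shape
    g = np.asarray(group).astype(bool)
    if g.shape != (S,):
        raise ValueError("group must have one label per subject")
    if min(g.sum(), (~g).sum()) < 3:
        raise ValueError("need at least 3 subjects per group")
    if tail not in ("decrease", "increase", "both"):
        raise ValueError("tail must be decrease, increase or both")

    iu, ju = np.triu_indices(n, k=1)
    Y = E[:, iu, ju]                             # (S, n_edges)
    X = covariate_design(cov, S)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ beta

    df = S - 2
    if tail == "both":
        t_crit = sps.t.ppf(1 - edge_p / 2, df)
        supra_fn = lambda t: np.abs(t) > t_crit  # noqa: E731
    elif tail == "decrease":
        t_crit = sps.t.ppf(edge_p, df)
        supra_fn = lambda t: t < t_crit          # noqa: E731
    else:
        t_crit = sps.t.ppf(1 - edge_p, df)
        supra_fn = lambda t: t > t_crit          # noqa: E731

    t_obs = _edge_t(R, g)
    comps = _components_from_edges(n, iu, ju, supra_fn(t_obs))
    if not comps:
        logger.warning("no edge survives p < %g in tail %r", edge_p, tail)

    rng = np.random.default_rng(rng_seed)
    n1 = int(g.sum())
    masks = np.zeros((n_perm, S), dtype=bool)
    for p_i in range(n_perm):
        masks[p_i, rng.permutation(S)[:n1]] = True
    # chunk the permutation t computation to bound memory on large edge sets
    null_max = np.empty(n_perm, dtype=int)
    chunk = max(1, int(2e7 // max(Y.shape[1], 1)))
    for start in range(0, n_perm, chunk):
        T = _perm_t(R, masks[start:start + chunk])
        Sup = supra_fn(T)
        for k in range(T.shape[0]):
            null_max[start + k] = _max_component_size(n, iu, ju, Sup[k])

    components = []
    for nodes, e_idx in comps:
        size = int(e_idx.size)
        b = int((null_max >= size).sum())
        p_fwe = (1 + b) / (1 + n_perm)
        edges = tuple((int(iu[e]), int(ju[e])) for e in e_idx)
        components.append(
            NBSComponent(tuple(int(v) for v in nodes), edges, size, p_fwe)
        )
    components.sort(key=lambda c: -c.size)
    return NBSResult(
        edge_threshold_p=edge_p, tail=tail, n_perm=n_perm,
        components=components, null_max_sizes=null_max, t_stats=t_obs,
        seed=rng_seed,
    )


# ---------------------------------------------------------------------------
# partial correlation, demographics, power
# ---------------------------------------------------------------------------

def partial_correlation(
    x: np.ndarray, y: np.ndarray, cov: pd.DataFrame | np.ndarray | None
) -> tuple[float, float]:
    """Pearson correlation of covariate residuals, with a t-based p value.

    Both vectors are residualised on the covariates (plus intercept); the
    p value uses df = n - 2 - k where k is the number of covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must align")
    if n < 6:
        raise ValueError("need at least 6 subjects")
    X = covariate_design(cov, n)
    k = X.shape[1] - 1
    H = X @ np.linalg.lstsq(X, np.column_stack([x, y]), rcond=None)[0]
    rx = x - H[:, 0]
    ry = y - H[:, 1]
    sx, sy = rx.std(), ry.std()
    tol_x = 1e-10 * max(1.0, float(np.abs(x).max()))
    tol_y = 1e-10 * max(1.0, float(np.abs(y).max()))
    if sx <= tol_x or sy <= tol_y:
        raise ValueError("zero residual variance after covariate adjustment")
    r = float(np.dot(rx - rx.mean(), ry - ry.mean()) / (n * sx * sy))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1 - r**2))
    p = float(2 * sps.t.sf(abs(t), df))
    return r, p


def demographic_tests(
    table: pd.DataFrame,
    group_col: str = "group",
    categorical: tuple[str, ...] = ("sex",),
) -> pd.DataFrame:
    """Between-group tests for a phenotype table.

    Continuous variables: two-sided Mann-Whitney U.  Categorical variables:
    Pearson chi-square on the contingency table, falling back to Fisher's
    exact test (with a warning) when a category is absent in one group or an
    expected count is below 1.
    """
    if group_col not in table.columns:
        raise ValueError(f"missing group column {group_col!r}")
    groups = table[group_col]
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    rows = []
    for col in table.columns:
        if col == group_col or col.lower() in ("subject_id", "subject"):
            continue
        a = table.loc[groups == levels[0], col].dropna()
        b = table.loc[groups == levels[1], col].dropna()
        if col in categorical:
            ct = pd.crosstab(groups, table[col]).to_numpy()
            if ct.shape[1] < 2 or (ct == 0).any() or (sps.contingency.expected_freq(ct) < 1).any():
                if ct.shape == (2, 2):
                    warnings.warn(f"{col}: sparse table, using Fisher exact")
                    stat, p = sps.fisher_exact(ct)
                    test = "fisher"
                elif ct.shape[1] < 2:
                    stat, p, test = 0.0, 1.0, "chi2"
                else:
                    stat, p, *_ = sps.chi2_contingency(ct, correction=False)
                    test = "chi2"
            else:
                stat, p, *_ = sps.chi2_contingency(ct, correction=False)
                test = "chi2"
        else:
            if a.size == 0 or b.size == 0:
                continue
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
            test = "mannwhitney"
        rows.append((col, test, float(stat), float(p)))
    return pd.DataFrame(rows, columns=["variable", "test", "statistic", "p"])


def power_required_n(
    d: float, alpha: float = 0.05, power: float = 0.8, n_max: int = 100000
) -> int:
    """Smallest per-group n for a two-sided two-sample t test.

    Uses the exact noncentral-t power function with noncentrality
    d * sqrt(n/2) and 2n - 2 degrees of freedom.  For d = 0.80,
    alpha = 0.05 and power 0.8 this gives 26 per group.
    """
    if d <= 0:
        raise ValueError("effect size d must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    for n in range(2, n_max + 1):
        df = 2 * n - 2
        nc = d * np.sqrt(n / 2)
        t_crit = sps.t.ppf(1 - alpha / 2, df)
        achieved = sps.nct.sf(t_crit, df, nc) + sps.nct.cdf(-t_crit, df, nc)
        if achieved >= power:
            return n
    raise ValueError("requested power unreachable within n_max")
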