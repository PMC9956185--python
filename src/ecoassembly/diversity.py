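"""Alpha diversity, group comparisons, Bray-Curtis and NMDS ordination."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

from .io import OTUTable, SampleMetadata, ValidationError
from .matrices import PairwiseMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------


def shannon(abundances) -> float:
    """Shannon diversity H = -sum p_i ln p_i (natural log) over positive entries.

    Scale-invariant: counts and relative proportions give the same value.
    """
    a = np.asarray(abundances, dtype=float)
    if a.ndim != 1:
        raise ValueError("shannon expects a 1-d vector")
    if np.any(a < 0):
        raise ValueError("abundances must be non-negative")
    total = a.sum()
    if total <= 0:
        raise ValueError("shannon undefined for an all-zero vector")
    p = a[a > 0] / total
    return float(-(p * np.log(p)).sum())


def shannon_per_sample(table: OTUTable) -> pd.Series:
    """Shannon index of every sample column, as a Series indexed by sample id."""
    return pd.Series(
        [shannon(table.counts[:, j]) for j in range(table.n_samples)],
        index=table.sample_ids,
        name="shannon",
    )


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------


def bray_curtis(table: OTUTable) -> PairwiseMatrix:
    """Pairwise Bray-Curtis dissimilarity between sample columns.

    BC(A, B) = sum|a_i - b_i| / sum(a_i + b_i); 0 for identical columns and
    1 for disjoint supports.  Computed on the table as given (counts or
    relative proportions).
    """
    sums = table.counts.sum(axis=0)
    zero = np.where(sums <= 0)[0]
    if zero.size:
        raise ValidationError(f"sample {table.sample_ids[zero[0]]!r} has zero total abundance")
    condensed = pdist(table.counts.T, metric="braycurtis")
    values = squareform(condensed)
    np.fill_diagonal(values, 0.0)
    return PairwiseMatrix(list(table.sample_ids), values, "braycurtis")


# ---------------------------------------------------------------------------
# Non-metric multidimensional scaling
# ---------------------------------------------------------------------------


@dataclass
class Ordination:
    """NMDS result: sample coordinates, final Kruskal stress-1 and the
    monotone (raw-stress) trace of the winning restart."""

    labels: list[str]
    coordinates: np.ndarray  # samples x k, column-centered
    stress: float
    converged: bool
    seed: int
    n_restarts: int = 1
    raw_stress_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.stress < 0:
            raise ValueError("stress must be non-negative")
        means = np.abs(self.coordinates.mean(axis=0))
        if means.size and means.max() > 1e-9:
            raise ValueError("coordinates must be column-centered")

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"NMDS{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)


def kruskal_stress(coordinates: np.ndarray, d: PairwiseMatrix) -> float:
    """Kruskal stress-1 of a configuration against a dissimilarity matrix."""
    dist = pdist(coordinates)
    disp = _disparities(dist, _rank_order(d.condensed()))
    denom = float((dist**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dist - disp) ** 2).sum() / denom))


def _rank_order(d_cond: np.ndarray) -> np.ndarray:
    # stable order of dissimilarities; ties keep input order (PAVA handles them)
    return np.argsort(d_cond, kind="stable")


def _disparities(dist: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Monotone (isotonic) regression of configuration distances on the
    dissimilarity rank order: pool-adjacent-violators."""
    fitted = isotonic_regression(dist[order]).x
    disp = np.empty_like(dist)
    disp[order] = fitted
    return disp


def _smacof_single(
    d_cond: np.ndarray,
    n: int,
    k: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
):
    """One nonmetric SMACOF run from a random start.

    Alternates isotonic regression of distances on the dissimilarity ranks
    with a Guttman transform; the raw stress sum((dist - disparity)^2) is
    non-increasing across iterations.
    """
    order = _rank_order(d_cond)
    iu, ju = np.triu_indices(n, k=1)
    x = rng.standard_normal((n, k))
    x -= x.mean(axis=0)
    trace: list[float] = []
    converged = False
    prev = np.inf
    for _ in range(max_iter):
        dist = pdist(x)
        disp = _disparities(dist, order)
        raw = float(((dist - disp) ** 2).sum())
        trace.append(raw)
        if prev - raw < tol * max(prev, 1.0):
            converged = True
            break
        prev = raw
        # Guttman transform with unit weights
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, disp / dist, 0.0)
        b = np.zeros((n, n))
        b[iu, ju] = -ratio
        b[ju, iu] = -ratio
        b[np.diag_indices(n)] = -b.sum(axis=1)
        x = b @ x / n
        x -= x.mean(axis=0)
    dist = pdist(x)
    disp = _disparities(dist, order)
    denom = float((dist**2).sum())
    stress1 = float(np.sqrt(((dist - disp) ** 2).sum() / denom)) if denom > 0 else 0.0
    return x, stress1, converged, np.asarray(trace)


def nmds(
    d: PairwiseMatrix,
    k: int = 2,
    restarts: int = 50,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> Ordination:
    """Nonmetric MDS minimising Kruskal stress-1 with monotone regression.

    Runs ``restarts`` independent random starts and returns the configuration
    with the lowest stress.  Deterministic for a given seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    d_cond = d.condensed()
    if np.any(d_cond < 0):
        raise ValueError("dissimilarities must be non-negative")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(restarts):
        x, stress1, converged, trace = _smacof_single(d_cond, d.n, k, rng, max_iter, tol)
        if best is None or stress1 < best[1]:
            best = (x, stress1, converged, trace)
    x, stress1, converged, trace = best
    x = x - x.mean(axis=0)
    return Ordination(
        labels=list(d.labels),
        coordinates=x,
        stress=stress1,
        converged=converged,
        seed=seed,
        n_restarts=restarts,
        raw_stress_trace=trace,
    )


# ---------------------------------------------------------------------------
# Correlations and group tests
# ---------------------------------------------------------------------------


def spearman_env(
    alpha: pd.Series | dict,
    meta: SampleMetadata,
    variables: list[str] | None = None,
    min_pairs: int = 4,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Spearman rank correlation of a per-sample statistic against
    environmental variables.

    NA pairs are dropped per variable; constant variables yield NaN with a
    warning.  Optional Benjamini-Hochberg adjusted p-values in ``p_adj``.
    """
    alpha = pd.Series(alpha, dtype=float)
    if variables is None:
        variables = meta.env_vars
    rows = []
    for var in variables:
        env = pd.to_numeric(meta.get(var), errors="coerce")
        joined = pd.concat([alpha, env], axis=1, join="inner").dropna()
        n = len(joined)
        if n < min_pairs:
            logger.warning("spearman_env: %r has only %d paired observations", var, n)
            rows.append((var, np.nan, np.nan, n))
            continue
        x, y = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
        if np.all(y == y[0]) or np.all(x == x[0]):
            logger.warning("spearman_env: %r is constant; rho undefined", var)
            rows.append((var, np.nan, np.nan, n))
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append((var, float(rho), float(p), n))
    out = pd.DataFrame(rows, columns=["variable", "rho", "p", "n"])
    if bh_correct:
        out["p_adj"] = _benjamini_hochberg(out["p"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv)
    adj = pv[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def group_ttest(meta: SampleMetadata, variable: str, group_column: str = "layer"):
    """Welch two-sample t-test of ``variable`` between the two groups of
    ``group_column`` (e.g. surface vs bottom).  Returns (t, p)."""
    values = pd.to_numeric(meta.get(variable), errors="coerce")
    groups = meta.df[group_column].astype(str)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"group_ttest needs exactly 2 groups, found {levels}")
    a = values[groups == levels[0]].dropna().to_numpy()
    b = values[groups == levels[1]].dropna().to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def anova_shannon(groups: dict[str, np.ndarray]):
    """One-way ANOVA across >= 2 groups of alpha-diversity values.

    Degenerate input (any group with < 2 values, or zero variance everywhere)
    raises rather than returning an undefined F.  Returns (F, p).
    """
    if len(groups) < 2:
        raise ValueError("anova needs at least 2 groups")
    arrays = []
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
        arrays.append(v)
    pooled = np.concatenate(arrays)
    if np.allclose(pooled.var(), 0.0):
        raise ValueError("all values identical; F undefined")
    if all(np.allclose(a.var(), 0.0) for a in arrays):
        raise ValueError("zero within-group variance; F undefined")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)
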