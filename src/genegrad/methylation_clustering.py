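"""Gene grouping from DNA methylation profiles.

Builds the gene x 50 bp-segment methylation matrix, factorizes it with an
unscaled (covariance) PCA, clusters genes on the leading components with
k-medoids, and summarizes per-group methylation gradients with exact
order-statistic confidence intervals for the median.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .gene_binning import TES_WINDOW, TSS_WINDOW, mean_methylation_per_segment
from .mutation_gradients import GradientFactorization, _fix_sign

# ---------------------------------------------------------------------------
# Profile matrix
# ---------------------------------------------------------------------------


def build_profile_matrix(
    track: pd.DataFrame,
    segments: pd.DataFrame,
    coverage_min: int = 5,
    max_missing: float = 0.30,
) -> pd.DataFrame:
    """Gene x oriented-segment matrix of mean methylation fractions.

    Column order is fixed: tss_window k=0..n then tes_window k=0..n. Gene
    instances with more than ``max_missing`` missing segments are dropped;
    remaining gaps are filled by row-local linear interpolation with flanking
    fill.
    """
    if track.empty:
        raise ValueError("empty methylation track")
    means = mean_methylation_per_segment(track, segments, coverage_min=coverage_min)
    means["colkey"] = list(zip(means["region"], means["k"]))
    wide = means.pivot_table(
        index="gene_id", columns="colkey", values="mean_fraction", dropna=False
    )
    order = sorted(
        wide.columns, key=lambda rk: (0 if rk[0] == TSS_WINDOW else 1, rk[1])
    )
    wide = wide[order]
    wide.columns = [f"{r}:{k}" for r, k in order]
    frac_missing = wide.isna().mean(axis=1)
    wide = wide.loc[frac_missing <= max_missing]
    wide = wide.interpolate(axis=1, limit_direction="both")
    return wide


def pca_profiles(matrix: pd.DataFrame, n_components: int = 3) -> GradientFactorization:
    """Unscaled PCA of the methylation profile matrix.

    Columns are centred but not variance-scaled; degenerate (zero-variance)
    input yields zero coordinates and explained variances. Components are
    named mePC1..mePCn and sign-fixed as in the gradient factorization.
    """
    if len(matrix) < n_components:
        raise ValueError("need at least n_components rows")
    X = matrix.to_numpy(dtype=float)
    n_components = min(n_components, min(X.shape))
    Xc = X - X.mean(axis=0)
    total_var = float((Xc**2).sum())
    comp_names = [f"mePC{i+1}" for i in range(n_components)]
    # scale-aware zero-variance test: centring leaves float-eps residue
    if total_var <= max(float((X**2).sum()), 1.0) * 1e-18:
        loadings = pd.DataFrame(
            np.zeros((n_components, X.shape[1])), index=comp_names,
            columns=matrix.columns,
        )
        coords = pd.DataFrame(
            np.zeros((X.shape[0], n_components)), index=matrix.index,
            columns=comp_names,
        )
        return GradientFactorization(loadings, coords, np.zeros(n_components))
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    comps = _fix_sign(Vt[:n_components])
    coords = Xc @ comps.T
    evr = (s[:n_components] ** 2) / total_var
    loadings = pd.DataFrame(comps, index=comp_names, columns=matrix.columns)
    coordinates = pd.DataFrame(coords, index=matrix.index, columns=comp_names)
    return GradientFactorization(loadings, coordinates, np.asarray(evr))


# ---------------------------------------------------------------------------
# k-medoids clustering
# ---------------------------------------------------------------------------


def _kmedoids_once(
    D: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, float]:
    n = D.shape[0]
    medoids = rng.choice(n, size=k, replace=False)
    for _ in range(max_iter):
        assign = np.argmin(D[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for j in range(k):
            members = np.flatnonzero(assign == j)
            if members.size == 0:
                # re-seed an empty cluster at the worst-served point
                worst = int(np.argmax(D[np.arange(n), medoids[assign]]))
                new_medoids[j] = worst
                continue
            within = D[np.ix_(members, members)].sum(axis=1)
            new_medoids[j] = members[int(np.argmin(within))]
        if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
            break
        medoids = new_medoids
    assign = np.argmin(D[:, medoids], axis=1)
    cost = float(D[np.arange(n), medoids[assign]].sum())
    return medoids, assign, cost


@dataclasses.dataclass
class GeneGrouping:
    """Gene -> methylation group (c1..ck), with medoids and PC coordinates."""

    labels: pd.Series  # gene_id -> group label
    medoids: dict[str, str]  # group label -> medoid gene_id
    coordinates: pd.DataFrame


def cluster_genes(
    coordinates: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    restarts: int = 10,
    profile_matrix: pd.DataFrame | None = None,
) -> GeneGrouping:
    """k-medoids (Euclidean, multiple restarts) on the leading mePCs.

    Group labels c1..ck are assigned deterministically: descending group-mean
    whole-gene methylation, ties broken by ascending hypomethylation-dip
    width, so c1 is the most-methylated group and higher labels are
    progressively hypomethylated. When no ``profile_matrix`` is supplied,
    groups are ordered by their mean mePC1 coordinate instead.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(coordinates)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of genes ({n})")
    X = coordinates.to_numpy(dtype=float)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(restarts):
        medoids, assign, cost = _kmedoids_once(D, k, rng)
        if best is None or cost < best[2]:
            best = (medoids, assign, cost)
    medoids, assign, _ = best

    # deterministic renaming
    if profile_matrix is not None:
        prof = profile_matrix.reindex(coordinates.index)
        mean_meth = np.array(
            [prof.to_numpy()[assign == j].mean() for j in range(k)]
        )
        dip_width = np.array(
            [
                (prof.to_numpy()[assign == j].mean(axis=0) < 0.5).sum()
                for j in range(k)
            ]
        )
        order = sorted(range(k), key=lambda j: (-mean_meth[j], dip_width[j]))
    else:
        mean_pc1 = np.array([X[assign == j, 0].mean() for j in range(k)])
        order = sorted(range(k), key=lambda j: -mean_pc1[j])
    rename = {old: f"c{new + 1}" for new, old in enumerate(order)}
    labels = pd.Series(
        [rename[j] for j in assign], index=coordinates.index, name="group"
    )
    medoid_map = {
        rename[j]: coordinates.index[medoids[j]] for j in range(k)
    }
    return GeneGrouping(labels=labels, medoids=medoid_map, coordinates=coordinates)


# ---------------------------------------------------------------------------
# Group gradient summaries with order-statistic median CIs
# ---------------------------------------------------------------------------


def median_ci(values: np.ndarray, conf: float = 0.95) -> tuple[float, float, float]:
    """Median with the exact binomial order-statistic confidence interval.

    The bounds are the j-th and (n+1-j)-th order statistics with j the largest
    rank such that the two-sided coverage P(X_(j) <= median <= X_(n+1-j))
    under Binomial(n, 1/2) is at least ``conf``; when n is too small for that
    coverage the interval is clamped to [min, max].
    """
    values = np.sort(np.asarray(values, dtype=float))
    n = values.size
    if n == 0:
        raise ValueError("empty sample")
    if n == 1:
        return float(values[0]), np.nan, np.nan
    med = float(np.median(values))
    alpha = (1.0 - conf) / 2.0
    # largest j with P(B < j) <= alpha, i.e. cdf(j-1) <= alpha
    j = int(stats.binom.ppf(alpha, n, 0.5))
    while j >= 1 and stats.binom.cdf(j - 1, n, 0.5) > alpha:
        j -= 1
    j = max(j, 1)
    lo = float(values[j - 1])
    hi = float(values[n - j])
    return med, lo, hi


def group_gradient_summary(
    matrix: pd.DataFrame, grouping: GeneGrouping, conf: float = 0.95
) -> pd.DataFrame:
    """Per-group, per-segment median methylation with order-statistic CIs.

    Groups of size 1 yield an undefined (NaN) interval and are flagged in
    ``attrs['undefined_ci_groups']``.
    """
    labels = grouping.labels.reindex(matrix.index)
    rows = []
    flagged = []
    for group, sub in matrix.groupby(labels):
        vals = sub.to_numpy(dtype=float)
        if len(sub) == 1:
            flagged.append(group)
        for j, colname in enumerate(matrix.columns):
            col = vals[:, j]
            col = col[np.isfinite(col)]
            if col.size == 0:
                med, lo, hi = np.nan, np.nan, np.nan
            elif col.size == 1:
                med, lo, hi = float(col[0]), np.nan, np.nan
            else:
                med, lo, hi = median_ci(col, conf)
            rows.append(
                {"group": group, "segment": colname, "median": med,
                 "ci_low": lo, "ci_high": hi, "n": int(col.size)}
            )
    out = pd.DataFrame(rows)
    out.attrs["undefined_ci_groups"] = flagged
    return out


def silhouette_report(
    coordinates: pd.DataFrame, k_range=range(2, 8), seed: int = 0
) -> pd.DataFrame:
    """Mean silhouette score of the k-medoids solution over a range of k."""
    from sklearn.metrics import silhouette_score

    rows = []
    for k in k_range:
        grouping = cluster_genes(coordinates, k=k, seed=seed)
        score = silhouette_score(
            coordinates.to_numpy(), grouping.labels.to_numpy()
        )
        rows.append({"k": k, "silhouette": float(score)})
    return pd.DataFrame(rows)
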