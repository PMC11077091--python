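"""Per-bin relative mutation rates and factorization of rate profiles.

For every analysis set (tissue x signature x expression tertile), the local
relative mutation rate of each oriented bin position is estimated with a
negative-binomial offset regression:

    log mu_{g,b} = alpha + beta_b + log E_{g,b}

with one observation per (gene, bin position). The trinucleotide-expected
opportunity ``E_{g,b} = sum_t n_{g,b,t} w_t`` uses the signature's context
marginal (its three alt classes summed and renormalized over the 32 collapsed
contexts), so that ``exp(beta_b)`` is the rate of bin position b relative to
the reference bin after adjusting for sequence composition. The per-set
coefficient profiles are then stacked into a matrix and factorized with a
(optionally sparse) PCA.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import GLMFit, fit_count_glm
from .core_model import SignatureCatalog
from .gene_binning import REFERENCE

# ---------------------------------------------------------------------------
# Signature assignment (maximum-posterior stand-in)
# ---------------------------------------------------------------------------


def assign_signatures(
    mutations: pd.DataFrame,
    catalog: SignatureCatalog,
    exposures: pd.DataFrame,
) -> pd.DataFrame:
    """Label each mutation with its maximum-posterior signature.

    Posterior over signatures for a mutation of class t in sample s is
    proportional to ``exposure[s, sig] * w[sig, t]``. Ties are broken by
    lexicographic signature label; mutations from samples without exposures
    are left unlabelled (counted in ``attrs['n_unassigned']``).
    """
    if (exposures.values < 0).any():
        raise ValueError("exposures must be non-negative")
    sigs = sorted(exposures.columns)
    w = catalog.spectra[sigs]  # 96 x k
    out = mutations.copy()
    labels: list[object] = []
    posteriors: list[float] = []
    n_unassigned = 0
    w_arr = w.to_numpy()
    class_index = {c: i for i, c in enumerate(w.index)}
    expo = exposures[sigs]
    for row in out.itertuples(index=False):
        if row.sample_id not in expo.index:
            labels.append(pd.NA)
            posteriors.append(np.nan)
            n_unassigned += 1
            continue
        scores = expo.loc[row.sample_id].to_numpy() * w_arr[class_index[row.class96]]
        total = scores.sum()
        if total <= 0:
            labels.append(pd.NA)
            posteriors.append(np.nan)
            n_unassigned += 1
            continue
        best = int(np.argmax(scores))  # argmax takes the first (lexicographic) max
        labels.append(sigs[best])
        posteriors.append(float(scores[best] / total))
    out["signature"] = labels
    out["posterior"] = posteriors
    out.attrs["n_unassigned"] = n_unassigned
    return out


# ---------------------------------------------------------------------------
# Bin-rate regression
# ---------------------------------------------------------------------------


def compute_offsets(context_counts: np.ndarray, w32: np.ndarray) -> np.ndarray:
    """Trinucleotide-expected opportunity E = counts @ w per observation."""
    w32 = np.asarray(w32, dtype=float)
    if w32.shape != (32,):
        raise ValueError("w32 must be a 32-vector")
    total = w32.sum()
    if total <= 0:
        raise ValueError("context weights sum to zero")
    return np.asarray(context_counts, dtype=float) @ (w32 / total)


def fit_bin_rates(
    counts: pd.DataFrame,
    context_counts: np.ndarray,
    w32: np.ndarray,
    model: str = "nb",
    min_mutations: int = 50,
    count_col: str = "n",
) -> pd.DataFrame | None:
    """Fit the per-bin relative-rate regression for one analysis set.

    ``counts`` has one row per (gene, region, k) with an integer ``count_col``
    and region/k columns; ``context_counts`` is the matching (n, 32) matrix.
    Returns a RateCoefficientTable: one row per bin position (region, k) with
    beta (log relative rate vs the reference bin), SE, Wald 95% CI, p-value
    and exp(beta); attrs carry theta, convergence and totals. Sets with fewer
    than ``min_mutations`` mutations return None.
    """
    y_all = counts[count_col].to_numpy(dtype=float)
    total_mut = int(y_all.sum())
    if total_mut < min_mutations:
        return None
    E = compute_offsets(context_counts, w32)
    keep = E > 0
    sub = counts.loc[keep].reset_index(drop=True)
    y = y_all[keep]
    E = E[keep]

    positions = (
        sub[["region", "k"]]
        .drop_duplicates()
        .sort_values(["region", "k"])
        .reset_index(drop=True)
    )
    pos_key = list(zip(positions["region"], positions["k"]))
    if (REFERENCE, 0) not in pos_key:
        raise ValueError("reference bin missing from the data")
    # order columns with reference first so it is the dropped baseline level
    pos_key.sort(key=lambda rk: (rk[0] != REFERENCE, rk))
    pos_index = {rk: j for j, rk in enumerate(pos_key)}
    col = np.array(
        [pos_index[(r, k)] for r, k in zip(sub["region"], sub["k"])], dtype=int
    )
    n_pos = len(pos_key)
    X = np.zeros((len(sub), n_pos))
    X[:, 0] = 1.0  # intercept (reference bin level)
    for j in range(1, n_pos):
        X[col == j, j] = 1.0

    fit = fit_count_glm(y, X, np.log(E), model=model)

    rows = []
    z = stats.norm.ppf(0.975)
    for j, (region, k) in enumerate(pos_key):
        if j == 0:
            beta, se = 0.0, 0.0
            p = np.nan
        else:
            beta, se = fit.params[j], fit.bse[j]
            p = 2 * stats.norm.sf(abs(beta / se)) if se > 0 else np.nan
        rows.append(
            {
                "region": region,
                "k": k,
                "beta": beta,
                "se": se,
                "ci_low": beta - z * se,
                "ci_high": beta + z * se,
                "pvalue": p,
                "rel_rate": float(np.exp(beta)),
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["theta"] = fit.theta
    table.attrs["alpha_dispersion"] = fit.alpha
    table.attrs["converged"] = fit.converged
    table.attrs["model"] = fit.model
    table.attrs["total_mutations"] = total_mut
    table.attrs["intercept"] = float(fit.params[0])
    table.attrs["llf"] = fit.llf
    return table


# ---------------------------------------------------------------------------
# Coefficient matrix and factorization
# ---------------------------------------------------------------------------


def build_coefficient_matrix(
    tables: dict[tuple, pd.DataFrame],
    annotations: list[str] = ("tissue", "signature", "tertile"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stack per-set beta profiles into a (sets x bin positions) matrix.

    ``tables`` maps annotation tuples (e.g. (tissue, signature, tertile)) to
    RateCoefficientTables. Missing betas (bins skipped in a set) are imputed
    as 0 ("no deviation from the reference") and recorded in the returned
    boolean mask (True = observed). All sets must share the bin-position
    vocabulary of their union.
    """
    vocab: list[tuple] | None = None
    rows, masks, index = [], [], []
    all_positions = sorted(
        {
            (r, k)
            for t in tables.values()
            for r, k in zip(t["region"], t["k"])
            if r != REFERENCE
        }
    )
    for key, table in tables.items():
        have = {(r, k): b for r, k, b in zip(table["region"], table["k"], table["beta"])}
        unknown = set(have) - set(all_positions) - {(REFERENCE, 0)}
        if unknown:
            raise ValueError(f"set {key}: bin positions outside the shared vocabulary")
        rows.append([have.get(pos, 0.0) for pos in all_positions])
        masks.append([pos in have for pos in all_positions])
        index.append(key)
    cols = [f"{r}:{k}" for r, k in all_positions]
    idx = pd.MultiIndex.from_tuples(index, names=list(annotations))
    matrix = pd.DataFrame(rows, index=idx, columns=cols)
    mask = pd.DataFrame(masks, index=idx, columns=cols)
    return matrix, mask


def _fix_sign(loadings: np.ndarray) -> np.ndarray:
    """Flip each component so its largest-|weight| element is positive."""
    out = loadings.copy()
    for i in range(out.shape[0]):
        j = int(np.argmax(np.abs(out[i])))
        if out[i, j] < 0:
            out[i] = -out[i]
    return out


@dataclasses.dataclass
class GradientFactorization:
    """PCA of the per-set coefficient profiles."""

    loadings: pd.DataFrame  # components x bin positions
    coordinates: pd.DataFrame  # sets x components
    explained_variance_ratio: np.ndarray
    signature_means: pd.DataFrame | None = None  # per-signature mean coordinates


def factorize_gradients(
    matrix: pd.DataFrame, n_components: int = 3
) -> GradientFactorization:
    """Centred (unscaled) PCA of the coefficient matrix.

    Columns are centred but not variance-scaled; component signs are fixed so
    each component's largest-|weight| element is positive. Requested
    components are truncated to what the matrix supports.
    """
    if len(matrix) < 2:
        raise ValueError("factorization needs at least 2 rows")
    X = matrix.to_numpy(dtype=float)
    n_components = min(n_components, min(X.shape[0] - 1, X.shape[1]))
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float((Xc**2).sum())
    comps = _fix_sign(Vt[:n_components])
    coords = Xc @ comps.T
    evr = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    comp_names = [f"PC{i+1}" for i in range(n_components)]
    loadings = pd.DataFrame(comps, index=comp_names, columns=matrix.columns)
    coordinates = pd.DataFrame(coords, index=matrix.index, columns=comp_names)
    sig_means = None
    if isinstance(matrix.index, pd.MultiIndex) and "signature" in matrix.index.names:
        sig_means = coordinates.groupby(level="signature").mean()
    return GradientFactorization(loadings, coordinates, np.asarray(evr), sig_means)


def _soft_threshold(x: np.ndarray, lam: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - lam, 0.0)


def sparse_factorize(
    matrix: pd.DataFrame,
    l1_penalty: float,
    n_components: int = 3,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> GradientFactorization:
    """L1-penalized PCA by soft-thresholded power iteration with deflation.

    Each component solves ``max u' X v - l1_penalty * |v|_1`` with unit-norm
    u, v (rank-one alternating updates); the matrix is deflated between
    components. At penalty 0 this is exactly the power method, reproducing the
    plain PCA loadings (up to sign) to numerical accuracy; larger penalties
    drive loading entries exactly to zero.
    """
    if l1_penalty < 0:
        raise ValueError("penalty must be >= 0")
    if len(matrix) < 2:
        raise ValueError("factorization needs at least 2 rows")
    X0 = matrix.to_numpy(dtype=float)
    n_components = min(n_components, min(X0.shape[0] - 1, X0.shape[1]))
    Xc = X0 - X0.mean(axis=0)
    total_var = float((Xc**2).sum())
    X = Xc.copy()
    comps = np.zeros((n_components, X.shape[1]))
    evr = np.zeros(n_components)
    for c in range(n_components):
        # initialize from the leading singular vector for stable convergence
        _, _, Vt = np.linalg.svd(X, full_matrices=False)
        v = Vt[0]
        for it in range(max_iter):
            Xv = X @ v
            nu = np.linalg.norm(Xv)
            if nu == 0:
                break
            u = Xv / nu
            v_new = _soft_threshold(X.T @ u, l1_penalty)
            nv = np.linalg.norm(v_new)
            if nv == 0:
                v = v_new
                break
            v_new /= nv
            if np.linalg.norm(v_new - v) < tol or np.linalg.norm(v_new + v) < tol:
                v = v_new
                break
            v = v_new
        else:
            raise RuntimeError(
                f"sparse factorization did not converge for component {c + 1} "
                f"after {max_iter} iterations (penalty={l1_penalty})"
            )
        comps[c] = v
        proj = X @ v
        evr[c] = float((proj**2).sum()) / total_var if total_var > 0 else 0.0
        X = X - np.outer(proj, v)
    comps = _fix_sign(comps)
    coords = Xc @ comps.T
    comp_names = [f"PC{i+1}" for i in range(n_components)]
    loadings = pd.DataFrame(comps, index=comp_names, columns=matrix.columns)
    coordinates = pd.DataFrame(coords, index=matrix.index, columns=comp_names)
    sig_means = None
    if isinstance(matrix.index, pd.MultiIndex) and "signature" in matrix.index.names:
        sig_means = coordinates.groupby(level="signature").mean()
    return GradientFactorization(loadings, coordinates, evr, sig_means)


# ---------------------------------------------------------------------------
# Confounder adjustment
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CovariateAdjustment:
    """Base and covariate-adjusted bin-rate fits on identical observations."""

    base: pd.DataFrame
    adjusted: pd.DataFrame
    gamma: float
    gamma_se: float
    lrt_bins_base: float  # p-value of the bin-factor term in the base model
    lrt_bins_adjusted: float  # p-value of the bin-factor term given the covariate
    covariate_constant: bool = False


def _loglik_without_bins(
    y: np.ndarray, E: np.ndarray, extra: np.ndarray | None, model: str
) -> GLMFit:
    cols = [np.ones_like(y)]
    if extra is not None:
        cols.append(extra)
    X = np.column_stack(cols)
    return fit_count_glm(y, X, np.log(E), model=model)


def adjust_for_covariate(
    counts: pd.DataFrame,
    context_counts: np.ndarray,
    w32: np.ndarray,
    covariate: np.ndarray,
    model: str = "nb",
    count_col: str = "n",
) -> CovariateAdjustment:
    """Test whether a per-(gene, bin) covariate explains the bin gradient.

    Fits the base model (intercept + bin factor) and the adjusted model
    (+ gamma * covariate) on identical observations (rows with missing
    covariate dropped from both), and returns likelihood-ratio tests of the
    bin-factor term in each. A gradient explained by the covariate loses
    bin-factor significance in the adjusted model.
    """
    covariate = np.asarray(covariate, dtype=float)
    keep = np.isfinite(covariate)
    counts = counts.loc[keep].reset_index(drop=True)
    context_counts = np.asarray(context_counts)[keep]
    covariate = covariate[keep]

    E = compute_offsets(context_counts, w32)
    ok = E > 0
    counts = counts.loc[ok].reset_index(drop=True)
    E = E[ok]
    covariate = covariate[ok]
    y = counts[count_col].to_numpy(dtype=float)

    constant = bool(np.ptp(covariate) == 0)

    base = fit_bin_rates(counts, context_counts[ok], w32, model=model,
                         min_mutations=0, count_col=count_col)
    # adjusted model: rebuild the design with the covariate appended
    positions = sorted(
        {(r, k) for r, k in zip(counts["region"], counts["k"])},
        key=lambda rk: (rk[0] != REFERENCE, rk),
    )
    pos_index = {rk: j for j, rk in enumerate(positions)}
    col = np.array(
        [pos_index[(r, k)] for r, k in zip(counts["region"], counts["k"])]
    )
    n_pos = len(positions)
    X = np.zeros((len(counts), n_pos + (0 if constant else 1)))
    X[:, 0] = 1.0
    for j in range(1, n_pos):
        X[col == j, j] = 1.0
    if not constant:
        X[:, -1] = covariate
    adj_fit = fit_count_glm(y, X, np.log(E), model=model)

    z = stats.norm.ppf(0.975)
    rows = []
    for j, (region, k) in enumerate(positions):
        beta = 0.0 if j == 0 else adj_fit.params[j]
        se = 0.0 if j == 0 else adj_fit.bse[j]
        rows.append(
            {
                "region": region,
                "k": k,
                "beta": beta,
                "se": se,
                "ci_low": beta - z * se,
                "ci_high": beta + z * se,
                "pvalue": 2 * stats.norm.sf(abs(beta / se)) if se > 0 else np.nan,
                "rel_rate": float(np.exp(beta)),
            }
        )
    adjusted = pd.DataFrame(rows)
    adjusted.attrs["theta"] = adj_fit.theta
    adjusted.attrs["model"] = adj_fit.model

    df_bins = n_pos - 1
    null_base = _loglik_without_bins(y, E, None, model)
    lrt_base = 2 * (base.attrs["llf"] - null_base.llf)
    p_base = stats.chi2.sf(max(lrt_base, 0.0), df_bins)
    if constant:
        p_adj = p_base
        gamma, gamma_se = 0.0, np.nan
    else:
        null_adj = _loglik_without_bins(y, E, covariate, model)
        lrt_adj = 2 * (adj_fit.llf - null_adj.llf)
        p_adj = stats.chi2.sf(max(lrt_adj, 0.0), df_bins)
        gamma, gamma_se = float(adj_fit.params[-1]), float(adj_fit.bse[-1])

    return CovariateAdjustment(
        base=base,
        adjusted=adjusted,
        gamma=gamma,
        gamma_se=gamma_se,
        lrt_bins_base=float(p_base),
        lrt_bins_adjusted=float(p_adj),
        covariate_constant=constant,
    )
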