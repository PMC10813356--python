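"""Cohort-level statistics: rotated PCA with jackknife validation,
two-group tests and normality-gated correlation.

The central tool is a principal component analysis of standardized flux
variables followed by varimax rotation (with Kaiser normalization, the R
``stats::varimax`` default) and a leave-one-out jackknife that attaches a
standard error to every loading; a loading counts as significant when its
relative error (jackknife SE over the absolute loading) is below 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FluxDataset",
    "RotatedPCA",
    "PCA_VARIABLES",
    "standardize",
    "pca_varimax",
    "varimax",
    "jackknife_loadings",
    "compare_groups",
    "correlate_auto",
]

#: The canonical 17-variable input set: mitochondrial respiration,
#: superoxide production, nine glycolysis/PPP fluxes and six TCA-side
#: fluxes (d = net flux of a reversible reaction).
PCA_VARIABLES = (
    "JO2", "O2_superoxide",
    "hexose_uptake", "Z3", "dTAL", "dTKT1", "S7P_input", "Q4", "dQ2",
    "Q11", "lactate_production",
    "F2", "F3", "F4", "F6", "glutamine_uptake", "dAsp",
)

JACKKNIFE_RELATIVE_ERROR = 0.5


@dataclass
class FluxDataset:
    """Samples x variables matrix with per-sample metadata."""

    values: pd.DataFrame           # numeric, samples x variables
    metadata: pd.DataFrame         # same index; e.g. sex, cell_type

    def __post_init__(self):
        if not self.values.index.equals(self.metadata.index):
            raise ValueError("values and metadata indices differ")
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()].tolist()
            raise ValueError(f"missing values in {bad}")

    @property
    def n_samples(self) -> int:
        return len(self.values)


def standardize(dataset: FluxDataset) -> FluxDataset:
    """Center every variable to mean 0 and scale to unit (ddof=1) SD."""
    sd = dataset.values.std(ddof=1)
    zero = sd.index[sd == 0].tolist()
    if zero:
        raise ValueError(f"zero-variance variable(s): {zero}")
    z = (dataset.values - dataset.values.mean()) / sd
    return FluxDataset(z, dataset.metadata)


def _varimax_criterion(L: np.ndarray) -> float:
    sq = L**2
    return float(sq.var(axis=0).sum())


def _varimax_iterate(L, R0, tol, max_iter):
    """Kaiser's pairwise planar rotations with the exact per-pair angle.

    Each sweep rotates every column pair by the analytically optimal
    varimax angle (from the fourth-harmonic normal equation); unlike the
    simultaneous SVD update this does not stall in flat regions.
    """
    p, k = L.shape
    R = R0.copy()
    LR = L @ R
    for _ in range(max_iter):
        max_phi = 0.0
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = LR[:, i], LR[:, j]
                u = x**2 - y**2
                v = 2.0 * x * y
                num = 2.0 * (u @ v) - 2.0 * u.sum() * v.sum() / p
                den = (u @ u - v @ v) - (u.sum() ** 2 - v.sum() ** 2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-15:
                    continue
                max_phi = max(max_phi, abs(phi))
                c, s = np.cos(phi), np.sin(phi)
                G = np.array([[c, -s], [s, c]])
                LR[:, [i, j]] = LR[:, [i, j]] @ G
                R[:, [i, j]] = R[:, [i, j]] @ G
        if max_phi < tol:
            break
    return R


def varimax(loadings: np.ndarray, normalize: bool = True,
            tol: float = 1e-10, max_iter: int = 1000,
            n_starts: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation; returns (rotated loadings, rotation matrix R).

    With ``normalize`` (Kaiser), rows are scaled to unit communality
    before rotation and rescaled after, matching R's default.  The
    fixed-point iteration can stall on saddle configurations (e.g. two
    equally strong factors mixed at 45 degrees), so it is restarted from
    a small set of seeded random orthogonal rotations and the solution
    with the largest varimax criterion is kept; the procedure stays
    deterministic for a given input.
    """
    L = np.asarray(loadings, float).copy()
    p, k = L.shape
    if k < 2:
        return L, np.eye(k)
    comm = np.sqrt((L**2).sum(axis=1))
    if normalize:
        L = L / comm[:, None]
    rng = np.random.default_rng(1234)
    best_R, best_score = None, -np.inf
    for start in range(n_starts):
        if start == 0:
            R0 = np.eye(k)
        else:
            q, _ = np.linalg.qr(rng.standard_normal((k, k)))
            R0 = q
        R = _varimax_iterate(L, R0, tol, max_iter)
        score = _varimax_criterion(L @ R)
        if score > best_score + 1e-14:
            best_R, best_score = R, score
    rotated = L @ best_R
    if normalize:
        rotated = rotated * comm[:, None]
    return rotated, best_R


@dataclass
class RotatedPCA:
    """Varimax-rotated PCA of a standardized dataset."""

    loadings: pd.DataFrame          # variables x components (rotated)
    scores: pd.DataFrame            # samples x components
    explained_variance_share: pd.Series  # per rotated component
    rotation: np.ndarray            # k x k orthogonal matrix
    eigenvalues: np.ndarray         # all unrotated component variances
    jackknife_se: pd.DataFrame | None = None
    significant: pd.DataFrame | None = None

    @property
    def k(self) -> int:
        return self.loadings.shape[1]


def _pca_loadings(z: np.ndarray, k: int):
    """Unrotated correlation-scaled loadings via SVD (prcomp-style)."""
    n, p = z.shape
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eig = s**2 / (n - 1)
    if k > np.sum(s > 1e-10 * s[0]):
        raise ValueError(f"k={k} exceeds the rank of the data")
    # sign convention: largest-|loading| variable of each component positive
    load = vt[:k].T * np.sqrt(eig[:k])
    flip = np.sign(load[np.argmax(np.abs(load), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    return load * flip, eig


def pca_varimax(dataset: FluxDataset, k: int = 3,
                kaiser_normalize: bool = True) -> RotatedPCA:
    """Standardized PCA with the top ``k`` components varimax-rotated.

    Loadings are on the correlation scale (eigenvector x singular value /
    sqrt(n-1)), so a loading is the correlation between variable and
    component; explained-variance shares are sums of squared rotated
    loadings over the number of variables.
    """
    zds = standardize(dataset)
    z = zds.values.to_numpy()
    p = z.shape[1]
    load, eig = _pca_loadings(z, k)
    rotated, R = varimax(load, normalize=kaiser_normalize)
    # stable ordering/sign after rotation: by decreasing variance share,
    # dominant variable positive
    share = (rotated**2).sum(axis=0) / p
    order = np.argsort(-share)
    rotated = rotated[:, order]
    R = R[:, order]
    share = share[order]
    flip = np.sign(rotated[np.argmax(np.abs(rotated), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    rotated = rotated * flip
    R = R * flip
    cols = [f"PC{i+1}" for i in range(k)]
    loadings = pd.DataFrame(rotated, index=dataset.values.columns, columns=cols)
    # scores of standardized data on the rotated axes (unit-normed axes)
    axes = loadings.to_numpy() / np.sqrt((loadings.to_numpy()**2).sum(axis=0))
    scores = pd.DataFrame(z @ axes, index=dataset.values.index, columns=cols)
    return RotatedPCA(
        loadings=loadings,
        scores=scores,
        explained_variance_share=pd.Series(share, index=cols),
        rotation=R,
        eigenvalues=eig,
    )


def _align(ref: np.ndarray, cand: np.ndarray, min_corr: float = 0.6):
    """Match candidate components to reference ones by |cosine similarity|.

    The similarity is deliberately uncentered: Pearson correlation of two
    loading vectors subtracts their means, which makes orthogonal
    block-structured components look perfectly (anti-)correlated and the
    assignment ambiguous.  Returns the aligned candidate loadings and the
    worst matched |similarity| (for reporting alignment failures).
    """
    from scipy.optimize import linear_sum_assignment

    def _unit(M):
        norms = np.linalg.norm(M, axis=0)
        return M / np.where(norms == 0, 1.0, norms)

    sim = _unit(ref).T @ _unit(cand)  # (k, k) cosine similarities
    rows, cols = linear_sum_assignment(-np.abs(sim))
    aligned = cand[:, cols].copy()
    worst = 1.0
    for i, j in zip(rows, cols):
        if sim[i, j] < 0:
            aligned[:, i] *= -1.0
        worst = min(worst, abs(sim[i, j]))
    return aligned, worst


def jackknife_loadings(dataset: FluxDataset, k: int = 3,
                       min_alignment: float = 0.6) -> RotatedPCA:
    """Leave-one-out jackknife SEs and a significance mask for loadings.

    Each replicate refits the rotated PCA without one sample and is
    aligned to the full fit by maximal absolute loading correlation (with
    sign flip).  SE = sqrt((n-1)/n * sum (theta_i - theta_bar)^2); a
    loading is significant when SE / |loading| < 0.5.
    """
    n = dataset.n_samples
    if n < 3:
        raise ValueError("jackknife needs >= 3 samples")
    full = pca_varimax(dataset, k)
    ref = full.loadings.to_numpy()
    reps = []
    poor = []
    for i in range(n):
        sub = FluxDataset(
            dataset.values.drop(dataset.values.index[i]),
            dataset.metadata.drop(dataset.metadata.index[i]),
        )
        fit = pca_varimax(sub, k)
        aligned, worst = _align(ref, fit.loadings.to_numpy())
        if worst < min_alignment:
            poor.append((str(dataset.values.index[i]), worst))
        reps.append(aligned)
    if poor:
        import warnings

        warnings.warn(
            "weak component alignment in leave-one-out replicate(s): "
            + ", ".join(f"{s} (|r|={w:.2f})" for s, w in poor),
            stacklevel=2,
        )
    reps = np.stack(reps)  # (n, p, k)
    theta_bar = reps.mean(axis=0)
    se = np.sqrt((n - 1) / n * ((reps - theta_bar) ** 2).sum(axis=0))
    se_df = pd.DataFrame(se, index=full.loadings.index,
                         columns=full.loadings.columns)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = se / np.abs(ref)
    sig = pd.DataFrame(rel < JACKKNIFE_RELATIVE_ERROR,
                       index=full.loadings.index,
                       columns=full.loadings.columns)
    full.jackknife_se = se_df
    full.significant = sig
    return full


def compare_groups(values_a, values_b) -> dict:
    """Two-sided Mann-Whitney U test with group medians and IQRs.

    Exact p for group sizes up to 8, normal approximation with continuity
    correction beyond.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 observations")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = (
        "exact" if max(len(a), len(b)) <= 8 and not ties else "asymptotic"
    )
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)

    def _summ(x):
        q25, q50, q75 = np.percentile(x, [25, 50, 75])
        return {"median": q50, "q25": q25, "q75": q75, "n": len(x)}

    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "method": method,
        "group_a": _summ(a),
        "group_b": _summ(b),
    }


def correlate_auto(x, y, alpha: float = 0.05) -> dict:
    """Pearson if both variables pass Shapiro-Wilk normality, else Spearman."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input variable")
    p_x = stats.shapiro(x).pvalue
    p_y = stats.shapiro(y).pvalue
    if p_x > alpha and p_y > alpha:
        res = stats.pearsonr(x, y)
        method = "pearson"
    else:
        res = stats.spearmanr(x, y)
        method = "spearman"
    return {
        "method": method,
        "r": float(res.statistic),
        "p_value": float(res.pvalue),
        "shapiro_p": (float(p_x), float(p_y)),
    }
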