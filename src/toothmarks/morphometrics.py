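"""Geometric morphometrics: Procrustes superimposition, PCA, allometry, TPS.

Configurations are superimposed by Generalized Procrustes Analysis (GPA):
translation to a common centroid, optional scaling to unit centroid size
(*shape* space; skipping the scaling step gives *form* space), and iterative
rotation onto the evolving mean until convergence, followed by orthogonal
projection into the tangent space at the mean shape.  Reflections are never
allowed during superimposition: tooth marks have a consistent handedness
from the digitisation protocol.

Allometry (shape-size dependence) is tested by multivariate regression of the
tangent coordinates on log centroid size (or another per-specimen covariate
such as a stress index), with a Goodall-type F statistic and residual-
randomisation permutation p-values, as in standard Procrustes ANOVA practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .landmarks import LandmarkDataset

__all__ = [
    "AlignedSet",
    "PcaResult",
    "AllometryResult",
    "TpsWarp",
    "centroid_size",
    "procrustes_distance",
    "gpa",
    "pca_shapes",
    "allometry_test",
    "tps_grid",
    "tsne_embed",
    "oa_to_linear",
    "metric_pca",
]


def centroid_size(config: np.ndarray) -> float:
    """Square root of summed squared landmark distances to the centroid (mm)."""
    c = np.asarray(config, dtype=float)
    centred = c - c.mean(axis=0)
    return float(np.sqrt(np.sum(centred ** 2)))


def _optimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation (no reflection) mapping centred config ``a`` onto ``b``."""
    u, _, vt = np.linalg.svd(a.T @ b)
    r = u @ vt
    if np.linalg.det(r) < 0:  # disallow reflections
        u[:, -1] *= -1
        r = u @ vt
    return r


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Full Procrustes distance between two configurations (closed-form OPA)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    sa, sb = np.sqrt((a ** 2).sum()), np.sqrt((b ** 2).sum())
    if sa == 0 or sb == 0:
        raise ValueError("degenerate (zero-size) configuration")
    a, b = a / sa, b / sb
    r = _optimal_rotation(a, b)
    return float(np.sqrt(((a @ r - b) ** 2).sum()))


@dataclass
class AlignedSet:
    """GPA output: superimposed configurations plus tangent-space coordinates."""

    coords: np.ndarray          # (n, k, d) aligned configurations
    tangent: np.ndarray         # (n, k*d) tangent-projected flat coordinates
    centroid_sizes: np.ndarray  # (n,) original centroid sizes (mm)
    mean_shape: np.ndarray      # (k, d), centroid at origin
    scaled: bool
    specimen_ids: list = field(default_factory=list)
    iterations: int = 0

    @property
    def n(self) -> int:
        return self.coords.shape[0]


def gpa(
    dataset: LandmarkDataset | np.ndarray,
    scale: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> AlignedSet:
    """Generalized Procrustes Analysis.

    scale=True gives shape space (unit centroid sizes); scale=False retains
    size (form space).  Iterates rotation onto the evolving mean until the
    mean-shape change drops below ``tol``, then projects orthogonally into the
    tangent space at the mean.
    """
    if isinstance(dataset, LandmarkDataset):
        raw = dataset.coords
        ids = dataset.specimen_ids
    else:
        raw = np.asarray(dataset, dtype=float)
        ids = [f"specimen_{i+1}" for i in range(raw.shape[0])]
    if raw.ndim != 3 or raw.shape[0] < 2:
        raise ValueError("GPA needs at least 2 configurations of shape (k, d)")

    n, k, d = raw.shape
    sizes = np.array([centroid_size(c) for c in raw])
    if np.any(sizes == 0):
        raise ValueError("degenerate (zero-size) configuration")
    configs = raw - raw.mean(axis=1, keepdims=True)
    if scale:
        configs = configs / sizes[:, None, None]

    mean = configs[0].copy()
    mean = mean / np.sqrt((mean ** 2).sum()) if scale else mean
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            r = _optimal_rotation(configs[i], mean)
            configs[i] = configs[i] @ r
        new_mean = configs.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        if scale:
            nm = np.sqrt((new_mean ** 2).sum())
            if nm > 0:
                new_mean = new_mean / nm
        if np.sqrt(((new_mean - mean) ** 2).sum()) < tol:
            mean = new_mean
            break
        mean = new_mean

    # final rotation onto the converged mean
    for i in range(n):
        configs[i] = configs[i] @ _optimal_rotation(configs[i], mean)
    if scale:  # keep centroid sizes exactly 1 (rotation preserves them anyway)
        norms = np.sqrt((configs ** 2).sum(axis=(1, 2)))
        configs = configs / norms[:, None, None]

    # orthogonal projection onto the tangent space at the mean
    flat = configs.reshape(n, k * d)
    m = mean.reshape(k * d)
    mhat = m / np.sqrt(m @ m)
    radial = flat @ mhat
    tangent = flat - np.outer(radial - np.sqrt(m @ m), mhat)

    return AlignedSet(coords=configs, tangent=tangent, centroid_sizes=sizes,
                      mean_shape=mean, scaled=scale, specimen_ids=list(ids),
                      iterations=iterations)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: np.ndarray            # (n, m)
    variance_fraction: np.ndarray  # (m,), sums to 1 over computed components
    loadings: np.ndarray          # (m, p) orthonormal rows
    mean: np.ndarray              # (p,)
    columns: list | None = None

    def reconstruct(self) -> np.ndarray:
        return self.scores @ self.loadings + self.mean


def _pca(X: np.ndarray, columns=None) -> PcaResult:
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    centred = X - mean
    u, svals, vt = np.linalg.svd(centred, full_matrices=False)
    var = svals ** 2
    total = var.sum()
    if total <= 0:
        raise ValueError("zero total variance: all observations identical")
    scores = u * svals
    return PcaResult(scores=scores, variance_fraction=var / total,
                     loadings=vt, mean=mean, columns=columns)


def pca_shapes(aligned: AlignedSet) -> PcaResult:
    """PCA of the tangent-space coordinates."""
    if aligned.n < 3:
        raise ValueError("shape PCA needs at least 3 specimens")
    return _pca(aligned.tangent)


def oa_to_linear(oa: float) -> float:
    """Map an opening angle (degrees) into a linear feature cos(theta)+sin(theta)."""
    oa = float(oa)
    if not 0.0 < oa <= 180.0:
        raise ValueError(f"opening angle must lie in (0, 180]; got {oa}")
    t = math.radians(oa)
    return math.cos(t) + math.sin(t)


def metric_pca(metrics, standardize: bool = False) -> PcaResult:
    """PCA of the seven tooth-score measurements.

    OA (degrees) is first mapped through ``oa_to_linear`` so the angular
    variable lives on a linear scale commensurate with the six lengths.
    By default the decomposition is of the covariance of raw columns;
    ``standardize=True`` switches to the correlation scale.
    """
    import pandas as pd

    df = pd.DataFrame(metrics).copy()
    if df.isna().any().any():
        raise ValueError("metric table contains missing values")
    if "OA" in df.columns:
        df["OA"] = [oa_to_linear(v) for v in df["OA"]]
    X = df.to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("cannot standardise a constant column")
        X = X / sd
    return _pca(X, columns=list(df.columns))


# ---------------------------------------------------------------------------
# allometry (Procrustes ANOVA with residual randomisation)
# ---------------------------------------------------------------------------

@dataclass
class AllometryResult:
    F: float
    p: float
    slope: np.ndarray             # regression coefficient vector of the covariate
    diagnostics: dict             # residual normality W/p, |skewness|, |kurtosis|
    F_interaction: float | None = None
    p_interaction: float | None = None
    n_perm: int = 0


def _rss(Y: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray]:
    """Residual sum of squares (trace) and residuals of a least-squares fit."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    res = Y - X @ beta
    return float((res ** 2).sum()), res


def _rrpp_pvalue(Y, X_red, X_full, df_eff, n_perm, rng) -> tuple[float, float]:
    """Goodall-type F and residual-randomisation p for the extra term(s)."""
    n = Y.shape[0]
    rss_red, res_red = _rss(Y, X_red)
    rss_full, _ = _rss(Y, X_full)
    df_res = n - X_full.shape[1]
    ss_eff = rss_red - rss_full
    if rss_full <= 0 or df_res <= 0:
        raise ValueError("degenerate design for permutation F test")
    f_obs = (ss_eff / df_eff) / (rss_full / df_res)
    fitted_red = Y - res_red
    exceed = 0
    for _ in range(n_perm):
        Yp = fitted_red + res_red[rng.permutation(n)]
        rss_red_p, _ = _rss(Yp, X_red)
        rss_full_p, _ = _rss(Yp, X_full)
        fp = ((rss_red_p - rss_full_p) / df_eff) / (rss_full_p / df_res)
        if fp >= f_obs:
            exceed += 1
    return f_obs, (exceed + 1) / (n_perm + 1)


def allometry_test(
    aligned: AlignedSet,
    covariate: Sequence[float] | None = None,
    groups: Sequence | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> AllometryResult:
    """Test shape-size (or shape-covariate) dependence.

    ``covariate`` defaults to log centroid size.  With ``groups`` the
    covariate-by-group interaction (difference in allometric slopes) is also
    tested.  p-values come from residual randomisation (RRPP).
    """
    Y = aligned.tangent - aligned.tangent.mean(axis=0)
    n = Y.shape[0]
    if covariate is None:
        covariate = np.log(aligned.centroid_sizes)
    x = np.asarray(covariate, dtype=float)
    if x.size != n:
        raise ValueError("covariate length must match the number of specimens")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    xc = (x - x.mean()) / x.std()

    ones = np.ones((n, 1))
    if groups is None:
        X_red = ones
        X_full = np.hstack([ones, xc[:, None]])
        f_obs, p = _rrpp_pvalue(Y, X_red, X_full, 1, n_perm, rng)
        f_int = p_int = None
    else:
        g = np.asarray(groups)
        levels = np.unique(g)
        dummies = np.column_stack([(g == lv).astype(float) for lv in levels[1:]])
        X_red = np.hstack([ones, dummies])
        X_main = np.hstack([ones, dummies, xc[:, None]])
        f_obs, p = _rrpp_pvalue(Y, X_red, X_main, 1, n_perm, rng)
        inter = dummies * xc[:, None]
        X_int = np.hstack([X_main, inter])
        f_int, p_int = _rrpp_pvalue(Y, X_main, X_int, inter.shape[1], n_perm,
                                    rng)

    # slope of the covariate in the full (main-effects) design
    X_fit = np.hstack([ones, xc[:, None]]) if groups is None else X_main
    beta, *_ = np.linalg.lstsq(X_fit, Y, rcond=None)
    slope = beta[X_fit.shape[1] - 1 if groups is None else X_fit.shape[1] - 1]
    res = Y - X_fit @ beta
    dist = np.sqrt((res ** 2).sum(axis=1))  # residual Procrustes distances
    if np.ptp(dist) > 0 and 3 <= n <= 5000:
        w, wp = stats.shapiro(dist)
    else:
        w, wp = float("nan"), float("nan")
    diagnostics = {
        "W": float(w),
        "p": float(wp),
        "skew": float(abs(stats.skew(dist))),
        "kurtosis": float(abs(stats.kurtosis(dist))),
    }
    return AllometryResult(F=float(f_obs), p=float(p), slope=slope,
                           diagnostics=diagnostics, F_interaction=f_int,
                           p_interaction=p_int, n_perm=n_perm)


# ---------------------------------------------------------------------------
# thin-plate splines (2D)
# ---------------------------------------------------------------------------

def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log r^2 with U(0) = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        u = r2 * np.log(r2)
    return np.where(r2 > 0, u, 0.0)


@dataclass
class TpsWarp:
    """A fitted 2D thin-plate-spline interpolant and its warped grid."""

    reference: np.ndarray
    target: np.ndarray
    weights: np.ndarray       # (k, 2) non-affine weights
    affine: np.ndarray        # (3, 2) affine part [const; x; y]
    bending_energy: float
    grid: np.ndarray          # (m, 2) warped grid node coordinates
    grid_shape: tuple[int, int]

    def transform(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        d2 = ((points[:, None, :] - self.reference[None, :, :]) ** 2).sum(-1)
        U = _tps_kernel(d2)
        P = np.hstack([np.ones((points.shape[0], 1)), points])
        return U @ self.weights + P @ self.affine


def tps_grid(reference: np.ndarray, target: np.ndarray,
             grid: int = 20, margin: float = 0.1) -> TpsWarp:
    """Thin-plate-spline warp mapping reference landmarks exactly onto target.

    A regular ``grid x grid`` lattice over the (margin-expanded) reference
    bounding box is mapped through the interpolant; the bending energy of the
    non-affine part is reported (0 for any affine target).
    """
    ref = np.asarray(reference, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if ref.shape != tgt.shape or ref.ndim != 2 or ref.shape[1] != 2:
        raise ValueError("reference and target must be matching (k, 2) arrays")
    k = ref.shape[0]
    if k < 3:
        raise ValueError("TPS needs at least 3 landmarks")
    d2 = ((ref[:, None, :] - ref[None, :, :]) ** 2).sum(-1)
    K = _tps_kernel(d2)
    P = np.hstack([np.ones((k, 1)), ref])
    if np.linalg.matrix_rank(P) < 3:
        raise ValueError("collinear reference landmarks: TPS is degenerate")
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = tgt
    sol = np.linalg.solve(L, rhs)
    w, a = sol[:k], sol[k:]
    bending = float(np.trace(w.T @ K @ w))
    bending = max(bending, 0.0)

    lo = ref.min(axis=0)
    hi = ref.max(axis=0)
    span = hi - lo
    lo = lo - margin * span
    hi = hi + margin * span
    gx, gy = np.meshgrid(np.linspace(lo[0], hi[0], grid),
                         np.linspace(lo[1], hi[1], grid))
    nodes = np.column_stack([gx.ravel(), gy.ravel()])
    warp = TpsWarp(reference=ref, target=tgt, weights=w, affine=a,
                   bending_energy=bending, grid=np.empty((0, 2)),
                   grid_shape=(grid, grid))
    warp.grid = warp.transform(nodes)
    return warp


# ---------------------------------------------------------------------------
# t-SNE
# ---------------------------------------------------------------------------

def tsne_embed(features: np.ndarray, seed: int | None = None,
               n_iter: int = 500) -> np.ndarray:
    """3D t-SNE embedding with perplexity ceil(sqrt(n)) and 500 iterations."""
    from sklearn.manifold import TSNE

    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 10:
        raise ValueError("t-SNE needs a 2D feature matrix with n >= 10")
    n = X.shape[0]
    perplexity = math.ceil(math.sqrt(n))
    if n < 3 * perplexity:
        raise ValueError(
            f"n = {n} is too small for perplexity {perplexity}; t-SNE needs "
            f"n >= 3 * perplexity (add specimens or embed a larger sample)"
        )
    tsne = TSNE(n_components=3, perplexity=perplexity, max_iter=n_iter,
                init="random", random_state=seed, method="barnes_hut")
    return tsne.fit_transform(X)
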