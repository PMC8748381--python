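"""Multivariate curve resolution by alternating least squares (MCR-ALS).

Each peak cluster is a bilinear mixture: the recorded matrix X (time x
channel) is C @ S.T + E, where the columns of C are the elution
(concentration) profiles and the columns of S the component spectra.  The
decomposition is intrinsically ambiguous; two constraints natural to
chromatographic data restrict the rotational freedom here: non-negativity of
both profiles and spectra, and unimodality of each elution profile (a pure
component rises and falls once).

The alternating scheme needs an initial spectral estimate; the purity-based
SIMPLISMA selection provides it by picking the most "pure" time points, i.e.
rows of X dominated by a single underlying component.

Conventions: spectra are unit-normalized (Euclidean) with all intensity
scale carried by C, and the convergence metric is the lack of fit,
lof = 100 * sqrt(sum(E**2) / sum(X**2)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .clusters import PeakCluster

__all__ = [
    "BilinearFit",
    "ExtractedComponent",
    "simplisma",
    "mcr_als",
    "unimodal_project",
    "estimate_rank",
    "extract_components",
    "ms_noise_count",
    "resolve_cluster",
    "lack_of_fit",
]

RANK_CAP = 6  # at most six components extracted per peak cluster


def lack_of_fit(X: np.ndarray, C: np.ndarray, S: np.ndarray) -> float:
    """Percent lack of fit, 100*sqrt(sum(E^2)/sum(X^2))."""
    E = X - C @ S.T
    denom = float(np.sum(X**2))
    if denom == 0:
        return 0.0
    return 100.0 * float(np.sqrt(np.sum(E**2) / denom))


@dataclass
class BilinearFit:
    C: np.ndarray  # (n_time, n_comp) non-negative, unimodal columns
    S: np.ndarray  # (n_channel, n_comp) non-negative, unit-norm columns
    lof: float
    n_iter: int
    converged: bool
    lof_history: list[float] = field(default_factory=list)

    @property
    def rank(self) -> int:
        return self.C.shape[1]


@dataclass
class ExtractedComponent:
    """One resolved component of one cluster in one run."""

    run_id: str
    cluster_id: int
    profile: np.ndarray
    spectrum: np.ndarray  # unit Euclidean norm
    apex_time: float
    purity: float
    pure: bool  # eluted alone (cluster rank 1)
    truncated: bool = False  # apex on the cluster boundary
    ms_spectrum: dict[float, float] | None = None
    noise_count: int | None = None
    column_id: str = ""
    role: str = "calibration"


# ---------------------------------------------------------------------------
# SIMPLISMA


def simplisma(
    X: np.ndarray, n_max: int, alpha_pct: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Purity-based selection of initial spectra from the purest time points.

    For each row i (the spectrum recorded at one time point) the purity is
    p_i = sigma_i / (mu_i + alpha), with mu_i, sigma_i the mean and standard
    deviation across channels and alpha an offset equal to ``alpha_pct`` % of
    the maximum of the mean spectrum; the offset keeps near-baseline rows
    (tiny mean, noise-dominated) from looking spuriously pure.  After each
    selection, candidate rows are down-weighted by the determinant of the
    correlation-around-origin matrix of the already-selected rows plus the
    candidate, which suppresses directions already represented.

    Returns (spectra, purities): up to ``n_max`` rows of X (unit-normalized)
    in selection order, with their weighted purity scores.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.size == 0 or not np.any(X > 0):
        raise ValueError("SIMPLISMA needs a non-zero matrix")
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if alpha_pct <= 0:
        raise ValueError("alpha_pct must be positive")

    n_t, n_c = X.shape
    mu = X.mean(axis=1)
    sd = X.std(axis=1)
    alpha = (alpha_pct / 100.0) * float(X.mean(axis=0).max())
    purity0 = sd / (mu + alpha)

    # rows scaled for the correlation-around-origin determinant weights
    lam = np.sqrt(mu**2 + (sd + alpha) ** 2)
    Z = X / lam[:, None]

    # determinant weights computed incrementally: only the correlations of
    # each candidate row with the already-selected rows are needed
    selected: list[int] = []
    scores: list[float] = []
    self_corr = np.einsum("ij,ij->i", Z, Z) / n_c
    for _ in range(min(n_max, n_t)):
        if not selected:
            weights = np.ones(n_t)
        else:
            Zs = Z[selected]  # (k, n_c)
            cross = (Z @ Zs.T) / n_c  # (n_t, k)
            coo_sel = (Zs @ Zs.T) / n_c  # (k, k)
            k = len(selected)
            M = np.empty((n_t, k + 1, k + 1))
            M[:, 0, 0] = self_corr
            M[:, 0, 1:] = cross
            M[:, 1:, 0] = cross
            M[:, 1:, 1:] = coo_sel
            weights = np.maximum(np.linalg.det(M), 0.0)
        p = purity0 * weights
        p[selected] = -np.inf
        best = int(np.argmax(p))
        if not np.isfinite(p[best]) or p[best] <= 0:
            break
        selected.append(best)
        scores.append(float(p[best]))

    spectra = X[selected, :].astype(float)
    norms = np.linalg.norm(spectra, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return (spectra / norms).T, np.array(scores)  # (n_channel, n_sel)


# ---------------------------------------------------------------------------
# unimodality


def unimodal_project(y: np.ndarray) -> np.ndarray:
    """Least-squares unimodal (rise-then-fall) non-negative fit of y about
    its maximum: isotonic increasing up to the argmax (pool-adjacent-
    violators), antitonic decreasing after."""
    from sklearn.isotonic import isotonic_regression

    y = np.asarray(y, dtype=float)
    if y.size <= 2:
        return np.clip(y, 0.0, None)
    m = int(np.argmax(y))
    left = isotonic_regression(y[: m + 1], increasing=True)
    right = isotonic_regression(y[m:], increasing=False)
    out = np.concatenate([left, right[1:]])
    out[m] = max(left[-1], right[0])
    return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# ALS


def _nnls_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve min ||A x_i - b_i|| with x_i >= 0 for every column b_i of B.

    For the small ranks used here (<= 6 components) the NNLS optimum is
    found exactly by enumerating the 2^r - 1 possible support sets on the
    Gram system — the optimum is the feasible support solution with the
    lowest residual — which batches over all right-hand sides at once and
    is orders of magnitude faster than per-column active-set calls.
    Larger ranks fall back to scipy's NNLS.
    """
    r = A.shape[1]
    m = B.shape[1]
    if r > 8:
        out = np.empty((m, r))
        for i in range(m):
            out[i], _ = nnls(A, B[:, i])
        return out
    G = A.T @ A  # (r, r)
    C = A.T @ B  # (r, m)
    best_obj = np.full(m, np.inf)
    best_x = np.zeros((m, r))
    # objective: ||A x - b||^2 - ||b||^2 = x^T G x - 2 x^T c  (minimize)
    for mask in range(1, 1 << r):
        J = [j for j in range(r) if mask >> j & 1]
        GJ = G[np.ix_(J, J)]
        try:
            alpha = np.linalg.solve(GJ, C[J, :])  # (|J|, m)
        except np.linalg.LinAlgError:
            continue
        feasible = np.all(alpha >= 0, axis=0)
        if not feasible.any():
            continue
        obj = np.einsum("jm,jm->m", alpha, GJ @ alpha) - 2.0 * np.einsum(
            "jm,jm->m", alpha, C[J, :]
        )
        better = feasible & (obj < best_obj - 1e-15)
        if better.any():
            best_obj[better] = obj[better]
            best_x[better] = 0.0
            cols = np.flatnonzero(better)
            for jj, j in enumerate(J):
                best_x[cols, j] = alpha[jj, cols]
    # all-zero solution (objective 0) wins when nothing negative helps
    zero_better = best_obj > 0
    best_x[zero_better] = 0.0
    return best_x


def mcr_als(
    X: np.ndarray,
    init_spectra: np.ndarray,
    unimodal: bool = True,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> BilinearFit:
    """Alternating least squares under non-negativity (and unimodality of C).

    ``init_spectra`` is (n_channel, rank).  Iterates
    C <- argmin ||X - C S^T|| s.t. C >= 0, columns unimodal;
    S <- argmin ||X - C S^T|| s.t. S >= 0,
    stopping when the relative change of the lack of fit falls below ``tol``
    or after ``max_iter`` sweeps.  Ten consecutive lof increases flag the fit
    as diverged (non-converged).
    """
    X = np.clip(np.asarray(X, dtype=float), 0.0, None)
    n_t, n_c = X.shape
    S = np.asarray(init_spectra, dtype=float)
    if S.ndim != 2 or S.shape[0] != n_c:
        raise ValueError("init_spectra must be (n_channel, rank)")
    rank = S.shape[1]
    if rank > min(n_t, n_c):
        raise ValueError("rank exceeds matrix dimensions")

    lof_prev = np.inf
    history: list[float] = []
    converged = False
    bad_streak = 0
    C = np.zeros((n_t, rank))
    it = 0
    for it in range(1, max_iter + 1):
        # C-step: per-time-point NNLS against the current spectra
        C = _nnls_rows(S, X.T)
        if unimodal:
            for j in range(rank):
                C[:, j] = unimodal_project(C[:, j])
        # S-step: per-channel NNLS against the current profiles;
        # _nnls_rows(C, X) returns one row per channel -> (n_channel, rank)
        S = _nnls_rows(C, X)
        # unit-normalize spectra columns, push the scale into C
        norms = np.linalg.norm(S, axis=0)
        keep = norms > 0
        S[:, keep] = S[:, keep] / norms[keep][None, :]
        C[:, keep] = C[:, keep] * norms[keep][None, :]

        lof = lack_of_fit(X, C, S)
        history.append(lof)
        if lof > lof_prev + 1e-12:
            bad_streak += 1
            if bad_streak >= 10:
                break
        else:
            bad_streak = 0
        # relative lof change, with an absolute floor of tol percentage
        # points so near-perfect fits (lof ~ 0) still register as converged
        if np.isfinite(lof_prev) and abs(lof_prev - lof) <= tol * max(lof_prev, 1.0):
            converged = True
            lof_prev = lof
            break
        lof_prev = lof

    lof = history[-1] if history else lack_of_fit(X, C, S)
    return BilinearFit(C=C, S=S, lof=lof, n_iter=it, converged=converged, lof_history=history)


# ---------------------------------------------------------------------------
# rank estimation and extraction


def estimate_rank(
    X: np.ndarray,
    cap: int = RANK_CAP,
    lof_threshold: float = 2.0,
    noise_level: float | None = None,
    alpha_pct: float = 3.0,
    max_iter: int = 150,
) -> int:
    """Number of components to extract from a cluster, never above ``cap``.

    A candidate count comes from the SVD: singular values above a noise floor
    estimated from the cluster's edge rows (or the supplied ``noise_level``).
    Then ranks 1..candidate are fitted and the smallest rank whose lack of
    fit drops below ``lof_threshold`` (percent) is returned.  A cluster whose
    signal never rises above the noise floor has rank 0 and should have been
    dropped upstream.
    """
    X = np.clip(np.asarray(X, dtype=float), 0.0, None)
    if X.size == 0:
        return 0
    sv = np.linalg.svd(X, compute_uv=False)
    if noise_level is None:
        n_edge = max(2, X.shape[0] // 10)
        edges = np.vstack([X[:n_edge], X[-n_edge:]])
        noise_level = float(edges.std()) or float(X.std() * 1e-6)
    # signal presence: the matrix maximum must clear the expected extreme of
    # |noise| over m*n cells (sigma*sqrt(2 ln 2mn)) by a few Gumbel scales
    a = np.sqrt(2.0 * np.log(2.0 * X.size))
    extreme = noise_level * (a + 3.0 / a)
    if X.max() <= extreme:
        return 0
    # noise floor for singular values of an (m x n) iid-noise matrix
    floor = noise_level * (np.sqrt(X.shape[0]) + np.sqrt(X.shape[1]))
    candidate = int(np.sum(sv > max(floor, sv[0] * 1e-9)))
    candidate = min(max(candidate, 1), cap, min(X.shape))
    best = candidate
    for r in range(1, candidate + 1):
        init, _ = simplisma(X, r, alpha_pct=alpha_pct)
        if init.shape[1] < r:
            break
        fit = mcr_als(X, init, max_iter=max_iter)
        if fit.lof < lof_threshold:
            best = r
            break
    return best


def ms_noise_count(spectrum: dict[float, float] | np.ndarray, pct: float = 0.1) -> int:
    """Number of non-base signals above ``pct`` % of the base peak.

    A clean electrospray spectrum has only a handful of real fragments above
    this floor; a large count marks a noise-dominated extraction.
    """
    if isinstance(spectrum, dict):
        vals = np.array(list(spectrum.values()), dtype=float)
    else:
        vals = np.asarray(spectrum, dtype=float)
    vals = vals[vals > 0]
    if vals.size == 0:
        return 0
    base = vals.max()
    above = int(np.sum(vals > base * pct / 100.0))
    return max(above - 1, 0)  # the base peak itself does not count


def extract_components(
    fit: BilinearFit,
    cluster: PeakCluster,
    purities: np.ndarray | None = None,
    uv_purity_min_frac: float = 0.05,
    ms_noise_max: int | None = None,
    ms_spectra: list[dict[float, float] | None] | None = None,
    column_id: str = "",
    role: str = "calibration",
    cluster_id: int = 0,
    dominance_frac: float = 0.95,
) -> list[ExtractedComponent]:
    """Turn a bilinear fit into per-component records with lenient screens.

    The purity screen keeps every component whose SIMPLISMA purity exceeds
    ``uv_purity_min_frac`` of the cluster's top purity; the MS screen (when
    MS spectra are attached) drops components whose noise count exceeds
    ``ms_noise_max``.  Both screens are deliberately permissive — a missed
    true component (false negative) is worse than an extra candidate, which
    later cross-run diagnostics can still remove.  Components whose profile
    maximum sits on the cluster boundary are kept but flagged truncated.

    A component is flagged pure when it eluted alone (cluster rank 1) or
    when its profile dominates the cluster around its own apex: its share of
    the total fitted signal there is at least ``dominance_frac``.
    """
    out: list[ExtractedComponent] = []
    rank = fit.rank
    if purities is None:
        purities = np.ones(rank)
    top = float(np.max(purities)) if len(purities) else 1.0
    total_c = fit.C.sum(axis=1)
    for j in range(rank):
        profile = fit.C[:, j]
        if not np.any(profile > 0):
            continue
        i_apex = int(np.argmax(profile))
        lo = max(i_apex - 2, 0)
        hi = min(i_apex + 3, len(profile))
        share = float(profile[lo:hi].sum() / max(total_c[lo:hi].sum(), 1e-300))
        is_pure = rank == 1 or share >= dominance_frac
        purity = float(purities[j]) if j < len(purities) else 0.0
        if top > 0 and purity < uv_purity_min_frac * top:
            continue
        ms_spec = ms_spectra[j] if ms_spectra else None
        n_noise = ms_noise_count(ms_spec) if ms_spec is not None else None
        if ms_noise_max is not None and n_noise is not None and n_noise > ms_noise_max:
            continue
        out.append(
            ExtractedComponent(
                run_id=cluster.run_id,
                cluster_id=cluster_id,
                profile=profile.copy(),
                spectrum=fit.S[:, j].copy(),
                apex_time=float(cluster.time[i_apex]),
                purity=purity,
                pure=is_pure,
                truncated=i_apex in (0, len(profile) - 1),
                ms_spectrum=ms_spec,
                noise_count=n_noise,
                column_id=column_id,
                role=role,
            )
        )
    return out


def resolve_cluster(
    cluster: PeakCluster,
    cluster_id: int = 0,
    cap: int = RANK_CAP,
    alpha_pct: float = 3.0,
    lof_threshold: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 500,
    column_id: str = "",
    role: str = "calibration",
) -> tuple[BilinearFit | None, list[ExtractedComponent]]:
    """Rank-estimate, fit and extract one peak cluster end to end."""
    X = np.clip(cluster.submatrix, 0.0, None)
    rank = estimate_rank(
        X, cap=cap, lof_threshold=lof_threshold, noise_level=cluster.noise_level or None,
        alpha_pct=alpha_pct,
    )
    if rank == 0:
        return None, []
    init, purities = simplisma(X, rank, alpha_pct=alpha_pct)
    fit = mcr_als(X, init, tol=tol, max_iter=max_iter)
    comps = extract_components(
        fit,
        cluster,
        purities=purities,
        column_id=column_id,
        role=role,
        cluster_id=cluster_id,
    )
    return fit, comps
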