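"""Compiled numerical kernels for the spectral inversion.

The spectrum deconvolution solves, per candidate (λ∥, λ⊥) pair,

    min_{w >= 0}  ||A w - S||² + α ||w_iso||²,    α = (reg · σ_max(A))²

(equivalently: A augmented with ridge rows reg·σ_max·I over the
isotropic columns; the fiber weight is unpenalized), where A stacks one fiber-decay column and one isotropic-decay column per
grid diffusivity. The outer 2-D search over (λ∥, λ⊥) evaluates this
inner problem thousands of times per voxel fit, so both the nonnegative
solver (Lawson–Hanson on the normal equations) and the Nelder–Mead
driver live here as numba-compiled kernels. scipy's NNLS is used only
as an independent oracle in the test suite, never on this path.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Lawson–Hanson tolerances; _SOLVE_JITTER guards the passive-set solve
# against exactly duplicated columns at α = 0 without moving the solution
# at the accuracy level the inversion is checked to (1e-6).
_W_TOL = 1e-11
_SOLVE_JITTER = 1e-13


@njit(cache=True)
def sigma_max_sq(AtA: np.ndarray) -> float:
    """Largest eigenvalue of AtA (= σ_max(A)²) by power iteration."""
    n = AtA.shape[0]
    v = np.ones(n) / np.sqrt(n)
    lam = 0.0
    for _ in range(60):
        w = AtA @ v
        new_lam = np.sqrt(w @ w)
        if new_lam == 0.0:
            return 0.0
        v = w / new_lam
        if abs(new_lam - lam) <= 1e-12 * new_lam:
            lam = new_lam
            break
        lam = new_lam
    return lam


@njit(cache=True)
def nnls_normal(AtA: np.ndarray, Atb: np.ndarray, max_iter: int) -> np.ndarray:
    """Nonnegative least squares via Lawson–Hanson on normal equations.

    Solves min_{x>=0} ||Ax - b||² given AtA = AᵀA and Atb = Aᵀb.
    """
    n = Atb.size
    x = np.zeros(n)
    passive = np.zeros(n, dtype=np.bool_)
    scale = np.abs(Atb).max()
    if scale == 0.0:
        return x
    tol = _W_TOL * scale
    jitter = _SOLVE_JITTER * np.trace(AtA) / n

    # Warm start (Bro & de Jong style): begin from the unconstrained
    # solution and deactivate all negative coefficients at once. The
    # standard Lawson-Hanson loop below then restores exactness; this
    # only saves the column-by-column build-up when the solution is
    # dense, as it is under the ridge.
    passive[:] = True
    for _ in range(n):
        idx = np.flatnonzero(passive)
        m = idx.size
        if m == 0:
            break
        sub = np.empty((m, m))
        rhs = np.empty(m)
        for a in range(m):
            rhs[a] = Atb[idx[a]]
            for bcol in range(m):
                sub[a, bcol] = AtA[idx[a], idx[bcol]]
            sub[a, a] += jitter
        s = np.linalg.solve(sub, rhs)
        if np.all(s > 0.0):
            for a in range(m):
                x[idx[a]] = s[a]
            break
        for a in range(m):
            if s[a] <= 0.0:
                passive[idx[a]] = False
    w = Atb - AtA @ x

    for _ in range(max_iter):
        # most violated KKT multiplier among the active (zero) set
        j_best = -1
        w_best = tol
        for j in range(n):
            if not passive[j] and w[j] > w_best:
                w_best = w[j]
                j_best = j
        if j_best < 0:
            break
        passive[j_best] = True

        while True:
            idx = np.flatnonzero(passive)
            m = idx.size
            sub = np.empty((m, m))
            rhs = np.empty(m)
            for a in range(m):
                rhs[a] = Atb[idx[a]]
                for bcol in range(m):
                    sub[a, bcol] = AtA[idx[a], idx[bcol]]
                sub[a, a] += jitter
            s = np.linalg.solve(sub, rhs)
            if np.all(s > 0.0):
                x[:] = 0.0
                for a in range(m):
                    x[idx[a]] = s[a]
                break
            # step toward s until the first passive coefficient hits zero
            alpha = 1.0
            for a in range(m):
                if s[a] <= 0.0:
                    denom = x[idx[a]] - s[a]
                    if denom > 0.0:
                        ratio = x[idx[a]] / denom
                        if ratio < alpha:
                            alpha = ratio
            for a in range(m):
                xi = x[idx[a]] + alpha * (s[a] - x[idx[a]])
                x[idx[a]] = xi
                if xi <= tol:
                    x[idx[a]] = 0.0
                    passive[idx[a]] = False
        w = Atb - AtA @ x
    return x


@njit(cache=True)
def nnls_direct(A: np.ndarray, b: np.ndarray, max_iter: int) -> np.ndarray:
    """Lawson–Hanson NNLS solving passive subproblems on A itself.

    Working on A's columns (QR/SVD via lstsq) instead of the normal
    equations keeps full accuracy on ill-conditioned designs — the
    unregularized exactness path. The ridge path uses
    :func:`nnls_normal`, whose diagonal is already conditioned by α.
    """
    m, n = A.shape
    x = np.zeros(n)
    passive = np.zeros(n, dtype=np.bool_)
    # column equilibration: unit-norm columns precondition the walk and
    # make the gradient selection rule scale-free
    norms = np.empty(n)
    An = A.copy()
    for j in range(n):
        nj = np.sqrt((A[:, j] * A[:, j]).sum())
        norms[j] = nj if nj > 0.0 else 1.0
        An[:, j] = A[:, j] / norms[j]
    A = An
    Atb = A.T @ b
    scale = np.abs(Atb).max()
    if scale == 0.0:
        return x
    # machine-level optimality: on consistent (noise-free) systems the
    # active-set walk must continue until the KKT residual is at eps
    # scale, or ill-conditioned designs stall on a wrong support
    tol = 2e-15 * scale

    w = Atb.copy()
    banned = np.zeros(n, dtype=np.bool_)  # anti-cycling on degenerate pivots
    for _ in range(max_iter):
        j_best = -1
        w_best = tol
        for j in range(n):
            if not passive[j] and not banned[j] and w[j] > w_best:
                w_best = w[j]
                j_best = j
        if j_best < 0:
            break
        passive[j_best] = True
        moved = False

        while True:
            idx = np.flatnonzero(passive)
            sub = A[:, idx].copy()
            # thin QR + back-substitution: the exact LS minimizer with
            # no small-singular-value truncation (unlike lstsq/gelsd)
            q, r = np.linalg.qr(sub)
            rhs = q.T @ b
            k = idx.size
            s = np.empty(k)
            for a in range(k - 1, -1, -1):
                acc = rhs[a]
                for c in range(a + 1, k):
                    acc -= r[a, c] * s[c]
                s[a] = acc / r[a, a] if r[a, a] != 0.0 else 0.0
            if np.all(s > 0.0):
                x[:] = 0.0
                for a in range(idx.size):
                    x[idx[a]] = s[a]
                moved = True
                break
            alpha = 1.0
            for a in range(idx.size):
                if s[a] <= 0.0:
                    denom = x[idx[a]] - s[a]
                    if denom > 0.0:
                        ratio = x[idx[a]] / denom
                        if ratio < alpha:
                            alpha = ratio
            if alpha > 0.0:
                moved = True
            dropped_entering = False
            for a in range(idx.size):
                xi = x[idx[a]] + alpha * (s[a] - x[idx[a]])
                x[idx[a]] = xi
                if xi <= tol:
                    x[idx[a]] = 0.0
                    passive[idx[a]] = False
                    if idx[a] == j_best:
                        dropped_entering = True
            if dropped_entering and alpha == 0.0:
                break  # degenerate pivot: entering column exited at once
        if moved:
            banned[:] = False
        elif not passive[j_best]:
            # bar the degenerate column until any genuine step is taken,
            # so the walk cannot cycle on it
            banned[j_best] = True
        # residual-first gradient: A.T @ (b - Ax) stays accurate at eps
        # scale, whereas Atb - A.T @ (A x) cancels catastrophically
        w = A.T @ (b - A @ x)
    return x / norms


@njit(cache=True)
def inner_solve(
    lpar: float,
    lperp: float,
    cos2: np.ndarray,
    b_ms: np.ndarray,
    signal: np.ndarray,
    A_iso: np.ndarray,
    AtA_iso: np.ndarray,
    Ats_iso: np.ndarray,
    reg_weight: float,
):
    """Inner spectrum fit at fixed fiber diffusivities.

    Returns (weights, data_residual_norm); weights[0] is the fiber
    weight, weights[1:] the isotropic grid weights.
    """
    n_vol = signal.size
    n_iso = A_iso.shape[1]
    n = n_iso + 1

    fiber_col = np.empty(n_vol)
    for k in range(n_vol):
        fiber_col[k] = np.exp(-b_ms[k] * lperp - b_ms[k] * (lpar - lperp) * cos2[k])

    AtA = np.empty((n, n))
    Atb = np.empty(n)
    AtA[0, 0] = fiber_col @ fiber_col
    for j in range(n_iso):
        v = 0.0
        for k in range(n_vol):
            v += fiber_col[k] * A_iso[k, j]
        AtA[0, j + 1] = v
        AtA[j + 1, 0] = v
    AtA[1:, 1:] = AtA_iso
    Atb[0] = fiber_col @ signal
    Atb[1:] = Ats_iso

    if reg_weight > 0.0:
        # Tikhonov on the spectrum weights only (the ill-posed part of the
        # inversion); the fiber weight is well determined and unpenalized.
        # Penalty (reg·σ_max(A))²·||w_iso||², i.e. ridge rows appended to A.
        alpha = reg_weight * reg_weight * sigma_max_sq(AtA)
        AtA_reg = AtA.copy()
        for j in range(1, n):
            AtA_reg[j, j] += alpha
        x = nnls_normal(AtA_reg, Atb, 3 * n)
    else:
        A = np.empty((n_vol, n))
        A[:, 0] = fiber_col
        A[:, 1:] = A_iso
        x = nnls_direct(A, signal, 3 * n)
    # residual evaluated directly (the quadratic-form shortcut
    # S·S − 2x·Atb + x·AtA·x cancels catastrophically near zero)
    res2 = 0.0
    for k in range(n_vol):
        pred = x[0] * fiber_col[k]
        for j in range(n_iso):
            pred += x[j + 1] * A_iso[k, j]
        diff = signal[k] - pred
        res2 += diff * diff
    return x, np.sqrt(res2)


@njit(cache=True)
def _penalized_objective(
    lpar: float,
    lperp: float,
    lpar_lo: float,
    lpar_hi: float,
    lperp_lo: float,
    lperp_hi: float,
    cos2: np.ndarray,
    b_ms: np.ndarray,
    signal: np.ndarray,
    A_iso: np.ndarray,
    AtA_iso: np.ndarray,
    Ats_iso: np.ndarray,
    reg_weight: float,
    scale: float,
) -> float:
    """Inner residual at the box-clipped point plus smooth bound penalties."""
    cp = min(max(lpar, lpar_lo), lpar_hi)
    cq = min(max(lperp, lperp_lo), lperp_hi)
    penalty = (lpar - cp) ** 2 + (lperp - cq) ** 2
    if cq > cp:  # fiber must satisfy λ∥ >= λ⊥
        penalty += (cq - cp) ** 2
        cq = cp
    _, res = inner_solve(cp, cq, cos2, b_ms, signal, A_iso, AtA_iso, Ats_iso, reg_weight)
    return res + 1e3 * scale * penalty


@njit(cache=True)
def fit_diffusivities(
    starts: np.ndarray,
    lpar_lo: float,
    lpar_hi: float,
    lperp_lo: float,
    lperp_hi: float,
    cos2: np.ndarray,
    b_ms: np.ndarray,
    signal: np.ndarray,
    A_iso: np.ndarray,
    AtA_iso: np.ndarray,
    Ats_iso: np.ndarray,
    reg_weight: float,
    ftol: float,
    maxfev: int,
):
    """Multistart Nelder–Mead over (λ∥, λ⊥) minimizing the inner residual.

    Returns (best_lpar, best_lperp, best_residual, converged).
    """
    scale = np.sqrt(signal @ signal) + 1e-30
    best_f = np.inf
    best_p = starts[0].copy()
    any_converged = False

    for s in range(starts.shape[0]):
        # initial simplex around the start point
        simplex = np.empty((3, 2))
        fvals = np.empty(3)
        simplex[0] = starts[s]
        simplex[1, 0] = starts[s, 0] + 0.10 * (lpar_hi - lpar_lo)
        simplex[1, 1] = starts[s, 1]
        simplex[2, 0] = starts[s, 0]
        simplex[2, 1] = starts[s, 1] + 0.10 * (lperp_hi - lperp_lo)
        for i in range(3):
            fvals[i] = _penalized_objective(
                simplex[i, 0], simplex[i, 1], lpar_lo, lpar_hi, lperp_lo, lperp_hi,
                cos2, b_ms, signal, A_iso, AtA_iso, Ats_iso, reg_weight, scale,
            )
        nfev = 3
        converged = False
        while nfev < maxfev:
            order = np.argsort(fvals)
            simplex = simplex[order]
            fvals = fvals[order]
            if fvals[2] - fvals[0] <= ftol * (abs(fvals[0]) + ftol):
                converged = True
                break
            centroid = 0.5 * (simplex[0] + simplex[1])
            xr = centroid + (centroid - simplex[2])
            fr = _penalized_objective(
                xr[0], xr[1], lpar_lo, lpar_hi, lperp_lo, lperp_hi,
                cos2, b_ms, signal, A_iso, AtA_iso, Ats_iso, reg_weight, scale,
            )
            nfev += 1
            if fr < fvals[0]:
                xe = centroid + 2.0 * (centroid - simplex[2])
                fe = _penalized_objective(
                    xe[0], xe[1], lpar_lo, lpar_hi, lperp_lo, lperp_hi,
                    cos2, b_ms, signal, A_iso, AtA_iso, Ats_iso, reg_weight, scale,
                )
                nfev += 1
                if fe < fr:
                    simplex[2], fvals[2] = xe, fe
                else:
                    simplex[2], fvals[2] = xr, fr
            elif fr < fvals[1]:
                simplex[2], fvals[2] = xr, fr
            else:
                if fr < fvals[2]:
                    xc = centroid + 0.5 * (xr - centroid)
                else:
                    xc = centroid + 0.5 * (simplex[2] - centroid)
                fc = _penalized_objective(
                    xc[0], xc[1], lpar_lo, lpar_hi, lperp_lo, lperp_hi,
                    cos2, b_ms, signal, A_iso, AtA_iso, Ats_iso, reg_weight, scale,
                )
                nfev += 1
                if fc < min(fr, fvals[2]):
                    simplex[2], fvals[2] = xc, fc
                else:  # shrink toward the best vertex
                    for i in range(1, 3):
                        simplex[i] = simplex[0] + 0.5 * (simplex[i] - simplex[0])
                        fvals[i] = _penalized_objective(
                            simplex[i, 0], simplex[i, 1],
                            lpar_lo, lpar_hi, lperp_lo, lperp_hi,
                            cos2, b_ms, signal, A_iso, AtA_iso, Ats_iso,
                            reg_weight, scale,
                        )
                        nfev += 1
        order = np.argsort(fvals)
        if fvals[order[0]] < best_f:
            best_f = fvals[order[0]]
            best_p = simplex[order[0]].copy()
            any_converged = converged

    lpar = min(max(best_p[0], lpar_lo), lpar_hi)
    lperp = min(max(best_p[1], lperp_lo), lperp_hi)
    if lperp > lpar:
        lperp = lpar
    return lpar, lperp, best_f, any_converged
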