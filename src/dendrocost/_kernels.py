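"""Numba kernels for the steady-state protein boundary-value problem.

The shaft protein equation
``0 = tau*m + D_p p'' - lambda_p p - lambda_p s(p)``
with the quasi-steady spine occupancy
``s(p) = u_p p E / (u_p p + (nu_p+lambda_p) E)``, ``E = rho*eta_p``,
is discretised with a conservative finite-volume scheme (half cells at both
ends) so that the discrete flux balance
``J_0 + tau*sum(w*m) = lambda_p*sum(w*(p+s))`` holds to solver precision
with trapezoidal weights ``w``. The nonlinear spine sink is handled by a
Newton linearisation (tridiagonal Jacobian solves); the mRNA amplitude is
then bracketed and bisected in log-space until the spatial minimum of the
shaft density reaches the distal filling target.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _thomas(lower, diag, upper, rhs):
    """Solve a tridiagonal system (Thomas algorithm)."""
    n = diag.shape[0]
    cp = np.empty(n)
    dp = np.empty(n)
    cp[0] = upper[0] / diag[0]
    dp[0] = rhs[0] / diag[0]
    for i in range(1, n):
        denom = diag[i] - lower[i] * cp[i - 1]
        cp[i] = upper[i] / denom
        dp[i] = (rhs[i] - lower[i] * dp[i - 1]) / denom
    x = np.empty(n)
    x[n - 1] = dp[n - 1]
    for i in range(n - 2, -1, -1):
        x[i] = dp[i] - cp[i] * x[i + 1]
    return x


@njit(cache=True)
def protein_newton(m, J0, tau, Dp, lam_p, up, cexit, E, dx, p, tol, maxit):
    """Newton solve of the finite-volume protein BVP, in-place on ``p``.

    ``m`` is the dendritic mRNA density on the grid, ``J0`` the protein
    influx at x = 0 (soma face), ``cexit = nu_p + lambda_p`` the total spine
    exit rate and ``E = rho*eta_p`` the spine capacity density. Returns the
    iteration count (negative if not converged).
    """
    n = m.shape[0]
    lower = np.empty(n)
    diag = np.empty(n)
    upper = np.empty(n)
    rhs = np.empty(n)
    a_int = Dp / (dx * dx)          # coupling for interior (w = dx)
    a_end = 2.0 * Dp / (dx * dx)    # coupling for boundary half cells

    dmax_prev = np.inf
    for it in range(maxit):
        pmax = 0.0
        for i in range(n):
            if p[i] > pmax:
                pmax = p[i]
        # residual and Jacobian
        for i in range(n):
            denom = up * p[i] + cexit * E
            s = up * p[i] * E / denom
            sp = up * cexit * E * E / (denom * denom)
            if i == 0:
                flux = a_end * (p[1] - p[0]) + 2.0 * J0 / dx
                lower[i] = 0.0
                upper[i] = a_end
                diag[i] = -a_end - lam_p - lam_p * sp
            elif i == n - 1:
                flux = a_end * (p[n - 2] - p[n - 1])
                lower[i] = a_end
                upper[i] = 0.0
                diag[i] = -a_end - lam_p - lam_p * sp
            else:
                flux = a_int * (p[i + 1] - 2.0 * p[i] + p[i - 1])
                lower[i] = a_int
                upper[i] = a_int
                diag[i] = -2.0 * a_int - lam_p - lam_p * sp
            rhs[i] = -(flux + tau * m[i] - lam_p * p[i] - lam_p * s)
        delta = _thomas(lower, diag, upper, rhs)
        dmax = 0.0
        for i in range(n):
            p[i] += delta[i]
            if p[i] < 0.0:
                p[i] = 0.0
            if abs(delta[i]) > dmax:
                dmax = abs(delta[i])
        scale = pmax if pmax > 0.0 else 1.0
        if dmax <= tol * scale:
            return it + 1
        # Newton is quadratic once in the basin; a step that stops shrinking
        # while already tiny relative to the solution is the roundoff floor
        if it >= 3 and dmax <= 1e-7 * scale and dmax >= 0.25 * dmax_prev:
            return it + 1
        dmax_prev = dmax
    return -maxit


@njit(cache=True)
def spine_occupancy_kernel(p, up, cexit, E):
    s = np.empty_like(p)
    for i in range(p.shape[0]):
        s[i] = up * p[i] * E / (up * p[i] + cexit * E)
    return s


@njit(cache=True)
def solve_amplitude(
    m_hat, m_soma_hat, tau, Dp, lam_p, up, cexit, E, dx,
    p_target, A_init, tol_newton, tol_amp,
):
    """Find the mRNA amplitude A with ``min_x p = p_target``.

    The unit-amplitude dendritic mRNA shape ``m_hat`` and somatic pool
    ``m_soma_hat`` are both scaled by A; the somatic protein influx is
    ``tau * A * m_soma_hat`` (all somatic synthesis is exported). The
    spatial minimum of the shaft density increases monotonically with A,
    so a log-space bracket + bisection is exact. Returns
    ``(A, p, status)`` with status 0 on success, 1 if bracketing failed,
    2 if the inner Newton failed.
    """
    n = m_hat.shape[0]
    p = np.zeros(n)
    m = np.empty(n)

    def _eval(A, p_ws):
        for i in range(n):
            m[i] = A * m_hat[i]
        J0 = tau * A * m_soma_hat
        it = protein_newton(m, J0, tau, Dp, lam_p, up, cexit, E, dx,
                            p_ws, tol_newton, 80)
        pmin = p_ws[0]
        for i in range(1, n):
            if p_ws[i] < pmin:
                pmin = p_ws[i]
        return pmin, it

    A_prev = A_init
    pmin, it = _eval(A_prev, p)
    if it < 0:
        return A_prev, p, 2
    # bracket in decades
    if pmin < p_target:
        A_lo = A_prev
        ok = False
        for _ in range(320):
            A_hi = A_lo * 10.0
            for i in range(n):
                p[i] *= 10.0
            pmin, it = _eval(A_hi, p)
            A_prev = A_hi
            if it < 0:
                return A_hi, p, 2
            if pmin >= p_target:
                ok = True
                break
            A_lo = A_hi
        if not ok:
            return A_lo, p, 1
    else:
        A_hi = A_prev
        ok = False
        for _ in range(320):
            A_lo = A_hi / 10.0
            for i in range(n):
                p[i] *= 0.1
            pmin, it = _eval(A_lo, p)
            A_prev = A_lo
            if it < 0:
                return A_lo, p, 2
            if pmin < p_target:
                ok = True
                break
            A_hi = A_lo
        if not ok:
            return A_hi, p, 1

    lo = np.log(A_lo)
    hi = np.log(A_hi)
    for _ in range(200):
        if hi - lo <= tol_amp:
            break
        mid = 0.5 * (lo + hi)
        A_mid = np.exp(mid)
        ratio = A_mid / A_prev
        for i in range(n):
            p[i] *= ratio
        pmin, it = _eval(A_mid, p)
        A_prev = A_mid
        if it < 0:
            return A_mid, p, 2
        if pmin >= p_target:
            hi = mid
        else:
            lo = mid
    A = np.exp(hi)
    ratio = A / A_prev
    for i in range(n):
        p[i] *= ratio
    for i in range(n):
        m[i] = A * m_hat[i]
    it = protein_newton(m, tau * A * m_soma_hat, tau, Dp, lam_p, up, cexit,
                        E, dx, p, tol_newton, 80)
    if it < 0:
        return A, p, 2
    return A, p, 0
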