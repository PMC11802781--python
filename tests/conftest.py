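"""Shared fixtures and independent numerical oracles."""

import numpy as np
import pytest

import dendrocost as dc


@pytest.fixture(scope="session")
def camkii():
    return dc.camkii_preset()


@pytest.fixture(scope="session")
def shank3():
    return dc.shank3_preset()


@pytest.fixture(scope="session")
def geom250():
    return dc.default_geometry(250.0)


@pytest.fixture(scope="session")
def geom500():
    return dc.default_geometry(500.0)


@pytest.fixture()
def fast_species():
    """A moderate synthetic species for quick single solves."""
    return dc.SpeciesParams(
        name="fast",
        D_m0=0.001, D_p=0.05,
        halflife_m=8 * 3600.0, halflife_p=8 * 86400.0,
        tau=0.01, eta_p=1000.0, u_p=0.03, nu_p=3e-4,
        N_aa=450, N_nt=2700,
        transport=dc.TransportParams(v=1.0, beta=0.5, alpha=0.05),
    )


# ---------------------------------------------------------------------------
# independent oracles (kept free of the package's solver internals)

def dense_linear_protein_solve(species, geom, m, m_soma):
    """Direct dense solve of the *linear* protein BVP (no spine exchange).

    Finite-volume discretisation assembled independently with numpy and
    solved with a dense linear solver. Influx tau*m_soma at x = 0, sealed
    tip, sink lambda_p only.
    """
    n = geom.n_nodes
    dx = geom.grid_dx
    x = np.linspace(0.0, geom.L, n)
    Dp, lam = species.D_p, species.lambda_p
    A = np.zeros((n, n))
    b = np.zeros(n)
    a_int = Dp / dx**2
    a_end = 2.0 * a_int
    for i in range(1, n - 1):
        A[i, i - 1] = a_int
        A[i, i + 1] = a_int
        A[i, i] = -2.0 * a_int - lam
        b[i] = -species.tau * m[i]
    A[0, 0] = -a_end - lam
    A[0, 1] = a_end
    b[0] = -species.tau * m[0] - 2.0 * species.tau * m_soma / dx
    A[-1, -1] = -a_end - lam
    A[-1, -2] = a_end
    b[-1] = -species.tau * m[-1]
    return np.linalg.solve(A, b), x


def time_integrate_protein(species, geom, m, J0, p0, s0, t_end, dt):
    """Backward-Euler time integration of the shaft/spine protein system.

    Independent re-implementation of the dynamics (conservative stencil,
    implicit shaft, implicit-in-s spine exchange) used as the dynamical
    fixed-point oracle.
    """
    from scipy.linalg import solve_banded

    n = geom.n_nodes
    dx = geom.grid_dx
    E = geom.rho * species.eta_p
    cexit = species.nu_p + species.lambda_p
    a_int = species.D_p / dx**2
    a_end = 2.0 * a_int
    lower = np.zeros(n); upper = np.zeros(n); diag = np.empty(n)
    lower[1:-1] = a_int; upper[1:-1] = a_int
    upper[0] = a_end; lower[-1] = a_end
    diag[0] = diag[-1] = -a_end
    diag[1:-1] = -2.0 * a_int
    diag = diag - species.lambda_p
    ab = np.zeros((3, n))
    ab[0, 1:] = -dt * upper[:-1]
    ab[1] = 1.0 - dt * diag
    ab[2, :-1] = -dt * lower[1:]
    influx = np.zeros(n)
    influx[0] = 2.0 * J0 / dx

    p, s = p0.copy(), s0.copy()
    steps = int(round(t_end / dt))
    for _ in range(steps):
        uptake = species.u_p * p * (1.0 - s / E)
        rhs = p + dt * (species.tau * m + influx - uptake + species.nu_p * s)
        p = solve_banded((1, 1), ab, rhs)
        s = (s + dt * species.u_p * p) / (1.0 + dt * (cexit + species.u_p * p / E))
    return p, s


def ranksum_enumeration(x, y):
    """Exact two-sided rank-sum p-value by full enumeration (tie-free)."""
    from itertools import combinations

    pooled = np.concatenate([x, y])
    assert len(np.unique(pooled)) == len(pooled), "enumeration oracle needs no ties"
    ranks = np.argsort(np.argsort(pooled)) + 1
    n1 = len(x)
    observed = ranks[:n1].sum()
    all_sums = [sum(c) for c in combinations(ranks, n1)]
    mean = np.mean(all_sums)
    dev = abs(observed - mean)
    extreme = sum(1 for s in all_sums if abs(s - mean) >= dev - 1e-12)
    return extreme / len(all_sums)
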