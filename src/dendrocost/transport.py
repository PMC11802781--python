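"""Run-and-pause transport and its mapping to an ensemble diffusion constant.

Motor-driven mRNA movement is modelled as a three-state process: anterograde
and retrograde runs at instantaneous velocity ``v`` (densities ``m_plus``,
``m_minus``) terminating with rate ``beta``, and a resting state ``m_zero``
that diffuses with ``D_m0``, decays with ``lambda_m`` and re-enters each
moving state with rate ``alpha``. At steady state this linear
constant-coefficient system is solved exactly by eigenmode decomposition on
a closed dendrite with a somatic source. The one-state solver then uses an
*ensemble* diffusion constant ``D_eff`` obtained by fitting the one-state
diffusion-decay profile to the total three-state density.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import ConfigurationError, NumericalError
from .params import TransportParams, transported_fraction

__all__ = [
    "ThreeStateProfile", "EffectiveDiffusionFit",
    "solve_three_state", "effective_diffusion", "transported_fraction",
    "normalised_cosh_profile",
]


@dataclass(frozen=True)
class ThreeStateProfile:
    """Steady-state densities of the three transport states on a grid."""

    x: np.ndarray
    m_plus: np.ndarray
    m_minus: np.ndarray
    m_zero: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.m_plus + self.m_minus + self.m_zero


def normalised_cosh_profile(x: np.ndarray, L: float, ell: float) -> np.ndarray:
    """``cosh((L-x)/ell)/cosh(L/ell)``, evaluated overflow-safely."""
    x = np.asarray(x, dtype=float)
    # cosh ratio via exponentials relative to the soma value
    e = np.exp(-x / ell) * (1.0 + np.exp(-2.0 * (L - x) / ell))
    return e / (1.0 + np.exp(-2.0 * L / ell))


def _diffusion_only_profile(x, L, D, lam, J):
    """Closed-form one-state diffusion-decay profile for somatic influx J."""
    ell = np.sqrt(D / lam)
    # -D m'(0) = J  =>  amplitude J*ell/(D*tanh(L/ell))
    amp = J * ell / (D * np.tanh(L / ell))
    return amp * normalised_cosh_profile(x, L, ell)


def solve_three_state(
    params: TransportParams,
    D_m0: float,
    lambda_m: float,
    L: float,
    source: float = 1.0,
    dx: float = 1.0,
) -> ThreeStateProfile:
    """Steady state of the three-state transport model on [0, L].

    Boundary conditions: a somatic source injecting net flux ``source`` into
    the anterograde state at x = 0 (retrograde arrivals reflect into
    anterograde), a reflecting tip where anterograde runs turn retrograde
    (``m_plus(L) = m_minus(L)``), and no diffusive flux of the resting state
    through either end. Decay acts on the resting state only, following the
    three-state dynamics.
    """
    if not lambda_m > 0 or not D_m0 > 0 or not L > 0:
        raise ConfigurationError("lambda_m, D_m0 and L must all be > 0")
    x = np.arange(0.0, L + 0.5 * dx, dx)
    v, alpha, beta = params.v, params.alpha, params.beta

    if v == 0.0 or alpha == 0.0:
        # Moving states carry no spatial structure of their own:
        # total density reduces to the one-state diffusion-decay profile.
        m0 = _diffusion_only_profile(x, L, D_m0, lambda_m, source)
        ratio = alpha / beta
        if v == 0.0:
            # moving states equilibrate to (alpha/beta) m0 and add no shape
            m_plus = ratio * m0
            m_minus = ratio * m0
        else:
            m_plus = np.zeros_like(m0)
            m_minus = np.zeros_like(m0)
        return ThreeStateProfile(x, m_plus, m_minus, m0)

    # y = (m_plus, m_minus, m_zero, m_zero'); y' = A y
    A = np.array([
        [-beta / v, 0.0, alpha / v, 0.0],
        [0.0, beta / v, -alpha / v, 0.0],
        [0.0, 0.0, 0.0, 1.0],
        [-beta / D_m0, -beta / D_m0, (2.0 * alpha + lambda_m) / D_m0, 0.0],
    ])
    w, V = np.linalg.eig(A)
    # Anchor growing modes at x = L, decaying modes at x = 0, so every basis
    # function is bounded by 1 in magnitude on [0, L].
    anchor = np.where(w.real > 0.0, L, 0.0)

    def basis(xv):
        return V * np.exp(w * (xv - anchor))[None, :]  # 4 x 4, column = mode

    B0, BL = basis(0.0), basis(L)
    bc = np.zeros((4, 4), dtype=complex)
    rhs = np.zeros(4, dtype=complex)
    bc[0] = v * (B0[0] - B0[1])     # net advective flux at soma = source
    rhs[0] = source
    bc[1] = B0[3]                   # m_zero'(0) = 0
    bc[2] = BL[0] - BL[1]           # reflecting tip
    bc[3] = BL[3]                   # m_zero'(L) = 0
    try:
        coef = np.linalg.solve(bc, rhs)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            "three-state boundary system is singular",
            {"params": params, "lambda_m": lambda_m, "L": L},
        ) from exc

    prof = np.real(
        (V[:, None, :] * np.exp(w[None, None, :] * (x[None, :, None] - anchor)))
        @ coef
    )
    m_plus, m_minus, m0 = prof[0], prof[1], prof[2]
    total = m_plus + m_minus + m0
    if np.min(total) < -1e-6 * np.max(np.abs(total)):
        raise NumericalError(
            "three-state solution has negative total density",
            {"min_total": float(np.min(total))},
        )
    clip = lambda a: np.clip(a, 0.0, None)
    return ThreeStateProfile(x, clip(m_plus), clip(m_minus), clip(m0))


@dataclass(frozen=True)
class EffectiveDiffusionFit:
    """Result of mapping the three-state profile to one-state diffusion."""

    D_eff: float
    ell: float           # fitted decay length, um
    theta: float         # transported fraction
    residual: float      # RMS deviation of unit-normalised profiles
    strategy: str


def effective_diffusion(
    params: TransportParams,
    D_m0: float,
    lambda_m: float,
    L: float,
    dx: float = 1.0,
    strategy: str = "profile",
    residual_tol: float = 0.5,
) -> EffectiveDiffusionFit:
    """Ensemble diffusion constant summarising run-and-pause transport.

    ``strategy='profile'`` minimises the squared deviation between the
    unit-normalised one-state diffusion-decay steady profile and the
    unit-normalised total three-state density. ``strategy='decay_length'``
    instead matches the soma-to-tip density ratio. In both cases
    ``D_eff = lambda_m * ell**2`` for the fitted length ``ell``.
    """
    prof = solve_three_state(params, D_m0, lambda_m, L, source=1.0, dx=dx)
    total = prof.total
    norm = np.trapezoid(total, prof.x)
    if norm <= 0:
        raise NumericalError("three-state total density vanishes")
    target = total / norm
    span = target.max() - target.min()
    if span < 1e-12 * target.max():
        raise NumericalError(
            "flat three-state profile: effective diffusion unidentifiable",
            {"span": float(span)},
        )

    if strategy == "decay_length":
        ratio = target[-1] / target[0]
        # cosh(L/ell) = 1/ratio
        arg = max(1.0 / ratio, 1.0 + 1e-15)
        ell = L / float(np.arccosh(arg))
    elif strategy == "profile":
        def sse(log_ell):
            ell = np.exp(log_ell)
            model = normalised_cosh_profile(prof.x, L, ell)
            model = model / np.trapezoid(model, prof.x)
            return float(np.sum((model - target) ** 2))

        res = minimize_scalar(
            sse, bounds=(np.log(1e-2), np.log(1e5)), method="bounded",
            options={"xatol": 1e-10},
        )
        ell = float(np.exp(res.x))
    else:
        raise ConfigurationError(f"unknown fit strategy {strategy!r}")

    model = normalised_cosh_profile(prof.x, L, ell)
    model = model / np.trapezoid(model, prof.x)
    residual = float(np.sqrt(np.mean((model - target) ** 2)) / np.mean(target))
    if residual > residual_tol:
        raise NumericalError(
            "effective-diffusion fit residual above tolerance",
            {"residual": residual, "tolerance": residual_tol},
        )
    theta = transported_fraction(params.alpha, params.beta)
    return EffectiveDiffusionFit(
        D_eff=float(lambda_m * ell * ell), ell=ell, theta=theta,
        residual=residual, strategy=strategy,
    )


@functools.lru_cache(maxsize=512)
def cached_effective_diffusion(
    v: float, beta: float, alpha: float, D_m0: float, lambda_m: float, L: float,
) -> EffectiveDiffusionFit:
    """Memoised ``effective_diffusion`` keyed by scalar parameters."""
    return effective_diffusion(
        TransportParams(v=v, beta=beta, alpha=alpha), D_m0, lambda_m, L
    )
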