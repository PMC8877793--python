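"""Parameter containers and ODE right-hand sides.

Two systems are defined:

* the classic three-gene repressilator with linear (first-order) degradation,
  in the standard dimensionless form

  .. math::

     \\dot m_i = -m_i + \\frac{\\alpha}{1 + p_{i-1}^n} + \\alpha_0, \\qquad
     \\dot p_i = -\\beta\\,(p_i - m_i)

* three such repressilators built from independent molecular species that
  interact *only* through competition for shared degradation enzymes,
  modelled by Michaelis–Menten saturation with a common substrate pool:

  .. math::

     \\dot m_{i,j} = \\frac{\\alpha_i}{1 + p_{i,j-1}^n} + \\alpha_{0,i}
                     - \\frac{k\\, m_{i,j}}{K_m + \\sum_{r,s} m_{r,s}}, \\qquad
     \\dot p_{i,j} = \\beta_i m_{i,j}
                     - \\frac{k\\, p_{i,j}}{K_p + \\sum_{r,s} p_{r,s}}

  where ``i`` indexes the repressilator, ``j`` the species within its cycle
  (the predecessor of species 1 is species 3), and the sums run over all nine
  mRNA (resp. protein) species.  One maximum rate ``k`` serves both
  degradation channels: the same enzyme pool degrades everything.

The three activation rates are constructed from a single offset γ as
``(α₂−γ, α₂, α₂+γ)`` with α₂ = 6, so γ directly controls how dissimilar the
oscillators' natural frequencies are.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ClassicParams",
    "CoupledParams",
    "SystemState",
    "classic_rhs",
    "coupled_rhs",
    "build_params",
    "DEFAULTS",
]

#: Reference parameter set: Hill cooperativity, repressed-promoter rate,
#: protein/mRNA decay ratio, maximum degradation rate, central activation rate.
DEFAULTS = dict(n=2.4, alpha0=0.1, beta=1.0, k=10.0, alpha2=6.0)


@dataclass(frozen=True)
class ClassicParams:
    """Parameters of the single uncoupled repressilator."""

    alpha: float = 6.0
    alpha0: float = 0.1
    n: float = 2.4
    beta: float = 1.0

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.alpha0 < 0:
            raise ValueError(f"alpha0 must be non-negative, got {self.alpha0}")
        if not self.n > 0:
            raise ValueError(f"n must be positive, got {self.n}")
        if not self.beta > 0:
            raise ValueError(f"beta must be positive, got {self.beta}")


@dataclass(frozen=True)
class CoupledParams:
    """Parameters of the three-repressilator system with shared degradation.

    ``alphas`` holds the per-repressilator free-promoter activation rates;
    when built via :func:`build_params` they are ``(α₂−γ, α₂, α₂+γ)``.
    ``km`` / ``kp`` are the Michaelis constants of the mRNA and protein
    degradation channels; small values mean a strongly saturated (hence
    strongly coupling) enzyme pool.
    """

    alphas: tuple[float, float, float]
    alpha0s: tuple[float, float, float] = (0.1, 0.1, 0.1)
    betas: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n: float = 2.4
    k: float = 10.0
    km: float = 1.0
    kp: float = 1.0
    gamma: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "alphas", tuple(float(a) for a in self.alphas))
        object.__setattr__(self, "alpha0s", tuple(float(a) for a in self.alpha0s))
        object.__setattr__(self, "betas", tuple(float(b) for b in self.betas))
        if len(self.alphas) != 3 or len(self.alpha0s) != 3 or len(self.betas) != 3:
            raise ValueError("alphas, alpha0s and betas must have length 3")
        if any(a <= 0 for a in self.alphas):
            raise ValueError(f"all alphas must be positive, got {self.alphas}")
        if not self.k > 0:
            raise ValueError(f"k must be positive, got {self.k}")
        if not self.km > 0 or not self.kp > 0:
            raise ValueError(
                f"Michaelis constants must be positive, got km={self.km}, kp={self.kp}"
            )

    def to_dict(self) -> dict:
        return {
            "alphas": list(self.alphas),
            "alpha0s": list(self.alpha0s),
            "betas": list(self.betas),
            "n": self.n,
            "k": self.k,
            "km": self.km,
            "kp": self.kp,
            "gamma": self.gamma,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CoupledParams":
        return cls(
            alphas=tuple(d["alphas"]),
            alpha0s=tuple(d["alpha0s"]),
            betas=tuple(d["betas"]),
            n=d["n"],
            k=d["k"],
            km=d["km"],
            kp=d["kp"],
            gamma=d.get("gamma"),
        )


@dataclass
class SystemState:
    """3×3 mRNA and protein concentrations of the coupled system.

    ``m[i, j]`` / ``p[i, j]``: repressilator ``i``, species ``j`` (0-based
    internally; documentation and config use the 1-based convention).
    """

    m: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.m.shape != (3, 3) or self.p.shape != (3, 3):
            raise ValueError("SystemState requires 3x3 m and p arrays")

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.m.ravel(), self.p.ravel()])

    @classmethod
    def from_flat(cls, y: Sequence[float]) -> "SystemState":
        y = np.asarray(y, dtype=float)
        if y.shape != (18,):
            raise ValueError(f"expected an 18-vector, got shape {y.shape}")
        return cls(m=y[:9].reshape(3, 3), p=y[9:].reshape(3, 3))


def _check_finite(state: np.ndarray) -> None:
    if not np.all(np.isfinite(state)):
        raise FloatingPointError(
            "non-finite state encountered (integrator blow-up?)"
        )


def classic_rhs(state: np.ndarray, params: ClassicParams) -> np.ndarray:
    """Time derivatives of the classic repressilator.

    Parameters
    ----------
    state
        6-vector ``(m1, m2, m3, p1, p2, p3)``.
    params
        :class:`ClassicParams`.

    Returns
    -------
    numpy.ndarray
        6-vector of derivatives.  Species ``i`` is repressed by protein
        ``i−1``, cyclically (species 1 by protein 3).
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (6,):
        raise ValueError(f"expected a 6-vector, got shape {state.shape}")
    _check_finite(state)
    m, p = state[:3], state[3:]
    p_prev = np.clip(np.roll(p, 1), 0.0, None)
    dm = -m + params.alpha / (1.0 + p_prev ** params.n) + params.alpha0
    dp = -params.beta * (p - m)
    return np.concatenate([dm, dp])


def coupled_rhs(state: np.ndarray, params: CoupledParams) -> np.ndarray:
    """Time derivatives of the enzymatically coupled three-repressilator system.

    Parameters
    ----------
    state
        18-vector: the nine mRNAs ``m[i, j]`` (row-major) followed by the
        nine proteins.  Small negative entries (adaptive-stepper overshoot)
        are clamped to zero in the Hill terms and saturation sums.
    params
        :class:`CoupledParams`.

    Notes
    -----
    Every species is degraded by the same enzyme pool, so each saturating
    denominator contains the *total* mRNA (resp. protein) load; that shared
    denominator is the only interaction between the three repressilators.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (18,):
        raise ValueError(f"expected an 18-vector, got shape {state.shape}")
    _check_finite(state)
    m = state[:9].reshape(3, 3)
    p = state[9:].reshape(3, 3)
    m_pos = np.clip(m, 0.0, None)
    p_pos = np.clip(p, 0.0, None)
    m_sum = m_pos.sum()
    p_sum = p_pos.sum()
    alphas = np.asarray(params.alphas)[:, None]
    alpha0s = np.asarray(params.alpha0s)[:, None]
    betas = np.asarray(params.betas)[:, None]
    p_prev = np.roll(p_pos, 1, axis=1)  # predecessor of species j is j-1, cyclic
    dm = (alphas / (1.0 + p_prev ** params.n) + alpha0s
          - params.k * m_pos / (params.km + m_sum))
    dp = betas * m - params.k * p_pos / (params.kp + p_sum)
    return np.concatenate([dm.ravel(), dp.ravel()])


def build_params(
    gamma: float,
    km: float,
    kp: float,
    *,
    n: float = DEFAULTS["n"],
    alpha0: float = DEFAULTS["alpha0"],
    beta: float = DEFAULTS["beta"],
    k: float = DEFAULTS["k"],
    alpha2: float = DEFAULTS["alpha2"],
) -> CoupledParams:
    """Construct :class:`CoupledParams` from the activation-rate offset γ.

    The three activation rates are ``(α₂−γ, α₂, α₂+γ)``; all other
    parameters default to the reference values ``n=2.4, α₀=0.1, β=1,
    k=10, α₂=6``.

    Raises
    ------
    ValueError
        If ``gamma`` is negative or ``gamma >= alpha2`` (the weakest
        repressilator's activation rate would be non-positive), or if a
        Michaelis constant is non-positive.
    """
    if gamma < 0:
        raise ValueError(f"gamma must be non-negative, got {gamma}")
    if gamma >= alpha2:
        raise ValueError(
            f"gamma={gamma} >= alpha2={alpha2}: alpha_1 would be non-positive"
        )
    return CoupledParams(
        alphas=(alpha2 - gamma, alpha2, alpha2 + gamma),
        alpha0s=(alpha0,) * 3,
        betas=(beta,) * 3,
        n=n,
        k=k,
        km=km,
        kp=kp,
        gamma=float(gamma),
    )


def params_from_config(config: dict) -> CoupledParams:
    """:func:`build_params` from a plain config mapping.

    Required keys: ``gamma``, ``km``, ``kp``.  Optional overrides: ``n``,
    ``alpha0``, ``beta``, ``k``, ``alpha2`` (reference values otherwise).
    Unknown keys are rejected to catch config typos.
    """
    allowed = {"gamma", "km", "kp", "n", "alpha0", "beta", "k", "alpha2"}
    unknown = set(config) - allowed
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    missing = {"gamma", "km", "kp"} - set(config)
    if missing:
        raise ValueError(f"missing required parameter keys: {sorted(missing)}")
    kwargs = {key: config[key] for key in allowed - {"gamma", "km", "kp"}
              if key in config}
    return build_params(config["gamma"], config["km"], config["kp"], **kwargs)
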