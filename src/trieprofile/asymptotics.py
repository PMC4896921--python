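"""Large-deviation asymptotics of the unique k-mer profile.

On the scale ``k = alpha * ln n`` the profile obeys
``ln mu(n, k) / ln n -> psi(alpha)``, with the rate function defined
piecewise on ``[alpha_min, alpha_ext]``::

    psi_1(alpha) = tau_alpha + alpha * ln sum_i e^{-beta_i tau_alpha}
                                            on [alpha_min, alpha_bar]
    psi_2(alpha) = 2 - alpha * ln(1/sigma2)  on [alpha_bar, alpha_ext]

where ``tau_alpha`` is the unique root of the Gibbs-tilt equation

    sum_i beta_i e^{-beta_i tau} / sum_i e^{-beta_i tau} = 1/alpha.

The tilted distribution ``theta_i = e^{-beta_i tau}/sum_j e^{-beta_j tau}``
is the composition that dominates the sum.  ``tau`` increases with
``alpha``; ``tau = 1`` at the fundamental ratio (where ``psi = 1`` is
maximal) and ``tau = 2`` at the transition ratio, where the two branches
meet continuously.  ``psi`` vanishes at both ends of its domain.

The second-order correction is

    xi(alpha) = -(V-1)/2 * ln(alpha ln n)/ln n   on [alpha_min, alpha_bar]
    xi(alpha) = ln(1 - sigma2)/ln n              on [alpha_bar, alpha_ext]

(note ``alpha * ln n = k``).  In the finite range ``psi`` alone
overestimates the observed exponent noticeably — the next term is
``O(1/ln n)`` — while ``psi + xi`` tracks it closely.

A bounded oscillation of ``ln mu(n, k)`` (amplitude at most
``ln(p_max/p_min)``) exists because the dominating composition must sit
on the integer lattice; it is not computed here, as exact summation
supersedes the asymptotics wherever the oscillation would be visible.

For a binary alphabet the tilt has a closed form,

    tau_alpha = ln[(1/alpha_min - 1/alpha) / (1/alpha - 1/alpha_max)]
                / ln(p_max/p_min),

exposed as :func:`psi_binary` and used to cross-check the root-finder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model import BernoulliModel, compute_ratios

__all__ = [
    "TauSolution",
    "AsymptoticEstimate",
    "tau_root",
    "psi",
    "xi",
    "psi_binary",
    "log_profile_estimate",
]

_ENDPOINT_TOL = 1e-9
_ROOT_TOL = 1e-13


@dataclass(frozen=True)
class TauSolution:
    """Root of the tilt equation at a given ratio ``alpha``.

    ``thetas`` is the tilted symbol distribution; ``psi1``/``psi2`` are
    the two branch values and ``psi`` the applicable one.
    """

    alpha: float
    tau: float
    thetas: np.ndarray
    psi1: float
    psi2: float
    psi: float


@dataclass(frozen=True)
class AsymptoticEstimate:
    """First- and second-order profile exponents at one length ratio.

    ``psi`` and ``xi`` are ``None`` outside ``[alpha_min, alpha_ext]``,
    where only the regime label (carrying the sign information of the
    exponent bound) applies.
    """

    alpha: float
    psi: float | None
    xi: float | None
    psi_plus_xi: float | None
    regime: str


def _tilt_mean(betas: np.ndarray, tau: float) -> tuple[float, np.ndarray]:
    """Mean of beta under the tilt e^{-beta tau}, with the tilted weights."""
    logw = -betas * tau
    logw -= logw.max()  # shift for stability; cancels in the ratio
    w = np.exp(logw)
    w /= w.sum()
    return float(np.dot(w, betas)), w


def tau_root(model: BernoulliModel, alpha: float) -> TauSolution:
    """Solve the tilt equation for ``tau`` at ratio ``alpha``.

    Requires ``alpha_min < alpha < alpha_max`` strictly (the root runs to
    -inf/+inf at the endpoints, which :func:`psi` short-circuits) and a
    non-uniform model (all ``beta_i`` equal leaves no equation to solve).
    """
    if model.is_uniform:
        raise ValueError("tilt equation has no root for a uniform model")
    r = compute_ratios(model)
    if not (r.alpha_min < alpha < r.alpha_max):
        raise ValueError(
            f"alpha={alpha} outside the open interval "
            f"({r.alpha_min}, {r.alpha_max})"
        )
    betas = model.betas
    target = 1.0 / alpha

    def f(tau: float) -> float:
        return _tilt_mean(betas, tau)[0] - target

    lo, hi = -1.0, 3.0
    # f is strictly decreasing in tau; expand the bracket until it straddles 0
    while f(lo) < 0.0:
        lo *= 2.0
    while f(hi) > 0.0:
        hi *= 2.0
    tau = float(brentq(f, lo, hi, xtol=_ROOT_TOL, rtol=8.9e-16, maxiter=200))
    _, thetas = _tilt_mean(betas, tau)
    # log-sum-exp of -beta_i * tau
    m = float((-betas * tau).max())
    lse = m + math.log(np.exp(-betas * tau - m).sum())
    psi1 = tau + alpha * lse
    psi2 = 2.0 - alpha * math.log(1.0 / model.sigma2)
    use_psi1 = alpha <= r.alpha_bar
    return TauSolution(
        alpha=float(alpha),
        tau=tau,
        thetas=thetas,
        psi1=psi1,
        psi2=psi2,
        psi=psi1 if use_psi1 else psi2,
    )


def psi(model: BernoulliModel, alpha: float) -> float:
    """Rate function ``psi(alpha)`` on ``[alpha_min, alpha_ext]``.

    Branch ``psi_1`` (via the tilt root) applies up to the transition
    ratio, branch ``psi_2`` beyond it; the endpoints return their limit
    values (0) exactly, and ``psi`` peaks at 1 at the fundamental ratio.
    """
    r = compute_ratios(model)
    if not (r.alpha_min - _ENDPOINT_TOL <= alpha <= r.alpha_ext + _ENDPOINT_TOL):
        raise ValueError(
            f"alpha={alpha} outside [{r.alpha_min}, {r.alpha_ext}]"
        )
    if abs(alpha - r.alpha_min) <= _ENDPOINT_TOL:
        return 0.0
    if abs(alpha - r.alpha_ext) <= _ENDPOINT_TOL:
        return 0.0
    if alpha >= r.alpha_bar:
        return 2.0 - alpha * math.log(1.0 / model.sigma2)
    return tau_root(model, alpha).psi1


def xi(model: BernoulliModel, n: int, alpha: float) -> float:
    """Second-order correction ``xi(alpha)`` at finite ``n``.

    ``-(V-1)/2 * ln(k)/ln n`` up to the transition ratio (with
    ``k = alpha * ln n``), ``ln(1-sigma2)/ln n`` beyond it.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    r = compute_ratios(model)
    if not (r.alpha_min - _ENDPOINT_TOL <= alpha <= r.alpha_ext + _ENDPOINT_TOL):
        raise ValueError(
            f"alpha={alpha} outside [{r.alpha_min}, {r.alpha_ext}]"
        )
    ln_n = math.log(n)
    if alpha < r.alpha_bar:
        return -((model.V - 1) / 2.0) * math.log(alpha * ln_n) / ln_n
    return math.log1p(-model.sigma2) / ln_n


def psi_binary(model: BernoulliModel, alpha: float) -> float:
    """Closed-form ``psi`` for a non-uniform binary model (first branch).

    Evaluates the tilt from its explicit two-symbol solution instead of
    root-finding; valid on ``[alpha_min, alpha_bar]`` and identical to
    :func:`psi` there to solver precision.
    """
    if model.V != 2:
        raise ValueError("closed form requires a binary alphabet")
    if model.is_uniform:
        raise ValueError("closed form requires a non-uniform model")
    r = compute_ratios(model)
    if not (r.alpha_min - _ENDPOINT_TOL <= alpha <= r.alpha_bar + _ENDPOINT_TOL):
        raise ValueError(
            f"alpha={alpha} outside [{r.alpha_min}, {r.alpha_bar}]"
        )
    if abs(alpha - r.alpha_min) <= _ENDPOINT_TOL:
        return 0.0
    tau = (
        math.log((1.0 / r.alpha_min - 1.0 / alpha) / (1.0 / alpha - 1.0 / r.alpha_max))
        / math.log(model.p_max / model.p_min)
    )
    betas = model.betas
    m = float((-betas * tau).max())
    lse = m + math.log(np.exp(-betas * tau - m).sum())
    return tau + alpha * lse


def log_profile_estimate(model: BernoulliModel, n: int, k: int) -> AsymptoticEstimate:
    """Asymptotic estimate of ``ln mu(n,k)/ln n`` at integer length ``k``.

    Assigns the regime from ``alpha = k/ln n``: ``below_completion``
    (alpha < alpha_min, exponent <= 0), ``transition_phase`` (up to
    alpha_max, where common/transition/rare words coexist),
    ``decay_phase`` (up to alpha_ext), ``beyond_extinction`` (exponent
    <= 0 again).  ``psi``/``xi`` are filled inside the central interval.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    alpha = k / math.log(n)
    r = compute_ratios(model)
    if alpha < r.alpha_min - _ENDPOINT_TOL:
        return AsymptoticEstimate(alpha, None, None, None, "below_completion")
    if alpha > r.alpha_ext + _ENDPOINT_TOL:
        return AsymptoticEstimate(alpha, None, None, None, "beyond_extinction")
    if alpha <= r.alpha_max:
        regime = "transition_phase"
    else:
        regime = "decay_phase"
    p = psi(model, alpha)
    x = xi(model, n, alpha)
    return AsymptoticEstimate(alpha, p, x, p + x, regime)
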