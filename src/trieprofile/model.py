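"""Biased Bernoulli source models and their characteristic length thresholds.

A memoryless (Bernoulli) source over an alphabet of ``V`` symbols with
probabilities ``p_1..p_V`` governs how quickly prefixes of random words
separate from one another.  Five ratios, all expressed in characters per
nat of ``ln n``, delimit the regimes of the unique k-mer profile of a set
of ``n`` random words:

``alpha_min = 1/max(beta_i)``
    below ``alpha_min * ln n`` essentially every k-mer is repeated
    (completion length);
``alpha_tilde = 1/entropy``
    the profile exponent peaks there (fundamental ratio);
``alpha_bar = sigma2 / sum(p_i^2 * beta_i)``
    where the rate function switches branch (transition ratio);
``alpha_max = 1/min(beta_i)``
    beyond it no common k-mer remains;
``alpha_ext = 2/ln(1/sigma2)``
    beyond ``alpha_ext * ln n`` essentially no repeat survives
    (extinction length),

with ``beta_i = ln(1/p_i)`` the self-information of symbol ``i`` and
``sigma2 = sum(p_i^2)`` the probability that two independent characters
coincide.  All logarithms are natural.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "BernoulliModel",
    "RatioSet",
    "make_model",
    "gc_model",
    "uniform_model",
    "compute_ratios",
]

_SUM_TOL = 1e-6


@dataclass(frozen=True)
class BernoulliModel:
    """A memoryless source: ordered alphabet plus symbol probabilities.

    Derived fields are pure functions of ``probs``:

    - ``betas``: self-information ``ln(1/p_i)`` per symbol, in nats;
    - ``sigma2``: coincidence probability ``sum(p_i^2)``;
    - ``entropy``: Shannon entropy ``sum(p_i * ln(1/p_i))`` in nats.
    """

    alphabet: tuple[str, ...]
    probs: np.ndarray
    betas: np.ndarray
    sigma2: float
    entropy: float

    @property
    def V(self) -> int:
        return len(self.alphabet)

    @property
    def p_min(self) -> float:
        return float(self.probs.min())

    @property
    def p_max(self) -> float:
        return float(self.probs.max())

    @property
    def is_uniform(self) -> bool:
        return bool(np.allclose(self.probs, 1.0 / self.V, rtol=0, atol=1e-12))

    def __post_init__(self) -> None:
        object.__setattr__(self, "probs", np.asarray(self.probs, dtype=float))
        object.__setattr__(self, "betas", np.asarray(self.betas, dtype=float))
        self.probs.setflags(write=False)
        self.betas.setflags(write=False)

    def __repr__(self) -> str:  # keep the numbers readable in logs
        ps = ", ".join(f"{a}:{p:.4g}" for a, p in zip(self.alphabet, self.probs))
        return f"BernoulliModel({ps})"


@dataclass(frozen=True)
class RatioSet:
    """The five characteristic ratios of a model, optionally with lengths.

    Ratios are dimensionless (characters per nat of ``ln n``); the length
    counterparts ``k_* = alpha_* * ln n`` are in characters and are only
    set when a word-set size ``n`` was supplied.
    """

    alpha_min: float
    alpha_tilde: float
    alpha_bar: float
    alpha_max: float
    alpha_ext: float
    n: int | None = None
    k_min: float | None = None
    k_tilde: float | None = None
    k_bar: float | None = None
    k_max: float | None = None
    k_ext: float | None = None

    def as_dict(self) -> dict[str, float]:
        d = {
            "alpha_min": self.alpha_min,
            "alpha_tilde": self.alpha_tilde,
            "alpha_bar": self.alpha_bar,
            "alpha_max": self.alpha_max,
            "alpha_ext": self.alpha_ext,
        }
        if self.n is not None:
            d.update(
                k_min=self.k_min,
                k_tilde=self.k_tilde,
                k_bar=self.k_bar,
                k_max=self.k_max,
                k_ext=self.k_ext,
            )
        return d


def make_model(
    probs: Sequence[float], alphabet: Sequence[str] | None = None
) -> BernoulliModel:
    """Build a :class:`BernoulliModel` from a probability vector.

    Probabilities must be strictly positive and sum to 1 within ``1e-6``;
    small deviations (typical of frequencies estimated from a finite
    sequence) are silently renormalized, larger ones raise ``ValueError``.
    The default alphabet is ``ACGT`` for V=4, ``01`` for V=2, else symbol
    indices as strings.
    """
    p = np.asarray(probs, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError("need at least 2 symbol probabilities")
    if not np.all(p > 0):
        raise ValueError("all probabilities must be strictly positive")
    total = float(p.sum())
    if abs(total - 1.0) > _SUM_TOL:
        raise ValueError(f"probabilities sum to {total!r}, not 1 within {_SUM_TOL}")
    p = p / total
    if alphabet is None:
        if p.size == 4:
            alphabet = tuple("ACGT")
        elif p.size == 2:
            alphabet = ("0", "1")
        else:
            alphabet = tuple(str(i) for i in range(p.size))
    alphabet = tuple(str(a) for a in alphabet)
    if len(alphabet) != p.size:
        raise ValueError("alphabet length does not match probability vector")
    if len(set(alphabet)) != len(alphabet):
        raise ValueError("alphabet symbols must be distinct")
    betas = -np.log(p)
    return BernoulliModel(
        alphabet=alphabet,
        probs=p,
        betas=betas,
        sigma2=float(np.sum(p * p)),
        entropy=float(np.sum(p * betas)),
    )


def gc_model(gc: float, alphabet: Sequence[str] = "ACGT") -> BernoulliModel:
    """Degenerate quaternary DNA model parameterized by GC-content.

    Sets ``p_C = p_G = gc/2`` and ``p_A = p_T = (1-gc)/2`` in ACGT order,
    the standard strand-symmetric approximation for a genome of known
    GC-content.
    """
    if not 0.0 < gc < 1.0:
        raise ValueError("GC-content must lie strictly between 0 and 1")
    at = (1.0 - gc) / 2.0
    cg = gc / 2.0
    return make_model([at, cg, cg, at], alphabet)


def uniform_model(V: int) -> BernoulliModel:
    """Uniform source on ``V`` symbols (degenerate transition phase)."""
    return make_model(np.full(V, 1.0 / V))


def compute_ratios(model: BernoulliModel, n: int | None = None) -> RatioSet:
    """Characteristic ratios of ``model``; lengths too when ``n`` is given.

    The ordering ``alpha_min <= alpha_tilde <= alpha_bar <= alpha_max <=
    alpha_ext`` always holds, with the first four coinciding at
    ``1/ln V`` exactly when the model is uniform.
    """
    b = model.betas
    p = model.probs
    alpha_min = 1.0 / float(b.max())
    alpha_max = 1.0 / float(b.min())
    alpha_tilde = 1.0 / model.entropy
    alpha_bar = model.sigma2 / float(np.sum(p * p * b))
    alpha_ext = 2.0 / math.log(1.0 / model.sigma2)
    if n is None:
        return RatioSet(alpha_min, alpha_tilde, alpha_bar, alpha_max, alpha_ext)
    if n < 2:
        raise ValueError("word-set size n must be >= 2 for length thresholds")
    ln_n = math.log(n)
    return RatioSet(
        alpha_min,
        alpha_tilde,
        alpha_bar,
        alpha_max,
        alpha_ext,
        n=int(n),
        k_min=alpha_min * ln_n,
        k_tilde=alpha_tilde * ln_n,
        k_bar=alpha_bar * ln_n,
        k_max=alpha_max * ln_n,
        k_ext=alpha_ext * ln_n,
    )
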