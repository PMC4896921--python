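"""Exact finite-n expectation of the unique k-mer profile.

For a set of ``n`` random words drawn from a Bernoulli source, the
expected number of unique (k+1)-mers — leaves at depth k+1 of the trie —
is a sum over character compositions ``(k_1..k_V)`` of ``k``::

    mu(n, k) = n * sum  multinomial(k; k_1..k_V) * phi * psi_n(phi)
    phi      = prod p_i^{k_i}                      (word probability)
    psi_n    = sum_i p_i [ (1-phi*p_i)^{n-1} - (1-phi)^{n-1} ]

The sum is split by the sign of the objective function
``rho = sum (k_i/k) beta_i - ln(n)/k``: compositions with ``rho >= 0``
(equivalently ``n*phi <= 1``, rare and transition words) contribute
``S(k)``, the rest (common words, ``n*phi > 1``) contribute ``T(k)``,
and ``mu = S + T``.  Both criteria are evaluated from the single
log-space quantity ``ln(phi) + ln(n)`` so the partition is consistent
bit-for-bit.

Numerics: per-composition terms are assembled in log space
(``lgamma``-based multinomials), powers use ``exp((n-1)*log1p(-x))``,
the difference in ``psi_n`` is taken as ``e^y * expm1((n-1)*d)`` with
``d = log1p(-phi*p_i) - log1p(-phi)`` to avoid cancellation when
``(n-1)*phi`` is tiny, and the final accumulation uses exact summation
(`math.fsum`).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterator, NamedTuple, Sequence

import numpy as np
from scipy.special import gammaln

from .model import BernoulliModel

__all__ = [
    "Composition",
    "ProfileRow",
    "MuResult",
    "enumerate_compositions",
    "composition_counts",
    "psi_n_term",
    "mu_exact",
    "brute_force_mu",
    "profile_table",
]

DEFAULT_COMPOSITION_BUDGET = 10**7


class BudgetExceededError(RuntimeError):
    """Composition count exceeds the configured budget (use asymptotics)."""


@dataclass(frozen=True)
class Composition:
    """One character composition of a word length ``k``.

    ``weight`` (the multinomial coefficient) and ``phi`` (the word
    probability) are held in log space; ``rho`` is the objective value in
    nats per character and ``side`` is ``"D"`` (rho >= 0, rare/transition)
    or ``"E"`` (rho < 0, common).
    """

    counts: tuple[int, ...]
    k: int
    log_weight: float
    log_phi: float
    rho: float
    side: str

    @property
    def weight(self) -> float:
        return math.exp(self.log_weight)

    @property
    def phi(self) -> float:
        return math.exp(self.log_phi)


class MuResult(NamedTuple):
    """The split expectation: rare/transition sum, common sum, total."""

    S: float
    T: float
    mu: float


@dataclass
class ProfileRow:
    """Per-length record of the predicted (and optionally observed) profile.

    ``mu = S + T`` is the predicted count of unique (k+1)-mers; ``psi``
    and ``psi_plus_xi`` are the first- and second-order exponents of
    ``ln mu / ln n`` where defined; ``B_obs`` is an observed count of
    depth-(k+1) leaves and ``log_ratio_obs = ln(B_obs)/ln(n)``.
    """

    k: int
    S: float
    T: float
    mu: float
    psi: float | None = None
    psi_plus_xi: float | None = None
    B_obs: float | None = None
    log_ratio_obs: float | None = None


def composition_counts(k: int, V: int) -> np.ndarray:
    """All compositions ``k_1+..+k_V = k`` as an ``(C, V)`` int array.

    Rows are in ascending lexicographic order on ``(k_1..k_V)``;
    ``C = C(k+V-1, V-1)``.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if V < 1:
        raise ValueError("V must be >= 1")
    if V == 1:
        return np.array([[k]], dtype=np.int64)
    rows = []
    for k1 in range(k + 1):
        rest = composition_counts(k - k1, V - 1)
        block = np.empty((rest.shape[0], V), dtype=np.int64)
        block[:, 0] = k1
        block[:, 1:] = rest
        rows.append(block)
    return np.concatenate(rows, axis=0)


def n_compositions(k: int, V: int) -> int:
    return math.comb(k + V - 1, V - 1)


def enumerate_compositions(
    k: int, model: BernoulliModel, n: int
) -> Iterator[Composition]:
    """Yield every composition of ``k`` with weight, phi, rho and side.

    Deterministic ascending lexicographic order on ``(k_1..k_V)``.  The
    D/E side is decided from ``ln(phi) + ln(n)`` — the same quantity that
    defines ``rho`` — so the two criteria agree exactly.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    counts = composition_counts(k, model.V)
    log_w = gammaln(k + 1) - gammaln(counts + 1).sum(axis=1)
    log_phi = counts @ np.log(model.probs)
    ln_n = math.log(n)
    for c, lw, lp in zip(counts, log_w, log_phi):
        # rho * k = sum k_i beta_i - ln n = -(log_phi + ln n)
        excess = -(lp + ln_n)
        rho = excess / k if k > 0 else -math.inf
        yield Composition(
            counts=tuple(int(x) for x in c),
            k=k,
            log_weight=float(lw),
            log_phi=float(lp),
            rho=float(rho),
            side="D" if excess >= 0 else "E",
        )


def _psi_n_vector(probs: np.ndarray, n: int, log_phi: np.ndarray) -> np.ndarray:
    """Vectorized ``psi_n`` for an array of log word probabilities.

    Returns ``sum_i p_i [(1-phi p_i)^{n-1} - (1-phi)^{n-1}]`` per entry,
    always in ``[0, 1)``.
    """
    phi = np.exp(log_phi)
    x = np.log1p(-np.outer(phi, probs))  # ln(1 - phi p_i), (C, V)
    with np.errstate(divide="ignore"):
        y = np.log1p(-phi)  # ln(1 - phi), -inf at phi == 1 (empty word)
    d = x - y[:, None]  # >= 0, no cancellation: both args are O(phi)
    nm1 = n - 1
    with np.errstate(over="ignore", invalid="ignore"):
        safe = (nm1 * y)[:, None] > -700.0  # e^{(n-1)y} representable
        diff = np.where(
            safe,
            np.exp(nm1 * y)[:, None] * np.expm1(nm1 * d),
            np.exp(nm1 * x),  # (1-phi)^{n-1} underflows; term is (1-phi p_i)^{n-1}
        )
    return diff @ probs


def psi_n_term(model: BernoulliModel, n: int, phi: float) -> float:
    """Expectation factor ``psi_n`` for a single word probability ``phi``.

    ``phi = 1`` is the empty-word convention used at ``k = 0``.
    """
    if not 0.0 < phi <= 1.0:
        raise ValueError("phi must lie in (0, 1]")
    if n < 2:
        raise ValueError("n must be >= 2")
    return float(_psi_n_vector(model.probs, n, np.array([math.log(phi)]))[0])


def mu_exact(
    model: BernoulliModel,
    n: int,
    k: int,
    budget: int = DEFAULT_COMPOSITION_BUDGET,
) -> MuResult:
    """Exact expectation ``mu(n, k)`` of the number of unique (k+1)-mers.

    Returns the triple ``(S, T, mu)``.  Raises
    :class:`BudgetExceededError` when the composition count
    ``C(k+V-1, V-1)`` exceeds ``budget`` (asymptotic mode is the remedy).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if k < 0:
        raise ValueError("k must be >= 0")
    C = n_compositions(k, model.V)
    if C > budget:
        raise BudgetExceededError(
            f"{C} compositions exceed budget {budget}; use the asymptotic estimate"
        )
    counts = composition_counts(k, model.V)
    log_w = gammaln(k + 1) - gammaln(counts + 1).sum(axis=1)
    log_phi = counts @ np.log(model.probs)
    psin = _psi_n_vector(model.probs, n, log_phi)
    # terms <= n, so exponentiating per term cannot overflow
    terms = n * np.exp(log_w + log_phi) * psin
    side_D = (log_phi + math.log(n)) <= 0.0
    order = np.argsort(-terms, kind="stable")  # descending magnitude
    S = math.fsum(terms[order][side_D[order]])
    T = math.fsum(terms[order][~side_D[order]])
    return MuResult(S=S, T=T, mu=S + T)


def brute_force_mu(model: BernoulliModel, n: int, k: int, limit: int = 10**6) -> float:
    """Exhaustive-enumeration expectation of the unique (k+1)-mer count.

    Enumerates every assignment of (k+1)-character prefixes to the ``n``
    words, counts words whose full prefix occurs once while its length-k
    prefix heads at least two words, and returns the probability-weighted
    mean.  Only feasible when ``V**(n*(k+1)) <= limit``; this is the
    independent oracle for :func:`mu_exact`.
    """
    V = model.V
    states = V ** (n * (k + 1))
    if states > limit:
        raise ValueError(f"{states} assignments exceed the brute-force limit {limit}")
    words = list(itertools.product(range(V), repeat=k + 1))
    word_prob = {w: math.prod(model.probs[i] for i in w) for w in words}
    expectation = 0.0
    for assignment in itertools.product(words, repeat=n):
        prob = math.prod(word_prob[w] for w in assignment)
        full_counts: dict[tuple[int, ...], int] = {}
        stem_counts: dict[tuple[int, ...], int] = {}
        for w in assignment:
            full_counts[w] = full_counts.get(w, 0) + 1
            stem_counts[w[:k]] = stem_counts.get(w[:k], 0) + 1
        uniques = sum(
            1 for w, c in full_counts.items() if c == 1 and stem_counts[w[:k]] >= 2
        )
        expectation += prob * uniques
    return expectation


def profile_table(
    model: BernoulliModel,
    n: int,
    k_range: Sequence[int],
    include_asymptotics: bool = True,
    budget: int = DEFAULT_COMPOSITION_BUDGET,
) -> list[ProfileRow]:
    """Predicted profile rows for each ``k`` in ``k_range``.

    Exact columns always; first- and second-order exponents filled for
    lengths inside ``[alpha_min ln n, alpha_ext ln n]`` when requested.
    """
    from . import asymptotics  # deferred: avoids a cycle at import time

    rows = []
    for k in k_range:
        S, T, mu = mu_exact(model, n, k, budget=budget)
        row = ProfileRow(k=int(k), S=S, T=T, mu=mu)
        if include_asymptotics and k >= 1 and not model.is_uniform:
            est = asymptotics.log_profile_estimate(model, n, k)
            row.psi = est.psi
            row.psi_plus_xi = est.psi_plus_xi
        rows.append(row)
    return rows
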