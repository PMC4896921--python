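"""Side-by-side comparison of predicted and observed profiles.

A comparison report merges, per word length ``k``, the exact expectation
``mu(n, k)`` (with its S/T split), the asymptotic exponents, and the
observed count ``B(k+1)`` of depth-(k+1) leaves — the same column layout
used to study where a real sequence departs from the random model.
Rows where ``|B_obs - mu| > 5 * sqrt(mu)`` are flagged as departures;
under the Bernoulli model fluctuations of ``B`` are of order
``sqrt(mu)``, so flagged rows indicate structure (typically long
repeats) the random model does not produce.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import asymptotics
from .empirical import EmpiricalProfile, ReplicateSummary
from .exact import mu_exact
from .model import BernoulliModel, RatioSet, compute_ratios

__all__ = ["ComparisonReport", "compare"]

DEPARTURE_SIGMA = 5.0


@dataclass
class ComparisonReport:
    """Per-length prediction/observation table plus threshold block."""

    model: BernoulliModel
    n: int
    rows: pd.DataFrame
    thresholds: RatioSet
    metadata: dict = field(default_factory=dict)

    @property
    def flagged(self) -> pd.DataFrame:
        """Rows departing from the prediction by more than 5 sigma."""
        return self.rows[self.rows["departure"]]

    def to_tsv(self, path_or_buf=None, raw: bool = False):
        """Write the row table as TSV.

        By default expectations print with 1 decimal and exponents with
        4; ``raw=True`` keeps full precision.
        """
        df = self.rows
        if not raw:
            df = df.copy()
            for col in ("S", "T", "mu", "B_obs"):
                df[col] = pd.to_numeric(df[col]).round(1)
            for col in ("log_ratio_obs", "psi", "psi_plus_xi"):
                df[col] = pd.to_numeric(df[col]).round(4)
        return df.to_csv(path_or_buf, sep="\t", index=False)

    @staticmethod
    def read_tsv(path_or_buf) -> pd.DataFrame:
        return pd.read_csv(path_or_buf, sep="\t")


def _observed_counts(observed, n: int) -> dict[int, float]:
    if observed is None:
        return {}
    if isinstance(observed, ReplicateSummary):
        if observed.n != n:
            raise ValueError(f"observation n={observed.n} does not match n={n}")
        return observed.mean_profile
    if isinstance(observed, EmpiricalProfile):
        if observed.n != n:
            raise ValueError(f"observation n={observed.n} does not match n={n}")
        return {k: float(v) for k, v in observed.depth_counts.items()}
    raise TypeError("observed must be an EmpiricalProfile or ReplicateSummary")


def compare(
    model: BernoulliModel,
    n: int,
    k_range: Sequence[int],
    observed: EmpiricalProfile | ReplicateSummary | None = None,
) -> ComparisonReport:
    """Build a comparison report over ``k_range`` (word lengths ``k``).

    The observed column for row ``k`` is ``B(k+1)``, the leaf count at
    depth ``k+1``, which ``mu(n, k)`` predicts.  With no observation the
    report is prediction-only.
    """
    obs = _observed_counts(observed, n)
    ln_n = math.log(n)
    records = []
    for k in k_range:
        S, T, mu = mu_exact(model, n, k)
        rec: dict = {"k": int(k), "S": S, "T": T, "mu": mu}
        if k >= 1 and not model.is_uniform:
            est = asymptotics.log_profile_estimate(model, n, k)
            rec["psi"] = est.psi
            rec["psi_plus_xi"] = est.psi_plus_xi
            rec["regime"] = est.regime
        else:
            rec["psi"] = None
            rec["psi_plus_xi"] = None
            rec["regime"] = None
        b = obs.get(k + 1)
        rec["B_obs"] = b
        rec["log_ratio_obs"] = math.log(b) / ln_n if b else None
        rec["departure"] = (
            b is not None and abs(b - mu) > DEPARTURE_SIGMA * math.sqrt(max(mu, 1e-300))
        )
        records.append(rec)
    df = pd.DataFrame.from_records(records)
    meta = {"model": repr(model), "n": int(n)}
    if isinstance(observed, ReplicateSummary):
        meta["seeds"] = list(observed.seeds)
        meta["reps"] = observed.reps
        meta["extinction_histogram"] = observed.extinction_histogram
    elif isinstance(observed, EmpiricalProfile):
        meta.update(observed.metadata)
        meta["extinction_level"] = observed.extinction_level
    return ComparisonReport(
        model=model,
        n=int(n),
        rows=df,
        thresholds=compute_ratios(model, n),
        metadata=meta,
    )
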