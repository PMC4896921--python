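"""Observed unique k-mer profiles of concrete sequences.

The leaf-depth profile ``B(k)`` of a sequence counts, for each length
``k``, the suffixes whose shortest unique prefix has length exactly
``k`` — equivalently the leaves at depth ``k`` of the sequence's suffix
tree.  It is computed here from a suffix array plus adjacent LCPs: with
a terminal sentinel ordered before every symbol, the depth of suffix
``i`` is ``1 + max(LCP with its two suffix-array neighbours)``.  The
deepest leaf (the extinction level) is one more than the length of the
longest repeated substring.

Word sets of the theory are realized as the suffix set of a single
generated sequence of length ``n``; the residual edge bias relative to
``n`` independent words is negligible at the sizes profiled here.
Suffixes made unique only by the sentinel get depth (suffix length + 1)
and are counted as-is; this boundary effect touches only the last few
positions of each segment.

FASTA input is supported with multi-record files and characters outside
``ACGT`` splitting the sequence into hard segments, so that no repeated
substring can span a record boundary or an ambiguity run.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from ._suffix import lcp_array, suffix_array
from .model import BernoulliModel, make_model

__all__ = [
    "EmpiricalProfile",
    "ReplicateSummary",
    "generate_sequence",
    "leaf_depth_profile",
    "extinction_level",
    "run_replicates",
    "read_fasta",
    "estimate_model",
]

GENERATOR_ID = "numpy.random.default_rng (PCG64)"


@dataclass
class EmpiricalProfile:
    """Leaf-depth histogram of one sequence (or set of segments).

    ``depth_counts[k]`` is ``B(k)``, the number of suffixes whose
    shortest unique prefix has length ``k``; counts sum to ``n``, the
    number of analyzed suffixes.
    """

    n: int
    depth_counts: dict[int, int]
    metadata: dict = field(default_factory=dict)

    @property
    def extinction_level(self) -> int:
        return max(k for k, b in self.depth_counts.items() if b > 0)

    @property
    def completion_level(self) -> int:
        return min(k for k, b in self.depth_counts.items() if b > 0)

    def B(self, k: int) -> int:
        """Observed number of depth-``k`` leaves."""
        return self.depth_counts.get(k, 0)


@dataclass
class ReplicateSummary:
    """Aggregate of replicate profiles over the same model and size."""

    model: BernoulliModel
    n: int
    profiles: list[EmpiricalProfile]
    seeds: list[int]

    @property
    def reps(self) -> int:
        return len(self.profiles)

    def mean_B(self, k: int) -> float:
        return sum(p.B(k) for p in self.profiles) / self.reps

    @property
    def mean_profile(self) -> dict[int, float]:
        ks: set[int] = set()
        for p in self.profiles:
            ks.update(p.depth_counts)
        return {k: self.mean_B(k) for k in sorted(ks)}

    def cv_B(self, k: int) -> float:
        """Coefficient of variation of B(k) across replicates."""
        vals = np.array([p.B(k) for p in self.profiles], dtype=float)
        m = vals.mean()
        return float(vals.std(ddof=1) / m) if self.reps > 1 and m > 0 else math.nan

    @property
    def extinction_histogram(self) -> dict[int, int]:
        hist: dict[int, int] = {}
        for p in self.profiles:
            e = p.extinction_level
            hist[e] = hist.get(e, 0) + 1
        return dict(sorted(hist.items()))


def generate_sequence(
    model: BernoulliModel, length: int, seed: int
) -> np.ndarray:
    """Length ``length`` of i.i.d. symbol indices from ``model``.

    Deterministic in ``seed``; indices refer to ``model.alphabet``.  Use
    ``model.alphabet`` to render as text.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(model.probs)
    cum[-1] = 1.0  # guard against rounding in the last bin
    u = rng.random(length)
    return np.searchsorted(cum, u, side="right").astype(np.int32)


def _encode_segments(segments: Sequence[np.ndarray], n_symbols_hint: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate integer segments with distinct low sentinels.

    Segment symbols are shifted up by the number of segments so that each
    inter-segment sentinel is a unique smallest value; returns the
    encoded text and a boolean mask of sentinel positions.
    """
    n_seg = len(segments)
    parts = []
    for i, seg in enumerate(segments):
        shifted = seg.astype(np.int64) + n_seg
        parts.append(shifted)
        parts.append(np.array([i], dtype=np.int64))
    text = np.concatenate(parts)
    sentinel = text < n_seg
    return text, sentinel


def leaf_depth_profile(
    sequence: str | np.ndarray | Sequence[str] | Sequence[np.ndarray],
    alphabet: Sequence[str] | None = None,
) -> EmpiricalProfile:
    """Leaf depths (shortest unique prefix lengths) of every suffix.

    ``sequence`` may be a string, an integer index array, or a list of
    either (hard segments that no repeat may span).  Each segment is
    closed by its own sentinel, smaller than every symbol; sentinel
    suffixes themselves are not counted.
    """
    segments = _as_segments(sequence, alphabet)
    total = sum(int(s.size) for s in segments)
    if total < 2:
        raise ValueError("need at least 2 sequence characters to profile")
    text, sentinel_mask = _encode_segments(segments)
    sa = suffix_array(text)
    lcp = lcp_array(text, sa)
    m = text.size
    # depth of the suffix at SA position j: 1 + max(lcp[j], lcp[j+1])
    neigh = np.maximum(lcp, np.concatenate([lcp[1:], np.zeros(1, dtype=np.int64)]))
    depths = neigh + 1
    keep = ~sentinel_mask[sa]
    counts = np.bincount(depths[keep])
    depth_counts = {int(k): int(c) for k, c in enumerate(counts) if c > 0}
    return EmpiricalProfile(
        n=total,
        depth_counts=depth_counts,
        metadata={"segments": len(segments)},
    )


def extinction_level(profile: EmpiricalProfile) -> int:
    """Deepest leaf: 1 + length of the longest repeated substring."""
    return profile.extinction_level


def _as_segments(
    sequence, alphabet: Sequence[str] | None
) -> list[np.ndarray]:
    if isinstance(sequence, np.ndarray):
        return [np.asarray(sequence)]
    if isinstance(sequence, str):
        return [_encode_string(sequence, alphabet)]
    segs = []
    for seg in sequence:
        if isinstance(seg, str):
            segs.append(_encode_string(seg, alphabet))
        else:
            segs.append(np.asarray(seg))
    return [s for s in segs if s.size > 0]


def _encode_string(s: str, alphabet: Sequence[str] | None) -> np.ndarray:
    if alphabet is None:
        alphabet = sorted(set(s))
    index = {c: i for i, c in enumerate(alphabet)}
    try:
        return np.array([index[c] for c in s], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"symbol {e.args[0]!r} not in alphabet {alphabet}") from None


def run_replicates(
    model: BernoulliModel, n: int, reps: int, base_seed: int
) -> ReplicateSummary:
    """Profile ``reps`` independent sequences of length ``n``.

    Replicate ``r`` uses seed ``base_seed + r``, so a summary is fully
    determined by ``(model, n, reps, base_seed)``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    profiles = []
    seeds = []
    for r in range(reps):
        seed = base_seed + r
        seq = generate_sequence(model, n, seed)
        prof = leaf_depth_profile(seq)
        prof.metadata.update(seed=seed, generator=GENERATOR_ID)
        profiles.append(prof)
        seeds.append(seed)
    return ReplicateSummary(model=model, n=n, profiles=profiles, seeds=seeds)


def read_fasta(path: str | Path) -> tuple[list[str], dict]:
    """Read a (possibly gzipped) FASTA file into hard segments.

    Records are uppercased; record boundaries and runs of characters
    outside ``ACGT`` split the sequence, so no repeated substring can
    span them.  Returns the segment list and metadata (record ids,
    total length kept, characters dropped).
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        first = fh.read(1)
        if first == "":
            raise ValueError(f"{path}: empty file")
        if first != ">":
            raise ValueError(f"{path}: not FASTA (must start with '>')")
        fh.seek(0)
        records = list(SeqIO.parse(fh, "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    segments: list[str] = []
    dropped = 0
    ids = []
    for rec in records:
        ids.append(rec.id)
        seq = str(rec.seq).upper()
        current: list[str] = []
        for c in seq:
            if c in "ACGT":
                current.append(c)
            else:
                dropped += 1
                if current:
                    segments.append("".join(current))
                    current = []
        if current:
            segments.append("".join(current))
    if not segments:
        raise ValueError(f"{path}: no ACGT sequence after filtering")
    meta = {
        "path": str(path),
        "records": ids,
        "length": sum(len(s) for s in segments),
        "non_acgt_dropped": dropped,
        "segments": len(segments),
    }
    return segments, meta


def estimate_model(
    sequence: str | Iterable[str], mode: str = "exact"
) -> BernoulliModel:
    """Estimate a Bernoulli model from a nucleotide sequence.

    ``mode="exact"`` returns the per-symbol frequencies over the observed
    alphabet.  ``mode="degenerate-gc"`` returns the strand-symmetric DNA
    model ``p_A = p_T = (f_A+f_T)/2``, ``p_C = p_G = (f_C+f_G)/2``
    (requires an ACGT alphabet).
    """
    if isinstance(sequence, str):
        segments = [sequence]
    else:
        segments = list(sequence)
    counts: dict[str, int] = {}
    for seg in segments:
        for c in seg:
            counts[c] = counts.get(c, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty sequence")
    if mode == "exact":
        alphabet = sorted(counts)
        freqs = [counts[a] / total for a in alphabet]
        return make_model(freqs, alphabet)
    if mode == "degenerate-gc":
        if set(counts) - set("ACGT"):
            raise ValueError(
                f"degenerate-gc mode requires an ACGT alphabet, got {sorted(counts)}"
            )
        f = {c: counts.get(c, 0) / total for c in "ACGT"}
        at = (f["A"] + f["T"]) / 2.0
        cg = (f["C"] + f["G"]) / 2.0
        return make_model([at, cg, cg, at], "ACGT")
    raise ValueError(f"unknown mode {mode!r}")
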