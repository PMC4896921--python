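import gzip
import math

import numpy as np
import pytest

from trieprofile import (
    estimate_model,
    extinction_level,
    generate_sequence,
    leaf_depth_profile,
    make_model,
    mu_exact,
    read_fasta,
    run_replicates,
)
from .conftest import naive_depth_profile


class TestGenerateSequence:
    def test_reproducible(self, binary_model):
        a = generate_sequence(binary_model, 1000, 42)
        b = generate_sequence(binary_model, 1000, 42)
        assert np.array_equal(a, b)
        c = generate_sequence(binary_model, 1000, 43)
        assert not np.array_equal(a, c)

    def test_law_of_large_numbers(self, binary_model):
        s = generate_sequence(binary_model, 10**6, 7)
        freq = np.mean(s == 0)
        assert abs(freq - 0.7) < 0.002

    def test_near_degenerate_distribution(self):
        m = make_model([1 - 1e-6, 1e-6])
        s = generate_sequence(m, 10_000, 0)
        assert np.mean(s == 0) > 0.999


class TestLeafDepthProfile:
    def test_all_distinct_symbols(self):
        p = leaf_depth_profile("ABC")
        assert p.depth_counts == {1: 3}
        assert p.extinction_level == 1
        assert p.completion_level == 1

    def test_run_of_identical_symbols(self):
        """'AAAA': longest repeat 'AAA' puts the deepest leaf at 4."""
        p = leaf_depth_profile("AAAA")
        assert p.depth_counts == {2: 1, 3: 1, 4: 2}
        assert extinction_level(p) == 4

    def test_counts_conserve_length(self, binary_model):
        s = generate_sequence(binary_model, 50_000, 3)
        p = leaf_depth_profile(s)
        assert sum(p.depth_counts.values()) == p.n == 50_000

    def test_matches_naive_oracle(self):
        """Suffix-array profiler equals the quadratic-DP shortest-unique-
        prefix oracle on hundreds of random small sequences."""
        rng = np.random.default_rng(123)
        alphabets = ["AB", "ACGT", "ABC"]
        for trial in range(500):
            sigma = alphabets[trial % len(alphabets)]
            L = int(rng.integers(2, 201))
            s = "".join(rng.choice(list(sigma), L))
            got = leaf_depth_profile(s).depth_counts
            assert got == naive_depth_profile(s), f"trial {trial}: {s}"

    def test_extinction_is_longest_repeat_plus_one(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            L = int(rng.integers(5, 120))
            s = "".join(rng.choice(list("AB"), L))
            prof = leaf_depth_profile(s)
            longest = 0
            for i in range(L):  # overlapping occurrences count as repeats
                for j in range(i + 1, L):
                    m = 0
                    while j + m < L and s[i + m] == s[j + m]:
                        m += 1
                    longest = max(longest, m)
            assert prof.extinction_level == longest + 1

    def test_segments_break_repeats(self):
        """A repeat split across segments must not be seen as a repeat."""
        joined = leaf_depth_profile("ACGTACGT")
        split = leaf_depth_profile(["ACGTA", "CGT"])
        assert joined.extinction_level == 5  # 'ACGT' repeated
        assert split.extinction_level < joined.extinction_level
        assert split.n == joined.n == 8

    def test_rejects_trivial_input(self):
        with pytest.raises(ValueError):
            leaf_depth_profile("A")


class TestReplicates:
    def test_single_rep_equals_profile(self, binary_model):
        summary = run_replicates(binary_model, 5000, 1, 9)
        direct = leaf_depth_profile(generate_sequence(binary_model, 5000, 9))
        assert summary.profiles[0].depth_counts == direct.depth_counts
        assert summary.mean_profile == {
            k: float(v) for k, v in direct.depth_counts.items()
        }

    def test_deterministic_summary(self, binary_model):
        s1 = run_replicates(binary_model, 2000, 3, 11)
        s2 = run_replicates(binary_model, 2000, 3, 11)
        assert s1.seeds == s2.seeds == [11, 12, 13]
        assert s1.mean_profile == s2.mean_profile
        assert s1.extinction_histogram == s2.extinction_histogram

    def test_mean_profile_matches_exact_expectation(self, binary_model):
        """Model/measurement consistency at reduced scale: mean B(k) within
        3 standard errors of mu(n, k-1) wherever mu >= 10."""
        n, reps = 100_000, 50
        summary = run_replicates(binary_model, n, reps, 77)
        checked = 0
        for k in sorted(summary.mean_profile):
            if k < 2:
                continue
            mu = mu_exact(binary_model, n, k - 1).mu
            if mu < 10:
                continue
            vals = np.array([p.B(k) for p in summary.profiles], dtype=float)
            se = vals.std(ddof=1) / math.sqrt(reps)
            se = max(se, math.sqrt(mu / reps))  # guard against zero spread
            assert abs(vals.mean() - mu) <= 3.0 * se, f"k={k}"
            checked += 1
        assert checked >= 10


class TestFasta:
    def _write(self, tmp_path, name, text, compress=False):
        p = tmp_path / name
        if compress:
            with gzip.open(p, "wt") as fh:
                fh.write(text)
        else:
            p.write_text(text)
        return p

    def test_simple_record(self, tmp_path):
        path = self._write(tmp_path, "x.fa", ">x\nACGT\n")
        segments, meta = read_fasta(path)
        assert segments == ["ACGT"]
        assert meta["length"] == 4

    def test_lowercase_folds(self, tmp_path):
        path = self._write(tmp_path, "x.fa", ">x\nacgt\n")
        assert read_fasta(path)[0] == ["ACGT"]

    def test_gzipped_multi_record_with_ambiguity(self, tmp_path):
        path = self._write(
            tmp_path, "x.fa.gz", ">a\nACGTNNACG\n>b\nTTTT\n", compress=True
        )
        segments, meta = read_fasta(path)
        assert segments == ["ACGT", "ACG", "TTTT"]
        assert meta["non_acgt_dropped"] == 2
        assert meta["segments"] == 3

    def test_invalid_leading_content(self, tmp_path):
        path = self._write(tmp_path, "bad.fa", "AC>NGT\n")
        with pytest.raises(ValueError):
            read_fasta(path)

    def test_empty_file(self, tmp_path):
        path = self._write(tmp_path, "empty.fa", "")
        with pytest.raises(ValueError):
            read_fasta(path)


class TestEstimateModel:
    def test_exact_uniform(self):
        m = estimate_model("ACGT")
        assert np.allclose(m.probs, 0.25)

    def test_degenerate_gc_pairs_frequencies(self):
        seq = "A" * 1655 + "C" * 3334 + "G" * 3330 + "T" * 1681
        m = estimate_model(seq, "degenerate-gc")
        assert m.probs[0] == m.probs[3] == pytest.approx(0.1668)
        assert m.probs[1] == m.probs[2] == pytest.approx(0.3332)

    def test_degenerate_requires_acgt(self):
        with pytest.raises(ValueError):
            estimate_model("ABAB", "degenerate-gc")
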