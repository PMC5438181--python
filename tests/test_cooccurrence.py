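"""Conditional binomial column test, terminal trimming, dataset shift null."""

import math

import numpy as np
import pytest

from codoncons.cooccurrence import (
    column_pvalues,
    column_stats,
    family_significant,
    global_shift_test,
    trim_termini,
    trimmed_columns,
)
from codoncons.families import FamilyMember, HomologFamily
from codoncons.orfeome import OrfRecord

from test_families import encode_trivial


def oracle_conditional_p(n: int, m: int, p0: float) -> float:
    """P(X>=m | X>=1) by explicit term-by-term binomial enumeration."""
    pmf = [math.comb(n, k) * p0**k * (1 - p0) ** (n - k) for k in range(n + 1)]
    tail_m = sum(pmf[m:])
    tail_1 = sum(pmf[1:])
    return tail_m / tail_1


def gapless_family(n: int, L: int) -> HomologFamily:
    protein = "K" * L
    members = [
        FamilyMember(f"sp{i}", f"g{i}", protein, OrfRecord(f"g{i}", f"sp{i}", encode_trivial(protein)))
        for i in range(n)
    ]
    return HomologFamily(family_id="f", members=members)


class TestColumnStats:
    def test_single_peak_column_p_is_one(self):
        fam = gapless_family(5, 100)
        peaks = [np.array([50])] + [np.array([], dtype=int)] * 4
        stats = column_stats(fam, peaks)
        by_col = {s.column: s for s in stats}
        assert by_col[50].m == 1 and by_col[50].p_value == pytest.approx(1.0)

    def test_example_n10_p001_m3(self):
        # conditional tail for n=10, p0=0.01, m=3 is about 1.19e-3
        from codoncons.cooccurrence import _conditional_tail

        tail = _conditional_tail(10, 0.01)
        assert tail[3] == pytest.approx(oracle_conditional_p(10, 3, 0.01), rel=1e-9)
        assert tail[3] == pytest.approx(1.19e-3, rel=0.01)

    def test_all_members_one_column_highly_significant(self):
        fam = gapless_family(20, 300)
        peaks = [np.array([150])] * 20
        stats = column_stats(fam, peaks)
        p = {s.column: s.p_value for s in stats}[150]
        assert p < 1e-4

    def test_member_counts_once_despite_multiple_peaks(self):
        fam = gapless_family(3, 100)
        peaks = [np.array([48, 50, 52]), np.array([50]), np.array([], dtype=int)]
        stats = column_stats(fam, peaks)
        assert {s.column: s.m for s in stats}[50] == 2

    def test_m_zero_has_no_pvalue(self):
        fam = gapless_family(3, 100)
        peaks = [np.array([10]), np.array([], dtype=int), np.array([], dtype=int)]
        stats = column_stats(fam, peaks)
        by_col = {s.column: s for s in stats}
        assert by_col[90].m == 0 and by_col[90].p_value is None

    def test_single_member_family_rejected(self):
        with pytest.raises(ValueError):
            column_pvalues(10, np.ones(10, bool), [np.array([1])])

    def test_p_monotone_in_m(self):
        from codoncons.cooccurrence import _conditional_tail

        tail = _conditional_tail(15, 0.05)
        assert np.all(np.diff(tail[1:]) <= 1e-15)
        assert tail[1] == pytest.approx(1.0)

    @pytest.mark.parametrize("p0", [0.001, 0.01, 0.1])
    @pytest.mark.parametrize("n", [2, 5, 12])
    def test_matches_enumeration_oracle(self, n, p0):
        from codoncons.cooccurrence import _conditional_tail

        tail = _conditional_tail(n, p0)
        for m in range(1, n + 1):
            assert tail[m] == pytest.approx(oracle_conditional_p(n, m, p0), abs=1e-12)


class TestTrimming:
    def test_gapless_300(self):
        mask = trimmed_columns(np.ones(300, bool))
        trimmed = np.nonzero(mask)[0] + 1  # 1-based
        assert trimmed.min() == 1 and trimmed.max() == 300
        assert set(trimmed) == set(range(1, 52)) | set(range(250, 301))

    def test_first_gapfree_column_12(self):
        elig = np.ones(400, bool)
        elig[:11] = False  # first gap-free column is 12 (1-based)
        mask = trimmed_columns(elig)
        n_side = set(np.nonzero(mask[:200])[0] + 1)
        assert n_side == set(range(12, 63))

    def test_short_gapless_alignment_fully_trimmed(self):
        assert trimmed_columns(np.ones(80, bool)).all()

    def test_no_gapfree_column_trims_everything(self):
        assert trimmed_columns(np.zeros(120, bool)).all()

    def test_trim_bounded_by_terminal_gap_run_plus_window(self):
        elig = np.ones(500, bool)
        elig[:37] = False
        elig[-23:] = False
        mask = trimmed_columns(elig)
        inner = np.nonzero(mask)[0]
        assert inner.min() >= 0 and inner.max() < 500
        assert mask[: 37 + 51].sum() == 51  # N-side block
        assert not mask[37 + 51 : 500 - 23 - 51].any()


class TestFamilySignificant:
    def make_stats(self, fam, pvals, trimmed_cols=()):
        peaks = [np.array([], dtype=int)] * fam.n
        stats = column_stats(fam, peaks)
        for s in stats:
            s.p_value = pvals.get(s.column)
            if s.p_value is not None:
                s.m = 2
            s.trimmed = s.column in trimmed_cols
        return stats

    def test_all_p_one_not_significant(self):
        fam = gapless_family(4, 200)
        stats = self.make_stats(fam, {c: 1.0 for c in range(200)})
        sig, col = family_significant(stats)
        assert not sig and col is not None

    def test_one_low_p_outside_trim(self):
        fam = gapless_family(4, 300)
        stats = self.make_stats(fam, {100: 5e-6})
        sig, col = family_significant(stats)
        assert sig and col == 100

    def test_significant_column_inside_trim_ignored(self):
        fam = gapless_family(4, 300)
        stats = self.make_stats(fam, {20: 5e-6})
        trim_termini(fam, stats)
        sig, col = family_significant(stats)
        assert not sig

    def test_tie_breaks_to_most_n_terminal(self):
        fam = gapless_family(4, 300)
        stats = self.make_stats(fam, {120: 1e-5, 110: 1e-5})
        _, col = family_significant(stats)
        assert col == 110


class TestGlobalShiftTest:
    def planted_dataset(self, n_families=5, n=10, L=200):
        out = []
        for f in range(n_families):
            fam = gapless_family(n, L)
            out.append((fam, [np.array([100])] * n))
        return out

    def test_planted_dataset_tiny_p(self):
        res = global_shift_test(self.planted_dataset(), n_permutations=100, seed=0)
        assert res.observed > res.null_mean + 5 * res.null_sd
        assert res.p_normal < 1e-10
        assert res.p_empirical <= 1 / 50

    def test_single_member_statistic_zero_p_one(self):
        protein = "K" * 50
        fam = HomologFamily(
            family_id="f",
            members=[FamilyMember("a", "g", protein, OrfRecord("g", "a", encode_trivial(protein)))],
        )
        res = global_shift_test([(fam, [np.array([10])])], n_permutations=20, seed=0)
        assert res.observed == 0 and res.p_normal == 1.0

    def test_too_few_permutations_error(self):
        with pytest.raises(ValueError):
            global_shift_test(self.planted_dataset(1), n_permutations=5, seed=0)

    def test_uniform_peaks_randomized_p_calibrated(self):
        # over replicate null datasets the smoothed permutation p is ~uniform
        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(60):
            fams = []
            for _ in range(3):
                fam = gapless_family(6, 150)
                peaks = [np.sort(rng.choice(150, size=2, replace=False)) for _ in range(6)]
                fams.append((fam, peaks))
            res = global_shift_test(fams, n_permutations=60, seed=rng)
            pvals.append(res.p_randomized)
        frac = np.mean(np.array(pvals) < 0.05)
        sigma = (0.05 * 0.95 / 60) ** 0.5
        assert frac <= 0.05 + 3 * sigma
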