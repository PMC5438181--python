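"""Fisher/binomial enrichment tests against enumeration oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from codoncons.enrichment import (
    Domain,
    boundary_enrichment,
    go_enrichment,
    length_matched_controls,
    nc_window_test,
)


def oracle_fisher_two_sided(a, b, c, d):
    """Two-sided Fisher p by hypergeometric enumeration (sum of tables with
    probability <= observed, fixed margins)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def hyper(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
            if 0 <= x <= r1 and 0 <= c1 - x <= r2
            else 0.0
        )

    p_obs = hyper(a)
    return sum(p for x in range(0, min(r1, c1) + 1) if (p := hyper(x)) <= p_obs * (1 + 1e-9))


def oracle_binom_two_sided(k, n, p):
    """Two-sided exact binomial p by pmf enumeration (minlike method)."""
    pmf = [math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(n + 1)]
    p_obs = pmf[k]
    return min(1.0, sum(q for q in pmf if q <= p_obs * (1 + 1e-9)))


def go_frame(rows):
    return pd.DataFrame(rows, columns=["family_id", "go_term", "go_class"])


class TestGoEnrichment:
    def test_identical_proportions_not_significant(self):
        rows = [(f"c{i}", "T", "molecular_function") for i in range(5)]
        rows += [(f"b{i}", "T", "molecular_function") for i in range(5)]
        crcc = {f"c{i}" for i in range(10)}
        bg = {f"b{i}" for i in range(10)}
        (res,) = go_enrichment(go_frame(rows), crcc, bg)
        assert res.p_value > 0.5

    def test_matches_hypergeometric_oracle(self):
        # families: 100 with CRCC (10 term-positive), 900 without (10 positive)
        rows = [(f"c{i}", "T", "biological_process") for i in range(10)]
        rows += [(f"b{i}", "T", "biological_process") for i in range(10)]
        crcc = {f"c{i}" for i in range(100)}
        bg = {f"b{i}" for i in range(900)}
        (res,) = go_enrichment(go_frame(rows), crcc, bg)
        assert res.table == ((10, 90), (10, 890))
        assert res.p_value == pytest.approx(oracle_fisher_two_sided(10, 90, 10, 890), rel=1e-8)
        assert res.direction == "enriched"

    def test_term_in_every_family_degenerate(self):
        rows = [(f, "T", "cellular_component") for f in ["c0", "c1", "b0", "b1"]]
        (res,) = go_enrichment(go_frame(rows), {"c0", "c1"}, {"b0", "b1"})
        assert res.degenerate and res.p_value == 1.0

    def test_top_n_restriction(self):
        rows = []
        for t in range(15):
            for f in range(15 - t):  # term t seen in 15-t families
                rows.append((f"c{f}", f"T{t}", "molecular_function"))
        crcc = {f"c{i}" for i in range(15)}
        bg = {"b0"}
        res = go_enrichment(go_frame(rows), crcc, bg, top_n=10)
        assert len(res) == 10
        assert {r.unit for r in res} == {f"T{t}" for t in range(10)}

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError):
            go_enrichment(go_frame([]), {"x"}, {"x"})


class TestBoundaryEnrichment:
    def test_crccs_on_boundaries_enriched(self):
        domains = {f"p{i}": [Domain(f"p{i}", 100, 200)] for i in range(20)}
        lengths = {f"p{i}": 300 for i in range(20)}
        crccs = {f"p{i}": [100, 200] for i in range(20)}
        res = boundary_enrichment(crccs, domains, lengths, near_window=10)
        assert res.direction == "enriched" and res.p_value < 1e-6

    def test_single_crcc_valid_but_underpowered(self):
        domains = {"p": [Domain("p", 50, 120)]}
        res = boundary_enrichment({"p": [60]}, domains, {"p": 200}, near_window=10)
        assert 0 < res.p_value <= 1.0
        assert res.p_value >= 0.05

    def test_unannotated_protein_excluded(self):
        domains = {"p": [Domain("p", 50, 120)]}
        crccs = {"p": [85], "q": [10]}  # q has no domains: ignored
        res = boundary_enrichment(crccs, domains, {"p": 200, "q": 50})
        assert res.extra["total_crccs"] == 1

    def test_matches_binomial_oracle(self):
        domains = {"p": [Domain("p", 100, 200)]}
        lengths = {"p": 400}
        crccs = {"p": [100, 105, 300, 310, 320]}
        res = boundary_enrichment(crccs, domains, lengths, near_window=10)
        k, n, q = res.table
        assert res.p_value == pytest.approx(oracle_binom_two_sided(k, n, q), rel=1e-9)

    def test_within_mode(self):
        domains = {"p": [Domain("p", 1, 100)]}
        res = boundary_enrichment({"p": [5, 10, 20]}, domains, {"p": 200}, mode="within")
        assert res.direction == "enriched"


class TestNcWindowTest:
    def setup_case(self, positions):
        domains = {"p": [Domain("p", 60, 200)]}
        return {"p": positions}, domains, {"p": 300}

    def test_equal_counts_p_one(self):
        crccs, domains, lengths = self.setup_case([70, 210])  # one in each window
        res = nc_window_test(crccs, domains, lengths, window=50, mode="following")
        assert res.p_value == pytest.approx(1.0)

    def test_nine_vs_one_matches_oracle(self):
        n_side = list(range(61, 70))  # 9 CRCCs after the N boundary
        c_side = [205]  # 1 after the C boundary
        crccs, domains, lengths = self.setup_case(n_side + c_side)
        res = nc_window_test(crccs, domains, lengths, window=50, mode="following")
        assert res.extra["n_side"] == 9 and res.extra["c_side"] == 1
        assert res.p_value == pytest.approx(oracle_binom_two_sided(9, 10, 0.5), rel=1e-9)

    def test_zero_crccs_flagged(self):
        crccs, domains, lengths = self.setup_case([])
        res = nc_window_test(crccs, domains, lengths)
        assert res.degenerate

    def test_overlapping_windows_skip_domain(self):
        domains = {"p": [Domain("p", 60, 80)]}  # windows of 50 overlap
        res = nc_window_test({"p": [70]}, domains, {"p": 300}, window=50)
        assert res.degenerate and res.extra["skipped_domains"] == 1


class TestLengthMatchedControls:
    def test_basic_matching(self):
        matching = length_matched_controls(
            [("a", 100), ("b", 200)], [("x", 101), ("y", 199), ("z", 500)]
        )
        assert matching == {"a": "x", "b": "y"}

    def test_tie_prefers_shorter_control(self):
        matching = length_matched_controls([("a", 100)], [("long", 101), ("short", 99)])
        assert matching == {"a": "short"}

    def test_no_control_reused(self):
        matching = length_matched_controls(
            [("a", 100), ("b", 100)], [("x", 100), ("y", 150)]
        )
        assert set(matching.values()) == {"x", "y"}

    def test_pool_exhausted_errors(self):
        with pytest.raises(ValueError, match="exhausted"):
            length_matched_controls([("a", 1), ("b", 2)], [("x", 1)])

    def test_greedy_beats_random_pairing(self, rng):
        targets = [(f"t{i}", int(rng.integers(50, 500))) for i in range(200)]
        pool = [(f"p{i}", int(rng.integers(50, 500))) for i in range(400)]
        matching = length_matched_controls(targets, pool)
        lengths = dict(targets) | dict(pool)
        greedy = np.mean([abs(lengths[a] - lengths[b]) for a, b in matching.items()])
        perm = rng.permutation(len(targets))
        rand = np.mean(
            [abs(targets[i][1] - pool[perm[i]][1]) for i in range(len(targets))]
        )
        assert greedy <= rand
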