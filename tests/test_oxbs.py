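"""Unit and property tests for BS/OxBS 5mC/5hmC estimation and calling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cafepi import oxbs, simulate
from cafepi.oxbs import OxbsConfig, bh_adjust, fisher_exact
from cafepi.simulate import SimConfig

from conftest import make_estimates


def fisher_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration of the two-sided Fisher p."""
    r1, r2, c1 = a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or b + d == 0:
        return 1.0
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = math.comb(n, c1)
    probs = [math.comb(r1, x) * math.comb(r2, c1 - x) / denom for x in range(lo, hi + 1)]
    p_obs = probs[a - lo]
    return sum(p for p in probs if p <= p_obs * (1 + 1e-7))


def bh_oracle(p):
    """Brute-force step-up: q_(i) = min over j >= i of p_(j) * m / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        q[idx] = min(
            min(p[order[j - 1]] * m / j for j in range(rank_i, m + 1)), 1.0
        )
    return q


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[5, 5], [5, 5]], 1.0),
            ([[2, 1], [1, 2]], 1.0),  # enumeration: probs {.05,.45,.45,.05}, all <= obs
            ([[10, 0], [0, 10]], 2 / math.comb(20, 10)),
            ([[0, 0], [3, 4]], 1.0),  # empty margin convention
            ([[3, 0], [4, 0]], 1.0),
        ],
    )
    def test_reference_tables(self, table, expected):
        assert fisher_exact(table) == pytest.approx(expected, rel=1e-7)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [2, 3]])

    @given(
        st.tuples(*(st.integers(0, 40) for _ in range(4))),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_enumeration(self, cells):
        a, b, c, d = cells
        assert fisher_exact([[a, b], [c, d]]) == pytest.approx(
            fisher_oracle(a, b, c, d), rel=1e-7, abs=1e-12
        )


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.05], [0.05]),
            ([0.005, 0.01, 0.03, 0.04], [0.02, 0.02, 0.04, 0.04]),
        ],
    )
    def test_hand_computed(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_pvalue_order(self, p):
        q = bh_adjust(p)
        assert np.all((q >= 0) & (q <= 1 + 1e-12))
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_matches_stepup_oracle(self, p):
        assert bh_adjust(p) == pytest.approx(bh_oracle(p), abs=1e-12)


class TestEstimateSites:
    def _one_site(self, u_bs, c_bs, u_ox, c_ox):
        df = pd.DataFrame(
            [{"chrom": "chrS", "start": 100, "strand": "+",
              "u_bs": u_bs, "c_bs": c_bs, "u_ox": u_ox, "c_ox": c_ox}]
        )
        return oxbs.estimate_sites(df).iloc[0]

    def test_direct_arithmetic(self):
        row = self._one_site(80, 20, 50, 50)
        assert row["mc"] == pytest.approx(0.5)
        assert row["hmc"] == pytest.approx(0.3)

    def test_negative_hmc_clamped(self):
        row = self._one_site(40, 60, 50, 50)
        assert row["mc"] == pytest.approx(0.5)
        assert row["hmc"] == 0.0

    def test_low_coverage_excluded_from_testing_universe(self):
        df = pd.DataFrame(
            [
                {"chrom": "chrS", "start": 0, "strand": "+",
                 "u_bs": 3, "c_bs": 2, "u_ox": 1, "c_ox": 2},
                {"chrom": "chrS", "start": 50, "strand": "+",
                 "u_bs": 40, "c_bs": 10, "u_ox": 20, "c_ox": 30},
            ]
        )
        est = oxbs.estimate_sites(df, OxbsConfig(min_coverage=10))
        assert not est.loc[0, "testable"]
        assert np.isnan(est.loc[0, "mc"]) and np.isnan(est.loc[0, "q_within"])
        # a single-site BH universe: q equals p
        assert est.loc[1, "q_within"] == pytest.approx(est.loc[1, "p_within"])

    def test_bias_shrinks_with_coverage(self):
        """Estimator consistency: mean absolute error decreases with depth."""
        maes = []
        for cov in (20, 100, 500):
            cfg = SimConfig(
                n_sites=400, coverage_mean=cov, fixed_coverage=True, seed=11,
                conv_eff=1.0, protect_5mC=1.0, protect_5hmC_bs=1.0,
                protect_5hmC_ox=0.0, base_mc=0.5, base_hmc=0.3,
                frac_demeth=0.0, frac_hmc_gain=0.0,
            )
            _, counts = simulate.simulate_bsoxbs(cfg)
            est = oxbs.estimate_sites(counts["A"])
            maes.append(
                (est["mc"] - 0.5).abs().mean() + (est["hmc"] - 0.3).abs().mean()
            )
        assert maes[0] > maes[1] > maes[2]


class TestCalling:
    def test_within_condition_flags(self):
        est = make_estimates([{"start": 0, "mc": 0.5, "hmc": 0.2}])
        est["p_within"] = [0.049]
        called = oxbs.call_hmc_sites(est)
        assert bool(called.loc[0, "is_hmc"])
        assert bool(called.loc[0, "is_5mC"])  # mc = 0.50 exactly, inclusive rule

        est["p_within"] = [0.2]
        called = oxbs.call_hmc_sites(est)
        assert not bool(called.loc[0, "is_hmc"])

    @pytest.mark.parametrize(
        "b_hmc,a_hmc,b_mc,a_mc,expected",
        [
            (0.80, 0.20, 0.30, 0.60, "gain-in-B"),
            (0.75, 0.10, 0.20, 0.60, "gain-in-B"),  # threshold inclusive
            (0.80, 0.20, 0.60, 0.60, "none"),       # 5mC strictly lower required
            (0.74, 0.10, 0.20, 0.60, "none"),       # below the 0.75 floor
            (0.10, 0.80, 0.60, 0.30, "gain-in-A"),
        ],
    )
    def test_differential_direction_rule(self, b_hmc, a_hmc, b_mc, a_mc, expected):
        a = make_estimates([{"start": 0, "mc": a_mc, "hmc": a_hmc}])
        b = make_estimates([{"start": 0, "mc": b_mc, "hmc": b_hmc}])
        calls = oxbs.differential_hmc(a, b)
        assert calls.loc[0, "direction"] == expected

    def test_coordinate_mismatch_names_offenders(self):
        a = make_estimates([{"start": 0, "mc": 0.5, "hmc": 0.1}])
        b = make_estimates([{"start": 50, "mc": 0.5, "hmc": 0.1}])
        with pytest.raises(ValueError, match="50"):
            oxbs.differential_hmc(a, b)

    def test_label_swap_symmetry(self):
        cfg = SimConfig(
            n_sites=300, coverage_mean=100, seed=5,
            conv_eff=1.0, protect_5mC=1.0, protect_5hmC_bs=1.0, protect_5hmC_ox=0.0,
        )
        _, counts = simulate.simulate_bsoxbs(cfg)
        est_a = oxbs.estimate_sites(counts["A"])
        est_b = oxbs.estimate_sites(counts["B"])
        fwd = oxbs.differential_hmc(est_a, est_b)
        rev = oxbs.differential_hmc(est_b, est_a)
        mapping = {"gain-in-B": "gain-in-A", "gain-in-A": "gain-in-B", "none": "none"}
        assert list(rev["direction"]) == [mapping[d] for d in fwd["direction"]]


class TestBedgraph:
    def test_empty_and_single_site(self):
        empty = pd.DataFrame(columns=["chrom", "start", "mc", "hmc"])
        assert oxbs.export_bedgraph(empty, "mc").strip().startswith("track")

        one = pd.DataFrame(
            [{"chrom": "chr1", "start": 100, "mc": 0.5, "hmc": 0.1}]
        )
        text = oxbs.export_bedgraph(one, "mc")
        assert text.splitlines()[1] == "chr1\t100\t101\t0.5"

    def test_round_trip(self):
        df = pd.DataFrame(
            {"chrom": "chrS", "start": [0, 50, 100], "mc": [0.25, 0.5, 1.0]}
        )
        back = oxbs.read_bedgraph(oxbs.export_bedgraph(df, "mc"))
        assert list(back["start"]) == [0, 50, 100]
        assert back["value"].tolist() == [0.25, 0.5, 1.0]

    def test_unsorted_rejected(self):
        df = pd.DataFrame({"chrom": "chrS", "start": [100, 0], "mc": [0.5, 0.5]})
        with pytest.raises(ValueError, match="sorted"):
            oxbs.export_bedgraph(df, "mc")
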