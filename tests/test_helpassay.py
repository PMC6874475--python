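"""Tests for HELP scoring, the moderated t-test, DMR calling and annotation."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from cafepi import helpassay, simulate
from cafepi.helpassay import (
    call_dmrs,
    center_scores,
    classify_cpg_context,
    feature_distribution,
    fragment_score,
    moderated_t_test,
    tag_score,
    trimmed_mean,
)
from cafepi.simulate import SimConfig


def trimmed_mean_oracle(values, frac):
    x = sorted(values)
    k = int(np.floor(frac * len(x)))
    kept = x[k : len(x) - k] if k else x
    return float(np.mean(kept))


class TestTrimmedMean:
    def test_reference_values(self):
        assert trimmed_mean([7.0] * 6) == 7.0
        assert trimmed_mean(np.arange(1, 16), 0.25) == 8.0  # mean of 4..12
        assert trimmed_mean([1, 2, 9], 0.0) == 4.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            trimmed_mean([])

    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50),
        st.floats(0, 0.49),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_sort_discard_oracle(self, values, frac):
        assert trimmed_mean(values, frac) == pytest.approx(
            trimmed_mean_oracle(values, frac), rel=1e-9, abs=1e-6
        )


class TestFragmentScore:
    def test_equal_channels_score_zero(self):
        probes = np.linspace(100, 200, 15)
        assert fragment_score(probes, probes) == 0.0

    def test_doubled_hpaii_scores_one(self):
        probes = np.linspace(100, 200, 15)
        assert fragment_score(2 * probes, probes) == pytest.approx(1.0)

    def test_noisy_recovery(self, rng):
        """Signal +1 with 10% probe noise is recovered within 0.15 on average."""
        errs = []
        for _ in range(1000):
            base = 500.0
            noise = lambda: np.exp(rng.normal(0, 0.1, size=15))
            score = fragment_score(base * 2.0 * noise(), base * noise())
            errs.append(abs(score - 1.0))
        assert np.mean(errs) < 0.15


class TestCenterScores:
    def test_symmetric_scores_unchanged(self):
        scores = pd.DataFrame({"s1": [-1.0, 0.0, 1.0]})
        centered, cats = center_scores(scores)
        pd.testing.assert_frame_equal(centered, scores)
        assert list(cats["s1"]) == ["methylated", "hypomethylated", "hypomethylated"]

    def test_constant_shift_removed(self):
        base = pd.DataFrame({"s1": [-1.0, 0.0, 1.0], "s2": [0.5, -0.5, 0.0]})
        centered, _ = center_scores(base + 3.0)
        shifted_back, _ = center_scores(base)
        pd.testing.assert_frame_equal(centered, shifted_back)

    def test_categories_match_sign_counts(self, rng):
        scores = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        centered, cats = center_scores(scores)
        assert ((cats == "hypomethylated").sum() == (centered >= 0).sum()).all()


class TestTagScore:
    def test_endpoint_semantics(self):
        assert tag_score(0, 100, 1000, 1000) == 0.0          # fully methylated
        assert tag_score(100, 100, 1000, 1000) == 100.0      # fully hypomethylated
        assert tag_score(50, 100, 1000, 1000) == 50.0
        assert np.isnan(tag_score(5, 0, 1000, 1000))         # unscorable locus

    @given(
        st.integers(0, 10_000),
        st.integers(1, 10_000),
        st.integers(1, 10_000_000),
        st.integers(1, 10_000_000),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_monotone(self, h, m, ht, mt):
        s = tag_score(h, m, ht, mt)
        assert 0.0 <= s <= 100.0
        assert tag_score(h + 1, m, ht, mt) >= s


class TestModeratedT:
    def test_zero_prior_df_is_classical_t(self, rng):
        a = rng.normal(size=(100, 4))
        b = rng.normal(size=(100, 5))
        res = moderated_t_test(a, b, prior_df=0)
        ref = scipy.stats.ttest_ind(b, a, axis=1, equal_var=True)
        np.testing.assert_allclose(res.t, ref.statistic, atol=1e-9)
        np.testing.assert_allclose(res.p, ref.pvalue, atol=1e-9)

    def test_infinite_prior_df_pools_all_variance(self, rng):
        a = rng.normal(size=(50, 4))
        b = rng.normal(size=(50, 4))
        res = moderated_t_test(a, b, prior_df=np.inf)
        assert np.allclose(res.s2_post, res.s2_post[0])

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(99)
        a = rng.normal(size=(2000, 4))
        b = rng.normal(size=(2000, 4))
        res = moderated_t_test(a, b)
        rate = float(np.mean(res.p < 0.05))
        assert rate == pytest.approx(0.05, abs=0.01)

    def test_matches_limma_reference(self, tmp_path):
        """Cross-check the empirical-Bayes shrinkage against limma's eBayes."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        rng = np.random.default_rng(5)
        mat = rng.normal(size=(80, 8)) * rng.gamma(2, 0.5, size=(80, 1))
        mat[:10, 4:] += 1.5
        df = pd.DataFrame(mat)
        csv = tmp_path / "mat.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "limma.R"
        script.write_text(textwrap.dedent("""
            suppressMessages(library(limma))
            args <- commandArgs(trailingOnly=TRUE)
            m <- as.matrix(read.csv(args[1]))
            design <- cbind(Intercept=1, Group=c(0,0,0,0,1,1,1,1))
            fit <- eBayes(lmFit(m, design))
            out <- data.frame(t=fit$t[,2], p=fit$p.value[,2],
                              d0=fit$df.prior, s0=fit$s2.prior)
            write.csv(out, args[2], row.names=FALSE)
        """))
        out = tmp_path / "limma_out.csv"
        proc = subprocess.run(
            ["Rscript", str(script), str(csv), str(out)],
            capture_output=True, text=True,
        )
        if proc.returncode != 0:
            pytest.skip(f"limma not runnable: {proc.stderr[-300:]}")
        ref = pd.read_csv(out)
        res = moderated_t_test(mat[:, :4], mat[:, 4:])
        assert res.df_prior == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        assert res.s2_prior == pytest.approx(ref["s0"].iloc[0], rel=1e-4)
        np.testing.assert_allclose(res.t, ref["t"], rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(res.p, ref["p"], rtol=1e-6, atol=1e-10)


class TestCallDmrs:
    def _centered(self, rows, n_per_group=4):
        cols = [f"A{i}" for i in range(n_per_group)] + [
            f"B{i}" for i in range(n_per_group)
        ]
        groups = {c: c[0] for c in cols}
        return pd.DataFrame(rows, columns=cols), groups

    def test_delta_threshold_is_strict(self):
        # delta exactly 1.5 must not be called even at tiny p
        scores, groups = self._centered(
            [[0.0, 0.001, -0.001, 0.0, 1.5, 1.501, 1.499, 1.5],
             [0.0, 0.002, -0.002, 0.0, 2.0, 2.002, 1.998, 2.0]]
        )
        calls = call_dmrs(scores, groups, case="B", control="A")
        assert calls.loc[0, "delta"] == pytest.approx(1.5)
        assert calls.loc[0, "status"] == "none"
        assert calls.loc[1, "status"] == "hypo"

    def test_hyper_direction(self):
        scores, groups = self._centered(
            [[2.0, 2.01, 1.99, 2.0, 0.0, 0.01, -0.01, 0.0],
             [0.0, 0.02, -0.02, 0.01, 0.0, 0.01, -0.01, 0.0]]
        )
        calls = call_dmrs(scores, groups, case="B", control="A")
        assert calls.loc[0, "status"] == "hyper"
        assert calls.loc[1, "status"] == "none"


class TestGenomicContext:
    ISLANDS = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "start": [10_000, 40_000], "end": [11_000, 41_000]}
    )

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (10_500, "island"),
            (11_000 + 500, "shore"),
            (11_000 + 2000, "other"),   # half-open flank excludes the boundary
            (10_000 - 1, "shore"),
            (10_000 - 2000, "shore"),
            (10_000 - 2001, "other"),
            (25_000, "other"),
        ],
    )
    def test_boundary_conventions(self, pos, expected):
        positions = pd.DataFrame({"chrom": ["chr1"], "pos": [pos]})
        assert classify_cpg_context(positions, self.ISLANDS).iloc[0] == expected

    def test_partition_is_total(self, rng):
        positions = pd.DataFrame(
            {"chrom": "chr1", "pos": rng.integers(0, 60_000, size=500)}
        )
        labels = classify_cpg_context(positions, self.ISLANDS)
        assert set(labels) <= {"island", "shore", "other"}
        assert len(labels) == 500

    def test_malformed_bed_interval_rejected(self):
        bad = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [50]})
        positions = pd.DataFrame({"chrom": ["chr1"], "pos": [10]})
        with pytest.raises(ValueError, match="malformed"):
            classify_cpg_context(positions, bad)


class TestFeatureDistribution:
    def test_identical_sets_give_zero_chisquare(self):
        classes = pd.Series(["island"] * 10 + ["shore"] * 30 + ["other"] * 60)
        dist = feature_distribution(classes, classes)
        assert dist["chi2"].iloc[0] == pytest.approx(0.0)
        np.testing.assert_allclose(dist["prop_loci"], dist["prop_background"])

    def test_single_class_loci(self):
        background = pd.Series(["island"] * 10 + ["other"] * 90)
        loci = pd.Series(["island"] * 5)
        dist = feature_distribution(loci, background).set_index("class")
        assert dist.loc["island", "prop_loci"] == 1.0

    def test_background_subsamples_look_like_background(self, rng):
        """A uniform subsample of the background should rarely reject."""
        background = pd.Series(
            rng.choice(["island", "shore", "other"], p=[0.1, 0.2, 0.7], size=5000)
        )
        rejects = 0
        for _ in range(100):
            sub = background.sample(n=500, random_state=rng.integers(2**31))
            p = feature_distribution(sub, background)["chi2_p"].iloc[0]
            rejects += p <= 0.01
        assert rejects <= 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            feature_distribution(pd.Series([], dtype=object), pd.Series(["a"]))


class TestDmrRecovery:
    def test_hypomethylation_dominant_design(self):
        """85% hypo perturbations should yield >=5x more hypo than hyper calls."""
        cfg = SimConfig(
            n_fragments=800, n_samples_per_group=4, help_effect=2.5,
            help_noise_sd=0.5, probe_noise_cv=0.1,
            frac_help_perturbed=0.3, hypo_share=0.85, seed=21,
        )
        truth, probes, groups = simulate.simulate_help_array(cfg)
        centered, _ = center_scores(helpassay.score_fragments(probes))
        calls = call_dmrs(centered, groups, case="B", control="A")
        n_hypo = int((calls["status"] == "hypo").sum())
        n_hyper = int((calls["status"] == "hyper").sum())
        assert n_hypo >= 5 * max(n_hyper, 1)
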