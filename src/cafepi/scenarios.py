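"""End-to-end evaluation scenarios over the synthetic study conditions.

Each function simulates the relevant inputs at the study's stated
conditions, runs the corresponding analysis stage and measures recovery
against the generator's ground truth.  These drive both the test suite and
``scripts/acceptance.py``; problem sizes are chosen to finish in seconds on
one CPU while leaving comfortably narrow Monte-Carlo error.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import helpassay, integrate, metabolomics as mx, oxbs, simulate
from .simulate import SimConfig

#: ideal BS/OxBS chemistry: complete conversion of unmodified C, complete
#: protection of 5mC (both libraries) and of 5hmC in BS, complete oxidation
#: of 5hmC in OxBS
IDEAL_CHEMISTRY = dict(
    conv_eff=1.0, protect_5mC=1.0, protect_5hmC_bs=1.0, protect_5hmC_ox=0.0
)


def estimator_recovery(seed: int = 1) -> dict:
    """Mean absolute 5mC/5hmC error at true (0.5, 0.3), coverage 200, n=2000."""
    cfg = SimConfig(
        n_sites=2000, coverage_mean=200, seed=seed,
        base_mc=0.5, base_hmc=0.3, frac_demeth=0.0, frac_hmc_gain=0.0,
        **IDEAL_CHEMISTRY,
    )
    truth, counts = simulate.simulate_bsoxbs(cfg)
    est = oxbs.estimate_sites(counts["A"])
    return {
        "mc_mae": float((est["mc"] - 0.5).abs().mean()),
        "hmc_mae": float((est["hmc"] - 0.3).abs().mean()),
        "n": int(len(est)),
    }


def differential_hmc_performance(seed: int = 1) -> dict:
    """Sensitivity and null false-call rate of the 5hmC-gain rule.

    500 perturbed sites (5hmC 0.1 -> 0.8 with 5mC 0.6 -> 0.2) among 1500
    nulls, coverage 200; also verifies exact label-swap symmetry.
    """
    cfg = SimConfig(
        n_sites=2000, coverage_mean=200, seed=seed,
        base_mc=0.6, base_hmc=0.1, delta_mc=0.4, hmc_gain_level=0.8,
        frac_demeth=0.0, frac_hmc_gain=0.25,
        **IDEAL_CHEMISTRY,
    )
    truth, counts = simulate.simulate_bsoxbs(cfg)
    est_a = oxbs.estimate_sites(counts["A"])
    est_b = oxbs.estimate_sites(counts["B"])
    calls = oxbs.differential_hmc(est_a, est_b)
    merged = calls.merge(truth[["chrom", "start", "perturbation"]], on=["chrom", "start"])
    perturbed = merged["perturbation"] == "hmc_gain"
    sens = float((merged.loc[perturbed, "is_hit"]).mean())
    null_rate = float((merged.loc[~perturbed, "direction"] != "none").mean())

    swapped = oxbs.differential_hmc(est_b, est_a)
    mapping = {"gain-in-B": "gain-in-A", "gain-in-A": "gain-in-B", "none": "none"}
    symmetric = list(swapped["direction"]) == [mapping[d] for d in calls["direction"]]
    return {
        "sensitivity": sens,
        "null_false_call_rate": null_rate,
        "label_swap_symmetric": symmetric,
        "n_perturbed": int(perturbed.sum()),
        "n_null": int((~perturbed).sum()),
    }


def dmr_performance(seed: int = 1, effect: float = 2.0) -> dict:
    """DMR-caller recovery at effect 2.0 log2 units, n=4 vs 4, noise SD 0.5.

    Perturbation directions are balanced (half hypo, half hyper) so the
    per-sample median centering is unbiased and the effect reaching the
    caller is the stated one; direction asymmetry is exercised separately in
    :func:`hypomethylation_dominance`.
    """
    cfg = SimConfig(
        n_fragments=4000, n_samples_per_group=4, seed=seed,
        help_effect=effect, help_noise_sd=0.5, probe_noise_cv=0.1,
        frac_help_perturbed=0.5, hypo_share=0.5,
    )
    truth, probes, groups = simulate.simulate_help_array(cfg)
    centered, _ = helpassay.center_scores(helpassay.score_fragments(probes))
    calls = helpassay.call_dmrs(centered, groups, case="B", control="A")
    calls = calls.join(truth.set_index("fragment")["perturbation"])
    expected = calls["perturbation"].map({"hypo": "hypo", "hyper": "hyper", "none": "none"})
    is_perturbed = expected != "none"
    called = calls["status"] != "none"
    correct = called & (calls["status"] == expected)
    sens = float(correct[is_perturbed].mean())
    n_calls = int(called.sum())
    fdr = float((called & ~is_perturbed).sum() / n_calls) if n_calls else 0.0
    return {
        "sensitivity": sens,
        "empirical_fdr": fdr,
        "n_perturbed": int(is_perturbed.sum()),
        "n_fragments": int(len(calls)),
    }


def hypomethylation_dominance(seed: int = 1, outdir: str | Path | None = None) -> dict:
    """End-to-end pipeline run; hypo vs hyper DMR calls with 85% hypo truth."""
    cfg = SimConfig(n_sites=500, seed=seed)
    import tempfile

    if outdir is None:
        with tempfile.TemporaryDirectory() as tmp:
            manifest = integrate.run_pipeline(cfg, tmp)
    else:
        manifest = integrate.run_pipeline(cfg, outdir)
    n_hypo = manifest["summary"]["n_dmr_hypo_primary"]
    n_hyper = manifest["summary"]["n_dmr_hyper_primary"]
    return {
        "n_hypo": n_hypo,
        "n_hyper": n_hyper,
        "ratio": n_hypo / max(n_hyper, 1),
        "signature": manifest["summary"]["signature"],
        "n_hypo_overexpressed": manifest["summary"]["n_hypo_overexpressed"],
        "n_fragments": cfg.n_fragments,
    }


def mid_roundtrip(seed: int = 1, n_noisefree: int = 200, n_noisy: int = 1000) -> dict:
    """Natural-abundance correction round-trips, noise-free and at 1% noise."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_noisefree):
        n = int(rng.integers(1, 7))
        truth = rng.dirichlet(np.ones(n + 1))
        m = mx.build_correction_matrix(n)
        rec = mx.correct_natural_abundance(m @ truth, m)
        worst = max(worst, float(np.abs(rec.fractions - truth).max()))

    errs = []
    m4 = mx.build_correction_matrix(4)
    for _ in range(n_noisy):
        truth = rng.dirichlet(np.ones(5))
        obs = simulate.simulate_mid_signals(truth, mx.CARBON_13_ABUNDANCE, 1.0, 0.01, 1.0, rng=rng)
        rec = mx.correct_natural_abundance(mx.raw_mid(obs), m4)
        errs.append(float(np.abs(rec.fractions - truth).mean()))
    return {
        "noisefree_max_error": worst,
        "noisy_mean_component_error": float(np.mean(errs)),
        "n_noisefree": n_noisefree,
        "n_noisy": n_noisy,
    }


def calibration_recovery(seed: int = 1, noise_cv: float = 0.01) -> dict:
    """Spiked-standard recovery through the calibration-curve path.

    Standards span 0-3% 5hmC and 0-10% 5mC; response ratios follow a linear
    forward model with 1% multiplicative measurement noise on standards and
    samples alike.  Reports the worst relative recovery error over spiked
    samples inside the calibration range.
    """
    rng = np.random.default_rng(seed)
    slope = {"5hmC": 0.0102, "5mC": 0.0098}
    intercept = {"5hmC": 0.001, "5mC": 0.002}
    standards = {"5hmC": [0.0, 0.5, 1.0, 2.0, 3.0], "5mC": [0.0, 2.0, 4.0, 6.0, 8.0, 10.0]}
    curves = {}
    for analyte, pcts in standards.items():
        pcts = np.asarray(pcts)
        ratios = (slope[analyte] * pcts + intercept[analyte]) * np.exp(
            rng.normal(0, noise_cv, size=pcts.size)
        )
        curves[analyte] = mx.fit_calibration(analyte, pcts, ratios)

    spiked = [(1.0, 2.0), (2.0, 5.0), (3.0, 10.0)]
    worst = 0.0
    for pct_hmc, pct_mc in spiked:
        r_hmc = (slope["5hmC"] * pct_hmc + intercept["5hmC"]) * np.exp(rng.normal(0, noise_cv))
        r_mc = (slope["5mC"] * pct_mc + intercept["5mC"]) * np.exp(rng.normal(0, noise_cv))
        areas = {"C": 1.0 - r_hmc - r_mc, "5mC": r_mc, "5hmC": r_hmc}
        levels = mx.quantify_global(areas, curves)
        worst = max(
            worst,
            abs(levels["pct_5hmC"] - pct_hmc) / pct_hmc,
            abs(levels["pct_5mC"] - pct_mc) / pct_mc,
        )
    return {"max_relative_error": worst, "n_samples": len(spiked)}


def pipeline_determinism(seed: int = 1, workdir: str | Path | None = None) -> dict:
    """Two pipeline runs with identical config: manifests must match byte-wise."""
    import tempfile

    cfg = SimConfig(n_sites=200, n_fragments=300, seed=seed)

    def _run(base: Path) -> tuple[bytes, dict]:
        manifest = integrate.run_pipeline(cfg, base)
        return (Path(base) / "manifest.json").read_bytes(), manifest

    if workdir is None:
        with tempfile.TemporaryDirectory() as tmp:
            b1, m1 = _run(Path(tmp) / "run1")
            b2, m2 = _run(Path(tmp) / "run2")
    else:
        workdir = Path(workdir)
        b1, m1 = _run(workdir / "run1")
        b2, m2 = _run(workdir / "run2")
    return {
        "identical_manifests": b1 == b2 and m1["outputs"] == m2["outputs"],
        "n_outputs": len(m1["outputs"]),
    }
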