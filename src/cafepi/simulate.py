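"""Synthetic study inputs with the statistical structure the pipeline assumes.

Emulates every measurement the analysis consumes, with known ground truth
for parameter-recovery testing:

* paired BS/OxBS per-CpG read counts for two conditions (MSC-like "A" and
  CAF-like "B"), via binomial conversion sampling given true 5mC/5hmC and
  the chemistry of the two libraries;
* HELP array probe intensities (HpaII and MspI channels, nominally 15
  probes per fragment) as log-normal noise around fragment baselines, with
  hypomethylation encoded as a 2^signal scaling of the HpaII channel;
* HELP-tagging per-locus read counts (Poisson, HpaII rate proportional to
  the hypomethylation level times the MspI rate);
* a gene x sample log-expression matrix coupled 1:1 to HELP fragments, so
  hypomethylated fragments' genes are overexpressed in condition B;
* GC-MS isotopomer ion signals from a true MID through the forward
  natural-abundance convolution, plus an internal-standard channel.

One global seed; each generator draws from its own deterministically
derived substream, so adding or reordering generator calls never perturbs
the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metabolomics import build_correction_matrix

#: substream indices off the global seed (stable; order never changes)
_STREAMS = {
    "bsoxbs": 0,
    "help_array": 1,
    "help_tagging": 2,
    "expression": 3,
    "mid": 4,
    "help_array2": 5,
}

CHROM = "chrS"
CPG_SPACING = 50
CPG_OFFSET = 100


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-generator RNG derived from the one global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[name],)))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic inputs.

    Chemistry defaults reflect typical published BS/OxBS performance:
    near-complete conversion of unmodified C, near-complete protection of
    5mC in both libraries and of 5hmC in BS, and efficient oxidation of
    5hmC in OxBS (so only ~5% of 5hmC reads survive unconverted there).
    """

    n_sites: int = 2000
    coverage_mean: float = 50.0
    fixed_coverage: bool = False
    conv_eff: float = 0.995
    protect_5mC: float = 0.99
    protect_5hmC_bs: float = 0.99
    protect_5hmC_ox: float = 0.05
    # truth layout: condition A is uniform; in condition B the first
    # frac_demeth of sites lose delta_mc of 5mC, the next frac_hmc_gain gain
    # 5hmC to hmc_gain_level while losing delta_mc of 5mC (oxidation of 5mC)
    base_mc: float = 0.6
    base_hmc: float = 0.1
    frac_demeth: float = 0.1
    delta_mc: float = 0.4
    frac_hmc_gain: float = 0.25
    hmc_gain_level: float = 0.8
    seed: int = 0
    # HELP array / tagging dimensions
    n_fragments: int = 2000
    probes_per_fragment: int = 15
    n_samples_per_group: int = 4
    help_effect: float = 2.5
    help_noise_sd: float = 0.5
    probe_noise_cv: float = 0.1
    frac_help_perturbed: float = 0.3
    hypo_share: float = 0.85
    tag_depth: float = 100.0
    # expression (genes mapped 1:1 to fragments)
    n_samples_expr: int = 6
    expr_log_fc: float = 2.0
    expr_noise_sd: float = 0.5
    expr_baseline: float = 7.0

    def __post_init__(self) -> None:
        probs = (
            "conv_eff protect_5mC protect_5hmC_bs protect_5hmC_ox base_mc "
            "base_hmc frac_demeth frac_hmc_gain hmc_gain_level hypo_share"
        ).split()
        for name in probs:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.frac_demeth + self.frac_hmc_gain > 1.0 + 1e-12:
            raise ValueError("frac_demeth + frac_hmc_gain must not exceed 1")
        if self.base_mc + self.base_hmc > 1.0 + 1e-12:
            raise ValueError("base_mc + base_hmc must not exceed 1")
        perturbed = self.frac_demeth > 0 or self.frac_hmc_gain > 0
        if perturbed and self.delta_mc > self.base_mc:
            raise ValueError("delta_mc cannot exceed base_mc")
        if (
            self.frac_hmc_gain > 0
            and (self.base_mc - self.delta_mc) + self.hmc_gain_level > 1.0 + 1e-12
        ):
            raise ValueError(
                "5hmC-gain sites would have true_mc + true_hmc > 1; "
                "lower hmc_gain_level or raise delta_mc"
            )
        if self.n_sites < 1 or self.n_fragments < 1 or self.probes_per_fragment < 1:
            raise ValueError("dimensions must be >= 1")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


def site_truth(cfg: SimConfig) -> pd.DataFrame:
    """Per-site true 5mC/5hmC for both conditions, plus perturbation labels."""
    n = cfg.n_sites
    n_dem = int(round(cfg.frac_demeth * n))
    n_gain = int(round(cfg.frac_hmc_gain * n))
    perturb = np.array(["none"] * n, dtype=object)
    perturb[:n_dem] = "demeth"
    perturb[n_dem : n_dem + n_gain] = "hmc_gain"

    mc_a = np.full(n, cfg.base_mc)
    hmc_a = np.full(n, cfg.base_hmc)
    mc_b = mc_a.copy()
    hmc_b = hmc_a.copy()
    mc_b[perturb != "none"] -= cfg.delta_mc
    hmc_b[perturb == "hmc_gain"] = cfg.hmc_gain_level

    starts = CPG_OFFSET + CPG_SPACING * np.arange(n)
    return pd.DataFrame(
        {
            "chrom": CHROM,
            "start": starts,
            "end": starts + 1,
            "strand": "+",
            "perturbation": perturb,
            "true_mc_a": mc_a,
            "true_hmc_a": hmc_a,
            "true_mc_b": mc_b,
            "true_hmc_b": hmc_b,
        }
    )


def _sample_counts(
    rng: np.random.Generator, cfg: SimConfig, mc: np.ndarray, hmc: np.ndarray
) -> pd.DataFrame:
    """Draw one condition's BS and OxBS count table given true proportions."""
    n = len(mc)
    unmod = 1.0 - mc - hmc
    pi_bs = mc * cfg.protect_5mC + hmc * cfg.protect_5hmC_bs + unmod * (1 - cfg.conv_eff)
    pi_ox = mc * cfg.protect_5mC + hmc * cfg.protect_5hmC_ox + unmod * (1 - cfg.conv_eff)
    out = {}
    for lib, pi in (("bs", pi_bs), ("ox", pi_ox)):
        if cfg.fixed_coverage:
            cov = np.full(n, int(round(cfg.coverage_mean)))
        else:
            cov = np.maximum(1, rng.poisson(cfg.coverage_mean, size=n))
        u = rng.binomial(cov, np.clip(pi, 0.0, 1.0))
        out[f"u_{lib}"] = u
        out[f"c_{lib}"] = cov - u
    starts = CPG_OFFSET + CPG_SPACING * np.arange(n)
    return pd.DataFrame(
        {"chrom": CHROM, "start": starts, "strand": "+", **out}
    )


def simulate_bsoxbs(cfg: SimConfig) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Truth table plus paired BS/OxBS count tables for conditions A and B."""
    rng = substream(cfg.seed, "bsoxbs")
    truth = site_truth(cfg)
    counts = {
        "A": _sample_counts(rng, cfg, truth["true_mc_a"].to_numpy(), truth["true_hmc_a"].to_numpy()),
        "B": _sample_counts(rng, cfg, truth["true_mc_b"].to_numpy(), truth["true_hmc_b"].to_numpy()),
    }
    return truth, counts


def fragment_truth(cfg: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-fragment perturbation truth for the HELP array design.

    The first frac_help_perturbed of fragments change methylation in group
    B; of those, hypo_share become hypomethylated (+help_effect on the log2
    ratio) and the rest hypermethylated (-help_effect).
    """
    n = cfg.n_fragments
    n_pert = int(round(cfg.frac_help_perturbed * n))
    n_hypo = int(round(cfg.hypo_share * n_pert))
    perturb = np.array(["none"] * n, dtype=object)
    perturb[:n_hypo] = "hypo"
    perturb[n_hypo:n_pert] = "hyper"
    effect = np.zeros(n)
    effect[perturb == "hypo"] = cfg.help_effect
    effect[perturb == "hyper"] = -cfg.help_effect
    frag_len = 1000
    starts = CPG_OFFSET + frag_len * np.arange(n)
    return pd.DataFrame(
        {
            "fragment": [f"frag{i:05d}" for i in range(n)],
            "chrom": CHROM,
            "start": starts,
            "end": starts + frag_len,
            "perturbation": perturb,
            "true_effect": effect,
        }
    )


def simulate_help_array(
    cfg: SimConfig, truth: pd.DataFrame | None = None, stream: str = "help_array"
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Probe-level HELP array intensities for two groups of samples.

    Returns (fragment truth, probe table, sample -> group map).  The probe
    table is long format: fragment, sample, probe, hpaii, mspi.  The MspI
    channel is log-normal around a per-fragment baseline; the HpaII channel
    multiplies that baseline by 2^score, where a fragment's score in a
    sample is its true group effect plus Gaussian sample noise
    (help_noise_sd); probe noise is i.i.d. log-normal with sigma
    probe_noise_cv on both channels.
    """
    rng = substream(cfg.seed, stream)
    if truth is None:
        truth = fragment_truth(cfg)
    n = len(truth)
    samples = [f"A{i + 1}" for i in range(cfg.n_samples_per_group)] + [
        f"B{i + 1}" for i in range(cfg.n_samples_per_group)
    ]
    groups = {s: s[0] for s in samples}
    baseline = np.exp(rng.normal(np.log(1000.0), 0.5, size=n))
    effect = truth["true_effect"].to_numpy()

    frames = []
    for s in samples:
        score = np.where(groups[s] == "B", effect, 0.0)
        if cfg.help_noise_sd > 0:
            score = score + rng.normal(0.0, cfg.help_noise_sd, size=n)
        probe_shape = (n, cfg.probes_per_fragment)
        noise_h = (
            np.exp(rng.normal(0.0, cfg.probe_noise_cv, size=probe_shape))
            if cfg.probe_noise_cv > 0
            else np.ones(probe_shape)
        )
        noise_m = (
            np.exp(rng.normal(0.0, cfg.probe_noise_cv, size=probe_shape))
            if cfg.probe_noise_cv > 0
            else np.ones(probe_shape)
        )
        hpaii = baseline[:, None] * (2.0**score)[:, None] * noise_h
        mspi = baseline[:, None] * noise_m
        frames.append(
            pd.DataFrame(
                {
                    "fragment": np.repeat(truth["fragment"].to_numpy(), cfg.probes_per_fragment),
                    "sample": s,
                    "probe": np.tile(np.arange(cfg.probes_per_fragment), n),
                    "hpaii": hpaii.ravel(),
                    "mspi": mspi.ravel(),
                }
            )
        )
    return truth, pd.concat(frames, ignore_index=True), groups


def simulate_help_tagging(
    cfg: SimConfig, levels: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-locus HELP-tagging read counts with known hypomethylation levels.

    HpaII counts are Poisson with rate level * tag_depth; MspI counts are
    Poisson(tag_depth).  ``levels`` (in [0, 1], 0 = fully methylated)
    defaults to a uniform draw per locus.
    """
    rng = substream(cfg.seed, "help_tagging")
    n = cfg.n_fragments
    if levels is None:
        levels = rng.uniform(0.0, 1.0, size=n)
    levels = np.asarray(levels, dtype=float)
    if ((levels < 0) | (levels > 1)).any():
        raise ValueError("hypomethylation levels must lie in [0, 1]")
    starts = CPG_OFFSET + 1000 * np.arange(len(levels))
    return pd.DataFrame(
        {
            "locus": [f"locus{i:05d}" for i in range(len(levels))],
            "chrom": CHROM,
            "start": starts,
            "end": starts + 1,
            "true_level": levels,
            "hpaii_reads": rng.poisson(levels * cfg.tag_depth),
            "mspi_reads": rng.poisson(cfg.tag_depth, size=len(levels)),
        }
    )


def simulate_expression(
    cfg: SimConfig, frag_truth: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Gene x sample log2 expression tied 1:1 to HELP fragment truth.

    Genes of hypomethylated fragments gain expr_log_fc in group B; all
    entries get i.i.d. Gaussian noise with sd expr_noise_sd.
    """
    rng = substream(cfg.seed, "expression")
    genes = [f.replace("frag", "gene") for f in frag_truth["fragment"]]
    n = len(genes)
    samples = [f"A{i + 1}" for i in range(cfg.n_samples_expr)] + [
        f"B{i + 1}" for i in range(cfg.n_samples_expr)
    ]
    groups = {s: s[0] for s in samples}
    up = (frag_truth["perturbation"] == "hypo").to_numpy()
    mat = np.empty((n, len(samples)))
    for j, s in enumerate(samples):
        mean = cfg.expr_baseline + np.where(up & (groups[s] == "B"), cfg.expr_log_fc, 0.0)
        noise = rng.normal(0.0, cfg.expr_noise_sd, size=n) if cfg.expr_noise_sd > 0 else 0.0
        mat[:, j] = mean + noise
    return pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=samples), groups


def simulate_mid_signals(
    true_mid,
    abundance: float,
    total_signal: float,
    noise_cv: float,
    internal_standard_signal: float,
    rng: np.random.Generator | None = None,
    n_atoms: int | None = None,
) -> np.ndarray:
    """Forward model for GC-MS isotopomer signals from a true MID.

    observed = total_signal * (CorrectionMatrix @ true_mid), with
    multiplicative log-normal noise of coefficient of variation noise_cv.
    Returns the observed channel vector; the caller pairs it with the
    internal-standard channel.
    """
    mid = np.asarray(true_mid, dtype=float)
    if abs(mid.sum() - 1.0) > 1e-9 or (mid < 0).any():
        raise ValueError("true_mid must be a simplex vector")
    if total_signal < 0 or noise_cv < 0 or internal_standard_signal < 0:
        raise ValueError("negative signal parameters")
    m = build_correction_matrix(len(mid) - 1, abundance, n_atoms=n_atoms)
    observed = total_signal * (m @ mid)
    if noise_cv > 0:
        if rng is None:
            raise ValueError("an RNG is required when noise_cv > 0")
        observed = observed * np.exp(rng.normal(0.0, noise_cv, size=observed.shape))
    return observed


def cpg_islands(cfg: SimConfig, island_every: int = 200, island_len: int = 500) -> pd.DataFrame:
    """A regular CpG-island annotation over the synthetic chromosome."""
    starts = np.arange(0, cfg.n_sites * CPG_SPACING + CPG_OFFSET, island_every * CPG_SPACING)
    return pd.DataFrame({"chrom": CHROM, "start": starts, "end": starts + island_len})
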