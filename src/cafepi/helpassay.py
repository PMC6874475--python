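"""HELP assay and HELP-tagging methylation scoring and differential calling.

The HELP assay compares genomic digestion by the methylation-sensitive HpaII
against its methylation-insensitive isoschizomer MspI at the same CCGG sites.
On the array platform each HpaII-amplifiable fragment is represented by ~15
probes per channel; the fragment-level methylation score is the
log2(HpaII/MspI) ratio of 25%-trimmed-mean probe intensities, centered per
sample.  Higher scores mean more HpaII signal, i.e. hypomethylation.  The
sequencing version (HELP-tagging) replaces intensities with per-locus read
counts, normalized against a deeply sequenced MspI profile onto a 0-100
scale (0 fully methylated, 100 fully hypomethylated).

Differential methylation between two groups of samples uses a moderated
t-test — an empirical-Bayes shrinkage of per-fragment variances toward a
prior fitted across all fragments — with Benjamini-Hochberg correction and
an absolute score difference above 1.5 required for a call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.special import digamma, polygamma

from .oxbs import bh_adjust


def trimmed_mean(values, trim_fraction: float = 0.25) -> float:
    """Robust mean after discarding floor(trim_fraction * n) from each tail."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("trimmed_mean of empty vector")
    if not 0.0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must lie in [0, 0.5)")
    return float(scipy.stats.trim_mean(x, trim_fraction))


def fragment_score(hpaii_probes, mspi_probes, trim_fraction: float = 0.25) -> float:
    """Raw fragment methylation score: log2 of trimmed-mean channel ratio."""
    h = trimmed_mean(hpaii_probes, trim_fraction)
    m = trimmed_mean(mspi_probes, trim_fraction)
    if h <= 0 or m <= 0:
        raise ValueError("nonpositive trimmed channel mean")
    return float(np.log2(h / m))


def score_fragments(probes: pd.DataFrame, trim_fraction: float = 0.25) -> pd.DataFrame:
    """Collapse a probe-level table to raw fragment x sample scores.

    ``probes`` columns: fragment, sample, hpaii, mspi (one row per probe).
    Returns a fragment x sample DataFrame of raw log2 ratios.
    """
    df = probes.sort_values(["fragment", "sample"], kind="stable")
    sizes = df.groupby(["fragment", "sample"], sort=False).size()
    if sizes.nunique() == 1:
        # uniform probe count: trim along a reshaped axis in one shot
        k = int(sizes.iloc[0])
        h = scipy.stats.trim_mean(
            df["hpaii"].to_numpy().reshape(-1, k), trim_fraction, axis=1
        )
        m = scipy.stats.trim_mean(
            df["mspi"].to_numpy().reshape(-1, k), trim_fraction, axis=1
        )
        if (h <= 0).any() or (m <= 0).any():
            raise ValueError("nonpositive trimmed channel mean")
        raw = pd.Series(np.log2(h / m), index=sizes.index)
    else:
        raw = df.groupby(["fragment", "sample"], sort=False).apply(
            lambda g: fragment_score(g["hpaii"], g["mspi"], trim_fraction),
            include_groups=False,
        )
    scores = raw.unstack("sample")
    scores.columns.name = None
    return scores


def center_scores(scores: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subtract the per-sample median and categorize fragments.

    A fragment is ``hypomethylated`` in a sample when its centered score is
    >= 0 (the zero tie goes to hypomethylated so every fragment gets exactly
    one category) and ``methylated`` when it is < 0.
    """
    if scores.shape[0] < 1:
        raise ValueError("need at least one fragment")
    centered = scores - scores.median(axis=0)
    categories = pd.DataFrame(
        np.where(centered >= 0, "hypomethylated", "methylated"),
        index=centered.index,
        columns=centered.columns,
    )
    return centered, categories


def tag_score(
    hpaii_reads, mspi_reads, hpaii_library_total: float, mspi_library_total: float
):
    """HELP-tagging 0-100 methylation score for one locus (vectorized).

    The HpaII read density is normalized by the MspI density; the resulting
    ratio r is mapped to 100 * min(1, r), so 0 = fully methylated (no HpaII
    cutting) and 100 = fully hypomethylated (HpaII cuts as freely as MspI).
    Loci with zero MspI reads are unscored (NaN).
    """
    if hpaii_library_total <= 0 or mspi_library_total <= 0:
        raise ValueError("library totals must be positive")
    h = np.asarray(hpaii_reads, dtype=float)
    m = np.asarray(mspi_reads, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (h / hpaii_library_total) / (m / mspi_library_total)
    score = 100.0 * np.minimum(1.0, r)
    score = np.where(m > 0, score, np.nan)
    if score.ndim == 0:
        return float(score)
    return score


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


@dataclass(frozen=True)
class ModeratedTResult:
    delta: np.ndarray      # mean(case/group B) - mean(control/group A)
    t: np.ndarray          # moderated t statistic per row
    p: np.ndarray          # two-sided p-value
    df_prior: float        # fitted (or forced) prior degrees of freedom d0
    s2_prior: float        # fitted prior variance s0^2
    df_residual: float     # per-row residual df d = n_a + n_b - 2
    s2_post: np.ndarray    # shrunken variances


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of a scaled inverse-chi-square variance prior.

    Matches the mean and variance of log sample variances against the theory
    for s^2 ~ s0^2 * F(df, d0): e = log(s2) - digamma(df/2) + log(df/2) has
    mean log(s0^2) + digamma(d0/2) - log(d0/2) and excess variance
    trigamma(d0/2) beyond trigamma(df/2).  When the observed spread of
    log-variances does not exceed the sampling spread, the prior df is
    infinite and every row shares s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        raise ValueError("need at least two positive sample variances")
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    evar = np.var(e, ddof=1) - polygamma(1, df / 2.0)
    if evar <= 0:
        return np.inf, float(np.exp(np.mean(e)))
    half_d0 = _trigamma_inverse(float(evar))
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(np.mean(e) + digamma(half_d0) - np.log(half_d0)))
    return d0, s0_sq


def moderated_t_test(
    group_a: pd.DataFrame | np.ndarray,
    group_b: pd.DataFrame | np.ndarray,
    prior_df: float | None = None,
) -> ModeratedTResult:
    """Row-wise moderated two-sample t-test (group B minus group A).

    Per row a pooled variance s^2 with d = n_a + n_b - 2 residual df is
    shrunk toward a prior (d0, s0^2) fitted across rows by method of moments:
    s~^2 = (d0 s0^2 + d s^2) / (d0 + d), t = delta / (s~ sqrt(1/n_a + 1/n_b))
    with d + d0 degrees of freedom.  ``prior_df`` overrides the fit: 0 gives
    the ordinary pooled t-test, ``inf`` uses s0^2 everywhere.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[0] != b.shape[0]:
        raise ValueError("inputs must be row-aligned 2D matrices")
    n_a, n_b = a.shape[1], b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValueError("need >= 2 samples per group")
    df = n_a + n_b - 2
    if df <= 0:
        raise ValueError("zero residual degrees of freedom")

    delta = b.mean(axis=1) - a.mean(axis=1)
    ss = a.var(axis=1, ddof=1) * (n_a - 1) + b.var(axis=1, ddof=1) * (n_b - 1)
    s2 = ss / df

    if prior_df is None:
        d0, s0_sq = fit_variance_prior(s2, df)
    elif prior_df == 0:
        d0, s0_sq = 0.0, float(np.nan)
    elif np.isinf(prior_df):
        d0 = np.inf
        _, s0_sq = fit_variance_prior(s2, df)
    else:
        d0 = float(prior_df)
        _, s0_sq = fit_variance_prior(s2, df)

    if d0 == 0:
        s2_post = s2
    elif np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)

    se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = delta / se
    df_total = df + d0
    if np.isinf(df_total):
        p = 2.0 * scipy.stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * scipy.stats.t.sf(np.abs(t), df_total)
    return ModeratedTResult(delta, t, p, d0, s0_sq, float(df), s2_post)


def call_dmrs(
    centered: pd.DataFrame,
    groups: dict[str, str] | pd.Series,
    case: str,
    control: str,
    alpha: float = 0.05,
    min_delta: float = 1.5,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Differential methylation calls on a centered fragment x sample matrix.

    delta = mean(case) - mean(control) on the centered log2(HpaII/MspI)
    scale, so positive delta means the case group is hypomethylated at the
    fragment.  status is ``hypo`` when p < alpha and delta > +min_delta
    (strict), ``hyper`` when p < alpha and delta < -min_delta, else ``none``.
    q is the BH adjustment of p over all fragments, reported alongside.
    """
    groups = pd.Series(groups)
    a_cols = [c for c in centered.columns if groups.get(c) == control]
    b_cols = [c for c in centered.columns if groups.get(c) == case]
    res = moderated_t_test(centered[a_cols], centered[b_cols], prior_df=prior_df)
    sig = res.p < alpha
    status = np.select(
        [sig & (res.delta > min_delta), sig & (res.delta < -min_delta)],
        ["hypo", "hyper"],
        "none",
    )
    return pd.DataFrame(
        {
            "delta": res.delta,
            "t_mod": res.t,
            "p": res.p,
            "q": bh_adjust(res.p),
            "status": status,
        },
        index=centered.index,
    )


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent half-open intervals per chromosome."""
    out = []
    for chrom, g in intervals.groupby("chrom"):
        g = g.sort_values("start")
        cur_s = cur_e = None
        for s, e in zip(g["start"], g["end"]):
            if s < 0 or e <= s:
                raise ValueError(f"malformed interval {chrom}:{s}-{e}")
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def classify_cpg_context(
    positions: pd.DataFrame, islands: pd.DataFrame, shore_width: int = 2000
) -> pd.Series:
    """Classify positions as CpG ``island``, ``shore`` or ``other``.

    ``positions`` has columns chrom, pos (0-based).  A shore is the
    half-open flank [start - shore_width, start) or [end, end + shore_width)
    of a merged island; positions inside any island are islands regardless
    of proximity to another island's flank.
    """
    isl = merge_intervals(islands)
    labels = np.full(len(positions), "other", dtype=object)
    for chrom, g in isl.groupby("chrom"):
        mask = (positions["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        pos = positions.loc[mask, "pos"].to_numpy()
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        # idx of first interval with start > pos; candidate container is idx-1
        idx = np.searchsorted(starts, pos, side="right")
        in_island = (idx > 0) & (pos < ends[np.maximum(idx - 1, 0)])
        near = np.zeros(len(pos), dtype=bool)
        for s, e in zip(starts, ends):
            near |= ((pos >= s - shore_width) & (pos < s)) | (
                (pos >= e) & (pos < e + shore_width)
            )
        sub = np.where(in_island, "island", np.where(near, "shore", "other"))
        labels[mask] = sub
    return pd.Series(labels, index=positions.index, name="context")


def feature_distribution(
    loci_classes: pd.Series, background_classes: pd.Series
) -> pd.DataFrame:
    """Compare the feature-class distribution of loci against a background.

    Returns one row per class with counts and proportions for both sets plus
    a single chi-square goodness-of-fit test of the locus counts against the
    background proportions (stored on every row for convenience).
    """
    if len(loci_classes) == 0 or len(background_classes) == 0:
        raise ValueError("both locus sets must be nonempty")
    classes = sorted(set(background_classes))
    missing = set(loci_classes) - set(classes)
    if missing:
        raise ValueError(f"locus classes absent from background universe: {missing}")
    obs = loci_classes.value_counts().reindex(classes, fill_value=0).to_numpy()
    bg = background_classes.value_counts().reindex(classes, fill_value=0).to_numpy()
    bg_prop = bg / bg.sum()
    expected = bg_prop * obs.sum()
    chi2, p = scipy.stats.chisquare(obs, expected)
    return pd.DataFrame(
        {
            "class": classes,
            "n_loci": obs,
            "prop_loci": obs / obs.sum(),
            "n_background": bg,
            "prop_background": bg_prop,
            "chi2": chi2,
            "chi2_p": p,
        }
    )
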