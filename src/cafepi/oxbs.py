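"""Per-CpG 5mC/5hmC estimation from paired bisulfite / oxidative-bisulfite counts.

In a bisulfite (BS) library both 5-methylcytosine (5mC) and
5-hydroxymethylcytosine (5hmC) resist conversion, while in an
oxidative-bisulfite (OxBS) library only 5mC does.  The OxBS unconverted
fraction therefore estimates 5mC, and the BS-minus-OxBS difference estimates
5hmC.  This module implements that estimator together with the selection
rules used to call hydroxymethylated sites within a condition (Fisher exact
test of BS vs OxBS proportions, Benjamini-Hochberg correction) and to call
differential hydroxymethylation between two conditions (the CAF-vs-MSC rule:
higher 5hmC in the gaining condition, 5hmC at least ``tau_hmc``, and lower
5mC).

Counts enter as a :class:`pandas.DataFrame` with one row per CpG:

======  ======================================================
column  meaning
======  ======================================================
chrom   chromosome name
start   0-based position of the CpG (half-open intervals)
strand  ``+`` (reverse-strand counts must be pre-collapsed)
u_bs    unconverted read count, BS library
c_bs    converted read count, BS library
u_ox    unconverted read count, OxBS library
c_ox    converted read count, OxBS library
======  ======================================================
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

SITE_KEY = ["chrom", "start"]

COUNT_COLUMNS = ["u_bs", "c_bs", "u_ox", "c_ox"]


@dataclass(frozen=True)
class OxbsConfig:
    """Thresholds governing site estimation and calling.

    min_coverage : minimum reads per library for a site to be testable.
    alpha_within : per-site Fisher p-value cutoff for the 5hmC call.
    tau_hmc      : minimum 5hmC proportion required of the gaining condition
                   in a differential call (inclusive).
    tau_mc       : 5mC proportion at or above which a site is flagged 5mC
                   (inclusive).
    alpha_between: BH-adjusted q cutoff for reported differential hits.
    """

    min_coverage: int = 10
    alpha_within: float = 0.05
    tau_hmc: float = 0.75
    tau_mc: float = 0.50
    alpha_between: float = 0.05

    def __post_init__(self) -> None:
        for name in ("alpha_within", "tau_hmc", "tau_mc", "alpha_between"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 contingency table.

    Sums hypergeometric probabilities of every table sharing the observed
    margins whose probability does not exceed the observed table's (to within
    a relative tolerance of 1e-7, so the observed table is never excluded by
    floating-point jitter).  Tables with an empty margin carry no information
    about association and return p = 1 by convention.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("contingency table entries must be nonnegative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(scipy.stats.fisher_exact(t, alternative="two-sided").pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), input order.

    q_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def estimate_sites(counts: pd.DataFrame, cfg: OxbsConfig = OxbsConfig()) -> pd.DataFrame:
    """Estimate per-site 5mC and 5hmC with a within-condition Fisher test.

    Adds to a copy of ``counts``:

    * ``testable`` — both libraries reach ``cfg.min_coverage``;
    * ``mc`` — u_ox / (u_ox + c_ox), the OxBS unconverted fraction;
    * ``hmc`` — BS unconverted fraction minus ``mc``, clamped at 0;
    * ``p_within`` — Fisher p of [[u_bs, c_bs], [u_ox, c_ox]];
    * ``q_within`` — BH-adjusted over the testable universe only.

    Untestable sites keep NaN estimates and never enter the multiple-testing
    universe.
    """
    df = counts.copy()
    cnt = df[COUNT_COLUMNS].to_numpy()
    if (cnt < 0).any():
        raise ValueError("negative read counts")
    n_bs = df["u_bs"] + df["c_bs"]
    n_ox = df["u_ox"] + df["c_ox"]
    df["testable"] = (n_bs >= cfg.min_coverage) & (n_ox >= cfg.min_coverage)

    with np.errstate(invalid="ignore", divide="ignore"):
        mc = df["u_ox"] / n_ox
        bs_frac = df["u_bs"] / n_bs
    df["mc"] = mc.where(df["testable"])
    df["hmc"] = (bs_frac - mc).clip(lower=0.0).where(df["testable"])

    pvals = np.full(len(df), np.nan)
    idx = np.flatnonzero(df["testable"].to_numpy())
    for i in idx:
        pvals[i] = fisher_exact([[cnt[i, 0], cnt[i, 1]], [cnt[i, 2], cnt[i, 3]]])
    df["p_within"] = pvals
    q = np.full(len(df), np.nan)
    if idx.size:
        q[idx] = bh_adjust(pvals[idx])
    df["q_within"] = q
    return df


def call_hmc_sites(estimates: pd.DataFrame, cfg: OxbsConfig = OxbsConfig()) -> pd.DataFrame:
    """Flag hydroxymethylated and methylated sites within one condition.

    ``is_hmc`` requires Fisher p_within < alpha_within and a positive 5hmC
    estimate; ``is_5mC`` applies the 50% rule inclusively (mc >= tau_mc).
    """
    df = estimates.copy()
    df["is_hmc"] = (df["p_within"] < cfg.alpha_within) & (df["hmc"] > 0)
    df["is_hmc"] = df["is_hmc"].fillna(False)
    df["is_5mC"] = (df["mc"] >= cfg.tau_mc).fillna(False)
    return df


def _rounded_hmc_table(row) -> list[list[int]]:
    """2x2 table of rounded 5hmC-supporting counts, n = BS coverage."""
    out = []
    for side in ("b", "a"):
        n = int(row[f"u_bs_{side}"] + row[f"c_bs_{side}"])
        k = int(round(row[f"hmc_{side}"] * n))
        out.append([k, n - k])
    return out


def differential_hmc(
    a: pd.DataFrame, b: pd.DataFrame, cfg: OxbsConfig = OxbsConfig()
) -> pd.DataFrame:
    """Call differential hydroxymethylation between condition A and B.

    Both inputs are estimate tables from :func:`estimate_sites` (optionally
    via :func:`call_hmc_sites`) over the same sites.  ``gain-in-B`` is called
    when B has the higher 5hmC, B's 5hmC is at least ``tau_hmc`` (inclusive)
    and B's 5mC is strictly below A's; ``gain-in-A`` by the mirror rule.  A
    between-condition Fisher test on rounded 5hmC-supporting counts (with the
    BS coverage as trial count) yields p_between, BH-adjusted over all
    compared sites; reported hits (``is_hit``) additionally require
    q_between < alpha_between.
    """
    keys_a = set(map(tuple, a[SITE_KEY].itertuples(index=False)))
    keys_b = set(map(tuple, b[SITE_KEY].itertuples(index=False)))
    if keys_a != keys_b:
        off = sorted(keys_a.symmetric_difference(keys_b))[:20]
        raise ValueError(f"site coordinates differ between conditions, e.g. {off}")

    merged = a.merge(b, on=SITE_KEY, suffixes=("_a", "_b"), validate="one_to_one")
    merged = merged[merged["testable_a"] & merged["testable_b"]].reset_index(drop=True)

    hmc_a, hmc_b = merged["hmc_a"], merged["hmc_b"]
    mc_a, mc_b = merged["mc_a"], merged["mc_b"]
    gain_b = (hmc_b > hmc_a) & (hmc_b >= cfg.tau_hmc) & (mc_b < mc_a)
    gain_a = (hmc_a > hmc_b) & (hmc_a >= cfg.tau_hmc) & (mc_a < mc_b)
    merged["direction"] = np.select([gain_b, gain_a], ["gain-in-B", "gain-in-A"], "none")

    merged["p_between"] = [
        fisher_exact(_rounded_hmc_table(row)) for _, row in merged.iterrows()
    ]
    merged["q_between"] = bh_adjust(merged["p_between"])
    merged["is_hit"] = (merged["direction"] != "none") & (
        merged["q_between"] < cfg.alpha_between
    )
    return merged


def export_bedgraph(estimates: pd.DataFrame, field: str) -> str:
    """Serialize one estimate field (``mc`` or ``hmc``) as bedGraph text.

    Sites must be coordinate-sorted; CpG intervals are single-base,
    0-based half-open.
    """
    if field not in ("mc", "hmc"):
        raise ValueError(f"field must be 'mc' or 'hmc', got {field!r}")
    df = estimates
    sorted_ok = (
        df[SITE_KEY]
        .equals(df[SITE_KEY].sort_values(SITE_KEY).reset_index(drop=True))
    )
    if not sorted_ok:
        raise ValueError("estimates must be sorted by (chrom, start)")
    buf = io.StringIO()
    buf.write(f'track type=bedGraph name="{field}"\n')
    for _, row in df.iterrows():
        v = row[field]
        if pd.isna(v):
            continue
        buf.write(f"{row['chrom']}\t{int(row['start'])}\t{int(row['start']) + 1}\t{v:g}\n")
    return buf.getvalue()


def read_bedgraph(text: str) -> pd.DataFrame:
    """Parse bedGraph text produced by :func:`export_bedgraph`."""
    rows = []
    for line in text.splitlines():
        if not line or line.startswith(("track", "#", "browser")):
            continue
        chrom, start, end, value = line.split("\t")
        rows.append((chrom, int(start), int(end), float(value)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def differential_to_bed(calls: pd.DataFrame) -> str:
    """BED6 of reported hits: name = direction, score = round(1000 * hmc_b)."""
    hits = calls[calls["is_hit"]]
    lines = [
        f"{r['chrom']}\t{int(r['start'])}\t{int(r['start']) + 1}\t"
        f"{r['direction']}\t{int(round(1000 * r['hmc_b']))}\t+"
        for _, r in hits.iterrows()
    ]
    return "\n".join(lines) + ("\n" if lines else "")
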