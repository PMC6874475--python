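"""Epigenome-transcriptome integration and the end-to-end pipeline.

Combines differential-methylation and differential-expression results into
the study's gene-set outputs: the genes concurrently hypomethylated and
overexpressed in CAFs, and the conserved CAF signature — promoters
aberrantly methylated in the same direction in both the primary-CAF and the
de novo-CAF comparison.  Also carries the small worked-example statistics
(2^-ddCt relative expression, marker-positive cell fractions) and
``run_pipeline``, which drives simulate -> estimate/call -> score/DMR ->
integrate and writes a checksum manifest.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import helpassay, oxbs, simulate
from .simulate import SimConfig


def intersect_hypo_overexpressed(hypo: set[str], overexpressed: set[str]) -> list[str]:
    """Genes both hypomethylated and overexpressed, in sorted order."""
    return sorted(set(hypo) & set(overexpressed))


def conserved_signature(
    calls_primary: pd.DataFrame, calls_denovo: pd.DataFrame
) -> pd.DataFrame:
    """Promoters aberrantly methylated in the same direction in both comparisons.

    Inputs are DMR tables indexed by gene/promoter id with a ``status``
    column (hypo | hyper | none).  Membership requires a non-none status in
    both comparisons and identical direction; discordant genes are excluded.
    Returns the member table (gene, status) sorted by gene.
    """
    for name, calls in (("primary", calls_primary), ("denovo", calls_denovo)):
        if calls.index.duplicated().any():
            dups = calls.index[calls.index.duplicated()].tolist()[:10]
            raise ValueError(f"duplicate gene keys in {name} comparison: {dups}")
    merged = calls_primary[["status"]].join(
        calls_denovo[["status"]], how="inner", lsuffix="_primary", rsuffix="_denovo"
    )
    member = (
        (merged["status_primary"] != "none")
        & (merged["status_primary"] == merged["status_denovo"])
    )
    out = merged.loc[member, ["status_primary"]].rename(
        columns={"status_primary": "status"}
    )
    return out.sort_index()


def signature_tallies(signature: pd.DataFrame) -> dict[str, int]:
    """Hypo/hyper membership counts of a conserved signature."""
    counts = signature["status"].value_counts()
    return {
        "hypo": int(counts.get("hypo", 0)),
        "hyper": int(counts.get("hyper", 0)),
        "total": int(len(signature)),
    }


def ddct_fold_change(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression by the 2^-ddCt method (target vs reference gene)."""
    cts = (ct_target_case, ct_ref_case, ct_target_control, ct_ref_control)
    if not all(math.isfinite(c) for c in cts):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_control - ct_ref_control)
    return 2.0 ** (-ddct)


def fraction_positive(n_positive: int, n_total: int) -> tuple[float, int]:
    """Marker-positive cell fraction and the percent rounded half away from zero."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_positive <= n_total:
        raise ValueError("n_positive must lie in [0, n_total]")
    frac = n_positive / n_total
    percent = int(math.floor(frac * 100.0 + 0.5))
    return frac, percent


def overexpressed_genes(
    expression: pd.DataFrame,
    groups: dict[str, str],
    case: str = "B",
    control: str = "A",
    alpha: float = 0.05,
) -> set[str]:
    """Genes significantly up in the case group (moderated t p < alpha, delta > 0)."""
    a_cols = [c for c in expression.columns if groups[c] == control]
    b_cols = [c for c in expression.columns if groups[c] == case]
    res = helpassay.moderated_t_test(expression[a_cols], expression[b_cols])
    up = (res.p < alpha) & (res.delta > 0)
    return set(expression.index[up])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def run_pipeline(cfg: SimConfig, outdir: str | Path) -> dict:
    """Simulate the full study and run every analysis stage over it.

    Writes all intermediate and final tables under ``outdir`` and a
    ``manifest.json`` recording the config, the seed and a sha256 checksum
    of every output; byte-identical for identical config.  Returns the
    manifest as a dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    def emit(name: str, df: pd.DataFrame, index: bool = False) -> None:
        path = outdir / name
        _write_tsv(df, path, index=index)
        written[name] = _sha256(path)

    # --- OxBS: estimate 5mC/5hmC and call differential hydroxymethylation
    truth, counts = simulate.simulate_bsoxbs(cfg)
    emit("site_truth.tsv", truth)
    ocfg = oxbs.OxbsConfig()
    est = {}
    for cond, tab in counts.items():
        emit(f"site_counts_{cond}.tsv", tab)
        est[cond] = oxbs.call_hmc_sites(oxbs.estimate_sites(tab, ocfg), ocfg)
    diff = oxbs.differential_hmc(est["A"], est["B"], ocfg)
    emit("hmc_differential.tsv", diff)
    (outdir / "hmc_gains.bed").write_text(oxbs.differential_to_bed(diff))
    written["hmc_gains.bed"] = _sha256(outdir / "hmc_gains.bed")

    # --- HELP array: fragment scores and DMR calls for two comparisons
    # (a "primary CAF" and a "de novo CAF" experiment sharing fragment truth)
    frag_truth = simulate.fragment_truth(cfg)
    emit("fragment_truth.tsv", frag_truth)
    dmr_calls = {}
    for label, stream in (("primary", "help_array"), ("denovo", "help_array2")):
        _, probes, groups = simulate.simulate_help_array(cfg, frag_truth, stream=stream)
        raw = helpassay.score_fragments(probes)
        centered, _ = helpassay.center_scores(raw)
        calls = helpassay.call_dmrs(centered, groups, case="B", control="A")
        dmr_calls[label] = calls
        emit(f"dmr_{label}.tsv", calls, index=True)

    signature = conserved_signature(dmr_calls["primary"], dmr_calls["denovo"])
    emit("conserved_signature.tsv", signature, index=True)
    tallies = signature_tallies(signature)

    # --- genomic context of hypomethylated loci vs the fragment background
    islands = simulate.cpg_islands(cfg)
    emit("cpg_islands.bed", islands)
    frag_pos = frag_truth.rename(columns={"start": "pos"})[["chrom", "pos"]]
    context = helpassay.classify_cpg_context(frag_pos, islands)
    hypo_idx = frag_truth["fragment"].isin(
        dmr_calls["primary"].index[dmr_calls["primary"]["status"] == "hypo"]
    )
    if hypo_idx.any():
        dist = helpassay.feature_distribution(context[hypo_idx], context)
        emit("context_distribution.tsv", dist)

    # --- expression integration: hypomethylated AND overexpressed genes
    expression, expr_groups = simulate.simulate_expression(cfg, frag_truth)
    emit("expression.tsv", expression, index=True)
    hypo_genes = {
        g.replace("frag", "gene")
        for g in dmr_calls["primary"].index[dmr_calls["primary"]["status"] == "hypo"]
    }
    over = overexpressed_genes(expression, expr_groups)
    both = intersect_hypo_overexpressed(hypo_genes, over)
    emit("hypo_overexpressed.tsv", pd.DataFrame({"gene": both}))

    manifest = {
        "seed": cfg.seed,
        "config": asdict(cfg),
        "outputs": dict(sorted(written.items())),
        "summary": {
            "n_hmc_gain_calls": int((diff["direction"] == "gain-in-B").sum()),
            "n_dmr_hypo_primary": int((dmr_calls["primary"]["status"] == "hypo").sum()),
            "n_dmr_hyper_primary": int((dmr_calls["primary"]["status"] == "hyper").sum()),
            "signature": tallies,
            "n_hypo_overexpressed": len(both),
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
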