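#!/usr/bin/env python
"""HELP fragment scoring, DMR calling and genomic-context distribution.

Scores each fragment as the centered log2(HpaII/MspI) of 25%-trimmed probe
means, calls differential methylation with the moderated t-test (p < 0.05
and |delta| > 1.5), summarizes hypo- vs hypermethylation, scores the
HELP-tagging loci on the 0-100 scale, and compares the genomic-feature
distribution of hypomethylated loci against the full fragment background.
"""

import argparse
from pathlib import Path

import pandas as pd

from cafepi import helpassay, io


def main(indir: str = "results/sim", outdir: str = "results/help") -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    probes = io.read_probe_table(Path(indir) / "help_probes.tsv")
    groups = {s: s[0] for s in probes["sample"].unique()}
    centered, categories = helpassay.center_scores(helpassay.score_fragments(probes))
    centered.to_csv(out / "scores_centered.tsv", sep="\t", float_format="%.6g")

    calls = helpassay.call_dmrs(centered, groups, case="B", control="A")
    calls.to_csv(out / "dmr_calls.tsv", sep="\t", float_format="%.6g")
    n_hypo = int((calls["status"] == "hypo").sum())
    n_hyper = int((calls["status"] == "hyper").sum())
    print(f"DMRs: {n_hypo} hypomethylated vs {n_hyper} hypermethylated in B "
          f"({n_hypo / max(n_hyper, 1):.1f}-fold hypo dominance)")

    tags = pd.read_csv(Path(indir) / "help_tagging.tsv", sep="\t")
    tags["tag_score"] = helpassay.tag_score(
        tags["hpaii_reads"], tags["mspi_reads"],
        tags["hpaii_reads"].sum(), tags["mspi_reads"].sum(),
    )
    tags.to_csv(out / "tagging_scores.tsv", sep="\t", index=False, float_format="%.6g")

    islands = io.read_bed(Path(indir) / "cpg_islands.bed")
    truth = pd.read_csv(Path(indir) / "fragment_truth.tsv", sep="\t")
    positions = truth.rename(columns={"start": "pos"})[["chrom", "pos"]]
    context = helpassay.classify_cpg_context(positions, islands)
    hypo_mask = truth["fragment"].isin(calls.index[calls["status"] == "hypo"])
    dist = helpassay.feature_distribution(context[hypo_mask], context)
    dist.to_csv(out / "context_distribution.tsv", sep="\t", index=False,
                float_format="%.6g")
    shore = dist.set_index("class")
    print("hypomethylated loci by context: "
          + ", ".join(f"{c}={shore.loc[c, 'prop_loci']:.2f}" for c in shore.index))


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--indir", default="results/sim")
    ap.add_argument("--outdir", default="results/help")
    a = ap.parse_args()
    main(a.indir, a.outdir)
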