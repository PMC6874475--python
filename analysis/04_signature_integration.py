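#!/usr/bin/env python
"""Conserved methylation signature and hypomethylated-and-overexpressed genes.

Runs two HELP comparisons sharing fragment truth (a "primary CAF" and a
"de novo CAF" experiment), intersects their DMR calls into the conserved
signature (same direction in both), then intersects hypomethylated genes
with genes significantly overexpressed in the case group.  Also prints the
two small worked-example statistics: the 2^-ddCt relative expression and
the marker-positive stromal-cell fraction.
"""

import argparse
from pathlib import Path

from cafepi import helpassay, integrate, simulate
from cafepi.simulate import SimConfig


def main(seed: int = 1, outdir: str = "results/signature") -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=seed)
    frag_truth = simulate.fragment_truth(cfg)

    calls = {}
    for label, stream in (("primary", "help_array"), ("denovo", "help_array2")):
        _, probes, groups = simulate.simulate_help_array(cfg, frag_truth, stream=stream)
        centered, _ = helpassay.center_scores(helpassay.score_fragments(probes))
        calls[label] = helpassay.call_dmrs(centered, groups, case="B", control="A")

    signature = integrate.conserved_signature(calls["primary"], calls["denovo"])
    signature.to_csv(out / "conserved_signature.tsv", sep="\t")
    tallies = integrate.signature_tallies(signature)
    print(f"conserved signature: {tallies['total']} promoters "
          f"({tallies['hypo']} hypomethylated, {tallies['hyper']} hypermethylated)")

    expression, expr_groups = simulate.simulate_expression(cfg, frag_truth)
    hypo_genes = {
        g.replace("frag", "gene")
        for g in calls["primary"].index[calls["primary"]["status"] == "hypo"]
    }
    over = integrate.overexpressed_genes(expression, expr_groups)
    both = integrate.intersect_hypo_overexpressed(hypo_genes, over)
    (out / "hypo_overexpressed.tsv").write_text("gene\n" + "\n".join(both) + "\n")
    truly_coupled = int((frag_truth["perturbation"] == "hypo").sum())
    print(f"{len(both)} genes concurrently hypomethylated and overexpressed "
          f"(generator coupled {truly_coupled})")

    fold = integrate.ddct_fold_change(20.0, 18.0, 22.0, 18.0)
    print(f"example 2^-ddCt relative expression (target Ct 22->20 vs stable ref): "
          f"{fold:.1f}-fold")
    frac, pct = integrate.fraction_positive(14, 181)
    print(f"marker-positive stromal cells: 14/181 = {frac:.4f} ({pct}%)")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results/signature")
    a = ap.parse_args()
    main(a.seed, a.outdir)
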