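#!/usr/bin/env python
"""Generate the full set of synthetic study inputs.

Writes BS/OxBS site-count tables for the MSC-like (A) and CAF-like (B)
conditions, the site and fragment truth tables, HELP array probe
intensities, HELP-tagging counts, the expression matrix and the CpG-island
annotation under results/sim/.
"""

import argparse
from pathlib import Path

from cafepi import io, simulate
from cafepi.simulate import SimConfig


def main(seed: int = 1, outdir: str = "results/sim") -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=seed)

    truth, counts = simulate.simulate_bsoxbs(cfg)
    truth.to_csv(out / "site_truth.tsv", sep="\t", index=False)
    for cond, tab in counts.items():
        io.write_site_counts(tab, out / f"site_counts_{cond}.tsv")

    frag_truth, probes, groups = simulate.simulate_help_array(cfg)
    frag_truth.to_csv(out / "fragment_truth.tsv", sep="\t", index=False)
    probes.to_csv(out / "help_probes.tsv", sep="\t", index=False, float_format="%.6g")

    tags = simulate.simulate_help_tagging(cfg)
    tags.to_csv(out / "help_tagging.tsv", sep="\t", index=False, float_format="%.6g")

    expr, _ = simulate.simulate_expression(cfg, frag_truth)
    expr.to_csv(out / "expression.tsv", sep="\t", float_format="%.6g")

    io.write_bed(simulate.cpg_islands(cfg), out / "cpg_islands.bed")

    n_gain = int((truth["perturbation"] == "hmc_gain").sum())
    n_hypo = int((frag_truth["perturbation"] == "hypo").sum())
    n_hyper = int((frag_truth["perturbation"] == "hyper").sum())
    print(f"simulated {cfg.n_sites} CpG sites ({n_gain} with true 5hmC gain in B)")
    print(f"simulated {cfg.n_fragments} HELP fragments "
          f"({n_hypo} hypomethylated, {n_hyper} hypermethylated in B)")
    print(f"outputs under {out}/")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results/sim")
    a = ap.parse_args()
    main(a.seed, a.outdir)
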