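# Methods

## BS/OxBS estimation and calling

Counts at a CpG are modeled per library as `u ~ Binomial(coverage, π)` with

```
π_BS   = mc·p_5mC + hmc·p_5hmC,BS + (1 − mc − hmc)·(1 − conv_eff)
π_OxBS = mc·p_5mC + hmc·p_5hmC,Ox + (1 − mc − hmc)·(1 − conv_eff)
```

where `mc`, `hmc` are the true modified proportions (constrained to
`mc + hmc ≤ 1`) and the protection/conversion probabilities describe the
chemistry. The estimators are plug-in: `m̂C` is the OxBS unconverted
fraction and `ĥmC` the BS−OxBS difference, clamped at 0 (the chemistry
can produce small negative differences at unmodified sites; the clamp is
deliberate and one-sided). The within-condition test is the two-sided
Fisher exact test of `[[u_bs, c_bs], [u_ox, c_ox]]` (conditional on
margins, enumerating tables with probability ≤ the observed within
relative tolerance 1e-7; empty-margin tables return p = 1). BH
adjustment runs over the *testable* universe only: sites with
≥ `min_coverage` (default 10) reads in all four count columns. Sites
below that are carried with NaN estimates and never enter m.

Differential calling applies the direction rule exactly as printed
above (gain in B iff `hmc_B > hmc_A`, `hmc_B ≥ 0.75` inclusive,
`mc_B < mc_A` strict; mirrored for A), which makes label-swap symmetry
exact by construction. The between-condition Fisher test needs a count
table; we use rounded 5hmC-supporting counts
`[[round(hmc·n), n − round(hmc·n)]]` per condition with n the BS
coverage. This is one documented choice among alternatives
(difference-of-differences tests exist); it is isolated in a single
helper so it can be swapped. Reported hits additionally require
BH-adjusted q < 0.05 across compared sites.

Sign conventions: coordinates are 0-based half-open; CpGs are reported
on the forward strand and reverse-strand counts must be pre-collapsed by
the caller.

At the default chemistry (conv_eff 0.995, 5mC protection 0.99, 5hmC
protection 0.99 BS / 0.05 OxBS) a site with true `hmc = 0.8` yields an
expected estimate of ≈ 0.752 — just above the 0.75 call threshold — so
differential sensitivity at default coverage 50 is chemistry- and
depth-limited (~0.5). The evaluation scenarios therefore use ideal
chemistry (conv_eff 1, protections 1/1/0) when measuring estimator
recovery and calling performance, which is also the regime in which the
estimators are calibrated (unconverted fractions converge to `mc + hmc`
in BS and `mc` in OxBS as coverage grows).

## HELP scoring and differential methylation

Fragment scores are `log2(trim_mean(HpaII)/trim_mean(MspI))` with 25%
trimming (drop `floor(0.25·n)` probes per tail; 3 of 15). Centering
subtracts the per-sample median — a robust choice given the asymmetric,
hypomethylation-dominant changes this design expects. Categories are
assigned from the centered score sign; an exact zero is categorized
hypomethylated so the two categories partition all fragments (the
strict-inequality pair would leave zero unassigned). Both per-sample
categories and (via group means) per-group categories can be derived
from the returned matrix.

The moderated t-test shrinks per-fragment pooled variances `s²` (d
residual df) toward a prior `(d0, s0²)` fitted across fragments by
method of moments on log variances: with
`e = log s² − ψ(d/2) + log(d/2)`, the excess of `Var(e)` over `ψ'(d/2)`
identifies `d0` through `ψ'(d0/2)` (Newton inversion of the trigamma),
and `s0²` follows from the mean of `e`. Then
`s̃² = (d0·s0² + d·s²)/(d0 + d)` and `t = Δ/(s̃·√(1/n_a + 1/n_b))` on
`d + d0` df (normal in the infinite-prior limit). Forcing `d0 = 0`
recovers the classical pooled t exactly; the implementation is
cross-checked against limma's eBayes in the test suite. When the
observed spread of log-variances does not exceed the sampling spread the
prior df is infinite and all fragments share `s0²`.

`Δ` is defined as mean(case) − mean(control) on the centered log-ratio
scale, so a positive Δ means hypomethylation in the case group (higher
HpaII/MspI = less methylation). The 1.5 threshold is interpreted in
these same log2-ratio units and applied strictly (Δ = 1.5 exactly is not
called). One consequence of median centering worth knowing: when a large
asymmetric fraction of fragments truly changes, the per-sample median
shifts toward the change and absorbs part of the effect (~0.15 units at
25% perturbed, 85% one-directional), slightly lowering sensitivity; the
DMR benchmark therefore uses a direction-balanced design where the
median is unbiased, and direction asymmetry is exercised separately in
the end-to-end dominance scenario.

HELP-tagging: `tag_score = 100·min(1, r)` with r the HpaII/MspI
library-normalized density ratio. The published description fixes only
the normalization and the 0/100 endpoint semantics; this formula is the
simplest monotone map satisfying both and is isolated behind one
function. Loci with zero MspI reads are unscored.

CpG context: islands are merged; shores are the half-open 2-kb flanks
`[start−w, start)` and `[end, end+w)` (w configurable); island
membership takes priority, and everything else is "other" — a total
partition. Feature distributions are compared with a chi-square
goodness-of-fit of locus counts against background proportions.

## Tracer metabolomics

The natural-abundance correction matrix for an n-carbon fragment places
`Binomial(n_atoms − j, a)` probabilities at shifts `j..n` in column j
(truncated at n, so columns sum to ≤ 1), with `a = 0.0107` for ¹³C.
`n_atoms` defaults to the backbone carbon count; derivatization atoms
(e.g. TBDMS silicon/carbon) can be folded in by passing a larger
`n_atoms`, but are excluded by default since the instrument-protocol
details are not part of this package. The matrix is lower-triangular
with positive diagonal, so the correction is an exact triangular solve;
negative components (possible under noise) are clipped and the MID
renormalized, with clipping flagged on the result rather than silently
absorbed. Round-trip accuracy is 1e-9 noise-free and ~1e-3 mean
component error at 1% multiplicative signal noise.

Internal-standard normalization divides every channel by the norvaline
signal, making total abundances comparable across injections; MIDs and
abundance ratios are invariant to common signal rescaling by
construction.

Global %5mC/%5hmC: response ratio = analyte area over combined
C+5mC+5hmC area; OLS calibration of ratio vs known percentage; sample
percentage = (ratio − intercept)/slope floored at 0. The %5hmC of the
simulated truth follows the ratio-of-concentrations convention
[5hmC]/([5hmC]+[C]) while sample quantification always goes through the
calibration-curve path.

## Synthetic data

The generator produces exactly the structures the analyses assume:
binomial BS/OxBS counts with Poisson(coverage_mean) coverage floored at
1 (negative-binomial overdispersion deliberately deferred — Poisson is
adequate for estimator testing), log-normal HELP probe intensities
around per-fragment baselines with hypomethylation as a `2^signal`
HpaII scaling, Poisson HELP-tagging counts, Gaussian log-expression
coupled 1:1 to hypomethylated fragments, and forward natural-abundance
convolution of true MIDs. One global seed feeds named, deterministically
derived substreams, so adding a generator never perturbs the others and
identical configs give byte-identical outputs.

Default study conditions: coverage_mean 50 (sequencing depth per CpG is
a free parameter, not an inference from any dataset), 2000 sites with
baseline (mc, hmc) = (0.6, 0.1), 25% of sites gaining 5hmC to 0.8 with
5mC dropping to 0.2 (the gain sites sit at `mc + hmc = 1`, the boundary
the truth constraint allows) and 10% demethylating only; 2000 HELP
fragments, 15 probes, 4 samples per group, perturbation effect 2.5 log2
units with 85% hypomethylating, sample-score noise SD 0.5 and 10% probe
noise; expression log-FC 2.0, noise SD 0.5, 6 samples per group.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: read-level errors and mapping artifacts,
strand asymmetries, regional correlation of methylation along the
genome, array batch/spatial effects, probe cross-hybridization,
chromatographic peak-shape and co-elution artifacts, and biological
replicate heterogeneity beyond i.i.d. noise. Recovery rates measured
here are upper bounds for comparably sized real designs.

## Evaluation scenario sizes

The packaged scenarios (`cafepi.scenarios`) use n = 2000 sites at
coverage 200 for estimator recovery and differential calling (500
perturbed + 1500 null), 4000 fragments (2000 perturbed,
direction-balanced, effect 2.0) for the DMR benchmark, a 500-site /
2000-fragment end-to-end run for the dominance and signature outputs,
200 + 1000 replicates for the MID round trips, and 3 spiked samples for
calibration recovery — sizes at which Monte-Carlo error is a small
fraction of each acceptance margin while the full suite runs in
minutes on one CPU.

## Known limitations

- The per-site Fisher test treats each condition as one pooled library;
  replicate-aware differential 5hmC models are out of scope.
- The between-condition test on rounded supporting counts is slightly
  anti-conservative at very low coverage (rounding can exaggerate a
  difference of one read).
- The moderated-t prior assumes exchangeable variances across fragments;
  strong mean-variance trends would call for a trended prior, not
  implemented here.
- The 0.75 differential-5hmC threshold interacts with non-ideal
  chemistry as described above; with real libraries the threshold
  effectively demands both high hydroxymethylation and good oxidation
  efficiency.
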