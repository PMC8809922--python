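# Methods

This note documents the statistical model behind `eqtm-kit`, the defaults
and their rationale, what the synthetic-data generator does and does not
emulate, and the numerical conventions used throughout.

## Data model and coordinate conventions

All matrices are features × samples with unique identifiers and finite
values. Methylation is carried as M-values (log2 methylated/unmethylated
signal ratio; larger = more methylated); expression as log2 intensities.
Rows containing missing or non-numeric cells are dropped at load time with
a logged count — no imputation is attempted, since dropping is
conservative and easy to reason about. Annotation files carry 1-based
positions (array-manifest convention); internally every position is
0-based and every exported interval is BED-style half-open. Strand is
ignored: probes are point coordinates and only distances to a TSS matter.

## Differential methylation

Probes flagged as overlapping a SNP are excluded before testing; sex
chromosomes are *not* pre-excluded (their absence from results, when it
happens, should be a finding, not an assumption). Each probe is tested
with a two-sided Welch (unequal-variance) t-test; Welch is the default
because the pooled-variance assumption buys little at 12 + 12 samples and
costs robustness, but a config switch restores the pooled test.
Benjamini–Hochberg is applied once, jointly across all tested probes —
never per chromosome — and the significance rule is FDR < 0.05 together
with |ΔM| > 0.3 as a strict inequality (a probe at exactly 0.3 is not
called). Probes constant within both groups get t = 0, p = 1 and a logged
count rather than an error.

Windows of 10 Mb tile each chromosome from coordinate 0, the terminal
window truncated at the declared chromosome length. Domain calling uses
the strict ratio rule: a window is a hypomethylated domain iff
n_hypo/n_hyper > 1.5, with the n_hyper = 0, n_hypo ≥ 1 case treated as a
hypo domain (and symmetrically); a 3:2 window is deliberately `none`.
Ratios with a zero denominator are reported as NaN, never infinity, in
the per-chromosome table. The density→count reconstruction rounds
half-away-from-zero, which is the convention that reproduces printed
density tables exactly.

## Differential expression

Expression probes mapping to the same gene are averaged per sample
(unweighted); probes mapping to several genes contribute to each, the
less lossy choice, with a logged count. Genes are tested with the same
Welch t-test on log2 values. Tiering uses *raw* p < 0.05 — this stage of
the analysis tradition does not FDR-correct — with strict fold-change
cutoffs |log2FC| > 2 (strong) and > 1 (weak); BH is available by config.
The strong tier is reported as its own label even though it also
satisfies the weak criterion.

## Cis eQTM model

Pairs are promoter-region probes (promoter, 5′-UTR or first exon) within
a closed 1 Mb window of a gene TSS, on either side; by default only
probes called hypomethylated enter pairing, matching the analysis flow in
which promoter hypomethylation is the phenomenon of interest.

Latent factors ("peers") are computed by residualizing each gene's
expression against intercept + age + sex + batch and taking the first k
left-singular directions of the sample × gene residual matrix (k = 5 by
default). Because residuals are centered, these directions have zero mean
already; they are standardized to unit variance and sign-fixed so each
factor's largest-magnitude element is positive, making output
deterministic. This is a deliberate, transparent stand-in for the PEER
construct: it captures "directions of shared expression variation not
explained by known covariates" without an iterative Bayesian fit.

Each pair is fit by OLS:
`E_g ~ 1 + M_p + age + sex + batch + factors`, with the methylation
coefficient's two-sided t-test p-value and its partial R²
`(RSS_reduced − RSS_full)/RSS_reduced` (reduced model omits methylation).
No multiplicity correction is applied to eQTM p-values by default
(config-switchable to BH). A constant methylation column flags the fit
degenerate instead of failing.

The sequential variance decomposition adds blocks in the fixed order
age → sex → peers → methylation and reports R² increments. Batch enters
with the sex block: it is a known covariate without its own reporting
slot, and folding it there keeps the four-block narrative while still
correcting for it (a config flag gives batch its own block). Per gene,
the decomposition uses the single cis probe with the smallest eQTM p
(ties: smallest distance, then probe id). Cohort-level percentages are
per-gene means of the cumulative R² values and of the corrected
methylation partial R² — means over genes, not pooled sums of squares.
By construction of nested OLS the cumulative sequence is non-decreasing
and bounded by 1, and the methylation increment of the decomposition
equals the per-pair partial R² when computed on the same blocks; both
facts are asserted in tests.

## Validation statistics

Fisher's exact test is two-sided by the probability-mass rule (sum over
tables with the observed margins whose point probability is ≤ the
observed one), the dominant convention; a zero margin yields p = 1 with a
warning. Percentages round half away from zero. Over-representation uses
the upper-tail hypergeometric survival function per gene set, with the
10–500 size filter applied *after* intersecting each set with the
universe (sizes outside the universe are meaningless to the model), and
BH across surviving sets.

## Synthetic-data generator

The generator emulates the statistical structure of a paired
methylation + expression case/control study on a pseudo-genome of 22
autosomes with realistic Mb lengths:

    M[p,i] = μ_p + ΔM_p·1[case_i] + Σ_k γ_pk h_ki + ε,     ε ~ N(0, noise_sd_m²)
    E[g,i] = α_g + β_g·M[c(g),i] + a_g·age_i + s_g·1[female_i]
             + Σ_k λ_gk h_ki + ε′,                          ε′ ~ N(0, noise_sd_e²)

with latent confounders h_k ~ N(0,1) shared between the two layers —
the sharing is what makes latent-factor correction consequential and
testable. Defaults define the study conditions: 12 cases vs 12 controls;
5,000 probes and 800 genes (structure of the full array at desk scale —
full scale adds nothing to any test); 10% of probes carry a planted
effect of magnitude 0.8 M-units, negative with probability 0.95 (the
95:5 hypo:hyper imbalance); 25% of probes are SNP-flagged, matching the
retention scale of typical 450K probe filtering; five latent confounders;
10% of genes carry a planted cis effect β = 2.0 wired to a dedicated
promoter probe placed within 200 kb of the TSS. Ages are Uniform(20, 60),
sex Bernoulli(1/2), two batches alternating — stand-in distributions, as
covariate distributions are rarely published. Covariate effects a_g, s_g
are drawn N(0, age_beta²) and N(0, sex_beta²) per gene.

Every planted quantity is recorded in a truth ledger, including per-gene
variance fractions computed as sequential R² increments of the *noiseless*
generative blocks in the analysis order (age, sex + batch, latents,
methylation). Using sequential projections rather than raw component
variances makes the truth fractions non-negative, ≤ 1, and directly
comparable to what the decomposition estimates; the batch indicator is
included in the truth's sex block because the analysis folds batch there.

**What the generator does not emulate:** beta-value/intensity-level
noise, CpG-island spatial autocorrelation, region-dependent methylation
effects, probe cross-reactivity, expression count noise, or any
nonlinearity. Passing recovery tests therefore demonstrates correctness
of the estimators under the linear-Gaussian assumptions, not robustness
to real-array artefacts.

**A structural caveat worth knowing:** with a coherent 95:5 imbalance,
the planted cis effects give many genes the *same* case/control shift, so
at the default settings one estimated latent factor tends to align with
the group contrast and absorb part of that shared signal. Per-pair β
estimates remain unbiased (identification comes from within-group
methylation variation) but their spread widens — the cohort *mean* β
still recovers the planted 2.0 within 10%. Tight per-pair recovery
(≥ 95% of pairs within 10%) is checked under a clean configuration —
two strong latents (latent_sd = 1.0), matching k = 2, expression noise
0.05 — where the factor space is well-specified and the latents, not the
group direction, dominate the SVD. Null-calibration and power checks
(ΔM = −0.8 against noise 0.2; KS uniformity at 2,000 probes) run without
latent confounding, since those properties are statements about the
tests themselves, not about confounder correction.

## Problem sizes and determinism

All tests and the acceptance script run at the desk scale above (a full
pipeline pass takes a few seconds). Every random draw flows from a single
`numpy` `default_rng(seed)`; the same configuration and seed reproduce
bit-identical datasets, and SVD sign-fixing plus stable sorts make every
downstream table deterministic.

## Known limitations

- The PEER stand-in is an SVD, not the variational Bayesian PEER; with
  few samples and many strong factors the two can order factors
  differently.
- The eQTM stage fits each pair independently by OLS; no kinship,
  repeated-measures or count-model structure is supported.
- Chromosome lengths are a flat Mb table; no centromere/assembly-gap
  masking, so window densities near gaps are nominal.
- The over-representation test assumes an exchangeable universe; no
  probe-density or expression-level bias correction is applied.
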