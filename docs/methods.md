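# Methods

`hormonescan` implements a comparative-genomics pipeline linking sexual
size dimorphism (SSD) to the number of hormone response elements (HREs)
near genes, together with a synthetic-data generator that makes every
stage testable without genome downloads. This note records the models,
the defaults and why they were chosen, the numerical decisions, and the
known limitations.

## Motif model and scanning

HREs are short, degenerate DNA motifs. The canonical androgen response
element (ARE) `AGAACANNNTGTTCT` and estrogen response element (ERE)
`GGTCANNNTGACC` are inverted half-site palindromes around a spacer. The
scanner treats a motif `N` as a spacer matching `A/C/G/T` only: an
assembly-gap `N` in the subject never matches, so unresolved sequence
cannot inflate counts. Every valid start position is reported, including
overlaps. Palindromic motifs are scanned on the forward strand only —
the reverse-strand scan would return the identical site set and double
every count — while non-palindromic motifs contribute both their own
matches (`+`) and those of their reverse complement (`-`), with starts
always in forward-reference coordinates. Matching is case-insensitive
and soft-masking is ignored. Coordinates are 0-based half-open
throughout; BED output needs no shifting.

## Windows and the two counting modes

Gene annotations carry a TOGA-style category; by default only `Intact`
and `ParalogousProjection` genes anchor windows, reflecting a hypothesis
about sex-biased regulation of whatever is expressed, duplicated or not.
A window is symmetric about the TSS — `[tss − flank, tss + flank + 1)`,
clamped to the contig — regardless of gene strand; the conventional
flank grid is 10, 50, 100 and 1 000 kb. A hit belongs to a window when
its start position lies inside (start, not midpoint or full containment;
the choice is immaterial at these flank sizes but fixed and tested).

Two counting modes serve two analyses:

* **dedup** (species-level): all windows are merged into a disjoint
  per-contig union (touching intervals merge) and each motif occurrence
  counts at most once per HRE class, however many genes it sits near.
  The union length is reported as `interrogated_bp`.
* **per-gene** (gene-centric): every (gene, hit) pair with the hit in
  that gene's window counts, so one occurrence may contribute to several
  genes. The per-gene sum is therefore an upper bound on the dedup
  count, with equality exactly when no windows share a hit.

## Traits

SSD = ln(male mass / female mass); positive means males are larger.
Body size is the arithmetic mean of the two masses (a geometric option
exists), in kilograms internally. The analysis table is the inner join
of traits and counts restricted to the tips of the phylogeny, with
ln-transformed count and body-size columns. A species with a zero count
in either class cannot enter the ln-scale models and is dropped with a
warning.

## Phylogenetic GLS with Pagel's lambda

The headline model is

    SSD ~ ln(HRE count) + ln(body size)

fit by generalized least squares with residual covariance
`sigma^2 V(lambda)`, where `V(lambda)` multiplies the off-diagonal of
the Brownian-motion covariance `C` (shared root-to-MRCA path lengths) by
lambda in [0, 1]. At fixed lambda the solution is analytic
(`beta = (X'V^-1X)^-1 X'V^-1 y`, ML `sigma^2 = r'V^-1 r / n`); lambda is
estimated by bounded 1-D maximization of the profile log-likelihood
(xatol 1e-8), with both endpoints also evaluated because the bounded
optimizer can miss a boundary optimum. Standard errors apply the
`n/(n − p)` small-sample correction and p-values are two-sided t with
`n − p` degrees of freedom. The reported R² is the deviance ratio in the
V-metric against the GLS intercept-only fit, which reduces to ordinary
R² at lambda = 0. ML (not REML) mirrors the convention of the R
packages this analysis family is usually run with; the implementation
was cross-checked against `nlme::gls` + `ape::corPagel` (identical
coefficients, log-likelihood, and ML lambda on frozen fixtures).

Design points: per-order analyses are independent fits on subset tables
(never order-as-covariate), refused below 20 species; zero-length
terminal branches are rejected at tree load; a non-positive-definite
covariance raises rather than being silently ridged (`jitter=True` adds
`1e-10·mean(diag)` on request); branch-length rescaling is absorbed by
`sigma^2` and leaves estimates, tests, lambda and R² unchanged.

The genome-quality check regresses ln(count) on ln(contig N50) with the
same machinery and reports the slope sign, so quality confounding
planted in synthetic data can be detected.

## Phylogenetic PCA

Counts are log10-transformed (zero counts are an error), centered on the
GLS mean `a = (1'C^-1 1)^-1 1'C^-1 X`, and the evolutionary covariance
`R = (X − 1a)' C^-1 (X − 1a)/(n − 1)` is eigen-decomposed; scores are
`(X − 1a) E`. Brownian motion (lambda = 1) is the default, with a fixed
lambda as an option. Eigenvector signs are fixed so each component's
largest-magnitude loading is positive. Verified against
`phytools::phyl.pca` (eigenvalues, ancestral mean, score magnitudes).

## Gene-centric scan

Each gene with at least 10 carrying species and at least two distinct
count values gets its own PGLS of SSD on `ln(count + 1) + ln(body)` over
exactly those species (species lacking the annotation are missing data,
not zeros; the `+1` offset is needed because per-gene zero counts are
real observations, unlike species totals). Lambda is re-estimated per
gene by default. The direction summary is the proportion of
successfully fitted genes with a positive count effect — significance
not required. The significance export keeps genes with positive effect
and uncorrected p < 0.05, the input convention of external GO-enrichment
tools; a Benjamini–Hochberg q-value column is attached for users but
never used for that filter.

## Synthetic-data generator

The generator emulates the structure of the real inputs with full
ground-truth control. Standing conditions (the defaults):

* **Tree**: Yule, birth rate 1, depth rescaled to 1, tips extended past
  the final speciation by the exponential waiting time so terminal
  branches are strictly positive; 64 species by default.
* **Motif rates**: log expected planted motifs per gene window evolve by
  Brownian motion (variance 0.5 per unit depth) from root rates of
  ln 2.5 (ARE) and ln 0.4 (ERE) — chosen so a 20-gene genome carries
  realistic totals (tens of AREs, a handful of EREs) with occasional
  zero ERE totals exercising the zero-count path. Realized per-gene
  counts are Poisson (negative binomial optional). An optional burst
  clade has its ARE log-rate raised by ln(multiplier), default 4×,
  emulating a lineage-specific ARE explosion; genes can share one
  species rate (co-varying, the default) or evolve independent rates
  (exchangeable genes, the appropriate null for gene-level direction
  statistics).
* **Traits**: ln body mass is Brownian (variance 1, root 1 kg);
  SSD = 0.5·ln(ARE total) + 0.3·ln(body) + eps with
  eps ~ MVN(0, 0.25²·V(lambda=0.5)). Male/female masses are back-solved
  so `ln(m/f) = SSD` and `(m+f)/2 = body` hold exactly.
* **Genomes** (emitted on demand): one contig per species, GC 0.41,
  genes at regular TSS spacing, planted instances placed uniformly
  without overlap by a stars-and-bars draw, strands alternating for
  non-palindromic motifs. With `clean_background` (default) any
  spurious occurrence arising from background or planting junctions is
  resampled, so a scan recovers exactly the planted set.

What the generator does **not** emulate: repeat structure, isochores,
assembly fragmentation, annotation error, real taxon sampling, and
measurement error in body masses. Passing tests therefore demonstrate
correctness of the computations and recoverability under the stated
model, not robustness to the messiness of real assemblies.

Problem sizes for the validation experiments were fixed at 64–256
species, 50 replicates per grid cell, 500 null replicates, and 40 genes
for the direction experiment — large enough for the Monte-Carlo error
targets while keeping a full run around a minute on one CPU.

## Known limitations

* **Plug-in lambda anticonservatism.** With lambda fixed at its
  generative value the ARE-effect t-test is calibrated (the suite
  asserts this directly). With lambda estimated by ML, the test can
  reject somewhat above the nominal level at moderate n, especially
  when the predictor is strongly tree-structured (the burst scenario);
  REML reduces but does not remove this. This is a property of the
  plug-in procedure itself — the estimates match the R reference
  implementations — and the acceptance suite measures it honestly
  rather than correcting for it.
* Lambda is bounded to [0, 1]; unconstrained estimates (as `nlme`
  returns) can leave this range on small trees.
* The default motif file ships only the two canonical motifs; the
  additional ARE variants used in pooled analyses are user-supplied
  data, not code.
* No position-weight-matrix scoring, chromatin context, or
  measurement-error modelling; OU and other correlation structures are
  out of scope.
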