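# Methods

`craave` analyzes pooled CRISPR screens in which an AAV-delivered sgRNA
library is read out by amplicon sequencing — the screen's reference
("control") samples are sequencing runs of the injected AAV input
library, and each "treatment" sample is the episomal sgRNA population
recovered from one animal. The package covers five stages: exact
protospacer counting, per-sgRNA negative-binomial (NB) testing, gene
aggregation with an empirical null (geopagg), cohort bootstrapping, and
a ground-truthed screen simulator.

## Counting model

A read is assigned to a guide when exactly one library protospacer
occurs as an exact substring of the read. The read is scanned at every
offset (no fixed-position assumption, since amplicon layouts vary);
`orientation="both"` additionally scans the reverse complement. Reads
matching no protospacer are `unassigned`; reads containing two or more
distinct protospacers are `ambiguous` and discarded — exact counting
must be unambiguous, so multi-matches are never fractionally assigned.
`N` bases never match, base qualities are ignored, and
`assigned + unassigned + ambiguous` always equals the reads processed.
Duplicate protospacers in a library are a hard error because exact
matching cannot distinguish them.

## Per-sgRNA model

**Normalization.** Each sample is scaled so its median count over
retained guides equals the grand median of per-sample medians
(`target / median_j`). Scaling one sample's raw counts by a constant
therefore leaves every downstream p-value unchanged whenever that
sample's median is not itself the grand median.

**Coverage filter.** Guides with fewer than 100 raw reads *summed*
across control samples are removed before normalization (the summed
reading is the weaker, coverage-motivated one; the threshold is
configurable). The filter deliberately uses raw counts: a size factor
must not rescue or doom a guide.

**Dispersion.** Per-guide sample variance over control replicates is
regressed on the mean, on the log-log scale, by weighted least squares:
`log sigma^2 = a + b log mu`. Two numerical choices matter:

- *Jensen correction* (default on). With k control replicates and
  nu = k−1, `E[log s^2] = log sigma^2 + psi(nu/2) − log(nu/2)`; at
  k = 3 the naive fit is biased by −0.58 and its fitted variances are
  anti-conservative by a factor of ~1.8. The fit adds
  `log(nu/2) − psi(nu/2)` to every log-variance so the line targets
  `log sigma^2` itself. The correction is exact under normality and
  asymptotic for counts.
- *Weights* (default `uniform`). Because `var(log s^2) ≈ psi'(nu/2)` is
  nearly constant in the mean, uniform weights are close to efficient.
  Weighting by the control mean (available as `weight_scheme="mean"`)
  concentrates leverage in the high-abundance tail and inflates the
  variance of the intercept — an extrapolation to log mu = 0 — several
  fold, without improving the slope. Unreliable low-abundance variance
  estimates are already excluded by the coverage filter.

With a single control sample no variance can be estimated; the fallback
is `sigma2 = mu (1 + kappa)` with kappa = 0.01 (configurable), i.e. a
near-Poisson null. Fitted variances at or below the mean are clamped to
`mu (1 + 1e−6)` with a warning (the NB moment parameterization requires
overdispersion).

**Test.** Each guide's null is NB with mean mu (control mean of
normalized counts) and variance sigma2 from the fitted line,
moment-parameterized as `r = mu^2/(sigma2 − mu)`, `p = mu/sigma2`. The
observed statistic is the rounded arithmetic mean of the guide's
normalized treatment counts, so a single-mouse analysis and a cohort
analysis share one code path; averaging across mice makes the test
conservative under the null (the mean of m NB draws has variance
sigma2/m), which is the safe direction for hit calling.
`p_under = P(X ≤ obs)` and `p_over = P(X ≥ obs)`; both include the mass
at `obs`, so `p_under + p_over = 1 + pmf(obs)`. Benjamini-Hochberg
correction is applied separately within each direction. The guide
phenotype is `phi = log2((mu_treat + a)/(mu_ctrl + a))` with
pseudocount a = 1 guarding zeros.

## geopagg

Per gene group i with member FDRs x_j:

- **Drop-First weights**: the member with the minimum FDR gets w = 0.5,
  all others w = 1 — a gene must carry more than one good guide to score
  well. Ties on the minimum break toward the most extreme phenotype in
  the test's direction, then lexicographic sgrna_id (deterministic).
- **q_i** = `exp(sum w_j ln x_j / sum w_j)`, the weighted geometric mean
  (FDRs floored at 1e−300 before the log). q_i is bounded by the member
  extremes and invariant to member order.
- **phi_i** = unweighted arithmetic mean of member phenotypes.
- **gamma_i** = `phi_i · (−log10 q_i)` (default). The product is the
  reading under which a depleted gene with small q sorts first in the
  ascending under-abundance list; the additive alternative
  `phi_i − log10 q_i` is available as `gamma_variant="additive"` for
  sensitivity analysis.

**Amalgam null.** One quasi-gene per real gene group (times a
configurable factor) is assembled by sampling that gene's membership
size from the non-targeting controls, without replacement *within* each
amalgam gene; the pool is replenished between amalgam genes because
matching every real gene generally needs far more draws than NTCs exist
(e.g. 2,420 genes × 5 members from 250 NTCs). Amalgam construction is
seeded and the seed recorded in the run manifest.

**Empirical FDR.** Within each direction, real and amalgam genes are
ranked by gamma (ascending for depletion, descending for enrichment;
ties break by smaller q, then real-before-amalgam, then id). With
c_i = amalgams at rank ≤ i, `delta_i = min(max(c_i / i, q_i), 1)`. The
monotone constraint `delta_i ≥ delta_{i−1}` chains over the *real*
(reported) genes: an amalgam's own delta (its raw value, kept for
diagnostics) must not propagate, since an amalgam at rank 1 trivially
has c_1/1 = 1 and would otherwise erase the entire list. Each real
gene reports the direction with the smaller delta; hits are real genes
with delta < 0.1. Gene groups targeting distinct transcription start
sites (`_P1`/`_P2`) are scored fully independently.

A caveat on the amalgam null: all amalgam genes draw from one finite
NTC pool. When the number of amalgams is much larger than the pool,
each NTC recurs in many amalgams and a chance phenotype offset of the
pool shifts every amalgam coherently. Marginal exchangeability with
null real genes still holds, but amalgam ranks become mutually
correlated — rank tests that assume independent amalgams will
anti-conserve, and the delta estimate itself becomes noisier. Raising
`amalgam_factor` does not help (same pool); more NTCs in the library
design does.

## Cohort bootstrap

Treatment samples are grouped by mouse; at every cohort size s from 1
to N, 50 replicates draw s mice uniformly without replacement (control
columns always included) and the full per-sgRNA + geopagg pipeline is
rerun with the cohort parameters. Replicate overlap is
`|hits_rep ∩ hits_full| / |hits_full|`; a full-cohort hit's recovery
rate at size s is the fraction of replicates re-identifying it.
Duplicate subsets at small s are allowed (50 replicates regardless of
how many distinct subsets exist). Subset RNGs are seeded by
(master seed, s, r), so adding sizes never reshuffles existing
replicates; the amalgam seed is one fixed derivation from the master
seed, identical in the full-cohort run and every replicate, so a
replicate holding the complete cohort reproduces the full-cohort hit
set exactly (overlap 1.0 at s = N by construction, not by chance).

## Simulator

`simulate_library` draws unique random 20-nt protospacers with uniform
or per-gene guide counts and an optional dual-TSS fraction.
`simulate_screen_counts` draws input abundances log-normal (log-sd 0.8
— screens' input libraries are long-tailed; no distributional form is
established, so log-normal is a pragmatic default), scales them to a
target depth (default 500 reads/guide), and emits control columns as NB
noise with `var = m + alpha m^2` (alpha = 0.01, a mild overdispersion
placeholder — the true overdispersion of episome-derived counts is
unknown and exposed in config) and treatment columns as NB noise around
`input × 2^effect × coverage_mouse`, with log-normal per-mouse coverage
factors (log-sd 0.2). Essential genes (default 10% of genes at mean
effect −2) carry the effect on `n_active` of their guides (default 4 of
5, jittered with sd 0.25 — mirroring the observation that credible hits
show at least two concordant guides); NTCs are always null. Low-titer
mode multiplies coverage by 0.05 and zero-inflates treatment counts
(p = 0.3) to emulate dropout at low viral dose. `simulate_fastq` embeds
each protospacer at a random offset in random background and re-draws
on collision, so counting round-trips exactly.

What the simulator does *not* model: brain-region structure, co-infection
(MOI) effects, PCR jackpotting, sequencing error (reads are error-free,
so exact matching recovers every read — real unassigned fractions are
higher), and guide-level off-target effects. A green recovery test
therefore establishes that the statistics behave as designed under the
assumed NB world, not that the thresholds are optimal for any
particular real screen.

## Defaults that matter

| parameter | default | meaning |
|---|---|---|
| `min_control_reads` | 100 | raw control-sum coverage filter |
| `pseudocount` | 1.0 | phi zero-guard |
| `weight_scheme` | `uniform` | dispersion-fit weights (`mean` optional) |
| `single_control_kappa` | 0.01 | fallback overdispersion, 1 control |
| `fdr_threshold` | 0.1 | hit threshold on delta |
| `amalgam_factor` | 1 | amalgam genes per real gene |
| `gamma_variant` | `product` | gene-score form |
| bootstrap `reps` | 50 | replicates per cohort size |

## Known limitations

- The NB null is fit marginally per guide; no shrinkage across guides
  and no per-mouse covariates (a deliberate non-goal).
- delta is a step estimate from a finite amalgam set; with few NTCs it
  is coarse and correlated across genes (see the amalgam caveat above).
- Exact matching tolerates no sequencing errors by design; expect a
  higher unassigned fraction on real data than on simulated reads.
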