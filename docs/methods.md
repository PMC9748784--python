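# Methods

## The model family

`borderindel` simulates and fits a hierarchy of models for the length of a
neutrally evolving DNA segment flanked by conserved sequence (introns
between exons being the motivating case). Length is the only state
variable; substitutions, segmental duplications and transposable elements
are outside the model. Per generation, with `L` the current length:

* an insertion of length `i` occurs with probability `p_ins f(i) (L+1)` —
  there are `L+1` insertion sites, one more than there are characters, so a
  zero-length segment can regrow (the immortal-link construction);
* a deletion of length `d` is proposed with probability `p_del g(d) L` and
  *applied* only with probability `p_valid = max((L-d+1)/L, 0)` — of the
  `L` anchored placements, only `L-d+1` keep the deletion inside the
  neutral segment, and a deletion protruding into the conserved flank is
  rejected by purifying selection ("border-induced selection").

The members of the hierarchy differ only in the indel-length laws `f`, `g`:

| model | length law | closed forms |
|-------|------------|--------------|
| M1 | all indels 1 bp | stationary law geometric(1-r), mean `r/(1-r)` |
| M2 | constant `mu_i`/`mu_d` bp | mean `(r+mu_d-1)/(1-r)` for `L >> mu_d`; a lower bound under strong deletion bias |
| M3 | truncated Zipfian `k^-a / sum i^-a` on `{1..m_max}` | none; simulation + exact chain solve |
| M4 | M3 plus conserved segments (below) | mixture mean `le + pc*li + (1+pc) E[M3]` |

Throughout, `r = (p_ins mu_i)/(p_del mu_d)` is the expected inserted bp per
expected deleted bp per site — the single parameter that controls the
stationary law. Jointly rescaling `(p_ins, p_del)` only rescales time:
for the one-generation transition matrix `P`, the rescaled chain is
`I + c(P - I)`, which has the same stationary vector. The package exploits
this both in tests and in the exact solver.

M4 composes M3 draws rather than changing the dynamics: an intron carries
conserved edges of total length `le`; with probability `pc` it also carries
one internal conserved segment of length `li`, which splits the neutral
material into two independent full-rate M3 stretches. `le` and `li` are
integers biologically, but the fitter treats them as nonnegative reals so a
trust-region step is meaningful; simulated M4 lengths are therefore floats.

## Parameters and defaults

* `m_max = 150` bp — truncation of the Zipfian indel-length law.
* Mean indel lengths for intron fits: insertions 16.5 bp, deletions 4.5 bp
  (mammalian intron indel spectra); M2 uses the integers 17/5.
  The Zipf exponent is recovered from a target mean by bisection-style root
  finding (`zipf_exponent_for_mean`); the mean is strictly decreasing in the
  exponent, so the inverse is unique. Exponents themselves are rarely
  reported, which is why the mean is the interface.
* `p_del = 1e-7` per site per generation for intron-scale runs; only `r`
  matters for the stationary law, so any convenient scale may be used as
  long as `p_event(L) = p_ins(L+1) + p_del L` stays below 1 over the
  reachable lengths (the kernel aborts with a clear error otherwise).
* Replicates default to 10 000; initial length 0; length cap `1e7`
  (an order of magnitude above the longest known human intron) to catch
  runaway `r >= 1` misconfigurations.

## Simulation

The simulator is a discrete-generation Gillespie scheme: waiting times
between events are geometric with success probability `p_event(L)`, so
run time scales with the number of events (about `1e5` per replicate at
intron-fitted parameters) rather than generations (about `1e9`). Proposed
deletions that fail the `p_valid` acceptance are *null events* — they
consume the waiting time but change nothing. A thinned formulation
(deletion rate `p_del g(d) (L-d+1)` with no rejection step) has the same
stationary law, since self-loops do not affect it; null events were chosen
for simplicity. Each replicate runs an independent splitmix64 RNG stream
seeded from a `SeedSequence` of the master seed, so results are exactly
reproducible and replicates stay independent under any execution order.

**Convergence.** The classical horizon is the smallest `n` with
`(1 + (r-1) p_del mu_d)^n` below a tolerance (`1e-6` by default). That
factor comes from linearizing the expectation recursion and ignores
deletion rejection, and in the rejection-dominated regime (stationary mean
comparable to `mu_d`) it underestimates the relaxation time by an order of
magnitude or more: at `r = 0.25, mu_i = 5, mu_d = 15` the nominal horizon
yields a mean of ~6.5 where the exact stationary mean is 21.65. The
simulator therefore verifies stationarity empirically: after the nominal
horizon it keeps advancing the whole sample in doubling chunks until the
mean per-replicate drift over a chunk is statistically indistinguishable
from zero (|drift| below 3 standard errors of the paired drift, or below
0.5% of the mean) twice in a row. Converged runs pay ~1.5-2.5x the nominal
cost; under-converged runs keep extending up to a configurable number of
doublings and flag `converged=False` if the budget is exhausted.

**Exact oracle.** For parameter sets whose stationary mass fits in a few
thousand states, `chain_stationary_pmf` builds the truncated one-generation
transition matrix (insertions past the cap reflected into the top state,
which the caller keeps negligible) and solves the balance equations
directly with a sparse LU factorization, replacing one balance row by the
normalization constraint. Rates are first rescaled jointly so the matrix
is comfortably stochastic — exact, by the rescaling invariance above. The
simulator is validated against this oracle in total variation, and the
oracle against the closed-form geometric law of M1.

## Comparing models to data

All comparisons use the density of log10(length) on fixed shared edges:
log10(1) to log10(1e7) in steps of 0.05 (140 bins), wide enough for the
full span of human intron lengths. Zero-length simulated sequences cannot
be log-binned; they are excluded with an explicit count (`n_excluded`).
Observed data enter either as plain text (one positive integer per line) or
as a GFF3 annotation, from which intron lengths are extracted per gene from
the transcript with the longest total CDS (exons sorted by start; intron
between `[s1,e1]` and `[s2,e2]` has length `s2-e1-1`; strand is irrelevant
to a length). The fit objective is the mean squared per-bin density
difference (`mse_log`).

**M1-M3 fits** are a grid search over `r`, by default 60 points uniform in
`log10(1-r)` between 0.37 and 0.9999 — the stationary mean diverges like
`1/(1-r)`, so resolution must concentrate near 1. `p_ins` is always derived
from `(r, p_del, mu_i, mu_d)`, never fitted independently. Every grid point
simulates with the same seed (common random numbers), making the argmin
stable; ties break toward larger `r`.

**M4 fits** minimize the same objective over `(r, le, li, pc)`. The
surface is hostile in two ways: it is rough in `r` (a stochastic simulation
re-run per candidate) and razor-sharp in `le`/`li`, because the conserved
lengths place a spike of near-constant intron lengths only a few bins wide
in log space — a few bp of misalignment changes the objective by two orders
of magnitude, and any coarse search aliases past the optimum. The fitter
therefore exploits the mixture structure: for fixed `r`, one reservoir of
`2n` neutral draws gives the M4 density as
`(1-pc) hist(le + X1) + pc hist(le + li + X1 + X2)` for *any* `(le, li,
pc)` without re-simulation, so `(le, li)` is scanned densely (~4 bp, then
1 bp locally) and the mixture weight `pc` is solved in closed form per
candidate. This runs over a 7-point `r` grid, each candidate is re-scored
through the full simulation path, and a bound-constrained trust-region
(`trf`) least-squares polish runs from the best point with `r` parameterized
as `log10(1-r)`. The reported optimum is the best full-simulation
evaluation seen anywhere, so a stalled polish cannot worsen the result.
In `simulate_m4` the internal-segment indicators are stratified (a fixed
random permutation of an equispaced grid thresholded at `pc`) rather than
i.i.d. Bernoulli: the mixture fraction is then exact to `1/n` and varies
smoothly with `pc`, removing mixture-weight noise from the objective.

## Synthetic data and what passing tests show

`fixtures` generates all test data programmatically: exact geometric draws
for M1 (no simulation needed), simulator-backed M3/M4 samples at known
ground truth, and a toy GFF3 builder whose intron lengths are known by
construction. Recovery tests (grid fit recovering `r`; M4 fit recovering
`pc` within ±0.1 and `le` within ~20%) demonstrate identifiability under
the model's own assumptions — stationarity, a single internal conserved
segment, perfectly conserved flanks, Zipfian indel lengths with known
means. Real intron data violate all of these to some degree (multiple
conserved elements, non-equilibrium lengths, lineage-specific rates), so
passing recovery tests bound estimator behaviour, not biological truth.

## Numerical choices and scales

* Exponent inversion: Brent root finding on `a` in [0, 50], `xtol=1e-10`.
* Indel-length sampling: inverse-CDF binary search on the cumulative pmf
  (support at most `m_max` values; exact and cheap).
* Stationary solve: sparse direct LU; truncation chosen by the caller so
  boundary mass is negligible (checked in tests at < 1e-5).
* Drift test: 3 SE two-pass rule as above; at typical replicate counts the
  residual bias it can leave is below the Monte-Carlo standard error.
* Replicate counts in the shipped tests and the acceptance script are
  1 000-10 000 depending on the cost per replicate; means then carry
  ~1-3% Monte-Carlo error, and standard deviations of heavy-tailed length
  distributions ~5%. These counts are stated next to each quantity.
* Reported summary statistics are the raw replicate mean and s.d.
  (zero-length replicates included); log-density modes are bin centers of
  the shared binning. At strong deletion bias the stationary law carries a
  few percent of its mass at length zero, so a mean over plotted (nonzero)
  lengths would sit visibly higher — about 22.7 vs 21.65 at
  `r=0.25, mu_i=5, mu_d=15` — which is worth keeping in mind when comparing
  against figures drawn on a log axis.

## Known limitations

* M4 is a composition rule, not a stochastic model of conserved-segment
  birth and death; at most one internal segment is supported.
* The expectation trajectories (`m1_expectation`, `m2_expectation`) are
  exact only where their linearization holds (`L_inf >> mu_d` for M2); the
  simulator and the exact chain solver are authoritative elsewhere.
* Fitting assumes the observed lengths are a stationary sample; there is
  no treatment of phylogenetic correlation or non-equilibrium dynamics.
* The Zipfian law is assumed, not selected; alternative indel-length laws
  are out of scope.
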