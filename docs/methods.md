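# Methods

`admixkit` infers the demographic history of admixed populations from the
lengths of local-ancestry tracts, embeds ancestry-masked haplotypes in a
joint PCA space with subcontinental reference panels, and overlays
local-ancestry calls on identity-by-descent (IBD) segments.  Everything
can be exercised end to end on synthetic cohorts from the bundled forward
simulator, which doubles as the oracle for the analytic tract model.

## Pulse-migration model

A history is a *migration schedule*: for each generation before present
`t` (`t = 1` is the sampled generation) and each source population `p`, a
replacement fraction `m_p(t)`.  The founding generation `T0` is fully
specified (`Σ_p m_p(T0) = 1`); the sampled generation receives no
migrants.  The genome fraction a sampled lineage owes to source `p` is

    a_p = Σ_t m_p(t) · Π_{1 < s < t} (1 − M(s)),      M(s) = Σ_q m_q(s),

the probability that the lineage's most recent migrant ancestor entered
at generation `t` from `p` and was not replaced since.

Three nested hypotheses are built on this:

* `base` — founding EUR/NAT admixture at `t0`, one AFR pulse at `t_afr`;
  free parameters `(t0, t_afr)`.
* `base+eur_pulse`, `base+afr_pulse` — the base model plus one later
  pulse with free `(t_pulse, m_pulse)`.

Magnitudes that are not free parameters (the founding EUR/NAT split and
the base AFR pulse size) are pinned in closed form so that the
schedule-implied `a_p` equal the observed genome-wide ancestry fractions
(estimated from tract lengths) *exactly*; the round-trip identity holds
to 1e-10 and is property-tested.  Continuous event times are mapped to
the integer generation grid by splitting a pulse across the two adjacent
generations in proportion to the fractional part; a fractional founding
time becomes a full founding at `ceil(t0)` plus a replacement pulse of
magnitude `1 − frac(t0)` at `floor(t0)`.  With split pulses the pinning
equations become quadratic in the AFR magnitude; the quadratic is fitted
exactly through three evaluations and solved, taking the root in [0, 1].
Parameter sets admitting no schedule with all fractions in [0, 1] are
infeasible and are treated as −∞ log-likelihood by the optimizer.

## Expected tract-length spectrum

Along a haplotype, the local state is `(t, p)` — the most recent migrant
ancestor's entry generation and source.  Crossovers on the `t − 1`
meioses of the lineage occur at rate `t − 1` per Morgan; a crossover at
the meiosis of the lineage's generation-`d` individual (`2 ≤ d < t`)
switches to that individual's other haplotype, i.e. a fresh gamete of a
random generation-`d + 1` individual, while a crossover at the migrant's
own meiosis leaves ancestry unchanged.  Treating this as a Markov chain
(the classical tract model, and the default, `depth = 0`), tract lengths
of ancestry `p` are phase-type sojourn times in the class of `p`-states.

Expected bin counts on a finite chromosome of length `L` are computed
from the class sub-generator `A`, the stationary weights, the entry rate
vector and the exit rates, with three tract kinds: interior tracts,
tracts truncated at either chromosome end (counted at their truncated
lengths, as tract extraction from data produces them), and a separate
whole-chromosome category per chromosome.  All required integrals
(`∫ e^{As} ds` and its first two running moments) are evaluated either by
eigendecomposition with series-stabilised scalar integrals (reference
path) or by a Taylor propagation of `e^{Ah}` and its running integrals
(numba fast path; no eigendecomposition, stable for defective
generators).  The two paths agree to ~1e-11 and this equality is
asserted in the tests.  Expected total tract length per ancestry equals
`a_p × genome length × haplotypes` to 1e-6 relative — a conservation
identity that exercises every term.

**Known approximation.**  Real meioses toggle between the *same two*
parental gametes, so successive crossovers at one meiosis are strongly
correlated in which ancestry they expose.  The Markov chain forgets this
and consequently underestimates the frequency of very long and
whole-chromosome tracts.  `ancestry_chain(schedule, depth=k)` constructs
an exact pair-of-gametes chain for the top `k` meioses (exact whenever
`2 + k ≥ T0`), which the test suite uses to demonstrate exact agreement
with the forward simulator at small founding times.  For deep histories
the exact construction is exponentially large, and the residual error of
any tractable depth is statistically resolvable in cohorts of ~2,000
haplotypes (max per-bin z ≈ 7–9 against simulation at `t0 = 12`), though
invisible at the 100–300-haplotype scale typical of real cohorts.  Time
estimates are nearly unaffected (see below).  The package default is the
classical `depth = 0` model.

## Fitting and likelihood

The observed spectrum uses, by default, 50 equal-width bins from 0.2 cM
(the local-ancestry call resolution; shorter tracts are dropped) to the
longest chromosome, plus the whole-chromosome categories.  The fit
maximises a Poisson *composite* likelihood over bins and categories
(`Σ o ln μ − μ − ln o!`) by multi-start Nelder–Mead (10 Latin-hypercube
starts by default, times bounded to (2, 25) generations, magnitudes to
(0.001, 0.999), ordering constraints by penalty, tolerance 1e-6 on the
log-likelihood).  Reported standard errors come from the numerical
Hessian of the composite likelihood and are optimistic (tract
dependence is ignored); they are for orientation only.  BIC is reported
as a convenience with the observed tract count as sample size, but model
choice should use the calibrated test below.  On cohorts of 100 diploids
(10 × 150 cM) simulated at `t0 = 12, t_afr = 6`, the median absolute
error is ≈ 0.1 generations for both times — the Markov approximation
biases the tail of the spectrum, not the decay rates that carry the time
information.

## Simulation-calibrated model selection

Because the composite likelihood overstates information, naive nested
comparisons favour extra pulses.  The guard: fit the base model, forward
simulate replicate cohorts of the observed size from the fitted null,
recompute the likelihood gain of the pulse alternative on each, and
reject the null only if the observed gain exceeds the empirical 95th
percentile of the simulated gains.  P-values use the add-one convention
`(1 + #{sim ≥ obs}) / (n_sim + 1)`.

The gain statistic is *conditional*: the alternative's `(t_pulse,
m_pulse)` are optimised with `(t0, t_afr)` held at the null optimum,
identically for observed and simulated data.  A Monte-Carlo calibrated
test is exact for any fixed data→statistic map, and the conditional
statistic is an order of magnitude cheaper than the full 4-parameter
refit, which matters at thousands of inner refits (`refit="full"`
restores the full refit).  Measured operating characteristics at the
harness scale (40 diploids, 6 × 100 cM, 200 inner simulations): null
rejection rate 5/100; power 0.90 at `m_pulse = 0.15` (pulse at
generation 4 under `t0 = 12`), rising to ~1 at `m_pulse = 0.3`.

The default `n_sim` is 1000, matching the resolution floor of p = 1/1000
in the add-one convention; the test harnesses use 150–200 inner
simulations and 25–100 outer replicates, a scaled-down version of the
same design chosen for single-CPU runtimes.

## Forward simulator

The simulator is an explicit pedigree, not a Markov approximation —
which is what makes it a valid oracle.  Each ancestral generation holds
`N = max(200, 10 × n_individuals)` individuals (configurable; the
default limits pedigree collapse).  Founding-generation individuals are
migrants drawn from the founding fractions; later individuals are new
migrants with probability `M(t)` or children of a monogamous pair drawn
uniformly from the previous generation (pairs re-drawn each generation,
selfing impossible).  Meioses have Poisson(length in Morgans) crossovers
at uniform positions with no interference and a fair-coin starting
haplotype.  Only individuals ancestral to the sample are materialised.
Tracts tile each chromosome exactly; alleles are painted afterwards
under a Balding–Nichols model (per-locus ancestral frequency
Uniform(0.05, 0.95), population frequencies Beta-distributed around it
at the chosen FST), and ground-truth IBD segments can be copied between
haplotypes.

What the generator does *not* emulate: linkage disequilibrium within
source populations, non-uniform recombination maps, crossover
interference, genotyping error, phasing error, and hemizygous X
chromosomes (sex-bias analyses compare two autosome-like compartments
with different schedules).  Passing tests therefore validate the
inference machinery under the model's own assumptions — clean phasing
and error-free local-ancestry truth — not robustness to the artefacts of
real panels.

Caveat for validation studies: all haplotypes of one simulated cohort
share one pedigree, so cohort-level ancestry fractions drift at the
`√(p q t0 / 2N)` scale; comparisons against analytic expectations should
pool independent cohorts (different seeds) or inflate tolerances
accordingly.

## Ancestry-specific PCA

Admixed haplotypes are masked to the target ancestry: a locus is kept
iff its local-ancestry call matches the target *and* the call posterior
is ≥ 0.95.  Haplotypes below 25% target ancestry are excluded, as are
reference-panel units above 10% contaminant (European) ancestry; all
exclusions are logged.  The masked haplotypes are row-concatenated with
the fully-observed reference panel on the shared locus set and embedded
by subspace PCA: columns centred on observed entries, missing entries
initialised at column means, then alternating rank-k SVD and
re-imputation of missing entries from the rank-k reconstruction until
the largest imputed-entry change drops below `tol` (default 1e-6, max
200 iterations; non-convergence returns a flagged result).  With no
missing data this is ordinary PCA (asserted to 1e-8).  Alleles are not
variance-standardised by default (haploid 0/1 data; a switch exists).
Component signs anchor the first reference population's centroid to be
nonnegative.  On the synthetic benchmark (two reference populations at
FST 0.1, 10,000 loci, 50% masking) nearest-reference-centroid
assignment recovers the true source of ≥ 90% of masked haplotypes.

## IBD detection and overlay

Haploid GERMLINE-style detection: consecutive slices of 128 markers
(default) are hashed; exact slice matches seed candidate pairs; matches
extend across adjacent slices while a slice has ≤ 2 allele mismatches,
then refine to the marker level inside the first failing slice; merged
segments below 3 cM are discarded.  GERMLINE's `err_hom`/`err_het`
distinction is diploid; on haplotypes we allow ≤ 2 allele mismatches per
slice (the `err_hom = 2` reading) and heterozygous mismatches cannot
occur (`err_het = 0`).  Haploid mode is conservative: corrupting a
single slice splits or truncates a match (tested).  Guaranteed seeding
requires a segment to span two slice boundaries, so the detectable floor
is about two slice spans; fixtures use 32-marker slices at 20 markers/cM
so that 4 cM segments are recoverable with endpoint error below one
slice span.

Each segment's ancestry profile is the length-weighted average of the
two haplotypes' local-ancestry calls over the interval; when the two
disagree on the majority ancestry the profile is still the average and
the segment is flagged discordant (such disagreements are
local-ancestry call errors — a truly IBD interval has one ancestry).
Sharing between populations sums segment lengths and normalises by unit
pairs (`n_p n_q` between, `n (n − 1) / 2` within).  Standard errors use
the chromosome-weighted (delete-one, unequal block size) jackknife with
genetic-length weights `h_j = M / m_j`; leave-one-out estimates are
rescaled to the full genome so homogeneous per-cM sharing gives SE = 0.
The hand-worked two-chromosome example in the tests pins the exact
arithmetic.  The segment-length vs ancestry relation is an OLS of the
European proportion on segment length via statsmodels.

## Pipeline, seeding, numerics

All randomness descends from one master seed through SHA-256 stage-name
substreams, so any stage reproduces in isolation and a full run is
hash-stable.  Configuration is YAML with round-trip identity.  Degenerate
inputs are defined errors: empty spectra, single-chromosome jackknifes,
zero-variance regressions, all-missing PCA rows (excluded with a log
entry), infeasible schedules.  Ties in the sex-bias Wilcoxon use the
exact null for n ≤ 25 without ties and the tie-corrected normal
approximation otherwise; all-zero differences return p = 1 with a
warning.

Problem sizes in the test harnesses and `scripts/acceptance.py` (replicate
counts, 6 × 100 cM selection cohorts, 8,000–10,000-locus PCA benchmarks)
are the package's single-CPU defaults for validation studies; every
threshold the study fixes (0.95 posterior, 0.25/0.10/0.95 ancestry
filters, 3 cM floor, 128-marker slices, 95% rejection rule) is a
configurable constant with that fixed default.

## Known limitations

* The analytic tract model is the classical Markov approximation; its
  long-tract bias is quantified above and in the test suite, and the
  exact pair-of-gametes chain is available only for shallow histories.
* The composite-likelihood SEs and BIC are heuristic; inference about
  extra pulses should use the calibrated test only.
* Pinning magnitudes to point estimates of ancestry proportions ignores
  their sampling error (it is small at genome scale and absorbed by the
  simulation calibration, which re-estimates proportions per replicate).
* The IBD detector is exact-match seeded: segments shorter than two
  slice spans, or heavily mutated/genotyping-error-laden data, reduce
  recall; parameters mirror the published settings rather than modern
  IBD callers.
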