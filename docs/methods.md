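# Methods

## Data-generating process

A cohort of N individuals is simulated as independent draws from a
p-variate normal distribution. With one latent group the mean is **0**;
with two, group 2's mean is shifted by a standardized difference d on
*every* indicator (a deliberately favorable arrangement: all indicators
are equally informative about group membership). The covariance is
compound-symmetric — unit variances, one common pairwise correlation ρ —
so ρ is interpretable directly as the correlation between any two
indicators *within* a group. Group membership is an independent fair coin
per unit: group sizes are binomial, equal only in expectation.

Per replicate, d and ρ are drawn uniformly from scenario-specific ranges
rather than fixed, emulating the uncertainty of a real a-priori design
analysis. Default factor levels (indicator counts p ∈ {3, 6, 12}; sample
sizes N ∈ {50, 100, 250, 500, 1000, 2000}; ρ ranges (−.10, .10),
(.10, .30), (.40, .60); d ranges (.20, .60), (.60, 1.00), (1.00, 2.00))
span the conditions typical of behavioral research: modest effects, small
to moderate cohorts, correlated indicators. The default replicate count
for full grid runs is 500.

Degenerate corner: for p = 12 the compound-symmetry structure requires
ρ > −1/11 ≈ −0.0909, but the lowest ρ range extends to −0.10. Sampled
values below the bound are truncated to −1/(p−1) + 10⁻⁶ with a runtime
warning. This affects ~4.5% of draws in that one cell and keeps the
generated correlation essentially at the boundary the range intends.

What the generator does *not* emulate: non-Gaussian margins (skew, floor
and ceiling effects), outliers, unequal mixing proportions, group-specific
correlations, or unequally informative indicators. Conclusions drawn from
these simulations therefore describe a best case for the clustering
methods; real behavioral data can only be harder.

## Mixture clustering (MGC)

Gaussian mixtures are fit by EM for every combination of g = 1..5
components and six covariance families — spherical, diagonal and full
shapes, each either shared across components or component-specific (EII,
VII, EEI, VVI, EEE, VVV). The six families cover the constraint spectrum
from 1 to g·p(p+1)/2 covariance parameters at tractable cost; reference
mixture software sweeps a larger set (14 families including rotated
ellipsoidal ones), so quantitative agreement with results produced by that
sweep is approximate by construction.

Model selection maximizes BIC = 2 log L − m log N with m the free-parameter
count ((g−1) mixing + g·p means + family-specific covariance terms). Ties
break toward fewer components, then the simpler family.

EM details: initialization from the complete-linkage hierarchical partition
at each g plus one k-means restart (fixed internal seed), keeping the
better log-likelihood — deterministic given the data. Convergence when the
log-likelihood change falls below 10⁻⁵·(1 + |log L|), cap 500 iterations.
Component covariances are floored at eigenvalue 10⁻⁶; any fit that hits the
floor (or empties a component) is flagged degenerate and excluded from
selection, and a replicate where *every* fit fails raises — the engine
counts such replicates instead of aborting. The log-likelihood trace is
retained on every fit so the EM ascent property is directly testable.

## Partitional methods and selection

PAM implements classic BUILD (greedy seeding by largest cost reduction)
and SWAP (steepest single-exchange descent, cap 100 passes) on the
Euclidean distance matrix. SWAP terminates at a local optimum; on small
fixtures this coincides with the exhaustive optimum except in constructed
cases, where it matches R `cluster::pam` exactly. HAC is complete-linkage
agglomeration (SciPy), cut at each candidate k. Indicators are generated
at unit variance, so distances are computed on the raw values with no
rescaling step.

Number-of-clusters selection for both: the average silhouette width over
k = 2..5 (singleton clusters score 0; ties toward smaller k). Because the
silhouette is undefined at k = 1, the one-cluster possibility is screened
first by the Duda-Hart test applied to the method's own 2-cluster
partition: homogeneity is rejected when Je(2)/Je(1) — pooled within-cluster
over total sum of squares — falls below
1 − 2/(πp) − z₁₋α·√(2(1 − 8/(π²p))/(Np)), one-sided at α = .05. If the
test does not reject, k = 1 is reported and the silhouette is never
consulted; it does not override a silhouette optimum at larger k.

A calibration caveat established empirically in this package: the
Duda-Hart critical value is an asymptotic normal approximation whose
implied null spread of the ratio (≈0.07 at N = 100, p = 3) far exceeds the
true sampling spread (≈0.02), so the test's actual level on homogeneous
Gaussian data is far below nominal (≈0.3% for the sum-of-squares-optimal
split, ≈0% for the HAC split) — it is strongly conservative, which inflates
one-cluster detection on orthogonal data and does not prevent the
correlation-driven false positives documented in the results.

## Evaluation

Recovered partitions are scored with the plain (unadjusted) Rand index —
the fraction of unit pairs co-clustered in both or separated in both
partitions — matching the convention that 0.5 reads as chance agreement
for two balanced groups. When the truth is a single cluster the index
against the all-ones labeling is still reported; it is then a function of
the recovered cluster sizes only and should be read descriptively.
Summaries per scenario × method give the full selected-k tally, binned
proportions (1, 2, 3, >3), the proportion selecting the true k, and the
Rand mean and population SD over replicates.

## Seeding and determinism

One master seed drives everything. Each (scenario, replicate) pair derives
an independent child stream via `SeedSequence(master, spawn_key=(crc32(label),
replicate))`, so results are bit-identical across runs, scenario orderings
and parallel schedules; the parallel path (joblib over scenarios) is
optional and provably output-equivalent.

## Power utilities

The two-sample t-test power is exact (noncentral t with noncentrality
d·√(n/2), 2n − 2 df). The correlation-test power integrates the exact
sampling density of the correlation coefficient under bivariate normality
over the rejection region of the null t-test; under this calculation
N = 193 is the minimal sample achieving 80% power for r = .20 at α = .05
(the large-sample Fisher-z approximation, also provided, gives 0.798
there — marginally conservative). Effect-size conversion uses
d = 2r/√(1 − r²) with exact inverse. The median-split artifact has closed
forms — −√12 for a uniform variable (two adjacent half-width uniforms),
−2√(2/π)/√(1 − 2/π) from half-normal moments for a normal variable — with
an optional simulation mode that agrees within Monte-Carlo error.

## Problem sizes used in the shipped checks

The full 216-scenario × 500-replicate design is runnable via `run_study`
but the shipped test suite exercises scaled-down versions chosen as
adequate for the properties asserted: 50 replicates for the false-positive
demonstration (the acceptance script uses 300), 60 replicates at N = 500
for the correlation-ordering check and at N = 250 for the large-effect
regime. The qualitative orderings these assert were verified stable at
those sizes.

## Known limitations

Six covariance families rather than the full 14-family sweep of reference
mixture software; single-swap PAM (no FastPAM-style acceleration, no
multi-start); selection limited to k ≤ 5 as in the study design; the
Gaussian, equal-proportion, common-ρ generator above. The package measures
design-level operating characteristics; it does not attempt
figure-for-figure replication of any particular published table, whose
exact seeds and software defaults are unknown.
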