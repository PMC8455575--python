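# Methods

## Fragment-level model

All statistics operate on *epiallele tables*: per sample and amplicon
region, counts of fragment methylation patterns over `{M, U, N}` with one
character per CpG in genomic order. Pattern calling is offset-based —
amplicon reads all start at the primer, so site states are read at fixed
offsets (C → M, T → U, other base or quality below `min_base_quality`
→ N) with no alignment step. Reads shorter than the last offset are
dropped and tallied.

The completeness rule is applied uniformly: fragments containing any N are
excluded from epiallele-level statistics (count spectrum, epipolymorphism,
linkage) so epiallele frequencies form a proper distribution, but their
callable sites still contribute to per-CpG percentages. A site with zero
callable fragments is reported missing, never 0.

Epipolymorphism is computed over the full region's epiallele distribution
(9 or 6 CpGs here), not over sliding 4-mers as in some earlier
heterogeneity work; with the full region the score answers "how many
distinct whole-region alleles coexist", which is the question the linkage
analysis also addresses. The linkage matrix uses the Pearson formula on
0/1 indicators (the phi coefficient) weighted by pattern counts; pairs
involving a constant site are undefined and excluded from the mean — never
imputed as 0, which would fake evidence of independence. Both statistics
refuse to run below `min_fragments` (default 10; small-sample E and r are
badly biased) and the threshold is echoed in the summary output.

CpG density is a Gaussian KDE over CpG genomic positions evaluated at each
CpG (self-inclusive), bandwidth 10.73 bp by default, normalised to
integrate to 1 over the point set; only the relative ordering of densities
is interpreted.

## Synthetic data

The generator produces fragment populations under three mechanisms:

* `clustered` — sites start methylated with probability
  `baseline_methylation`; with probability `allele_event_prob` the whole
  allele is then demethylated as a block. A two-allele mix (baseline 1,
  event probability q) has E = 2q(1−q) and pairwise r = 1 analytically.
* `site_independent` — each site is demethylated independently with
  probability `site_event_prob`; pairwise r → 0.
* `drift` — the clustered backbone plus independent per-site
  demethylation. This is the package's model of stochastic epiallele
  drift with aging: raising the per-site rate s drives E up while mean
  pairwise linkage falls as r̄ = 0.3(1−s)/(0.3+0.7s) for the default
  0.3 block probability. A purely site-independent drift would pin r̄
  near 0 at every rate and could not reproduce the falling-linkage
  signature, which is why the backbone is part of the definition.

Reads are emitted as one merged amplicon-length fragment per template
(the analysis is fragment-level; mate geometry adds nothing here) over a
deterministic synthetic reference whose only CG dinucleotides sit at the
declared offsets. Unmethylated and non-CpG cytosines convert to T;
conversion failure (default 0.005) retains C at non-CpG cytosines;
sequencing error (default 0.001) substitutes uniformly among the other
bases. N pattern states are emitted as an `N` base at phred 2 so calling
round-trips exactly at zero error rates.

The cohort generator draws donor ages uniformly per group, sets each
donor's target mean methylation from the group model — controls:
`intercept + slope·age` (preset 135 − 1·age, i.e. 80 % at 55 falling to
50 % at 85); cases: an age-flat 65 % from age 45 — plus donor-level
Gaussian noise, clipped to [0, 100]. The noise SD default is 4 percentage
points, a typical interindividual spread for a targeted region in bulk
cortex. Within a donor, fragments come from an allele-block /
independent-site mixture sharing the marginal mean, so the mixture weight
(`allele_linkage`, default 0.6) directly equals the expected pairwise phi
correlation. Case donors get a disease duration drawn uniformly from 1–5
years and onset = age − duration. All preset values live in
`src/epiallele/presets/motor_cortex_cohort.cfg`; the amplicon panel (9 + 6 CpGs,
denser spacing in the 6-CpG region) uses placeholder chromosome-1
coordinates with realistic spacing.

What the generator does **not** emulate: PCR duplicates and index
hopping, paired-end mate geometry, cell-type composition shifts with age,
batch effects, or any group difference in variance. Tests passing on this
synthetic cohort therefore demonstrate that the pipeline recovers the
statistical structure it assumes — not that real cortex data satisfy
those assumptions.

## NIPALS PCA

Columns are centered and scaled to unit variance (n−1 SD) over observed
entries; components are extracted one at a time by alternating
least-squares between score and loading vectors, with missing cells
skipped in every inner product, and the matrix is deflated after each
component. Convergence: relative score change below `tol` (default 1e−9,
1000 iterations max); non-convergence is carried as a flag in the result,
not silently ignored. Signs are fixed by making each component's
largest-magnitude loading positive, so outputs are deterministic.
Explained variance per component is the drop in observed sum of squares
relative to the scaled total; with complete data scores, loadings and
variance fractions match the eigendecomposition of the scaled covariance.
Two components are retained by default (the plotted pair). Zero-variance
and all-missing columns are rejected by name.

## Age models

The clock is a single-locus linear regression fitted on controls only,
by default at the first CpG of the 6-CpG region (global CpG 10 of the
panel), with a region-mean option (`--clock-cpg mean10_15`). Percent
methylation is regressed directly (the axis scale of the data the clock
mimics); a logit variant was considered and left out — at 50–80 %
methylation the logit is nearly affine, so it would change nothing but the
units. The fit is inverted to an epigenetic age t̂ = (m−a)/b, which
requires b ≠ 0 (a flat clock is uninvertible and raises). Acceleration
Δ = t̂ − age is computed for cases only by default; the OLS residual
property makes the mean Δ of the fitting set 0, so control accelerations
are only meaningful relative to each other and are labelled when emitted.

Correlations are two-sided Pearson tests on complete pairs (n ≥ 3,
non-constant). The age × group comparison is the standard ANCOVA
interaction from `m ~ age * group`, reported as the slope difference with
its single-df F (= t²) and p. No multiple-testing correction is applied;
the report counts the tests performed so a reader can apply one.

## Numerical and design notes

* Problem sizes: presets use 2000 fragments/sample/region and 21 donors;
  mechanism-signature checks use 50 000 fragments on a 5-point rate grid —
  large enough that Monte-Carlo error is an order of magnitude below every
  asserted margin.
* Tables are written with 6 significant digits, `NA` for missing, a
  `# generated-by` provenance line, and deterministic row order, so
  equal-seed runs are byte-identical.
* Determinism: one integer seed per command; internal streams are derived
  from it (`numpy.random.default_rng`).
* Degenerate inputs fail loudly: empty pattern sets, all-N fragments,
  constant vectors, singular ANCOVA designs, zero bandwidth, inverted
  clocks with b = 0.

## Limitations

Single-locus clocks inherit the noise of one CpG; the 6-CpG-region mean
option trades locus specificity for stability. The acceleration–onset
correlation in the synthetic cohort arises mechanically from age-flat case
methylation plus onset ≈ age − duration, so its size should not be read
as a biological effect estimate. The epipolymorphism–age correlation in
controls is likewise a consequence of mean methylation drifting toward
50 %, where pattern entropy peaks — the package reports it, the generator
does not model an independent heterogeneity process.
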