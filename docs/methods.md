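# Methods

`meioxo` simulates meiotic crossover formation in an F2 plant population,
estimates genetic distance and crossover interference from fluorescence
class counts, calls crossovers from sparse genotyping-by-sequencing (GBS)
allele counts, and summarises crossover landscapes against SNP density.
This note records the models, the defaults and why, the numerical choices,
and what the synthetic data can and cannot establish.

## Crossover simulation

**Two pathways.** Crossovers are drawn from two independent processes per
chromosome: Class I (interfering, ZMM-pathway) and Class II
(non-interfering). Each is parameterised by a base intensity in cM/Mb,
modulated along the chromosome by polymorphism responses (below), giving a
piecewise-constant intensity track. All rates refer to the gamete genetic
map: a track integrating to *g* cM contributes *g*/100 expected crossovers
per gamete.

**Interference model.** Class I events are a stationary gamma-renewal
("counting") process on the cumulative genetic scale of the bivalent (twice
the gamete map), with shape ν ≥ 1 and unit mean spacing; each event is then
retained with probability 1/2, since any crossover involves two of the four
chromatids. ν = 1 reduces exactly to a Poisson process (no interference),
which is the analytic check used in the tests; larger ν suppresses nearby
double crossovers and drives the two-interval coefficient of coincidence
below 1. Stationarity is obtained by starting the renewal 30 mean spacings
before the origin (burn-in), which is simpler than sampling the equilibrium
forward-recurrence distribution and exact to well below Monte-Carlo
resolution. Class II events are an inhomogeneous Poisson process on the
bivalent, thinned identically. Default ν = 5, a mid-range value that
produces strong but incomplete interference; it is configurable and no
result in this package depends on its exact value.

**Obligate crossover.** Off by default. When enabled, chromosomes with no
bivalent event are redrawn, which guarantees a chiasma per bivalent but
slightly inflates the realised map relative to the nominal one.

**Polymorphism responses.** The Class I multiplier is
`1 + A·exp(−d/L)` inside heterozygous blocks, with `d` the distance to the
nearest heterozygous/homozygous block boundary (defaults A = 1, L = 300 kb)
— a minimal emulation of the boundary-stimulation (juxtaposition) effect;
it is illustrative, not fitted to data. The Class II multiplier is
`1/(1 + s·ρ)` with ρ the local SNP density in SNPs/kb (default s = 1), so
Class II crossovers are progressively inhibited where the homologs
diverge. An `msh2_active` flag models the mismatch-detection pathway: when
off, both responses become neutral except a weak residual
(MSH2-independent) Class II inhibition, `1/(1 + 0.05·ρ)` by default. The
intensity is defined genome-wide — crossovers occur inside homozygous
blocks too; they are simply invisible to genotyping there, which lets the
tests quantify caller blindness directly.

**Default rates.** `classI_base = 3.0` cM/Mb and `classII_base = 3.0` cM/Mb
(the latter mostly suppressed at typical densities). On a fully
heterozygous five-chromosome Arabidopsis-scale genome (119 Mb) at the
genome-average Col×Ler density of 6.7 SNPs/kb this yields an effective map
of ≈ 400 cM and ≈ 8 crossovers per F2 individual, matching the familiar
wild-type hybrid figures; the unsuppressed Class II base corresponds to the
strongly elevated Class II activity seen when its helicase-mediated
dissolution is removed.

**F2 individuals and GBS tables.** Each F2 carries two independent gametes
per chromosome with random parental starting phase; the genotype mosaic
(AA/AB/BB) is the overlay of the two. Marker sites are shared across
individuals (they are the fixed parental SNPs), placed proportionally to
the SNP-density track and only inside heterozygous blocks. Per site and
individual, depth is Poisson with a per-individual gamma coverage
multiplier (shape 10, mean 1) that also scales the reported library size
(base 500,000 reads); alt-allele reads are binomial with success 0, ½ or 1
by genotype, perturbed by the sequencing error rate. Site mapping quality
is drawn from a two-component mixture (uniform 110–250 for good sites,
40–100 for a configurable failing fraction); the scale is arbitrary and
exists to exercise the "> 100" quality filter.

## Fluorescence estimators

**Seed system.** A selfed F1 hemizygous for two linked seed-expressed
fluorophores in coupling phase produces, with q = 1 − r,
P(green only) = P(red only) = (1 − q²)/4, P(both) = (2 + q²)/4,
P(neither) = q²/4 (a seed shows a colour iff at least one of its two
gametes carries that transgene). Inverting the single-colour fraction
f = (NG + NR)/NT gives

    cM = 100 · (1 − √(1 − 2 f)),

the exact inverse of the selfing algebra (verified in the tests by
brute-force enumeration of the 4×4 gamete-pair table). The square-root form
is used deliberately: a literal reading of the commonly printed formula
(dividing by 2 rather than taking the square root) is not the inverse of
any gamete model and appears to be a typographic corruption. The standard
error is delta-method propagation of the binomial variance of f:
SE = 100·√(f(1−f)/NT)/√(1−2f). The estimator is undefined (reported, not
clamped) for f > 0.5. Seed classification from two-channel intensity tables
uses fixed user-supplied thresholds, matching manual thresholding practice;
a histogram-valley helper exists but is never applied automatically.

**Pollen system.** Two-colour counts give cM = 100·Y/(Y + RY). For the
three-marker (eight-class) layout, interval-b recombinants are the
{m1 only, m2+m3 only} classes plus both double-crossover classes
{m1+m3 only, m2 only}; interval c analogously. Genetic distances divide
recombinant totals by all grains; the expected double-crossover count under
independence is (d_b/100)(d_c/100)·N, and CoC = observed/expected,
interference = 1 − CoC. CoC is implemented as observed over expected — the
only direction under which "interference = 1 − CoC" behaves correctly —
even though the ratio is sometimes described verbally in the opposite
order. Class keys are positional (m1, m2, m3 ordered by genomic position);
mapping colours to positions is a configuration concern.

**Group comparisons** (Welch's t, Kruskal–Wallis + Mann–Whitney with
Bonferroni, one-way ANOVA + Tukey HSD) are delegated to scipy/statsmodels;
they are standard inference, not this package's contribution.

## Crossover calling

Filters follow GBS practice with strict boundary semantics: site mapping
quality must exceed 100, a marker row's depth in its library must exceed
2.5× (i.e. ≥ 3 reads), and libraries under 100,000 total reads are
discarded (exactly 100,000 is kept). Quality and coverage are row-level
predicates, so site filters and the library filter commute.

Genotypes are called per site from the alt-allele fraction: AA ≤ 0.1,
AB in [0.3, 0.7], BB ≥ 0.9, otherwise missing (and always missing at zero
depth). Each site also carries relative log-likelihoods of the three states
(binomial with p = 0.05/0.5/0.95), capped at 4 nats so that no single deep
site can outvote its neighbourhood.

Segmentation is a sliding-window vote over informative sites followed by
run merging. Two modes exist: a plain majority vote over a k-site window,
and the default likelihood vote, which sums the capped per-state
log-likelihoods over the window and takes the argmax. The likelihood vote
is what makes low coverage workable: at depth 1–2 a heterozygous site
frequently *looks* homozygous under the band rule (a single read is always
0% or 100% alt), and counted votes in AB regions then split almost evenly
between AA and BB; weighting by likelihood keeps such sites from creating
spurious segments. Runs supported by fewer than `min_support` sites are
merged into the larger flanking run (ties to the left). Finally, each
surviving boundary is refined to the exact changepoint maximising the
flanking states' summed evidence within the two runs — windowed votes
otherwise misplace boundaries by a few sites whenever the two states carry
asymmetric per-site evidence (homozygous evidence is stronger per read than
heterozygous evidence).

Crossovers are called one per adjacent segment pair, with flanking markers
the last informative site of the left segment and the first of the right,
midpoint the floor of their mean. Direct AA↔BB switches are retained but
flagged `suspect` (in an F2 they require a double crossover between
adjacent markers, or an artefact). Marker positions are 1-based in tables;
BED output is 0-based half-open.

**Smoothing defaults.** The package default is window 5 / support 3. The
benchmark studies use settings matched to their data, as an analyst would:
window 5 / support 2 for dense high-coverage data (40×, 1 marker per 5 kb —
minimal smoothing, maximal resolution), window 13 / support 4 for 2.5×
noisy data (after the depth filter, wider windows are needed to average
out miscalls). At the dense/clean setting the caller reproduces true
per-individual counts in ≥ 99% of individuals, with every matched midpoint
inside the true flanking-marker interval; the residual ~0–1% are true
segments spanning fewer markers than `min_support` (including zero-marker
segments), which no caller can recover at finite marker density. At
2.5×/0.5% error the population mean count is biased low by ~1–3%
(short-segment loss), within the 5% envelope the package targets.

## Landscape analysis

Calls are binned by midpoint into half-open fixed-width windows tiling each
chromosome from 0 (the short final window is kept by default, its density
normalised by true length; `drop_partial` discards it), normalised per F2.
Scaled-arm profiles map each arm linearly onto telomere (0) → centromere
(1) and aggregate. Windowed profiles across populations are compared with
Spearman correlation on identical grids.

For the polymorphism analysis, 100-kb windows are ranked by SNPs/kb
(ties broken by chromosome then start, so the grouping is deterministic
under row permutation) and partitioned into consecutive runs of 12; the
trailing remainder — the highest-density windows — is excluded and
reported. Per group, each population's crossover frequency is the mean over
member windows of 100·count/(2·n_individuals) (two gametes per F2), in cM
per window; Δ cM curves are element-wise differences on identical group
definitions. Trend lines use an in-package loess (local quadratic, tricube
weights, span 0.75 by default): no installed backend provides
degree-2 local regression, and the ~40-line implementation reproduces
constants and, at full span, straight lines exactly. Rank correlations of
Δ cM against density are delegated to scipy.

## Pipeline and reproducibility

A single YAML configuration drives `simulate → filter → call → landscape`;
unknown keys are rejected by name and defaults are echoed back. All
randomness descends from one root seed through `numpy` SeedSequence
spawning (one child stream per individual), so identical config + seed
reproduce byte-identical outputs; every output file carries the tool
version, config hash and seed in `#` header lines, and a JSON manifest
records per-stage tallies and output checksums. VCF ingestion (per-sample
AD depths, biallelic sites only) uses cyvcf2.

## What the synthetic data does and does not show

The generator reproduces the *structure* of the measurement problem: two
crossover pathways with and without interference, density- and
boundary-dependent modulation, marker sparsity and blindness in homozygous
tracts, binomial read noise, and multinomial fluorescence classes with
known ground truth. Passing tests therefore demonstrate that the
estimators invert their own generative models exactly, that the caller
attains the information-theoretic limit on clean dense data and degrades
gracefully at 2.5×, and that landscape statistics recover injected
pathway responses. They do not validate the biological realism of the
response shapes (qualitative emulations, not fits), segregation distortion,
structural variation, mapping artefacts correlated along the genome, or
TIGER's exact behaviour on real GBS data — the segmenter here is a
deliberate, documented simplification, not a reimplementation.

## Benchmark problem sizes

The bundled studies use: 200 F2 individuals over two chromosomes
(20 + 15 Mb) for caller benchmarks; 2 × 500 F2 over two 20-Mb chromosomes
with a 0.3→12 SNPs/kb gradient for landscape recovery; 30,000 gametes for
interference limits; 200 replicates for estimator round-trips; and 200 F2
on the 119-Mb five-chromosome genome for the wild-type crossover count.
These sizes give Monte-Carlo error comfortably inside every tolerance the
tests assert while keeping a full run in the low tens of seconds.
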