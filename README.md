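# meioxo

Measurement and analysis of meiotic crossover recombination in plant F2
populations: fluorescent-tagged-line (FTL) genetic-distance and
interference estimators, a genotype-switch crossover caller for sparse
GBS-style allele-count tables, SNP-density-binned recombination-landscape
analysis, and a synthetic meiosis simulator that generates every input the
pipeline consumes with known ground truth.

It is written for researchers studying how interhomolog polymorphism shapes
the two crossover pathways — interfering Class I (ZMM) and non-interfering
Class II — in hybrids such as Arabidopsis Col×L*er*, where mismatch
detection stimulates Class I and suppresses Class II crossovers at
polymorphic sites.

## What it computes

**Seed-system genetic distance.** For a selfed F1 hemizygous for two linked
seed fluorophores in coupling phase, with NG green-only, NR red-only seeds
of NT total and f = (NG+NR)/NT:

    cM = 100 · (1 − √(1 − 2f))

the exact inverse of the selfing class probabilities
P(green-only) = P(red-only) = (1−q²)/4, P(both) = (2+q²)/4,
P(neither) = q²/4 with q = 1 − r.

**Pollen-system distance and interference.** Two-colour counts give
cM = 100·Y/(Y+RY). Eight-class three-fluorophore counts give two adjacent
interval distances d_b, d_c, the coefficient of coincidence
CoC = DCO_obs / ((d_b/100)(d_c/100)·N), and interference = 1 − CoC.

**Crossover calling.** Library filter (< 100,000 reads discarded), marker
filters (quality > 100, depth > 2.5×), three-state genotype calls from
allele fractions, sliding-window likelihood-vote segmentation with exact
changepoint refinement, and one crossover per genotype switch at the
midpoint between flanking informative markers.

**Landscape analysis.** Per-F2-normalised crossover counts in fixed
windows, telomere→centromere scaled-arm profiles, Spearman profile
correlations, 100-kb windows ranked by SNP density and grouped into runs
of 12, per-group crossover frequency, Δ cM curves between genotypes, and a
tricube local-quadratic (loess) trend.

**Simulation.** Class I crossovers from a stationary gamma-renewal process
(shape ν; ν = 1 is the Poisson, no-interference limit) on the bivalent
genetic scale with 1/2 chromatid thinning; Class II as superposed Poisson;
both modulated by SNP-density and heterozygosity-boundary responses;
GBS-like noisy allele counts; multinomial seed and pollen class counts.

## Worked example

Seed counts (NG = NR = 180 of NT = 2000, i.e. f = 0.18):

```
$ printf 'green_only,red_only,both,neither\n180,180,1320,320\n' > seeds.csv
$ meioxo ftl-seed --counts seeds.csv
cM=20.00	SE=1.074	n=2000
```

f = 0.18 inverts to exactly 20 cM — these are the expectation counts at a
recombination fraction of 0.2 — with a binomial delta-method standard
error of 1.07 cM.

Pollen interference from eight-class counts with half the independent
expectation of double crossovers:

```
$ printf 'm1m2m3,none,m1,m2m3,m1m2,m3,m1m3,m2\n4025,4025,475,475,475,475,25,25\n' > pollen.csv
$ meioxo ftl-interference --counts pollen.csv
d_b=10.00	d_c=10.00	CoC=0.500	interference=0.500	n=10000
```

Both intervals measure 10 cM; 50 observed double crossovers against 100
expected gives CoC = 0.5, i.e. interference 0.5.

End-to-end simulated run (60 F2 individuals, two chromosomes):

```
$ meioxo run --config examples/demo.yaml --out-dir demo_out
INFO meioxo: simulate: 72000 marker rows
INFO meioxo: filter: {'individuals_in': 60, 'individuals_dropped': 0, ...}
run complete; manifest with 7 outputs written
$ head -7 demo_out/crossovers.bed
#meioxo v0.1.0
#seed=7
#config_hash=ce134486d67f03e5
chrom	start	end	individual	score	transition
chr1	894563	894564	F2_0001	0	BB->AB
chr1	1310101	1310102	F2_0002	0	AB->AA
chr1	4532950	4532951	F2_0003	0	AB->AA
```

The manifest (`demo_out/manifest.json`) records 76 simulated crossovers and
76 calls, per-stage filter tallies, and SHA-256 checksums of every output;
rerunning with the same config and seed reproduces the files byte for
byte. `meioxo call` ingests existing marker TSVs (or VCFs via
`meioxo.io.convert_vcf_to_marker_table`), and `meioxo landscape
bin|corr|density-groups|delta` run the windowed analyses on any call set.

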