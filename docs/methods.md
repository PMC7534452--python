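# Methods

This note documents the models behind `nampanel`, the defaults and why they
were chosen, and what the synthetic data can and cannot establish.

## Breeding and meiosis model

Each RIL population descends from a cross between an all-REF recurrent
parent and one alternate founder: an F1 is selfed and then advanced by
single-seed descent to generation t (default t = 8), so every line is one
independent lineage of t−1 meiosis rounds per chromosome copy. Expected
residual heterozygosity at F_t is (1/2)^(t−1) ≈ 0.78% at F8; it is kept
(not forced to zero) so heterozygote handling downstream is exercised.

Crossovers are placed as a Poisson process on the genetic (cM) scale with
no interference; the expected count per gamete and chromosome is
length_cM/100. Under this process the realized recombination fraction
between loci d cM apart is the Haldane value r(d) = (1 − e^(−2d/100))/2.
The Kosambi function is used on the *estimation* side only, as the
distance↔fraction convention of the mapping pipeline; at the marker
densities of interest (≤ ~1 cM intervals) Kosambi and Haldane agree to
well under 1%, so the simulation/estimation mismatch is negligible and the
estimation-consistency tests quantify it explicitly. Genetic and physical
coordinates are related by a constant per-chromosome rate (the default
genome is five Arabidopsis-like chromosomes, ~119 Mb and ~510 cM).

Founder dense-SNP alleles are drawn independently per SNP: a sharing count
q (how many of the k alternates carry ALT) is drawn from a profile
(uniform over 1..k by default) and q alternates are chosen uniformly.
Founders therefore carry **no ancestral haplotype structure**. This is the
one deliberate simplification with a visible consequence: in the real
panel, faster LD decay in merged populations comes from historical
recombination among founders; here it emerges from the same mechanism that
matters for mapping — SNPs shared by different founder subsets decorrelate
when populations are pooled — so the *ordering* of decay distances
(1 ⊃ 7 ⊃ 14 populations) is reproduced, but absolute distances are not
comparable to the real panel's.

## GBS observation model

Observed populations are produced by subsetting markers uniformly among
SNPs polymorphic in the cross (independently per population, so GBS sets
rarely overlap across populations), then setting each call MISSING with a
per-population missing rate and flipping homozygotes with a genotyping
error rate. Defaults follow the packaged per-population summary of the
14-population study (sizes 137–150, 563–1525 GBS markers, 16.4–27.1%
missing; panel means 1170 markers and 21.6% missing). The error rate is
not reported for the real pipeline; the default 0.1% reflects
deep-coverage GBS calling with a read-depth filter. Read-level simulation
(FASTQ, barcodes, restriction sites) is out of scope.

## Linkage maps

Maps are estimated per chromosome from adjacent-marker recombinant
fractions R̂ = recombinants / informative lines, counting only lines
homozygous and non-missing at both markers, then r = R̂/(2(1−R̂))
(Haldane–Waddington correction for selfing RILs) and d = Kosambi(r),
accumulated from 0 per chromosome. Two practical points the implementation
enforces:

* **Estimate from observed calls, not filled ones.** Missingness is
  independent of recombination, so complete-pair restriction is unbiased;
  run-filling re-admits only non-recombinant lines and would shrink the
  map by roughly P(both flanks observed).
* **Singleton masking.** A homozygous call whose nearest homozygous
  neighbors agree with each other and differ from it is masked before
  estimation: at ≤1 cM spacing a genuine double crossover within one
  marker is orders of magnitude rarer than a genotyping error, and
  unmasked errors inflate dense maps by ~0.1 cM per interval. This plays
  the role of the error model in multipoint map estimators; it can be
  disabled (`mask_errors=False`) for error-free data.

R̂ ≥ 0.5 is clamped to 0.4999 and flagged rather than rejected (sampling
noise on short chromosomes); intervals with no informative line fall back
to the chromosome's mean cM-per-bp rate times the physical gap, flagged.
Adjacent-pair estimation is deliberately not full multipoint EM: with
≤27% missing and ≥137 lines it is consistent, and the multipoint HMM
below supplies the genotype-probability machinery where multipoint
information matters. Genome-wide length recovery on simulated data is the
tested accuracy claim (within 15% at n = 150); individual 1-cM intervals
have sampling errors of order 50% at that sample size and are only
accurate on average.

## Imputation

**Fill-in.** Per line and chromosome, every maximal missing run whose
nearest non-missing flanks are the same homozygous state is set to that
state; runs touching chromosome ends, spanning a state change (breakpoint
regions), or flanked by a heterozygote stay missing. Observed calls are
never altered.

**Multipoint filter.** A per-chromosome Markov chain over {REF, ALT, HET}
with stationary distribution ((1−h)/2, (1−h)/2, h), h = (1/2)^(t−1),
jumps to stationarity across an interval with probability calibrated so
the homozygote-to-opposite-homozygote transition equals the interval's
RIL recombinant fraction R(d). Emissions are 1−ε for the matching call
(default ε = 0.01), ε/2 for each other state, uniform for MISSING.
Forward–backward posteriors (validated against exhaustive path enumeration
to 1e−10) revert any filled call whose posterior falls below the 0.99
threshold. On study-condition simulations this takes ~21.6% missing to
~1–3%, matching the direction and order of magnitude of the real panel's
post-imputation rates (0.8–3.2%).

**Dense projection.** Between consecutive homozygous GBS anchors of equal
state, every dense SNP strictly inside receives that parent's allele (for
ALT anchors, the alternate founder's allele at that SNP — REF wherever the
founder carries the reference base); SNPs colocated with an anchor take
the anchor's implied state (anchors own their position, interiors are
strictly between); everything else — unlike anchors, heterozygous calls,
chromosome-end overhangs — stays missing. The error model for a d-cM
anchored interval is rate = (d/100)², i.e. the double-crossover
probability with r ≈ d/100; this linear form (not the Kosambi
alternative, provided as an option) is the one consistent with the
printed study values 0.0016% at 0.4 cM and 1.93% at 13.9 cM. Because the
position of an erroneous SNP inside the interval averages the two
sub-interval probabilities, realized error is below the bound (≈2/3 of it
for uniform SNP placement); the tests check the bound over ≥10⁴
projected calls against the truth mosaic.

## QTL scans

Phenotypes are y = a·x + e with e ~ N(0,1), x the 0/1 homozygote
indicator (heterozygous or missing lines draw x from the empirical class
ratio so no line is dropped) and a = √(PVE/((1−PVE)·Var x)). The LOD
curve is computed at marker positions only (no pseudomarker grid — at
0.4 cM spacing a grid adds nothing). Two scan engines share the same
genotype-probability input:

* `scan_em` — maximum likelihood over a two-homozygote normal mixture
  with per-line genotype-probability weights (EM, tolerance 1e−8);
* `scan_hk` — regression on the expected genotype, vectorized over
  phenotype columns.

At a fully observed marker both equal the marker-regression LOD
(n/2)·log10(RSS₀/RSS₁) (tested to 1e−6). Permutation thresholds and the
power pipeline use the regression engine: permutations need thousands of
scans, the two engines coincide at the ~1–3% post-imputation missingness
the pipeline operates at, and the null distribution of the max-LOD is the
same. Support intervals take the contiguous span where LOD ≥ peak − 1.5,
expanded outward to the nearest scanned positions below the cutoff
(endpoints included, one-sided at chromosome ends, leftmost peak on
ties). Estimated PVE uses 1 − 10^(−2·LOD/n); at detected small-effect
QTL its mean exceeds the simulated target (Beavis-type ascertainment
inflation), which the tests assert rather than correct.

## NAM association

Merged panels index SNPs by physical position (`chrom_bp`); perfectly
linked *neighboring* SNPs — identical in both state and missing pattern —
collapse to their first member with a representatives map for exact
reconstruction. The joint map retains SNPs whose ALT state is shared by at
least 11 of the 14 alternates, recodes calls in non-polymorphic crosses to
MISSING, and re-estimates distances on the merged data.

Kinship is the centered cross-product K = G_c G_cᵀ/p over post-collapse
SNP codes (REF 0, ALT 1, HET 0.5, missing mean-imputed per SNP) —
centered, not standardized, for stability at desk scale; the tested SNP is
not excluded (a leave-one-chromosome-out variant would be the next step,
noted as a limitation). The association model is the standard exact mixed
model: one spectral decomposition of K, then maximum likelihood in the
rotated basis with the variance ratio λ = σ_g²/σ_e² profiled by a grid
plus bounded 1-D optimization on log₁₀λ over [−5, 5] (tolerance 1e−8),
and a χ²₁ likelihood-ratio test of β = 0. With K = I it reproduces OLS to
1e−6; under a polygenic background transmitted through a 14-population
kinship its type-I error stays at nominal while naive regression inflates
(both tested). Detection uses P ≤ 10⁻⁴ inclusive (LRT 15.137,
LOD-equivalent 3.29); lines missing the tested SNP are dropped for that
test.

## LD and the incompatibility screen

r² is the squared Pearson correlation of 0/1 codes over pairwise-complete
homozygous lines, with p from the correlation test. Decay curves average
r² in 50 log-spaced distance bins (pairs capped at 10 Mb by default;
configurable) and enforce monotone decay by isotonic regression; the
reported d_at_r² is the first bin center at or below the level, or the
smallest sampled distance when the curve starts below it.

The incompatibility screen thins to the least-missing SNP per 1-Mb window
per chromosome, tests all between-chromosome pairs with Bonferroni
correction, then refines each significant pair over every SNP pair within
one window, ranking by the frequency of the most depleted
homozygote-combination class (ties by p). Ranking by depletion rather
than r² is deliberate: RIL populations carry strong long-range
intra-chromosomal LD, so distortion leaks along chromosome arms and
distant window pairs tie with the causal pair on r² alone, while the
missing class localizes sharply. A lethality simulator removes (or
down-samples to a survival fraction) lines carrying a chosen two-locus
class, reproducing the depleted-combination signature seen in real RIL
panels.

## Power experiments

Shared scenario: a SNP carried by all alternates is drawn per replicate,
one panel-wide phenotype simulated at the target PVE, one random
population drop order drawn, and detection evaluated at the causal SNP on
the full panel and every nested subset (the drop order is reused across
subset sizes, and the same phenotype is reused — matching progressive
dropping rather than independent subsets). Private scenario: the effect
size realizes the target PVE inside the single segregating population;
the panel-wide PVE is diluted by roughly n_seg/n_total, and the
segregating population is never dropped. PVE grid: 5, 7.5, 10, 15, 20,
40, 80%. Kinship is recomputed per subset (cached by the population
subset, on a thinned SNP set of ≤800 columns). Missing dosages at the
causal SNP are filled by empirical-frequency draws before phenotype
simulation so the same x is simulated and tested.

The density comparison simulates a QTL at a random dense marker, scans
with the dense and a nested sparse marker set (each with its own 5%
permutation threshold; detection additionally requires the peak on the
true chromosome), and aggregates detection rates, estimated PVE and
1.5-LOD interval widths; percent reduction is computed on replicates
detected by both marker sets.

## Problem sizes and determinism

The test suite and acceptance script run at desk scale by design: a
three-chromosome genome (53 Mb, 240 cM), one 150-line population with 400
GBS markers for single-population experiments, and a 14 × 25-line merged
panel (~1300 dense SNPs) for panel experiments; replicate counts are 100
(power, incompatibility recovery), 200 per effect size (density), 500
(scan calibration) and 2000 (mixed-model calibration). Every experiment
is configurable up to the study's full sizes (150 lines/population, 1000
replicates) through the same functions. All randomness flows from
explicit seeds through numpy Generators; a fixed master seed reproduces
every result bit-identically.

## Known limitations

* No crossover interference; no segregation distortion other than the
  explicit lethality simulator.
* Founder alleles carry no haplotype structure (see above), so absolute
  LD decay distances and absolute power levels are not calibrated to the
  real panel — ordering and calibration properties are.
* The mixed model uses K only (no population fixed effects); map
  estimation is adjacent-pair, not multipoint EM.
* The simulator does not reproduce the real study's line-exclusion QC
  (its thresholds are not published).
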