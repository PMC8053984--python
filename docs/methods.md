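# Methods

## The SDR model

The packaged coordinate model places a 145.5 kb sex-determining region
(SDR) on an f-haplotype reference chromosome, flanked by 50 kb of shared
(pseudo-autosomal-like) sequence on each side. Three breakpoints split
it into regions A (20 kb), B (8 kb), C (60 kb) and D (57.5 kb); the
region lengths are design defaults chosen so that (i) region D can host
*VviAPT3* 47 kb downstream of the C/D breakpoint and (ii) region B —
which carries no sex-linked SNPs — is narrower than the scan's default
clustering gap (10 kb), so boundary estimation from flagged sites
bridges it. The gene map holds 2/2/11/1 genes in A/B/C/D; the
transaldolase gene is modelled on the minus strand spanning most of
region B, putting its 5′ end at the B/C boundary (the H1 crossover) and
its 3′-end intron near the A/B boundary (the first H2 crossover) — the
only orientation consistent with H1 being f-like and H2 M-like across B.

1,066 sex-linked sites are placed uniformly at random within regions A
(200), C (500) and D (366) under a fixed seed (2021) and then frozen;
the paper-scale count is fixed but its split across regions is not, so
the split is an arbitrary default roughly proportional to region length.
Region B carries 50 *diagnostic markers* instead: ancestry-defined
positions that separate H1 (f-like B) from H2 (M-like B). They stand in
for the structural (TE/sequence-similarity) evidence that distinguishes
the two hermaphrodite haplotypes in real assemblies; consequently they
are treated as untranscribed and excluded from ASE tables, and in a
dioecious panel they cosegregate with sex just like the sex-linked
sites (both are fixed f/M differences).

Haplotype templates are pure functions of ancestry: f is f-like
everywhere, M M-like everywhere, H1 switches f→M at the B/C boundary,
and H2 is M-like only between the A/B and C/D boundaries. The 10
unordered diploid combinations then yield pairwise-distinct per-region
dosage signatures, verified exhaustively in the tests.

The *VviINP1* indel is represented by a synthetic 56 bp amplicon
sequence (flanks plus an 8 bp motif); the f allele lacks the motif.
The sequences are stand-ins — only the 8 bp length difference and motif
presence/absence carry information.

## Simulators

*Genotype panels.* Diploid dosages are composed site-wise from the two
templates. Genotyping error flips a call to one of the two other states
with equal probability (symmetric error; the real error process is not
characterised, so the least-informative choice is used); missingness is
i.i.d. Bernoulli. 150 neutral sites with Hardy–Weinberg genotypes at
uniform(0.05, 0.5) allele frequencies are added in the flanks as scan
negatives. Everything is reproducible from the seed.

*Allele depths.* Total depth per site is Poisson with the stated mean
(default 20×, inside the 3–50× range of real shotgun panels); the
M-supporting read count is binomial with success probability ε, ½ or
1−ε for dosage 0/1/2 (ε = sequencing base error, default 0.01). Depths
are generated from the *observed* (post-error) genotypes, and missing
genotypes yield zero depth, so the error and missingness rates
genuinely stress the downstream caller. For RNA, sites outside
annotated genes get zero depth and each allele copy is weighted by a
per-gene expression multiplier (f copies 1, M copies m), scaling both
expected depth and allelic balance; the default effect specification
expresses the M allele of *VviYABBY3* only in female-sterile samples
(m = 1) and silences it otherwise (m = 0).

*Bulk pools.* Windowed (500 bp) unique-mapping depth is Poisson around
the expected pattern: female bulk 2 units on the f assembly and 0 on
the M assembly inside the SDR, male bulk 1 unit on each, flanks 2 units
everywhere; `unit_coverage` (default 30) converts units to raw depth.
Partial boundary windows get length-weighted means. Pool sizes (13+13)
only gate validation — per-pool coverage is a free parameter because
the real pools' total coverage is not stated.

What the simulators do **not** emulate: read mapping and mappability,
TE sequence content, linked selection or population structure, depth
overdispersion, reference bias in RNA counts, and recombination outside
the fixed H1/H2 breakpoints. Passing tests therefore demonstrate the
correctness of the statistical machinery under the stated generative
model, not robustness to every artefact of real sequencing data.

## Analysis components and numerical choices

*Cosegregation scan.* A site is sex-linked when the fraction of
informative accessions violating the dioecious expectation (females
hom-ref, males het) is ≤ 2% (default; tolerates genotyping error).
Hermaphroditic accessions are excluded. MAF is computed over
non-missing calls; at a fully sex-linked site it equals
n_males / 2(n_f + n_m). The Hardy–Weinberg test is the exact
conditional test (enumeration over heterozygote counts of compatible
parity, two-sided via the sum of configurations no more probable than
the observed; no mid-p), computed with log-gamma arithmetic and checked
against an exact-rational enumeration oracle for every triple with
n ≤ 30. LD is composite r² on unphased dosages over pairwise-complete
samples; monomorphic inputs report NaN. Boundary estimation clusters
flagged sites with a 10 kb gap limit and returns the largest cluster's
span (ties: longer span, then lower coordinate).

*Bulk-depth delineation.* Tracks are normalized by half the
flanking-window median (≥ 20 flank windows required), so flanks sit at
2.0 units. Fold classes use midpoint thresholds 0.5/1.5. The SDR is the
longest run of windows matching (female 2×, male 1×) on the f assembly
and (female 0×, male 1×) on the M assembly, after a five-window
majority-vote smoothing that tolerates isolated discordant windows;
runs below 20 windows report an empty interval. At unit coverage 30 the
boundary error is ≤ 2 windows in ≥ 95% of seeded replicates.

*Painting and classification.* Painting is the M-allele dosage at model
sites (missing preserved). Region calls take the modal non-missing
state when supported by ≥ 5 sites at ≥ 0.8 concordance (defaults);
region B is called from the diagnostic markers. Classification matches
the signature table exactly; with one no-call region the unique
consistent completion is accepted; otherwise "unknown". Breakpoints are
placed at the floor midpoint between flanking informative sites of a
same-ancestry run transition (floor = ties break toward the lower
coordinate).

*Bayes-factor predictor.* Three models per site (hom-f, het, hom-M) are
needed rather than two so that homozygous-M regions (e.g. H1/H1 in C)
are callable. Defaults: base error 0.01, minimum site depth 3, decision
threshold ln 100 with equal model priors — conservative values; the
threshold is the winner's margin over the runner-up. Binomial
coefficients are omitted (they cancel in ratios), so zero-depth sites
contribute zero to every model. For RNA input, sites in genes whose
effect specification departs from biallelic expression (multiplier ≠ 1
in any group) are excluded before summation — monoallelic expression
would otherwise masquerade as homozygosity. The INP1 read-length caller
keeps modes carrying ≥ 10% of spanning reads, maps each mode to the
intact or deleted length within a ±2 bp tolerance, and errors on
incompatible modes.

*ASE association.* The statistic is the difference in group mean
M-allele read fractions (samples with depth < 10 dropped; the test is
skipped when a group retains < 2 samples). The "correlation" is
implemented as a label-permutation test (default 10,000 draws, add-one
rule), chosen for validity at the small sample sizes involved; the
statistic on fractions rather than raw counts removes depth as a
nuisance. Benjamini–Hochberg q-values flag sites; raw p-values are
reported. Under the default effect specification the female-sterile
factor separates groups completely through region A and partially
through region D (H2 returns D to f-like), with the top-ranked site in
*VviYABBY3*; region B contributes no transcribed SNPs.

## Validation panels

The acceptance script and the end-to-end tests use three fixed class
mixes: a 193-accession DNA panel (69 f/f, 68 M/f, 20 H1/f, 10 H2/f, 10
H1/H1, 16 H1/H2 — i.e. 137 dioecious wild plus 56 H carriers), a
167-genotype marker panel (60/59/18/10/10/10), and a 48-sample
transcriptome panel of 29 wild-class (15 f/f, 14 M/f) plus 19
cultivated-class samples (7 H1/f, 4 H2/f, 4 H1/H1, 4 H1/H2). The totals
follow the published validation cohorts; the per-class splits within
them are design defaults fixed once. Conditions: genotype error 0.005,
missingness 0.02, mean depth 20×, base error 0.01; INP1 spanning reads
at depth 30 with 0.005 length-jitter probability. H2/H2 and the H/M
classes are exercised in the unit tests (the algebra covers all 10) but
left out of the validation mixes, mirroring the observed cohorts where
H2/H2 has never been seen.

## Known limitations

- Region-B calls rest on simulator-provided diagnostic markers; real
  data would need assay markers or assembly comparison to type H1 vs H2
  across B.
- The predictor assumes sites are independent within a region; linked
  errors (e.g. mapping artefacts over a TE cluster) would concentrate
  rather than average out.
- The ASE permutation test conditions on observed depths and ignores
  overdispersion between biological replicates.
- The bulk-depth delineator presumes known flank windows for
  normalization; with no flank annotation the CLI falls back to the
  outer quarters of the assembly.
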