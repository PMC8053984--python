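# vitis-sdr

Toolkit for the grapevine sex-determining region (SDR): simulation of
f/M/H1/H2 haplotype panels, discovery of sex-linked SNPs, bulk-pool
read-depth delineation of the SDR, chromosome painting and
haplotype-combination classification, Bayes-factor flower-sex
prediction, and allele-specific-expression (ASE) association.

## The problem

Wild grapevines (*Vitis* spp.) are dioecious: a single ~145.5 kb region
on chromosome 2 determines flower sex, with females f/f and males M/f
under dominance M > H > f. Cultivated grapevines are hermaphroditic
thanks to two recombinant haplotypes — H1 (one crossover) and H2 (a
double crossover) — that are chimeras of M and f. The three crossover
breakpoints partition the SDR into four regions:

| Region | Genes (default model)           | Role                              |
|--------|---------------------------------|-----------------------------------|
| A      | *VviYABBY3*, *VviSKU5*          | female-sterility; f-like on every H |
| B      | β-fructofuranosidase, transaldolase | breakpoint region, no sex-linked SNPs |
| C      | 11 genes incl. *VviINP1*        | male-sterility; M-like on every H |
| D      | *VviAPT3*                       | M-like on H1, f-like on H2        |

Unordered diploid combinations of {f, M, H1, H2} give **10 genotype
classes**, each with a unique numeric signature over (A, B, C, D) where
0 = homozygous f, 1 = heterozygous, 2 = homozygous M — e.g. H1/f ↦
(0, 0, 1, 1), H1/H2 ↦ (0, 1, 2, 1). The signature table is a bijection,
so region-level genotype calls identify the haplotype pair, and the
two-factor rule (female-sterile iff A ∈ {1, 2}; male-sterile iff C = 0)
gives the flower phenotype.

## The predictor

For each site with `ref` f-supporting and `alt` M-supporting reads, the
read counts are scored under three binomial models of the M-read
fraction — hom-f (ε), het (½), hom-M (1−ε), with ε the base error rate.
Per region the site log-likelihoods are summed (sites independent), so
the log Bayes factor between models is additive over sites:

    ln BF(g, g′) = Σ_sites [ ln P(ref_i, alt_i | g) − ln P(ref_i, alt_i | g′) ]

A region state is called when the best model beats both rivals by
ln BF ≥ ln 100; otherwise the region is a no-call and the classifier
falls back to the unique consistent signature when one exists. The
*VviINP1* 8 bp indel marker (intact on M/H1/H2, deleted on f) provides
an orthogonal readout of male sterility: deleted/deleted ⇔ male-sterile.

## Worked example

```python
import vitis_sdr as v

model = v.build_sdr_model()                      # 145.5 kb SDR, 1,066 sex-linked sites
panel = v.simulate_panel(
    model,
    {"f/f": 2, "M/f": 2, "H1/f": 2, "H1/H2": 2},
    error_rate=0.005, missing_rate=0.02, seed=7,
)
depths = v.simulate_allele_depths(panel, mean_depth=20, base_error=0.01, seed=8)
for pred in v.predict_panel(depths, model):
    print(f"{pred.sample:12s} numeric={pred.numeric} class={pred.class_label:6s} "
          f"phenotype={pred.phenotype:13s} lnBF(A)={pred.region_bfs['A'].min_log_bf:8.1f}")
```

prints

```
H1xH2_000    numeric=(0, 1, 2, 1) class=H1/H2  phenotype=hermaphrodite lnBF(A)=  2459.2
H1xH2_001    numeric=(0, 1, 2, 1) class=H1/H2  phenotype=hermaphrodite lnBF(A)=  2450.2
H1xf_000     numeric=(0, 0, 1, 1) class=H1/f   phenotype=hermaphrodite lnBF(A)=  2299.8
H1xf_001     numeric=(0, 0, 1, 1) class=H1/f   phenotype=hermaphrodite lnBF(A)=  2412.8
Mxf_000      numeric=(1, 1, 1, 1) class=M/f    phenotype=male          lnBF(A)=  6318.7
Mxf_001      numeric=(1, 1, 1, 1) class=M/f    phenotype=male          lnBF(A)=  6234.7
fxf_000      numeric=(0, 0, 0, 0) class=f/f    phenotype=female        lnBF(A)=  2492.0
fxf_001      numeric=(0, 0, 0, 0) class=f/f    phenotype=female        lnBF(A)=  2231.9
```

Each accession's per-region numeric genotype matches its class
signature, the class label identifies the simulated haplotype pair, and
`lnBF(A)` is the winning model's margin (log Bayes factor against the
runner-up) in the female-sterility region.

The same steps are available from a shell:

```sh
vitis-sdr simulate-panel --classes "f/f=5,M/f=5,H1/f=2" --seed 3 \
    --out-vcf panel.vcf --out-samples samples.tsv --out-depth-tsv depths.tsv
vitis-sdr scan --vcf panel.vcf --samples samples.tsv --out scan.tsv
vitis-sdr predict --depth-tsv depths.tsv --out predictions.jsonl
```

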