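# sigkit

Somatic mutational-signature analysis for cancer genomics cohorts:
context catalogs, de novo signature extraction, sparse reference
refitting with cohort rules, per-mutation attribution, signature-injection
power simulation, and environmental-exposure association models.

The package targets studies of the kind exemplified by never-smoker lung
cancer: whole-genome somatic variant calls per patient, questions about
which mutational processes are active (tobacco-associated SBS4, clock-like
SBS5, APOBEC SBS2/13, aristolochic-acid SBS22a, ...), and whether exposures
such as ambient PM2.5 or secondhand smoke shift mutation burdens, signature
activities, telomere length, or driver-gene prevalence. Because such
cohorts are controlled-access, a first-class synthetic-cohort generator
reproduces their statistical structure so every stage is testable
end-to-end.

## The model

**Catalogs.** Somatic events are classified into fixed context schemas:
SBS-96 pyrimidine-centered trinucleotides (optionally SBS-288 with a
transcribed/untranscribed/intergenic strand prefix), DBS-78 doublets,
ID-83 indels (homopolymer run length, tandem-repeat copies, microhomology),
plus configurable copy-number (68 categories: allele state × total-CN ×
length, with two sub-100 kb bins) and structural-variant (38 categories:
clustered status × type × size, with a sub-1 kb bin) schemas. A catalog is
the nonnegative matrix **V** (categories × samples).

**Extraction.** De novo signatures come from replicated nonnegative matrix
factorization V ≈ WH minimizing the generalized Kullback–Leibler
divergence by multiplicative updates, after capping each sample column at
10,000 mutations so hypermutators cannot dominate. Replicates run on
Poisson-bootstrapped catalogs; pooled signatures are consensus-clustered
(replicate-matched, cosine distance), rank stability is the mean
silhouette, and the selected rank is the largest stable rank whose error is
near-optimal.

**Assignment.** Per-sample activities over a reference signature set are
fit by forward-stagewise sparse regression with nonnegative least squares:
a signature enters the support only if it raises the reconstruction cosine
similarity by more than an addition penalty (default 0.05; relaxed 0.01
for sensitivity analyses), and is pruned if its removal costs at most the
removal penalty (default 0.01). Cohort rules constrain candidates: SBS23
and SBS32 are globally excluded; SBS3 is admitted only where ID6 is
active, SBS92 only where ID3 is active; a microsatellite-instability flag
rescues SBS33 and the MMR-deficiency set (SBS6/14/15/20/21/26/44).
Individual mutations are attributed by Bayes' rule,
P(s | c, j) ∝ W[c,s]·H[s,j], normalized over the reconstructed count of
context c in sample j.

**Power simulation.** Detectability of a target signature (e.g. SBS4 in
passive smokers) is measured by spike-in: at each level ℓ ∈ {1, 2, 5, 10,
15, 20}%, round(ℓ·total) mutations are removed uniformly without
replacement, re-injected as multinomial draws from the target profile,
perturbed with 10% per-category Gaussian noise, and re-fit with the
relaxed penalty; detection means strictly positive assigned activity.

**Associations.** Individual PM2.5 exposure is the mean of annual
region-level values from the diagnosis year back to the series start
(1998), dichotomized at 20 µg/m³. Signature presence (activity > 0, or
above the cohort median for signatures present in >50% of cases) and
driver genes (prevalence > 2%) are modeled by multivariable logistic
regression (odds ratios per 10 µg/m³); log10 burdens and log2
telomere-length ratios by OLS, reported as percent change per unit
(10^β − 1). Families are corrected by Benjamini–Hochberg FDR; categorical
enrichments use two-sided Fisher exact tests, group comparisons Wilcoxon
rank-sum.

## Worked example

Simulate a 120-patient cohort with PM2.5 effects on three signatures
(+12%, +2.3%, +6% mutations per µg/m³ on SBS4-, SBS5- and ID3-like
signatures), extract signatures de novo, refit activities, and run the
dose-response models:

```bash
sigkit simulate --preset pollution --n 120 --seed 17 --out fx/
sigkit extract  --catalog fx/catalog.tsv --kmin 2 --kmax 8 \
                --replicates 10 --seed 5 --out-dir ex/
# -> selected k=6; results in ex
#    per_k_stability: {... "6": 0.909, "7": 0.712, "8": 0.563}
#    mean_reconstruction_cosine: 0.9995
sigkit assign   --catalog fx/catalog.tsv --reference fx/panel.tsv \
                --add-penalty 0.01 --out acts.tsv
sigkit associate --cohort fx/cohort.tsv --activities acts.tsv \
                 --mode pm25-dose --out assoc.tsv
# -> "burden":   {"beta": 0.0337, "p": 3.5e-46, "percent_change": 0.081}
#    "telomere": {"beta": -0.0042, "p": 0.178, "percent_change": -0.003}
```

Reading the output: the generator planted six signatures and the
extraction's stability score collapses exactly past rank 6 (0.91 → 0.71),
so k=6 is selected with near-perfect per-sample reconstruction (cosine
0.9995). The burden model says each additional µg/m³ of PM2.5 multiplies
total mutation count by 10^0.0337, i.e. +8.1% — dominated by the strongly
dose-responsive SBS4-like signature — while the planted negative telomere
slope has the right sign but, at n=120, is not yet significant (p=0.18).

Other subcommands: `sigkit catalog` (VCF/TSV + FASTA → context catalog),
`sigkit powersim` (injection power study), `sigkit attribute` (driver
mutations → signatures).

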