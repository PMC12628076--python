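# coldtol

Analysis pipeline for high-throughput cold-tolerance developmental assays in
*Caenorhabditis elegans*.

## The problem

Cold tolerance varies heritably among *C. elegans* wild isolates. A scalable
way to measure it is a 96-well developmental assay: synchronized L1 larvae
are chilled (e.g. 4 °C for 12 or 24 h), returned to 20 °C with food, and
imaged ~48 h later. Because animals elongate as they develop, body length is
a proxy for developmental rate, and the length gap between cold-treated and
control animals measures how much the cold exposure slowed a strain down —
a larger gap means lower cold tolerance.

`coldtol` takes the per-animal length tables produced by image-analysis
pipelines (CellProfiler/easyXpress-style exports: plate, well, strain,
treatment, object class, length in µm) and runs the downstream statistics:

1. **QC** — drop non-animal objects (MDHD class, debris < 165 µm), drop
   wells with < 5 or > 60 animals, drop outlier wells whose median length
   falls outside ±1.5 × IQR within strain × treatment × plate-design groups.
2. **Phenotypes** — per-well median lengths, per-strain reaction norms, and
   the cold-tolerance delta: mean(control well medians) − (cold well
   median), per strain and plate design.
3. **Mixed model** — REML fit of

   ```
   median length ~ treatment + plate design + (1|strain) + (1|strain:treatment)
   ```

   with boundary-corrected likelihood-ratio tests for the random terms
   (halved χ²₁ p-values, since σ² = 0 sits on the parameter boundary) and
   type-III F tests with Satterthwaite denominator df for the fixed terms.
4. **Heritability** — broad-sense heritability of the trait and of its
   plasticity, sharing one denominator:

   ```
   H²_strain           = σ²_strain / (σ²_strain + σ²_strain:treatment + σ²_residual)
   H²_strain:treatment = σ²_strain:treatment / (same denominator)
   ```

5. **Variance equality** — a Brown–Forsythe (median-centred Levene) test
   comparing the spread of well medians between treatments, plus the
   Shapiro–Wilk screen that motivates the median centring.

A synthetic assay generator (`coldtol.synthetic_data`) mirrors the mixed
model exactly — strain effects, strain-by-treatment effects, plate-design
and treatment fixed effects, well noise, and the QC-exercising artifacts —
so the whole pipeline runs and is testable without any external data.

## Worked example

Simulate an assay at the default conditions (7 strains × 12 wells × 3 plate
designs × {control, cold}, ~50 animals/well, artifacts on) and run every
stage:

```sh
coldtol all --seed 1 --outdir run/
```

prints

```
variance components (µm²): strain=709.4 strain:treatment=952.4 residual=1167.9
H2_strain=0.251 H2_strain:treatment=0.337
LRT strain: chisq(1)=1.15 p(halved)=0.141
LRT strain:treatment: chisq(1)=124.39 p(halved)=3.46e-29
ANOVA treatment: F(1,6.00)=79.50 p=0.000111
ANOVA design_id: F(2,465.02)=21.45 p=1.23e-09
Brown-Forsythe F(1,479) = 0.881, p = 0.348
```

Reading this output: cold treatment strongly retards development (the
treatment F test against its strain-by-treatment error stratum, with
denominator df ≈ n_strains − 1 = 6); strains differ markedly in *how much*
they slow down (the large strain:treatment χ², H² of plasticity ≈ 0.34)
while the main strain term is weaker in this draw; plate design has a small
but detectable effect; and the spread of well medians does not differ
between treatments (Brown–Forsythe p = 0.35). `run/` contains the cleaned
well table, the per-well delta table, reaction norms, and JSON reports with
a full run manifest.

The stages are also available separately (`coldtol simulate | qc |
phenotype | fit | variance-test`) and as library functions
(`coldtol.run_qc`, `coldtol.fit_reml`, `coldtol.heritability`, ...), e.g.
for real exported object tables with foreign column names via the
column-mapping layer in `coldtol.io_tables`.

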