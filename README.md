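# hipshape

Landmark-based statistical shape modelling of the proximal femur with
candidate-SNP association testing, plus a fully synthetic data generator so
the whole pipeline can be exercised and verified without access-restricted
imaging or genotype data.

The pipeline mirrors a standard DXA hip-shape analysis:

1. **Alignment** (`hipshape.gpa`) — generalized Procrustes analysis of
   53-point 2D outlines: translation, size and rotation are removed and a
   consensus mean estimated.  The converged frame is gauge-fixed to a
   canonical orientation so results do not depend on how input images happen
   to be oriented.
2. **Shape model** (`hipshape.ssm`) — PCA of the aligned residuals yields up
   to 10 orthonormal deformation modes ("hip shape modes", HSMs).  A saved
   reference model can be applied to a *new* cohort: each configuration is
   superimposed on the reference mean individually and scored in
   reference-SD units, so new-cohort scores are deviations from the
   reference mean shape (their mean/SD need not be 0/1).
3. **Association** (`hipshape.genassoc`) — per-SNP QC (MAF ≥ 1 %, call rate
   ≥ 95 %, Hardy–Weinberg conditional exact test p > 5×10⁻⁷) and additive
   linear association of mode scores on effect-allele dosage under three
   covariate models (age+sex; +height; +BMI), with Bonferroni thresholding
   and an adult-lookup results table.  A reference table of adult candidate
   SNP effect estimates ships with the package
   (`hipshape/data/reference_candidate_snps.tsv`).
4. **Rendering** (`hipshape.shape_render`) — reconstruct outlines from mode
   scores: single-mode ±2 SD pairs (solid/dashed) and multi-mode composite
   allele effects (betas × an illustrative scale, default 20, always
   recorded in the output), exported as SVG + lossless TSV.
5. **Synthetic data** (`hipshape.synthgen`) — a stylised 53-point femur
   template, a smooth orthonormal mode basis constructed orthogonal to the
   similarity-transform subspace (so planted variance cannot be absorbed by
   Procrustes), HWE genotypes, covariates, planted per-allele mode effects,
   nuisance rigid transforms, landmark noise, longitudinal cohorts with a
   shared latent score fraction, and a truth ledger for recovery tests.

## Command line

Each stage is independently invokable; every run writes a `manifest.json`.

```sh
hipshape simulate --seed 1 --n-subjects 400 --timepoint age14 --out sim/
hipshape build-model --landmarks sim/landmarks.csv --k 10 --out model.json
hipshape apply-model --model model.json --landmarks sim/landmarks.csv --out scores.tsv
hipshape assoc --scores scores.tsv --dosages sim/dosages.tsv \
    --covariates sim/covariates.tsv --model-spec model1 --model-spec model2 \
    --model-spec model3 --timepoint age14 --out assoc/
hipshape render --model model.json --mode 1 --sd 2 --out fig_mode1
hipshape render --model model.json --composite "1:-0.054,5:-0.072" --scale 20 --out fig_effect
hipshape report --assoc-dir assoc14/ --assoc-dir assoc18/ --out lookup.tsv
```

## File formats

* landmarks: wide CSV (`id,x1,y1,…,x53,y53`) or long TSV
  (`subject, point_index, x, y`);
* covariates: TSV (`id, age, sex, height_cm, weight_kg, bmi`), sex coded
  female = 0 / male = 1, BMI derived from height/weight when absent;
* dosages: TSV (`snp_id, effect_allele, other_allele, eaf, [n_AA, n_Aa,
  n_aa], <one column per subject>`) or VCF (DS field, else GT; dosages are
  flipped when the configured effect allele is REF);
* shape model: schema-versioned JSON with full-precision floats
  (orthonormality is re-checked on load);
* scores: TSV (`id, hsm1…hsmK`).

All writers emit full-precision decimals and all readers parse round-trip
exactly, so write→read is bit-identical.

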