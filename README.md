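# ssgblup

Single-step genomic evaluation for livestock breeding: pedigree BLUP,
single-step GBLUP (ssGBLUP) and iteratively weighted ssGBLUP (wssGBLUP) for
the single-trait animal model, together with everything the workflow needs —
numerator relationship matrices, genotype quality control, VanRaden genomic
relationship matrices, SNP-effect back-solving with nonlinear weighting,
PEV-based reliabilities, EM-REML variance components, and the forward
(partial-data) validation protocol. A synthetic population generator with
known genetic truth makes every stage testable end to end.

The package is written for quantitative geneticists and breeding-program
analysts who want a transparent, desk-scale (pedigrees up to a few thousand
animals) implementation of the single-step machinery that production tools
implement at scale.

## The model

The animal model is

```
y = Xb + Za + e,      a ~ N(0, K σ²ₐ),   e ~ N(0, I σ²ₑ),
```

with fixed effects `b` (contemporary group, sex, optional covariates) and
breeding values `a`. Henderson's mixed-model equations

```
[ X'X      X'Z          ] [ b̂ ]   [ X'y ]
[ Z'X   Z'Z + λ K⁻¹     ] [ û ] = [ Z'y ],    λ = σ²ₑ/σ²ₐ,
```

are solved with K⁻¹ = A⁻¹ (pedigree BLUP) or the single-step

```
H⁻¹ = A⁻¹ + [0 0; 0  τ(αG + βA₂₂)⁻¹ − ωA₂₂⁻¹],   α=0.95, β=0.05, τ=ω=1,
```

where `G = MM′ / 2Σpᵢ(1−pᵢ)` is VanRaden's genomic relationship matrix from
the centered dosage matrix `M`, and `A₂₂` is the pedigree block of the
genotyped animals. Reliability is `Rel = 1 − PEV/σ²ₐ`.

Weighted ssGBLUP replaces `G` with `G* = MDM′ / 2Σpᵢ(1−pᵢ)` and iterates:
solve the single-step MME (iteration 1: D = I, i.e. plain ssGBLUP),
back-solve SNP effects `â = (1/k) D M′ G⁻¹ û_g`, set nonlinear weights
`dᵢᵢ = 1.125^(|âᵢ|/sd(â) − 2)`, normalize so `Σ dᵢ·2pᵢ(1−pᵢ)` is conserved,
rebuild `G*`, repeat (three iterations by default).

## Worked example

Predicting young selection candidates — genotyped final-generation animals
whose phenotypes are hidden — from their relatives' records:

```bash
python examples/single_step_evaluation.py
```

```
candidates: 200 genotyped, unphenotyped final-generation animals
accuracy (r with TBV) parent average: 0.632
accuracy (r with TBV) pedigree BLUP:  0.632
accuracy (r with TBV) ssGBLUP:        0.674
```

A candidate without own records or progeny has a pedigree EBV equal to its
parent average; genomic relationships add Mendelian-sampling information,
which is the single-step accuracy gain. Adding the SNP-weighting loop on the
same population (`python examples/weighted_snp_effects.py`):

```
 iteration  weight_min  weight_max  weight_mean  cor_with_previous  accuracy
         1      1.0000      1.0000       1.0000                NaN    0.6736
         2      0.9069      1.4885       0.9961             0.9997    0.6843
         3      0.9108      1.6983       0.9957             1.0000    0.6888
```

Iteration 1 is plain ssGBLUP; with an oligogenic trait (30 QTL) the
nonlinear weights lift candidate accuracy at iterations 2–3. The other
examples cover the generator (`simulate_population.py`), relationship
matrices (`pedigree_relationships.py`), QC (`genotype_qc.py`) and the
forward-validation report (`forward_validation.py`).

A thin CLI wraps the same library calls for file-based runs:

```bash
ssgblup simulate -c sim.yaml -o data/
ssgblup evaluate -c run.yaml --method wssgblup
ssgblup validate -c run.yaml
```

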