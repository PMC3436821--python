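# ibbpair

Paired-sample significance testing for count data: spectral counts in
label-free proteomics, read counts in bulk or single-cell RNA-seq, feature
counts in metabolomics — any design where each subject contributes a linked
before/after (or tumor/normal) pair of samples and the question is whether a
feature shows a *common* fold change across subjects.

## The model

For one feature and subject *n* the data are a 2×2 contingency table: counts
*a*, *b* before and after treatment, with per-sample totals *t_a*, *t_b*.
Conditioning two Poisson counts on their sum *s = a + b* turns the pair into
a single binomial observation,

    a | s  ~  Binomial(s, p(φ)),      p(φ) = φ t_a / (φ t_a + t_b),

whose only parameter is the true fold change φ = π_a/π_b.  Rather than
forcing one fixed φ across subjects, the test treats it as a random effect:

    u ~ Beta(α, β),    φ = u / (1 − u),

an inverted-beta (beta-prime-type) law in which φ = 1 corresponds to
u = 0.5.  Marginalizing u gives the inverted beta-binomial likelihood; with
equal totals it is the closed-form beta-binomial, otherwise a 1-D integral
evaluated by Gauss–Jacobi quadrature in log space.  The hypothesis of no
effect is H₀: α = β, tested by the likelihood ratio

    S = 2 (ℓ(α̂, β̂) − ℓ(α̂₀, α̂₀)),     p = P(χ²₁ ≥ S),

and α̂/β̂ estimates the common fold change, with a Wald interval from the
observed information.  Technical variation that is over- or under-dispersed
relative to Poisson is handled by raising the conditional binomial pmf to a
power *v* and renormalizing over its finite support (v < 1 over-dispersed,
v > 1 under-dispersed; v = 1 is exact Poisson).

The package also ships the classical Mantel–Haenszel and DerSimonian–Laird
combinations of 2×2 tables as baselines, forest-plot summaries, and a
synthetic-data generator that draws from the model's own generative chain.

## Worked example

Three subjects, counts (57, 95), (27, 50), (55, 135), all totals
13,331,120 (`examples/worked_example.py`):

```
v=1.0: fold change = 0.498 (95% CI 0.399-0.622), S = 8.132, p = 0.0043
v=5.0: fold change = 0.510 (95% CI 0.420-0.620), S = 8.583, p = 0.0034
v=0.2: fold change = 0.485 (95% CI 0.305-0.771), S = 5.833, p = 0.0157

forest records (log fold change, v = 1):
   subject1: -0.511 [-0.857, -0.172]  weight 0.36
   subject2: -0.616 [-1.124, -0.129]  weight 0.18
   subject3: -0.898 [-1.230, -0.577]  weight 0.45
   combined: -0.696 [-0.918, -0.475]  weight 1.00
```

The gene is consistently down-regulated before treatment: the common fold
change is about 0.5 with p ≈ 0.004 under the standard Poisson model.  On a
noisier platform (v = 0.2) the per-subject intervals widen and the p-value
rises to ≈ 0.016 — weaker, but still significant.

The other examples show the Mantel–Haenszel failure mode on
mixed-direction data (`examples/meta_baselines.py`), calibration and power
on synthetic data (`examples/simulation_calibration.py`), and why the
normal approximation to small-count log fold changes fails
(`examples/normal_approximation.py`).

A thin command-line interface wraps the same functions:

```
ibbpair simulate --n-features 100 --n-pairs 3 --seed 1 \
    --out counts.tsv --design-out design.tsv
ibbpair test --counts counts.tsv --design design.tsv --out results.tsv
ibbpair forest --counts counts.tsv --design design.tsv \
    --feature feature1 --out forest.tsv --plot forest.png
ibbpair baseline --method mh --counts counts.tsv --design design.tsv --out mh.tsv
```

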