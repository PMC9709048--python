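# mixedstock

Bayesian **many-to-many mixed stock analysis (MSA)** for maternally inherited
haplotype data, extended with rookery-size and inverse-distance covariates.

Mixed stock analysis asks where the animals in a mixed foraging aggregation
were born. Given mtDNA haplotype counts sampled at source populations
("rookeries") and at mixed aggregations, the many-to-many model estimates,
for every rookery *j* and mixed stock *i*, both the rookery-centric
destination probabilities δ<sub>jm</sub> (including an unsampled sink, UNK)
and the mixed-stock-centric contributions θ<sub>ij</sub>. This package
implements the modified model in which the expected contributions are
weighted by source size and by dispersal plausibility:

```
Estimate ~ SourceContribution * SourceSize * P
```

concretely

```
theta[i,j] = S[j] * delta[j,i] * P[i,j] / sum_j' S[j'] * delta[j',i] * P[i,j']
P[i,j]    = (1/D[i,j]) / sum_j' (1/D[i,j'])
```

where S is the annual nest count of each rookery and D the effective
distance (km, measured along plausible ocean-current routes) between each
mixed stock and rookery. Rookery haplotype frequencies f<sub>j</sub> and
destinations δ<sub>j</sub> carry Dirichlet priors; all count tables are
multinomial. The sampler is a data-augmentation Gibbs/Metropolis scheme
(conjugate updates for f, adaptive Metropolis on each δ simplex), run as
3 chains from random prior draws and checked with the Gelman–Rubin shrink
factor (threshold 1.08). With a matrix of ones in place of P the model
reduces exactly to the base many-to-many model, which the test suite uses
for ground-truthing.

Also included:

- **Model comparison** by posterior differencing plus the Test of Practical
  Equivalence (89% HDI against a ROPE of −0.05..0.05).
- A **distances-as-priors** comparison mode (Dirichlet(κ·P) priors on θ).
- **Orphan-haplotype filtering** (mixed-stock haplotypes never described in
  a rookery are removed and reported), rookery relative sizes, and
  haplotype (h) / nucleotide (π) diversity.
- A **simulator** with known ground truth for recovery experiments, and a
  thin `msa` CLI (`simulate`, `fit`, `compare`, `diversity`, `report`).

It is intended for researchers analysing natal origins of migratory marine
animals (the packaged example tables describe Atlantic green turtle
rookeries) and for method work on dispersal covariates in MSA.

## Worked example

`examples/03_fit_synthetic.py` simulates 4 rookeries / 2 mixed stocks / 6
haplotypes with 100 samples per site and fits the distance-weighted model:

```
posterior mean contributions (theta):
        R01    R02    R03    R04
MS01  0.592  0.260  0.080  0.068
MS02  0.143  0.682  0.124  0.051

simulated truth:
[[0.71  0.198 0.09  0.002]
 [0.124 0.768 0.105 0.002]]

max PSRF over monitored parameters: 1.022 (converged: True)
```

Each θ row is a probability vector: mixed stock MS01 is estimated to draw
59% of its members from rookery R01, matching the simulated truth up to
posterior shrinkage at n = 100 per site. The other examples cover relative
rookery sizes (`01`), dispersal weights (`02`), the equivalence test between
the base and distance-weighted models (`04`), and diversity summaries
(`05`).

From the shell:

```
msa simulate --seed 7 --out sim/
msa fit --rookeries sim/rookeries.csv --mixed sim/mixed.csv \
        --sizes sim/sizes.csv --distances sim/distances.csv \
        --mode distance_weighted --seed 42 --out run1/
msa compare run1/ run2/ --out compare.csv
```

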