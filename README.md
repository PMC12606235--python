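# callsim

Analysis of individual signatures and vocal convergence in ultrasonic
contact calls, built around dyadic call similarity.

Group-living bats (and many other mammals and birds) produce short
frequency-modulated "contact calls" that carry individual signatures.
When unfamiliar animals are housed together, their calls can converge —
become more similar — and the degree of convergence may track the strength
of the social relationship.  Testing this requires a chain of machinery:
detecting calls in ultrasonic recordings, measuring their acoustic
structure, quantifying how similar two individuals' calls are while
accounting for within-individual variability, and fitting regression
models to dyadic similarity data in which every individual appears in many
pairs.  `callsim` implements that chain, together with a synthetic-data
generator that produces recordings with known ground truth so every stage
can be validated.

## The core quantities

**Caller similarity.** A linear discriminant analysis (DFA) classifies
calls to callers using 35 acoustic measures.  For bats *i*, *j* with
centroids μᵢ, μⱼ and pooled within-class covariance Σ, the dissimilarity is
the Mahalanobis centroid distance

    D(i, j) = √((μᵢ − μⱼ)ᵀ Σ⁻¹ (μᵢ − μⱼ))

normalized per analysis to a similarity S = 1 − D/max(D) ∈ (0, 1], with
exact zeros replaced by 0.001 so a beta outcome model applies.

**Multi-membership regression.** Dyadic similarities are not independent:
each bat contributes to many pairs.  The models give every bat a random
intercept entering each of its pairs with weight ½:

    logit(μ_d) = α + X_d β + ½u_i + ½u_j,   u_b ~ Normal(0, σ²_bat)
    S_d ~ Beta(μ_d φ, (1 − μ_d) φ)

fitted by Hamiltonian Monte Carlo with analytic gradients and a
non-centered random-effect parameterization (flat priors on coefficients,
half-Student-t(3, 0, 2.5) on scales, Gamma(0.01, 0.01) on φ), with
R-hat/ESS diagnostics and posterior predictive checks.  A battery of five models with nested dyad-inclusion
rules separates the contributions of kinship, co-housing, affiliation and
food sharing; a Gaussian variant models pre/post-introduction *changes* in
similarity, alongside a Mantel test and a permuted DFA for site signatures
with bats (not calls) as the permutation unit.

## Worked example

```python
from callsim import synth, similarity

# 6 bats at 2 sites, 60 synthesized calls each, features extracted
profiles, social = synth.make_population(6, 2, seed=5)
table = synth.simulate_feature_table(profiles, 60, seed=11)

acc = similarity.classify_loocv(table)
print(f"LOOCV caller accuracy: {acc['overall']:.3f} (chance 0.167)")
S = similarity.similarity_from_table(table)
print(S.S.round(3).iloc[:3, :3])
```

prints

```
LOOCV caller accuracy: 0.933 (chance 0.167)
        bat000  bat001  bat002
bat000   1.000   0.190   0.456
bat001   0.190   1.000   0.001
bat002   0.456   0.001   1.000
```

Calls are assigned to the correct simulated caller 93% of the time
(5.6× the 1/6 chance level), confirming individual signatures; the
similarity matrix shows bat000/bat002 with relatively similar calls
(S = 0.456) while bat001/bat002 attain the maximum centroid distance and
therefore the floor similarity 0.001.

Fitting the dyadic model to simulated data with a known co-housing effect:

```python
from callsim.mm import BetaMultiMembership

dyads, truth = synth.generate_dyadic_dataset(
    25, {"cohoused": 0.5}, phi=30, sigma_bat=0.3, seed=1
)
res = BetaMultiMembership.from_dyads(dyads, ["cohoused"]).fit(
    chains=4, draws=1500, warmup=800, seed=0
)
print(res.summary_text())
```

```
BetaMultiMembership (beta outcome)
dyads: 300   bats: 25   chains: 4   draws/chain: 700
max R-hat: 1.0043
              mean      sd   ci_2.5  ci_97.5    rhat   ess_bulk   ess_tail
alpha      -0.0488  0.0818  -0.2156   0.1066  1.0026   864.4184  1041.3397
cohoused    0.5587  0.0470   0.4636   0.6446  1.0024  3301.9568  1340.5820
sigma_bat   0.3738  0.0690   0.2608   0.5257  1.0032   811.7221   976.4654
phi        26.4618  2.1796  22.4745  30.9504  1.0024  2599.7705  1203.7537
```

The 95% credible interval for the co-housing coefficient (0.46–0.64, logit
scale) covers the generating value 0.5; σ_bat and φ are likewise
recovered, and all R-hat values sit well below the 1.01 flagging
threshold.

A YAML-configured command line drives full runs
(`callsim run-all --seed 7`), executing simulate → detect → features →
similarity → models → convergence and writing CSV/JSON artifacts plus a
manifest with per-stage seeds and output hashes; identical configs yield
byte-identical outputs.

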