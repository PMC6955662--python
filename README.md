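# sced — randomization designs and randomization tests for single-case experiments

Single-case experimental designs (SCEDs, including N-of-1 trials) measure one
participant, behaviour or setting repeatedly under different conditions.  When
the order of conditions — or the moment the intervention starts — is
randomized, the experiment carries its own exact inference: under the null
hypothesis that the treatment is ineffective, the observed data would have
been the same under every other admissible assignment, so the observed test
statistic can be located in the reference distribution of the statistic over
all assignments the randomization scheme allows.  The resulting
randomization-test p-value needs no distributional assumptions and no
between-subject replication.

`sced` implements this workflow for four classical design families:

| family | randomized element | admissible set size R |
|---|---|---|
| phase designs (AB, ABAB, …) | phase change points, ≥ m occasions per phase | C(n − km + k − 1, k − 1) |
| alternation designs (CRD / ATD / RBD) | per-occasion condition labels | C(n, n_A)-type counts, run-limited subsets, (t!)^b |
| multiple baseline designs | per-unit intervention start days (staggered) | W!/(W − u)! for distinct starts |
| changing criterion designs | phase change moments per boundary | ∏ candidate-list sizes |

and the matching level-change statistics: the sum of B-phase means minus the
sum of A-phase means, (B̄₁ + B̄₂) − (Ā₁ + Ā₂); the pooled alternation
difference Ā − B̄; the multiple-baseline mean of per-unit differences
Σᵤ(B̄ᵤ − Āᵤ)/u; and the changing-criterion mean absolute deviation
Σ|C_i − m_ij|/N against the phase criteria.  P-values count reference
statistics as extreme as or more extreme than the observed one, observed
included, so p ≥ 1/R — the reciprocal of the number of admissible
assignments is the lowest attainable p-value, and a design with 1/R > α has
zero power at level α.  Reference distributions are exhaustive when R is
modest and seeded uniform Monte Carlo samples (observed included, denominator
n_mc) when R is astronomically large.  A simulation module estimates power
under configurable level-shift / noise / autocorrelation models.

## Worked example

An ABAB withdrawal design with 24 measurement occasions and at least three
occasions per phase admits 455 assignments.  Generate a synthetic series with
a 25-point level shift over 8-point noise under the realized assignment
AAAAAABBBBBBAAAAAABBBBBB, and test it:

```python
from sced import *

spec = PhaseDesignSpec(("A", "B", "A", "B"), n=24, min_phase_length=3)
labels = labels_from_changepoints((7, 13, 19), 24, spec.phase_pattern)
realized = Assignment(design_family="phase", labels=labels, change_points=(7, 13, 19))

model = EffectModel(mu=30.0, delta=25.0, sigma=8.0)
series = generate_series(spec, realized, model, seed=7)

res, ref = randomization_test(series, spec, StatisticSpec("phase_mean_diff_BA"),
                              realized, tail="right", method="exhaustive",
                              return_reference=True)
print("R =", res.R)                      # R = 455
print("observed =", round(res.observed, 2))   # observed = 48.86
print("p =", round(res.p_value, 4))      # p = 0.0044 -> reject at alpha = 0.05
```

The observed statistic 48.86 (the B-phases averaged ~49 points above the
A-phases) is exceeded or matched by only 2 of the 455 reference statistics
(min −25.8, median 27.65, max 49.19), so p = 2/455 ≈ 0.0044 and the null of
an ineffective treatment is rejected at α = 0.05.  The lowest p-value this
design could ever produce is 1/455 ≈ 0.0022.

The same run from the shell:

```
sced simulate --design phase --pattern ABAB --n 24 --min-phase-length 3 \
     --effect effect.yaml --seed 7 --out series.csv --assignment-out truth.csv
sced test --design phase --pattern ABAB --n 24 --min-phase-length 3 \
     --data series.csv --assignment truth.csv \
     --statistic phase_mean_diff_BA --tail right --method exhaustive
sced enumerate --design atd --n 6 --counts A=3,B=3 --max-run 2 --count-only   # 14
sced power --design phase --pattern ABAB --n 24 --min-phase-length 3 \
     --statistic phase_mean_diff_BA --effect effect.yaml --n-sims 1000 --seed 1
```

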