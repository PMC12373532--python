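# hyperdisc

Hyperbolic delay-discounting estimation from monetary-choice data, with a
cohort-level inference layer (robust regression, Sobel mediation,
default-prior Bayes factors) and a synthetic two-wave cohort generator that
makes the whole pipeline verifiable by parameter recovery.

The package is aimed at behavioural scientists and decision researchers who
relate individual temporal discount rates — estimated from the standard
27-item monetary-choice questionnaire — to covariates such as income shocks
and negative affect, cross-sectionally and longitudinally.

## The model

Each questionnaire item offers a smaller immediate amount $A_i$ against a
larger delayed amount $A_d$ after $D$ days.  Subjective value is hyperbolic,

$$U(A, D) = \frac{A}{1 + kD},$$

with $k$ (1/day) the individual's temporal discount rate, and choices are
probabilistic through a softmax with inverse temperature $\beta$:

$$P(\text{immediate}) = \frac{1}{1 + \exp\!\big(-\beta\,(U_\text{immediate} - U_\text{delayed})\big)}.$$

Per participant, $(k, \beta)$ is estimated by bounded maximum likelihood
($k \in [10^{-4}, 0.25]$, $\beta \in [10^{-3}, 10]$) with multi-start
L-BFGS-B; fit quality is summarised by McFadden's pseudo-$R^2$ against a
coin-flip null, $1 - \mathrm{NLL}/(n \ln 2)$, and balanced accuracy.
Downstream, $\log k$ is regressed on z-scored covariates by iteratively
reweighted least squares with Tukey bisquare weights ($c = 4.685$), mediation
is tested with the Sobel product-of-paths statistic, and nested models are
compared by Jeffreys–Zellner–Siow Bayes factors computed from each model's
$R^2$.  See `docs/methods.md` for assumptions, parameters and numerical
choices.

## Worked example

```python
import hyperdisc as hd

bank = hd.ItemBank.kirby27()          # canonical published 27-item bank
ds = hd.simulate_choices(bank, hd.ModelParams(k=0.0137, beta=1.0), seed=42)
fit = hd.HyperbolicChoiceModel(ds, bank).fit()
print(fit.summary())
```

```
Hyperbolic discounting fit
==========================
participant:        sim (t1)
trials:             27
k (1/day):          0.0152186
log k:              -4.1852
beta:               2.448
NLL (nats):         1.5680
pseudo-R2:          0.9162
balanced accuracy:  0.9688
converged:          True (25 starts)
```

The simulated chooser had a true rate of k = 0.0137/day (a typical cohort
median; it means a reward loses half its value over ~73 days); from 27
binary choices the fit recovers k = 0.0152 — within sampling error of the
truth — with near-perfect prediction of the observed choices.

A full synthetic study, end to end:

```python
cfg = hd.CohortConfig(n_participants=1145, seed=5)
tab = hd.generate_cohort(cfg, bank)                       # covariates + choices
res = hd.run_cross_section(tab.choices, tab.covariates, bank)
print(res.models["shock_demographics"].summary())
```

```
Robust linear fit (rlm-bisquare); n = 1145, df = 1139, R^2 = 0.0472  [standardized]
             coef      se       t       p
intercept  0.0174  0.0297  0.5841  0.5592
shock01    0.0904  0.0298  3.0308  0.0025
age       -0.0256  0.0298 -0.8607  0.3896
gender     0.0279  0.0298  0.9347  0.3501
education -0.1343  0.0298 -4.5101  0.0000
income    -0.1322  0.0298 -4.4368  0.0000
```

The generator planted standardized effects of +0.12 (binarised income
shock), −0.14 (education) and −0.15 (income) on log k; after fitting every
participant's discount rate from simulated choices and re-running the
regression, each coefficient comes back within two standard errors of its
planted value with the expected residual df (1145 − 6 = 1139).

The same objects are available from a shell:

```bash
hyperdisc simulate-cohort --n 200 --seed 7 --panel --out data/
hyperdisc analyze --choices data/choices.csv --covariates data/cohort.csv \
    --frame cross_section_t1 --frame panel --seed 7 --out out/
```

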