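# distopt

Evolutionary fitting of univariate Gaussian mixture models with an explicit
mode-overlap penalty.

Many one-dimensional biomedical readouts — sensory thresholds, evoked-potential
amplitudes, log expression intensities — are multimodal: the sample mixes
subgroups, each approximately Gaussian. The usual way to decompose such data is
a Gaussian mixture model (GMM)

    p(x | Θ) = Σ_{m=1..M} α_m N(x; μ_m, σ_m),    Σ α_m = 1,

fitted by likelihood maximization (EM). Likelihood, however, does not care
whether the fitted components are *separable*: EM happily returns nearly
superimposed components that fit the density well but define no usable
subgroups. `distopt` fits the GMM with a genetic algorithm whose error function
combines

* a **χ² distribution error** on B histogram bins,
  χ² = Σ_j (k_j − p_j N)² / (p_j N), with k_j the observed count and p_j the
  mixture probability of bin j, and
* a **mode-overlap error** in [0, 1]: for each component, the fraction of its
  weighted density mass at the data points covered by the strongest competing
  component, maximized over components (0 = fully separated, 1 = a component
  entirely underneath another).

The fitness is −[t·χ²/(χ²+B) + (1−t)·overlap], where the *overlap tolerance*
t ∈ (0, 1] sets the trade-off: t = 1 is pure distribution fitting, smaller t
pushes the fit toward separable modes. From the fitted model the package
derives Bayesian decision boundaries (the points where adjacent weight-scaled
component densities cross), a maximum-posterior classifier, AIC for choosing
the number of modes, and a likelihood-ratio statistic. A minimal deterministic
EM fitter is included as the comparison baseline, and built-in synthetic
scenarios make everything runnable without external data.

## Worked example

Generate a trimodal synthetic sample (true modes at 0, 5 and 10, unit sds,
equal weights, n = 1000) and fit it:

```sh
distopt simulate trimodal_separated --out sample.txt
distopt fit sample.txt -m 3 --seed 1 --out model.json
```

`model.json` contains the fitted components and diagnostics (abridged):

```
components:  mean 0.030   sd 1.146   weight 0.348
             mean 4.991   sd 0.843   weight 0.321
             mean 9.959   sd 1.171   weight 0.332
chi_square:  13.997
overlap:     0.0059
aic:         5039.04
boundaries:  [2.844, 7.129]
seed:        1
```

The three recovered means sit within 0.05 of the truth; χ² ≈ 14 on 11 bins is
consistent with sampling noise, and the overlap error below 0.01 says the
modes are essentially disjoint. The two decision boundaries near 2.8 and 7.1
cut the line into three classification cells; `distopt classify sample.txt
--model model.json` labels each point accordingly. The seed recorded in the
document reproduces the fit exactly.

Scanning the number of modes picks the true M by AIC:

```sh
distopt scan sample.txt --components 2:4 --seed 1
```

```
components  aic      chi_square  overlap
2           5419.51  265.11      0.115
3           5039.04   14.00      0.006
4           5170.15   58.67      0.992
```

The same operations are available as library calls
(`distopt.distribution_optimization`, `distopt.em_fit`, `distopt.classify`,
`distopt.aic`, ...); the CLI is a thin wrapper.

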