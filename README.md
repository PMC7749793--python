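# eegcomplexity

EEG signal complexity as a prognostic biomarker of cognitive decline.

Resting-state EEG carries two complementary kinds of spectral information:
how much power a frequency band holds (**relative band power, BP**) and how
complex the band-filtered signal is (**Tsallis entropy, TE**). In
Parkinson's disease, low baseline theta-band complexity in the *eyes-open*
condition flags patients at risk of cognitive decline over the following
years, while the same measure taken eyes-closed does not — a dissociation
that band power does not show. This package implements that full analysis
chain as a tested, reusable library:

1. **Features** — zero-phase Hann-window FIR band-pass into the canonical
   bands (δ 1–4, θ 4–8, α 8–13, β 13–30, γ 30–45 Hz); per electrode and
   band the Tsallis entropy

   *S<sub>q</sub>* = (1 − Σ<sub>i</sub> p<sub>i</sub><sup>q</sup>) / (q − 1)

   of the z-scored amplitude histogram (q = 2, B = 100 bins by default,
   amplitude-scale invariant), and relative band power
   BP<sub>b</sub> = P<sub>b</sub> / Σ<sub>b'</sub> P<sub>b'</sub>;
   electrode values are summarized into ten scalp regions of interest and
   a global median.
2. **Cognition** — reliable change indices over follow-up:
   SE<sub>M</sub> = sd(baseline)·√(1 − RS), S<sub>diff</sub> = √(2·SE<sub>M</sub>²),
   RCI = (follow-up − baseline)/S<sub>diff</sub>; per-test RCIs are
   direction-harmonized (positive = decline), averaged into four domain
   scores and an overall RCI.
3. **Inference** — multiple imputation by chained equations (m = 20,
   predictive-mean matching), stepwise forward selection of confounders on
   each imputed dataset with a strict majority vote, linear regression of
   overall RCI on each baseline EEG predictor pooled by Rubin's rules
   (Barnard–Rubin degrees of freedom), and LMG relative-importance
   decomposition of R².
4. **Group statistics** — normalized histograms, Mann–Whitney U / Welch t
   with Holm–Šidák step-down correction, eyes-closed→eyes-open transition
   contrasts (the Berger α-suppression), per-subject TE–BP correlations,
   and extreme-group regional summaries.
5. **Synthetic cohort** — a generator producing multichannel EEG (bursting
   theta pacemakers whose count sets signal complexity, narrowband rhythms,
   1/f background) and longitudinal score panels with a planted
   eyes-open-only complexity→decline coupling, configurable reliability and
   missing-at-random entries, so the entire pipeline is testable without
   patient data.

## Worked example

Simulate the default study design (42 patients, 24 controls — here at a
reduced montage of 10 electrodes and 100 Hz to keep the example fast) and
run the four pooled decline regressions:

```python
from eegcomplexity import SimulationConfig, reduced_config, simulate_cohort
from eegcomplexity.features import compute_feature_table
from eegcomplexity.pipeline import analyze_decline, regression_table

cfg = reduced_config(SimulationConfig(seed=7), n_channels=10)
cohort = simulate_cohort(cfg)
table = compute_feature_table(
    cohort.iter_recordings(groups=("PD",)), groups=cohort.groups
)
models = analyze_decline(table, cohort.panel, cohort.subjects, m=20, seed=7)
print(regression_table(models)[["model", "p_predictor", "adj_r2", "p_age"]])
```

Output (seed 7):

```
model  p_predictor  adj_r2  p_age
te_EC       0.6788  0.1610 0.0036
te_EO       0.0000  0.6216    NaN
bp_EC       0.2262  0.1889 0.0068
bp_EO       0.0684  0.2280 0.0054
```

The eyes-open theta entropy regression is highly significant
(p = 1.1 × 10⁻⁹, adjusted R² = 0.62, LMG share 0.63) while the eyes-closed
one is null (p = 0.68) — exactly the planted asymmetry: the generator
couples 3-year decline to the eyes-open complexity latent only. `p_age` is
the pooled p-value of age where the majority vote retained it as a
confounder (`NaN` = not included).

The same pipeline runs from the shell:

```bash
eegcomplexity simulate --out cohort/ --seed 7
eegcomplexity run --out results/ --seed 7
eegcomplexity stability --recording cohort/PD01_EO.tsv --seed 1 --out stab.json
```

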