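# patchdive

Foraging patch quality from penguin biologging data: dive detection and
typing from time-depth-recorder (TDR) records, GPS–dive fusion, the Index
of Patch Quality (IPQ) by inverse optimality, diving-bout analysis, and a
linear-mixed-model hypothesis battery — together with a synthetic GPS+TDR
generator with known ground truth, so every stage can be validated by
parameter recovery.

It is written for movement ecologists analysing central-place foragers
(penguins and other diving seabirds or pinnipeds) who want a reproducible,
scriptable version of the classic dive-analysis workflow: zero-offset
correction, dive metrics, k-means dive typing with Calinski–Harabasz
selection, and prey-patch inference from optimal-diving theory, e.g. to
test for an Ashmole's halo of prey depletion around a large colony.

## The model

During the bottom phase of a dive, energy gain is a diminishing-returns
power law, and the post-dive surface pause needed for recovery grows
exponentially with dive duration:

```
g(t) = a · t^x            s(u) = b · e^{c·u}
```

where `t` is bottom time, `u` dive duration, and the exponent `x` is the
**Index of Patch Quality**.  A diver maximizing its long-run gain rate
`g(u − τ) / (u + s(u))` (τ = descent + ascent transit time) chooses an
optimal duration; by inverse optimality the observed `u` of each dive
then reveals the patch quality:

```
x = (1 + b·c·e^{c·u}) (u − τ) / (b·e^{c·u} + u)
```

`b` and `c` are estimated from observed (u, s) pairs of foraging dives by
a median-based (Theil–Sen) fit of `log s = log b + c·u`.  Dives whose
pause exceeds 325 s (the inflection of the pause-frequency curve, used
as the diving-bout threshold) are excluded, as are computed values above
5.  A widely printed variant of the formula with denominator
`b·c·e^{c·u} + u` is available as `form="as_printed"`; it does not follow
from the rate-maximization above and fails the forward-model inversion
check, so the derivation-consistent form is the default (see
`docs/methods.md`).

## Worked example

```python
from patchdive import GeneratorConfig, run_pipeline

cfg = GeneratorConfig(n_birds=6, trips_per_bird=2,
                      max_range_incubation_km=18, max_range_brood_km=8)
out = run_pipeline(cfg, seed=3)          # simulate -> dives -> IPQ -> models
c = out["constants"]
print(f"pause model: b = {c.b:.2f} s, c = {c.c:.5f} /s  (n = {c.n_dives_used})")
print(out["results"].query("scope == 'all'")[
    ["model_id", "scope", "slope", "slope_se", "lrt_chi2", "p_value"]])
```

prints

```
pause model: b = 19.56 s, c = 0.01011 /s  (n = 608)
    model_id scope      slope  slope_se  lrt_chi2   p_value
           1   all   0.008676 0.0004714     268.7 2.224e-60
           2   all    0.01008  0.001735     29.87 4.615e-08
           3   all    0.09871   0.02539     14.93 0.0001113
           4   all  0.0009345   0.00225    0.1655    0.6841
           5   all   0.003511 0.0009504     8.883  0.002878
           6   all     -9.168     1.173      12.7 0.0003654
           7   all      7.334    0.8732     16.45 4.994e-05
```

The pause constants recover the generator's `b = 20 s, c = 0.01 /s`.
Models 1–3 validate the IPQ (wigglier bottom phases, larger bouts and
in-bout dives all score higher).  Model 4's distance slope (the halo) is
positive but not significant at this 6-bird scale — the dedicated
recovery study in `tests/test_acceptance.py` shows it is estimated within
its standard error at realistic sample sizes.  Model 5 recovers the
seasonal increase in near-colony patch quality, model 6 the shallower
incubation foraging dives, and model 7 the longer incubation trips.

A command-line interface mirrors the stages:

```sh
patchdive simulate --seed 1 --out data/          # GPS, TDR, truth tables
patchdive dives    --tdr-csv data/tdr.csv --out dives.csv
patchdive classify --dives-csv dives.csv --out typed.csv --seed 1
patchdive ipq      --dives-csv typed.csv --out-dir ipq/
patchdive pipeline --seed 1 --out results/       # everything at once
```

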