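# uadese

Response-surface modelling and genetic-algorithm optimization for
ultrasound-assisted deep-eutectic-solvent extraction (UADESE) of raspberry
anthocyanins — the complete desk workflow of an extraction-optimization
study, as a tested Python package.

It is aimed at natural-product and food chemists running designed
extraction experiments: you bring a Box–Behnken design table with measured
yields; the package fits the response surface, judges it by ANOVA, finds
and rounds the optimal operating point, and covers the assay arithmetic of
the downstream purification (pH-differential quantification, partition
coefficients, counter-current chromatography bookkeeping, HPLC purity).

## The model

Four factors — water content in the solvent $X_1$ (%), ultrasonic power
$X_2$ (W), extraction temperature $X_3$ (°C) and extraction time $X_4$
(min) — are coded so their low/center/high levels map to −1/0/+1, and the
anthocyanin yield $Y$ (mg/g) is fitted with the full second-order
polynomial

$$Y = \beta_0 + \sum_j \beta_j X_j + \sum_j \beta_{jj} X_j^2
      + \sum_{i<j} \beta_{ij} X_i X_j + e$$

by ordinary least squares over a 29-run Box–Behnken design (24 edge runs +
5 center replicates). The ANOVA uses partial (drop-one-term) sums of
squares and splits the residual into lack of fit and pure error using the
center replicates. Terms failing a significance threshold (default
α = 0.05) are removed; the reduced surface is then maximized over the
coded cube $[-1,1]^4$ two ways — a real-coded genetic algorithm
(rank scaling, stochastic-uniform selection, elitism, scattered crossover,
shrinking Gaussian mutation) and the closed-form stationary point of the
quadratic — which must agree.

Supporting assay formulas:

- pH-differential yield: $c = \Delta\Delta A \cdot M_\omega \cdot DF
  \cdot 1000 \cdot V / (\varepsilon \cdot L \cdot m)$, as
  cyanidin-3-glucoside ($M_\omega$ = 449.2 g/mol, ε = 26 900 L/(mol·cm));
- HPLC purity $w_i = f_i A_i / \sum_j f_j A_j$;
- partition coefficient $K = A_{\text{upper}}/A_{\text{lower}}$ with the
  $K \in [0.5, 2]$ solvent-system suitability window;
- stationary-phase retention $S_r = (V_s/V_c) \times 100\%$.

## Worked example

```sh
uadese run --alpha 0.05 --seed 42 --out results/
```

or equivalently `python analysis/02_optimize_extraction.py`, prints:

```
full model: R2 = 0.9371, R2_adj = 0.8742
reduced model terms: Intercept, water_content, extraction_temperature, extraction_time,
  water_content^2, ultrasonic_power^2, extraction_temperature^2, extraction_time^2,
  water_content*extraction_time, ultrasonic_power*extraction_temperature
optimum (coded, analytic stationary point): -0.0734, +0.0952, +0.1935, +0.1761
optimum (natural): water_content = 29.27 %, ultrasonic_power = 209.52 W,
  extraction_temperature = 50.97 degC, extraction_time = 31.76 min
predicted yield at optimum: 1.3247 mg/g
GA cross-check: best fitness 1.3247 mg/g (gap to analytic 4.69e-06)
rounded operating point: water_content = 29 %, ultrasonic_power = 210 W,
  extraction_temperature = 51 degC, extraction_time = 32 min
predicted yield at rounded point: 1.3245 mg/g
```

Reading: the quadratic explains 94% of the yield variation; water content
and temperature dominate (strong negative curvature — yield rises, peaks,
falls); the surface's interior maximum predicts ~1.325 mg/g of
anthocyanins at 29% water, 210 W, 51 °C and 32 min, and rounding the
settings to what the equipment can actually hold costs under 0.001 mg/g.

The bundled 29-run design table ships as package data
(`uadese/data/bbd_29run_yields.csv`); pass `--design your_table.csv` to
analyse your own experiment. The `analysis/` scripts walk the full study
in order: surface fitting and ANOVA, optimization, assay calculations, and
a truth-known synthetic validation of the whole chain.

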