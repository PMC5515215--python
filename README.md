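# quorumflow

Analysis toolkit for community quorum sensing (QS) and quorum quenching
(QQ) in activated-sludge biofilms. Engineered sludge communities both
produce N-acyl homoserine lactone (AHL) signals and enzymatically
destroy them; the balance between the two activities tracks — and may
drive — the transition between loose floccular biomass and dense
microbial granules. `quorumflow` implements the numerical core of that
kind of study for microbial ecologists and bioprocess researchers:

* **V6 tag profiling** (`quorumflow.tags`): scan sequencing reads with
  the universal degenerate 16S primer `5'-CGACRRCCATGCANCACCT-3'`,
  extract the 33-nt V6 tag downstream of each match as a taxon proxy,
  apply the two artefact filters (≥ 2 covering reads; no single read
  type ≥ 50% of coverage), and build per-sample abundance tables with
  top-N selection (default 50).
* **Degradation kinetics** (`quorumflow.kinetics`): half-lives of
  spiked AHLs under zero-order (t½ = C₀/2k) or first-order
  (t½ = ln 2 / k) kinetics, adsorption partitioning from the
  heat-inactivated and synthetic-wastewater controls, Welch t-tests
  with Holm–Šidák correction, and the half-life vs acyl-chain-length
  trend (Spearman).
* **LC-MS/MS quantification** (`quorumflow.quant`): matrix-matched
  linear calibration over 0.5–200 µg/l, LOD/LOQ at signal-to-noise 3.3
  and 10, extraction-efficiency correction from 5 and 50 µg/l spikes,
  and MRM identity confirmation (retention time, two transition ions,
  intensity ratio).
* **Isolate phenotyping** (`quorumflow.isolates`): classify isolates as
  AHL producer / quencher / both / neither from biosensor + LC-MS/MS
  evidence and 2-h residual-AHL assays, with category and
  quench-spectrum summaries.
* **Community–signal correlation** (`quorumflow.community`): Pearson
  correlation of taxa abundances with AHL concentration series,
  Benjamini–Hochberg FDR, positive/negative/neutral classification,
  complete-linkage Euclidean clustering, and floccular-vs-granular
  stage comparison.
* **Synthetic data** (`quorumflow.synthetic`): seeded generators for
  every input above with planted ground truth, so the whole pipeline is
  testable without external data.

Model-fitting components follow the scikit-learn estimator convention
(`FirstOrderDecayFitter`, `CalibrationModel`, `CorrelationAnalysis`,
`TaxaClusterer`: `fit()`, fitted attributes with a trailing underscore,
`get_params`/`set_params`), with thin module-level functions over them.

## Worked example

Estimate the enzymatic half-life of C6-HSL from a simulated spiking
experiment (5 µM spike, 20% adsorption, 10% measurement noise):

```python
import numpy as np
from quorumflow.synthetic import DecaySimPlan, gen_decay
from quorumflow.kinetics import (adsorption_fraction, fit_first_order,
                                 fit_zero_order, select_model)

plan = DecaySimPlan(ahl="C6-HSL", order=1, rate_constant=np.log(2) / 1.95,
                    adsorption_fraction=0.2, noise_cv=0.1, seed=42)
series = gen_decay(plan)   # live, heat_inactivated, sww_control

frac, _ = adsorption_fraction(series["sww_control"], series["heat_inactivated"])
fit = select_model(fit_zero_order(series["live"]), fit_first_order(series["live"]))
print(f"adsorption fraction: {frac:.3f}")
print(f"selected order: {fit.order}")
print(f"half-life: {fit.half_life:.2f} +/- {fit.half_life_se:.2f} h "
      f"(r^2 = {fit.r_squared:.3f})")
```

Output:

```
adsorption fraction: 0.215
selected order: 1
half-life: 2.08 +/- 0.34 h (r^2 = 0.934)
```

The adsorption estimate (21.5%) recovers the planted 20% instantaneous
loss to biomass; model selection picks first-order kinetics and the
fitted half-life of 2.08 ± 0.34 h brackets the planted 1.95 h — a
single noisy series; averaging replicates tightens the estimate (see
the acceptance script below).

A full synthetic demonstration of every stage, written as TSV files
with provenance headers:

```sh
quorumflow all --seed 1 --out demo_out
```

Other subcommands (`tags`, `kinetics`, `quant`, `screen`, `correlate`)
run single stages on user-supplied TSV/FASTQ inputs; see
`quorumflow <cmd> --help`.

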