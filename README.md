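# mihcquant

Quantitative analysis of the tumor immune microenvironment from multiplex
immunohistochemistry (mIHC), focused on natural-killer (NK) cells and their
receptors in gastric-cancer tissue-microarray (TMA) cohorts.

mIHC yields a per-cell table of marker intensities (here an 11-antibody
panel: CD57, NKG2A, CD16, HLA-E, CD3, CD20, CD45, CD68, CK, SMA, Ki-67) per
TMA core, plus a cytokeratin(CK)-positive tumor-region geometry. `mihcquant`
turns those inputs into immune-cell densities, composition fractions,
association statistics and a survival screen:

1. **Thresholding** — per-channel positivity cut-offs, either manual or
   derived from the bimodal intensity distribution: a two-component Gaussian
   mixture is fitted on log-intensity and the threshold is the decision
   boundary where posterior membership in the two components is equal.
   Positivity is strict: a cell is positive iff intensity > threshold.
2. **Hierarchical phenotyping** — an ordered lineage cascade on CD45+ cells:
   CD3+ → T cell (CD57± recorded), else CD20+ → B cell, else CD57+ →
   CD57+ NK cell, else CD68+ → macrophage, else other immune. CD45− cells
   are tumor cells if CK+. CD16 (activating) and NKG2A (inhibitory) receptor
   statuses are attached to every immune cell, giving non-exclusive subsets
   such as CD57+NKG2A+ NK cells. MSS/MSI-L/MSI-H classification (0 / 1 / ≥2
   unstable microsatellite markers of 5) and the five-subtype molecular
   cascade (EBV+ → MSI-H → EMT-like → non-EMT p53± ) are included.
3. **Compartmentalization** — cells inside (boundary-inclusive) the CK+
   tumor region are *tumoral*, all others *stromal*; densities are counts
   per mm² of the matching compartment area, "total" densities use the
   whole core.
4. **Association statistics** — Spearman rank correlations among immune and
   HLA-E+ tumor-cell densities, Welch t-tests across molecular/clinical
   strata, simple linear fits. Unadjusted p-values, significance at p < 0.05.
5. **Survival screen** — per variable × compartment × endpoint (OS, PFS):
   the covariate is dichotomized at the maximally selected rank-statistic
   cutpoint (the split maximizing the absolute standardized log-rank
   statistic over all splits leaving ≥ `minprop` of patients per side), and
   a univariate Cox proportional-hazards model (Newton–Raphson on the
   partial likelihood, Efron or Breslow ties) reports the hazard ratio of
   high vs low with a Wald 95% CI. Kaplan–Meier estimation and the log-rank
   test are implemented from first principles and oracle-tested.

Because raw cell-level data of such studies are rarely deposited, the
package ships a first-class **synthetic cohort generator** that emulates the
statistical structure of a ~55-patient gastric-cancer TMA: immune
composition (T 65.5%, macrophage 25.4%, B 5.3%, CD57+ NK 3.8% of CD45+
cells; NK cells are 20% of CD45+CD57+ cells), receptor co-expression rates,
bimodal log-normal channel intensities, tumor-region geometry, HLA-E
expression linked to intratumoral immune densities, and proportional-hazards
outcomes linked to tumoral NK density. Generator truth labels are written to
separate files so recovery tests cannot leak.

## Worked example

```python
import mihcquant as mq

cfg = mq.SimConfig(seed=1)                       # 55-patient defaults
cells = mq.simulate_pooled_cells(cfg, 210_000)   # ~105k CD45+ cells
panel = mq.derive_panel(cells, seed=1)           # mixture thresholds
calls = mq.gate_cells(cells, panel)              # cascade phenotyping
comp = mq.pooled_composition(calls)
print({k: round(100 * v, 1) for k, v in comp.items()})
```

prints

```
{'T_of_CD45': 65.6, 'B_of_CD45': 5.4, 'NK_of_CD45': 3.9,
 'macrophage_of_CD45': 25.2, 'other_immune_of_CD45': 0.0,
 'NK_of_CD45_CD57': 20.4, 'T_of_CD45_CD57': 79.6}
```

i.e. after simulating intensities, deriving thresholds from the intensity
distributions alone and gating, the recovered composition matches the
configured cohort: T cells dominate the CD45+ infiltrate, CD57+ NK cells are
the rarest population, and four fifths of CD45+CD57+ lymphocytes are CD57+
T cells rather than NK cells.

The full pipeline (simulate → gate → quantify → associate → screen) runs
from the shell:

```bash
mihcquant run-all --out results_dir --seed 1
```

writing `thresholds.csv`, `gated_cells.csv`, `core_quant.csv`,
`analysis_table.csv`, `correlations.csv`, `comparisons.csv`,
`survival_screen.csv` and a JSON run manifest. Identical config + seed gives
byte-identical outputs.

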