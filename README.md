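# metaconc

What sets the concentrations of metabolites inside cells, beyond the
kinetics of the enzymes that make and consume them?  One systematic answer:
their physico-chemical properties.  Across organisms and growth conditions,
hydrophobic and uncharged small molecules sit at consistently lower
intracellular concentrations than polar, charged ones — plausibly because
high concentrations of greasy metabolites leak through membranes, aggregate,
and bind non-specifically.

`metaconc` implements the complete analysis behind that observation, for
metabolomics datasets of simultaneously measured concentrations:

* **Descriptor engine** (`metaconc.chem`) — from SMILES or SDF structures:
  rule-based protonation to the pH-7 majority microspecies, seeded 3D
  embedding (RDKit ETKDG), and a Shrake–Rupley solvent-accessible surface
  (Bondi radii, 1.4 Å probe, deterministic Fibonacci point lattice, 960
  points/atom) split into polar (N, O, and their hydrogens) and non-polar
  area.  Eight parameters per metabolite: MW, PSA, NPSA, NCA (charged
  atoms), HBI (H-bond donors + acceptors), NRB (rotatable bonds), and
  externally predicted LogP/LogS consumed as input columns.
* **Statistics** (`metaconc.stats`) — per condition, Pearson R between each
  parameter and log10 concentration; Monte-Carlo permutation p-values for R²
  (10⁵ shuffles, strict inequality); Benjamini–Hochberg FDR control at 0.01
  over the single family of all condition × parameter tests; leave-one-out
  OLS prediction of log10 concentration from NPSA and NCA, scored as the
  fraction of predictions within one order of magnitude against a
  mean-concentration baseline; subgroup correlations (amino acids,
  phosphorylated nucleotides), fold-change per phosphate group, and the
  model-implied concentration span across a parameter's range.
* **Synthetic cohorts** (`metaconc.synthetic`) — multi-condition compendia
  with log10 c = β₀ + β_NPSA·NPSA + β_NCA·NCA + N(0, σ), plus ~35 packaged
  real metabolite structures, so the whole pipeline is testable offline.
* **I/O and CLI** (`metaconc.io`, `metaconc.cli`) — TSV readers/writers
  (mol/L, `NA` for missing) and a `metaconc` command with `descriptors`,
  `correlate`, `predict`, `simulate` and `run` subcommands.

The model at the core is ordinary least squares on the log scale,

    log10 c_i = β0 + β1·NPSA_i + β2·NCA_i + ε_i,

fit leaving each metabolite out in turn; significance of the single-parameter
correlations comes from the permutation null of R², not from parametric
assumptions.

## Worked example

```python
from metaconc import GeneratorConfig, generate_table, filter_small, loo_predict

descriptors, conditions, truth = generate_table(GeneratorConfig(seed=1))
table, dropped = filter_small(conditions[0], descriptors, mw_max=300)
report = loo_predict(table, features=("NPSA", "NCA"))
print(f"n={len(report.rows)}  R2={report.r2_fit:.2f}  "
      f"within 10x: {report.accuracy_1oom:.0%} (baseline {report.baseline_1oom:.0%})  "
      f"mean deviation {report.mean_fold_deviation:.1f}-fold")
```

prints

```
n=93  R2=0.37  within 10x: 75% (baseline 72%)  mean deviation 4.6-fold
```

i.e. in this condition the two descriptors explain 37% of the variance in
log concentrations, and 75% of leave-one-out predictions land within one
order of magnitude of the measurement, versus 72% for always predicting the
mean concentration; the typical miss is 4.6-fold.  (Averaged over all 21
conditions — see `analysis/04_loo_prediction.py` — R² is 0.43 and the
accuracy gap widens to 81% vs 67%.)

The numbered drivers under `analysis/` run the full study on the synthetic
compendium and the packaged structures:

```
python analysis/01_simulate_compendium.py   # 93 metabolites x 21 conditions
python analysis/02_fixture_descriptors.py   # descriptors for real structures
python analysis/03_correlation_grid.py      # 168-test grid, permutation + FDR
python analysis/04_loo_prediction.py        # per-condition LOO scoring
python analysis/05_subgroup_effects.py      # amino acids, fold per phosphate
```

Outputs land under `results/`.

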