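# Methods

## The question and the model

Metabolomics platforms can measure dozens of intracellular metabolite
concentrations simultaneously, per growth condition.  The analysis asks
whether simple physico-chemical properties of the metabolites — above all
hydrophobic surface and charge — explain systematic variation in those
concentrations.  Two layers of inference are used:

1. **Screening.**  For each condition and each of eight parameters (MW,
   PSA, NPSA, NCA, HBI, NRB, LogP, LogS), the Pearson correlation R between
   the parameter and log10 concentration, with a permutation p-value for R²
   and FDR control across the whole grid.
2. **Prediction.**  A two-variable linear model, log10 c = β₀ + β₁·NPSA +
   β₂·NCA, evaluated leave-one-out so each metabolite is predicted by a
   model that never saw it.

Everything is done on the log10 scale: concentrations span many orders of
magnitude, the "within one order of magnitude" accuracy criterion is
symmetric only on logs, and the mean-concentration baseline is therefore
the arithmetic mean of log10 concentrations (the geometric mean
concentration).

## Descriptors

**Protonation.**  Concentrations are cytosolic, so structures are first
converted to their pH-7 majority microspecies by functional-group rules
rather than a pKa model: carboxylic and sulfonic acids are deprotonated
(−1); each phosphate loses up to two P–OH protons (monoesters −2, diesters
−1, matching pKa₂ ≈ 6.5 and pKa₃ ≈ 12); aliphatic amines and guanidines are
protonated (+1).  Aromatic nitrogens (imidazole pKa ≈ 6, so histidine stays
neutral), amides, anilines, thiols and alcohols are untouched.  The rules
match only neutral groups, so the operation is idempotent.  NCA then counts
atoms with nonzero formal charge in this canonical resonance structure — a
carboxylate contributes one charged oxygen, a zwitterionic amino acid
counts 2.

**Hydrogen-bond inventory.**  HBD counts hydrogens on N/O (water = 2
donors), HBA counts N and O heavy atoms except positively charged nitrogens
whose lone pair is engaged; HBI = HBD + HBA.  This is the Lipinski-style
inventory; toolkits differ in these conventions, which is why the counters
are implemented here explicitly rather than taken from a library default.

**Rotatable bonds.**  Single, non-ring bonds between two non-terminal heavy
atoms, excluding amide C–N bonds (partial double-bond character).

**Surface areas.**  A single 3D conformer is generated per molecule with
RDKit's ETKDG at a fixed random seed, followed by MMFF94 (or UFF)
relaxation; the same (structure, seed) pair always gives identical
coordinates.  Areas are solvent-accessible Shrake–Rupley areas: each atom's
sphere (Bondi vdW radius + 1.4 Å water probe) is sampled with a
deterministic Fibonacci golden-angle lattice of 960 points; a point is
exposed iff it lies strictly outside every other expanded sphere (boundary
points count as buried — a deterministic tie-break); the atom's area is its
exposed fraction times 4π(r+probe)².  At 960 points the error against the
closed form for an unoccluded sphere is below 1% (in practice ~10⁻¹⁴,
because every lattice point of an isolated atom is exposed; occluded
configurations converge as the point density grows and are verified against
the spherical-cap closed form).  PSA sums the per-atom areas of N, O and
their hydrogens; NPSA = total − PSA, so the partition is exact by
construction.  The choice of the *accessible* rather than the
molecular/solvent-excluded surface is deliberate: the probe-expanded
Shrake–Rupley area is the standard numerical definition, is deterministic,
and preserves the between-molecule ordering that the correlations use;
absolute areas from excluded-surface tools would differ by a systematic
offset without affecting rank-scale conclusions.

**LogP/LogS** are octanol/water partition and aqueous solubility estimates
from external predictors; they are consumed as input columns and never
recomputed here.

## Statistics

**Complete cases.**  Each (condition, parameter) test uses its own
complete-case subset: metabolites missing either the concentration or that
parameter are dropped for that test only.  The MW ≤ 300 Da filter removes
bulky cofactors (NAD(P)H, CoA esters, triphosphates), which face different
selective pressures; on the packaged structure set it retains 92% of
metabolites.

**Permutation test.**  The parameter column is shuffled 10⁵ times against
the fixed concentrations; p is the fraction of shuffles with R² strictly
greater than observed.  No +1 pseudo-count is added, so the smallest
reportable p is 0, to be read as "< 10⁻⁵".  A 10⁻¹² tolerance on the strict
comparison keeps permutations whose R² is mathematically equal to the
observed one (e.g. order reversals at small n) from being counted through
floating-point summation noise.  Shuffling is vectorised in chunks of
20,000 permutations; a full 168-test grid at 10⁵ shuffles runs in ~40 s on
one CPU.

**FDR.**  Benjamini–Hochberg step-up (statsmodels) at rate 0.01 over the
single flattened family of all condition × parameter tests — 21 × 8 = 168
in the compendium configuration.  Degenerate cells (constant parameter,
< 3 cases) are recorded as NA and excluded from the family.  The test suite
checks the flags against an independently coded brute-force step-up.

**LOO prediction.**  OLS via `numpy.linalg.lstsq` with an explicit rank
check; n fits of size n−1.  Reported per condition: the fraction of
|residual| ≤ 1 (accuracy), the same criterion around the mean log10
concentration (baseline), 10^(mean |residual|) as the mean fold deviation
(the alternative averaging, mean of 10^|residual|, is also reported; the
two differ by Jensen's inequality and the package treats the first as
primary), the squared correlation of predicted vs observed, and metabolites
deviating more than 30-fold (the threshold that operationalises
"consistently deviating" metabolites such as glutamate in real data;
configurable).

**Subgroups.**  Correlations restricted to packaged id lists (20
proteinogenic amino acids; mono/di/tri-phosphate nucleotides).  The
fold-change per phosphate group is 10^slope from OLS of log10 c on
phosphate count; the span effect of a parameter is 10^(|slope|·range), the
model-implied fold change from one end of the observed parameter range to
the other.

## The synthetic generator

`generate_table` draws NPSA ~ U(20, 220) Å², NCA ~ categorical(0..4 with
weights 0.30/0.30/0.20/0.12/0.08), MW ~ U(50, 300) Da, and log10 c =
−3.5 − 0.01·NPSA + 0.25·NCA + N(0, 0.75) independently per condition
(93 metabolites × 21 conditions by default).  The defaults are the study
conditions the rest of the package is exercised under: they imply R² ≈ 0.43
for the NPSA+NCA model, ≈ 80% order-of-magnitude accuracy, a ~4-fold mean
deviation and a ~100-fold concentration span across the 200 Å² NPSA span —
the regime reported for comprehensive bacterial datasets.  The NPSA range
is set to a 200 Å² span (within the realistic 0–300 Å² envelope) precisely
because, at β = −0.01/Å², that is the span that produces the ~100-fold
concentration range.  Companion descriptors (PSA, HBI, NRB, LogP, LogS) are
filled with plausibly correlated values; the vectors need not correspond to
realizable molecules, and concentrations depend on NPSA and NCA only.
Noise is Gaussian in log10 space (log-normal concentrations).

What passing on synthetic data does *not* show: real measurement error is
not i.i.d. Gaussian on logs (platform-specific, partly systematic —
extraction can bias against lipophilic compounds), real descriptors are
mutually constrained by chemistry, and real effect sizes vary between
organisms and platforms.  The generator validates the machinery and its
calibration, not the biological claim.

## Numerical and design choices

* Seeds: every stochastic component (conformer embedding, permutation
  shuffles, the generator) takes an explicit seed; the grid derives
  per-test seeds from one master seed via a `default_rng` stream.
  Re-running the pipeline with the same config is byte-identical.
* Replicate measurements within a condition should be collapsed (median)
  before the table is read; the readers treat each column as one condition.
* TSV dialect: tab-separated, `.` decimal, `NA` missing; concentrations in
  mol/L.
* Degenerate inputs (constant parameter, < 3 points, rank-deficient LOO
  design, single phosphate level) raise typed errors rather than returning
  NaN silently; the pipeline records skipped cells and aborts with a
  stage-labelled error on structural failures, removing partial outputs.
* Problem sizes in the shipped drivers and acceptance script (93 × 21
  compendium, 10⁵ permutation shuffles in the acceptance run, 2×10⁴ in the
  quick driver, 50-replicate recovery checks) were chosen so each analysis
  completes in seconds to tens of seconds while keeping Monte-Carlo error
  well inside the asserted tolerances.

## Known limitations

* The protonation rules cover the functional groups of central metabolism;
  exotic groups (e.g. N-oxides, enols with unusual pKa) fall through to
  "unchanged".
* One conformer per molecule: surface areas of very flexible molecules are
  single-conformer estimates, not ensemble averages.
* LogP/LogS must be supplied externally; without them those two columns of
  the grid are NA and the FDR family shrinks accordingly.
* Each condition is analysed independently; no mixed-effects pooling across
  conditions, and no causal interpretation of the correlations.
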