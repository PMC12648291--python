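# Methods

## The internal-symmetry statistic

Bacterial ferredoxins fold as two tandem β-α-β half-domains related by an
ancient gene duplication.  The package quantifies the residual symmetry of a
protein as the cophenetic distance between its two halves: place the N- and
C-terminal halves of every protein in a collection as separate leaves on one
phylogenetic tree with branch lengths in substitutions/site, and sum the
branch lengths along the path connecting a protein's two half-leaves.  A
recently duplicated (symdoxin-like) protein has near-identical halves and a
paired distance near zero; anciently diverged halves give large distances.
Flags are reported at distance < 1 and < 2; both thresholds are
configuration values.

Pipeline conventions:

* **Gap filtering.** Alignment columns whose gap fraction is *strictly*
  greater than 10% are removed (a column at exactly 10% is kept).  The
  operation is idempotent and returns the old→new column map.
* **Midpoint split.** Each row is cut at column `floor(n_cols/2)` of the
  filtered alignment.  For curated cases a fixed cut column, an
  `(n_end, c_start)` pair (which excises an inter-domain linker), or a
  per-parent mapping may be supplied.  Halves are suffixed `_N`/`_C`.
* **Stacking.** The N and C blocks are stacked into one alignment by
  treating column *i* of each block as homologous — the premise of the
  internal-repeat comparison.  The narrower block is padded with trailing
  gap columns.
* **Distances.** p-distance over columns where both rows are ungapped, or
  its Poisson correction `−ln(1−p)` (default).  A pair with no comparable
  columns, or `p ≥ 1` under the Poisson model, is an error rather than a
  silent saturation value.
* **Trees.** In-package neighbor joining (Saitou–Nei Q-matrix, standard
  two-decomposition branch lengths, negative estimates clamped to zero,
  ties broken by lexicographic label pair) so that desk-scale runs need no
  external software.  Externally inferred maximum-likelihood trees can be
  imported via Newick and used unchanged — the cophenetic statistic is
  agnostic to how the tree was built, only its branch-length scale matters.

## Charge properties

Net charge is the Henderson–Hasselbalch sum over ionizable groups
(N-terminus, His, Lys, Arg positive; C-terminus, Asp, Glu, Cys, Tyr
negative).  Free cysteines are treated as ionizable: pI is a property of
the apo sequence even though the thiols are cluster ligands in the
holo-protein.  The default pKa table (N-term 7.5, C-term 3.55, D 4.05,
E 4.45, C 9.0, Y 10.0, H 5.98, K 10.0, R 12.0) reproduces the widely used
Biopython table; any table can be substituted through `PKaSet`.

The isoelectric point is found by bisection on pH ∈ [0, 14], narrowing the
bracket below 10⁻⁴ pH.  Because net charge is strictly decreasing in pH the
midpoint tracks a brute-force fine-grid scan to ~10⁻³ pH; a charge-based
stopping rule alone would leave up to ~0.1 pH of slack on shallow-titrating
sequences, so the bracket criterion governs.

Anaerobe enrichment is the observed count of short (<60 aa) sequences in
anaerobic hosts divided by the independence expectation
`n_short · n_anaerobe / n_total`.  A two-sided Fisher exact p-value is
available as supplementary output.

## Curve models

* **Two-state van't Hoff melt** (signal vs temperature, Kelvin internally;
  the CLI accepts Celsius):
  `y(T) = [(a_N+b_N T) + (a_D+b_D T)·E]/(1+E)` with
  `E = exp[−ΔH/R(1/T − 1/Tm)]` and R fixed at 1.9872×10⁻³ kcal K⁻¹ mol⁻¹.
  Evaluation uses the logistic form `y = (1−s)·baseline_N + s·baseline_D`,
  `s = expit(−ΔH/R(1/T−1/Tm))`, which is overflow-safe far from Tm.
  Fits initialise baselines from the first/last three points, Tm at the
  steepest observed slope, ΔH = 50 kcal/mol.  A fit whose transition
  amplitude at Tm is under 5% of the data range, or whose Tm falls outside
  the measured range, raises a non-convergence error carrying the best
  iterate — this is how monotone featureless input is rejected.
* **Hill melt.** The signal is normalised to an unfolded fraction with
  linear baselines through the first/last three points, then
  `θ(T) = T^h/(T^h + Tm^h)` is fitted (evaluated as
  `expit(h·(ln T − ln Tm))` for stability at large h).  θ(Tm) = 0.5
  exactly, so Tm means the half-transition temperature in both melt models.
* **Nernst titration.** Fraction reduced
  `f(E) = 1/(1+exp[(E−Em)/(RT/nF)])`, n = 1, T = 298 K by default
  (RT/nF ≈ 25.7 mV).  A pure-exponential variant without the leading
  "1 +" is evaluable behind `form="as_printed"` for auditability; it is
  not a fraction outside the reduced plateau (f(Em) = 1, unbounded below
  Em) and is never used for fitting.  `fit_nernst` models absorbance as
  `a_ox + (a_red − a_ox)·f(E)` — plateaus are fitted, not imposed — and
  requires both plateaus to be approached (f ≥ 0.9 and ≤ 0.1 at the window
  ends), otherwise the transition is declared unbracketed.  The fit is
  order-agnostic, so reduction- and oxidation-direction sweeps of the same
  couple give the same Em.
* **First-order decay.** `A(t) = A₀e^{−kt}`, initialised log-linearly and
  refined on the raw absorbances; half-life = ln2/k (minutes).  A
  non-negative log-linear slope is flagged as non-decaying.
* **Spectral decomposition.** A composite spectrum is projected onto
  monomer and dimer basis spectra by nonnegative least squares on a shared
  field grid; collinear bases are rejected.  The monomer:dimer *weight*
  ratio equals the molar ratio only up to per-basis intensity scale
  factors (a dimer carries two clusters); these scales are caller-supplied
  and default to 1, so the reported ratio is a signal-weight ratio unless
  the caller provides calibrated scales.

All fits use scipy trust-region least squares (`xtol = ftol = gtol =
1e-10`) with the fixed initialisations above and no random restarts, so
results are deterministic.  Standard errors come from the Jacobian at the
solution.

## Synthetic-data generators

Generators are pure functions of (parameters, seed) and always emit their
ground truth.

* **Duplication–divergence families** (default 30 families, 26-residue
  halves, `VKK` linker — the linker of the designed symdoxins; `DKA` is the
  other natural choice).  An ancestral half with one cluster motif is
  duplicated, fused, and each half accumulates substitutions independently:
  every mutable site flips with probability `rate_per_half` to a uniformly
  chosen different residue.  The motif's four cysteines and its CP
  dipeptide are immutable, and non-motif positions are drawn from (and
  mutate within) the 19-letter non-Cys alphabet, so every simulated
  sequence carries exactly two scanner-detectable motifs — mining failures
  cannot confound the symmetry statistic.  The motif sits at a fixed
  position (default 7, as in the designed semidoxins, where it is
  positionally conserved); this bounds the p-distance of any pair of halves
  strictly below 1, keeping the Poisson correction defined even between
  unrelated families.  The truth table records per-family rates and exact
  half boundaries, so analyses can excise the linker with an
  `(n_end, c_start)` split.
* **Curves.** Direct model evaluation plus i.i.d. Gaussian noise with σ
  expressed as a fraction of the clean signal's dynamic range (scale
  invariance).  Defaults: melt grid Tm ± 40 K (40 points), titration grid
  Em ± 150 mV (25 points), decay grid 0–600 min (61 points) with a 120-min
  half-life, matching the magnitudes of the real experiments.
* **Spectra.** Basis line shapes are sums of first-derivative Gaussian
  lines (the natural line shape of field-modulated CW-EPR); the monomer
  basis is a sharp two-line feature, the dimer basis broader split
  features, mixed 2:1 by default.
* **Genome tables.** Joint (short, anaerobe) labels are drawn from the
  four-cell distribution whose joint probability is `fold` times the
  product of the marginals.  Defaults N = 5000, p_short = 0.05,
  p_anaerobe = 0.08, fold = 10: a ten-fold plant requires
  `fold · p_anaerobe ≤ 1`, so the anaerobe marginal is set just inside that
  bound while keeping short sequences rare, which makes ~80% of short
  sequences land in anaerobes — "nearly all", as observed for real short
  ferredoxins.  Emitted sequences are consistent with their labels (short:
  one motif, <60 aa; long: two motifs, ≥60 aa).

What the generators deliberately do **not** emulate: insertions/deletions
(so alignment is trivial and gap handling is exercised only through crafted
fixtures), non-star family phylogenies, compositional biases of real
proteomes, correlated instrument noise, and baseline drift.  Passing tests
therefore demonstrate correctness of the estimators under the stated
models, not robustness to alignment error or structured noise in real data.

## Numerical and design choices

* Sequence validation is strict: the 20 standard residues only; B/Z/X/U
  are rejected at parse time with the offending position rather than
  silently translated.
* Classification thresholds — semidoxin-like size ≤ 40 aa with exactly one
  motif, "short" < 60 aa (strict) — are configuration values; the size
  cutoffs bracket the ~30 aa semidoxin scale with slack for termini and
  linkers.
* The motif template `C..C..C...CP` is configurable; it abstracts the
  spacing common to the designed and natural semidoxin sequences.  Matches
  are non-overlapping, leftmost-first.
* Newick round-trips preserve topology and branch lengths; trees from any
  source are accepted as long as the half-leaves are named
  `<parent>_N`/`<parent>_C`.
* The acidic-pI cutoff in the symmetry/pI report defaults to 5.0 and is a
  configuration value, not a biological claim.
* Desk-scale problem sizes throughout (tens of families, hundreds of
  leaves, 100–200 replicate seeds) — chosen so the full statistical suite
  runs in seconds while leaving the estimators' asymptotics clearly
  visible.

## Known limitations

* Neighbor joining is O(n³) pure Python/numpy; fine for hundreds of
  leaves, not for tens of thousands.
* The paired statistic assumes the tree contains both halves of every
  parent as leaves; proteins dropped during splitting (a half with no
  residues) are excluded with a warning.
* p/Poisson distances ignore rate heterogeneity across sites; for
  publication-grade trees import an external maximum-likelihood tree.
* The EPR decomposition is phenomenological: it reports basis weights, not
  spin populations, and leaves weight→molar conversion to the caller's
  scale factors.
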