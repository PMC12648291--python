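# semidox

Tools for studying the internal symmetry and biophysics of bacterial
ferredoxins and their putative evolutionary precursors, the half-ferredoxin
**semidoxins** (~28–30 aa peptides carrying a single [4Fe-4S] cluster-binding
motif) and the internally symmetric single-chain **symdoxins** built from two
fused semidoxin repeats.

The package is aimed at molecular-evolution and protein-design researchers
who want to (1) mine protein sequence sets for semidoxin-like peptides,
(2) quantify how far the two halves of a ferredoxin have diverged since the
ancestral gene duplication, and (3) fit the standard biophysical
characterisation curves of iron–sulfur peptides.

## What it computes

**Motif mining.** Cluster-binding sites are found with a fixed-spacing
cysteine template, `C-x-x-C-x-x-C-x-x-x-C-P`, and sequences are classified as
`semidoxin_like` (≤40 aa, one motif), `short_ferredoxin` (<60 aa, two
motifs), `ferredoxin` (≥60 aa, ≥2 motifs) or `other`.

**Internal-symmetry statistic.** Aligned ferredoxins are split at the
alignment midpoint (after removing columns with >10% gaps) into N- and
C-terminal halves, a tree is built over all halves (in-package neighbor
joining on Poisson-corrected distances, or an imported Newick tree), and for
each protein the *cophenetic distance* — the branch-length sum along the path
between its two half-leaves, in substitutions/site — is reported, with
symmetry flags at distance < 1 and < 2.

**Charge properties.** Henderson–Hasselbalch net charge
`Q(pH) = Σ₊ 1/(1+10^(pH−pKa)) − Σ₋ 1/(1+10^(pKa−pH))` and the isoelectric
point (zero-charge pH, by bisection), plus the fold enrichment of short
sequences in anaerobic genomes over the independence expectation
`n_short · n_anaerobe / n_total`.

**Curve models.** Two-state van't Hoff melt with sloping baselines
`y(T) = [(a_N+b_N T) + (a_D+b_D T)·E]/(1+E)`, `E = exp[−ΔH/R(1/T−1/Tm)]`
(R = 1.9872×10⁻³ kcal K⁻¹ mol⁻¹); Hill-form melting temperature; Nernst
titration `f(E) = 1/(1+exp[(E−Em)/(RT/nF)])` with n = 1 (RT/nF ≈ 25.7 mV at
298 K); first-order decay `A(t) = A₀e^{−kt}` with half-life ln2/k; and
nonnegative least-squares decomposition of a composite EPR spectrum onto
monomer and dimer basis line shapes.

**Synthetic data.** Every input has a generator with planted ground truth:
duplication–divergence sequence families with controllable per-half
substitution rate, noisy melt/titration/decay curves, mixed composite
spectra, and genome label tables with a planted anaerobe × short-sequence
enrichment fold.

## Worked example

```python
import numpy as np
import semidox as sx

# classify the designed semidoxins/symdoxins and the natural peptide PD1
recs = [sx.SequenceRecord(id=k, residues=v) for k, v in sx.DESIGN_PEPTIDES.items()]
print(sx.classification_report(recs))

# isoelectric point of PD1
print("pI(PD1) =", round(sx.isoelectric_point(sx.DESIGN_PEPTIDES["PD1"]), 2))

# internal symmetry of simulated duplication-divergence families
rates = np.linspace(0.02, 0.45, 30)
cfg = sx.SimConfig(seed=1, n_families=30, rate_per_half=rates)
records, truth = sx.simulate_duplication_divergence(cfg)
aln = sx.Alignment(ids=[r.id for r in records], rows=[r.residues for r in records])
n, c, pairs = sx.split_halves(aln, split_col=(26, 29))   # excise the VKK linker
tree = sx.nj_tree(sx.pairwise_distance(sx.stack_halves(n, c)))
results, mean = sx.paired_symmetry(tree, pairs)
print("mean cophenetic distance:", round(mean, 3))

# midpoint potential from a noisy synthetic titration
E, A = sx.simulate_titration(Em=-438.0, noise=0.02, seed=1)
fit, _ = sx.fit_nernst((E, A))
print("fitted Em =", round(fit.Em, 1), "mV")
```

This prints (abridged): the nine peptides classify as five `semidoxin_like`
(AN, AC, SN, SC at 28 aa and PD1 at 30 aa, one motif each) and four
`short_ferredoxin` (the 54–56 aa symdoxins, two motifs each);
`pI(PD1) = 8.87` — PD1 is basic, unusual for a ferredoxin;
`mean cophenetic distance: 0.43` over the 30 simulated families, with the
per-family distance tracking the planted substitution rate (low-rate
families sit near 0, i.e. recently "duplicated" and internally symmetric);
and `fitted Em = -437.9 mV`, recovering the generator's −438 mV midpoint
from a 2%-noise titration.

The same stages are scriptable via the `semidox` CLI
(`mine`, `symmetry`, `pi`, `enrich`, `fit`, `simulate`); each run writes its
configuration to a `manifest.json` beside the output.

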