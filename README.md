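# quatevol

Toolkit for studying how **homo-oligomeric assembly evolves across a protein
family**, modelled on the workflow used for prokaryotic citrate synthases
(CS): ancestral sequence resurrection on a fixed phylogeny, parsimony
reconstruction of oligomeric-state transitions, mass-photometry (MP)
deconvolution of assembly states, and quantification of enzyme function
(Michaelis–Menten kinetics), thermal stability (melt midpoints) and in-vivo
complementation (growth rates).

It is aimed at molecular-evolution and biochemistry groups who have a tree,
an alignment, and per-variant biophysical measurements, and want one
reproducible pipeline from those inputs to a per-protein summary — plus
synthetic-data generators with known ground truth so every stage can be
validated without any external download.

## What it computes

**Ancestral reconstruction.** For a reversible amino-acid model (LG by
default) with rate matrix Q (normalized so branch lengths are expected
substitutions/site) and K discrete-gamma rate categories, per-site
likelihoods are computed by Felsenstein pruning and marginal posteriors
PP(s) at each internal node by the inside–outside decomposition, with rate
categories weighted empirical-Bayes per site. The MAP residue per site gives
the ML ancestor; the **altAll** ancestor substitutes the second-most-probable
residue at every site where its PP exceeds a threshold (0.2 by default),
concentrating all plausible alternatives into one "worst-case" sequence.
Gap structure is reconstructed separately by Fitch parsimony on the binary
(residue=1 / gap=0) alignment and overlaid on the reconstructed residues.

**Oligomeric-state history.** Sankoff parsimony with unit costs on a
discrete trait alphabet (dimer, hexamer, octamer, polydisperse, ...) returns
the minimum transition count, one most-parsimonious labelling, the implied
per-branch events, and per-state counts of independent origins and
reversions (with the number of co-optimal labellings, so ambiguity is
visible).

**Mass photometry.** Contrast-to-mass calibration against protein standards;
a stoichiometry-constrained Gaussian-mixture fit (component means tied to
n·m₀) selected by BIC; particle fractions, subunit ("active-site") fractions
f_n = n·w_n / Σ m·w_m, monodisperse/polydisperse classification, and
condition-to-condition shift reports.

**Functional assays.** DTNB-coupled initial rates (Beer–Lambert with
ε = 14 150 M⁻¹cm⁻¹ at 412 nm), Michaelis–Menten fits v = Vmax·S/(Km+S) with
kcat = Vmax/[E], melt midpoints by min–max scaling and 50 %-unfolded
interpolation (with a split-and-rescale two-transition variant), and maximum
growth rates from logistic fits of OD₆₀₀ curves.

## Worked example

```python
from quatevol import (lg_model, discrete_gamma, marginal_posteriors,
                      ml_ancestor, altall_ancestor, trait_min_transitions,
                      detect_oligomers, subunit_fractions)
from quatevol.simulate import (random_binary_tree, simulate_alignment,
                               simulate_mp_events)

tree = random_binary_tree(12, seed=31, mean_branch_length=1.0)
tree.branch_length[:] = 0.008
model, rates = lg_model(), discrete_gamma(1.0, 4)
sim = simulate_alignment(tree, model, rates, 500, seed=32)

root = tree.root
post = marginal_posteriors(tree, sim.msa, model, rates, nodes=[root])[root]
ml, alt = ml_ancestor(post), altall_ancestor(post, threshold=0.2)
acc = sum(a == b for a, b in zip(ml.sequence, sim.residues[root])) / 500
print(f"root accuracy {acc:.3f}, altAll alters {alt.altered_sites} sites")

mp = simulate_mp_events({2: 0.7, 6: 0.3}, monomer_kda=48.0,
                        n_events=5000, seed=5)
profile = detect_oligomers(mp.events, monomer_mass=48.0, n_max=12)
print({c.n: round(c.particle_fraction, 3) for c in profile.components})
print({n: round(f, 3) for n, f in subunit_fractions(profile).items()})
```

prints

```
root accuracy 0.994, altAll alters 6 sites
{2: 0.71, 6: 0.29}
{2: 0.449, 6: 0.551}
```

i.e. on short branches the ML ancestor recovers 99.4 % of the true simulated
root residues and the altAll ancestor differs at the 6 ambiguously
reconstructed sites; the MP deconvolution recovers the simulated 70:30
dimer:hexamer particle mixture within ±0.01, and weighting by subunits shows
that the hexamers — 29 % of particles — carry 55 % of active sites.

The same stages run from the shell:

```bash
quatevol run --seed 1 --out out/            # full synthetic pipeline
quatevol asr --tree tree.nwk --msa aln.fasta --out asr/
quatevol traits --tree tree.nwk --traits traits.csv
quatevol massphot profile --events events.csv --monomer-kda 48
quatevol assays tm --melt melt.csv --split-c 65
```

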