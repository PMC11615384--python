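# Methods

This note documents the models implemented in `quatevol`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical decisions a maintainer would want written down.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Substitution model and likelihood

The likelihood core implements a general time-reversible amino-acid model.
From a symmetric exchangeability matrix S and equilibrium frequencies π, the
rate matrix is Q_ij = S_ij π_j (i ≠ j), diagonal set so rows sum to zero,
globally rescaled so −Σ_i π_i Q_ii = 1. Branch lengths are therefore
expected substitutions per site. The LG model ships as a text asset
(`data/lg.dat`, values of Le & Gascuel 2008); by default the model's
published frequencies are used, with a config switch (`frequencies:
empirical`) to substitute alignment frequencies (+1 pseudocount) instead.

Transition probabilities use the spectral decomposition of the symmetrized
matrix D^{1/2} Q D^{−1/2} (D = diag π), giving P(t) for many branch lengths
from one `eigh`. A generic `expm` route exists for arbitrary valid Q and is
cross-checked against the spectral path and an independent Taylor-series
oracle in the tests.

Rate heterogeneity follows Yang's discrete-gamma approximation: K
equal-weight categories whose rates are the conditional means of
gamma(α, rate α) over its K quantile bands, computed with the
incomplete-gamma identity and renormalized to mean exactly 1. **K = 4 by
default** (the conventional choice in ML phylogenetics; doubling K beyond 8
moves total log-likelihoods by far less than 0.1 % on simulated data, which
the suite checks). The category means deviate from 1 by ≈ ±1.27/√α as
α → ∞; the tests verify the quadrature oracle at moderate α and the limit at
large α.

Per-site likelihoods come from Felsenstein pruning with per-site, per-node
scaling factors (log-accumulated) to prevent underflow. Gaps and unknown
residues ('X') are missing data: all-ones partials, so an all-gap column
contributes exactly log 1 = 0. Unrooted (basal-trifurcation) Newick input is
accepted as-is; under a reversible model the root placement is immaterial,
and the suite verifies likelihood invariance under explicit rerooting to
1e-9 relative.

Branch lengths and α are taken as given from the input tree and config —
there is no re-optimization. This mirrors the common practice of reusing the
tree-search estimates for downstream ancestral reconstruction; exposing an
optimizer was considered and deferred because it adds nothing to the
reconstruction logic being validated here.

## Marginal ancestral reconstruction

Posteriors at internal nodes use the inside–outside decomposition: the
"inside" (postorder) partials from pruning are combined with "outside"
(preorder) partials; their product at node v, state s, summed over rate
categories with the uniform 1/K prior, is proportional to the joint
probability of the data with state s at v — normalizing over s therefore
weights rate categories by their per-site posterior (empirical Bayes), the
behaviour expected from mainstream ASR software. A uniform-weighting
variant (`equal_category_weights`) exists for sensitivity analysis only.

The ML ancestor takes the per-site MAP residue; exact ties resolve to the
earlier residue in the fixed order `ARNDCQEGHILKMFPSTWYV` (deterministic and
documented, relevant only for degenerate posteriors). The altAll ancestor
swaps in the second-most-probable residue at every site where that residue's
posterior is **strictly greater** than the threshold (default 0.2; 0.3 is
the conventional stricter variant). Equality keeps the ML state. The
threshold must lie in (0, 0.5]: above 0.5 no runner-up can qualify, at or
below 0 every site would.

Sequence divergence between two reconstructions counts residue differences
only over sites where both sequences carry a residue; sites where exactly
one is gapped are reported separately as gap mismatches, since residue and
indel disagreements are different quantities.

## Gap and trait parsimony

Ancestral gap states come from Fitch parsimony on the binary
residue-present/absent encoding of the alignment (bottom-up set
intersection, change counted per empty intersection; top-down assignment
preferring the parent's state). Genuinely ambiguous nodes — the root
included — resolve to **presence** (1) by default: the biologically
conservative choice that keeps residues rather than deleting them. The
tie-break is configurable. The Fitch pass requires a bifurcating tree;
multifurcating trees go through the Sankoff routine.

Oligomeric-state history uses Sankoff parsimony with unit costs over an
arbitrary trait alphabet; leaves with unknown state carry the full state
set. The traceback prefers the parent's state on ties (minimizing spurious
event calls), then alphabet order; the root takes the first minimum-cost
state in alphabet order. Because most-parsimonious labellings are often not
unique, the reconstruction also reports the exact number of co-optimal
labellings (computed by a counting DP alongside the cost DP), so any
origin/reversion statement can be qualified by the ambiguity of the
labelling it was read from. An origin of state X is a branch on which X
arises; a reversion is an origin at a node one of whose strict ancestors in
the same labelling also carries X.

## Mass photometry

Calibration fits mass = slope·contrast + intercept by least squares through
per-standard contrast **modes** (Gaussian-KDE peak — robust to stray
landing events), requiring ≥ 2 standards with ≥ 50 events each.

Oligomer deconvolution fits a Gaussian mixture to the event masses in which
each component mean is tied to an integer multiple of the monomer mass:
μ_n = n·m₀(1 + δ_n) with |δ_n| ≤ 10 %. The 10 % band covers the instrument's
2–5 % mass error plus the mass of a purification tag (whether the tag is
included in m₀ is the caller's responsibility). EM is initialized from
nearest-multiple histogram assignment; σ_n is floored at 0.2 % of m₀ to keep
zero-variance degenerate inputs well-posed. The retained stoichiometry
subset is chosen by BIC over nested candidate sets ranked by initial
histogram support. Events below the **40 kDa instrument floor** (the
practical lower detection bound of the technique) are excluded from fitting
and reported; particle fractions are scaled so that assigned components plus
the unassigned (sub-floor) fraction sum to exactly 1.

Particle fractions answer "what share of complexes"; subunit fractions
f_n = n·w_n / Σ_m m·w_m answer "what share of active sites" — both are
emitted, since either weighting may be wanted when comparing to published
per-subunit plots.

Classification thresholds: **monodisperse(n)** if one stoichiometry holds
≥ 0.80 of particles; **polydisperse** if ≥ 3 stoichiometries each hold
≥ 0.05; otherwise **mixed**. The underlying phenomenology ("mostly dimers",
ladders of multimers-of-dimers with minor oddmers) has no canonical numeric
rule, so these two thresholds are explicit, surfaced in the config and in
every report, and the classifier additionally flags even-n ladders
(≥ 3 even stoichiometries) and odd-mer presence. The classification is
monotone: growing the dominant component never flips monodisperse to
polydisperse (tested).

## Functional assays

*Initial rates.* The fitted window grows from the first point and keeps the
largest extension whose linear fit retains R² ≥ 0.99 (≥ 5 points) — a
reproducible stand-in for manual window picking. Rates convert by
Beer–Lambert with ε = 14 150 M⁻¹cm⁻¹ for the TNB anion at 412 nm and a
1 cm default path (both configurable; plate-reader paths differ). A flat
trace has R² defined as 1 (zero residuals) and rate 0. Note the window rule
biases rates low when substrate depletion is appreciable within the trace;
initial-rate assays should be run (or simulated) with small fractional
consumption, as the acceptance checks do.

*Michaelis–Menten.* Unweighted nonlinear least squares (the default of the
common commercial fitters), initialized at Vmax₀ = max v and Km₀ = S at
half-max; kcat = Vmax/[E] (or Vmax directly for per-site velocities).
Negative parameter estimates and non-convergence are hard errors; Km outside
the measured substrate range raises a warning in the fit record.

*Melts.* Tm is read directly from the min–max-scaled curve as the linear
interpolation of the 0.5 crossing — deliberately plot-based rather than a
Boltzmann fit, matching how CD melt midpoints are conventionally read; the
scaled curve is oriented to increase with temperature, making the estimate
invariant to affine transformations (including sign) of the raw signal.
Multiple crossings report the first with a multimodality flag. The two-step
variant partitions at a configurable split (default 65 °C), min–max scales
each segment independently, and reads each segment's midpoint. A segment
whose range is below 5 % of the full curve's range contains no transition
and reports None, reducing the analysis to the other segment; only if both
segments are flat is it an error. Per-segment (not global) scaling is used
because the two transitions generally have unequal amplitudes.

*Growth.* Logistic fit N(t) = K/(1 + (K/N₀ − 1)e^{−rt}) with µmax = r.
When the culture never approaches the fitted plateau (max OD < K/2, e.g.
purely exponential data) or the fit fails, µmax falls back to the maximum of
the Savitzky–Golay-smoothed d ln OD/dt, and the method used is reported.
Cultures ending within the noise band of their starting OD are flagged
no-growth with µmax = 0. Gompertz and richer model families were left out:
the logistic + derivative pair covers the synthetic conditions and keeps the
estimate interpretable.

## Synthetic data: what is and is not emulated

Every generator embeds its ground truth in its return value, and every
analysis stage has at least one recovery test wired to a generator. Fixed
seeds reproduce outputs bit-for-bit (NumPy `default_rng`).

* *Alignments* evolve root sequences drawn from π down the tree with
  per-site gamma categories; indels are block deletions whose
  presence/absence evolves as a two-state Markov process over geometric
  blocks (mean 10 columns, loss 0.05 / gain 0.01 per unit branch length by
  default). This exercises gap parsimony but is not a full indel model: no
  insertions creating new columns, no length evolution.
* *Trait histories* are symmetric CTMC jumps with the complete event list —
  used to verify that parsimony never exceeds the true event count, not to
  emulate any particular lineage.
* *MP events* draw a stoichiometry per particle and add Gaussian mass error,
  σ = 4 % of mass by default (typical for the instrument); an optional
  linear contrast map supports calibration tests. Real event streams also
  contain unbinding events, surface artifacts and baseline drift, none of
  which are simulated — passing recovery tests bounds estimator error under
  clean mixtures only.
* *Kinetic traces* use the closed-form (Lambert-W) Michaelis–Menten progress
  curve; *rate tables* default to the 25–500 µM substrate series with 2 %
  multiplicative noise and 3 replicates. *Melts* are sums of two-state
  Boltzmann transitions (steepness k = 1.2 °C, i.e. 10–90 % width ≈ 5 °C —
  cooperative unfolding; the split-and-rescale midpoint readout is only
  unbiased when transitions are well separated relative to this width) on a
  1 °C grid over 20–95 °C. *Growth* is noiseless-logistic plus
  multiplicative noise; no lag-phase term beyond the initial condition, no
  evaporation or OD nonlinearity.

Default study conditions elsewhere: mass-photometry runs use 5000 events;
simulated proteins default to a 48 kDa monomer; the default trait alphabet
is {dimer, hexamer, octamer, polydisperse}.

## Pipeline determinism and problem sizes

The pipeline runs its stages sequentially from one validated config
(strict schema, unknown keys rejected, all violations reported together).
Reports are stamped with the config hash, seed and package version — never
wall-clock time — and serialized with sorted keys, so identical configs
produce byte-identical reports; the suite asserts this at the byte level for
the report and all FASTA/CSV artifacts.

Oracle checks enumerate all internal-state assignments; the cost is
20^(leaves−1) per column, so the suite runs every rooted binary shape at
3–5 leaves with 200 random columns and two 6-leaf shapes (3.2 M assignments
per column) at 12 columns, with K = 2 categories — sizes chosen to keep the
exhaustive oracle exact while the whole check remains a desk-scale
computation. Reconstruction-accuracy experiments use 12-leaf trees with
500-site alignments at K = 4, α = 1.

## Known limitations

* No branch-length/α optimization, tree search, or support computation —
  the tree is an input.
* Marginal (not joint) ancestral reconstruction; parsimony (not Mk-model
  likelihood) for discrete traits.
* The mixture fitter assumes a single monomer species; heteromeric mixtures
  or proteolytic fragments will be mis-assigned to the nearest n·m₀.
* Initial-rate extraction assumes the linear regime is at the trace start;
  lag phases (e.g. coupled-assay activation) are not modelled.
* The altAll construction treats sites independently; correlated
  reconstruction uncertainty is not represented.
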