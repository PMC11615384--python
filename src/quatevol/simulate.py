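"""Synthetic data generators with embedded ground truth.

Every analysis stage in this package has a matching generator here, so the
whole pipeline can be exercised end-to-end — and its estimates checked
against known truth — without any external download:

* sequences evolved on a tree under a reversible substitution model with
  discrete-gamma rate heterogeneity and block indels (presence/absence
  evolving as a two-state Markov process), recording true ancestral states;
* discrete oligomeric-trait histories (continuous-time Markov jumps) with
  the full event list;
* mass-photometry event streams as mixtures of n-mer masses with Gaussian
  measurement error and an optional linear contrast map;
* Michaelis-Menten rate tables and closed-form progress traces;
* one- and two-transition sigmoidal melt curves;
* logistic growth curves.

All functions accept either an integer seed or a ``numpy.random.Generator``;
a fixed seed reproduces outputs bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import lambertw

from .assays import (DEFAULT_EPSILON_M_CM, DEFAULT_PATH_CM, GrowthCurve,
                     KineticTrace, MeltCurve, RateTable)
from .massphot import EventTable
from .models import GammaRates, SubstitutionModel
from .phylo import AMINO_ACIDS, GAP, MSA, PhyloTree


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def random_binary_tree(n_leaves: int, seed=None, mean_branch_length: float = 0.3,
                       labels: list[str] | None = None) -> PhyloTree:
    """Random rooted binary topology with exponential branch lengths.

    Built by successive random joins (equivalent to a uniform coalescent
    topology); branch lengths are i.i.d. exponential with the given mean.
    """
    rng = _rng(seed)
    if n_leaves < 2:
        raise ValueError("need at least two leaves")
    if labels is None:
        labels = [f"t{i+1}" for i in range(n_leaves)]
    parent: list[int] = []
    children: list[list[int]] = []
    labs: list[str | None] = []
    active = []
    for lab in labels:
        parent.append(-1)
        children.append([])
        labs.append(lab)
        active.append(len(parent) - 1)
    while len(active) > 1:
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[int(i)], active[int(j)]
        parent.append(-1)
        children.append([a, b])
        labs.append(None)
        new = len(parent) - 1
        parent[a] = parent[b] = new
        active = [x for x in active if x not in (a, b)] + [new]
    blen = rng.exponential(mean_branch_length, size=len(parent))
    blen[active[0]] = 0.0
    tree = PhyloTree(parent=np.array(parent), children=children,
                     branch_length=blen, labels=labs)
    return tree


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

@dataclass
class IndelSpec:
    """Block indels: alignment columns grouped into blocks whose presence
    evolves as a two-state (present/absent) Markov process down the tree."""

    mean_block_length: int = 10
    loss_rate: float = 0.0   # present -> absent, per unit branch length
    gain_rate: float = 0.0   # absent -> present


@dataclass
class SimulatedAlignment:
    """Leaf alignment plus the full simulated history."""

    msa: MSA
    tree: PhyloTree
    #: residue sequences (no gaps) for every node, indexed by node id
    residues: dict[int, str]
    #: per-node 0/1 presence per site
    presence: dict[int, np.ndarray]
    site_categories: np.ndarray

    def ancestral_sequence(self, node: int) -> str:
        """Residues with simulated gap structure applied."""
        return "".join(GAP if p == 0 else c
                       for c, p in zip(self.residues[node], self.presence[node]))


def simulate_alignment(tree: PhyloTree, model: SubstitutionModel,
                       rates: GammaRates, length: int,
                       indels: IndelSpec | None = None,
                       seed=None) -> SimulatedAlignment:
    """Evolve an alignment down ``tree`` and keep the true ancestral states.

    Root residues are drawn from the model's equilibrium frequencies; each
    site is assigned one gamma rate category; along each branch of length t
    the child state is drawn from P(r_k * t).
    """
    rng = _rng(seed)
    cats = rng.integers(0, rates.K, size=length)
    root = tree.root
    states: dict[int, np.ndarray] = {
        root: rng.choice(20, size=length, p=model.pi)}
    for node in tree.preorder():
        for child in tree.children[node]:
            t = float(tree.branch_length[child])
            out = np.empty(length, dtype=np.int64)
            for k in range(rates.K):
                m = cats == k
                if not m.any():
                    continue
                P = model.transition_matrix(float(rates.rates[k]) * t)
                cum = P.cumsum(axis=1)
                u = rng.random(int(m.sum()))
                par = states[node][m]
                out[m] = (u[:, None] > cum[par]).sum(axis=1)
            states[child] = out

    presence: dict[int, np.ndarray] = {}
    if indels is None or (indels.loss_rate == 0 and indels.gain_rate == 0):
        for node in range(tree.n_nodes):
            presence[node] = np.ones(length, dtype=np.int8)
    else:
        # block structure: geometric block lengths covering the alignment
        edges = [0]
        while edges[-1] < length:
            edges.append(edges[-1] + int(rng.geometric(
                1.0 / max(indels.mean_block_length, 1))))
        edges[-1] = length
        blocks = list(zip(edges[:-1], edges[1:]))
        nb = len(blocks)
        g, l = indels.gain_rate, indels.loss_rate
        tot = g + l
        bstate: dict[int, np.ndarray] = {root: np.ones(nb, dtype=np.int8)}
        for node in tree.preorder():
            for child in tree.children[node]:
                t = float(tree.branch_length[child])
                # 2-state analytic transition probabilities
                decay = np.exp(-tot * t)
                p_present_given_present = g / tot + l / tot * decay
                p_present_given_absent = g / tot * (1 - decay)
                par = bstate[node]
                stay = np.where(par == 1, p_present_given_present,
                                p_present_given_absent)
                bstate[child] = (rng.random(nb) < stay).astype(np.int8)
        for node in range(tree.n_nodes):
            site = np.empty(length, dtype=np.int8)
            for b, (a0, a1) in enumerate(blocks):
                site[a0:a1] = bstate[node][b]
            presence[node] = site

    residues = {node: "".join(AMINO_ACIDS[s] for s in seq)
                for node, seq in states.items()}
    leaf_idx = tree.leaf_indices()
    labels = [tree.labels[i] for i in leaf_idx]
    seqs = ["".join(GAP if presence[i][c] == 0 else residues[i][c]
                    for c in range(length)) for i in leaf_idx]
    msa = MSA(labels=labels, sequences=seqs)
    return SimulatedAlignment(msa=msa, tree=tree, residues=residues,
                              presence=presence, site_categories=cats)


# ---------------------------------------------------------------------------
# trait histories
# ---------------------------------------------------------------------------

@dataclass
class SimulatedTraits:
    leaf_traits: dict[str, str]
    node_traits: dict[int, str]
    events: list[tuple[int, str, str]]  # (child node of the branch, from, to)

    @property
    def n_events(self) -> int:
        return len(self.events)


def simulate_trait_history(tree: PhyloTree, alphabet: list[str],
                           rate: float, seed=None,
                           root_state: str | None = None) -> SimulatedTraits:
    """Symmetric continuous-time Markov trait evolution with event records.

    ``rate`` is the total rate of leaving the current state; on a jump the
    new state is uniform over the other states.
    """
    if rate < 0:
        raise ValueError("trait substitution rate must be >= 0")
    if not alphabet:
        raise ValueError("trait alphabet is empty")
    rng = _rng(seed)
    root = tree.root
    node_traits = {root: root_state if root_state is not None
                   else alphabet[int(rng.integers(len(alphabet)))]}
    events = []
    for node in tree.preorder():
        for child in tree.children[node]:
            state = node_traits[node]
            t = float(tree.branch_length[child])
            pos = 0.0
            while rate > 0 and len(alphabet) > 1:
                pos += rng.exponential(1.0 / rate)
                if pos >= t:
                    break
                others = [s for s in alphabet if s != state]
                new = others[int(rng.integers(len(others)))]
                events.append((child, state, new))
                state = new
            node_traits[child] = state
    leaf_traits = {tree.labels[i]: node_traits[i] for i in tree.leaf_indices()}
    return SimulatedTraits(leaf_traits=leaf_traits, node_traits=node_traits,
                           events=events)


# ---------------------------------------------------------------------------
# mass photometry
# ---------------------------------------------------------------------------

@dataclass
class SimulatedMP:
    events: EventTable
    composition: dict[int, float]
    monomer_kda: float
    true_subunit_fractions: dict[int, float] = field(init=False)

    def __post_init__(self) -> None:
        tot = sum(n * f for n, f in self.composition.items())
        self.true_subunit_fractions = {n: n * f / tot
                                       for n, f in self.composition.items()}


def simulate_mp_events(composition: dict[int, float], monomer_kda: float,
                       n_events: int = 5000, sigma_rel: float = 0.04,
                       calibration: tuple[float, float] | None = None,
                       seed=None) -> SimulatedMP:
    """Draw per-particle masses from a mixture of n-mer peaks.

    Each particle picks a stoichiometry n with probability ``composition[n]``
    and lands at mass ~ Normal(n * m0, sigma_rel * n * m0) — a measurement
    error of about 4% of mass is typical for the instrument.  With
    ``calibration`` = (slope, intercept), a raw ``contrast`` column is
    emitted alongside masses for calibration-recovery tests.
    """
    if abs(sum(composition.values()) - 1.0) > 1e-9:
        raise ValueError("composition fractions must sum to 1")
    if monomer_kda <= 0:
        raise ValueError("monomer mass must be > 0")
    rng = _rng(seed)
    ns = np.array(sorted(composition))
    probs = np.array([composition[n] for n in ns])
    draw = rng.choice(len(ns), size=n_events, p=probs)
    mean = ns[draw] * monomer_kda
    masses = rng.normal(mean, np.maximum(sigma_rel * mean, 1e-12))
    masses = np.maximum(masses, 1e-3)
    data = pd.DataFrame({"mass_kda": masses})
    if calibration is not None:
        slope, intercept = calibration
        data["contrast"] = (masses - intercept) / slope
    return SimulatedMP(events=EventTable(data=data),
                       composition=dict(composition), monomer_kda=monomer_kda)


# ---------------------------------------------------------------------------
# kinetics, melts, growth
# ---------------------------------------------------------------------------

@dataclass
class SimulatedRates:
    table: RateTable
    kcat_s: float
    km_uM: float
    enzyme_uM: float


def simulate_rate_table(kcat_s: float, km_uM: float, enzyme_uM: float,
                        substrate_uM=(25, 50, 75, 100, 150, 250, 500),
                        noise_cv: float = 0.0, replicates: int = 1,
                        seed=None) -> SimulatedRates:
    """Michaelis-Menten initial rates with multiplicative Gaussian noise."""
    rng = _rng(seed)
    S = np.tile(np.asarray(substrate_uM, float), replicates)
    rep = np.repeat(np.arange(replicates), len(substrate_uM))
    vmax = kcat_s * enzyme_uM
    v = vmax * S / (km_uM + S)
    if noise_cv > 0:
        v = v * (1.0 + noise_cv * rng.standard_normal(len(v)))
    table = RateTable(substrate_uM=S, velocity=v, replicate=rep,
                      velocity_units="uM_per_s")
    return SimulatedRates(table=table, kcat_s=kcat_s, km_uM=km_uM,
                          enzyme_uM=enzyme_uM)


@dataclass
class SimulatedTrace:
    trace: KineticTrace
    v0_uM_per_s: float


def simulate_progress_trace(kcat_s: float, km_uM: float, enzyme_uM: float,
                            s0_uM: float, duration_s: float = 120.0,
                            n_points: int = 121, noise_sd_au: float = 0.0,
                            epsilon_M_cm: float = DEFAULT_EPSILON_M_CM,
                            path_cm: float = DEFAULT_PATH_CM,
                            seed=None) -> SimulatedTrace:
    """Closed-form Michaelis-Menten progress curve converted to absorbance.

    Substrate follows the Schnell-Mendoza solution
    S(t) = Km * W((S0/Km) * exp((S0 - Vmax t)/Km)) with the Lambert W
    function; product P = S0 - S(t) maps to A412 via Beer-Lambert.
    """
    rng = _rng(seed)
    t = np.linspace(0.0, duration_s, n_points)
    vmax = kcat_s * enzyme_uM
    arg = (s0_uM / km_uM) * np.exp((s0_uM - vmax * t) / km_uM)
    S = km_uM * np.real(lambertw(arg))
    P_uM = s0_uM - S
    a412 = P_uM * 1e-6 * epsilon_M_cm * path_cm
    if noise_sd_au > 0:
        a412 = a412 + noise_sd_au * rng.standard_normal(len(a412))
    trace = KineticTrace(time_s=t, a412=a412, epsilon_M_cm=epsilon_M_cm,
                         path_cm=path_cm, enzyme_nM=enzyme_uM * 1e3,
                         substrate_uM=s0_uM)
    v0 = vmax * s0_uM / (km_uM + s0_uM)
    return SimulatedTrace(trace=trace, v0_uM_per_s=v0)


@dataclass
class SimulatedMelt:
    curve: MeltCurve
    midpoints_C: tuple[float, ...]


def simulate_melt(midpoints_C=(70.0,), slopes_C=None, amplitudes=None,
                  t_min: float = 20.0, t_max: float = 95.0, step: float = 1.0,
                  noise_sd: float = 0.0, seed=None) -> SimulatedMelt:
    """Sum of two-state Boltzmann transitions plus Gaussian noise.

    The noiseless unfolded fraction is sum_i a_i / (1 + exp((Tm_i - T)/k_i));
    amplitudes default to equal shares and slopes to k = 1.2 degC (a 10-90%
    transition width of ~5 degC, typical of cooperative unfolding; well
    separated transitions keep the split-and-rescale midpoint readout
    unbiased).  ``noise_sd`` is in units of the total signal range.
    """
    rng = _rng(seed)
    midpoints_C = tuple(midpoints_C)
    slopes_C = (tuple(slopes_C) if slopes_C is not None
                else tuple(1.2 for _ in midpoints_C))
    if amplitudes is None:
        amplitudes = tuple(1.0 / len(midpoints_C) for _ in midpoints_C)
    T = np.arange(t_min, t_max + step / 2, step)
    y = np.zeros_like(T)
    for tm, k, a in zip(midpoints_C, slopes_C, amplitudes):
        y = y + a / (1.0 + np.exp((tm - T) / k))
    if noise_sd > 0:
        y = y + noise_sd * rng.standard_normal(len(y))
    return SimulatedMelt(curve=MeltCurve(temperature_C=T, signal=y),
                         midpoints_C=midpoints_C)


@dataclass
class SimulatedGrowth:
    curve: GrowthCurve
    mu_max_h: float


def simulate_growth(r_h: float = 0.8, capacity: float = 1.2, n0: float = 0.05,
                    t_max_h: float = 24.0, interval_h: float = 0.25,
                    noise_cv: float = 0.0, seed=None) -> SimulatedGrowth:
    """Logistic growth curve OD(t) = K / (1 + (K/N0 - 1) e^{-rt}) + noise."""
    rng = _rng(seed)
    t = np.arange(0.0, t_max_h + interval_h / 2, interval_h)
    od = capacity / (1.0 + (capacity / n0 - 1.0) * np.exp(-r_h * t))
    if noise_cv > 0:
        od = np.maximum(od * (1.0 + noise_cv * rng.standard_normal(len(od))), 0.0)
    return SimulatedGrowth(curve=GrowthCurve(time_h=t, od600=od), mu_max_h=r_h)
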