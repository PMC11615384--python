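"""End-to-end pipeline: simulate -> ASR -> trait parsimony -> MP -> assays.

Stages run sequentially in dependency order; every report is stamped with
the config hash, seed and package version (never wall-clock time), so a
rerun with the same config produces a byte-identical report.  Each stage
reads only its declared inputs and writes its own artifacts — no stage
mutates another stage's data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .asr import (altall_ancestor, apply_gap_mask, marginal_posteriors,
                  ml_ancestor, sequence_divergence)
from .assays import (GrowthCurve, MeltCurve, RateTable, estimate_tm,
                     fit_michaelis_menten, max_growth_rate, two_step_tm)
from .config import RunConfig, validate_config
from .likelihood import PruningEngine
from .massphot import classify_dispersity, detect_oligomers, subunit_fractions
from .models import discrete_gamma, lg_model
from .parsimony import fitch_gap_states, trait_min_transitions
from .phylo import MSA, PhyloTree
from .simulate import (IndelSpec, random_binary_tree, simulate_alignment,
                       simulate_growth, simulate_melt, simulate_mp_events,
                       simulate_rate_table, simulate_trait_history)

SCHEMA_VERSION = "1"


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


@dataclass
class StudyReport:
    """Machine-readable consolidated results of one pipeline run."""

    payload: dict

    def to_json(self) -> str:
        return json.dumps(self.payload, sort_keys=True, indent=1,
                          default=_jsonable)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def run_pipeline(config: RunConfig | str, out_dir: str | Path | None = None,
                 ) -> StudyReport:
    """Execute the configured stages and return the consolidated report.

    With ``out_dir`` set, per-stage artifacts (FASTA ancestors, posterior
    CSV, trait JSON, event CSVs) and the report itself are written there.
    """
    cfg = config if isinstance(config, RunConfig) else validate_config(config)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.seed)
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "quatevol_version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": seed,
    }

    # ---- stage: simulate ----------------------------------------------
    tree = msa = sim = None
    if cfg.tree.newick_path:
        tree = PhyloTree.read(cfg.tree.newick_path)
    if cfg.stages.simulate:
        if tree is None:
            tree = random_binary_tree(cfg.tree.n_leaves, seed=seed,
                                      mean_branch_length=cfg.tree.mean_branch_length)
        model = lg_model()
        rates = discrete_gamma(cfg.alignment.gamma_alpha, cfg.alignment.gamma_k)
        sim = simulate_alignment(
            tree, model, rates, cfg.alignment.length,
            indels=IndelSpec(**cfg.alignment.indel.model_dump()),
            seed=seed + 1)
        msa = sim.msa
        if out is not None:
            tree.write(out / "tree.nwk")
            msa.to_fasta(out / "alignment.fasta")
        report["simulate"] = {
            "n_leaves": len(tree.leaf_indices()),
            "alignment_length": msa.length,
        }
    elif cfg.alignment.fasta_path:
        msa = MSA.from_fasta(cfg.alignment.fasta_path)

    # ---- stage: asr ----------------------------------------------------
    if cfg.stages.asr:
        if tree is None or msa is None:
            raise ValueError("asr stage needs a tree and an alignment "
                             "(enable simulate or provide paths)")
        if cfg.alignment.frequencies == "empirical":
            model = lg_model(frequencies=msa.empirical_frequencies(pseudocount=1.0))
        else:
            model = lg_model()
        rates = discrete_gamma(cfg.alignment.gamma_alpha, cfg.alignment.gamma_k)
        engine = PruningEngine(tree, msa, model, rates)
        internal = [i for i in range(tree.n_nodes) if not tree.is_leaf(i)]
        tables = marginal_posteriors(tree, msa, model, rates, nodes=internal,
                                     engine=engine)
        gaps = fitch_gap_states(tree, msa.binary_matrix(
            order=[tree.labels[i] for i in tree.leaf_indices()]))
        nodes_out = {}
        frames = []
        for node in internal:
            ml = apply_gap_mask(ml_ancestor(tables[node]), gaps.states[node])
            alt = apply_gap_mask(
                altall_ancestor(tables[node], cfg.asr.altall_threshold),
                gaps.states[node])
            div = sequence_divergence(ml, alt)
            nodes_out[str(node)] = {
                "ml_sequence": ml.sequence,
                "altall_sequence": alt.sequence,
                "altall_altered_sites": alt.altered_sites,
                "ml_vs_altall_residue_differences": div.residue_differences,
                "mean_pp": float(np.nanmean(ml.pp)) if len(ml.pp) else None,
            }
            frames.append(tables[node].to_frame())
        report["asr"] = {
            "log_likelihood": engine.total_log_likelihood,
            "gap_parsimony_changes": gaps.total_changes,
            "altall_threshold": cfg.asr.altall_threshold,
            "nodes": nodes_out,
        }
        if out is not None:
            with open(out / "ancestors_ml.fasta", "w") as fh:
                for node, rec in nodes_out.items():
                    fh.write(f">node{node}\n{rec['ml_sequence']}\n")
            with open(out / "ancestors_altall.fasta", "w") as fh:
                for node, rec in nodes_out.items():
                    fh.write(f">node{node}\n{rec['altall_sequence']}\n")
            pd.concat(frames).to_csv(out / "posteriors.csv", index=False,
                                     float_format="%.6g")

    # ---- stage: traits -------------------------------------------------
    if cfg.stages.traits:
        if tree is None:
            raise ValueError("traits stage needs a tree")
        if cfg.traits.traits_path:
            df = pd.read_csv(cfg.traits.traits_path)
            leaf_traits = dict(zip(df["leaf_label"], df["trait"]))
            true_events = None
        else:
            sim_traits = simulate_trait_history(
                tree, cfg.traits.alphabet, cfg.traits.rate, seed=seed + 2)
            leaf_traits = sim_traits.leaf_traits
            true_events = sim_traits.n_events
        rec = trait_min_transitions(tree, leaf_traits,
                                    alphabet=sorted(set(map(str, leaf_traits.values()))))
        report["traits"] = {
            "leaf_traits": {k: str(v) for k, v in sorted(leaf_traits.items())},
            "min_transitions": rec.min_transitions,
            "true_simulated_events": true_events,
            "origins": rec.origins,
            "reversions": rec.reversions,
            "n_optimal_labellings": rec.n_optimal_labellings,
            "events": [{"parent": e.parent, "child": e.child,
                        "from": e.from_state, "to": e.to_state}
                       for e in rec.events],
        }
        if out is not None:
            (out / "traits.json").write_text(
                json.dumps(rec.to_dict(), sort_keys=True, indent=1,
                           default=_jsonable) + "\n")

    # ---- stage: massphot ----------------------------------------------
    if cfg.stages.massphot:
        mp_out = {}
        for i, prot in enumerate(cfg.proteins):
            mp = simulate_mp_events(prot.composition, prot.monomer_kda,
                                    n_events=cfg.massphot.n_events,
                                    sigma_rel=cfg.massphot.sigma_rel,
                                    seed=seed + 100 + i)
            profile = detect_oligomers(mp.events, prot.monomer_kda,
                                       n_max=cfg.massphot.n_max,
                                       mass_floor=cfg.massphot.mass_floor_kda,
                                       mass_tol=cfg.massphot.mass_tol)
            cls = classify_dispersity(profile,
                                      theta_mono=cfg.massphot.theta_mono,
                                      theta_min=cfg.massphot.theta_min)
            true_sub = mp.true_subunit_fractions
            est_sub = subunit_fractions(profile)
            mp_out[prot.name] = {
                "profile": profile.to_dict(),
                "dispersity": cls.label,
                "even_series": cls.even_series,
                "oddmers_present": cls.oddmers_present,
                "true_particle_fractions": {str(k): v for k, v
                                            in sorted(prot.composition.items())},
                "true_subunit_fractions": {str(k): v for k, v
                                           in sorted(true_sub.items())},
                "max_subunit_fraction_error": max(
                    abs(est_sub.get(n, 0.0) - true_sub.get(n, 0.0))
                    for n in set(est_sub) | set(true_sub)),
            }
            if out is not None:
                mp.events.to_csv(out / f"mp_events_{prot.name}.csv")
        report["massphot"] = mp_out

    # ---- stage: assays -------------------------------------------------
    if cfg.stages.assays:
        a = cfg.assays
        assay_out = {}
        for i, prot in enumerate(cfg.proteins):
            sim_rates = simulate_rate_table(
                prot.kcat_s, prot.km_uM, a.enzyme_uM,
                substrate_uM=a.substrate_uM, noise_cv=a.rate_noise_cv,
                replicates=a.replicates, seed=seed + 200 + i)
            mm = fit_michaelis_menten(sim_rates.table, enzyme_uM=a.enzyme_uM)
            melt = simulate_melt(midpoints_C=prot.melt_midpoints_C,
                                                                  noise_sd=a.melt_noise_sd, seed=seed + 300 + i)
            if len(prot.melt_midpoints_C) > 1:
                tm = two_step_tm(melt.curve, split_C=a.split_C)
                tm_rec = {"tm1_C": tm.tm_C, "tm2_C": tm.tm2_C,
                          "split_C": tm.split_C}
            else:
                tm = estimate_tm(melt.curve)
                tm_rec = {"tm_C": tm.tm_C}
            growth = simulate_growth(r_h=prot.growth_rate_h,
                                     noise_cv=a.growth_noise_cv,
                                     seed=seed + 400 + i)
            gfit = max_growth_rate(growth.curve)
            assay_out[prot.name] = {
                "kcat_s": mm.kcat_s, "km_uM": mm.km_uM,
                "kcat_true_s": prot.kcat_s, "km_true_uM": prot.km_uM,
                "melt": tm_rec, "melt_true_C": list(prot.melt_midpoints_C),
                "mu_max_h": gfit.mu_max_h, "mu_max_true_h": prot.growth_rate_h,
                "growth_model": gfit.model,
            }
        report["assays"] = assay_out

    rep = StudyReport(payload=report)
    if out is not None:
        rep.write(out / "report.json")
    return rep
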