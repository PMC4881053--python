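"""End-to-end pipeline drivers and truth-based evaluation.

These functions wire the stages together on a synthetic dataset (or any
dataset presented with the same in-memory interfaces) and, where ground
truth is available, score each stage against it. The numbered scripts under
``analysis/`` and the acceptance harness are thin wrappers over this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotate, genome_context, phylo, structure as structure_mod
from .annotate import RGeneCall, _SeedIndex
from .core_io import AlignParams, DEFAULT_PARAMS, FastaRecord, translate
from .evolution import (
    FamilyMatrix,
    classify_selection,
    codon_align_pair,
    ng86,
    reconstruct_counts,
    selection_summary,
)
from .synthetic_data import SimulationResult


# ---------------------------------------------------------------------------
# identification
# ---------------------------------------------------------------------------

def annotated_spans(sim: SimulationResult) -> dict:
    spans: dict = {sp: {} for sp in sim.species}
    for sp, models in sim.gene_models.items():
        for m in models:
            spans[sp].setdefault(m.chromosome, []).append((m.start, m.end))
    return spans


def run_identification(sim: SimulationResult,
                       params: AlignParams = DEFAULT_PARAMS,
                       max_iter: int = 10) -> list[RGeneCall]:
    proteomes = sim.proteomes()
    calls = annotate.iterative_identify(
        proteomes, sim.genomes, sim.seeds, params=params,
        max_iter=max_iter, annotated_spans=annotated_spans(sim))
    annotate.classify_calls(calls, proteomes, params)
    return calls


def score_identification(sim: SimulationResult,
                         calls: list[RGeneCall]) -> dict:
    """Recall / architecture accuracy / background FPR / unannotated-locus
    recovery against the generator truth."""
    truth = sim.truth_table()
    truth_r = {(r.species, r.gene_id) for _, r in truth[truth.is_r].iterrows()}
    truth_bg = {(r.species, r.gene_id)
                for _, r in truth[~truth.is_r].iterrows()}
    called = {(c.species, c.gene_id) for c in calls if not c.chromosome}
    tp = len(called & truth_r)
    fp = len(called & truth_bg)
    labels = {(r.species, r.gene_id): r.architecture
              for _, r in truth[truth.is_r].iterrows()}
    by_call = {(c.species, c.gene_id): c.architecture for c in calls}
    arch_ok = sum(1 for k, v in labels.items() if by_call.get(k) == v)
    # unannotated loci: found iff an iterative genome call overlaps
    genome_calls = [c for c in calls if c.chromosome]
    found = 0
    for _, u in sim.unannotated.iterrows():
        for c in genome_calls:
            if (c.species == u.species and c.chromosome == u.chromosome
                    and c.locus_start <= u.end and u.start <= c.locus_end):
                found += 1
                break
    return {
        "recall": tp / len(truth_r) if truth_r else 1.0,
        "architecture_accuracy": arch_ok / len(labels) if labels else 1.0,
        "background_fpr": fp / len(truth_bg) if truth_bg else 0.0,
        "unannotated_recovery": (found / len(sim.unannotated)
                                 if len(sim.unannotated) else 1.0),
        "n_r_truth": len(truth_r),
        "n_background": len(truth_bg),
        "n_calls": len(calls),
    }


# ---------------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------------

def score_clusters(sim: SimulationResult) -> dict:
    """Planted-cluster recovery: multi-gene memberships must match exactly;
    9-gene-spaced boundary pairs must never merge."""
    truth = sim.truth_table()
    exact = 0
    n_species = 0
    boundary_merged = 0
    fractions = []
    for sp in sim.species:
        sub = truth[(truth.species == sp) & truth.is_r]
        rids = set(sub.gene_id)
        if not rids:
            continue
        n_species += 1
        clusters = genome_context.call_clusters(sim.gene_models[sp], rids)
        recovered = {frozenset(c.members) for c in clusters if c.size >= 2}
        planted: dict[str, set] = {}
        for _, r in sub.iterrows():
            if r.cluster_id:
                planted.setdefault(r.cluster_id, set()).add(r.gene_id)
        planted_sets = {frozenset(v) for v in planted.values() if len(v) >= 2}
        if recovered == planted_sets:
            exact += 1
        fractions.append(genome_context.clustered_fraction(clusters))
        # boundary families: two copies, 9 intervening genes, same family
        fam_of = dict(zip(sub.gene_id, sub.family_id))
        boundary_fams = set(
            sim.family_meta[sim.family_meta.kind == "boundary"].family_id)
        for members in recovered:
            fams = {fam_of[m] for m in members}
            if fams & boundary_fams and len(members) >= 2:
                sub_members = [m for m in members
                               if fam_of[m] in boundary_fams]
                fams_b = {}
                for m in sub_members:
                    fams_b.setdefault(fam_of[m], []).append(m)
                if any(len(v) >= 2 for v in fams_b.values()):
                    boundary_merged += 1
    return {
        "cluster_exact_fraction": exact / n_species if n_species else 1.0,
        "boundary_merged": boundary_merged,
        "mean_clustered_fraction": float(np.mean(fractions)) if fractions else 0.0,
    }


# ---------------------------------------------------------------------------
# structure
# ---------------------------------------------------------------------------

def run_structure(sim: SimulationResult, calls: list[RGeneCall],
                  params: AlignParams = DEFAULT_PARAMS) -> pd.DataFrame:
    """Classify every annotated R-gene call, using the best seed-database
    protein as the InDel reference."""
    seed_index = _SeedIndex()
    for rec in sim.seeds:
        seed_index.add(rec.id, rec.seq)
    models = {}
    for sp, mlist in sim.gene_models.items():
        for m in mlist:
            models[(sp, m.gene_id)] = m
    rows = []
    for call in calls:
        if call.chromosome:
            continue
        m = models.get((call.species, call.gene_id))
        if m is None or not m.cds:
            continue
        ref = None
        cand = seed_index.candidates(m.protein)
        if cand:
            # deterministic cheap choice: most shared words, then id
            best = max(cand, key=lambda sid: (
                _shared_words(m.protein, seed_index.seqs[sid]), sid))
            ref = seed_index.seqs[best]
        sc = structure_mod.classify_structure(m.cds, ref, params,
                                              gene_id=m.gene_id)
        rows.append({"species": call.species, "gene_id": m.gene_id,
                     "class": sc.cls, "evidence": ";".join(sc.evidence)})
    return pd.DataFrame(rows)


def _shared_words(a: str, b: str, w: int = 6) -> int:
    wa = {a[i:i + w] for i in range(len(a) - w + 1)}
    wb = {b[i:i + w] for i in range(len(b) - w + 1)}
    return len(wa & wb)


def score_structure(sim: SimulationResult,
                    structure_calls: pd.DataFrame) -> dict:
    truth = sim.truth_table()
    t = truth[truth.is_r].set_index(["species", "gene_id"])
    merged = structure_calls.set_index(["species", "gene_id"]).join(
        t[["structure_class", "defect_class"]], how="inner")
    startstop = merged[merged.defect_class.isin(
        ["LackStart", "LackStop", "LackBoth", "Pseudo-premature-stop"])]
    fsindel = merged[merged.defect_class.isin(
        ["Pseudo-frameshift", "InDel"])]
    complete = merged[merged.defect_class == "Complete"]

    def acc(df):
        return (float((df["class"] == df.structure_class).mean())
                if len(df) else 1.0)

    return {
        "startstop_accuracy": acc(startstop),
        "frameshift_indel_accuracy": acc(fsindel),
        "complete_accuracy": acc(complete),
        "overall_accuracy": acc(merged),
        "n_scored": int(len(merged)),
    }


# ---------------------------------------------------------------------------
# phylogenetics (supergene trees and the rate comparison)
# ---------------------------------------------------------------------------

def truth_families(sim: SimulationResult) -> FamilyMatrix:
    truth = sim.truth_table()
    members: dict[str, dict[str, list[str]]] = {}
    for _, r in truth.iterrows():
        members.setdefault(r.family_id, {}).setdefault(
            r.species, []).append(r.gene_id)
    return FamilyMatrix(members=members)


def supergene_tree(sim: SimulationResult, family_ids: list[str],
                   params: AlignParams = DEFAULT_PARAMS):
    """Center-star align one representative per species for each family
    covering all species, pool 4D sites into a supergene and return
    (NJ tree, supergene).

    Strictly single-copy families use their single member; multi-copy
    families contribute their lexicographically first structurally intact
    copy (families with a species lacking an intact copy are skipped)."""
    fams = truth_families(sim)
    models = {}
    for sp, mlist in sim.gene_models.items():
        for m in mlist:
            models[(sp, m.gene_id)] = m

    def intact(sp, gid):
        m = models[(sp, gid)]
        return m.cds and len(m.cds) % 3 == 0 and "*" not in m.protein

    site_sets = []
    for fam in sorted(set(family_ids) & set(fams.members)):
        per_sp = fams.members[fam]
        prots, cds = {}, {}
        for sp in sim.species:
            good = sorted(g for g in per_sp.get(sp, []) if intact(sp, g))
            if not good:
                break
            m = models[(sp, good[0])]
            prots[sp], cds[sp] = m.protein, m.cds
        else:
            aln = phylo.align_family(prots, cds, params)
            site_sets.append(phylo.extract_4d_sites(aln))
    supergene = phylo.concatenate_supergene(site_sets)
    if len(supergene) < 3 or not next(iter(supergene.values()), ""):
        raise ValueError("too few families cover all species for a supergene")
    tree = phylo.nj_tree(phylo.k2p_matrix(supergene))
    return tree, supergene


def run_rate_comparison(sim: SimulationResult,
                        params: AlignParams = DEFAULT_PARAMS) -> dict:
    meta = sim.family_meta
    r_ids = sorted(meta[meta.is_r].family_id)
    bg_ids = sorted(meta[~meta.is_r].family_id)
    tree_r, sg_r = supergene_tree(sim, r_ids, params)
    tree_bg, sg_bg = supergene_tree(sim, bg_ids, params)
    rates = phylo.compare_rates(tree_r, tree_bg)
    return {
        "tree_r": tree_r, "tree_bg": tree_bg,
        "supergene_r_sites": len(next(iter(sg_r.values()), "")),
        "supergene_bg_sites": len(next(iter(sg_bg.values()), "")),
        "total_ratio": rates["total_ratio"],
        "per_leaf_ratio": rates["per_leaf_ratio"],
        "supergene_r": sg_r, "supergene_bg": sg_bg,
    }


# ---------------------------------------------------------------------------
# family birth-death
# ---------------------------------------------------------------------------

def run_family_dynamics(sim: SimulationResult) -> dict:
    fams = truth_families(sim)
    meta = sim.family_meta
    r_ids = set(meta[meta.is_r].family_id)
    counts = fams.counts(sim.species)
    counts_r = counts.loc[sorted(set(counts.index) & r_ids)]
    events = reconstruct_counts(counts_r, sim.tree)
    return {"counts": counts_r, "events": events}


def score_family_events(sim: SimulationResult,
                        events) -> dict:
    """Compare reconstructed per-branch gains/losses with simulated truth.

    Exact recovery is only expected when each family's events sit on a
    single non-root-adjacent branch; the general Poisson default is scored
    by total-event correlation instead."""
    truth = (sim.branch_events.groupby("branch")[["gain", "loss"]]
             .sum().reset_index())
    rec = events.per_branch[["branch", "gain", "loss"]]
    merged = truth.merge(rec, on="branch", suffixes=("_true", "_rec"),
                         how="outer").fillna(0)
    exact = bool(
        (merged.gain_true == merged.gain_rec).all()
        and (merged.loss_true == merged.loss_rec).all())
    return {"exact": exact, "table": merged}


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def run_selection(sim: SimulationResult, species_a: str, species_b: str,
                  params: AlignParams = DEFAULT_PARAMS) -> pd.DataFrame:
    """NG86 Ka/Ks for one-to-one R-gene ortholog pairs (same family, single
    copy in both species, structurally intact)."""
    truth = sim.truth_table()
    models = {}
    for sp, mlist in sim.gene_models.items():
        for m in mlist:
            models[(sp, m.gene_id)] = m
    results = []
    r_truth = truth[truth.is_r & (truth.structure_class == "Complete")]
    for fam, grp in r_truth.groupby("family_id"):
        in_a = grp[grp.species == species_a]
        in_b = grp[grp.species == species_b]
        if len(in_a) != 1 or len(in_b) != 1:
            continue
        ga, gb = in_a.iloc[0].gene_id, in_b.iloc[0].gene_id
        pairs = codon_align_pair(models[(species_a, ga)].cds,
                                 models[(species_b, gb)].cds, params)
        res = ng86(pairs, pair_ids=(ga, gb))
        results.append(classify_selection(res))
    return selection_summary(results)
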