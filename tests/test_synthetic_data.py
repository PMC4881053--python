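"""Generator contracts: planted architectures, codon evolution, defects,
family/copy-number simulation, genome layout and determinism."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from rgevo import annotate
from rgevo.core_io import reverse_complement, translate
from rgevo.synthetic_data import (
    ARCHITECTURE_WEIGHTS,
    SimulationConfig,
    back_translate,
    build_domain_protein,
    evolve_cds,
    plant_defects,
    simulate,
    simulate_families,
    write_outputs,
)


# ---------------------------------------------------------------------------
# domain-architecture construction
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("label", sorted(ARCHITECTURE_WEIGHTS))
def test_planted_architecture_is_scanner_recoverable(label, rng):
    protein, coords, critical = build_domain_protein(label, rng)
    hits = annotate.scan_all(protein)
    assert annotate.classify_architecture(hits, len(protein)) == label
    # recorded coordinates bracket the scanned hits for each named domain
    for h in hits:
        lo, hi = coords[h.domain]
        assert h.start >= lo - 30 and h.end <= hi + 30


def test_nbs_only_protein_has_no_lrr(rng):
    protein, _, _ = build_domain_protein("NBS", rng)
    assert annotate.scan_lrr(protein) is None


def test_unknown_label_errors(rng):
    with pytest.raises(ValueError):
        build_domain_protein("NBS-KINASE", rng)


def test_mean_emitted_length_near_500(rng):
    labels = list(ARCHITECTURE_WEIGHTS)
    w = np.array([ARCHITECTURE_WEIGHTS[l] for l in labels])
    lengths = []
    for _ in range(60):
        lab = labels[int(rng.choice(len(labels), p=w / w.sum()))]
        protein, _, _ = build_domain_protein(lab, rng)
        lengths.append(len(protein))
    assert 400 <= np.mean(lengths) <= 600


# ---------------------------------------------------------------------------
# codon evolution
# ---------------------------------------------------------------------------

def _random_cds(rng, n_codons=200):
    protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), n_codons))
    return back_translate(protein, rng, add_stop=False)


def test_evolve_omega_zero_preserves_protein(rng):
    cds = _random_cds(rng)
    out = evolve_cds(cds, 0.1, 0.0, rng)
    assert translate(out) == translate(cds)
    assert out != cds  # synonymous changes did happen


def test_evolve_zero_branch_identity(rng):
    cds = _random_cds(rng)
    assert evolve_cds(cds, 0.0, 0.5, rng) == cds


def test_evolve_realized_divergence_matches_branch_length(rng):
    cds = _random_cds(rng, 2000)
    out = evolve_cds(cds, 0.05, 1.0, rng)
    diff = sum(1 for a, b in zip(cds, out) if a != b)
    # multiple hits at one site make the observed count slightly lower
    assert 0.8 * 0.05 * len(cds) <= diff <= 0.05 * len(cds)


def test_evolve_never_creates_internal_stop(rng):
    cds = _random_cds(rng, 300) + "TAA"
    out = evolve_cds(cds, 0.2, 1.0, rng, constrained_codons={0, 300})
    assert "*" not in translate(out)[:-1]


def test_evolve_rejects_negative_omega(rng):
    with pytest.raises(ValueError):
        evolve_cds("ATGAAA", 0.1, -1.0, rng)


def test_evolve_deterministic_under_seed():
    cds = _random_cds(np.random.default_rng(0), 100)
    a = evolve_cds(cds, 0.1, 0.5, np.random.default_rng(5))
    b = evolve_cds(cds, 0.1, 0.5, np.random.default_rng(5))
    assert a == b


# ---------------------------------------------------------------------------
# structural defects
# ---------------------------------------------------------------------------

@pytest.fixture()
def intact_gene(rng):
    protein, _, critical = build_domain_protein("CC-NBS-LRR", rng)
    return back_translate(protein, rng), frozenset(critical)


def test_defect_premature_stop(intact_gene, rng):
    cds, crit = intact_gene
    mut, ev = plant_defects(cds, "Pseudo-premature-stop", rng, crit)
    assert "*" in translate(mut)[:-1]
    assert ev["event"] == "premature_stop"


def test_defect_lack_start_keeps_frame(intact_gene, rng):
    cds, crit = intact_gene
    mut, _ = plant_defects(cds, "LackStart", rng, crit)
    assert not mut.startswith("ATG")
    assert len(mut) % 3 == 0
    assert "*" not in translate(mut)[:-1]


def test_defect_indel_in_frame_no_stop(intact_gene, rng):
    cds, crit = intact_gene
    mut, ev = plant_defects(cds, "InDel", rng, crit)
    assert len(mut) % 3 == 0
    assert len(cds) - len(mut) == 27
    assert "*" not in translate(mut)[:-1]


def test_defect_frameshift_changes_length_mod3(intact_gene, rng):
    cds, crit = intact_gene
    mut, _ = plant_defects(cds, "Pseudo-frameshift", rng, crit)
    assert len(mut) % 3 == 2


def test_defect_too_short_errors(rng):
    with pytest.raises(ValueError, match="too short"):
        plant_defects("ATG" + "GCT" * 10 + "TAA", "InDel", rng)


# ---------------------------------------------------------------------------
# family simulation
# ---------------------------------------------------------------------------

def test_zero_rates_keep_counts_constant():
    cfg = SimulationConfig(n_r_families=4, n_background_families=30,
                           gain_rate=0.0, loss_rate=0.0, seed=1)
    rng = np.random.default_rng(cfg.seed)
    sim = simulate_families(cfg, rng)
    counts = sim["node_counts"]
    for fam, grp in counts.groupby("family_id"):
        assert grp["count"].nunique() == 1


def test_leaf_count_equals_root_plus_path_changes():
    cfg = SimulationConfig(n_r_families=8, n_background_families=30,
                           gain_rate=0.4, loss_rate=0.4, seed=3)
    rng = np.random.default_rng(cfg.seed)
    sim = simulate_families(cfg, rng)
    counts = sim["node_counts"].set_index(["family_id", "node"])["count"]
    events = sim["branch_events"]
    tree = sim["tree"]
    for leaf in tree.leaf_node_iter():
        path = []
        nd = leaf
        while nd.parent_node is not None:
            path.append(nd.taxon.label if nd.taxon else nd.label)
            nd = nd.parent_node
        for fam in events.family_id.unique():
            root_count = counts[(fam, "root")]
            net = events[(events.family_id == fam)
                         & events.branch.isin(path)].net.sum()
            assert counts[(fam, path[0])] == root_count + net


# ---------------------------------------------------------------------------
# layout and whole-dataset properties
# ---------------------------------------------------------------------------

def test_embedded_cds_extractable_by_coordinates(small_sim):
    for sp in small_sim.species[:3]:
        for m in small_sim.gene_models[sp][:40]:
            seg = small_sim.genomes[sp][m.chromosome][m.start - 1 : m.end]
            cds = seg if m.strand == "+" else reverse_complement(seg)
            assert cds == m.cds


def test_truth_labels_use_known_vocabulary(small_sim):
    truth = small_sim.truth_table()
    assert set(truth[truth.is_r].architecture) <= set(ARCHITECTURE_WEIGHTS)
    assert set(truth.structure_class) <= {
        "Complete", "InDel", "LackStart", "LackStop", "LackBoth", "Pseudo"}
    assert truth.gene_id.is_unique


def test_every_gene_in_gff_and_proteome(small_sim):
    truth = small_sim.truth_table()
    for sp in small_sim.species:
        ids_models = {m.gene_id for m in small_sim.gene_models[sp]}
        ids_truth = set(truth[truth.species == sp].gene_id)
        assert ids_models == ids_truth


def test_byte_identical_outputs_under_fixed_seed(tmp_path):
    cfg = dict(n_r_families=6, n_background_families=110, seed=11)
    a = simulate(SimulationConfig(**cfg))
    b = simulate(SimulationConfig(**cfg))
    dir_a, dir_b = tmp_path / "a", tmp_path / "b"
    write_outputs(a, dir_a)
    write_outputs(b, dir_b)
    files = sorted(p.relative_to(dir_a) for p in dir_a.rglob("*")
                   if p.is_file())
    assert files
    for rel in files:
        assert (dir_a / rel).read_bytes() == (dir_b / rel).read_bytes(), rel
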