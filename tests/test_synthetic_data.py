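import json

import pytest

from intronevo.gene_models import intron_positions, splice_site_report
from intronevo.synthetic_data import (ConfigError, SimulationConfig,
                                      build_paper_fixture, simulate)


def counts_by(fixture, clade, species_group=None, species=None):
    inv = fixture.inventory
    by_gene = {g.gene_id: g for g in fixture.structures}
    rows = inv[(inv["clade"] == clade) & (inv["exception"] == 0)]
    if species_group:
        rows = rows[rows["group"] == species_group]
    if species:
        rows = rows[rows["species_id"].isin(species)]
    return sorted(by_gene[g].n_introns for g in rows["gene_id"])


def test_species_counts_per_major_group(paper_fixture):
    inv = paper_fixture.inventory
    species = inv.drop_duplicates("species_id")
    got = species.groupby("group")["species_id"].count().to_dict()
    assert got == {"Osteoglossomorpha": 2, "Elopomorpha": 4,
                   "Otocephala": 8, "Euteleostei": 13}
    assert species[species["group"] == "Euteleostei"]["order"].nunique() == 11
    assert species[species["group"] == "Otocephala"]["order"].nunique() == 6


def test_leaf_intron_counts_match_encoded_structures(paper_fixture):
    fx = paper_fixture
    assert counts_by(fx, "base", species_group="Elopomorpha") == [8, 8, 8]
    assert counts_by(fx, "base", species_group="Osteoglossomorpha") == [8, 8]
    assert counts_by(fx, "cladeI",
                     species=["anchovy", "herring", "milkfish"]) == [7, 7, 7]
    assert counts_by(fx, "cladeI", species=["zebrafish", "loach"]) == [4, 4]
    assert counts_by(fx, "cladeI",
                     species=["tetra", "electric_eel", "catfish"]) == [3, 3, 3]
    assert counts_by(fx, "cladeI", species_group="Euteleostei") == [0] * 10
    assert counts_by(fx, "cladeI_HCE1") == [1, 1, 1]
    assert counts_by(fx, "cladeI_HCE2") == [0, 0, 0]
    assert counts_by(fx, "cladeII", species_group="Otocephala") == [8, 8, 8]
    salm = ["masu_salmon", "rainbow_trout", "pike"]
    assert counts_by(fx, "cladeII", species=salm) == [0, 0, 0]
    eut = paper_fixture.inventory.query(
        "group == 'Euteleostei' and species_id not in @salm")
    assert counts_by(fx, "cladeII", species_group="Euteleostei",
                     species=list(eut["species_id"])) == [7] * 10


def test_exception_genes_flagged_without_structures(paper_fixture):
    inv = paper_fixture.inventory
    flagged = set(inv[inv["exception"] == 1]["gene_id"])
    assert flagged == {"EHE7", "PeHE1", "AcHE2", "MfHE2", "AcHE4", "AcHE5"}
    structured = {g.gene_id for g in paper_fixture.structures}
    assert not flagged & structured
    assert not flagged & set(paper_fixture.gene_tree.leaf_ids())


def test_fixture_sequences_are_consistent_and_canonical(paper_fixture):
    aln = paper_fixture.alignment
    for g in paper_fixture.structures:
        assert g.protein() == aln.ungapped(g.gene_id)
        assert all(r.canonical for r in splice_site_report(g))
        assert len(intron_positions(g)) == g.n_introns  # all coding introns


def test_fixture_gene_lengths_match_cost_model_scale(paper_fixture):
    g8 = next(g for g in paper_fixture.structures if g.n_introns == 8)
    g0 = next(g for g in paper_fixture.structures if g.n_introns == 0)
    assert len(g8.genomic_seq) / 1000 == pytest.approx(3.0, rel=0.05)
    assert len(g0.genomic_seq) / 1000 == pytest.approx(1.0, rel=0.06)


def test_fixture_write_is_deterministic_and_byte_identical(tmp_path):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    build_paper_fixture(seed=3).write(d1)
    build_paper_fixture(seed=3).write(d2)
    for p1 in sorted(d1.iterdir()):
        assert p1.read_bytes() == (d2 / p1.name).read_bytes()


def test_simulation_deterministic_under_seed():
    cfg = SimulationConfig(species_tree="[&R] ((a,b),(c,d));",
                           p_intron_loss=0.3, p_intron_gain=0.1, seed=99)
    s1, s2 = simulate(cfg), simulate(cfg)
    assert s1.gene_tree.to_newick() == s2.gene_tree.to_newick()
    assert [g.genomic_seq for g in s1.structures] == \
           [g.genomic_seq for g in s2.structures]
    assert s1.ground_truth.events == s2.ground_truth.events


def test_zero_event_probabilities_inherit_root_structure():
    cfg = SimulationConfig(species_tree="[&R] ((a,b),(c,d));",
                           p_intron_loss=0.0, p_intron_gain=0.0,
                           substitution_rate=0.0, seed=1)
    sim = simulate(cfg)
    root = set(sim.ground_truth.root_sites)
    assert len(sim.structures) == 4
    for g in sim.structures:
        assert sim.ground_truth.leaf_sites[g.gene_id] == root
        assert g.n_introns == len(root)


def test_simulated_history_replays_to_emitted_leaves():
    cfg = SimulationConfig(species_tree="[&R] ((a,b)ab,(c,(d,e)de)cde)r;",
                           duplication_branches=(("L1", "cde"),),
                           gene_loss_branches=(("L1", "ab"),),
                           p_intron_loss=0.2, p_intron_gain=0.05, seed=42)
    sim = simulate(cfg)
    truth = sim.ground_truth
    # replay: walk events down the species tree per lineage
    state = {("L1", "r"): set(truth.root_sites)}
    by_branch = {}
    for e in truth.events:
        by_branch.setdefault((e["lineage"], e["branch"]), []).append(e)

    def walk(node, lineage, sites):
        for ev in by_branch.get((lineage, node.id), []):
            if ev["kind"] == "intron_loss":
                sites = sites - {ev["site"]}
            elif ev["kind"] == "intron_gain":
                sites = sites | {ev["site"]}
            elif ev["kind"] == "gene_loss":
                return
        lineages = [lineage]
        for ev in by_branch.get((lineage, node.id), []):
            if ev["kind"] == "duplication":
                lineages = ev["daughters"]
        for lid in lineages:
            if node.is_leaf:
                assert truth.leaf_sites[f"{node.id}__{lid}"] == sites
            else:
                for child in node.children:
                    walk(child, lid, sites)

    root = sim.species_tree.root
    root_dups = [e for e in by_branch.get(("L1", root.id), [])
                 if e["kind"] == "duplication"]
    start = root_dups[0]["daughters"] if root_dups else ["L1"]
    for lid in start:
        for child in root.children:
            walk(child, lid, set(truth.root_sites))
    # every emitted gene was visited via some lineage
    assert set(truth.leaf_sites) == {g.gene_id for g in sim.structures}


def test_gene_loss_branch_removes_lineage_below(paper_fixture):
    cfg = SimulationConfig(species_tree="[&R] ((a,b)ab,(c,d)cd)r;",
                           gene_loss_branches=(("L1", "ab"),),
                           p_intron_loss=0.0, seed=0)
    sim = simulate(cfg)
    assert sorted(sim.gene_to_species.values()) == ["c", "d"]


def test_probability_out_of_range_is_a_config_error():
    with pytest.raises(ConfigError):
        SimulationConfig(p_intron_loss=1.5)
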