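import random

import pandas as pd
import pytest

from intronevo.intron_events import (dollo_reconstruct, fitch_reconstruct,
                                     infer_events, summarize_pathway)
from intronevo.intron_homology import IntronSite, IntronSiteMatrix
from intronevo.reconcile import lca_map
from intronevo.trees import RootedTree

from .oracles import min_dollo_losses, min_fitch_changes, random_tree


def one_gene_per_species(newick, states_by_site):
    """Matrix + reconciliation for a congruent one-gene-per-species family."""
    st = RootedTree.from_newick(newick, assume_rooted=True)
    gt = RootedTree.from_newick(newick, assume_rooted=True)
    leaves = st.leaf_ids()
    g2s = {l: l for l in leaves}
    rec = lca_map(gt, st, g2s)
    sites = [IntronSite(site_id=sid, column=i, phase=0)
             for i, sid in enumerate(states_by_site)]
    df = pd.DataFrame({sid: [states_by_site[sid].get(l, "?") for l in leaves]
                       for sid in states_by_site}, index=leaves)
    matrix = IntronSiteMatrix(genes=leaves, sites=sites, states=df)
    return st, rec, matrix


def test_all_present_site_is_present_at_root_with_zero_losses():
    st, rec, matrix = one_gene_per_species(
        "[&R] ((a,b),(c,d));", {"s0": {l: "1" for l in "abcd"}})
    states = dollo_reconstruct(matrix, st, rec)
    assert states.root_complement() == ["s0"]
    assert states.losses_per_site() == {"s0": 0}
    fstates = fitch_reconstruct(matrix, st, rec)
    assert fstates.present == states.present  # identical on all-present sites


def test_site_in_two_sister_leaves_gains_once_on_their_stem():
    st, rec, matrix = one_gene_per_species(
        "[&R] ((a,b)ab,(c,d)cd)r;",
        {"s0": {"a": "1", "b": "1", "c": "0", "d": "0"}})
    fstates = fitch_reconstruct(matrix, st, rec)
    assert fstates.changes_per_site["s0"] == 1
    states = dollo_reconstruct(matrix, st, rec)
    assert states.gain_node["s0"] == ("L1", "ab")
    assert states.losses_per_site()["s0"] == 0


def test_fitch_root_tie_resolves_toward_present():
    st, rec, matrix = one_gene_per_species(
        "[&R] (a,b)r;", {"s0": {"a": "1", "b": "0"}})
    fstates = fitch_reconstruct(matrix, st, rec)
    assert ("L1", "r") in fstates.present["s0"]


def test_site_present_in_zero_genes_is_dropped():
    st, rec, matrix = one_gene_per_species(
        "[&R] (a,b);", {"s0": {"a": "0", "b": "0"}})
    states = dollo_reconstruct(matrix, st, rec)
    assert states.dropped_sites == ["s0"]
    assert states.site_ids == []


def _random_states(leaves, rng):
    return {l: rng.choice(["1", "1", "0", "0", "?"]) for l in leaves}


def test_dollo_loss_counts_match_exhaustive_minimum_on_random_matrices():
    rng = random.Random(4)
    checked = 0
    while checked < 25:
        n = rng.randint(3, 5)
        newick = random_tree([f"t{i}" for i in range(n)], rng, True)
        st0 = RootedTree.from_newick(newick, assume_rooted=True)
        states_site = _random_states(st0.leaf_ids(), rng)
        if "1" not in states_site.values():
            continue
        st, rec, matrix = one_gene_per_species(newick, {"s0": states_site})
        got = dollo_reconstruct(matrix, st, rec).losses_per_site()["s0"]
        oracle = min_dollo_losses(
            st, {l: {"1": True, "0": False, "?": None}[v]
                 for l, v in states_site.items()})
        assert got == oracle
        checked += 1


def test_fitch_change_counts_match_exhaustive_minimum_on_random_matrices():
    rng = random.Random(9)
    checked = 0
    while checked < 25:
        n = rng.randint(3, 5)
        newick = random_tree([f"t{i}" for i in range(n)], rng, True)
        st0 = RootedTree.from_newick(newick, assume_rooted=True)
        states_site = _random_states(st0.leaf_ids(), rng)
        if "1" not in states_site.values():
            continue
        st, rec, matrix = one_gene_per_species(newick, {"s0": states_site})
        got = fitch_reconstruct(matrix, st, rec).changes_per_site["s0"]
        oracle = min_fitch_changes(
            st, {l: {"1": True, "0": False, "?": None}[v]
                 for l, v in states_site.items()})
        assert got == oracle
        checked += 1


def test_dollo_losses_never_undercut_fitch_changes_minus_one():
    rng = random.Random(13)
    for _ in range(20):
        n = rng.randint(3, 5)
        newick = random_tree([f"t{i}" for i in range(n)], rng, False)
        st0 = RootedTree.from_newick(newick, assume_rooted=True)
        states_site = _random_states(st0.leaf_ids(), rng)
        if "1" not in states_site.values():
            continue
        st, rec, matrix = one_gene_per_species(newick, {"s0": states_site})
        dollo = dollo_reconstruct(matrix, st, rec).losses_per_site()["s0"]
        fitch = fitch_reconstruct(matrix, st, rec).changes_per_site["s0"]
        assert dollo >= fitch - 1


# --------------------------------------------------------------- fixture
def test_fixture_teleost_root_reconstructed_with_eight_introns(fitted):
    assert sorted(fitted.history.root_complement) == \
        [f"i{n}" for n in range(1, 9)]


def test_fixture_event_pathway_matches_encoding(paper_fixture, fitted,
                                                lineage_ids):
    losses = fitted.history.losses_by_branch()
    expected = {}
    for clade, per_branch in paper_fixture.expected["intron_losses"].items():
        for branch, sites in per_branch.items():
            expected[(lineage_ids[clade], branch)] = sorted(sites)
    assert losses == expected


def test_fixture_gain_sits_on_salmonid_esocid_clade_i_copy(fitted,
                                                           lineage_ids):
    gains = fitted.history.gains()
    assert len(gains) == 1
    (gain,) = gains
    assert gain.lineage == lineage_ids["cladeI_HCE1"]
    assert gain.branch_child == "SalmEsoc"
    # the gained site is a novel one, outside the ancestral numbering
    assert fitted.matrix.site(gain.site_id).ancestral_number is None


def test_fixture_pathway_summary_counts(fitted, lineage_ids):
    pathway = fitted.pathway
    assert pathway.n_loss_branches == 6
    assert pathway.max_cumulative_by_lineage[lineage_ids["cladeI"]] == 8
    assert pathway.total_gains == 1
    # no intron events in the basal (pre-duplication) lineage
    base = lineage_ids["base"]
    assert not any(lid == base for lid, _ in fitted.history.losses_by_branch())


def test_fixture_missing_clade_ii_genes_generate_no_events(fitted,
                                                           lineage_ids):
    # clade II was lost in otophysans; no intron losses may be charged
    # below the otophysan stem in that lineage
    cII = lineage_ids["cladeII"]
    stree = fitted.reconciliation.species_tree
    below = {n.id for n in stree.preorder()
             if stree.is_ancestor_or_equal("Otophysi", n.id)}
    for (lid, branch), _ in fitted.history.losses_by_branch().items():
        assert not (lid == cII and branch in below)


def test_replaying_history_reproduces_every_leaf_row(fitted):
    replayed = fitted.history.replay()
    matrix = fitted.matrix
    for gid in matrix.genes:
        observed = {s.site_id for s in matrix.sites
                    if matrix.state(gid, s.site_id) == "1"}
        assert replayed[gid] == observed


def test_no_events_yields_empty_summary():
    st, rec, matrix = one_gene_per_species(
        "[&R] ((a,b),(c,d));", {"s0": {l: "1" for l in "abcd"}})
    states = dollo_reconstruct(matrix, st, rec)
    summary = summarize_pathway(infer_events(states, st, matrix))
    assert summary.n_loss_branches == 0
    assert summary.total_site_losses == 0
    assert (summary.cumulative["cumulative_losses"] == 0).all()
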