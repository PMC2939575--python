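"""Synthetic data: the packaged 27-species fixture and a gene-family simulator.

The fixture encodes the hatching-enzyme study system: a 27-species teleost
tree (2 osteoglossomorphs, 4 elopomorphs, 8 otocephalans, 13 euteleosts;
within-order relationships not constrained by published mitogenomic
phylogenies are left as polytomies), a single ancestral 9-exon-8-intron
gene, a duplication on the clupeocephalan stem producing the clade I (HCE)
and clade II (LCE) lineages, loss of clade II in otophysans, the stepwise
clade I intron losses (site 2 on the otocephalan stem; 6-8 on the otophysan
stem; 1 on the characiphysan stem; all eight on the euteleost stem), the
clade II losses (site 8 on the euteleost stem; everything on the
salmoniform/esociform stem), and the salmoniform/esociform clade I
duplication with a single novel intron gained in one copy. Lineage-specific
exception genes are carried in the inventory with an ``exception`` flag and
no committed structure. Toy sequences are same-length proteins (so the
identity alignment is exact) with canonical GT...AG introns of 250 bp and
about 1 kbp of exonic sequence, matching the mean lengths the cost model
uses.

The simulator evolves gene content and intron complements top-down over an
arbitrary species tree with designated duplication/gene-loss branches,
per-branch per-site intron-loss probabilities, rare novel-site gains (each
novel site is gained exactly once, so histories satisfy the Dollo
constraint by construction), and light protein substitution. It returns the
emitted structures, the exact alignment, the gene tree, and the full ground
truth for recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .gene_models import GeneStructure
from .intron_homology import CodonAlignment
from .trees import RootedTree

__all__ = ["PaperFixture", "build_paper_fixture", "SimulationConfig",
           "SimulationResult", "GroundTruth", "simulate", "TELEOST27_NEWICK"]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
CODON_OF = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}

TELEOST27_NEWICK = (
    "[&R] ((arowana,bonytongue)Osteoglossomorpha,"
    "((eel,pelican_eel,tarpon,aldrovandia)Elopomorpha,"
    "(((anchovy,herring)Clupeiformes,"
    "(milkfish,((zebrafish,loach)Cypriniformes,"
    "(tetra,electric_eel,catfish)Characiphysi)Otophysi)Ostariophysi)Otocephala,"
    "(((masu_salmon,rainbow_trout)Salmoniformes,pike)SalmEsoc,"
    "stomias,cod,john_dory,medaka,killifish,(tilapia,seabass)Perciformes,"
    "flounder,fugu,stickleback)Euteleostei)Clupeocephala)Elopocephala)Teleostei;"
)

# species -> (major group, order)
SPECIES_TABLE = [
    ("arowana", "Osteoglossomorpha", "Osteoglossiformes"),
    ("bonytongue", "Osteoglossomorpha", "Osteoglossiformes"),
    ("eel", "Elopomorpha", "Anguilliformes"),
    ("pelican_eel", "Elopomorpha", "Saccopharyngiformes"),
    ("tarpon", "Elopomorpha", "Elopiformes"),
    ("aldrovandia", "Elopomorpha", "Notacanthiformes"),
    ("anchovy", "Otocephala", "Clupeiformes"),
    ("herring", "Otocephala", "Clupeiformes"),
    ("milkfish", "Otocephala", "Gonorynchiformes"),
    ("zebrafish", "Otocephala", "Cypriniformes"),
    ("loach", "Otocephala", "Cypriniformes"),
    ("tetra", "Otocephala", "Characiformes"),
    ("electric_eel", "Otocephala", "Gymnotiformes"),
    ("catfish", "Otocephala", "Siluriformes"),
    ("masu_salmon", "Euteleostei", "Salmoniformes"),
    ("rainbow_trout", "Euteleostei", "Salmoniformes"),
    ("pike", "Euteleostei", "Esociformes"),
    ("stomias", "Euteleostei", "Stomiiformes"),
    ("cod", "Euteleostei", "Gadiformes"),
    ("john_dory", "Euteleostei", "Zeiformes"),
    ("medaka", "Euteleostei", "Beloniformes"),
    ("killifish", "Euteleostei", "Cyprinodontiformes"),
    ("tilapia", "Euteleostei", "Perciformes"),
    ("seabass", "Euteleostei", "Perciformes"),
    ("flounder", "Euteleostei", "Pleuronectiformes"),
    ("fugu", "Euteleostei", "Tetraodontiformes"),
    ("stickleback", "Euteleostei", "Gasterosteiformes"),
]

PROTEIN_LENGTH = 300
ANCESTRAL_CODONS = [30 * (k + 1) for k in range(8)]   # sites 1..8, phase 0
NOVEL_CODON = 45                                      # salmonid/esocid gain
INTRON_LENGTH = 250
UTR5, UTR3 = 12, 30


def back_translate(protein: str) -> str:
    return "".join(CODON_OF[a] for a in protein)


def make_gene_structure(gene_id: str, species_id: str, protein: str,
                        intron_offsets: Sequence[int], rng: np.random.Generator,
                        intron_length: int = INTRON_LENGTH,
                        exception: bool = False) -> GeneStructure:
    """Assemble a plus-strand gene with GT...AG introns at the given CDS
    offsets (nucleotides from the CDS start)."""
    cds = back_translate(protein) + "TAA"
    bases = np.array(list("ACGT"))
    utr5 = "".join(rng.choice(bases, UTR5))
    utr3 = "".join(rng.choice(bases, UTR3))
    spliced = utr5 + cds + utr3
    cuts = sorted(UTR5 + off for off in intron_offsets)
    pieces, exons, pos = [], [], 0
    genome_pos = 0
    last = 0
    for cut in cuts + [len(spliced)]:
        exon_seq = spliced[last:cut]
        pieces.append(exon_seq)
        exons.append((genome_pos, genome_pos + len(exon_seq)))
        genome_pos += len(exon_seq)
        if cut != len(spliced):
            filler = "".join(rng.choice(bases, intron_length - 10))
            intron = "GTAAGT" + filler + "TTAG"
            pieces.append(intron)
            genome_pos += len(intron)
        last = cut
    return GeneStructure(
        gene_id=gene_id, species_id=species_id, strand="+", exons=exons,
        cds_start=UTR5, cds_end=UTR5 + len(cds),
        genomic_seq="".join(pieces), exception=exception)


def _mutate(protein: str, n: int, rng: np.random.Generator) -> str:
    if n <= 0:
        return protein
    aa = list(protein)
    positions = rng.choice(len(aa), size=min(n, len(aa)), replace=False)
    for p in positions:
        choices = [c for c in AA_ALPHABET if c != aa[p]]
        aa[p] = choices[int(rng.integers(len(choices)))]
    return "".join(aa)


# ---------------------------------------------------------------------------
# the packaged study fixture
# ---------------------------------------------------------------------------

ANCESTRAL_SET = frozenset(range(1, 9))
FIXTURE_GENES = [
    # gene_id, species, clade label, intron complement (ancestral numbers),
    # novel gain flag, exception flag
    ("AwHE", "arowana", "base", ANCESTRAL_SET, False, False),
    ("BtHE", "bonytongue", "base", ANCESTRAL_SET, False, False),
    ("EHE4", "eel", "base", ANCESTRAL_SET, False, False),
    ("EHE7", "eel", "base", None, False, True),
    ("PeHE1", "pelican_eel", "base", None, False, True),
    ("TpHE", "tarpon", "base", ANCESTRAL_SET, False, False),
    ("AaHE", "aldrovandia", "base", ANCESTRAL_SET, False, False),
    # clade I, otocephalans
    ("AcHE1", "anchovy", "cladeI", ANCESTRAL_SET - {2}, False, False),
    ("AcHE2", "anchovy", "cladeI", None, False, True),
    ("HhHE1", "herring", "cladeI", ANCESTRAL_SET - {2}, False, False),
    ("MfHE1", "milkfish", "cladeI", ANCESTRAL_SET - {2}, False, False),
    ("MfHE2", "milkfish", "cladeI", None, False, True),
    ("ZHE1", "zebrafish", "cladeI", frozenset({1, 3, 4, 5}), False, False),
    ("MaHE1", "loach", "cladeI", frozenset({1, 3, 4, 5}), False, False),
    ("PiHE1", "tetra", "cladeI", frozenset({3, 4, 5}), False, False),
    ("EeHE1", "electric_eel", "cladeI", frozenset({3, 4, 5}), False, False),
    ("SaHE1", "catfish", "cladeI", frozenset({3, 4, 5}), False, False),
    # clade I, euteleosts (HCE)
    ("MsHCE1", "masu_salmon", "cladeI_HCE1", frozenset(), True, False),
    ("RbHCE1", "rainbow_trout", "cladeI_HCE1", frozenset(), True, False),
    ("PkHCE1", "pike", "cladeI_HCE1", frozenset(), True, False),
    ("MsHCE2", "masu_salmon", "cladeI_HCE2", frozenset(), False, False),
    ("RbHCE2", "rainbow_trout", "cladeI_HCE2", frozenset(), False, False),
    ("PkHCE2", "pike", "cladeI_HCE2", frozenset(), False, False),
    ("StHCE", "stomias", "cladeI", frozenset(), False, False),
    ("GmHCE", "cod", "cladeI", frozenset(), False, False),
    ("JdHCE", "john_dory", "cladeI", frozenset(), False, False),
    ("MHCE", "medaka", "cladeI", frozenset(), False, False),
    ("FhHCE", "killifish", "cladeI", frozenset(), False, False),
    ("OnHCE", "tilapia", "cladeI", frozenset(), False, False),
    ("DlHCE", "seabass", "cladeI", frozenset(), False, False),
    ("PoHCE", "flounder", "cladeI", frozenset(), False, False),
    ("TrHCE", "fugu", "cladeI", frozenset(), False, False),
    ("GaHCE", "stickleback", "cladeI", frozenset(), False, False),
    # clade II, otocephalans
    ("AcHE3", "anchovy", "cladeII", ANCESTRAL_SET, False, False),
    ("AcHE4", "anchovy", "cladeII", None, False, True),
    ("AcHE5", "anchovy", "cladeII", None, False, True),
    ("HhHE2", "herring", "cladeII", ANCESTRAL_SET, False, False),
    ("MfHE3", "milkfish", "cladeII", ANCESTRAL_SET, False, False),
    # clade II, euteleosts (LCE): 8th intron lost on the euteleost stem;
    # everything lost in salmoniforms/esociforms
    ("MsLCE", "masu_salmon", "cladeII", frozenset(), False, False),
    ("RbLCE", "rainbow_trout", "cladeII", frozenset(), False, False),
    ("PkLCE", "pike", "cladeII", frozenset(), False, False),
    ("StLCE", "stomias", "cladeII", ANCESTRAL_SET - {8}, False, False),
    ("GmLCE", "cod", "cladeII", ANCESTRAL_SET - {8}, False, False),
    ("JdLCE", "john_dory", "cladeII", ANCESTRAL_SET - {8}, False, False),
    ("MLCE", "medaka", "cladeII", ANCESTRAL_SET - {8}, False, False),
    ("FhLCE", "killifish", "cladeII", ANCESTRAL_SET - {8}, False, False),
    ("OnLCE", "tilapia", "cladeII", ANCESTRAL_SET - {8}, False, False),
    ("DlLCE", "seabass", "cladeII", ANCESTRAL_SET - {8}, False, False),
    ("PoLCE", "flounder", "cladeII", ANCESTRAL_SET - {8}, False, False),
    ("TrLCE", "fugu", "cladeII", ANCESTRAL_SET - {8}, False, False),
    ("GaLCE", "stickleback", "cladeII", ANCESTRAL_SET - {8}, False, False),
]


@dataclass
class PaperFixture:
    species_tree: RootedTree
    gene_tree: RootedTree
    structures: list[GeneStructure]
    alignment: CodonAlignment
    gene_to_species: dict[str, str]
    inventory: pd.DataFrame
    basal_reference: list[str]
    expected: dict
    clade_representatives: dict[str, str]

    def structures_table(self) -> pd.DataFrame:
        rows = []
        for g in self.structures:
            for start, end in g.exons:
                rows.append({"gene_id": g.gene_id, "species_id": g.species_id,
                             "strand": g.strand, "exon_start": start,
                             "exon_end": end, "cds_start": g.cds_start,
                             "cds_end": g.cds_end,
                             "exception": int(g.exception)})
        return pd.DataFrame(rows)

    def write(self, outdir: Union[str, Path]) -> dict[str, Path]:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "species_tree": out / "species_tree.nwk",
            "gene_tree": out / "gene_tree.nwk",
            "structures": out / "structures.tsv",
            "genomic": out / "genomic.fasta",
            "alignment": out / "alignment.fasta",
            "gene_map": out / "gene_map.tsv",
            "expected": out / "expected_events.json",
        }
        paths["species_tree"].write_text(self.species_tree.to_newick() + "\n")
        paths["gene_tree"].write_text(self.gene_tree.to_newick() + "\n")
        self.structures_table().to_csv(paths["structures"], sep="\t", index=False)
        with open(paths["genomic"], "w") as fh:
            for g in self.structures:
                fh.write(f">{g.gene_id}\n{g.genomic_seq}\n")
        paths["alignment"].write_text(self.alignment.to_fasta())
        self.inventory.to_csv(paths["gene_map"], sep="\t", index=False)
        import json
        paths["expected"].write_text(json.dumps(self.expected, indent=2,
                                                sort_keys=True))
        return paths


def _mirror_gene_tree(snode, genes_by_species: dict[str, list[str]]
                      ) -> Optional[str]:
    """Newick fragment mirroring the species topology over present genes."""
    if snode.is_leaf:
        gids = genes_by_species.get(snode.id, [])
        if not gids:
            return None
        if len(gids) == 1:
            return gids[0]
        return "(" + ",".join(gids) + ")"
    frags = [f for f in (_mirror_gene_tree(c, genes_by_species)
                         for c in snode.children) if f]
    if not frags:
        return None
    if len(frags) == 1:
        return frags[0]
    return "(" + ",".join(frags) + ")"


def build_paper_fixture(seed: int = 2010) -> PaperFixture:
    """Build the packaged 27-species hatching-enzyme study fixture.

    ``seed`` only randomises the toy sequences (ancestral protein, UTRs,
    intron filler, light per-gene substitution); the encoded structures and
    event pathway are fixed.
    """
    rng = np.random.default_rng(seed)
    stree = RootedTree.from_newick(TELEOST27_NEWICK)
    ancestral_protein = "".join(
        np.array(list(AA_ALPHABET))[rng.integers(0, 20, PROTEIN_LENGTH)])

    structures: list[GeneStructure] = []
    rows_aln: dict[str, str] = {}
    gene_to_species: dict[str, str] = {}
    inventory_rows = []
    order_of = {sp: o for sp, _, o in SPECIES_TABLE}
    group_of = {sp: g for sp, g, _ in SPECIES_TABLE}

    for gene_id, species, clade, complement, novel, exception in FIXTURE_GENES:
        gene_to_species[gene_id] = species
        inventory_rows.append({
            "gene_id": gene_id, "species_id": species,
            "group": group_of[species], "order": order_of[species],
            "clade": clade, "exception": int(exception)})
        if exception:
            continue  # exceptions carry no committed structure
        protein = _mutate(ancestral_protein, 3, rng)
        offsets = sorted(ANCESTRAL_CODONS[n - 1] * 3 for n in complement)
        if novel:
            offsets = sorted(offsets + [NOVEL_CODON * 3])
        structures.append(make_gene_structure(gene_id, species, protein,
                                              offsets, rng))
        rows_aln[gene_id] = protein

    inventory = pd.DataFrame(inventory_rows)
    alignment = CodonAlignment(rows=rows_aln)

    # gene tree: mirror the species topology inside each lineage
    genes_by_sp = lambda names: {gene_to_species[g]: [g] for g in names}
    canonical = {g.gene_id for g in structures}
    base = [r["gene_id"] for r in inventory_rows
            if r["clade"] == "base" and r["gene_id"] in canonical]
    cI = [r["gene_id"] for r in inventory_rows
          if r["clade"] == "cladeI" and r["gene_id"] in canonical]
    cII = [r["gene_id"] for r in inventory_rows
           if r["clade"] == "cladeII" and r["gene_id"] in canonical]
    hce1 = [r["gene_id"] for r in inventory_rows if r["clade"] == "cladeI_HCE1"]
    hce2 = [r["gene_id"] for r in inventory_rows if r["clade"] == "cladeI_HCE2"]

    osteo = _mirror_gene_tree(stree["Osteoglossomorpha"],
                              genes_by_sp([g for g in base
                                           if group_of[gene_to_species[g]]
                                           == "Osteoglossomorpha"]))
    elopo = _mirror_gene_tree(stree["Elopomorpha"],
                              genes_by_sp([g for g in base
                                           if group_of[gene_to_species[g]]
                                           == "Elopomorpha"]))
    cI_oto = _mirror_gene_tree(stree["Otocephala"], genes_by_sp(cI))
    salm_dup = "({},{})".format(
        _mirror_gene_tree(stree["SalmEsoc"], genes_by_sp(hce1)),
        _mirror_gene_tree(stree["SalmEsoc"], genes_by_sp(hce2)))
    eut_I_rest = [g for g in cI
                  if group_of[gene_to_species[g]] == "Euteleostei"]
    cI_eut_frags = [salm_dup]
    for child in stree["Euteleostei"].children:
        if child.id == "SalmEsoc":
            continue
        frag = _mirror_gene_tree(child, genes_by_sp(eut_I_rest))
        if frag:
            cI_eut_frags.append(frag)
    cI_eut = "(" + ",".join(cI_eut_frags) + ")"
    clade_I = f"({cI_oto},{cI_eut})"
    clade_II = _mirror_gene_tree(stree["Clupeocephala"], genes_by_sp(cII))
    newick = f"[&R] ({osteo},({elopo},({clade_I},{clade_II})DupClupeo));"
    gene_tree = RootedTree.from_newick(newick)

    expected = {
        "duplication_branches": ["Clupeocephala", "SalmEsoc"],
        "gene_losses": [{"branch_child": "Otophysi", "clade": "cladeII"}],
        "intron_losses": {
            "cladeI": {"Otocephala": ["i2"],
                       "Otophysi": ["i6", "i7", "i8"],
                       "Characiphysi": ["i1"],
                       "Euteleostei": [f"i{n}" for n in range(1, 9)]},
            "cladeII": {"Euteleostei": ["i8"],
                        "SalmEsoc": [f"i{n}" for n in range(1, 8)]},
        },
        "intron_gains": {"cladeI_HCE1": {"SalmEsoc": [f"c{NOVEL_CODON}p0"]}},
        "n_loss_branches": 6,
        "max_cumulative_losses": {"cladeI": 8},
        "root_intron_count": 8,
        "leaf_intron_counts": {
            "elopomorph_base": 8, "clupeiform_gonorynchiform_cladeI": 7,
            "cypriniform_cladeI": 4, "characiphysan_cladeI": 3,
            "euteleost_cladeI": 0, "otocephalan_cladeII": 8,
            "euteleost_cladeII": 7, "salmoniform_esociform_cladeII": 0},
    }
    clade_reps = {"base": "AwHE", "cladeI": "ZHE1", "cladeII": "MLCE",
                  "cladeI_HCE1": "MsHCE1", "cladeI_HCE2": "MsHCE2"}
    basal_reference = [g for g in base]
    return PaperFixture(
        species_tree=stree, gene_tree=gene_tree, structures=structures,
        alignment=alignment, gene_to_species=gene_to_species,
        inventory=inventory, basal_reference=basal_reference,
        expected=expected, clade_representatives=clade_reps)


# ---------------------------------------------------------------------------
# simulator
# ---------------------------------------------------------------------------

class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Generative settings for a simulated gene-family history.

    Duplications and gene losses are designated as (lineage id, branch child
    node id) pairs; the root lineage is ``L1`` and each duplication creates
    two daughters numbered sequentially in traversal order. Intron losses
    are independent Bernoulli draws per (branch, present site); gains occur
    per branch with probability ``p_intron_gain`` at a globally unused
    position, so every novel site is gained exactly once.
    """

    species_tree: str = "teleost27"
    duplication_branches: tuple[tuple[str, str], ...] = ()
    gene_loss_branches: tuple[tuple[str, str], ...] = ()
    p_intron_loss: float = 0.1
    p_intron_gain: float = 0.0
    substitution_rate: float = 0.01
    n_ancestral_sites: int = 8
    protein_length: int = PROTEIN_LENGTH
    intron_length_bp: int = INTRON_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_intron_loss", "p_intron_gain", "substitution_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.n_ancestral_sites >= self.protein_length:
            raise ConfigError("more ancestral sites than codon boundaries")


@dataclass
class GroundTruth:
    events: list[dict]                  # kind/lineage/branch/site records
    site_map: dict[str, tuple[int, int]]  # site id -> (codon column, phase)
    root_sites: list[str]
    gene_lineage: dict[str, str]
    leaf_sites: dict[str, set[str]]

    def losses(self) -> list[dict]:
        return [e for e in self.events if e["kind"] == "intron_loss"]

    def gains(self) -> list[dict]:
        return [e for e in self.events if e["kind"] == "intron_gain"]


@dataclass
class SimulationResult:
    config: SimulationConfig
    species_tree: RootedTree
    gene_tree: RootedTree
    structures: list[GeneStructure]
    alignment: CodonAlignment
    gene_to_species: dict[str, str]
    ground_truth: GroundTruth


def simulate(cfg: SimulationConfig) -> SimulationResult:
    """Evolve a gene family down the species tree; deterministic under seed."""
    rng = np.random.default_rng(cfg.seed)
    newick = TELEOST27_NEWICK if cfg.species_tree == "teleost27" \
        else cfg.species_tree
    stree = RootedTree.from_newick(newick, assume_rooted=True)

    L = cfg.protein_length
    ancestral_protein = "".join(
        np.array(list(AA_ALPHABET))[rng.integers(0, 20, L)])
    codons = [(k + 1) * L // (cfg.n_ancestral_sites + 1)
              for k in range(cfg.n_ancestral_sites)]
    site_map: dict[str, tuple[int, int]] = {
        f"i{k + 1}": (codons[k], 0) for k in range(cfg.n_ancestral_sites)}
    used_codons = set(codons)
    root_sites = sorted(site_map, key=lambda s: site_map[s])

    dups = set(cfg.duplication_branches)
    gene_losses = set(cfg.gene_loss_branches)
    events: list[dict] = []
    gene_lineage: dict[str, str] = {}
    leaf_sites: dict[str, set[str]] = {}
    structures: list[GeneStructure] = []
    rows_aln: dict[str, str] = {}
    gene_to_species: dict[str, str] = {}
    lineage_counter = [1]

    def new_lineage() -> str:
        lineage_counter[0] += 1
        return f"L{lineage_counter[0]}"

    def branch_evolve(lineage: str, branch_child: str, sites: set[str],
                      protein: str) -> Optional[tuple[set[str], str]]:
        if (lineage, branch_child) in gene_losses:
            events.append({"kind": "gene_loss", "lineage": lineage,
                           "branch": branch_child})
            return None
        sites = set(sites)
        for site in sorted(sites, key=lambda s: site_map[s]):
            if rng.random() < cfg.p_intron_loss:
                sites.discard(site)
                events.append({"kind": "intron_loss", "lineage": lineage,
                               "branch": branch_child, "site": site})
        if rng.random() < cfg.p_intron_gain:
            free = sorted(set(range(1, L)) - used_codons)
            if free:
                codon = free[int(rng.integers(len(free)))]
                phase = int(rng.integers(3))
                used_codons.add(codon)
                site = f"g{codon}p{phase}"
                site_map[site] = (codon, phase)
                sites.add(site)
                events.append({"kind": "intron_gain", "lineage": lineage,
                               "branch": branch_child, "site": site})
        n_sub = rng.binomial(L, cfg.substitution_rate)
        protein = _mutate(protein, int(n_sub), rng)
        return sites, protein

    def emit(leaf, lineage: str, sites: set[str], protein: str) -> str:
        gene_id = f"{leaf.id}__{lineage}"
        gene_to_species[gene_id] = leaf.id
        gene_lineage[gene_id] = lineage
        leaf_sites[gene_id] = set(sites)
        offsets = sorted(site_map[s][0] * 3 + site_map[s][1] for s in sites)
        structures.append(make_gene_structure(
            gene_id, leaf.id, protein, offsets, rng,
            intron_length=cfg.intron_length_bp))
        rows_aln[gene_id] = protein
        return gene_id

    def visit(node, lineage: str, sites: set[str], protein: str
              ) -> Optional[str]:
        """Returns the newick fragment of the gene tree below this point."""
        if (lineage, node.id) in dups:
            a, b = new_lineage(), new_lineage()
            events.append({"kind": "duplication", "lineage": lineage,
                           "branch": node.id, "daughters": [a, b]})
            frags = [descend(node, lid, sites, protein) for lid in (a, b)]
            frags = [f for f in frags if f]
            if not frags:
                return None
            return frags[0] if len(frags) == 1 else "(" + ",".join(frags) + ")"
        return descend(node, lineage, sites, protein)

    def descend(node, lineage: str, sites: set[str], protein: str
                ) -> Optional[str]:
        if node.is_leaf:
            return emit(node, lineage, sites, protein)
        frags = []
        for child in node.children:
            evolved = branch_evolve(lineage, child.id, sites, protein)
            if evolved is None:
                continue
            frag = visit(child, lineage, *evolved)
            if frag:
                frags.append(frag)
        if not frags:
            return None
        return frags[0] if len(frags) == 1 else "(" + ",".join(frags) + ")"

    frag = visit(stree.root, "L1", set(root_sites), ancestral_protein)
    if frag is None:
        raise ConfigError("all gene lineages lost; nothing to emit")
    if "," not in frag:
        frag = f"({frag})"
    gene_tree = RootedTree.from_newick(f"[&R] {frag};")

    truth = GroundTruth(events=events, site_map=dict(site_map),
                        root_sites=root_sites, gene_lineage=gene_lineage,
                        leaf_sites=leaf_sites)
    return SimulationResult(
        config=cfg, species_tree=stree, gene_tree=gene_tree,
        structures=structures, alignment=CodonAlignment(rows=rows_aln),
        gene_to_species=gene_to_species, ground_truth=truth)
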