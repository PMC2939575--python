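"""Intron-site homology: projection onto a protein alignment and the
presence/absence character matrix.

Two introns are treated as the same evolutionary character when they project
to the same alignment column with the same phase; equal columns with unequal
phases are always distinct sites. Sites present in a designated basal
reference set of genes are the "ancestral" sites and are numbered 1..n
left-to-right; all other sites are lineage-specific/novel (``ancestral_number
= None``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from Bio import AlignIO

from .gene_models import GeneStructure, IntronPosition, intron_positions

log = logging.getLogger(__name__)

PRESENT, ABSENT, MISSING = "1", "0", "?"

__all__ = [
    "CodonAlignment", "IntronSite", "IntronSiteMatrix",
    "project_intron", "cluster_sites", "column_slop_merge", "build_matrix",
    "PRESENT", "ABSENT", "MISSING",
]


@dataclass
class CodonAlignment:
    """A protein multiple alignment with per-gene residue -> column maps.

    ``offsets`` gives, per gene, the index within the full protein of the
    first aligned residue (0 when the alignment covers the whole protein,
    positive when only e.g. the mature-enzyme portion was aligned).
    """

    rows: dict[str, str]
    offsets: dict[str, int] = field(default_factory=dict)
    gap: str = "-"

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")
        self._colmap: dict[str, list[int]] = {}
        for gene, row in self.rows.items():
            self._colmap[gene] = [i for i, ch in enumerate(row) if ch != self.gap]

    @classmethod
    def from_fasta(cls, path: Union[str, Path],
                   offsets: Optional[Mapping[str, int]] = None) -> "CodonAlignment":
        aln = AlignIO.read(str(path), "fasta")
        return cls(rows={rec.id: str(rec.seq) for rec in aln},
                   offsets=dict(offsets or {}))

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.rows

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def ungapped(self, gene_id: str) -> str:
        return self.rows[gene_id].replace(self.gap, "")

    def n_residues(self, gene_id: str) -> int:
        return len(self._colmap[gene_id])

    def column_of_residue(self, gene_id: str, residue_index: int) -> Optional[int]:
        """Alignment column of a (full-protein) residue index, or None."""
        local = residue_index - self.offsets.get(gene_id, 0)
        cols = self._colmap[gene_id]
        if 0 <= local < len(cols):
            return cols[local]
        return None

    def residue_at_column(self, gene_id: str, column: int) -> Optional[str]:
        ch = self.rows[gene_id][column]
        return None if ch == self.gap else ch

    def to_fasta(self) -> str:
        return "".join(f">{g}\n{s}\n" for g, s in self.rows.items())


@dataclass(frozen=True)
class IntronSite:
    site_id: str
    column: int
    phase: int
    ancestral_number: Optional[int] = None


@dataclass
class IntronSiteMatrix:
    """Genes x homologous intron sites; states present/absent/missing."""

    genes: list[str]
    sites: list[IntronSite]
    states: pd.DataFrame  # index = genes, columns = site_ids, values in {1,0,?}

    def state(self, gene_id: str, site_id: str) -> str:
        return self.states.at[gene_id, site_id]

    def site(self, site_id: str) -> IntronSite:
        return next(s for s in self.sites if s.site_id == site_id)

    def present_count(self, gene_id: str) -> int:
        return int((self.states.loc[gene_id] == PRESENT).sum())

    def ancestral_sites(self) -> list[IntronSite]:
        return [s for s in self.sites if s.ancestral_number is not None]

    def site_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"site_id": s.site_id, "column": s.column, "phase": s.phase,
              "ancestral_number": s.ancestral_number} for s in self.sites],
            columns=["site_id", "column", "phase", "ancestral_number"])

    def to_tsv(self) -> str:
        return self.states.to_csv(sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def project_intron(g: GeneStructure, aln: CodonAlignment,
                   p: IntronPosition) -> Optional[tuple[int, int]]:
    """Project one intron onto the alignment as ``(column, phase)``.

    Phase-1/2 introns map to the column of the residue whose codon they
    interrupt; phase-0 introns map to the column of the residue immediately
    following the insertion point (the boundary before that codon). Returns
    ``None`` when the insertion point lies outside the aligned region.
    """
    column = aln.column_of_residue(g.gene_id, p.codon_index)
    if column is None:
        return None
    return column, p.phase


# ---------------------------------------------------------------------------
# site clustering
# ---------------------------------------------------------------------------

def column_slop_merge(sites: Sequence[tuple[int, int]],
                      tolerance: int = 0) -> dict[tuple[int, int], tuple[int, int]]:
    """Merge same-phase (column, phase) keys whose columns lie within
    ``tolerance`` of a neighbour, onto the leftmost column of each chain.

    Merging is the transitive closure of the |dc| <= tolerance relation
    within one phase; tolerance 0 is the identity. Returns a mapping from
    every input key to its merged representative.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    mapping: dict[tuple[int, int], tuple[int, int]] = {}
    by_phase: dict[int, list[int]] = {}
    for col, phase in sites:
        by_phase.setdefault(phase, []).append(col)
    for phase, cols in by_phase.items():
        cols = sorted(set(cols))
        anchor = cols[0] if cols else 0
        prev = None
        for col in cols:
            if prev is None or col - prev > tolerance:
                anchor = col
            mapping[(col, phase)] = (anchor, phase)
            prev = col
    return mapping


def cluster_sites(projections: Mapping[str, Sequence[tuple[int, int]]],
                  basal_reference: Iterable[str] = (),
                  tolerance: int = 0) -> list[IntronSite]:
    """Cluster per-gene ``(column, phase)`` projections into homologous sites.

    ``projections`` maps gene ids to their projected introns (from one
    shared alignment). Sites observed in at least one basal-reference gene
    get ancestral numbers 1..n in column order; others get ``None``.
    """
    keys = [k for projs in projections.values() for k in projs]
    merged = column_slop_merge(keys, tolerance)
    basal = set(basal_reference)
    all_keys = sorted(set(merged.values()))
    ancestral_keys = sorted({merged[k] for gene, projs in projections.items()
                             if gene in basal for k in projs})
    numbers = {key: i + 1 for i, key in enumerate(ancestral_keys)}
    sites = []
    for col, phase in all_keys:
        number = numbers.get((col, phase))
        sid = f"i{number}" if number is not None else f"c{col}p{phase}"
        sites.append(IntronSite(site_id=sid, column=col, phase=phase,
                                ancestral_number=number))
    return sites


# ---------------------------------------------------------------------------
# matrix construction
# ---------------------------------------------------------------------------

def build_matrix(genes: Sequence[GeneStructure], aln: CodonAlignment,
                 basal_reference: Iterable[str] = (),
                 tolerance: int = 0,
                 include_exceptions: bool = False) -> IntronSiteMatrix:
    """Build the genes x intron-sites character matrix.

    Genes absent from the alignment (or scored as exceptions, unless
    ``include_exceptions``) are excluded with a warning; genes with no
    alignable region are dropped rather than scored all-missing. Cells are
    ``?`` (missing) where the site's column is a gap in, or outside, the
    gene's aligned row. Row and site order are deterministic: input gene
    order; sites by (column, phase).
    """
    kept: list[GeneStructure] = []
    for g in genes:
        if g.exception and not include_exceptions:
            log.info("%s: flagged as lineage-specific exception; excluded", g.gene_id)
            continue
        if g.gene_id not in aln:
            log.warning("%s: not in alignment; excluded from matrix", g.gene_id)
            continue
        if aln.n_residues(g.gene_id) == 0:
            log.warning("%s: no alignable region; dropped", g.gene_id)
            continue
        kept.append(g)

    projections: dict[str, list[tuple[int, int]]] = {}
    for g in kept:
        projs = []
        for p in intron_positions(g):
            key = project_intron(g, aln, p)
            if key is None:
                log.info("%s: intron at CDS offset %d not projectable; missing",
                         g.gene_id, p.cds_offset)
                continue
            projs.append(key)
        projections[g.gene_id] = projs

    sites = cluster_sites(projections, basal_reference, tolerance)
    merged = column_slop_merge(
        [k for projs in projections.values() for k in projs], tolerance)

    gene_ids = [g.gene_id for g in kept]
    data = {}
    for g in kept:
        own = {merged[k] for k in projections[g.gene_id]}
        row = {}
        for s in sites:
            if (s.column, s.phase) in own:
                row[s.site_id] = PRESENT
            elif aln.residue_at_column(g.gene_id, s.column) is None:
                row[s.site_id] = MISSING
            else:
                row[s.site_id] = ABSENT
        data[g.gene_id] = row
    states = pd.DataFrame.from_dict(data, orient="index")
    states = states.reindex(index=gene_ids, columns=[s.site_id for s in sites])
    if states.empty:
        states = pd.DataFrame(index=pd.Index(gene_ids, dtype=object),
                              columns=pd.Index([], dtype=object), dtype=object)
    return IntronSiteMatrix(genes=gene_ids, sites=sites, states=states)
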