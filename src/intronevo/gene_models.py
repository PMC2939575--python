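"""Gene structures, intron positions/phases, and splice-site checks.

A :class:`GeneStructure` is an ordered list of exon intervals on the coding
strand plus the CDS offsets within the spliced transcript. Everything
downstream works in a single convention: 0-based, half-open coordinates on
the coding strand. Minus-strand input records are normalised at the parser
boundary (coordinates flipped, sequence reverse-complemented), so a round
trip through a minus-strand record and its plus-strand equivalent yields
identical intron positions.

The intron insertion point of intron *i* is the CDS offset of the first base
of the downstream exon; its phase is that offset modulo 3 (0 = between
codons, 1/2 = within a codon).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}

__all__ = [
    "GeneStructure",
    "IntronPosition",
    "SpliceSiteReport",
    "GeneStructureError",
    "FrameError",
    "parse_structures",
    "intron_positions",
    "splice_site_report",
    "predict_terminal_intron",
    "intron_position_table",
]


class GeneStructureError(ValueError):
    """Structural problem in an input gene record (names the gene)."""


class FrameError(GeneStructureError):
    """CDS length is not a positive multiple of three."""


@dataclass
class GeneStructure:
    """One gene copy: exon intervals on the coding strand plus CDS offsets.

    ``exons`` are 0-based half-open intervals into the gene region (coding
    strand); ``cds_start``/``cds_end`` are offsets within the concatenation
    of the exons (the spliced transcript), with ``cds_end`` one past the stop
    codon. ``genomic_seq``, when present, is the coding-strand sequence of
    the whole gene region the exon coordinates index into.
    """

    gene_id: str
    species_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    genomic_seq: Optional[str] = None
    exception: bool = False

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise GeneStructureError(f"{self.gene_id}: strand must be + or -")
        if not self.exons:
            raise GeneStructureError(f"{self.gene_id}: no exons")
        prev_end = -1
        for start, end in self.exons:
            if end <= start:
                raise GeneStructureError(f"{self.gene_id}: empty exon {start}-{end}")
            if start < prev_end:
                raise GeneStructureError(
                    f"{self.gene_id}: exons overlap or are out of order at {start}")
            prev_end = end
        cds_len = self.cds_end - self.cds_start
        if cds_len <= 0 or cds_len % 3 != 0:
            raise FrameError(
                f"{self.gene_id}: CDS length {cds_len} is not a positive multiple of 3")
        if self.cds_end > self.spliced_length:
            raise GeneStructureError(
                f"{self.gene_id}: CDS end {self.cds_end} exceeds spliced length "
                f"{self.spliced_length}")
        if self.genomic_seq is not None and self.exons[-1][1] > len(self.genomic_seq):
            raise GeneStructureError(
                f"{self.gene_id}: exon coordinates exceed sequence bounds")

    # ------------------------------------------------------------- derived
    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def spliced_length(self) -> int:
        return sum(end - start for start, end in self.exons)

    def spliced_seq(self) -> str:
        if self.genomic_seq is None:
            raise GeneStructureError(f"{self.gene_id}: no genomic sequence attached")
        return "".join(self.genomic_seq[s:e] for s, e in self.exons)

    def cds_seq(self) -> str:
        return self.spliced_seq()[self.cds_start:self.cds_end]

    def protein(self) -> str:
        aa = str(Seq(self.cds_seq()).translate())
        return aa[:-1] if aa.endswith("*") else aa

    def intron_interval(self, i: int) -> tuple[int, int]:
        """Genomic interval (coding strand) of intron ``i`` (0-based)."""
        if not 0 <= i < self.n_introns:
            raise IndexError(f"{self.gene_id}: no intron {i}")
        return self.exons[i][1], self.exons[i + 1][0]

    def spliced_to_genomic(self, offset: int) -> int:
        """Map a spliced-transcript offset to a gene-region coordinate."""
        if offset < 0 or offset > self.spliced_length:
            raise GeneStructureError(f"{self.gene_id}: spliced offset {offset} out of range")
        remaining = offset
        for start, end in self.exons:
            if remaining <= end - start:
                return start + remaining
            remaining -= end - start
        return self.exons[-1][1]


@dataclass(frozen=True)
class IntronPosition:
    """A coding-region intron located by its CDS insertion offset."""

    intron_index: int
    cds_offset: int

    @property
    def codon_index(self) -> int:
        return self.cds_offset // 3

    @property
    def phase(self) -> int:
        return self.cds_offset % 3


@dataclass(frozen=True)
class SpliceSiteReport:
    intron_index: int
    donor_dinucleotide: str
    acceptor_dinucleotide: str

    @property
    def canonical(self) -> bool:
        return self.donor_dinucleotide == "GT" and self.acceptor_dinucleotide == "AG"


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _normalise_minus(exons, seq, seq_len):
    """Flip minus-strand coordinates onto the coding strand."""
    if seq is not None:
        seq_len = len(seq)
        seq = str(Seq(seq).reverse_complement())
    if seq_len is None:
        seq_len = max(e for _, e in exons)
    flipped = sorted((seq_len - e, seq_len - s) for s, e in exons)
    return flipped, seq


def _load_fasta(seqs) -> dict[str, str]:
    if seqs is None:
        return {}
    if isinstance(seqs, Mapping):
        return {k: str(v) for k, v in seqs.items()}
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(seqs), "fasta")}


def parse_structures(records: Union[str, Path, pd.DataFrame],
                     seqs: Union[None, str, Path, Mapping[str, str]] = None,
                     *, fmt: Optional[str] = None) -> list[GeneStructure]:
    """Parse gene structures from a TSV exon table or a GFF3 file.

    TSV columns: ``gene_id``, ``species_id``, ``strand``, ``exon_start``,
    ``exon_end`` (one row per exon; 0-based half-open) with optional
    per-gene ``cds_start``/``cds_end`` spliced offsets and an optional
    ``exception`` flag column. GFF3 input (1-based, inclusive) is converted
    at this boundary; the species is taken from a ``species=`` attribute on
    the gene feature. ``seqs`` supplies gene-region sequences keyed by
    gene id (TSV) or seqid (GFF3).
    """
    sequences = _load_fasta(seqs)
    if fmt is None:
        if isinstance(records, pd.DataFrame):
            fmt = "tsv"
        else:
            fmt = "gff3" if str(records).endswith((".gff", ".gff3")) else "tsv"
    if fmt == "tsv":
        table = records if isinstance(records, pd.DataFrame) else pd.read_csv(
            records, sep="\t", dtype={"gene_id": str, "species_id": str})
        return _parse_tsv(table, sequences)
    if fmt == "gff3":
        return _parse_gff3(str(records), sequences)
    raise ValueError(f"unknown structure format {fmt!r}")


def _parse_tsv(table: pd.DataFrame, sequences: dict[str, str]) -> list[GeneStructure]:
    required = {"gene_id", "species_id", "strand", "exon_start", "exon_end"}
    missing = required - set(table.columns)
    if missing:
        raise GeneStructureError(f"exon table lacks columns {sorted(missing)}")
    out = []
    for gene_id, grp in table.groupby("gene_id", sort=False):
        strand = grp["strand"].iloc[0]
        exons = [(int(s), int(e)) for s, e in zip(grp["exon_start"], grp["exon_end"])]
        seq = sequences.get(gene_id)
        if strand == "-":
            exons, seq = _normalise_minus(exons, seq, None)
        else:
            exons = sorted(exons)
        spliced = sum(e - s for s, e in exons)
        cds_start = int(grp["cds_start"].iloc[0]) if "cds_start" in grp else 0
        cds_end = int(grp["cds_end"].iloc[0]) if "cds_end" in grp else spliced
        exception = bool(grp["exception"].iloc[0]) if "exception" in grp else False
        out.append(GeneStructure(
            gene_id=str(gene_id), species_id=str(grp["species_id"].iloc[0]),
            strand=strand, exons=exons, cds_start=cds_start, cds_end=cds_end,
            genomic_seq=seq, exception=exception))
    return out


def _parse_gff3(path: str, sequences: dict[str, str]) -> list[GeneStructure]:
    import gffutils

    db = gffutils.create_db(path, ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    out = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if len(mrnas) > 1:
            raise GeneStructureError(f"{gene.id}: more than one mRNA per gene")
        parent = mrnas[0] if mrnas else gene
        exon_feats = sorted(db.children(parent, featuretype="exon"),
                            key=lambda f: f.start)
        cds_feats = sorted(db.children(parent, featuretype="CDS"),
                           key=lambda f: f.start)
        if not exon_feats:
            exon_feats = cds_feats
        strand = gene.strand or "+"
        region = sequences.get(gene.seqid)
        origin = min(f.start for f in exon_feats) - 1 if region is None else 0
        # 1-based inclusive -> 0-based half-open, region-local
        exons = [(f.start - 1 - origin, f.end - origin) for f in exon_feats]
        exons = sorted(exons)
        if strand == "-":
            plus_order = exons
            exons, region = _normalise_minus(exons, region,
                                             None if region is not None else
                                             max(e for _, e in plus_order))
        spliced = sum(e - s for s, e in exons)
        if cds_feats and cds_feats is not exon_feats:
            cds_lo = min(f.start for f in cds_feats) - 1 - origin
            cds_hi = max(f.end for f in cds_feats) - origin
            if strand == "-":
                length = (max(e for _, e in plus_order))
                if region is not None:
                    length = len(region)
                cds_lo, cds_hi = length - cds_hi, length - cds_lo
            cds_start = _genomic_to_spliced(exons, cds_lo, gene.id)
            cds_end = _genomic_to_spliced(exons, cds_hi, gene.id)
        else:
            cds_start, cds_end = 0, spliced
        species = gene.attributes.get("species", [gene.seqid])[0]
        out.append(GeneStructure(
            gene_id=gene.id, species_id=species, strand=strand, exons=exons,
            cds_start=cds_start, cds_end=cds_end, genomic_seq=region))
    return out


def _genomic_to_spliced(exons, pos, gene_id):
    spliced = 0
    for start, end in exons:
        if start <= pos <= end:
            return spliced + pos - start
        spliced += end - start
    raise GeneStructureError(f"{gene_id}: CDS boundary {pos} outside exons")


# ---------------------------------------------------------------------------
# intron positions and splice sites
# ---------------------------------------------------------------------------

def intron_positions(g: GeneStructure) -> list[IntronPosition]:
    """Coding-region intron insertion points, ascending by CDS offset.

    Introns whose insertion point falls in a UTR are excluded (logged, not
    an error); the analysis concerns coding-region introns only.
    """
    out = []
    spliced = 0
    cds_len = g.cds_end - g.cds_start
    for i in range(g.n_introns):
        spliced += g.exons[i][1] - g.exons[i][0]
        cds_offset = spliced - g.cds_start
        if 0 <= cds_offset < cds_len:
            out.append(IntronPosition(intron_index=i, cds_offset=cds_offset))
        else:
            log.info("%s: intron %d lies in a UTR; excluded", g.gene_id, i)
    return out


def splice_site_report(g: GeneStructure) -> list[SpliceSiteReport]:
    """Donor/acceptor dinucleotides for every intron (GT...AG check)."""
    if g.genomic_seq is None:
        raise GeneStructureError(
            f"{g.gene_id}: splice-site check requires a genomic sequence")
    seq = g.genomic_seq.upper()
    out = []
    for i in range(g.n_introns):
        start, end = g.intron_interval(i)
        out.append(SpliceSiteReport(
            intron_index=i,
            donor_dinucleotide=seq[start:start + 2],
            acceptor_dinucleotide=seq[end - 2:end]))
    return out


def predict_terminal_intron(g: GeneStructure, window: int = 10) -> bool:
    """Predict an unconfirmed terminal intron from a downstream donor ``GT``.

    When the final exon of a gene could not be located directly (as is
    common when the last exon carries little coding sequence), the presence
    of a canonical 5'-splice-site ``GT`` just downstream of the last
    confirmed coding position predicts that one more intron and exon exist.
    Returns ``False`` when the annotated CDS already ends in a stop codon
    within the last exon (no further exon is needed), or when no ``GT``
    occurs within ``window`` bases downstream of the candidate boundary.
    """
    if g.genomic_seq is None:
        raise GeneStructureError(
            f"{g.gene_id}: terminal-intron prediction requires a genomic sequence")
    cds = g.cds_seq().upper()
    if len(cds) >= 3 and cds[-3:] in STOP_CODONS:
        return False
    boundary = g.spliced_to_genomic(g.cds_end)
    downstream = g.genomic_seq.upper()[boundary:boundary + window + 1]
    return "GT" in downstream


def intron_position_table(genes: Iterable[GeneStructure]) -> pd.DataFrame:
    """Flat per-intron table (with the canonical GT...AG flag when possible)."""
    rows = []
    for g in genes:
        reports = {r.intron_index: r for r in splice_site_report(g)} \
            if g.genomic_seq is not None else {}
        for p in intron_positions(g):
            rep = reports.get(p.intron_index)
            rows.append({
                "gene_id": g.gene_id, "intron_index": p.intron_index,
                "cds_offset": p.cds_offset, "codon_index": p.codon_index,
                "phase": p.phase,
                "canonical": rep.canonical if rep else None})
    return pd.DataFrame(rows, columns=["gene_id", "intron_index", "cds_offset",
                                       "codon_index", "phase", "canonical"])
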