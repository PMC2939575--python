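import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from intronevo.gene_models import (FrameError, GeneStructure,
                                   GeneStructureError, intron_positions,
                                   parse_structures, predict_terminal_intron,
                                   splice_site_report)
from intronevo.synthetic_data import make_gene_structure


def toy_table(exons, strand="+", gene="g1", cds=None):
    rows = [{"gene_id": gene, "species_id": "sp", "strand": strand,
             "exon_start": s, "exon_end": e} for s, e in exons]
    df = pd.DataFrame(rows)
    if cds is not None:
        df["cds_start"], df["cds_end"] = cds
    return df


def test_single_exon_gene_has_zero_introns():
    genes = parse_structures(toy_table([(0, 903)]))
    assert genes[0].n_introns == 0
    assert intron_positions(genes[0]) == []


def test_nine_exon_gene_has_eight_introns(paper_fixture):
    g = next(s for s in paper_fixture.structures if s.gene_id == "AwHE")
    assert len(g.exons) == 9
    assert g.n_introns == 8
    assert len(intron_positions(g)) == 8


def test_minus_strand_record_equals_plus_strand_equivalent():
    # 60 bp toy gene: 3 exons of 12/24/24 nt, CDS covers everything
    rng = np.random.default_rng(5)
    plus = make_gene_structure("p", "sp", "MKLV" + "A" * 14 + "WY",
                               [12, 30], rng, intron_length=20)
    # express the same gene as a minus-strand record on the opposite strand
    L = len(plus.genomic_seq)
    minus_seq = str(Seq(plus.genomic_seq).reverse_complement())
    rows = toy_table([(L - e, L - s) for s, e in plus.exons], strand="-",
                     cds=(plus.cds_start, plus.cds_end))
    genes = parse_structures(rows, {"g1": minus_seq})
    minus = genes[0]
    assert minus.exons == plus.exons
    assert minus.genomic_seq == plus.genomic_seq
    assert minus.protein() == plus.protein()
    assert [(p.cds_offset, p.phase) for p in intron_positions(minus)] == \
           [(p.cds_offset, p.phase) for p in intron_positions(plus)]


@pytest.mark.parametrize("cds_offset,phase", [(300, 0), (301, 1), (302, 2)])
def test_intron_phase_is_cds_offset_mod_3(cds_offset, phase):
    exons = [(0, cds_offset), (cds_offset + 100, cds_offset + 100 + 903 - cds_offset)]
    genes = parse_structures(toy_table(exons))
    (pos,) = intron_positions(genes[0])
    assert pos.cds_offset == cds_offset
    assert pos.phase == phase
    assert pos.codon_index == cds_offset // 3


def test_phase_partition_matches_per_nucleotide_scan(paper_fixture):
    # brute force: an insertion point at CDS nucleotide n interrupts codon
    # n//3 after n%3 bases; the reported phases must match that scan exactly
    for g in paper_fixture.structures[:6]:
        spliced = 0
        expected = []
        cds_len = g.cds_end - g.cds_start
        for i in range(g.n_introns):
            spliced += g.exons[i][1] - g.exons[i][0]
            n = spliced - g.cds_start
            if 0 <= n < cds_len:
                expected.append((n // 3, n % 3))
        got = [(p.codon_index, p.phase) for p in intron_positions(g)]
        assert got == expected


def test_utr_introns_are_excluded_not_errors():
    # intron sits at spliced offset 10, within the 12 nt 5' UTR
    genes = parse_structures(toy_table([(0, 10), (100, 1005)],
                                       cds=(12, 915)))
    assert genes[0].n_introns == 1
    assert intron_positions(genes[0]) == []


def test_splice_site_reports_flag_non_canonical_donor():
    rng = np.random.default_rng(0)
    g = make_gene_structure("g", "sp", "MKLVAY", [9], rng, intron_length=20)
    (rep,) = splice_site_report(g)
    assert rep.donor_dinucleotide == "GT" and rep.acceptor_dinucleotide == "AG"
    assert rep.canonical
    seq = list(g.genomic_seq)
    seq[g.intron_interval(0)[0]] = "C"  # break the donor
    broken = GeneStructure(gene_id="g", species_id="sp", strand="+",
                           exons=g.exons, cds_start=g.cds_start,
                           cds_end=g.cds_end, genomic_seq="".join(seq))
    (rep2,) = splice_site_report(broken)
    assert not rep2.canonical


def test_all_fixture_introns_are_canonical(paper_fixture):
    for g in paper_fixture.structures:
        assert all(r.canonical for r in splice_site_report(g))


def test_terminal_intron_predicted_from_downstream_gt(paper_fixture):
    # truncate a 9-exon gene to its first 8 exons, CDS ending at the last
    # confirmed coding position: the real intron 8 donor GT sits right
    # downstream, so the 9th exon is predicted
    g = next(s for s in paper_fixture.structures if s.gene_id == "EHE4")
    cut = sum(e - s for s, e in g.exons[:8]) - g.cds_start
    truncated = GeneStructure(
        gene_id="EHE4_trunc", species_id=g.species_id, strand="+",
        exons=g.exons[:8], cds_start=g.cds_start,
        cds_end=g.cds_start + cut - cut % 3, genomic_seq=g.genomic_seq)
    assert predict_terminal_intron(truncated) is True


def test_no_terminal_intron_when_stop_codon_in_last_exon():
    rng = np.random.default_rng(1)
    g = make_gene_structure("bt", "sp", "MKLVAY", [9], rng, intron_length=20)
    # CDS ends with the stop codon inside the final exon
    assert g.cds_seq()[-3:] == "TAA"
    assert predict_terminal_intron(g) is False


def test_no_terminal_intron_without_gt_in_window():
    seq = "ATG" * 10 + "CCCCCCCCCCCC"  # no GT downstream
    g = GeneStructure(gene_id="g", species_id="sp", strand="+",
                      exons=[(0, 30)], cds_start=0, cds_end=30,
                      genomic_seq=seq)
    assert predict_terminal_intron(g, window=10) is False


def test_structural_errors_name_the_gene():
    with pytest.raises(GeneStructureError, match="bad1"):
        parse_structures(toy_table([(0, 100), (50, 200)], gene="bad1",
                                   cds=(0, 150)))
    with pytest.raises(FrameError, match="bad2"):
        parse_structures(toy_table([(0, 100)], gene="bad2"))


def test_gff3_parsing_matches_tsv(tmp_path):
    rng = np.random.default_rng(3)
    g = make_gene_structure("gene1", "sp1", "MKLVAYWCDE", [15], rng,
                            intron_length=20)
    gff = tmp_path / "g.gff3"
    lines = ["##gff-version 3",
             f"chr1\t.\tgene\t1\t{len(g.genomic_seq)}\t.\t+\t.\tID=gene1;species=sp1",
             f"chr1\t.\tmRNA\t1\t{len(g.genomic_seq)}\t.\t+\t.\tID=m1;Parent=gene1"]
    for s, e in g.exons:
        lines.append(f"chr1\t.\texon\t{s + 1}\t{e}\t.\t+\t.\tParent=m1")
    cds_lo = g.spliced_to_genomic(g.cds_start)
    cds_hi = g.spliced_to_genomic(g.cds_end)
    # CDS features per exon overlap
    for s, e in g.exons:
        lo, hi = max(s, cds_lo), min(e, cds_hi)
        if lo < hi:
            lines.append(f"chr1\t.\tCDS\t{lo + 1}\t{hi}\t.\t+\t0\tParent=m1")
    gff.write_text("\n".join(lines) + "\n")
    (parsed,) = parse_structures(str(gff), {"chr1": g.genomic_seq})
    assert parsed.exons == g.exons
    assert (parsed.cds_start, parsed.cds_end) == (g.cds_start, g.cds_end)
    assert parsed.species_id == "sp1"
    assert parsed.protein() == g.protein()
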