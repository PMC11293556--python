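import numpy as np
import pandas as pd
import pytest

from dartcall.annotation_io import (PileupConfig, SiteCountTable, SnpMask,
                                    TranscriptModel, load_snp_mask,
                                    load_transcript_models,
                                    pileup_site_counts, read_site_counts,
                                    select_longest_isoform, write_calls_bed,
                                    write_site_counts, write_snp_vcf)
from conftest import random_count_table


# ---------------------------------------------------------------------------
# GTF / transcript models
# ---------------------------------------------------------------------------

TOY_GTF = """\
chr1\ttest\texon\t1\t100\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\ttest\texon\t201\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\ttest\tCDS\t51\t100\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\ttest\tCDS\t201\t300\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
"""


def test_load_two_exon_coding_transcript(tmp_path):
    path = tmp_path / "toy.gtf"
    path.write_text(TOY_GTF)
    ts = load_transcript_models(path)
    tm = ts["t1"]
    assert tm.exons == ((0, 100), (200, 400))
    assert (tm.cds_start, tm.cds_end) == (50, 300)
    assert tm.mature_length == 300
    assert tm.gene_id == "g1"


def test_load_empty_gtf(tmp_path):
    path = tmp_path / "empty.gtf"
    path.write_text("")
    assert len(load_transcript_models(path)) == 0


def _isoform_gtf(lengths_by_id):
    lines = []
    for tid, length in lengths_by_id.items():
        lines.append(f'chrX\tt\texon\t1\t{length}\t.\t+\t.\t'
                     f'gene_id "g"; transcript_id "{tid}";')
    return "\n".join(lines) + "\n"


def test_longest_isoform_and_tie_break(tmp_path):
    path = tmp_path / "iso.gtf"
    path.write_text(_isoform_gtf({"NM_3": 500, "NM_2": 800, "NM_1": 800}))
    ts = load_transcript_models(path)
    # 800-nt tie resolved to the lexicographically smallest id
    assert select_longest_isoform(ts, "g").transcript_id == "NM_1"
    path2 = tmp_path / "iso2.gtf"
    path2.write_text(_isoform_gtf({"a": 1000, "b": 400}))
    ts2 = load_transcript_models(path2)
    assert select_longest_isoform(ts2, "g").transcript_id == "a"
    with pytest.raises(KeyError):
        select_longest_isoform(ts2, "nope")


def test_transcript_model_invariants():
    with pytest.raises(ValueError):  # overlapping exons
        TranscriptModel("t", "g", "c", "+", ((0, 100), (50, 200)))
    with pytest.raises(ValueError):  # CDS outside exon span
        TranscriptModel("t", "g", "c", "+", ((0, 100),), 50, 200)
    tm = TranscriptModel("t", "g", "c", "-", ((0, 100), (200, 300)),
                         cds_start=50, cds_end=250)
    assert tm.mature_length == 200
    # minus strand: mature 0 is the genomic 3' end
    assert tm.genomic_to_mature(299) == 0
    assert tm.genomic_to_mature(0) == 199
    assert tm.genomic_to_mature(150) is None  # intronic


# ---------------------------------------------------------------------------
# SNP mask / VCF
# ---------------------------------------------------------------------------

def test_vcf_coordinate_conversion_and_dedup(tmp_path):
    path = tmp_path / "m.vcf"
    write_snp_vcf([(("chr1"), 100), ("chr1", 100), ("chr2", 4)], path)
    mask = load_snp_mask(path)
    assert ("chr1", 100) in mask          # POS=101 in the file
    assert ("chr1", 101) not in mask
    assert len(mask) == 2


def test_empty_vcf(tmp_path):
    path = tmp_path / "empty.vcf"
    path.write_text("##fileformat=VCFv4.2\n##contig=<ID=chr1>\n"
                    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    assert len(load_snp_mask(path)) == 0


def test_mask_union_of_multiple_vcfs(tmp_path):
    a, b = tmp_path / "a.vcf", tmp_path / "b.vcf"
    write_snp_vcf([("chr1", 10)], a)
    write_snp_vcf([("chr1", 20), ("chr1", 10)], b)
    assert len(load_snp_mask([a, b])) == 2


def test_mask_accepts_stranded_keys():
    mask = SnpMask([("chr1", 5)])
    assert ("chr1", 5, "+") in mask and ("chr1", 5, "-") in mask


# ---------------------------------------------------------------------------
# Site-count tables
# ---------------------------------------------------------------------------

def test_site_count_roundtrip_randomized(tmp_path):
    rng = np.random.default_rng(0)
    tables = [random_count_table(rng, n=150, sample_id=f"s{i}",
                                 condition=c, replicate=i)
              for i, c in enumerate(["YTH", "WT", "YTHmut"], start=1)]
    path = tmp_path / "counts.tsv"
    write_site_counts(tables, path)
    back = read_site_counts(path)
    assert len(back) == len(tables)
    for orig, rt in zip(tables, back):
        assert (orig.sample_id, orig.condition, orig.replicate) == \
               (rt.sample_id, rt.condition, rt.replicate)
        pd.testing.assert_frame_equal(
            orig.df.reset_index(drop=True), rt.df.reset_index(drop=True),
            check_dtype=False)


@pytest.mark.parametrize("bad_row", [
    {"m": 5, "k": 3},              # m > k
    {"m": 1, "k": 3, "ref": "G"},  # non-C reference
    {"m": 0, "k": 0},              # zero coverage retained
])
def test_schema_violations_fatal(bad_row):
    row = {"chrom": "chr1", "pos": 1, "strand": "+", "ref": "C"}
    row.update(bad_row)
    with pytest.raises(ValueError):
        SiteCountTable("s", "YTH", 1, pd.DataFrame([row]))


def test_calls_bed_score_scaling(tmp_path):
    from dartcall.edit_detection import EditSite
    calls = {("chr1", 7, "+"): EditSite("chr1", 7, "+", 5, 20, 1e-6, 1e-5)}
    path = tmp_path / "c.bed"
    write_calls_bed(calls, path)
    chrom, start, end, name, score, strand = \
        path.read_text().strip().split("\t")
    assert (chrom, start, end, strand) == ("chr1", "7", "8", "+")
    assert score == "250"  # round(1000 * 0.25)
    write_calls_bed({}, path)
    assert path.read_text() == ""


# ---------------------------------------------------------------------------
# Pileup vs a naive per-read oracle
# ---------------------------------------------------------------------------

def _make_bam(tmp_path, reads, ref_seq, name="toy"):
    import pysam
    fa = tmp_path / f"{name}.fa"
    fa.write_text(f">chr1\n{ref_seq}\n")
    pysam.faidx(str(fa))
    sam = tmp_path / f"{name}.sam"
    body = "\n".join(reads)
    sam.write_text("@HD\tVN:1.6\tSO:coordinate\n"
                   f"@SQ\tSN:chr1\tLN:{len(ref_seq)}\n" + body + "\n")
    bam = tmp_path / f"{name}.bam"
    pysam.sort("-o", str(bam), str(sam))
    pysam.index(str(bam))
    return bam, fa


def _naive_pileup(reads, ref_seq):
    """Per-read, per-column counting oracle (full-length M-only reads)."""
    cols = {}
    for line in reads:
        f = line.split("\t")
        if int(f[1]) & 0x400:   # duplicate flag
            continue
        start = int(f[3]) - 1
        for i, base in enumerate(f[9]):
            cols.setdefault(start + i, []).append(base)
    out = {}
    for pos, bases in cols.items():
        ref = ref_seq[pos]
        if ref == "C":
            out[(pos, "+")] = (sum(b == "T" for b in bases), len(bases))
        if ref == "G":
            out[(pos, "-")] = (sum(b == "A" for b in bases), len(bases))
    return out


def test_pileup_matches_naive_oracle_both_strands(tmp_path):
    rng = np.random.default_rng(1)
    ref = "".join(rng.choice(list("ACGT"), size=60))
    reads = []
    for i in range(40):
        start = int(rng.integers(0, 40))
        seq = list(ref[start:start + 20])
        for j in range(len(seq)):
            if seq[j] == "C" and rng.random() < 0.3:
                seq[j] = "T"
            elif seq[j] == "G" and rng.random() < 0.3:
                seq[j] = "A"
        reads.append(f"r{i}\t0\tchr1\t{start + 1}\t60\t{len(seq)}M\t*\t0\t0\t"
                     f"{''.join(seq)}\t{'I' * len(seq)}")
    bam, fa = _make_bam(tmp_path, reads, ref)
    table = pileup_site_counts(bam, fa, PileupConfig())
    expected = _naive_pileup(reads, ref)
    got = {(int(r.pos), r.strand): (int(r.m), int(r.k))
           for r in table.df.itertuples()}
    assert got == {k: v for k, v in expected.items() if v[1] > 0}


def test_pileup_minus_strand_example(tmp_path):
    # genomic G with A-carrying reads counts as editing on the minus strand
    ref = "AAGAA"
    reads = []
    for i in range(8):
        base = "A" if i < 2 else "G"
        seq = "AA" + base + "AA"
        reads.append(f"r{i}\t0\tchr1\t1\t60\t5M\t*\t0\t0\t{seq}\t{'I' * 5}")
    bam, fa = _make_bam(tmp_path, reads, ref)
    table = pileup_site_counts(bam, fa, PileupConfig())
    row = table.df[(table.df.pos == 2) & (table.df.strand == "-")].iloc[0]
    assert (row.m, row.k) == (2, 8)


def test_pileup_excludes_duplicate_reads(tmp_path):
    ref = "ACAAA"
    reads = [f"r{i}\t1024\tchr1\t1\t60\t5M\t*\t0\t0\tATAAA\t{'I' * 5}"
             for i in range(5)]
    bam, fa = _make_bam(tmp_path, reads, ref)
    table = pileup_site_counts(bam, fa, PileupConfig())
    # only duplicate-flagged coverage -> no rows at all
    assert len(table.df) == 0
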