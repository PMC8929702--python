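"""Reading, aggregation and round-trip behavior of the count I/O layer."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contness import counts_io as cio
from contness.errors import FormatError, ValidationError

SAMPLES2 = [
    cio.SampleMeta("s1", "WT", "ctrl", 1),
    cio.SampleMeta("s2", "WT", "stress", 1),
]


def _poolcount_file(tmp_path, text, name="pc.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


def test_read_poolcount_parses_rows_and_columns(tmp_path):
    p = _poolcount_file(
        tmp_path,
        "barcode\tscaffold\tstrand\tpos\ts1\ts2\n"
        "AAA\tchr1\t+\t150\t5\t0\n"
        "CCC\tchr1\t-\t160\t0\t2\n"
        "GGG\tchr2\t+\t300\t7\t1\n",
    )
    table = cio.read_poolcount(p, SAMPLES2)
    assert len(table.sites) == 3
    assert table.sample_ids == ["s1", "s2"]
    assert table.per_sample_totals().tolist() == [12, 3]


def test_read_poolcount_missing_position_column(tmp_path):
    p = _poolcount_file(
        tmp_path, "barcode\tscaffold\tstrand\ts1\ts2\nAAA\tchr1\t+\t5\t0\n"
    )
    with pytest.raises(FormatError, match="pos"):
        cio.read_poolcount(p, SAMPLES2)


def test_read_poolcount_negative_count_rejected(tmp_path):
    p = _poolcount_file(
        tmp_path,
        "barcode\tscaffold\tstrand\tpos\ts1\ts2\nAAA\tchr1\t+\t150\t-3\t0\n",
    )
    with pytest.raises(ValidationError, match="row 0"):
        cio.read_poolcount(p, SAMPLES2)


def test_poolcount_roundtrip_identity(fixture_files, tmp_path):
    pool, _genes, samples = fixture_files
    meta = cio.read_sample_table(samples)
    table = cio.read_poolcount(pool, meta)
    out = tmp_path / "again.tsv"
    cio.write_poolcount(table, out)
    again = cio.read_poolcount(out, meta)
    pd.testing.assert_frame_equal(table.sites, again.sites)
    pd.testing.assert_frame_equal(table.counts, again.counts)


@pytest.mark.parametrize(
    "row,expect_len",
    [("geneA\tchr1\t100\t200\t+\n", 101)],
)
def test_read_gene_table_tsv(tmp_path, row, expect_len):
    p = tmp_path / "genes.tsv"
    p.write_text("locus\tscaffold\tstart\tend\tstrand\n" + row)
    gt = cio.read_gene_table(p, dialect="tsv")
    g = gt.genes.iloc[0]
    assert g["locus"] == "geneA"
    assert g["end"] - g["start"] + 1 == expect_len


def test_read_gene_table_gff3_locus_tag(tmp_path):
    p = tmp_path / "genes.gff3"
    p.write_text(
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t100\t200\t.\t+\t.\tID=g1;locus_tag=geneA\n"
        "chr1\tsrc\tCDS\t100\t200\t.\t+\t0\tID=c1\n"
    )
    gt = cio.read_gene_table(p, dialect="gff3")
    assert gt.loci == ["geneA"]
    assert gt.genes.iloc[0]["start"] == 100 and gt.genes.iloc[0]["end"] == 200


@pytest.mark.parametrize(
    "body,err",
    [
        ("geneA\tchr1\t300\t200\t+\n", "start"),
        ("geneA\tchr1\t100\t200\t+\ngeneA\tchr1\t400\t500\t+\n", "duplicate"),
    ],
)
def test_read_gene_table_validation(tmp_path, body, err):
    p = tmp_path / "genes.tsv"
    p.write_text("locus\tscaffold\tstart\tend\tstrand\n" + body)
    with pytest.raises(ValidationError, match=err):
        cio.read_gene_table(p, dialect="tsv")


def _site_table(rows):
    sites = pd.DataFrame(
        [(r[0], r[1], "+", r[2]) for r in rows],
        columns=["site_id", "scaffold", "strand", "position"],
    )
    counts = pd.DataFrame([r[3] for r in rows], columns=["s1", "s2"])
    return cio.SiteCountTable(sites=sites, counts=counts, samples=SAMPLES2)


def _one_gene(start=100, end=200):
    return cio.GeneTable(
        genes=pd.DataFrame(
            [("g1", "chr1", start, end, "+")],
            columns=["locus", "scaffold", "start", "end", "strand"],
        )
    )


def test_aggregate_counts_total_and_unique_definitions():
    sites = _site_table(
        [("a", "chr1", 150, (5, 5)), ("b", "chr1", 160, (0, 1)), ("c", "chr1", 300, (7, 7))]
    )
    total, unique = cio.aggregate_counts(sites, _one_gene(), trim_frac=0.0)
    assert total.values.loc["g1"].tolist() == [5, 6]
    assert unique.values.loc["g1"].tolist() == [1, 2]


def test_aggregate_counts_trim_excludes_edge_sites():
    # gene [100, 200], trim 0.2 of length 101 -> window [120, 180]
    sites = _site_table(
        [("a", "chr1", 110, (9, 9)), ("b", "chr1", 150, (5, 5))]
    )
    total, _ = cio.aggregate_counts(sites, _one_gene(), trim_frac=0.2)
    assert total.values.loc["g1"].tolist() == [5, 5]


def test_aggregate_matches_brute_force_oracle(fixture_files):
    pool, genes, samples = fixture_files
    meta = cio.read_sample_table(samples)
    table = cio.read_poolcount(pool, meta)
    gene_table = cio.read_gene_table(genes, dialect="tsv")
    total, unique = cio.aggregate_counts(table, gene_table, trim_frac=0.0)

    counts = table.counts.to_numpy()
    for _, g in gene_table.genes.iterrows():
        mask = (
            (table.sites["scaffold"] == g["scaffold"])
            & (table.sites["position"] >= g["start"])
            & (table.sites["position"] <= g["end"])
        ).to_numpy()
        np.testing.assert_array_equal(
            total.values.loc[g["locus"]].to_numpy(), counts[mask].sum(axis=0)
        )
        np.testing.assert_array_equal(
            unique.values.loc[g["locus"]].to_numpy(), (counts[mask] > 0).sum(axis=0)
        )
    # totals dominate uniques when derived from one site table
    assert (total.values.to_numpy() >= unique.values.to_numpy()).all()


@settings(max_examples=25, deadline=None)
@given(split=st.integers(min_value=0, max_value=200), data=st.data())
def test_aggregate_additive_over_disjoint_site_splits(fixture_files, split, data):
    pool, genes, samples = fixture_files
    meta = cio.read_sample_table(samples)
    table = cio.read_poolcount(pool, meta)
    gene_table = cio.read_gene_table(genes, dialect="tsv")
    n = len(table.sites)
    k = min(split, n)
    parts = []
    for sl in (slice(0, k), slice(k, n)):
        parts.append(
            cio.SiteCountTable(
                sites=table.sites.iloc[sl].reset_index(drop=True),
                counts=table.counts.iloc[sl].reset_index(drop=True),
                samples=meta,
            )
        )
    whole_t, whole_u = cio.aggregate_counts(table, gene_table)
    part_t = sum(cio.aggregate_counts(p, gene_table)[0].values for p in parts)
    part_u = sum(cio.aggregate_counts(p, gene_table)[1].values for p in parts)
    pd.testing.assert_frame_equal(whole_t.values, part_t)
    # row-disjoint splits share no sites, so unique counts add as well
    pd.testing.assert_frame_equal(whole_u.values, part_u)


def test_gene_counts_roundtrip_preserves_flavor(tmp_path):
    m = cio.GeneCountMatrix(
        flavor="unique",
        values=pd.DataFrame([[1, 2], [3, 4]], index=["g1", "g2"], columns=["s1", "s2"]),
    )
    path = tmp_path / "m.tsv"
    cio.write_gene_counts(m, path)
    back = cio.read_gene_counts(path)
    assert back.flavor == "unique"
    pd.testing.assert_frame_equal(back.values, m.values)


def test_gene_counts_empty_matrix_roundtrip(tmp_path):
    m = cio.GeneCountMatrix(
        flavor="total", values=pd.DataFrame(columns=["s1", "s2"], dtype=np.int64)
    )
    path = tmp_path / "empty.tsv"
    cio.write_gene_counts(m, path)
    back = cio.read_gene_counts(path)
    assert back.flavor == "total"
    assert len(back.values) == 0 and list(back.values.columns) == ["s1", "s2"]


def test_gene_counts_duplicate_row_rejected(tmp_path):
    path = tmp_path / "dup.tsv"
    path.write_text("#flavor=total\ngene\ts1\ng1\t1\ng1\t2\n")
    with pytest.raises(ValidationError, match="duplicate"):
        cio.read_gene_counts(path)
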