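"""Reading, writing and gene-level aggregation of transposon-insertion count data.

The entry point of an analysis is a *poolcount-style* table: one row per
insertion site (or barcode), with metadata columns (``barcode``, ``scaffold``,
``strand``, ``pos``) followed by one integer read-count column per sequenced
sample.  Together with a gene annotation (GFF3 or a 5-column TSV) and a
sample-metadata table mapping each count column to a
(genetic background, environment, replicate) triple, the site-level counts are
aggregated into two gene x sample matrices:

* **total** counts — the sum of reads over all insertion sites inside the gene
  body, a proxy for the abundance of all mutants of that gene;
* **unique** counts — the number of distinct insertion sites with non-zero
  reads in that sample, a complexity measure robust to jackpot sites.

All genomic coordinates are 1-based inclusive (GFF convention); the insertion
position is the single reported 5' position of the transposon junction.
Sites are assigned to genes irrespective of strand, and a site falling in two
overlapping genes contributes to both.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "SampleMeta",
    "SiteCountTable",
    "GeneTable",
    "GeneCountMatrix",
    "read_sample_table",
    "write_sample_table",
    "read_poolcount",
    "write_poolcount",
    "read_gene_table",
    "aggregate_counts",
    "write_gene_counts",
    "read_gene_counts",
]

_META_COLUMNS = ("barcode", "scaffold", "strand", "pos")


@dataclass(frozen=True)
class SampleMeta:
    """One sequenced sample: a (background, environment, replicate) cell."""

    sample_id: str
    background: str
    environment: str
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: replicate must be a positive "
                f"integer, got {self.replicate}"
            )


@dataclass
class SiteCountTable:
    """Per-insertion-site read counts across samples.

    ``sites`` holds one row per site (site_id, scaffold, strand, position);
    ``counts`` is positionally aligned with ``sites`` and has one integer
    column per sample_id.
    """

    sites: pd.DataFrame
    counts: pd.DataFrame
    samples: list[SampleMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sites) != len(self.counts):
            raise ValidationError("sites and counts row counts differ")
        if (self.sites["position"] < 1).any():
            bad = int(self.sites.index[self.sites["position"] < 1][0])
            raise ValidationError(f"row {bad}: position must be >= 1")
        if (self.counts.to_numpy() < 0).any():
            bad = int(np.argwhere((self.counts.to_numpy() < 0).any(axis=1))[0, 0])
            raise ValidationError(f"row {bad}: negative count")
        ids = {s.sample_id for s in self.samples}
        missing = [c for c in self.counts.columns if c not in ids]
        if self.samples and missing:
            raise ValidationError(
                f"count columns without sample metadata: {missing}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def per_sample_totals(self) -> pd.Series:
        """Observed insertions per experiment (column sums)."""
        return self.counts.sum(axis=0)


@dataclass
class GeneTable:
    """Gene coordinates: locus, scaffold, start, end, strand (1-based inclusive)."""

    genes: pd.DataFrame

    def __post_init__(self) -> None:
        g = self.genes
        if g["locus"].duplicated().any():
            dup = g.loc[g["locus"].duplicated(), "locus"].iloc[0]
            raise ValidationError(f"duplicate locus {dup!r}")
        bad = g["start"] > g["end"]
        if bad.any():
            row = g[bad].iloc[0]
            raise ValidationError(
                f"gene {row['locus']!r}: start {row['start']} > end {row['end']}"
            )
        if (g["start"] < 1).any():
            raise ValidationError("gene start coordinates must be >= 1")

    @property
    def loci(self) -> list[str]:
        return list(self.genes["locus"])

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneCountMatrix:
    """Gene x sample count matrix of one flavor ("total" or "unique")."""

    flavor: str
    values: pd.DataFrame  # index: gene ids; columns: sample ids; dtype int

    def __post_init__(self) -> None:
        if self.flavor not in ("total", "unique"):
            raise ValidationError(f"unknown flavor {self.flavor!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("gene counts must be non-negative")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate gene row {dup!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# sample metadata


def read_sample_table(path) -> list[SampleMeta]:
    """Read a sample-metadata TSV (sample_id, background, environment, replicate)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = ["sample_id", "background", "environment", "replicate"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"sample table is missing column {col!r}")
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in sample table")
    return [
        SampleMeta(
            sample_id=row.sample_id,
            background=row.background,
            environment=row.environment,
            replicate=int(row.replicate),
        )
        for row in df.itertuples()
    ]


def write_sample_table(samples: list[SampleMeta], path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "background": [s.background for s in samples],
            "environment": [s.environment for s in samples],
            "replicate": [s.replicate for s in samples],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# poolcount I/O


def read_poolcount(path, sample_map: list[SampleMeta]) -> SiteCountTable:
    """Read a poolcount-style TSV of per-site read counts.

    The header must contain the metadata columns ``barcode``, ``scaffold``,
    ``strand`` and ``pos`` (``position`` is accepted as an alias), followed by
    one count column per sample in *sample_map*.  Extra count columns not in
    *sample_map* are dropped.  Rows whose scaffold matches no gene are kept —
    they simply aggregate to nothing.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "position" in df.columns and "pos" not in df.columns:
        df = df.rename(columns={"position": "pos"})
    for col in _META_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"poolcount file is missing required column {col!r}")
    for s in sample_map:
        if s.sample_id not in df.columns:
            raise FormatError(
                f"poolcount file has no count column for sample {s.sample_id!r}"
            )
    sample_ids = [s.sample_id for s in sample_map]

    try:
        positions = pd.to_numeric(df["pos"], errors="raise").astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-numeric position: {exc}") from exc
    sites = pd.DataFrame(
        {
            "site_id": df["barcode"].astype(str),
            "scaffold": df["scaffold"].astype(str),
            "strand": df["strand"].astype(str),
            "position": positions,
        }
    )

    counts = pd.DataFrame(index=df.index)
    for sid in sample_ids:
        col = pd.to_numeric(df[sid], errors="coerce")
        if col.isna().any():
            row = int(col.index[col.isna()][0])
            raise ValidationError(f"row {row}, sample {sid!r}: non-numeric count")
        if (col < 0).any():
            row = int(col.index[col < 0][0])
            raise ValidationError(f"row {row}, sample {sid!r}: negative count")
        counts[sid] = col.astype(np.int64)

    return SiteCountTable(sites=sites, counts=counts, samples=list(sample_map))


def write_poolcount(table: SiteCountTable, path) -> None:
    """Write a SiteCountTable back to poolcount TSV (inverse of read_poolcount)."""
    out = pd.DataFrame(
        {
            "barcode": table.sites["site_id"],
            "scaffold": table.sites["scaffold"],
            "strand": table.sites["strand"],
            "pos": table.sites["position"],
        }
    )
    for sid in table.counts.columns:
        out[sid] = table.counts[sid]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene annotation


def _parse_gff3_attributes(attr: str) -> dict:
    out = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        k, v = part.split("=", 1)
        out[k] = v
    return out


def read_gene_table(path, dialect: str = "tsv") -> GeneTable:
    """Read gene coordinates from a 5-column TSV or a GFF3 file.

    TSV dialect: columns (locus, scaffold, start, end, strand), header
    optional.  GFF3 dialect: rows of type ``gene``; the locus is taken from
    the ``locus_tag`` attribute, falling back to ``ID`` then ``Name``.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#", header=None)
        if str(df.iloc[0, 0]).lower() in ("locus", "gene", "locus_tag"):
            df = df.iloc[1:].reset_index(drop=True)
        if df.shape[1] < 5:
            raise FormatError(
                f"gene TSV needs 5 columns (locus, scaffold, start, end, strand), "
                f"got {df.shape[1]}"
            )
        genes = pd.DataFrame(
            {
                "locus": df.iloc[:, 0].astype(str),
                "scaffold": df.iloc[:, 1].astype(str),
                "start": pd.to_numeric(df.iloc[:, 2]).astype(np.int64),
                "end": pd.to_numeric(df.iloc[:, 3]).astype(np.int64),
                "strand": df.iloc[:, 4].astype(str),
            }
        )
    elif dialect == "gff3":
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 9:
                    raise FormatError("GFF3 rows must have 9 tab-separated columns")
                if fields[2] != "gene":
                    continue
                attrs = _parse_gff3_attributes(fields[8])
                locus = attrs.get("locus_tag") or attrs.get("ID") or attrs.get("Name")
                if locus is None:
                    raise FormatError(
                        "GFF3 gene row lacks locus_tag/ID/Name attribute"
                    )
                rows.append(
                    (locus, fields[0], int(fields[3]), int(fields[4]), fields[6])
                )
        genes = pd.DataFrame(
            rows, columns=["locus", "scaffold", "start", "end", "strand"]
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return GeneTable(genes=genes)


# ---------------------------------------------------------------------------
# aggregation


def aggregate_counts(
    sites: SiteCountTable,
    genes: GeneTable,
    trim_frac: float = 0.0,
) -> tuple[GeneCountMatrix, GeneCountMatrix]:
    """Aggregate site-level counts to per-gene total and unique matrices.

    For a gene spanning [start, end] of length L = end - start + 1 and a
    trim fraction t, a site is assigned to the gene when its position lies in
    [start + floor(t*L), end - floor(t*L)].  Total counts sum the reads of
    assigned sites; unique counts count assigned sites with non-zero reads in
    that sample.  Strand is ignored; overlapping genes each receive the site.
    """
    if not (0.0 <= trim_frac < 0.5):
        raise ValidationError(f"trim_frac must be in [0, 0.5), got {trim_frac}")

    sample_ids = sites.sample_ids
    n_genes = len(genes)
    totals = np.zeros((n_genes, len(sample_ids)), dtype=np.int64)
    uniques = np.zeros((n_genes, len(sample_ids)), dtype=np.int64)

    count_arr = sites.counts.to_numpy()
    # sort sites once per scaffold for interval slicing
    by_scaffold: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    scaff = sites.sites["scaffold"].to_numpy()
    pos = sites.sites["position"].to_numpy()
    for sc in np.unique(scaff):
        idx = np.flatnonzero(scaff == sc)
        order = np.argsort(pos[idx], kind="stable")
        by_scaffold[sc] = (pos[idx][order], idx[order])

    g = genes.genes
    for gi, row in enumerate(g.itertuples()):
        entry = by_scaffold.get(row.scaffold)
        if entry is None:
            continue
        sorted_pos, orig_idx = entry
        length = row.end - row.start + 1
        trim = int(np.floor(trim_frac * length))
        lo, hi = row.start + trim, row.end - trim
        a = np.searchsorted(sorted_pos, lo, side="left")
        b = np.searchsorted(sorted_pos, hi, side="right")
        if a == b:
            continue
        sub = count_arr[orig_idx[a:b]]
        totals[gi] = sub.sum(axis=0)
        uniques[gi] = (sub > 0).sum(axis=0)

    loci = genes.loci
    total_m = GeneCountMatrix(
        flavor="total",
        values=pd.DataFrame(totals, index=loci, columns=sample_ids),
    )
    unique_m = GeneCountMatrix(
        flavor="unique",
        values=pd.DataFrame(uniques, index=loci, columns=sample_ids),
    )
    return total_m, unique_m


# ---------------------------------------------------------------------------
# gene-count matrix I/O


def write_gene_counts(matrix: GeneCountMatrix, path) -> None:
    """Write a gene-count TSV with a '#flavor=' header comment."""
    buf = io.StringIO()
    buf.write(f"#flavor={matrix.flavor}\n")
    out = matrix.values.copy()
    out.insert(0, "gene", out.index)
    out.to_csv(buf, sep="\t", index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_gene_counts(path) -> GeneCountMatrix:
    """Read a gene-count TSV written by :func:`write_gene_counts`."""
    flavor = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#flavor="):
            flavor = first.strip().split("=", 1)[1]
            rest = fh.read()
        else:
            rest = first + fh.read()
    if flavor is None:
        raise FormatError("gene-count file lacks '#flavor=' header comment")
    df = pd.read_csv(io.StringIO(rest), sep="\t")
    if "gene" not in df.columns:
        raise FormatError("gene-count file must have a 'gene' first column")
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise ValidationError(f"duplicate gene row {dup!r}")
    values = df.set_index("gene")
    values.index.name = None
    values = values.astype(np.int64)
    return GeneCountMatrix(flavor=flavor, values=values)
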