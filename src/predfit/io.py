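"""File-format helpers: FASTA genomes, GFF3-flavoured gene tables,
supplementary-format spreadsheets."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GFF_COLUMNS = [
    "seqid",
    "source",
    "type",
    "start",
    "end",
    "score",
    "strand",
    "frame",
    "attributes",
]


def write_fasta(genome: str, path, seq_id: str = "chromosome") -> None:
    SeqIO.write([SeqRecord(Seq(genome), id=seq_id, description="")], str(path), "fasta")


def read_fasta(path) -> str:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected a single-sequence FASTA, found {len(records)}")
    return str(records[0].seq)


def write_genes_gff(genes: pd.DataFrame, path, seq_id: str = "chromosome") -> None:
    """Serialise a gene table as 9-column GFF3-flavoured TSV."""
    out = pd.DataFrame(
        {
            "seqid": seq_id,
            "source": "predfit",
            "type": "gene",
            "start": genes["start"],
            "end": genes["end"],
            "score": ".",
            "strand": genes["strand"],
            "frame": ".",
            "attributes": "gene_id=" + genes["gene_id"].astype(str),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_genes_gff(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", names=GFF_COLUMNS, comment="#")
    gene_ids = df["attributes"].str.extract(r"gene_id=([^;]+)")[0]
    if gene_ids.isna().any():
        raise ValueError("every GFF row needs a gene_id attribute")
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "start": df["start"].astype(int),
            "end": df["end"].astype(int),
            "strand": df["strand"],
        }
    )


def read_table(path) -> pd.DataFrame:
    """Read a supplementary-style table from .xlsx, .tsv or .csv.

    Header-driven and tolerant: column names are matched downstream
    case-insensitively; legacy binary .xls is not supported — export to
    .xlsx or TSV first.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".xlsx":
        return pd.read_excel(path, engine="openpyxl")
    if suffix == ".xls":
        raise ValueError("legacy .xls is unsupported; export the sheet to .xlsx or .tsv")
    if suffix in (".tsv", ".txt"):
        return pd.read_csv(path, sep="\t")
    if suffix == ".csv":
        return pd.read_csv(path)
    raise ValueError(f"unrecognised table format: {path.name}")


def find_column(df: pd.DataFrame, *candidates: str) -> str:
    """Case-insensitive, substring-tolerant column lookup."""
    lowered = {c.lower().strip(): c for c in df.columns}
    for cand in candidates:
        if cand.lower() in lowered:
            return lowered[cand.lower()]
    for cand in candidates:
        for low, orig in lowered.items():
            if cand.lower() in low:
                return orig
    raise KeyError(
        f"none of the expected headers {list(candidates)} found; "
        f"table has {list(df.columns)}"
    )
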