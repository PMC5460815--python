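"""Readers and writers for the pipeline's file formats.

FASTA goes through Biopython; tabular formats are TSV via pandas. Gene loci
are read from either GFF3 (1-based closed coordinates, ``gene`` features,
``ID=`` attribute) or a minimal TSV with explicit columns. Report tables are
written with ``#``-prefixed header comments stating units and coordinate
conventions.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DwdfamError


def read_fasta(path) -> dict[str, str]:
    """id -> sequence, preserving file order (requires unique ids)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise DwdfamError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(path, sequences: dict[str, str], width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_aligned_fasta(path) -> tuple[list[str], list[str]]:
    seqs = read_fasta(path)
    return list(seqs), list(seqs.values())


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_tsv(path, table: pd.DataFrame, comments: list[str] | None = None,
              index: bool = False) -> None:
    buf = _io.StringIO()
    for line in comments or []:
        buf.write(f"# {line}\n")
    table.to_csv(buf, sep="\t", index=index)
    Path(path).write_text(buf.getvalue())


def read_domains(path) -> pd.DataFrame:
    """Domain annotation TSV: protein_id, domain_name, start, end
    (1-based closed, protein coordinates)."""
    df = read_tsv(path)
    required = {"protein_id", "domain_name", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise DwdfamError(f"domain table {path} missing columns {sorted(missing)}")
    return df


def write_gff3(path, loci: pd.DataFrame, source: str = "dwdfam") -> None:
    """Write gene loci as GFF3 ``gene`` features (1-based closed)."""
    lines = ["##gff-version 3"]
    for row in loci.itertuples():
        lines.append(
            "\t".join(
                [
                    str(row.chromosome),
                    source,
                    "gene",
                    str(int(row.start)),
                    str(int(row.end)),
                    ".",
                    str(row.strand),
                    ".",
                    f"ID={row.gene_id}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_loci(path) -> pd.DataFrame:
    """Read gene loci from GFF3 or a minimal TSV.

    GFF3: ``gene`` features only; gene_id from the ``ID=`` attribute.
    TSV: columns ``gene_id, chromosome, start, end, strand``.
    """
    path = Path(path)
    text = path.read_text()
    if text.startswith("##gff-version") or path.suffix.lower() in (".gff", ".gff3"):
        rows = []
        for line in text.splitlines():
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            if "ID" not in attrs:
                raise DwdfamError(f"gene feature without ID attribute in {path}")
            rows.append(
                (attrs["ID"], parts[0], int(parts[3]), int(parts[4]), parts[6])
            )
        return pd.DataFrame(
            rows, columns=["gene_id", "chromosome", "start", "end", "strand"]
        )
    df = read_tsv(path)
    required = {"gene_id", "chromosome", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise DwdfamError(f"locus table {path} missing columns {sorted(missing)}")
    if "strand" not in df.columns:
        df["strand"] = "+"
    return df


def read_blocks(path) -> pd.DataFrame:
    df = read_tsv(path)
    missing = {"block_id", "gene_a", "gene_b"} - set(df.columns)
    if missing:
        raise DwdfamError(f"block table {path} missing columns {sorted(missing)}")
    return df


def read_expression(path) -> pd.DataFrame:
    """FPKM matrix TSV: first column gene_id, one column per tissue."""
    df = read_tsv(path)
    return df.set_index(df.columns[0])


def write_expression(path, matrix: pd.DataFrame) -> None:
    write_tsv(path, matrix.rename_axis("gene_id"),
              comments=["FPKM matrix: rows = genes, columns = tissues"],
              index=True)


def read_cds_pairs(path) -> list[tuple[str, str, str, str]]:
    """CDS FASTA holding consecutive pairs: records 2k and 2k+1 form pair k.

    Returns ``(id_a, cds_a, id_b, cds_b)`` tuples.
    """
    seqs = read_fasta(path)
    items = list(seqs.items())
    if len(items) % 2:
        raise DwdfamError(f"CDS pair FASTA {path} holds an odd number of records")
    return [
        (items[i][0], items[i][1], items[i + 1][0], items[i + 1][1])
        for i in range(0, len(items), 2)
    ]
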