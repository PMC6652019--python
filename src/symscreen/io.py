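"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA is handled through Biopython, GFF3 reading through gffutils; tables are
tab-separated with a header row.
"""
from __future__ import annotations

import json
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GENE_TABLE_COLUMNS

_GFF_SOURCE = "symscreen"


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    """Write a gene table as GFF3 (one ``gene`` feature per model)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            attrs = (
                f"ID={row.gene_id};ordinal={row.ordinal};"
                f"intron_count={row.intron_count};"
                f"protein_length={row.protein_length};affinity={row.affinity}"
            )
            fh.write(
                "\t".join(
                    [
                        str(row.scaffold),
                        _GFF_SOURCE,
                        "gene",
                        str(row.start),
                        str(row.end),
                        ".",
                        row.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read gene models back into the canonical gene-table frame."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    rows = []
    for feat in db.features_of_type("gene"):
        rows.append(
            {
                "gene_id": feat.id,
                "scaffold": feat.seqid,
                "ordinal": int(feat.attributes["ordinal"][0]),
                "start": feat.start,
                "end": feat.end,
                "strand": feat.strand,
                "intron_count": int(feat.attributes["intron_count"][0]),
                "protein_length": int(feat.attributes["protein_length"][0]),
                "affinity": feat.attributes["affinity"][0],
            }
        )
    frame = pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS)
    return frame.sort_values(["scaffold", "ordinal"], kind="stable").reset_index(
        drop=True
    )


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    raise TypeError(f"cannot serialize {type(obj)!r}")


def write_alignment_fasta(sequences: dict[str, str], path: str | Path) -> None:
    write_fasta(sequences, path)


def read_alignment_fasta(path: str | Path) -> dict[str, str]:
    return read_fasta(path)
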