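"""Plain-text readers and writers for the tabular and sequence formats the
pipeline exchanges between stages.

Every artifact is a flat text file (TSV, FASTA, GFF3/BED6, JSON) so that any
stage can be re-run from its on-disk inputs.  Column schemas:

probe table      probe_id  sequence  replicate  array  fluorescence  is_background
expression table gene_id   stage     replicate  fpkm
category map     gene_id   category_id
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

PROBE_COLUMNS = ["probe_id", "sequence", "replicate", "array", "fluorescence", "is_background"]
EXPRESSION_COLUMNS = ["gene_id", "stage", "replicate", "fpkm"]
CATEGORY_COLUMNS = ["gene_id", "category_id"]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def check_dna(seq: str, allow_n: bool = False) -> None:
    allowed = set(DNA_ALPHABET + ("N" if allow_n else ""))
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"illegal characters in DNA sequence: {sorted(bad)}")


# ---------------------------------------------------------------------------
# TSV tables

def write_probe_table(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, PROBE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_probe_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "sequence": str})
    missing = set(PROBE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"probe table {path} missing columns: {sorted(missing)}")
    df["is_background"] = df["is_background"].astype(bool)
    return df


def write_expression_table(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, EXPRESSION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_expression_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "stage": str})
    missing = set(EXPRESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"expression table {path} missing columns: {sorted(missing)}")
    return df


def write_category_map(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, CATEGORY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_category_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(CATEGORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"category map {path} missing columns: {sorted(missing)}")
    return df


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gene_list(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# JSON helpers

def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
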