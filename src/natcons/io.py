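"""Readers and writers for the pipeline's plain-text formats.

Expression tables are TSV with a ``probeset_id`` key column and either
``<tissue>_rep<k>`` (raw) or ``<tissue>`` (averaged) value columns.
Sequences travel as FASTA, annotations as BED6, homology groups as a
three-column TSV, configuration as YAML and reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .expression import ExpressionMatrix

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_homology",
    "write_homology",
    "write_json",
]


def read_expression_table(path: str | Path, species: str, protocol: str) -> ExpressionMatrix:
    """Parse an expression TSV into an :class:`ExpressionMatrix`.

    Raises informative errors for duplicate probeset ids, non-numeric cells
    and ragged rows (with the offending id or line where recoverable).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "probeset_id":
        raise ValueError(f"{path}: first column must be 'probeset_id', got {df.columns[0]!r}")
    dup = df["probeset_id"][df["probeset_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate probeset id {dup.iloc[0]!r}")
    df = df.set_index("probeset_id")
    try:
        data = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression cell ({exc})") from exc
    if data.isna().any().any():
        bad = data.index[data.isna().any(axis=1)][0]
        raise ValueError(f"{path}: missing cell in row {bad!r}")
    return ExpressionMatrix(species=species, protocol=protocol, data=data)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.data.sort_index()
    out.index.name = "probeset_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_fasta(path: str | Path) -> dict[str, str]:
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sorted(sequences.items())
    ]
    SeqIO.write(recs, str(path), "fasta")


_BED6 = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED6 file (0-based half-open intervals)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValueError(f"{path}: BED6 requires 6 columns, found {df.shape[1]}")
    df = df.iloc[:, :6]
    df.columns = _BED6
    if (~df["strand"].isin(["+", "-"])).any():
        raise ValueError(f"{path}: strandless BED records")
    return df.astype({"start": int, "end": int})


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df[_BED6].sort_values(["chrom", "start", "end", "name"]).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_homology(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = {"group_id", "species", "gene_id"}
    if not expected.issubset(df.columns):
        raise ValueError(f"{path}: homology table needs columns {sorted(expected)}")
    return df


def write_homology(df: pd.DataFrame, path: str | Path) -> None:
    df.sort_values(["group_id", "species", "gene_id"]).to_csv(path, sep="\t", index=False)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=_jsonable) + "\n")


def write_yaml(payload: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
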