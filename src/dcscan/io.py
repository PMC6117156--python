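"""Readers and writers for the pipeline's tabular and sequence formats.

Variant tables are TSV with columns homolog, pos1, aa1, pos2, aa2 (0/"" for
absent slots; positions are 1-based within the mutated segment) plus
stage-specific value columns.  Alignments are FASTA via Biopython.
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

from .calibration import CalibrationParams
from .dca import ALPHABET, decode, encode

_ID_COLS = ["homolog", "pos1", "aa1", "pos2", "aa2"]


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"aa1": str, "aa2": str})
    for col in ("pos1", "pos2", "count_unselected", "count_selected"):
        df[col] = df[col].astype(int)
    return df


def read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    for col in ("pos1", "pos2"):
        if col in df:
            df[col] = df[col].astype(int)
    return df


def write_params(params: CalibrationParams, path, extra: dict | None = None) -> None:
    doc = {"a": params.a, "c": params.c, "l": params.l, "rt": params.rt}
    if extra:
        doc.update(extra)
    Path(path).write_text(yaml.safe_dump(doc))


def read_params(path) -> CalibrationParams:
    doc = yaml.safe_load(Path(path).read_text())
    return CalibrationParams(a=doc["a"], c=doc["c"], l=doc["l"], rt=doc.get("rt", 0.592))


def write_fasta(msa: np.ndarray, path, alphabet: str = ALPHABET, names=None) -> None:
    seqs = decode(np.asarray(msa), alphabet)
    names = names or [f"seq{k}" for k in range(len(seqs))]
    records = [SeqRecord(Seq(s), id=n, description="") for s, n in zip(seqs, names)]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path, alphabet: str = ALPHABET) -> np.ndarray:
    seqs = [str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")]
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return encode(seqs, alphabet)


def write_matrix(matrix: np.ndarray, path) -> None:
    pd.DataFrame(matrix).to_csv(path, sep="\t", index=False, header=False)


def read_matrix(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)


def write_contacts(pairs, path) -> None:
    pd.DataFrame(sorted({(min(i, j), max(i, j)) for i, j in pairs}), columns=["i", "j"]).to_csv(
        path, sep="\t", index=False
    )


def read_contacts(path) -> list[tuple[int, int]]:
    df = pd.read_csv(path, sep="\t")
    return [(int(i), int(j)) for i, j in zip(df["i"], df["j"])]


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
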