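"""Readers and writers for the tabular and sequence formats the pipeline exchanges.

All tables are tab-separated with a header row, UTF-8, identifiers never quoted.
FASTA goes through Biopython (wrapped lines and CRLF tolerated on read; 60-column
wrapping on write). GMT follows the two-leading-column convention
(set name, description, then member ids).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A malformed record in an input file; message carries the line number."""


# ---------------------------------------------------------------------------
# count matrices / sample sheets
# ---------------------------------------------------------------------------

def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a feature-by-sample count table (first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate feature id {dup!r}")
    return df


def write_counts(df: pd.DataFrame, path: str | Path, index_label: str = "feature_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_samples(path: str | Path) -> pd.Series:
    """Read sample-to-group map (columns: sample_id, group)."""
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "group"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns 'sample_id' and 'group'")
    return df.set_index("sample_id")["group"]


def write_samples(groups: pd.Series, path: str | Path) -> None:
    df = groups.rename("group").rename_axis("sample_id").reset_index()
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Parse FASTA into an ordered id -> uppercase-sequence dict.

    Duplicate identifiers are rejected; wrapped and single-line records parse
    identically (Biopython semantics).
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate FASTA identifier {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT record needs name, description and >=1 member"
                )
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


# ---------------------------------------------------------------------------
# edge lists / SIF
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Two-column tab-separated edge list with a header row."""
    edges: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            return edges
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: edge needs two node ids")
            edges.append((fields[0], fields[1]))
    return edges


def write_edge_list(edges: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_a\tnode_b\n")
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def read_sif(path: str | Path) -> list[tuple[str, str, str]]:
    """SIF records as (source, interaction type, target) triples."""
    triples: list[tuple[str, str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: SIF record needs source, type, target")
            for target in fields[2:]:
                triples.append((fields[0], fields[1], target))
    return triples


def write_sif(triples: list[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for src, kind, dst in triples:
            fh.write(f"{src}\t{kind}\t{dst}\n")


# ---------------------------------------------------------------------------
# JSON manifests
# ---------------------------------------------------------------------------

def read_json(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
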