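"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA goes through Biopython, trees through dendropy, tables through
pandas. All tables are tab-separated with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into a list of (id, sequence) pairs, order preserved."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records, path) -> None:
    """Write (id, sequence) pairs as FASTA."""
    seqs = [SeqRecord(Seq(s), id=str(i), description="") for i, s in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_newick(path) -> dendropy.Tree:
    """Parse a newick tree, preserving underscores in tip labels."""
    return dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", unquoted_underscores=True).strip()


def read_json(path):
    return json.loads(Path(path).read_text())


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
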