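"""Readers and writers for the pipeline's file formats.

All tables are plain TSV; sequences are FASTA (Biopython); configuration
is YAML or JSON validated against the known keys.  Genomic intervals use
0-based half-open coordinates internally; GFF3's 1-based closed
convention is converted exactly at this boundary.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from codonscape.codon_core import CodingSequence

__all__ = [
    "read_cds_fasta",
    "read_gene_table",
    "read_counts_tsv",
    "read_trna_reads",
    "read_footprint_track",
    "read_gff3_cds",
    "write_tsv",
    "load_config_file",
]


def read_cds_fasta(
    path: str | Path, organisms: pd.Series | dict | None = None
) -> list[CodingSequence]:
    """Read a CDS collection; organism tags come from an ``organism=``
    token in the description, a ``<organism>_`` id prefix, or the
    supplied gene→organism mapping (which wins)."""
    organisms = dict(organisms) if organisms is not None else {}
    genes = []
    for record in SeqIO.parse(str(path), "fasta"):
        organism = organisms.get(record.id)
        if organism is None:
            for token in record.description.split():
                if token.startswith("organism="):
                    organism = token.split("=", 1)[1]
            if organism is None:
                prefix = record.id.split("_")[0]
                organism = prefix if prefix in ("host", "virus", "organelle") else "host"
        genes.append(
            CodingSequence(
                gene_id=record.id, sequence=str(record.seq), organism=organism
            )
        )
    return genes


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Sidecar gene table: gene_id, organism, length_nt."""
    df = pd.read_csv(path, sep="\t").set_index("gene_id")
    missing = {"organism", "length_nt"} - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns {sorted(missing)}")
    return df


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Gene × sample count table; columns follow <sample>__<assay>__<rep>."""
    return pd.read_csv(path, sep="\t").set_index("gene_id")


def read_trna_reads(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"read_id", "length", "gene_id", "anticodon", "genome"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"tRNA read table missing columns {sorted(missing)}")
    return df


def read_footprint_track(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "codon_index", "codon", "short_count", "long_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"footprint track missing columns {sorted(missing)}")
    return df


def read_gff3_cds(path: str | Path) -> pd.DataFrame:
    """CDS features from a GFF3 file, converted to 0-based half-open.

    Returns a frame with seqid, start, end, strand, gene_id (from the
    ID= or Parent= attribute).  A feature spanning 1..9 in GFF3 becomes
    [0, 9) internally.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype != "CDS":
                continue
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            rows.append(
                {
                    "seqid": seqid,
                    "start": int(start) - 1,  # 1-based closed -> 0-based half-open
                    "end": int(end),
                    "strand": strand,
                    "gene_id": attr_map.get("ID", attr_map.get("Parent", "")),
                }
            )
    return pd.DataFrame(rows, columns=["seqid", "start", "end", "strand", "gene_id"])


def write_tsv(df: pd.DataFrame | pd.Series, path: str | Path, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(df, pd.Series):
        df = df.to_frame()
    df.to_csv(path, sep="\t", index=index)
    return path


def load_config_file(path: str | Path, known_keys: set[str]) -> dict:
    """Load a YAML/JSON config mapping, rejecting unknown keys."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    unknown = set(data) - known_keys
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return data
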