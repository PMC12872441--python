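"""tRNA-seq read filtering and anticodon-level pool quantification.

Input is a pre-summarised alignment table (one row per read×hit) rather
than a BAM file; a documented TSV export of the aligner output is the
contract.  A read is kept for quantification when

1. it is at least 20 nt long,
2. every gene it hits encodes the same anticodon,
3. that anticodon is not NNN (undetermined), TTA (suppressor) or
   TCA (selenocysteine), and
4. all hits fall on the same source genome.

Multi-hit reads passing the filter are counted once (the filter
guarantees a unique anticodon).  The pool is the proportion of retained
reads per anticodon×genome; the scoring pool combines host nuclear and
viral tRNAs by default, with organellar sources trackable separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = ["TRNAPool", "filter_trna_reads", "pool_proportions"]

EXCLUDED_ANTICODONS = frozenset({"NNN", "TTA", "TCA"})

#: required columns of the alignment-summary table (one row per hit)
ALIGNMENT_COLUMNS = ("read_id", "length", "gene_id", "anticodon", "genome")


@dataclass
class TRNAPool:
    """Anticodon-level tRNA abundances.

    ``table`` has columns anticodon, genome, count, proportion, where the
    proportions sum to 1 over the whole pool scope.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        total = self.table["proportion"].sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pool proportions sum to {total}, not 1")
        present = set(self.table["anticodon"]) & EXCLUDED_ANTICODONS
        if present:
            raise ValueError(f"excluded anticodons present: {sorted(present)}")

    def anticodon_proportions(self) -> pd.Series:
        """Proportions summed over source genomes, indexed by anticodon."""
        return self.table.groupby("anticodon")["proportion"].sum()

    def genome_fractions(self) -> pd.Series:
        """Aggregate pool fraction per source genome."""
        return self.table.groupby("genome")["proportion"].sum()

    @classmethod
    def from_counts(cls, counts: pd.Series | dict) -> "TRNAPool":
        """Build a pool from raw per-anticodon counts (single genome).

        ``counts`` maps anticodon (or (anticodon, genome)) to read count.
        """
        s = pd.Series(counts, dtype=float)
        if s.sum() <= 0:
            raise ValueError("pool has no reads")
        if isinstance(s.index, pd.MultiIndex):
            df = s.rename("count").rename_axis(["anticodon", "genome"]).reset_index()
        else:
            df = s.rename("count").rename_axis("anticodon").reset_index()
            df["genome"] = "host"
        df["proportion"] = df["count"] / df["count"].sum()
        return cls(df[["anticodon", "genome", "count", "proportion"]])


def filter_trna_reads(
    alignments: pd.DataFrame,
    min_length: int = 20,
    drop_unknown_anticodon: bool = True,
) -> pd.DataFrame:
    """Apply the four read-retention criteria to an alignment summary.

    Returns one row per retained read with columns
    (read_id, length, anticodon, genome).  Rows with a missing/empty
    anticodon annotation are dropped with a warning when
    ``drop_unknown_anticodon`` is set, otherwise they raise.
    """
    missing = set(ALIGNMENT_COLUMNS) - set(alignments.columns)
    if missing:
        raise ValueError(f"alignment table missing columns {sorted(missing)}")
    df = alignments.copy()
    unknown = df["anticodon"].isna() | (df["anticodon"].astype(str).str.len() == 0)
    if unknown.any():
        if not drop_unknown_anticodon:
            raise ValueError(f"{int(unknown.sum())} hits lack an anticodon annotation")
        warnings.warn(
            f"dropping {int(unknown.sum())} hits with unknown anticodon",
            stacklevel=2,
        )
        df = df[~unknown]
    if df.empty:
        return pd.DataFrame(columns=["read_id", "length", "anticodon", "genome"])

    grouped = df.groupby("read_id").agg(
        length=("length", "first"),
        n_anticodons=("anticodon", "nunique"),
        n_genomes=("genome", "nunique"),
        anticodon=("anticodon", "first"),
        genome=("genome", "first"),
    )
    keep = (
        (grouped["length"] >= min_length)
        & (grouped["n_anticodons"] == 1)
        & (grouped["n_genomes"] == 1)
        & ~grouped["anticodon"].isin(EXCLUDED_ANTICODONS)
    )
    out = grouped.loc[keep, ["length", "anticodon", "genome"]].reset_index()
    return out


def pool_proportions(
    retained_reads: pd.DataFrame, scope_genomes: list[str] | None = None
) -> TRNAPool:
    """Anticodon×genome counts and proportions from filtered reads.

    ``scope_genomes`` restricts the pool (default: every genome present;
    pass e.g. ["host", "virus"] to exclude organellar tRNAs from scoring).
    """
    df = retained_reads
    if scope_genomes is not None:
        df = df[df["genome"].isin(scope_genomes)]
    if df.empty:
        raise ValueError("no retained reads in the requested scope")
    counts = (
        df.groupby(["anticodon", "genome"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )
    counts["proportion"] = counts["count"] / counts["count"].sum()
    return TRNAPool(counts)
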