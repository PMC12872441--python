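"""RPKM/TPM quantification, expression filtering and translation efficiency.

Count tables are pandas DataFrames indexed by gene id with one column per
sample/replicate (the TSV header convention is ``<sample>__<assay>__<rep>``).
A sidecar gene table provides ``organism`` and ``length_nt``.

Conventions used throughout:

* RPKM library sizes are per organism — the total reads uniquely aligned
  to coding regions of the same organism as the gene.
* Gene-level footprint counts exclude the first five codons (including
  the start) and the last five codons (including the stop).
* Genes with RNA or footprint RPKM < 10 in any replicate are discarded
  (strict "<": the boundary is retained).
* TPM can be computed over all genes or rescaled separately within the
  host or virus gene set ("scope").
* Translation efficiency is the geometric mean over replicates of the
  footprint/RNA TPM ratio in the all-genes scope — a deterministic
  simplification of a DESeq2-style mean fold-change; the method tag on
  the output records this.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "compute_rpkm",
    "compute_tpm",
    "filter_expressed_genes",
    "count_footprints_for_gene",
    "compute_te",
]

TE_METHOD_TAG = "geometric-mean TPM ratio (DESeq2 fold-change simplification)"


def _as_frame(counts: pd.DataFrame | pd.Series) -> pd.DataFrame:
    if isinstance(counts, pd.Series):
        return counts.to_frame(name=counts.name or "sample")
    return counts


def compute_rpkm(
    counts: pd.DataFrame | pd.Series,
    gene_lengths_nt: pd.Series,
    library_size: float | pd.Series | None = None,
    organisms: pd.Series | None = None,
) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads.

    RPKM = count / (length_kb * library_size_in_millions).  When
    ``library_size`` is omitted it is computed from the counts: per
    organism per sample if ``organisms`` (gene → organism tag) is given,
    otherwise per sample over all genes.
    """
    df = _as_frame(counts)
    lengths = gene_lengths_nt.reindex(df.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("gene lengths must be positive for every gene")
    if library_size is None:
        if organisms is not None:
            org = organisms.reindex(df.index)
            lib = df.groupby(org.to_numpy()).transform("sum")
        else:
            lib = pd.DataFrame(
                np.broadcast_to(df.sum(axis=0).to_numpy(), df.shape),
                index=df.index,
                columns=df.columns,
            )
    elif np.isscalar(library_size):
        lib = pd.DataFrame(float(library_size), index=df.index, columns=df.columns)
    else:
        lib = pd.DataFrame(
            np.broadcast_to(
                pd.Series(library_size).reindex(df.columns).to_numpy(), df.shape
            ),
            index=df.index,
            columns=df.columns,
        )
    if (lib <= 0).any().any():
        if library_size is not None:
            raise ValueError("library size must be positive")
        # an organism with no mapped reads in a sample (e.g. virus before
        # infection): RPKM undefined -> NaN, so the genes fail the filter
        warnings.warn(
            "zero library size for some organism/sample; RPKM set to NaN",
            stacklevel=2,
        )
        lib = lib.where(lib > 0)
    return df.div(lengths / 1e3, axis=0) / (lib / 1e6)


def compute_tpm(
    counts: pd.DataFrame | pd.Series,
    gene_lengths_nt: pd.Series,
    scope: str = "all",
    organisms: pd.Series | None = None,
) -> pd.DataFrame:
    """Transcripts per million, optionally rescaled within one organism.

    ``scope`` in {"all", "host", "virus"}; for a restricted scope only
    the genes of that organism enter the normalisation (and the output).
    TPM_g = 1e6 * (count_g / length_g) / sum_scope(count / length).
    """
    df = _as_frame(counts)
    if scope != "all":
        if organisms is None:
            raise ValueError("scoped TPM requires an organisms series")
        df = df[organisms.reindex(df.index) == scope]
        if df.empty:
            raise ValueError(f"no genes in scope {scope!r}")
    lengths = gene_lengths_nt.reindex(df.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("gene lengths must be positive for every gene")
    rate = df.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("all-zero counts within scope")
    tpm = rate.div(totals, axis=1) * 1e6
    tpm.attrs["scope"] = scope
    return tpm


def filter_expressed_genes(
    rna_rpkm: pd.DataFrame,
    rpf_rpkm: pd.DataFrame,
    threshold: float = 10.0,
) -> pd.Index:
    """Genes expressed above threshold in every replicate of both assays.

    A gene is retained iff RNA RPKM >= threshold and footprint RPKM >=
    threshold in every replicate column; values strictly below the
    threshold in any single replicate discard the gene.
    """
    if rna_rpkm.shape[1] == 0 or rpf_rpkm.shape[1] == 0:
        raise ValueError("replicate columns missing")
    genes = rna_rpkm.index.intersection(rpf_rpkm.index)
    ok_rna = (rna_rpkm.loc[genes] >= threshold).all(axis=1)
    ok_rpf = (rpf_rpkm.loc[genes] >= threshold).all(axis=1)
    return genes[ok_rna & ok_rpf]


def count_footprints_for_gene(
    per_codon_counts: np.ndarray | pd.Series | list,
    exclude_start: int = 5,
    exclude_end: int = 5,
) -> int | None:
    """Gene-level footprint count over the interior of the ORF.

    Sums per-codon counts excluding the first five codons (start codon
    included) and the last five codons (stop codon included).  ORFs too
    short to have any countable position return None with a warning.
    """
    v = np.asarray(per_codon_counts, dtype=float)
    if v.size <= exclude_start + exclude_end:
        warnings.warn(
            f"ORF of {v.size} codons has no countable interior; excluded",
            stacklevel=2,
        )
        return None
    return int(v[exclude_start : v.size - exclude_end].sum())


def compute_te(
    rna_tpm: pd.DataFrame,
    rpf_tpm: pd.DataFrame,
    genes: pd.Index | None = None,
) -> pd.Series:
    """Translation efficiency per gene.

    Geometric mean over replicate columns of footprint TPM / RNA TPM.
    Columns of the two tables are paired positionally (replicate order).
    Genes with zero RNA TPM in any replicate are excluded from the
    output rather than smoothed.  The method tag is stored in
    ``result.attrs["method"]``.
    """
    if rna_tpm.shape[1] != rpf_tpm.shape[1]:
        raise ValueError("RNA and footprint tables need matching replicates")
    idx = rna_tpm.index.intersection(rpf_tpm.index)
    if genes is not None:
        idx = idx.intersection(genes)
    rna = rna_tpm.loc[idx].to_numpy(dtype=float)
    rpf = rpf_tpm.loc[idx].to_numpy(dtype=float)
    valid = (rna > 0).all(axis=1)
    ratios = rpf[valid] / rna[valid]
    with np.errstate(divide="ignore"):
        te = np.exp(np.mean(np.log(np.where(ratios > 0, ratios, np.nan)), axis=1))
    out = pd.Series(te, index=idx[valid], name="TE").dropna()
    out.attrs["method"] = TE_METHOD_TAG
    return out
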