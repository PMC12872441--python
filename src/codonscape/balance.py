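"""Expression-weighted codon demand and the tRNA supply/demand balance.

Codon demand weights each gene's codon counts by its mRNA abundance:

    U_i = sum_g TPM_RNA,g * c_ig,          (c_ig = count of codon i in g)
    cu_i = min(1, U_i / U_max),            U_max = top-3 geometric mean.

The balance score compares the tRNA supply (relative adaptiveness w)
with the demand:

    ratio'_i = w_i / cu_i,
    balance_i = min(1, ratio'_i / ratio'_max),

ratio'_max again the top-3 geometric mean.  A codon with ratio' > 1 has
"excessive" tRNAs (supply exceeds its weighted usage); ratio' <= 1 is
"moderate".  Group contrasts between AU3 and GC3 codons use one-sided
Wilcoxon rank-sum tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from codonscape.adaptation import top3_geometric_mean
from codonscape.codon_core import CodingSequence, STANDARD_CODE, classify_third_base

__all__ = [
    "codon_usage_weighted",
    "balance_scores",
    "balance_by_class",
    "wilcoxon_rank_sum",
]


def codon_usage_weighted(
    genes: list[CodingSequence], rna_tpm: pd.Series
) -> pd.DataFrame:
    """Expression-weighted codon usage U and rescaled usage cu per codon.

    ``rna_tpm`` is indexed by gene id; genes missing from it contribute
    nothing.  Stop codons are excluded.  Returns a per-codon table with
    columns ``U`` and ``cu``; U_max is stored in ``df.attrs["U_max"]``.
    """
    if not genes:
        raise ValueError("no genes supplied")
    usage = pd.Series(0.0, index=list(STANDARD_CODE.sense_codons))
    for gene in genes:
        tpm = float(rna_tpm.get(gene.gene_id, 0.0))
        if tpm == 0.0:
            continue
        counts = pd.Series(list(gene.sense_codons())).value_counts()
        usage = usage.add(tpm * counts, fill_value=0.0)
    usage = usage.reindex(list(STANDARD_CODE.sense_codons), fill_value=0.0)
    U_max = top3_geometric_mean(usage)
    out = pd.DataFrame({"U": usage, "cu": np.minimum(1.0, usage / U_max)})
    out.attrs["U_max"] = U_max
    return out.sort_index()


def balance_scores(w: pd.Series | pd.DataFrame, demand: pd.DataFrame) -> pd.DataFrame:
    """Per-codon supply/demand ratio, balance score and excess class.

    Codons with cu = 0 cannot be scored (infinite ratio); they are
    returned with NaN ratio/balance and class ``"unscored"``.
    """
    if isinstance(w, pd.DataFrame):
        w = w["w"]
    codons = w.index.intersection(demand.index)
    if codons.empty:
        raise ValueError("no codons shared between supply and demand tables")
    w = w.loc[codons]
    cu = demand.loc[codons, "cu"]
    ratio = w.where(cu > 0) / cu.where(cu > 0)
    scored = ratio.dropna()
    if scored.empty:
        raise ValueError("no codon has positive demand")
    ratio_max = top3_geometric_mean(scored)
    balance = np.minimum(1.0, ratio / ratio_max)
    klass = pd.Series("unscored", index=codons)
    klass[ratio > 1.0] = "excessive"
    klass[(ratio <= 1.0) & ratio.notna()] = "moderate"
    out = pd.DataFrame(
        {
            "w": w,
            "cu": cu,
            "ratio_prime": ratio,
            "balance": balance,
            "class": klass,
            "third_base_class": [classify_third_base(c) for c in codons],
        }
    )
    out.attrs["ratio_prime_max"] = ratio_max
    return out.sort_index()


def wilcoxon_rank_sum(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> dict:
    """One- or two-sided Wilcoxon rank-sum (Mann–Whitney U) test.

    Uses the exact null distribution when both groups have <= 50
    tie-free observations, the normal approximation otherwise.  A
    degenerate comparison (every value identical) is reported with a
    NaN p value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty group in rank-sum test")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return {"statistic": float("nan"), "p_value": float("nan"), "method": "degenerate"}
    has_ties = np.unique(pooled).size < pooled.size
    if max(x.size, y.size) <= 50 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(x, y, alternative=alternative, method=method)
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue), "method": method}


def balance_by_class(balance: pd.DataFrame, alternative: str = "less") -> dict:
    """Summarise balance scores for AU3 vs GC3 codons with a rank-sum test.

    ``alternative`` states the direction for the AU3 group relative to
    GC3 (default "less": AU3 balance below GC3, the host-cell situation
    when AU-ending codons are in demand excess).  Unscored codons are
    dropped.  Returns group medians/means/sizes and the test result.
    """
    scored = balance.dropna(subset=["balance"])
    groups = {
        k: g["balance"].to_numpy()
        for k, g in scored.groupby("third_base_class")
    }
    for name in ("AU3", "GC3"):
        if name not in groups or groups[name].size == 0:
            raise ValueError(f"group {name} is empty")
    test = wilcoxon_rank_sum(groups["AU3"], groups["GC3"], alternative=alternative)
    return {
        "AU3": {
            "n": int(groups["AU3"].size),
            "median": float(np.median(groups["AU3"])),
            "mean": float(np.mean(groups["AU3"])),
        },
        "GC3": {
            "n": int(groups["GC3"].size),
            "median": float(np.median(groups["GC3"])),
            "mean": float(np.mean(groups["GC3"])),
        },
        "test": test,
        "alternative": alternative,
    }
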