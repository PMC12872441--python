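"""Ribosome-profiling landscape: occupancy, pauses, short-footprint ratios.

Footprint tracks are tables of A-site-assigned counts at codon
resolution, stratified into a short (21–22 nt, A-site-empty ribosome)
and a long (29–30 nt, A-site-occupied) length class::

    gene_id  codon_index  codon  short_count  long_count

``codon_index`` is 0-based from the start codon.  A-site assignment
(5'-end + length-specific offset) happens upstream; the nucleotide-
resolution track is kept only for the periodicity QC.

Analyses and their exclusion zones (each rule is applied by the
operation it belongs to, not merged into one mask):

* codon occupancy: genes with mean footprints per codon > 1; the first
  four codons and the stop codon are excluded from the codon-type
  averages; e_kg = RPF_kg / (RPF_g / l_g).
* pause sites: position k is a putative pause when e_kg strictly
  exceeds the gene mean plus k standard deviations (default 2).
* short-footprint ratio: occupancy-eligible genes, start and stop
  codons excluded; SFR_i = short / (short + long) per codon type, with
  a short/long variant behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from codonscape.balance import wilcoxon_rank_sum
from codonscape.codon_core import STANDARD_CODE, classify_third_base

__all__ = [
    "OccupancyTable",
    "PauseCallSet",
    "MetageneProfile",
    "codon_occupancy",
    "detect_pauses",
    "short_footprint_ratio",
    "occupancy_by_class",
    "calibrate_offsets",
    "periodicity_qc",
]

TRACK_COLUMNS = ("gene_id", "codon_index", "codon", "short_count", "long_count")


def _check_track(track: pd.DataFrame) -> None:
    missing = set(TRACK_COLUMNS) - set(track.columns)
    if missing:
        raise ValueError(f"footprint track missing columns {sorted(missing)}")


@dataclass
class OccupancyTable:
    """Relative ribosome densities and codon-type occupancies."""

    positions: pd.DataFrame  # gene_id, codon_index, codon, count, e, in_type_mean
    per_codon_type: pd.Series  # mean e per codon, over pooled included positions
    gene_stats: pd.DataFrame  # mean_rpf, length, included per gene

    @property
    def included_genes(self) -> pd.Index:
        return self.gene_stats.index[self.gene_stats["included"]]


@dataclass
class PauseCallSet:
    """Putative pause sites called per gene."""

    calls: pd.DataFrame  # gene_id, codon_index, codon, e, threshold, is_pause
    gene_fraction: pd.Series  # paused fraction of included positions per gene
    per_codon_type: pd.Series  # pause count / codon-type occurrence count
    k: float


@dataclass
class MetageneProfile:
    """Start/stop metagene summaries used for A-site offset calibration."""

    histograms: dict[int, pd.Series] = field(default_factory=dict)
    offsets: dict[int, int] = field(default_factory=dict)
    uncalibrated: list[int] = field(default_factory=list)
    frame_fractions: tuple[float, float, float] | None = None
    periodogram: pd.Series | None = None
    dominant_period: float | None = None


def codon_occupancy(
    track: pd.DataFrame,
    min_mean_rpf: float = 1.0,
    exclude_first: int = 4,
    pooling: str = "positions",
) -> OccupancyTable:
    """Relative density e_kg and per-codon-type occupancy.

    Counts pool both length classes.  RPF_g and l_g run over all
    non-stop positions, so a gene with no exclusions has mean(e) = 1
    exactly.  Genes with RPF_g / l_g strictly above ``min_mean_rpf``
    are included; the first ``exclude_first`` codons and the stop codon
    are left out of the codon-type averages.  ``pooling`` is
    ``"positions"`` (simple mean over all included positions, pooled
    across genes) or ``"genes"`` (mean of per-gene means).
    """
    _check_track(track)
    df = track.copy()
    df["count"] = df["short_count"].astype(float) + df["long_count"].astype(float)
    df["is_stop"] = df["codon"].map(STANDARD_CODE.is_stop)

    sense = df[~df["is_stop"]]
    gene_stats = sense.groupby("gene_id")["count"].agg(["sum", "size"])
    gene_stats.columns = ["rpf", "length"]
    gene_stats["mean_rpf"] = gene_stats["rpf"] / gene_stats["length"]
    gene_stats["included"] = gene_stats["mean_rpf"] > min_mean_rpf

    df = df.merge(gene_stats[["mean_rpf", "included"]], on="gene_id", how="left")
    df["e"] = np.where(df["is_stop"], np.nan, df["count"] / df["mean_rpf"])
    df["in_type_mean"] = (
        df["included"]
        & ~df["is_stop"]
        & (df["codon_index"] >= exclude_first)
    )

    pool = df[df["in_type_mean"]]
    if pooling == "positions":
        per_type = pool.groupby("codon")["e"].mean()
    elif pooling == "genes":
        per_type = (
            pool.groupby(["gene_id", "codon"])["e"].mean().groupby("codon").mean()
        )
    else:
        raise ValueError(f"unknown pooling {pooling!r}")

    positions = df[
        ["gene_id", "codon_index", "codon", "count", "e", "in_type_mean"]
    ]
    return OccupancyTable(
        positions=positions,
        per_codon_type=per_type.rename("occupancy"),
        gene_stats=gene_stats,
    )


def detect_pauses(
    occupancy: OccupancyTable,
    k: float = 2.0,
    sd_mode: str = "population",
) -> PauseCallSet:
    """Call putative pause sites: e strictly above gene mean + k·sd.

    The mean and sd are taken over each gene's included positions (the
    same set that enters codon-type occupancy).  ``sd_mode`` selects the
    population (divide by n, default) or sample (n−1) standard
    deviation.  Genes with fewer than two included positions get no
    calls, with a warning.
    """
    if sd_mode not in ("population", "sample"):
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    ddof = 0 if sd_mode == "population" else 1
    pool = occupancy.positions[occupancy.positions["in_type_mean"]].copy()

    rows = []
    skipped = 0
    for gene_id, g in pool.groupby("gene_id"):
        e = g["e"].to_numpy()
        if e.size < 2:
            skipped += 1
            continue
        threshold = e.mean() + k * e.std(ddof=ddof)
        g = g.assign(threshold=threshold, is_pause=g["e"] > threshold)
        rows.append(g)
    if skipped:
        warnings.warn(
            f"{skipped} genes with <2 included positions got no pause calls",
            stacklevel=2,
        )
    if not rows:
        empty = pd.DataFrame(
            columns=["gene_id", "codon_index", "codon", "e", "threshold", "is_pause"]
        )
        return PauseCallSet(empty, pd.Series(dtype=float), pd.Series(dtype=float), k)

    calls = pd.concat(rows, ignore_index=True)
    gene_fraction = calls.groupby("gene_id")["is_pause"].mean()
    occurrences = calls.groupby("codon").size()
    pause_counts = calls[calls["is_pause"]].groupby("codon").size()
    per_type = (pause_counts / occurrences).reindex(occurrences.index).fillna(0.0)
    return PauseCallSet(
        calls=calls[
            ["gene_id", "codon_index", "codon", "e", "threshold", "is_pause"]
        ],
        gene_fraction=gene_fraction.rename("pause_fraction"),
        per_codon_type=per_type.rename("normalized_pause_rate"),
        k=k,
    )


def short_footprint_ratio(
    track: pd.DataFrame,
    eligible_genes: pd.Index | None = None,
    mode: str = "total",
) -> pd.Series:
    """Short-footprint ratio per codon type.

    ``mode="total"``: short / (short + long), the tRNA-accessibility
    ratio in [0, 1] (high = A-site often empty, low accessibility).
    ``mode="long"``: the short-over-long variant.  Start and stop codons
    are excluded; ``eligible_genes`` (default: all genes in the track)
    should be the occupancy-eligible set.  Codon types with no
    footprints are returned as NaN (unscored).
    """
    _check_track(track)
    if mode not in ("total", "long"):
        raise ValueError(f"unknown mode {mode!r}")
    df = track
    if eligible_genes is not None:
        df = df[df["gene_id"].isin(eligible_genes)]
    df = df[(df["codon_index"] > 0) & ~df["codon"].map(STANDARD_CODE.is_stop)]
    agg = df.groupby("codon")[["short_count", "long_count"]].sum()
    short = agg["short_count"].astype(float)
    long_ = agg["long_count"].astype(float)
    if mode == "total":
        denom = short + long_
        out = short.where(denom > 0) / denom.where(denom > 0)
    else:
        out = short.where(long_ > 0) / long_.where(long_ > 0)
    return out.rename("sfr")


def occupancy_by_class(
    values: pd.Series, alternative: str = "greater"
) -> dict:
    """AU3 vs GC3 contrast for any per-codon-type statistic.

    ``values`` is indexed by codon (occupancy, SFR, W, ...); NaNs are
    dropped.  ``alternative`` gives the direction of the AU3 group
    relative to GC3 in a one-sided Wilcoxon rank-sum test ("greater"
    matches the host-mRNA expectation for SFR and occupancy).  A
    degenerate comparison is reported with NaN p.
    """
    s = values.dropna()
    labels = pd.Series([classify_third_base(c) for c in s.index], index=s.index)
    groups = {k: s[labels == k].to_numpy() for k in ("AU3", "GC3")}
    for name, g in groups.items():
        if g.size == 0:
            raise ValueError(f"group {name} is empty")
    test = wilcoxon_rank_sum(groups["AU3"], groups["GC3"], alternative=alternative)
    return {
        "AU3": {"n": int(groups["AU3"].size), "median": float(np.median(groups["AU3"]))},
        "GC3": {"n": int(groups["GC3"].size), "median": float(np.median(groups["GC3"]))},
        "test": test,
        "alternative": alternative,
    }


def calibrate_offsets(
    reads: pd.DataFrame,
    cds_starts: pd.Series,
    window: tuple[int, int] = (-40, 20),
    min_enrichment_sd: float = 2.0,
    overrides: dict[int, int] | None = None,
) -> MetageneProfile:
    """Infer per-length A-site offsets from start-codon metagene peaks.

    ``reads`` has columns (gene_id, length, five_prime_pos) with
    positions 0-based on the transcript; ``cds_starts`` maps gene id to
    the start-codon position.  For each footprint length the histogram
    of 5'-end positions relative to the start codon is scanned at or
    upstream of the start (d <= 0) for a peak exceeding the window mean
    by ``min_enrichment_sd`` standard deviations; the most upstream such
    peak position d gives offset = -d (the initiating ribosome's
    footprint 5' end sits furthest upstream).  Lengths without a peak
    are left uncalibrated with a warning.  ``overrides`` (length →
    offset) are echoed verbatim and skip inference.
    """
    profile = MetageneProfile()
    lo, hi = window
    for length, g in reads.groupby("length"):
        length = int(length)
        if overrides and length in overrides:
            profile.offsets[length] = int(overrides[length])
            continue
        d = g["five_prime_pos"].to_numpy() - cds_starts.reindex(
            g["gene_id"]
        ).to_numpy()
        d = d[(d >= lo) & (d < hi)]
        hist = pd.Series(0, index=range(lo, hi), dtype=int)
        if d.size:
            vc = pd.Series(d).value_counts()
            hist.loc[vc.index] = vc.to_numpy()
        profile.histograms[length] = hist
        counts = hist.to_numpy(dtype=float)
        cutoff = counts.mean() + min_enrichment_sd * counts.std()
        upstream = hist[hist.index <= 0]
        peaks = upstream[upstream > cutoff]
        if peaks.empty:
            profile.uncalibrated.append(length)
            warnings.warn(
                f"footprint length {length}: no start-proximal peak above "
                "background; offset left uncalibrated",
                stacklevel=2,
            )
            continue
        profile.offsets[length] = int(-peaks.index.min())
    if overrides:
        for length, off in overrides.items():
            profile.offsets[int(length)] = int(off)
    return profile


def periodicity_qc(nt_counts: np.ndarray | pd.Series | list) -> MetageneProfile:
    """Frame fractions and discrete-Fourier periodogram of an A-site track.

    ``nt_counts`` is a nucleotide-resolution count vector along ORFs
    (position 0 = first nt of a codon).  Reports the fraction of counts
    per reading frame and the FFT periodogram with the dominant period
    (3 nt for well-phased ribosome footprints).
    """
    x = np.asarray(nt_counts, dtype=float)
    if x.size == 0 or x.sum() == 0:
        raise ValueError("all-zero or empty track")
    frames = tuple(float(x[f::3].sum() / x.sum()) for f in range(3))
    centered = x - x.mean()
    power = np.abs(np.fft.rfft(centered)) ** 2
    freqs = np.fft.rfftfreq(x.size)
    spect = pd.Series(power[1:], index=freqs[1:], name="power")
    dominant = float(1.0 / spect.idxmax()) if not spect.empty else float("nan")
    profile = MetageneProfile()
    profile.frame_fractions = frames
    profile.periodogram = spect
    profile.dominant_period = dominant
    return profile
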