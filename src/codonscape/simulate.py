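"""Synthetic host/virus translation datasets with known ground truth.

The generator emulates the study conditions of an AT-rich giant virus
infecting a GC-rich amoeba host:

* a host gene set whose synonymous codon choice is biased toward GC3
  and a viral gene set biased toward AU3;
* a tRNA pool correlated with host codon usage (supply follows the
  host's demand), with a small viral tRNA contribution;
* a time course in which the viral share of the mRNA pool rises from 0
  to a majority of reads;
* ribosome footprints whose per-codon dwell time is inversely
  proportional to relative adaptiveness w (slowly decoded codons
  accumulate footprints), with multiplicative log-normal noise,
  injected pause sites of known position and fold, and a short
  footprint-length class drawn per codon type;
* tRNA-seq reads with a configurable contaminant fraction violating
  each read-filter criterion.

Every random draw flows from one ``numpy.random.default_rng(seed)`` in
a fixed order, so a seed fully determines the dataset (and the emitted
file bytes).  The ground-truth record carries everything needed to
score the estimators: the generating pool, the true wobble constraints,
per-gene pause positions and the short-class probabilities.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from codonscape.adaptation import compute_w_scores, relative_adaptiveness
from codonscape.codon_core import (
    CodingSequence,
    STANDARD_CODE,
    WobbleConstraintSet,
    classify_third_base,
    reverse_complement,
)
from codonscape.trna import TRNAPool

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_genes",
    "simulate_trna_pool",
    "simulate_expression",
    "simulate_footprints",
    "simulate_dataset",
    "write_dataset",
    "VIRAL_ANTICODONS",
]

#: anticodons of the six virus-encoded tRNAs (two Leu-TAA, one Leu-CAA,
#: Trp-CCA, Cys-GCA, His-GTG) — named for the codons TTA/TTG/TGG/TGC/CAC
VIRAL_ANTICODONS: tuple[str, ...] = ("TAA", "TAA", "CAA", "CCA", "GCA", "GTG")


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults are the study conditions."""

    seed: int
    # gene sets
    n_host_genes: int = 300
    n_virus_genes: int = 100
    mean_gene_length: int = 400  # codons; typical eukaryotic/giant-virus ORF
    gene_length_sigma: float = 0.25
    min_gene_length: int = 80
    max_gene_length: int = 1000
    host_au3_weight: float = 0.25  # GC-rich host: GC3 preferred 3:1
    virus_au3_weight: float = 0.9  # AT-rich virus (GC ~28%)
    # tRNA pool
    trna_coupling: float = 0.5  # pool weight = coupling*host usage + rest uniform
    viral_trna_fraction: float = 0.018  # ~1.8% of the pool is virus-encoded
    n_trna_reads: int = 20000
    contaminant_fraction: float = 0.1
    # adaptation ground truth
    true_s: tuple[float, float, float, float, float] = (
        1.0,
        0.0,
        1.0,
        0.0065956,
        0.90832489,
    )
    # expression time course
    timepoints: tuple[str, ...] = ("t0", "t2", "t4", "t8")
    viral_mrna_share: tuple[float, ...] = (0.0, 0.15, 0.35, 0.62)
    tpm_sigma: float = 1.0  # log-normal spread of true TPMs
    rna_depth: int = 400000  # RNA-seq reads per replicate
    n_replicates: int = 2
    # footprints
    total_footprints: int = 2000000  # per replicate
    dwell_noise_sigma: float = 0.3
    pause_fraction: float = 0.01
    pause_fold: float = 20.0
    p_short_au3: float = 0.35  # host AU3 codons: lower tRNA accessibility
    p_short_gc3: float = 0.2
    init_peak_weight: float = 0.05  # dwell share concentrated on the start codon

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in (
            "host_au3_weight",
            "virus_au3_weight",
            "trna_coupling",
            "viral_trna_fraction",
            "contaminant_fraction",
            "pause_fraction",
            "p_short_au3",
            "p_short_gc3",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for share in self.viral_mrna_share:
            if not 0.0 <= share <= 1.0:
                raise ValueError(f"viral mRNA share {share} outside [0, 1]")
        if len(self.viral_mrna_share) != len(self.timepoints):
            raise ValueError("one viral share per timepoint required")


@dataclass
class SyntheticDataset:
    """A complete simulated experiment plus its ground truth."""

    config: SimulationConfig
    genes: list[CodingSequence]
    trna_reads: pd.DataFrame
    true_pool: TRNAPool
    expression: dict[str, dict]  # timepoint -> {rna_counts, rpf_counts, true_tpm}
    footprints: dict[str, dict[str, pd.DataFrame]]  # timepoint -> replicate -> track
    truth: dict

    @property
    def gene_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "organism": [g.organism for g in self.genes],
                "length_nt": [3 * g.length for g in self.genes],
            }
        ).set_index("gene_id")


# ---------------------------------------------------------------------------
# gene sets

def _synonymous_classes() -> dict[str, dict[str, list[str]]]:
    by_aa: dict[str, dict[str, list[str]]] = {}
    for codon, aa in STANDARD_CODE.codon_to_aa.items():
        by_aa.setdefault(aa, {"AU3": [], "GC3": []})[
            classify_third_base(codon)
        ].append(codon)
    for groups in by_aa.values():
        groups["AU3"].sort()
        groups["GC3"].sort()
    return by_aa


_SYN = _synonymous_classes()
# amino acids drawn proportionally to synonymous family size, so the
# unbiased codon distribution matches the codon-table baseline
_AA_NAMES = sorted(_SYN)
_AA_WEIGHTS = np.array([len(_SYN[a]["AU3"]) + len(_SYN[a]["GC3"]) for a in _AA_NAMES])
_AA_PROBS = _AA_WEIGHTS / _AA_WEIGHTS.sum()


def _sample_codon(aa: str, au3_weight: float, rng: np.random.Generator) -> str:
    groups = _SYN[aa]
    au3, gc3 = groups["AU3"], groups["GC3"]
    if not au3:
        pool = gc3
    elif not gc3:
        pool = au3
    else:
        pool = au3 if rng.random() < au3_weight else gc3
    return pool[rng.integers(len(pool))]


def simulate_genes(config: SimulationConfig, rng: np.random.Generator | None = None) -> list[CodingSequence]:
    """Host genes with GC3-biased and viral genes with AU3-biased codons.

    Each gene starts with ATG, ends with TAA, and has a log-normally
    distributed length.  Amino acids are drawn proportionally to
    synonymous-family size; the third-base class of each synonymous
    choice is Bernoulli with the organism's AU3 weight.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    genes: list[CodingSequence] = []
    specs = [("host", config.n_host_genes, config.host_au3_weight)] + [
        ("virus", config.n_virus_genes, config.virus_au3_weight)
    ]
    for organism, n, au3_weight in specs:
        for i in range(n):
            length = int(
                np.clip(
                    np.round(
                        rng.lognormal(
                            np.log(config.mean_gene_length), config.gene_length_sigma
                        )
                    ),
                    config.min_gene_length,
                    config.max_gene_length,
                )
            )
            aas = rng.choice(len(_AA_NAMES), size=length - 1, p=_AA_PROBS)
            codons = ["ATG"] + [
                _sample_codon(_AA_NAMES[j], au3_weight, rng) for j in aas
            ]
            codons.append("TAA")
            genes.append(
                CodingSequence(
                    gene_id=f"{organism}_{i:04d}",
                    sequence="".join(codons),
                    organism=organism,
                )
            )
    return genes


# ---------------------------------------------------------------------------
# tRNA pool and reads

def _host_codon_usage(genes: list[CodingSequence]) -> pd.Series:
    counts = pd.Series(0.0, index=list(STANDARD_CODE.sense_codons))
    for g in genes:
        if g.organism != "host":
            continue
        vc = pd.Series(list(g.sense_codons())).value_counts()
        counts = counts.add(vc, fill_value=0.0)
    return counts.reindex(list(STANDARD_CODE.sense_codons), fill_value=0.0)


def true_pool_weights(
    config: SimulationConfig, genes: list[CodingSequence]
) -> pd.DataFrame:
    """Generating pool: host weights coupled to host codon usage, plus
    the six viral anticodons at the configured aggregate fraction."""
    usage = _host_codon_usage(genes)
    host_weights: dict[str, float] = {}
    uniform = 1.0 / len(usage)
    for codon, u in usage.items():
        anticodon = reverse_complement(codon)
        host_weights[anticodon] = host_weights.get(anticodon, 0.0) + (
            config.trna_coupling * (u / usage.sum()) + (1 - config.trna_coupling) * uniform
        )
    host = pd.Series(host_weights)
    host = host / host.sum() * (1.0 - config.viral_trna_fraction)
    viral_counts = pd.Series(VIRAL_ANTICODONS).value_counts().sort_index()
    viral = viral_counts / viral_counts.sum() * config.viral_trna_fraction
    rows = [
        {"anticodon": ac, "genome": "host", "proportion": p} for ac, p in host.items()
    ] + [
        {"anticodon": ac, "genome": "virus", "proportion": p} for ac, p in viral.items()
    ]
    df = pd.DataFrame(rows)
    if config.viral_trna_fraction == 0:
        df = df[df["genome"] == "host"]
        df["proportion"] /= df["proportion"].sum()
    return df


def simulate_trna_pool(
    config: SimulationConfig,
    genes: list[CodingSequence],
    rng: np.random.Generator | None = None,
) -> tuple[TRNAPool, pd.DataFrame]:
    """The generating tRNA pool and a read table exercising the filter.

    Clean reads (1 − contaminant fraction of the total) are multinomial
    draws from the pool with lengths ≥ 20; contaminants split equally
    into too-short reads, excluded anticodons (NNN/TTA/TCA) and
    cross-genome multi-hit reads.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    weights = true_pool_weights(config, genes)
    pool_df = weights.copy()
    pool_df["count"] = pool_df["proportion"] * config.n_trna_reads
    true_pool = TRNAPool(pool_df[["anticodon", "genome", "count", "proportion"]])

    n_contam = rng.binomial(config.n_trna_reads, config.contaminant_fraction)
    n_clean = config.n_trna_reads - n_contam
    rows: list[dict] = []
    choice_idx = rng.choice(len(weights), size=n_clean, p=weights["proportion"].to_numpy())
    lengths = rng.integers(60, 91, size=n_clean)
    for r, (idx, length) in enumerate(zip(choice_idx, lengths)):
        ac = weights.iloc[idx]["anticodon"]
        genome = weights.iloc[idx]["genome"]
        rows.append(
            {
                "read_id": f"read_{r:06d}",
                "length": int(length),
                "gene_id": f"trna_{genome}_{ac}_1",
                "anticodon": ac,
                "genome": genome,
            }
        )
    host_acs = weights.loc[weights["genome"] == "host", "anticodon"].to_numpy()
    for r in range(n_contam):
        rid = f"contam_{r:06d}"
        kind = r % 3
        if kind == 0:  # too short
            ac = host_acs[rng.integers(len(host_acs))]
            rows.append(
                {
                    "read_id": rid,
                    "length": int(rng.integers(15, 20)),
                    "gene_id": f"trna_host_{ac}_1",
                    "anticodon": ac,
                    "genome": "host",
                }
            )
        elif kind == 1:  # excluded anticodon
            ac = ("NNN", "TTA", "TCA")[rng.integers(3)]
            rows.append(
                {
                    "read_id": rid,
                    "length": int(rng.integers(60, 91)),
                    "gene_id": f"trna_host_{ac}_1",
                    "anticodon": ac,
                    "genome": "host",
                }
            )
        else:  # multi-hit across genomes / anticodons
            ac1, ac2 = host_acs[rng.integers(len(host_acs), size=2)]
            length = int(rng.integers(60, 91))
            rows.append(
                {
                    "read_id": rid,
                    "length": length,
                    "gene_id": f"trna_host_{ac1}_1",
                    "anticodon": ac1,
                    "genome": "host",
                }
            )
            rows.append(
                {
                    "read_id": rid,
                    "length": length,
                    "gene_id": f"trna_organelle_{ac2}_1",
                    "anticodon": ac2,
                    "genome": "organelle",
                }
            )
    reads = pd.DataFrame(rows, columns=["read_id", "length", "gene_id", "anticodon", "genome"])
    return true_pool, reads


# ---------------------------------------------------------------------------
# expression time course

def simulate_expression(
    config: SimulationConfig,
    genes: list[CodingSequence],
    rng: np.random.Generator | None = None,
) -> dict[str, dict]:
    """Per-timepoint RNA count tables with a rising viral mRNA share.

    True TPMs are log-normal per gene; read weights (TPM × length) are
    rescaled so the viral genes occupy the configured share of reads at
    each timepoint, then counts are Poisson at the configured depth.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    gene_ids = [g.gene_id for g in genes]
    is_virus = np.array([g.organism == "virus" for g in genes])
    lengths = np.array([3 * g.length for g in genes], dtype=float)
    base_tpm = rng.lognormal(mean=0.0, sigma=config.tpm_sigma, size=len(genes))

    out: dict[str, dict] = {}
    for tp, share in zip(config.timepoints, config.viral_mrna_share):
        read_w = base_tpm * lengths
        host_w = read_w[~is_virus].sum()
        virus_w = read_w[is_virus].sum()
        w = read_w.copy()
        if share == 0.0:
            w[is_virus] = 0.0
        elif share == 1.0:
            w[~is_virus] = 0.0
        else:
            # rescale the viral block so its share of read weight is `share`
            w[is_virus] *= (share / (1 - share)) * (host_w / virus_w)
        p = w / w.sum()
        rna = {}
        for rep in range(1, config.n_replicates + 1):
            rna[f"{tp}__RNA__rep{rep}"] = rng.poisson(config.rna_depth * p)
        tpm = (w / lengths) / (w / lengths).sum() * 1e6
        out[tp] = {
            "rna_counts": pd.DataFrame(rna, index=gene_ids),
            "true_tpm": pd.Series(tpm, index=gene_ids, name="tpm"),
            "viral_share": share,
        }
    return out


# ---------------------------------------------------------------------------
# footprints

def _p_short_map(config: SimulationConfig) -> pd.Series:
    return pd.Series(
        {
            c: (
                config.p_short_au3
                if classify_third_base(c) == "AU3"
                else config.p_short_gc3
            )
            for c in STANDARD_CODE.sense_codons
        }
    )


def simulate_footprints(
    config: SimulationConfig,
    genes: list[CodingSequence],
    pool: TRNAPool | pd.Series,
    gene_weights: pd.Series,
    rng: np.random.Generator | None = None,
    n_replicates: int | None = None,
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Footprint tracks whose dwell follows 1/w at the true constraints.

    Per sense codon position the dwell weight is (1/w_i) × log-normal
    noise; a fraction of positions (outside the first four codons) is
    multiplied by the pause fold.  Per replicate,
    ``config.total_footprints`` footprints are multinomially spread over
    all positions with gene totals ∝ ``gene_weights`` (typically TPM ×
    length), and each footprint falls in the short class with the codon
    type's probability.  Returns one track per replicate plus the
    ground truth (pause positions, dwell, p_short, w).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_replicates = n_replicates or config.n_replicates
    W = compute_w_scores(pool, WobbleConstraintSet.from_vector(config.true_s))
    w = relative_adaptiveness(W)["w"]
    positive = w[w > 0]
    fill = float(np.exp(np.mean(np.log(positive)))) if not positive.empty else 1.0
    w_safe = w.where(w > 0, fill)
    p_short = _p_short_map(config)

    frames = []
    truth_pauses: dict[str, list[int]] = {}
    dwell_all = []
    for g in genes:
        codons = g.codons
        sense = [not STANDARD_CODE.is_stop(c) for c in codons]
        inv_w = np.array(
            [1.0 / w_safe[c] if s else 0.0 for c, s in zip(codons, sense)]
        )
        noise = rng.lognormal(0.0, config.dwell_noise_sigma, size=len(codons))
        dwell = inv_w * noise
        # initiation enrichment on the start codon (offset calibration signal)
        dwell[0] += config.init_peak_weight * dwell.sum()
        eligible = [
            i for i in range(4, len(codons)) if sense[i]
        ]  # pauses only where they are callable
        # exactly pause_fraction of each gene's positions, randomly placed
        n_pause = round(len(eligible) * config.pause_fraction)
        pause_pos = sorted(
            rng.choice(eligible, size=n_pause, replace=False).tolist()
        ) if n_pause else []
        dwell[pause_pos] *= config.pause_fold
        truth_pauses[g.gene_id] = pause_pos
        dwell_all.append(dwell)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": g.gene_id,
                    "codon_index": np.arange(len(codons)),
                    "codon": codons,
                }
            )
        )
    track_base = pd.concat(frames, ignore_index=True)
    dwell_flat = np.concatenate(dwell_all)
    gene_w = gene_weights.reindex([g.gene_id for g in genes]).fillna(0.0)
    # per-position sampling probability: gene weight × within-gene dwell
    gene_of_pos = track_base["gene_id"].to_numpy()
    dwell_sums = pd.Series(dwell_flat).groupby(gene_of_pos).transform("sum").to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        rel_dwell = np.where(dwell_sums > 0, dwell_flat / dwell_sums, 0.0)
    pos_p = rel_dwell * gene_w.reindex(gene_of_pos).to_numpy()
    if pos_p.sum() == 0:
        raise ValueError("all-zero dwell: no gene has positive weight")
    pos_p = pos_p / pos_p.sum()
    p_short_pos = p_short.reindex(track_base["codon"]).fillna(0.0).to_numpy()

    tracks: dict[str, pd.DataFrame] = {}
    for rep in range(1, n_replicates + 1):
        counts = rng.multinomial(config.total_footprints, pos_p)
        short = rng.binomial(counts, p_short_pos)
        t = track_base.copy()
        t["short_count"] = short
        t["long_count"] = counts - short
        tracks[f"rep{rep}"] = t
    truth = {
        "pauses": truth_pauses,
        "p_short": p_short.to_dict(),
        "w": w.to_dict(),
        "true_s": list(config.true_s),
        "dwell": dwell_flat,
        "positions": track_base,
    }
    return tracks, truth


# ---------------------------------------------------------------------------
# full dataset

def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate genes, tRNA reads, expression time course and footprints.

    A single RNG seeded from ``config.seed`` drives every step in a
    fixed order, so the dataset is fully reproducible.
    """
    rng = np.random.default_rng(config.seed)
    genes = simulate_genes(config, rng)
    true_pool, trna_reads = simulate_trna_pool(config, genes, rng)
    expression = simulate_expression(config, genes, rng)

    lengths = pd.Series(
        {g.gene_id: 3.0 * g.length for g in genes}, name="length_nt"
    )
    footprints: dict[str, dict[str, pd.DataFrame]] = {}
    truth_fp: dict[str, dict] = {}
    for tp in config.timepoints:
        gene_weights = expression[tp]["true_tpm"] * lengths
        tracks, truth = simulate_footprints(
            config, genes, true_pool, gene_weights, rng
        )
        footprints[tp] = tracks
        truth_fp[tp] = truth
        # gene-level footprint counts (all positions) per replicate
        rpf = {
            f"{tp}__RPF__{rep}": t.groupby("gene_id")[["short_count", "long_count"]]
            .sum()
            .sum(axis=1)
            for rep, t in tracks.items()
        }
        expression[tp]["rpf_counts"] = pd.DataFrame(rpf).reindex(
            [g.gene_id for g in genes]
        )
    truth = {
        "true_s": list(config.true_s),
        "true_pool": {
            (row.anticodon, row.genome): row.proportion
            for row in true_pool.table.itertuples()
        },
        "viral_mrna_share": dict(zip(config.timepoints, config.viral_mrna_share)),
        "footprints": truth_fp,
    }
    return SyntheticDataset(
        config=config,
        genes=genes,
        trna_reads=trna_reads,
        true_pool=true_pool,
        expression=expression,
        footprints=footprints,
        truth=truth,
    )


def write_dataset(dataset: SyntheticDataset, directory: str | Path) -> dict:
    """Write the dataset as FASTA/TSV/JSON and return a checksum manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    fasta = directory / "cds.fasta"
    with fasta.open("w") as fh:
        for g in dataset.genes:
            fh.write(f">{g.gene_id} organism={g.organism}\n")
            for i in range(0, len(g.sequence), 60):
                fh.write(g.sequence[i : i + 60] + "\n")
    files["cds_fasta"] = fasta

    genes_tsv = directory / "genes.tsv"
    dataset.gene_table.to_csv(genes_tsv, sep="\t")
    files["gene_table"] = genes_tsv

    trna_tsv = directory / "trna_reads.tsv"
    dataset.trna_reads.to_csv(trna_tsv, sep="\t", index=False)
    files["trna_reads"] = trna_tsv

    for tp, bundle in dataset.expression.items():
        p = directory / f"rna_counts_{tp}.tsv"
        bundle["rna_counts"].rename_axis("gene_id").to_csv(p, sep="\t")
        files[f"rna_counts_{tp}"] = p
        p = directory / f"rpf_counts_{tp}.tsv"
        bundle["rpf_counts"].rename_axis("gene_id").to_csv(p, sep="\t")
        files[f"rpf_counts_{tp}"] = p

    for tp, reps in dataset.footprints.items():
        frames = []
        for rep, t in reps.items():
            t = t.copy()
            t["replicate"] = rep
            t["timepoint"] = tp
            frames.append(t)
        p = directory / f"footprints_{tp}.tsv"
        pd.concat(frames, ignore_index=True).to_csv(p, sep="\t", index=False)
        files[f"footprints_{tp}"] = p

    truth_path = directory / "ground_truth.json"
    truth_json = {
        "true_s": dataset.truth["true_s"],
        "true_pool": {
            f"{ac}|{genome}": prop
            for (ac, genome), prop in dataset.truth["true_pool"].items()
        },
        "viral_mrna_share": dataset.truth["viral_mrna_share"],
        "pauses": {
            tp: dataset.truth["footprints"][tp]["pauses"]
            for tp in dataset.config.timepoints
        },
        "p_short": dataset.truth["footprints"][dataset.config.timepoints[0]][
            "p_short"
        ],
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(dataset.config).items()
        },
    }
    truth_path.write_text(json.dumps(truth_json, indent=1, sort_keys=True))
    files["ground_truth"] = truth_path

    manifest = {
        name: {
            "path": str(path.relative_to(directory)),
            "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
        }
        for name, path in files.items()
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
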