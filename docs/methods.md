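# Methods

This note records the models implemented in `codonscape`, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
choices a maintainer would otherwise have to reverse-engineer.

## Pairing model

Codons and anticodons are held in the DNA alphabet, 5'→3'. An anticodon
can decode a codon when its positions 2–3 Watson–Crick pair the codon's
first two bases and its wobble position (base 34, the first base of the
written anticodon) pairs the codon's third base either Watson–Crick or
through one of five wobble routes, named codon-base:anticodon-base —
A:I, C:I, G:U, U:G, and A:G. Inosine is identified with genomically
encoded A at the wobble position (the standard tAI convention; no
modification data is read), and A:G is emitted only for the codon AUA
(decoded by the anticodon written GAT), a special isoleucine route. The
orientation convention matters: "G:U" here means a codon *ending in G*
read by an anticodon with U (T) at the wobble position. Stop codons are
excluded from every score.

Each wobble class carries a selective constraint s ∈ [0, 1] — the cost
of that pairing relative to Watson–Crick (s = 0). The packaged default
vector is (s_A:I, s_C:I, s_G:U, s_U:G, s_A:G) =
(1, 0, 1, 0.0065956, 0.90832489), the fitted values for the
amoeba/mimivirus system: in that pool the C:I and U:G routes are
essentially free while A:I and G:U contribute nothing.

## Supply, demand, balance

* W_i = Σ_j (1 − s_ij)·tRNA_j over the pairing enumeration; tRNA_j is
  the anticodon's proportion of the pool (host nuclear + viral by
  default; organellar sources are tracked and can be included).
* Normalisers use the geometric mean of the three largest values
  (W_N, U_max, ratio′_max) rather than the single maximum, so one
  outlier codon does not compress the scale; ties are resolved by value
  (duplicates allowed). If fewer than three values are positive the
  geometric mean of the positive ones is used, with a warning.
* w_i = min(1, W_i/W_N). tAI_g is the geometric mean of w over the
  gene's codons, stop excluded. Codons with w = 0 would annihilate the
  product; by default they are substituted with the geometric mean of
  the positive w values (classical tAI convention); a strict mode
  (tAI = 0) is available.
* Demand: U_i = Σ_g TPM_RNA,g·c_ig over the expression-filtered gene
  set, host + virus combined per timepoint (the balance is a property of
  the whole cell, not of one genome); a scope flag restricts to host
  only. cu_i = min(1, U_i/U_max). Codons with cu = 0 are reported
  unscored rather than given infinite ratios.
* Balance_i = min(1, ratio′_i/ratio′_max) with ratio′ = w/cu;
  ratio′ > 1 is classed "excessive", otherwise "moderate".

A caveat worth knowing: because ratio′_max is recomputed per timepoint,
the *rescaled* balance need not move monotonically even when every raw
AU3 ratio′ falls monotonically with rising viral mRNA share. At mock
infection the normaliser tends to be dominated by a few AU3 codons fed
through the nearly free U:G route (e.g. AUU supplied by the abundant
anticodon of AUC). The tests therefore assert monotone decline for the
raw AU3 supply/demand ratio and a late-below-mock drop for the rescaled
score.

## Constraint fitting

The five constraints are fitted by maximising Spearman's ρ between
per-gene tAI and an expression ranking (footprint TPM) with Nelder–Mead,
over subsets of the most highly expressed genes (defaults 2000–5000;
truncated with a warning on smaller gene sets) and five uniform initial
points (0, 0.25, …, 1)·**1**. Evaluation clamps s into [0,1]^5;
tolerances are 10⁻⁶ on simplex and objective, 2000 iterations max.
Because the rank objective is piecewise constant, each run restarts from
its own optimum (fresh simplex) up to twice, stopping early when the
objective stops improving; all fits are reported, best first. The inner
objective is vectorised (W is affine in 1 − s given the pool; tAI is
exp(C·log w / l) for a gene × codon count matrix C) and is tested for
exact agreement with the scalar reference path.

In recovery experiments the expression ranking is tAI at the true
constraints times log-normal measurement noise with σ = 0.002 — about
3% of the tAI spread across genes. Noise-free rankings make "match the
truth objective" require exact rank recovery of a piecewise-constant
function, which a simplex method attains only by luck; tiny measurement
noise keeps the problem honest and realistic.

## Expression quantification

RPKM uses per-organism library sizes (reads uniquely aligned to coding
regions of the same organism); an organism with zero reads in a sample
(virus at mock infection) yields NaN RPKM and those genes simply fail
the filter. Gene-level footprint counts exclude the first five codons
(start included) and last five codons (stop included); ORFs of ≤ 10
codons are excluded with a warning. The expression filter discards genes
with RNA or footprint RPKM strictly below 10 in any replicate (the
boundary is retained). TPM can be rescaled within the host-only or
virus-only gene set for within-organism comparisons. Translation
efficiency is the geometric mean across replicates of footprint TPM over
RNA TPM in the all-genes scope — a deterministic simplification of a
DESeq2-style mean fold-change, recorded in the output's method tag so a
median-of-ratios variant can be swapped in for real-data replication;
genes with zero RNA TPM are excluded, not smoothed.

## tRNA quantification

Input is a pre-summarised alignment table (read, length, hit gene,
anticodon, genome), not BAM — alignment is out of scope and the TSV
contract keeps the module testable. A read is retained iff length ≥ 20,
all hits share one anticodon, that anticodon is not NNN/TTA
(suppressor)/TCA (selenocysteine), and all hits lie on one genome.
Retained multi-hit reads are counted once (the filter guarantees a
unique anticodon). Proportions are per anticodon × genome over the
scoring scope.

## Ribosome landscape

Footprint tracks are A-site-assigned counts at codon resolution, split
into short (21–22 nt) and long (29–30 nt) classes; both classes are
summed for occupancy and pause statistics. Exclusion zones differ by
operation, on purpose: gene-level counting drops five codons at each
end, while occupancy/pause statistics drop the first four codons and the
stop. The normalisation RPF_g/l_g runs over all non-stop positions, so a
gene with no exclusions has mean(e) = 1 exactly. Genes enter codon-type
statistics only when mean footprints per codon strictly exceed 1.
Codon-type occupancy is the simple mean of e over all included positions
pooled across genes (a gene-mean-of-means flag exists); replicates are
analysed separately. Pause thresholds use the population standard
deviation by default (sample form behind a flag) and a strict
inequality: positions equal to mean + k·sd are not pauses; genes with
fewer than two included positions get no calls. Per-codon-type pause
rates divide call counts by the codon type's occurrence count among
included positions. The short-footprint ratio uses occupancy-eligible
genes, excludes the start and stop codons, and reports short/total by
default with a short/long variant behind a flag; codon types with no
footprints are unscored (NaN).

A-site offsets are calibrated per footprint length from the start-codon
metagene: among 5'-end positions at or upstream of the start whose count
exceeds the window mean by two standard deviations, the most upstream
peak is taken (the initiating ribosome's 5' end lies exactly one offset
upstream of the start codon); a manual override table wins when
supplied, and lengths without a peak are left uncalibrated with a
warning. Periodicity QC reports reading-frame fractions and an FFT
periodogram of the mean-centred nucleotide track, with the dominant
period (3 nt for well-phased data).

Rank-sum tests (AU3 vs GC3, one-sided) use the exact null when both
groups have ≤ 50 tie-free observations and the normal approximation
otherwise; fully degenerate comparisons are reported with NaN p.

## Synthetic data: what it emulates, and what it does not

The generator draws everything from one `numpy.random.default_rng(seed)`
in a fixed order, so a seed determines the dataset down to file bytes.

* **Gene sets** — amino acids drawn proportionally to synonymous-family
  size; the third-base class of each synonymous choice is Bernoulli with
  the organism's AU3 weight (host 0.25, virus 0.9 — reproducing a
  GC ≈ 59% host CDS and a strongly AU3-biased viral CDS). Lengths are
  log-normal, mean 400 codons (σ = 0.25, clipped to 80–1000), a typical
  eukaryotic/giant-virus ORF scale.
* **tRNA pool** — anticodon weights mix the host's Watson–Crick demand
  with a uniform floor (coupling 0.5, giving a supply–usage rank
  correlation in the range reported for real cells) plus six
  virus-encoded tRNAs (two Leu-TAA, Leu-CAA, Trp-CCA, Cys-GCA, His-GTG)
  at 1.8% of the pool. Read tables carry a 10% contaminant fraction
  split across the three filter-violating modes.
* **Expression** — log-normal true TPMs; per timepoint the viral block
  of read weight is rescaled to the configured share (defaults 0, 0.15,
  0.35, 0.62 across 0–8 h.p.i.) and counts are Poisson at the configured
  depth.
* **Footprints** — per-position dwell = (1/w at the true constraints) ×
  log-normal noise (σ = 0.3), an intentionally minimal stand-in for
  elongation kinetics: it yields the supply–occupancy anticorrelation
  analytically and is checkable, but it is not a queueing model and
  carries no sequence-context, structure or amino-acid effects. Exactly
  1% of each gene's callable positions (past codon 4, non-stop) are made
  pauses by multiplying dwell by 20 — a fixed per-gene fraction rather
  than a per-position coin flip, since pause-free genes have thresholds
  sitting in the noise tail and would say nothing about detector
  quality. 2×10⁶ footprints per replicate are spread multinomially with
  gene totals ∝ TPM × length; each footprint is short-class with its
  codon's probability (defaults 0.35 for AU3, 0.2 for GC3, mimicking
  lower tRNA accessibility on AU3 codons). A 5% dwell share on the start
  codon emulates the initiation peak that offset calibration needs.
* **Not emulated** — sequence-level reads (FASTQ), mapping bias, UMIs,
  RNase digestion bias, tRNA modification signatures, kinetic coupling
  between timepoints. Passing tests therefore certify the estimators
  against this generative model, not against every artefact of real
  libraries.

## Problem sizes

Tests and the acceptance script run at desk scale: 60–300 host genes,
20–100 viral genes, 10⁴–2×10⁴ tRNA reads, 1.5×10⁵–2×10⁶ footprints per
replicate. At these sizes pause recovery achieves recall ≥ 0.96 with
FDR ≤ 0.09 across seeds, constraint recovery errs by ≤ 0.07, and the
whole acceptance run takes seconds on one CPU.

## Known limitations

* The wobble model is the five-route constraint set; rarer decoding
  routes (e.g. U:U, modified-base expansions) are not represented.
* TE is a TPM-ratio statistic, not a shrunken fold-change; low-count
  genes are noisier than a DESeq2 estimate would be.
* The pause detector inherits the mean + k·sd rule's behaviour on
  heavy-tailed dwell distributions: codons that are merely slow can be
  flagged in genes whose density profile is otherwise flat.
* Organelle genetic-code variants and frameshifts are out of scope; the
  standard code is assumed throughout.
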