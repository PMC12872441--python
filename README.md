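# codonscape

Codon-resolution analysis of the translation landscape when tRNA supply
and codon demand disagree — the situation of an AT-rich giant virus
(GC ≈ 28% genome, AU-ending "AU3" codons) expressing its genes inside a
GC-rich amoeba host (GC ≈ 58%, GC3 codons) whose tRNA pool barely changes
during infection. The package is for researchers combining ribosome
profiling (Ribo-seq), RNA-seq and tRNA-seq to ask: which codons are well
supplied with tRNAs, where do ribosomes slow down or pause, and what
happens to the supply/demand balance as the transcriptome shifts?

## The model

**tRNA supply.** The absolute adaptiveness of sense codon *i* is the
wobble-weighted supply of tRNAs able to decode it,

&nbsp;&nbsp;&nbsp;&nbsp;*W<sub>i</sub>* = Σ<sub>j</sub> (1 − *s<sub>ij</sub>*) · tRNA<sub>j</sub>,

where tRNA<sub>j</sub> is anticodon *j*'s proportion of the pool and
*s<sub>ij</sub>* ∈ [0, 1] penalises non-Watson–Crick pairing. Five wobble
classes are modelled (codon base : anticodon wobble base): A:I, C:I,
G:U, U:G, and A:G for the codon AUA only; inosine is the genomically
encoded A. Relative adaptiveness rescales by the geometric mean of the
three largest W ( *W<sub>N</sub>* ): *w<sub>i</sub>* = min(1, *W<sub>i</sub>*/*W<sub>N</sub>*),
and a gene's tRNA adaptation index is the geometric mean of *w* over its
codons: tAI<sub>g</sub> = (Π<sub>k</sub> *w*)<sup>1/l<sub>g</sub></sup>.
The five constraints can be fitted by Nelder–Mead maximisation of
Spearman's ρ between tAI and footprint TPM over the most highly
expressed genes.

**Codon demand and balance.** Demand weights codon counts by mRNA
abundance, *U<sub>i</sub>* = Σ<sub>g</sub> TPM<sub>RNA,g</sub>·*c<sub>ig</sub>*,
rescaled to cu<sub>i</sub> = min(1, *U<sub>i</sub>*/*U*<sub>max</sub>)
(top-3 geometric mean again). The balance score rescales ratio′ =
*w*/cu the same way; ratio′ > 1 means "excessive" tRNAs for that codon.

**Ribosome landscape.** Footprints come in a short (21–22 nt,
A-site-empty) and long (29–30 nt, A-site-occupied) class. Relative
density *e<sub>kg</sub>* = RPF<sub>kg</sub>/(RPF<sub>g</sub>/l<sub>g</sub>)
yields per-codon occupancy (decoding-time proxy); positions with
*e* above the gene mean + 2 s.d. are putative pauses; the short-footprint
ratio SFR = RPF<sub>S</sub>/RPF<sub>T</sub> per codon type is an inverse
proxy for tRNA accessibility. AU3/GC3 contrasts use one-sided Wilcoxon
rank-sum tests.

A fully seeded synthetic-data generator produces host/virus gene sets,
tRNA reads (with filter-violating contaminants), an expression time
course with a rising viral mRNA share, and footprint tracks whose dwell
is ∝ 1/*w* with injected pauses — so every estimator can be scored
against ground truth without any downloads.

## Worked example

```bash
python examples/05_balance_timecourse.py
```

```
 time  viral mRNA share  AU3 median  GC3 median  one-sided p
   t0              0.00       0.685       0.246            1
   t2              0.15       0.733       0.405            1
   t4              0.35       0.749       0.677        0.582
   t8              0.62       0.444       0.670     5.08e-11
```

At mock infection the host's rarely used AU3 codons enjoy excess tRNA
supply (high balance); once AU3-rich viral mRNAs dominate the
transcriptome (8 h.p.i., 62% of reads), the AU3 balance collapses below
GC3 and the one-sided rank-sum test becomes decisive. Similarly,

```bash
python examples/06_occupancy_pauses_sfr.py
```

```
80/110 genes pass mean RPF > 1
Spearman(W-score, occupancy) = -0.926  (supply anticorrelates with dwell)
pauses: 318 called, recall 0.99, FDR 0.02 against injected ground truth
host SFR median AU3 0.349 vs GC3 0.201 (one-sided p = 4.3e-18)
```

shows well-supplied codons decoded fast (negative W–occupancy
correlation), injected pauses recovered by the mean + 2 s.d. rule, and
lower tRNA accessibility (higher SFR) on host AU3 codons. The other
`examples/*.py` scripts cover simulation, pool quantification, TE,
constraint fitting, offset calibration/periodicity QC and the full
pipeline runner.

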