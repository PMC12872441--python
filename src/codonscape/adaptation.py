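"""tRNA adaptation scores and wobble-constraint fitting.

The absolute adaptiveness of a sense codon i is the wobble-weighted sum
of the proportions of the tRNAs that can decode it,

    W_i = sum_j (1 - s_ij) * tRNA_j,

where j runs over the anticodons returned by
:func:`codonscape.codon_core.enumerate_pairings` and s_ij is 0 for a
Watson–Crick pair and the class constraint otherwise.  Relative
adaptiveness rescales W by the geometric mean of the three largest
W values (W_N), capped at 1:

    w_i = min(1, W_i / W_N).

The tRNA adaptation index of a gene is the geometric mean of w over its
codons (stop codon excluded).  tAI = 1 means every codon of the gene is
maximally supported by the pool; values near 0 mean poor support.

The five wobble constraints can be fitted by Nelder–Mead maximisation of
Spearman's correlation between tAI and an expression ranking (footprint
TPM), over subsets of the most highly expressed genes and a grid of
initial points; evaluation clamps s into [0, 1]^5.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import spearmanr

from codonscape.codon_core import (
    CodingSequence,
    GeneticCode,
    STANDARD_CODE,
    WobbleConstraintSet,
    enumerate_pairings,
)
from codonscape.trna import TRNAPool

__all__ = [
    "compute_w_scores",
    "relative_adaptiveness",
    "top3_geometric_mean",
    "compute_tai",
    "optimize_constraints",
    "ConstraintFit",
    "DEFAULT_SUBSET_SIZES",
    "DEFAULT_INITIALIZATIONS",
]

DEFAULT_SUBSET_SIZES: tuple[int, ...] = (2000, 3000, 4000, 5000)
DEFAULT_INITIALIZATIONS: tuple[tuple[float, ...], ...] = tuple(
    tuple([v] * 5) for v in (0.0, 0.25, 0.5, 0.75, 1.0)
)


def _pool_series(pool: TRNAPool | pd.Series | dict) -> pd.Series:
    if isinstance(pool, TRNAPool):
        return pool.anticodon_proportions()
    s = pd.Series(pool, dtype=float)
    total = s.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(
            f"tRNA pool must be normalized proportions (sum={total:.6g})"
        )
    return s


def compute_w_scores(
    pool: TRNAPool | pd.Series | dict,
    constraints: WobbleConstraintSet = WobbleConstraintSet(),
    genetic_code: GeneticCode = STANDARD_CODE,
) -> pd.Series:
    """Absolute adaptiveness W per sense codon, indexed by codon."""
    trna = _pool_series(pool)
    scores = {}
    for codon in genetic_code.sense_codons:
        w = 0.0
        for anticodon, klass in enumerate_pairings(codon, genetic_code):
            supply = trna.get(anticodon, 0.0)
            if supply:
                w += (1.0 - constraints[klass]) * supply
        scores[codon] = w
    return pd.Series(scores, name="W").sort_index()


def top3_geometric_mean(values: pd.Series | np.ndarray) -> float:
    """Geometric mean of the three largest values.

    Falls back (with a warning) to the geometric mean of the positive
    values when fewer than three are positive; this keeps degenerate
    pools scorable.
    """
    v = np.sort(np.asarray(values, dtype=float))[::-1]
    top = v[:3]
    if (top <= 0).any():
        positive = v[v > 0]
        if positive.size == 0:
            raise ValueError("no positive values to normalize by")
        warnings.warn(
            f"fewer than 3 positive values; normalizer uses {positive.size}",
            stacklevel=2,
        )
        top = positive
    return float(np.exp(np.mean(np.log(top))))


def relative_adaptiveness(W: pd.Series) -> pd.DataFrame:
    """Relative adaptiveness w = min(1, W / W_N), W_N = top-3 geometric mean.

    Returns a per-codon table with columns ``W`` and ``w``; W_N is stored
    in ``df.attrs["W_N"]``.
    """
    W_N = top3_geometric_mean(W)
    w = np.minimum(1.0, W / W_N)
    out = pd.DataFrame({"W": W, "w": w})
    out.attrs["W_N"] = W_N
    return out


def compute_tai(
    gene: CodingSequence | list[str],
    w: pd.Series | pd.DataFrame,
    zero_w: str = "substitute",
) -> float:
    """tRNA adaptation index: geometric mean of w over the gene's codons.

    The stop codon is excluded.  Codons with w = 0 (no decoding supply)
    are handled per ``zero_w``: ``"substitute"`` replaces them by the
    geometric mean of all positive w values (classical convention);
    ``"strict"`` lets them drive tAI to 0.
    """
    if isinstance(w, pd.DataFrame):
        w = w["w"]
    if isinstance(gene, CodingSequence):
        codons = list(gene.sense_codons())
    else:
        codons = [c for c in gene if not STANDARD_CODE.is_stop(c)]
    if not codons:
        raise ValueError("gene has no sense codons")
    values = w.reindex(codons).to_numpy(dtype=float)
    if np.isnan(values).any():
        missing = sorted({c for c, v in zip(codons, values) if math.isnan(v)})
        raise KeyError(f"codons without w-score: {missing}")
    if zero_w == "substitute":
        positive = w[w > 0]
        if (values == 0).any():
            if positive.empty:
                return 0.0
            fill = float(np.exp(np.mean(np.log(positive))))
            values = np.where(values == 0, fill, values)
    elif zero_w != "strict":
        raise ValueError(f"unknown zero_w mode {zero_w!r}")
    if (values == 0).any():
        return 0.0
    return float(np.exp(np.mean(np.log(values))))


@dataclass
class ConstraintFit:
    """Result of one Nelder–Mead run for the wobble constraint vector."""

    s: tuple[float, float, float, float, float]
    objective: float  # Spearman rho at the fitted s
    subset_size: int
    initialization: tuple[float, float, float, float, float]
    converged: bool
    n_iterations: int = 0

    def as_dict(self) -> dict:
        return {
            "s": list(self.s),
            "objective": self.objective,
            "subset_size": self.subset_size,
            "initialization": list(self.initialization),
            "converged": self.converged,
            "n_iterations": self.n_iterations,
        }


def _clamp(s: np.ndarray) -> np.ndarray:
    return np.clip(s, 0.0, 1.0)


class _TaiEvaluator:
    """Vectorised tAI-of-every-gene as a function of the constraint vector.

    W is affine in (1 - s): W = wc_supply + class_supply @ (1 - s), with
    the per-codon class supplies precomputed from the pairing enumeration.
    tAI is then exp(counts @ log w / length) over a gene × codon count
    matrix.  Matches compute_w_scores/compute_tai exactly (tested).
    """

    def __init__(
        self,
        gene_codons: list[list[str]],
        pool: pd.Series,
        zero_w: str,
        genetic_code: GeneticCode = STANDARD_CODE,
    ):
        self.zero_w = zero_w
        codons = list(genetic_code.sense_codons)
        self.codon_index = {c: i for i, c in enumerate(codons)}
        from codonscape.codon_core import WOBBLE_CLASSES

        n = len(codons)
        self.wc_supply = np.zeros(n)
        self.class_supply = np.zeros((n, len(WOBBLE_CLASSES)))
        for i, codon in enumerate(codons):
            for anticodon, klass in enumerate_pairings(codon, genetic_code):
                supply = float(pool.get(anticodon, 0.0))
                if not supply:
                    continue
                if klass == "WC":
                    self.wc_supply[i] += supply
                else:
                    self.class_supply[i, WOBBLE_CLASSES.index(klass)] += supply
        self.counts = np.zeros((len(gene_codons), n))
        for g, cl in enumerate(gene_codons):
            for c in cl:
                self.counts[g, self.codon_index[c]] += 1
        self.lengths = self.counts.sum(axis=1)

    def w_vector(self, s: np.ndarray) -> np.ndarray:
        W = self.wc_supply + self.class_supply @ (1.0 - _clamp(s))
        top = np.sort(W)[::-1][:3]
        top = top[top > 0]
        if top.size == 0:
            return np.zeros_like(W)
        W_N = np.exp(np.mean(np.log(top)))
        return np.minimum(1.0, W / W_N)

    def tai(self, s: np.ndarray) -> np.ndarray:
        w = self.w_vector(s)
        positive = w[w > 0]
        if positive.size == 0:
            return np.zeros(self.counts.shape[0])
        if self.zero_w == "substitute":
            fill = np.exp(np.mean(np.log(positive)))
            w = np.where(w > 0, w, fill)
            logw = np.log(w)
        else:
            with np.errstate(divide="ignore"):
                logw = np.where(w > 0, np.log(np.where(w > 0, w, 1.0)), -np.inf)
        with np.errstate(invalid="ignore"):
            return np.exp(self.counts @ logw / self.lengths)


def _tai_vector(
    gene_codons: list[list[str]], pool: pd.Series, s: np.ndarray, zero_w: str
) -> np.ndarray:
    constraints = WobbleConstraintSet.from_vector(_clamp(s))
    W = compute_w_scores(pool, constraints)
    if (W <= 0).all():
        return np.zeros(len(gene_codons))
    w = relative_adaptiveness(W)["w"]
    return np.array([compute_tai(c, w, zero_w=zero_w) for c in gene_codons])


def optimize_constraints(
    genes: list[CodingSequence],
    expression: pd.Series,
    pool: TRNAPool | pd.Series | dict,
    subset_sizes: tuple[int, ...] = DEFAULT_SUBSET_SIZES,
    initializations: tuple[tuple[float, ...], ...] = DEFAULT_INITIALIZATIONS,
    zero_w: str = "substitute",
    maxiter: int = 2000,
    tol: float = 1e-6,
    restarts: int = 2,
) -> list[ConstraintFit]:
    """Fit the wobble constraint vector against an expression ranking.

    For each subset size (top-N genes by ``expression``, typically
    footprint TPM) and each initial point, Nelder–Mead maximises the
    Spearman correlation between per-gene tAI and expression, with s
    clamped into [0, 1]^5 at evaluation.  Because the rank objective is
    piecewise constant, each run is restarted from its own optimum (a
    fresh simplex) up to ``restarts`` times or until the objective stops
    improving.  Returns every fit, sorted with the best objective first;
    the run is deterministic given its inputs.
    """
    trna = _pool_series(pool)
    expr = expression.dropna()
    gene_map = {g.gene_id: g for g in genes}
    expr = expr[expr.index.isin(gene_map)]
    if expr.empty:
        raise ValueError("no overlap between expression and gene set")
    if expr.nunique() == 1:
        raise ValueError("constant expression vector: correlation undefined")
    ranked = expr.sort_values(ascending=False)

    fits: list[ConstraintFit] = []
    for size in subset_sizes:
        if size > len(ranked):
            warnings.warn(
                f"subset size {size} exceeds {len(ranked)} genes; truncating",
                stacklevel=2,
            )
        subset = ranked.iloc[: min(size, len(ranked))]
        codon_lists = [list(gene_map[g].sense_codons()) for g in subset.index]
        evaluator = _TaiEvaluator(codon_lists, trna, zero_w)
        y = subset.to_numpy()

        def neg_rho(s: np.ndarray) -> float:
            tai = evaluator.tai(s)
            if np.all(tai == tai[0]):
                return 0.0  # degenerate tAI: no ranking signal
            rho = spearmanr(tai, y).statistic
            return -rho if np.isfinite(rho) else 0.0

        for init in initializations:
            x0 = np.asarray(init, dtype=float)
            res = None
            n_iter = 0
            for _ in range(restarts + 1):
                nxt = minimize(
                    neg_rho,
                    x0=x0,
                    method="Nelder-Mead",
                    options={"maxiter": maxiter, "xatol": tol, "fatol": tol},
                )
                n_iter += int(nxt.nit)
                if res is not None and nxt.fun >= res.fun - tol:
                    if nxt.fun < res.fun:
                        res = nxt
                    break
                res = nxt
                x0 = _clamp(res.x)
            res.nit = n_iter
            s_fit = _clamp(res.x)
            fits.append(
                ConstraintFit(
                    s=tuple(float(v) for v in s_fit),
                    objective=float(-res.fun),
                    subset_size=len(subset),
                    initialization=tuple(float(v) for v in init),
                    converged=bool(res.success),
                    n_iterations=int(res.nit),
                )
            )
    fits.sort(key=lambda f: f.objective, reverse=True)
    return fits


def evaluate_constraints(
    genes: list[CodingSequence],
    expression: pd.Series,
    pool: TRNAPool | pd.Series | dict,
    s: tuple[float, ...],
    zero_w: str = "substitute",
) -> ConstraintFit:
    """Spearman objective at a fixed constraint vector (no optimisation)."""
    trna = _pool_series(pool)
    gene_map = {g.gene_id: g for g in genes}
    expr = expression.dropna()
    expr = expr[expr.index.isin(gene_map)]
    codon_lists = [list(gene_map[g].sense_codons()) for g in expr.index]
    tai = _tai_vector(codon_lists, trna, np.asarray(s, dtype=float), zero_w)
    rho = spearmanr(tai, expr.to_numpy()).statistic
    return ConstraintFit(
        s=tuple(float(v) for v in s),
        objective=float(rho),
        subset_size=len(expr),
        initialization=tuple(float(v) for v in s),
        converged=True,
    )
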