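"""Genetic-code bookkeeping and codon–anticodon pairing under wobble rules.

Codons and anticodons are kept in the DNA alphabet (T, not U) and written
5'→3'.  The wobble position of an anticodon is its first base (position 34
in tRNA numbering), which pairs the third base of the codon.  Inosine at
the wobble position is represented by the genomically encoded A, as in
tRNA gene annotation: no chemical-modification input is read.

Five non-Watson–Crick pairing classes are modelled, named
``codonThirdBase:anticodonWobbleBase``:

    A:I   codon ...A read by anticodon A.. (inosine)
    C:I   codon ...C read by anticodon A.. (inosine)
    G:U   codon ...G read by anticodon T..
    U:G   codon ...T read by anticodon G..
    A:G   codon ATA read by anticodon GAT only (a special isoleucine
          decoding route; no other codon receives this class)

Each class carries a selective constraint s in [0, 1]: the penalty of the
pairing (0 = as good as Watson–Crick, 1 = no decoding).  Watson–Crick
pairs are fixed at s = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "GeneticCode",
    "STANDARD_CODE",
    "WobbleConstraintSet",
    "CodingSequence",
    "MalformedCDSError",
    "codons_of",
    "classify_third_base",
    "gc_content",
    "enumerate_pairings",
    "reverse_complement",
    "WOBBLE_CLASSES",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: ordered names of the wobble classes; the order matches the constraint
#: vector layout used throughout the package.
WOBBLE_CLASSES: tuple[str, ...] = ("A:I", "C:I", "G:U", "U:G", "A:G")

# codon third base -> (anticodon wobble base, class name) for each
# non-Watson-Crick route.  A:G is restricted to codon ATA (checked at use).
_WOBBLE_ROUTES: dict[str, list[tuple[str, str]]] = {
    "A": [("A", "A:I"), ("G", "A:G")],
    "C": [("A", "C:I")],
    "G": [("T", "G:U")],
    "T": [("G", "U:G")],
}


class MalformedCDSError(ValueError):
    """Raised for coding sequences whose length is not a codon multiple
    or that contain characters outside {A, C, G, T, U, N}."""


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class GeneticCode:
    """A codon → amino-acid table plus its stop-codon set."""

    codon_to_aa: dict[str, str]
    stop_codons: frozenset[str]
    name: str = "standard"

    def __post_init__(self) -> None:
        n = len(self.codon_to_aa) + len(self.stop_codons)
        if n != 64:
            raise ValueError(f"genetic code must cover 64 codons, got {n}")

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(sorted(self.codon_to_aa))

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon]


def _standard_code() -> GeneticCode:
    table = unambiguous_dna_by_id[1]
    return GeneticCode(
        codon_to_aa=dict(table.forward_table),
        stop_codons=frozenset(table.stop_codons),
    )


STANDARD_CODE: GeneticCode = _standard_code()


@dataclass(frozen=True)
class WobbleConstraintSet:
    """Selective constraints for the five wobble pairing classes.

    ``values`` follows the order of :data:`WOBBLE_CLASSES`:
    (s_A:I, s_C:I, s_G:U, s_U:G, s_A:G).  The default is the fitted set
    for the amoeba/mimivirus system.
    """

    values: tuple[float, float, float, float, float] = (
        1.0,
        0.0,
        1.0,
        0.0065956,
        0.90832489,
    )

    def __post_init__(self) -> None:
        if len(self.values) != 5:
            raise ValueError("constraint vector must have length 5")
        if not all(0.0 <= v <= 1.0 for v in self.values):
            raise ValueError(f"constraints must lie in [0, 1]: {self.values}")

    def __getitem__(self, pairing_class: str) -> float:
        if pairing_class == "WC":
            return 0.0
        return self.values[WOBBLE_CLASSES.index(pairing_class)]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(WOBBLE_CLASSES, self.values))

    @classmethod
    def from_vector(cls, s) -> "WobbleConstraintSet":
        return cls(values=tuple(float(v) for v in s))


def codons_of(sequence: str) -> list[str]:
    """Split a nucleotide sequence into uppercase DNA codons.

    U is normalised to T.  Raises :class:`MalformedCDSError` when the
    length is not a multiple of 3 or the alphabet is invalid.
    """
    seq = sequence.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise MalformedCDSError(
            f"sequence length {len(seq)} is not a multiple of 3"
        )
    bad = set(seq) - {"A", "C", "G", "T", "N"}
    if bad:
        raise MalformedCDSError(f"invalid nucleotides {sorted(bad)}")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def classify_third_base(codon: str) -> str:
    """Classify a codon as AU3 (third base A/U) or GC3 (third base G/C)."""
    codon = codon.upper().replace("U", "T")
    if len(codon) != 3 or set(codon) - {"A", "C", "G", "T"}:
        raise ValueError(f"not a valid codon: {codon!r}")
    return "AU3" if codon[2] in "AT" else "GC3"


def gc_content(sequence: str) -> float:
    """Fraction of G+C over unambiguous bases; N is ignored entirely."""
    seq = sequence.upper().replace("U", "T")
    if not seq:
        raise ValueError("empty sequence")
    counted = sum(seq.count(b) for b in "ACGT")
    if counted == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return (seq.count("G") + seq.count("C")) / counted


def enumerate_pairings(
    codon: str, genetic_code: GeneticCode = STANDARD_CODE
) -> list[tuple[str, str]]:
    """Every anticodon that can decode ``codon``, with its pairing class.

    The anticodon's positions 2–3 must Watson–Crick pair the codon's
    first two bases; the wobble position (anticodon base 1) pairs the
    codon's third base either Watson–Crick or through one of the five
    wobble routes.  Stop codons are excluded from all scoring and raise.

    Returns ``[(anticodon, class)]`` with class in {"WC"} ∪ WOBBLE_CLASSES,
    the Watson–Crick entry first.
    """
    codon = codon.upper().replace("U", "T")
    if genetic_code.is_stop(codon):
        raise ValueError(f"stop codon {codon} has no decoding tRNA")
    if codon not in genetic_code.codon_to_aa:
        raise ValueError(f"unknown codon {codon!r}")
    # anticodon positions 2-3 are fixed by WC pairing of codon positions 1-2
    stem = reverse_complement(codon[:2])  # anticodon bases 2..3
    out: list[tuple[str, str]] = [(reverse_complement(codon), "WC")]
    for wobble_base, klass in _WOBBLE_ROUTES[codon[2]]:
        if klass == "A:G" and codon != "ATA":
            continue
        out.append((wobble_base + stem, klass))
    return out


@dataclass
class CodingSequence:
    """A CDS with its codon decomposition and organism tag.

    ``organism`` is one of {"host", "virus", "organelle"}.  The stop codon,
    if present as the final codon, is flagged and excluded from ``length``
    (gene length in codons, l_g).  An internal stop sets
    ``internal_stop=True`` with a warning rather than raising.
    """

    gene_id: str
    sequence: str
    organism: str = "host"
    genetic_code: GeneticCode = field(default=STANDARD_CODE, repr=False)
    codons: list[str] = field(init=False)
    has_stop: bool = field(init=False)
    internal_stop: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        all_codons = codons_of(self.sequence)
        if not all_codons:
            raise MalformedCDSError(f"{self.gene_id}: empty CDS")
        self.sequence = "".join(all_codons)
        self.has_stop = self.genetic_code.is_stop(all_codons[-1])
        body = all_codons[:-1] if self.has_stop else all_codons
        if any(self.genetic_code.is_stop(c) for c in body):
            self.internal_stop = True
            warnings.warn(
                f"{self.gene_id}: internal stop codon before the final codon",
                stacklevel=2,
            )
        self.codons = all_codons

    @property
    def length(self) -> int:
        """Gene length in codons, excluding the stop codon."""
        return len(self.codons) - (1 if self.has_stop else 0)

    def sense_codons(self) -> Iterator[str]:
        """Codons counted in adaptation scores: everything but stops."""
        for c in self.codons:
            if not self.genetic_code.is_stop(c):
                yield c
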