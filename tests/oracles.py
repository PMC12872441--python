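"""Independent brute-force oracles used by several test modules.

These deliberately avoid the package's pairing/scoring code paths: the
pairing oracle scans all 64 anticodons with a per-position predicate,
and the W oracle sums (1 - s) * supply over that enumeration.
"""

import numpy as np

_PAIRS_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_BASES = "ACGT"
ALL_ANTICODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]

CLASS_ORDER = ("A:I", "C:I", "G:U", "U:G", "A:G")


def brute_force_pairings(codon):
    """Scan all 64 anticodons with a per-position pairing predicate."""
    out = []
    for anticodon in ALL_ANTICODONS:
        # antiparallel: codon[0]:anticodon[2], codon[1]:anticodon[1],
        # codon[2]:anticodon[0] (the wobble position)
        if (codon[0], anticodon[2]) not in _PAIRS_WC:
            continue
        if (codon[1], anticodon[1]) not in _PAIRS_WC:
            continue
        third, wob = codon[2], anticodon[0]
        if (third, wob) in _PAIRS_WC:
            out.append((anticodon, "WC"))
        elif third == "A" and wob == "A":
            out.append((anticodon, "A:I"))
        elif third == "C" and wob == "A":
            out.append((anticodon, "C:I"))
        elif third == "G" and wob == "T":
            out.append((anticodon, "G:U"))
        elif third == "T" and wob == "G":
            out.append((anticodon, "U:G"))
        elif codon == "ATA" and wob == "G":
            out.append((anticodon, "A:G"))
    return sorted(out)


def brute_force_w(codon, pool, s_vector):
    """W-score by direct summation over the brute-force enumeration."""
    s_by_class = dict(zip(CLASS_ORDER, s_vector))
    s_by_class["WC"] = 0.0
    return sum(
        (1.0 - s_by_class[klass]) * pool.get(anticodon, 0.0)
        for anticodon, klass in brute_force_pairings(codon)
    )


def brute_force_pause_scan(e_by_gene, k, ddof=0):
    """Pause calls by a direct per-gene mean + k*sd scan.

    ``e_by_gene`` maps gene -> list of (position, e).  Returns the set of
    (gene, position) flagged.
    """
    flagged = set()
    for gene, pairs in e_by_gene.items():
        e = np.array([v for _, v in pairs], dtype=float)
        if e.size < 2:
            continue
        threshold = e.mean() + k * e.std(ddof=ddof)
        for (pos, v) in pairs:
            if v > threshold:
                flagged.add((gene, pos))
    return flagged
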