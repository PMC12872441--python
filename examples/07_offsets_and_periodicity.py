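"""A-site offset calibration and 3-nt periodicity QC.

The A-site offset per footprint length is read off the start-codon
metagene (the initiating ribosome's 5' ends pile up one offset upstream
of the start); the periodogram of an A-site-assigned nucleotide track
should be dominated by period 3.
"""

import numpy as np
import pandas as pd

from codonscape.landscape import calibrate_offsets, periodicity_qc

rng = np.random.default_rng(7)
rows = []
starts = {}
for g in range(8):
    gid = f"g{g}"
    starts[gid] = 120
    for length, offset in ((29, 15), (21, 8)):
        # initiation peak + elongating ribosomes across 100 codons
        occupancy = [(0, 12)] + [(3 * c, int(rng.integers(1, 4))) for c in range(1, 100)]
        for codon_start, n in occupancy:
            rows.extend(
                {"gene_id": gid, "length": length,
                 "five_prime_pos": 120 + codon_start - offset}
                for _ in range(n)
            )
profile = calibrate_offsets(pd.DataFrame(rows), pd.Series(starts))
print("inferred A-site offsets by footprint length:", profile.offsets)

track = np.tile([9.0, 1.0, 1.0], 200) + rng.poisson(0.5, 600)
qc = periodicity_qc(track)
print(f"frame fractions: {[round(f, 3) for f in qc.frame_fractions]}")
print(f"dominant period: {qc.dominant_period:.2f} nt")
# Offsets of 15 (long) and 8 (short) recover the simulated geometry, and
# frame 0 dominance plus a period-3 peak certify well-phased footprints.
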