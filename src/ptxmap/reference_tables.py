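"""Published per-linkage-group summary for a *Populus deltoides* x
*P. simonii* F1 pseudo-testcross map (19 chromosomes, 150 progeny).

These printed per-group statistics — SNP number and genetic length of the
19 maternal (DLG) and paternal (SLG) linkage groups, the physical
chromosome sizes of the *P. trichocarpa* reference assembly, and the
counts of markers anchored to that reference — are used as worked-example
inputs for the summary and correlation reports: mean adjacent marker
intervals, Pearson correlations among group statistics, anchored
fractions and per-Mb length differences are all recomputed from these
columns, not stored.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

POPULUS_GROUPS = pd.DataFrame(
    {
        "group": [f"LG{i}" for i in range(1, 20)],
        "maternal_snps": [240, 162, 134, 120, 112, 130, 81, 141, 90, 145,
                          85, 75, 85, 102, 73, 72, 59, 61, 45],
        "maternal_len_cm": [471.20, 328.55, 279.22, 254.00, 225.29, 303.32,
                            186.87, 242.47, 165.32, 249.87, 172.13, 150.29,
                            167.25, 176.57, 151.34, 155.82, 135.89, 144.89,
                            106.87],
        "paternal_snps": [155, 119, 94, 80, 86, 106, 70, 107, 82, 89,
                          45, 46, 64, 74, 48, 30, 64, 36, 35],
        "paternal_len_cm": [512.67, 327.69, 290.22, 203.88, 261.80, 339.89,
                            176.52, 268.86, 189.55, 265.25, 155.20, 163.38,
                            184.52, 219.07, 162.67, 118.28, 197.88, 158.74,
                            159.97],
        "chrom_size_mb": [50.50, 25.26, 21.82, 24.27, 25.89, 27.91, 15.61,
                          19.47, 12.95, 22.58, 18.50, 15.76, 16.32, 18.92,
                          15.28, 14.49, 16.08, 16.96, 15.94],
    }
).set_index("group")

#: markers of each parental map anchored to the reference genome
POPULUS_ANCHORED = {"maternal": (1654, 2012), "paternal": (1157, 1430)}

#: progeny count of the mapping family
POPULUS_N_PROGENY = 150


def populus_group_table() -> pd.DataFrame:
    """Copy of the published per-group statistics (19 rows)."""
    return POPULUS_GROUPS.copy()


def populus_totals() -> dict[str, float]:
    t = POPULUS_GROUPS.sum(numeric_only=True)
    return {
        "maternal_snps": int(t["maternal_snps"]),
        "maternal_len_cm": float(np.round(t["maternal_len_cm"], 2)),
        "paternal_snps": int(t["paternal_snps"]),
        "paternal_len_cm": float(np.round(t["paternal_len_cm"], 2)),
        "chrom_size_mb": float(np.round(t["chrom_size_mb"], 2)),
        "n_groups": len(POPULUS_GROUPS),
    }
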