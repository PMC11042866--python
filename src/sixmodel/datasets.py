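"""Small built-in reference tables.

``si162_reference_biomarkers`` holds the reported validation statistics of
the nine biomarker genes whose expression across the seven-cell melanoma
panel tracks Si162 sensitivity (unpaired t-test p, linear fold change
resistant/sensitive, Pearson r against the IC50 profile and its p-value,
n = 7 samples).  The r-values serve as inputs for recomputing the
correlation p-values with :func:`sixmodel.screen.pearson_with_p`'s
t-transform.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["si162_reference_biomarkers", "SI162_N_SAMPLES"]

#: Number of cell lines behind the reference correlations.
SI162_N_SAMPLES = 7

_ROWS = [
    # gene, t_test_p, fc_rs, r, r_p
    ("LRBA", 0.007207, 1.380658, 0.932858, 0.002163),
    ("MGMT", 0.005927, 1.135193, 0.897511, 0.006108),
    ("CAND1", 0.007251, 1.114019, 0.919897, 0.00334),
    ("ADD1", 3.5e-05, 1.111973, 0.895198, 0.00645),
    ("SETD2", 0.009224, 1.101595, 0.914935, 0.00387),
    ("CNTN6", 0.001001, 1.069136, 0.933926, 0.00208),
    ("FGF18", 0.003809, 1.061887, 0.902283, 0.005436),
    ("C18orf25", 0.007107, 1.048878, 0.905983, 0.004946),
    ("RPL13", 0.008296, 1.021695, 0.926089, 0.00274),
]


def si162_reference_biomarkers() -> pd.DataFrame:
    """Reported statistics of the nine validated Si162-response biomarker genes."""
    return pd.DataFrame(
        _ROWS, columns=["gene", "t_p", "fc_rs", "r", "r_p"]
    ).set_index("gene")
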