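"""Published benchmark MAPE tables for contact-vs-camera PRV agreement.

A 10-subject benchmark study compared the five PRV indicators of a
camera-derived BVP against a simultaneously recorded contact BVP, scoring
each subject by MAPE over 11 overlapped data segments, once on the raw
peak-to-peak intervals (PPI) and once after z-score outlier normalization
(NNI).  Only the per-subject MAPE tables are public (the underlying
recordings are not shareable), so the tables serve here as reference
inputs for the aggregation arithmetic: column means, and the PPI-to-NNI
improvement deltas that quantify how much outlier replacement helps.

Column ``mean_nn`` is labelled "Mean PP" in the original PPI table; the
indicator order matches :data:`prvkit.evaluation.INDICATORS`.
"""

from __future__ import annotations

import pandas as pd

from .evaluation import INDICATORS, MAPETable

# MAPE (%) per subject computed from raw peak-to-peak intervals.
_PPI_ROWS = {
    1: [0.03, 5.63, 3.35, 2.81, 6.03],
    2: [0.02, 10.89, 11.11, 6.19, 16.18],
    3: [0.02, 20.10, 14.62, 16.43, 26.60],
    4: [0.08, 19.22, 9.61, 17.89, 21.83],
    5: [0.01, 40.25, 35.88, 50.01, 46.42],
    6: [0.10, 14.86, 6.37, 7.60, 12.54],
    7: [0.02, 9.62, 3.38, 6.73, 9.44],
    8: [0.01, 10.53, 4.70, 7.38, 11.24],
    9: [0.01, 8.35, 7.12, 8.00, 13.94],
    10: [0.02, 20.74, 7.83, 2.91, 10.53],
}

# MAPE (%) per subject after normalization to NNI.
_NNI_ROWS = {
    1: [0.05, 1.58, 2.20, 2.32, 4.36],
    2: [0.08, 1.70, 7.89, 4.65, 13.00],
    3: [0.11, 2.50, 3.41, 2.56, 5.94],
    4: [0.11, 9.92, 5.70, 8.89, 12.44],
    5: [0.19, 4.79, 7.96, 6.53, 12.89],
    6: [0.13, 2.89, 5.56, 6.99, 11.43],
    7: [0.13, 2.58, 2.20, 3.40, 5.71],
    8: [0.10, 6.98, 3.86, 5.83, 9.02],
    9: [0.09, 3.24, 7.74, 5.57, 12.65],
    10: [0.16, 9.87, 7.83, 2.91, 10.53],
}


def _as_table(rows: dict[int, list[float]]) -> MAPETable:
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=INDICATORS)
    return MAPETable(frame)


def benchmark_ppi_table() -> MAPETable:
    """Benchmark per-subject MAPE table computed from raw PPI."""
    return _as_table(_PPI_ROWS)


def benchmark_nni_table() -> MAPETable:
    """Benchmark per-subject MAPE table computed from normalized NNI."""
    return _as_table(_NNI_ROWS)
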