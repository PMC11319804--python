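"""Bundled reference tables.

Published four-zone lobar deposition percentages (SPECT in vivo vs a
patient-specific CFD model) for a cohort of six mild-asthma patients, as
reported in a SPECT-CFD validation study of nebulised 1.32 um aerosol.
Values are percent of intrathoracic lobar dose over the merged RUL+RML,
RLL, LUL and LLL zones.  These serve as worked-example inputs to the
comparison metric.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["asthma_cohort"]

_ROWS = [
    # patient, method, RUL_RML, RLL, LUL, LLL
    (1, "SPECT", 26.13, 27.41, 18.00, 28.47),
    (1, "CFD", 24.38, 25.86, 16.59, 33.17),
    (2, "SPECT", 25.34, 31.84, 16.59, 26.23),
    (2, "CFD", 18.78, 35.30, 14.90, 31.02),
    (3, "SPECT", 17.27, 33.90, 14.47, 34.36),
    (3, "CFD", 19.35, 33.07, 16.03, 31.56),
    (4, "SPECT", 22.33, 26.68, 21.44, 29.55),
    (4, "CFD", 24.19, 27.07, 21.16, 27.57),
    (5, "SPECT", 24.93, 28.68, 22.42, 23.97),
    (5, "CFD", 25.73, 28.11, 21.35, 24.81),
    (6, "SPECT", 23.19, 32.30, 14.98, 29.52),
    (6, "CFD", 20.78, 29.93, 19.00, 30.29),
]


def asthma_cohort() -> pd.DataFrame:
    """Six-patient SPECT vs CFD lobar deposition table.

    Returns a DataFrame with columns ``patient``, ``method`` and the four
    merged lobar zones ``RUL_RML``, ``RLL``, ``LUL``, ``LLL`` (percent).
    """
    return pd.DataFrame(
        _ROWS, columns=["patient", "method", "RUL_RML", "RLL", "LUL", "LLL"]
    )
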