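"""Published screening results bundled as package data.

The original screening study reported, for a panel of 17 hot-melt-extruded
pharmaceutical filaments, the Pearson correlation of each filament's
normalized flexibility profile with three commercial reference filaments
(ABS, a dissolvable support filament, PLA), the resulting mean score, the
rounded 0/1 feedability call, and the observed printer feedability — plus
the pairwise consistency matrix of the three references and the correlation
eigenvalues of the component analysis.  The raw instrument curves were never
deposited, so these printed numbers are the only quantitative surface the
pipeline's arithmetic can be checked against; they are inputs to the
acceptance checks, not outputs of this package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REFERENCE_NAMES = ("ABS", "Dissolvable", "PLA")

# filament: (feedable?, C_ABS, C_Dissolvable, C_PLA, printed mean, printed 0/1)
_PANEL_ROWS = [
    ("HPMCAS", "N", 0.38, 0.64, 0.18, 0.40, 0),
    ("Mowiflex", "Y", 0.76, 0.69, 0.74, 0.73, 1),
    ("PEO", "Y", 0.92, 0.71, 0.82, 0.82, 1),
    ("PVPVA64", "N", -0.08, 0.22, -0.12, 0.01, 0),
    ("Soluplus", "N", -0.56, 0.40, -0.75, -0.30, 0),
    ("Eudragit EPO", "N", -0.70, 0.30, -0.79, -0.40, 0),
    ("EUD", "Y", 0.94, 0.65, 0.88, 0.82, 1),
    ("HD", "N", 0.32, 0.60, 0.18, 0.37, 0),
    ("HP10", "Y", 0.85, 0.82, 0.67, 0.78, 1),
    ("HP10D", "Y", 0.96, 0.53, 0.94, 0.81, 1),
    ("HP20", "Y", 0.94, 0.70, 0.87, 0.84, 1),
    ("HP20D", "Y", 0.90, 0.48, 0.95, 0.78, 1),
    ("HP30", "Y", 0.95, 0.77, 0.89, 0.87, 1),
    ("HP30D", "Y", 0.91, 0.40, 0.94, 0.75, 1),
    ("HP70", "Y", 0.70, 0.73, 0.51, 0.65, 1),
    ("HP90", "Y", 0.81, 0.81, 0.74, 0.79, 1),
    ("SP", "N", 0.49, 0.63, 0.28, 0.47, 0),
]


def load_published_panel() -> pd.DataFrame:
    """Per-filament published correlation triplets and feedability calls.

    Columns: ``filament_id``, ``feedability`` (observed Y/N in the printer),
    ``C_ABS``, ``C_Dissolvable``, ``C_PLA``, ``published_mean`` (2-dp mean
    score as printed) and ``published_rounded`` (printed 0/1 call).
    """
    return pd.DataFrame(
        _PANEL_ROWS,
        columns=[
            "filament_id", "feedability",
            "C_ABS", "C_Dissolvable", "C_PLA",
            "published_mean", "published_rounded",
        ],
    )


def load_reference_consistency_matrix() -> pd.DataFrame:
    """Published pairwise correlations among the three commercial references.

    The dissolvable filament correlates only 0.62/0.51 with ABS/PLA (which
    correlate 0.92 with each other) — the pattern that motivated treating it
    as an outlier for the component analysis while keeping it in the mean
    feedability score.
    """
    mat = np.array([[1.0, 0.62, 0.92], [0.62, 1.0, 0.51], [0.92, 0.51, 1.0]])
    names = list(REFERENCE_NAMES)
    return pd.DataFrame(mat, index=names, columns=names)


def load_published_eigenvalues() -> np.ndarray:
    """Leading correlation-matrix eigenvalues of the published component
    analysis (all later components were below 1).  Only the leading three
    were printed; the sub-1 tail is represented by a single placeholder
    value so Kaiser-rule selection can be exercised on the list."""
    return np.array([10.13, 3.57, 1.51, 0.9])
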