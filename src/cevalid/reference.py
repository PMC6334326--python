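"""Reference validation dataset of the ertapenem CE assay.

The published validation of the assay reports its calibration ANOVA only as
sums of squares, and its robustness study only as per-factor absolute
deviations.  This module packages those reference numbers and, where the raw
observations are not available, constructs synthetic datasets that reproduce
them exactly, so the full statistical pipeline can be exercised against the
reference results without simulation.
"""

from __future__ import annotations

import numpy as np

from .stats import CalibrationDataset

#: Reference calibration ANOVA components (corrected-area units squared):
#: six levels (70–120 µg/mL) in triplicate, N = 18.
REFERENCE_ANOVA = {
    "ss_between": 27348000160.07,
    "ss_regression": 27315622241.54,
    "ss_deviation": 32377918.53,
    "ss_residue": 32932159.12,
    "ss_total": 27380932319.19,
    "n_levels": 6,
    "replicates": 3,
    "alpha": 0.05,
}

#: Reference robustness deviations |D| (% content) per factor A–G and side.
REFERENCE_DEVIATIONS = {
    1: {"A": 0.62, "B": 1.03, "C": 0.17, "D": 1.01, "E": 0.08, "F": 0.40, "G": 0.59},
    -1: {"A": 0.29, "B": 0.63, "C": 0.01, "D": 0.08, "E": 0.66, "F": 0.23, "G": 0.40},
}

#: Reference response law of the assay (corrected area vs µg/mL).
REFERENCE_SLOPE = 2281.7
REFERENCE_INTERCEPT = -24495.0

#: Reference system-suitability replicates at 100 µg/mL: corrected peak
#: area, migration time (min), plate number, asymmetry.
REFERENCE_SST = [
    (200747, 3.17, 11120, 0.85),
    (206731, 3.20, 10947, 0.83),
    (206201, 3.19, 11045, 0.84),
    (205646, 3.19, 10895, 0.85),
    (203986, 3.19, 10824, 0.84),
    (205936, 3.21, 10624, 0.84),
    (207729, 3.23, 10537, 0.85),
    (200253, 3.23, 11046, 0.84),
    (205686, 3.23, 10782, 0.84),
    (204768, 3.20, 10868, 0.84),
]

#: Acid dissociation constants of the analyte (strongest acidic / basic pKa).
REFERENCE_PKAS = (3.22, 9.03)


def reference_calibration_dataset() -> CalibrationDataset:
    """Synthetic 18-point calibration replica matching the reference ANOVA.

    The raw replicate areas behind the reference ANOVA were never published;
    this constructs a synthetic dataset whose own ANOVA reproduces the
    reference sums of squares exactly (to floating precision):

    - the slope is chosen so the regression SS over Sxx = 5250 matches;
    - level means sit on that line plus a quadratic contrast
      (5, −1, −4, −4, −1, 5) — orthogonal to both the constant and the
      linear trend — scaled to the deviation-of-linearity SS;
    - within-level residuals follow the zero-sum pattern (1, 0, −1) scaled
      to the residue (pure error) SS.
    """
    x = np.array([70.0, 80.0, 90.0, 100.0, 110.0, 120.0])
    r = REFERENCE_ANOVA["replicates"]
    sxx_total = r * float(np.sum((x - x.mean()) ** 2))  # 5250
    slope = np.sqrt(REFERENCE_ANOVA["ss_regression"] / sxx_total)
    contrast = np.array([5.0, -1.0, -4.0, -4.0, -1.0, 5.0])
    dev = contrast * np.sqrt(
        REFERENCE_ANOVA["ss_deviation"] / (r * float(np.sum(contrast**2)))
    )
    within = np.array([1.0, 0.0, -1.0]) * np.sqrt(
        REFERENCE_ANOVA["ss_residue"] / (x.size * 2.0)
    )
    level_means = REFERENCE_INTERCEPT + slope * x + dev
    areas = [m + within for m in level_means]
    return CalibrationDataset(levels=x, areas=areas)
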