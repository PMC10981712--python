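"""Packaged reference tables for the chrysotile-asbestos-mine survey.

These are the published summary statistics of the 84-sample soil survey
around a large open-pit chrysotile asbestos mine in an arid plateau region
(mining, beneficiation, residue, residential and bare-land zones), plus the
mean composition of the four asbestos source materials sampled there
(ore, tailings, finished products, dust).  They serve as the packaged
defaults for desk calculations and as calibration anchors for the
synthetic survey generator; units are mg·kg⁻¹ dry soil throughout.
"""

from __future__ import annotations

import pandas as pd

from .core_data import DEFAULT_ELEMENTS

#: Survey descriptive statistics (84 samples): min, max, mean, sd.
SURVEY_SUMMARY = pd.DataFrame(
    {
        "As": (1.29, 206.10, 21.79, 31.54),
        "Hg": (0.002, 0.103, 0.010, 0.011),
        "Cd": (0.04, 0.29, 0.09, 0.04),
        "Pb": (2.72, 175.38, 16.62, 18.30),
        "Cr": (24.91, 1826.35, 580.04, 559.74),
        "Cu": (4.00, 117.74, 20.25, 13.82),
        "Zn": (16.58, 122.20, 41.72, 15.95),
        "Ni": (15.25, 1951.19, 636.93, 632.68),
    },
    index=["min", "max", "mean", "sd"],
)[list(DEFAULT_ELEMENTS)].T

#: Mean heavy-metal content of the asbestos source materials.
SOURCE_MATERIAL_MEANS = pd.Series(
    {
        "As": 14.73,
        "Hg": 0.02,
        "Cd": 0.07,
        "Pb": 6.23,
        "Cr": 1339.17,
        "Cu": 10.33,
        "Zn": 13.33,
        "Ni": 1788.33,
    }
)[list(DEFAULT_ELEMENTS)]
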