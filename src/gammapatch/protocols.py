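"""Stimulus protocol grids used for tuning-curve fitting.

These are the parametric stimulus sets of the study design this package
models: gratings covarying orientation with spatial frequency, size or
contrast, and full-screen hue patches covarying hue with saturation, value
or size.  Contrasts are in percent, sizes in dva, spatial frequencies in
cpd, orientations and hues in degrees; saturation is a fraction and value a
percent.
"""

from __future__ import annotations

import numpy as np

# gratings -----------------------------------------------------------------
SF_VALUES = np.array([0.5, 1.0, 2.0, 4.0, 8.0])  # cpd
ORI_8 = np.array([0.0, 22.5, 45.0, 67.5, 90.0, 112.5, 135.0, 157.5])  # deg
ORI_4 = np.array([0.0, 45.0, 90.0, 135.0])
SIZE_VALUES = np.array([0.3, 0.6, 1.2, 2.4, 4.8, 9.6])  # dva
CON_VALUES_M1 = np.array([0.0, 3.12, 6.25, 12.5, 25.0, 50.0, 100.0])  # percent
CON_VALUES_M2 = np.array([0.0, 6.25, 12.5, 25.0, 50.0, 100.0])

#: stand-in radius (dva) for full-screen stimuli, beyond any fitted size
#: midpoint so the size sigmoid is at its ceiling
FULL_SCREEN_SIZE_DVA = 25.0
FULL_CONTRAST = 100.0

# hue patches ---------------------------------------------------------------
HUE_36 = np.arange(0.0, 360.0, 10.0)
HUE_6 = np.arange(0.0, 360.0, 60.0)
SAT_VALUES = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
VAL_VALUES = np.array([0.0, 25.0, 50.0, 75.0, 100.0])  # percent
HUE_SIZE_VALUES_M1 = np.array([0.15, 0.3, 0.6, 1.2, 2.4, 4.8, 9.6])  # dva
HUE_SIZE_VALUES_M2 = np.array([0.5, 0.68, 0.92, 1.26, 1.72, 2.34, 3.2])

#: value levels below this percent are outside the modelled domain
VAL_MIN_PERCENT = 25.0
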