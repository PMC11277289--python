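import numpy as np
import pytest

from gammapatch import protocols as P
from gammapatch.synthetic_data import (
    RECOVERY_GRATING_SHAPE,
    RECOVERY_HUE_SHAPE,
)
from gammapatch.tuning_models import (
    HuePatchStimulus,
    grating_grid,
    hue_grid,
    hue_product,
    load_median_shapes,
)

GRATING_PARAM_NAMES = ("mu", "sigma", "alpha", "kappa", "m", "sigma0", "k", "c0")
HUE_PARAM_NAMES = (
    "alpha_r", "kappa_r", "alpha_c", "kappa_c", "a_c",
    "m", "sigma0", "l", "s0", "g", "o",
)
VAL_LEVELS_FIT = np.array([25.0, 50.0, 75.0, 100.0])


@pytest.fixture(scope="session")
def median_shapes_m1():
    return load_median_shapes("M1")


@pytest.fixture(scope="session")
def recovery_shapes():
    return RECOVERY_GRATING_SHAPE, RECOVERY_HUE_SHAPE


def grating_protocol_grids(shape, sizeori_f=2.0):
    """The three noiseless grating protocol grids for a given shape."""
    sfori = grating_grid(
        shape, ("f", P.SF_VALUES), ("theta", P.ORI_8),
        r=P.FULL_SCREEN_SIZE_DVA, c=P.FULL_CONTRAST,
    )
    sizeori = grating_grid(
        shape, ("r", P.SIZE_VALUES), ("theta", P.ORI_8),
        f=sizeori_f, c=P.FULL_CONTRAST,
    )
    conori = grating_grid(
        shape, ("c", P.CON_VALUES_M1), ("theta", P.ORI_4),
        f=sizeori_f, r=P.FULL_SCREEN_SIZE_DVA,
    )
    return sfori, sizeori, conori


def hue_protocol_curves(shape):
    """Noiseless hue-protocol responses: hue36, huesize, huesat, hueval."""
    fs = P.FULL_SCREEN_SIZE_DVA
    hue36 = np.array(
        [hue_product(HuePatchStimulus(h, 1.0, 100.0, fs), shape) for h in P.HUE_36]
    )
    huesize = np.array(
        [hue_product(HuePatchStimulus(0.0, 1.0, 100.0, r), shape)
         for r in P.HUE_SIZE_VALUES_M1]
    )
    huesat = hue_grid(shape, ("H", P.HUE_6), ("S", P.SAT_VALUES), V=100.0, R=fs)
    hueval = hue_grid(shape, ("H", P.HUE_6), ("V", VAL_LEVELS_FIT), S=1.0, R=fs)
    return hue36, huesize, huesat, hueval


def relative_error(true, est, circular_period=None):
    if circular_period is not None:
        half = circular_period / 2
        return abs((est - true + half) % circular_period - half) / abs(true)
    return abs(est - true) / abs(true)
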