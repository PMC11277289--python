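"""Separable multiplicative tuning models for gratings and hue patches.

Gamma band responses to a stimulus are modelled as the product of unit-gain
single-feature factors, each bounded in [0, 1] before gain/offset scaling:

Gratings (8 shape parameters mu, sigma, alpha, kappa, m, sigma0, k, c0)::

    F(f, theta, r, c) = N(log2 f; mu, sigma) * VM(2*theta; 2*alpha, kappa)
                        * sig(m, sigma0; log2 r) * sig(k, c0; log2 c)

Hue patches (11 parameters alpha_r, kappa_r, alpha_c, kappa_c, a_c,
m, sigma0, l, s0, g, o)::

    F(H, S, V, R) = [VM(H; alpha_r, kappa_r) + a_c * VM(H; alpha_c, kappa_c)]
                    * (g*V/100 + o) * sig(m, sigma0; log2 R) * sig(l, s0; S)

where N and VM are Gaussian / von Mises densities normalized to peak at 1,
and sig(slope, mid; x) = 1 / (1 + 10^(-slope*(x - mid_transformed))) is a
base-10 sigmoid on the (log2-transformed where noted) argument.  Orientation
has period 180 deg (angles doubled inside the von Mises); hue has period
360 deg.  A scaled estimate is G*F + O with gain and offset fit per
electrode; G and O do not affect correlations.

Shape parameters are fit per electrode by bounded nonlinear least squares on
the two-feature protocol grids, cross-validated over random trial halves,
and pooled across electrodes by (circular where needed) medians.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import pearsonr

from . import protocols
from .exceptions import DegenerateInputError, ValidationError
from .separability import TuningMatrix

__all__ = [
    "GratingStimulus",
    "HuePatchStimulus",
    "GratingShape",
    "HueShape",
    "ScaleFit",
    "CurveFit",
    "GratingFitResult",
    "HueFitResult",
    "sf_tuning",
    "ori_tuning",
    "size_tuning",
    "con_tuning",
    "hue_tuning",
    "hue_size_tuning",
    "sat_tuning",
    "val_tuning",
    "grating_product",
    "hue_product",
    "scale",
    "fit_grating_shape",
    "fit_hue_shape",
    "cross_validate_grating",
    "cross_validate_hue",
    "median_pool",
    "circular_median",
    "load_median_shapes",
    "grating_grid",
    "hue_grid",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------
@dataclass
class GratingStimulus:
    """An achromatic grating: spatial frequency f (cpd), orientation theta
    (deg), radius r (dva; full screen as a large value), contrast c (%)."""

    f: float
    theta: float
    r: float
    c: float

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValidationError(f"spatial frequency must be > 0, got {self.f}")
        if self.r <= 0:
            raise ValidationError(f"grating radius must be > 0, got {self.r}")
        if not 0 <= self.c <= 100:
            raise ValidationError(f"contrast must be in [0, 100] %, got {self.c}")


@dataclass
class HuePatchStimulus:
    """A uniform chromatic patch: hue H (deg), saturation S (fraction),
    value V (percent), radius R (dva; 0 encodes 'no patch')."""

    H: float
    S: float
    V: float
    R: float

    def __post_init__(self) -> None:
        self.H = float(self.H) % 360.0
        if not 0 <= self.S <= 1:
            raise ValidationError(f"saturation must be in [0, 1], got {self.S}")
        if not 0 <= self.V <= 100:
            raise ValidationError(f"value must be in [0, 100] %, got {self.V}")
        if self.R < 0:
            raise ValidationError(f"radius must be >= 0, got {self.R}")


@dataclass
class GratingShape:
    """The eight shape parameters of the grating product model."""

    mu: float  # SF center, log2 cpd
    sigma: float  # SF spread, octaves
    alpha: float  # orientation center, deg
    kappa: float  # orientation concentration
    m: float  # size sigmoid slope
    sigma0: float  # size midpoint, dva
    k: float  # contrast sigmoid slope
    c0: float  # contrast midpoint, percent

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValidationError("sigma must be > 0")
        if self.kappa < 0:
            raise ValidationError("kappa must be >= 0")
        if self.sigma0 <= 0 or self.c0 <= 0:
            raise ValidationError("sigmoid midpoints must be > 0")
        self.alpha = float(self.alpha) % 180.0


@dataclass
class HueShape:
    """The eleven shape parameters of the hue-patch product model."""

    alpha_r: float  # red lobe center, deg
    kappa_r: float
    alpha_c: float  # cyan lobe center, deg
    kappa_c: float
    a_c: float  # cyan lobe gain relative to red
    m: float  # size sigmoid slope
    sigma0: float  # size midpoint, dva
    l: float  # saturation sigmoid slope
    s0: float  # saturation midpoint, fraction
    g: float  # value line slope
    o: float  # value line intercept

    def __post_init__(self) -> None:
        if self.kappa_r < 0 or self.kappa_c < 0:
            raise ValidationError("concentrations must be >= 0")
        if self.a_c < 0:
            raise ValidationError("a_c must be >= 0")
        if self.sigma0 <= 0:
            raise ValidationError("size midpoint must be > 0")
        if not 0 <= self.s0 <= 1:
            raise ValidationError("s0 must be in [0, 1]")
        self.alpha_r = float(self.alpha_r) % 360.0
        self.alpha_c = float(self.alpha_c) % 360.0


@dataclass
class ScaleFit:
    """Gain/offset of the scaled estimate G*F + O."""

    G: float
    O: float


# --------------------------------------------------------------------------
# single-feature factors (unit gain, zero offset) and public tuning curves
# --------------------------------------------------------------------------
def _gauss_peak1(x, mu, sigma):
    return np.exp(-0.5 * ((np.asarray(x, dtype=float) - mu) / sigma) ** 2)


def _vonmises_peak1(ang_rad, center_rad, kappa):
    return np.exp(kappa * (np.cos(np.asarray(ang_rad, dtype=float) - center_rad) - 1.0))


def _sigmoid10(z):
    return 1.0 / (1.0 + 10.0 ** (-np.asarray(z, dtype=float)))


def _sigmoid_log2(x, slope, midpoint):
    """Base-10 sigmoid on log2 x; the x = 0 limit of the factor is 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValidationError("sigmoid argument must be >= 0")
    out = np.zeros(np.shape(x))
    pos = x > 0
    with np.errstate(divide="ignore"):
        out[pos] = _sigmoid10(slope * (np.log2(x[pos]) - np.log2(midpoint)))
    return out if out.ndim else float(out)


def sf_tuning(f, mu: float, sigma: float, A: float = 1.0, B: float = 0.0):
    """Gaussian spatial-frequency tuning on log2 cpd, peak-normalized."""
    if sigma <= 0:
        raise ValidationError("sigma must be > 0")
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValidationError("spatial frequency must be > 0")
    return A * _gauss_peak1(np.log2(f), mu, sigma) + B


def ori_tuning(theta_deg, alpha: float, kappa: float, A: float = 1.0, B: float = 0.0):
    """von Mises orientation tuning with 180 deg period (angles doubled)."""
    if kappa < 0:
        raise ValidationError("kappa must be >= 0")
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    return A * _vonmises_peak1(2.0 * th, 2.0 * np.deg2rad(alpha), kappa) + B


def size_tuning(r, m: float, sigma0: float, A: float = 1.0, B: float = 0.0):
    """Sigmoid size tuning on log2 dva; A/2 + B at r = sigma0."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValidationError("size must be > 0")
    return A * _sigmoid_log2(r, m, sigma0) + B


def con_tuning(c, k: float, c0: float, A: float = 1.0, B: float = 0.0):
    """Sigmoid contrast tuning on log2 percent; A/2 + B at c = c0."""
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise ValidationError("contrast must be > 0")
    return A * _sigmoid_log2(c, k, c0) + B


def hue_tuning(
    H_deg,
    alpha_r: float,
    kappa_r: float,
    alpha_c: float,
    kappa_c: float,
    a_c: float,
    A: float = 1.0,
    B: float = 0.0,
):
    """Dual von Mises hue tuning (red + cyan lobes), period 360 deg."""
    if kappa_r < 0 or kappa_c < 0 or a_c < 0:
        raise ValidationError("kappa_r, kappa_c and a_c must be >= 0")
    H = np.deg2rad(np.asarray(H_deg, dtype=float))
    lobes = _vonmises_peak1(H, np.deg2rad(alpha_r), kappa_r) + a_c * _vonmises_peak1(
        H, np.deg2rad(alpha_c), kappa_c
    )
    return A * lobes + B


hue_size_tuning = size_tuning  # same sigmoid on log2-transformed radius


def sat_tuning(S, l: float, s0: float, A: float = 1.0, B: float = 0.0):
    """Sigmoid saturation tuning on the untransformed fraction S."""
    S = np.asarray(S, dtype=float)
    return A * _sigmoid10(l * (S - s0)) + B


def val_tuning(V_percent, g: float, o: float):
    """Linear value dependence g*V/100 + o; V below 25 % is outside the
    modelled domain and is clamped with a warning."""
    V = np.asarray(V_percent, dtype=float)
    if np.any(V < protocols.VAL_MIN_PERCENT):
        warnings.warn(
            f"value below {protocols.VAL_MIN_PERCENT} % is outside the modelled "
            "domain; clamping",
            stacklevel=2,
        )
        V = np.clip(V, protocols.VAL_MIN_PERCENT, None)
    return g * V / 100.0 + o


def grating_product(stim: GratingStimulus, shape: GratingShape):
    """Unscaled product-model response to a grating (all four factors)."""
    return float(
        sf_tuning(stim.f, shape.mu, shape.sigma)
        * ori_tuning(stim.theta, shape.alpha, shape.kappa)
        * _sigmoid_log2(stim.r, shape.m, shape.sigma0)
        * _sigmoid_log2(stim.c, shape.k, shape.c0)
    )


def hue_product(stim: HuePatchStimulus, shape: HueShape):
    """Unscaled product-model response to a uniform hue patch.

    R = 0 drives the size factor to its floor (0), so the response is 0.
    """
    return float(
        hue_tuning(
            stim.H, shape.alpha_r, shape.kappa_r, shape.alpha_c, shape.kappa_c, shape.a_c
        )
        * val_tuning(stim.V, shape.g, shape.o)
        * _sigmoid_log2(stim.R, shape.m, shape.sigma0)
        * sat_tuning(stim.S, shape.l, shape.s0)
    )


def scale(response, G: float, O: float):
    """Scaled estimate G*F + O."""
    return G * np.asarray(response, dtype=float) + O


# --------------------------------------------------------------------------
# convenience grid evaluators (used by synthetic data and tests)
# --------------------------------------------------------------------------
def grating_grid(
    shape: GratingShape,
    rows: tuple[str, Sequence[float]],
    cols: tuple[str, Sequence[float]],
    **fixed: float,
) -> TuningMatrix:
    """Evaluate the grating product model on a 2-D feature grid.

    ``rows`` and ``cols`` are ``(feature_name, values)`` with names among
    {'f', 'theta', 'r', 'c'}; the remaining features come from ``fixed``.
    """
    return _grid(shape, rows, cols, fixed, grating_product, GratingStimulus)


def hue_grid(
    shape: HueShape,
    rows: tuple[str, Sequence[float]],
    cols: tuple[str, Sequence[float]],
    **fixed: float,
) -> TuningMatrix:
    """Evaluate the hue product model on a 2-D feature grid
    (names among {'H', 'S', 'V', 'R'})."""
    return _grid(shape, rows, cols, fixed, hue_product, HuePatchStimulus)


def _grid(shape, rows, cols, fixed, product, stim_cls) -> TuningMatrix:
    rname, rvals = rows
    cname, cvals = cols
    out = np.empty((len(rvals), len(cvals)))
    for i, rv in enumerate(rvals):
        for j, cv in enumerate(cvals):
            kw = dict(fixed)
            kw[rname] = rv
            kw[cname] = cv
            out[i, j] = product(stim_cls(**kw), shape)
    return TuningMatrix(
        out, axis_a=np.asarray(rvals, float), axis_b=np.asarray(cvals, float),
        name_a=rname, name_b=cname,
    )


# --------------------------------------------------------------------------
# least-squares fitting of shape parameters
# --------------------------------------------------------------------------
@dataclass
class CurveFit:
    """One single-feature curve fit: shape parameters plus gain/offset."""

    params: dict
    A: float
    B: float
    n_points: int
    converged: bool
    message: str = ""


@dataclass
class GratingFitResult:
    shape: GratingShape | None
    sf: CurveFit
    ori: CurveFit
    size: CurveFit
    con: CurveFit

    @property
    def ok(self) -> bool:
        return all(c.converged for c in (self.sf, self.ori, self.size, self.con))


@dataclass
class HueFitResult:
    shape: HueShape | None
    hue: CurveFit
    size: CurveFit
    sat: CurveFit
    val: CurveFit

    @property
    def ok(self) -> bool:
        return all(c.converged for c in (self.hue, self.size, self.sat, self.val))


def _fit_ls(
    residual: Callable[[np.ndarray], np.ndarray],
    inits: Sequence[Sequence[float]],
    bounds: tuple[np.ndarray, np.ndarray],
):
    """Bounded least squares from several starting points; lowest cost wins.

    Multi-start with tight tolerances matters here: sigmoids with shallow
    slopes and Gaussians peaking beyond the probed grid sit on nearly flat
    cost ridges where a single local solve can stall far from the zero-cost
    solution.
    """
    best = None
    lo, hi = bounds
    for p0 in inits:
        try:
            res = least_squares(
                residual, np.clip(np.asarray(p0, float), lo, hi), bounds=bounds,
                ftol=1e-13, xtol=1e-13, gtol=1e-13,
            )
        except Exception:  # singular jacobian etc.
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    return best


def _curve(
    residual, inits, lo, hi, y, n_shape: int, names: Sequence[str],
    n_points: int | None = None,
) -> CurveFit:
    y = np.asarray(y, dtype=float)
    n_points = y.size if n_points is None else n_points
    if np.ptp(y) == 0:
        return CurveFit(
            params={n: np.nan for n in names}, A=np.nan, B=np.nan,
            n_points=n_points, converged=False, message="flat input: unidentifiable",
        )
    res = _fit_ls(residual, inits, (np.asarray(lo, float), np.asarray(hi, float)))
    if res is None:
        return CurveFit(
            params={n: np.nan for n in names}, A=np.nan, B=np.nan,
            n_points=n_points, converged=False, message="did not converge",
        )
    p = res.x
    return CurveFit(
        params=dict(zip(names, p[:n_shape])),
        A=float(p[n_shape]) if len(p) > n_shape else 1.0,
        B=float(p[n_shape + 1]) if len(p) > n_shape + 1 else 0.0,
        n_points=n_points, converged=True,
    )


def _sigmoid_starts(x_levels: np.ndarray, y: np.ndarray) -> list[list[float]]:
    """Starting points for a (slope, midpoint, A, B) sigmoid fit."""
    A0, B0 = np.ptp(y) or 1.0, y.min()
    pos = x_levels[x_levels > 0]
    mids = [np.sqrt(pos.min() * pos.max()), pos.max()]
    return [[sl, m0, A0, B0] for sl in (0.5, 2.0) for m0 in mids]


def fit_grating_shape(
    sfori: TuningMatrix,
    sizeori: TuningMatrix,
    conori: TuningMatrix,
) -> GratingFitResult:
    """Fit the eight grating shape parameters from the three protocol grids.

    ``sfori`` carries spatial frequencies (cpd) on rows and orientations
    (deg) on columns; ``sizeori`` sizes (dva) x orientations; ``conori``
    contrasts (%) x orientations.  Each single-feature curve is fit with its
    own gain A and offset B on the protocol's full grid, pooled (averaged)
    across the orthogonal orientation axis — for these balanced designs the
    pooled fit has the same least-squares optimum as the raw-grid fit but a
    zero cost floor, which keeps shallow-ridge parameters resolvable.
    Zero-contrast rows enter through the analytic limit of the contrast
    factor (0).  Non-convergence is flagged on the returned record, never
    raised.
    """
    for tm, what in ((sfori, "sfori"), (sizeori, "sizeori"), (conori, "conori")):
        if tm.axis_a is None or tm.axis_b is None:
            raise ValidationError(f"{what} needs both feature axes")

    # SF: Gaussian on log2 cpd
    y_sf = sfori.values.mean(axis=1)
    lf = np.log2(sfori.axis_a)
    A0, B0 = np.ptp(y_sf) or 1.0, y_sf.min()
    peak = lf[np.argmax(y_sf)]
    mu_starts = [peak - 1.0, peak, peak + 1.0, lf.max() + 2.0]
    sf = _curve(
        lambda p: p[2] * _gauss_peak1(lf, p[0], p[1]) + p[3] - y_sf,
        [[mu0, s0_, A0, B0] for mu0 in mu_starts for s0_ in (0.7, 1.5)],
        [lf.min() - 3, 1e-2, -np.inf, -np.inf],
        [lf.max() + 3, 10.0, np.inf, np.inf],
        y_sf, 2, ["mu", "sigma"], n_points=sfori.values.size,
    )

    # orientation: von Mises on doubled angles
    y_or = sfori.values.mean(axis=0)
    th = np.deg2rad(sfori.axis_b)
    alpha0 = sfori.axis_b[np.argmax(y_or)]
    A0, B0 = np.ptp(y_or) or 1.0, y_or.min()
    ori = _curve(
        lambda p: p[2] * _vonmises_peak1(2 * th, 2 * np.deg2rad(p[0]), p[1]) + p[3]
        - y_or,
        [[alpha0, k0, A0, B0] for k0 in (0.3, 1.0, 4.0)],
        [alpha0 - 90.0, 0.0, -np.inf, -np.inf],
        [alpha0 + 90.0, 100.0, np.inf, np.inf],
        y_or, 2, ["alpha", "kappa"], n_points=sfori.values.size,
    )

    # size: sigmoid on log2 dva, pooled across orientations
    y_sz = sizeori.values.mean(axis=1)
    size = _curve(
        lambda p: p[2] * _sigmoid_log2(sizeori.axis_a, p[0], p[1]) + p[3] - y_sz,
        _sigmoid_starts(sizeori.axis_a, y_sz),
        [1e-3, sizeori.axis_a.min() / 8, -np.inf, -np.inf],
        [100.0, sizeori.axis_a.max() * 8, np.inf, np.inf],
        y_sz, 2, ["m", "sigma0"], n_points=sizeori.values.size,
    )

    # contrast: sigmoid on log2 percent; c = 0 rows use the 0 factor limit
    y_cn = conori.values.mean(axis=1)
    cpos = conori.axis_a[conori.axis_a > 0]
    con = _curve(
        lambda p: p[2] * _sigmoid_log2(conori.axis_a, p[0], p[1]) + p[3] - y_cn,
        _sigmoid_starts(cpos, y_cn),
        [1e-3, cpos.min() / 8, -np.inf, -np.inf],
        [100.0, cpos.max() * 8, np.inf, np.inf],
        y_cn, 2, ["k", "c0"], n_points=conori.values.size,
    )

    shape = None
    if all(c.converged for c in (sf, ori, size, con)):
        shape = GratingShape(
            mu=sf.params["mu"], sigma=sf.params["sigma"],
            alpha=ori.params["alpha"] % 180.0, kappa=ori.params["kappa"],
            m=size.params["m"], sigma0=size.params["sigma0"],
            k=con.params["k"], c0=con.params["c0"],
        )
    return GratingFitResult(shape=shape, sf=sf, ori=ori, size=size, con=con)


def fit_hue_shape(
    hue36: np.ndarray,
    huesize: np.ndarray,
    huesat: TuningMatrix,
    hueval: TuningMatrix,
    hue_values: np.ndarray | None = None,
    size_values: np.ndarray | None = None,
    full_screen_r: float = protocols.FULL_SCREEN_SIZE_DVA,
) -> HueFitResult:
    """Fit the eleven hue shape parameters from the four hue protocols.

    ``hue36`` are the 36 full-screen responses over the hue circle,
    ``huesize`` the red-hue size curve, ``huesat`` a hues x saturations grid
    and ``hueval`` a hues x value-percent grid (axes on the TuningMatrix).
    The hue lobes are fit on the 36 hues plus the max-saturation and
    max-value responses of the six grid hues (48 points); lobe centers start
    at red (0 deg) and cyan (180 deg) and may move at most 80 / 100 deg.
    The value line is fit on the value levels >= 25 % (24 points) with the
    already-fitted hue/saturation/size factors as known multipliers, which
    pins down the absolute scale of (g, o).
    """
    hue_values = protocols.HUE_36 if hue_values is None else np.asarray(hue_values)
    size_values = (
        protocols.HUE_SIZE_VALUES_M1 if size_values is None else np.asarray(size_values)
    )
    hue36 = np.asarray(hue36, dtype=float)
    huesize = np.asarray(huesize, dtype=float)
    if hue36.shape != hue_values.shape:
        raise ValidationError("hue36 and hue_values length mismatch")
    if huesize.shape != size_values.shape:
        raise ValidationError("huesize and size_values length mismatch")
    if huesat.axis_a is None or huesat.axis_b is None:
        raise ValidationError("huesat needs hue (rows) and saturation (cols) axes")
    if hueval.axis_a is None or hueval.axis_b is None:
        raise ValidationError("hueval needs hue (rows) and value-percent (cols) axes")

    # hue lobes: 36 hues + 6 max-saturation + 6 max-value points
    j_smax = int(np.argmax(huesat.axis_b))
    j_vmax = int(np.argmax(hueval.axis_b))
    hx = np.concatenate([hue_values, huesat.axis_a, hueval.axis_a])
    hy = np.concatenate([hue36, huesat.values[:, j_smax], hueval.values[:, j_vmax]])
    hrad = np.deg2rad(hx)

    def hue_resid(p):
        ar, kr, ac, kc, g_c, A, B = p
        lobes = _vonmises_peak1(hrad, np.deg2rad(ar), kr) + g_c * _vonmises_peak1(
            hrad, np.deg2rad(ac), kc
        )
        return A * lobes + B - hy

    A0, B0 = np.ptp(hy) or 1.0, hy.min()
    hue = _curve(
        hue_resid,
        [[0.0, kr0, 180.0, kc0, 0.5, A0, B0]
         for kr0 in (1.0, 4.0) for kc0 in (1.0, 4.0)],
        [-80.0, 0.0, 80.0, 0.0, 0.0, -np.inf, -np.inf],
        [80.0, 100.0, 280.0, 100.0, 10.0, np.inf, np.inf],
        hy, 5, ["alpha_r", "kappa_r", "alpha_c", "kappa_c", "a_c"],
    )

    # size: red-hue size curve (7 points)
    size = _curve(
        lambda p: p[2] * _sigmoid_log2(size_values, p[0], p[1]) + p[3] - huesize,
        _sigmoid_starts(size_values, huesize),
        [1e-3, size_values.min() / 8, -np.inf, -np.inf],
        [100.0, size_values.max() * 8, np.inf, np.inf],
        huesize, 2, ["m", "sigma0"],
    )

    # saturation: hues x saturations grid, pooled across hues
    y_sat = huesat.values.mean(axis=0)
    sx = huesat.axis_b
    sat = _curve(
        lambda p: p[2] * _sigmoid10(p[0] * (sx - p[1])) + p[3] - y_sat,
        [[sl, m0, np.ptp(y_sat) or 1.0, y_sat.min()]
         for sl in (1.0, 4.0, 10.0) for m0 in (0.3, 0.5, 0.8)],
        [1e-3, 0.0, -np.inf, -np.inf],
        [1000.0, 1.0, np.inf, np.inf],
        y_sat, 2, ["l", "s0"], n_points=huesat.values.size,
    )

    # value line on levels >= 25 % (4 values x 6 hues = 24 points), with the
    # fitted hue/size/saturation factors as known multipliers
    keep = hueval.axis_b >= protocols.VAL_MIN_PERCENT
    vgrid = hueval.values[:, keep]
    vlevels = hueval.axis_b[keep]
    n_val = vgrid.size
    val_names = ["g", "o"]
    if hue.converged and size.converged and sat.converged:
        hfac = hue_tuning(
            hueval.axis_a, hue.params["alpha_r"], hue.params["kappa_r"],
            hue.params["alpha_c"], hue.params["kappa_c"], hue.params["a_c"],
        )
        mult = (
            hfac
            * _sigmoid_log2(full_screen_r, size.params["m"], size.params["sigma0"])
            * _sigmoid10(sat.params["l"] * (1.0 - sat.params["s0"]))
        )
        Vn = np.tile(vlevels / 100.0, (len(hueval.axis_a), 1))
        W = np.repeat(mult, len(vlevels)).reshape(vgrid.shape)
        X = np.column_stack([(W * Vn).ravel(), W.ravel()])
        try:
            beta, *_ = np.linalg.lstsq(X, vgrid.ravel(), rcond=None)
            val = CurveFit(
                params={"g": float(beta[0]), "o": float(beta[1])},
                A=1.0, B=0.0, n_points=n_val, converged=True,
            )
        except np.linalg.LinAlgError:
            val = CurveFit(
                params={n: np.nan for n in val_names}, A=np.nan, B=np.nan,
                n_points=n_val, converged=False, message="singular value-line fit",
            )
    else:
        val = CurveFit(
            params={n: np.nan for n in val_names}, A=np.nan, B=np.nan,
            n_points=n_val, converged=False, message="upstream fit failed",
        )

    shape = None
    if all(c.converged for c in (hue, size, sat, val)):
        shape = HueShape(
            alpha_r=hue.params["alpha_r"] % 360.0, kappa_r=hue.params["kappa_r"],
            alpha_c=hue.params["alpha_c"] % 360.0, kappa_c=hue.params["kappa_c"],
            a_c=hue.params["a_c"], m=size.params["m"], sigma0=size.params["sigma0"],
            l=sat.params["l"], s0=sat.params["s0"],
            g=val.params["g"], o=val.params["o"],
        )
    return HueFitResult(shape=shape, hue=hue, size=size, sat=sat, val=val)


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------
@dataclass
class CrossValIteration:
    shape: GratingShape | HueShape | None
    scale_fits: dict
    correlations: dict


@dataclass
class CrossValResult:
    iterations: list
    mean_correlations: dict


def _split_means(resp: np.ndarray, rng: np.random.Generator):
    """Random half-split of the trailing trial axis; returns fold means."""
    n = resp.shape[-1]
    if n < 2:
        raise ValidationError("need >= 2 trials per condition to cross-validate")
    perm = rng.permutation(n)
    half = n // 2
    return resp[..., perm[:half]].mean(axis=-1), resp[..., perm[half:]].mean(axis=-1)


def _scale_and_corr(actual: np.ndarray, predicted: np.ndarray):
    X = np.column_stack([predicted.ravel(), np.ones(predicted.size)])
    beta, *_ = np.linalg.lstsq(X, actual.ravel(), rcond=None)
    r = float(pearsonr(predicted.ravel(), actual.ravel()).statistic)
    return ScaleFit(G=float(beta[0]), O=float(beta[1])), r


def cross_validate_grating(
    sfori_trials: np.ndarray,
    sizeori_trials: np.ndarray,
    conori_trials: np.ndarray,
    sf_values: np.ndarray = protocols.SF_VALUES,
    ori_values: np.ndarray = protocols.ORI_8,
    size_values: np.ndarray = protocols.SIZE_VALUES,
    con_values: np.ndarray = protocols.CON_VALUES_M1,
    con_ori_values: np.ndarray = protocols.ORI_4,
    sizeori_f: float = 4.0,
    n_iter: int = 3,
    seed: int | None = None,
) -> CrossValResult:
    """Two-fold cross-validation of the grating product model.

    Inputs are per-trial band-ratio arrays of shape (rows, cols, trials).
    Per iteration, trials are randomly halved per condition; shape
    parameters are fit on fold-1 averages, the product model is evaluated
    on the stimulus grids, and gain/offset plus the Pearson correlation are
    computed against fold-2 averages.  Correlations are averaged over
    iterations.
    """
    rng = np.random.default_rng(seed)
    iters: list[CrossValIteration] = []
    for _ in range(n_iter):
        folds = {
            "sfori": _split_means(np.asarray(sfori_trials, float), rng),
            "sizeori": _split_means(np.asarray(sizeori_trials, float), rng),
            "conori": _split_means(np.asarray(conori_trials, float), rng),
        }
        fit = fit_grating_shape(
            TuningMatrix(folds["sfori"][0], axis_a=sf_values, axis_b=ori_values),
            TuningMatrix(folds["sizeori"][0], axis_a=size_values, axis_b=ori_values),
            TuningMatrix(folds["conori"][0], axis_a=con_values, axis_b=con_ori_values),
        )
        if fit.shape is None:
            iters.append(CrossValIteration(None, {}, {}))
            continue
        grids = {
            "sfori": grating_grid(
                fit.shape, ("f", sf_values), ("theta", ori_values),
                r=protocols.FULL_SCREEN_SIZE_DVA, c=protocols.FULL_CONTRAST,
            ),
            "sizeori": grating_grid(
                fit.shape, ("r", size_values), ("theta", ori_values),
                f=sizeori_f, c=protocols.FULL_CONTRAST,
            ),
            "conori": grating_grid(
                fit.shape, ("c", con_values), ("theta", con_ori_values),
                f=sizeori_f, r=protocols.FULL_SCREEN_SIZE_DVA,
            ),
        }
        scales, corrs = {}, {}
        for key, (_, test_mean) in folds.items():
            scales[key], corrs[key] = _scale_and_corr(test_mean, grids[key].values)
        iters.append(CrossValIteration(fit.shape, scales, corrs))
    mean_corr = {
        k: float(np.mean([it.correlations[k] for it in iters if it.correlations]))
        for k in ("sfori", "sizeori", "conori")
    }
    return CrossValResult(iterations=iters, mean_correlations=mean_corr)


def cross_validate_hue(
    hue36_trials: np.ndarray,
    huesize_trials: np.ndarray,
    huesat_trials: np.ndarray,
    hueval_trials: np.ndarray,
    hue_values: np.ndarray = protocols.HUE_36,
    size_values: np.ndarray = protocols.HUE_SIZE_VALUES_M1,
    grid_hues: np.ndarray = protocols.HUE_6,
    sat_values: np.ndarray = protocols.SAT_VALUES,
    val_values: np.ndarray = protocols.VAL_VALUES,
    n_iter: int = 3,
    seed: int | None = None,
) -> CrossValResult:
    """Two-fold cross-validation of the hue product model (see
    :func:`cross_validate_grating`)."""
    rng = np.random.default_rng(seed)
    fs_r = protocols.FULL_SCREEN_SIZE_DVA
    iters: list[CrossValIteration] = []
    for _ in range(n_iter):
        folds = {
            "hue": _split_means(np.asarray(hue36_trials, float), rng),
            "huesize": _split_means(np.asarray(huesize_trials, float), rng),
            "huesat": _split_means(np.asarray(huesat_trials, float), rng),
            "hueval": _split_means(np.asarray(hueval_trials, float), rng),
        }
        fit = fit_hue_shape(
            folds["hue"][0], folds["huesize"][0],
            TuningMatrix(folds["huesat"][0], axis_a=grid_hues, axis_b=sat_values),
            TuningMatrix(folds["hueval"][0], axis_a=grid_hues, axis_b=val_values),
            hue_values=hue_values, size_values=size_values,
        )
        if fit.shape is None:
            iters.append(CrossValIteration(None, {}, {}))
            continue
        sh = fit.shape
        preds = {
            "hue": np.array(
                [hue_product(HuePatchStimulus(h, 1.0, 100.0, fs_r), sh)
                 for h in hue_values]
            ),
            "huesize": np.array(
                [hue_product(HuePatchStimulus(0.0, 1.0, 100.0, r), sh)
                 for r in size_values]
            ),
            "huesat": hue_grid(
                sh, ("H", grid_hues), ("S", sat_values), V=100.0, R=fs_r
            ).values,
            "hueval": hue_grid(
                sh, ("H", grid_hues),
                ("V", np.clip(val_values, protocols.VAL_MIN_PERCENT, None)),
                S=1.0, R=fs_r,
            ).values,
        }
        scales, corrs = {}, {}
        for key, (_, test_mean) in folds.items():
            scales[key], corrs[key] = _scale_and_corr(test_mean, preds[key])
        iters.append(CrossValIteration(fit.shape, scales, corrs))
    mean_corr = {
        k: float(np.mean([it.correlations[k] for it in iters if it.correlations]))
        for k in ("hue", "huesize", "huesat", "hueval")
    }
    return CrossValResult(iterations=iters, mean_correlations=mean_corr)


# --------------------------------------------------------------------------
# pooling and packaged median parameters
# --------------------------------------------------------------------------
def circular_median(angles_deg: Sequence[float], period: float = 360.0) -> float:
    """Median of angles on a circle of the given period.

    Chooses the sample angle minimizing the summed wrapped distance to all
    others; exact ties are resolved by the circular mean of the minimizers.
    """
    a = np.asarray(angles_deg, dtype=float) % period
    if a.size == 0:
        raise ValidationError("need at least one angle")
    d = np.abs(a[:, None] - a[None, :])
    d = np.minimum(d, period - d)
    cost = d.sum(axis=1)
    winners = a[np.isclose(cost, cost.min())]
    if winners.size == 1:
        return float(winners[0])
    scale_ = 2 * np.pi / period
    z = np.exp(1j * winners * scale_).mean()
    return float((np.angle(z) / scale_) % period)


def median_pool(shapes: Sequence[GratingShape] | Sequence[HueShape]):
    """Elementwise median of shape parameters across electrodes, with
    circular medians for orientation/hue centers."""
    if len(shapes) == 0:
        raise ValidationError("median_pool needs at least one shape")
    cls = type(shapes[0])
    circular = {"alpha": 180.0, "alpha_r": 360.0, "alpha_c": 360.0}
    pooled = {}
    for f in fields(cls):
        vals = [getattr(s, f.name) for s in shapes]
        if f.name in circular:
            pooled[f.name] = circular_median(vals, circular[f.name])
        else:
            pooled[f.name] = float(np.median(vals))
    return cls(**pooled)


def load_median_shapes(subject: str = "M1") -> tuple[GratingShape, HueShape]:
    """Packaged median tuning parameters for the two macaque subjects.

    Hue lobe centers are stored in radians in the table and converted to
    degrees here.
    """
    path = resources.files("gammapatch.data") / "median_tuning_params.csv"
    df = pd.read_csv(path).set_index("parameter")[subject]
    grating = GratingShape(
        mu=df["sf_center_mu"], sigma=df["sf_spread_sigma"],
        alpha=df["ori_center_alpha"], kappa=df["ori_spread_kappa"],
        m=df["size_slope_m"], sigma0=df["size_midpoint_sigma0"],
        k=df["con_slope_k"], c0=df["con_midpoint_c0"],
    )
    hue = HueShape(
        alpha_r=np.rad2deg(df["hue_center_r_rad"]) % 360.0,
        kappa_r=df["hue_spread_r_kappa"],
        alpha_c=np.rad2deg(df["hue_center_c_rad"]) % 360.0,
        kappa_c=df["hue_spread_c_kappa"],
        a_c=df["hue_gain_ac"],
        m=df["hue_size_slope_m"], sigma0=df["hue_size_midpoint_sigma0"],
        l=df["sat_slope_l"], s0=df["sat_midpoint_s0"],
        g=df["val_slope_g"], o=df["val_intercept_o"],
    )
    return grating, hue
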