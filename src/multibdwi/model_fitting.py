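"""Per-voxel inversion of the three decay models and whole-volume maps.

Fitting operates on the normalized ratio S(b)/S(0) (matching how the models
are written), so the scale of the raw signal never enters the estimates.

* ADC uses the conventional two-point closed form from b = 0 and 1000
  s/mm^2 only (mirroring routine clinical DWI); a log-linear fit over all
  b-values is available via ``FittingConfig(adc_all_b=True)``.
* The biexponential fit is segmented: D and the slow-compartment intercept
  come from a log-linear fit of the high-b points (b >= ``b_split_threshold``,
  default 200 s/mm^2, the first weighting beyond the perfusion-sensitive
  regime); f follows from the intercept; D* from a bounded 1-D search; an
  optional (default on) bounded full nonlinear refinement polishes all
  three. D* >= D is enforced by fitting D* as D plus a non-negative offset.
* The stretched-exponential fit is a bounded nonlinear least squares with
  DDC initialized from the two-point ADC and alpha from 0.8.

The pseudodiffusion axis is the only direction with multiple local minima;
its global grid initialization plus machine-level solver tolerances make
noise-free forward-fit round trips exact to solver precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .signal_models import (
    BiexpParams,
    BValueScheme,
    DecayCurve,
    MonoexpParams,
    StretchedParams,
    predict_biexp,
    predict_mono,
    predict_stretched,
)

__all__ = [
    "FittingConfig",
    "FitResult",
    "ParameterMaps",
    "fit_adc",
    "fit_biexp",
    "fit_stretched",
    "fit_volume",
    "MAP_NAMES",
]

MAP_NAMES = ("adc", "d", "d_star", "f", "ddc", "alpha")

ModelParams = Union[MonoexpParams, BiexpParams, StretchedParams]


@dataclass(frozen=True)
class FittingConfig:
    """Knobs of the fitting layer.

    b_split_threshold : s/mm^2; high-b points (>= threshold) feed the
        segmented D estimate. Must be a value present in the scheme.
    refine : run the full bounded nonlinear refinement after the segmented
        biexponential steps.
    adc_all_b : use all b-values (log-linear LSQ) for ADC instead of the
        two-point b = 0/1000 form.
    biexp_variant : fast-compartment exponent convention, passed through to
        :func:`multibdwi.signal_models.predict_biexp`.
    Bounds are wide enough to hold brain-tissue values with margin.
    """

    b_split_threshold: float = 200.0
    refine: bool = True
    adc_all_b: bool = False
    biexp_variant: str = "dstar-plus-d"
    d_bounds: tuple[float, float] = (1e-6, 5e-3)
    d_star_bounds: tuple[float, float] = (1e-4, 5e-1)
    f_bounds: tuple[float, float] = (0.0, 1.0)
    ddc_bounds: tuple[float, float] = (1e-6, 1e-1)
    alpha_bounds: tuple[float, float] = (0.01, 1.0)
    xtol: float = 1e-15
    ftol: float = 1e-15
    max_iter: int = 400

    def __post_init__(self) -> None:
        for lo, hi in (
            self.d_bounds,
            self.d_star_bounds,
            self.f_bounds,
            self.ddc_bounds,
            self.alpha_bounds,
        ):
            if not lo < hi:
                raise ValueError(f"inconsistent bounds ({lo}, {hi})")

    def validate_scheme(self, scheme: BValueScheme) -> None:
        if self.b_split_threshold not in scheme.values:
            raise ValueError(
                f"b_split_threshold {self.b_split_threshold} not in scheme "
                f"{scheme.values}"
            )


@dataclass(frozen=True)
class FitResult:
    """Outcome of a single-curve fit.

    ``params`` is None when the curve was degenerate (e.g. non-positive
    signal where positive is required); such failures are flagged rather
    than raised so that volume fitting can degrade per voxel.
    """

    params: Optional[ModelParams]
    residual_sse: float
    converged: bool
    n_points: int

    def __post_init__(self) -> None:
        if self.residual_sse < 0:
            raise ValueError("residual_sse must be non-negative")


def _clip(x: float, bounds: tuple[float, float]) -> float:
    return float(min(max(x, bounds[0]), bounds[1]))


# ---------------------------------------------------------------------------
# monoexponential


def fit_adc(curve: DecayCurve, config: FittingConfig | None = None) -> FitResult:
    """Two-point ADC = ln(S(0)/S(1000)) / 1000.

    Requires b = 0 and b = 1000 in the scheme; a flat or rising curve gives
    a non-positive ADC and is flagged (converged=False, params=None). With
    ``config.adc_all_b`` a log-linear least squares over every positive
    signal is used instead.
    """
    config = config or FittingConfig()
    b = curve.b
    s = curve.normalized
    if config.adc_all_b:
        pos = s > 0
        n = int(pos.sum())
        if n < 2:
            return FitResult(None, 0.0, False, n)
        slope, _ = np.polyfit(b[pos], np.log(s[pos]), 1)
        adc = -float(slope)
        if adc <= 0:
            return FitResult(None, 0.0, False, n)
        params = MonoexpParams(adc=adc)
        sse = float(np.sum((predict_mono(params, b) - s) ** 2))
        return FitResult(params, sse, True, n)

    if 1000.0 not in curve.scheme.values:
        raise ValueError("two-point ADC needs b = 1000 s/mm^2 in the scheme")
    s1000 = s[curve.scheme.values.index(1000.0)]
    if s1000 <= 0:
        return FitResult(None, 0.0, False, 2)
    adc = float(np.log(1.0 / s1000) / 1000.0)
    if adc <= 0:
        return FitResult(None, 0.0, False, 2)
    params = MonoexpParams(adc=adc)
    resid = predict_mono(params, np.array([0.0, 1000.0])) - np.array([1.0, s1000])
    return FitResult(params, float(np.sum(resid**2)), True, 2)


# ---------------------------------------------------------------------------
# biexponential (segmented then refined)


def _biexp_model(theta: np.ndarray, b: np.ndarray, variant: str) -> np.ndarray:
    d, delta, f = theta
    d_star = d + delta
    if variant == "dstar-plus-d":
        fast = np.exp(-b * (d_star + d))
    else:
        fast = np.exp(-b * d_star)
    return (1.0 - f) * np.exp(-b * d) + f * fast


def _biexp_jac(theta: np.ndarray, b: np.ndarray, variant: str) -> np.ndarray:
    d, delta, f = theta
    slow = np.exp(-b * d)
    if variant == "dstar-plus-d":
        fast = np.exp(-b * (2 * d + delta))
        dd = -b * (1.0 - f) * slow - 2 * b * f * fast
    else:
        fast = np.exp(-b * (d + delta))
        dd = -b * (1.0 - f) * slow - b * f * fast
    ddelta = -b * f * fast
    df = fast - slow
    return np.column_stack([dd, ddelta, df])


def fit_biexp(curve: DecayCurve, config: FittingConfig | None = None) -> FitResult:
    """Segmented IVIM fit, optionally followed by full nonlinear refinement.

    Steps: (1) log-linear fit of b >= b_split_threshold gives D and the
    slow-compartment intercept; (2) f = 1 - exp(intercept); (3) bounded 1-D
    least squares for D* with D and f fixed, seeded from a global
    log-spaced grid over the pseudodiffusion axis (the only direction with
    multiple local minima); (4) bounded full refinement of (D, D*, f) with
    an analytic Jacobian when ``config.refine`` (default). Degenerate
    curves come back flagged with boundary parameters.
    """
    config = config or FittingConfig()
    config.validate_scheme(curve.scheme)
    b = curve.b
    s = curve.normalized
    if len(b) < 6:
        raise ValueError("biexponential fit needs at least 6 b-values")

    hi_mask = (b >= config.b_split_threshold) & (s > 0)
    if hi_mask.sum() < 2 or np.all(s[1:] >= s[0]):
        # non-decaying / degenerate curve: nothing to estimate
        params = BiexpParams(
            d=config.d_bounds[0] * 2, d_star=config.d_star_bounds[0] * 2, f=0.0
        )
        return FitResult(params, float("nan"), False, len(b))

    slope, intercept = np.polyfit(b[hi_mask], np.log(s[hi_mask]), 1)
    d0 = _clip(-float(slope), config.d_bounds)
    f0 = _clip(1.0 - float(np.exp(intercept)), config.f_bounds)

    # step 3: global grid + local polish for the pseudodiffusion offset
    grid = np.geomspace(1e-5, config.d_star_bounds[1], 48)
    preds = _biexp_model((d0, grid, f0), b[:, None], config.biexp_variant)
    costs = np.sum((preds - s[:, None]) ** 2, axis=0)
    k = int(np.argmin(costs))

    def dstar_cost(delta: float) -> float:
        resid = _biexp_model(np.array([d0, delta, f0]), b, config.biexp_variant) - s
        return float(np.sum(resid**2))

    lo1d = grid[max(k - 1, 0)]
    hi1d = grid[min(k + 1, len(grid) - 1)]
    res1d = minimize_scalar(
        dstar_cost, bounds=(lo1d, hi1d), method="bounded",
        options={"xatol": 1e-8},
    )
    delta0 = float(res1d.x)

    if not config.refine:
        params = BiexpParams(d=d0, d_star=d0 + delta0, f=f0)
        return FitResult(params, dstar_cost(delta0), True, len(b))

    lo = np.array([config.d_bounds[0], 0.0, config.f_bounds[0]])
    hi = np.array([config.d_bounds[1], config.d_star_bounds[1], config.f_bounds[1]])
    x0 = np.clip(np.array([d0, delta0, f0]), lo + 1e-12, hi - 1e-12)
    sol = least_squares(
        lambda th: _biexp_model(th, b, config.biexp_variant) - s,
        x0,
        jac=lambda th: _biexp_jac(th, b, config.biexp_variant),
        bounds=(lo, hi),
        xtol=config.xtol,
        ftol=config.ftol,
        gtol=1e-15,
        max_nfev=config.max_iter,
    )
    d, delta, f = sol.x
    params = BiexpParams(d=float(d), d_star=float(d + delta), f=float(f))
    return FitResult(params, float(2.0 * sol.cost), True, len(b))


# ---------------------------------------------------------------------------
# stretched exponential


def _stretched_model(theta: np.ndarray, b: np.ndarray) -> np.ndarray:
    ddc, alpha = theta
    return np.exp(-((b * ddc) ** alpha))


def _stretched_jac(theta: np.ndarray, b: np.ndarray) -> np.ndarray:
    ddc, alpha = theta
    u = (b * ddc) ** alpha
    m = np.exp(-u)
    pos = b > 0
    dddc = np.zeros_like(b)
    dalpha = np.zeros_like(b)
    dddc[pos] = -m[pos] * alpha * u[pos] / ddc
    dalpha[pos] = -m[pos] * u[pos] * np.log(b[pos] * ddc)
    return np.column_stack([dddc, dalpha])


def fit_stretched(curve: DecayCurve, config: FittingConfig | None = None) -> FitResult:
    """Bounded nonlinear fit of (DDC, alpha) on the normalized signal."""
    config = config or FittingConfig()
    b = curve.b
    s = curve.normalized
    if np.count_nonzero(b > 0) < 4:
        raise ValueError("stretched-exponential fit needs >= 4 nonzero b-values")

    adc_res = fit_adc(curve, config) if 1000.0 in curve.scheme.values else None
    ddc0 = (
        adc_res.params.adc
        if adc_res is not None and adc_res.converged
        else 1e-3
    )
    ddc0 = _clip(ddc0, config.ddc_bounds)

    lo = np.array([config.ddc_bounds[0], config.alpha_bounds[0]])
    hi = np.array([config.ddc_bounds[1], config.alpha_bounds[1]])

    def solve(x0: np.ndarray):
        return least_squares(
            lambda th: _stretched_model(th, b) - s,
            np.clip(x0, lo + 1e-12, hi),
            jac=lambda th: _stretched_jac(th, b),
            bounds=(lo, hi),
            xtol=config.xtol,
            ftol=config.ftol,
            gtol=1e-15,
            max_nfev=config.max_iter,
        )

    best = solve(np.array([ddc0, 0.8]))
    ddc, alpha = best.x
    params = StretchedParams(ddc=float(ddc), alpha=float(alpha))
    return FitResult(params, float(2.0 * best.cost), bool(best.success), len(b))


# ---------------------------------------------------------------------------
# whole volumes


@dataclass
class ParameterMaps:
    """Voxel-wise parameter grids sharing one spatial shape.

    ``maps`` holds 3D float arrays keyed by ``adc, d, d_star, f, ddc,
    alpha`` (mm^2/s or dimensionless); voxels outside the mask, and voxels
    whose fit failed, carry NaN. ``quality`` is the summed residual SSE of
    the three fits (NaN outside the mask, +inf where any fit failed).
    """

    maps: dict[str, np.ndarray]
    quality: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.maps.values()} | {self.quality.shape}
        if len(shapes) != 1:
            raise ValueError("all parameter grids must share one shape")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.quality.shape

    @property
    def in_plane_voxel_area(self) -> float:
        """Axial in-plane voxel area, mm^2."""
        return float(self.voxel_size[0] * self.voxel_size[1])


def fit_volume(
    volume: np.ndarray,
    scheme: BValueScheme,
    mask: np.ndarray,
    config: FittingConfig | None = None,
    affine: np.ndarray | None = None,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> ParameterMaps:
    """Fit all three models at every masked voxel of a 4D volume.

    The 4th axis indexes b-values. Per-voxel failures are recorded in the
    quality grid and leave NaN in the affected parameter maps; they never
    abort the volume. Output is deterministic for identical inputs.
    """
    config = config or FittingConfig()
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if volume.ndim != 4:
        raise ValueError("volume must be 4D (x, y, z, b)")
    if volume.shape[-1] != len(scheme):
        raise ValueError(
            f"4th dimension ({volume.shape[-1]}) must match scheme length "
            f"({len(scheme)})"
        )
    if mask.shape != volume.shape[:3]:
        raise ValueError("mask shape must match spatial shape of volume")

    shape = volume.shape[:3]
    maps = {name: np.full(shape, np.nan) for name in MAP_NAMES}
    quality = np.full(shape, np.nan)

    for idx in zip(*np.nonzero(mask)):
        sig = volume[idx]
        if sig[0] <= 0:
            quality[idx] = np.inf
            continue
        try:
            curve = DecayCurve(scheme=scheme, signal=tuple(sig))
        except ValueError:
            quality[idx] = np.inf
            continue
        total_sse = 0.0
        ok = True
        res = fit_adc(curve, config)
        if res.converged and res.params is not None:
            maps["adc"][idx] = res.params.adc
            total_sse += res.residual_sse
        else:
            ok = False
        res = fit_biexp(curve, config)
        if res.converged and res.params is not None:
            maps["d"][idx] = res.params.d
            maps["d_star"][idx] = res.params.d_star
            maps["f"][idx] = res.params.f
            total_sse += res.residual_sse
        else:
            ok = False
        res = fit_stretched(curve, config)
        if res.converged and res.params is not None:
            maps["ddc"][idx] = res.params.ddc
            maps["alpha"][idx] = res.params.alpha
            total_sse += res.residual_sse
        else:
            ok = False
        quality[idx] = total_sse if ok else np.inf

    return ParameterMaps(
        maps=maps,
        quality=quality,
        affine=np.eye(4) if affine is None else np.asarray(affine, dtype=float),
        voxel_size=tuple(float(v) for v in voxel_size),
    )
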