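"""Forward models for multi-b-value diffusion-weighted signal decay.

Three models of the normalized signal ratio S(b)/S(0) as a function of the
diffusion weighting b (s/mm^2):

* monoexponential:        exp(-b * ADC)
* biexponential (IVIM):   (1 - f) exp(-b D) + f exp(-b (D* + D))
* stretched exponential:  exp(-(b * DDC)^alpha)

All diffusion coefficients are carried internally in mm^2/s (typical brain
tissue values are ~1e-3 mm^2/s); reporting layers rescale by 1e3 where table
output in "x 10^-3" units is wanted.

The biexponential fast-compartment exponent is (D* + D) by default; the more
common convention with exponent D* alone is available through the
``variant`` switch of :func:`predict_biexp` (the difference is absorbed into
the D* estimate, since D* >> D).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_B_VALUES",
    "BValueScheme",
    "DecayCurve",
    "MonoexpParams",
    "BiexpParams",
    "StretchedParams",
    "predict_mono",
    "predict_biexp",
    "predict_stretched",
]

#: 12-point acquisition grid used throughout (s/mm^2).
DEFAULT_B_VALUES: tuple[float, ...] = (
    0, 10, 20, 40, 60, 70, 80, 100, 200, 400, 800, 1000,
)


@dataclass(frozen=True)
class BValueScheme:
    """Ordered set of diffusion weightings, s/mm^2.

    Values must be non-negative, strictly increasing, and start at b = 0
    (the unweighted reference needed to normalize the decay).
    """

    values: tuple[float, ...] = DEFAULT_B_VALUES

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if len(vals) < 2:
            raise ValueError("a b-value scheme needs at least two values")
        if vals[0] != 0.0:
            raise ValueError("first b-value must be 0 (normalization reference)")
        if any(v < 0 for v in vals):
            raise ValueError("b-values must be non-negative")
        if any(b >= a for b, a in zip(vals, vals[1:])):
            raise ValueError("b-values must be strictly increasing")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class DecayCurve:
    """One voxel's (or ROI-mean) signal over a b-value scheme.

    ``signal`` is in arbitrary scanner units; S(0) must be positive so the
    curve can be normalized.
    """

    scheme: BValueScheme
    signal: tuple[float, ...]

    def __post_init__(self) -> None:
        sig = tuple(float(s) for s in self.signal)
        if len(sig) != len(self.scheme):
            raise ValueError(
                f"signal length {len(sig)} != scheme length {len(self.scheme)}"
            )
        if sig[0] <= 0:
            raise ValueError("S(0) must be positive")
        if any(s < 0 for s in sig):
            raise ValueError("signal intensities must be non-negative")
        object.__setattr__(self, "signal", sig)

    @property
    def normalized(self) -> np.ndarray:
        """Signal divided by S(0)."""
        s = np.asarray(self.signal, dtype=float)
        return s / s[0]

    @property
    def b(self) -> np.ndarray:
        return self.scheme.array


@dataclass(frozen=True)
class MonoexpParams:
    """Apparent diffusion coefficient, mm^2/s."""

    adc: float

    def __post_init__(self) -> None:
        if not self.adc > 0:
            raise ValueError(f"adc must be positive, got {self.adc}")


@dataclass(frozen=True)
class BiexpParams:
    """IVIM parameters: true diffusion D, pseudodiffusion D*, perfusion fraction f.

    D and D* are in mm^2/s; f is the dimensionless capillary volume fraction.
    D* >= D is required so the slow and fast compartments stay identifiable
    (pseudodiffusion is physically an order of magnitude faster than tissue
    diffusion).
    """

    d: float
    d_star: float
    f: float

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise ValueError(f"d must be positive, got {self.d}")
        if not self.d_star > 0:
            raise ValueError(f"d_star must be positive, got {self.d_star}")
        if self.d_star < self.d:
            raise ValueError(
                f"d_star ({self.d_star}) must be >= d ({self.d}): the fast "
                "compartment may not decay slower than the tissue compartment"
            )
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"f must lie in [0, 1], got {self.f}")


@dataclass(frozen=True)
class StretchedParams:
    """Stretched-exponential parameters.

    ``ddc`` is the distributed diffusion coefficient (mm^2/s), a weighted
    composite of the continuous ADC distribution inside a voxel. ``alpha``
    in (0, 1] indexes intravoxel heterogeneity: alpha = 1 recovers a single
    monoexponential decay, lower alpha means a broader mix of decay rates.
    """

    ddc: float
    alpha: float

    def __post_init__(self) -> None:
        if not self.ddc > 0:
            raise ValueError(f"ddc must be positive, got {self.ddc}")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")


def _check_b(b) -> np.ndarray:
    arr = np.asarray(b, dtype=float)
    if np.any(arr < 0):
        raise ValueError("b-values must be non-negative")
    return arr


def predict_mono(params: MonoexpParams, b) -> np.ndarray | float:
    """Monoexponential signal ratio S(b)/S(0) = exp(-b * ADC)."""
    arr = _check_b(b)
    out = np.exp(-arr * params.adc)
    return out if arr.ndim else float(out)


def predict_biexp(
    params: BiexpParams, b, variant: str = "dstar-plus-d"
) -> np.ndarray | float:
    """Biexponential (IVIM) signal ratio.

    ``variant="dstar-plus-d"`` (default) uses the fast-compartment exponent
    (D* + D); ``variant="dstar"`` uses D* alone. The two conventions differ
    only by a shift of D* by D.
    """
    arr = _check_b(b)
    if variant == "dstar-plus-d":
        fast = np.exp(-arr * (params.d_star + params.d))
    elif variant == "dstar":
        fast = np.exp(-arr * params.d_star)
    else:
        raise ValueError(f"unknown biexponential variant {variant!r}")
    out = (1.0 - params.f) * np.exp(-arr * params.d) + params.f * fast
    return out if arr.ndim else float(out)


def predict_stretched(params: StretchedParams, b) -> np.ndarray | float:
    """Stretched-exponential signal ratio exp(-(b * DDC)^alpha)."""
    arr = _check_b(b)
    out = np.exp(-((arr * params.ddc) ** params.alpha))
    return out if arr.ndim else float(out)
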