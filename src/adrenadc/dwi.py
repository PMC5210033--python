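"""Diffusion-weighted series containers and voxel-wise ADC fitting.

The signal model is the monoexponential decay

    S(b) = S0 * exp(-b * ADC)

so ``ln S`` is linear in the b-value and the apparent diffusion
coefficient (ADC, mm^2/s) is minus the slope of an ordinary
least-squares fit of ``ln S`` against ``b``. A segmented biexponential
(IVIM-style) variant separates the perfusion-contaminated low-b regime
(b < 100 s/mm^2 by convention) from the diffusion-dominated high-b
regime; with only four b-values a full four-parameter fit is
under-determined, so the segmented form is the only one offered and the
monoexponential fit is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FitFailureError, ValidationError

__all__ = ["DWISeries", "ADCMap", "fit_adc_voxel", "compute_adc_map"]


def _check_b_values(b_values) -> np.ndarray:
    b = np.asarray(b_values, dtype=float)
    if b.ndim != 1 or b.size < 2:
        raise ValidationError("b_values must be a 1-D sequence with >= 2 entries")
    if not np.all(np.diff(b) > 0):
        raise ValidationError("b_values must be strictly increasing")
    if b[0] < 0:
        raise ValidationError("b_values must be non-negative")
    return b


@dataclass
class DWISeries:
    """A 4-D multi-b DWI acquisition on a regular voxel grid.

    ``signal`` is indexed ``(x, y, z, b)``; ``b_values`` (s/mm^2) is
    strictly increasing and matches the last axis; ``voxel_size`` is in mm.
    """

    signal: np.ndarray
    b_values: np.ndarray
    voxel_size: tuple[float, float, float]
    subject_id: str = "unknown"
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.b_values = _check_b_values(self.b_values)
        if self.signal.ndim != 4:
            raise ValidationError("signal must be 4-D, indexed (x, y, z, b)")
        if self.signal.shape[-1] != self.b_values.size:
            raise ValidationError(
                f"signal b axis ({self.signal.shape[-1]}) does not match "
                f"b_values ({self.b_values.size})"
            )
        if not np.all(np.isfinite(self.signal)) or np.any(self.signal < 0):
            raise ValidationError("signal values must be finite and >= 0")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValidationError("voxel_size must be 3 positive reals (mm)")
        self.voxel_size = vs

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    def volume_at(self, b: float) -> np.ndarray:
        """The 3-D signal volume acquired at b-value ``b``."""
        idx = np.flatnonzero(np.isclose(self.b_values, b))
        if idx.size == 0:
            raise ValidationError(f"b = {b} s/mm^2 not in series b_values {self.b_values}")
        return self.signal[..., idx[0]]


@dataclass
class ADCMap:
    """Voxel-wise ADC volume (mm^2/s) plus a mask of successful fits.

    ``adc`` is NaN wherever ``fit_mask`` is False.
    """

    adc: np.ndarray
    voxel_size: tuple[float, float, float]
    fit_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    perfusion_fraction: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.adc = np.asarray(self.adc, dtype=float)
        if self.adc.ndim != 3:
            raise ValidationError("adc must be a 3-D array")
        if self.fit_mask is None:
            self.fit_mask = np.isfinite(self.adc)
        self.fit_mask = np.asarray(self.fit_mask, dtype=bool)
        if self.fit_mask.shape != self.adc.shape:
            raise ValidationError("fit_mask shape must equal adc shape")
        if np.any(self.adc[self.fit_mask] < 0):
            raise ValidationError("adc must be >= 0 wherever the fit succeeded")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.adc.shape


def fit_adc_voxel(signals, b_values) -> float:
    """Fit one voxel's ADC by log-linear ordinary least squares.

    Only strictly positive signals enter the fit (the log of a
    non-positive magnitude is undefined); at least two such points at
    distinct b-values are required. A negative fitted slope magnitude
    (signal rising with b) clamps the returned ADC at 0.

    With exactly two b-values this reduces to the two-point formula
    ``ln(S1/S2) / (b2 - b1)``.

    Raises
    ------
    FitFailureError
        Fewer than two positive signals.
    ValidationError
        b_values not strictly increasing or length mismatch.
    """
    b = _check_b_values(b_values)
    s = np.asarray(signals, dtype=float)
    if s.shape != b.shape:
        raise ValidationError("signals and b_values must have the same length")
    pos = s > 0
    if pos.sum() < 2:
        raise FitFailureError(
            f"need >= 2 positive signals, got {int(pos.sum())} (signals={s.tolist()})"
        )
    if np.ptp(s[pos]) == 0:  # flat signal: slope is exactly zero
        return 0.0
    bb, ls = b[pos], np.log(s[pos])
    slope = np.polyfit(bb, ls, 1)[0]
    return max(-float(slope), 0.0)


def compute_adc_map(
    series: DWISeries,
    b_subset=None,
    model: str = "mono",
    b_split: float = 100.0,
) -> ADCMap:
    """Compute a voxel-wise ADC map from a multi-b series.

    Parameters
    ----------
    series
        The input 4-D acquisition.
    b_subset
        Optional subset of ``series.b_values`` (>= 2 entries) to fit over;
        default uses all b-values.
    model
        ``"mono"`` (default): log-linear OLS over the chosen b-values.
        ``"biexp"``: segmented IVIM-style fit — the diffusion coefficient
        comes from the b >= ``b_split`` points only, and the perfusion
        fraction ``f = 1 - S_int / S(0)`` from the extrapolated high-b
        intercept ``S_int``; stored in ``perfusion_fraction``.
    b_split
        Perfusion/diffusion split point for the biexponential model
        (s/mm^2).

    Voxels with fewer than two positive signals over the fitted b-values
    are excluded from ``fit_mask`` and set to NaN.
    """
    if b_subset is None:
        b_idx = np.arange(series.b_values.size)
    else:
        b_sub = _check_b_values(b_subset)
        b_idx = []
        for bv in b_sub:
            hit = np.flatnonzero(np.isclose(series.b_values, bv))
            if hit.size == 0:
                raise ValidationError(f"b_subset value {bv} not in series b_values")
            b_idx.append(hit[0])
        b_idx = np.asarray(b_idx)
    if b_idx.size < 2:
        raise ValidationError("need >= 2 b-values to fit an ADC")

    if model == "mono":
        adc, ok = _ols_neg_slope(series.signal, series.b_values, b_idx)
        pf = None
    elif model == "biexp":
        hi = b_idx[series.b_values[b_idx] >= b_split]
        if hi.size < 2:
            raise ValidationError(
                f"biexp model needs >= 2 b-values at b >= {b_split} s/mm^2"
            )
        adc, ok = _ols_neg_slope(series.signal, series.b_values, hi)
        # extrapolated high-b intercept vs the measured b=0 signal
        icpt, iok = _ols_intercept(series.signal, series.b_values, hi)
        s0 = series.signal[..., 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            pf = np.where((s0 > 0) & iok, 1.0 - np.exp(icpt) / np.where(s0 > 0, s0, 1.0), np.nan)
        pf = np.clip(pf, 0.0, 1.0, out=pf, where=np.isfinite(pf))
        ok &= iok
    else:
        raise ValidationError(f"unknown model {model!r}; expected 'mono' or 'biexp'")

    adc = np.where(ok, np.clip(adc, 0.0, None), np.nan)
    return ADCMap(
        adc=adc,
        voxel_size=series.voxel_size,
        fit_mask=ok,
        origin=series.origin,
        perfusion_fraction=pf,
    )


def _wols(signal4d: np.ndarray, b_values: np.ndarray, b_idx: np.ndarray):
    """Masked per-voxel OLS of log-signal on b. Returns slope, intercept, ok."""
    s = signal4d[..., b_idx]
    b = b_values[b_idx]
    pos = s > 0
    w = pos.astype(float)
    n = w.sum(-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ls = np.where(pos, np.log(np.where(pos, s, 1.0)), 0.0)
        sw = np.maximum(n, 1.0)
        bbar = (w * b).sum(-1) / sw
        ybar = (w * ls).sum(-1) / sw
        db = b - bbar[..., None]
        sxx = (w * db * db).sum(-1)
        sxy = (w * db * (ls - ybar[..., None])).sum(-1)
        ok = (n >= 2) & (sxx > 0)
        slope = np.where(ok, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
        icpt = ybar - slope * bbar
    return slope, icpt, ok


def _ols_neg_slope(signal4d, b_values, b_idx):
    slope, _, ok = _wols(signal4d, b_values, b_idx)
    return -slope, ok


def _ols_intercept(signal4d, b_values, b_idx):
    _, icpt, ok = _wols(signal4d, b_values, b_idx)
    return icpt, ok
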