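"""ROI-signal conditioning: linear detrend, band-pass filter, nuisance regression.

These are the two numerically defined cleaning steps applied to ROI-level
BOLD series before connectivity is computed: (a) removal of linear drift
together with restriction to the low-frequency band that resting-state
fluctuations occupy (0.01-0.08 Hz by default, at TR = 2 s), and (b)
ordinary-least-squares removal of nuisance covariates (six head-motion
parameters plus global, white-matter and CSF mean signals).

Input is already ROI-level: volume-space steps (slice timing, realignment,
normalisation, smoothing) are out of scope for this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .timeseries import SubjectTimeseries

logger = logging.getLogger(__name__)

__all__ = ["FilterSpec", "detrend", "bandpass", "regress_nuisance", "clean"]


@dataclass(frozen=True)
class FilterSpec:
    """Passband for the band-pass filter, in Hz, at a given TR.

    Defaults follow the resting-state convention: keep 0.01-0.08 Hz.
    The band must sit strictly inside (0, Nyquist) with low < high.
    """

    low_hz: float = 0.01
    high_hz: float = 0.08
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        nyquist = 1.0 / (2.0 * self.tr_seconds)
        if not (0.0 < self.low_hz < self.high_hz < nyquist):
            raise ValueError(
                f"passband [{self.low_hz}, {self.high_hz}] Hz must satisfy "
                f"0 < low < high < Nyquist ({nyquist:g} Hz at TR="
                f"{self.tr_seconds:g} s)"
            )

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)


def _as_array(ts) -> tuple[np.ndarray, SubjectTimeseries | None]:
    if isinstance(ts, SubjectTimeseries):
        return ts.data, ts
    return np.asarray(ts, dtype=float), None


def _wrap(out: np.ndarray, template: SubjectTimeseries | None):
    return template.with_data(out) if template is not None else out


def detrend(ts):
    """Remove the per-column least-squares linear trend (and mean).

    Accepts a :class:`SubjectTimeseries` or a plain T x M array and returns
    the same kind.  Idempotent up to floating-point error.
    """
    data, template = _as_array(ts)
    if data.shape[0] < 3:
        raise ValueError("need at least 3 time points to detrend")
    out = sps.detrend(data, axis=0, type="linear")
    return _wrap(out, template)


def bandpass(ts, spec: FilterSpec = FilterSpec(), method: str = "fft"):
    """Restrict each column to the [low_hz, high_hz] band.

    ``method="fft"`` (default) zeroes DFT bins outside the band — the sharp
    ideal filter conventional in resting-state toolboxes.  ``method="butter"``
    applies a zero-phase 4th-order Butterworth as a windowed alternative.
    Output length equals input length; no NaN/Inf is ever introduced.
    """
    data, template = _as_array(ts)
    t = data.shape[0]
    if t < 20:
        raise ValueError("need at least 20 time points to band-pass filter")

    if method == "fft":
        freqs = np.fft.rfftfreq(t, d=spec.tr_seconds)
        spectrum = np.fft.rfft(data, axis=0)
        keep = (freqs >= spec.low_hz) & (freqs <= spec.high_hz)
        spectrum[~keep, :] = 0.0
        out = np.fft.irfft(spectrum, n=t, axis=0)
    elif method == "butter":
        nyq = spec.nyquist_hz
        sos = sps.butter(4, [spec.low_hz / nyq, spec.high_hz / nyq],
                         btype="bandpass", output="sos")
        out = sps.sosfiltfilt(sos, data, axis=0)
    else:
        raise ValueError(f"unknown band-pass method: {method!r}")
    return _wrap(out, template)


def regress_nuisance(ts: SubjectTimeseries, nuisance: np.ndarray | None = None):
    """Replace each node series by its OLS residual on the nuisance design.

    The design is an intercept plus every nuisance column (motion, global,
    WM, CSF ...).  Residuals are exactly orthogonal to each covariate.
    Linearly dependent covariate columns are dropped with a warning rather
    than failing.
    """
    data, template = _as_array(ts)
    if nuisance is None:
        if template is None or template.nuisance is None:
            raise ValueError("no nuisance matrix supplied")
        nuisance = template.nuisance
    nuisance = np.asarray(nuisance, dtype=float)
    if nuisance.ndim != 2 or nuisance.shape[0] != data.shape[0]:
        raise ValueError("nuisance must be T x K with T matching the data")
    if nuisance.shape[1] < 1:
        raise ValueError("nuisance design needs at least one column")
    if not np.any(nuisance):
        raise ValueError("nuisance design is identically zero")

    design = np.column_stack([np.ones(data.shape[0]), nuisance])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # Greedily keep a maximal independent subset of covariate columns.
        kept = [0]
        for j in range(1, design.shape[1]):
            trial = design[:, kept + [j]]
            if np.linalg.matrix_rank(trial) > len(kept):
                kept.append(j)
        dropped = sorted(set(range(design.shape[1])) - set(kept))
        logger.warning("rank-deficient nuisance design; dropped columns %s",
                       [j - 1 for j in dropped])
        design = design[:, kept]

    beta, *_ = np.linalg.lstsq(design, data, rcond=None)
    out = data - design @ beta
    return _wrap(out, template)


def clean(ts: SubjectTimeseries, spec: FilterSpec = FilterSpec(),
          method: str = "fft") -> SubjectTimeseries:
    """Full conditioning chain: detrend, band-pass, then nuisance regression.

    Detrending precedes filtering to avoid drift leaking through the sharp
    ideal filter; nuisance regression runs last, mirroring the usual
    step ordering of resting-state pipelines.
    """
    out = detrend(ts)
    out = bandpass(out, spec, method=method)
    if ts.nuisance is not None:
        # Filter the covariates identically so the regression matches bands.
        nuis = bandpass(detrend(ts.nuisance), spec, method=method)
        out = regress_nuisance(out, nuis)
    return out
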