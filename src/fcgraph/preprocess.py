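"""Temporal cleaning of ROI BOLD time series.

The fixed pipeline order is: nuisance regression -> linear detrend ->
band-pass filter (0.01-0.08 Hz, zero phase) -> motion scrubbing.  Framewise
displacement (FD) follows the Power convention: the sum of absolute
backward differences of the three translations (mm) plus the three
rotations (radians) converted to arc length on a 50 mm sphere.  Volumes
with FD above 0.5 mm are censored together with one preceding and two
subsequent volumes, and a subject/visit is excluded when less than five
minutes of data survive censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

#: Rotation-to-displacement conversion radius, mm (head modelled as a sphere).
FD_ROTATION_RADIUS_MM = 50.0
#: Censoring threshold on framewise displacement, mm.
DEFAULT_FD_THRESHOLD_MM = 0.5
#: Minimum retained acquisition time, seconds (correlations stabilize ~5 min).
DEFAULT_MIN_SECONDS = 300.0
#: Band-pass edges, Hz.
BANDPASS_HZ = (0.01, 0.08)
#: Volumes discarded at acquisition start for magnetization to stabilize.
DEFAULT_N_DISCARD_LEAD = 10

PIPELINE_ORDER = ("nuisance_regression", "detrend", "bandpass", "scrub")


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class RoiTimeSeries:
    """T x N BOLD matrix with acquisition metadata."""

    data: np.ndarray = field(repr=False)
    tr: float
    subject_id: str = ""
    visit_id: str = ""
    n_discarded_lead: int = 0

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[0] < 2:
            raise PreprocessError(f"time series must be T x N with T >= 2, got shape {data.shape}")
        if not np.isfinite(data).all():
            raise PreprocessError("time series contains non-finite values")
        if not self.tr > 0:
            raise PreprocessError(f"tr must be positive, got {self.tr}")
        object.__setattr__(self, "data", data)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class MotionParams:
    """T x 6 rigid-body trace: translations x/y/z in mm, rotations in radians."""

    params: np.ndarray = field(repr=False)

    def __post_init__(self):
        p = np.asarray(self.params, dtype=float)
        if p.ndim != 2 or p.shape[1] != 6:
            raise PreprocessError(f"motion parameters must be T x 6, got shape {p.shape}")
        if not np.isfinite(p).all():
            raise PreprocessError("motion parameters contain non-finite values")
        object.__setattr__(self, "params", p)

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]


@dataclass(frozen=True)
class FDTrace:
    """Per-volume framewise displacement in mm; fd[0] = 0 by convention."""

    fd: np.ndarray = field(repr=False)

    @property
    def mean_fd(self) -> float:
        return float(np.mean(self.fd))


@dataclass(frozen=True)
class CensorMask:
    """Boolean keep-vector over volumes plus the retained duration."""

    keep: np.ndarray = field(repr=False)
    tr: float

    @property
    def n_kept(self) -> int:
        return int(np.count_nonzero(self.keep))

    @property
    def retained_seconds(self) -> float:
        return self.n_kept * self.tr


@dataclass(frozen=True)
class NuisanceSet:
    """T x K nuisance regressors: 6 motion parameters plus white-matter, CSF
    and whole-brain signal time-courses in the canonical K=9 configuration."""

    regressors: np.ndarray = field(repr=False)

    def __post_init__(self):
        r = np.asarray(self.regressors, dtype=float)
        if r.ndim != 2 or r.shape[1] < 1:
            raise PreprocessError(f"nuisance set must be T x K with K >= 1, got shape {r.shape}")
        dead = np.flatnonzero(np.all(r == 0, axis=0))
        if len(dead):
            raise PreprocessError(f"nuisance columns {dead.tolist()} are constant zero")
        object.__setattr__(self, "regressors", r)


def compute_fd(motion: MotionParams) -> FDTrace:
    """Framewise displacement: sum of |Δtranslation| + 50 mm * sum of |Δrotation|."""
    p = motion.params
    if p.shape[0] < 2:
        raise PreprocessError("need at least 2 volumes to compute framewise displacement")
    d = np.abs(np.diff(p, axis=0))
    fd = d[:, :3].sum(axis=1) + FD_ROTATION_RADIUS_MM * d[:, 3:].sum(axis=1)
    return FDTrace(fd=np.concatenate([[0.0], fd]))


def scrub_mask(fd: FDTrace, tr: float, threshold_mm: float = DEFAULT_FD_THRESHOLD_MM) -> CensorMask:
    """Censor every volume with FD above threshold plus 1 preceding and 2
    subsequent volumes; windows are clipped at the series boundaries and
    overlapping windows union."""
    values = np.asarray(fd.fd, dtype=float)
    T = len(values)
    keep = np.ones(T, dtype=bool)
    for t in np.flatnonzero(values > threshold_mm):
        keep[max(t - 1, 0): min(t + 3, T)] = False
    return CensorMask(keep=keep, tr=tr)


def passes_duration_gate(mask: CensorMask, min_seconds: float = DEFAULT_MIN_SECONDS) -> bool:
    """True iff the retained acquisition time reaches the minimum duration."""
    return mask.retained_seconds >= min_seconds


def regress_nuisance(ts: RoiTimeSeries, nuis: NuisanceSet) -> RoiTimeSeries:
    """Replace every node series by its OLS residual on [intercept | nuisance]."""
    X = np.column_stack([np.ones(ts.n_volumes), nuis.regressors])
    if X.shape[0] != nuis.regressors.shape[0] or nuis.regressors.shape[0] != ts.n_volumes:
        raise PreprocessError(
            f"nuisance rows ({nuis.regressors.shape[0]}) do not match time series volumes ({ts.n_volumes})"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        collinear = [
            j - 1
            for j in range(1, X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise PreprocessError(f"nuisance design is rank-deficient; collinear columns: {collinear}")
    beta, *_ = np.linalg.lstsq(X, ts.data, rcond=None)
    return replace(ts, data=ts.data - X @ beta)


def detrend_and_bandpass(ts: RoiTimeSeries, band_hz: tuple[float, float] = BANDPASS_HZ) -> RoiTimeSeries:
    """Remove each node's best-fit line, then apply a zero-phase band-pass.

    Realization: second-order Butterworth applied forward-backward
    (``filtfilt``), so the effective amplitude response is the squared
    magnitude of the analog prototype and the phase is exactly zero.
    """
    low, high = band_hz
    nyquist = 0.5 / ts.tr
    if high >= nyquist:
        raise PreprocessError(
            f"band edge {high} Hz is not below the Nyquist frequency {nyquist:.4f} Hz for tr={ts.tr}"
        )
    detrended = signal.detrend(ts.data, axis=0, type="linear")
    sos = signal.butter(2, [low, high], btype="bandpass", fs=1.0 / ts.tr, output="sos")
    # mirror-extend by the full series length: the 0.01 Hz edge has a long
    # impulse response and the default padding leaves visible transients
    filtered = signal.sosfiltfilt(sos, detrended, axis=0, padtype="even", padlen=ts.n_volumes - 1)
    return replace(ts, data=filtered)


def apply_censor(ts: RoiTimeSeries, mask: CensorMask) -> RoiTimeSeries:
    """Drop censored volumes, concatenating kept volumes in original order."""
    if len(mask.keep) != ts.n_volumes:
        raise PreprocessError(f"mask length {len(mask.keep)} does not match T={ts.n_volumes}")
    if mask.n_kept == 0:
        raise PreprocessError("all volumes censored")
    return replace(ts, data=ts.data[mask.keep])


def preprocess_timeseries(
    ts: RoiTimeSeries,
    motion: MotionParams,
    nuis: NuisanceSet,
    fd_threshold_mm: float = DEFAULT_FD_THRESHOLD_MM,
    min_seconds: float = DEFAULT_MIN_SECONDS,
) -> tuple[RoiTimeSeries, FDTrace, CensorMask, bool]:
    """Run the full temporal pipeline in its fixed order.

    Returns the cleaned, censored series together with the FD trace, the
    censor mask and the duration-gate verdict.  Mean FD (the head-motion
    covariate) is summarized on the pre-scrub trace.
    """
    if motion.n_volumes != ts.n_volumes:
        raise PreprocessError(
            f"motion trace has {motion.n_volumes} volumes, time series has {ts.n_volumes}"
        )
    fd = compute_fd(motion)
    cleaned = regress_nuisance(ts, nuis)
    cleaned = detrend_and_bandpass(cleaned)
    mask = scrub_mask(fd, tr=ts.tr, threshold_mm=fd_threshold_mm)
    ok = passes_duration_gate(mask, min_seconds=min_seconds)
    censored = apply_censor(cleaned, mask)
    return censored, fd, mask, ok
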