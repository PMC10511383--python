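"""Preprocessing of raw cyclic rheometer recordings.

Cyclic compression/tension and torsion recordings show considerable
hysteresis; the hyperelastic (equilibrium) response used for fitting is
approximated by averaging the loading and unloading branches of one cycle.
The pipeline per recording is

    moving average -> zero-phase low-pass -> unit conversion
    -> cycle segmentation at driver extrema
    -> resampling of both branches onto a common abscissa grid
    -> branch averaging,

reduced to 60 points per loading mode.  Axial data are expressed as nominal
stress P = f_z / A over stretch lambda = (H + dz)/H; torsion data as
apparent shear stress tau = 2 t / (pi r^3) over the outer-radius amount of
shear gamma = r theta / H.  Because tau is odd in gamma, the symmetric
+/- gamma sweeps are folded onto a [0, gamma_max] grid, which also cancels
odd-order drift.

The first or the third cycle is selected to represent the unconditioned or
the preconditioned response, respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, sosfiltfilt

from .fe import SpecimenGeometry

__all__ = [
    "MODES",
    "N_POINTS",
    "MalformedRecordingError",
    "RawRecording",
    "ProcessedCurve",
    "SpecimenRecord",
    "segment_cycles",
    "extract_hyperelastic_response",
    "read_raw_csv",
    "write_raw_csv",
    "read_processed_csv",
    "write_processed_csv",
]

#: loading modes of the protocol rows used for hyperelastic fitting
MODES = ("compression_tension", "shear_015", "shear_030")

#: points per mode after resampling; with one axial and two torsion modes the
#: 180-point residual implicitly weighs shear 2:1 against compression/tension
N_POINTS = 60

#: fraction of the driver span a branch must cover to count as a full branch
_FULL_BRANCH_FRACTION = 0.9

#: maximum tolerated grid coverage gap before refusing to extrapolate
_COVERAGE_GAP = 0.10


class MalformedRecordingError(ValueError):
    """Recording does not contain the expected cyclic structure."""


@dataclass
class RawRecording:
    """One mode's raw cyclic recording.

    ``driver`` is the axial displacement dz (m) or end rotation theta (rad);
    ``response`` the force f_z (N) or torque t (N m).
    """

    mode: str
    time: np.ndarray
    driver: np.ndarray
    response: np.ndarray
    n_cycles: int = 3
    specimen_id: str = ""

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        t = np.asarray(self.time, float)
        if t.size < 8 or np.any(np.diff(t) <= 0.0):
            raise MalformedRecordingError("time must be strictly increasing")
        self.time = t
        self.driver = np.asarray(self.driver, float)
        self.response = np.asarray(self.response, float)
        if not (self.time.size == self.driver.size == self.response.size):
            raise MalformedRecordingError("time/driver/response lengths differ")


@dataclass
class ProcessedCurve:
    """One mode's 60-point hyperelastic response curve.

    ``abscissa`` is stretch lambda (axial, spanning compression lambda < 1
    and tension lambda > 1) or amount of shear gamma in [0, gamma_max];
    ``ordinate`` the corresponding stress in Pa.
    """

    mode: str
    abscissa: np.ndarray
    ordinate: np.ndarray
    cycle_used: int

    def __post_init__(self) -> None:
        self.abscissa = np.asarray(self.abscissa, float)
        self.ordinate = np.asarray(self.ordinate, float)
        if self.abscissa.shape != self.ordinate.shape:
            raise ValueError("abscissa/ordinate shape mismatch")


@dataclass
class SpecimenRecord:
    """Everything known about one tested specimen."""

    specimen_id: str
    brain_id: int
    anatomical_region: str
    geometry: SpecimenGeometry
    raw: dict[str, RawRecording] = field(default_factory=dict)
    curves: dict[tuple[str, int], ProcessedCurve] = field(default_factory=dict)
    fits: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CycleBranches:
    """Index ranges of one cycle's monotone loading/unloading branches."""

    cycle: int
    loading: slice
    unloading: slice


def _extrema_indices(driver: np.ndarray) -> np.ndarray:
    """Indices of the driver's turning points (plus both endpoints)."""
    n = driver.size
    win = max(3, int(round(0.005 * n)) | 1)
    smooth = uniform_filter1d(driver, win, mode="nearest")
    d = np.diff(smooth)
    sign = np.sign(d)
    sign[sign == 0] = 1
    turns = np.flatnonzero(np.diff(sign) != 0) + 1
    # refine each turning point on the raw signal
    refined = []
    for t in turns:
        lo, hi = max(0, t - win), min(n, t + win + 1)
        seg = driver[lo:hi]
        idx = lo + (np.argmax(seg) if d[t - 1] > 0 else np.argmin(seg))
        refined.append(idx)
    idx = np.unique(np.concatenate([[0], refined, [n - 1]]).astype(np.intp))
    return idx


def segment_cycles(rec: RawRecording) -> list[CycleBranches]:
    """Split a cyclic recording into full-range loading/unloading branches.

    Branches are delimited by driver extrema; only branches covering at
    least 90% of the driver span count (partial lead-in/out ramps are
    dropped).  Consecutive full branches are paired into cycles in temporal
    order.  Raises if fewer than ``n_cycles`` pairs are found.
    """
    drv = rec.driver
    idx = _extrema_indices(drv)
    span = drv.max() - drv.min()
    if span <= 0.0:
        raise MalformedRecordingError("driver signal is constant")
    branches = []
    for a, b in zip(idx[:-1], idx[1:]):
        if b - a < 3:
            continue
        seg = drv[a : b + 1]
        if abs(seg[-1] - seg[0]) >= _FULL_BRANCH_FRACTION * span:
            branches.append((slice(a, b + 1), seg[-1] > seg[0]))
    pairs = []
    i = 0
    while i + 1 < len(branches):
        (s1, up1), (s2, up2) = branches[i], branches[i + 1]
        if up1 == up2:  # should not happen for a clean cyclic driver
            i += 1
            continue
        loading, unloading = (s1, s2) if up1 else (s2, s1)
        pairs.append(
            CycleBranches(cycle=len(pairs) + 1, loading=loading, unloading=unloading)
        )
        i += 2
    if len(pairs) < rec.n_cycles:
        raise MalformedRecordingError(
            f"found {len(pairs)} full cycles, expected {rec.n_cycles} "
            f"(mode {rec.mode})"
        )
    return pairs


# ---------------------------------------------------------------------------
# filtering and extraction
# ---------------------------------------------------------------------------

def _denoise(rec: RawRecording, cycles_hint: int) -> np.ndarray:
    """Centered moving average followed by a zero-phase low-pass filter.

    Both stages run per monotone branch with odd-reflection boundary
    extension, so branch reversals (where the waveform has a corner) are
    never mixed.  Moving-average window: 1% of the branch samples; low-pass
    cutoff: 20x the ramp frequency (1 / mean branch duration), skipped near
    Nyquist.  On clean signals the pipeline is amplitude-preserving to well
    below 1%.
    """
    y = rec.response
    idx = _extrema_indices(rec.driver)
    fs = (rec.time.size - 1) / (rec.time[-1] - rec.time[0])
    durations = [
        rec.time[b] - rec.time[a] for a, b in zip(idx[:-1], idx[1:]) if b - a > 20
    ]
    sos = None
    if durations:
        cutoff = 20.0 / float(np.mean(durations))
        if cutoff < 0.45 * fs:
            sos = butter(4, cutoff, btype="low", fs=fs, output="sos")

    out = y.astype(float).copy()
    for a, b in zip(idx[:-1], idx[1:]):
        n = b - a + 1
        if n < 12:
            continue
        seg = y[a : b + 1]
        win = max(3, int(round(0.01 * n)) | 1)
        padn = min(n - 1, 3 * win + 30)
        padded = np.pad(seg, padn, mode="reflect", reflect_type="odd")
        smooth = uniform_filter1d(padded, win, mode="nearest")
        if sos is not None:
            smooth = sosfiltfilt(sos, smooth, padlen=min(len(smooth) - 1, 3 * padn))
        out[a : b + 1] = smooth[padn : padn + n]
    return out


def _to_stress_units(rec: RawRecording, geom: SpecimenGeometry):
    """Convert (driver, response) to (abscissa, stress): (lambda, P) or (gamma, tau)."""
    if rec.mode == "compression_tension":
        absc = (geom.height + rec.driver) / geom.height
        scale = 1.0 / geom.cross_section
    else:
        absc = geom.radius * rec.driver / geom.height
        scale = 2.0 / (np.pi * geom.radius**3)
    return absc, scale


def _resample_branch(x: np.ndarray, y: np.ndarray, grid: np.ndarray) -> np.ndarray:
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    gap = max(grid[0] - xs[0], 0.0) + max(xs[-1] - grid[-1], 0.0)
    # np.interp would clamp outside the branch range; refuse to extrapolate
    span = grid[-1] - grid[0]
    if xs[0] > grid[0] + _COVERAGE_GAP * span or xs[-1] < grid[-1] - _COVERAGE_GAP * span:
        raise MalformedRecordingError(
            f"branch covers [{xs[0]:.4g}, {xs[-1]:.4g}], "
            f"grid needs [{grid[0]:.4g}, {grid[-1]:.4g}]"
        )
    return np.interp(grid, xs, ys)


def extract_hyperelastic_response(
    rec: RawRecording,
    cycle: int,
    geom: SpecimenGeometry,
    n_points: int = N_POINTS,
    denoise: bool = True,
) -> ProcessedCurve:
    """Average the selected cycle's loading/unloading branches onto a grid.

    For axial recordings the grid is uniform in stretch over the cycle's
    common coverage of [0.85, 1.15]-type sweeps; for torsion the symmetric
    +/- gamma branches are folded onto a uniform [0, gamma_max] grid using
    the oddness of tau in gamma.  The branch mean is the hyperelastic
    estimate.  ``denoise=False`` bypasses the moving-average/low-pass stage
    (useful for clean signals, where the filters would only introduce their
    sub-percent passband bias).
    """
    if cycle not in (1, 3):
        raise ValueError("cycle must be 1 (unconditioned) or 3 (preconditioned)")
    pairs = segment_cycles(rec)
    if cycle > len(pairs):
        raise MalformedRecordingError(f"cycle {cycle} not present")
    branches = pairs[cycle - 1]

    y = _denoise(rec, rec.n_cycles) if denoise else rec.response
    absc, scale = _to_stress_units(rec, geom)
    stress = y * scale

    sl_load, sl_unload = branches.loading, branches.unloading
    if rec.mode == "compression_tension":
        lo = max(absc[sl_load].min(), absc[sl_unload].min())
        hi = min(absc[sl_load].max(), absc[sl_unload].max())
        grid = np.linspace(lo, hi, n_points)
        y_load = _resample_branch(absc[sl_load], stress[sl_load], grid)
        y_unload = _resample_branch(absc[sl_unload], stress[sl_unload], grid)
    else:
        gmax = min(
            np.abs(absc[sl_load]).max(), np.abs(absc[sl_unload]).max()
        )
        grid = np.linspace(0.0, gmax, n_points)
        y_load = _fold_odd(absc[sl_load], stress[sl_load], grid)
        y_unload = _fold_odd(absc[sl_unload], stress[sl_unload], grid)
    ordinate = 0.5 * (y_load + y_unload)
    return ProcessedCurve(
        mode=rec.mode, abscissa=grid, ordinate=ordinate, cycle_used=cycle
    )


def _fold_odd(x: np.ndarray, y: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Fold a symmetric +/- sweep onto non-negative abscissae via oddness."""
    pos = _resample_branch(x, y, grid)
    neg = _resample_branch(x, y, -grid)
    return 0.5 * (pos - neg)


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def write_raw_csv(recs: list[RawRecording], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "time_s": r.time,
                "driver": r.driver,
                "response": r.response,
                "mode": r.mode,
                "specimen_id": r.specimen_id,
            }
        )
        for r in recs
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_raw_csv(path) -> list[RawRecording]:
    """Read raw recordings (columns time_s, driver, response, mode, specimen_id)."""
    df = pd.read_csv(path)
    out = []
    for (sid, mode), g in df.groupby(["specimen_id", "mode"], sort=False):
        out.append(
            RawRecording(
                mode=mode,
                time=g["time_s"].to_numpy(),
                driver=g["driver"].to_numpy(),
                response=g["response"].to_numpy(),
                specimen_id=str(sid),
            )
        )
    return out


def write_processed_csv(curves: list[ProcessedCurve], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "mode": c.mode,
                "abscissa": c.abscissa,
                "ordinate_Pa": c.ordinate,
                "cycle_used": c.cycle_used,
            }
        )
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_processed_csv(path) -> list[ProcessedCurve]:
    """Read already-averaged hyperelastic curves, bypassing raw preprocessing.

    Layout: one CSV per specimen with columns mode, abscissa, ordinate_Pa,
    cycle_used - the same shape this module writes.
    """
    df = pd.read_csv(Path(path))
    out = []
    for (mode, cyc), g in df.groupby(["mode", "cycle_used"], sort=False):
        out.append(
            ProcessedCurve(
                mode=mode,
                abscissa=g["abscissa"].to_numpy(),
                ordinate=g["ordinate_Pa"].to_numpy(),
                cycle_used=int(cyc),
            )
        )
    return out
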