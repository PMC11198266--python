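"""Time-varying elastance model for noninvasive LV pressure estimation.

The left ventricle is modelled as a time-varying elastance

    E(t) = P(t) / (V(t) - V0),

whose *normalized* shape is approximately load- and contractility-independent
across subjects.  Given a single-beat LV volume curve ``V(t)`` (e.g. from
short-axis cine CMR contours) and a brachial blood-pressure reading, the LV
pressure curve is synthesized in three steps:

1. a normalized elastance waveform ``E_N(u)`` on dimensionless time
   ``u in [0, 1]`` is stretched linearly in time so that the *middle of its
   downslope* coincides with the end-systolic (minimum-volume) frame;
2. the waveform is scaled in amplitude with an affine map
   ``E(t) = a * E_N(t) + b`` so that the resulting pressure curve attains the
   peak systolic LV pressure (approximated from the brachial cuff reading)
   and the prescribed end-diastolic pressure (EDP, default 7 mmHg);
3. ``P(t) = E(t) * (V(t) - V0)`` with the unloaded volume ``V0`` set to 0 mL
   by default.

The default normalized waveform is a double-Hill curve (an activation Hill
term times a relaxation Hill term), a standard smooth single-peaked
parameterisation; any digitized waveform may be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VolumeTimeSeries",
    "BrachialPressure",
    "NormalizedElastanceCurve",
    "ScaledElastanceResult",
    "double_hill_elastance",
    "elastance_from_samples",
    "estimate_peak_lv_pressure",
    "align_elastance_to_cycle",
    "scale_elastance_amplitude",
    "solve_amplitude_scaling",
    "compute_pressure_curve",
    "InvalidParameterError",
    "DegenerateCycleError",
    "ScalingError",
    "ConvergenceError",
    "ShapeError",
]


class InvalidParameterError(ValueError):
    """A physical parameter is outside its admissible range."""


class DegenerateCycleError(ValueError):
    """The volume curve does not describe a usable cardiac cycle."""


class ScalingError(RuntimeError):
    """No amplitude scaling satisfies both pressure constraints."""


class ConvergenceError(RuntimeError):
    """The amplitude-scaling fixed point did not converge."""


class ShapeError(ValueError):
    """Elastance shape parameters produce an inadmissible waveform."""


MIN_FRAMES = 20


@dataclass(frozen=True)
class VolumeTimeSeries:
    """One cardiac cycle of LV volume samples.

    Parameters
    ----------
    times : array of float
        Sample times in seconds, strictly increasing, starting at 0.
    volumes : array of float
        LV cavity volumes in mL, all positive.
    heart_rate : float
        Heart rate in beats per minute; the cycle duration must agree with
        ``60 / heart_rate`` to within 5%.
    """

    times: np.ndarray
    volumes: np.ndarray
    heart_rate: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.volumes, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "volumes", v)
        if t.ndim != 1 or v.ndim != 1 or len(t) != len(v):
            raise InvalidParameterError("times and volumes must be 1-D and equal length")
        if len(t) < MIN_FRAMES:
            raise InvalidParameterError(
                f"at least {MIN_FRAMES} frames required, got {len(t)}"
            )
        if t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise InvalidParameterError("times must start at 0 and be strictly increasing")
        if np.any(v <= 0):
            raise InvalidParameterError("all volumes must be positive")
        if not np.isfinite(self.heart_rate) or self.heart_rate <= 0:
            raise InvalidParameterError("heart_rate must be positive")
        expected = 60.0 / self.heart_rate
        if abs(self.duration - expected) > 0.05 * expected:
            raise InvalidParameterError(
                f"cycle duration {self.duration:.3f} s inconsistent with "
                f"heart rate {self.heart_rate} bpm (expected ~{expected:.3f} s)"
            )

    @property
    def frame_count(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def es_index(self) -> int:
        """Frame of minimum volume (end systole); ties broken to earliest."""
        return int(np.argmin(self.volumes))

    @property
    def ed_index(self) -> int:
        """Frame of maximum volume (end diastole); ties broken to earliest."""
        return int(np.argmax(self.volumes))

    @property
    def edv(self) -> float:
        return float(self.volumes[self.ed_index])

    @property
    def esv(self) -> float:
        return float(self.volumes[self.es_index])


@dataclass(frozen=True)
class BrachialPressure:
    """Brachial cuff systolic/diastolic pressure in mmHg."""

    sbp: float
    dbp: float

    def __post_init__(self) -> None:
        if not (0 < self.dbp < self.sbp < 300):
            raise InvalidParameterError(
                f"require 0 < dbp < sbp < 300 mmHg, got sbp={self.sbp}, dbp={self.dbp}"
            )


@dataclass(frozen=True)
class NormalizedElastanceCurve:
    """Dimensionless single-peaked elastance waveform on normalized time [0, 1].

    ``e_norm`` starts at ``baseline``, rises to a unique global maximum of 1,
    and relaxes monotonically back toward the baseline.  The *middle of the
    downslope* is the unique descending-limb time where the waveform equals
    ``(1 + baseline) / 2`` — the anchor used for time alignment.
    """

    t_norm: np.ndarray
    e_norm: np.ndarray
    baseline: float = field(init=False)
    peak_time: float = field(init=False)
    downslope_mid_time: float = field(init=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.t_norm, dtype=float)
        e = np.asarray(self.e_norm, dtype=float)
        object.__setattr__(self, "t_norm", t)
        object.__setattr__(self, "e_norm", e)
        if t.ndim != 1 or len(t) != len(e) or len(t) < 10:
            raise ShapeError("t_norm and e_norm must be 1-D, equal length >= 10")
        if t[0] != 0.0 or abs(t[-1] - 1.0) > 1e-12 or np.any(np.diff(t) <= 0):
            raise ShapeError("t_norm must increase strictly from 0 to 1")
        k = int(np.argmax(e))
        if abs(e[k] - 1.0) > 1e-9:
            raise ShapeError("waveform must be normalized to a maximum of 1")
        if k == 0 or k == len(e) - 1:
            raise ShapeError("peak must lie strictly inside (0, 1)")
        if np.any(np.diff(e[k:]) > 1e-12):
            raise ShapeError("waveform must be nonincreasing after its peak")
        baseline = float(e[0])
        if not (0 <= baseline < 1):
            raise ShapeError("baseline must lie in [0, 1)")
        object.__setattr__(self, "baseline", baseline)
        object.__setattr__(self, "peak_time", float(t[k]))
        # Locate the mid-downslope crossing by inverse linear interpolation on
        # the descending limb, consistent with __call__'s interpolation rule.
        target = 0.5 * (1.0 + baseline)
        down_t, down_e = t[k:], e[k:]
        idx = np.nonzero(down_e <= target)[0]
        if len(idx) == 0:
            raise ShapeError("waveform never relaxes to the mid-downslope level")
        j = int(idx[0])
        if j == 0:
            tm = float(down_t[0])
        else:
            e0, e1 = down_e[j - 1], down_e[j]
            t0, t1 = down_t[j - 1], down_t[j]
            tm = float(t0 + (target - e0) * (t1 - t0) / (e1 - e0))
        object.__setattr__(self, "downslope_mid_time", tm)

    def __call__(self, u: np.ndarray | float) -> np.ndarray | float:
        """Evaluate the waveform at normalized time ``u`` (held at the
        baseline outside [0, 1])."""
        return np.interp(u, self.t_norm, self.e_norm, left=self.baseline, right=self.baseline)


def double_hill_elastance(
    *,
    baseline: float = 0.05,
    tau_rise: float = 0.269,
    n_rise: float = 1.32,
    tau_fall: float = 0.452,
    n_fall: float = 21.9,
    n_grid: int = 2001,
) -> NormalizedElastanceCurve:
    """Build the default normalized elastance waveform.

    The shape is the product of an activation and a relaxation Hill term,

        h(u) = [ (u/tau_rise)^n_rise / (1 + (u/tau_rise)^n_rise) ]
               * [ 1 / (1 + (u/tau_fall)^n_fall) ],

    rescaled to peak at 1 and lifted onto the diastolic ``baseline``.  The
    defaults place the peak near 40% of the cycle with a sharp relaxation,
    the canonical human normalized-elastance morphology.
    """
    if not (0 <= baseline < 1):
        raise ShapeError("baseline must lie in [0, 1)")
    if min(tau_rise, n_rise, tau_fall, n_fall) <= 0:
        raise ShapeError("Hill parameters must be positive")
    u = np.linspace(0.0, 1.0, n_grid)
    with np.errstate(over="ignore"):
        rise = (u / tau_rise) ** n_rise
        fall = (u / tau_fall) ** n_fall
        h = (rise / (1.0 + rise)) / (1.0 + fall)
    h /= h.max()
    e = baseline + (1.0 - baseline) * h
    e[0] = baseline  # exact anchor; h(0) = 0 analytically
    # Enforce exact monotone relaxation past the peak against float jitter.
    k = int(np.argmax(e))
    e[k] = 1.0
    e[k:] = np.minimum.accumulate(e[k:])
    return NormalizedElastanceCurve(t_norm=u, e_norm=e)


def elastance_from_samples(t_norm: np.ndarray, e_norm: np.ndarray) -> NormalizedElastanceCurve:
    """Wrap a user-supplied digitized elastance waveform.

    The samples are sorted by time, rescaled to span [0, 1] in time and to a
    unit peak in amplitude, then validated against the single-peak contract.
    """
    t = np.asarray(t_norm, dtype=float)
    e = np.asarray(e_norm, dtype=float)
    order = np.argsort(t)
    t, e = t[order], e[order]
    t = (t - t[0]) / (t[-1] - t[0])
    e = e / e.max()
    return NormalizedElastanceCurve(t_norm=t, e_norm=e)


def estimate_peak_lv_pressure(
    bp: BrachialPressure,
    method: str = "identity",
    c1: float = 1.0,
    c0: float = 0.0,
) -> float:
    """Approximate peak systolic LV pressure from the brachial reading.

    ``"identity"`` takes the brachial systolic pressure unchanged;
    ``"affine"`` returns ``c1 * sbp + c0`` for user-calibrated brachial-to-LV
    transfer expressions.
    """
    if method == "identity":
        p = float(bp.sbp)
    elif method == "affine":
        p = float(c1 * bp.sbp + c0)
    else:
        raise InvalidParameterError(f"unknown peak-pressure method {method!r}")
    if p <= 0:
        raise InvalidParameterError(f"estimated peak pressure {p} mmHg is not positive")
    return p


def align_elastance_to_cycle(
    curve: NormalizedElastanceCurve, vts: VolumeTimeSeries
) -> np.ndarray:
    """Map the normalized waveform onto the cardiac time grid (unscaled).

    A linear time map sends normalized time 0 to cycle start and the middle
    of the elastance downslope to the end-systolic (minimum-volume) frame.
    Beyond the mapped support the waveform is held at its baseline for the
    remainder of diastole.
    """
    k = vts.es_index
    if k == 0 or k == vts.frame_count - 1:
        raise DegenerateCycleError(
            "minimum volume at the first or last frame; cannot align elastance"
        )
    t_es = float(vts.times[k])
    stretch = t_es / curve.downslope_mid_time
    u = vts.times / stretch
    return np.asarray(curve(u), dtype=float)


@dataclass(frozen=True)
class ScaledElastanceResult:
    """Affine-scaled elastance and the synthesized LV pressure curve.

    ``elastance_of_t = scale_a * E_N(mapped t) + offset_b`` in mmHg/mL, and
    ``pressure_of_t = elastance_of_t * (V(t) - v0)`` in mmHg.
    """

    scale_a: float
    offset_b: float
    elastance_of_t: np.ndarray
    pressure_of_t: np.ndarray
    lvp_systole_target: float
    edp_target: float
    v0: float


def solve_amplitude_scaling(
    e_aligned: np.ndarray,
    volumes: np.ndarray,
    ed_index: int,
    lvp_systole: float,
    edp: float,
    v0: float,
    *,
    rel_tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[float, float, np.ndarray]:
    """Solve for the affine amplitude scaling ``(a, b)``.

    Finds ``a, b`` with ``max_t (a e(t) + b)(V(t) - v0) = lvp_systole`` and
    ``(a e + b)(V - v0) = edp`` at the end-diastolic frame.  For a *known*
    peak frame the two constraints are a linear 2x2 system; the peak frame
    itself depends on ``(a, b)``, so the system is iterated as a fixed point
    over the candidate peak frame, which converges in a handful of steps for
    physiological waveforms.

    Returns ``(a, b, pressure_curve)``.
    """
    e = np.asarray(e_aligned, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if e.shape != v.shape:
        raise InvalidParameterError("elastance and volume grids must match")
    if not (lvp_systole > edp > 0):
        raise InvalidParameterError("require lvp_systole > edp > 0")
    w = v - v0
    if np.any(w <= 0):
        raise InvalidParameterError("v0 must be below the minimum volume")

    def solve_for_peak(k: int) -> tuple[float, float]:
        de = e[k] - e[ed_index]
        if abs(de) < 1e-15:
            raise ScalingError(
                "elastance at the candidate peak equals the end-diastolic value"
            )
        a = (lvp_systole / w[k] - edp / w[ed_index]) / de
        b = edp / w[ed_index] - a * e[ed_index]
        return a, b

    k = int(np.argmax(e * w))
    seen: dict[int, tuple[float, float]] = {}
    for _ in range(max_iter):
        a, b = solve_for_peak(k)
        seen[k] = (a, b)
        p = (a * e + b) * w
        k_new = int(np.argmax(p))
        if k_new == k:
            break
        if k_new in seen:
            # Cycle between candidate peaks: keep the candidate whose solved
            # pressure curve best honours the peak constraint.
            best = min(
                seen,
                key=lambda kk: abs(
                    np.max((seen[kk][0] * e + seen[kk][1]) * w) - lvp_systole
                ),
            )
            a, b = seen[best]
            p = (a * e + b) * w
            break
        k = k_new
    else:
        raise ConvergenceError("amplitude scaling did not converge in 200 iterations")

    if a <= 0 or np.max(p) <= 0:
        raise ScalingError("no admissible scaling with positive peak pressure")
    if abs(np.max(p) - lvp_systole) > rel_tol * lvp_systole:
        # The argmax fixed point meets the constraint exactly on convergence;
        # a residual above tolerance means the two targets are geometrically
        # incompatible with this waveform.
        raise ScalingError(
            f"peak-pressure constraint violated: max P = {np.max(p):.3f}, "
            f"target {lvp_systole:.3f} mmHg"
        )
    return float(a), float(b), p


def scale_elastance_amplitude(
    e_aligned: np.ndarray,
    vts: VolumeTimeSeries,
    lvp_systole: float,
    edp: float,
    v0: float = 0.0,
) -> ScaledElastanceResult:
    """Scale the aligned elastance so the pressure curve meets both targets."""
    a, b, p = solve_amplitude_scaling(
        e_aligned, vts.volumes, vts.ed_index, lvp_systole, edp, v0
    )
    return ScaledElastanceResult(
        scale_a=a,
        offset_b=b,
        elastance_of_t=a * np.asarray(e_aligned, dtype=float) + b,
        pressure_of_t=p,
        lvp_systole_target=float(lvp_systole),
        edp_target=float(edp),
        v0=float(v0),
    )


def compute_pressure_curve(
    scaled: ScaledElastanceResult, vts: VolumeTimeSeries
) -> np.ndarray:
    """P(t) = E(t) * (V(t) - v0) on the cardiac grid."""
    if scaled.elastance_of_t.shape != vts.volumes.shape:
        raise InvalidParameterError("scaled elastance grid does not match the volume grid")
    return scaled.elastance_of_t * (vts.volumes - scaled.v0)
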