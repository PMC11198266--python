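"""Pressure-volume loop assembly and ventricular energetic parameters.

The PV loop is the closed trajectory of LV pressure against volume over one
beat.  From it this module derives the seven hemodynamic parameters used in
noninvasive PV analysis:

* stroke work (SW, J) — area enclosed by the loop;
* potential energy (PE, J) — area between the end-systolic pressure-volume
  relationship (ESPVR, the line from V0 through the maximal-elastance point)
  and the volume axis, i.e. stored energy not converted to ejection;
* ventricular efficiency (VE, %) = 100 * SW / (SW + PE);
* mean external power (J/s) = SW * HR / 60;
* contractility (Emax, mmHg/mL) — peak of P/(V - V0) over the beat, the
  ESPVR slope;
* energy per ejected volume (J/mL) = (SW + PE) / SV;
* arterial elastance (Ea, mmHg/mL) — |slope| from the Emax point to the
  volume axis at EDV, i.e. ESP / (EDV - ESV).

Areas in mmHg*mL are converted to joules with 1 mmHg*mL = 1.33322e-4 J.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .elastance import (
    BrachialPressure,
    InvalidParameterError,
    VolumeTimeSeries,
    align_elastance_to_cycle,
    double_hill_elastance,
    estimate_peak_lv_pressure,
    scale_elastance_amplitude,
)

__all__ = [
    "MMHG_ML_TO_J",
    "PVLoop",
    "PVParameters",
    "assemble_pv_loop",
    "stroke_work",
    "emax_point",
    "potential_energy",
    "ventricular_efficiency",
    "external_power",
    "energy_per_ejected_volume",
    "arterial_elastance",
    "compute_all_parameters",
    "DegenerateLoopError",
    "GeometryError",
]

#: 1 mmHg * 1 mL expressed in joules (133.322 Pa * 1e-6 m^3).
MMHG_ML_TO_J = 1.33322e-4


class DegenerateLoopError(ValueError):
    """The (V, P) samples do not form a usable closed loop."""


class GeometryError(ValueError):
    """A loop-geometry precondition (V0 < ESV < EDV, SV > 0, ...) fails."""


@dataclass(frozen=True)
class PVLoop:
    """Paired (volume, pressure) samples over one beat, implicitly closed.

    Orientation is normalized on construction so that the signed shoelace
    area is positive (ejection traversed at higher pressure than filling).
    """

    volumes: np.ndarray
    pressures: np.ndarray
    v0: float = 0.0
    heart_rate: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.volumes, dtype=float)
        p = np.asarray(self.pressures, dtype=float)
        if v.ndim != 1 or v.shape != p.shape:
            raise DegenerateLoopError("volumes and pressures must be 1-D and paired")
        if len(v) < 3:
            raise DegenerateLoopError("a loop needs at least 3 points")
        if np.any(v <= 0):
            raise DegenerateLoopError("all volumes must be positive")
        if not np.all(np.isfinite(p)):
            raise DegenerateLoopError("all pressures must be finite")
        # Drop a duplicated closing point; closure is implicit.
        if v[0] == v[-1] and p[0] == p[-1]:
            v, p = v[:-1], p[:-1]
        if np.all(v == v[0]) and np.all(p == p[0]):
            raise DegenerateLoopError("all loop points coincide")
        if _signed_area(v, p) < 0:
            v, p = v[::-1].copy(), p[::-1].copy()
        object.__setattr__(self, "volumes", v)
        object.__setattr__(self, "pressures", p)

    @property
    def edv(self) -> float:
        return float(self.volumes.max())

    @property
    def esv(self) -> float:
        return float(self.volumes.min())


def _signed_area(x: np.ndarray, y: np.ndarray) -> float:
    """Shoelace signed area of the implicitly closed polygon."""
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def assemble_pv_loop(
    vts: VolumeTimeSeries, pressures: np.ndarray, v0: float = 0.0
) -> PVLoop:
    """Pair a volume curve with its pressure curve into a closed PV loop."""
    p = np.asarray(pressures, dtype=float)
    if p.shape != vts.volumes.shape:
        raise DegenerateLoopError("pressure series length does not match the volume curve")
    return PVLoop(volumes=vts.volumes, pressures=p, v0=v0, heart_rate=vts.heart_rate)


def stroke_work(loop: PVLoop) -> float:
    """Area enclosed by the PV loop, in joules."""
    area = _signed_area(loop.volumes, loop.pressures)
    if area <= 0:
        warnings.warn("degenerate PV loop encloses no area; stroke work set to 0")
        return 0.0
    return area * MMHG_ML_TO_J


def emax_point(loop: PVLoop) -> tuple[float, float, float]:
    """Maximal time-varying elastance over the beat.

    Returns ``(esv_at_emax, esp, emax)`` where ``emax = max P/(V - v0)``,
    evaluated per sample with ties broken to the earliest frame.
    """
    w = loop.volumes - loop.v0
    if np.any(w <= 0):
        raise GeometryError("v0 must be below the minimum loop volume")
    ratios = loop.pressures / w
    k = int(np.argmax(ratios))
    return float(loop.volumes[k]), float(loop.pressures[k]), float(ratios[k])


def potential_energy(loop: PVLoop, *, subtract_diastolic: bool = False) -> float:
    """Energy stored in the ventricular wall at end systole, in joules.

    Default convention: the triangle under the ESPVR from ``v0`` to the
    maximal-elastance point, ``0.5 * esp * (esv - v0)``.  With
    ``subtract_diastolic=True`` a linearized diastolic limb from
    ``(v0, 0)`` to ``(esv, P_min)`` is subtracted — a second-order
    correction at typical end-diastolic pressures.
    """
    esv, esp, _ = emax_point(loop)
    if esv <= loop.v0:
        raise GeometryError("end-systolic volume must exceed v0")
    area = 0.5 * esp * (esv - loop.v0)
    if subtract_diastolic:
        p_floor = float(loop.pressures.min())
        area -= 0.5 * max(p_floor, 0.0) * (esv - loop.v0)
    return area * MMHG_ML_TO_J


def ventricular_efficiency(sw: float, pe: float) -> float:
    """Fraction of total pressure-volume area converted to external work, %."""
    if sw < 0 or pe < 0:
        raise GeometryError("stroke work and potential energy must be nonnegative")
    if sw + pe == 0:
        raise GeometryError("efficiency undefined when SW + PE = 0")
    return 100.0 * sw / (sw + pe)


def external_power(sw: float, hr: float) -> float:
    """Mean external power over the cycle: SW * HR / 60, in J/s."""
    if hr <= 0:
        raise InvalidParameterError("heart rate must be positive")
    return sw * hr / 60.0


def energy_per_ejected_volume(sw: float, pe: float, sv: float) -> float:
    """Total pressure-volume area per ejected millilitre, in J/mL."""
    if sv <= 0:
        raise GeometryError("stroke volume must be positive")
    return (sw + pe) / sv


def arterial_elastance(loop: PVLoop) -> float:
    """Effective arterial elastance: ESP / (EDV - ESV at Emax), in mmHg/mL."""
    esv, esp, _ = emax_point(loop)
    if loop.edv <= esv:
        raise GeometryError("EDV must exceed the end-systolic volume at Emax")
    return esp / (loop.edv - esv)


@dataclass(frozen=True)
class PVParameters:
    """The derived hemodynamic parameter set for one beat."""

    stroke_work: float  # J
    potential_energy: float  # J
    ventricular_efficiency: float  # %
    external_power: float  # J/s
    contractility_emax: float  # mmHg/mL
    energy_per_ejected_volume: float  # J/mL
    arterial_elastance: float  # mmHg/mL
    esp: float  # mmHg
    esv: float  # mL
    edv: float  # mL
    sv: float  # mL

    def __post_init__(self) -> None:
        if self.sv <= 0:
            raise GeometryError("stroke volume must be positive")
        if not (0 <= self.ventricular_efficiency <= 100):
            raise GeometryError("efficiency must lie in [0, 100]%")


def parameters_from_loop(loop: PVLoop, *, subtract_diastolic: bool = False) -> PVParameters:
    """Compute the full parameter set from an assembled loop."""
    sw = stroke_work(loop)
    esv_at_emax, esp, emax = emax_point(loop)
    pe = potential_energy(loop, subtract_diastolic=subtract_diastolic)
    sv = loop.edv - loop.esv  # loop width
    hr = loop.heart_rate if loop.heart_rate is not None else np.nan
    return PVParameters(
        stroke_work=sw,
        potential_energy=pe,
        ventricular_efficiency=ventricular_efficiency(sw, pe),
        external_power=external_power(sw, hr) if np.isfinite(hr) else np.nan,
        contractility_emax=emax,
        energy_per_ejected_volume=energy_per_ejected_volume(sw, pe, sv),
        arterial_elastance=arterial_elastance(loop),
        esp=esp,
        esv=esv_at_emax,
        edv=loop.edv,
        sv=sv,
    )


def compute_all_parameters(
    vts: VolumeTimeSeries,
    bp: BrachialPressure,
    *,
    edp_mmhg: float = 7.0,
    v0_ml: float = 0.0,
    peak_pressure_method: str = "identity",
    peak_pressure_c1: float = 1.0,
    peak_pressure_c0: float = 0.0,
    elastance_curve=None,
    subtract_diastolic: bool = False,
) -> PVParameters:
    """Run the full pipeline for one patient: pressure synthesis then metrics.

    The elastance waveform defaults to the double-Hill shape; pass a
    :class:`~pvloop.elastance.NormalizedElastanceCurve` to substitute a
    digitized waveform.
    """
    curve = elastance_curve if elastance_curve is not None else double_hill_elastance()
    lvp = estimate_peak_lv_pressure(
        bp, method=peak_pressure_method, c1=peak_pressure_c1, c0=peak_pressure_c0
    )
    aligned = align_elastance_to_cycle(curve, vts)
    scaled = scale_elastance_amplitude(aligned, vts, lvp, edp_mmhg, v0_ml)
    loop = assemble_pv_loop(vts, scaled.pressure_of_t, v0=v0_ml)
    return parameters_from_loop(loop, subtract_diastolic=subtract_diastolic)
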