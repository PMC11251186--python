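"""Calibration of single-particle observations to mass.

Two orthogonal single-particle techniques are covered:

* charge detection mass spectrometry (CDMS): each ion event carries an
  m/z and a normalized single-ion intensity; intensity is converted to
  charge with an instrument calibration factor and mass follows from
  the standard charge-deconvolution identity ``M = z * (m/z - m_H+)``.
* mass photometry (MP): each landing event carries a ratiometric
  contrast, linear in mass; the line is fitted to a calibrant protein
  ladder and inverted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

PROTON_MASS_DA = 1.007276

#: Instrument-calibrated conversion from normalized single-ion intensity
#: to elementary charges.
DEFAULT_CHARGE_FACTOR = 14.713

#: Calibrant ladders (kDa) for the two instruments used.
MP_CALIBRANTS_KDA = (73.0, 149.0, 483.0, 800.0)
MP_CALIBRANTS_HIGH_KDA = (335.0, 670.0, 1340.0)


@dataclass(frozen=True)
class IonEvent:
    """A single CDMS ion observation."""

    mz: float
    intensity_norm: float


@dataclass(frozen=True)
class MPEvent:
    """A single mass-photometry landing event (ratiometric contrast)."""

    contrast: float


@dataclass(frozen=True)
class MassEvent:
    """A calibrated single-particle mass observation."""

    mass_kda: float
    source: str  # "cdms" | "mp"
    charge: int | None = None


@dataclass
class ChargeCalibration:
    factor_k: float = DEFAULT_CHARGE_FACTOR
    round_to_integer: bool = True
    proton_mass_da: float = PROTON_MASS_DA

    def __post_init__(self) -> None:
        if self.factor_k <= 0:
            raise ValueError("charge calibration factor must be positive")


@dataclass
class MPCalibration:
    slope: float  # contrast per kDa
    intercept: float
    r2: float
    calibrant_masses_kda: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("MP calibration slope must be nonzero")


def intensity_to_charge(intensity_norm: float, cal: ChargeCalibration | None = None) -> float:
    """Convert a normalized single-ion intensity to charge.

    Raw charge is ``factor_k * intensity``; with ``round_to_integer``
    (default, charges are physically integral) it is rounded half-up and
    floored at 1.
    """
    cal = cal or ChargeCalibration()
    if intensity_norm <= 0:
        raise ValueError("intensity must be positive")
    z = cal.factor_k * intensity_norm
    if cal.round_to_integer:
        z = max(1, int(np.floor(z + 0.5)))
    return z


def cdms_event_to_mass(event: IonEvent, cal: ChargeCalibration | None = None) -> MassEvent:
    """Invert one ion event to a mass event (kDa) via M = z·(m/z − m_p)."""
    cal = cal or ChargeCalibration()
    z = intensity_to_charge(event.intensity_norm, cal)
    mass_da = z * (event.mz - cal.proton_mass_da)
    if mass_da <= 0:
        raise ValueError("event inverts to nonpositive mass")
    return MassEvent(mass_kda=mass_da / 1000.0, source="cdms", charge=int(round(z)))


def cdms_events_to_masses(
    events, cal: ChargeCalibration | None = None
) -> np.ndarray:
    """Vectorized CDMS inversion; returns masses in kDa."""
    cal = cal or ChargeCalibration()
    mz = np.asarray([e.mz for e in events], dtype=float)
    inten = np.asarray([e.intensity_norm for e in events], dtype=float)
    if np.any(inten <= 0):
        raise ValueError("intensity must be positive")
    z = cal.factor_k * inten
    if cal.round_to_integer:
        z = np.maximum(1, np.floor(z + 0.5))
    mass = z * (mz - cal.proton_mass_da) / 1000.0
    return mass


def fit_mp_calibration(calibrant_events, calibrant_masses) -> MPCalibration:
    """Least-squares contrast-vs-mass line through per-calibrant medians.

    ``calibrant_events`` maps calibrant mass (kDa) -> iterable of
    contrasts (or an equivalent two-column DataFrame with columns
    ``mass_kda`` and ``contrast``).  The median contrast per calibrant is
    used, which is robust to aberrant landing events.
    """
    if isinstance(calibrant_events, pd.DataFrame):
        grouped = calibrant_events.groupby("mass_kda")["contrast"].median()
        calibrant_events = {m: [v] for m, v in grouped.items()}
        calibrant_masses = list(grouped.index)
    masses = sorted(set(float(m) for m in calibrant_masses))
    if len(masses) < 2:
        raise ValueError("need at least two distinct calibrant masses")
    medians = []
    for m in masses:
        contrasts = np.asarray(list(calibrant_events[m]), dtype=float)
        if contrasts.size == 0:
            raise ValueError(f"no events for calibrant {m} kDa")
        medians.append(np.median(contrasts))
    medians = np.asarray(medians)
    if np.allclose(medians, medians[0]):
        raise ValueError("zero contrast variance across calibrants")
    res = stats.linregress(masses, medians)
    return MPCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        calibrant_masses_kda=tuple(masses),
    )


def mp_contrast_to_mass(events, cal: MPCalibration) -> list[MassEvent]:
    """Invert MP contrasts to masses; nonpositive masses are dropped and
    the dropped count logged."""
    out, dropped = [], 0
    for e in events:
        contrast = e.contrast if isinstance(e, MPEvent) else float(e)
        mass = (contrast - cal.intercept) / cal.slope
        if mass <= 0:
            dropped += 1
            continue
        out.append(MassEvent(mass_kda=mass, source="mp"))
    if dropped:
        log.info("mp_contrast_to_mass: dropped %d events with nonpositive mass", dropped)
    return out


def read_ion_events(path) -> list[IonEvent]:
    """Read a TSV with columns mz, intensity_norm."""
    df = pd.read_csv(path, sep="\t")
    return [IonEvent(r.mz, r.intensity_norm) for r in df.itertuples()]


def read_mp_events(path) -> list[MPEvent]:
    """Read a TSV with column contrast."""
    df = pd.read_csv(path, sep="\t")
    return [MPEvent(c) for c in df["contrast"]]
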