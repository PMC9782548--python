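"""Core containers for single-voxel MRS data.

A free induction decay (FID) is the complex time-domain signal recorded
after excitation; its discrete Fourier transform is the spectrum.  Every
stage of the pipeline consumes and produces :class:`FIDSignal` objects so
that acquisition metadata (dwell time, transmitter frequency, nucleus,
ppm reference) travels with the samples.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Nucleus",
    "AcquisitionParams",
    "ResonanceLine",
    "PeakTable",
    "FIDSignal",
]


class Nucleus(str, enum.Enum):
    """Observed nucleus; fixes the default ppm reference convention."""

    P31 = "P31"
    H1 = "H1"

    @classmethod
    def coerce(cls, value: "Nucleus | str") -> "Nucleus":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip())
        except ValueError:
            raise ValueError(
                f"unknown nucleus {value!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


@dataclass(frozen=True)
class AcquisitionParams:
    """Sampling grid and frequency-axis metadata of an acquisition.

    Parameters
    ----------
    n_points:
        Number of complex samples N.
    spectral_width:
        Acquisition bandwidth in Hz; the dwell time is ``1/spectral_width``.
    spectrometer_freq:
        Transmitter frequency in MHz, used for ppm <-> Hz conversion
        (1 ppm == ``spectrometer_freq`` Hz).
    nucleus:
        Observed nucleus.
    ref_ppm:
        Chemical shift assigned to the centre of the spectral window
        (the carrier).  0.0 for PCr-referenced 31P, 4.7 for
        water-referenced 1H.
    """

    n_points: int
    spectral_width: float
    spectrometer_freq: float
    nucleus: Nucleus
    ref_ppm: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "nucleus", Nucleus.coerce(self.nucleus))
        if int(self.n_points) != self.n_points or self.n_points < 4:
            raise ValueError(f"n_points must be an integer >= 4, got {self.n_points}")
        object.__setattr__(self, "n_points", int(self.n_points))
        if not self.spectral_width > 0:
            raise ValueError(f"spectral_width must be > 0, got {self.spectral_width}")
        if not self.spectrometer_freq > 0:
            raise ValueError(
                f"spectrometer_freq must be > 0, got {self.spectrometer_freq}"
            )

    @property
    def dwell_time(self) -> float:
        """Sampling interval in seconds."""
        return 1.0 / self.spectral_width

    @property
    def time_axis(self) -> np.ndarray:
        """Sample times in seconds, ``t[n] = n * dwell_time``."""
        return np.arange(self.n_points) * self.dwell_time

    @property
    def ppm_span(self) -> float:
        """Width of the spectral window in ppm."""
        return self.spectral_width / self.spectrometer_freq

    def hz_offset(self, shift_ppm: float | np.ndarray) -> np.ndarray:
        """Frequency offset from the carrier, in Hz, of a chemical shift."""
        return (np.asarray(shift_ppm, dtype=float) - self.ref_ppm) * self.spectrometer_freq


@dataclass(frozen=True)
class ResonanceLine:
    """One Lorentzian line of a metabolite resonance.

    Multiplets are represented as several lines sharing a metabolite name;
    their amplitudes act as stoichiometric weights within the metabolite.
    """

    metabolite: str
    shift_ppm: float
    amplitude: float
    lw_hz: float
    phase_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(
                f"{self.metabolite}: amplitude must be >= 0, got {self.amplitude}"
            )
        if not self.lw_hz > 0:
            raise ValueError(f"{self.metabolite}: lw_hz must be > 0, got {self.lw_hz}")


@dataclass(frozen=True)
class PeakTable:
    """Ordered collection of resonance lines forming a ground truth / basis."""

    lines: tuple[ResonanceLine, ...]
    nucleus: Nucleus

    def __post_init__(self) -> None:
        object.__setattr__(self, "lines", tuple(self.lines))
        object.__setattr__(self, "nucleus", Nucleus.coerce(self.nucleus))
        if not self.lines:
            raise ValueError("peak table must contain at least one line")

    @property
    def metabolites(self) -> list[str]:
        """Distinct metabolite names in first-appearance order."""
        seen: dict[str, None] = {}
        for line in self.lines:
            seen.setdefault(line.metabolite, None)
        return list(seen)

    def lines_of(self, metabolite: str) -> list[ResonanceLine]:
        return [ln for ln in self.lines if ln.metabolite == metabolite]

    def total_amplitude(self, metabolite: str) -> float:
        return float(sum(ln.amplitude for ln in self.lines_of(metabolite)))

    def scaled(
        self,
        global_factor: float = 1.0,
        per_metabolite: dict[str, float] | None = None,
    ) -> "PeakTable":
        """Return a copy with amplitudes rescaled (globally and/or per metabolite)."""
        per_metabolite = per_metabolite or {}
        new_lines = []
        for ln in self.lines:
            f = global_factor * per_metabolite.get(ln.metabolite, 1.0)
            new_lines.append(replace(ln, amplitude=ln.amplitude * f))
        return PeakTable(tuple(new_lines), self.nucleus)


@dataclass(frozen=True)
class FIDSignal:
    """Complex time-domain signal plus its acquisition metadata."""

    samples: np.ndarray
    acq: AcquisitionParams
    provenance: str = "raw"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.complex128)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size != self.acq.n_points:
            raise ValueError(
                f"samples must be a 1-D array of length {self.acq.n_points}, "
                f"got shape {samples.shape}"
            )
        if not np.all(np.isfinite(samples.view(float))):
            raise ValueError("FID samples must be finite")

    def with_samples(self, samples: np.ndarray, provenance: str | None = None) -> "FIDSignal":
        return FIDSignal(samples, self.acq, provenance or self.provenance)

    def __len__(self) -> int:
        return self.acq.n_points
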