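"""Raw-signal surrogates: extracted-ion chromatograms and centroided MS2 spectra."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["XicTrace", "Ms2Spectrum"]


@dataclass
class XicTrace:
    """Extracted-ion chromatogram for one peptide form or isobaric class.

    ``trace_id`` is a form id for chromatographically unique forms and an
    isobaric-class id for co-eluting positional isomers (which share one
    precursor m/z and hence one XIC).
    """

    trace_id: str
    rt_min: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.rt_min = np.asarray(self.rt_min, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt_min.shape != self.intensity.shape or self.rt_min.ndim != 1:
            raise ValueError("rt_min and intensity must be matching 1-D arrays")
        if len(self.rt_min) >= 2 and not np.all(np.diff(self.rt_min) > 0):
            raise ValueError("retention times must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    def intensity_at(self, rt: float) -> float:
        """Linear interpolation of the trace at one retention time."""
        return float(np.interp(rt, self.rt_min, self.intensity))


@dataclass
class Ms2Spectrum:
    """Centroided MS2 spectrum: (m/z, intensity) pairs for one precursor class."""

    precursor_id: str
    rt_min: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be matching 1-D arrays")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if len(self.mz) >= 2 and np.any(np.diff(self.mz) == 0):
            # merge exact duplicates so m/z is strictly increasing
            uniq, inv = np.unique(self.mz, return_inverse=True)
            summed = np.zeros_like(uniq)
            np.add.at(summed, inv, self.intensity)
            self.mz, self.intensity = uniq, summed

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum())
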