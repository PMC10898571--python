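"""Shot-noise SNR of the collagen Raman band and the thickness detection limit.

The figure of merit for geometry optimization is the signal-to-noise ratio
of the collagen band (910–950 cm⁻¹) in the difference between the FBR and
day-0 measurements.  The signal is the collagen yield times the
baseline-subtracted collagen reference intensity; the noise is photon shot
noise, the square root of the total band counts contributed by every
material of *both* samples (differencing makes their shot noise additive):

    SNR = n_FBR^coll · I_Raman^coll
          / sqrt( Σ_FBR n·I_Raw + Σ_IC n·I_Raw )

The thickness limit of detection follows from the linearity of the collagen
signal in cap thickness: t_LOD = z · t_ref / SNR(t_ref) with z the
one-sided detection quantile (1.645 for 95%) and t_ref = 100 µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .transport import RamanYieldTable

__all__ = [
    "Spectrum",
    "ReferenceIntensities",
    "SNRResult",
    "band_intensities",
    "compute_snr",
    "lod_from_snr",
    "combine_detectors",
    "detection_criterion",
    "DEFAULT_BAND",
]

#: Collagen band integration window (cm⁻¹): proline/hydroxyproline region.
DEFAULT_BAND = (910.0, 950.0)


@dataclass
class Spectrum:
    """A Raman spectrum: wavenumber axis (cm⁻¹, ascending) + photon counts."""

    wavenumbers: np.ndarray
    counts: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.wavenumbers.ndim != 1 or self.wavenumbers.shape != self.counts.shape:
            raise ValueError("wavenumbers and counts must be matching 1-D arrays")
        if len(self.wavenumbers) < 4:
            raise ValueError("a spectrum needs at least 4 channels")
        d = np.diff(self.wavenumbers)
        if np.any(d <= 0):
            raise ValueError("wavenumber axis must be strictly increasing")

    def __len__(self) -> int:
        return len(self.wavenumbers)

    def band_slice(self, band: tuple[float, float]) -> np.ndarray:
        lo, hi = band
        if lo < self.wavenumbers[0] or hi > self.wavenumbers[-1]:
            raise ValueError(f"band {band} outside spectral axis")
        return (self.wavenumbers >= lo) & (self.wavenumbers <= hi)

    def copy_with(self, counts: np.ndarray, **meta) -> "Spectrum":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return Spectrum(self.wavenumbers.copy(), np.asarray(counts, dtype=float), new_meta)


@dataclass(frozen=True)
class ReferenceIntensities:
    """Band intensities of the material reference spectra.

    ``raman[m]`` is the baseline-subtracted count in the collagen window
    (I_Raman), ``raw[m]`` the un-subtracted total (I_Raw).
    """

    raman: Mapping[str, float]
    raw: Mapping[str, float]

    def __post_init__(self) -> None:
        for m in self.raman:
            if m not in self.raw:
                raise ValueError(f"material {m!r} missing from raw intensities")

    @classmethod
    def from_spectra(cls, spectra: Mapping[str, Spectrum],
                     band: tuple[float, float] = DEFAULT_BAND,
                     edge_channels: int = 3) -> "ReferenceIntensities":
        raman, raw = {}, {}
        for mat, spec in spectra.items():
            raman[mat], raw[mat] = band_intensities(spec, band, edge_channels)
        return cls(raman, raw)


@dataclass(frozen=True)
class SNRResult:
    """SNR of the collagen band plus the implied thickness detection limit."""

    snr: float
    signal: float
    noise: float
    thickness_um: float = 100.0
    criterion: float = 1.645

    @property
    def t_lod_um(self) -> float:
        """Limit of detection implied by this SNR at its model thickness (µm)."""
        return lod_from_snr(self.snr, self.thickness_um, self.criterion, rounded=False)

    @property
    def t_lod_um_display(self) -> int:
        return int(round(self.t_lod_um))


def band_intensities(spectrum: Spectrum, band: tuple[float, float] = DEFAULT_BAND,
                     edge_channels: int = 3) -> tuple[float, float]:
    """(I_Raman, I_Raw) of a band: counts with/without a local linear baseline.

    I_Raw sums the counts over the band.  The local linear baseline is the
    straight line through the mean counts of ``edge_channels``-wide windows
    centred on the band edges; I_Raman sums counts minus that line.
    """
    mask = spectrum.band_slice(band)
    if mask.sum() < 4:
        raise ValueError("band must cover at least 4 channels")
    counts = spectrum.counts
    wn = spectrum.wavenumbers
    i_raw = float(counts[mask].sum())

    half = edge_channels // 2
    lo_idx = int(np.argmin(np.abs(wn - band[0])))
    hi_idx = int(np.argmin(np.abs(wn - band[1])))
    lo_sl = slice(max(lo_idx - half, 0), lo_idx + half + 1)
    hi_sl = slice(max(hi_idx - half, 0), hi_idx + half + 1)
    x1, y1 = wn[lo_sl].mean(), counts[lo_sl].mean()
    x2, y2 = wn[hi_sl].mean(), counts[hi_sl].mean()
    slope = (y2 - y1) / (x2 - x1)
    baseline = y1 + slope * (wn[mask] - x1)
    i_raman = float((counts[mask] - baseline).sum())
    return i_raman, i_raw


def compute_snr(yields: RamanYieldTable, refs: ReferenceIntensities,
                thickness_um: float = 100.0, criterion: float = 1.645) -> SNRResult:
    """Shot-noise SNR of the collagen band from model yields + reference intensities."""
    for sample in ("FBR", "InitialConditions"):
        if sample not in yields.samples:
            raise ValueError(f"yield table lacks the {sample!r} sample")
    signal = yields.get("FBR", "collagen") * refs.raman.get("collagen", 0.0)
    total = 0.0
    for sample in ("FBR", "InitialConditions"):
        for material, n in yields.items(sample):
            if n == 0.0:
                continue
            if material not in refs.raw:
                raise ValueError(f"no raw reference intensity for {material!r}")
            total += n * refs.raw[material]
    if total <= 0:
        raise ValueError("total band count is zero; shot noise undefined")
    noise = float(np.sqrt(total))
    return SNRResult(snr=float(signal / noise), signal=float(signal), noise=noise,
                     thickness_um=thickness_um, criterion=criterion)


def lod_from_snr(snr_at_ref: float, reference_thickness_um: float = 100.0,
                 criterion: float = 1.645, rounded: bool = True) -> float:
    """Thickness limit of detection from the SNR at a reference thickness.

    Assumes the collagen signal is proportional to cap thickness, so the
    thickness at which SNR reaches the detection criterion is
    ``criterion · t_ref / SNR(t_ref)``.  ``rounded`` mirrors the whole-µm
    display convention.
    """
    if snr_at_ref <= 0:
        raise ValueError("SNR must be positive to define a detection limit")
    t = criterion * reference_thickness_um / snr_at_ref
    return float(round(t)) if rounded else float(t)


def combine_detectors(parts: Sequence[SNRResult | tuple[float, float]]) -> SNRResult:
    """Combine disjoint detector areas: signals add, noises add in quadrature."""
    if len(parts) == 0:
        raise ValueError("need at least one detector part")
    signals, noises = [], []
    thickness, criterion = 100.0, 1.645
    for p in parts:
        if isinstance(p, SNRResult):
            signals.append(p.signal)
            noises.append(p.noise)
            thickness, criterion = p.thickness_um, p.criterion
        else:
            s, n = p
            signals.append(float(s))
            noises.append(float(n))
    noises = np.asarray(noises)
    if np.any(noises <= 0):
        raise ValueError("noises must be positive")
    signal = float(np.sum(signals))
    noise = float(np.sqrt(np.sum(noises**2)))
    return SNRResult(snr=signal / noise, signal=signal, noise=noise,
                     thickness_um=thickness, criterion=criterion)


def detection_criterion(confidence: float = 0.95) -> float:
    """One-sided standard-normal detection quantile (0.95 → 1.645)."""
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie in (0, 1)")
    return float(stats.norm.ppf(confidence))
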