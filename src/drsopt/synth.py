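"""Synthetic Raman data with the statistical structure the analysis assumes.

Reference spectra of the five phantom materials are synthesized from the
band positions reported for them (polystyrene's dominant 1004 cm⁻¹ ring
breathing mode; collagen's 850/930 cm⁻¹ proline–hydroxyproline pair, amide
III and amide I; lipid CH₂ bands in skin and fat) as sums of Gaussian or
Lorentzian profiles on a smooth fluorescence-like background.  Composite
phantom measurements are yield-weighted mixtures of the references with
per-channel Poisson shot noise — exactly the linear-mixture + shot-noise
model underlying the SNR objective — and thickness series mimic the
calibration experiment: eight thicknesses, two replicates, a day-0 partner
for every FBR spectrum.

Relative Raman cross-sections of the materials are not published; the mixture
weights and band heights here are documented defaults, and every analysis
built on them is relative/structural rather than absolute-count matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .snr import ReferenceIntensities, SNRResult, Spectrum, compute_snr
from .transport import RamanYieldTable

__all__ = [
    "GENERATOR_VERSION",
    "PAPER_THICKNESSES_UM",
    "BandTable",
    "DEFAULT_BAND_TABLES",
    "GeneratorSpec",
    "WeightModel",
    "ThicknessSeries",
    "make_reference_spectrum",
    "reference_spectra",
    "make_composite_spectrum",
    "make_thickness_series",
    "expected_snr",
    "calibrate_noise_to_snr",
]

GENERATOR_VERSION = "1"

#: Calibration thickness list used by the study: eight values, two replicates.
PAPER_THICKNESSES_UM = (10.0, 20.0, 40.0, 60.0, 80.0, 100.0, 150.0, 200.0)


@dataclass(frozen=True)
class BandTable:
    """Raman bands of one material: (center cm⁻¹, width cm⁻¹, height, profile).

    ``background`` holds polynomial coefficients (constant first) in the
    normalized coordinate (ν − 800)/1000, mimicking broad fluorescence.
    """

    bands: tuple[tuple[float, float, float, str], ...]
    background: tuple[float, ...] = (0.0,)

    def evaluate(self, wavenumbers: np.ndarray) -> np.ndarray:
        wn = np.asarray(wavenumbers, dtype=float)
        out = np.zeros_like(wn)
        for center, width, height, profile in self.bands:
            if profile == "gaussian":
                out += height * np.exp(-0.5 * ((wn - center) / width) ** 2)
            elif profile == "lorentzian":
                out += height * width**2 / ((wn - center) ** 2 + width**2)
            else:
                raise ValueError(f"unknown band profile {profile!r}")
        u = (wn - 800.0) / 1000.0
        out += np.polyval(self.background[::-1], u)
        return out


def _g(c, w, h):
    return (c, w, h, "gaussian")


def _l(c, w, h):
    return (c, w, h, "lorentzian")


#: Default band tables.  Heights are relative; polystyrene's sharp bands
#: dominate the raw spectra (its reference is plotted scaled down 5-fold in
#: the study), and the biological materials share the broad protein/lipid
#: bands with material-specific balance.
DEFAULT_BAND_TABLES: dict[str, BandTable] = {
    "polystyrene": BandTable(
        bands=(_g(1004, 4, 5.0), _g(1032, 5, 1.0), _g(1155, 6, 0.3),
               _l(1450, 8, 0.8), _l(1583, 6, 0.4), _l(1602, 5, 0.9),
               _l(1634, 6, 0.5)),
        background=(0.12, 0.03, -0.02),
    ),
    "collagen": BandTable(
        bands=(_g(850, 9, 0.75), _g(875, 8, 0.45), _g(930, 9, 0.85),
               _g(1065, 18, 0.35), _g(1245, 15, 0.55), _g(1270, 12, 0.5),
               _g(1450, 14, 0.7), _g(1670, 16, 1.0)),
        background=(0.3, 0.05, -0.05),
    ),
    "skin": BandTable(
        bands=(_g(850, 10, 0.25), _g(935, 10, 0.3), _g(1004, 5, 0.25),
               _g(1080, 18, 0.3), _g(1270, 15, 0.45), _g(1300, 10, 0.5),
               _g(1450, 13, 1.0), _g(1655, 16, 0.8)),
        background=(0.55, 0.1, -0.12),
    ),
    "fat": BandTable(
        bands=(_g(870, 8, 0.25), _g(1080, 16, 0.45), _g(1265, 10, 0.5),
               _g(1300, 9, 1.0), _g(1440, 12, 1.2), _g(1655, 12, 0.45),
               _g(1745, 10, 0.3)),
        background=(0.4, 0.05, -0.08),
    ),
    "muscle": BandTable(
        bands=(_g(855, 9, 0.2), _g(940, 11, 0.35), _g(1004, 5, 0.3),
               _g(1095, 16, 0.3), _g(1320, 14, 0.45), _g(1450, 13, 0.9),
               _g(1660, 15, 1.0)),
        background=(0.45, 0.08, -0.1),
    ),
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Axis, count scale, noise model and master seed of the generator."""

    axis_start: float = 800.0
    axis_stop: float = 1800.0
    axis_step: float = 2.0
    count_scale: float = 1.0e4
    integration_time_s: float = 900.0
    laser_power_mw: float = 45.0
    poisson_noise: bool = True
    seed: int = 0
    band_tables: Mapping[str, BandTable] = field(default_factory=lambda: DEFAULT_BAND_TABLES)

    def __post_init__(self) -> None:
        if self.axis_step <= 0 or self.count_scale <= 0:
            raise ValueError("axis_step and count_scale must be positive")

    def axis(self) -> np.ndarray:
        n = int(round((self.axis_stop - self.axis_start) / self.axis_step)) + 1
        return self.axis_start + self.axis_step * np.arange(n)

    def child_rng(self, index: int) -> np.random.Generator:
        """Deterministic per-sample stream: master seed + sample counter."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(index,)))

    def base_meta(self) -> dict:
        return {
            "generator_version": GENERATOR_VERSION,
            "seed": self.seed,
            "count_scale": self.count_scale,
            "integration_time_s": self.integration_time_s,
            "laser_power_mw": self.laser_power_mw,
        }


@dataclass(frozen=True)
class WeightModel:
    """Material mixture weights of a composite measurement.

    Background materials contribute fixed weights; the collagen weight grows
    linearly with cap thickness (the thin-slab Born linearity), so
    ``collagen = collagen_per_um · t``.  Weights can also be taken from a
    transport :class:`RamanYieldTable` so the generator reproduces a
    specific instrument geometry.
    """

    base: Mapping[str, float] = field(default_factory=lambda: {
        "skin": 1.0, "fat": 0.5, "muscle": 0.2, "polystyrene": 0.3})
    collagen_per_um: float = 0.0025

    @classmethod
    def from_yield_table(cls, table: RamanYieldTable,
                         thickness_um: float) -> "WeightModel":
        base = {m: v for m, v in table.items("FBR") if m != "collagen"}
        return cls(base=base,
                   collagen_per_um=table.get("FBR", "collagen") / thickness_um)

    def weights_at(self, thickness_um: float) -> dict[str, float]:
        w = dict(self.base)
        w["collagen"] = self.collagen_per_um * thickness_um
        return w

    def yield_table_at(self, thickness_um: float) -> RamanYieldTable:
        fbr = self.weights_at(thickness_um)
        ic = {m: v for m, v in self.base.items()}
        ic["collagen"] = 0.0
        return RamanYieldTable({"FBR": fbr, "InitialConditions": ic})


def make_reference_spectrum(material: str, spec: GeneratorSpec,
                            noisy: bool = False,
                            rng: np.random.Generator | None = None) -> Spectrum:
    """Reference spectrum of one material at the generator's count scale."""
    if material not in spec.band_tables:
        raise KeyError(f"no band table for material {material!r}")
    wn = spec.axis()
    expected = spec.band_tables[material].evaluate(wn) * spec.count_scale
    counts = expected
    if noisy:
        rng = rng if rng is not None else spec.child_rng(0)
        counts = rng.poisson(expected).astype(float)
    meta = spec.base_meta() | {"material": material, "noisy": noisy}
    return Spectrum(wn, counts, meta)


def reference_spectra(spec: GeneratorSpec, noisy: bool = False) -> dict[str, Spectrum]:
    """Reference spectra for every material in the band table."""
    return {m: make_reference_spectrum(m, spec, noisy=noisy,
                                       rng=spec.child_rng(1000 + i))
            for i, m in enumerate(sorted(spec.band_tables))}


def make_composite_spectrum(weights: Mapping[str, float], spec: GeneratorSpec,
                            rng: np.random.Generator | None = None,
                            label: str | None = None) -> Spectrum:
    """Yield-weighted mixture of references with optional Poisson draw."""
    w = {m: v for m, v in weights.items() if v != 0.0}
    if not w:
        raise ValueError("at least one positive weight required")
    if any(v < 0 for v in w.values()):
        raise ValueError("weights must be nonnegative")
    wn = spec.axis()
    expected = np.zeros_like(wn)
    for material, weight in w.items():
        if material not in spec.band_tables:
            raise KeyError(f"no band table for material {material!r}")
        expected += weight * spec.band_tables[material].evaluate(wn)
    expected *= spec.count_scale
    counts = expected
    if spec.poisson_noise:
        rng = rng if rng is not None else spec.child_rng(0)
        counts = rng.poisson(expected).astype(float)
    meta = spec.base_meta() | {"label": label or "composite",
                              "weights": dict(weights),
                              "noisy": bool(spec.poisson_noise)}
    return Spectrum(wn, counts, meta)


@dataclass(frozen=True)
class SeriesRecord:
    thickness_um: float
    replicate: int
    fbr: Spectrum
    initial: Spectrum


@dataclass(frozen=True)
class ThicknessSeries:
    """A generated calibration dataset: paired FBR / day-0 spectra."""

    records: tuple[SeriesRecord, ...]
    spec: GeneratorSpec
    weight_model: WeightModel

    def __len__(self) -> int:
        return len(self.records)

    def thicknesses(self) -> np.ndarray:
        return np.array([r.thickness_um for r in self.records])

    def to_dir(self, path: str | Path) -> Path:
        """Write spectra CSVs + manifest.csv + generator-spec JSON."""
        import json

        import pandas as pd

        from .io import write_spectrum

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, rec in enumerate(self.records):
            fbr_name = f"fbr_t{rec.thickness_um:g}um_r{rec.replicate}.csv"
            ic_name = f"initial_t{rec.thickness_um:g}um_r{rec.replicate}.csv"
            write_spectrum(rec.fbr, path / fbr_name)
            write_spectrum(rec.initial, path / ic_name)
            rows.append({"index": i, "thickness_um": rec.thickness_um,
                         "replicate": rec.replicate, "fbr": fbr_name,
                         "initial": ic_name})
        pd.DataFrame(rows).to_csv(path / "manifest.csv", index=False)
        meta = self.spec.base_meta() | {
            "axis": [self.spec.axis_start, self.spec.axis_stop, self.spec.axis_step],
            "poisson_noise": self.spec.poisson_noise,
            "weight_base": dict(self.weight_model.base),
            "collagen_per_um": self.weight_model.collagen_per_um,
        }
        (path / "generator.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
        return path


def make_thickness_series(spec: GeneratorSpec,
                          thicknesses_um: Sequence[float] = PAPER_THICKNESSES_UM,
                          replicates: int = 2,
                          weight_model: WeightModel | None = None) -> ThicknessSeries:
    """Generate the calibration series: each (thickness, replicate) yields an
    FBR spectrum and its own day-0 partner, with per-item seeds derived from
    the master seed by a counter so the dataset is extensible and exactly
    reproducible."""
    if any(t < 0 for t in thicknesses_um):
        raise ValueError("thicknesses must be nonnegative")
    wm = weight_model or WeightModel()
    records = []
    counter = 0
    for t in thicknesses_um:
        for rep in range(1, replicates + 1):
            rng_fbr = spec.child_rng(counter)
            rng_ic = spec.child_rng(counter + 1)
            counter += 2
            w_fbr = wm.weights_at(t)
            w_ic = wm.weights_at(0.0)
            fbr = make_composite_spectrum(w_fbr, spec, rng_fbr,
                                          label=f"FBR t={t:g}um rep{rep}")
            ic = make_composite_spectrum(w_ic, spec, rng_ic,
                                         label=f"IC t={t:g}um rep{rep}")
            records.append(SeriesRecord(t, rep, fbr, ic))
    return ThicknessSeries(tuple(records), spec, wm)


def expected_snr(spec: GeneratorSpec, weight_model: WeightModel | None = None,
                 thickness_um: float = 100.0) -> SNRResult:
    """Analytic shot-noise SNR of a generated pair from expectations.

    Uses the noise-free references for the band intensities and the weight
    model as the yield table, i.e. the exact expected value of the
    difference-spectrum band SNR at this count scale.
    """
    wm = weight_model or WeightModel()
    noise_free = replace(spec, poisson_noise=False)
    refs = ReferenceIntensities.from_spectra(
        {m: make_reference_spectrum(m, noise_free) for m in spec.band_tables})
    return compute_snr(wm.yield_table_at(thickness_um), refs,
                       thickness_um=thickness_um)


def calibrate_noise_to_snr(spec: GeneratorSpec, target_snr_at_100um: float,
                           weight_model: WeightModel | None = None) -> GeneratorSpec:
    """Rescale the count scale so the expected SNR at t = 100 µm hits a target.

    Shot-noise SNR grows as the square root of the count scale, so the
    calibration is exact: scale' = scale · (target / current)².
    """
    if target_snr_at_100um <= 0:
        raise ValueError("target SNR must be positive")
    wm = weight_model or WeightModel()
    if wm.collagen_per_um <= 0:
        raise ValueError("weight model has no collagen signal; target unreachable")
    current = expected_snr(spec, wm, thickness_um=100.0).snr
    factor = (target_snr_at_100um / current) ** 2
    return replace(spec, count_scale=spec.count_scale * factor)
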