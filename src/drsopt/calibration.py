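"""Experimental spectral-analysis chain: normalization, difference spectra,
PLS thickness calibration, and regression-based limits of detection.

Raw spectra are first normalized so the polystyrene 1004 cm⁻¹ ring-breathing
band spans [0, 1] — an affine per-spectrum transform that removes the
instrument gain and, after differencing FBR against day-0 measurements,
cancels the implant's own bands.  The difference spectra feed either a
single-band estimate (area of the 930 cm⁻¹ collagen band vs. thickness) or a
multivariate PLS calibration of thickness on the full spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import LeaveOneOut

from .snr import DEFAULT_BAND, Spectrum, band_intensities

__all__ = [
    "DEFAULT_NORMALIZATION_WINDOW",
    "normalize_to_polystyrene",
    "difference_spectrum",
    "collagen_band_area",
    "PLSThicknessModel",
    "CalibrationResult",
    "fit_pls",
    "predict_thickness",
    "RegressionLOD",
    "fit_regression_lod",
]

#: Window (cm⁻¹) enclosing the polystyrene 1004 cm⁻¹ band used for min-max
#: normalization.
DEFAULT_NORMALIZATION_WINDOW = (990.0, 1020.0)


class NormalizationError(ValueError):
    pass


def normalize_to_polystyrene(spectrum: Spectrum,
                             window: tuple[float, float] = DEFAULT_NORMALIZATION_WINDOW
                             ) -> Spectrum:
    """Min-max normalize a spectrum on the polystyrene 1004 cm⁻¹ window.

    The whole spectrum is mapped by the affine transform that sends the
    window's minimum to 0 and maximum to 1, making spectra from different
    acquisitions comparable and implant bands cancellable by subtraction.
    """
    mask = spectrum.band_slice(window)
    w = spectrum.counts[mask]
    lo, hi = float(w.min()), float(w.max())
    if hi <= lo:
        raise NormalizationError("normalization window is flat; no 1004 cm⁻¹ band")
    return spectrum.copy_with((spectrum.counts - lo) / (hi - lo),
                              normalized=f"minmax{window}")


def difference_spectrum(fbr: Spectrum, initial: Spectrum) -> Spectrum:
    """FBR minus day-0 spectrum on a shared axis (no resampling)."""
    if not np.array_equal(fbr.wavenumbers, initial.wavenumbers):
        raise ValueError("spectra must share an identical wavenumber axis")
    return fbr.copy_with(fbr.counts - initial.counts,
                         difference_of=(fbr.meta.get("label"), initial.meta.get("label")))


def collagen_band_area(diff: Spectrum,
                       band: tuple[float, float] = DEFAULT_BAND,
                       edge_channels: int = 3) -> float:
    """Baseline-subtracted area of the collagen band in a difference spectrum."""
    i_raman, _ = band_intensities(diff, band, edge_channels)
    return i_raman


# ---------------------------------------------------------------------------
# PLS calibration


@dataclass
class CalibrationResult:
    """Fitted PLS thickness calibration with its cross-validation diagnostics."""

    model: "PLSThicknessModel"
    n_components: int
    loo_rmse_um: float
    loo_predictions_um: np.ndarray
    component_rmse_um: dict[int, float]

    def predict(self, spectra: Sequence[Spectrum]) -> np.ndarray:
        X = self.model._design(spectra)
        return self.model._pls.predict(X).ravel()

    def summary(self) -> str:
        lines = [
            "PLS thickness calibration",
            "=" * 41,
            f"training spectra        {len(self.model.thicknesses_um):>6d}",
            f"channels                {len(self.model.wavenumbers):>6d}",
            f"components (LOO-best)   {self.n_components:>6d}",
            f"LOO-CV RMSE             {self.loo_rmse_um:>9.2f} um",
            "-" * 41,
            "components  LOO RMSE (um)",
        ]
        for k, r in sorted(self.component_rmse_um.items()):
            marker = " *" if k == self.n_components else ""
            lines.append(f"{k:>10d}  {r:>12.3f}{marker}")
        return "\n".join(lines)


class PLSThicknessModel:
    """PLS regression from difference spectra to collagen-cap thickness.

    The component count is chosen by minimum leave-one-out RMSE up to
    ``max_components`` (capped by sample and channel counts), ties broken
    toward fewer components.  Spectra are mean-centred by the underlying
    PLS; channels are not variance-scaled (spectral channels share units).
    """

    def __init__(self, spectra: Sequence[Spectrum], thicknesses_um: Sequence[float],
                 max_components: int = 8):
        if len(spectra) != len(thicknesses_um):
            raise ValueError("one thickness per spectrum required")
        if len(spectra) < 4:
            raise ValueError("need at least 4 training pairs")
        t = np.asarray(thicknesses_um, dtype=float)
        if np.allclose(t, t[0]):
            raise ValueError("degenerate response: all thicknesses equal")
        self.wavenumbers = spectra[0].wavenumbers
        for s in spectra[1:]:
            if not np.array_equal(s.wavenumbers, self.wavenumbers):
                raise ValueError("training spectra must share one axis")
        self.X = np.vstack([s.counts for s in spectra])
        self.thicknesses_um = t
        self.max_components = max_components
        self._pls: PLSRegression | None = None

    def _design(self, spectra: Sequence[Spectrum]) -> np.ndarray:
        for s in spectra:
            if not np.array_equal(s.wavenumbers, self.wavenumbers):
                raise ValueError("test spectra must match the training axis")
        return np.vstack([s.counts for s in spectra])

    @staticmethod
    def _fit_one(X, y, k: int) -> PLSRegression:
        import warnings

        pls = PLSRegression(n_components=k, scale=False)
        with warnings.catch_warnings():
            # rank-deficient (e.g. noise-free) data exhausts the y residual
            # before k components; the fit is still exact
            warnings.filterwarnings("ignore", message="y residual is constant")
            pls.fit(X, y)
        return pls

    def _loo_rmse(self, k: int) -> tuple[float, np.ndarray]:
        preds = np.empty(len(self.thicknesses_um))
        for train, test in LeaveOneOut().split(self.X):
            pls = self._fit_one(self.X[train], self.thicknesses_um[train], k)
            preds[test] = pls.predict(self.X[test]).ravel()
        rmse = float(np.sqrt(np.mean((preds - self.thicknesses_um) ** 2)))
        return rmse, preds

    def fit(self, n_components: int | None = None) -> CalibrationResult:
        cap = min(self.max_components, len(self.thicknesses_um) - 1,
                  self.X.shape[1])
        per_k: dict[int, float] = {}
        preds_by_k: dict[int, np.ndarray] = {}
        ks = [n_components] if n_components is not None else range(1, cap + 1)
        for k in ks:
            per_k[k], preds_by_k[k] = self._loo_rmse(k)
        best = min(per_k, key=lambda k: (per_k[k], k))
        self._pls = self._fit_one(self.X, self.thicknesses_um, best)
        return CalibrationResult(model=self, n_components=best,
                                 loo_rmse_um=per_k[best],
                                 loo_predictions_um=preds_by_k[best],
                                 component_rmse_um=per_k)


def fit_pls(training: Sequence[tuple[Spectrum, float]],
            max_components: int = 8,
            n_components: int | None = None) -> CalibrationResult:
    """Fit the PLS thickness calibration on (difference spectrum, µm) pairs."""
    spectra = [s for s, _ in training]
    thick = [t for _, t in training]
    return PLSThicknessModel(spectra, thick, max_components).fit(n_components)


def predict_thickness(result: CalibrationResult, test: Sequence[Spectrum],
                      true_thicknesses_um: Sequence[float] | None = None
                      ) -> tuple[np.ndarray, float | None]:
    """Predict thicknesses for test difference spectra; RMSE if truths given."""
    preds = result.predict(test)
    if true_thicknesses_um is None:
        return preds, None
    truth = np.asarray(true_thicknesses_um, dtype=float)
    rmse = float(np.sqrt(np.mean((preds - truth) ** 2)))
    return preds, rmse


def save_calibration(result: CalibrationResult, path) -> None:
    """Persist a fitted calibration as a portable JSON archive.

    Stores the linear predictor (mean spectrum, coefficient vector,
    response mean) plus the axis and diagnostics — enough to predict on new
    spectra without refitting.
    """
    import json
    from pathlib import Path

    pls = result.model._pls
    payload = {
        "format": "drsopt-pls-calibration/1",
        "n_components": result.n_components,
        "loo_rmse_um": result.loo_rmse_um,
        "wavenumbers": result.model.wavenumbers.tolist(),
        "x_mean": pls._x_mean.tolist(),
        "coef": pls.coef_.ravel().tolist(),
        "y_mean": float(np.ravel(pls.intercept_)[0]),
    }
    Path(path).write_text(json.dumps(payload))


@dataclass(frozen=True)
class LoadedCalibration:
    """A calibration archive reloaded for prediction only."""

    wavenumbers: np.ndarray
    x_mean: np.ndarray
    coef: np.ndarray
    y_mean: float
    n_components: int
    loo_rmse_um: float

    def predict(self, spectra: Sequence[Spectrum]) -> np.ndarray:
        X = np.vstack([s.counts for s in spectra])
        for s in spectra:
            if not np.array_equal(s.wavenumbers, self.wavenumbers):
                raise ValueError("spectrum axis does not match the calibration")
        return (X - self.x_mean) @ self.coef + self.y_mean


def load_calibration(path) -> LoadedCalibration:
    import json
    from pathlib import Path

    d = json.loads(Path(path).read_text())
    if d.get("format") != "drsopt-pls-calibration/1":
        raise ValueError("not a drsopt calibration archive")
    return LoadedCalibration(
        wavenumbers=np.asarray(d["wavenumbers"]),
        x_mean=np.asarray(d["x_mean"]),
        coef=np.asarray(d["coef"]),
        y_mean=float(d["y_mean"]),
        n_components=int(d["n_components"]),
        loo_rmse_um=float(d["loo_rmse_um"]),
    )


# ---------------------------------------------------------------------------
# single-band regression LOD (the cadaver-style analysis)


@dataclass(frozen=True)
class RegressionLOD:
    """OLS of band area against thickness and the detection limits it implies.

    ``t_lod_um`` converts the residual scatter into a thickness at the
    one-sided detection criterion, ``criterion · RMSE_residual / |slope|``.
    ``t_lod_unit_um`` is the same quantity at criterion 1, reported alongside
    because the ratio RMSE/|slope| is itself sometimes quoted as a detection
    limit.
    """

    slope: float
    intercept: float
    r_squared: float
    residual_rmse: float
    criterion: float

    @property
    def t_lod_um(self) -> float:
        return self.criterion * self.residual_rmse / abs(self.slope)

    @property
    def t_lod_unit_um(self) -> float:
        return self.residual_rmse / abs(self.slope)


def fit_regression_lod(pairs: Sequence[tuple[float, float]],
                       criterion: float = 1.645) -> RegressionLOD:
    """Fit band area vs. thickness by OLS and derive the regression LOD.

    ``pairs`` are (band area, thickness µm).  Raises when fewer than three
    pairs, no thickness spread, or a zero slope make the LOD undefined.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 (area, thickness) pairs")
    area = np.asarray([a for a, _ in pairs], dtype=float)
    thick = np.asarray([t for _, t in pairs], dtype=float)
    if np.allclose(thick, thick[0]):
        raise ValueError("no thickness spread")
    fit = stats.linregress(thick, area)
    if fit.slope == 0:
        raise ValueError("zero slope: LOD undefined")
    resid = area - (fit.intercept + fit.slope * thick)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return RegressionLOD(slope=float(fit.slope), intercept=float(fit.intercept),
                         r_squared=float(fit.rvalue**2), residual_rmse=rmse,
                         criterion=criterion)
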