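"""Constrained source/detector geometry search over the surface grid.

For a fixed source pattern the detector space is the 21 × 21 grid of point
detectors spanning ±5 mm (0.5 mm pitch, 441 positions) centred over the
implant.  One diffusion-system factorization is shared by the excitation
solve and all 441 adjoint detector solves, which keeps a full SNR-surface
sweep cheap.  Extended collection areas (rectangles, fiber arrays) combine
their member points with additive signal and quadrature shot noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .patterns import (
    MPE_SKIN_MW_MM2,
    SurfacePattern,
    line_source,
    mpe_check,
    point_detector,
    point_source,
    rectangle_detector,
)
from .phantom import MATERIALS, Discretization
from .snr import ReferenceIntensities, SNRResult, combine_detectors, lod_from_snr
from .transport import DiffusionSolver, FluenceField, reflection_factor

__all__ = [
    "GridSpec",
    "SNRSurface",
    "RankedConfiguration",
    "GeometryOptimizer",
    "interpolation_matrix",
]


@dataclass(frozen=True)
class GridSpec:
    """The 21 × 21 detector/excitation grid, −5 to +5 mm per axis."""

    n_per_axis: int = 21
    half_extent: float = 5.0

    @property
    def pitch(self) -> float:
        return 2 * self.half_extent / (self.n_per_axis - 1)

    def axis(self) -> np.ndarray:
        return np.linspace(-self.half_extent, self.half_extent, self.n_per_axis)

    def positions(self) -> np.ndarray:
        """(n², 2) grid positions, x-major order."""
        ax = self.axis()
        X, Y = np.meshgrid(ax, ax, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel()])

    @property
    def n_positions(self) -> int:
        return self.n_per_axis**2


@dataclass
class SNRSurface:
    """Per-detector SNR over the grid for one fixed source pattern."""

    grid: GridSpec
    source: SurfacePattern
    snr: np.ndarray  # (n, n), x-major
    signal: np.ndarray
    noise: np.ndarray
    thickness_um: float
    criterion: float

    @property
    def max_snr(self) -> float:
        return float(self.snr.max())

    @property
    def argmax_position(self) -> tuple[float, float]:
        i, j = np.unravel_index(int(np.argmax(self.snr)), self.snr.shape)
        ax = self.grid.axis()
        return float(ax[i]), float(ax[j])

    @property
    def argmax_offset(self) -> float:
        """Radial offset of the SNR maximum from the surface centre (mm)."""
        x, y = self.argmax_position
        return float(np.hypot(x, y))

    def result_at(self, x: float, y: float) -> SNRResult:
        ax = self.grid.axis()
        i = int(np.argmin(np.abs(ax - x)))
        j = int(np.argmin(np.abs(ax - y)))
        if abs(ax[i] - x) > 1e-9 or abs(ax[j] - y) > 1e-9:
            raise ValueError(f"({x}, {y}) is not a grid position")
        return SNRResult(snr=float(self.snr[i, j]), signal=float(self.signal[i, j]),
                         noise=float(self.noise[i, j]), thickness_um=self.thickness_um,
                         criterion=self.criterion)

    def to_frame(self):
        """Dense CSV-friendly matrix with axis header row/column."""
        import pandas as pd

        ax = self.grid.axis()
        return pd.DataFrame(self.snr, index=ax, columns=ax)


@dataclass(frozen=True)
class RankedConfiguration:
    """One candidate geometry with its figure of merit."""

    name: str
    source: SurfacePattern
    detectors: tuple[SurfacePattern, ...]
    result: SNRResult
    mpe_pass: bool
    mpe_margin: float
    disjoint: bool

    @property
    def feasible(self) -> bool:
        return self.mpe_pass and self.disjoint

    @property
    def t_lod_um(self) -> float:
        return lod_from_snr(self.result.snr, self.result.thickness_um,
                            self.result.criterion, rounded=False)

    @property
    def detector_area(self) -> float:
        return float(sum(d.area for d in self.detectors))


def interpolation_matrix(disc: Discretization, points: np.ndarray) -> sp.csr_matrix:
    """Sparse trilinear interpolation operator from the node grid to points."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    npts = len(points)
    nx, ny, nz = disc.shape
    axes = (disc.xs, disc.ys, disc.zs)
    idx = np.empty((npts, 3), dtype=np.intp)
    frac = np.empty((npts, 3))
    for d, ax in enumerate(axes):
        i = np.clip(np.searchsorted(ax, points[:, d]) - 1, 0, len(ax) - 2)
        idx[:, d] = i
        frac[:, d] = np.clip((points[:, d] - ax[i]) / (ax[i + 1] - ax[i]), 0.0, 1.0)

    rows, cols, vals = [], [], []
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (np.where(dx, frac[:, 0], 1 - frac[:, 0])
                     * np.where(dy, frac[:, 1], 1 - frac[:, 1])
                     * np.where(dz, frac[:, 2], 1 - frac[:, 2]))
                node = ((idx[:, 0] + dx) * ny + idx[:, 1] + dy) * nz + idx[:, 2] + dz
                rows.append(np.arange(npts))
                cols.append(node)
                vals.append(w)
    return sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(npts, nx * ny * nz),
    )


class GeometryOptimizer:
    """SNR-surface evaluation and constrained geometry ranking.

    Parameters
    ----------
    solver : DiffusionSolver
        Transport solver on the phantom discretization (factorization reused
        across the whole sweep).
    refs : ReferenceIntensities
        Collagen-band intensities of the five material reference spectra.
    grid : GridSpec
        Detector grid (default: the 21 × 21 / ±5 mm specification).
    detector_area : float
        Collection area of one point detector in mm² (0.1 × 0.1 mm²).
    thickness_um : float
        Collagen-cap thickness of the modelled FBR sample (SNR₁₀₀ uses 100).
    """

    def __init__(self, solver: DiffusionSolver, refs: ReferenceIntensities,
                 grid: GridSpec | None = None, detector_area: float = 0.01,
                 thickness_um: float = 100.0, criterion: float = 1.645):
        self.solver = solver
        self.refs = refs
        self.grid = grid or GridSpec()
        self.detector_area = detector_area
        self.thickness_um = thickness_um
        self.criterion = criterion
        self._sens_cache: np.ndarray | None = None  # (n_nodes, n_positions)
        self._fine = None

    # -- shared pieces ----------------------------------------------------

    def _fine_grid(self):
        if self._fine is None:
            pts, vol = self.solver.disc.collagen_subgrid(self.thickness_um)
            P = interpolation_matrix(self.solver.disc, pts) if len(pts) else None
            self._fine = (P, vol)
        return self._fine

    def _measurement_matrix(self, positions: np.ndarray) -> sp.csc_matrix:
        disc = self.solver.disc
        table = self.solver.optics.band("emission")
        cols = []
        for k, (x, y) in enumerate(positions):
            mat = disc.phantom.material_at(x, y, 0.0).item()
            aref = reflection_factor(table[mat].n)
            vec = self.solver._trilinear_vector(x, y, 0.0) * (self.detector_area / (2 * aref))
            cols.append(sp.csc_matrix(vec[:, None]))
        return sp.hstack(cols).tocsc()

    def _sensitivity_sweep(self) -> np.ndarray:
        """Adjoint fields for every grid detector (cached; one factorization)."""
        if self._sens_cache is None:
            M = self._measurement_matrix(self.grid.positions())
            out = np.empty((self.solver.disc.n_nodes, M.shape[1]))
            for lo in range(0, M.shape[1], 64):
                hi = min(lo + 64, M.shape[1])
                out[:, lo:hi] = self.solver.solve(M[:, lo:hi].toarray(), "emission")
            self._sens_cache = out
        return self._sens_cache

    def _per_detector_results(self, exc: FluenceField,
                              sens: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(signal, noise) per detector column from one excitation field."""
        disc = self.solver.disc
        volumes = self.solver.cell_volumes()
        refs = self.refs
        yields = {}
        for m in MATERIALS:
            if m == "collagen":
                continue
            w = exc.values * volumes * (disc.labels == m)
            yields[m] = w @ sens
        P, vol = self._fine_grid()
        if P is not None:
            exc_fine = P @ exc.values
            yields["collagen"] = vol * (exc_fine @ (P @ sens))
        else:
            yields["collagen"] = np.zeros(sens.shape[1])

        signal = yields["collagen"] * refs.raman["collagen"]
        total = yields["collagen"] * refs.raw["collagen"]
        for m in MATERIALS:
            if m == "collagen":
                continue
            total = total + 2.0 * yields[m] * refs.raw[m]  # FBR + day-0 samples
        noise = np.sqrt(total)
        return signal, noise

    # -- operations -------------------------------------------------------

    def snr_surface(self, source: SurfacePattern) -> SNRSurface:
        """Eq.-1 SNR at every grid point detector for a fixed source."""
        exc = self.solver.fluence(source)
        sens = self._sensitivity_sweep()
        signal, noise = self._per_detector_results(exc, sens)
        n = self.grid.n_per_axis
        return SNRSurface(grid=self.grid, source=source,
                          snr=(signal / noise).reshape(n, n),
                          signal=signal.reshape(n, n), noise=noise.reshape(n, n),
                          thickness_um=self.thickness_um, criterion=self.criterion)

    def integrate_detector_area(self, surface: SNRSurface,
                                rect: SurfacePattern) -> SNRResult:
        """Combine the grid points inside a rectangular collection area."""
        cx, cy = rect.center
        pos = self.grid.positions()
        eps = 1e-9
        inside = ((np.abs(pos[:, 0] - cx) <= rect.width / 2 + eps)
                  & (np.abs(pos[:, 1] - cy) <= rect.length / 2 + eps))
        if not inside.any():
            raise ValueError("rectangle contains no grid points")
        parts = list(zip(surface.signal.ravel()[inside], surface.noise.ravel()[inside]))
        combined = combine_detectors(parts)
        return replace(combined, thickness_um=self.thickness_um, criterion=self.criterion)

    def fiber_subset_snr(self, source: SurfacePattern, offset_mm: float = 1.5,
                         n_fibers: int = 7,
                         span: tuple[float, float] = (-0.5, 0.5)) -> SNRResult:
        """SNR of a linear fiber-bundle footprint at a lateral offset.

        The bundle images ``n_fibers`` collection points spaced evenly over
        ``span`` (mm along y) at ``x = offset_mm``; signals add, shot noise
        combines in quadrature (each fiber is an independent channel summed
        on the CCD).
        """
        ys = np.linspace(span[0], span[1], n_fibers)
        points = np.column_stack([np.full(n_fibers, offset_mm), ys])
        exc = self.solver.fluence(source)
        M = self._measurement_matrix(points)
        sens = self.solver.solve(M.toarray(), "emission")
        signal, noise = self._per_detector_results(exc, sens)
        combined = combine_detectors(list(zip(signal, noise)))
        return replace(combined, thickness_um=self.thickness_um, criterion=self.criterion)

    def optimize(self, candidates: list[tuple[str, SurfacePattern, tuple[SurfacePattern, ...]]]
                 | None = None,
                 mpe: float = MPE_SKIN_MW_MM2,
                 top_k: int | None = None) -> list[RankedConfiguration]:
        """Evaluate a candidate family and rank feasible geometries by SNR.

        The default family covers the study's presets: the centred point
        source with its best single point detector, and the 10 × 2 mm line
        source with a parallel collection rectangle (offset sweep, 0.5 mm
        steps), its symmetric pair, and the 7-fiber bundle footprint.
        Candidates violating the MPE or source/detector disjointness are kept
        in the ranking but flagged infeasible; feasible ones rank first,
        descending SNR, ties broken by smaller collection area then name.
        """
        if candidates is None:
            candidates = self.default_candidates()

        surfaces: dict[int, SNRSurface] = {}
        ranked: list[RankedConfiguration] = []
        for name, source, detectors in candidates:
            key = id(source)
            if key not in surfaces:
                surfaces[key] = self.snr_surface(source)
            surface = surfaces[key]
            parts = []
            for det in detectors:
                if det.shape == "rectangle" and det.area > 2 * self.detector_area:
                    parts.append(self.integrate_detector_area(surface, det))
                else:
                    parts.append(surface.result_at(*det.center))
            result = combine_detectors(parts)
            passes, margin = mpe_check(source, mpe)
            disjoint = all(source.disjoint_from(d) for d in detectors)
            ranked.append(RankedConfiguration(
                name=name, source=source, detectors=tuple(detectors),
                result=result, mpe_pass=passes, mpe_margin=margin,
                disjoint=disjoint))

        ranked.sort(key=lambda c: (not c.feasible, -c.result.snr,
                                   c.detector_area, c.name))
        if not any(c.feasible for c in ranked):
            raise RuntimeError("no feasible configuration in the candidate set")
        return ranked[:top_k] if top_k else ranked

    def default_candidates(self):
        """The preset candidate family (see :meth:`optimize`)."""
        cands = []
        src_pt = point_source((0.0, 0.0))
        surface = self.snr_surface(src_pt)
        # best single point detector disjoint from the excitation spot
        pos = self.grid.positions()
        snr_flat = surface.snr.ravel()
        order = np.argsort(-snr_flat)
        for k in order:
            det = point_detector(tuple(pos[k]))
            if src_pt.disjoint_from(det):
                cands.append(("point-point", src_pt, (det,)))
                break

        src_line = line_source((0.0, 0.0), length=10.0, width=2.0)
        offsets = [1.5, 2.0, 2.5, 3.0, 3.5]
        for off in offsets:
            rect = rectangle_detector((off, 0.0), length=10.0, width=2.0)
            cands.append((f"line-rect(+{off:g})", src_line, (rect,)))
            pair = (rect, rectangle_detector((-off, 0.0), length=10.0, width=2.0))
            cands.append((f"line-rect-pair(±{off:g})", src_line, pair))
        return cands
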