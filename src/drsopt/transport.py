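"""Diffuse photon transport on the phantom and Raman yield computation.

Steady-state diffusion approximation, ``-∇·(κ∇φ) + µa φ = q`` with
``κ = 1/(3(µa + µs'))``, discretized by a node-centred finite-volume scheme
on the structured grid of :class:`~drsopt.phantom.Discretization`.  Boundary
faces carry the Robin (partial-current) condition ``κ ∂φ/∂n = -φ/(2A)`` with
the internal-reflection factor ``A`` derived from the refractive-index
mismatch.  Collimated beams are represented as isotropic sources buried one
transport mean free path (``1/µs'``) below the illuminated surface.

Raman emission is treated in the Born (single-conversion) approximation: an
isotropic emitter per node with strength proportional to the excitation
fluence, so the detected yield for a material is the volume integral of
excitation × detection-sensitivity over that material's region.  For the
micron-scale collagen slab the integral runs on the refined cell-centred
sub-grid with trilinearly interpolated fields.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .phantom import MATERIALS, Discretization

__all__ = [
    "MaterialOptics",
    "OpticalProperties",
    "default_optics",
    "FluenceField",
    "RamanYieldTable",
    "DiffusionSolver",
    "solve_fluence",
    "detector_sensitivity",
    "raman_yield",
    "yield_table",
]


@dataclass(frozen=True)
class MaterialOptics:
    """Absorption/reduced-scattering (mm⁻¹) and refractive index of one material."""

    mua: float
    musp: float
    n: float = 1.4

    def __post_init__(self) -> None:
        if self.mua <= 0 or self.musp <= 0:
            raise ValueError("mua and musp must be positive")
        if self.n < 1:
            raise ValueError("refractive index must be >= 1")

    @property
    def kappa(self) -> float:
        """Diffusion coefficient 1/(3(µa + µs')) in mm."""
        return 1.0 / (3.0 * (self.mua + self.musp))

    @property
    def mu_eff(self) -> float:
        """Effective attenuation sqrt(µa/κ) in mm⁻¹."""
        return float(np.sqrt(self.mua / self.kappa))


def reflection_factor(n_rel: float) -> float:
    """Internal-reflection A-factor for a tissue/air index ratio.

    Uses the Groenhuis polynomial fit for the effective reflectance
    R_eff(n_rel) and returns A = (1 + R_eff)/(1 - R_eff).
    """
    r_eff = -1.440 / n_rel**2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel
    r_eff = min(max(r_eff, 0.0), 0.999)
    return (1.0 + r_eff) / (1.0 - r_eff)


class OpticalProperties:
    """Per-material, per-band optical properties.

    ``bands`` maps a band tag (``"excitation"``, ``"emission"``) to a
    ``{material: MaterialOptics}`` table.  A missing emission band falls back
    to the excitation values (the default: the Raman shift at 785 nm moves
    the emission into a spectrally similar window).
    """

    def __init__(self, excitation: Mapping[str, MaterialOptics],
                 emission: Mapping[str, MaterialOptics] | None = None):
        self._bands = {
            "excitation": dict(excitation),
            "emission": dict(emission) if emission is not None else dict(excitation),
        }

    def band(self, tag: str) -> dict[str, MaterialOptics]:
        if tag not in self._bands:
            raise KeyError(f"unknown band {tag!r}; expected 'excitation' or 'emission'")
        return self._bands[tag]

    def for_materials(self, tag: str, materials: Iterable[str]) -> dict[str, MaterialOptics]:
        table = self.band(tag)
        missing = [m for m in materials if m not in table]
        if missing:
            raise KeyError(f"no optical properties for material(s): {missing}")
        return {m: table[m] for m in materials}

    @classmethod
    def from_dict(cls, d: Mapping) -> "OpticalProperties":
        """Build from nested plain dicts, e.g. parsed YAML/JSON."""
        def parse(band: Mapping) -> dict[str, MaterialOptics]:
            return {m: MaterialOptics(**v) for m, v in band.items()}

        if "excitation" in d:
            em = parse(d["emission"]) if "emission" in d else None
            return cls(parse(d["excitation"]), em)
        return cls(parse(d))


def default_optics() -> OpticalProperties:
    """Literature-style 785 nm defaults for the phantom materials.

    The source study does not publish its optical properties; these values
    are representative of skin, subcutaneous fat and muscle at 785 nm, with
    polystyrene as a low-absorption scatterer and the hydrated collagen cap
    taken optically equal to skin.  All downstream geometry conclusions are
    property-level (symmetries, trends), not absolute-value claims.
    """
    table = {
        "skin": MaterialOptics(mua=0.02, musp=1.6, n=1.4),
        "fat": MaterialOptics(mua=0.01, musp=1.0, n=1.44),
        "muscle": MaterialOptics(mua=0.03, musp=0.7, n=1.37),
        "polystyrene": MaterialOptics(mua=0.002, musp=2.0, n=1.59),
        "collagen": MaterialOptics(mua=0.02, musp=1.6, n=1.4),
    }
    return OpticalProperties(table)


@dataclass(frozen=True)
class FluenceField:
    """A nodal field on the solver grid (excitation fluence or adjoint sensitivity)."""

    disc: Discretization
    values: np.ndarray  # flattened, C order over (ix, iy, iz)
    band: str
    pattern: object = None

    def grid(self) -> np.ndarray:
        return self.values.reshape(self.disc.shape)

    def at(self, points: np.ndarray, method: str = "linear") -> np.ndarray:
        """Interpolate the field at (n, 3) points in mm.

        ``linear`` (trilinear) is used for volume integrals; ``cubic`` is a
        higher-order probe for point evaluations of the smooth field.
        """
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator(
            (self.disc.xs, self.disc.ys, self.disc.zs), self.grid(),
            method=method, bounds_error=False, fill_value=0.0)
        return interp(points)


class RamanYieldTable:
    """Detected Raman photon yields keyed by (sample, material).

    ``table[sample][material]`` is the detected Raman yield per launched
    excitation photon per unit conversion efficiency, for one fixed
    source/detector pattern pair.  Materials absent from a sample are
    reported as 0.
    """

    def __init__(self, entries: Mapping[str, Mapping[str, float]],
                 source=None, detector=None):
        self._entries = {s: dict(m) for s, m in entries.items()}
        self.source = source
        self.detector = detector
        for sample, mats in self._entries.items():
            for mat, val in mats.items():
                if val < -1e-15:
                    raise ValueError(f"negative yield for {sample}/{mat}: {val}")

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self._entries)

    def materials(self, sample: str) -> tuple[str, ...]:
        return tuple(self._entries[sample])

    def get(self, sample: str, material: str) -> float:
        return self._entries[sample].get(material, 0.0)

    def items(self, sample: str):
        return self._entries[sample].items()

    def to_frame(self):
        import pandas as pd

        rows = [
            {"sample": s, "material": m, "yield": v}
            for s, mats in self._entries.items()
            for m, v in mats.items()
        ]
        return pd.DataFrame(rows)


class SolverError(RuntimeError):
    pass


class DiffusionSolver:
    """Finite-volume diffusion solver with a cached sparse LU factorization.

    One factorization per wavelength band serves every right-hand side of a
    geometry sweep (sources and all adjoint detector solves), which is what
    makes the 441-point detector sweeps cheap.
    """

    def __init__(self, disc: Discretization, optics: OpticalProperties,
                 boundary_model: str = "extrapolated", method: str = "direct"):
        if boundary_model not in ("extrapolated", "robin"):
            raise ValueError("boundary_model must be 'extrapolated' or 'robin'")
        if method not in ("direct", "cg"):
            raise ValueError("method must be 'direct' or 'cg'")
        self.disc = disc
        self.optics = optics
        self.boundary_model = boundary_model
        self.method = method
        self._K: dict[str, sp.csc_matrix] = {}
        self._lu: dict[str, object] = {}
        self._cell_volumes: np.ndarray | None = None
        materials = set(disc.labels.tolist())
        for band in ("excitation", "emission"):
            optics.for_materials(band, materials)
        self._n_ghost = self._ghost_planes()

    def _surface_zb(self, band: str) -> np.ndarray:
        """Extrapolation length 2Aκ per surface column (nx, ny), in mm."""
        nx, ny, nz = self.disc.shape
        table = self.optics.band(band)
        surf = self.disc.labels.reshape(nx, ny, nz)[:, :, 0]
        zb = np.empty((nx, ny))
        for mat in np.unique(surf):
            mo = table[mat]
            zb[surf == mat] = 2.0 * reflection_factor(mo.n) * mo.kappa
        return zb

    def _ghost_planes(self) -> int:
        """Fictitious planes above the surface for the extrapolated boundary.

        The zero-fluence plane sits at z = -zb; ghost planes extend the
        surface material upward at the grid spacing and the top plane links
        to the zero plane through the residual gap (kept ≥ 0.2 h for a
        well-conditioned link).  With no ghost planes the scheme degenerates
        to the plain Robin flux φ/(2A).
        """
        if self.boundary_model == "robin":
            return 0
        hz = self.disc.spacing[2]
        zb_min = float(self._surface_zb("excitation").min())
        return max(0, int(np.floor(zb_min / hz - 0.2)))

    # -- assembly ---------------------------------------------------------

    @property
    def ext_shape(self) -> tuple[int, int, int]:
        nx, ny, nz = self.disc.shape
        return nx, ny, nz + self._n_ghost

    def _node_optics(self, band: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(µa, κ, A) per node of the extended grid, shaped (nx, ny, nz_ext).

        Ghost planes extend the surface column's material upward.
        """
        table = self.optics.band(band)
        mua = np.empty(len(MATERIALS))
        kap = np.empty(len(MATERIALS))
        aref = np.empty(len(MATERIALS))
        for i, m in enumerate(MATERIALS):
            if m in table:
                mo = table[m]
                mua[i], kap[i], aref[i] = mo.mua, mo.kappa, reflection_factor(mo.n)
            else:
                mua[i] = kap[i] = aref[i] = np.nan
        nx, ny, nz = self.disc.shape
        idx = self.disc.material_indices().reshape(nx, ny, nz)
        if self._n_ghost:
            ghost = np.repeat(idx[:, :, :1], self._n_ghost, axis=2)
            idx = np.concatenate([ghost, idx], axis=2)
        return mua[idx], kap[idx], aref[idx]

    def cell_volumes(self) -> np.ndarray:
        """Finite-volume cell volume per node (halved on boundary planes)."""
        if self._cell_volumes is None:
            nx, ny, nz = self.disc.shape
            hx, hy, hz = self.disc.spacing

            def w(n):
                a = np.ones(n)
                a[0] = a[-1] = 0.5
                return a

            W = w(nx)[:, None, None] * w(ny)[None, :, None] * w(nz)[None, None, :]
            self._cell_volumes = (W * hx * hy * hz).ravel()
        return self._cell_volumes

    def _assemble(self, band: str) -> sp.csc_matrix:
        nx, ny, nze = self.ext_shape
        hx, hy, hz = self.disc.spacing
        mua, kappa, aref = self._node_optics(band)

        def w(n):
            a = np.ones(n)
            a[0] = a[-1] = 0.5
            return a

        wx, wy, wz = w(nx), w(ny), w(nze)
        idx = np.arange(nx * ny * nze).reshape(nx, ny, nze)

        rows, cols, vals = [], [], []
        diag = mua * (wx[:, None, None] * wy[None, :, None] * wz[None, None, :]) * hx * hy * hz

        # interior face conductances, harmonic-mean kappa
        def faces(axis, h_along, trans_area):
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[axis] = slice(0, -1)
            sl_hi[axis] = slice(1, None)
            k1, k2 = kappa[tuple(sl_lo)], kappa[tuple(sl_hi)]
            kh = 2.0 * k1 * k2 / (k1 + k2)
            cond = kh * trans_area / h_along
            i, j = idx[tuple(sl_lo)].ravel(), idx[tuple(sl_hi)].ravel()
            c = cond.ravel()
            rows.extend([i, j, i, j])
            cols.extend([j, i, i, j])
            vals.extend([-c, -c, c, c])

        faces(0, hx, (wy[None, :, None] * wz[None, None, :] * hy * hz) * np.ones((nx - 1, 1, 1)))
        faces(1, hy, (wx[:, None, None] * wz[None, None, :] * hx * hz) * np.ones((1, ny - 1, 1)))
        faces(2, hz, (wx[:, None, None] * wy[None, :, None] * hx * hy) * np.ones((1, 1, nze - 1)))

        # Robin outflux phi/(2A) on the lateral and bottom faces; the top
        # face either carries Robin too ("robin" model) or links through the
        # residual gap to the zero-fluence extrapolation plane at z = -zb.
        extra = np.zeros((nx, ny, nze))
        for axis, (ht1, ht2, wt1, wt2) in (
            (0, (hy, hz, wy[:, None], wz[None, :])),
            (1, (hx, hz, wx[:, None], wz[None, :])),
            (2, (hx, hy, wx[:, None], wy[None, :])),
        ):
            area = ht1 * ht2 * wt1 * wt2
            for side in (0, -1):
                if axis == 2 and side == 0 and self.boundary_model == "extrapolated":
                    continue
                sl = [slice(None)] * 3
                sl[axis] = side
                extra[tuple(sl)] += area / (2.0 * aref[tuple(sl)])

        if self.boundary_model == "extrapolated":
            zb = self._surface_zb(band)
            gap = np.maximum(zb - self._n_ghost * hz, 0.2 * hz)
            area_xy = hx * hy * wx[:, None] * wy[None, :]
            extra[:, :, 0] += kappa[:, :, 0] * area_xy / gap

        rows.append(idx.ravel())
        cols.append(idx.ravel())
        vals.append((diag + extra).ravel())

        n = nx * ny * nze
        K = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        ).tocsc()
        return K

    # -- extended-grid embedding ------------------------------------------

    def _embed(self, rhs: np.ndarray) -> np.ndarray:
        """Physical-node RHS → extended grid (ghost planes carry no source)."""
        if self._n_ghost == 0:
            return rhs
        nx, ny, nz = self.disc.shape
        cols = rhs.reshape(nx, ny, nz, -1)
        ext = np.zeros((nx, ny, nz + self._n_ghost) + cols.shape[3:])
        ext[:, :, self._n_ghost:] = cols
        return ext.reshape(-1, *rhs.shape[1:]) if rhs.ndim > 1 else ext.ravel()

    def _restrict(self, sol: np.ndarray) -> np.ndarray:
        if self._n_ghost == 0:
            return sol
        nx, ny, nz = self.disc.shape
        ext = sol.reshape(nx, ny, nz + self._n_ghost, -1)
        phys = ext[:, :, self._n_ghost:]
        return (phys.reshape(-1, sol.shape[1]) if sol.ndim > 1
                else phys.ravel().copy())

    def matrix(self, band: str) -> sp.csc_matrix:
        if band not in self._K:
            other = "emission" if band == "excitation" else "excitation"
            if other in self._K and self.optics.band(band) == self.optics.band(other):
                self._K[band] = self._K[other]
            else:
                self._K[band] = self._assemble(band)
        return self._K[band]

    def factorization(self, band: str):
        if band not in self._lu:
            # identical band tables share one factorization (the default:
            # emission optics fall back to excitation)
            other = "emission" if band == "excitation" else "excitation"
            if other in self._lu and self.optics.band(band) == self.optics.band(other):
                self._lu[band] = self._lu[other]
                return self._lu[band]
            try:
                self._lu[band] = splu(self.matrix(band))
            except RuntimeError as exc:  # pragma: no cover - degenerate optics
                raise SolverError(f"diffusion system factorization failed: {exc}") from exc
        return self._lu[band]

    # -- right-hand sides -------------------------------------------------

    def _trilinear_vector(self, x: float, y: float, z: float) -> np.ndarray:
        """Unit point mass distributed trilinearly onto the 8 enclosing nodes."""
        nx, ny, nz = self.disc.shape
        vec = np.zeros(nx * ny * nz)

        def locate(ax, v):
            i = int(np.clip(np.searchsorted(ax, v) - 1, 0, len(ax) - 2))
            f = (v - ax[i]) / (ax[i + 1] - ax[i])
            return i, float(np.clip(f, 0.0, 1.0))

        ix, fx = locate(self.disc.xs, x)
        iy, fy = locate(self.disc.ys, y)
        iz, fz = locate(self.disc.zs, z)
        for dx, px in ((0, 1 - fx), (1, fx)):
            for dy, py in ((0, 1 - fy), (1, fy)):
                for dz, pz in ((0, 1 - fz), (1, fz)):
                    wgt = px * py * pz
                    if wgt:
                        vec[((ix + dx) * ny + iy + dy) * nz + iz + dz] += wgt
        return vec

    def surface_entry_depth(self, x: float, y: float) -> float:
        """Burial depth 1/µs' of the material at the illuminated surface point."""
        mat = self.disc.phantom.material_at(x, y, 0.0).item()
        return 1.0 / self.optics.band("excitation")[mat].musp

    def source_vector(self, points: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
        """RHS for a collimated illumination pattern sampled at surface points.

        Each (x, y) point contributes an isotropic source buried at one
        transport mean free path; weights are normalized so the total
        launched power is 1 (the photon budget is held fixed across pattern
        shapes so geometries stay comparable).
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if weights is None:
            weights = np.ones(len(points))
        weights = np.asarray(weights, dtype=float)
        if weights.sum() <= 0:
            raise ValueError("pattern has no positive weight")
        weights = weights / weights.sum()
        vec = np.zeros(self.disc.n_nodes)
        for (x, y), wgt in zip(points, weights):
            z0 = self.surface_entry_depth(x, y)
            vec += wgt * self._trilinear_vector(x, y, z0)
        return vec

    def measurement_vector(self, points: np.ndarray, area_mm2: float) -> np.ndarray:
        """Measurement functional of a surface detector: area × exitance.

        Exitance under the partial-current condition is φ/(2A); the detector
        reads it over its collection area, sampled at the listed surface
        points (equal split).
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        vec = np.zeros(self.disc.n_nodes)
        table = self.optics.band("emission")
        for x, y in points:
            mat = self.disc.phantom.material_at(x, y, 0.0).item()
            aref = reflection_factor(table[mat].n)
            vec += self._trilinear_vector(x, y, 0.0) / (2.0 * aref)
        return vec * (area_mm2 / len(points))

    # -- solves -----------------------------------------------------------

    def solve(self, rhs: np.ndarray, band: str) -> np.ndarray:
        """Solve for one RHS (1-D) or many (2-D, columns) on physical nodes.

        ``method='direct'`` factorizes once (sparse LU) and reuses the
        factorization for every subsequent RHS; ``method='cg'`` runs
        conjugate gradients per RHS to 1e-10 relative residual, cheaper for
        a handful of one-off solves on large grids.
        """
        b = self._embed(rhs)
        if self.method == "cg":
            from scipy.sparse.linalg import cg

            K = self.matrix(band)
            cols = b.reshape(b.shape[0], -1)
            out = np.empty_like(cols)
            for j in range(cols.shape[1]):
                x, info = cg(K, cols[:, j], rtol=1e-10, maxiter=20000)
                if info != 0:  # pragma: no cover - non-convergence
                    raise SolverError(f"CG failed to converge (info={info})")
                out[:, j] = x
            return self._restrict(out.reshape(b.shape))
        lu = self.factorization(band)
        return self._restrict(lu.solve(b))

    def fluence(self, pattern, band: str = "excitation") -> FluenceField:
        """Excitation fluence of a surface illumination pattern."""
        pts, wgt = pattern_points(pattern, self.disc)
        phi = self.solve(self.source_vector(pts, wgt), band)
        return FluenceField(self.disc, phi, band, pattern)

    def sensitivity(self, pattern, band: str = "emission") -> FluenceField:
        """Adjoint detection-sensitivity field of a surface detector pattern."""
        pts, area = detector_points(pattern, self.disc)
        psi = self.solve(self.measurement_vector(pts, area), band)
        return FluenceField(self.disc, psi, band, pattern)


def pattern_points(pattern, disc: Discretization) -> tuple[np.ndarray, np.ndarray | None]:
    """Surface sample points + weights for a source pattern.

    Accepts a :class:`~drsopt.patterns.SurfacePattern` or a bare (x, y)
    point / array of points.
    """
    sample = getattr(pattern, "sample_points", None)
    if callable(sample):
        pts = sample()
        return pts, None
    pts = np.atleast_2d(np.asarray(pattern, dtype=float))
    return pts, None


def detector_points(pattern, disc: Discretization) -> tuple[np.ndarray, float]:
    """Surface sample points + collection area (mm²) for a detector pattern."""
    sample = getattr(pattern, "sample_points", None)
    if callable(sample):
        return sample(), pattern.area
    pts = np.atleast_2d(np.asarray(pattern, dtype=float))
    return pts, 0.01  # default: the 0.1 × 0.1 mm² point detector


# -- public operations ----------------------------------------------------


def solve_fluence(disc: Discretization, optics: OpticalProperties, pattern,
                  band: str = "excitation") -> FluenceField:
    """One-shot excitation solve (builds and discards a solver)."""
    return DiffusionSolver(disc, optics).fluence(pattern, band)


def detector_sensitivity(disc: Discretization, optics: OpticalProperties, pattern,
                         band: str = "emission") -> FluenceField:
    """One-shot adjoint solve (builds and discards a solver)."""
    return DiffusionSolver(disc, optics).sensitivity(pattern, band)


def raman_yield(excitation: FluenceField, sensitivity: FluenceField,
                disc: Discretization, material: str,
                solver: DiffusionSolver | None = None,
                thickness_um: float | None = None) -> float:
    """Detected Raman yield of one material (Born volume integral).

    Coarse-grid materials integrate excitation × sensitivity × cell volume
    over their nodes; the collagen slab integrates interpolated fields on
    the refined sub-grid (its thickness is far below the node spacing).
    """
    if material not in MATERIALS:
        raise KeyError(f"unknown material {material!r}")
    if excitation.disc is not disc or sensitivity.disc is not disc:
        raise ValueError("fields must live on the given discretization")
    if material == "collagen":
        pts, vol = disc.collagen_subgrid(thickness_um)
        if len(pts) == 0:
            return 0.0
        return float(np.sum(excitation.at(pts) * sensitivity.at(pts)) * vol)
    volumes = (solver.cell_volumes() if solver is not None
               else _plain_cell_volumes(disc))
    mask = disc.labels == material
    return float(np.sum(excitation.values[mask] * sensitivity.values[mask] * volumes[mask]))


def _plain_cell_volumes(disc: Discretization) -> np.ndarray:
    nx, ny, nz = disc.shape
    hx, hy, hz = disc.spacing

    def w(n):
        a = np.ones(n)
        a[0] = a[-1] = 0.5
        return a

    W = w(nx)[:, None, None] * w(ny)[None, :, None] * w(nz)[None, None, :]
    return (W * hx * hy * hz).ravel()


def yield_table(disc: Discretization, optics: OpticalProperties,
                source, detector,
                thickness_um: float | None = None,
                solver: DiffusionSolver | None = None) -> RamanYieldTable:
    """Per-material yields for the FBR and initial-conditions sample pair.

    Fields are solved once on the shared discretization (the micron-scale
    collagen slab perturbs the photon field negligibly — its optics match
    skin — so the FBR and day-0 samples share the same fluence and
    sensitivity and differ only in the emitting regions).
    """
    solver = solver or DiffusionSolver(disc, optics)
    exc = solver.fluence(source)
    sens = solver.sensitivity(detector)
    t = thickness_um if thickness_um is not None else disc.phantom.config.collagen_thickness_um

    entries: dict[str, dict[str, float]] = {"FBR": {}, "InitialConditions": {}}
    for material in MATERIALS:
        if material == "collagen":
            y = raman_yield(exc, sens, disc, "collagen", solver=solver, thickness_um=t)
            entries["FBR"]["collagen"] = y
            entries["InitialConditions"]["collagen"] = 0.0
        else:
            y = raman_yield(exc, sens, disc, material, solver=solver)
            entries["FBR"][material] = y
            entries["InitialConditions"][material] = y
    return RamanYieldTable(entries, source=source, detector=detector)
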