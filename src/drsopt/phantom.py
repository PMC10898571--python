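"""Digital phantom of a subcutaneous implant with a fibrotic collagen cap.

The phantom mimics the foreign-body-response (FBR) measurement sample: a
polystyrene disk implanted under a skin + fat bilayer on a thick muscle bed,
with a thin collagen slab on the disk's top face standing in for the fibrotic
capsule.  Coordinates: origin at the centre of the sample surface, ``z``
increasing downward into the tissue (mm).  With collagen thickness ``t = 0``
the phantom is the "initial conditions" (day-0) sample; with ``t > 0`` it is
the "FBR" sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MATERIALS",
    "PhantomConfig",
    "Phantom",
    "Discretization",
    "build_phantom",
    "build_discretization",
    "thickness_from_mass",
]

#: Canonical material labels, in solver index order.
MATERIALS = ("skin", "fat", "muscle", "polystyrene", "collagen")


class GeometryError(ValueError):
    """Phantom geometry is inconsistent (e.g. implant outside the domain)."""


@dataclass(frozen=True)
class PhantomConfig:
    """Geometric parameters of the layered implant phantom.

    All lateral/depth lengths in mm; ``collagen_thickness_um`` in µm.
    ``implant_top_depth`` is the depth of the top of the collagen + implant
    assembly below the surface, i.e. the bottom of the fat layer where the
    subcutaneous pocket sits; the collagen slab occupies
    ``[implant_top_depth, implant_top_depth + t)`` and the polystyrene disk
    directly underneath it.
    """

    lateral_extent: float = 20.0
    depth_extent: float = 20.0
    skin_thickness: float = 0.75
    fat_thickness: float = 0.75
    implant_radius: float = 4.0
    implant_thickness: float = 2.0
    implant_top_depth: float = 1.5
    collagen_thickness_um: float = 100.0
    implant_center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        for name in (
            "lateral_extent",
            "depth_extent",
            "skin_thickness",
            "fat_thickness",
            "implant_radius",
            "implant_thickness",
            "implant_top_depth",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0.0 <= self.collagen_thickness_um <= 500.0:
            raise ValueError(
                f"collagen_thickness_um must lie in [0, 500], got {self.collagen_thickness_um}"
            )

    @property
    def collagen_thickness_mm(self) -> float:
        return self.collagen_thickness_um * 1e-3

    def with_thickness(self, thickness_um: float) -> "PhantomConfig":
        """Same phantom with a different collagen-cap thickness (µm)."""
        return replace(self, collagen_thickness_um=thickness_um)


@dataclass(frozen=True)
class Phantom:
    """A built phantom supporting vectorized material-membership queries."""

    config: PhantomConfig

    @property
    def is_fbr(self) -> bool:
        """True when a collagen cap is present (the "FBR" sample)."""
        return self.config.collagen_thickness_um > 0

    @property
    def materials_present(self) -> tuple[str, ...]:
        if self.is_fbr:
            return MATERIALS
        return tuple(m for m in MATERIALS if m != "collagen")

    def material_at(self, x, y, z) -> np.ndarray:
        """Material label at each query point.

        Points are broadcast against each other; depths outside ``[0,
        depth_extent]`` raise.  Layering is resolved top-down: the implant
        assembly (collagen slab, then polystyrene disk) overrides the
        skin/fat/muscle background within its cylinder.
        """
        cfg = self.config
        x, y, z = np.broadcast_arrays(
            np.asarray(x, dtype=float), np.asarray(y, dtype=float), np.asarray(z, dtype=float)
        )
        if np.any(z < 0) or np.any(z > cfg.depth_extent):
            raise GeometryError("query depth outside the phantom domain")

        out = np.full(z.shape, "muscle", dtype=object)
        out[z < cfg.skin_thickness + cfg.fat_thickness] = "fat"
        out[z < cfg.skin_thickness] = "skin"

        cx, cy = cfg.implant_center
        r2 = (x - cx) ** 2 + (y - cy) ** 2
        in_cyl = r2 <= cfg.implant_radius**2
        t = cfg.collagen_thickness_mm
        top = cfg.implant_top_depth
        coll = in_cyl & (z >= top) & (z < top + t)
        disk = in_cyl & (z >= top + t) & (z < top + t + cfg.implant_thickness)
        out[coll] = "collagen"
        out[disk] = "polystyrene"
        return out


def build_phantom(config: PhantomConfig | None = None, **overrides) -> Phantom:
    """Construct the layered implant phantom.

    Parameters may be given as a :class:`PhantomConfig` or as keyword
    overrides of the defaults (skin 0.75 mm, fat 0.75 mm, 8 mm diameter /
    2 mm thick disk 1.5 mm below the surface, 100 µm collagen cap, 20 mm
    cube domain).
    """
    cfg = config if config is not None else PhantomConfig(**overrides)
    if config is not None and overrides:
        cfg = replace(cfg, **overrides)
    bottom = cfg.implant_top_depth + cfg.collagen_thickness_mm + cfg.implant_thickness
    if bottom > cfg.depth_extent:
        raise GeometryError(
            f"implant bottom at {bottom:.3f} mm exceeds domain depth {cfg.depth_extent} mm"
        )
    cx, cy = cfg.implant_center
    if max(abs(cx), abs(cy)) + cfg.implant_radius > cfg.lateral_extent / 2.0:
        raise GeometryError("implant extends beyond the lateral domain")
    return Phantom(cfg)


@dataclass(frozen=True)
class Discretization:
    """Structured grid over the phantom used by the transport solver.

    A uniform node lattice at ``base_spacing`` covers the whole domain; the
    thin collagen slab, far below grid resolution, is handled by a separate
    cell-centred integration sub-grid at ``refined_spacing`` restricted to
    the slab (fields are interpolated onto it when integrating emission).
    """

    phantom: Phantom
    base_spacing: float
    refined_spacing: float
    # node axes (1-D) and flattened node data, C order (ix, iy, iz)
    xs: np.ndarray = field(repr=False)
    ys: np.ndarray = field(repr=False)
    zs: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)  # per-node material, object array

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.xs), len(self.ys), len(self.zs))

    @property
    def n_nodes(self) -> int:
        return len(self.xs) * len(self.ys) * len(self.zs)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (
            float(self.xs[1] - self.xs[0]),
            float(self.ys[1] - self.ys[0]),
            float(self.zs[1] - self.zs[0]),
        )

    def node_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Flattened (x, y, z) of every node, C order."""
        X, Y, Z = np.meshgrid(self.xs, self.ys, self.zs, indexing="ij")
        return X.ravel(), Y.ravel(), Z.ravel()

    def material_indices(self) -> np.ndarray:
        """Per-node index into :data:`MATERIALS`."""
        lut = {m: i for i, m in enumerate(MATERIALS)}
        return np.array([lut[m] for m in self.labels], dtype=np.intp)

    def collagen_subgrid(self, thickness_um: float | None = None):
        """Cell-centred integration sub-grid tiling the collagen slab.

        Returns ``(points (n, 3), cell_volume mm³)`` or ``(empty, 0.0)`` when
        the slab is empty.  ``thickness_um`` overrides the phantom's own
        thickness so a family of slabs can reuse one field solve.
        """
        cfg = self.phantom.config
        t = (thickness_um if thickness_um is not None else cfg.collagen_thickness_um) * 1e-3
        if t <= 0:
            return np.empty((0, 3)), 0.0
        h = self.refined_spacing
        nz = max(1, int(round(t / h)))
        dz = t / nz
        z = cfg.implant_top_depth + (np.arange(nz) + 0.5) * dz
        nxy = max(1, int(round(2 * cfg.implant_radius / h)))
        dxy = 2 * cfg.implant_radius / nxy
        ax = -cfg.implant_radius + (np.arange(nxy) + 0.5) * dxy
        cx, cy = cfg.implant_center
        X, Y, Z = np.meshgrid(ax + cx, ax + cy, z, indexing="ij")
        mask = (X - cx) ** 2 + (Y - cy) ** 2 <= cfg.implant_radius**2
        pts = np.column_stack([X[mask], Y[mask], Z[mask]])
        return pts, dxy * dxy * dz

    def to_frame(self):
        """Node table (x, y, z, material) as a DataFrame, for caching/export."""
        import pandas as pd

        x, y, z = self.node_coordinates()
        return pd.DataFrame({"x": x, "y": y, "z": z, "material": self.labels})


def build_discretization(
    phantom: Phantom,
    base_spacing: float = 0.6,
    refined_spacing: float = 0.08,
) -> Discretization:
    """Grid the phantom for the diffusion solve.

    Node count per axis follows ``floor(extent / spacing) + 1`` with the
    actual spacing stretched to span the extent exactly, so a 20 mm cube at
    0.6 mm nominal spacing yields 34³ = 39,304 nodes.
    """
    if base_spacing <= 0 or refined_spacing <= 0:
        raise ValueError("spacings must be positive")
    if refined_spacing > base_spacing:
        raise ValueError("refined_spacing must not exceed base_spacing")
    cfg = phantom.config
    if base_spacing > min(cfg.lateral_extent, cfg.depth_extent):
        raise ValueError("base_spacing exceeds the domain size")

    half = cfg.lateral_extent / 2.0
    nx = int(np.floor(cfg.lateral_extent / base_spacing)) + 1
    nz = int(np.floor(cfg.depth_extent / base_spacing)) + 1
    xs = np.linspace(-half, half, nx)
    zs = np.linspace(0.0, cfg.depth_extent, nz)
    X, Y, Z = np.meshgrid(xs, xs, zs, indexing="ij")
    labels = phantom.material_at(X.ravel(), Y.ravel(), Z.ravel())
    return Discretization(
        phantom=phantom,
        base_spacing=base_spacing,
        refined_spacing=refined_spacing,
        xs=xs,
        ys=xs.copy(),
        zs=zs,
        labels=labels,
    )


def thickness_from_mass(
    mass_deposited_g: float,
    collagen_fraction: float,
    area_mm2: float,
    density_ug_mm3: float = 500.0,
) -> float:
    """Mimicked capsule thickness (µm) from deposited solution mass.

    ``t = mass · fraction / (density · area)``: the collagen mass in the
    deposited solution spread uniformly over the implant's top face at the
    fibrotic-capsule collagen density (default 500 µg/mm³).
    """
    if mass_deposited_g < 0:
        raise ValueError("mass must be nonnegative")
    if not 0 < collagen_fraction <= 1:
        raise ValueError("collagen_fraction must lie in (0, 1]")
    if area_mm2 <= 0 or density_ug_mm3 <= 0:
        raise ValueError("area and density must be positive")
    mass_ug = mass_deposited_g * 1e6
    t_mm = mass_ug * collagen_fraction / (density_ug_mm3 * area_mm2)
    return t_mm * 1e3
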