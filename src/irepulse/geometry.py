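"""Voxelized computational domain for two-needle electroporation planning.

The tissue is modelled as a finite cylinder (default 80 mm tall, 20 mm in
diameter) with a pair of parallel needle electrodes inserted along the
cylinder axis, symmetric about it.  The exposed electrode segments carry the
Dirichlet boundary data of the field solve (source at the applied voltage,
sink at ground); every other tissue surface is electrically insulated.

The domain is discretized on a regular voxel grid by voxel-center membership
tests (a "staircase" representation).  Each voxel carries one label:

==========  ====================================================
``EXTERIOR``  outside the tissue cylinder (bounding-box complement)
``TISSUE``    conductive tissue, unknowns of the Laplace solve
``SOURCE``    energized electrode, potential fixed at ``voltage_V``
``SINK``      grounded electrode, potential fixed at 0
==========  ====================================================

All configuration lengths are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "EXTERIOR",
    "TISSUE",
    "SOURCE",
    "SINK",
    "ConfigurationError",
    "CylinderSpec",
    "ElectrodePairSpec",
    "VoxelDomain",
    "build_domain",
    "load_geometry_config",
]

EXTERIOR = np.uint8(0)
TISSUE = np.uint8(1)
SOURCE = np.uint8(2)
SINK = np.uint8(3)


class ConfigurationError(ValueError):
    """Raised for geometrically impossible or unresolvable configurations."""


@dataclass(frozen=True)
class CylinderSpec:
    """Tissue cylinder, axis along the grid z-axis.

    Parameters
    ----------
    height_mm : float
        Cylinder height (extent along z), mm.
    diameter_mm : float
        Cylinder diameter, mm.
    """

    height_mm: float = 80.0
    diameter_mm: float = 20.0

    def __post_init__(self) -> None:
        if self.height_mm <= 0 or self.diameter_mm <= 0:
            raise ConfigurationError("cylinder height and diameter must be positive")

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0


@dataclass(frozen=True)
class ElectrodePairSpec:
    """Parallel needle-electrode pair.

    The electrodes run parallel to the cylinder axis at ``x = +-s/2`` (where
    ``s`` is the center-to-center spacing), ``y = 0``; their exposed segments
    are centered at the cylinder's axial midpoint.  ``spacing_mm`` is
    interpreted center-to-center by default (the common clinical convention);
    set ``spacing_mode="edge"`` to read it as the gap between electrode
    surfaces instead.
    """

    diameter_mm: float = 1.0
    exposed_mm: float = 15.0
    spacing_mm: float = 5.0
    voltage_V: float = 900.0
    spacing_mode: str = "center"  # "center" | "edge"

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0 or self.exposed_mm <= 0 or self.spacing_mm <= 0:
            raise ConfigurationError("electrode dimensions must be positive")
        if self.voltage_V < 0:
            raise ConfigurationError("source voltage must be non-negative")
        if self.spacing_mode not in ("center", "edge"):
            raise ConfigurationError("spacing_mode must be 'center' or 'edge'")
        if self.center_spacing_mm <= self.diameter_mm:
            raise ConfigurationError("electrodes overlap: spacing must exceed diameter")

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0

    @property
    def center_spacing_mm(self) -> float:
        """Center-to-center distance between the two electrode axes, mm."""
        if self.spacing_mode == "edge":
            return self.spacing_mm + self.diameter_mm
        return self.spacing_mm


@dataclass(frozen=True)
class VoxelDomain:
    """Labelled voxel grid with physical spacing.

    ``labels`` has shape ``grid_shape`` (nx, ny, nz); ``origin`` is the
    physical (x, y, z) coordinate of the center of voxel (0, 0, 0), mm.
    """

    labels: np.ndarray
    voxel_mm: float
    origin: tuple[float, float, float]
    cylinder: CylinderSpec | None = None
    electrodes: ElectrodePairSpec | None = None

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def voltage_V(self) -> float:
        return 0.0 if self.electrodes is None else self.electrodes.voltage_V

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centers along one axis, mm."""
        n = self.labels.shape[axis]
        return self.origin[axis] + self.voxel_mm * np.arange(n)

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.labels == TISSUE

    @property
    def source_mask(self) -> np.ndarray:
        return self.labels == SOURCE

    @property
    def sink_mask(self) -> np.ndarray:
        return self.labels == SINK

    def counts(self) -> dict[str, int]:
        return {
            "tissue": int(np.sum(self.labels == TISSUE)),
            "source": int(np.sum(self.labels == SOURCE)),
            "sink": int(np.sum(self.labels == SINK)),
            "exterior": int(np.sum(self.labels == EXTERIOR)),
        }

    def tissue_volume_mm3(self) -> float:
        """Voxel-count estimate of the conductive-tissue volume."""
        return float(np.sum(self.labels != EXTERIOR)) * self.voxel_mm**3

    def with_voltage(self, voltage_V: float) -> "VoxelDomain":
        """Same geometry with a different applied voltage (labels unchanged)."""
        if self.electrodes is None:
            raise ConfigurationError("domain has no electrodes to energize")
        return replace(self, electrodes=replace(self.electrodes, voltage_V=voltage_V))


def build_domain(
    cyl: CylinderSpec,
    elec: ElectrodePairSpec | None,
    voxel_mm: float,
) -> VoxelDomain:
    """Voxelize the cylinder-plus-electrodes geometry.

    Labels are assigned by voxel-center membership: a voxel is part of an
    electrode if its center lies inside the electrode cylinder, part of the
    tissue if inside the tissue cylinder, exterior otherwise.

    Raises
    ------
    ConfigurationError
        If the voxel size cannot resolve the electrode cross-section, or the
        electrodes extend outside the tissue cylinder.
    """
    if voxel_mm <= 0:
        raise ConfigurationError("voxel size must be positive")
    if elec is not None and voxel_mm > elec.diameter_mm:
        raise ConfigurationError(
            f"voxel size {voxel_mm} mm too coarse for electrode diameter "
            f"{elec.diameter_mm} mm"
        )

    R = cyl.radius_mm
    H = cyl.height_mm
    nx = int(np.ceil(2 * R / voxel_mm))
    nz = int(np.ceil(H / voxel_mm))
    # grid centered on the cylinder axis; x=y=0 is the axis, z in [0, H]
    ox = -(nx * voxel_mm) / 2 + voxel_mm / 2
    oz = (H - nz * voxel_mm) / 2 + voxel_mm / 2
    xs = ox + voxel_mm * np.arange(nx)
    zs = oz + voxel_mm * np.arange(nz)
    X, Y = np.meshgrid(xs, xs, indexing="ij")

    labels = np.zeros((nx, nx, nz), dtype=np.uint8)
    in_cyl = X**2 + Y**2 <= R**2
    in_slab = (zs >= 0) & (zs <= H)
    labels[in_cyl[:, :, None] & in_slab[None, None, :]] = TISSUE

    if elec is not None:
        s = elec.center_spacing_mm
        r = elec.radius_mm
        if s / 2 + r > R:
            raise ConfigurationError("electrodes extend outside the tissue cylinder")
        if elec.exposed_mm > H:
            raise ConfigurationError("exposed electrode length exceeds cylinder height")
        z0 = H / 2 - elec.exposed_mm / 2
        z1 = H / 2 + elec.exposed_mm / 2
        in_z = (zs >= z0) & (zs <= z1)
        src2d = (X - s / 2) ** 2 + Y**2 <= r**2
        snk2d = (X + s / 2) ** 2 + Y**2 <= r**2
        if not src2d.any() or not snk2d.any() or not in_z.any():
            raise ConfigurationError(
                "voxel grid contains no voxel inside an electrode; refine voxel_mm"
            )
        zmask = in_z[None, None, :]
        labels[(src2d[:, :, None] & zmask)] = SOURCE
        labels[(snk2d[:, :, None] & zmask)] = SINK

    return VoxelDomain(
        labels=labels,
        voxel_mm=voxel_mm,
        origin=(ox, ox, oz),
        cylinder=cyl,
        electrodes=elec,
    )


def load_geometry_config(path: str | Path) -> tuple[CylinderSpec, ElectrodePairSpec, float]:
    """Read a YAML/JSON geometry config.

    Recognized keys: ``cylinder.height_mm``, ``cylinder.diameter_mm``,
    ``electrode.diameter_mm``, ``electrode.exposed_mm``,
    ``electrode.spacing_mm``, ``electrode.spacing_mode``, ``voltage_V``,
    ``voxel_mm``.  Missing keys fall back to the defaults of the study
    geometry.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    c = cfg.get("cylinder", {})
    e = cfg.get("electrode", {})
    cyl = CylinderSpec(
        height_mm=float(c.get("height_mm", 80.0)),
        diameter_mm=float(c.get("diameter_mm", 20.0)),
    )
    elec = ElectrodePairSpec(
        diameter_mm=float(e.get("diameter_mm", 1.0)),
        exposed_mm=float(e.get("exposed_mm", 15.0)),
        spacing_mm=float(e.get("spacing_mm", 5.0)),
        spacing_mode=str(e.get("spacing_mode", "center")),
        voltage_V=float(cfg.get("voltage_V", 900.0)),
    )
    voxel_mm = float(cfg.get("voxel_mm", 0.5))
    return cyl, elec, voxel_mm
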