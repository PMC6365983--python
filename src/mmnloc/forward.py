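"""EEG forward modelling on a three-shell spherical head.

The head is modelled as three concentric spherical shells (brain, skull,
scalp) with piecewise-constant conductivity.  The electric potential of a
current dipole inside the innermost shell has an analytic solution as a
truncated series of Legendre polynomials; each harmonic order propagates
through the shells via a small boundary-value linear system.  This module
provides

* :func:`make_standard_montage` — a deterministic quasi-uniform electrode
  layout on the scalp sphere (Fibonacci lattice),
* :func:`build_source_grid` — a regular volumetric source lattice clipped to
  the brain shell, with synthetic tissue and region labels,
* :func:`compute_leadfield` — the analytic gain matrix (common-average
  referenced) mapping dipole moments at grid points to scalp potentials,
* :func:`normalize_leadfield` — per-source column-block normalisation used
  to suppress depth/norm artefacts in beamformer maps.

Units: positions are stored in metres in the head frame (RAS, origin at the
sphere centre); source grids are expressed in millimetres for reporting.
Gain entries are in volts per (ampere·metre).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "ElectrodeMontage",
    "SphericalHeadModel",
    "SourceGrid",
    "Leadfield",
    "make_standard_montage",
    "build_source_grid",
    "compute_leadfield",
    "normalize_leadfield",
    "default_head_model",
    "load_region_table",
    "label_tissue",
    "OutOfDomainError",
    "EmptyGridError",
    "DegenerateSourceError",
]


class OutOfDomainError(ValueError):
    """A source position lies on or outside the brain shell."""


class EmptyGridError(ValueError):
    """Requested lattice spacing produces no points inside the brain."""


class DegenerateSourceError(ValueError):
    """A leadfield source block is identically zero."""


@dataclass(frozen=True)
class SphericalHeadModel:
    """Three concentric shells: brain < skull < scalp.

    radii in metres, conductivities in S/m, both ordered inside-out.
    """

    centre: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radii: tuple[float, float, float] = (0.080, 0.085, 0.092)
    conductivities: tuple[float, float, float] = (0.33, 0.0042, 0.33)

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, float)
        if not np.all(np.diff(r) > 0):
            raise ValueError("shell radii must be strictly increasing")
        if not np.all(np.asarray(self.conductivities, float) > 0):
            raise ValueError("conductivities must be positive")

    @property
    def brain_radius(self) -> float:
        return self.radii[0]

    @property
    def scalp_radius(self) -> float:
        return self.radii[-1]


def default_head_model() -> SphericalHeadModel:
    """The package default: 80/85/92 mm shells, 0.33/0.0042/0.33 S/m."""
    return SphericalHeadModel()


@dataclass(frozen=True)
class ElectrodeMontage:
    """Labelled sensor positions on the scalp sphere, common-average referenced."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n, 3) metres, head frame
    reference: str = "common-average"

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, float)
        object.__setattr__(self, "positions", pos)
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("electrode labels must be unique")
        if len(self.labels) < 4:
            raise ValueError("a montage needs at least 4 sensors")
        if pos.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_sensors, 3)")
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < 1e-3:
            raise ValueError("two sensors are closer than 1 mm")

    @property
    def n_sensors(self) -> int:
        return len(self.labels)


def make_standard_montage(
    n_sensors: int, head: SphericalHeadModel | None = None
) -> ElectrodeMontage:
    """Deterministic quasi-uniform montage on the scalp sphere.

    Uses the Fibonacci lattice: ``z_i = 1 - (2i+1)/n``, azimuth advancing by
    the golden angle.  Sensors are labelled ``A1 … An``.
    """
    if n_sensors < 4:
        raise ValueError("n_sensors must be >= 4")
    head = head or default_head_model()
    i = np.arange(n_sensors)
    z = 1.0 - (2.0 * i + 1.0) / n_sensors
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    s = np.sqrt(1.0 - z**2)
    unit = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    pos = head.scalp_radius * unit + np.asarray(head.centre)
    labels = tuple(f"A{k + 1}" for k in i)
    return ElectrodeMontage(labels=labels, positions=pos)


# ---------------------------------------------------------------------------
# source grid


@dataclass(frozen=True)
class SourceGrid:
    """Regular volumetric lattice of candidate sources inside the brain shell.

    Positions are in millimetres relative to the head centre.  ``tissue``
    holds ``"grey"``/``"white"`` labels from a synthetic core/shell proxy;
    ``region`` holds coarse anatomical labels from the bundled region table
    (``"other"`` where no region sphere covers the point).
    """

    spacing: float  # mm
    points: np.ndarray  # (n, 3) mm
    inside_mask: np.ndarray  # (n,) bool
    tissue: np.ndarray  # (n,) unicode
    region: np.ndarray  # (n,) unicode
    grid_id: str = "grid"

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def region_indices(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.region == name)


def label_tissue(points_mm: np.ndarray, head: SphericalHeadModel) -> np.ndarray:
    """Synthetic tissue labels: a central core (radius 0.45·brain) is 'white'.

    This crude core/shell proxy exists only to exercise the grey-matter-only
    analysis path; it makes no anatomical claim.
    """
    r = np.linalg.norm(points_mm, axis=1)
    white = r < 0.45 * head.brain_radius * 1e3
    return np.where(white, "white", "grey")


def load_region_table() -> tuple[dict[str, np.ndarray], float]:
    """Bundled synthetic region centroids (mm, head frame).

    Stand-ins for atlas centroids of the canonical mismatch-response network
    (bilateral IFG/STG) plus left parietal, motor and prefrontal regions,
    affinely shrunk to fit the spherical brain shell.
    """
    ref = importlib.resources.files("mmnloc.data").joinpath("regions.yaml")
    cfg = yaml.safe_load(ref.read_text())
    scale = float(cfg.get("scale", 1.0))
    return {
        name: scale * np.asarray(xyz, float)
        for name, xyz in cfg["centroids"].items()
    }, float(cfg.get("radius_mm", 15.0))


def _label_regions(
    points_mm: np.ndarray,
    table: dict[str, np.ndarray] | None,
    radius_mm: float | None,
) -> np.ndarray:
    if table is None:
        table, radius_mm = load_region_table()
    region = np.full(points_mm.shape[0], "other", dtype="U16")
    # nearest centroid wins inside its sphere
    best = np.full(points_mm.shape[0], np.inf)
    for name, centre in table.items():
        d = np.linalg.norm(points_mm - centre[None, :], axis=1)
        hit = (d <= radius_mm) & (d < best)
        region[hit] = name
        best[hit] = d[hit]
    return region


def build_source_grid(
    head: SphericalHeadModel,
    spacing: float = 10.0,
    exclude_white: bool = False,
    region_table: dict[str, np.ndarray] | None = None,
    region_radius_mm: float | None = None,
    grid_id: str | None = None,
) -> SourceGrid:
    """Regular lattice with the given spacing (mm), clipped strictly to the brain.

    The lattice is aligned to the head centre (a point at the origin is always
    a lattice node).  With ``exclude_white`` the synthetic white-matter core is
    dropped, mirroring grey-matter-only source spaces.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    rb = head.brain_radius * 1e3  # mm
    if spacing > 2 * rb:
        raise EmptyGridError("spacing exceeds brain diameter")
    nmax = int(np.floor(rb / spacing))
    ax = spacing * np.arange(-nmax, nmax + 1)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    inside = np.linalg.norm(pts, axis=1) < rb
    pts = pts[inside]
    if pts.shape[0] == 0:
        raise EmptyGridError("no lattice points fall inside the brain shell")
    tissue = label_tissue(pts, head)
    if exclude_white:
        keep = tissue == "grey"
        pts, tissue = pts[keep], tissue[keep]
    region = _label_regions(pts, region_table, region_radius_mm)
    return SourceGrid(
        spacing=float(spacing),
        points=pts,
        inside_mask=np.ones(pts.shape[0], bool),
        tissue=np.asarray(tissue, dtype="U16"),
        region=region,
        grid_id=grid_id or f"sphere-{spacing:g}mm" + ("-grey" if exclude_white else ""),
    )


# ---------------------------------------------------------------------------
# analytic leadfield


@dataclass(frozen=True)
class Leadfield:
    """Gain matrix: n_sensors × (3·n_sources), V per (A·m), common-average."""

    gain: np.ndarray
    normalised: bool
    grid_ref: str
    montage_ref: str

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1] // 3

    def source_block(self, j: int) -> np.ndarray:
        return self.gain[:, 3 * j : 3 * j + 3]

    def blocks(self) -> np.ndarray:
        """Gain reshaped to (n_sources, n_sensors, 3)."""
        n_e = self.gain.shape[0]
        return self.gain.reshape(n_e, -1, 3).transpose(1, 0, 2)


def _shell_transfer(head: SphericalHeadModel, n_max: int) -> np.ndarray:
    """Per-order surface coefficients for a unit dipole series term.

    For harmonic order n, the primary (infinite-medium) potential of the
    dipole contributes a term proportional to (r1/r)^(n+1) inside the brain
    shell.  Solving the interface conditions (continuity of V and of the
    radial current) plus the insulating outer boundary yields the potential
    at the scalp surface for that unit term.  Returns ``v[n]`` for
    n = 1 … n_max (index 0 unused).
    """
    r1, r2, r3 = head.radii
    s1, s2, s3 = head.conductivities
    out = np.zeros(n_max + 1)
    for n in range(1, n_max + 1):
        t12 = (r1 / r2) ** n
        t21 = (r2 / r1) ** (n + 1)
        t23 = (r2 / r3) ** n
        t32 = (r3 / r2) ** (n + 1)
        np1 = n + 1.0
        # unknowns: a1, a2, b2, a3, b3
        A = np.array(
            [
                [1.0, -t12, -t21, 0.0, 0.0],
                [s1 * n, -s2 * n * t12, s2 * np1 * t21, 0.0, 0.0],
                [0.0, 1.0, 1.0, -t23, -t32],
                [0.0, s2 * n, -s2 * np1, -s3 * n * t23, s3 * np1 * t32],
                [0.0, 0.0, 0.0, n, -np1],
            ]
        )
        b = np.array([-1.0, s1 * np1, 0.0, 0.0, 0.0])
        a1, a2, b2, a3, b3 = np.linalg.solve(A, b)
        out[n] = a3 + b3
    return out


def compute_leadfield(
    head: SphericalHeadModel,
    montage: ElectrodeMontage,
    grid: SourceGrid | np.ndarray,
    n_terms: int = 100,
) -> Leadfield:
    """Analytic three-shell leadfield for unit dipoles along x, y, z.

    ``grid`` may be a :class:`SourceGrid` (positions in mm) or a raw (n, 3)
    array in mm.  The returned gain is common-average referenced: every
    column has zero mean across sensors.
    """
    if n_terms < 20:
        raise ValueError("n_terms must be >= 20")
    if isinstance(grid, SourceGrid):
        pts_mm = grid.points
        grid_ref = grid.grid_id
    else:
        pts_mm = np.asarray(grid, float)
        grid_ref = "ad-hoc"
    src = pts_mm * 1e-3 - np.asarray(head.centre)[None, :]
    r1 = head.brain_radius
    b = np.linalg.norm(src, axis=1)
    if np.any(b >= r1 * (1 - 1e-12)):
        raise OutOfDomainError("source on or outside the brain shell")

    elec = montage.positions - np.asarray(head.centre)[None, :]
    ee = elec / np.linalg.norm(elec, axis=1, keepdims=True)  # (nE,3)
    # radial unit vectors; arbitrary axis for a dipole at the exact centre
    er = np.where(b[:, None] > 0, src / np.where(b[:, None] > 0, b[:, None], 1.0), [0.0, 0.0, 1.0])
    cosg = np.clip(ee @ er.T, -1.0, 1.0)  # (nE, nS)
    rho = b / r1  # (nS,)

    v = _shell_transfer(head, n_terms)
    # Legendre recurrences accumulated into
    #   A = sum_n f_n rho^(n-1) * n * P_n(c)
    #   B = sum_n f_n rho^(n-1) * P'_n(c)
    P_nm1 = np.ones_like(cosg)  # P_0
    P_n = cosg.copy()  # P_1
    dP_nm1 = np.zeros_like(cosg)  # P'_0
    dP_n = np.ones_like(cosg)  # P'_1
    rpow = np.ones_like(rho)  # rho^(n-1), n = 1
    A = np.zeros_like(cosg)
    B = np.zeros_like(cosg)
    for n in range(1, n_terms + 1):
        w = v[n] * rpow  # (nS,)
        A += w[None, :] * n * P_n
        B += w[None, :] * dP_n
        # advance to n+1
        P_np1 = ((2 * n + 1) * cosg * P_n - n * P_nm1) / (n + 1)
        dP_np1 = dP_nm1 + (2 * n + 1) * P_n
        P_nm1, P_n = P_n, P_np1
        dP_nm1, dP_n = dP_n, dP_np1
        rpow = rpow * rho

    pref = 1.0 / (4.0 * np.pi * head.conductivities[0] * r1**2)
    # V(e, j, m) = pref * ( A_ej (m·er_j) + B_ej (m·(ee_e - c_ej er_j)) )
    nE, nS = cosg.shape
    gain = np.empty((nE, 3 * nS))
    for k in range(3):
        gain[:, k::3] = pref * (
            A * er[None, :, k] + B * (ee[:, k, None] - cosg * er[None, :, k])
        )
    gain -= gain.mean(axis=0, keepdims=True)  # common-average reference
    return Leadfield(
        gain=gain, normalised=False, grid_ref=grid_ref, montage_ref=f"montage-{nE}"
    )


def normalize_leadfield(L: Leadfield) -> Leadfield:
    """Divide each 3-column source block by its Frobenius norm (idempotent)."""
    blocks = L.gain.reshape(L.gain.shape[0], -1, 3)
    norms = np.sqrt((blocks**2).sum(axis=(0, 2)))
    if np.any(norms == 0):
        raise DegenerateSourceError("all-zero source block cannot be normalised")
    gain = (blocks / norms[None, :, None]).reshape(L.gain.shape)
    return replace(L, gain=gain, normalised=True)
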