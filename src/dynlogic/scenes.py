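"""Synthetic scenes: parabolic arcs and blobs embedded in noise at controlled SNR.

Two dialects are generated from one :class:`SceneSpec`:

raster
    a ``height x width`` float grid of intensities: i.i.d. Gaussian background
    noise (mean 0, sd ``noise_sigma``) plus, for every arc/blob, a signal of
    peak height ``signal_amplitude`` with a transverse Gaussian profile.  The
    amplitude signal-to-noise ratio is ``signal_amplitude / noise_sigma``;
    the reference "sub-noise" condition uses SNR = 1/3.
points
    a marked point set: uniform clutter at ``clutter_rate`` points per unit
    area plus ``n_object_points_per_arc`` points per arc, drawn at uniform arc
    parameters with isotropic transverse Gaussian scatter.  Here the SNR is an
    object-to-clutter density ratio:
    (points per unit arc length x transverse width) / clutter density.

All randomness derives from ``SceneSpec.seed`` through a fixed
``numpy.random.SeedSequence`` spawning scheme (child 0: raster noise, child 1:
clutter, children 2+k: object k), so identical specs give bit-identical
scenes.

Coordinates are continuous with origin at the top-left, x rightward,
y downward; pixel (row r, col c) has center (c + 0.5, r + 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial import cKDTree

from .observations import Domain, ObservationSet

__all__ = [
    "ArcSpec",
    "BlobSpec",
    "SceneSpec",
    "SceneError",
    "arc_points",
    "simulate_scene",
    "raster_to_observations",
    "write_pgm",
    "read_pgm",
    "write_grid_csv",
    "read_grid_csv",
]


class SceneError(ValueError):
    """Raised for invalid scene specifications."""


@dataclass(frozen=True)
class ArcSpec:
    """A parabolic arc: c(u) = vertex + R(rotation) @ (u, curvature * u^2),
    u in [-half_extent, half_extent].

    The sign of the bend on screen (smile vs frown, with y pointing down) is
    set by the rotation; curvature is kept nonnegative by canonicalization.
    """

    vertex_x: float
    vertex_y: float
    curvature: float
    rotation: float
    half_extent: float
    transverse_sigma: float

    def __post_init__(self) -> None:
        if not self.half_extent > 0:
            raise SceneError("arc half_extent must be positive")
        if not self.transverse_sigma > 0:
            raise SceneError("arc transverse_sigma must be positive")

    @property
    def vertex(self) -> np.ndarray:
        return np.array([self.vertex_x, self.vertex_y])


@dataclass(frozen=True)
class BlobSpec:
    """An isotropic Gaussian blob of spatial sd ``sigma``."""

    center_x: float
    center_y: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise SceneError("blob sigma must be positive")

    @property
    def center(self) -> np.ndarray:
        return np.array([self.center_x, self.center_y])


@dataclass(frozen=True)
class SceneSpec:
    """Full description of a synthetic scene (both dialects)."""

    domain_width: float
    domain_height: float
    arcs: tuple[ArcSpec, ...] = ()
    blobs: tuple[BlobSpec, ...] = ()
    signal_amplitude: float = 1.0 / 3.0  # raster dialect, intensity units
    noise_sigma: float = 1.0  # raster dialect, intensity units
    n_object_points_per_arc: int = 100  # point dialect
    clutter_rate: float = 0.0  # point dialect, points per unit area
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.domain_width > 0 and self.domain_height > 0):
            raise SceneError("domain sides must be positive")
        if not self.noise_sigma > 0:
            raise SceneError("noise_sigma must be positive")
        if self.clutter_rate < 0:
            raise SceneError("clutter_rate must be nonnegative")
        object.__setattr__(self, "arcs", tuple(self.arcs))
        object.__setattr__(self, "blobs", tuple(self.blobs))

    @property
    def domain(self) -> Domain:
        return Domain(self.domain_width, self.domain_height)

    @property
    def snr(self) -> float:
        """Amplitude SNR of the raster dialect."""
        return self.signal_amplitude / self.noise_sigma

    def point_snr(self, arc: ArcSpec) -> float:
        """Density SNR of the point dialect for one arc:
        (object points per unit arc length x transverse width) / clutter rate."""
        if self.clutter_rate == 0:
            return np.inf
        length = _arc_length(arc)
        lineal = self.n_object_points_per_arc / length
        return lineal / (self.clutter_rate * 2.0 * arc.transverse_sigma)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["arcs"] = [asdict(a) for a in self.arcs]
        d["blobs"] = [asdict(b) for b in self.blobs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise SceneError(f"unknown SceneSpec keys: {sorted(unknown)}")
        d["arcs"] = tuple(ArcSpec(**a) for a in d.get("arcs", ()))
        d["blobs"] = tuple(BlobSpec(**b) for b in d.get("blobs", ()))
        return cls(**d)


def _rotation(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def arc_points(arc: ArcSpec, u: np.ndarray) -> np.ndarray:
    """Curve points c(u) = vertex + R(rotation) @ (u, a u^2), shape (len(u), 2)."""
    u = np.asarray(u, dtype=float)
    local = np.stack([u, arc.curvature * u * u], axis=-1)
    return local @ _rotation(arc.rotation).T + arc.vertex


def _arc_length(arc: ArcSpec, n: int = 512) -> float:
    u = np.linspace(-arc.half_extent, arc.half_extent, n)
    pts = arc_points(arc, u)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _check_objects_inside(spec: SceneSpec) -> None:
    dom = spec.domain
    for k, arc in enumerate(spec.arcs):
        u = np.linspace(-arc.half_extent, arc.half_extent, 257)
        if not dom.contains(arc_points(arc, u)).all():
            raise SceneError(f"arc {k} extends outside the domain")
    for k, blob in enumerate(spec.blobs):
        if not dom.contains(blob.center[None, :]).all():
            raise SceneError(f"blob {k} center outside the domain")


def _render_raster(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = int(round(spec.domain_height)), int(round(spec.domain_width))
    grid = rng.normal(0.0, spec.noise_sigma, size=(h, w))
    if not (spec.arcs or spec.blobs):
        return grid
    cols, rows = np.meshgrid(np.arange(w) + 0.5, np.arange(h) + 0.5)
    centers = np.column_stack([cols.ravel(), rows.ravel()])
    for arc in spec.arcs:
        # transverse profile: peak amplitude at the centerline, Gaussian falloff
        n_samp = max(64, int(np.ceil(_arc_length(arc) / 0.1)))
        u = np.linspace(-arc.half_extent, arc.half_extent, n_samp)
        tree = cKDTree(arc_points(arc, u))
        d, _ = tree.query(centers, k=1)
        grid += (
            spec.signal_amplitude
            * np.exp(-0.5 * (d / arc.transverse_sigma) ** 2)
        ).reshape(h, w)
    for blob in spec.blobs:
        d2 = ((centers - blob.center) ** 2).sum(axis=1)
        grid += (
            spec.signal_amplitude * np.exp(-0.5 * d2 / blob.sigma**2)
        ).reshape(h, w)
    return grid


def _sample_points(spec: SceneSpec, root: np.random.SeedSequence) -> ObservationSet:
    dom = spec.domain
    children = root.spawn(2 + len(spec.arcs) + len(spec.blobs))
    clutter_rng = np.random.default_rng(children[1])
    n_clutter = clutter_rng.poisson(spec.clutter_rate * dom.area)
    pts = [
        np.column_stack(
            [
                clutter_rng.uniform(0, dom.width, n_clutter),
                clutter_rng.uniform(0, dom.height, n_clutter),
            ]
        )
    ]
    for k, arc in enumerate(spec.arcs):
        rng = np.random.default_rng(children[2 + k])
        u = rng.uniform(-arc.half_extent, arc.half_extent, spec.n_object_points_per_arc)
        xy = arc_points(arc, u) + rng.normal(
            0.0, arc.transverse_sigma, size=(spec.n_object_points_per_arc, 2)
        )
        pts.append(xy)
    for k, blob in enumerate(spec.blobs):
        rng = np.random.default_rng(children[2 + len(spec.arcs) + k])
        xy = blob.center + rng.normal(
            0.0, blob.sigma, size=(spec.n_object_points_per_arc, 2)
        )
        pts.append(xy)
    xy = np.vstack(pts) if pts else np.empty((0, 2))
    # object points may scatter slightly past the boundary; clip into the domain
    xy[:, 0] = np.clip(xy[:, 0], 0.0, dom.width)
    xy[:, 1] = np.clip(xy[:, 1], 0.0, dom.height)
    n = len(xy)
    return ObservationSet(
        ids=np.arange(n),
        weights=np.ones(n),
        dialect="points",
        positions=xy,
        domain=dom,
    )


def simulate_scene(spec: SceneSpec, dialect: str = "raster"):
    """Generate a scene.

    ``dialect='raster'`` returns a ``(height, width)`` float array of
    intensities; ``dialect='points'`` returns an :class:`ObservationSet`.
    Output is fully determined by ``spec.seed``.
    """
    _check_objects_inside(spec)
    root = np.random.SeedSequence(spec.seed)
    if dialect == "raster":
        noise_rng = np.random.default_rng(root.spawn(1)[0])
        return _render_raster(spec, noise_rng)
    if dialect == "points":
        return _sample_points(spec, root)
    raise SceneError(f"unknown dialect {dialect!r}")


def raster_to_observations(
    grid: np.ndarray, background_rule: str | float = "median"
) -> ObservationSet:
    """Convert an intensity grid to a weighted point set.

    Each pixel becomes an observation at its center (c + 0.5, r + 0.5) with
    weight ``max(0, intensity - b)`` where ``b`` is the background estimate
    (``'median'`` — the default, robust and parameter-free — or an explicit
    float).  Zero-weight pixels are dropped; weights are not renormalized, so
    the total above-background mass is preserved.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise SceneError("empty grid")
    if not np.isfinite(grid).all():
        raise SceneError("grid contains non-finite values")
    if background_rule == "median":
        b = float(np.median(grid))
    else:
        b = float(background_rule)
    h, w = grid.shape
    weights = np.maximum(0.0, grid - b).ravel()
    cols, rows = np.meshgrid(np.arange(w) + 0.5, np.arange(h) + 0.5)
    centers = np.column_stack([cols.ravel(), rows.ravel()])
    keep = weights > 0
    warnings = []
    if not keep.any():
        warnings.append("all pixel weights are zero after background subtraction")
    return ObservationSet(
        ids=np.flatnonzero(keep),
        weights=weights[keep],
        dialect="raster-derived",
        positions=centers[keep],
        domain=Domain(float(w), float(h)),
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Raster serialization: PGM (P2/P5) with an affine-scale comment, and CSV grid.


def write_pgm(grid: np.ndarray, path, maxval: int = 65535, binary: bool = False) -> None:
    """Write a float grid as PGM.  Intensities are affinely mapped onto
    [0, maxval]; the inverse map is stored in a ``# affine offset step``
    comment so :func:`read_pgm` recovers values up to quantization."""
    grid = np.asarray(grid, dtype=float)
    lo, hi = float(grid.min()), float(grid.max())
    step = (hi - lo) / maxval if hi > lo else 1.0
    codes = np.round((grid - lo) / step).astype(np.uint16 if maxval > 255 else np.uint8)
    header = (
        f"{'P5' if binary else 'P2'}\n# affine {lo!r} {step!r}\n"
        f"{grid.shape[1]} {grid.shape[0]}\n{maxval}\n"
    )
    if binary:
        with open(path, "wb") as fh:
            fh.write(header.encode("ascii"))
            fh.write(codes.astype(">u2" if maxval > 255 else "u1").tobytes())
    else:
        with open(path, "w") as fh:
            fh.write(header)
            for row in codes:
                fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_pgm(path) -> np.ndarray:
    """Read a P2/P5 PGM; applies the ``# affine`` comment if present."""
    with open(path, "rb") as fh:
        data = fh.read()
    if not data[:2] in (b"P2", b"P5"):
        raise SceneError(f"{path}: not a P2/P5 PGM file")
    magic = data[:2].decode()
    offset, step = 0.0, 1.0
    tokens: list[bytes] = []
    i = 2
    while len(tokens) < 3:
        while i < len(data) and data[i : i + 1].isspace():
            i += 1
        if data[i : i + 1] == b"#":
            j = data.index(b"\n", i)
            comment = data[i + 1 : j].decode().strip()
            if comment.startswith("affine"):
                _, o, s = comment.split()
                offset, step = float(o), float(s)
            i = j + 1
            continue
        j = i
        while j < len(data) and not data[j : j + 1].isspace():
            j += 1
        tokens.append(data[i:j])
        i = j
    w, h, maxval = (int(t) for t in tokens)
    if magic == "P2":
        codes = np.array(data[i:].split(), dtype=float).reshape(h, w)
    else:
        dtype = ">u2" if maxval > 255 else "u1"
        codes = np.frombuffer(data[i + 1 :], dtype=dtype, count=h * w).astype(float)
        codes = codes.reshape(h, w)
    return offset + step * codes


def write_grid_csv(grid: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(grid, dtype=float), delimiter=",", fmt="%.17g")


def read_grid_csv(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))
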