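"""Bottom-up observation sets: weighted points, raster-derived pixels, feature vectors.

An :class:`ObservationSet` is the bottom-up signal container consumed by the
dynamic-logic engine.  Three dialects exist:

``points``
    continuous 2-D positions with nonnegative weights (default 1), e.g. a
    point-process scene with clutter;
``raster-derived``
    pixel centers of an intensity grid, weighted by above-background intensity;
``features``
    vectors ``x[n, i]`` in [0, 1] measuring the strength of association of
    bottom-up signal *i* with observation *n* (binary in the crisp limit),
    optionally partitioned into named feature blocks (e.g. a "cognitive" and a
    "language" block of a dual model).

Coordinate convention (stated everywhere and tested): continuous coordinates,
origin at the top-left corner of the domain, x rightward, y downward; pixel
(row r, col c) covers [c, c+1) x [r, r+1) with center (c + 0.5, r + 0.5).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Domain",
    "ObservationSet",
    "ObservationError",
    "read_observations",
    "write_observations",
]


class ObservationError(ValueError):
    """Raised for malformed observation data or files."""


@dataclass(frozen=True)
class Domain:
    """Axis-aligned bounding rectangle [0, width] x [0, height]."""

    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ObservationError(
                f"domain sides must be positive, got {self.width} x {self.height}"
            )

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> np.ndarray:
        return np.array([self.width / 2.0, self.height / 2.0])

    @property
    def scale(self) -> float:
        """Characteristic length: geometric mean of the sides."""
        return float(np.sqrt(self.width * self.height))

    def contains(self, xy: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        xy = np.atleast_2d(xy)
        return (
            (xy[:, 0] >= -atol)
            & (xy[:, 0] <= self.width + atol)
            & (xy[:, 1] >= -atol)
            & (xy[:, 1] <= self.height + atol)
        )


@dataclass
class ObservationSet:
    """Weighted bottom-up observations in one of three dialects.

    Exactly one of ``positions`` / ``features`` is populated.
    """

    ids: np.ndarray
    weights: np.ndarray
    dialect: str  # points | raster-derived | features
    positions: np.ndarray | None = None  # (N, 2)
    features: np.ndarray | None = None  # (N, K), values in [0, 1]
    domain: Domain | None = None
    feature_blocks: dict[str, range] | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.positions is None) == (self.features is None):
            raise ObservationError(
                "exactly one of positions / features must be populated"
            )
        if self.dialect not in ("points", "raster-derived", "features"):
            raise ObservationError(f"unknown dialect {self.dialect!r}")
        if np.any(self.weights < 0):
            raise ObservationError("weights must be nonnegative")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
            if self.domain is None:
                raise ObservationError("spatial dialects require a domain")
            inside = self.domain.contains(self.positions)
            if self.N and not inside.all():
                n = int(np.flatnonzero(~inside)[0])
                raise ObservationError(
                    f"observation id {self.ids[n]} lies outside the domain"
                )
        if self.features is not None:
            self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
            bad = (self.features < 0) | (self.features > 1)
            if bad.any():
                n, i = map(int, np.argwhere(bad)[0])
                raise ObservationError(
                    f"feature x[{n},{i}] = {self.features[n, i]} outside [0, 1]"
                )
        if self.feature_blocks is not None:
            self._check_blocks()

    def _check_blocks(self) -> None:
        K = self.features.shape[1] if self.features is not None else 0
        seen: set[int] = set()
        for name, rng in self.feature_blocks.items():
            idx = set(rng)
            if not idx or min(idx) < 0 or max(idx) >= K:
                raise ObservationError(
                    f"feature block {name!r} range {rng} out of bounds for K={K}"
                )
            if idx & seen:
                raise ObservationError(f"feature block {name!r} overlaps another block")
            seen |= idx
        if seen and seen != set(range(K)):
            raise ObservationError("feature blocks must partition the feature range")

    @property
    def N(self) -> int:
        return len(self.ids)

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    def data(self) -> np.ndarray:
        """The observation matrix of the active dialect."""
        return self.positions if self.positions is not None else self.features


_BLOCK_RE = re.compile(r"^\s*(\w+)\s*:\s*(\d+)\s*-\s*(\d+)\s*$")


def _parse_blocks(text: str) -> dict[str, range]:
    """Parse a block header like ``cognitive:0-9,language:10-19``."""
    blocks: dict[str, range] = {}
    for part in text.split(","):
        m = _BLOCK_RE.match(part)
        if m is None:
            raise ObservationError(f"malformed feature-block declaration {part!r}")
        name, lo, hi = m.group(1), int(m.group(2)), int(m.group(3))
        if hi < lo:
            raise ObservationError(f"feature block {name!r} has empty range {lo}-{hi}")
        blocks[name] = range(lo, hi + 1)
    return blocks


def _format_blocks(blocks: dict[str, range]) -> str:
    return ",".join(f"{k}:{r.start}-{r.stop - 1}" for k, r in blocks.items())


def write_observations(obs: ObservationSet, path) -> None:
    """Serialize to CSV.  Point dialects: ``id,x,y,weight``; feature dialect:
    ``id,f0..fK,weight`` with optional ``# blocks:`` and ``# domain:`` comment
    lines.  Floats are written at full round-trip precision."""
    lines: list[str] = []
    lines.append(f"# dialect: {obs.dialect}")
    if obs.domain is not None:
        lines.append(f"# domain: {obs.domain.width!r} {obs.domain.height!r}")
    if obs.feature_blocks:
        lines.append(f"# blocks: {_format_blocks(obs.feature_blocks)}")
    if obs.features is not None:
        K = obs.features.shape[1]
        lines.append("id," + ",".join(f"f{i}" for i in range(K)) + ",weight")
        for n in range(obs.N):
            feats = ",".join(repr(float(v)) for v in obs.features[n])
            lines.append(f"{obs.ids[n]},{feats},{float(obs.weights[n])!r}")
    else:
        lines.append("id,x,y,weight")
        for n in range(obs.N):
            x, y = obs.positions[n]
            lines.append(
                f"{obs.ids[n]},{float(x)!r},{float(y)!r},{float(obs.weights[n])!r}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_observations(path, dialect: str | None = None) -> ObservationSet:
    """Read an observation CSV written by :func:`write_observations`.

    ``dialect`` may be given to enforce a dialect; the header is checked
    against it.  Malformed rows raise with their line number; features outside
    [0, 1] are rejected naming row and column.
    """
    declared = None
    domain = None
    blocks = None
    header = None
    rows: list[tuple[int, list[str]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("dialect:"):
                    declared = body.split(":", 1)[1].strip()
                elif body.startswith("domain:"):
                    w, h = body.split(":", 1)[1].split()
                    domain = Domain(float(w), float(h))
                elif body.startswith("blocks:"):
                    blocks = _parse_blocks(body.split(":", 1)[1])
                continue
            if header is None:
                header = [c.strip() for c in line.split(",")]
                continue
            rows.append((lineno, [c.strip() for c in line.split(",")]))
    if header is None:
        raise ObservationError(f"{path}: no header row found")
    use_dialect = dialect or declared
    if use_dialect is None:
        use_dialect = "features" if header[1].startswith("f") else "points"
    is_feature = use_dialect == "features"
    expected = (
        ["id", "x", "y", "weight"]
        if not is_feature
        else ["id"] + [f"f{i}" for i in range(len(header) - 2)] + ["weight"]
    )
    if header != expected:
        raise ObservationError(
            f"{path}: header {header} does not match dialect {use_dialect!r}"
        )
    ids, weights, payload = [], [], []
    for lineno, cells in rows:
        if len(cells) != len(header):
            raise ObservationError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(cells)}"
            )
        try:
            ids.append(int(cells[0]))
            vals = [float(c) for c in cells[1:-1]]
            weights.append(float(cells[-1]))
        except ValueError as exc:
            raise ObservationError(f"{path}:{lineno}: {exc}") from exc
        if is_feature:
            for i, v in enumerate(vals):
                if not 0.0 <= v <= 1.0:
                    raise ObservationError(
                        f"{path}:{lineno}: feature column f{i} value {v} "
                        "outside [0, 1]"
                    )
        payload.append(vals)
    arr = np.array(payload, dtype=float).reshape(len(payload), -1)
    if is_feature:
        return ObservationSet(
            ids=np.array(ids, dtype=int),
            weights=np.array(weights, dtype=float),
            dialect="features",
            features=arr,
            feature_blocks=blocks,
        )
    if domain is None and len(arr):
        domain = Domain(float(arr[:, 0].max()) + 1.0, float(arr[:, 1].max()) + 1.0)
    return ObservationSet(
        ids=np.array(ids, dtype=int),
        weights=np.array(weights, dtype=float),
        dialect=use_dialect,
        positions=arr if len(arr) else np.empty((0, 2)),
        domain=domain,
    )
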