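"""Flow-cytometry event I/O, transformation, gating and normalization.

Events flow through a fixed preprocessing order:

    read_fcs -> arcsinh_transform -> apply_gate -> normalize

The gate is drawn in transformed (arcsinh) coordinates, and the
normalization constant is the dataset-wide maximum of the transformed
target fluorescence channel (SYBR green I / FL1 by convention), so that
every sample — including deployment-time samples — is scaled by the same
value.

The FCS reader/writer here is deliberately minimal: list-mode files with
datatype ``F`` (float32), ``D`` (float64) or ``I`` (unsigned integer),
versions 2.0/3.0/3.1.  That covers the files this package writes and the
common output of modern acquisition software.
"""

from __future__ import annotations

import logging
import os
import struct
import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
import yaml
from shapely.geometry import Polygon

logger = logging.getLogger(__name__)

__all__ = [
    "EventMatrix",
    "PolygonGate",
    "read_fcs",
    "write_fcs",
    "arcsinh_transform",
    "apply_gate",
    "normalize",
    "compute_norm_constant",
    "read_gate",
    "write_gate",
]


@dataclass
class EventMatrix:
    """Single-cell events for one sample: ``values`` is (n_events, n_channels)."""

    sample_id: str
    channels: list[str]
    values: np.ndarray
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values.reshape(0, len(self.channels))
        if self.values.ndim != 2 or self.values.shape[1] != len(self.channels):
            raise ValueError(
                f"values shape {self.values.shape} incompatible with "
                f"{len(self.channels)} channels"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite event values in sample {self.sample_id!r}")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def channel(self, name: str) -> np.ndarray:
        """Column of a single channel."""
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in sample {self.sample_id!r}; "
                f"available: {self.channels}"
            ) from None
        return self.values[:, idx]


@dataclass
class PolygonGate:
    """A simple polygon in the plane of two (transformed) channels.

    Boundary points count as inside (closed-polygon semantics).
    """

    channel_x: str
    channel_y: str
    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        if self.vertices.shape[0] < 3:
            raise ValueError("a polygon gate needs at least 3 vertices")
        poly = Polygon(self.vertices)
        if not poly.is_simple:
            raise ValueError("gate polygon is self-intersecting")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside or on the polygon boundary."""
        poly = Polygon(self.vertices)
        pts = shapely.points(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
        return shapely.covers(poly, pts)

    @classmethod
    def rectangle(
        cls, channel_x: str, channel_y: str, x0: float, x1: float, y0: float, y1: float
    ) -> "PolygonGate":
        return cls(channel_x, channel_y, [(x0, y0), (x1, y0), (x1, y1), (x0, y1)])


# ---------------------------------------------------------------------------
# FCS reading / writing


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    delim = raw[:1].decode("latin-1")
    body = raw[1:].decode("latin-1")
    if body.endswith(delim):
        body = body[:-1]
    parts = body.split(delim)
    # doubled delimiters (escapes) are not supported by this minimal reader
    return {
        parts[i].strip(): parts[i + 1]
        for i in range(0, len(parts) - 1, 2)
        if parts[i].strip()
    }


def read_fcs(path: str | os.PathLike, channels: list[str] | None = None) -> EventMatrix:
    """Read a list-mode FCS file, restricted to *channels* in the given order.

    ``sample_id`` is the file's base name without extension.  Raises
    ``KeyError`` naming the missing channel (and listing the available
    ones) if a requested channel is absent.
    """
    path = os.fspath(path)
    with open(path, "rb") as fh:
        header = fh.read(58)
        if len(header) < 58 or not header[:3] == b"FCS":
            raise IOError(f"{path}: not an FCS file")
        version = header[:6].decode("latin-1")
        if version not in ("FCS2.0", "FCS3.0", "FCS3.1"):
            raise IOError(f"{path}: unsupported FCS version {version!r}")

        def _off(lo: int, hi: int) -> int:
            s = header[lo:hi].decode("latin-1").strip()
            return int(s) if s else 0

        text_start, text_end = _off(10, 18), _off(18, 26)
        data_start, data_end = _off(26, 34), _off(34, 42)
        fh.seek(text_start)
        text = _parse_text_segment(fh.read(text_end - text_start + 1))

        if data_start == 0:
            data_start = int(text["$BEGINDATA"])
            data_end = int(text["$ENDDATA"])

        n_par = int(text["$PAR"])
        n_tot = int(text["$TOT"])
        datatype = text["$DATATYPE"].strip().upper()
        mode = text.get("$MODE", "L").strip().upper()
        if mode != "L":
            raise IOError(f"{path}: only list-mode ($MODE=L) files are supported")
        byteord = text["$BYTEORD"].strip()
        little = byteord.startswith("1")
        endian = "<" if little else ">"

        names = [
            text.get(f"$P{i}N", f"P{i}").strip() for i in range(1, n_par + 1)
        ]
        bits = [int(text[f"$P{i}B"]) for i in range(1, n_par + 1)]

        fh.seek(data_start)
        raw = fh.read(data_end - data_start + 1)

    if datatype == "F":
        data = np.frombuffer(raw[: n_tot * n_par * 4], dtype=endian + "f4")
    elif datatype == "D":
        data = np.frombuffer(raw[: n_tot * n_par * 8], dtype=endian + "f8")
    elif datatype == "I":
        if len(set(bits)) != 1 or bits[0] not in (16, 32):
            raise IOError(f"{path}: unsupported integer widths {sorted(set(bits))}")
        width = bits[0] // 8
        data = np.frombuffer(
            raw[: n_tot * n_par * width], dtype=f"{endian}u{width}"
        )
    else:
        raise IOError(f"{path}: unsupported $DATATYPE {datatype!r}")

    values = data.reshape(n_tot, n_par).astype(float)
    sample_id = os.path.splitext(os.path.basename(path))[0]

    if channels is None:
        return EventMatrix(sample_id, names, values)
    cols = []
    for ch in channels:
        if ch not in names:
            raise KeyError(
                f"channel {ch!r} not found in {path}; available: {names}"
            )
        cols.append(names.index(ch))
    return EventMatrix(sample_id, list(channels), values[:, cols])


def write_fcs(path: str | os.PathLike, events: EventMatrix) -> None:
    """Write an FCS 3.0 file (float32 list mode, little-endian)."""
    path = os.fspath(path)
    values = np.asarray(events.values, dtype="<f4")
    n_tot, n_par = values.shape

    keywords = {
        "$DATATYPE": "F",
        "$MODE": "L",
        "$BYTEORD": "1,2,3,4",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
    }
    for i, name in enumerate(events.channels, start=1):
        keywords[f"$P{i}N"] = name
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        rng = float(values[:, i - 1].max()) if n_tot else 1.0
        keywords[f"$P{i}R"] = str(int(max(rng, 1.0)) + 1)

    # iterate: BEGINDATA/ENDDATA widths depend on the text length
    begin_data, end_data = 0, 0
    for _ in range(8):
        kw = dict(keywords)
        kw["$BEGINDATA"] = str(begin_data)
        kw["$ENDDATA"] = str(end_data)
        text = "/" + "".join(f"{k}/{v}/" for k, v in kw.items())
        text_start = 58
        text_end = text_start + len(text) - 1
        new_begin = text_end + 1
        new_end = new_begin + n_tot * n_par * 4 - 1
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end

    header = (
        b"FCS3.0    "
        + f"{text_start:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + (f"{begin_data:>8d}".encode() if begin_data <= 99_999_999 else b"       0")
        + (f"{end_data:>8d}".encode() if end_data <= 99_999_999 else b"       0")
        + f"{0:>8d}".encode() * 2
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text.encode("latin-1"))
        fh.write(values.tobytes())


# ---------------------------------------------------------------------------
# Transformations


def arcsinh_transform(events: EventMatrix) -> EventMatrix:
    """Apply asinh elementwise; the variance-stabilizing transform for FCM."""
    return EventMatrix(
        events.sample_id,
        list(events.channels),
        np.arcsinh(events.values),
        list(events.warnings),
    )


def apply_gate(events: EventMatrix, gate: PolygonGate) -> EventMatrix:
    """Keep events inside or on the gate polygon; order preserved.

    Events must already be in the coordinate space the gate was drawn in
    (here: arcsinh-transformed intensities).  An empty result is returned
    with a warning attached rather than raising, so callers can decide.
    """
    x = events.channel(gate.channel_x)
    y = events.channel(gate.channel_y)
    mask = gate.contains(x, y)
    out = EventMatrix(
        events.sample_id,
        list(events.channels),
        events.values[mask],
        list(events.warnings),
    )
    if out.n_events == 0:
        msg = f"sample {events.sample_id!r}: no events survive the gate"
        warnings.warn(msg)
        out.warnings.append(msg)
    return out


def normalize(
    events: EventMatrix, norm_constant: float, target_channel: str | None = None
) -> EventMatrix:
    """Divide every channel by the shared dataset-level constant.

    The constant is the dataset-wide maximum of the transformed target
    fluorescence channel (see :func:`compute_norm_constant`), so training
    samples land in [0, 1] on that channel.  A deployment sample brighter
    on *target_channel* than anything seen in training may exceed 1;
    that is logged, not an error.
    """
    if not norm_constant > 0:
        raise ValueError(f"norm_constant must be > 0, got {norm_constant}")
    values = events.values / norm_constant
    out = EventMatrix(events.sample_id, list(events.channels), values, list(events.warnings))
    if target_channel is not None and out.n_events:
        peak = out.channel(target_channel).max()
        if peak > 1.0 + 1e-12:
            logger.warning(
                "sample %s: %s exceeds 1 after normalization (max %.4f); "
                "sample is brighter than the training data",
                events.sample_id, target_channel, peak,
            )
    return out


def compute_norm_constant(samples: list[EventMatrix], target_channel: str) -> float:
    """Dataset-wide maximum of *target_channel* over all samples.

    Computed after arcsinh transform and gating; all samples (training
    and later deployment) must be divided by this one value.
    """
    if not samples:
        raise ValueError("need at least one sample to compute the norm constant")
    maxima = [s.channel(target_channel).max() for s in samples if s.n_events > 0]
    if not maxima:
        raise ValueError("all samples are empty; cannot compute norm constant")
    return float(max(maxima))


# ---------------------------------------------------------------------------
# Gate file round-trip (structured text)


def write_gate(path: str | os.PathLike, gate: PolygonGate) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "channel_x": gate.channel_x,
                "channel_y": gate.channel_y,
                "vertices": [[float(x), float(y)] for x, y in gate.vertices],
            },
            fh,
        )


def read_gate(path: str | os.PathLike) -> PolygonGate:
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    return PolygonGate(spec["channel_x"], spec["channel_y"], spec["vertices"])
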