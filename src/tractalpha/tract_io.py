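"""Tractogram container and readers/writers for TRK, TCK and plain-text polylines.

All coordinates are handled in world millimeters.  TRK stores per-point
scalars natively; TCK and txt carry no scalars, so opacity written to those
formats goes to a plain-text sidecar (``<file>.alpha.txt``, one value per
line, blank line between streamlines).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ConfigurationError, TractographyFormatError

logger = logging.getLogger(__name__)

_FORMATS = ("trk", "tck", "txt")


@dataclass
class Tractogram:
    """A collection of streamlines with optional per-point scalar channels.

    Parameters
    ----------
    streamlines : list of (N, 3) float arrays
        Point sequences in world millimeter coordinates, N >= 2 each.
    scalars : dict mapping channel name to list of (N,) float arrays
        One value per point per streamline; lengths must mirror
        ``streamlines``.  The ``"alpha"`` channel, when present, holds
        opacities in [0, 1].
    affine : (4, 4) array
        Voxel-to-world transform carried from the source format (identity
        for synthetic data).
    """

    streamlines: list = field(default_factory=list)
    scalars: dict = field(default_factory=dict)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __len__(self):
        return len(self.streamlines)

    @property
    def total_points(self) -> int:
        return int(sum(len(s) for s in self.streamlines))

    def with_scalar(self, name: str, values: list) -> "Tractogram":
        """Return a copy carrying an additional per-point channel."""
        scalars = dict(self.scalars)
        scalars[name] = [np.asarray(v, dtype=float) for v in values]
        out = Tractogram(self.streamlines, scalars, self.affine)
        out.validate()
        return out

    def validate(self) -> None:
        """Enforce the container invariants; raises ``ValueError`` on breach."""
        for idx, s in enumerate(self.streamlines):
            s = np.asarray(s)
            if s.ndim != 2 or s.shape[1] != 3:
                raise ValueError(f"streamline {idx} is not an (N, 3) array")
            if len(s) < 2:
                raise ValueError(f"streamline {idx} has fewer than 2 points")
            if not np.all(np.isfinite(s)):
                raise ValueError(f"streamline {idx} contains non-finite coordinates")
        for name, channel in self.scalars.items():
            if len(channel) != len(self.streamlines):
                raise ValueError(
                    f"scalar channel {name!r} has {len(channel)} entries "
                    f"for {len(self.streamlines)} streamlines"
                )
            for idx, (s, v) in enumerate(zip(self.streamlines, channel)):
                if len(np.atleast_1d(v)) != len(s):
                    raise ValueError(
                        f"scalar channel {name!r} length mismatch on streamline {idx}"
                    )
        if "alpha" in self.scalars:
            for v in self.scalars["alpha"]:
                v = np.asarray(v, dtype=float)
                if v.size and (v.min() < 0.0 or v.max() > 1.0):
                    raise ValueError("alpha channel values outside [0, 1]")


def _clean_streamlines(streamlines, scalars):
    """Drop N<2 streamlines and deduplicate coincident consecutive points.

    Returns cleaned (streamlines, scalars) plus the counts of dropped
    streamlines and removed duplicate points, which callers log.
    """
    kept, kept_scalars = [], {name: [] for name in scalars}
    n_dropped = 0
    n_dedup = 0
    for idx, s in enumerate(streamlines):
        s = np.asarray(s, dtype=float)
        if len(s) >= 2:
            keep = np.ones(len(s), dtype=bool)
            keep[1:] = np.any(np.diff(s, axis=0) != 0.0, axis=1)
            n_dedup += int((~keep).sum())
            s = s[keep]
        if len(s) < 2:
            n_dropped += 1
            continue
        kept.append(s)
        for name in scalars:
            v = np.asarray(scalars[name][idx], dtype=float).reshape(-1)
            kept_scalars[name].append(v[keep] if len(v) == len(keep) else v)
    return kept, kept_scalars, n_dropped, n_dedup


def _resolve_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        if fmt not in _FORMATS:
            raise ConfigurationError(f"unknown tractogram format {fmt!r}")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in _FORMATS:
        return suffix
    raise ConfigurationError(
        f"cannot infer format from extension {path.suffix!r}; pass format explicitly"
    )


def read_tractogram(path, format: str = "auto") -> Tractogram:
    """Read a tractogram, returning world-millimeter coordinates.

    Streamlines with fewer than 2 points are dropped and coincident
    consecutive points removed; both events are logged with counts.
    """
    path = Path(path)
    fmt = _resolve_format(path, format)
    if fmt == "txt":
        streamlines, scalars, affine = _read_txt(path)
    else:
        streamlines, scalars, affine = _read_nib(path, fmt)
    streamlines, scalars, n_dropped, n_dedup = _clean_streamlines(streamlines, scalars)
    if n_dropped:
        logger.info("dropped %d streamline(s) with fewer than 2 points", n_dropped)
    if n_dedup:
        logger.info("removed %d coincident consecutive point(s)", n_dedup)
    tractogram = Tractogram(streamlines, scalars, affine)
    tractogram.validate()
    return tractogram


def _read_nib(path: Path, fmt: str):
    try:
        obj = nib.streamlines.load(str(path))
    except Exception as exc:  # nibabel raises assorted errors on corrupt input
        raise TractographyFormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
    expected = {"trk": nib.streamlines.trk.TrkFile, "tck": nib.streamlines.tck.TckFile}
    if not isinstance(obj, expected[fmt]):
        raise TractographyFormatError(
            f"{path} is not a {fmt.upper()} file (detected {type(obj).__name__})"
        )
    tg = obj.tractogram  # coordinates already in RAS+ mm
    streamlines = [np.asarray(s, dtype=float) for s in tg.streamlines]
    scalars = {}
    for name in tg.data_per_point.keys():
        scalars[name] = [
            np.asarray(v, dtype=float).reshape(-1) for v in tg.data_per_point[name]
        ]
    affine = np.asarray(obj.header.get("voxel_to_rasmm", np.eye(4)), dtype=float)
    sidecar = path.with_suffix(path.suffix + ".alpha.txt")
    if fmt == "tck" and sidecar.exists():
        scalars["alpha"] = _read_sidecar(sidecar)
    return streamlines, scalars, affine


def _read_txt(path: Path):
    streamlines, current = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                if current:
                    streamlines.append(np.asarray(current, dtype=float))
                    current = []
                continue
            parts = line.split()
            if len(parts) != 3:
                raise TractographyFormatError(
                    f"{path}:{lineno}: expected 'x y z', got {line!r}"
                )
            try:
                current.append([float(p) for p in parts])
            except ValueError as exc:
                raise TractographyFormatError(f"{path}:{lineno}: {exc}") from exc
    if current:
        streamlines.append(np.asarray(current, dtype=float))
    scalars = {}
    sidecar = path.with_suffix(path.suffix + ".alpha.txt")
    if sidecar.exists():
        scalars["alpha"] = _read_sidecar(sidecar)
    return streamlines, scalars, np.eye(4)


def _read_sidecar(path: Path):
    channels, current = [], []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                if current:
                    channels.append(np.asarray(current, dtype=float))
                    current = []
                continue
            current.append(float(line))
    if current:
        channels.append(np.asarray(current, dtype=float))
    return channels


def write_tractogram(tractogram: Tractogram, path, format: str = "auto") -> None:
    """Write a tractogram; validates invariants before any bytes are written.

    TRK embeds scalar channels natively.  TCK and txt cannot carry scalars,
    so an ``"alpha"`` channel is written to a sidecar file instead.
    """
    path = Path(path)
    fmt = _resolve_format(path, format)
    tractogram.validate()
    if fmt == "trk":
        _write_nib(tractogram, path, nib.streamlines.trk.TrkFile)
    elif fmt == "tck":
        _write_nib(tractogram, path, nib.streamlines.tck.TckFile, scalars=False)
        _write_sidecars(tractogram, path)
    else:
        _write_txt(tractogram, path)
        _write_sidecars(tractogram, path)


def _write_nib(tractogram, path, cls, scalars=True):
    data_per_point = {}
    if scalars:
        for name, channel in tractogram.scalars.items():
            data_per_point[name] = [
                np.asarray(v, dtype=np.float32).reshape(-1, 1) for v in channel
            ]
    nib_tg = nib.streamlines.Tractogram(
        streamlines=[np.asarray(s, dtype=np.float32) for s in tractogram.streamlines],
        data_per_point=data_per_point or None,
        affine_to_rasmm=np.eye(4),
    )
    header = cls.create_empty_header()
    cls(nib_tg, header=header).save(str(path))


def _write_txt(tractogram, path):
    with open(path, "w") as fh:
        for i, s in enumerate(tractogram.streamlines):
            if i:
                fh.write("\n")
            for p in s:
                fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")


def _write_sidecars(tractogram, path):
    if "alpha" not in tractogram.scalars:
        return
    sidecar = path.with_suffix(path.suffix + ".alpha.txt")
    with open(sidecar, "w") as fh:
        for i, v in enumerate(tractogram.scalars["alpha"]):
            if i:
                fh.write("\n")
            for a in np.asarray(v, dtype=float).reshape(-1):
                fh.write(f"{a:.9g}\n")
    logger.info("wrote opacity sidecar %s", sidecar)
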