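"""List-mode file format and provenance headers.

A list-mode file is a small JSON header followed by named numpy columns:

    magic ``MPLM`` | uint32 header length | UTF-8 JSON header | columns,
    each stored with ``numpy.save`` in file order given by the header.

The header records the format version, the seed, a scenario digest, the
scanner-config digest, physics constants, the multiples policy and the
per-truth-class counts, so every artifact carries its full provenance.
Round trips are lossless and bit-exact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Optional

import numpy as np

from .coincidence import CoincidenceList
from .mc import SinglesList

MAGIC = b"MPLM"
VERSION = 1

_SINGLES_FIELDS = (
    "decay_id",
    "module",
    "position",
    "energy_true",
    "energy",
    "time",
    "n_scatters",
)
_COINC_FIELDS = (
    "module",
    "position",
    "energy",
    "time",
    "decay_id",
    "n_scatters",
    "label",
)


def config_digest(config) -> str:
    """Stable digest of a scanner configuration."""
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_listmode(
    stream: SinglesList | CoincidenceList,
    path: str | Path,
    header: Optional[Dict] = None,
    strip_truth: bool = False,
) -> None:
    """Write a singles or coincidence stream with its provenance header.

    ``strip_truth`` zeroes the ground-truth lineage (decay ids, scatter
    counts, labels) for prompts-only exports to downstream sinogram
    analyses.
    """
    if strip_truth:
        import copy

        stream = copy.copy(stream)
        stream.decay_id = np.zeros_like(stream.decay_id)
        stream.n_scatters = np.zeros_like(stream.n_scatters)
        if isinstance(stream, CoincidenceList):
            stream.label = np.zeros_like(stream.label)
    if isinstance(stream, SinglesList):
        kind, fields = "singles", _SINGLES_FIELDS
    elif isinstance(stream, CoincidenceList):
        kind, fields = "coincidences", _COINC_FIELDS
    else:
        raise TypeError(f"cannot serialise {type(stream).__name__}")
    meta = dict(header or {})
    meta.update(
        {
            "format": "monopet-listmode",
            "version": VERSION,
            "kind": kind,
            "fields": list(fields),
            "n_records": len(stream),
        }
    )
    if kind == "coincidences":
        meta["counts_by_class"] = stream.counts_by_class()
    blob = json.dumps(meta, sort_keys=True).encode()
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(np.uint32(len(blob)).tobytes())
        fh.write(blob)
        for f in fields:
            np.save(fh, getattr(stream, f), allow_pickle=False)


def read_listmode(path: str | Path):
    """Read a list-mode file; returns ``(stream, header)``.

    Raises on version mismatch, truncation (naming the missing column) or
    unordered singles records.
    """
    with open(path, "rb") as fh:
        magic = fh.read(4)
        if magic != MAGIC:
            raise ValueError("not a monopet list-mode file")
        (hlen,) = np.frombuffer(fh.read(4), dtype=np.uint32)
        header = json.loads(fh.read(int(hlen)).decode())
        if header.get("version") != VERSION:
            raise ValueError(
                f"unsupported list-mode version {header.get('version')!r}"
            )
        fields = header["fields"]
        columns = {}
        for f in fields:
            try:
                columns[f] = np.load(fh, allow_pickle=False)
            except Exception as exc:
                raise ValueError(f"truncated file: column {f!r} unreadable") from exc
        n = header["n_records"]
        for f, col in columns.items():
            if len(col) != n:
                raise ValueError(
                    f"truncated file: column {f!r} has {len(col)} of {n} records"
                )
    if header["kind"] == "singles":
        stream: SinglesList | CoincidenceList = SinglesList(**columns)
        if n > 1 and np.any(np.diff(stream.time) < 0):
            raise ValueError("singles records are not time-ordered")
    else:
        stream = CoincidenceList(**columns)
        counts = header.get("counts_by_class")
        if counts is not None and counts != stream.counts_by_class():
            raise ValueError("header truth-class counts disagree with records")
    return stream, header


def write_image(image, path: str | Path, header: Optional[Dict] = None) -> None:
    """Raw little-endian float32 volume plus a JSON sidecar header."""
    path = Path(path)
    data = np.asarray(image.values, dtype="<f4")
    data.tofile(path)
    meta = dict(header or {})
    meta.update(
        {
            "shape": list(image.grid.shape),
            "voxel_size_mm": list(image.grid.voxel_size),
            "origin_mm": list(image.grid.origin),
            "units": image.units,
            "dtype": "<f4",
            "order": "C",
        }
    )
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=2, sort_keys=True)
    )


def read_image(path: str | Path):
    """Read a raw volume written by :func:`write_image`."""
    from .grids import ImageVolume, VoxelGrid

    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    grid = VoxelGrid(
        tuple(meta["origin_mm"]), tuple(meta["voxel_size_mm"]), tuple(meta["shape"])
    )
    values = np.fromfile(path, dtype="<f4").reshape(grid.shape)
    return ImageVolume(grid, values.astype(np.float64), units=meta.get("units", ""))


def write_nifti(image, path: str | Path) -> None:
    """Optional NIfTI export for viewing in standard tools."""
    import nibabel as nib

    affine = np.diag(list(image.grid.voxel_size) + [1.0])
    affine[:3, 3] = np.asarray(image.grid.origin) + np.asarray(
        image.grid.voxel_size
    ) / 2.0
    nib.save(nib.Nifti1Image(np.asarray(image.values, dtype=np.float32), affine), str(path))
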