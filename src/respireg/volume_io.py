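"""Reading and writing 4-D grayscale CT stacks.

Two on-disk layouts are supported:

``png``
    One directory per phase holding zero-padded per-slice PNG (or TIFF)
    files, ``<phase>/<index:04d>.png`` with 1-based indices.
``raw``
    One raw binary volume per phase next to a MetaImage-style text header
    (``NDims``, ``DimSize``, ``ElementSpacing``, ``ElementType``,
    ``ElementDataFile``).

All in-memory intensities are 8-bit.  16-bit inputs are linearly rescaled
to 0-255 using the dataset-global min and max (per-slice scaling would
distort inter-slice entropy comparisons); the applied rescale is recorded
in ``provenance``.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import FormatError

__all__ = ["Volume4D", "default_phase_labels", "read_dataset", "write_dataset"]

_IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


def default_phase_labels(n_phases: int) -> list[str]:
    """T00, T10, ... for ten phases; evenly spaced percentages otherwise."""
    labels = [f"T{(100 * i) // n_phases:02d}" for i in range(n_phases)]
    if len(set(labels)) != n_phases:  # too many phases for distinct percentages
        labels = [f"P{i:03d}" for i in range(n_phases)]
    return labels


@dataclass
class Volume4D:
    """A 4-D intensity stack indexed ``[phase][slice][row][col]``.

    Slice indices are 0-based in memory; file names and CSV reports use the
    conventional 1-based numbering.
    """

    data: np.ndarray
    phase_labels: list[str]
    slice_spacing_mm: float = 2.5
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4-D data, got ndim={self.data.ndim}")
        if self.data.dtype != np.uint8:
            raise ValueError("Volume4D holds 8-bit intensities; rescale first")
        if len(self.phase_labels) != self.data.shape[0]:
            raise ValueError("one phase label per phase is required")

    @property
    def n_phases(self) -> int:
        return self.data.shape[0]

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def phase_index(self, label: str) -> int:
        try:
            return self.phase_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown phase label {label!r}; have {self.phase_labels}")

    def get_slice(self, phase: int | str, slice_index: int) -> np.ndarray:
        p = self.phase_index(phase) if isinstance(phase, str) else phase
        return self.data[p, slice_index]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _rescale_to_uint8(stacks: list[np.ndarray]) -> tuple[list[np.ndarray], str]:
    """Global min-max rescale of >8-bit stacks; no-op for uint8 input."""
    if all(s.dtype == np.uint8 for s in stacks):
        return stacks, ""
    lo = min(float(s.min()) for s in stacks)
    hi = max(float(s.max()) for s in stacks)
    if hi <= lo:
        return [np.zeros_like(s, dtype=np.uint8) for s in stacks], (
            f"rescaled constant input (min=max={lo}) to 0"
        )
    out = [
        np.clip(np.rint((s.astype(np.float64) - lo) / (hi - lo) * 255), 0, 255).astype(np.uint8)
        for s in stacks
    ]
    return out, f"rescaled [{lo:g}, {hi:g}] -> [0, 255]"


def _read_png_phase(phase_dir: Path) -> np.ndarray:
    import imageio.v3 as iio

    files = sorted(
        f for f in phase_dir.iterdir() if f.suffix.lower() in _IMAGE_SUFFIXES
    )
    if not files:
        raise FormatError(f"no slice images in {phase_dir}")
    indices = []
    for f in files:
        m = re.fullmatch(r"0*(\d+)", f.stem)
        indices.append(int(m.group(1)) if m else None)
    if all(i is not None for i in indices):
        expected = list(range(min(indices), min(indices) + len(indices)))
        if sorted(indices) != expected:
            missing = sorted(set(range(min(indices), max(indices) + 1)) - set(indices))
            raise FormatError(
                f"missing slice(s) {missing} in {phase_dir}"
            )
    slices = []
    for f in files:
        img = np.asarray(iio.imread(f))
        if img.ndim == 3:  # collapse grayscale-coded RGB
            img = img[..., 0]
        slices.append(img)
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise FormatError(f"inconsistent slice dimensions {shapes} in {phase_dir}")
    return np.stack(slices)


def _parse_mhd(path: Path) -> dict[str, str]:
    meta = {}
    for line in path.read_text().splitlines():
        if "=" in line:
            key, _, value = line.partition("=")
            meta[key.strip()] = value.strip()
    return meta


_ELEMENT_DTYPES = {"MET_UCHAR": np.uint8, "MET_USHORT": np.uint16, "MET_SHORT": np.int16}


def _read_raw_phase(header: Path) -> tuple[np.ndarray, float]:
    meta = _parse_mhd(header)
    if meta.get("NDims") != "3":
        raise FormatError(f"{header}: expected NDims = 3")
    try:
        dx, dy, dz = (int(v) for v in meta["DimSize"].split())
        dtype = _ELEMENT_DTYPES[meta["ElementType"]]
        datafile = header.parent / meta["ElementDataFile"]
    except KeyError as exc:
        raise FormatError(f"{header}: missing header field {exc}")
    spacing = 1.0
    if "ElementSpacing" in meta:
        spacing = float(meta["ElementSpacing"].split()[-1])
    expected = dx * dy * dz * np.dtype(dtype).itemsize
    actual = datafile.stat().st_size
    if actual != expected:
        raise FormatError(
            f"{datafile}: header declares {dz} slices of {dy}x{dx} "
            f"({expected} bytes) but the file holds {actual} bytes"
        )
    data = np.fromfile(datafile, dtype=dtype).reshape(dz, dy, dx)
    return data, spacing


def read_dataset(root, layout: str = "png", slice_spacing_mm: float | None = None) -> Volume4D:
    """Read a 4-D dataset from ``root``.

    Phases are ordered by label (directory or header file name); slices by
    zero-padded file name or header order.
    """
    root = Path(root)
    if not root.exists():
        raise FormatError(f"dataset root {root} does not exist")
    spacing = slice_spacing_mm
    if layout == "png":
        phase_dirs = sorted(d for d in root.iterdir() if d.is_dir())
        if not phase_dirs:
            raise FormatError(f"no phase directories under {root}")
        labels = [d.name for d in phase_dirs]
        stacks = [_read_png_phase(d) for d in phase_dirs]
    elif layout == "raw":
        headers = sorted(root.glob("*.mhd"))
        if not headers:
            raise FormatError(f"no .mhd headers under {root}")
        labels = [h.stem for h in headers]
        stacks = []
        for h in headers:
            stack, sp = _read_raw_phase(h)
            stacks.append(stack)
            spacing = spacing if spacing is not None else sp
    else:
        raise ValueError(f"unknown layout {layout!r} (expected 'png' or 'raw')")

    shapes = {s.shape for s in stacks}
    if len(shapes) != 1:
        raise FormatError(f"phases have inconsistent dimensions: {shapes}")
    stacks, note = _rescale_to_uint8(stacks)
    provenance = str(root) + (f" ({note})" if note else "")
    return Volume4D(
        data=np.stack(stacks),
        phase_labels=labels,
        slice_spacing_mm=spacing if spacing is not None else 2.5,
        provenance=provenance,
    )


def write_dataset(volume: Volume4D, root, layout: str = "png") -> dict:
    """Write ``volume`` under ``root``; returns a manifest with checksums.

    Lossless for 8-bit data in both layouts.
    """
    if volume.data.size == 0:
        raise ValueError("refusing to write an empty volume")
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    files: list[dict] = []
    if layout == "png":
        import imageio.v3 as iio

        for p, label in enumerate(volume.phase_labels):
            d = root / label
            d.mkdir(parents=True, exist_ok=True)
            for k in range(volume.n_slices):
                path = d / f"{k + 1:04d}.png"
                iio.imwrite(path, volume.data[p, k])
                files.append({"path": str(path.relative_to(root)), "sha256": _sha256(path)})
    elif layout == "raw":
        h, w = volume.frame_shape
        for p, label in enumerate(volume.phase_labels):
            raw = root / f"{label}.raw"
            raw.write_bytes(volume.data[p].tobytes())
            header = root / f"{label}.mhd"
            header.write_text(
                "ObjectType = Image\n"
                "NDims = 3\n"
                f"DimSize = {w} {h} {volume.n_slices}\n"
                f"ElementSpacing = 1 1 {volume.slice_spacing_mm}\n"
                "ElementType = MET_UCHAR\n"
                f"ElementDataFile = {raw.name}\n"
            )
            for path in (raw, header):
                files.append({"path": str(path.relative_to(root)), "sha256": _sha256(path)})
    else:
        raise ValueError(f"unknown layout {layout!r} (expected 'png' or 'raw')")
    manifest = {
        "layout": layout,
        "phases": list(volume.phase_labels),
        "n_slices": volume.n_slices,
        "frame_shape": list(volume.frame_shape),
        "slice_spacing_mm": volume.slice_spacing_mm,
        "files": files,
    }
    return manifest
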