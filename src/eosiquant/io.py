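"""Readers and writers: TIFF images, spectral cubes, ground-truth sidecars.

Images travel as 8/16-bit (multi-page) TIFF with a JSON sidecar carrying
the pixel size when the TIFF tags cannot.  Spectral cubes have two
interconvertible on-disk forms:

* **binary cube** — magic ``EQCUBE01``, three little-endian uint32
  (rows, cols, n_wavenumbers), the float64 wavenumber axis, then the
  float64 spectra matrix (pixels × wavenumbers, row-major);
* **text matrix** — plain text, ``# shape: rows cols`` header comment,
  first data row = wavenumber axis, each further row = one pixel spectrum.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence, Union

import numpy as np
import tifffile

from .image import IntensityImage
from .raman import SpectralCube

_CUBE_MAGIC = b"EQCUBE01"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_image(images: Union[IntensityImage, Sequence[IntensityImage]], path) -> None:
    """Write one or more images as a (multi-page) TIFF plus metadata sidecar."""
    path = Path(path)
    if isinstance(images, IntensityImage):
        images = [images]
    pages = []
    for img in images:
        arr = np.asarray(img.pixels)
        if arr.dtype not in (np.uint8, np.uint16):
            raise ValueError(f"unsupported bit depth for TIFF output: {arr.dtype}")
        pages.append(arr)
    tifffile.imwrite(
        path,
        np.stack(pages) if len(pages) > 1 else pages[0],
        photometric="minisblack",
    )
    meta = {"pixel_size": images[0].pixel_size, "bit_depth": [img.bit_depth for img in images]}
    _sidecar(path).write_text(json.dumps(meta))


def read_image(path) -> Union[IntensityImage, List[IntensityImage]]:
    """Read a (multi-page) TIFF; returns a list when there are several pages."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    if data.dtype not in (np.uint8, np.uint16):
        raise ValueError(f"unsupported bit depth: {data.dtype}")
    pixel_size = None
    bit_depths = None
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        pixel_size = meta.get("pixel_size")
        bit_depths = meta.get("bit_depth")
    if data.ndim == 2:
        bd = bit_depths[0] if bit_depths else "native"
        return IntensityImage(data, pixel_size=pixel_size, bit_depth=bd)
    images = []
    for i, page in enumerate(data):
        bd = bit_depths[i] if bit_depths and i < len(bit_depths) else "native"
        images.append(IntensityImage(page, pixel_size=pixel_size, bit_depth=bd))
    return images


def write_ground_truth(truth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_json_dict(), indent=1))


def write_cube(cube: SpectralCube, path, fmt: str = "binary") -> None:
    """Write a spectral cube in binary (``EQCUBE01``) or text-matrix form."""
    path = Path(path)
    rows, cols = cube.spatial_shape
    if fmt == "binary":
        with open(path, "wb") as fh:
            fh.write(_CUBE_MAGIC)
            np.asarray([rows, cols, cube.wavenumber_axis.size], dtype="<u4").tofile(fh)
            cube.wavenumber_axis.astype("<f8").tofile(fh)
            cube.spectra.astype("<f8").tofile(fh)
    elif fmt == "text":
        body = np.vstack([cube.wavenumber_axis, cube.spectra])
        np.savetxt(path, body, header=f"shape: {rows} {cols}")
    else:
        raise ValueError(f"unknown cube format {fmt!r}")


def read_cube(path, fmt: str = "binary") -> SpectralCube:
    """Read a spectral cube written by :func:`write_cube`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "binary":
        raw = path.read_bytes()
        if raw[: len(_CUBE_MAGIC)] != _CUBE_MAGIC:
            raise ValueError(f"{path}: not an EQCUBE01 file")
        off = len(_CUBE_MAGIC)
        dims = np.frombuffer(raw, dtype="<u4", count=3, offset=off)
        rows, cols, nw = (int(x) for x in dims)
        off += 12
        expected = off + 8 * nw + 8 * rows * cols * nw
        if len(raw) < expected:
            raise ValueError(f"{path}: truncated cube (have {len(raw)} bytes, need {expected})")
        axis = np.frombuffer(raw, dtype="<f8", count=nw, offset=off)
        off += 8 * nw
        spectra = np.frombuffer(raw, dtype="<f8", count=rows * cols * nw, offset=off)
        return SpectralCube(
            spectra=spectra.reshape(rows * cols, nw).copy(),
            wavenumber_axis=axis.copy(),
            spatial_shape=(rows, cols),
        )
    if fmt == "text":
        with open(path) as fh:
            header = fh.readline()
        if "shape:" not in header:
            raise ValueError(f"{path}: missing shape header")
        rows, cols = (int(x) for x in header.split("shape:")[1].split())
        body = np.loadtxt(path)
        axis, spectra = body[0], body[1:]
        if spectra.shape[0] != rows * cols:
            raise ValueError(f"{path}: matrix has {spectra.shape[0]} rows, header promises {rows * cols}")
        return SpectralCube(spectra=spectra, wavenumber_axis=axis, spatial_shape=(rows, cols))
    raise ValueError(f"unknown cube format {fmt!r}")
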