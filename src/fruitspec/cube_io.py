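"""Hyperspectral cube I/O, fruit segmentation and mean-spectrum extraction.

Cubes are exchanged as ENVI header + raw binary (interleaves BSQ/BIL/BIP,
float32/float64/uint16) or as multi-page TIFF with wavelengths in the image
description; in memory the band axis is always last and wavelengths are
strictly increasing.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from skimage import filters, measure, morphology

from .datatypes import HyperCube

__all__ = [
    "ObjectSpectrum",
    "read_cube",
    "write_cube",
    "build_mask",
    "extract_object_spectra",
]

# ENVI numeric data-type codes
_ENVI_DTYPES = {4: np.float32, 5: np.float64, 12: np.uint16}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5, np.dtype(np.uint16): 12}

#: default segmentation band per region: where fruit/background contrast
#: is maximal for typical fruit reflectance
DEFAULT_MASK_BAND = {"VIS-NIR": 800.0, "NIR": 1100.0}


@dataclass
class ObjectSpectrum:
    """Mean spectrum of one connected fruit object."""

    object_id: int
    pixel_count: int
    mean_spectrum: np.ndarray
    centroid: tuple[float, float]

    def __post_init__(self) -> None:
        if self.pixel_count < 1:
            raise ValueError("object must contain at least one pixel")


# --------------------------------------------------------------------------
# ENVI dialect

def _parse_envi_header(text: str) -> dict:
    """Parse an ENVI header into a flat dict; brace values may span lines."""
    if not text.lstrip().upper().startswith("ENVI"):
        raise ValueError("not an ENVI header (missing ENVI magic line)")
    body = text.lstrip()[4:]
    fields: dict[str, str] = {}
    pos = 0
    while pos < len(body):
        eq = body.find("=", pos)
        if eq < 0:
            break
        key = body[pos:eq].strip().lower()
        rest = body[eq + 1 :].lstrip()
        offset = len(body) - len(rest)
        if rest.startswith("{"):
            close = rest.find("}")
            if close < 0:
                raise ValueError(f"unterminated brace value for {key!r}")
            value = rest[1:close]
            pos = offset + close + 1
        else:
            nl = rest.find("\n")
            nl = len(rest) if nl < 0 else nl
            value = rest[:nl]
            pos = offset + nl
        if key:
            fields[key] = value.strip()
    return fields


def _header_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".hdr") if path.suffix != ".hdr" else path


def write_cube(
    cube: HyperCube,
    path,
    dialect: str = "ENVI",
    interleave: str = "bsq",
    dtype=None,
) -> Path:
    """Write a cube; returns the data file path.

    ENVI writes ``<path>`` (raw binary) plus ``<path>.hdr``; TIFF writes a
    multi-page file with one page per band and a JSON description carrying
    wavelengths and region.
    """
    path = Path(path)
    data = cube.data if dtype is None else np.asarray(cube.data, dtype=dtype)
    if dialect.upper() == "ENVI":
        interleave = interleave.lower()
        if interleave not in ("bsq", "bil", "bip"):
            raise ValueError(f"unknown interleave {interleave!r}")
        code = _ENVI_CODES.get(np.dtype(data.dtype))
        if code is None:
            raise ValueError(f"unsupported ENVI dtype {data.dtype}")
        rows, cols, bands = data.shape
        if interleave == "bsq":
            ordered = np.transpose(data, (2, 0, 1))
        elif interleave == "bil":
            ordered = np.transpose(data, (0, 2, 1))
        else:
            ordered = data
        wl = ", ".join(f"{w:g}" for w in cube.wavelengths)
        header = (
            "ENVI\n"
            f"description = {{fruitspec reflectance cube, region {cube.region}}}\n"
            f"samples = {cols}\n"
            f"lines = {rows}\n"
            f"bands = {bands}\n"
            "header offset = 0\n"
            "file type = ENVI Standard\n"
            f"data type = {code}\n"
            f"interleave = {interleave}\n"
            "byte order = 0\n"
            "wavelength units = nm\n"
            f"wavelength = {{{wl}}}\n"
        )
        _header_path(path).write_text(header)
        ordered = np.ascontiguousarray(ordered)
        ordered.tofile(path)
        return path
    if dialect.upper() == "TIFF":
        desc = json.dumps(
            {"wavelengths": list(map(float, cube.wavelengths)), "region": cube.region}
        )
        tifffile.imwrite(path, np.transpose(data, (2, 0, 1)), description=desc)
        return path
    raise ValueError(f"unknown dialect {dialect!r}; expected ENVI or TIFF")


def read_cube(path, dialect: str = "ENVI", region: str | None = None) -> HyperCube:
    """Read an ENVI or TIFF cube back into the band-last memory layout."""
    path = Path(path)
    if dialect.upper() == "ENVI":
        hdr = _parse_envi_header(_header_path(path).read_text())
        try:
            rows = int(hdr["lines"])
            cols = int(hdr["samples"])
            bands = int(hdr["bands"])
            code = int(hdr["data type"])
            interleave = hdr["interleave"].lower()
        except KeyError as e:
            raise ValueError(f"ENVI header missing required field {e}") from e
        if "wavelength" not in hdr:
            raise ValueError("ENVI header lists no wavelengths")
        wavelengths = np.array(
            [float(v) for v in hdr["wavelength"].replace("\n", " ").split(",") if v.strip()]
        )
        if wavelengths.size != bands:
            raise ValueError(
                f"header declares {bands} bands but lists {wavelengths.size} wavelengths"
            )
        if code not in _ENVI_DTYPES:
            raise ValueError(f"unsupported ENVI data type code {code}")
        raw = np.fromfile(path, dtype=_ENVI_DTYPES[code])
        expected = rows * cols * bands
        if raw.size != expected:
            raise ValueError(
                f"binary holds {raw.size} values but header implies {expected} "
                f"({rows}x{cols}x{bands})"
            )
        if interleave == "bsq":
            data = np.transpose(raw.reshape(bands, rows, cols), (1, 2, 0))
        elif interleave == "bil":
            data = np.transpose(raw.reshape(rows, bands, cols), (0, 2, 1))
        elif interleave == "bip":
            data = raw.reshape(rows, cols, bands)
        else:
            raise ValueError(f"unknown interleave {interleave!r}")
        region = region or hdr.get("description", "")
        tag = "VIS-NIR" if "VIS-NIR" in str(region) else "NIR"
        return HyperCube(np.ascontiguousarray(data), wavelengths, tag)
    if dialect.upper() == "TIFF":
        with tifffile.TiffFile(path) as tf:
            stack = tf.asarray()
            desc = tf.pages[0].description
        meta = json.loads(desc)
        wavelengths = np.asarray(meta["wavelengths"], dtype=float)
        if stack.ndim != 3 or stack.shape[0] != wavelengths.size:
            raise ValueError(
                f"TIFF has shape {stack.shape} but {wavelengths.size} wavelengths"
            )
        return HyperCube(
            np.transpose(stack, (1, 2, 0)), wavelengths, meta.get("region", "NIR")
        )
    raise ValueError(f"unknown dialect {dialect!r}; expected ENVI or TIFF")


# --------------------------------------------------------------------------
# segmentation

def build_mask(
    cube: HyperCube,
    method: str = "otsu",
    band: float | None = None,
    threshold: float | None = None,
    min_pixels: int = 20,
) -> np.ndarray:
    """Threshold one band into a foreground mask (fruit = brighter).

    ``band`` is a wavelength in nm (nearest band is used); default is the
    region's high-contrast band (800 nm VIS-NIR, 1100 nm NIR).  ``otsu``
    computes the threshold from the band histogram; ``fixed`` requires an
    explicit ``threshold``.  Objects smaller than ``min_pixels`` are
    dropped (8-connectivity).
    """
    if band is None:
        band = DEFAULT_MASK_BAND.get(cube.region, float(np.median(cube.wavelengths)))
    idx = cube.band_index(band)
    img = cube.data[:, :, idx]
    if method == "otsu":
        thr = float(filters.threshold_otsu(img))
    elif method == "fixed":
        if threshold is None:
            raise ValueError("method 'fixed' requires an explicit threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown masking method {method!r}")
    mask = img > thr
    if min_pixels > 1:
        mask = morphology.remove_small_objects(
            mask, max_size=min_pixels - 1, connectivity=2
        )
    if not mask.any():
        raise ValueError(
            f"empty foreground: no pixels above threshold {thr:.4g} at "
            f"{cube.wavelengths[idx]:g} nm"
        )
    return mask


def extract_object_spectra(cube: HyperCube, mask: np.ndarray) -> list[ObjectSpectrum]:
    """Label connected fruit objects and return each one's mean spectrum.

    8-connectivity; objects are ordered row-major by centroid.  The mean is
    the unweighted average over the object's pixels.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.data.shape[:2]:
        raise ValueError("mask shape does not match cube spatial shape")
    if not mask.any():
        raise ValueError("mask is empty; nothing to extract")
    labels = measure.label(mask, connectivity=2)
    props = measure.regionprops(labels)
    props.sort(key=lambda p: (p.centroid[0], p.centroid[1]))
    out = []
    for new_id, p in enumerate(props, start=1):
        sel = labels == p.label
        mean = cube.data[sel].mean(axis=0)
        out.append(
            ObjectSpectrum(
                object_id=new_id,
                pixel_count=int(p.area),
                mean_spectrum=mean,
                centroid=(float(p.centroid[0]), float(p.centroid[1])),
            )
        )
    return out
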