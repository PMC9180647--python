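"""Minimal ENVI image I/O: text ``.hdr`` plus flat binary, BSQ/BIL/BIP.

Supports the header fields this pipeline needs (samples, lines, bands, data
type, interleave, byte order, wavelength list). Cubes are exchanged as
(lines, samples, bands) arrays.
"""

from __future__ import annotations

import os
import re

import numpy as np

_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
           5: np.float64, 12: np.uint16}
_DTYPE_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}


def _parse_header(text: str) -> dict:
    """Parse ENVI header key = value pairs; braces delimit multi-line lists."""
    if not text.lstrip().lower().startswith("envi"):
        raise ValueError("not an ENVI header (missing 'ENVI' magic)")
    fields: dict[str, str] = {}
    body = text.lstrip()[4:]
    pattern = re.compile(r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.MULTILINE | re.DOTALL)
    pos = 0
    while True:
        m = pattern.search(body, pos)
        if m is None:
            break
        fields[m.group(1).strip().lower()] = m.group(2).strip()
        pos = m.end()
    return fields


def read_envi(hdr_path: str) -> tuple[np.ndarray, np.ndarray]:
    """Read an ENVI cube; returns (values[lines, samples, bands], wavelengths_nm)."""
    with open(hdr_path) as fh:
        fields = _parse_header(fh.read())
    lines = int(fields["lines"])
    samples = int(fields["samples"])
    bands = int(fields["bands"])
    dtype = np.dtype(_DTYPES[int(fields["data type"])])
    if int(fields.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")
    interleave = fields.get("interleave", "bsq").lower()

    data_path = fields.get("data file")
    if data_path is None:
        stem = hdr_path[:-4] if hdr_path.endswith(".hdr") else hdr_path
        for cand in (stem, stem + ".dat", stem + ".img", stem + ".raw"):
            if os.path.exists(cand) and not cand.endswith(".hdr"):
                data_path = cand
                break
        if data_path is None:
            raise FileNotFoundError(f"no data file found next to {hdr_path}")

    flat = np.fromfile(data_path, dtype=dtype)
    if flat.size != lines * samples * bands:
        raise ValueError("data file size does not match header dimensions")
    if interleave == "bsq":
        cube = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = flat.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")

    wl_field = fields.get("wavelength")
    if wl_field is not None:
        wl = np.array([float(x) for x in wl_field.strip("{}").replace("\n", " ").split(",")
                       if x.strip()])
    else:
        wl = np.arange(bands, dtype=float)
    return np.ascontiguousarray(cube), wl


def write_envi(hdr_path: str, values: np.ndarray, wavelengths_nm: np.ndarray,
               interleave: str = "bsq", dtype=np.float32) -> None:
    """Write (lines, samples, bands) values and a matching ``.hdr``."""
    values = np.asarray(values)
    if values.ndim != 3:
        raise ValueError("cube must be 3-D (lines, samples, bands)")
    lines, samples, bands = values.shape
    if len(wavelengths_nm) != bands:
        raise ValueError("wavelength list must match the band axis")
    dtype = np.dtype(dtype)
    arr = values.astype(dtype)
    interleave = interleave.lower()
    if interleave == "bsq":
        flat = arr.transpose(2, 0, 1)
    elif interleave == "bil":
        flat = arr.transpose(0, 2, 1)
    elif interleave == "bip":
        flat = arr
    else:
        raise ValueError(f"unknown interleave {interleave!r}")

    stem = hdr_path[:-4] if hdr_path.endswith(".hdr") else hdr_path
    flat.tofile(stem + ".dat")
    wl_str = ",\n ".join(f"{w:.4f}" for w in wavelengths_nm)
    header = (
        "ENVI\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"data file = {stem + '.dat'}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{\n {wl_str}}}\n"
    )
    with open(stem + ".hdr", "w") as fh:
        fh.write(header)
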