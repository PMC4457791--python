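"""Spectrum and table I/O in open formats.

Native interchange format is two-column xy-text (whitespace separated) or CSV;
both round-trip at >= 12 significant digits. Profile-mode mzML is supported for
interoperability through a self-contained reader/writer pair: writing emits a
minimal uncompressed 64-bit mzML document, reading handles 32/64-bit float
arrays with or without zlib compression. Vendor raw formats are out of scope.
"""

from __future__ import annotations

import base64
import struct
import warnings
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd

from serumpep.spectrum import RawSpectrum

_FORMATS = ("xy-text", "csv", "mzml")


class SpectrumParseError(ValueError):
    """Raised when a spectrum file cannot be parsed."""


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".txt", ".xy", ".tsv", ".dat"):
        return "xy-text"
    if suffix == ".csv":
        return "csv"
    if suffix == ".mzml":
        return "mzml"
    raise ValueError(f"cannot infer spectrum format from suffix {suffix!r}")


def read_spectrum(path, format: str | None = None, sample_id: str | None = None) -> RawSpectrum:
    """Read a single profile spectrum.

    Parameters
    ----------
    path:
        File to read.
    format:
        One of ``xy-text``, ``csv``, ``mzml``; inferred from the suffix when omitted.
    sample_id:
        Overrides the sample id (defaults to the file stem).

    The returned spectrum always satisfies the container invariants; if the
    file's m/z values are unsorted they are sorted with a warning, and
    duplicated m/z values are a parse error.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    sid = sample_id or path.stem

    if fmt == "mzml":
        mz, intensity = _read_mzml_arrays(path)
    else:
        sep = "," if fmt == "csv" else None
        mz_l, int_l = [], []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(sep)
                if lineno == 1 and _looks_like_header(parts):
                    continue
                if len(parts) != 2:
                    raise SpectrumParseError(
                        f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
                try:
                    mz_l.append(float(parts[0]))
                    int_l.append(float(parts[1]))
                except ValueError as exc:
                    raise SpectrumParseError(f"{path}:{lineno}: non-numeric entry") from exc
        mz = np.asarray(mz_l)
        intensity = np.asarray(int_l)

    if len(mz) < 2:
        raise SpectrumParseError(f"{path}: fewer than 2 data points")
    if np.any(np.diff(mz) == 0):
        raise SpectrumParseError(f"{path}: duplicated m/z values")
    if np.any(np.diff(mz) < 0):
        warnings.warn(f"{path}: m/z values unsorted; sorting", stacklevel=2)
        order = np.argsort(mz)
        mz, intensity = mz[order], intensity[order]
    return RawSpectrum(sample_id=sid, mz=mz, intensity=intensity)


def _looks_like_header(parts) -> bool:
    try:
        [float(p) for p in parts]
        return False
    except ValueError:
        return True


def write_spectrum(spectrum: RawSpectrum, path, format: str | None = None) -> Path:
    """Write a spectrum losslessly (12 significant digits for text formats)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "mzml":
        _write_mzml(spectrum, path)
        return path
    sep = "," if fmt == "csv" else " "
    with open(path, "w") as fh:
        if fmt == "csv":
            fh.write("mz,intensity\n")
        for m, i in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{m:.12g}{sep}{i:.12g}\n")
    return path


# ---------------------------------------------------------------------------
# tables

def write_table(df: pd.DataFrame, path) -> Path:
    """Write a cohort/feature table as CSV (12 significant digits, header row,
    missing values as empty fields)."""
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.12g", na_rep="")
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# minimal profile-spectrum mzML

def _encode_array(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *map(float, values))
    return base64.b64encode(raw).decode("ascii")


def _write_mzml(spectrum: RawSpectrum, path: Path) -> None:
    n = len(spectrum)
    mz_b64 = _encode_array(spectrum.mz)
    int_b64 = _encode_array(spectrum.intensity)
    sid = escape(spectrum.sample_id, {'"': "&quot;"})
    doc = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <run id="run1">
    <spectrumList count="1">
      <spectrum index="0" id="scan={sid}" defaultArrayLength="{n}">
        <cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(mz_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(int_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
    </spectrumList>
  </run>
</mzML>
"""
    path.write_text(doc)


def _read_mzml_arrays(path: Path):
    """Read the first spectrum of an mzML file.

    A deliberately small reader (ElementTree + base64): 32/64-bit float
    arrays, uncompressed or zlib, identified by the standard cvParam
    accessions. Covers everything this pipeline writes plus common exports.
    """
    import xml.etree.ElementTree as ET
    import zlib

    ns = "{http://psi.hupo.org/ms/mzml}"
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise SpectrumParseError(f"{path}: not well-formed XML") from exc
    spectrum = root.find(f".//{ns}spectrum")
    if spectrum is None:
        spectrum = root.find(".//spectrum")  # tolerate missing namespace
        ns = ""
    if spectrum is None:
        raise SpectrumParseError(f"{path}: no spectrum found")

    arrays = {}
    for bda in spectrum.iter(f"{ns}binaryDataArray"):
        accs = {cv.get("accession") for cv in bda.iter(f"{ns}cvParam")}
        binary = bda.find(f"{ns}binary")
        if binary is None or binary.text is None:
            raise SpectrumParseError(f"{path}: binaryDataArray without data")
        raw = base64.b64decode(binary.text.strip())
        if "MS:1000574" in accs:  # zlib compression
            raw = zlib.decompress(raw)
        if "MS:1000523" in accs:
            dtype = "<f8"
        elif "MS:1000521" in accs:
            dtype = "<f4"
        else:
            raise SpectrumParseError(f"{path}: unsupported binary data type")
        values = np.frombuffer(raw, dtype=dtype).astype(float)
        if "MS:1000514" in accs:
            arrays["mz"] = values
        elif "MS:1000515" in accs:
            arrays["intensity"] = values
    if "mz" not in arrays or "intensity" not in arrays:
        raise SpectrumParseError(f"{path}: missing m/z or intensity array")
    return arrays["mz"], arrays["intensity"]
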