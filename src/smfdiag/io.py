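"""File formats: spectra (mzML / two-column CSV), manifests, feature matrices.

mzML support is a deliberately small reader/writer pair built on lxml: one
profile spectrum per file, binary data arrays identified by the standard PSI-MS
accessions (m/z array MS:1000514, intensity array MS:1000515), 32- or 64-bit
floats, zlib or uncompressed. The writer emits 64-bit zlib-compressed arrays,
and a write-read round trip is bit-exact.
"""

from __future__ import annotations

import base64
import warnings
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .preprocess import FeatureMatrix, RawSpectrum

__all__ = [
    "read_spectrum",
    "write_spectrum_csv",
    "write_spectrum_mzml",
    "write_manifest",
    "read_manifest",
    "write_feature_matrix",
    "read_feature_matrix",
]

_NS = "http://psi.hupo.org/ms/mzml"


def _encode_array(a: np.ndarray) -> str:
    raw = np.asarray(a, dtype="<f8").tobytes()
    return base64.b64encode(zlib.compress(raw)).decode("ascii")


def write_spectrum_mzml(spectrum: RawSpectrum, path) -> None:
    """Write one profile spectrum as a minimal mzML 1.1 file."""
    root = etree.Element("mzML", nsmap={None: _NS}, version="1.1.0")
    run = etree.SubElement(root, "run", id=spectrum.sample_id)
    slist = etree.SubElement(run, "spectrumList", count="1")
    spec = etree.SubElement(
        slist,
        "spectrum",
        index="0",
        id=f"sample={spectrum.sample_id}",
        defaultArrayLength=str(len(spectrum)),
    )

    def cv(parent, accession, name, value=""):
        etree.SubElement(
            parent, "cvParam", cvRef="MS", accession=accession, name=name, value=value
        )

    cv(spec, "MS:1000128", "profile spectrum")
    cv(spec, "MS:1000511", "ms level", "1")
    alist = etree.SubElement(spec, "binaryDataArrayList", count="2")
    for accession, name, data in (
        ("MS:1000514", "m/z array", spectrum.mz),
        ("MS:1000515", "intensity array", spectrum.intensity),
    ):
        b64 = _encode_array(data)
        arr = etree.SubElement(alist, "binaryDataArray", encodedLength=str(len(b64)))
        cv(arr, "MS:1000523", "64-bit float")
        cv(arr, "MS:1000574", "zlib compression")
        cv(arr, accession, name)
        etree.SubElement(arr, "binary").text = b64
    Path(path).write_bytes(
        etree.tostring(root, xml_declaration=True, encoding="utf-8", pretty_print=True)
    )


def _read_mzml(path) -> tuple[np.ndarray, np.ndarray]:
    """Read the first spectrum's m/z and intensity arrays from an mzML file."""
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as e:
        raise ValueError(f"{path}: failed to parse mzML ({e})") from e
    ns = {"m": _NS}
    spectra = tree.findall(".//m:spectrum", ns) or tree.findall(".//spectrum")
    if not spectra:
        raise ValueError(f"{path}: no spectra found")
    arrays: dict[str, np.ndarray] = {}
    bdas = spectra[0].findall(".//m:binaryDataArray", ns) or spectra[0].findall(
        ".//binaryDataArray"
    )
    for arr in bdas:
        accs = {
            cv.get("accession")
            for cv in arr.findall(".//m:cvParam", ns) + arr.findall(".//cvParam")
        }
        binary = arr.find("m:binary", ns)
        if binary is None:
            binary = arr.find("binary")
        if binary is None or not binary.text:
            continue
        raw = base64.b64decode(binary.text)
        if "MS:1000574" in accs:  # zlib compression
            raw = zlib.decompress(raw)
        dtype = "<f4" if "MS:1000521" in accs else "<f8"
        data = np.frombuffer(raw, dtype=dtype).astype(float)
        if "MS:1000514" in accs:
            arrays["mz"] = data
        elif "MS:1000515" in accs:
            arrays["intensity"] = data
    if "mz" not in arrays or "intensity" not in arrays:
        raise ValueError(f"{path}: missing m/z or intensity binary data array")
    return arrays["mz"], arrays["intensity"]


def write_spectrum_csv(spectrum: RawSpectrum, path) -> None:
    """Two-column (mz, intensity) CSV with full float precision."""
    pd.DataFrame({"mz": spectrum.mz, "intensity": spectrum.intensity}).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_spectrum(path, format: str | None = None, sample_id: str | None = None) -> RawSpectrum:
    """Read and validate one spectrum from mzML or two-column CSV/TSV.

    The format is inferred from the suffix unless given. An unsorted axis is
    sorted with a warning; negative intensities are clipped with a warning;
    empty or malformed files raise.
    """
    path = Path(path)
    if format is None:
        format = "mzml" if path.suffix.lower() == ".mzml" else "csv"
    sid = sample_id or path.stem

    if format == "mzml":
        mz, inten = _read_mzml(path)
    elif format == "csv":
        try:
            sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
            df = pd.read_csv(path, sep=sep, comment="#")
        except Exception as e:
            raise ValueError(f"{path}: failed to parse CSV ({e})") from e
        if df.shape[1] < 2 or len(df) == 0:
            raise ValueError(f"{path}: expected two non-empty columns (mz, intensity)")
        mz = df.iloc[:, 0].to_numpy(dtype=float)
        inten = df.iloc[:, 1].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown spectrum format: {format!r}")

    if len(mz) == 0:
        raise ValueError(f"{path}: empty spectrum")
    if np.any(np.diff(mz) <= 0):
        warnings.warn(f"{path}: m/z axis not strictly increasing; sorting")
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        keep = np.r_[True, np.diff(mz) > 0]
        mz, inten = mz[keep], inten[keep]
    if np.any(inten < 0):
        warnings.warn(f"{path}: negative intensities clipped to 0")
        inten = np.clip(inten, 0.0, None)
    return RawSpectrum(mz=mz, intensity=inten, sample_id=sid)


def write_manifest(sample_ids, groups, path, **extra_columns) -> None:
    df = pd.DataFrame({"sample_id": sample_ids, "group": groups, **extra_columns})
    df.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise ValueError(f"{path}: manifest needs sample_id and group columns")
    return df


def write_feature_matrix(matrix: FeatureMatrix, path) -> None:
    """CSV with sample_id index column and feature m/z (4 decimals) header."""
    matrix.to_frame().to_csv(path, float_format="%.10g")


def read_feature_matrix(path, manifest: pd.DataFrame | None = None) -> FeatureMatrix:
    df = pd.read_csv(path, index_col=0)
    labels = None
    if manifest is not None:
        lookup = dict(zip(manifest["sample_id"].astype(str), manifest["group"]))
        labels = [lookup[str(s)] for s in df.index]
    return FeatureMatrix.from_frame(df, labels=labels)
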