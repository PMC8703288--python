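"""Containers and I/O for centroided LC-MS runs.

A :class:`SyntheticRun` stores all centroids of a run in flat arrays
(scan index, m/z, intensity) sorted by scan — effectively a CSR layout —
plus the scan-time axis and a metadata dict.  Runs round-trip through two
on-disk forms:

* a compact internal JSON serialization (lossless, carries metadata), and
* centroid-mode mzML, written by a minimal writer here and readable by
  any mzML consumer; the package reads it back with a compact lxml-based
  parser that handles the standard centroid encodings (32/64-bit floats,
  optional zlib compression).
"""

from __future__ import annotations

import base64
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np

__all__ = ["SyntheticRun", "write_mzml", "read_mzml", "load_run"]


@dataclass
class SyntheticRun:
    """Time-ordered centroided spectra of one LC-MS run."""

    times_min: np.ndarray          # (n_scans,), strictly increasing
    scan_index: np.ndarray         # (n_peaks,), sorted ascending
    mz: np.ndarray                 # (n_peaks,)
    intensity: np.ndarray          # (n_peaks,)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.scan_index = np.asarray(self.scan_index, dtype=np.int64)
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.times_min.size and np.any(np.diff(self.times_min) <= 0):
            raise ValueError("scan times must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")
        if np.any(self.mz <= 0):
            raise ValueError("m/z values must be > 0")
        self._offsets = np.concatenate(
            ([0], np.cumsum(np.bincount(self.scan_index,
                                        minlength=self.n_scans)))
        )

    @property
    def n_scans(self) -> int:
        return self.times_min.size

    @property
    def n_peaks(self) -> int:
        return self.mz.size

    def spectrum(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """(m/z, intensity) arrays of scan ``i``, sorted by m/z."""
        lo, hi = self._offsets[i], self._offsets[i + 1]
        order = np.argsort(self.mz[lo:hi], kind="stable")
        return self.mz[lo:hi][order], self.intensity[lo:hi][order]

    # -- internal serialization ------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": "osmoquant-run/1",
            "times_min": self.times_min.tolist(),
            "scan_index": self.scan_index.tolist(),
            "mz": self.mz.tolist(),
            "intensity": self.intensity.tolist(),
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "SyntheticRun":
        return cls(
            times_min=np.asarray(payload["times_min"]),
            scan_index=np.asarray(payload["scan_index"]),
            mz=np.asarray(payload["mz"]),
            intensity=np.asarray(payload["intensity"]),
            metadata=dict(payload.get("metadata", {})),
        )

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load_json(cls, path: str | Path) -> "SyntheticRun":
        return cls.from_dict(json.loads(Path(path).read_text()))


# -- mzML ----------------------------------------------------------------

_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="http://obo.cvs.sourceforge.net/obo/obo/ontology/phenotype/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <run id="{run_id}">
    <spectrumList count="{n_scans}">
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _binary_array(values: np.ndarray, accession: str, name: str,
                  unit: str) -> str:
    raw = np.asarray(values, dtype="<f8").tobytes()
    packed = zlib.compress(raw)
    encoded = base64.b64encode(packed).decode("ascii")
    return (
        f'          <binaryDataArray encodedLength="{len(encoded)}">\n'
        f'            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
        f'            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>\n'
        f'            <cvParam cvRef="MS" accession="{accession}" name="{name}" value=""{unit}/>\n'
        f"            <binary>{encoded}</binary>\n"
        f"          </binaryDataArray>\n"
    )


def write_mzml(run: SyntheticRun, path: str | Path) -> None:
    """Write a run as centroid-mode mzML (64-bit, zlib-compressed arrays)."""
    run_id = escape(str(run.metadata.get("sample_id", Path(path).stem)), {'"': "&quot;"})
    parts = [_MZML_HEADER.format(run_id=run_id, n_scans=run.n_scans)]
    for i in range(run.n_scans):
        mz, inten = run.spectrum(i)
        parts.append(
            f'      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{mz.size}">\n'
            f'        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>\n'
            f'        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>\n'
            f'        <scanList count="1">\n'
            f"          <scan>\n"
            f'            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{run.times_min[i]:.7f}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>\n'
            f"          </scan>\n"
            f"        </scanList>\n"
            f'        <binaryDataArrayList count="2">\n'
        )
        parts.append(_binary_array(
            mz, "MS:1000514", "m/z array",
            ' unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"'))
        parts.append(_binary_array(
            inten, "MS:1000515", "intensity array",
            ' unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"'))
        parts.append(
            "        </binaryDataArrayList>\n"
            "      </spectrum>\n"
        )
    parts.append(_MZML_FOOTER)
    Path(path).write_text("".join(parts))


def _decode_binary_array(elem, ns: str) -> np.ndarray:
    accessions = {cv.get("accession") for cv in elem.findall(f"{ns}cvParam")}
    binary = elem.find(f"{ns}binary")
    raw = base64.b64decode(binary.text or "")
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: str | Path) -> SyntheticRun:
    """Read a centroid-mode mzML file into a :class:`SyntheticRun`.

    Handles 32/64-bit float arrays with optional zlib compression and
    scan start times in minutes or seconds; spectra are taken in file
    order.
    """
    from lxml import etree

    tree = etree.parse(str(path))
    root = tree.getroot()
    ns = ""
    if root.tag.startswith("{"):
        ns = root.tag[: root.tag.index("}") + 1]
    times, scan_idx, mzs, intens = [], [], [], []
    for i, spectrum in enumerate(root.iter(f"{ns}spectrum")):
        t = 0.0
        for cv in spectrum.iter(f"{ns}cvParam"):
            if cv.get("accession") == "MS:1000016":
                t = float(cv.get("value"))
                if "second" in (cv.get("unitName") or "minute"):
                    t /= 60.0
                break
        times.append(t)
        mz = inten = np.empty(0)
        for array in spectrum.iter(f"{ns}binaryDataArray"):
            accessions = {cv.get("accession")
                          for cv in array.findall(f"{ns}cvParam")}
            values = _decode_binary_array(array, ns)
            if "MS:1000514" in accessions:
                mz = values
            elif "MS:1000515" in accessions:
                inten = values
        mzs.append(mz)
        intens.append(inten)
        scan_idx.append(np.full(mz.size, i, dtype=np.int64))
    return SyntheticRun(
        times_min=np.asarray(times),
        scan_index=np.concatenate(scan_idx) if scan_idx else np.empty(0, np.int64),
        mz=np.concatenate(mzs) if mzs else np.empty(0),
        intensity=np.concatenate(intens) if intens else np.empty(0),
        metadata={"sample_id": Path(path).stem, "source": str(path)},
    )


def load_run(path: str | Path) -> SyntheticRun:
    """Load a run from either mzML or the internal JSON serialization."""
    path = Path(path)
    if path.suffix.lower() == ".mzml":
        return read_mzml(path)
    return SyntheticRun.load_json(path)
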