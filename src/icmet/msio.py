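"""Reading and writing centroided negative-mode mzML scan data.

Self-contained mzML I/O over the standard library's XML tooling: the reader
streams ``<spectrum>`` elements with ``iterparse``, decoding base64 binary
arrays (32/64-bit float, plain or zlib-compressed) and scan start times in
minutes or seconds; the writer emits a minimal schema-shaped document
(uncompressed 64-bit arrays, one MS1 spectrum per scan).  Both are scoped to
centroided MS1 data, which is all the package consumes.
"""

from __future__ import annotations

import base64
import struct
import zlib
from pathlib import Path
from xml.etree import ElementTree
from xml.sax.saxutils import escape

import numpy as np

from .signal import Scan, ScanSet

__all__ = ["read_mzml", "write_mzml"]

_NS = "{http://psi.hupo.org/ms/mzml}"

_ACC_MS_LEVEL = "MS:1000511"
_ACC_POSITIVE = "MS:1000130"
_ACC_SCAN_START = "MS:1000016"
_ACC_64BIT = "MS:1000523"
_ACC_32BIT = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INTENSITY_ARRAY = "MS:1000515"


def _cv_params(element) -> dict[str, str]:
    return {
        cv.get("accession"): cv.get("value", "")
        for cv in element.iter(f"{_NS}cvParam")
    }


def _decode_array(bda) -> np.ndarray:
    params = _cv_params(bda)
    binary = bda.find(f"{_NS}binary")
    if binary is None or not (binary.text or "").strip():
        return np.empty(0)
    raw = base64.b64decode(binary.text)
    if _ACC_ZLIB in params:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_32BIT in params else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: "str | Path") -> ScanSet:
    """Load centroided MS1 scans from an mzML file into a :class:`ScanSet`."""
    scans = []
    polarity = "-"
    for _event, elem in ElementTree.iterparse(str(path), events=("end",)):
        if elem.tag != f"{_NS}spectrum":
            continue
        params = _cv_params(elem)
        if params.get(_ACC_MS_LEVEL, "1") != "1":
            elem.clear()
            continue
        if _ACC_POSITIVE in params:
            polarity = "+"
        rt = 0.0
        for scan_elem in elem.iter(f"{_NS}scan"):
            for cv in scan_elem.iter(f"{_NS}cvParam"):
                if cv.get("accession") == _ACC_SCAN_START:
                    rt = float(cv.get("value"))
                    if "second" in (cv.get("unitName") or "").lower():
                        rt /= 60.0
        mz = intensity = np.empty(0)
        for bda in elem.iter(f"{_NS}binaryDataArray"):
            params_b = _cv_params(bda)
            if _ACC_MZ_ARRAY in params_b:
                mz = _decode_array(bda)
            elif _ACC_INTENSITY_ARRAY in params_b:
                intensity = _decode_array(bda)
        scans.append(Scan(rt=rt, mz=mz, intensity=intensity))
        elem.clear()
    return ScanSet(scans=scans, polarity=polarity)


def _encode(values: np.ndarray) -> str:
    return base64.b64encode(
        struct.pack(f"<{len(values)}d", *np.asarray(values, dtype=float))
    ).decode()


_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <run id="{run_id}">
    <spectrumList count="{n}">
"""

_SPECTRUM = """      <spectrum index="{index}" id="scan={index}" defaultArrayLength="{npts}">
        <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <cvParam cvRef="MS" accession="{pol_acc}" name="{pol_name}" value=""/>
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""

_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def write_mzml(run: ScanSet, path: "str | Path", run_id: str = "synthetic_run") -> None:
    """Write a :class:`ScanSet` as centroided mzML."""
    if run.polarity == "+":
        pol_acc, pol_name = "MS:1000130", "positive scan"
    else:
        pol_acc, pol_name = "MS:1000129", "negative scan"
    with open(path, "w") as fh:
        fh.write(_HEADER.format(run_id=escape(run_id), n=len(run.scans)))
        for i, scan in enumerate(run.scans):
            mz_b64 = _encode(scan.mz)
            int_b64 = _encode(scan.intensity)
            fh.write(
                _SPECTRUM.format(
                    index=i,
                    npts=len(scan.mz),
                    rt=repr(scan.rt),
                    pol_acc=pol_acc,
                    pol_name=pol_name,
                    mz_len=len(mz_b64),
                    mz_b64=mz_b64,
                    int_len=len(int_b64),
                    int_b64=int_b64,
                )
            )
        fh.write(_FOOTER)
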