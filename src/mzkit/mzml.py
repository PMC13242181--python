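"""mzML reading and writing for :class:`~mzkit.peakmap.PeakMap`.

The reader is a streaming parser over the mzML schema (stdlib
``xml.etree`` iterparse): it accepts 32- or 64-bit binary arrays,
zlib-compressed or plain, and converts scan and chromatogram times
declared in minutes to seconds.  The writer produces indexed mzML with
zlib-compressed 64-bit arrays for both the spectrum and chromatogram
lists, so ``read(write(pm))`` reproduces every array bit-identically.
"""

from __future__ import annotations

import base64
import hashlib
import io
import logging
import os
import xml.etree.ElementTree as ET
import zlib
from xml.sax.saxutils import quoteattr

import numpy as np

from .peakmap import Chromatogram, PeakMap, Precursor, Spectrum

__all__ = ["read_mzml", "write_mzml", "MzMLFormatError"]

logger = logging.getLogger(__name__)


class MzMLFormatError(ValueError):
    """Raised when an mzML document cannot be parsed."""


# --------------------------------------------------------------------------
# reading

def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(elem) -> dict[str, dict]:
    """accession -> {value, unit_accession} for direct cvParam children."""
    out = {}
    for child in elem:
        if _local(child.tag) == "cvParam":
            out[child.get("accession")] = {
                "value": child.get("value"),
                "unit": child.get("unitAccession"),
                "unit_name": child.get("unitName"),
            }
    return out


_MINUTE_UNITS = {"UO:0000031", "MS:1000038"}


def _to_seconds(value: float, unit: str | None, unit_name: str | None) -> float:
    if (unit in _MINUTE_UNITS) or (unit_name and "minute" in unit_name):
        return value * 60.0
    return value


def _decode_binary_array(bda) -> tuple[np.ndarray, dict[str, dict]]:
    params = {}
    text = ""
    for child in bda.iter():
        name = _local(child.tag)
        if name == "cvParam":
            params[child.get("accession")] = {
                "value": child.get("value"),
                "unit": child.get("unitAccession"),
                "unit_name": child.get("unitName"),
            }
        elif name == "binary":
            text = child.text or ""
    raw = base64.b64decode(text)
    if "MS:1000574" in params:  # zlib
        raw = zlib.decompress(raw)
    elif any(acc in params for acc in ("MS:1000778", "MS:1000782", "MS:1000785")):
        raise MzMLFormatError("numpress-compressed arrays are not supported")
    if "MS:1000521" in params:  # 32-bit float
        dtype = "<f4"
    elif "MS:1000522" in params:  # 64-bit integer
        dtype = "<i8"
    elif "MS:1000519" in params:  # 32-bit integer
        dtype = "<i4"
    else:  # MS:1000523 64-bit float (default)
        dtype = "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(np.float64), params


def _read_arrays(elem) -> dict[str, tuple[np.ndarray, dict]]:
    """Arrays keyed by role: 'mz', 'intensity' or 'time'."""
    arrays: dict[str, tuple[np.ndarray, dict]] = {}
    for child in elem.iter():
        if _local(child.tag) != "binaryDataArray":
            continue
        arr, params = _decode_binary_array(child)
        if "MS:1000514" in params:
            arrays["mz"] = (arr, params)
        elif "MS:1000515" in params:
            arrays["intensity"] = (arr, params)
        elif "MS:1000595" in params:
            arrays["time"] = (arr, params["MS:1000595"])
    return arrays


def _parse_precursor(elem) -> Precursor | None:
    mz = charge = half_width = None
    for child in elem.iter():
        name = _local(child.tag)
        if name == "isolationWindow":
            params = _cv_params(child)
            if "MS:1000827" in params and mz is None:
                mz = float(params["MS:1000827"]["value"])
            if "MS:1000828" in params:
                half_width = float(params["MS:1000828"]["value"])
        elif name == "selectedIon":
            params = _cv_params(child)
            if "MS:1000744" in params:
                mz = float(params["MS:1000744"]["value"])
            if "MS:1000041" in params:
                charge = int(float(params["MS:1000041"]["value"]))
    if mz is None:
        return None
    return Precursor(mz, charge, half_width)


def _parse_spectrum(elem) -> Spectrum:
    params = _cv_params(elem)
    if "MS:1000128" in params:
        logger.warning("spectrum %s is profile mode; loaded unchanged", elem.get("id"))
    ms_level = int(float(params["MS:1000511"]["value"])) if "MS:1000511" in params else 1
    polarity = "+" if "MS:1000130" in params else "-" if "MS:1000129" in params else "?"
    rt = 0.0
    precursors = []
    for child in elem.iter():
        name = _local(child.tag)
        if name == "scan":
            sparams = _cv_params(child)
            if "MS:1000016" in sparams:
                p = sparams["MS:1000016"]
                rt = _to_seconds(float(p["value"]), p["unit"], p["unit_name"])
        elif name == "precursor":
            prec = _parse_precursor(child)
            if prec is not None:
                precursors.append(prec)
    arrays = _read_arrays(elem)
    n = int(elem.get("defaultArrayLength", 0))
    mzs = arrays["mz"][0] if "mz" in arrays else np.zeros(n)
    intens = arrays["intensity"][0] if "intensity" in arrays else np.zeros(n)
    return Spectrum(rt, mzs, intens, ms_level, polarity, tuple(precursors))


def _isolation_target(elem) -> float | None:
    for child in elem.iter():
        if _local(child.tag) == "isolationWindow":
            params = _cv_params(child)
            if "MS:1000827" in params:
                return float(params["MS:1000827"]["value"])
    return None


def _parse_chromatogram(elem) -> Chromatogram:
    params = _cv_params(elem)
    if "MS:1001473" in params:
        kind = "SRM"
    elif "MS:1000235" in params:
        kind = "TIC"
    else:
        kind = "EIC"
    precursor_mz = product_mz = None
    for child in elem:
        name = _local(child.tag)
        if name == "precursor":
            precursor_mz = _isolation_target(child)
        elif name == "product":
            product_mz = _isolation_target(child)
    arrays = _read_arrays(elem)
    n = int(elem.get("defaultArrayLength", 0))
    if "time" in arrays:
        rts_raw, unit = arrays["time"]
        rts = np.array([_to_seconds(t, unit["unit"], unit["unit_name"]) for t in rts_raw])
    else:
        rts = np.zeros(n)
    intens = arrays["intensity"][0] if "intensity" in arrays else np.zeros(n)
    return Chromatogram(kind, rts, intens, precursor_mz, product_mz)


def read_mzml(source) -> PeakMap:
    """Read an mzML file (path or binary file-like) into a PeakMap."""
    if isinstance(source, (str, os.PathLike)):
        if not os.path.exists(source):
            raise FileNotFoundError(f"no such mzML file: {source}")
        fh = open(source, "rb")
        close = True
        origin = str(source)
    else:
        fh, close = source, False
        origin = "<stream>"
    spectra: list[Spectrum] = []
    chromatograms: list[Chromatogram] = []
    instrument = None
    try:
        for event, elem in ET.iterparse(fh, events=("end",)):
            name = _local(elem.tag)
            if name == "spectrum":
                spectra.append(_parse_spectrum(elem))
                elem.clear()
            elif name == "chromatogram":
                chromatograms.append(_parse_chromatogram(elem))
                elem.clear()
            elif name == "instrumentConfiguration" and instrument is None:
                params = _cv_params(elem)
                if "MS:1000031" in params:
                    instrument = params["MS:1000031"]["value"]
    except ET.ParseError as exc:
        raise MzMLFormatError(
            f"malformed mzML in {origin} at line {exc.position[0]}, "
            f"column {exc.position[1]}: {exc}"
        ) from exc
    finally:
        if close:
            fh.close()
    metadata = {"source": origin}
    if instrument:
        metadata["instrument"] = instrument
    return PeakMap(tuple(spectra), tuple(chromatograms), metadata)


# --------------------------------------------------------------------------
# writing

_CV_HEAD = (
    '<cvList count="2">'
    '<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology"'
    ' URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>'
    '<cv id="UO" fullName="Unit Ontology"'
    ' URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>'
    "</cvList>"
)


def _cv(accession: str, name: str, value=None, unit: tuple[str, str, str] | None = None) -> str:
    s = f'<cvParam cvRef="MS" accession={quoteattr(accession)} name={quoteattr(name)}'
    if value is not None:
        s += f" value={quoteattr(repr(value) if isinstance(value, float) else str(value))}"
    else:
        s += ' value=""'
    if unit:
        ref, acc, uname = unit
        s += (
            f" unitCvRef={quoteattr(ref)} unitAccession={quoteattr(acc)}"
            f" unitName={quoteattr(uname)}"
        )
    return s + "/>"


_UNIT_SECOND = ("UO", "UO:0000010", "second")
_UNIT_MINUTE = ("UO", "UO:0000031", "minute")
_UNIT_MZ = ("MS", "MS:1000040", "m/z")
_UNIT_COUNTS = ("MS", "MS:1000131", "number of detector counts")


def _binary_array(values: np.ndarray, kind_cv: str) -> str:
    raw = np.ascontiguousarray(values, dtype="<f8").tobytes()
    data = base64.b64encode(zlib.compress(raw)).decode("ascii")
    parts = [
        f'<binaryDataArray encodedLength="{len(data)}">',
        _cv("MS:1000523", "64-bit float"),
        _cv("MS:1000574", "zlib compression"),
        kind_cv,
        f"<binary>{data}</binary>",
        "</binaryDataArray>",
    ]
    return "".join(parts)


def _precursor_xml(p: Precursor) -> str:
    parts = ["<precursor>"]
    if p.isolation_window is not None:
        parts.append("<isolationWindow>")
        parts.append(_cv("MS:1000827", "isolation window target m/z", p.mz, _UNIT_MZ))
        parts.append(_cv("MS:1000828", "isolation window lower offset", p.isolation_window, _UNIT_MZ))
        parts.append(_cv("MS:1000829", "isolation window upper offset", p.isolation_window, _UNIT_MZ))
        parts.append("</isolationWindow>")
    parts.append('<selectedIonList count="1"><selectedIon>')
    parts.append(_cv("MS:1000744", "selected ion m/z", p.mz, _UNIT_MZ))
    if p.charge is not None:
        parts.append(_cv("MS:1000041", "charge state", p.charge))
    parts.append("</selectedIon></selectedIonList>")
    parts.append(
        '<activation><cvParam cvRef="MS" accession="MS:1000044"'
        ' name="dissociation method" value=""/></activation>'
    )
    parts.append("</precursor>")
    return "".join(parts)


def _spectrum_xml(index: int, s: Spectrum, rt_unit: str) -> str:
    parts = [
        f'<spectrum index="{index}" id="scan={index + 1}" defaultArrayLength="{len(s)}">',
        _cv("MS:1000511", "ms level", s.ms_level),
        _cv("MS:1000579", "MS1 spectrum") if s.ms_level == 1 else _cv("MS:1000580", "MSn spectrum"),
        _cv("MS:1000127", "centroid spectrum"),
    ]
    if s.polarity == "+":
        parts.append(_cv("MS:1000130", "positive scan"))
    elif s.polarity == "-":
        parts.append(_cv("MS:1000129", "negative scan"))
    rt_value = s.rt / 60.0 if rt_unit == "minute" else s.rt
    unit = _UNIT_MINUTE if rt_unit == "minute" else _UNIT_SECOND
    parts.append(
        '<scanList count="1">'
        + _cv("MS:1000795", "no combination")
        + "<scan>"
        + _cv("MS:1000016", "scan start time", rt_value, unit)
        + "</scan></scanList>"
    )
    if s.precursors:
        parts.append(f'<precursorList count="{len(s.precursors)}">')
        parts.extend(_precursor_xml(p) for p in s.precursors)
        parts.append("</precursorList>")
    parts.append('<binaryDataArrayList count="2">')
    parts.append(_binary_array(s.mzs, _cv("MS:1000514", "m/z array", unit=_UNIT_MZ)))
    parts.append(_binary_array(s.intensities, _cv("MS:1000515", "intensity array", unit=_UNIT_COUNTS)))
    parts.append("</binaryDataArrayList></spectrum>")
    return "".join(parts)


_CHROM_KIND_CV = {
    "SRM": _cv("MS:1001473", "selected reaction monitoring chromatogram"),
    "TIC": _cv("MS:1000235", "total ion current chromatogram"),
    "EIC": _cv("MS:1000627", "selected ion current chromatogram"),
}


def _chromatogram_xml(index: int, c: Chromatogram, rt_unit: str) -> str:
    parts = [
        f'<chromatogram index="{index}" id="chrom={index + 1}" defaultArrayLength="{len(c)}">',
        _CHROM_KIND_CV[c.kind],
    ]
    if c.precursor_mz is not None:
        parts.append(
            "<precursor><isolationWindow>"
            + _cv("MS:1000827", "isolation window target m/z", c.precursor_mz, _UNIT_MZ)
            + "</isolationWindow></precursor>"
        )
    if c.product_mz is not None:
        parts.append(
            "<product><isolationWindow>"
            + _cv("MS:1000827", "isolation window target m/z", c.product_mz, _UNIT_MZ)
            + "</isolationWindow></product>"
        )
    unit = _UNIT_MINUTE if rt_unit == "minute" else _UNIT_SECOND
    rts = c.rts / 60.0 if rt_unit == "minute" else c.rts
    parts.append('<binaryDataArrayList count="2">')
    parts.append(_binary_array(rts, _cv("MS:1000595", "time array", unit=unit)))
    parts.append(_binary_array(c.intensities, _cv("MS:1000515", "intensity array", unit=_UNIT_COUNTS)))
    parts.append("</binaryDataArrayList></chromatogram>")
    return "".join(parts)


def write_mzml(pm: PeakMap, target, rt_unit: str = "second") -> None:
    """Write a PeakMap as indexed mzML (path or binary file-like target).

    ``rt_unit`` selects the declared unit of scan/chromatogram times;
    values are converted accordingly so the data are unchanged.
    """
    if rt_unit not in ("second", "minute"):
        raise ValueError("rt_unit must be 'second' or 'minute'")
    run_id = str(pm.metadata.get("run_id", "run1"))
    instrument = str(pm.metadata.get("instrument", "unknown instrument"))

    header = (
        '<?xml version="1.0" encoding="utf-8"?>\n'
        '<indexedmzML xmlns="http://psi.hupo.org/ms/mzml">\n'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">'
        + _CV_HEAD
        + "<fileDescription><fileContent>"
        + _cv("MS:1000579", "MS1 spectrum")
        + "</fileContent></fileDescription>"
        + '<softwareList count="1"><software id="mzkit" version="0.1.0">'
        + '<cvParam cvRef="MS" accession="MS:1000799" name="custom unreleased software tool" value="mzkit"/>'
        + "</software></softwareList>"
        + '<instrumentConfigurationList count="1"><instrumentConfiguration id="IC1">'
        + f'<cvParam cvRef="MS" accession="MS:1000031" name="instrument model" value={quoteattr(instrument)}/>'
        + "</instrumentConfiguration></instrumentConfigurationList>"
        + '<dataProcessingList count="1"><dataProcessing id="DP1">'
        + '<processingMethod order="1" softwareRef="mzkit">'
        + _cv("MS:1000544", "Conversion to mzML")
        + "</processingMethod></dataProcessing></dataProcessingList>"
        + f'<run id={quoteattr(run_id)} defaultInstrumentConfigurationRef="IC1">'
    )

    chunks: list[bytes] = [header.encode("utf-8")]
    spectrum_offsets: list[tuple[str, int]] = []
    chrom_offsets: list[tuple[str, int]] = []

    chunks.append(
        f'<spectrumList count="{len(pm.spectra)}" defaultDataProcessingRef="DP1">'.encode()
    )
    offset = sum(len(c) for c in chunks)
    for i, s in enumerate(pm.spectra):
        spectrum_offsets.append((f"scan={i + 1}", offset))
        chunk = _spectrum_xml(i, s, rt_unit).encode("utf-8")
        chunks.append(chunk)
        offset += len(chunk)
    chunks.append(b"</spectrumList>")
    offset += len(chunks[-1])

    if pm.chromatograms:
        chunk = (
            f'<chromatogramList count="{len(pm.chromatograms)}"'
            ' defaultDataProcessingRef="DP1">'.encode()
        )
        chunks.append(chunk)
        offset += len(chunk)
        for i, c in enumerate(pm.chromatograms):
            chrom_offsets.append((f"chrom={i + 1}", offset))
            chunk = _chromatogram_xml(i, c, rt_unit).encode("utf-8")
            chunks.append(chunk)
            offset += len(chunk)
        chunks.append(b"</chromatogramList>")
        offset += len(chunks[-1])

    chunks.append(b"</run></mzML>\n")
    offset += len(chunks[-1])

    index_parts = ['<indexList count="2">', '<index name="spectrum">']
    index_parts += [
        f"<offset idRef={quoteattr(idref)}>{off}</offset>" for idref, off in spectrum_offsets
    ]
    index_parts.append('</index><index name="chromatogram">')
    index_parts += [
        f"<offset idRef={quoteattr(idref)}>{off}</offset>" for idref, off in chrom_offsets
    ]
    index_parts.append("</index></indexList>")
    index_parts.append(f"<indexListOffset>{offset}</indexListOffset>")
    chunks.append("".join(index_parts).encode("utf-8"))

    body = b"".join(chunks) + b"<fileChecksum>"
    sha1 = hashlib.sha1(body).hexdigest()
    body += sha1.encode("ascii") + b"</fileChecksum></indexedmzML>\n"

    if isinstance(target, (str, os.PathLike)):
        with open(target, "wb") as fh:
            fh.write(body)
    else:
        target.write(body)


def peakmap_to_bytes(pm: PeakMap) -> bytes:
    buf = io.BytesIO()
    write_mzml(pm, buf)
    return buf.getvalue()


def peakmap_from_bytes(data: bytes) -> PeakMap:
    return read_mzml(io.BytesIO(data))
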