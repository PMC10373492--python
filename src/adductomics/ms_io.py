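"""Spectrum/run data model and mzML I/O for DIA LC-HRMS acquisitions.

A run is an RT-ordered list of MS1 full scans interleaved with DIA MS2 scans,
each MS2 tagged with the isolation window it was acquired under. The DIA
scheme divides the precursor range into contiguous, non-overlapping windows
of fixed width (10 m/z in the acquisitions this package targets: 16 windows
covering 195-355 m/z and 26 windows covering 347-607 m/z).

Both reading and writing are implemented directly on the mzML XML (lxml):
plain or indexed mzML, centroid or profile spectra, 32/64-bit float arrays,
zlib-compressed or uncompressed. Writing (used by the simulator) emits
minimal standard-compliant mzML that the reader round-trips exactly.
"""

from __future__ import annotations

import base64
import struct
import zlib
from dataclasses import dataclass

import numpy as np
from lxml import etree

__all__ = [
    "Spectrum",
    "Run",
    "DiaScheme",
    "build_dia_scheme",
    "window_for_mz",
    "read_mzml",
    "write_mzml",
    "centroid_profile",
    "MzmlFormatError",
]


class MzmlFormatError(ValueError):
    """Raised when an mzML file violates the expected acquisition layout."""


@dataclass(frozen=True)
class DiaScheme:
    """Contiguous non-overlapping DIA isolation windows of equal width."""

    precursor_lo: float
    precursor_hi: float
    window_width: float
    n_windows: int
    centers: np.ndarray

    def contains(self, mz: float) -> bool:
        return self.precursor_lo <= mz < self.precursor_hi


def build_dia_scheme(lo: float, hi: float, width: float) -> DiaScheme:
    """Divide [lo, hi) into contiguous windows of ``width`` m/z.

    The range must be an integer multiple of the width; centers sit at
    window midpoints.
    """
    if hi <= lo:
        raise ValueError("hi must exceed lo")
    if width <= 0:
        raise ValueError("width must be positive")
    n_float = (hi - lo) / width
    n = int(round(n_float))
    if abs(n_float - n) > 1e-9 or n < 1:
        raise ValueError(
            f"precursor range {lo}-{hi} is not divisible by window width {width}"
        )
    centers = lo + width * (np.arange(n) + 0.5)
    return DiaScheme(float(lo), float(hi), float(width), n, centers)


def window_for_mz(scheme: DiaScheme, mz: float) -> int:
    """Index of the half-open window [lo, hi) containing ``mz``.

    A boundary m/z belongs to the upper window.
    """
    if not scheme.contains(mz):
        raise ValueError(
            f"m/z {mz} outside DIA range [{scheme.precursor_lo}, {scheme.precursor_hi})"
        )
    idx = int((mz - scheme.precursor_lo) // scheme.window_width)
    return min(idx, scheme.n_windows - 1)


@dataclass
class Spectrum:
    """One centroided scan: m/z strictly ascending, intensities non-negative."""

    ms_level: int
    rt: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray
    isolation_center: float | None = None
    isolation_width: float | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz array must be strictly ascending")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.ms_level == 2:
            if self.isolation_center is None or self.isolation_width is None:
                raise ValueError("MS2 spectra require an isolation window")
        elif self.isolation_center is not None:
            raise ValueError("MS1 spectra carry no isolation window")


@dataclass
class Run:
    """RT-ordered spectra plus the acquisition geometry they were taken under."""

    spectra: list[Spectrum]
    polarity: str = "positive"
    ms1_range: tuple[float, float] = (110.0, 650.0)
    dia_scheme: DiaScheme | None = None

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.spectra]
        if rts != sorted(rts):
            raise ValueError("spectra must be sorted by retention time")
        if self.dia_scheme is not None:
            for s in self.spectra:
                if s.ms_level == 2 and not _center_in_scheme(
                    self.dia_scheme, s.isolation_center
                ):
                    raise MzmlFormatError(
                        f"MS2 isolation center {s.isolation_center} at RT "
                        f"{s.rt:.3f} min matches no DIA window"
                    )

    def ms1_spectra(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 1]

    def ms2_spectra(self, window: int | None = None) -> list[Spectrum]:
        out = [s for s in self.spectra if s.ms_level == 2]
        if window is not None:
            if self.dia_scheme is None:
                raise ValueError("run has no DIA scheme")
            center = self.dia_scheme.centers[window]
            out = [s for s in out if abs(s.isolation_center - center) < 1e-6]
        return out


def _center_in_scheme(scheme: DiaScheme, center: float | None) -> bool:
    if center is None:
        return False
    return bool(np.any(np.abs(scheme.centers - center) < 1e-6))


def centroid_profile(mz: np.ndarray, intensity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pick local maxima from a profile trace.

    Each strict local maximum above zero becomes one centroid whose m/z is
    the intensity-weighted mean of the apex point and its two neighbours.
    """
    mz = np.asarray(mz, float)
    inten = np.asarray(intensity, float)
    if mz.size < 3:
        return np.empty(0), np.empty(0)
    is_max = (inten[1:-1] > inten[:-2]) & (inten[1:-1] >= inten[2:]) & (inten[1:-1] > 0)
    idx = np.nonzero(is_max)[0] + 1
    if idx.size == 0:
        return np.empty(0), np.empty(0)
    w = inten[idx - 1] + inten[idx] + inten[idx + 1]
    cmz = (
        mz[idx - 1] * inten[idx - 1] + mz[idx] * inten[idx] + mz[idx + 1] * inten[idx + 1]
    ) / w
    return cmz, inten[idx]


# mzML controlled-vocabulary accessions used by the reader
_ACC_MS_LEVEL = "MS:1000511"
_ACC_SCAN_START = "MS:1000016"
_ACC_POS = "MS:1000130"
_ACC_NEG = "MS:1000129"
_ACC_PROFILE = "MS:1000128"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_ISO_TARGET = "MS:1000827"
_ACC_ISO_LOWER = "MS:1000828"
_ACC_ISO_UPPER = "MS:1000829"


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(elem) -> dict[str, dict]:
    """Accession -> {value, unit} for the element's direct cvParam children."""
    out = {}
    for child in elem:
        if _local(child.tag) == "cvParam":
            out[child.get("accession")] = {
                "value": child.get("value"),
                "unit": child.get("unitName"),
            }
    return out


def _decode_binary(bda_elem, sid: str) -> tuple[str | None, np.ndarray]:
    params = _cv_params(bda_elem)
    kind = (
        "mz"
        if _ACC_MZ_ARRAY in params
        else "intensity"
        if _ACC_INT_ARRAY in params
        else None
    )
    raw = b""
    for child in bda_elem:
        if _local(child.tag) == "binary" and child.text:
            raw = base64.b64decode(child.text)
    if _ACC_ZLIB in params:
        raw = zlib.decompress(raw)
    if _ACC_F32 in params:
        arr = np.frombuffer(raw, dtype="<f4").astype(float)
    elif _ACC_F64 in params or raw:
        arr = np.frombuffer(raw, dtype="<f8").astype(float)
    else:
        arr = np.empty(0)
    return kind, arr


def _parse_spectrum_elem(elem, centroid: bool, sid: str) -> tuple[Spectrum, str | None]:
    top = _cv_params(elem)
    if _ACC_MS_LEVEL not in top:
        raise MzmlFormatError(f"spectrum {sid!r} lacks an ms level")
    level = int(top[_ACC_MS_LEVEL]["value"])
    polarity = "positive" if _ACC_POS in top else "negative" if _ACC_NEG in top else None
    is_profile = _ACC_PROFILE in top

    rt = None
    center = width = None
    mz = inten = None
    for node in elem.iter():
        tag = _local(node.tag)
        if tag == "scan":
            p = _cv_params(node)
            if _ACC_SCAN_START in p:
                rt = float(p[_ACC_SCAN_START]["value"])
                if (p[_ACC_SCAN_START]["unit"] or "minute") in ("second", "seconds"):
                    rt /= 60.0
        elif tag == "isolationWindow":
            p = _cv_params(node)
            if _ACC_ISO_TARGET in p:
                center = float(p[_ACC_ISO_TARGET]["value"])
                lo = float(p.get(_ACC_ISO_LOWER, {"value": "0"})["value"] or 0)
                hi = float(p.get(_ACC_ISO_UPPER, {"value": "0"})["value"] or 0)
                width = lo + hi
        elif tag == "binaryDataArray":
            kind, arr = _decode_binary(node, sid)
            if kind == "mz":
                mz = arr
            elif kind == "intensity":
                inten = arr
    if rt is None:
        raise MzmlFormatError(f"spectrum {sid!r} lacks a scan start time")
    if mz is None or inten is None:
        raise MzmlFormatError(f"spectrum {sid!r} lacks m/z or intensity arrays")
    if mz.size != inten.size:
        raise MzmlFormatError(f"spectrum {sid!r} has mismatched array lengths")
    if level == 2 and center is None:
        raise MzmlFormatError(f"MS2 spectrum {sid!r} lacks an isolation window")
    if centroid and is_profile:
        mz, inten = centroid_profile(mz, inten)
    order = np.argsort(mz, kind="stable")
    return (
        Spectrum(level, rt, mz[order], inten[order], center, width),
        polarity,
    )


def read_mzml(
    path: str,
    centroid: bool = False,
    scheme: DiaScheme | None = None,
) -> Run:
    """Read an mzML file (plain or indexed) into a :class:`Run`.

    Retention times are converted to minutes. With ``centroid=True``,
    spectra flagged as profile are converted by local-maximum picking.
    If ``scheme`` is given, every MS2 isolation center must match one of
    its windows; otherwise the scheme is inferred from the isolation
    windows present in the file.
    """
    spectra: list[Spectrum] = []
    polarity: str | None = None
    widths: list[float] = []
    try:
        context = etree.iterparse(path, events=("end",))
    except OSError as exc:
        raise MzmlFormatError(f"cannot open mzML file {path!r}: {exc}") from exc
    try:
        for _event, elem in context:
            if _local(elem.tag) != "spectrum":
                continue
            sid = elem.get("id", "?")
            spec, pol = _parse_spectrum_elem(elem, centroid, sid)
            if pol is not None:
                if polarity is None:
                    polarity = pol
                elif polarity != pol:
                    raise MzmlFormatError(
                        f"mixed polarity: spectrum {sid!r} is {pol}, run is {polarity}"
                    )
            if spec.ms_level == 2:
                widths.append(spec.isolation_width)
            spectra.append(spec)
            elem.clear()
    except etree.XMLSyntaxError as exc:
        raise MzmlFormatError(f"invalid mzML in {path!r}: {exc}") from exc
    spectra.sort(key=lambda s: s.rt)
    if scheme is None:
        scheme = _infer_scheme(spectra, widths)
    return Run(spectra, polarity or "positive", dia_scheme=scheme)


def _infer_scheme(spectra: list[Spectrum], widths: list[float]) -> DiaScheme | None:
    centers = sorted({s.isolation_center for s in spectra if s.ms_level == 2})
    if not centers:
        return None
    width = widths[0]
    lo = centers[0] - width / 2.0
    hi = centers[-1] + width / 2.0
    n = int(round((hi - lo) / width))
    scheme = build_dia_scheme(lo, lo + n * width, width)
    for c in centers:
        if not _center_in_scheme(scheme, c):
            raise MzmlFormatError(
                f"MS2 isolation centers are not on a contiguous {width} m/z grid "
                f"(offending center {c})"
            )
    return scheme


# ---------------------------------------------------------------------------
# Minimal mzML writing (simulator output)

_MZML_HEADER = (
    '<?xml version="1.0" encoding="utf-8"?>\n'
    '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n'
    '  <cvList count="2">\n'
    '    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>\n'
    '    <cv id="UO" fullName="Unit Ontology" URI="http://obo.cvs.sourceforge.net/obo/obo/ontology/phenotype/unit.obo"/>\n'
    "  </cvList>\n"
    '  <fileDescription><fileContent>\n'
    '    <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>\n'
    "  </fileContent></fileDescription>\n"
    '  <softwareList count="1"><software id="adductomics" version="0.1.0"/></softwareList>\n'
    '  <instrumentConfigurationList count="1"><instrumentConfiguration id="IC1"/></instrumentConfigurationList>\n'
    '  <dataProcessingList count="1"><dataProcessing id="dp1">\n'
    '    <processingMethod order="1" softwareRef="adductomics"/>\n'
    "  </dataProcessing></dataProcessingList>\n"
)


def _b64_doubles(arr: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{arr.size}d", *arr)).decode("ascii")


def _binary_array_xml(arr: np.ndarray, kind_accession: str, kind_name: str) -> str:
    data = _b64_doubles(np.asarray(arr, float))
    return (
        f'          <binaryDataArray encodedLength="{len(data)}">\n'
        f'            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
        f'            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
        f'            <cvParam cvRef="MS" accession="{kind_accession}" name="{kind_name}" value=""/>\n'
        f"            <binary>{data}</binary>\n"
        f"          </binaryDataArray>\n"
    )


def _spectrum_xml(spec: Spectrum, index: int, polarity: str) -> str:
    pol_param = (
        '<cvParam cvRef="MS" accession="MS:1000130" name="positive scan" value=""/>'
        if polarity == "positive"
        else '<cvParam cvRef="MS" accession="MS:1000129" name="negative scan" value=""/>'
    )
    lines = [
        f'      <spectrum index="{index}" id="scan={index + 1}" defaultArrayLength="{spec.mz.size}">\n'
        f'        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{spec.ms_level}"/>\n'
        f'        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>\n'
        f"        {pol_param}\n"
        f'        <scanList count="1">\n'
        f'          <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>\n'
        f"          <scan>\n"
        f'            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{spec.rt:.6f}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>\n'
        f"          </scan>\n"
        f"        </scanList>\n"
    ]
    if spec.ms_level == 2:
        half = spec.isolation_width / 2.0
        lines.append(
            f'        <precursorList count="1">\n'
            f"          <precursor>\n"
            f"            <isolationWindow>\n"
            f'              <cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="{spec.isolation_center:.4f}"/>\n'
            f'              <cvParam cvRef="MS" accession="MS:1000828" name="isolation window lower offset" value="{half:.4f}"/>\n'
            f'              <cvParam cvRef="MS" accession="MS:1000829" name="isolation window upper offset" value="{half:.4f}"/>\n'
            f"            </isolationWindow>\n"
            f'            <selectedIonList count="1"><selectedIon>\n'
            f'              <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{spec.isolation_center:.4f}"/>\n'
            f"            </selectedIon></selectedIonList>\n"
            f"            <activation>\n"
            f'              <cvParam cvRef="MS" accession="MS:1000422" name="beam-type collision-induced dissociation" value=""/>\n'
            f"            </activation>\n"
            f"          </precursor>\n"
            f"        </precursorList>\n"
        )
    lines.append('        <binaryDataArrayList count="2">\n')
    lines.append(_binary_array_xml(spec.mz, "MS:1000514", "m/z array"))
    lines.append(_binary_array_xml(spec.intensity, "MS:1000515", "intensity array"))
    lines.append("        </binaryDataArrayList>\n      </spectrum>\n")
    return "".join(lines)


def write_mzml(run: Run, path: str) -> None:
    """Serialize a run to minimal, standard-compliant mzML (uncompressed
    64-bit arrays). Deterministic: identical runs give byte-identical files."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_MZML_HEADER)
        fh.write('  <run id="run1" defaultInstrumentConfigurationRef="IC1">\n')
        fh.write(
            f'    <spectrumList count="{len(run.spectra)}" defaultDataProcessingRef="dp1">\n'
        )
        for i, spec in enumerate(run.spectra):
            fh.write(_spectrum_xml(spec, i, run.polarity))
        fh.write("    </spectrumList>\n  </run>\n</mzML>\n")
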