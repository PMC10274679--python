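"""Tandem-spectrum I/O, preprocessing and theoretical b/y fragment ions.

MGF is the required text format (read and write); mzML is supported for
reading via pyteomics.  Because no mzML *writer* is installed in the target
environment, :func:`write_mzml` is a minimal hand-written serializer
producing uncompressed 64-bit little-endian peak arrays — just enough mzML
for the pyteomics reader to round-trip what this package writes.

Fragment chemistry is deliberately minimal: b and y ions at charges
1..``max_fragment_charge`` (default 2), which is the standard sufficient set
for tryptic HCD-style data.  Site-localized modifications (variable mods and
a localized mass offset) shift every fragment containing the site; an
unlocalized offset leaves the fragment series unshifted — shifted variants
are generated per candidate site during delta-mass localization.
"""

from __future__ import annotations

import base64
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import zlib
from lxml import etree
from pyteomics import mgf as _pmgf

from .mod_model import (
    AA_MASS,
    CARBAMIDOMETHYL,
    MASS_PROTON,
    MASS_WATER,
    Modification,
    Peptidoform,
)

DEFAULT_UNASSIGNED_CHARGES = (2, 3)


class SpectrumError(ValueError):
    """Raised for malformed spectrum files."""


@dataclass
class Spectrum:
    """A centroided MS/MS scan.

    Peaks are stored as parallel numpy arrays sorted ascending by m/z.
    """

    scan_id: str
    precursor_mz: float
    precursor_charge: int
    mz: np.ndarray
    intensity: np.ndarray
    retention_time: float | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise SpectrumError(f"{self.scan_id}: peak array length mismatch")
        if np.any(self.intensity < 0):
            raise SpectrumError(f"{self.scan_id}: negative intensity")
        if self.precursor_charge < 1:
            raise SpectrumError(f"{self.scan_id}: precursor charge < 1")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def precursor_neutral_mass(self) -> float:
        z = self.precursor_charge
        return self.precursor_mz * z - z * MASS_PROTON


@dataclass(frozen=True)
class FragmentIon:
    series: str  # "b" | "y"
    index: int  # 1-based ion number
    charge: int
    mz: float
    carries_offset: bool = False


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".mgf":
        return "mgf"
    if suffix == ".mzml":
        return "mzml"
    raise SpectrumError(f"cannot infer spectrum format from {path.name!r}")


def read_spectra(
    path: str | Path,
    format: str | None = None,
    default_charges: Sequence[int] = DEFAULT_UNASSIGNED_CHARGES,
) -> list[Spectrum]:
    """Read MS/MS spectra from MGF or mzML.

    A spectrum without an assigned precursor charge is expanded into one
    :class:`Spectrum` per entry of ``default_charges`` (same scan id), so
    downstream rank-1 selection competes the charge hypotheses.
    """
    path = Path(path)
    if not path.exists():
        raise SpectrumError(f"no such file: {path}")
    fmt = _infer_format(path, format)
    out: list[Spectrum] = []
    if fmt == "mgf":
        with _pmgf.MGF(str(path)) as reader:
            for i, rec in enumerate(reader):
                params = rec.get("params", {})
                title = str(params.get("title", f"index={i}"))
                pepmass = params.get("pepmass")
                if pepmass is None:
                    raise SpectrumError(f"{path}: record {title!r} lacks PEPMASS")
                mz0 = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
                charges = params.get("charge")
                rt = params.get("rtinseconds")
                zs = [int(charges[0])] if charges else list(default_charges)
                for z in zs:
                    out.append(
                        Spectrum(
                            scan_id=title,
                            precursor_mz=mz0,
                            precursor_charge=z,
                            mz=rec["m/z array"],
                            intensity=rec["intensity array"],
                            retention_time=float(rt) if rt is not None else None,
                        )
                    )
    elif fmt == "mzml":
        out.extend(_read_mzml(path, default_charges))
    else:
        raise SpectrumError(f"unknown spectrum format {fmt!r}")
    return out


def _decode_binary_array(bda, ns: str) -> np.ndarray:
    """Decode one mzML binaryDataArray (64/32-bit float, zlib optional)."""
    accs = {cv.get("accession") for cv in bda.findall(f"{ns}cvParam")}
    node = bda.find(f"{ns}binary")
    raw = base64.b64decode(node.text or "")
    if "MS:1000574" in accs:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accs else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: Path, default_charges: Sequence[int]) -> list[Spectrum]:
    """Minimal mzML reader (lxml): MS2 scans with precursor and peak arrays.

    Covers centroided mzML as produced by :func:`write_mzml` and standard
    converters (uncompressed or zlib, 32/64-bit float arrays).
    """
    ns = "{http://psi.hupo.org/ms/mzml}"
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise SpectrumError(f"{path}: not valid mzML ({exc})") from None
    out: list[Spectrum] = []
    for spec in tree.iter(f"{ns}spectrum"):
        params = {
            cv.get("accession"): cv.get("value")
            for cv in spec.findall(f"{ns}cvParam")
        }
        if params.get("MS:1000511") != "2":  # ms level
            continue
        sid = spec.get("id", "")
        ion = spec.find(
            f"{ns}precursorList/{ns}precursor/{ns}selectedIonList/{ns}selectedIon"
        )
        if ion is None:
            raise SpectrumError(f"{path}: MS2 scan {sid!r} lacks a selected ion")
        ion_params = {
            cv.get("accession"): cv.get("value")
            for cv in ion.findall(f"{ns}cvParam")
        }
        if "MS:1000744" not in ion_params:
            raise SpectrumError(f"{path}: MS2 scan {sid!r} lacks a precursor m/z")
        mz0 = float(ion_params["MS:1000744"])
        charge = ion_params.get("MS:1000041")
        mz_arr = inten_arr = None
        for bda in spec.findall(f"{ns}binaryDataArrayList/{ns}binaryDataArray"):
            accs = {cv.get("accession") for cv in bda.findall(f"{ns}cvParam")}
            if "MS:1000514" in accs:
                mz_arr = _decode_binary_array(bda, ns)
            elif "MS:1000515" in accs:
                inten_arr = _decode_binary_array(bda, ns)
        if mz_arr is None or inten_arr is None:
            raise SpectrumError(f"{path}: MS2 scan {sid!r} lacks peak arrays")
        zs = [int(charge)] if charge is not None else list(default_charges)
        for z in zs:
            out.append(
                Spectrum(
                    scan_id=str(sid),
                    precursor_mz=mz0,
                    precursor_charge=z,
                    mz=mz_arr,
                    intensity=inten_arr,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_mgf(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra to MGF with fixed formatting (byte-deterministic)."""
    with Path(path).open("w") as fh:
        for sp in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={sp.scan_id}\n")
            fh.write(f"PEPMASS={sp.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={sp.precursor_charge}+\n")
            if sp.retention_time is not None:
                fh.write(f"RTINSECONDS={sp.retention_time:.2f}\n")
            for mz, inten in zip(sp.mz, sp.intensity):
                fh.write(f"{mz:.5f} {inten:.2f}\n")
            fh.write("END IONS\n\n")


def _b64_doubles(values: np.ndarray) -> str:
    raw = struct.pack(f"<{values.size}d", *map(float, values))
    return base64.b64encode(raw).decode("ascii")


def write_mzml(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write a minimal mzML file readable by the pyteomics mzML parser.

    Uncompressed 64-bit m/z and intensity arrays, MS level 2, one selected
    ion with charge state per spectrum.  Not a full mzML implementation.
    """
    NS = "http://psi.hupo.org/ms/mzml"
    root = etree.Element(f"{{{NS}}}mzML", nsmap={None: NS}, version="1.1.0")
    cv_list = etree.SubElement(root, f"{{{NS}}}cvList", count="1")
    etree.SubElement(
        cv_list, f"{{{NS}}}cv", id="MS",
        fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    run = etree.SubElement(root, f"{{{NS}}}run", id="run1")
    slist = etree.SubElement(
        run, f"{{{NS}}}spectrumList", count=str(len(spectra)),
        defaultDataProcessingRef="dp1",
    )

    def cv(parent, accession, name, value="", unit=None):
        attrs = {"cvRef": "MS", "accession": accession, "name": name, "value": value}
        if unit:
            attrs.update(
                unitCvRef="MS", unitAccession=unit[0], unitName=unit[1]
            )
        etree.SubElement(parent, f"{{{NS}}}cvParam", **attrs)

    for i, sp in enumerate(spectra):
        spec = etree.SubElement(
            slist, f"{{{NS}}}spectrum", index=str(i), id=sp.scan_id,
            defaultArrayLength=str(sp.n_peaks),
        )
        cv(spec, "MS:1000511", "ms level", "2")
        cv(spec, "MS:1000580", "MSn spectrum")
        cv(spec, "MS:1000127", "centroid spectrum")
        plist = etree.SubElement(spec, f"{{{NS}}}precursorList", count="1")
        prec = etree.SubElement(plist, f"{{{NS}}}precursor")
        silist = etree.SubElement(prec, f"{{{NS}}}selectedIonList", count="1")
        sion = etree.SubElement(silist, f"{{{NS}}}selectedIon")
        cv(sion, "MS:1000744", "selected ion m/z", f"{sp.precursor_mz:.6f}",
           unit=("MS:1000040", "m/z"))
        cv(sion, "MS:1000041", "charge state", str(sp.precursor_charge))
        balist = etree.SubElement(spec, f"{{{NS}}}binaryDataArrayList", count="2")
        for arr, acc, name, unit in (
            (sp.mz, "MS:1000514", "m/z array", ("MS:1000040", "m/z")),
            (sp.intensity, "MS:1000515", "intensity array",
             ("MS:1000131", "number of detector counts")),
        ):
            encoded = _b64_doubles(arr)
            bda = etree.SubElement(
                balist, f"{{{NS}}}binaryDataArray", encodedLength=str(len(encoded))
            )
            cv(bda, "MS:1000523", "64-bit float")
            cv(bda, "MS:1000576", "no compression")
            cv(bda, acc, name, unit=unit)
            etree.SubElement(bda, f"{{{NS}}}binary").text = encoded
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess(spectrum: Spectrum, top_n: int = 150, min_mz: float = 100.0) -> Spectrum:
    """Keep the ``top_n`` most intense peaks above ``min_mz``.

    Ties in intensity are broken in favour of the lower m/z peak; the output
    is re-sorted ascending by m/z.  Idempotent for fixed parameters.
    """
    if top_n < 1:
        raise SpectrumError("top_n must be >= 1")
    keep = spectrum.mz >= min_mz
    mz, inten = spectrum.mz[keep], spectrum.intensity[keep]
    if mz.size > top_n:
        # sort by (-intensity, mz): stable lexsort, last key primary
        order = np.lexsort((mz, -inten))[:top_n]
        mz, inten = mz[order], inten[order]
    return replace(spectrum, mz=mz, intensity=inten)


# ---------------------------------------------------------------------------
# Theoretical fragments
# ---------------------------------------------------------------------------

def _site_deltas(pf: Peptidoform, fixed: Iterable[Modification]) -> np.ndarray:
    """Per-position mass additions (fixed + variable mods + localized offset).

    Index 0 additionally absorbs any N-terminal variable modification, so
    prefix sums over this array give b-ion neutral masses directly.
    """
    n = len(pf.sequence)
    deltas = np.zeros(n)
    for fm in fixed:
        for i, aa in enumerate(pf.sequence):
            if aa in fm.residues:
                deltas[i] += fm.mass_delta
    for pos, vm in pf.var_mod_sites:
        deltas[max(pos, 0)] += vm.mass_delta
    if not pf.offset.is_zero and isinstance(pf.offset_site, int):
        deltas[pf.offset_site] += pf.offset.mass_delta
    return deltas


def fragment_mz_arrays(
    pf: Peptidoform,
    max_fragment_charge: int = 2,
    fixed: Iterable[Modification] = (CARBAMIDOMETHYL,),
    offset_site: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized fragment m/z computation.

    Returns ``(mz, series, shifted)`` arrays: ``series`` is 0 for b, 1 for
    y; ``shifted`` marks fragments containing the offset site.  If the form
    carries an unlocalized non-zero offset and ``offset_site`` is None, the
    returned series is unshifted (localization supplies sites).
    ``offset_site`` overrides the form's own site.
    """
    seq = pf.sequence
    n = len(seq)
    if offset_site is not None:
        site: int | None = offset_site
        base_pf = replace(pf, offset_site="unlocalized")
    else:
        site = pf.offset_site if isinstance(pf.offset_site, int) else None
        base_pf = pf
    residue = np.array([AA_MASS[aa] for aa in seq])
    residue += _site_deltas(base_pf, fixed)
    if offset_site is not None:
        residue[offset_site] += pf.offset.mass_delta
    prefix = np.cumsum(residue)  # b_i neutral mass = prefix[i-1]
    total = prefix[-1] + MASS_WATER
    b_neutral = prefix[:-1]
    y_neutral = total - prefix[:-1]  # y_(n-i) pairs with b_i

    mzs, series, shifted = [], [], []
    if site is not None:
        b_shift = np.arange(1, n) > site  # b_i contains site iff i-1 >= site
        y_shift = np.arange(n - 1, 0, -1) > (n - 1 - site)
    else:
        b_shift = np.zeros(n - 1, dtype=bool)
        y_shift = np.zeros(n - 1, dtype=bool)
    for z in range(1, max_fragment_charge + 1):
        mzs.append((b_neutral + z * MASS_PROTON) / z)
        series.append(np.zeros(n - 1, dtype=np.int8))
        shifted.append(b_shift)
        mzs.append((y_neutral + z * MASS_PROTON) / z)
        series.append(np.ones(n - 1, dtype=np.int8))
        shifted.append(y_shift)
    return (
        np.concatenate(mzs),
        np.concatenate(series),
        np.concatenate(shifted),
    )


def theoretical_fragments(
    pf: Peptidoform,
    max_fragment_charge: int = 2,
    fixed: Iterable[Modification] = (CARBAMIDOMETHYL,),
) -> list[FragmentIon]:
    """All b/y ions of a peptidoform at charges 1..``max_fragment_charge``.

    Site-localized deltas (variable mods, a localized offset) shift every
    fragment containing the site; an unlocalized offset contributes the
    unshifted series only (see
    :func:`fpopseek.search_engine.localize_delta_mass`).
    """
    n = len(pf.sequence)
    mz, series, shifted = fragment_mz_arrays(pf, max_fragment_charge, fixed)
    ions: list[FragmentIon] = []
    per_charge = 2 * (n - 1)
    for z in range(1, max_fragment_charge + 1):
        base = (z - 1) * per_charge
        for i in range(n - 1):
            ions.append(FragmentIon("b", i + 1, z, float(mz[base + i]), bool(shifted[base + i])))
        for i in range(n - 1):
            j = base + (n - 1) + i
            ions.append(FragmentIon("y", n - 1 - i, z, float(mz[j]), bool(shifted[j])))
    return ions
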