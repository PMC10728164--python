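"""Readers and writers for the formats the pipeline touches.

Spectra: mzML (read via pyteomics, written by a minimal built-in writer
with uncompressed 64-bit arrays) and two-column whitespace/CSV peak lists.
Mobilograms: two-column text with a ``#key value`` sidecar header carrying
charge, ion mass and gas parameters.  Tables: CSV via pandas; ground truth
and reports: JSON.
"""

from __future__ import annotations

import base64
import json
import struct
import zlib
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from lxml import etree

from .chem import ProteinSequence
from .errors import ConfigurationError
from .mobility import GasParameters, Mobilogram
from .spectra import DeconvolvedSpecies, Spectrum


def read_fasta(path, identifier: Optional[str] = None,
               numbering_origin: int = 1) -> ProteinSequence:
    """First (or named) record of a FASTA file as a ProteinSequence."""
    for rec in SeqIO.parse(str(path), "fasta"):
        if identifier is None or identifier in rec.id:
            return ProteinSequence(identifier=rec.id, residues=str(rec.seq),
                                   numbering_origin=numbering_origin)
    raise ConfigurationError(f"no matching record in {path}")


# ---------------------------------------------------------------------------
# peak lists and spectra


def read_peaklist(path, metadata: Optional[dict] = None) -> Spectrum:
    """Two-column (m/z, intensity) text, whitespace- or comma-separated;
    '#'-prefixed lines are ignored."""
    mz, inten = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            mz.append(float(parts[0]))
            inten.append(float(parts[1]))
    order = np.argsort(mz)
    return Spectrum(np.asarray(mz)[order], np.asarray(inten)[order],
                    metadata or {})


def write_peaklist(path, s: Spectrum) -> None:
    with open(path, "w") as fh:
        for k, v in sorted(s.metadata.items()):
            fh.write(f"# {k} {v}\n")
        for mzv, iv in zip(s.mz, s.intensity):
            fh.write(f"{mzv:.6f}\t{iv:.4f}\n")


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(
        struct.pack(f"<{arr.size}d", *arr.astype(float))).decode()


def write_mzml(path, spectra: Sequence[Spectrum]) -> None:
    """Minimal mzML: uncompressed little-endian 64-bit arrays, MS level 1
    unless the spectrum metadata says otherwise."""
    chunks = ['<?xml version="1.0" encoding="utf-8"?>\n'
              '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n'
              f'<run id="run1">\n<spectrumList count="{len(spectra)}">\n']
    for i, s in enumerate(spectra):
        level = int(s.metadata.get("ms_level", 1))
        mzb, ib = _b64(s.mz), _b64(s.intensity)
        chunks.append(
            f'<spectrum index="{i}" id="scan={i + 1}" '
            f'defaultArrayLength="{len(s)}">\n'
            f'<cvParam cvRef="MS" accession="MS:1000511" name="ms level" '
            f'value="{level}"/>\n'
            '<binaryDataArrayList count="2">\n'
            f'<binaryDataArray encodedLength="{len(mzb)}">\n'
            '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
            '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
            '<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" '
            'value="" unitName="m/z"/>\n'
            f'<binary>{mzb}</binary>\n</binaryDataArray>\n'
            f'<binaryDataArray encodedLength="{len(ib)}">\n'
            '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
            '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
            '<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" '
            'value="" unitName="number of detector counts"/>\n'
            f'<binary>{ib}</binary>\n</binaryDataArray>\n'
            '</binaryDataArrayList>\n</spectrum>\n')
    chunks.append('</spectrumList>\n</run>\n</mzML>\n')
    Path(path).write_text("".join(chunks))


def _decode_binary_array(bda, ns: str) -> tuple[Optional[str], np.ndarray]:
    """Decode one <binaryDataArray>: returns (array name, values)."""
    dtype, compressed, name = np.float64, False, None
    for cv in bda.findall(f"{ns}cvParam"):
        acc = cv.get("accession")
        if acc == "MS:1000521":
            dtype = np.float32
        elif acc == "MS:1000523":
            dtype = np.float64
        elif acc == "MS:1000574":
            compressed = True
        elif acc == "MS:1000514":
            name = "mz"
        elif acc == "MS:1000515":
            name = "intensity"
    node = bda.find(f"{ns}binary")
    raw = base64.b64decode(node.text or "")
    if compressed:
        raw = zlib.decompress(raw)
    return name, np.frombuffer(raw, dtype=np.dtype(dtype).newbyteorder("<"))


def read_mzml(path) -> list[Spectrum]:
    """Read mzML spectra (uncompressed or zlib, 32/64-bit float arrays)."""
    tree = etree.parse(str(path))
    root = tree.getroot()
    ns = root.tag.split("}")[0] + "}" if root.tag.startswith("{") else ""
    out = []
    for sp in root.iter(f"{ns}spectrum"):
        meta = {"id": sp.get("id"), "ms_level": 1}
        for cv in sp.findall(f"{ns}cvParam"):
            if cv.get("accession") == "MS:1000511":
                meta["ms_level"] = int(cv.get("value"))
        arrays: dict[str, np.ndarray] = {}
        for bda in sp.iter(f"{ns}binaryDataArray"):
            name, vals = _decode_binary_array(bda, ns)
            if name:
                arrays[name] = vals
        if "mz" not in arrays or "intensity" not in arrays:
            raise ConfigurationError(
                f"spectrum {meta['id']} lacks m/z or intensity array")
        out.append(Spectrum(np.asarray(arrays["mz"], dtype=float),
                            np.asarray(arrays["intensity"], dtype=float), meta))
    return out


def read_spectrum(path) -> Spectrum:
    """Dispatch on extension: .mzML -> first scan; anything else -> peak list."""
    p = Path(path)
    if p.suffix.lower() == ".mzml":
        spectra = read_mzml(p)
        if not spectra:
            raise ConfigurationError(f"{path} contains no spectra")
        return spectra[0]
    return read_peaklist(p)


# ---------------------------------------------------------------------------
# mobilograms


def write_mobilogram(path, m: Mobilogram, g: GasParameters = GasParameters()) -> None:
    with open(path, "w") as fh:
        fh.write(f"# charge {m.charge}\n# ion_mass {m.ion_mass}\n")
        fh.write(f"# gas_mass {g.gas_mass}\n# temperature {g.temperature}\n")
        for x, y in zip(m.inverse_K0, m.intensity):
            fh.write(f"{x:.8f}\t{y:.6f}\n")


def read_mobilogram(path) -> tuple[Mobilogram, GasParameters]:
    header: dict[str, float] = {}
    xs, ys = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, val = line[1:].split()
                header[key] = float(val)
            else:
                a, b = line.replace(",", " ").split()
                xs.append(float(a))
                ys.append(float(b))
    for req in ("charge", "ion_mass"):
        if req not in header:
            raise ConfigurationError(f"mobilogram sidecar header lacks {req}")
    g = GasParameters(gas_mass=header.get("gas_mass", 28.0134),
                      temperature=header.get("temperature", 305.0))
    return Mobilogram(np.asarray(xs), np.asarray(ys),
                      charge=int(header["charge"]),
                      ion_mass=header["ion_mass"]), g


# ---------------------------------------------------------------------------
# reports


def species_frame(species: Sequence[DeconvolvedSpecies]) -> pd.DataFrame:
    return pd.DataFrame([{
        "monoisotopic_mass": sp.monoisotopic_mass, "charge": sp.charge,
        "abundance": sp.abundance, "fit_score": sp.fit_score, "snr": sp.snr,
        "quality_factor": sp.quality_factor, "flags": ";".join(sp.flags)}
        for sp in species])


def matches_frame(matches) -> pd.DataFrame:
    return pd.DataFrame([{
        "level": m.level, "label": m.candidate_label,
        "observed_mass": m.species.monoisotopic_mass,
        "candidate_mass": m.candidate_mass, "ppm_error": m.ppm_error}
        for m in matches])


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True,
                                     default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dict__"):
        return {k: v for k, v in vars(obj).items() if not k.startswith("_")}
    raise TypeError(f"not JSON serializable: {type(obj)}")
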