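"""Centroided spectra and the MGF peak-list interchange format.

The pipeline's interchange format is Mascot Generic Format (MGF): plain
text, one BEGIN IONS/END IONS block per MS2 spectrum with KEY=VALUE headers
followed by "mz intensity" peak lines. Reference libraries additionally
carry compound name, adduct and SMILES in the block headers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np


@dataclass
class Spectrum:
    """A centroided mass spectrum.

    Peaks are stored as parallel numpy arrays sorted strictly ascending by
    m/z. ``provenance`` is a USI-style ``file:scan`` identifier.
    """

    peaks_mz: np.ndarray
    peaks_intensity: np.ndarray
    ms_level: int = 2
    precursor_mz: Optional[float] = None
    rt: Optional[float] = None
    drift: Optional[float] = None
    provenance: str = ""
    metadata: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.peaks_mz = np.asarray(self.peaks_mz, dtype=float)
        self.peaks_intensity = np.asarray(self.peaks_intensity, dtype=float)
        if self.peaks_mz.shape != self.peaks_intensity.shape:
            raise ValueError("m/z and intensity arrays must have equal length")
        if np.any(self.peaks_intensity < 0):
            raise ValueError("peak intensities must be non-negative")
        order = np.argsort(self.peaks_mz, kind="stable")
        self.peaks_mz = self.peaks_mz[order]
        self.peaks_intensity = self.peaks_intensity[order]
        if self.peaks_mz.size > 1 and np.any(np.diff(self.peaks_mz) <= 0):
            # merge exact duplicates rather than reject: centroiders can emit them
            mz, inv = np.unique(self.peaks_mz, return_inverse=True)
            intensity = np.zeros_like(mz)
            np.add.at(intensity, inv, self.peaks_intensity)
            self.peaks_mz, self.peaks_intensity = mz, intensity
        if self.ms_level == 2 and self.precursor_mz is not None and self.precursor_mz <= 0:
            raise ValueError("MS2 spectra require a positive precursor m/z")

    @property
    def n_peaks(self) -> int:
        return int(self.peaks_mz.size)

    @property
    def total_intensity(self) -> float:
        return float(self.peaks_intensity.sum())

    def base_peak(self) -> Tuple[float, float]:
        i = int(np.argmax(self.peaks_intensity))
        return float(self.peaks_mz[i]), float(self.peaks_intensity[i])

    def with_provenance(self, provenance: str) -> "Spectrum":
        return replace(self, provenance=provenance)


def peaks_from_pairs(pairs: Iterable[Tuple[float, float]]) -> Tuple[np.ndarray, np.ndarray]:
    """Split an iterable of (mz, intensity) pairs into parallel arrays."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0:
        return np.empty(0), np.empty(0)
    return arr[:, 0], arr[:, 1]


# ---------------------------------------------------------------------------
# MGF reading / writing

_HEADER_KEYS = {
    "PEPMASS": "precursor_mz",
    "RTINSECONDS": "rt_seconds",
    "RTINMINUTES": "rt_minutes",
    "ION_MOBILITY": "drift",
}


def read_mgf(path) -> List[Spectrum]:
    """Parse an MGF file into a list of MS2 :class:`Spectrum` objects.

    Recognizes PEPMASS, RTINSECONDS/RTINMINUTES, ION_MOBILITY and TITLE;
    every other KEY=VALUE header is preserved verbatim in ``metadata``.
    """
    spectra: List[Spectrum] = []
    path = Path(path)
    in_block = False
    headers: Dict[str, str] = {}
    peaks: List[Tuple[float, float]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "BEGIN IONS":
            in_block, headers, peaks = True, {}, []
        elif line == "END IONS":
            if not in_block:
                raise ValueError(f"{path}:{lineno}: END IONS without BEGIN IONS")
            spectra.append(_block_to_spectrum(headers, peaks, default_id=f"{path.name}:{len(spectra) + 1}"))
            in_block = False
        elif in_block and "=" in line:
            key, _, value = line.partition("=")
            headers[key.strip().upper()] = value.strip()
        elif in_block:
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: malformed peak line {line!r}")
            peaks.append((float(fields[0]), float(fields[1])))
    if in_block:
        raise ValueError(f"{path}: unterminated BEGIN IONS block")
    return spectra


def _block_to_spectrum(
    headers: Dict[str, str], peaks: List[Tuple[float, float]], default_id: str
) -> Spectrum:
    precursor = None
    if "PEPMASS" in headers:
        precursor = float(headers["PEPMASS"].split()[0])
    rt = None
    if "RTINSECONDS" in headers:
        rt = float(headers["RTINSECONDS"]) / 60.0
    elif "RTINMINUTES" in headers:
        rt = float(headers["RTINMINUTES"])
    drift = float(headers["ION_MOBILITY"]) if "ION_MOBILITY" in headers else None
    provenance = headers.get("TITLE", default_id)
    extra = {
        k: v
        for k, v in headers.items()
        if k not in {"PEPMASS", "RTINSECONDS", "RTINMINUTES", "ION_MOBILITY", "TITLE", "CHARGE", "MSLEVEL"}
    }
    mz, intensity = peaks_from_pairs(peaks)
    return Spectrum(
        peaks_mz=mz,
        peaks_intensity=intensity,
        ms_level=int(headers.get("MSLEVEL", 2)),
        precursor_mz=precursor,
        rt=rt,
        drift=drift,
        provenance=provenance,
        metadata=extra,
    )


def write_mgf(spectra: Sequence[Spectrum], path) -> None:
    """Write spectra as MGF, preserving peaks to 1e-4 Da / 1e-2 intensity."""
    lines: List[str] = []
    for spectrum in spectra:
        lines.append("BEGIN IONS")
        if spectrum.provenance:
            lines.append(f"TITLE={spectrum.provenance}")
        if spectrum.precursor_mz is not None:
            lines.append(f"PEPMASS={spectrum.precursor_mz:.6f}")
        lines.append("CHARGE=1+")
        lines.append(f"MSLEVEL={spectrum.ms_level}")
        if spectrum.rt is not None:
            lines.append(f"RTINSECONDS={spectrum.rt * 60.0:.3f}")
        if spectrum.drift is not None:
            lines.append(f"ION_MOBILITY={spectrum.drift:.5f}")
        for key, value in spectrum.metadata.items():
            lines.append(f"{key.upper()}={value}")
        for mz, inten in zip(spectrum.peaks_mz, spectrum.peaks_intensity):
            lines.append(f"{mz:.5f} {inten:.3f}")
        lines.append("END IONS")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def split_provenance(provenance: str) -> Tuple[str, int]:
    """Split a ``file:scan`` provenance string; scan defaults to -1."""
    if ":" in provenance:
        file_id, _, scan = provenance.rpartition(":")
        try:
            return file_id, int(scan)
        except ValueError:
            return provenance, -1
    return provenance, -1
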