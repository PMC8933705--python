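"""Centroided MS2 spectra: in-memory container and mzML/MGF readers."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from pyteomics import mgf, mzml

__all__ = ["SpectrumPeaks", "SpectrumStore", "read_spectra"]


@dataclass
class SpectrumPeaks:
    """A centroided MS2 spectrum: sorted m/z and intensity arrays.

    ``spectrum_id`` follows the ``<run>.<scan>.<scan>.<charge>`` convention
    common to search-engine PSM tables; MGF titles are matched as a fallback.
    """

    spectrum_id: str
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float = 0.0
    precursor_charge: int = 0

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(self.intensity < 0):
            raise ValueError("negative peak intensity")
        order = np.argsort(self.mz, kind="stable")
        if not np.all(order == np.arange(len(order))):
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    @property
    def base_peak(self) -> float:
        """Intensity of the most intense peak (0 for an empty spectrum)."""
        return float(self.intensity.max()) if self.intensity.size else 0.0

    def __len__(self) -> int:
        return int(self.mz.size)


def centroid_profile(
    mz: np.ndarray, intensity: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Local-maximum peak picking for profile-mode scans (fallback only)."""
    if len(mz) < 3:
        return mz, intensity
    inner = intensity[1:-1]
    keep = (inner >= intensity[:-2]) & (inner > intensity[2:]) & (inner > 0)
    idx = np.flatnonzero(keep) + 1
    return mz[idx], intensity[idx]


class SpectrumStore:
    """Dictionary-like store of :class:`SpectrumPeaks` keyed by spectrum id.

    MGF title strings are registered as alias keys so PSM tables referring
    to either convention resolve.
    """

    def __init__(self) -> None:
        self._spectra: dict[str, SpectrumPeaks] = {}
        self._aliases: dict[str, str] = {}

    def add(self, spectrum: SpectrumPeaks, aliases: Iterable[str] = ()) -> None:
        self._spectra[spectrum.spectrum_id] = spectrum
        for alias in aliases:
            self._aliases[alias] = spectrum.spectrum_id

    def get(self, spectrum_id: str) -> SpectrumPeaks | None:
        if spectrum_id in self._spectra:
            return self._spectra[spectrum_id]
        key = self._aliases.get(spectrum_id)
        return self._spectra.get(key) if key is not None else None

    def __contains__(self, spectrum_id: str) -> bool:
        return self.get(spectrum_id) is not None

    def __len__(self) -> int:
        return len(self._spectra)

    def ids(self) -> list[str]:
        return list(self._spectra)


def _scan_number(mzml_id: str) -> str:
    # mzML native ids look like "controllerType=0 controllerNumber=1 scan=42"
    for token in mzml_id.split():
        if token.startswith("scan="):
            return token[5:]
    return mzml_id


def _read_mzml(path: Path, store: SpectrumStore) -> None:
    run = path.stem
    with mzml.MzML(str(path)) as reader:
        for entry in reader:
            if entry.get("ms level") != 2:
                continue
            mz = np.asarray(entry["m/z array"], dtype=float)
            inten = np.asarray(entry["intensity array"], dtype=float)
            if entry.get("profile spectrum") is not None:
                warnings.warn(
                    f"{path.name}: profile-mode scan centroided by "
                    "local-maximum picking"
                )
                mz, inten = centroid_profile(mz, inten)
            charge, prec_mz = 0, 0.0
            try:
                ion = entry["precursorList"]["precursor"][0][
                    "selectedIonList"
                ]["selectedIon"][0]
                prec_mz = float(ion.get("selected ion m/z", 0.0))
                charge = int(ion.get("charge state", 0))
            except (KeyError, IndexError):
                pass
            scan = _scan_number(entry["id"])
            sid = f"{run}.{scan}.{scan}.{charge}"
            store.add(SpectrumPeaks(sid, mz, inten, prec_mz, charge))


def _read_mgf(path: Path, store: SpectrumStore) -> None:
    run = path.stem
    with mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader, start=1):
            params = entry["params"]
            title = str(params.get("title", f"{run}.{i}"))
            charge = 0
            if params.get("charge"):
                charge = int(params["charge"][0])
            prec_mz = float(params.get("pepmass", (0.0,))[0])
            scans = str(params.get("scans", i))
            sid = f"{run}.{scans}.{scans}.{charge}"
            spectrum = SpectrumPeaks(
                sid,
                np.asarray(entry["m/z array"], dtype=float),
                np.asarray(entry["intensity array"], dtype=float),
                prec_mz,
                charge,
            )
            store.add(spectrum, aliases=[title])


def read_spectra(paths: Iterable[str | Path]) -> SpectrumStore:
    """Read MS2 scans from mzML and/or MGF files into one unified store."""
    store = SpectrumStore()
    for path in paths:
        path = Path(path)
        suffix = path.suffix.lower()
        if suffix == ".mzml":
            _read_mzml(path, store)
        elif suffix == ".mgf":
            _read_mgf(path, store)
        else:
            raise ValueError(f"unsupported spectrum format: {path}")
    return store
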