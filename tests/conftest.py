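import numpy as np
import pytest

from glycofdr.candidates import IsotopeSet
from glycofdr.composition import GlycanComposition, build_database
from glycofdr.scoring import ScoringParams
from glycofdr.simulate import make_glycan_series
from glycofdr.spectra import SpectrumPeaks


@pytest.fixture
def yeast_db():
    """HexNAc(2)Hex(4..20) series, no adducts: 17 entries."""
    return build_database(make_glycan_series(2, 4, 20))


@pytest.fixture
def default_params():
    p = ScoringParams()
    p.validate()
    return p


@pytest.fixture
def iso_set():
    return IsotopeSet()


def spectrum_from_peaks(peaks, spectrum_id="t.1.1.2", charge=2):
    """Build a SpectrumPeaks from (m/z, intensity) pairs."""
    if peaks:
        mz, inten = zip(*peaks)
    else:
        mz, inten = (), ()
    return SpectrumPeaks(
        spectrum_id, np.asarray(mz, float), np.asarray(inten, float),
        precursor_charge=charge,
    )


@pytest.fixture
def make_spectrum():
    return spectrum_from_peaks


def random_composition(rng):
    """Random nonempty composition over all residue classes."""
    counts = {
        "HexNAc": int(rng.integers(0, 7)),
        "Hex": int(rng.integers(0, 16)),
        "Fuc": int(rng.integers(0, 3)),
        "NeuAc": int(rng.integers(0, 3)),
        "NeuGc": int(rng.integers(0, 2)),
        "Phospho": int(rng.integers(0, 2)),
        "Sulfo": int(rng.integers(0, 2)),
    }
    if sum(counts.values()) == 0:
        counts["HexNAc"] = 1
    return GlycanComposition(counts)
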