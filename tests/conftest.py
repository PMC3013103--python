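import numpy as np
import pytest

from psmvalid.digest import DigestParams, Ptm, build_digest_index
from psmvalid.io_formats import (Modification, ProteinRecord, PsmCandidate,
                                 SpectrumRecord)


@pytest.fixture()
def toy_database():
    return [
        ProteinRecord("P1", "P1 first", "MKAAAARGGGKLLLLLLR"),
        ProteinRecord("P2", "P2 second", "SSSSSKTTTTTTRPPPPK"),
    ]


@pytest.fixture()
def wide_params():
    # wide-open mass window: every tryptic peptide observable
    return DigestParams(max_missed_cleavages=1, min_mass=1.0, max_mass=1e6,
                        searched_ptms=(Ptm("M", 15.994915, "oxidation"),))


@pytest.fixture()
def toy_index(toy_database, wide_params):
    return build_digest_index(toy_database, wide_params)


@pytest.fixture()
def toy_spectrum():
    peaks = np.array([[300.0, 10.0], [400.0, 5.0], [500.0, 1.0]])
    return SpectrumRecord("spec1", precursor_mh=800.0, charge=1, peaks=peaks)


def make_candidate(**overrides):
    base = dict(spectrum_id="spec1", rank=1, peptide_sequence="AAAAR",
                modifications=(), protein_accession="P1", xcorr=2.5,
                delta_cn=0.0, sp=500.0, sp_rank=1, matched_ions=5,
                total_ions=8, label=1)
    base.update(overrides)
    return PsmCandidate(**base)


@pytest.fixture()
def candidate_factory():
    return make_candidate
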