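import math

import numpy as np
import pytest
from scipy import stats

from psmvalid import features as ft
from psmvalid.digest import DigestParams, Ptm, build_digest_index, peptide_mass
from psmvalid.io_formats import Modification, ProteinRecord, SpectrumRecord


# ---------------------------------------------------------------------------
# Protein hit count

class TestPhc:
    def test_zero_hits_upper_tail_is_zero(self):
        assert ft.phc(0, 10, 1000, 100) == 0.0

    def test_worked_poisson_example(self):
        # lambda = 100 * 10/1000 = 1; P(X >= 5) = 1 - e^-1 * sum_{i<5} 1/i!
        expected = -math.log10(1 - math.exp(-1) * (1 + 1 + 0.5 + 1 / 6 + 1 / 24))
        assert ft.phc(5, 10, 1000, 100) == pytest.approx(expected, abs=1e-9)
        assert ft.phc(5, 10, 1000, 100) == pytest.approx(2.4365, abs=1e-3)

    def test_monotone_in_k(self):
        vals = [ft.phc(k, 10, 1000, 100) for k in range(0, 15)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_monotone_decreasing_in_relative_abundance(self):
        # at fixed k, a protein with more observable peptides is less surprising
        vals = [ft.phc(8, n, 10000, 2000) for n in (5, 10, 20, 40)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_lower_tail_mode_is_literal_k_or_fewer(self):
        lam = 2000 * 10 / 10000
        expected = -stats.poisson.logcdf(3, lam) / math.log(10)
        assert ft.phc(3, 10, 10000, 2000, tail="lower") == pytest.approx(expected)

    def test_no_observable_peptides(self):
        assert ft.phc(0, 0, 1000, 100) == 0.0
        with pytest.raises(ValueError, match="no observable peptides"):
            ft.phc(1, 0, 1000, 100)

    @pytest.mark.parametrize("kwargs", [
        dict(k=-1, n=10, d=100, p=50), dict(k=60, n=10, d=100, p=50),
        dict(k=1, n=200, d=100, p=50), dict(k=1, n=10, d=100, p=0),
    ])
    def test_invalid_inputs_raise(self, kwargs):
        with pytest.raises(ValueError):
            ft.phc(**kwargs)

    def test_poisson_matches_exact_binomial_oracle(self):
        """In the realistic regime (thousands of instances, rare peptides)
        the Poisson tail tracks the exact binomial sum to < 0.05 log10."""
        rng = np.random.default_rng(42)
        for _ in range(300):
            p_total = int(rng.integers(2000, 50001))
            frac = 10 ** rng.uniform(-4, math.log10(min(0.01, 10.0 / p_total)))
            d = 200_000
            n = max(1, int(round(frac * d)))
            frac = n / d
            lam = p_total * frac
            k = min(p_total, int(rng.binomial(p_total, frac)) + int(rng.integers(0, 9)))
            if k == 0:
                continue
            ours = ft.phc(k, n, d, p_total)
            exact = -stats.binom.logsf(k - 1, p_total, frac) / math.log(10)
            assert ours == pytest.approx(exact, abs=0.05), (p_total, frac, k)


# ---------------------------------------------------------------------------
# Potential coverage ratio

class TestPcr:
    @pytest.fixture()
    def two_peptide_index(self):
        # two disjoint observable tryptic peptides: 10-mer and 30-mer
        seq = "AAAAAAAAAK" + "C" * 29 + "K"
        db = [ProteinRecord("P1", "", seq)]
        params = DigestParams(max_missed_cleavages=0, min_mass=1, max_mass=1e9,
                              searched_ptms=())
        return build_digest_index(db, params)

    def test_partial_coverage_by_residues(self, two_peptide_index):
        assert ft.pcr("P1", {"AAAAAAAAAK"}, two_peptide_index) == pytest.approx(0.25)

    def test_full_and_empty_coverage(self, two_peptide_index):
        full = {"AAAAAAAAAK", "C" * 29 + "K"}
        assert ft.pcr("P1", full, two_peptide_index) == 1.0
        assert ft.pcr("P1", set(), two_peptide_index) == 0.0

    def test_unknown_matched_peptide_excluded_with_warning(self, two_peptide_index,
                                                           caplog):
        with caplog.at_level("WARNING"):
            val = ft.pcr("P1", {"AAAAAAAAAK", "NOTINDB"}, two_peptide_index)
        assert val == pytest.approx(0.25)
        assert "excluded from PCR" in caplog.text

    def test_overlapping_peptides_not_double_counted(self):
        # missed-cleavage peptide overlaps its two sub-peptides completely
        seq = "AAAKCCCK"
        db = [ProteinRecord("P1", "", seq)]
        params = DigestParams(max_missed_cleavages=1, min_mass=1, max_mass=1e9,
                              searched_ptms=())
        index = build_digest_index(db, params)
        assert ft.pcr("P1", {"AAAK", "AAAKCCCK"}, index) == 1.0

    def test_monotone_under_added_peptides(self, two_peptide_index):
        v1 = ft.pcr("P1", set(), two_peptide_index)
        v2 = ft.pcr("P1", {"AAAAAAAAAK"}, two_peptide_index)
        v3 = ft.pcr("P1", {"AAAAAAAAAK", "C" * 29 + "K"}, two_peptide_index)
        assert v1 <= v2 <= v3


# ---------------------------------------------------------------------------
# PTM percentage

PTMS = (Ptm("M", 15.994915, "ox"), Ptm("STY", 79.966331, "phos"))


class TestPtmPercentage:
    def test_quarter_modified(self, candidate_factory):
        c = candidate_factory(peptide_sequence="MSTYK",
                              modifications=(Modification(1, 15.994915),))
        assert ft.ptm_percentage(c, PTMS) == pytest.approx(25.0)

    def test_no_modifiable_residues(self, candidate_factory):
        c = candidate_factory(peptide_sequence="AAGGK", modifications=())
        assert ft.ptm_percentage(c, PTMS) == 0.0

    def test_fully_modified(self, candidate_factory):
        mods = tuple(Modification(i, 79.966331) for i in (1, 2, 3))
        c = candidate_factory(peptide_sequence="STYAK", modifications=mods)
        assert ft.ptm_percentage(c, PTMS) == pytest.approx(100.0)

    def test_mod_on_non_target_residue_raises(self, candidate_factory):
        c = candidate_factory(peptide_sequence="AGK",
                              modifications=(Modification(1, 79.966331),))
        with pytest.raises(ValueError, match="not a target"):
            ft.ptm_percentage(c, PTMS)


# ---------------------------------------------------------------------------
# Spectral quality

class TestSpectralQuality:
    def test_single_peak(self):
        spec = SpectrumRecord("s", 500.0, 1, np.array([[100.0, 10.0]]))
        q = ft.spectral_quality_features(spec)
        assert q["summed_intensity"] == 10.0
        assert q["intensity_mean"] == 10.0
        assert q["intensity_std"] == 0.0
        assert q["peak_count"] == 1.0
        assert [q[f"intensity_bin{i}"] for i in range(1, 6)] == [0, 0, 0, 0, 1]

    def test_constant_intensities_all_in_top_bin(self):
        peaks = np.column_stack([np.arange(4) + 100.0, np.ones(4)])
        q = ft.spectral_quality_features(SpectrumRecord("s", 500.0, 1, peaks))
        assert q["intensity_mean"] == 1.0 and q["intensity_std"] == 0.0
        assert q["intensity_bin5"] == 1.0

    def test_hand_binned_example(self):
        peaks = np.array([[100.0, 10.0], [200.0, 5.0], [300.0, 1.0]])
        q = ft.spectral_quality_features(SpectrumRecord("s", 500.0, 1, peaks))
        bins = [q[f"intensity_bin{i}"] for i in range(1, 6)]
        assert bins == pytest.approx([1 / 3, 0, 1 / 3, 0, 1 / 3])

    def test_bins_sum_to_one_on_random_spectra(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(1, 200))
            peaks = np.column_stack([np.sort(rng.uniform(100, 2000, n)),
                                     rng.lognormal(5, 1, n)])
            q = ft.spectral_quality_features(SpectrumRecord("s", 500.0, 1, peaks))
            assert sum(q[f"intensity_bin{i}"] for i in range(1, 6)) == \
                   pytest.approx(1.0)

    def test_empty_peak_list_raises(self):
        spec = SpectrumRecord("s", 500.0, 1, np.empty((0, 2)))
        with pytest.raises(ValueError, match="no peaks"):
            ft.spectral_quality_features(spec)


# ---------------------------------------------------------------------------
# Published + Sequest groups

class TestPublishedFeatures:
    def test_residue_tallies_and_cterm_codes(self, toy_index, toy_spectrum,
                                             candidate_factory):
        c = candidate_factory(peptide_sequence="AAPPK")
        out = ft.published_features(c, ntt=2, spectrum=toy_spectrum,
                                    index=toy_index)
        assert out["proline_count"] == 2
        assert out["arginine_count"] == 0
        assert out["c_terminal_code"] == 2  # Lys
        assert ft.c_terminal_code("AAAAR") == 1
        assert ft.c_terminal_code("AAAAG") == 3

    def test_mass_window_counting_toy(self):
        db = [ProteinRecord("P1", "", "AAAAKAAAGKAAACK")]
        params = DigestParams(max_missed_cleavages=0, min_mass=1, max_mass=1e9,
                              searched_ptms=())
        index = build_digest_index(db, params)
        masses = index.sorted_masses
        center = float((masses.max() + masses.min()) / 2)
        window = float((masses.max() - masses.min()) / 2) + 0.001
        assert index.count_in_mass_window(center, window) == len(masses)
        assert index.count_in_mass_window(float(masses.min()), 0.001) == 1

    @pytest.mark.parametrize("charge, seq, expected", [
        (2, "AAAAG", 1),   # charge exceeds all basics -> mobile
        (1, "RAAAG", 3),   # charge <= arginines -> non-mobile
        (2, "KHAAG", 2),   # in between -> partially mobile
    ])
    def test_mobile_proton_factor(self, charge, seq, expected):
        assert ft.mobile_proton_factor(charge, seq) == expected


class TestSequestFeatures:
    def test_ion_fraction_and_passthrough(self, toy_spectrum, candidate_factory):
        c = candidate_factory(matched_ions=5, total_ions=20)
        out = ft.sequest_features(c, toy_spectrum)
        assert out["ion_fraction"] == 0.25
        assert out["xcorr"] == c.xcorr and out["delta_cn"] == c.delta_cn

    def test_delta_mh_zero_at_exact_match(self, candidate_factory):
        seq = "AAAAR"
        mh = peptide_mass(seq) + 1.00728
        spec = SpectrumRecord("s", mh, 1, np.array([[100.0, 1.0]]))
        out = ft.sequest_features(candidate_factory(peptide_sequence=seq), spec)
        assert out["delta_mh"] == pytest.approx(0.0, abs=1e-12)

    def test_modification_shifts_theoretical_mass(self, candidate_factory):
        seq, delta = "MAAAR", 15.994915
        mh = peptide_mass(seq) + delta + 1.00728
        spec = SpectrumRecord("s", mh, 1, np.array([[100.0, 1.0]]))
        c = candidate_factory(peptide_sequence=seq,
                              modifications=(Modification(1, delta),))
        assert ft.sequest_features(c, spec)["delta_mh"] == pytest.approx(
            0.0, abs=1e-12)

    def test_zero_total_ions_raises(self, toy_spectrum, candidate_factory):
        c = candidate_factory(total_ions=0, matched_ions=0)
        with pytest.raises(ValueError, match="total_ions"):
            ft.sequest_features(c, toy_spectrum)


# ---------------------------------------------------------------------------
# Matrix assembly

def _tiny_dataset(candidate_factory, toy_database):
    spectra = [
        SpectrumRecord("s1", peptide_mass("AAAAR") + 1.00728, 1,
                       np.array([[300.0, 10.0], [400.0, 5.0]])),
        SpectrumRecord("s2", peptide_mass("TTTTTTR") + 1.00728, 1,
                       np.array([[350.0, 8.0]])),
    ]
    candidates = [
        candidate_factory(spectrum_id="s1", rank=1, peptide_sequence="AAAAR",
                          protein_accession="P1", label=1),
        candidate_factory(spectrum_id="s1", rank=2, peptide_sequence="GGGK",
                          protein_accession="P1", delta_cn=0.2, label=0),
        candidate_factory(spectrum_id="s2", rank=1, peptide_sequence="TTTTTTR",
                          protein_accession="P2", label=0),
    ]
    return spectra, candidates


class TestBuildFeatureMatrix:
    def test_shape_order_and_shared_columns(self, candidate_factory,
                                            toy_database, toy_index):
        spectra, candidates = _tiny_dataset(candidate_factory, toy_database)
        df = ft.build_feature_matrix(candidates, spectra, toy_database,
                                     toy_index)
        assert list(df.columns) == list(ft.FEATURE_NAMES) + ["label"]
        assert len(df) == 3
        # per-spectrum quality features shared across a spectrum's candidates
        s1 = df.loc["s1"]
        assert s1["summed_intensity"].nunique() == 1
        # per-protein features shared across a protein's candidates
        p1_rows = df[[c.protein_accession == "P1" for c in sorted(
            candidates, key=lambda c: (c.spectrum_id, c.rank))]]
        assert p1_rows["phc"].nunique() == 1
        assert p1_rows["pcr"].nunique() == 1

    def test_permutation_invariance_bit_exact(self, candidate_factory,
                                              toy_database, toy_index):
        spectra, candidates = _tiny_dataset(candidate_factory, toy_database)
        df1 = ft.build_feature_matrix(candidates, spectra, toy_database,
                                      toy_index)
        df2 = ft.build_feature_matrix(candidates[::-1], spectra[::-1],
                                      toy_database, toy_index)
        assert df1.equals(df2)

    def test_unresolvable_references_raise(self, candidate_factory,
                                           toy_database, toy_index):
        spectra, candidates = _tiny_dataset(candidate_factory, toy_database)
        bad = candidates + [candidate_factory(spectrum_id="ghost")]
        with pytest.raises(ValueError, match="unresolvable"):
            ft.build_feature_matrix(bad, spectra, toy_database, toy_index)

    def test_roundtrip_via_tsv(self, tmp_path, candidate_factory,
                               toy_database, toy_index):
        spectra, candidates = _tiny_dataset(candidate_factory, toy_database)
        df = ft.build_feature_matrix(candidates, spectra, toy_database,
                                     toy_index)
        path = tmp_path / "features.tsv"
        ft.write_feature_matrix(df, path, header_comment="hdr")
        back = ft.read_feature_matrix(path)
        assert list(back.columns) == list(df.columns)
        np.testing.assert_allclose(back.to_numpy(), df.to_numpy(), rtol=1e-12)


class TestSplitSpectra:
    def test_disjoint_and_complete(self):
        ids = [f"s{i}" for i in range(100)]
        train, test = ft.split_spectra(ids, fraction=0.5, seed=1)
        assert train | test == set(ids)
        assert not train & test
        assert len(train) == 50

    def test_deterministic_given_seed(self):
        ids = [f"s{i}" for i in range(31)]
        assert ft.split_spectra(ids, 0.3, seed=9) == \
               ft.split_spectra(ids, 0.3, seed=9)
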