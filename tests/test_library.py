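import numpy as np
import pytest

from revmet.chem import PROTON_MASS, parse_formula
from revmet.conjugates import assemble_amide
from revmet.library import (
    GateConfig,
    LCMSRun,
    LibraryEntry,
    apply_adduct_inclusion,
    build_library,
    diagnostic_fragment_check,
    diagnostic_status,
    extract_candidates,
    ms2_explanation_score,
    write_library,
)
from revmet.chem import get_adduct
from revmet.spectra import Spectrum, read_mgf
from revmet.simulate import simulate_reaction_run, NoiseConfig

from _oracles import explained_fraction_oracle


def _spec(mz, intensity, precursor=200.0, prov="f:1", rt=None):
    return Spectrum(peaks_mz=mz, peaks_intensity=intensity, precursor_mz=precursor,
                    provenance=prov, rt=rt)


class TestExplanationScore:
    parent = dict(parse_formula("C6H11NO4"))  # glycine x 3OH-C4:0 conjugate

    def test_all_peaks_explained_scores_one(self):
        glycine_frag = 76.039305  # C2H5NO2 + proton
        water_loss = 144.065519  # parent - H2O + proton
        spectrum = _spec([glycine_frag, water_loss], [500.0, 800.0])
        assert ms2_explanation_score(spectrum, self.parent, 0.01) == 1.0

    def test_pure_noise_scores_zero(self):
        spectrum = _spec([123.4567, 222.2222, 345.6789], [10.0, 10.0, 10.0])
        assert ms2_explanation_score(spectrum, self.parent, 0.001) == 0.0

    def test_half_explained_scores_half(self):
        glycine_frag = 76.039305
        spectrum = _spec([glycine_frag, 157.7531], [300.0, 300.0])
        score = ms2_explanation_score(spectrum, self.parent, 0.005)
        assert score == pytest.approx(0.5, abs=1e-12)

    def test_matches_exhaustive_oracle_on_random_peaks(self, rng):
        parent = dict(parse_formula("C5H9NO3"))
        for _ in range(10):
            n = int(rng.integers(2, 10))
            mz = rng.uniform(40.0, 150.0, n)
            intensity = rng.uniform(1.0, 100.0, n)
            spectrum = _spec(mz, intensity)
            got = ms2_explanation_score(spectrum, parent, 0.01)
            expected = explained_fraction_oracle(
                spectrum.peaks_mz, spectrum.peaks_intensity, parent, 0.01
            )
            assert got == pytest.approx(expected, abs=1e-9)

    def test_empty_spectrum_warns_and_scores_zero(self):
        spectrum = _spec([], [])
        with pytest.warns(UserWarning, match="empty"):
            assert ms2_explanation_score(spectrum, self.parent) == 0.0


class TestDiagnosticFragments:
    def test_glutamic_acid_consensus_triplet(self, rng):
        from revmet.conjugates import AmineHead

        glu = AmineHead.from_smiles(
            "glutamic acid", "OC(=O)CCC(N)C(=O)O", [84.0444, 102.0550, 130.0499]
        )
        hit = _spec([84.0444, 102.0550, 130.0499, 301.2], [50, 60, 70, 500])
        assert diagnostic_status(hit, glu, 0.01) == "pass"
        missing = _spec([84.0444, 102.0550, 301.2], [50, 60, 500])
        assert diagnostic_status(missing, glu, 0.01) == "fail"
        # relaxed policy: any two of three suffice
        assert diagnostic_status(missing, glu, 0.01, min_diag=2) == "pass"

    def test_uncurated_head_passes_vacuously(self, glycine):
        spectrum = _spec([100.0], [10.0])
        assert diagnostic_status(spectrum, glycine, 0.01) == "uncurated"
        assert diagnostic_fragment_check(spectrum, glycine, 0.01) is True


class TestAdductInclusion:
    def _entry(self, target, adduct_name, mz=300.0):
        return LibraryEntry(
            target=target,
            adduct=get_adduct(adduct_name),
            spectrum=_spec([100.0, 150.0], [10.0, 20.0], precursor=mz),
            ms1_intensity=1e5,
            feature_height=1e6,
        )

    def test_sodium_without_anchor_is_dropped(self, glycine, hydroxybutyrate_tail):
        target = assemble_amide(glycine, hydroxybutyrate_tail)
        entries = [self._entry(target, "[M+Na]+")]
        assert apply_adduct_inclusion(entries) == []
        assert entries[0].rejected_by == "adduct_inclusion"

    def test_proton_anchor_keeps_sodium(self, glycine, hydroxybutyrate_tail):
        target = assemble_amide(glycine, hydroxybutyrate_tail)
        entries = [self._entry(target, "[M+H]+"), self._entry(target, "[M+Na]+")]
        assert len(apply_adduct_inclusion(entries)) == 2

    def test_ammonium_anchors_potassium(self, glycine, hydroxybutyrate_tail):
        target = assemble_amide(glycine, hydroxybutyrate_tail)
        entries = [self._entry(target, "[M+NH4]+"), self._entry(target, "[M+K]+")]
        assert len(apply_adduct_inclusion(entries)) == 2


class TestExtraction:
    def test_planted_features_are_recovered_exactly(self, small_world):
        run = small_world["run"]
        truth = small_world["run_truth"]
        entries = extract_candidates(
            run, small_world["targets"], [get_adduct("[M+H]+"), get_adduct("[M+Na]+")]
        )
        got_scans = {e.spectrum.provenance for e in entries}
        expected_scans = {f"{t.run}:{t.scans[0]}" for t in truth}
        assert got_scans == expected_scans

    def test_precursor_offset_beyond_ppm_window_is_excluded(self, small_world):
        run = small_world["run"]
        shifted = LCMSRun(
            name="shifted",
            ms1_scans=[
                Spectrum(
                    peaks_mz=s.peaks_mz * (1 + 25e-6),
                    peaks_intensity=s.peaks_intensity,
                    ms_level=1, rt=s.rt, provenance=s.provenance,
                )
                for s in run.ms1_scans
            ],
            ms2_scans=[
                Spectrum(
                    peaks_mz=s.peaks_mz, peaks_intensity=s.peaks_intensity,
                    precursor_mz=s.precursor_mz * (1 + 25e-6),
                    rt=s.rt, provenance=s.provenance,
                )
                for s in run.ms2_scans
            ],
        )
        entries = extract_candidates(
            shifted, small_world["targets"], [get_adduct("[M+H]+"), get_adduct("[M+Na]+")]
        )
        assert entries == []

    def test_feature_below_height_floor_is_excluded(self, small_world):
        targets = small_world["targets"][:3]
        plan = {(t.name, "[M+H]+"): 9e4 for t in targets[:1]}
        run, truth = simulate_reaction_run(
            targets, NoiseConfig(), seed=55, height_plan=plan, adducts=("[M+H]+",)
        )
        audit = []
        entries = extract_candidates(
            run, targets, [get_adduct("[M+H]+")], _audit=audit
        )
        low = [t for t in truth if not t.expect_accept]
        assert len(low) == 1
        assert all(e.target.name != low[0].compound for e in entries)
        assert any(r["rejected_by"] == "feature_height" for r in audit)

    def test_profile_mode_run_is_rejected(self, small_world):
        run = LCMSRun(name="profile", centroided=False)
        with pytest.raises(ValueError, match="centroid"):
            extract_candidates(run, small_world["targets"], [get_adduct("[M+H]+")])

    def test_empty_run_yields_empty_list(self, small_world):
        run = LCMSRun(name="empty")
        assert extract_candidates(run, small_world["targets"], [get_adduct("[M+H]+")]) == []


class TestBuildLibrary:
    def test_acceptance_matches_generator_truth(self, small_world):
        library = small_world["library"]
        truth = small_world["run_truth"]
        accepted = {(e.target.name, e.adduct.name) for e in library.entries}
        expected = {(t.compound, t.adduct) for t in truth if t.expect_accept}
        assert accepted == expected

    def test_impossible_explanation_gate_empties_library(self, small_world):
        config = GateConfig(explanation_min=1.1)
        library = build_library([small_world["run"]], small_world["targets"], config)
        assert library.entries == []
        assert library.summary["rejected_explanation_score"] > 0

    def test_audit_conserves_candidates(self, small_world):
        library = small_world["library"]
        audit = library.audit
        assert library.summary["candidates"] == len(audit)
        assert (audit["accepted"] | (audit["rejected_by"] != "")).all()
        assert library.summary["accepted"] == int(audit["accepted"].sum())

    def test_duplicate_ms2_scans_all_retained(self, small_world):
        run = small_world["run"]
        first = run.ms2_scans[0]
        dup = Spectrum(
            peaks_mz=first.peaks_mz, peaks_intensity=first.peaks_intensity,
            precursor_mz=first.precursor_mz, rt=first.rt,
            provenance=f"{run.name}:999",
        )
        run2 = LCMSRun(name=run.name, ms1_scans=run.ms1_scans,
                       ms2_scans=list(run.ms2_scans) + [dup])
        library = build_library([run2], small_world["targets"], GateConfig())
        provs = [e.spectrum.provenance for e in library.entries]
        assert f"{run.name}:999" in provs and first.provenance in provs

    def test_gate_loosening_grows_accepted_set(self, small_world):
        run, targets = small_world["run"], small_world["targets"]
        strict = build_library([run], targets, GateConfig(height_min=1e5, explanation_min=0.8))
        loose = build_library([run], targets, GateConfig(height_min=5e4, explanation_min=0.6))
        strict_set = {e.query_id for e in strict.entries}
        loose_set = {e.query_id for e in loose.entries}
        assert strict_set <= loose_set

    def test_library_write_read_round_trip(self, small_world, tmp_path):
        library = small_world["library"]
        mgf = tmp_path / "library.mgf"
        write_library(library, mgf, tsv_path=tmp_path / "library.tsv")
        back = read_mgf(mgf)
        assert len(back) == len(library.entries)
        for entry, spectrum in zip(library.entries, back):
            assert spectrum.metadata["COMPOUND"] == entry.target.name
            assert np.allclose(spectrum.peaks_mz, entry.spectrum.peaks_mz, atol=1e-4)
            assert np.allclose(
                spectrum.peaks_intensity, entry.spectrum.peaks_intensity, atol=1e-2
            )
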