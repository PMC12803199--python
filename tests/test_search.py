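import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from revmet.search import (
    HOMOLOG_DELTAS,
    NetworkEdge,
    SeedAnnotation,
    build_network,
    fasst_search,
    match_peaks,
    modified_cosine,
    propagate_annotations,
    raw_cosine,
)
from revmet.spectra import Spectrum

from _oracles import brute_force_cosine, brute_force_search
from conftest import random_spectrum_pair


def _spec(mz, intensity, precursor=None, prov="s:1"):
    return Spectrum(peaks_mz=mz, peaks_intensity=intensity,
                    precursor_mz=precursor, provenance=prov)


class TestMatchPeaks:
    def test_identical_spectra_pair_with_themselves(self):
        s = _spec([100.0, 200.0, 300.0], [1.0, 2.0, 3.0])
        assert match_peaks(s, s, 0.02) == [(0, 0), (1, 1), (2, 2)]

    def test_disjoint_spectra_do_not_pair(self):
        a = _spec([100.0, 200.0], [1.0, 1.0])
        b = _spec([150.0, 250.0], [1.0, 1.0])
        assert match_peaks(a, b, 0.02) == []

    def test_each_peak_used_at_most_once(self, rng):
        for _ in range(20):
            a, b = random_spectrum_pair(rng)
            pairs = match_peaks(a, b, 0.02)
            assert len({i for i, _ in pairs}) == len(pairs)
            assert len({j for _, j in pairs}) == len(pairs)


class TestCosines:
    def test_self_similarity_is_one(self):
        s = _spec([100.0, 200.0, 300.0], [5.0, 1.0, 3.0])
        cos, n = raw_cosine(s, s, 0.02)
        assert cos == pytest.approx(1.0, abs=1e-12)
        assert n == 3

    def test_no_match_scores_zero(self):
        a = _spec([100.0], [1.0])
        b = _spec([300.0], [1.0])
        assert raw_cosine(a, b, 0.02) == (0.0, 0)

    def test_degenerate_spectrum_raises(self):
        a = _spec([100.0, 200.0], [0.0, 0.0])
        b = _spec([100.0], [1.0])
        with pytest.raises(ValueError, match="degenerate"):
            raw_cosine(a, b, 0.02)

    def test_raw_cosine_equals_brute_force_on_toy_pair(self):
        a = _spec([100.0, 150.0, 200.0, 250.0, 300.0], [1.0, 4.0, 2.0, 8.0, 3.0])
        b = _spec([100.01, 150.015, 200.3, 250.005, 299.99], [2.0, 3.0, 5.0, 7.0, 1.0])
        got_cos, got_n = raw_cosine(a, b, 0.02)
        exp_cos, exp_n = brute_force_cosine(
            a.peaks_mz, a.peaks_intensity, b.peaks_mz, b.peaks_intensity, 0.02
        )
        assert got_cos == pytest.approx(exp_cos, abs=1e-12)
        assert got_n == exp_n

    def test_modified_cosine_shifted_copy_scores_one(self):
        a = _spec([100.0, 200.0, 300.0], [1.0, 2.0, 3.0], precursor=400.0)
        shift = 28.0313
        b = _spec([100.0 - shift, 200.0 - shift, 300.0 - shift], [1.0, 2.0, 3.0],
                  precursor=400.0 - shift)
        cos, n = modified_cosine(a, b, 0.02)
        assert cos == pytest.approx(1.0, abs=1e-12)
        assert n == 3

    def test_modified_never_below_raw(self, rng):
        for _ in range(50):
            a, b = random_spectrum_pair(rng)
            raw, _ = raw_cosine(a, b, 0.02)
            mod, _ = modified_cosine(a, b, 0.02)
            assert mod >= raw - 1e-12

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_symmetry_bounds_identity_property(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_spectrum_pair(rng)
        ab, n_ab = raw_cosine(a, b, 0.02)
        ba, n_ba = raw_cosine(b, a, 0.02)
        assert ab == pytest.approx(ba, abs=1e-12)
        assert n_ab == n_ba
        assert 0.0 <= ab <= 1.0
        self_cos, _ = raw_cosine(a, a, 0.02)
        assert self_cos == pytest.approx(1.0, abs=1e-12)


class TestFasstSearch:
    def _world(self, rng, n_corpus=60):
        library = [random_spectrum_pair(rng)[0] for _ in range(5)]
        for i, s in enumerate(library):
            s.provenance = f"lib:{i}"
        corpus = []
        for i in range(n_corpus):
            if i < 10:  # noisy copies of library spectra
                src = library[i % len(library)]
                corpus.append(
                    Spectrum(
                        peaks_mz=src.peaks_mz + rng.normal(0, 0.003, src.n_peaks),
                        peaks_intensity=src.peaks_intensity
                        * np.exp(rng.normal(0, 0.1, src.n_peaks)),
                        precursor_mz=src.precursor_mz + float(rng.normal(0, 0.003)),
                        provenance=f"copy_{i}.mzML:1",
                    )
                )
            else:
                corpus.append(random_spectrum_pair(rng)[1].with_provenance(f"rand_{i}.mzML:1"))
        return library, corpus

    def test_indexed_search_equals_all_pairs_scan(self, rng):
        library, corpus = self._world(rng)
        got = {
            (m.query_id, m.corpus_file, m.scan)
            for m in fasst_search(library, corpus, min_cos=0.5, min_matched=2)
        }
        expected = brute_force_search(library, corpus, 0.02, 0.02, 0.5, 2)
        assert got == expected

    def test_empty_corpus(self, rng):
        library, _ = self._world(rng)
        assert fasst_search(library, []) == []

    def test_min_matched_above_peak_count_empties_results(self, rng):
        library, corpus = self._world(rng)
        assert fasst_search(library, corpus, min_matched=99) == []

    def test_threshold_monotonicity(self, rng):
        library, corpus = self._world(rng)
        strict = {
            (m.query_id, m.corpus_file, m.scan)
            for m in fasst_search(library, corpus, min_cos=0.8, min_matched=4)
        }
        loose = {
            (m.query_id, m.corpus_file, m.scan)
            for m in fasst_search(library, corpus, min_cos=0.6, min_matched=2)
        }
        assert strict <= loose


class TestNetwork:
    def test_identical_features_form_unit_edge(self):
        a = _spec([100.0, 200.0, 300.0], [1, 2, 3], precursor=400.0, prov="f1")
        b = _spec([100.0, 200.0, 300.0], [1, 2, 3], precursor=400.0, prov="f2")
        edges = build_network([a, b])
        assert len(edges) == 1
        assert edges[0].cosine == pytest.approx(1.0, abs=1e-12)
        assert edges[0].delta_mass == 0.0
        assert edges[0].feature_a < edges[0].feature_b

    def test_homolog_pair_links_with_c2h4_delta(self):
        head_peaks = [84.0444, 102.0550, 130.0499]
        a = _spec(head_peaks + [310.2], [50, 60, 70, 100], precursor=332.2, prov="C12")
        b = _spec(head_peaks + [338.23], [50, 60, 70, 100], precursor=360.2313, prov="C14")
        edges = build_network([a, b], min_cos=0.5, min_matched=2)
        assert len(edges) == 1
        assert abs(abs(edges[0].delta_mass) - HOMOLOG_DELTAS["C2H4"]) < 0.01

    def test_noise_features_stay_unlinked(self, rng):
        features = []
        for i in range(8):
            mz = rng.uniform(100, 900, 10)
            features.append(_spec(mz, rng.uniform(1, 100, 10),
                                  precursor=float(rng.uniform(200, 800)), prov=f"n{i}"))
        assert build_network(features) == []


class TestPropagation:
    def _series(self):
        # seed C12:0 glutamate conjugate node with +C2H4 and -CH2 neighbors
        edges = [
            NetworkEdge("seed", "plus28", cosine=0.9, n_matched=3,
                        delta_mass=-HOMOLOG_DELTAS["C2H4"]),
            NetworkEdge("minus14", "seed", cosine=0.85, n_matched=3,
                        delta_mass=-HOMOLOG_DELTAS["CH2"]),
        ]
        seeds = [SeedAnnotation("seed", "glutamic acid", 12, 0, rt=5.0)]
        return edges, seeds

    def test_heavier_homolog_with_later_rt_is_annotated(self):
        edges, seeds = self._series()
        rt = {"seed": 5.0, "plus28": 6.2, "minus14": 4.1}
        annotations = propagate_annotations(edges, seeds, rt)
        names = {a.node: a.name for a in annotations}
        assert names["plus28"] == "3OH-C14:0 glutamic acid"
        assert names["minus14"] == "3OH-C11:0 glutamic acid"
        assert all(a.level == "putative" for a in annotations)

    def test_rt_violation_blocks_annotation(self):
        edges, seeds = self._series()
        rt = {"seed": 5.0, "plus28": 3.0, "minus14": 4.1}  # heavier but earlier
        annotations = propagate_annotations(edges, seeds, rt)
        assert "plus28" not in {a.node for a in annotations}

    def test_no_seeds_no_propagation(self):
        edges, _ = self._series()
        assert propagate_annotations(edges, [], {"seed": 5.0}) == []

    def test_conflicting_names_flagged_ambiguous(self):
        edges = [
            NetworkEdge("seedA", "middle", cosine=0.9, n_matched=3,
                        delta_mass=-HOMOLOG_DELTAS["CH2"]),
            NetworkEdge("middle", "seedB", cosine=0.9, n_matched=3,
                        delta_mass=-HOMOLOG_DELTAS["CH2"]),
        ]
        seeds = [
            SeedAnnotation("seedA", "glycine", 11, 0, rt=4.0),
            SeedAnnotation("seedB", "alanine", 13, 0, rt=6.0),
        ]
        rt = {"seedA": 4.0, "middle": 5.0, "seedB": 6.0}
        annotations = propagate_annotations(edges, seeds, rt)
        middle = [a for a in annotations if a.node == "middle"]
        assert len(middle) == 2 and all(a.ambiguous for a in middle)
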