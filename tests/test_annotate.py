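import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ntaflow import annotate
from ntaflow.annotate import MatchEvidence, assign_level, spectral_match_score
from ntaflow.types import Annotation, Spectrum, SpectralLibraryEntry

from conftest import build_table


def spectrum(pairs, precursor=300.0, mode="positive"):
    return Spectrum(precursor, mode, np.array(pairs, dtype=float))


def entry(spec, name="x", rt=None, standard=False, sources=frozenset()):
    shift = 1.00782 if spec.ion_mode == "positive" else -1.00782
    return SpectralLibraryEntry(
        name=name, spectrum=spec, neutral_mass=spec.precursor_mz - shift,
        rt=rt, sources=sources, is_authentic_standard=standard,
    )


class TestSpectralMatchScore:
    def test_identical_spectra_score_100(self):
        s = spectrum([[100.0, 50.0], [150.0, 30.0], [200.0, 80.0]])
        assert spectral_match_score(s, s) == pytest.approx(100.0)

    def test_disjoint_spectra_score_0(self):
        a = spectrum([[100.0, 50.0], [150.0, 50.0]])
        b = spectrum([[120.0, 50.0], [170.0, 50.0]])
        assert spectral_match_score(a, b) == 0.0

    def test_half_overlap_equal_intensities_scores_50(self):
        # cosine of unit-norm vectors sharing one of two equal components
        a = spectrum([[100.0000, 50.0], [150.0000, 50.0]])
        b = spectrum([[100.0000, 50.0], [200.0000, 50.0]])
        assert spectral_match_score(a, b) == pytest.approx(50.0)

    def test_symmetric(self):
        a = spectrum([[100.0, 10.0], [150.0, 90.0], [180.0, 40.0]])
        b = spectrum([[100.0, 70.0], [150.0, 20.0], [210.0, 10.0]])
        assert spectral_match_score(a, b) == pytest.approx(spectral_match_score(b, a))

    def test_sqrt_intensity_weighting(self):
        # shared fragment has intensity 25 in both; weights are sqrt(I)
        a = spectrum([[100.0, 25.0], [150.0, 100.0]])
        b = spectrum([[100.0, 25.0], [200.0, 100.0]])
        # cos = 5*5 / (sqrt(25+100) * sqrt(25+100)) = 25/125 = 0.2
        assert spectral_match_score(a, b) == pytest.approx(20.0)

    def test_tolerance_boundary(self):
        a = spectrum([[100.0, 50.0]])
        within = spectrum([[100.0 * (1 + 5e-6), 50.0]])
        outside = spectrum([[100.0 * (1 + 5e-5), 50.0]])
        assert spectral_match_score(a, within, fragment_tol_ppm=10) > 0
        assert spectral_match_score(a, outside, fragment_tol_ppm=10) == 0.0

    def test_empty_spectrum_raises(self):
        a = spectrum([[100.0, 50.0]])
        empty = Spectrum(300.0, "positive", np.empty((0, 2)))
        with pytest.raises(ValueError, match="empty"):
            spectral_match_score(a, empty)


def make_evidence(
    score=95.0, standard=False, rt_error=None, precursor_ppm=1.0,
    frag_ppm=1.0, n_matched=3,
):
    spec = spectrum([[100.0, 50.0], [150.0, 50.0]])
    e = entry(spec, standard=standard, rt=10.0 if rt_error is not None else None)
    return MatchEvidence(e, score, precursor_ppm, rt_error, frag_ppm, n_matched)


class TestAssignLevel:
    def test_level1_confirmed_standard(self):
        ev = make_evidence(score=99.0, standard=True, rt_error=0.03, frag_ppm=4.0)
        assert assign_level(ev, has_ms2=True) == 1

    def test_standard_with_bad_rt_falls_back(self):
        ev = make_evidence(score=99.0, standard=True, rt_error=0.08)
        assert assign_level(ev, has_ms2=True) == 2

    def test_standard_with_bad_fragment_ppm_falls_back(self):
        ev = make_evidence(score=99.0, standard=True, rt_error=0.03, frag_ppm=7.0)
        assert assign_level(ev, has_ms2=True) == 2

    def test_level2_score_over_90(self):
        assert assign_level(make_evidence(score=92.0), has_ms2=True) == 2

    def test_score_90_exact_is_level3(self):
        assert assign_level(make_evidence(score=90.0), has_ms2=True) == 3

    def test_level3_band(self):
        assert assign_level(make_evidence(score=50.5), has_ms2=True) == 3

    def test_level4_low_score(self):
        assert assign_level(make_evidence(score=30.0), has_ms2=True) == 4

    def test_level4_no_candidate(self):
        assert assign_level(None, has_ms2=True) == 4

    def test_level5_no_ms2(self):
        assert assign_level(None, has_ms2=False) == 5

    @given(
        score=st.floats(min_value=0, max_value=100),
        standard=st.booleans(),
        rt_error=st.one_of(st.none(), st.floats(min_value=0, max_value=0.5)),
        precursor_ppm=st.floats(min_value=0, max_value=10),
        frag_ppm=st.floats(min_value=0, max_value=20),
        has_candidate=st.booleans(),
        has_ms2=st.booleans(),
    )
    @settings(max_examples=200, deadline=None)
    def test_total_function_partitions_evidence_space(
        self, score, standard, rt_error, precursor_ppm, frag_ppm, has_candidate, has_ms2
    ):
        ev = (
            make_evidence(score, standard, rt_error, precursor_ppm, frag_ppm)
            if has_candidate
            else None
        )
        level = assign_level(ev, has_ms2)
        assert level in (1, 2, 3, 4, 5)
        if not has_candidate:
            assert level == (4 if has_ms2 else 5)


class TestAttributeSources:
    def test_multi_category_retained(self):
        tags = frozenset({"drug", "natural_product", "personal_care_product"})
        e = entry(spectrum([[100.0, 1.0]]), sources=tags)
        assert annotate.attribute_sources(e) == tags

    def test_empty_becomes_unknown(self):
        e = entry(spectrum([[100.0, 1.0]]))
        assert annotate.attribute_sources(e) == frozenset({"unknown"})

    def test_single_category(self):
        e = entry(spectrum([[100.0, 1.0]]), sources=frozenset({"exogenous_contaminant"}))
        assert annotate.attribute_sources(e) == frozenset({"exogenous_contaminant"})

    def test_none_entry(self):
        assert annotate.attribute_sources(None) == frozenset({"unknown"})


def transfer_oracle(table, anns, rt_tol=0.1, ppm_tol=2.0):
    """Brute-force all-pairs tolerance search + lowest-ppm tie rule."""
    out = {}
    for ann in anns:
        best = None
        for fid in table.features.index:
            mz = table.features.loc[fid, "mz"]
            rt = table.features.loc[fid, "rt"]
            ppm = abs(mz - ann.precursor_mz) / ann.precursor_mz * 1e6
            drt = abs(rt - ann.rt)
            if ppm <= ppm_tol and drt <= rt_tol:
                if best is None or ppm < best[0]:
                    best = (ppm, fid)
        if best is not None:
            prev = out.get(best[1])
            if prev is None or (ann.level, -ann.score) < (prev.level, -prev.score):
                out[best[1]] = ann
    return out


class TestTransferAnnotations:
    def make_ann(self, mz, rt, name="c", level=2, score=95.0):
        return Annotation(
            feature_id=None, compound_name=name, level=level, score=score,
            precursor_mz=mz, rt=rt,
        )

    def test_worked_example_attached(self):
        table = build_table(np.full((1, 3), 1e5), mz=[283.17556], rt=[10.05])
        ann = self.make_ann(283.17550, 10.00)
        attached, unmatched = annotate.transfer_annotations(table, [ann])
        assert list(attached) == ["F001"]
        assert attached["F001"].precursor_ppm_error == pytest.approx(0.21, abs=0.02)
        assert attached["F001"].rt_error_min == pytest.approx(0.05, abs=1e-9)
        assert not unmatched

    def test_rt_outside_tolerance_not_attached(self):
        table = build_table(np.full((1, 3), 1e5), mz=[283.17550], rt=[10.15])
        ann = self.make_ann(283.17550, 10.00)
        attached, unmatched = annotate.transfer_annotations(table, [ann])
        assert not attached
        assert unmatched == [ann]

    def test_lowest_ppm_wins(self):
        table = build_table(
            np.full((2, 3), 1e5),
            mz=[283.17550 * (1 + 1.0e-6), 283.17550 * (1 + 1.8e-6)],
            rt=[10.0, 10.0],
        )
        attached, _ = annotate.transfer_annotations(table, [self.make_ann(283.17550, 10.0)])
        assert list(attached) == ["F001"]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_feat, n_ann = 300, 120
        mzs = rng.uniform(100, 800, n_feat)
        rts = rng.uniform(0, 25, n_feat)
        table = build_table(np.full((n_feat, 2), 1e5), mz=mzs, rt=rts)
        anns = [
            self.make_ann(
                mzs[i] * (1 + rng.normal(0, 2e-6)),
                rts[i] + rng.normal(0, 0.07),
                name=f"c{i}",
                score=float(rng.uniform(50, 100)),
            )
            for i in rng.integers(0, n_feat, n_ann)
        ]
        attached, _ = annotate.transfer_annotations(table, anns)
        oracle = transfer_oracle(table, anns)
        assert set(attached) == set(oracle)
        for fid in oracle:
            assert attached[fid].compound_name == oracle[fid].compound_name


class TestEndToEndAnnotation:
    def test_planted_levels_recovered(self, default_sim):
        from ntaflow.filtering import require_product_ions

        truth = default_sim["truth"]
        spectra, library = default_sim["spectra"], default_sim["library"]
        rts = truth.feature_meta["rt"].to_dict()
        usable = require_product_ions(sorted(spectra), spectra)
        anns = annotate.annotate_spectra(
            {f: spectra[f] for f in usable}, library, rts=rts
        )
        by_id = {a.feature_id: a for a in anns}
        checked = 0
        for fid, plan in truth.annotation_plan.items():
            if plan["level"] in (1, 2, 3, 4) and fid in by_id:
                assert by_id[fid].level == plan["level"], fid
                checked += 1
        assert checked > 50

    def test_self_match_always_at_least_level2(self, default_sim):
        truth = default_sim["truth"]
        spectra, library = default_sim["spectra"], default_sim["library"]
        by_name = {e.name: e for e in library}
        for fid, plan in truth.annotation_plan.items():
            if plan["level"] == 2:
                score = spectral_match_score(spectra[fid], by_name[plan["name"]])
                assert score > 90

    def test_sources_transferred(self, default_sim):
        truth = default_sim["truth"]
        spectra, library = default_sim["spectra"], default_sim["library"]
        rts = truth.feature_meta["rt"].to_dict()
        anns = annotate.annotate_spectra(spectra, library, rts=rts)
        by_id = {a.feature_id: a for a in anns}
        for fid, plan in truth.annotation_plan.items():
            if plan["level"] in (1, 2) and fid in by_id and by_id[fid].level <= 2:
                expected = plan["sources"] if plan["sources"] else frozenset({"unknown"})
                assert by_id[fid].sources == expected


class TestDetectionFrequencyByGroup:
    def test_all_preterm_vs_none(self):
        ab = np.array([[5e4, 5e4, np.nan, np.nan]])
        table = build_table(ab, outcome=["preterm", "preterm", "term", "term"])
        anns = {"F001": Annotation(feature_id="F001", compound_name="c", level=2, score=95.0)}
        freq = annotate.detection_frequency_by_group(table, anns)
        row = freq.iloc[0]
        assert row["pct_serum_preterm"] == pytest.approx(100.0)
        assert row["pct_serum_term"] == pytest.approx(0.0)

    def test_planted_bias_recovered(self, rng):
        n = 95
        outcome = ["preterm"] * 35 + ["term"] * 60
        detect_p = np.where(np.arange(n) < 35, 0.9, 0.4)
        ab = np.where(rng.uniform(size=n) < detect_p, 5e4, np.nan)[None, :]
        table = build_table(ab, outcome=outcome)
        anns = {"F001": Annotation(feature_id="F001", compound_name="c", level=1, score=99.0)}
        freq = annotate.detection_frequency_by_group(table, anns).iloc[0]
        assert freq["pct_serum_preterm"] == pytest.approx(90.0, abs=10.0)
        assert freq["pct_serum_term"] == pytest.approx(40.0, abs=13.0)
        assert freq["pct_serum_preterm"] > freq["pct_serum_term"]

    def test_only_levels_1_2_reported(self):
        ab = np.full((2, 4), 5e4)
        table = build_table(ab, outcome=["preterm", "term", "preterm", "term"])
        anns = {
            "F001": Annotation(feature_id="F001", compound_name="a", level=2, score=95.0),
            "F002": Annotation(feature_id="F002", compound_name="b", level=3, score=70.0),
        }
        freq = annotate.detection_frequency_by_group(table, anns)
        assert list(freq["feature_id"]) == ["F001"]
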