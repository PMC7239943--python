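"""Four-criterion identification: fragment matching, tiers, table annotation."""

import numpy as np
import pandas as pd
import pytest

from icmet.chem import ADDUCTS, parse_formula, theoretical_envelope
from icmet.identify import (
    CompoundFeature,
    ExclusionRule,
    IdentificationCriteria,
    annotate_feature_table,
    load_putative_candidates,
    match_feature,
    match_fragments,
)
from icmet.library import MetaboliteRecord, ReferenceSpectrum, StandardsLibrary
from icmet.preprocess import FeatureTable
from icmet.simulate import SimulationConfig, simulate_feature_table, simulate_library


def _spectrum(mzs, intensities):
    return ReferenceSpectrum(tuple(zip(mzs, intensities)), precursor_mz=max(mzs))


class TestMatchFragments:
    def test_identical_spectra_pass(self):
        ref = _spectrum([80.0, 120.0, 150.0, 170.0], [50, 100, 30, 20])
        passed, n = match_fragments(ref, ref)
        assert passed and n == 4

    def test_missing_base_peak_fails_regardless(self):
        ref = _spectrum([80.0, 120.0, 150.0, 170.0], [50, 100, 30, 20])
        obs = _spectrum([80.0, 150.0, 170.0], [50, 30, 20])  # base 120 absent
        passed, n = match_fragments(obs, ref)
        assert not passed and n == 3

    @pytest.mark.parametrize("shift_ppm,expected", [(11.0, True), (13.0, False)])
    def test_tolerance_bracketing_at_12ppm(self, shift_ppm, expected):
        ref = _spectrum([80.0, 120.0, 150.0, 170.0], [50, 100, 30, 20])
        obs = _spectrum(
            [m * (1 + shift_ppm * 1e-6) for m in [80.0, 120.0, 150.0, 170.0]],
            [50, 100, 30, 20],
        )
        passed, _ = match_fragments(obs, ref, frag_tol=12.0)
        assert passed is expected

    def test_each_observed_peak_consumed_once(self):
        # one observed peak cannot satisfy base + extras simultaneously
        ref = _spectrum([100.0, 100.0005, 100.001], [100, 50, 30])
        obs = _spectrum([100.0], [100])
        passed, n = match_fragments(obs, ref, frag_tol=12.0)
        assert n == 1 and not passed

    def test_fewer_than_required_extras_fails(self):
        ref = _spectrum([80.0, 120.0, 150.0], [50, 100, 30])
        obs = _spectrum([120.0, 150.0], [100, 30])  # base + 1 extra only
        passed, _ = match_fragments(obs, ref, frag_min_extra=2)
        assert not passed


@pytest.fixture()
def glutamate_library():
    glu = parse_formula("C5H9NO4")
    ms2 = _spectrum([102.0555, 128.0353, 146.0459], [100.0, 60.0, 40.0])
    return StandardsLibrary(
        [
            MetaboliteRecord("glutamate", glu, ADDUCTS["[M-H]-"], rt=14.3, ms2=ms2),
            MetaboliteRecord(
                "lactate", parse_formula("C3H6O3"), ADDUCTS["[M-H]-"], rt=5.2
            ),
        ]
    )


class TestMatchFeature:
    def test_glutamate_identified_by_mass_and_rt(self, glutamate_library):
        feature = CompoundFeature.from_id("14.33_146.0453")
        res = match_feature(feature, glutamate_library)
        assert res.best is not None and res.best.name == "glutamate"
        assert res.evidence.ppm == pytest.approx(-3.98, abs=0.01)
        assert res.evidence.mass_pass and res.evidence.rt_pass
        # no measured envelope: tier capped below full identification
        assert res.tier == "identified_no_ms2"
        assert "no_observed_envelope" in res.flags

    def test_full_tier_with_envelope_and_ms2(self, glutamate_library):
        rec = glutamate_library["glutamate"]
        feature = CompoundFeature.from_id(
            "14.33_146.0453",
            observed_envelope=theoretical_envelope(rec.formula, rec.adduct, 3),
            ms2=rec.ms2,
        )
        res = match_feature(feature, glutamate_library)
        assert res.tier == "identified"
        assert res.evidence.isotope_score == 1.0
        assert res.evidence.frags_matched == 3

    def test_rt_outside_30s_excludes_candidate(self, glutamate_library):
        feature = CompoundFeature.from_id("14.83_146.0453")  # 31.8 s late
        res = match_feature(feature, glutamate_library)
        assert res.tier == "unidentified"

    def test_putative_tier_from_offline_candidates(self, glutamate_library):
        candidates = load_putative_candidates()
        env = theoretical_envelope(parse_formula("C5H6O5"), "[M-H]-", 3)
        # 2-oxoglutarate-mass feature far from any library RT
        feature = CompoundFeature.from_id("9.50_145.0142", observed_envelope=env)
        res = match_feature(feature, glutamate_library, putative_lib=candidates)
        assert res.tier == "putative"
        assert "2-oxoglutarate" in res.best.name

    def test_isomer_pair_resolved_by_retention_time(self):
        formula = parse_formula("C6H13O9P")
        lib = StandardsLibrary(
            [
                MetaboliteRecord("hexose-1P", formula, ADDUCTS["[M-H]-"], rt=10.0),
                MetaboliteRecord("hexose-6P", formula, ADDUCTS["[M-H]-"], rt=13.0),
            ]
        )
        early = match_feature(CompoundFeature.from_id("10.05_259.0224"), lib)
        late = match_feature(CompoundFeature.from_id("12.95_259.0224"), lib)
        assert early.best.name == "hexose-1P"
        assert late.best.name == "hexose-6P"

    def test_simulated_features_assigned_to_generating_record(
        self, standards_library, sim_dataset
    ):
        table, truth = sim_dataset
        correct = total = 0
        for fid in truth.identifiable:
            feature = CompoundFeature.from_id(
                fid, truth.envelopes.get(fid), truth.ms2.get(fid)
            )
            res = match_feature(feature, standards_library)
            total += 1
            correct += res.best is not None and res.best.name == truth.feature_source[fid]
        assert correct / total >= 0.99


class TestAnnotateFeatureTable:
    def _table(self, feature_ids):
        intensities = pd.DataFrame(
            np.ones((len(feature_ids), 4)),
            index=feature_ids,
            columns=["a1", "a2", "b1", "b2"],
        )
        meta = pd.DataFrame(
            {
                "group": ["A", "A", "B", "B"],
                "batch": ["1"] * 4,
                "role": ["sample"] * 4,
            },
            index=intensities.columns,
        )
        return FeatureTable(intensities, meta)

    def test_phosphate_exclusion_logged(self, glutamate_library):
        table = self._table(["15.28_96.9696", "14.33_146.0453"])
        rule = ExclusionRule(rt=15.28, rt_tol=0.05, reason="phosphate cluster")
        summary = annotate_feature_table(table, glutamate_library, exclusions=[rule])
        assert summary.removed == (("15.28_96.9696", "phosphate cluster"),)
        assert len(summary.results) == 1

    def test_no_exclusions_equals_rowwise_matching(self, glutamate_library):
        table = self._table(["14.33_146.0453", "5.21_89.0244", "9.00_500.0000"])
        summary = annotate_feature_table(table, glutamate_library)
        assert len(summary.results) == 3
        rowwise = [
            match_feature(CompoundFeature.from_id(fid), glutamate_library).tier
            for fid in table.features
        ]
        assert [r.tier for r in summary.results] == rowwise

    def test_malformed_id_skipped_not_fatal(self, glutamate_library):
        table = self._table(["garbage", "14.33_146.0453"])
        summary = annotate_feature_table(table, glutamate_library)
        assert summary.skipped == ("garbage",)
        assert len(summary.results) == 1

    def test_ground_truth_tier_counts(self, standards_library, sim_dataset):
        table, truth = sim_dataset
        summary = annotate_feature_table(
            table, standards_library, envelopes=truth.envelopes, ms2=truth.ms2
        )
        counts = summary.tier_counts
        n_ident = len(truth.identifiable)
        assert counts["identified"] + counts["identified_no_ms2"] == n_ident
        assert counts["unidentified"] == len(table.features) - n_ident


class TestMonotonicity:
    def test_tightening_tolerances_never_gains_identifications(
        self, standards_library, sim_dataset
    ):
        table, truth = sim_dataset
        base = IdentificationCriteria()

        def n_identified(crit):
            summary = annotate_feature_table(
                table, standards_library, crit,
                envelopes=truth.envelopes, ms2=truth.ms2,
            )
            counts = summary.tier_counts
            return counts["identified"] + counts["identified_no_ms2"]

        n_base = n_identified(base)
        tighter = [
            IdentificationCriteria(mass_tol=1.0),
            IdentificationCriteria(rt_tol=5.0),
            IdentificationCriteria(isotope_min=0.99),
            IdentificationCriteria(frag_tol=1.0),
            IdentificationCriteria(mass_tol=2.0, rt_tol=10.0, isotope_min=0.95),
        ]
        for crit in tighter:
            assert n_identified(crit) <= n_base

    def test_self_consistency_of_evidence(self, glutamate_library):
        rec = glutamate_library["glutamate"]
        feature = CompoundFeature.from_id(
            "14.33_146.0453",
            observed_envelope=theoretical_envelope(rec.formula, rec.adduct, 3),
            ms2=rec.ms2,
        )
        crit = IdentificationCriteria()
        res = match_feature(feature, glutamate_library, crit)
        ev = res.evidence
        assert ev.mass_pass == (abs(ev.ppm) <= crit.mass_tol)
        assert ev.rt_pass == (abs(ev.rt_delta_s) <= crit.rt_tol)
        assert ev.isotope_pass == (ev.isotope_score >= crit.isotope_min)
        assert res.tier == "identified"
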