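import numpy as np
import pytest

from oracles import oracle_features, random_peptidome
from ppv.core import AnnotationRecord, PeptideObservation, ProteinRecord, amidation_call
from ppv.features import (
    FEATURE_NAMES,
    build_design_matrix,
    collapse_forms,
    compute_features,
    default_epsilon,
    match_annotations,
)
from ppv.profile import build_profile


def _obs(start, stop, abundances, acc="P1", **kw):
    return PeptideObservation(
        protein_accession=acc, start=start, stop=stop,
        sequence="A" * (stop - start + 1), abundances=abundances, **kw
    )


class TestCollapseForms:
    def test_single_amidated_form(self):
        candidates = collapse_forms([_obs(5, 12, {"a": 10.0}, c_term_amidated=True)])
        assert candidates[0].amidation_fraction == 1.0

    def test_ninety_nine_percent_reports_yes(self):
        candidates = collapse_forms(
            [
                _obs(5, 12, {"a": 990.0}, c_term_amidated=True),
                _obs(5, 12, {"a": 10.0}),
            ]
        )
        assert candidates[0].amidation_fraction == pytest.approx(0.99)
        assert amidation_call(candidates[0].amidation_fraction) == "Yes"

    def test_even_split_is_ambiguous(self):
        candidates = collapse_forms(
            [
                _obs(5, 12, {"a": 50.0}, c_term_amidated=True),
                _obs(5, 12, {"a": 50.0}),
            ]
        )
        assert candidates[0].amidation_fraction == 0.5
        assert amidation_call(0.5) == "ambiguous"
        assert amidation_call(0.01) == "No"

    def test_sample_abundances_summed_across_forms(self):
        candidates = collapse_forms(
            [_obs(5, 12, {"a": 30.0, "b": 5.0}), _obs(5, 12, {"a": 20.0}, c_term_amidated=True)]
        )
        assert candidates[0].abundances == {"a": 50.0, "b": 5.0}
        assert candidates[0].total_abundance == 55.0


class TestComputeFeatures:
    def test_lone_peptide_closed_form(self):
        protein = ProteinRecord("P1", "A" * 40)
        obs = [_obs(5, 12, {"a": 1000.0})]
        profile = build_profile(protein, obs)
        candidate = collapse_forms(obs)[0]
        eps = 0.5
        v = dict(zip(FEATURE_NAMES, compute_features(candidate, profile, ["a"], eps)))
        assert v["intensity_start"] == pytest.approx(np.log10((1000 + eps) / eps))
        assert v["start_share"] == 1.0
        assert v["stop_share"] == 1.0
        assert v["cluster_share"] == 1.0
        assert v["cluster_span_ratio"] == 1.0
        assert v["log_ladder_count"] == 0.0
        assert v["sample_penetrance"] == 1.0

    def test_candidate_at_position_one_uses_zero_boundary(self):
        protein = ProteinRecord("P1", "A" * 40)
        obs = [_obs(1, 8, {"a": 100.0})]
        profile = build_profile(protein, obs)
        candidate = collapse_forms(obs)[0]
        v = dict(zip(FEATURE_NAMES, compute_features(candidate, profile, ["a"], 1.0)))
        assert v["intensity_start"] == pytest.approx(np.log10(101.0 / 1.0))

    def test_out_of_bounds_candidate_rejected(self):
        protein = ProteinRecord("P1", "A" * 10)
        obs = [_obs(1, 8, {"a": 100.0})]
        profile = build_profile(protein, obs)
        candidate = collapse_forms([_obs(1, 12, {"a": 1.0}, acc="P1")])[0]
        with pytest.raises(ValueError):
            compute_features(candidate, profile, ["a"], 1.0)

    def test_oracle_equivalence_on_random_peptidomes(self, rng):
        """All 14 features equal a first-principles recomputation, <= 1e-10."""
        for _ in range(100):
            proteins, observations, samples = random_peptidome(rng)
            candidates = collapse_forms(observations)
            eps = default_epsilon(candidates)
            for candidate in candidates:
                acc = candidate.protein_accession
                mine = [o for o in observations if o.protein_accession == acc]
                profile = build_profile(proteins[acc], mine)
                got = compute_features(candidate, profile, samples, eps)
                expected = oracle_features(
                    candidate.locus, proteins[acc], observations, samples, eps
                )
                np.testing.assert_allclose(got, expected, atol=1e-10, rtol=0)

    def test_monotone_in_own_abundance(self, rng):
        """Raising a candidate's own intensity never lowers f1, f5, f6, f8."""
        monotone = ["intensity_start", "log_abundance", "start_share", "cluster_share"]
        for _ in range(20):
            proteins, observations, samples = random_peptidome(rng)
            candidates = collapse_forms(observations)
            target = candidates[int(rng.integers(len(candidates)))]
            eps = default_epsilon(candidates)

            def featurize(obs_list):
                mine = [
                    o for o in obs_list
                    if o.protein_accession == target.protein_accession
                ]
                profile = build_profile(proteins[target.protein_accession], mine)
                cands = [
                    c for c in collapse_forms(obs_list) if c.locus == target.locus
                ]
                return dict(
                    zip(FEATURE_NAMES, compute_features(cands[0], profile, samples, eps))
                )

            before = featurize(observations)
            boosted = [
                o if o.locus != target.locus else _scaled(o, 3.0)
                for o in observations
            ]
            after = featurize(boosted)
            for name in monotone:
                assert after[name] >= before[name] - 1e-12

    def test_fractional_features_stay_in_unit_interval(self, rng):
        bounded = [
            "start_share", "stop_share", "cluster_share", "sample_penetrance",
            "amidation_fraction", "acetylation_fraction", "cluster_span_ratio",
        ]
        for _ in range(20):
            proteins, observations, samples = random_peptidome(rng)
            candidates = collapse_forms(observations)
            eps = default_epsilon(candidates)
            for candidate in candidates:
                acc = candidate.protein_accession
                mine = [o for o in observations if o.protein_accession == acc]
                profile = build_profile(proteins[acc], mine)
                v = dict(
                    zip(FEATURE_NAMES, compute_features(candidate, profile, samples, eps))
                )
                for name in bounded:
                    assert -1e-12 <= v[name] <= 1 + 1e-12
                assert v["log_ladder_count"] >= 0
                assert np.isfinite(list(v.values())).all()


def _scaled(obs, factor):
    return PeptideObservation(
        protein_accession=obs.protein_accession, start=obs.start, stop=obs.stop,
        sequence=obs.sequence,
        abundances={k: v * factor for k, v in obs.abundances.items()},
        n_term_acetyl=obs.n_term_acetyl, c_term_amidated=obs.c_term_amidated,
    )


class TestMatchAnnotations:
    def _candidate(self, start, stop, amid=0.0):
        return collapse_forms(
            [
                _obs(start, stop, {"a": 1000.0 * amid}, c_term_amidated=True)
                if amid > 0
                else _obs(start, stop, {"a": 1.0}),
            ]
            + ([_obs(start, stop, {"a": 1000.0 * (1 - amid)})] if 0 < amid < 1 else [])
        )[0]

    def test_full_match_requires_amidation_consistency(self):
        annotations = [AnnotationRecord("P1", 58, 68, "SP", amidated=True)]
        amidated = self._candidate(58, 68, amid=0.99)
        unmodified = self._candidate(58, 68, amid=0.0)
        assert match_annotations([amidated], annotations) == ["full"]
        # coordinates match but the required amidation is absent: not full,
        # and the candidate is strictly-inside-like neither => none... it is
        # the same interval, so not "partial" either
        assert match_annotations([unmodified], annotations) == ["none"]

    def test_partial_is_strict_containment(self):
        annotations = [AnnotationRecord("P1", 58, 68, "SP")]
        inside = self._candidate(60, 65)
        assert match_annotations([inside], annotations) == ["partial"]
        outside = self._candidate(50, 56)
        assert match_annotations([outside], annotations) == ["none"]

    def test_unannotated_protein_is_none(self):
        annotations = [AnnotationRecord("OTHER", 1, 10, "x")]
        assert match_annotations([self._candidate(1, 10)], annotations) == ["none"]


class TestDesignMatrix:
    def _toy(self, rng):
        proteins, observations, samples = random_peptidome(rng, n_proteins=2, n_peptides=12)
        candidates = collapse_forms(observations)
        profiles = {
            acc: build_profile(
                protein,
                [o for o in observations if o.protein_accession == acc],
            )
            for acc, protein in proteins.items()
        }
        return proteins, observations, candidates, profiles

    def test_labels_follow_full_matches(self, rng):
        proteins, observations, candidates, profiles = self._toy(rng)
        target = candidates[0]
        annotations = [
            AnnotationRecord(
                target.protein_accession, target.start, target.stop, "known",
                amidated=None,
            )
        ]
        design = build_design_matrix(candidates, profiles, annotations)
        assert int(design["label"].sum()) == int(
            (design["match_status"] == "full").sum()
        )
        row = design[
            (design["protein_accession"] == target.protein_accession)
            & (design["start"] == target.start)
            & (design["stop"] == target.stop)
        ]
        assert row["label"].tolist() == [1]

    def test_zero_positives_raises(self, rng):
        _, _, candidates, profiles = self._toy(rng)
        with pytest.raises(ValueError, match="annotation"):
            build_design_matrix(
                candidates, profiles, [AnnotationRecord("ZZZ", 1, 5, "x")]
            )

    def test_duplicate_candidates_rejected(self, rng):
        _, _, candidates, profiles = self._toy(rng)
        with pytest.raises(ValueError, match="duplicate"):
            build_design_matrix(candidates + [candidates[0]], profiles, [])
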