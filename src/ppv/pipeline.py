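"""High-level orchestration: observations -> profiles -> design -> predictions.

Thin glue used by the command-line interface and the test-bench; all science
lives in the per-stage modules.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assembly import AssembledPeptide, assemble_fragments
from .core import AnnotationRecord, CandidatePeptide, PeptideObservation, ProteinRecord, amidation_call
from .features import FEATURE_NAMES, build_design_matrix, collapse_forms, compute_features, default_epsilon
from .model import ModelBundle, classify_score_tier, rank_predictions, score_peptides
from .motifs import extract_flanks
from .profile import BackboneProfile, build_profile


def build_profiles(
    proteome: Mapping[str, ProteinRecord],
    observations: Sequence[PeptideObservation],
) -> dict[str, BackboneProfile]:
    """One backbone profile per protein that has observations."""
    by_protein: dict[str, list[PeptideObservation]] = {}
    for obs in observations:
        by_protein.setdefault(obs.protein_accession, []).append(obs)
    return {
        accession: build_profile(proteome[accession], obs_list)
        for accession, obs_list in by_protein.items()
    }


def design_from_observations(
    proteome: Mapping[str, ProteinRecord],
    observations: Sequence[PeptideObservation],
    annotations: Sequence[AnnotationRecord],
) -> pd.DataFrame:
    profiles = build_profiles(proteome, observations)
    candidates = collapse_forms(observations)
    return build_design_matrix(candidates, profiles, annotations)


def assembly_design(
    proteome: Mapping[str, ProteinRecord],
    observations: Sequence[PeptideObservation],
    annotations: Sequence[AnnotationRecord],
    overlap_min: int = 1,
    max_span: int = 100,
    max_per_protein: int = 500,
) -> tuple[pd.DataFrame, list[AssembledPeptide]]:
    """Design matrix over observed plus in-silico assembled candidates.

    Synthetic candidates inherit positional features from the observed
    profile; their abundance is the assembled (minimum-coverage) abundance
    and they carry no per-sample detections of their own.
    """
    profiles = build_profiles(proteome, observations)
    candidates = collapse_forms(observations)
    samples = sorted({s for c in candidates for s in c.abundances})
    epsilon = default_epsilon(candidates)

    by_protein: dict[str, list[PeptideObservation]] = {}
    for obs in observations:
        by_protein.setdefault(obs.protein_accession, []).append(obs)

    assembled_all: list[AssembledPeptide] = []
    observed_loci = {c.locus for c in candidates}
    synthetic: list[CandidatePeptide] = []
    for accession, obs_list in sorted(by_protein.items()):
        assembled = assemble_fragments(
            obs_list, overlap_min=overlap_min, max_span=max_span,
            max_per_protein=max_per_protein,
        )
        assembled_all.extend(assembled)
        profile = profiles[accession]
        for peptide in assembled:
            if not peptide.synthetic or peptide.locus in observed_loci:
                continue
            stop_total = profile.stop_intensity[peptide.stop]
            start_total = profile.start_intensity[peptide.start]
            synthetic.append(
                CandidatePeptide(
                    protein_accession=accession,
                    start=peptide.start,
                    stop=peptide.stop,
                    total_abundance=max(peptide.assembled_abundance, epsilon),
                    abundances={},
                    amidation_fraction=(
                        profile.amidated_stop_intensity[peptide.stop] / stop_total
                        if stop_total > 0 else 0.0
                    ),
                    acetylation_fraction=(
                        profile.acetylated_start_intensity[peptide.start] / start_total
                        if start_total > 0 else 0.0
                    ),
                    tissue=obs_list[0].tissue,
                )
            )

    all_candidates = candidates + synthetic
    frame_rows = []
    for c in all_candidates:
        vector = compute_features(c, profiles[c.protein_accession], samples, epsilon)
        frame_rows.append(vector)
    frame = pd.DataFrame(np.vstack(frame_rows), columns=FEATURE_NAMES)
    frame.insert(0, "protein_accession", [c.protein_accession for c in all_candidates])
    frame.insert(1, "start", [c.start for c in all_candidates])
    frame.insert(2, "stop", [c.stop for c in all_candidates])
    from .features import match_annotations

    frame["match_status"] = match_annotations(all_candidates, annotations)
    frame["label"] = (frame["match_status"] == "full").astype(int)
    frame["group_key"] = frame["protein_accession"]
    frame["total_abundance"] = [c.total_abundance for c in all_candidates]
    frame["tissue"] = [c.tissue for c in all_candidates]
    frame["synthetic"] = [False] * len(candidates) + [True] * len(synthetic)
    return frame, assembled_all


def prediction_table(
    design: pd.DataFrame,
    bundle: ModelBundle,
    proteome: Mapping[str, ProteinRecord],
    use_out_of_fold: bool = True,
    flank_width: int = 4,
) -> pd.DataFrame:
    """Ranked predictions with tiers, flanks and amidation calls.

    Out-of-fold scores (the honest, test-set probabilities) are used when the
    bundle was trained on this design; otherwise the final model scores.
    """
    frame = design.copy()
    if use_out_of_fold and len(bundle.oof_scores) == len(frame):
        frame["ppv_score"] = bundle.oof_scores
    else:
        frame["ppv_score"] = score_peptides(bundle, frame)
    frame["tier"] = [classify_score_tier(p) for p in frame["ppv_score"]]
    n_flanks, c_flanks, plus, minus = [], [], [], []
    for _, row in frame.iterrows():
        pair = extract_flanks(
            (row["protein_accession"], int(row["start"]), int(row["stop"])),
            proteome,
            w=flank_width,
        )
        n_flanks.append(pair.n_flank)
        c_flanks.append(pair.c_flank)
        plus.append(pair.plus_one)
        seq = proteome[row["protein_accession"]].sequence
        minus.append(seq[int(row["stop"]) - 1])
    frame["n_flank"] = n_flanks
    frame["c_flank"] = c_flanks
    frame["plus_one"] = plus
    frame["minus_one"] = minus
    frame["amidation_call"] = [
        amidation_call(f) for f in frame["amidation_fraction"]
    ]
    return rank_predictions(frame)
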