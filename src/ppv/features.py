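"""Candidate collapsing, the 14-dimensional MS feature vector, and labelling.

Peptide forms (modified vs unmodified rows) are collapsed into one candidate
per (protein, start, stop).  Each candidate is then described by fourteen
features derived purely from the positional structure and intensity of the
MS data — deliberately never from the amino-acid sequence itself:

==========================  ====================================================
intensity_start             log10 step of start intensity at start vs start-1
intensity_stop              log10 step of stop intensity at stop vs stop+1
coverage_step_start         log10 step of coverage at start vs start-1
coverage_step_stop          log10 step of coverage at stop vs stop+1
log_abundance               log10 total candidate intensity
start_share                 start intensity / coverage at the start position
stop_share                  stop intensity / coverage at the stop position
cluster_share               candidate intensity / intensity of all overlappers
sample_penetrance           fraction of samples where the candidate is detected
amidation_fraction          intensity-weighted C-terminal amidation fraction
acetylation_fraction        intensity-weighted N-terminal acetylation fraction
log_length                  log10 peptide length in residues
cluster_span_ratio          peptide length / containing cluster span
log_ladder_count            log10(1 + strictly contained observed peptides)
==========================  ====================================================

Sharp cluster boundaries (high start/stop steps and shares) are the hallmark
of genuinely processed peptides, while degradation ladders blur the interior
of a cluster — these features let a linear model exploit exactly that.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import AnnotationRecord, CandidatePeptide, PeptideObservation
from .profile import BackboneProfile, find_clusters

FEATURE_NAMES: list[str] = [
    "intensity_start",
    "intensity_stop",
    "coverage_step_start",
    "coverage_step_stop",
    "log_abundance",
    "start_share",
    "stop_share",
    "cluster_share",
    "sample_penetrance",
    "amidation_fraction",
    "acetylation_fraction",
    "log_length",
    "cluster_span_ratio",
    "log_ladder_count",
]


def collapse_forms(
    observations: Sequence[PeptideObservation],
) -> list[CandidatePeptide]:
    """One candidate per (protein, start, stop), PTM evidence as fractions.

    The amidation fraction is the summed intensity of amidated forms divided
    by the total intensity at the locus (acetylation analogous), so a locus
    seen 99% amidated reports 0.99.
    """
    by_locus: dict[tuple, list[PeptideObservation]] = {}
    for obs in observations:
        by_locus.setdefault(obs.locus, []).append(obs)

    candidates = []
    for (accession, start, stop), forms in by_locus.items():
        abundances: dict[str, float] = {}
        total = amidated = acetylated = 0.0
        for form in forms:
            a = form.total_abundance
            total += a
            if form.c_term_amidated:
                amidated += a
            if form.n_term_acetyl:
                acetylated += a
            for sample, value in form.abundances.items():
                if value > 0:
                    abundances[sample] = abundances.get(sample, 0.0) + value
        candidates.append(
            CandidatePeptide(
                protein_accession=accession,
                start=start,
                stop=stop,
                total_abundance=total,
                abundances=abundances,
                amidation_fraction=amidated / total,
                acetylation_fraction=acetylated / total,
                tissue=forms[0].tissue,
            )
        )
    candidates.sort(key=lambda c: c.locus)
    return candidates


def default_epsilon(candidates: Iterable[CandidatePeptide]) -> float:
    """Scale-free pseudo-intensity: half the smallest nonzero sample intensity."""
    smallest = min(
        (v for c in candidates for v in c.abundances.values() if v > 0),
        default=None,
    )
    if smallest is None:
        raise ValueError("no positive intensities to derive epsilon from")
    return 0.5 * smallest


def compute_features(
    candidate: CandidatePeptide,
    profile: BackboneProfile,
    samples: Sequence[str],
    epsilon: float,
) -> np.ndarray:
    """The 14 positional/intensity features for one candidate.

    Positions 0 and length+1 read as zero intensity, so boundary steps are
    defined for peptides touching the protein termini.  The candidate's own
    interval is excluded from its ladder count; ``cluster_share`` divides by
    every observed peptide overlapping the candidate (itself included).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    s, e = candidate.start, candidate.stop
    if s < 1 or e > profile.length:
        raise ValueError(
            f"candidate {candidate.locus} outside profile of length "
            f"{profile.length}"
        )
    start_i, stop_i, cov = (
        profile.start_intensity,
        profile.stop_intensity,
        profile.coverage,
    )

    f_start = np.log10((start_i[s] + epsilon) / (start_i[s - 1] + epsilon))
    f_stop = np.log10((stop_i[e] + epsilon) / (stop_i[e + 1] + epsilon))
    f_cov_start = np.log10((cov[s] + epsilon) / (cov[s - 1] + epsilon))
    f_cov_stop = np.log10((cov[e] + epsilon) / (cov[e + 1] + epsilon))
    f_abundance = np.log10(candidate.total_abundance)
    f_start_share = start_i[s] / cov[s] if cov[s] > 0 else 0.0
    f_stop_share = stop_i[e] / cov[e] if cov[e] > 0 else 0.0

    overlap_total = 0.0
    contained_loci: set[tuple[int, int]] = set()
    for (o_start, o_stop, abundance, _key) in profile.intervals:
        if o_start <= e and o_stop >= s:  # any overlap with [s, e]
            overlap_total += abundance
        if s <= o_start and o_stop <= e and (o_start, o_stop) != (s, e):
            contained_loci.add((o_start, o_stop))  # distinct loci, not forms
    ladder = len(contained_loci)
    f_cluster_share = (
        candidate.total_abundance / overlap_total if overlap_total > 0 else 0.0
    )
    n_detected = sum(1 for x in samples if candidate.abundances.get(x, 0) > 0)
    f_penetrance = n_detected / len(samples) if samples else 0.0
    length = e - s + 1
    clusters = find_clusters(profile)
    span = next(
        c.span for c in clusters if c.first <= s and e <= c.last
    )

    return np.array(
        [
            f_start,
            f_stop,
            f_cov_start,
            f_cov_stop,
            f_abundance,
            f_start_share,
            f_stop_share,
            f_cluster_share,
            f_penetrance,
            candidate.amidation_fraction,
            candidate.acetylation_fraction,
            np.log10(length),
            length / span,
            np.log10(1 + ladder),
        ]
    )


def match_annotations(
    candidates: Sequence[CandidatePeptide],
    annotations: Sequence[AnnotationRecord],
    amid_yes: float = 0.98,
    amid_no: float = 0.02,
) -> list[str]:
    """Per candidate: "full", "partial" or "none" against the known set.

    Full requires identical coordinates and PTM consistency: an annotated
    amidated peptide must show an amidation fraction above ``amid_yes``, an
    annotated non-amidated one below ``amid_no``; unknown annotation status
    is always consistent.  Partial means strictly inside a known interval on
    the same protein — shorter degradation fragments of a known peptide.
    """
    exact = {(a.protein_accession, a.start, a.stop): a for a in annotations}
    by_protein: dict[str, list[AnnotationRecord]] = {}
    for a in annotations:
        by_protein.setdefault(a.protein_accession, []).append(a)

    statuses = []
    for candidate in candidates:
        annotation = exact.get(candidate.locus)
        if annotation is not None and _amidation_consistent(
            candidate.amidation_fraction, annotation.amidated, amid_yes, amid_no
        ):
            statuses.append("full")
            continue
        partial = any(
            (a.start <= candidate.start and candidate.stop <= a.stop)
            and (a.start, a.stop) != (candidate.start, candidate.stop)
            for a in by_protein.get(candidate.protein_accession, [])
        )
        statuses.append("partial" if partial else "none")
    return statuses


def _amidation_consistent(
    fraction: float, annotated: bool | None, yes: float, no: float
) -> bool:
    if annotated is None:
        return True
    return fraction > yes if annotated else fraction < no


def build_design_matrix(
    candidates: Sequence[CandidatePeptide],
    profiles: Mapping[str, BackboneProfile],
    annotations: Sequence[AnnotationRecord],
    samples: Sequence[str] | None = None,
    epsilon: float | None = None,
) -> pd.DataFrame:
    """Candidates x 14 features plus label, match status and grouping key.

    Positives are exactly the full matches; partial matches stay negative
    (flagged), mirroring the risk that recently annotated peptides are
    mislabelled.  The group key (protein accession) keeps all variants of a
    precursor in one cross-validation fold.
    """
    keys = [c.locus for c in candidates]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate candidate loci in design matrix input")
    missing = {c.protein_accession for c in candidates} - set(profiles)
    if missing:
        raise ValueError(f"profiles missing for proteins: {sorted(missing)[:5]}")
    if samples is None:
        samples = sorted({s for c in candidates for s in c.abundances})
    if epsilon is None:
        epsilon = default_epsilon(candidates)

    matrix = np.vstack(
        [
            compute_features(c, profiles[c.protein_accession], samples, epsilon)
            for c in candidates
        ]
    )
    frame = pd.DataFrame(matrix, columns=FEATURE_NAMES)
    frame.insert(0, "protein_accession", [c.protein_accession for c in candidates])
    frame.insert(1, "start", [c.start for c in candidates])
    frame.insert(2, "stop", [c.stop for c in candidates])
    frame["match_status"] = match_annotations(candidates, annotations)
    frame["label"] = (frame["match_status"] == "full").astype(int)
    frame["group_key"] = frame["protein_accession"]
    frame["total_abundance"] = [c.total_abundance for c in candidates]
    frame["tissue"] = [c.tissue for c in candidates]
    if int(frame["label"].sum()) == 0:
        raise ValueError(
            "no positive examples: no candidate fully matches an annotation; "
            "supply a larger annotation set"
        )
    return frame
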