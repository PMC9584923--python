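"""Per-protein positional aggregation of peptide observations.

A backbone profile projects every observed peptide form of one protein onto
the residue axis: summed intensity of peptides starting/stopping at each
position, positional coverage, distinct start/stop counts, and the
modified-boundary subsets (amidated stops, acetylated starts).  Contiguous
covered stretches form peptide clusters.

Arrays are stored with one element of zero padding at each end so that
boundary arithmetic (position 0 and length+1) is well defined; index ``i``
addresses residue ``i`` directly (1-based).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import PeptideObservation, ProteinRecord


@dataclass
class BackboneProfile:
    protein_accession: str
    length: int
    start_intensity: np.ndarray
    stop_intensity: np.ndarray
    coverage: np.ndarray
    start_count: np.ndarray
    stop_count: np.ndarray
    amidated_stop_intensity: np.ndarray
    acetylated_start_intensity: np.ndarray
    #: (start, stop, abundance, form key) per observation, for cluster assignment
    intervals: list[tuple[int, int, float, tuple]] = field(default_factory=list)

    def __getitem__(self, array: str) -> np.ndarray:
        return getattr(self, array)


@dataclass
class ClusterInterval:
    """A maximal contiguous covered stretch of one protein."""

    protein_accession: str
    first: int
    last: int
    member_peptides: list[tuple] = field(default_factory=list)

    @property
    def span(self) -> int:
        return self.last - self.first + 1


def observation_abundance(
    obs: PeptideObservation, abundance_mode: str = "sum_samples"
) -> float:
    """Collapse per-sample intensities to one scalar (missing = not detected)."""
    values = [v for v in obs.abundances.values() if v > 0]
    if not values:
        return 0.0
    if abundance_mode == "sum_samples":
        return float(sum(values))
    if abundance_mode == "median_samples":
        return float(np.median(values))
    raise ValueError(f"unknown abundance mode {abundance_mode!r}")


def build_profile(
    protein: ProteinRecord,
    observations: Sequence[PeptideObservation],
    abundance_mode: str = "sum_samples",
) -> BackboneProfile:
    """Aggregate one protein's observations into positional arrays.

    Conservation identities by construction: the start, stop and coverage
    arrays each redistribute the same total abundance (coverage weighted by
    peptide length).
    """
    length = len(protein)
    shape = length + 2  # index 0 and length+1 are zero pads
    start_i = np.zeros(shape)
    stop_i = np.zeros(shape)
    cov = np.zeros(shape)
    start_c = np.zeros(shape, dtype=int)
    stop_c = np.zeros(shape, dtype=int)
    am_stop = np.zeros(shape)
    ac_start = np.zeros(shape)
    intervals: list[tuple[int, int, float, tuple]] = []

    for obs in observations:
        if obs.protein_accession != protein.accession:
            raise ValueError(
                f"observation {obs.key} does not belong to {protein.accession}"
            )
        if obs.stop > length:
            raise ValueError(
                f"observation {obs.key} exceeds protein length {length}"
            )
        a = observation_abundance(obs, abundance_mode)
        start_i[obs.start] += a
        stop_i[obs.stop] += a
        cov[obs.start : obs.stop + 1] += a
        start_c[obs.start] += 1
        stop_c[obs.stop] += 1
        if obs.c_term_amidated:
            am_stop[obs.stop] += a
        if obs.n_term_acetyl:
            ac_start[obs.start] += a
        intervals.append((obs.start, obs.stop, a, obs.key))

    return BackboneProfile(
        protein_accession=protein.accession,
        length=length,
        start_intensity=start_i,
        stop_intensity=stop_i,
        coverage=cov,
        start_count=start_c,
        stop_count=stop_c,
        amidated_stop_intensity=am_stop,
        acetylated_start_intensity=ac_start,
        intervals=intervals,
    )


def find_clusters(profile: BackboneProfile) -> list[ClusterInterval]:
    """Maximal runs of positions with coverage > 0, in backbone order.

    Every observation is assigned to exactly one cluster (the run containing
    its interval; runs are maximal, so no interval can straddle two).
    """
    covered = profile.coverage[1 : profile.length + 1] > 0
    clusters: list[ClusterInterval] = []
    first = None
    for pos in range(1, profile.length + 1):
        if covered[pos - 1] and first is None:
            first = pos
        elif not covered[pos - 1] and first is not None:
            clusters.append(
                ClusterInterval(profile.protein_accession, first, pos - 1)
            )
            first = None
    if first is not None:
        clusters.append(
            ClusterInterval(profile.protein_accession, first, profile.length)
        )
    for start, stop, _a, key in profile.intervals:
        for cluster in clusters:
            if cluster.first <= start and stop <= cluster.last:
                cluster.member_peptides.append(key)
                break
    return clusters


def cluster_containing(
    clusters: Sequence[ClusterInterval], start: int, stop: int
) -> ClusterInterval:
    for cluster in clusters:
        if cluster.first <= start and stop <= cluster.last:
            return cluster
    raise ValueError(f"no cluster contains [{start}, {stop}]")


def profile_to_rows(profile: BackboneProfile) -> "pd.DataFrame":
    """One row per residue position, for TSV export and plotting."""
    import pandas as pd

    idx = np.arange(1, profile.length + 1)
    return pd.DataFrame(
        {
            "pos": idx,
            "cov": profile.coverage[1 : profile.length + 1],
            "start_int": profile.start_intensity[1 : profile.length + 1],
            "stop_int": profile.stop_intensity[1 : profile.length + 1],
            "am_stop": profile.amidated_stop_intensity[1 : profile.length + 1],
            "ac_start": profile.acetylated_start_intensity[1 : profile.length + 1],
        }
    )
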