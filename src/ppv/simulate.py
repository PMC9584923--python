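"""Synthetic peptidome generator with known ground truth.

The simulator emulates the statistical structure a tissue peptidome shows
around genuinely processed peptides, so the whole pipeline can be exercised
and validated without any mass-spectrometry download:

* precursor proteins carry planted mature peptides whose flanks are
  rewritten to dibasic prohormone-convertase motifs (KR/RR/KK/RK), with an
  optional +1 Glycine that licenses C-terminal amidation;
* each planted peptide spawns a degradation ladder — fragments trimmed from
  either terminus by geometric residue counts, losing a constant abundance
  factor per trimmed residue (an exopeptidase model);
* every protein also sheds background turnover fragments at lower
  abundance, concentrated in random degradation-prone hotspot regions
  (uniform starts within the region, gamma-distributed lengths), so
  background forms dense but boundary-blurred clusters rather than the
  sharp, high-intensity boundary form that marks a genuinely processed
  peptide;
* per-sample intensities get multiplicative log-normal noise, and a sample
  records a peptide only when a logistic detection draw at its
  log-abundance succeeds;
* a configurable fraction of planted peptides is amidated despite lacking
  the +1 Glycine, with Glu/Pro biased into the -1/+1 positions, planting a
  recoverable non-canonical amidation motif.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import AnnotationRecord, PeptideObservation, ProteinRecord

#: amino-acid background composition (approximate vertebrate proteome
#: frequencies, normalised)
BACKGROUND_COMPOSITION = {
    "A": 0.070, "C": 0.023, "D": 0.047, "E": 0.071, "F": 0.037,
    "G": 0.066, "H": 0.026, "I": 0.043, "K": 0.057, "L": 0.100,
    "M": 0.021, "N": 0.036, "P": 0.063, "Q": 0.048, "R": 0.056,
    "S": 0.083, "T": 0.054, "V": 0.060, "W": 0.011, "Y": 0.028,
}

DIBASIC_PAIRS = ("KR", "RR", "KK", "RK")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic peptidome.

    The default preset is sized so that training completes in minutes on a
    single CPU while preserving the qualitative structure of real data:
    12-replicate sample groups, tens of precursors among hundreds of
    background proteins, ladder-dominated clusters, and signal abundance one
    decade above background.
    """

    seed: int = 0
    n_proteins: int = 300
    protein_length_range: tuple[int, int] = (200, 800)
    n_precursors: int = 40
    peptides_per_precursor: int = 2
    planted_length_range: tuple[int, int] = (8, 45)
    dibasic_flank_prob: float = 0.8
    plus_one_gly_prob: float = 0.5
    amidation_given_gly_prob: float = 0.9
    ladder_decay: float = 0.85  # geometric per-residue trimming survival
    n_ladder_fragments: int = 12
    background_fragments_per_protein: int = 20
    background_sites_per_protein: int = 1  # turnover hotspots sharing the fragments
    background_region_width: int = 40  # residues over which hotspot starts spread
    signal_log10_mean: float = 7.0
    signal_log10_sd: float = 0.8
    background_log10_mean: float = 6.0
    background_log10_sd: float = 0.8
    n_samples: int = 12
    sample_log10_sd: float = 0.3
    detection_midpoint: float = 5.5  # log10 intensity of 50% detection
    detection_slope: float = 1.5
    non_gly_amidation_rate: float = 0.3
    ep_bias: float = 0.6  # P(E/P at each of -1/+1 | non-Gly amidated)
    min_fragment_length: int = 7
    tissue: str = "sim"

    def __post_init__(self) -> None:
        for name in (
            "dibasic_flank_prob", "plus_one_gly_prob",
            "amidation_given_gly_prob", "non_gly_amidation_rate", "ep_bias",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]: {v}")
        if not 0.0 < self.ladder_decay < 1.0:
            raise ValueError("ladder_decay must lie in (0, 1)")
        if self.signal_log10_mean <= self.background_log10_mean:
            raise ValueError("signal abundance must exceed background abundance")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("protein_length_range", "planted_length_range"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        payload = asdict(self)
        for key in ("protein_length_range", "planted_length_range"):
            payload[key] = list(payload[key])
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


@dataclass
class PlantedPeptide:
    protein_accession: str
    start: int
    stop: int
    name: str
    amidated: bool
    plus_one_gly: bool
    true_log10_abundance: float | None = None

    @property
    def locus(self) -> tuple[str, int, int]:
        return (self.protein_accession, self.start, self.stop)

    def to_annotation(self) -> AnnotationRecord:
        return AnnotationRecord(
            protein_accession=self.protein_accession,
            start=self.start,
            stop=self.stop,
            name=self.name,
            amidated=self.amidated,
            source="simulated",
        )


@dataclass
class TruthSet:
    records: list[PlantedPeptide] = field(default_factory=list)

    def to_annotations(self) -> list[AnnotationRecord]:
        return [p.to_annotation() for p in self.records]

    @property
    def loci(self) -> set[tuple[str, int, int]]:
        return {p.locus for p in self.records}


def _random_sequence(rng: np.random.Generator, length: int) -> list[str]:
    letters = list(BACKGROUND_COMPOSITION)
    probs = np.array(list(BACKGROUND_COMPOSITION.values()))
    probs = probs / probs.sum()
    return list(rng.choice(letters, size=length, p=probs))


def generate_proteome(
    config: SimulationConfig,
) -> tuple[dict[str, ProteinRecord], TruthSet]:
    """Random proteome with planted, motif-flanked mature peptides.

    The first ``n_precursors`` proteins each receive
    ``peptides_per_precursor`` disjoint planted intervals; flanks are
    rewritten in place, so the emitted FASTA already carries the motifs.
    """
    rng = np.random.default_rng([config.seed, 0])
    lo, hi = config.protein_length_range
    plo, phi = config.planted_length_range
    if config.n_precursors > config.n_proteins:
        raise ValueError("more precursors than proteins")

    proteome: dict[str, ProteinRecord] = {}
    truth = TruthSet()
    margin = 6  # residues kept clear of protein termini for flank rewriting
    gap = 10  # minimum spacing between planted intervals

    for i in range(config.n_proteins):
        accession = f"SIM{i + 1:04d}"
        length = int(rng.integers(lo, hi + 1))
        residues = _random_sequence(rng, length)

        if i < config.n_precursors:
            k = config.peptides_per_precursor
            usable = length - 2 * margin
            segment = usable // k if k else 0
            if k and segment < phi + gap:
                raise ValueError(
                    f"protein of length {length} cannot fit {k} planted "
                    f"peptides of up to {phi} residues"
                )
            for j in range(k):
                pep_len = int(rng.integers(plo, phi + 1))
                seg_lo = margin + j * segment + 1
                seg_hi = margin + (j + 1) * segment - gap
                start = int(rng.integers(seg_lo, seg_hi - pep_len + 2))
                stop = start + pep_len - 1
                planted = _rewrite_flanks(residues, start, stop, config, rng)
                planted.protein_accession = accession
                planted.name = f"planted_{accession}_{j + 1}"
                truth.records.append(planted)

        proteome[accession] = ProteinRecord(
            accession=accession,
            sequence="".join(residues),
            description=f"synthetic protein {accession}",
        )

    for p in truth.records:
        assert proteome[p.protein_accession].subsequence(p.start, p.stop)
    return proteome, truth


def _rewrite_flanks(
    residues: list[str],
    start: int,
    stop: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> PlantedPeptide:
    """Install cleavage/amidation motifs around [start, stop] (1-based)."""
    if rng.random() < config.dibasic_flank_prob:
        pair = DIBASIC_PAIRS[rng.integers(len(DIBASIC_PAIRS))]
        residues[start - 3], residues[start - 2] = pair[0], pair[1]

    plus_one_gly = rng.random() < config.plus_one_gly_prob
    if plus_one_gly:
        residues[stop] = "G"
        if rng.random() < config.dibasic_flank_prob:
            pair = DIBASIC_PAIRS[rng.integers(len(DIBASIC_PAIRS))]
            residues[stop + 1], residues[stop + 2] = pair[0], pair[1]
        amidated = rng.random() < config.amidation_given_gly_prob
    else:
        amidated = rng.random() < config.non_gly_amidation_rate
        if amidated:
            # non-canonical amidation: bias Glu/Pro into -1 and +1
            if rng.random() < config.ep_bias:
                residues[stop - 1] = "E" if rng.random() < 0.5 else "P"
            if rng.random() < config.ep_bias:
                residues[stop] = "E" if rng.random() < 0.5 else "P"
            elif residues[stop] == "G":
                residues[stop] = "A"  # keep the site non-canonical
        elif rng.random() < config.dibasic_flank_prob:
            pair = DIBASIC_PAIRS[rng.integers(len(DIBASIC_PAIRS))]
            residues[stop], residues[stop + 1] = pair[0], pair[1]

    return PlantedPeptide(
        protein_accession="",
        start=start,
        stop=stop,
        name="",
        amidated=amidated,
        plus_one_gly=plus_one_gly,
    )


def simulate_peptidome(
    proteome: dict[str, ProteinRecord],
    truth: TruthSet,
    config: SimulationConfig,
) -> list[PeptideObservation]:
    """Observed peptide forms: planted peptides, their ladders, background.

    Fragments that retain the planted C-terminus inherit the amidation flag;
    trimmed-C fragments never carry it.  Observations undetected in every
    sample are dropped, mirroring real identification tables.
    """
    rng = np.random.default_rng([config.seed, 1])
    samples = [f"S{i + 1:02d}" for i in range(config.n_samples)]
    planted_by_protein: dict[str, set[tuple[int, int]]] = {}
    for p in truth.records:
        planted_by_protein.setdefault(p.protein_accession, set()).add(
            (p.start, p.stop)
        )

    # form key -> (protein, start, stop, amidated) with base abundance summed
    forms: dict[tuple[str, int, int, bool], float] = {}

    for planted in truth.records:
        base = 10.0 ** rng.normal(config.signal_log10_mean, config.signal_log10_sd)
        planted.true_log10_abundance = math.log10(base)
        key = (planted.protein_accession, planted.start, planted.stop, planted.amidated)
        forms[key] = forms.get(key, 0.0) + base
        lam = config.ladder_decay
        for _ in range(config.n_ladder_fragments):
            # geometric trim counts, support 0, 1, 2, ... with survival lam
            trim_n = rng.geometric(1.0 - lam) - 1
            trim_c = rng.geometric(1.0 - lam) - 1
            start = planted.start + trim_n
            stop = planted.stop - trim_c
            if stop - start + 1 < config.min_fragment_length:
                continue
            abundance = base * lam ** (trim_n + trim_c)
            amidated = planted.amidated and trim_c == 0
            key = (planted.protein_accession, start, stop, amidated)
            forms[key] = forms.get(key, 0.0) + abundance

    # background turnover: fragments with uniform random starts inside
    # degradation-prone hotspot regions and gamma-distributed lengths
    n_sites = max(1, config.background_sites_per_protein)
    per_site = config.background_fragments_per_protein // n_sites
    width = config.background_region_width
    for accession, protein in sorted(proteome.items()):
        length = len(protein)
        occupied = planted_by_protein.get(accession, set())
        for _site in range(n_sites):
            region_w = min(width, max(1, length - config.min_fragment_length))
            region_start = int(rng.integers(1, max(2, length - region_w - 20)))
            for _ in range(per_site):
                frag_len = config.min_fragment_length + int(
                    round(rng.gamma(shape=3.0, scale=4.0))
                )
                start = region_start + int(rng.integers(0, region_w))
                stop = min(start + frag_len - 1, length)
                if stop - start + 1 < config.min_fragment_length:
                    continue
                if (start, stop) in occupied:
                    continue
                abundance = 10.0 ** rng.normal(
                    config.background_log10_mean, config.background_log10_sd
                )
                key = (accession, start, stop, False)
                forms[key] = forms.get(key, 0.0) + abundance

    observations: list[PeptideObservation] = []
    for (accession, start, stop, amidated), base in sorted(forms.items()):
        abundances: dict[str, float] = {}
        for sample in samples:
            value = base * 10.0 ** rng.normal(0.0, config.sample_log10_sd)
            p_detect = 1.0 / (
                1.0
                + math.exp(
                    -config.detection_slope
                    * (math.log10(value) - config.detection_midpoint)
                )
            )
            if rng.random() < p_detect:
                abundances[sample] = value
        if not abundances:
            continue
        observations.append(
            PeptideObservation(
                protein_accession=accession,
                start=start,
                stop=stop,
                sequence=proteome[accession].subsequence(start, stop),
                abundances=abundances,
                n_term_acetyl=False,
                c_term_amidated=amidated,
                engine="maxquant",
                engine_score=float(rng.uniform(50, 150)),
                tissue=config.tissue,
                group="WT",
            )
        )
    return observations


# ---------------------------------------------------------------------------
# emitting the on-disk formats the io module reads


def write_fasta(proteome: dict[str, ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for record in proteome.values():
            fh.write(f">sp|{record.accession}|{record.accession}_SYN synthetic\n")
            seq = record.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_maxquant_table(
    observations: Sequence[PeptideObservation], path: str | Path
) -> None:
    samples = sorted({s for o in observations for s in o.abundances})
    rows = []
    for o in observations:
        row = {
            "Sequence": o.sequence,
            "Proteins": o.protein_accession,
            "Start position": o.start,
            "End position": o.stop,
            "Score": o.engine_score,
            "Amidated (C-term)": "yes" if o.c_term_amidated else "no",
            "Acetyl (N-term)": "yes" if o.n_term_acetyl else "no",
        }
        for s in samples:
            row[f"Intensity {s}"] = o.abundances.get(s, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_mascot_table(
    observations: Sequence[PeptideObservation], path: str | Path
) -> None:
    samples = sorted({s for o in observations for s in o.abundances})
    rows = []
    for o in observations:
        row = {
            "pep_seq": o.sequence,
            "prot_acc": o.protein_accession,
            "pep_start": o.start,
            "pep_end": o.stop,
            "pep_score": o.engine_score,
            "pep_amidated": "yes" if o.c_term_amidated else "no",
            "pep_acetylated": "yes" if o.n_term_acetyl else "no",
        }
        for s in samples:
            row[f"intensity_{s}"] = o.abundances.get(s, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
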