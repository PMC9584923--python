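"""Core domain types shared across the PPV pipeline.

Coordinate convention: peptide positions are 1-based and inclusive at both
ends (UniProt style, e.g. "P41539:58-68" spans 11 residues).  All positional
arithmetic in the package relies on this single convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field


AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"


@dataclass(frozen=True)
class ProteinRecord:
    """A protein backbone: the coordinate frame for all peptides."""

    accession: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.accession!r} has an empty sequence")
        if self.sequence != self.sequence.upper():
            object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)

    def subsequence(self, start: int, stop: int) -> str:
        """Residues at 1-based inclusive positions [start, stop]."""
        if start < 1 or stop > len(self.sequence) or stop < start:
            raise ValueError(
                f"{self.accession}: invalid interval {start}-{stop} "
                f"(length {len(self.sequence)})"
            )
        return self.sequence[start - 1 : stop]


@dataclass
class PeptideObservation:
    """One identified peptide form (modified and unmodified are distinct rows)."""

    protein_accession: str
    start: int
    stop: int
    sequence: str
    abundances: dict[str, float]  # sample id -> intensity; absent = not detected
    n_term_acetyl: bool = False
    c_term_amidated: bool = False
    engine: str = "maxquant"
    engine_score: float = 0.0
    tissue: str = ""
    group: str = ""
    multi_mapped: bool = False

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.stop - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"{self.protein_accession}:{self.start}-{self.stop} does not "
                f"span sequence of length {len(self.sequence)}"
            )
        if self.engine not in ("maxquant", "mascot"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if not any(v > 0 for v in self.abundances.values()):
            raise ValueError(
                f"{self.protein_accession}:{self.start}-{self.stop} has no "
                "positive abundance in any sample"
            )

    @property
    def key(self) -> tuple[str, int, int, bool, bool]:
        """Peptide-form identity: locus plus PTM flags."""
        return (
            self.protein_accession,
            self.start,
            self.stop,
            self.n_term_acetyl,
            self.c_term_amidated,
        )

    @property
    def locus(self) -> tuple[str, int, int]:
        return (self.protein_accession, self.start, self.stop)

    @property
    def total_abundance(self) -> float:
        return float(sum(self.abundances.values()))

    def __len__(self) -> int:
        return self.stop - self.start + 1


@dataclass(frozen=True)
class TransferFunction:
    """log10-log10 linear map from Mascot intensity to MaxQuant intensity."""

    a: float
    b: float
    n_fit: int
    r2: float

    def __post_init__(self) -> None:
        if self.n_fit < 2:
            raise ValueError("transfer function requires at least 2 fitted pairs")

    def apply(self, x: float) -> float:
        """Map a positive Mascot intensity onto the MaxQuant scale."""
        if x <= 0:
            raise ValueError("transfer function is defined for positive intensities")
        import math

        return 10.0 ** (self.a * math.log10(x) + self.b)


@dataclass(frozen=True)
class AnnotationRecord:
    """A known (annotated) peptide used as a positive training example."""

    protein_accession: str
    start: int
    stop: int
    name: str = ""
    amidated: bool | None = None  # None = unknown
    source: str = ""

    def __post_init__(self) -> None:
        if self.stop < self.start:
            raise ValueError(f"annotation {self.name!r}: stop < start")


@dataclass
class CandidatePeptide:
    """A candidate peptide: all observed forms at one (protein, start, stop)."""

    protein_accession: str
    start: int
    stop: int
    total_abundance: float
    abundances: dict[str, float] = field(default_factory=dict)
    amidation_fraction: float = 0.0
    acetylation_fraction: float = 0.0
    tissue: str = ""

    def __post_init__(self) -> None:
        if self.total_abundance <= 0:
            raise ValueError("candidate must carry positive abundance")
        for name in ("amidation_fraction", "acetylation_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]: {v}")

    @property
    def locus(self) -> tuple[str, int, int]:
        return (self.protein_accession, self.start, self.stop)

    def __len__(self) -> int:
        return self.stop - self.start + 1


def amidation_call(fraction: float, yes: float = 0.98, no: float = 0.02) -> str:
    """Report an amidation fraction as "Yes" (> 98%), "No" (< 2%) or "ambiguous"."""
    if fraction > yes:
        return "Yes"
    if fraction < no:
        return "No"
    return "ambiguous"
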