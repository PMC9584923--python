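"""Flanking-sequence validation of PPV predictions.

High-scoring predictions should carry the hallmarks of secretory-pathway
processing in the residues *around* them — dibasic prohormone-convertase
motifs (KR/RR/KK/RK) and a +1 Glycine consumed by amidation — even though no
sequence information enters the model.  This module extracts flanking
windows, contrasts high-scoring foreground predictions against a low-scoring
background via per-position Kullback-Leibler divergence (the quantity a KL
sequence logo displays), and tabulates residue enrichment at the -1/+1
positions of amidated peptides whose +1 residue is not Glycine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import AMINO_ACIDS, GAP, CandidatePeptide, ProteinRecord


@dataclass
class FlankPair:
    """w residues either side of a peptide, gap-padded past protein termini."""

    n_flank: str
    c_flank: str
    plus_one: str

    def __post_init__(self) -> None:
        alphabet = set(AMINO_ACIDS) | {GAP, "X"}
        for flank in (self.n_flank, self.c_flank):
            if not set(flank) <= alphabet:
                raise ValueError(f"invalid flank characters in {flank!r}")


@dataclass
class PositionDivergence:
    """Per-position KL(fg || bg) in bits with signed per-residue contributions."""

    total: np.ndarray  # per position
    contributions: pd.DataFrame  # position x residue


def extract_flanks(
    candidate: CandidatePeptide | tuple[str, int, int],
    proteome: Mapping[str, ProteinRecord],
    w: int = 4,
) -> FlankPair:
    """Flanking windows of width w read from the protein backbone."""
    if isinstance(candidate, tuple):
        accession, start, stop = candidate
    else:
        accession, start, stop = candidate.locus
    if accession not in proteome:
        raise ValueError(f"unknown protein {accession!r}")
    seq = proteome[accession].sequence
    if not (1 <= start <= stop <= len(seq)):
        raise ValueError(f"{accession}:{start}-{stop} outside protein bounds")

    n_chars = [
        seq[p - 1] if p >= 1 else GAP for p in range(start - w, start)
    ]
    c_chars = [
        seq[p - 1] if p <= len(seq) else GAP
        for p in range(stop + 1, stop + 1 + w)
    ]
    return FlankPair(
        n_flank="".join(n_chars),
        c_flank="".join(c_chars),
        plus_one=c_chars[0],
    )


def select_logo_sets(
    predictions: pd.DataFrame,
    fg_threshold: float = 0.01,
    bg_quantile: float = 0.80,
    drop_known: bool = True,
    score_column: str = "ppv_score",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Foreground (score > threshold) vs the lowest-scoring background slice.

    Fully matched known peptides are removed from both sets first when
    ``drop_known``, so any motif signal reflects the new predictions rather
    than the training peptides.
    """
    frame = predictions
    if drop_known and "match_status" in frame.columns:
        frame = frame[frame["match_status"] != "full"]
    foreground = frame[frame[score_column] > fg_threshold]
    if foreground.empty:
        raise ValueError(f"no predictions score above {fg_threshold}")
    cutoff = frame[score_column].quantile(bg_quantile)
    background = frame[frame[score_column] <= cutoff]
    return foreground, background


def _position_frequencies(
    flanks: Sequence[str], width: int, pseudocount: float
) -> np.ndarray:
    """(width x 20) residue frequencies; gaps carry no alphabet mass."""
    counts = np.full((width, len(AMINO_ACIDS)), pseudocount)
    index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for flank in flanks:
        if len(flank) != width:
            raise ValueError("flank width mismatch")
        for pos, residue in enumerate(flank):
            if residue in index:
                counts[pos, index[residue]] += 1
    return counts / counts.sum(axis=1, keepdims=True)


def kl_position_divergence(
    fg_flanks: Sequence[str],
    bg_flanks: Sequence[str],
    pseudocount: float = 0.5,
) -> PositionDivergence:
    """Per-position KL divergence (bits) between foreground and background.

    Both sets receive an additive pseudocount per residue per position, so
    the divergence is finite for residues unseen in the background.
    """
    if not fg_flanks or not bg_flanks:
        raise ValueError("foreground and background flank sets must be non-empty")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    width = len(fg_flanks[0])
    p_fg = _position_frequencies(fg_flanks, width, pseudocount)
    p_bg = _position_frequencies(bg_flanks, width, pseudocount)
    contrib = p_fg * np.log2(p_fg / p_bg)
    return PositionDivergence(
        total=contrib.sum(axis=1),
        contributions=pd.DataFrame(
            contrib,
            index=pd.RangeIndex(width, name="position"),
            columns=list(AMINO_ACIDS),
        ),
    )


def amidation_motif_enrichment(
    candidates: pd.DataFrame,
    amid_threshold: float = 0.98,
) -> pd.DataFrame:
    """Residue enrichment at -1/+1 around non-Glycine amidation sites.

    Canonical amidation consumes a +1 Glycine; amidated peptides *without*
    one point to a different enzymology, so their boundary residues are
    contrasted against all non-Glycine(+1) candidates.  Expects columns
    ``minus_one``, ``plus_one`` and ``amidation_fraction``.  Returns one row
    per (slot, residue) plus (-1, +1) residue pairs, with a zero-support
    flag where the background never shows the residue.
    """
    non_gly = candidates[candidates["plus_one"] != "G"]
    fg = non_gly[non_gly["amidation_fraction"] > amid_threshold]

    rows = []
    for slot, column in (("-1", "minus_one"), ("+1", "plus_one")):
        bg_freq = non_gly[column].value_counts(normalize=True)
        fg_freq = (
            fg[column].value_counts(normalize=True)
            if len(fg)
            else pd.Series(dtype=float)
        )
        for residue in sorted(set(bg_freq.index) | set(fg_freq.index)):
            if residue == GAP:
                continue
            bg = float(bg_freq.get(residue, 0.0))
            f = float(fg_freq.get(residue, 0.0))
            rows.append(
                {
                    "slot": slot,
                    "residue": residue,
                    "fg_freq": f,
                    "bg_freq": bg,
                    "enrichment": f / bg if bg > 0 else np.inf if f > 0 else 0.0,
                    "fg_count": int((fg[column] == residue).sum()) if len(fg) else 0,
                    "bg_count": int((non_gly[column] == residue).sum()),
                    "zero_support": len(fg) == 0 or bg == 0.0,
                }
            )
    pair_bg = (non_gly["minus_one"] + non_gly["plus_one"]).value_counts(normalize=True)
    pair_fg = (
        (fg["minus_one"] + fg["plus_one"]).value_counts(normalize=True)
        if len(fg)
        else pd.Series(dtype=float)
    )
    for pair in sorted(set(pair_bg.index) | set(pair_fg.index)):
        if GAP in pair:
            continue
        bg = float(pair_bg.get(pair, 0.0))
        f = float(pair_fg.get(pair, 0.0))
        rows.append(
            {
                "slot": "-1/+1",
                "residue": pair,
                "fg_freq": f,
                "bg_freq": bg,
                "enrichment": f / bg if bg > 0 else np.inf if f > 0 else 0.0,
                "fg_count": int(((fg["minus_one"] + fg["plus_one"]) == pair).sum()) if len(fg) else 0,
                "bg_count": int(((non_gly["minus_one"] + non_gly["plus_one"]) == pair).sum()),
                "zero_support": len(fg) == 0 or bg == 0.0,
            }
        )
    return pd.DataFrame(rows)
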