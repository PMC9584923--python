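"""In-silico assembly of overlapping observed fragments into longer peptides.

Tissue peptidomes are dominated by degradation ladders: nested, overlapping
fragments of longer precursor-derived peptides.  The assembler proposes
every (observed start, observed stop) pair that can be bridged by a chain of
pairwise-overlapping observed fragments lying inside the span — the
full-length peptide may never have survived intact, yet its boundaries and
interior are each witnessed by fragments.  Assembled spans that were not
themselves observed are marked synthetic and can be scored by a PPV model
trained with positive upsampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import PeptideObservation
from .profile import observation_abundance

logger = logging.getLogger(__name__)


@dataclass
class AssembledPeptide:
    protein_accession: str
    start: int
    stop: int
    supporting_chain: list[tuple[int, int]]
    synthetic: bool
    assembled_abundance: float

    @property
    def locus(self) -> tuple[str, int, int]:
        return (self.protein_accession, self.start, self.stop)


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return min(a[1], b[1]) - max(a[0], b[0]) + 1


def _chain(
    intervals: list[tuple[int, int]],
    s: int,
    e: int,
    overlap_min: int,
) -> list[tuple[int, int]] | None:
    """A left-to-right chain from a fragment starting at s to one stopping at e.

    Only fragments fully inside [s, e] participate.  Greedy frontier
    extension: repeatedly take the in-span fragment that overlaps the chain
    so far and reaches furthest right.  Equivalent to reachability in the
    pairwise-overlap graph because overlap is an interval relation.
    """
    inside = [iv for iv in intervals if s <= iv[0] and iv[1] <= e]
    seeds = [iv for iv in inside if iv[0] == s]
    if not seeds or not any(iv[1] == e for iv in inside):
        return None
    first = max(seeds, key=lambda iv: iv[1])
    chain = [first]
    reach = first[1]  # == chain[-1][1] throughout
    while reach < e:
        # any fragment extending right and overlapping the chain tail by
        # >= overlap_min; taking the furthest reach is optimal (classic
        # interval-cover argument), so failure here means no chain exists
        extensions = [
            iv
            for iv in inside
            if iv[1] > reach and _overlap(iv, chain[-1]) >= overlap_min
        ]
        if not extensions:
            return None
        nxt = max(extensions, key=lambda iv: iv[1])
        chain.append(nxt)
        reach = nxt[1]
    return chain


def assemble_fragments(
    observations: Sequence[PeptideObservation],
    overlap_min: int = 1,
    max_span: int = 100,
    max_per_protein: int = 500,
) -> list[AssembledPeptide]:
    """All chain-supported (observed start, observed stop) spans on one protein.

    The assembled abundance is the minimum positional coverage over the span:
    a chain is only as strong as its weakest bridge.  Observed spans are
    returned with synthetic=False; output is capped at ``max_per_protein``
    by descending assembled abundance (ties by locus) and the cap is logged.
    """
    if not observations:
        return []
    accessions = {o.protein_accession for o in observations}
    if len(accessions) != 1:
        raise ValueError("assemble_fragments expects observations of one protein")
    accession = accessions.pop()

    # collapse forms to distinct observed loci, abundance summed over forms
    loci: dict[tuple[int, int], float] = {}
    for o in observations:
        iv = (o.start, o.stop)
        loci[iv] = loci.get(iv, 0.0) + observation_abundance(o)
    intervals = sorted(loci)

    max_stop = max(e for _s, e in intervals)
    coverage = np.zeros(max_stop + 2)
    for (s, e), a in loci.items():
        coverage[s : e + 1] += a

    starts = sorted({s for s, _e in intervals})
    stops = sorted({e for _s, e in intervals})
    out: list[AssembledPeptide] = []
    for s in starts:
        for e in stops:
            if e <= s or e - s + 1 > max_span:
                continue
            chain = _chain(intervals, s, e, overlap_min)
            if chain is None:
                continue
            out.append(
                AssembledPeptide(
                    protein_accession=accession,
                    start=s,
                    stop=e,
                    supporting_chain=chain,
                    synthetic=(s, e) not in loci,
                    assembled_abundance=float(coverage[s : e + 1].min()),
                )
            )
    if len(out) > max_per_protein:
        logger.info(
            "%s: capping %d assembled peptides at %d",
            accession, len(out), max_per_protein,
        )
        out.sort(key=lambda p: (-p.assembled_abundance, p.start, p.stop))
        out = out[:max_per_protein]
    out.sort(key=lambda p: (p.start, p.stop))
    return out


def expansion_factor(
    assembled: Sequence[AssembledPeptide],
    observed: Sequence[PeptideObservation],
) -> float:
    """Synthetic assembled peptides per distinct observed peptide locus."""
    observed_loci = {(o.protein_accession, o.start, o.stop) for o in observed}
    if not observed_loci:
        raise ValueError("no observed peptides")
    n_synthetic = sum(1 for p in assembled if p.synthetic)
    return n_synthetic / len(observed_loci)
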