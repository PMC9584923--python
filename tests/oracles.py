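"""Independent brute-force oracles used to validate the implementation.

Everything here is written from the definitions alone, with per-position
loops and exhaustive enumeration — deliberately sharing no code with the
package internals it checks.
"""

from __future__ import annotations

import numpy as np

from ppv.core import PeptideObservation, ProteinRecord


# ---------------------------------------------------------------------------
# random small peptidomes


def random_peptidome(rng, n_proteins=None, n_peptides=None):
    """A random toy peptidome: proteins, observations, sample ids."""
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    n_proteins = n_proteins or int(rng.integers(1, 6))
    n_peptides = n_peptides or int(rng.integers(3, 51))
    samples = [f"s{i}" for i in range(int(rng.integers(1, 5)))]
    proteins = {}
    for i in range(n_proteins):
        length = int(rng.integers(30, 81))
        seq = "".join(rng.choice(list(alphabet), size=length))
        acc = f"T{i:03d}"
        proteins[acc] = ProteinRecord(acc, seq)
    accs = list(proteins)
    observations = []
    for _ in range(n_peptides):
        acc = accs[rng.integers(len(accs))]
        L = len(proteins[acc])
        start = int(rng.integers(1, L - 6))
        stop = int(rng.integers(start + 4, min(start + 25, L) + 1))
        abundances = {
            s: float(10 ** rng.uniform(2, 6))
            for s in samples
            if rng.random() < 0.8
        }
        if not abundances:
            abundances = {samples[0]: float(10 ** rng.uniform(2, 6))}
        observations.append(
            PeptideObservation(
                protein_accession=acc,
                start=start,
                stop=stop,
                sequence=proteins[acc].subsequence(start, stop),
                abundances=abundances,
                n_term_acetyl=bool(rng.random() < 0.2),
                c_term_amidated=bool(rng.random() < 0.3),
            )
        )
    return proteins, observations, samples


# ---------------------------------------------------------------------------
# positional feature oracle


def _abundance(obs):
    return sum(v for v in obs.abundances.values() if v > 0)


def oracle_positional(observations, position, which):
    """Positional totals by direct summation over observations."""
    total = 0.0
    for o in observations:
        a = _abundance(o)
        if which == "start" and o.start == position:
            total += a
        elif which == "stop" and o.stop == position:
            total += a
        elif which == "coverage" and o.start <= position <= o.stop:
            total += a
        elif which == "am_stop" and o.stop == position and o.c_term_amidated:
            total += a
        elif which == "ac_start" and o.start == position and o.n_term_acetyl:
            total += a
    return total


def oracle_cluster_span(observations, start, stop, protein_length):
    """Span of the maximal covered run containing [start, stop], by scanning."""
    covered = [False] * (protein_length + 2)
    for o in observations:
        for p in range(o.start, o.stop + 1):
            covered[p] = True
    first = start
    while first - 1 >= 1 and covered[first - 1]:
        first -= 1
    last = stop
    while last + 1 <= protein_length and covered[last + 1]:
        last += 1
    assert all(covered[first : last + 1])
    return last - first + 1


def oracle_features(candidate_locus, protein, observations, samples, epsilon):
    """All 14 features of one candidate, recomputed from first principles."""
    acc, s, e = candidate_locus
    mine = [o for o in observations if (o.protein_accession, o.start, o.stop) == (acc, s, e)]
    others = [o for o in observations if o.protein_accession == acc]
    total = sum(_abundance(o) for o in mine)
    amid = sum(_abundance(o) for o in mine if o.c_term_amidated)
    acet = sum(_abundance(o) for o in mine if o.n_term_acetyl)

    def pos(which, p):
        if p < 1 or p > len(protein):
            return 0.0
        return oracle_positional(others, p, which)

    f1 = np.log10((pos("start", s) + epsilon) / (pos("start", s - 1) + epsilon))
    f2 = np.log10((pos("stop", e) + epsilon) / (pos("stop", e + 1) + epsilon))
    f3 = np.log10((pos("coverage", s) + epsilon) / (pos("coverage", s - 1) + epsilon))
    f4 = np.log10((pos("coverage", e) + epsilon) / (pos("coverage", e + 1) + epsilon))
    f5 = np.log10(total)
    f6 = pos("start", s) / pos("coverage", s)
    f7 = pos("stop", e) / pos("coverage", e)
    overlap_total = sum(
        _abundance(o) for o in others if o.start <= e and o.stop >= s
    )
    f8 = total / overlap_total
    detected = set()
    for o in mine:
        for sample, v in o.abundances.items():
            if v > 0:
                detected.add(sample)
    f9 = len(detected) / len(samples)
    f10 = amid / total
    f11 = acet / total
    f12 = np.log10(e - s + 1)
    span = oracle_cluster_span(others, s, e, len(protein))
    f13 = (e - s + 1) / span
    contained = {
        (o.start, o.stop)
        for o in others
        if s <= o.start and o.stop <= e and (o.start, o.stop) != (s, e)
    }
    f14 = np.log10(1 + len(contained))
    return np.array([f1, f2, f3, f4, f5, f6, f7, f8, f9, f10, f11, f12, f13, f14])


# ---------------------------------------------------------------------------
# assembly oracle: exhaustive chain search over the overlap graph


def oracle_assemble(loci, overlap_min=1, max_span=100):
    """All chainable (start, stop) spans via transitive closure, brute force."""
    loci = sorted(set(loci))
    n = len(loci)
    starts = sorted({s for s, _ in loci})
    stops = sorted({e for _, e in loci})
    result = set()
    for s in starts:
        for e in stops:
            if e <= s or e - s + 1 > max_span:
                continue
            inside = [iv for iv in loci if s <= iv[0] and iv[1] <= e]
            seeds = [iv for iv in inside if iv[0] == s]
            ends = [iv for iv in inside if iv[1] == e]
            if not seeds or not ends:
                continue
            # adjacency by pairwise overlap >= overlap_min
            idx = {iv: i for i, iv in enumerate(inside)}
            adj = [[] for _ in inside]
            for i, a in enumerate(inside):
                for j, b in enumerate(inside):
                    if i < j and min(a[1], b[1]) - max(a[0], b[0]) + 1 >= overlap_min:
                        adj[i].append(j)
                        adj[j].append(i)
            # BFS from any seed
            frontier = [idx[iv] for iv in seeds]
            seen = set(frontier)
            while frontier:
                nxt = []
                for i in frontier:
                    for j in adj[i]:
                        if j not in seen:
                            seen.add(j)
                            nxt.append(j)
                frontier = nxt
            if any(idx[iv] in seen for iv in ends):
                result.add((s, e))
    return result


# ---------------------------------------------------------------------------
# AUC oracle: all positive-negative pairs


def oracle_auc(labels, scores):
    labels = list(labels)
    scores = list(scores)
    pos = [s for l, s in zip(labels, scores) if l]
    neg = [s for l, s in zip(labels, scores) if not l]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
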