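"""Reading and writing proteomes, engine peptide tables and peptidome TSVs.

Two search-engine dialects are supported: a MaxQuant-like table
(``Sequence``, ``Proteins``, ``Start position``, ``End position``,
``Intensity <sample>`` ..., ``Amidated (C-term)``, ``Acetyl (N-term)``,
``Score``) and a Mascot-like table (``pep_seq``, ``prot_acc``, ``pep_start``,
``pep_end``, ``pep_score``, ``intensity_<sample>`` ...).  Column names can be
remapped through a YAML config.  Abundances from the two engines are merged
through a log-linear transfer function fitted on peptides seen by both.
"""

from __future__ import annotations

import logging
import math
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import PeptideObservation, ProteinRecord, TransferFunction

logger = logging.getLogger(__name__)

#: default column layout per engine dialect
DIALECTS: dict[str, dict[str, str]] = {
    "maxquant": {
        "sequence": "Sequence",
        "protein": "Proteins",
        "start": "Start position",
        "stop": "End position",
        "score": "Score",
        "amidated": "Amidated (C-term)",
        "acetylated": "Acetyl (N-term)",
        "intensity_prefix": "Intensity ",
    },
    "mascot": {
        "sequence": "pep_seq",
        "protein": "prot_acc",
        "start": "pep_start",
        "stop": "pep_end",
        "score": "pep_score",
        "amidated": "pep_amidated",
        "acetylated": "pep_acetylated",
        "intensity_prefix": "intensity_",
    },
}

_UNIPROT_HEADER = re.compile(r"^(?:sp|tr)\|([^|]+)\|")


def read_proteome(path: str | Path) -> dict[str, ProteinRecord]:
    """Read a FASTA proteome into an accession-keyed mapping.

    UniProt-style headers (``sp|ACC|NAME``) yield ``ACC`` as accession;
    bare headers use the first whitespace-delimited token.
    """
    path = Path(path)
    records: dict[str, ProteinRecord] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        m = _UNIPROT_HEADER.match(entry.id)
        accession = m.group(1) if m else entry.id
        if accession in records:
            raise ValueError(f"duplicate accession in proteome: {accession!r}")
        records[accession] = ProteinRecord(
            accession=accession,
            sequence=str(entry.seq).upper(),
            description=entry.description,
        )
    if not records:
        raise ValueError(f"no FASTA entries found in {path}")
    return records


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV, ignoring '#'-prefixed provenance header lines."""
    return pd.read_csv(path, sep="\t", comment="#")


def _truthy(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in ("1", "yes", "true", "y")
    if pd.isna(value):
        return False
    return bool(value)


def load_observations(
    path: str | Path,
    engine: str,
    proteome: Mapping[str, ProteinRecord],
    min_length: int = 7,
    min_mascot_score: float = 20.0,
    column_map: Mapping[str, str] | None = None,
    tissue: str = "",
    group: str = "",
) -> list[PeptideObservation]:
    """Load one engine's peptide table, applying the standard row filters.

    Rows shorter than ``min_length`` residues are dropped, as are Mascot rows
    scoring below ``min_mascot_score``.  When start/stop columns are absent
    the peptide is located by exhaustive substring search in its protein;
    multi-locus matches produce one observation per locus, flagged as
    multi-mapped.
    """
    if engine not in DIALECTS:
        raise ValueError(f"unknown engine {engine!r}")
    cols = dict(DIALECTS[engine])
    if column_map:
        cols.update(column_map)

    table = _read_table(path)
    required = [cols["sequence"], cols["protein"]]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    prefix = cols["intensity_prefix"]
    sample_cols = [c for c in table.columns if c.startswith(prefix)]
    if not sample_cols:
        raise ValueError(f"{path}: no intensity columns with prefix {prefix!r}")

    unknown_rows = [
        (i, acc)
        for i, acc in table[cols["protein"]].items()
        if acc not in proteome
    ]
    if unknown_rows:
        listing = ", ".join(f"row {i}: {acc!r}" for i, acc in unknown_rows[:10])
        raise ValueError(f"{path}: unknown protein accessions ({listing})")

    observations: list[PeptideObservation] = []
    n_short = n_low_score = 0
    for i, row in table.iterrows():
        sequence = str(row[cols["sequence"]]).upper()
        if len(sequence) < min_length:
            n_short += 1
            continue
        score = float(row[cols["score"]]) if cols["score"] in table.columns else 0.0
        if engine == "mascot" and score < min_mascot_score:
            n_low_score += 1
            continue

        accession = row[cols["protein"]]
        protein = proteome[accession]
        abundances = {}
        for c in sample_cols:
            raw = row[c]
            if pd.isna(raw) or raw == "":
                continue
            try:
                value = float(raw)
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path} row {i}: malformed abundance {raw!r} in {c!r}"
                ) from exc
            if value > 0:
                abundances[c[len(prefix):]] = value

        loci = _locate(row, cols, protein, sequence, table.columns)
        if not loci:
            raise ValueError(
                f"{path} row {i}: sequence {sequence!r} not found in "
                f"protein {accession}"
            )
        for start, stop in loci:
            observations.append(
                PeptideObservation(
                    protein_accession=accession,
                    start=start,
                    stop=stop,
                    sequence=sequence,
                    abundances=dict(abundances),
                    n_term_acetyl=_truthy(row.get(cols["acetylated"], False)),
                    c_term_amidated=_truthy(row.get(cols["amidated"], False)),
                    engine=engine,
                    engine_score=score,
                    tissue=tissue,
                    group=group,
                    multi_mapped=len(loci) > 1,
                )
            )
    logger.info(
        "%s: %d observations loaded, %d dropped for length < %d, "
        "%d dropped for score < %g",
        path, len(observations), n_short, min_length, n_low_score,
        min_mascot_score,
    )
    return observations


def _locate(row, cols, protein: ProteinRecord, sequence: str, columns) -> list[tuple[int, int]]:
    """Resolve a peptide row to 1-based loci on its protein."""
    has_coords = (
        cols["start"] in columns
        and cols["stop"] in columns
        and not pd.isna(row[cols["start"]])
        and not pd.isna(row[cols["stop"]])
    )
    if has_coords:
        start, stop = int(row[cols["start"]]), int(row[cols["stop"]])
        if protein.subsequence(start, stop) != sequence:
            raise ValueError(
                f"{protein.accession}:{start}-{stop} does not match sequence "
                f"{sequence!r}"
            )
        return [(start, stop)]
    # substring search, 1-based inclusive, all occurrences (may overlap)
    loci = []
    offset = protein.sequence.find(sequence)
    while offset != -1:
        loci.append((offset + 1, offset + len(sequence)))
        offset = protein.sequence.find(sequence, offset + 1)
    return loci


def fit_transfer_function(
    paired: Sequence[tuple[float, float]],
) -> TransferFunction:
    """Least-squares fit of log10(maxquant) = a * log10(mascot) + b.

    ``paired`` holds (mascot_intensity, maxquant_intensity) for peptides
    quantified by both engines.
    """
    if len(paired) < 2:
        raise ValueError("need at least 2 paired intensities to fit")
    x = np.asarray([p[0] for p in paired], dtype=float)
    y = np.asarray([p[1] for p in paired], dtype=float)
    if (x <= 0).any() or (y <= 0).any():
        raise ValueError("intensities must be positive")
    lx, ly = np.log10(x), np.log10(y)
    a, b = np.polyfit(lx, ly, 1)
    pred = a * lx + b
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return TransferFunction(a=float(a), b=float(b), n_fit=len(paired), r2=r2)


def shared_intensity_pairs(
    maxquant_obs: Iterable[PeptideObservation],
    mascot_obs: Iterable[PeptideObservation],
) -> list[tuple[float, float]]:
    """(mascot, maxquant) total-intensity pairs for peptide keys in both engines."""
    mq = {o.key: o for o in maxquant_obs}
    pairs = []
    for obs in mascot_obs:
        if obs.key in mq:
            x, y = obs.total_abundance, mq[obs.key].total_abundance
            if x > 0 and y > 0:
                pairs.append((x, y))
    return pairs


def merge_engine_tables(
    maxquant_obs: Sequence[PeptideObservation],
    mascot_obs: Sequence[PeptideObservation],
    tf: TransferFunction,
) -> list[PeptideObservation]:
    """Merge two-engine outputs on the peptide-form key.

    Keys present in MaxQuant (alone or in both) keep the MaxQuant abundances
    bit-identically; Mascot-only keys have each per-sample intensity mapped
    through the transfer function onto the MaxQuant scale.
    """
    by_key: dict[tuple, PeptideObservation] = {}
    for obs in maxquant_obs:
        if obs.key in by_key and by_key[obs.key].sequence != obs.sequence:
            raise ValueError(f"conflicting sequences for key {obs.key}")
        by_key[obs.key] = obs
    merged = list(by_key.values())
    seen = set(by_key)
    for obs in mascot_obs:
        if obs.key in seen:
            prior = by_key.get(obs.key)
            if prior is not None and prior.sequence != obs.sequence:
                raise ValueError(f"conflicting sequences for key {obs.key}")
            continue
        transferred = {
            s: 10.0 ** (tf.a * math.log10(v) + tf.b)
            for s, v in obs.abundances.items()
            if v > 0
        }
        merged.append(
            PeptideObservation(
                protein_accession=obs.protein_accession,
                start=obs.start,
                stop=obs.stop,
                sequence=obs.sequence,
                abundances=transferred,
                n_term_acetyl=obs.n_term_acetyl,
                c_term_amidated=obs.c_term_amidated,
                engine="mascot",
                engine_score=obs.engine_score,
                tissue=obs.tissue,
                group=obs.group,
                multi_mapped=obs.multi_mapped,
            )
        )
        seen.add(obs.key)
    return merged


# ---------------------------------------------------------------------------
# peptidome TSV round-trip

_PEPTIDOME_COLUMNS = [
    "protein_accession", "start", "stop", "sequence", "n_term_acetyl",
    "c_term_amidated", "engine", "engine_score", "tissue", "group",
    "multi_mapped",
]


def observations_to_frame(observations: Sequence[PeptideObservation]) -> pd.DataFrame:
    """Flatten observations to a wide table with one intensity column per sample."""
    samples = sorted({s for o in observations for s in o.abundances})
    rows = []
    for o in observations:
        row = {c: getattr(o, c) for c in _PEPTIDOME_COLUMNS}
        for s in samples:
            row[f"intensity_{s}"] = o.abundances.get(s, np.nan)
        rows.append(row)
    return pd.DataFrame(rows, columns=_PEPTIDOME_COLUMNS + [f"intensity_{s}" for s in samples])


def write_observations(
    observations: Sequence[PeptideObservation],
    path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    path = Path(path)
    frame = observations_to_frame(observations)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_observations(path: str | Path) -> list[PeptideObservation]:
    frame = _read_table(path)
    sample_cols = [c for c in frame.columns if c.startswith("intensity_")]
    observations = []
    for _, row in frame.iterrows():
        abundances = {
            c[len("intensity_"):]: float(row[c])
            for c in sample_cols
            if not pd.isna(row[c])
        }
        observations.append(
            PeptideObservation(
                protein_accession=row["protein_accession"],
                start=int(row["start"]),
                stop=int(row["stop"]),
                sequence=row["sequence"],
                abundances=abundances,
                n_term_acetyl=bool(row["n_term_acetyl"]),
                c_term_amidated=bool(row["c_term_amidated"]),
                engine=row["engine"],
                engine_score=float(row["engine_score"]),
                tissue="" if pd.isna(row["tissue"]) else str(row["tissue"]),
                group="" if pd.isna(row["group"]) else str(row["group"]),
                multi_mapped=bool(row["multi_mapped"]),
            )
        )
    return observations


def read_annotations(path: str | Path) -> list["AnnotationRecord"]:
    """Read a known-peptide annotation TSV (accession, start, stop, name, amidated)."""
    from .core import AnnotationRecord

    frame = _read_table(path)
    records = []
    for _, row in frame.iterrows():
        amid = row.get("amidated")
        if amid is None or (not isinstance(amid, str) and pd.isna(amid)):
            amidated = None
        elif isinstance(amid, str) and amid.strip().lower() in ("", "unknown", "na"):
            amidated = None
        else:
            amidated = _truthy(amid)
        records.append(
            AnnotationRecord(
                protein_accession=row["protein_accession"],
                start=int(row["start"]),
                stop=int(row["stop"]),
                name=str(row.get("name", "")),
                amidated=amidated,
                source=str(row.get("source", "")),
            )
        )
    return records


def write_annotations(
    records: Sequence["AnnotationRecord"], path: str | Path
) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "protein_accession": r.protein_accession,
                "start": r.start,
                "stop": r.stop,
                "name": r.name,
                "amidated": "unknown" if r.amidated is None else ("yes" if r.amidated else "no"),
                "source": r.source,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
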