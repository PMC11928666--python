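"""Read and write the on-disk artifacts: FASTA sequences, annotation TSVs,
label TSVs and prediction TSVs.

Coordinate convention: transmembrane/signal segments are 1-based inclusive
residue intervals, matching the output convention of common signal-peptide
and transmembrane predictors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .constants import AMBIGUOUS, AMINO_ACIDS

log = logging.getLogger(__name__)

VALID_LETTERS = set(AMINO_ACIDS) | AMBIGUOUS


class ParseError(ValueError):
    """Raised when an on-disk artifact violates its documented format."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence.

    ``seq`` is uppercase over the 20 canonical letters plus the ambiguity
    letters X, B, Z, U, O; ambiguity letters are retained here (I/O is
    lossless) and dropped downstream by the descriptor code.
    """

    id: str
    seq: str
    gram: str | None = None
    taxon: str | None = None

    def __post_init__(self):
        if not self.id:
            raise ParseError("protein record with empty id")
        if not self.seq:
            raise ParseError(f"record {self.id!r} has an empty sequence")
        bad = set(self.seq.upper()) - VALID_LETTERS
        if bad:
            raise ParseError(
                f"record {self.id!r} contains invalid letters {sorted(bad)}")
        object.__setattr__(self, "seq", self.seq.upper())


class LocalizationLabel(IntEnum):
    """Ordinal location class: cytoplasmic < periplasmic < extracellular,
    reflecting the gradient of marine adaptations from the cytoplasm outward.
    """

    CYTOPLASMIC = 1
    PERIPLASMIC = 2
    EXTRACELLULAR = 3

    @classmethod
    def from_string(cls, s: str) -> "LocalizationLabel":
        key = s.strip().lower()
        table = {
            "cytoplasmic": cls.CYTOPLASMIC,
            "periplasmic": cls.PERIPLASMIC,
            "extracellular": cls.EXTRACELLULAR,
            "secreted": cls.EXTRACELLULAR,
        }
        if key not in table:
            raise ParseError(f"unknown localization label {s!r}")
        return table[key]


SEGMENT_KINDS = ("helix", "barrel", "signal", "outside")


@dataclass
class AnnotationBundle:
    """Per-protein external evidence as produced by signal-peptide /
    transmembrane predictors and domain annotation.

    sp_probs: (any-SP, Sec/SPI, lipoprotein-SPII, Tat) probabilities.
    tm_segments: (start, end, kind) 1-based inclusive; kind in
        {helix, barrel, signal, outside}.
    region_props: (pH, pB, pS, po, pi) residue-fraction composition of the
        protein over transmembrane-helix, beta-barrel, signal-peptide,
        outside and inside regions; sums to 1.
    domains: ordered accession list (order is meaningful: synteny).
    """

    sp_probs: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    tm_segments: list[tuple[int, int, str]] = field(default_factory=list)
    region_props: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, 1.0)
    domains: list[str] = field(default_factory=list)
    go_membrane: bool = False

    def validate(self, length: int) -> None:
        for p in self.sp_probs:
            if not 0.0 <= p <= 1.0:
                raise ParseError(f"signal-peptide probability {p} outside [0,1]")
        by_kind: dict[str, list[tuple[int, int]]] = {}
        for start, end, kind in self.tm_segments:
            if kind not in SEGMENT_KINDS:
                raise ParseError(f"unknown segment kind {kind!r}")
            if not (1 <= start <= end <= length):
                raise ParseError(
                    f"segment {start}-{end} outside sequence bounds 1..{length}")
            by_kind.setdefault(kind, []).append((start, end))
        for kind, segs in by_kind.items():
            segs.sort()
            for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
                if s2 <= e1:
                    raise ParseError(
                        f"overlapping {kind} segments {s1}-{e1} and {s2}-{e2}")
        if abs(sum(self.region_props) - 1.0) > 1e-9:
            raise ParseError("region proportions do not sum to 1")


def default_bundle() -> AnnotationBundle:
    """Bundle for a protein with no external evidence: no signal peptide, no
    transmembrane segments, fully internal."""
    return AnnotationBundle()


def region_props_from_segments(
    segments: Iterable[tuple[int, int, str]], length: int
) -> tuple[float, float, float, float, float]:
    """Residue-fraction composition (pH, pB, pS, po, pi) from 1-based
    inclusive segments; residues not covered by any segment count as inside.
    """
    counts = {k: 0 for k in SEGMENT_KINDS}
    covered = 0
    for start, end, kind in segments:
        n = end - start + 1
        counts[kind] += n
        covered += n
    pi = max(length - covered, 0)
    return (
        counts["helix"] / length,
        counts["barrel"] / length,
        counts["signal"] / length,
        counts["outside"] / length,
        pi / length,
    )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a FASTA file into ProteinRecords.

    Multi-line sequences are concatenated, letters uppercased; duplicate ids
    and empty sequences are rejected with the offending record named.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, seq=str(rec.seq)))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.seq), id=r.id, description="") for r in records),
        str(path), "fasta")


# ---------------------------------------------------------------------------
# Annotation TSV
#
# Columns: id, sp_any, sp_spi, sp_spii, sp_tat, tm_segments, domains,
# go_membrane.  tm_segments is a semicolon list "start-end:kind" (1-based
# inclusive); domains is a semicolon list of accessions; go_membrane is 0/1.

ANNOTATION_COLUMNS = [
    "id", "sp_any", "sp_spi", "sp_spii", "sp_tat",
    "tm_segments", "domains", "go_membrane",
]


def _parse_segments(cell: str) -> list[tuple[int, int, str]]:
    if not cell or pd.isna(cell):
        return []
    out = []
    for token in str(cell).split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            span, kind = token.split(":")
            start, end = span.split("-")
            out.append((int(start), int(end), kind))
        except ValueError as exc:
            raise ParseError(f"malformed segment token {token!r}") from exc
    return out


def read_annotations(
    path: str | Path, seq_lengths: dict[str, int]
) -> dict[str, AnnotationBundle]:
    """Read the annotation TSV; every protein in ``seq_lengths`` gets a
    bundle (a default one when absent from the table, with a warning)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str}, keep_default_na=False)
    missing_cols = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ParseError(f"annotation table missing columns {sorted(missing_cols)}")
    bundles: dict[str, AnnotationBundle] = {}
    for row in df.itertuples(index=False):
        if row.id not in seq_lengths:
            raise ParseError(f"annotated id {row.id!r} not among input sequences")
        length = seq_lengths[row.id]
        segments = _parse_segments(row.tm_segments)
        bundle = AnnotationBundle(
            sp_probs=(float(row.sp_any), float(row.sp_spi),
                      float(row.sp_spii), float(row.sp_tat)),
            tm_segments=segments,
            region_props=region_props_from_segments(segments, length),
            domains=[d for d in str(row.domains).split(";") if d],
            go_membrane=bool(int(row.go_membrane)),
        )
        bundle.validate(length)
        bundles[row.id] = bundle
    absent = set(seq_lengths) - set(bundles)
    if absent:
        log.warning("%d proteins without annotation rows; using default "
                    "(no-evidence) bundles", len(absent))
        for pid in absent:
            bundles[pid] = default_bundle()
    return bundles


def write_annotations(
    bundles: dict[str, AnnotationBundle], path: str | Path
) -> None:
    rows = []
    for pid, b in bundles.items():
        rows.append({
            "id": pid,
            "sp_any": b.sp_probs[0], "sp_spi": b.sp_probs[1],
            "sp_spii": b.sp_probs[2], "sp_tat": b.sp_probs[3],
            "tm_segments": ";".join(f"{s}-{e}:{k}" for s, e, k in b.tm_segments),
            "domains": ";".join(b.domains),
            "go_membrane": int(b.go_membrane),
        })
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Labels and predictions

def read_labels(path: str | Path) -> dict[str, LocalizationLabel]:
    """Read the id -> label TSV.  'secreted' is accepted as a synonym of
    extracellular.  A protein listed with two conflicting locations (a
    moonlighting annotation) is an error — such sequences must be removed
    upstream."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns[:2]) != ["id", "label"]:
        raise ParseError("labels TSV must have columns: id, label")
    labels: dict[str, LocalizationLabel] = {}
    for row in df.itertuples(index=False):
        lab = LocalizationLabel.from_string(row.label)
        if row.id in labels and labels[row.id] != lab:
            raise ParseError(
                f"conflicting locations for {row.id!r} (moonlighting protein)")
        labels[row.id] = lab
    return labels


def write_labels(labels: dict[str, LocalizationLabel], path: str | Path) -> None:
    pd.DataFrame(
        [{"id": k, "label": v.name.lower()} for k, v in labels.items()]
    ).to_csv(path, sep="\t", index=False)


PREDICTION_COLUMNS = ["id", "p_cyto", "p_peri", "p_extr", "call", "has_sp"]


def write_predictions(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=PREDICTION_COLUMNS)


def read_predictions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing = set(PREDICTION_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"predictions TSV missing columns {sorted(missing)}")
    return df
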