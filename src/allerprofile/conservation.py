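"""Consensus building, substitution-matrix conservation scoring, epitope mapping.

Given a gapped multiple alignment of allergen homologs, a majority-threshold
consensus is called per column (default threshold: strict majority, i.e.
4 of 6 rows for a six-species alignment).  Each sequence is then scored
against the consensus: identical residues count as identical, differing
residue pairs whose BLOSUM62 score reaches a cutoff (default 1) count as
similar, everything else — including residue-vs-gap columns — as dissimilar.
Columns with an ambiguous consensus, or where both symbols are gaps, are
excluded from the denominator.  The similarity percent is

    (identical + similar) / (columns - excluded) x 100.

IgE-binding epitopes are defined as 1-based inclusive intervals on an
ungapped reference sequence and are mapped through the reference's gaps to
alignment columns, so each epitope can be scored as its own sub-alignment.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import AlignIO
from Bio.Align import substitution_matrices

__all__ = [
    "AlignmentBlock",
    "SubstitutionMatrix",
    "ConsensusSequence",
    "EpitopeRegion",
    "SimilarityScore",
    "read_alignment",
    "read_epitopes",
    "load_substitution_matrix",
    "build_consensus",
    "similarity_to_consensus",
    "map_epitope",
    "consensus_similarity_table",
    "epitope_similarity_table",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
AMBIGUOUS = "X"
_ALLOWED = set(AMINO_ACIDS) | {AMBIGUOUS, GAP}


@dataclass
class AlignmentBlock:
    """Equal-length gapped amino-acid rows keyed by sequence id."""

    seq_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.seq_ids) != len(self.rows):
            raise ValueError("seq_ids and rows must be parallel")
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least two rows")
        length = len(self.rows[0])
        for sid, row in zip(self.seq_ids, self.rows):
            if len(row) != length:
                raise ValueError(
                    f"ragged alignment: row {sid!r} has length {len(row)}, "
                    f"expected {length}"
                )
        bad = sorted({ch for row in self.rows for ch in row} - _ALLOWED)
        if bad:
            raise ValueError(f"unknown characters in alignment: {bad}")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.seq_ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"sequence id {seq_id!r} not in alignment") from None

    def slice_columns(self, columns: list[int]) -> "AlignmentBlock":
        """Sub-alignment of the given 0-based columns, all rows."""
        return AlignmentBlock(
            list(self.seq_ids),
            ["".join(row[c] for c in columns) for row in self.rows],
        )


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric amino-acid score table with a name tag."""

    name: str
    scores: "substitution_matrices.Array"

    def score(self, a: str, b: str) -> float:
        return float(self.scores[a, b])


def load_substitution_matrix(name_or_path: str = "BLOSUM62") -> SubstitutionMatrix:
    """Load a named matrix (e.g. BLOSUM62) or an NCBI-style matrix text file."""
    if Path(name_or_path).is_file():
        with open(name_or_path) as fh:
            scores = substitution_matrices.read(fh)
        return SubstitutionMatrix(Path(name_or_path).stem, scores)
    return SubstitutionMatrix(
        name_or_path.upper(), substitution_matrices.load(name_or_path.upper())
    )


@dataclass
class ConsensusSequence:
    """Gapped consensus string aligned to its source block."""

    sequence: str
    threshold_count: int
    ambiguity: str = AMBIGUOUS


@dataclass(frozen=True)
class EpitopeRegion:
    """A linear epitope interval on an ungapped reference sequence.

    ``start``/``end`` are 1-based inclusive positions on the reference after
    removing gaps; ``peptide`` must equal that reference substring.
    """

    allergen: str
    epitope_id: str
    reference_id: str
    start: int
    end: int
    peptide: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.epitope_id}: need 1 <= start <= end, got "
                f"start={self.start}, end={self.end}"
            )
        if len(self.peptide) != self.end - self.start + 1:
            raise ValueError(
                f"{self.epitope_id}: peptide length {len(self.peptide)} does not "
                f"match interval [{self.start}, {self.end}]"
            )


@dataclass
class SimilarityScore:
    """Per-sequence conservation score with its column-count breakdown."""

    percent: float
    identical: int
    similar: int
    dissimilar: int
    excluded: int

    @property
    def defined(self) -> bool:
        """False when every column was excluded (denominator zero)."""
        return not math.isnan(self.percent)

    @property
    def total_columns(self) -> int:
        return self.identical + self.similar + self.dissimilar + self.excluded


def read_alignment(path, format: str = "fasta") -> AlignmentBlock:
    """Read a FASTA or Clustal alignment file, preserving row order."""
    if format not in ("fasta", "clustal"):
        raise ValueError("format must be 'fasta' or 'clustal'")
    aln = AlignIO.read(str(path), format)
    return AlignmentBlock(
        [rec.id for rec in aln], [str(rec.seq).upper() for rec in aln]
    )


def read_epitopes(path, sep: str = "\t") -> list[EpitopeRegion]:
    """Read an epitope table (allergen, epitope_id, reference_id, start, end, peptide)."""
    df = pd.read_csv(path, sep=sep)
    required = {"allergen", "epitope_id", "reference_id", "start", "end", "peptide"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        EpitopeRegion(
            allergen=str(r.allergen),
            epitope_id=str(r.epitope_id),
            reference_id=str(r.reference_id),
            start=int(r.start),
            end=int(r.end),
            peptide=str(r.peptide).upper(),
        )
        for r in df.itertuples()
    ]


def build_consensus(
    a: AlignmentBlock, threshold_count: int | None = None
) -> ConsensusSequence:
    """Majority-threshold consensus; gaps count as a symbol.

    Default threshold is a strict majority, ``floor(n/2) + 1`` rows.  A column
    emits its most frequent symbol only when that symbol is the unique maximum
    and its count reaches the threshold; otherwise the ambiguity character.
    """
    n = len(a.rows)
    if threshold_count is None:
        threshold_count = n // 2 + 1
    if not (1 <= threshold_count <= n):
        raise ValueError(
            f"threshold_count must be in [1, {n}], got {threshold_count}"
        )
    out = []
    for col in range(a.length):
        counts = Counter(row[col] for row in a.rows)
        (top, top_n), = counts.most_common(1)
        tied = sum(1 for c in counts.values() if c == top_n) > 1
        out.append(top if top_n >= threshold_count and not tied else AMBIGUOUS)
    return ConsensusSequence("".join(out), threshold_count)


def similarity_to_consensus(
    row: str,
    c: ConsensusSequence,
    m: SubstitutionMatrix,
    similar_cutoff: int = 1,
) -> SimilarityScore:
    """Score a gapped sequence against the consensus of its alignment.

    Column classification:

    * consensus ambiguous, or both symbols gaps -> excluded
    * identical symbols -> identical
    * residue vs gap (either way) -> dissimilar
    * differing residues with substitution score >= ``similar_cutoff`` -> similar
    * otherwise -> dissimilar
    """
    if len(row) != len(c.sequence):
        raise ValueError(
            f"row length {len(row)} does not match consensus length {len(c.sequence)}"
        )
    identical = similar = dissimilar = excluded = 0
    for r, s in zip(row.upper(), c.sequence):
        if s == c.ambiguity or (r == GAP and s == GAP):
            excluded += 1
        elif r == s:
            identical += 1
        elif r == GAP or s == GAP:
            dissimilar += 1
        elif m.score(r, s) >= similar_cutoff:
            similar += 1
        else:
            dissimilar += 1
    denom = len(row) - excluded
    percent = (identical + similar) / denom * 100.0 if denom else float("nan")
    return SimilarityScore(percent, identical, similar, dissimilar, excluded)


def _reference_columns(reference_row: str, start: int, end: int) -> list[int]:
    """Alignment columns (0-based) of ungapped reference positions start..end."""
    columns = []
    pos = 0  # 1-based ungapped position of the current residue
    for col, ch in enumerate(reference_row):
        if ch == GAP:
            continue
        pos += 1
        if start <= pos <= end:
            columns.append(col)
        if pos >= end:
            break
    if pos < end:
        raise ValueError(
            f"epitope interval [{start}, {end}] extends beyond the ungapped "
            f"reference length {pos}"
        )
    return columns


def map_epitope(a: AlignmentBlock, e: EpitopeRegion) -> AlignmentBlock:
    """Slice the alignment columns spanned by an epitope on its reference.

    Gaps in the reference row do not consume epitope coordinates; the returned
    block contains every row restricted to the mapped columns.
    """
    ref = a.row(e.reference_id)
    columns = _reference_columns(ref, e.start, e.end)
    found = "".join(ref[c] for c in columns).replace(GAP, "")
    if found != e.peptide:
        raise ValueError(
            f"epitope {e.epitope_id}: stated peptide {e.peptide!r} does not match "
            f"reference {e.reference_id!r} positions {e.start}..{e.end} "
            f"(found {found!r})"
        )
    return a.slice_columns(columns)


def consensus_similarity_table(
    a: AlignmentBlock,
    m: SubstitutionMatrix,
    threshold_count: int | None = None,
    similar_cutoff: int = 1,
) -> pd.Series:
    """Whole-alignment similarity-to-consensus percent for every row."""
    consensus = build_consensus(a, threshold_count)
    return pd.Series(
        {
            sid: similarity_to_consensus(row, consensus, m, similar_cutoff).percent
            for sid, row in zip(a.seq_ids, a.rows)
        },
        name="similarity_percent",
    )


def epitope_similarity_table(
    a: AlignmentBlock,
    epitopes: list[EpitopeRegion],
    m: SubstitutionMatrix,
    threshold_count: int | None = None,
    similar_cutoff: int = 1,
) -> pd.DataFrame:
    """Epitope x species table of similarity-to-consensus percents.

    Each epitope is mapped to its alignment columns, a consensus is built on
    that sub-alignment, and every row is scored against it.  An epitope whose
    consensus is entirely ambiguous yields NaN for all species (flagged rather
    than silently dropped).
    """
    records = {}
    for e in epitopes:
        sub = map_epitope(a, e)
        consensus = build_consensus(sub, threshold_count)
        records[e.epitope_id] = {
            sid: similarity_to_consensus(row, consensus, m, similar_cutoff).percent
            for sid, row in zip(sub.seq_ids, sub.rows)
        }
    table = pd.DataFrame.from_dict(records, orient="index")
    return table.reindex(columns=a.seq_ids)
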