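"""Reading, preprocessing and writing of short peptide sequences.

Peptides from phage-display biopanning come either as FASTA records or as
one-sequence-per-line plain text.  Circular (disulfide-constrained) library
peptides carry flanking cysteines that are not part of the displayed motif;
preprocessing linearizes them, removes duplicates and sequences with
ambiguous residues, and enforces a minimum length, keeping an audit trail
of every removal.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal, Optional, Sequence

from Bio import SeqIO

#: The 20 standard one-letter amino-acid codes, alphabetical.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Residue codes treated as ambiguous and grounds for exclusion.
AMBIGUOUS_RESIDUES: frozenset[str] = frozenset("XBZJOU")

Topology = Literal["linear", "circular"]
Label = Literal["positive", "negative", "unknown"]


@dataclass(frozen=True)
class Peptide:
    """A single identified peptide sequence.

    Parameters
    ----------
    id : str
        Record identifier (assigned sequentially when the input has none).
    sequence : str
        Amino-acid sequence, uppercased on construction.
    topology : {"linear", "circular"}
        Whether the peptide came from a disulfide-constrained (circular)
        library.  Circular peptides have their flanking cysteines stripped
        during preprocessing.
    """

    id: str
    sequence: str
    topology: Topology = "linear"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.strip().upper())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PeptideSet:
    """An ordered collection of peptides with an optional class label."""

    peptides: list[Peptide] = field(default_factory=list)
    label: Optional[Label] = None

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self) -> Iterator[Peptide]:
        return iter(self.peptides)

    def __getitem__(self, i: int) -> Peptide:
        return self.peptides[i]

    def sequences(self) -> list[str]:
        return [p.sequence for p in self.peptides]

    def ids(self) -> list[str]:
        return [p.id for p in self.peptides]


@dataclass
class PreprocessLog:
    """Counts of peptides touched or removed by each preprocessing rule.

    ``n_cysteine_stripped`` counts peptides whose flanking cysteines were
    removed (the peptide survives); the remaining counters are removals and
    satisfy ``n_input == surviving + removals``.
    """

    n_input: int = 0
    n_cysteine_stripped: int = 0
    n_duplicates_removed: int = 0
    n_ambiguous_removed: int = 0
    n_too_short_removed: int = 0
    n_overlap_removed: int = 0

    @property
    def n_removed(self) -> int:
        return (
            self.n_duplicates_removed
            + self.n_ambiguous_removed
            + self.n_too_short_removed
            + self.n_overlap_removed
        )


# ---------------------------------------------------------------------------
# Reading


def _unique_ids(raw_ids: Sequence[str]) -> list[str]:
    """Disambiguate duplicate ids with a numeric suffix; never drop records."""
    seen: Counter[str] = Counter()
    out = []
    for rid in raw_ids:
        seen[rid] += 1
        out.append(rid if seen[rid] == 1 else f"{rid}_{seen[rid]}")
    return out


def read_peptides(
    path: str | Path,
    format: Literal["fasta", "plain"] = "fasta",
    default_topology: Topology = "linear",
) -> PeptideSet:
    """Read peptides from a FASTA or plain-text file.

    Plain format is one sequence per line, with an optional leading
    ``id<TAB>`` field.  In FASTA, a record whose description contains the
    token ``circular`` is flagged as a circular peptide; everything else
    gets ``default_topology``.  Sequences are uppercased; records without
    an id receive sequential synthetic ids.

    Raises
    ------
    ValueError
        If the file is empty, or a FASTA file does not start with a
        header line.
    OSError
        If the file cannot be read.
    """
    path = Path(path)
    text = path.read_text()
    raw_ids: list[str] = []
    peptides: list[tuple[str, Topology]] = []

    if format == "fasta":
        for lineno, line in enumerate(text.splitlines(), start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: malformed FASTA, line {lineno} is not part of a "
                    f"record (expected '>' header first): {line[:40]!r}"
                )
            break
        for rec in SeqIO.parse(io.StringIO(text), "fasta"):
            topology: Topology = (
                "circular"
                if "circular" in rec.description.lower().split()
                else default_topology
            )
            raw_ids.append(rec.id)
            peptides.append((str(rec.seq), topology))
    elif format == "plain":
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if "\t" in line:
                rid, seq = line.split("\t", 1)
            else:
                rid, seq = "", line
            raw_ids.append(rid)
            peptides.append((seq.strip(), default_topology))
    else:  # pragma: no cover - guarded by Literal type
        raise ValueError(f"unknown format {format!r}")

    if not peptides:
        raise ValueError(f"{path}: no peptides")

    raw_ids = [
        rid if rid else f"seq_{i + 1}" for i, rid in enumerate(raw_ids)
    ]
    ids = _unique_ids(raw_ids)
    return PeptideSet(
        [Peptide(i, s, t) for i, (s, t) in zip(ids, peptides)]
    )


# ---------------------------------------------------------------------------
# Preprocessing


def _strip_circular_cysteines(p: Peptide) -> tuple[Peptide, bool]:
    """Remove at most one flanking C per end of a circular peptide.

    A circular peptide with a cysteine at only one end loses only that one.
    """
    if p.topology != "circular":
        return p, False
    seq = p.sequence
    stripped = False
    if seq.startswith("C"):
        seq = seq[1:]
        stripped = True
    if seq.endswith("C"):
        seq = seq[:-1]
        stripped = True
    return (replace(p, sequence=seq) if stripped else p), stripped


def _is_clean(seq: str) -> bool:
    return len(seq) > 0 and all(c in AMINO_ACIDS for c in seq)


def preprocess(
    peptide_set: PeptideSet,
    strip_circular_cysteines: bool = True,
    min_length: int = 3,
) -> tuple[PeptideSet, PreprocessLog]:
    """Apply the standard cleanup rules, in order.

    (i) strip one flanking cysteine per end of circular peptides;
    (ii) remove exact duplicate sequences keeping the first occurrence;
    (iii) remove sequences with ambiguous residues (X, B, Z — plus J, O, U
    and any non-alphabetic character, since only the 20 standard codes are
    modelled); (iv) remove sequences shorter than ``min_length``.

    Returns the surviving set and a :class:`PreprocessLog`.  Idempotent:
    preprocessing an already-preprocessed set removes nothing.

    Raises
    ------
    ValueError
        If the input is empty, or every peptide is removed.
    """
    if len(peptide_set) == 0:
        raise ValueError("cannot preprocess an empty peptide set")

    log = PreprocessLog(n_input=len(peptide_set))
    stage: list[Peptide] = []
    for p in peptide_set:
        if strip_circular_cysteines:
            p, stripped = _strip_circular_cysteines(p)
            if stripped:
                log.n_cysteine_stripped += 1
        stage.append(p)

    seen: set[str] = set()
    survivors: list[Peptide] = []
    for p in stage:
        if p.sequence in seen:
            log.n_duplicates_removed += 1
            continue
        seen.add(p.sequence)
        if not _is_clean(p.sequence):
            log.n_ambiguous_removed += 1
            continue
        if len(p.sequence) < min_length:
            log.n_too_short_removed += 1
            continue
        survivors.append(p)

    if not survivors:
        raise ValueError("empty set after preprocessing")
    return PeptideSet(survivors, label=peptide_set.label), log


def remove_overlap(
    set_a: PeptideSet, reference: PeptideSet
) -> tuple[PeptideSet, int]:
    """Drop from ``set_a`` every peptide whose sequence occurs in ``reference``.

    Matching is exact on the (already preprocessed, uppercased) sequence.
    Returns the filtered set and the number of peptides removed.  An empty
    result is permitted.
    """
    ref = set(reference.sequences())
    kept = [p for p in set_a if p.sequence not in ref]
    return PeptideSet(kept, label=set_a.label), len(set_a) - len(kept)


# ---------------------------------------------------------------------------
# Writing predictions


def write_predictions(records: Iterable, path: str | Path) -> None:
    """Write prediction records as a tab-separated table.

    Columns: id, sequence, mean_probability (6 decimals), votes, call.
    Records that failed to encode (``record.error`` set) get ``NA`` in the
    numeric columns and their error message in the call column.
    """
    records = list(records)
    if not records:
        raise ValueError("no prediction records to write")
    lines = ["id\tsequence\tmean_probability\tvotes\tcall"]
    for r in records:
        if getattr(r, "error", None):
            lines.append(f"{r.id}\t{r.sequence}\tNA\tNA\terror: {r.error}")
        else:
            lines.append(
                f"{r.id}\t{r.sequence}\t{r.mean_probability:.6f}\t{r.votes}\t{r.call}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(peptide_set: PeptideSet, path: str | Path) -> None:
    """Write a peptide set as FASTA, tagging circular records."""
    lines = []
    for p in peptide_set:
        tag = " circular" if p.topology == "circular" else ""
        lines.append(f">{p.id}{tag}")
        lines.append(p.sequence)
    Path(path).write_text("\n".join(lines) + "\n")
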