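"""Amino-acid composition (AAC) and dipeptide composition (DPC) encoders.

AAC is the 20-vector of residue frequencies: AAC_i = x_i / sum_i x_i, where
x_i counts residues of type i.  DPC is the 400-vector of adjacent-pair
frequencies over the L-1 overlapping dipeptides of a length-L sequence:
DPC_j = y_j / sum_j y_j.  Both are computed on the full descriptor space
before any feature selection, so a matrix restricted to a selected subset
has row sums <= 1.  Descriptor order is fixed alphabetically for
reproducible model files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from .peptide_io import AMINO_ACIDS, Peptide, PeptideSet

FeatureKind = Literal["AAC", "DPC"]

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_DIPEPTIDES = [a + b for a in AMINO_ACIDS for b in AMINO_ACIDS]
_DP_INDEX = {d: j for j, d in enumerate(_DIPEPTIDES)}


@dataclass(frozen=True, order=True)
class FeatureDescriptor:
    """One composition feature: a single residue (AAC) or a pair (DPC)."""

    kind: FeatureKind
    token: str

    def __post_init__(self) -> None:
        expected = 1 if self.kind == "AAC" else 2
        if len(self.token) != expected or any(
            c not in AMINO_ACIDS for c in self.token
        ):
            raise ValueError(
                f"invalid {self.kind} token {self.token!r}: must be "
                f"{expected} residue(s) from the 20-letter alphabet"
            )


def aac_descriptors() -> list[FeatureDescriptor]:
    """The full AAC descriptor list, alphabetical (A..Y)."""
    return [FeatureDescriptor("AAC", a) for a in AMINO_ACIDS]


def dpc_descriptors() -> list[FeatureDescriptor]:
    """The full DPC descriptor list, alphabetical (AA, AC, ..., YY)."""
    return [FeatureDescriptor("DPC", d) for d in _DIPEPTIDES]


def compute_aac(peptide: Peptide | str) -> np.ndarray:
    """Residue-frequency vector of length 20 (order ACDEFGHIKLMNPQRSTVWY)."""
    seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
    if len(seq) == 0:
        raise ValueError("cannot compute AAC of an empty sequence")
    v = np.zeros(20)
    for c in seq:
        v[_AA_INDEX[c]] += 1.0
    return v / len(seq)


def compute_dpc(peptide: Peptide | str) -> np.ndarray:
    """Overlapping adjacent-pair frequency vector of length 400.

    The L-1 dipeptides are read linearly; circular peptides were already
    linearized during preprocessing, so no wrap-around pair is counted.
    """
    seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
    if len(seq) < 2:
        raise ValueError("DPC requires a sequence of length >= 2")
    v = np.zeros(400)
    for a, b in zip(seq, seq[1:]):
        v[_DP_INDEX[a + b]] += 1.0
    return v / (len(seq) - 1)


@dataclass
class FeatureMatrix:
    """Per-peptide composition vectors over a declared descriptor list."""

    descriptors: list[FeatureDescriptor]
    X: np.ndarray
    row_ids: list[str]
    labels: Optional[np.ndarray] = None

    @property
    def tokens(self) -> list[str]:
        return [d.token for d in self.descriptors]

    def select(self, descriptors: Sequence[FeatureDescriptor]) -> "FeatureMatrix":
        """Restrict to a descriptor subset (column selection, given order)."""
        pos = {d: i for i, d in enumerate(self.descriptors)}
        cols = [pos[d] for d in descriptors]
        return FeatureMatrix(
            list(descriptors), self.X[:, cols], list(self.row_ids), self.labels
        )

    def to_tsv(self, path: str | Path) -> None:
        lines = ["id\t" + "\t".join(self.tokens)]
        for rid, row in zip(self.row_ids, self.X):
            lines.append(rid + "\t" + "\t".join(f"{v:.10g}" for v in row))
        Path(path).write_text("\n".join(lines) + "\n")


_LABEL_CODE = {"positive": 1, "negative": 0}


def encode(
    peptide_set: PeptideSet, descriptors: Sequence[FeatureDescriptor]
) -> FeatureMatrix:
    """Encode every peptide over the given (possibly mixed-kind) descriptors.

    The full composition of each kind present is computed first, then
    columns are selected and ordered exactly as listed, so normalization is
    always over the full 20/400 space.  Labels are copied from the set's
    label when it is "positive" or "negative".
    """
    descriptors = list(descriptors)
    kinds = {d.kind for d in descriptors}
    rows = []
    for p in peptide_set:
        parts = {}
        if "AAC" in kinds:
            parts["AAC"] = compute_aac(p)
        if "DPC" in kinds:
            parts["DPC"] = compute_dpc(p)
        row = np.empty(len(descriptors))
        for k, d in enumerate(descriptors):
            idx = _AA_INDEX[d.token] if d.kind == "AAC" else _DP_INDEX[d.token]
            row[k] = parts[d.kind][idx]
        rows.append(row)
    X = np.vstack(rows) if rows else np.empty((0, len(descriptors)))
    labels = None
    if peptide_set.label in _LABEL_CODE:
        labels = np.full(len(peptide_set), _LABEL_CODE[peptide_set.label])
    return FeatureMatrix(descriptors, X, peptide_set.ids(), labels)


def encode_pair(
    positives: PeptideSet,
    negatives: PeptideSet,
    descriptors: Sequence[FeatureDescriptor],
) -> FeatureMatrix:
    """Encode a labeled training pair: positives (label 1) then negatives (0)."""
    mp = encode(positives, descriptors)
    mn = encode(negatives, descriptors)
    return FeatureMatrix(
        list(descriptors),
        np.vstack([mp.X, mn.X]),
        mp.row_ids + mn.row_ids,
        np.concatenate(
            [np.ones(len(positives), dtype=int), np.zeros(len(negatives), dtype=int)]
        ),
    )


def base_descriptors(feature_kind: str) -> list[FeatureDescriptor]:
    """Full descriptor list underlying a model feature kind.

    AAC and OAAC start from the 20 residue compositions; DPC and ODPC from
    the 400 dipeptide compositions (the O-variants are then reduced by
    feature selection).
    """
    if feature_kind.upper() in ("AAC", "OAAC"):
        return aac_descriptors()
    if feature_kind.upper() in ("DPC", "ODPC"):
        return dpc_descriptors()
    raise ValueError(f"unknown feature kind {feature_kind!r}")
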