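"""Distance-based subspecies assignment against a type-strain reference panel.

*Lactobacillus delbrueckii* comprises six named subspecies, each anchored by a
type strain.  An isolate is assigned per locus to the subspecies whose type
strain is nearest by p-distance; the final call is the plurality vote over the
loci.  Isolates whose loci vote for different subspecies are flagged as
mosaics — at MLST resolution these are candidates for inter-subspecies
homologous recombination — and exact between-reference ties produce an
unresolved vote rather than a random one.  Neighbor-joining trees on the
p-distance matrix provide the supporting per-locus visualisation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from .mlst_core import DEFAULT_LOCI, IsolateRecord, LocusDef

__all__ = [
    "ReferencePanel",
    "ClassificationResult",
    "p_distance",
    "p_distance_matrix",
    "nj_tree",
    "classify_isolate",
]

UNRESOLVED = "unresolved"


def p_distance(a: str, b: str) -> float:
    """Proportion of mismatching sites between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    if not a:
        raise ValueError("empty sequences")
    x = np.frombuffer(a.upper().encode(), dtype=np.uint8)
    y = np.frombuffer(b.upper().encode(), dtype=np.uint8)
    return float((x != y).mean())


def p_distance_matrix(sequences: Sequence[str]) -> np.ndarray:
    """Symmetric pairwise p-distance matrix with a zero diagonal."""
    n = len(sequences)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = p_distance(sequences[i], sequences[j])
    return m


def nj_tree(matrix: np.ndarray, labels: Sequence[str]) -> str:
    """Neighbor-joining tree from a distance matrix, as a newick string.

    Negative branch lengths produced by the NJ algebra are clamped to zero.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(matrix, matrix.T):
        raise ValueError("matrix must be symmetric")
    if matrix.shape[0] < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    tree = nj(DistanceMatrix(matrix, list(labels)), neg_as_zero=True)
    return str(tree).strip()


@dataclass
class ReferencePanel:
    """Type-strain reference records keyed by subspecies name."""

    type_strains: dict[str, IsolateRecord]
    loci: tuple[LocusDef, ...] = DEFAULT_LOCI

    def __post_init__(self) -> None:
        for name, rec in self.type_strains.items():
            missing = [
                l.name for l in self.loci if l.name not in rec.sequences
            ]
            if missing:
                raise ValueError(
                    f"reference {name!r} is missing loci: {', '.join(missing)}"
                )

    @property
    def subspecies(self) -> tuple[str, ...]:
        return tuple(self.type_strains)


@dataclass
class ClassificationResult:
    """Per-locus nearest-reference calls and the majority-vote outcome."""

    isolate_id: str
    per_locus_calls: dict[str, str]  # locus -> subspecies or "unresolved"
    votes: dict[str, int]
    final_call: str
    mosaic_flag: bool
    per_locus_distances: dict[str, dict[str, float]] = field(default_factory=dict)


def classify_isolate(
    record: IsolateRecord, panel: ReferencePanel
) -> ClassificationResult:
    """Classify one isolate against the reference panel.

    Each locus votes for the subspecies whose type strain is nearest by
    p-distance; an exact tie gives an unresolved vote.  The final call is the
    strict plurality winner (``"unresolved"`` if tied); the mosaic flag is
    raised whenever resolved votes are split across subspecies.
    """
    calls: dict[str, str] = {}
    dists: dict[str, dict[str, float]] = {}
    for ldef in panel.loci:
        if ldef.name not in record.sequences:
            raise KeyError(
                f"isolate {record.isolate_id!r} is missing locus {ldef.name!r}"
            )
        seq = record.sequences[ldef.name]
        d = {
            name: p_distance(seq, ref.sequences[ldef.name])
            for name, ref in panel.type_strains.items()
        }
        dists[ldef.name] = d
        best = min(d.values())
        nearest = [name for name, v in d.items() if v == best]
        calls[ldef.name] = nearest[0] if len(nearest) == 1 else UNRESOLVED
    votes = Counter(v for v in calls.values() if v != UNRESOLVED)
    if votes:
        top = votes.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            final = UNRESOLVED
        else:
            final = top[0][0]
    else:
        final = UNRESOLVED
    mosaic = len(votes) >= 2
    return ClassificationResult(
        isolate_id=record.isolate_id,
        per_locus_calls=calls,
        votes=dict(votes),
        final_call=final,
        mosaic_flag=mosaic,
        per_locus_distances=dists,
    )
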