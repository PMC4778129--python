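"""Allele and sequence-type bookkeeping for a multi-locus sequence typing scheme.

Multi-locus sequence typing (MLST) genotypes a bacterial isolate by the
combination of allele identifiers observed at a fixed panel of housekeeping-gene
fragments.  Every distinct nucleotide sequence at a locus receives an integer
allele number; the vector of allele numbers across all loci is the isolate's
allele profile, and every distinct profile is a sequence type (ST).

The default scheme implemented here is the eight-locus panel used for
*Lactobacillus delbrueckii* (clpX, dnaA, groEL, murE, pheS, pyrG, recA, rpoB),
whose fragments concatenate to a 4,261 bp sequence.  All machinery is generic
over the locus panel, so toy schemes can be used in tests.

Conventions
-----------
* Allele numbers are assigned in first-occurrence order of the input stream and
  are contiguous from 1 within each locus.
* ST numbers are assigned in first-occurrence order of the profile stream and
  are contiguous from 1.
* Sequences must be exact-length, gap-free, unambiguous (A/C/G/T only) and free
  of stop codons in the declared reading frame.  Ambiguity codes are rejected
  rather than resolved.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "LocusDef",
    "DEFAULT_LOCI",
    "AlleleSequence",
    "AlleleDatabase",
    "STProfile",
    "IsolateRecord",
    "TypingResult",
    "SequenceValidationError",
    "ProfileTableError",
    "STOP_CODONS",
    "validate_sequence",
    "build_allele_database",
    "call_allele",
    "assign_sts",
    "type_isolates",
    "concatenate",
    "read_profiles",
    "write_profiles",
    "read_locus_fasta",
    "write_locus_fasta",
    "load_isolates",
    "read_metadata",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class LocusDef:
    """Definition of one MLST locus.

    Parameters
    ----------
    name : str
        Gene fragment name (e.g. ``"clpX"``).
    expected_length : int
        Exact amplicon length in bp; every allele of the locus must have it.
    frame_offset : int
        Offset (0, 1 or 2) of the first complete codon within the fragment.
    order_index : int
        1-based position of the locus in the concatenation / profile order.
    """

    name: str
    expected_length: int
    frame_offset: int = 0
    order_index: int = 1

    def __post_init__(self) -> None:
        if self.expected_length <= 0:
            raise ValueError(f"expected_length must be positive ({self.name})")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError(f"frame_offset must be 0, 1 or 2 ({self.name})")


#: The eight-locus L. delbrueckii panel with its published fragment lengths,
#: in concatenation order.  Fragments are assumed in-frame (offset 0).
DEFAULT_LOCI: tuple[LocusDef, ...] = (
    LocusDef("clpX", 508, 0, 1),
    LocusDef("dnaA", 598, 0, 2),
    LocusDef("groEL", 470, 0, 3),
    LocusDef("murE", 477, 0, 4),
    LocusDef("pheS", 491, 0, 5),
    LocusDef("pyrG", 563, 0, 6),
    LocusDef("recA", 551, 0, 7),
    LocusDef("rpoB", 603, 0, 8),
)


@dataclass(frozen=True)
class AlleleSequence:
    """A numbered allele: one unique nucleotide sequence at one locus."""

    locus: str
    allele_id: int
    sequence: str


class SequenceValidationError(ValueError):
    """An input sequence failed validation for its locus."""

    def __init__(self, isolate_id: str, locus: str, violations: Sequence[str]):
        self.isolate_id = isolate_id
        self.locus = locus
        self.violations = list(violations)
        super().__init__(
            f"invalid sequence for isolate {isolate_id!r} at locus {locus!r}: "
            + "; ".join(violations)
        )


class ProfileTableError(ValueError):
    """A profile table violated the PubMLST-dialect format or its invariants."""


def validate_sequence(locus: LocusDef, seq: str) -> list[str]:
    """Validate one sequence against its locus definition.

    Returns a list of violation strings; an empty list means the sequence is
    valid.  Checked rules: exact expected length, A/C/G/T alphabet only, and
    absence of stop codons among the complete codons in the declared frame.
    """
    violations: list[str] = []
    seq = seq.upper()
    if len(seq) != locus.expected_length:
        violations.append(
            f"wrong length: expected {locus.expected_length}, got {len(seq)}"
        )
    bad = set(seq) - _VALID_BASES
    if bad:
        violations.append(f"non-ACGT character(s): {','.join(sorted(bad))}")
    else:
        for start in range(locus.frame_offset, len(seq) - 2, 3):
            codon = seq[start : start + 3]
            if codon in STOP_CODONS:
                violations.append(
                    f"internal stop codon {codon} at position {start + 1}"
                )
                break
    return violations


class AlleleDatabase:
    """Per-locus registry mapping unique sequences to integer allele numbers.

    Allele numbers are assigned in insertion order, contiguous from 1 within
    each locus; re-adding a known sequence returns its existing number.
    """

    def __init__(self, loci: Sequence[LocusDef] = DEFAULT_LOCI):
        loci = sorted(loci, key=lambda l: l.order_index)
        names = [l.name for l in loci]
        if len(set(names)) != len(names):
            raise ValueError("duplicate locus names")
        self._loci: dict[str, LocusDef] = {l.name: l for l in loci}
        self._alleles: dict[str, list[AlleleSequence]] = {n: [] for n in names}
        self._index: dict[str, dict[str, int]] = {n: {} for n in names}

    @property
    def loci(self) -> tuple[LocusDef, ...]:
        return tuple(self._loci.values())

    @property
    def locus_names(self) -> tuple[str, ...]:
        return tuple(self._loci)

    def locus(self, name: str) -> LocusDef:
        try:
            return self._loci[name]
        except KeyError:
            raise KeyError(f"unknown locus {name!r}") from None

    def alleles(self, locus: str) -> tuple[AlleleSequence, ...]:
        self.locus(locus)
        return tuple(self._alleles[locus])

    def n_alleles(self, locus: str) -> int:
        return len(self.alleles(locus))

    def sequence(self, locus: str, allele_id: int) -> str:
        alleles = self.alleles(locus)
        if not 1 <= allele_id <= len(alleles):
            raise KeyError(f"locus {locus!r} has no allele {allele_id}")
        return alleles[allele_id - 1].sequence

    def lookup(self, locus: str, seq: str) -> Optional[int]:
        """Exact-match allele number for ``seq``, or None if novel."""
        self.locus(locus)
        return self._index[locus].get(seq.upper())

    def add(self, locus: str, seq: str, isolate_id: str = "<anonymous>") -> int:
        """Register ``seq`` (validating it), returning its allele number."""
        ldef = self.locus(locus)
        seq = seq.upper()
        existing = self._index[locus].get(seq)
        if existing is not None:
            return existing
        violations = validate_sequence(ldef, seq)
        if violations:
            raise SequenceValidationError(isolate_id, locus, violations)
        allele_id = len(self._alleles[locus]) + 1
        self._alleles[locus].append(AlleleSequence(locus, allele_id, seq))
        self._index[locus][seq] = allele_id
        return allele_id


@dataclass(frozen=True)
class STProfile:
    """A sequence type: an ST number plus its allele-number vector."""

    st_id: int
    alleles: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.st_id < 1:
            raise ValueError("st_id must be positive")
        if any(a < 1 for a in self.alleles):
            raise ValueError("allele numbers must be positive")


@dataclass
class IsolateRecord:
    """One isolate: its per-locus sequences and optional metadata."""

    isolate_id: str
    sequences: dict[str, str]
    metadata: dict[str, str] = field(default_factory=dict)


def build_allele_database(
    sequences: Mapping[str, Iterable[Union[str, tuple[str, str]]]],
    loci: Sequence[LocusDef] = DEFAULT_LOCI,
) -> AlleleDatabase:
    """Build an allele registry from per-locus sequence collections.

    ``sequences`` maps each locus name to an iterable of sequences, given
    either as plain strings or as ``(isolate_id, sequence)`` pairs (the
    isolate id is only used in error messages).  Allele numbers follow
    first-occurrence order of each stream; the operation is deterministic
    given input order and idempotent on re-runs.
    """
    db = AlleleDatabase(loci)
    for name in db.locus_names:
        for item in sequences.get(name, ()):
            if isinstance(item, str):
                isolate_id, seq = "<anonymous>", item
            else:
                isolate_id, seq = item
            db.add(name, seq, isolate_id)
    return db


def call_allele(
    db: AlleleDatabase, locus: str, seq: str, extend: bool = False
) -> Optional[int]:
    """Look up the allele number of ``seq`` at ``locus``.

    In query mode (default) an unseen sequence returns ``None`` (the novel
    marker).  With ``extend=True`` a valid unseen sequence is registered as
    the next allele number and that number returned.
    """
    found = db.lookup(locus, seq)
    if found is not None:
        return found
    if not extend:
        return None
    return db.add(locus, seq)


def assign_sts(
    vectors: Iterable[Sequence[int]], n_loci: int = 8
) -> tuple[list[int], list[STProfile]]:
    """Assign ST numbers to allele-profile vectors.

    Identical vectors share one ST; ST numbers are 1..m in first-occurrence
    order.  Returns ``(st_ids, registry)`` where ``st_ids[i]`` is the ST of
    input vector *i* and ``registry`` lists the distinct profiles by ST.
    """
    registry: list[STProfile] = []
    index: dict[tuple[int, ...], int] = {}
    st_ids: list[int] = []
    for vec in vectors:
        key = tuple(int(a) for a in vec)
        if len(key) != n_loci:
            raise ValueError(
                f"profile has {len(key)} entries, expected {n_loci}"
            )
        if any(a < 1 for a in key):
            raise ValueError("allele numbers must be positive")
        st = index.get(key)
        if st is None:
            st = len(registry) + 1
            index[key] = st
            registry.append(STProfile(st, key))
        st_ids.append(st)
    return st_ids, registry


@dataclass
class TypingResult:
    """Output of typing a collection of isolates against a locus panel."""

    db: AlleleDatabase
    st_of: dict[str, int]
    registry: list[STProfile]

    @property
    def n_sts(self) -> int:
        return len(self.registry)

    def isolate_counts(self) -> dict[int, int]:
        """Number of isolates carrying each ST."""
        counts: dict[int, int] = {}
        for st in self.st_of.values():
            counts[st] = counts.get(st, 0) + 1
        return counts


def type_isolates(
    records: Iterable[IsolateRecord],
    loci: Sequence[LocusDef] = DEFAULT_LOCI,
    db: Optional[AlleleDatabase] = None,
    extend: bool = True,
) -> TypingResult:
    """Type isolates: call alleles at every locus and assign STs.

    All loci of the panel must be present in each record.  With ``extend``
    (default) novel alleles are registered; otherwise a novel allele raises
    ``KeyError`` naming the isolate and locus.
    """
    if db is None:
        db = AlleleDatabase(loci)
        extend = True
    records = list(records)
    vectors = []
    ids = []
    for rec in records:
        vec = []
        for name in db.locus_names:
            if name not in rec.sequences:
                raise KeyError(
                    f"isolate {rec.isolate_id!r} is missing locus {name!r}"
                )
            try:
                allele = call_allele(db, name, rec.sequences[name], extend=extend)
            except SequenceValidationError as exc:
                raise SequenceValidationError(
                    rec.isolate_id, name, exc.violations
                ) from None
            if allele is None:
                raise KeyError(
                    f"novel allele for isolate {rec.isolate_id!r} at locus "
                    f"{name!r} (query mode)"
                )
            vec.append(allele)
        vectors.append(vec)
        ids.append(rec.isolate_id)
    st_ids, registry = assign_sts(vectors, n_loci=len(db.locus_names))
    return TypingResult(db, dict(zip(ids, st_ids)), registry)


def concatenate(
    record: Union[IsolateRecord, Sequence[int], STProfile],
    db: Optional[AlleleDatabase] = None,
    loci: Sequence[LocusDef] = DEFAULT_LOCI,
) -> str:
    """Concatenate an isolate's locus sequences in panel order.

    Accepts either an :class:`IsolateRecord` (sequences taken directly) or an
    allele vector / :class:`STProfile` together with the database that resolves
    allele numbers to sequences.  The result length equals the sum of locus
    lengths (4,261 bp for the default panel).
    """
    if isinstance(record, IsolateRecord):
        panel = db.loci if db is not None else tuple(
            sorted(loci, key=lambda l: l.order_index)
        )
        parts = []
        for ldef in panel:
            if ldef.name not in record.sequences:
                raise KeyError(
                    f"isolate {record.isolate_id!r} is missing locus "
                    f"{ldef.name!r}"
                )
            parts.append(record.sequences[ldef.name].upper())
        return "".join(parts)
    if db is None:
        raise ValueError("an AlleleDatabase is required to resolve allele numbers")
    vec = record.alleles if isinstance(record, STProfile) else tuple(record)
    names = db.locus_names
    if len(vec) != len(names):
        raise ValueError(f"profile has {len(vec)} entries, expected {len(names)}")
    return "".join(db.sequence(n, a) for n, a in zip(names, vec))


# ---------------------------------------------------------------------------
# Standard-format I/O
# ---------------------------------------------------------------------------

def read_profiles(
    path: Union[str, Path], loci: Sequence[LocusDef] = DEFAULT_LOCI
) -> list[STProfile]:
    """Read a PubMLST-dialect profile table (TSV: ``ST`` + locus columns)."""
    panel = sorted(loci, key=lambda l: l.order_index)
    names = [l.name for l in panel]
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "ST" not in df.columns:
        raise ProfileTableError("profile table is missing the 'ST' column")
    missing = [n for n in names if n not in df.columns]
    if missing:
        raise ProfileTableError(
            f"profile table is missing locus column(s): {', '.join(missing)}"
        )
    profiles = []
    seen: set[int] = set()
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        rowd = dict(zip(df.columns, row))
        try:
            st = int(rowd["ST"])
            vec = tuple(int(rowd[n]) for n in names)
        except (TypeError, ValueError):
            raise ProfileTableError(
                f"non-integer cell in profile table at line {row_no}"
            ) from None
        if st in seen:
            raise ProfileTableError(f"duplicated ST id {st}")
        seen.add(st)
        profiles.append(STProfile(st, vec))
    return profiles


def write_profiles(
    profiles: Iterable[STProfile],
    path: Union[str, Path],
    loci: Sequence[LocusDef] = DEFAULT_LOCI,
) -> None:
    """Write profiles as a PubMLST-dialect TSV, sorted by ST number."""
    panel = sorted(loci, key=lambda l: l.order_index)
    names = [l.name for l in panel]
    rows = sorted(profiles, key=lambda p: p.st_id)
    df = pd.DataFrame(
        [{"ST": p.st_id, **dict(zip(names, p.alleles))} for p in rows],
        columns=["ST", *names],
    )
    df.to_csv(path, sep="\t", index=False)


def read_locus_fasta(path: Union[str, Path]) -> list[tuple[str, str]]:
    """Read one per-locus FASTA; record ids are isolate ids."""
    return [
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_locus_fasta(
    entries: Iterable[tuple[str, str]], path: Union[str, Path]
) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in entries
    ]
    SeqIO.write(records, str(path), "fasta")


def load_isolates(
    fasta_by_locus: Mapping[str, Union[str, Path]],
    metadata: Optional[Mapping[str, Mapping[str, str]]] = None,
) -> list[IsolateRecord]:
    """Assemble isolate records from per-locus FASTA files.

    Every isolate id must appear in every locus file (complete profiles are
    required before typing).  ``metadata`` optionally maps isolate id to a
    metadata mapping (region, source, year ...).
    """
    per_locus = {
        locus: dict(read_locus_fasta(path))
        for locus, path in fasta_by_locus.items()
    }
    ids: Optional[list[str]] = None
    for locus, seqs in per_locus.items():
        if ids is None:
            ids = list(seqs)
        elif set(seqs) != set(ids):
            diff = set(ids) ^ set(seqs)
            raise KeyError(
                f"locus {locus!r} FASTA does not cover the same isolates "
                f"(mismatch: {sorted(diff)[:5]} ...)"
            )
    if ids is None:
        return []
    meta = metadata or {}
    return [
        IsolateRecord(
            iid,
            {locus: per_locus[locus][iid] for locus in per_locus},
            dict(meta.get(iid, {})),
        )
        for iid in ids
    ]


def read_metadata(path: Union[str, Path]) -> dict[str, dict[str, str]]:
    """Read an isolate metadata TSV (first column = isolate id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    key = df.columns[0]
    return {
        str(row[key]): {c: row[c] for c in df.columns[1:] if pd.notna(row[c])}
        for _, row in df.iterrows()
    }
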