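"""Per-locus and concatenated sequence diversity statistics.

Implements the summary statistics of a typical MLST diversity table: counts of
alleles and polymorphic sites, synonymous/nonsynonymous SNP classification,
G+C content, nucleotide diversity (pi) and the Nei-Gojobori (1986) dN/dS
ratio with Jukes-Cantor correction.

Definitions
-----------
pi
    Average number of nucleotide differences per site between two randomly
    chosen sequences: ``sum_{i<j} d_ij / C(n,2) / L``.  No multiple-hit
    correction is applied (the plain average-pairwise definition).
sSNP / nSNP
    A polymorphic site is *nonsynonymous* if any pair of codons observed at
    its codon position encodes different amino acids attributable to that
    site, otherwise *synonymous*.  A site yielding both kinds of pair is
    counted once, as nonsynonymous (single-class assignment, so the two
    counts are disjoint).
dN/dS
    Nei-Gojobori counting: per sequence pair, fractional synonymous /
    nonsynonymous site counts averaged over the pair, differences averaged
    over equal-weight minimal mutational pathways that avoid stop codons,
    Jukes-Cantor correction of the per-site proportions, then averaged over
    all pairs before taking the ratio.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .mlst_core import (
    DEFAULT_LOCI,
    IsolateRecord,
    LocusDef,
    STOP_CODONS,
    concatenate,
)

__all__ = [
    "DnDsResult",
    "DiversitySummary",
    "polymorphic_sites",
    "classify_snp_sites",
    "gc_content",
    "nucleotide_diversity",
    "dn_ds",
    "diversity_table",
]

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_CODON_TABLE.forward_table)
for _stop in _CODON_TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"


def as_matrix(alignment: Sequence[str]) -> np.ndarray:
    """Stack equal-length sequences into an (n, L) uint8 matrix."""
    seqs = [s.upper() for s in alignment]
    if not seqs:
        raise ValueError("empty alignment")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
    return np.array([np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs])


def polymorphic_sites(alignment: Sequence[str]) -> tuple[int, list[int]]:
    """Count segregating sites; returns ``(count, 1-based positions)``.

    A site is polymorphic iff at least two distinct bases are observed there.
    """
    arr = as_matrix(alignment)
    poly = (arr != arr[0]).any(axis=0)
    positions = [int(j) + 1 for j in np.flatnonzero(poly)]
    return len(positions), positions


def gc_content(alignment: Sequence[str]) -> float:
    """Mean G+C content over all sequences, as a percentage."""
    arr = as_matrix(alignment)
    gc = np.isin(arr, np.frombuffer(b"GC", dtype=np.uint8)).sum()
    return 100.0 * float(gc) / arr.size


def nucleotide_diversity(alignment: Sequence[str]) -> float:
    """Nucleotide diversity pi = mean pairwise differences per site."""
    arr = as_matrix(alignment)
    n, L = arr.shape
    if n < 2:
        raise ValueError("pi requires at least two sequences")
    npairs = n * (n - 1) // 2
    mismatch_pairs = 0
    for base in b"ACGT":
        c = (arr == base).sum(axis=0)
        mismatch_pairs -= (c * (c - 1) // 2).sum()
    mismatch_pairs += L * npairs
    return float(mismatch_pairs) / npairs / L


def classify_snp_sites(
    alignment: Sequence[str], frame: int = 0
) -> tuple[int, int, dict[int, str]]:
    """Classify polymorphic sites as nonsynonymous or synonymous.

    Returns ``(n_nsnp, n_ssnp, classes)`` with ``classes`` mapping 1-based
    positions to ``"n"`` or ``"s"``.  Sites outside complete codons (before
    ``frame`` or in a trailing incomplete codon) are excluded.  Observed stop
    codons raise ``ValueError``.
    """
    arr = as_matrix(alignment)
    n, L = arr.shape
    _, positions = polymorphic_sites(alignment)
    classes: dict[int, str] = {}
    for pos1 in positions:
        site = pos1 - 1
        if site < frame:
            continue
        cstart = site - (site - frame) % 3
        if cstart + 3 > L:
            continue
        offset = site - cstart
        codons = {row[cstart : cstart + 3].tobytes().decode() for row in arr}
        for codon in codons:
            if codon in STOP_CODONS:
                raise ValueError(
                    f"internal stop codon {codon} observed at position {cstart + 1}"
                )
        nonsyn = False
        for c1, c2 in itertools.combinations(sorted(codons), 2):
            if c1[offset] == c2[offset]:
                continue
            # isolate the effect of this site in both codon backgrounds
            h1 = c1[:offset] + c2[offset] + c1[offset + 1 :]
            h2 = c2[:offset] + c1[offset] + c2[offset + 1 :]
            if (
                CODON_TO_AA.get(h1, "*") != CODON_TO_AA[c1]
                or CODON_TO_AA.get(h2, "*") != CODON_TO_AA[c2]
            ):
                nonsyn = True
                break
        classes[pos1] = "n" if nonsyn else "s"
    n_nsnp = sum(1 for v in classes.values() if v == "n")
    n_ssnp = sum(1 for v in classes.values() if v == "s")
    return n_nsnp, n_ssnp, classes


# ---------------------------------------------------------------------------
# Nei-Gojobori dN/dS
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _syn_fraction(codon: str) -> float:
    """Fractional count of synonymous sites in one sense codon.

    Each position contributes (number of synonymous single-base changes)/3;
    changes creating a stop codon count as nonsynonymous.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon}")
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in STOP_CODONS and CODON_TO_AA[alt] == aa:
                syn += 1
        s += syn / 3.0
    return s


@lru_cache(maxsize=None)
def _pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons.

    Averaged with equal weight over the minimal mutational pathways between
    the codons that avoid stop-codon intermediates; if every pathway passes
    through a stop, all pathways are used (with the steps classified by amino
    acid as usual).
    """
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diffs):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                through_stop = True
            aa_cur = CODON_TO_AA[cur]
            aa_nxt = CODON_TO_AA[nxt]
            if aa_cur == aa_nxt and aa_nxt != "*":
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        paths.append((sd, nd, through_stop))
    allowed = [(sd, nd) for sd, nd, ts in paths if not ts]
    if not allowed:
        allowed = [(sd, nd) for sd, nd, _ in paths]
    sd = sum(p[0] for p in allowed) / len(allowed)
    nd = sum(p[1] for p in allowed) / len(allowed)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    """Jukes-Cantor distance; NaN when the proportion is uncorrectable."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        return float("nan")
    return -0.75 * float(np.log1p(-4.0 * p / 3.0))


@dataclass(frozen=True)
class DnDsResult:
    """Nei-Gojobori substitution estimates averaged over sequence pairs.

    ``dn``/``ds`` carry the Jukes-Cantor correction; ``pn``/``ps`` are the raw
    per-site proportions.  ``dnds`` is ``dn/ds`` (0 when dn == 0, NaN when
    ds == 0 with dn > 0; ``ratio_defined`` is False in the degenerate cases).
    """

    n_sites: float
    s_sites: float
    nd: float
    sd: float
    pn: float
    ps: float
    dn: float
    ds: float
    dnds: float
    dnds_raw: float
    ratio_defined: bool


def _ratio(num: float, den: float) -> tuple[float, bool]:
    if num == 0.0:
        return 0.0, den > 0.0
    if den == 0.0 or np.isnan(den) or np.isnan(num):
        return float("nan"), False
    return num / den, True


def dn_ds(alignment: Sequence[str], frame: int = 0) -> DnDsResult:
    """Nei-Gojobori dN/dS over all sequence pairs of a codon alignment.

    Only complete codons (from ``frame``) are used; a trailing incomplete
    codon is ignored.  Site counts, differences and corrected distances are
    averaged over all pairs, and the ratio is taken on the averages.
    """
    arr = as_matrix(alignment)
    n, L = arr.shape
    ncod = (L - frame) // 3
    if ncod < 1:
        raise ValueError("alignment shorter than one codon")
    if n < 2:
        raise ValueError("dN/dS requires at least two sequences")
    codons = [
        [
            row[frame + 3 * k : frame + 3 * k + 3].tobytes().decode()
            for k in range(ncod)
        ]
        for row in arr
    ]
    for row in codons:
        for c in row:
            if c in STOP_CODONS:
                raise ValueError(f"internal stop codon {c} in alignment")
    s_per_seq = [sum(_syn_fraction(c) for c in row) for row in codons]

    tot = {k: 0.0 for k in ("S", "N", "Sd", "Nd", "ps", "pn", "ds", "dn")}
    npairs = 0
    for i, j in itertools.combinations(range(n), 2):
        S = 0.5 * (s_per_seq[i] + s_per_seq[j])
        N = 3.0 * ncod - S
        sd = nd = 0.0
        diff_cods = np.flatnonzero(
            (arr[i, frame : frame + 3 * ncod] != arr[j, frame : frame + 3 * ncod])
            .reshape(ncod, 3)
            .any(axis=1)
        )
        for k in diff_cods:
            dsd, dnd = _pair_differences(codons[i][k], codons[j][k])
            sd += dsd
            nd += dnd
        ps = sd / S if S > 0 else 0.0
        pn = nd / N if N > 0 else 0.0
        tot["S"] += S
        tot["N"] += N
        tot["Sd"] += sd
        tot["Nd"] += nd
        tot["ps"] += ps
        tot["pn"] += pn
        tot["ds"] += _jukes_cantor(ps)
        tot["dn"] += _jukes_cantor(pn)
        npairs += 1
    mean = {k: v / npairs for k, v in tot.items()}
    dnds, defined = _ratio(mean["dn"], mean["ds"])
    dnds_raw, _ = _ratio(mean["pn"], mean["ps"])
    return DnDsResult(
        n_sites=mean["N"],
        s_sites=mean["S"],
        nd=mean["Nd"],
        sd=mean["Sd"],
        pn=mean["pn"],
        ps=mean["ps"],
        dn=mean["dn"],
        ds=mean["ds"],
        dnds=dnds,
        dnds_raw=dnds_raw,
        ratio_defined=defined,
    )


# ---------------------------------------------------------------------------
# Table assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiversitySummary:
    """One diversity-table row (a locus or the concatenation)."""

    locus: str
    size_bp: int
    n_seqs: int
    n_alleles: int
    n_polymorphic: int
    n_nsnp: int
    n_ssnp: int
    gc_percent: float
    pi: float
    dn: float
    ds: float
    dnds: float


def _summary_row(
    name: str,
    seqs: list[str],
    frame: int,
) -> DiversitySummary:
    unique = list(dict.fromkeys(seqs))
    n_poly, _ = polymorphic_sites(unique)
    if len(unique) >= 2:
        n_nsnp, n_ssnp, _ = classify_snp_sites(unique, frame)
        sub = dn_ds(unique, frame)
        dn, ds, dnds = sub.dn, sub.ds, sub.dnds
    else:
        n_nsnp = n_ssnp = 0
        dn = ds = dnds = 0.0
    pi = nucleotide_diversity(seqs) if len(seqs) >= 2 else float("nan")
    return DiversitySummary(
        locus=name,
        size_bp=len(seqs[0]),
        n_seqs=len(seqs),
        n_alleles=len(unique),
        n_polymorphic=n_poly,
        n_nsnp=n_nsnp,
        n_ssnp=n_ssnp,
        gc_percent=gc_content(seqs),
        pi=pi,
        dn=dn,
        ds=ds,
        dnds=dnds,
    )


def diversity_table(
    records: Iterable[IsolateRecord],
    loci: Sequence[LocusDef] = DEFAULT_LOCI,
    subset: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Diversity-table statistics per locus plus the concatenated row.

    ``subset`` optionally restricts the computation to the named isolates
    (e.g. one subspecies).  Allele counts (``n_alleles``) and the
    substitution statistics are computed on the distinct sequences observed
    in the subset; pi is computed over isolates.
    """
    records = list(records)
    if subset is not None:
        wanted = set(subset)
        records = [r for r in records if r.isolate_id in wanted]
    if not records:
        raise ValueError("empty isolate subset")
    panel = sorted(loci, key=lambda l: l.order_index)
    rows = []
    for ldef in panel:
        seqs = [r.sequences[ldef.name].upper() for r in records]
        rows.append(_summary_row(ldef.name, seqs, ldef.frame_offset))
    concat = [concatenate(r, loci=panel) for r in records]
    # locus boundaries break codon structure only if lengths are not multiples
    # of 3, so the concatenated row classifies within loci and sums.
    unique_concat = list(dict.fromkeys(concat))
    n_poly = sum(r.n_polymorphic for r in rows)
    n_nsnp = sum(r.n_nsnp for r in rows)
    n_ssnp = sum(r.n_ssnp for r in rows)
    if len(records) >= 2:
        pi_concat = nucleotide_diversity(concat)
    else:
        pi_concat = float("nan")
    # dN/dS of the concatenation: NG86 totals accumulated across loci over the
    # distinct concatenated sequences, honouring each locus reading frame.
    if len(unique_concat) >= 2:
        offsets = np.cumsum([0] + [l.expected_length for l in panel])
        S = N = Sd = Nd = 0.0
        for ldef, off in zip(panel, offsets[:-1]):
            segs = [s[off : off + ldef.expected_length] for s in unique_concat]
            sub = dn_ds(segs, ldef.frame_offset)
            S += sub.s_sites
            N += sub.n_sites
            Sd += sub.sd
            Nd += sub.nd
        ps = Sd / S if S else 0.0
        pn = Nd / N if N else 0.0
        dn_c, ds_c = _jukes_cantor(pn), _jukes_cantor(ps)
        dnds_c, _ = _ratio(dn_c, ds_c)
    else:
        dn_c = ds_c = dnds_c = 0.0
    rows.append(
        DiversitySummary(
            locus="concatenated",
            size_bp=len(concat[0]),
            n_seqs=len(records),
            n_alleles=len(unique_concat),
            n_polymorphic=n_poly,
            n_nsnp=n_nsnp,
            n_ssnp=n_ssnp,
            gc_percent=gc_content(concat),
            pi=pi_concat,
            dn=dn_c,
            ds=ds_c,
            dnds=dnds_c,
        )
    )
    return pd.DataFrame([r.__dict__ for r in rows])
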