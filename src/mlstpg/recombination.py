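"""Recombination detection: the PHI test and the standardized index of association.

PHI (pairwise homoplasy index)
    Works on a nucleotide alignment.  For every pair of nearby
    parsimony-informative sites the *refined incompatibility* score counts the
    minimum number of extra mutations (homoplasies) needed to fit both sites
    on one tree: with the observed character states as vertices of a bipartite
    "partition intersection" graph and the observed joint states as edges, the
    score is ``edges - vertices + components`` (0 iff the pair is compatible).
    PHI is the mean score over informative-site pairs that are close together;
    under clonal descent all sites share one genealogy, so nearby pairs are no
    more compatible than distant ones and site order is exchangeable.
    Recombination makes nearby sites *more* compatible than distant ones,
    pushing the observed statistic below its site-order permutation null; the
    p-value is the fraction of permutations with PHI <= observed (with the
    (r+1)/(N+1) correction).

I_A^S (standardized index of association)
    Works on allele profiles.  With ``d`` the number of loci at which a pair
    of profiles differs, linkage equilibrium makes the loci independent and
    Var(d) equal to ``V_e = sum_j h_j (1 - h_j)`` with ``h_j`` the unbiased
    allelic mismatch probability at locus *j*.  Clonality inflates the
    observed variance ``V_D``.  ``I_A^S = (V_D / V_e - 1) / (l - 1)`` is ~0
    under free recombination and positive under linkage disequilibrium; its
    p-value comes from Monte-Carlo resampling with independent within-locus
    allele permutations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.spatial.distance import pdist

from .mlst_core import STProfile
from .diversity import as_matrix

__all__ = [
    "PhiResult",
    "IAResult",
    "informative_sites",
    "incompatibility_matrix",
    "phi_test",
    "pairwise_mismatch_distribution",
    "ia_standardized",
]


def informative_sites(alignment: Sequence[str]) -> list[int]:
    """Parsimony-informative sites: >=2 states each carried by >=2 sequences.

    Returns 0-based column indices in alignment order.
    """
    arr = as_matrix(alignment)
    multi = np.zeros(arr.shape[1], dtype=np.int16)
    for base in b"ACGT":
        multi += (arr == base).sum(axis=0) >= 2
    return [int(j) for j in np.flatnonzero(multi >= 2)]


def _pair_score(col_a: np.ndarray, col_b: np.ndarray) -> int:
    """Refined incompatibility of two sites: edges - vertices + components."""
    pairs = set(zip(col_a.tolist(), col_b.tolist()))
    states_a = {p[0] for p in pairs}
    states_b = {p[1] for p in pairs}
    e = len(pairs)
    v = len(states_a) + len(states_b)
    # connected components of the bipartite graph via union-find
    parent: dict[tuple[int, int], tuple[int, int]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in states_a:
        parent[(0, a)] = (0, a)
    for b in states_b:
        parent[(1, b)] = (1, b)
    for a, b in pairs:
        ra, rb = find((0, a)), find((1, b))
        if ra != rb:
            parent[ra] = rb
    c = len({find(x) for x in parent})
    return e - v + c


_SCORE_LUT: Optional[np.ndarray] = None


def _score_lut() -> np.ndarray:
    """Refined-incompatibility score for every 16-bit joint-state mask.

    With four DNA states per site, the joint states observed at a site pair
    form a subset of the 4x4 grid, encodable as a 16-bit mask (bit
    ``4*a + b`` set iff the combination ``(a, b)`` occurs).  The score
    ``edges - vertices + components`` of the bipartite state graph depends
    only on that mask, so all 65,536 values are tabulated once.
    """
    global _SCORE_LUT
    if _SCORE_LUT is not None:
        return _SCORE_LUT
    lut = np.zeros(1 << 16, dtype=np.int16)
    for mask in range(1, 1 << 16):
        edges = [(c >> 2, c & 3) for c in range(16) if mask >> c & 1]
        states_a = {a for a, _ in edges}
        states_b = {b for _, b in edges}
        parent = list(range(8))  # vertices 0-3: a states, 4-7: b states

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in edges:
            ra, rb = find(a), find(b + 4)
            if ra != rb:
                parent[ra] = rb
        used = [find(a) for a in states_a] + [find(b + 4) for b in states_b]
        c = len(set(used))
        v = len(states_a) + len(states_b)
        lut[mask] = len(edges) - v + c
    _SCORE_LUT = lut
    return lut


_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


def incompatibility_matrix(alignment: Sequence[str]) -> tuple[np.ndarray, list[int]]:
    """Refined-incompatibility scores for all informative-site pairs.

    Returns ``(matrix, sites)`` where ``matrix[i, j]`` scores informative
    sites ``sites[i]`` and ``sites[j]``.
    """
    arr = as_matrix(alignment)
    sites = informative_sites(alignment)
    s = len(sites)
    if s == 0:
        return np.zeros((0, 0), dtype=np.int16), sites
    codes = _BASE_CODE[arr[:, sites]]
    if (codes < 0).any():
        raise ValueError("alignment contains non-ACGT characters")
    codes = codes.astype(np.int32)
    lut = _score_lut()
    m = np.zeros((s, s), dtype=np.int16)
    # chunk the (n, s, s) joint-state tensor to bound memory
    chunk = max(1, int(4e6 // (codes.shape[0] * s + 1)))
    for start in range(0, s, chunk):
        stop = min(start + chunk, s)
        joint = (codes[:, start:stop, None] << 2) | codes[:, None, :]
        masks = np.bitwise_or.reduce(1 << joint, axis=0)
        m[start:stop, :] = lut[masks]
    np.fill_diagonal(m, 0)
    return m, sites


@dataclass(frozen=True)
class PhiResult:
    """Outcome of the PHI permutation test."""

    phi_statistic: float
    p_value: float
    n_informative: int
    window: int
    n_permutations: int
    computable: bool = True


def _window_rank(window: int, n_informative: int, aln_length: int) -> int:
    """Informative-site rank distance corresponding to ``window`` alignment sites.

    The window is specified in alignment sites; pairing happens on the
    informative-site subalignment, so the window is converted to a k-nearest
    rank distance using the informative-site density.
    """
    k = int(round(window * n_informative / aln_length))
    return max(1, min(k, n_informative - 1))


def _phi_stat(m: np.ndarray, order: np.ndarray, k: int) -> float:
    total = 0.0
    npairs = 0
    for d in range(1, k + 1):
        if d >= len(order):
            break
        total += m[order[:-d], order[d:]].sum()
        npairs += len(order) - d
    return total / npairs


def phi_test(
    alignment: Sequence[str],
    window: int = 100,
    permutations: int = 1000,
    seed: Optional[int] = None,
) -> PhiResult:
    """PHI recombination test on a gap-free nucleotide alignment.

    ``window`` is in alignment sites (converted to a rank distance on the
    informative-site subalignment); significance comes from ``permutations``
    random site-order permutations and is deterministic given ``seed``.
    Fewer than 2 informative sites make the statistic uncomputable: the
    result is flagged and p = 1.
    """
    alignment = list(alignment)
    if len(alignment) < 4:
        raise ValueError("the PHI test requires at least 4 sequences")
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    m, sites = incompatibility_matrix(alignment)
    s = len(sites)
    if s < 2:
        return PhiResult(
            phi_statistic=float("nan"),
            p_value=1.0,
            n_informative=s,
            window=window,
            n_permutations=0,
            computable=False,
        )
    k = _window_rank(window, s, len(alignment[0]))
    identity = np.arange(s)
    observed = _phi_stat(m, identity, k)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(s)
        if _phi_stat(m, perm, k) <= observed:
            hits += 1
    p = (hits + 1) / (permutations + 1)
    return PhiResult(
        phi_statistic=observed,
        p_value=p,
        n_informative=s,
        window=window,
        n_permutations=permutations,
    )


# ---------------------------------------------------------------------------
# Standardized index of association
# ---------------------------------------------------------------------------

def _profile_matrix(profiles: Iterable[Union[STProfile, Sequence[int]]]) -> np.ndarray:
    rows = [
        tuple(p.alleles) if isinstance(p, STProfile) else tuple(p)
        for p in profiles
    ]
    if not rows:
        raise ValueError("no profiles")
    arities = {len(r) for r in rows}
    if len(arities) != 1:
        raise ValueError(f"ragged profiles: arities {sorted(arities)}")
    return np.asarray(rows, dtype=np.int64)


def pairwise_mismatch_distribution(
    profiles: Iterable[Union[STProfile, Sequence[int]]],
) -> np.ndarray:
    """Number of mismatching loci for every profile pair (length C(n,2))."""
    x = _profile_matrix(profiles)
    if x.shape[0] < 2:
        raise ValueError("need at least two profiles")
    return np.rint(pdist(x, metric="hamming") * x.shape[1]).astype(np.int64)


@dataclass(frozen=True)
class IAResult:
    """Standardized index of association and its Monte-Carlo significance."""

    ia_s: float
    v_d: float
    v_e: float
    p_value: Optional[float]
    n_loci: int
    n_profiles: int
    n_resamples: int


def _ia_from_matrix(x: np.ndarray) -> tuple[float, float, float]:
    n, l = x.shape
    d = np.rint(pdist(x, metric="hamming") * l)
    v_d = float(d.var())  # population variance of the C(n,2) mismatch counts
    v_e = 0.0
    for j in range(l):
        _, counts = np.unique(x[:, j], return_counts=True)
        p = counts / n
        h = (n / (n - 1)) * (1.0 - float((p**2).sum()))
        v_e += h * (1.0 - h)
    if v_e == 0.0:
        raise ValueError("all loci monomorphic: V_e = 0, I_A^S undefined")
    ia = (v_d / v_e - 1.0) / (l - 1)
    return ia, v_d, v_e


def ia_standardized(
    profiles: Iterable[Union[STProfile, Sequence[int]]],
    resamples: int = 1000,
    seed: Optional[int] = None,
) -> IAResult:
    """Standardized index of association over allele profiles.

    ``V_D`` is the variance of the pairwise mismatch distribution, ``V_e``
    the linkage-equilibrium expectation built from unbiased per-locus
    mismatch probabilities.  The p-value is the Monte-Carlo fraction of
    datasets (independent within-locus allele permutations) with I_A^S at
    least as large as observed, with the (r+1)/(N+1) correction;
    ``resamples=0`` skips it.  Deterministic given ``seed``.
    """
    x = _profile_matrix(profiles)
    n, l = x.shape
    if n < 3:
        raise ValueError("I_A^S requires at least 3 profiles")
    if l < 2:
        raise ValueError("I_A^S requires at least 2 loci")
    ia, v_d, v_e = _ia_from_matrix(x)
    p_value: Optional[float] = None
    if resamples > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        shuffled = x.copy()
        for _ in range(resamples):
            for j in range(l):
                shuffled[:, j] = rng.permutation(x[:, j])
            ia_null, _, _ = _ia_from_matrix(shuffled)
            if ia_null >= ia:
                hits += 1
        p_value = (hits + 1) / (resamples + 1)
    return IAResult(
        ia_s=ia,
        v_d=v_d,
        v_e=v_e,
        p_value=p_value,
        n_loci=l,
        n_profiles=n,
        n_resamples=resamples,
    )
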