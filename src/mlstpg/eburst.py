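"""eBURST-style clonal-complex clustering of sequence types.

Sequence types (STs) are linked when their allele profiles differ at exactly
one locus (single-locus variants, SLVs).  Connected components of the SLV
graph are the clonal groups: a *clonal complex* (CC) has at least three STs,
a *doubleton* exactly two, a *singleton* one.  Within each CC the *founder*
is the ST with the most SLVs — presumed the ancestral genotype from which the
complex radiated — with a deterministic tie-break chain (double-locus-variant
count, then isolate count, then smaller ST number) replacing eBURST's
bootstrap support.  *Subgroup founders* are non-founder members that have
diversified in their own right: at least two SLV links besides their link to
the founder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import networkx as nx

from .mlst_core import STProfile

__all__ = [
    "profile_distance",
    "build_slv_graph",
    "cluster_groups",
    "predict_founders",
    "export_snapshot",
    "ClonalGroup",
]


def profile_distance(a: Sequence[int], b: Sequence[int]) -> int:
    """Number of loci at which two allele profiles differ (0..l)."""
    if len(a) != len(b):
        raise ValueError(f"profile arity mismatch: {len(a)} vs {len(b)}")
    return sum(1 for x, y in zip(a, b) if x != y)


def build_slv_graph(
    profiles: Iterable[STProfile],
    isolate_counts: Optional[Mapping[int, int]] = None,
) -> nx.Graph:
    """Build the single-locus-variant graph over distinct STs.

    Nodes are ST numbers (weighted by isolate counts, default 1); an edge
    joins two STs iff their profiles differ at exactly one locus.
    """
    profiles = list(profiles)
    ids = [p.st_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ST ids in profile list")
    counts = isolate_counts or {}
    g = nx.Graph()
    for p in profiles:
        g.add_node(p.st_id, n_isolates=int(counts.get(p.st_id, 1)), profile=p.alleles)
    for i, p in enumerate(profiles):
        for q in profiles[i + 1 :]:
            if profile_distance(p.alleles, q.alleles) == 1:
                g.add_edge(p.st_id, q.st_id)
    return g


@dataclass
class ClonalGroup:
    """One eBURST group: clonal complex, doubleton, or singleton."""

    group_id: int
    member_sts: frozenset[int]
    group_type: str  # "CC" | "doubleton" | "singleton"
    n_isolates: int
    founder: Optional[int] = None
    subgroup_founders: frozenset[int] = field(default_factory=frozenset)


def _group_type(size: int) -> str:
    if size == 1:
        return "singleton"
    if size == 2:
        return "doubleton"
    return "CC"


def _dlv_count(graph: nx.Graph, st: int) -> int:
    """Double-locus variants of ``st`` among all STs in the graph."""
    mine = graph.nodes[st]["profile"]
    return sum(
        1
        for other, data in graph.nodes(data=True)
        if other != st and profile_distance(mine, data["profile"]) == 2
    )


def predict_founders(
    members: Iterable[int], graph: nx.Graph
) -> tuple[int, frozenset[int]]:
    """Predict the founder and subgroup founders of one clonal complex.

    The founder maximises SLV degree; ties break by (i) larger DLV count,
    (ii) larger isolate count, (iii) smaller ST number.  Subgroup founders
    are non-founder members whose SLV degree, not counting a direct link to
    the founder, is at least 2.  Raises ``ValueError`` for groups smaller
    than a CC (their founder is undefined).
    """
    members = sorted(members)
    if len(members) < 3:
        raise ValueError("founders are only defined for clonal complexes (>=3 STs)")

    def key(st: int):
        return (
            graph.degree(st),
            _dlv_count(graph, st),
            graph.nodes[st]["n_isolates"],
            -st,
        )

    founder = max(members, key=key)
    subgroup = frozenset(
        st
        for st in members
        if st != founder
        and graph.degree(st) - (1 if graph.has_edge(st, founder) else 0) >= 2
    )
    return founder, subgroup


def cluster_groups(graph: nx.Graph) -> list[ClonalGroup]:
    """Partition the SLV graph into clonal groups (connected components).

    Groups are numbered by decreasing isolate count (then decreasing ST
    count, then smallest member ST) so that CC1 is the largest complex.
    """
    comps = [sorted(c) for c in nx.connected_components(graph)]

    def weight(c: list[int]) -> int:
        return sum(graph.nodes[st]["n_isolates"] for st in c)

    comps.sort(key=lambda c: (-weight(c), -len(c), c[0]))
    groups = []
    for gid, comp in enumerate(comps, start=1):
        gtype = _group_type(len(comp))
        founder = None
        subgroup: frozenset[int] = frozenset()
        if gtype == "CC":
            founder, subgroup = predict_founders(comp, graph)
        groups.append(
            ClonalGroup(
                group_id=gid,
                member_sts=frozenset(comp),
                group_type=gtype,
                n_isolates=weight(comp),
                founder=founder,
                subgroup_founders=subgroup,
            )
        )
    return groups


def export_snapshot(
    groups: Sequence[ClonalGroup],
    graph: nx.Graph,
    basepath: Union[str, Path],
) -> tuple[Path, Path]:
    """Write the population snapshot as GraphML and DOT files.

    Node attributes carry the isolate count (dot size in eBURST diagrams),
    the group id/type and founder flags.  Returns the two paths written.
    """
    basepath = Path(basepath)
    basepath.parent.mkdir(parents=True, exist_ok=True)
    out = graph.copy()
    for grp in groups:
        for st in grp.member_sts:
            out.nodes[st]["group"] = grp.group_id
            out.nodes[st]["group_type"] = grp.group_type
            out.nodes[st]["is_founder"] = st == grp.founder
            out.nodes[st]["is_subgroup_founder"] = st in grp.subgroup_founders
    for _, data in out.nodes(data=True):
        data.pop("profile", None)  # tuples are not GraphML-serialisable
    graphml = basepath.with_suffix(".graphml")
    nx.write_graphml(out, graphml)
    dot = basepath.with_suffix(".dot")
    with open(dot, "w") as fh:
        fh.write("graph snapshot {\n")
        for node, data in sorted(out.nodes(data=True)):
            attrs = [
                f'width="{0.2 + 0.05 * data["n_isolates"]:.2f}"',
                f'n_isolates="{data["n_isolates"]}"',
                f'group="{data.get("group", "")}"',
            ]
            if data.get("is_founder"):
                attrs.append('founder="true"')
            fh.write(f'  "ST{node}" [{", ".join(attrs)}];\n')
        for a, b in sorted(out.edges()):
            fh.write(f'  "ST{a}" -- "ST{b}";\n')
        fh.write("}\n")
    return dot, graphml
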