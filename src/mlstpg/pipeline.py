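"""End-to-end orchestration: typing, diversity, eBURST, recombination, classification.

The pipeline mirrors a complete MLST population-genetics analysis: isolates
are typed against the locus panel, the diversity table is assembled per locus
and for the concatenation, STs are clustered into clonal groups, linkage and
mosaicism statistics are computed (I_A^S on profiles, PHI on the concatenated
alignment), and — when a reference panel is supplied — isolates are assigned
to subspecies.  Every numeric output cell is produced by the corresponding
module function; the pipeline only routes data and writes files.

All stochastic stages (PHI permutations, I_A^S resampling) require an
explicit seed; a structured JSON run log records parameters, seeds and stage
outcomes for reproducibility.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from . import __version__
from .mlst_core import (
    DEFAULT_LOCI,
    IsolateRecord,
    LocusDef,
    STProfile,
    TypingResult,
    concatenate,
    load_isolates,
    read_metadata,
    read_profiles,
    type_isolates,
    write_profiles,
)
from .diversity import diversity_table
from .eburst import build_slv_graph, cluster_groups, export_snapshot
from .recombination import ia_standardized, phi_test
from .subspecies import ReferencePanel, classify_isolate

logger = logging.getLogger("mlstpg")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "groups_table", "recombination_table"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``fasta_by_locus`` (sequence input) or ``profiles_path``
    (profile-table input, sequence stages skipped) must be provided.
    """

    outdir: Union[str, Path]
    fasta_by_locus: Optional[Mapping[str, Union[str, Path]]] = None
    profiles_path: Optional[Union[str, Path]] = None
    loci: Sequence[LocusDef] = DEFAULT_LOCI
    metadata_path: Optional[Union[str, Path]] = None
    subset: Optional[Sequence[str]] = None
    membership_path: Optional[Union[str, Path]] = None  # ST -> lineage labels
    reference_panel: Optional[ReferencePanel] = None
    seed: Optional[int] = None
    phi_window: int = 100
    phi_permutations: int = 1000
    ia_resamples: int = 1000

    def __post_init__(self) -> None:
        if (self.fasta_by_locus is None) == (self.profiles_path is None):
            raise ValueError(
                "provide exactly one of fasta_by_locus or profiles_path"
            )
        if self.seed is None and (self.phi_permutations or self.ia_resamples):
            raise ValueError("a seed is required for the stochastic stages")


def groups_table(groups, typing_sts: Optional[Mapping[int, int]] = None) -> pd.DataFrame:
    """Tabulate clonal groups: one row per ST with group membership and flags."""
    rows = []
    for grp in groups:
        for st in sorted(grp.member_sts):
            rows.append(
                {
                    "ST": st,
                    "group": grp.group_id,
                    "group_type": grp.group_type,
                    "is_founder": st == grp.founder,
                    "is_subgroup_founder": st in grp.subgroup_founders,
                    "n_isolates": (typing_sts or {}).get(st, 1),
                }
            )
    return pd.DataFrame(rows).sort_values("ST").reset_index(drop=True)


def _read_membership(path: Union[str, Path]) -> dict[int, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    st_col, lab_col = df.columns[:2]
    return {int(r[st_col]): str(r[lab_col]) for _, r in df.iterrows()}


def recombination_table(
    registry: Sequence[STProfile],
    membership: Optional[Mapping[int, str]],
    alignments: Optional[Mapping[str, list[str]]],
    seed: int,
    phi_window: int = 100,
    phi_permutations: int = 1000,
    ia_resamples: int = 1000,
) -> pd.DataFrame:
    """PHI and I_A^S rows for the whole ST collection and per lineage.

    ``alignments`` (population label -> concatenated unique-ST sequences) is
    optional; without it the PHI columns are left empty.  I_A^S is computed
    on unique ST profiles, as in standard linkage analyses of MLST data.
    """
    by_label: dict[str, list[STProfile]] = {"All": list(registry)}
    if membership:
        for prof in registry:
            label = membership.get(prof.st_id)
            if label is not None:
                by_label.setdefault(label, []).append(prof)
    rows = []
    for label, profs in by_label.items():
        row: dict[str, object] = {
            "population": label,
            "n_sts": len(profs),
        }
        aln = (alignments or {}).get(label)
        if aln is not None and len(aln) >= 4:
            phi = phi_test(
                aln, window=phi_window, permutations=phi_permutations, seed=seed
            )
            row["phi_p"] = phi.p_value
            row["phi_informative_sites"] = phi.n_informative
        else:
            row["phi_p"] = float("nan")
            row["phi_informative_sites"] = 0
        try:
            ia = ia_standardized(profs, resamples=ia_resamples, seed=seed)
            row["ia_s"] = ia.ia_s
            row["ia_p"] = ia.p_value
        except ValueError:
            row["ia_s"] = float("nan")
            row["ia_p"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every applicable stage and write the report bundle.

    Returns a mapping of artifact names to paths.  Stage failures raise
    :class:`PipelineError` naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    log: dict[str, object] = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "phi_window": config.phi_window,
            "phi_permutations": config.phi_permutations,
            "ia_resamples": config.ia_resamples,
        },
        "stages": [],
    }

    records: Optional[list[IsolateRecord]] = None
    typing: Optional[TypingResult] = None
    if config.fasta_by_locus is not None:
        try:
            meta = (
                read_metadata(config.metadata_path)
                if config.metadata_path
                else None
            )
            records = load_isolates(config.fasta_by_locus, meta)
            if config.subset:
                wanted = set(config.subset)
                records = [r for r in records if r.isolate_id in wanted]
            typing = type_isolates(records, config.loci)
        except Exception as exc:
            raise PipelineError("type", str(exc)) from exc
        registry = typing.registry
        profile_path = outdir / "profiles.tsv"
        write_profiles(registry, profile_path, config.loci)
        pd.DataFrame(
            sorted(typing.st_of.items()), columns=["isolate", "ST"]
        ).to_csv(outdir / "st_assignments.tsv", sep="\t", index=False)
        artifacts["profiles"] = profile_path
        artifacts["st_assignments"] = outdir / "st_assignments.tsv"
        log["stages"].append({"stage": "type", "n_isolates": len(records),
                              "n_sts": typing.n_sts})
    else:
        try:
            registry = read_profiles(config.profiles_path, config.loci)
        except Exception as exc:
            raise PipelineError("read_profiles", str(exc)) from exc
        log["stages"].append({"stage": "read_profiles", "n_sts": len(registry)})

    if records is not None:
        try:
            div = diversity_table(records, config.loci)
        except Exception as exc:
            raise PipelineError("diversity", str(exc)) from exc
        div_path = outdir / "diversity.tsv"
        div.to_csv(div_path, sep="\t", index=False, float_format="%.6g")
        artifacts["diversity"] = div_path
        log["stages"].append({"stage": "diversity", "rows": len(div)})

    try:
        counts = typing.isolate_counts() if typing is not None else None
        graph = build_slv_graph(registry, counts)
        groups = cluster_groups(graph)
        gt = groups_table(groups, counts)
    except Exception as exc:
        raise PipelineError("eburst", str(exc)) from exc
    groups_path = outdir / "groups.tsv"
    gt.to_csv(groups_path, sep="\t", index=False)
    dot, graphml = export_snapshot(groups, graph, outdir / "snapshot")
    artifacts["groups"] = groups_path
    artifacts["snapshot_dot"] = dot
    artifacts["snapshot_graphml"] = graphml
    log["stages"].append(
        {
            "stage": "eburst",
            "n_ccs": sum(1 for g in groups if g.group_type == "CC"),
            "n_doubletons": sum(1 for g in groups if g.group_type == "doubleton"),
            "n_singletons": sum(1 for g in groups if g.group_type == "singleton"),
        }
    )

    try:
        membership = (
            _read_membership(config.membership_path)
            if config.membership_path
            else None
        )
        alignments = None
        if records is not None:
            st_to_seq: dict[int, str] = {}
            for rec in records:
                st = typing.st_of[rec.isolate_id]
                st_to_seq.setdefault(st, concatenate(rec, loci=config.loci))
            alignments = {"All": [st_to_seq[p.st_id] for p in registry
                                  if p.st_id in st_to_seq]}
            if membership:
                for prof in registry:
                    label = membership.get(prof.st_id)
                    if label is not None and prof.st_id in st_to_seq:
                        alignments.setdefault(label, []).append(
                            st_to_seq[prof.st_id]
                        )
        rec_table = recombination_table(
            registry,
            membership,
            alignments,
            seed=config.seed,
            phi_window=config.phi_window,
            phi_permutations=config.phi_permutations,
            ia_resamples=config.ia_resamples,
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("recombination", str(exc)) from exc
    rec_path = outdir / "recombination.tsv"
    rec_table.to_csv(rec_path, sep="\t", index=False, float_format="%.6g")
    artifacts["recombination"] = rec_path
    log["stages"].append({"stage": "recombination", "rows": len(rec_table)})

    if config.reference_panel is not None and records is not None:
        try:
            results = [
                classify_isolate(r, config.reference_panel) for r in records
            ]
        except Exception as exc:
            raise PipelineError("classify", str(exc)) from exc
        cls = pd.DataFrame(
            [
                {
                    "isolate": r.isolate_id,
                    "final_call": r.final_call,
                    "mosaic": r.mosaic_flag,
                    **{f"vote_{k}": v for k, v in sorted(r.votes.items())},
                }
                for r in results
            ]
        )
        cls_path = outdir / "classification.tsv"
        cls.to_csv(cls_path, sep="\t", index=False)
        artifacts["classification"] = cls_path
        log["stages"].append({"stage": "classify", "n_isolates": len(results)})

    log_path = outdir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2))
    artifacts["run_log"] = log_path
    logger.info("pipeline complete: %d artifacts in %s", len(artifacts), outdir)
    return artifacts
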