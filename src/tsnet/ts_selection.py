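"""Tumor-suppressor gene-set definition.

A gene qualifies when it is differentially expressed at some stage (under
the chosen direction rule) and appears in at least one candidate list; a
user-supplied denylist models any downstream manual exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .expression_io import GeneList

logger = logging.getLogger(__name__)

DIRECTION_RULES = ("down_only", "any_direction")


@dataclass
class TSGeneSet:
    members: list[str]
    provenance: dict[str, list[str]] = field(default_factory=dict)
    stage_found: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.members)


def define_ts_genes(
    de_by_stage: Mapping[object, tuple[GeneList, GeneList]],
    list1: GeneList,
    list2: GeneList,
    list3: GeneList,
    denylist: GeneList | None = None,
    direction_rule: str = "down_only",
) -> TSGeneSet:
    """Intersect per-stage DE genes with the candidate lists, minus denylist.

    ``de_by_stage`` maps each stage to its (down, up) significant gene lists;
    ``direction_rule`` is ``down_only`` (default) or ``any_direction``.
    Members come out in deterministic lexicographic order.
    """
    if direction_rule not in DIRECTION_RULES:
        raise ValueError(f"direction_rule must be one of {DIRECTION_RULES}")
    deny = denylist.members if denylist is not None else set()

    de_genes: set[str] = set()
    stage_found: dict[str, set[str]] = {}
    for stage, (down, up) in de_by_stage.items():
        genes = set(down.members)
        if direction_rule == "any_direction":
            genes |= up.members
        de_genes |= genes
        for g in genes:
            stage_found.setdefault(g, set()).add(str(stage))

    candidates = list1.members | list2.members | list3.members
    members = sorted((de_genes & candidates) - deny)
    if not members:
        logger.warning("TS gene set is empty")

    provenance = {
        g: [lst.name for lst in (list1, list2, list3) if g in lst.members]
        for g in members
    }
    stages = {g: sorted(stage_found[g]) for g in members}
    return TSGeneSet(members, provenance, stages)


def write_ts_table(ts: TSGeneSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tprovenance\tstages\n")
        for g in ts.members:
            fh.write(f"{g}\t{';'.join(ts.provenance.get(g, []))}\t{','.join(ts.stage_found.get(g, []))}\n")
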