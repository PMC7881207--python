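"""Ranked cumulative score curves and the largest plus/minus gap."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

KINDS = ("s_plus", "s_minus", "n_plus", "n_minus")


@dataclass
class AccumulationCurve:
    gene_order: list[str]
    scores: np.ndarray
    cumulative: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        if not (len(self.gene_order) == self.scores.size == self.cumulative.size):
            raise ValueError("curve fields must have equal lengths")

    @property
    def final(self) -> float:
        return float(self.cumulative[-1])


def accumulate(scores: Mapping[str, float], kind: str = "s_plus") -> AccumulationCurve:
    """Sort scores ascending (ties broken by gene id) and take running sums."""
    if not scores:
        raise ValueError("cannot accumulate an empty score map")
    items = sorted(scores.items(), key=lambda kv: (kv[1], kv[0]))
    genes = [g for g, _ in items]
    vals = np.array([v for _, v in items], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("scores must be finite")
    return AccumulationCurve(genes, vals, np.cumsum(vals), kind)


def largest_gap(plus: AccumulationCurve, minus: AccumulationCurve) -> float:
    """Maximum over ranks of (plus cumulative - minus cumulative)."""
    if len(plus.gene_order) != len(minus.gene_order):
        raise ValueError("curves must have equal lengths")
    return float(np.max(plus.cumulative - minus.cumulative))


def write_curve(curve: AccumulationCurve, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tgene\tscore\tcumulative\n")
        for i, (g, s, c) in enumerate(zip(curve.gene_order, curve.scores, curve.cumulative), start=1):
            fh.write(f"{i}\t{g}\t{format(s, '.17g')}\t{format(c, '.17g')}\n")
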