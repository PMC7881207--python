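"""Binary TS-DE correlation networks and shared-node N-scores.

A network matrix G marks an edge between TS gene i and DE gene j.  Four
modes exist: ``pos_sig`` (r > T), ``pos_any`` (r > 0), ``neg_sig``
(r < -T) and ``neg_any`` (r < 0).  Inequalities are deliberately strict —
the S-score formulas in :mod:`tsnet.correlation_scores` use inclusive
bounds, and the two conventions are kept as-is rather than harmonized; they
differ only when an r lands exactly on the threshold.

For TS gene i, the shared-node count is the number of DE genes connected to
i and to at least one other TS gene.  N-scores divide the count in the
thresholded network by the count in the sign-only network:

    n_plus  = c_plus  / c_plus0     (pos_sig over pos_any)
    n_minus = c_minus / c_minus0    (neg_sig over neg_any)

with 0 when the denominator is 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .correlation_scores import CorrelationMatrix, _check_T

logger = logging.getLogger(__name__)

MODES = ("pos_sig", "pos_any", "neg_sig", "neg_any")


@dataclass
class NetworkMatrix:
    ts_ids: list[str]
    de_ids: list[str]
    g: np.ndarray
    mode: str
    T: float | None = None

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=np.uint8)
        if self.g.shape != (len(self.ts_ids), len(self.de_ids)):
            raise ValueError("network matrix shape mismatch")
        if not np.isin(self.g, (0, 1)).all():
            raise ValueError("network matrix entries must be 0/1")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


@dataclass
class NScoreRow:
    gene: str
    n_plus: float
    n_minus: float
    c_plus: int
    c_plus0: int
    c_minus: int
    c_minus0: int


def binarize(R: CorrelationMatrix, T: float | None, mode: str) -> NetworkMatrix:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if mode.endswith("_sig"):
        if T is None:
            raise ValueError(f"mode {mode} requires a threshold")
        _check_T(T)
        g = (R.r > T) if mode == "pos_sig" else (R.r < -T)
    else:
        g = (R.r > 0) if mode == "pos_any" else (R.r < 0)
        T = None
    return NetworkMatrix(list(R.ts_ids), list(R.de_ids), g.astype(np.uint8), mode, T)


def shared_node_count(G: NetworkMatrix, i: int) -> int:
    """Number of DE genes linked both to TS gene ``i`` and to >=1 other TS
    gene.  Zero for a single-row network."""
    n = G.g.shape[0]
    if not 0 <= i < n:
        raise IndexError(f"TS index {i} out of range for {n} genes")
    if n == 1:
        return 0
    others = G.g.sum(axis=0) - G.g[i]
    return int(((G.g[i] == 1) & (others >= 1)).sum())


def n_scores(R: CorrelationMatrix, T: float) -> list[NScoreRow]:
    """Shared-node ratio scores for every TS gene."""
    pos_sig = binarize(R, T, "pos_sig")
    pos_any = binarize(R, None, "pos_any")
    neg_sig = binarize(R, T, "neg_sig")
    neg_any = binarize(R, None, "neg_any")
    rows = []
    for i, gene in enumerate(R.ts_ids):
        c_plus = shared_node_count(pos_sig, i)
        c_plus0 = shared_node_count(pos_any, i)
        c_minus = shared_node_count(neg_sig, i)
        c_minus0 = shared_node_count(neg_any, i)
        if c_plus0 == 0 or c_minus0 == 0:
            logger.info("gene %s has an empty sign-level shared set; N-score set to 0", gene)
        rows.append(
            NScoreRow(
                gene=gene,
                n_plus=c_plus / c_plus0 if c_plus0 else 0.0,
                n_minus=c_minus / c_minus0 if c_minus0 else 0.0,
                c_plus=c_plus,
                c_plus0=c_plus0,
                c_minus=c_minus,
                c_minus0=c_minus0,
            )
        )
    return rows


def export_network(G: NetworkMatrix, shared_annotation: bool = True) -> list[dict]:
    """Edge list for the binary network.

    One record per edge with the TS gene, DE gene, edge sign, and (when
    requested) whether the DE node is shared by two or more TS genes.
    """
    sign = "+" if G.mode.startswith("pos") else "-"
    colsum = G.g.sum(axis=0)
    edges = []
    for i, ts in enumerate(G.ts_ids):
        for j in np.flatnonzero(G.g[i]):
            rec = {"ts_gene": ts, "de_gene": G.de_ids[j], "sign": sign}
            if shared_annotation:
                rec["shared"] = int(colsum[j] >= 2)
            edges.append(rec)
    return edges


def write_edge_table(edges: Sequence[dict], path: str | Path) -> None:
    has_shared = bool(edges) and "shared" in edges[0]
    with open(path, "w", encoding="utf-8") as fh:
        header = ["ts_gene", "de_gene", "sign"] + (["shared"] if has_shared else [])
        fh.write("\t".join(header) + "\n")
        for e in edges:
            cells = [e["ts_gene"], e["de_gene"], e["sign"]]
            if has_shared:
                cells.append(str(e["shared"]))
            fh.write("\t".join(cells) + "\n")
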