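"""Replicate-pair correlation quality checks."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .expression_io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class QCPair:
    sample_a: str
    sample_b: str
    r: float
    passed: bool | None = None

    def __post_init__(self) -> None:
        if self.sample_a == self.sample_b:
            raise ValueError("QC pair must involve two distinct samples")


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation.

    Constant input on either side yields 0 (with a warning) rather than NaN,
    so reports stay total.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("pearson needs vectors of length >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = float(np.sqrt(xc @ xc))
    ny = float(np.sqrt(yc @ yc))
    if nx == 0.0 or ny == 0.0:
        logger.warning("constant vector in pearson; returning r=0")
        return 0.0
    r = float((xc @ yc) / (nx * ny))
    return max(-1.0, min(1.0, r))


def qc_report(
    m: ExpressionMatrix,
    pairs: Sequence[tuple[str, str]],
    threshold: float = 0.9,
) -> list[QCPair]:
    """Correlate each named sample pair; a pair passes when r > threshold."""
    index = {s: i for i, s in enumerate(m.sample_ids)}
    out: list[QCPair] = []
    for a, b in pairs:
        for sid in (a, b):
            if sid not in index:
                raise KeyError(f"unknown sample id: {sid!r}")
        r = pearson(m.values[:, index[a]], m.values[:, index[b]])
        out.append(QCPair(a, b, r, passed=r > threshold))
    return out


def write_qc_report(report: Sequence[QCPair], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_a\tsample_b\tr\tpass\n")
        for q in report:
            fh.write(f"{q.sample_a}\t{q.sample_b}\t{format(q.r, '.17g')}\t{int(bool(q.passed))}\n")
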