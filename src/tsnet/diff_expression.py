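"""Tumor-vs-normal differential expression with BH false-discovery control.

The shipped test is Welch's unequal-variance t-test; the DE stage is kept
behind a small interface (``de_test``) so a different test can be plugged in
without touching downstream scoring, which consumes only the significant set
and its directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .expression_io import ExpressionMatrix, GeneList, SampleTable

logger = logging.getLogger(__name__)

_TINY_P = float(np.finfo(float).tiny)


@dataclass
class DEResult:
    probe_id: str
    statistic: float
    mean_diff: float  # tumor - normal, log units
    p: float
    q: float
    significant: bool
    direction: str  # up | down | none


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adjusted_(i) = min_{j >= i} p_(j) * n / j, capped at 1, returned in the
    input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n, dtype=float)
    out[order] = adjusted
    return out


def de_test(
    m: ExpressionMatrix,
    t: SampleTable,
    fdr: float = 0.01,
    paired: bool = False,
) -> list[DEResult]:
    """Per-probe Welch t-test of tumor vs normal with BH adjustment.

    Returns one result per probe, sorted by q ascending then probe id.
    Degenerate probes (zero variance in both groups) get p=1 when the group
    means agree and the machine-minimum p when they differ.
    """
    present = set(m.sample_ids)
    tumor_ids = [s for s in t.ids_where(condition="tumor") if s in present]
    normal_ids = [s for s in t.ids_where(condition="normal") if s in present]
    if len(tumor_ids) < 2 or len(normal_ids) < 2:
        raise ValueError(
            f"need >=2 samples per condition, got {len(normal_ids)} normal / {len(tumor_ids)} tumor"
        )
    col = {s: i for i, s in enumerate(m.sample_ids)}
    a = m.values[:, [col[s] for s in tumor_ids]]
    b = m.values[:, [col[s] for s in normal_ids]]

    if paired:
        stat, mean_diff, p = _paired_test(a, b, tumor_ids, normal_ids, t)
    else:
        stat, mean_diff, p = _welch_test(a, b)

    q = bh_adjust(p)
    results = []
    for i, probe in enumerate(m.probe_ids):
        sig = bool(q[i] < fdr)
        if not sig or mean_diff[i] == 0.0:
            direction = "none"
        elif mean_diff[i] < 0:
            direction = "down"
        else:
            direction = "up"
        results.append(
            DEResult(probe, float(stat[i]), float(mean_diff[i]), float(p[i]), float(q[i]), sig, direction)
        )
    results.sort(key=lambda r: (r.q, r.probe_id))
    return results


def _welch_test(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    mean_diff = ma - mb
    se2 = va / na + vb / nb
    degenerate = se2 == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = mean_diff / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = 2.0 * stats.t.sf(np.abs(stat), df)
    if np.any(degenerate):
        zero_diff = degenerate & (mean_diff == 0.0)
        sep = degenerate & (mean_diff != 0.0)
        stat[zero_diff] = 0.0
        p[zero_diff] = 1.0
        stat[sep] = np.sign(mean_diff[sep]) * np.inf
        p[sep] = _TINY_P
        if np.any(sep):
            logger.warning("%d probes separate the groups with zero variance; p set to machine minimum", int(sep.sum()))
    return stat, mean_diff, p


def _paired_test(
    a: np.ndarray,
    b: np.ndarray,
    tumor_ids: list[str],
    normal_ids: list[str],
    t: SampleTable,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    subj = {sid: t.subject_id[t.sample_ids.index(sid)] for sid in tumor_ids + normal_ids}
    normal_by_subject = {subj[s]: i for i, s in enumerate(normal_ids)}
    pairs = [(i, normal_by_subject[subj[s]]) for i, s in enumerate(tumor_ids) if subj[s] in normal_by_subject]
    if len(pairs) < 2:
        raise ValueError("paired test needs >=2 tumor/normal subject pairs")
    d = np.stack([a[:, i] - b[:, j] for i, j in pairs], axis=1)
    n = d.shape[1]
    mean_diff = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    degenerate = sd == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = mean_diff / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(np.abs(stat), n - 1)
    zero_diff = degenerate & (mean_diff == 0.0)
    sep = degenerate & (mean_diff != 0.0)
    stat[zero_diff], p[zero_diff] = 0.0, 1.0
    stat[sep] = np.sign(mean_diff[sep]) * np.inf
    p[sep] = _TINY_P
    return stat, mean_diff, p


def classify_regulation(
    results: Sequence[DEResult],
    down_name: str = "down",
    up_name: str = "up",
) -> tuple[GeneList, GeneList]:
    """Partition the significant probes by the sign of the tumor-normal shift."""
    down = {r.probe_id for r in results if r.significant and r.mean_diff < 0}
    up = {r.probe_id for r in results if r.significant and r.mean_diff > 0}
    return (
        GeneList(down_name, down, provenance="significant, tumor < normal"),
        GeneList(up_name, up, provenance="significant, tumor > normal"),
    )


def stage_overlap(a: GeneList, b: GeneList) -> tuple[int, int, int]:
    """Counts (only in a, only in b, shared)."""
    both = a.members & b.members
    return len(a.members) - len(both), len(b.members) - len(both), len(both)


def write_de_table(results: Sequence[DEResult], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("probe_id\tstatistic\tmean_diff\tp\tq\tsignificant\tdirection\n")
        for r in results:
            fh.write(
                f"{r.probe_id}\t{format(r.statistic, '.17g')}\t{format(r.mean_diff, '.17g')}\t"
                f"{format(r.p, '.17g')}\t{format(r.q, '.17g')}\t{int(r.significant)}\t{r.direction}\n"
            )
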