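"""TS-by-DE correlation matrix, calibrated threshold T and S-scores.

The threshold converts a Bonferroni-adjusted tail probability into a
critical correlation through the exact t/r identity

    T = |t| / sqrt(t^2 + df),   t = t-quantile(p, df),   df = n_samples - 2,

so an |r| at the threshold corresponds exactly to the chosen per-test
probability.  Per TS gene, over its correlation row r_1..r_m with the DE
genes:

    s_plus  = (sum of r_j with r_j >= T) / (sum of r_j with r_j > 0)
    s_minus = (sum of r_j with r_j <= -T) / (sum of r_j with r_j < 0)
    s_score = sum of r_j with |r_j| >= T        (signed)

Both ratios are defined as 0 when their denominator is empty.  Boundary
comparisons here are inclusive (>= T, <= -T); the network binarization in
:mod:`tsnet.network_scores` is strict by design — see that module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .expression_io import ExpressionMatrix, SampleTable

logger = logging.getLogger(__name__)

SAMPLE_SCOPES = ("all", "tumor_only")
TAILS = ("one", "two")


@dataclass
class CorrelationMatrix:
    """Pearson r between every TS gene (row) and DE gene (column)."""

    ts_ids: list[str]
    de_ids: list[str]
    r: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.shape != (len(self.ts_ids), len(self.de_ids)):
            raise ValueError("correlation matrix shape mismatch")
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")

    def row(self, gene: str) -> np.ndarray:
        return self.r[self.ts_ids.index(gene)]


@dataclass
class ThresholdSpec:
    alpha: float
    m_tests: int
    n_samples: int
    tails: str
    t: float
    T: float


@dataclass
class SScoreRow:
    gene: str
    s_plus: float
    s_minus: float
    s: float
    n_pos_sig: int
    n_neg_sig: int


def correlation_matrix(
    ts_expr: ExpressionMatrix,
    de_expr: ExpressionMatrix,
    sample_scope: str = "all",
    samples: SampleTable | None = None,
) -> CorrelationMatrix:
    """Row-by-row Pearson correlations between two matrices over shared
    sample columns.

    ``sample_scope="tumor_only"`` restricts the computation to tumor columns
    (requires ``samples``).  Constant rows correlate at 0 with a warning.
    """
    if sample_scope not in SAMPLE_SCOPES:
        raise ValueError(f"sample_scope must be one of {SAMPLE_SCOPES}")
    if ts_expr.sample_ids != de_expr.sample_ids:
        if set(ts_expr.sample_ids) != set(de_expr.sample_ids):
            raise ValueError("TS and DE matrices must cover the same samples")
        de_expr = de_expr.subset_samples(ts_expr.sample_ids)
    if sample_scope == "tumor_only":
        if samples is None:
            raise ValueError("tumor_only scope requires a sample table")
        tumor = set(samples.ids_where(condition="tumor"))
        keep = [s for s in ts_expr.sample_ids if s in tumor]
        ts_expr = ts_expr.subset_samples(keep)
        de_expr = de_expr.subset_samples(keep)
    n = len(ts_expr.sample_ids)
    if n < 3:
        raise ValueError(f"need >=3 scoped samples for correlations, got {n}")

    a = ts_expr.values - ts_expr.values.mean(axis=1, keepdims=True)
    b = de_expr.values - de_expr.values.mean(axis=1, keepdims=True)
    na = np.sqrt((a * a).sum(axis=1))
    nb = np.sqrt((b * b).sum(axis=1))
    const_a, const_b = na == 0, nb == 0
    if np.any(const_a) or np.any(const_b):
        logger.warning(
            "%d constant rows in correlation input; their r set to 0",
            int(const_a.sum() + const_b.sum()),
        )
    na = np.where(const_a, 1.0, na)
    nb = np.where(const_b, 1.0, nb)
    r = (a @ b.T) / np.outer(na, nb)
    r[const_a, :] = 0.0
    r[:, const_b] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    return CorrelationMatrix(list(ts_expr.probe_ids), list(de_expr.probe_ids), r, n)


def correlation_threshold(
    alpha: float,
    m_tests: int,
    n_samples: int,
    tails: str = "one",
) -> ThresholdSpec:
    """Bonferroni-calibrated critical correlation.

    p = alpha / m_tests (halved first for ``tails="two"``), t is the
    t-distribution quantile of p at df = n_samples - 2, and
    T = |t| / sqrt(t^2 + df).
    """
    if tails not in TAILS:
        raise ValueError(f"tails must be one of {TAILS}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    if n_samples < 3:
        raise ValueError("n_samples must be >= 3")
    p = alpha / m_tests
    if p >= 1:
        raise ValueError("alpha/m_tests must be < 1")
    if tails == "two":
        p = p / 2.0
    df = n_samples - 2
    t = float(stats.t.ppf(p, df))
    T = abs(t) / np.sqrt(t * t + df)
    return ThresholdSpec(alpha, m_tests, n_samples, tails, t, float(T))


def s_plus(row: Sequence[float], T: float) -> float:
    r = np.asarray(row, dtype=float)
    _check_T(T)
    denom = r[r > 0].sum()
    if denom == 0.0:
        return 0.0
    return float(r[r >= T].sum() / denom)


def s_minus(row: Sequence[float], T: float) -> float:
    r = np.asarray(row, dtype=float)
    _check_T(T)
    denom = r[r < 0].sum()
    if denom == 0.0:
        return 0.0
    return float(r[r <= -T].sum() / denom)


def s_score(row: Sequence[float], T: float) -> float:
    r = np.asarray(row, dtype=float)
    _check_T(T)
    return float(r[np.abs(r) >= T].sum())


def _check_T(T: float) -> None:
    if not 0 < T < 1:
        raise ValueError(f"threshold T must lie in (0, 1), got {T}")


def score_table(R: CorrelationMatrix, T: float) -> list[SScoreRow]:
    """All three S-scores plus supporting counts, one row per TS gene."""
    _check_T(T)
    rows = []
    for gene, r in zip(R.ts_ids, R.r):
        rows.append(
            SScoreRow(
                gene=gene,
                s_plus=s_plus(r, T),
                s_minus=s_minus(r, T),
                s=s_score(r, T),
                n_pos_sig=int((r >= T).sum()),
                n_neg_sig=int((r <= -T).sum()),
            )
        )
    return rows


def write_score_table(
    rows: Sequence[SScoreRow],
    path: str | Path,
    spec: ThresholdSpec | None = None,
    extra: dict[str, dict[str, float]] | None = None,
) -> None:
    """Write the per-gene score TSV; ``extra`` may add columns (e.g. N-scores)
    keyed by column name then gene."""
    extra = extra or {}
    extra_cols = list(extra)
    with open(path, "w", encoding="utf-8") as fh:
        header = ["gene", "s_plus", "s_minus", "s", "n_pos_sig", "n_neg_sig"] + extra_cols
        if spec is not None:
            header += ["T", "n_samples", "m_tests"]
        fh.write("\t".join(header) + "\n")
        for row in rows:
            cells = [
                row.gene,
                format(row.s_plus, ".17g"),
                format(row.s_minus, ".17g"),
                format(row.s, ".17g"),
                str(row.n_pos_sig),
                str(row.n_neg_sig),
            ]
            cells += [format(extra[c].get(row.gene, 0.0), ".17g") for c in extra_cols]
            if spec is not None:
                cells += [format(spec.T, ".17g"), str(spec.n_samples), str(spec.m_tests)]
            fh.write("\t".join(cells) + "\n")
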