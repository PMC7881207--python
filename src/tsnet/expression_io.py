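"""Readers, writers and small transforms for expression data.

File dialects (all UTF-8, tab-separated):

* expression matrix — header ``probe_id<TAB>sample1<TAB>...``, one probe
  per row, numeric body on log scale;
* sample table — exactly the columns ``sample_id``, ``condition``,
  ``stage``, ``subject_id``, ``smoking`` with ``NA`` for unknowns;
* gene list — one identifier per line, ``#`` starts a comment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

CONDITIONS = ("normal", "tumor")
STAGES = ("1", "2", "3", "4", "unknown")
SMOKING = ("yes", "no", "unknown")

_NA_TOKENS = ("", "NA")


@dataclass
class ExpressionMatrix:
    """Log-scale expression values, rows = probes/genes, columns = samples."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.probe_ids, "probe id")
        _check_unique(self.sample_ids, "sample id")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, probe_id: str) -> np.ndarray:
        return self.values[self.probe_ids.index(probe_id)]

    def subset_probes(self, probe_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {p: i for i, p in enumerate(self.probe_ids)}
        missing = [p for p in probe_ids if p not in index]
        if missing:
            raise KeyError(f"unknown probe ids: {missing[:5]}")
        rows = [index[p] for p in probe_ids]
        return ExpressionMatrix(list(probe_ids), list(self.sample_ids), self.values[rows])

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        cols = [index[s] for s in sample_ids]
        return ExpressionMatrix(list(self.probe_ids), list(sample_ids), self.values[:, cols])


@dataclass
class SampleTable:
    """Per-sample metadata: condition, tumor stage, subject pairing, smoking."""

    sample_ids: list[str]
    condition: list[str]
    stage: list[str]
    subject_id: list[str]
    smoking: list[str]

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        for name in ("condition", "stage", "subject_id", "smoking"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} length != number of samples")
        _check_unique(self.sample_ids, "sample id")
        for c in self.condition:
            if c not in CONDITIONS:
                raise ValueError(f"condition {c!r} not in {CONDITIONS}")
        for s in self.stage:
            if s not in STAGES:
                raise ValueError(f"stage {s!r} not in {STAGES}")
        for s in self.smoking:
            if s not in SMOKING:
                raise ValueError(f"smoking {s!r} not in {SMOKING}")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def condition_of(self, sample_id: str) -> str:
        return self.condition[self.sample_ids.index(sample_id)]

    def ids_where(self, *, condition: str | None = None, stage: str | None = None) -> list[str]:
        out = []
        for i, sid in enumerate(self.sample_ids):
            if condition is not None and self.condition[i] != condition:
                continue
            if stage is not None and self.stage[i] != stage:
                continue
            out.append(sid)
        return out

    def subset(self, sample_ids: Sequence[str]) -> "SampleTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return SampleTable(
            [self.sample_ids[i] for i in rows],
            [self.condition[i] for i in rows],
            [self.stage[i] for i in rows],
            [self.subject_id[i] for i in rows],
            [self.smoking[i] for i in rows],
        )


@dataclass
class GeneList:
    """Named set of gene/probe identifiers with a provenance tag."""

    name: str
    members: set[str] = field(default_factory=set)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.members = set(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what}: {x!r}")
        seen.add(x)


# ---------------------------------------------------------------------------
# expression matrix IO


def read_expression_matrix(
    path: str | Path,
    *,
    missing: str = "error",
    linear_scale: bool = False,
) -> ExpressionMatrix:
    """Parse a TSV expression matrix.

    ``missing`` is either ``"error"`` (any NA/blank/unparseable cell aborts)
    or ``"drop"`` (the offending probe row is discarded with a warning).
    ``linear_scale=True`` applies log2(x+1) at load, for linear-scale input
    such as RPKM, so correlations are comparable with log-scale arrays.
    """
    if missing not in ("error", "drop"):
        raise ValueError(f"unknown missing-value policy {missing!r}")
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    lines = [ln for ln in lines if ln != ""]
    if len(lines) < 2:
        raise ValueError(f"{path}: empty expression matrix body")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    if not sample_ids:
        raise ValueError(f"{path}: header has no sample columns")
    width = len(header)
    probe_ids: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != width:
            raise ValueError(
                f"{path}: ragged row at line {lineno}: "
                f"{len(parts)} fields, expected {width}"
            )
        probe = parts[0]
        if probe in seen:
            raise ValueError(f"{path}: duplicate probe id: {probe!r}")
        values: list[float] = []
        bad = False
        for cell in parts[1:]:
            if cell in _NA_TOKENS:
                bad = True
                break
            try:
                v = float(cell)
            except ValueError:
                bad = True
                break
            if not math.isfinite(v):
                bad = True
                break
            values.append(v)
        if bad:
            if missing == "drop":
                logger.warning("dropping probe %r (line %d): missing/unparseable value", probe, lineno)
                continue
            raise ValueError(f"{path}: missing or unparseable value for probe {probe!r} at line {lineno}")
        seen.add(probe)
        probe_ids.append(probe)
        rows.append(values)
    if not rows:
        raise ValueError(f"{path}: empty expression matrix body")
    values_arr = np.array(rows, dtype=float)
    if linear_scale:
        if np.any(values_arr < 0):
            raise ValueError(f"{path}: negative values under linear_scale; cannot log2(x+1)")
        values_arr = np.log2(values_arr + 1.0)
    return ExpressionMatrix(probe_ids, sample_ids, values_arr)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("probe_id\t" + "\t".join(m.sample_ids) + "\n")
        for probe, row in zip(m.probe_ids, m.values):
            fh.write(probe + "\t" + "\t".join(format(v, ".17g") for v in row) + "\n")


# ---------------------------------------------------------------------------
# sample table IO

_SAMPLE_COLUMNS = ("sample_id", "condition", "stage", "subject_id", "smoking")


def read_sample_table(path: str | Path) -> SampleTable:
    lines = [ln for ln in Path(path).read_text(encoding="utf-8").splitlines() if ln != ""]
    if not lines:
        raise ValueError(f"{path}: empty sample table")
    header = tuple(lines[0].split("\t"))
    if header != _SAMPLE_COLUMNS:
        raise ValueError(f"{path}: expected columns {_SAMPLE_COLUMNS}, got {header}")
    cols: dict[str, list[str]] = {c: [] for c in _SAMPLE_COLUMNS}
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != len(_SAMPLE_COLUMNS):
            raise ValueError(f"{path}: ragged row at line {lineno}")
        for c, v in zip(_SAMPLE_COLUMNS, parts):
            cols[c].append(v)
    stage = ["unknown" if s in _NA_TOKENS else s for s in cols["stage"]]
    smoking = ["unknown" if s in _NA_TOKENS else s for s in cols["smoking"]]
    return SampleTable(cols["sample_id"], cols["condition"], stage, cols["subject_id"], smoking)


def write_sample_table(t: SampleTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_SAMPLE_COLUMNS) + "\n")
        for i in range(len(t)):
            stage = "NA" if t.stage[i] == "unknown" else t.stage[i]
            smoking = "NA" if t.smoking[i] == "unknown" else t.smoking[i]
            fh.write("\t".join((t.sample_ids[i], t.condition[i], stage, t.subject_id[i], smoking)) + "\n")


# ---------------------------------------------------------------------------
# gene list IO


def read_gene_list(path: str | Path, name: str | None = None, provenance: str = "") -> GeneList:
    members: set[str] = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        token = line.split("#", 1)[0].strip()
        if token:
            members.add(token)
    if not members:
        raise ValueError(f"{path}: gene list is empty")
    return GeneList(name or Path(path).stem, members, provenance)


def write_gene_list(g: GeneList, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if g.provenance:
            fh.write(f"# {g.provenance}\n")
        for gene in sorted(g.members):
            fh.write(gene + "\n")


# ---------------------------------------------------------------------------
# transforms


def subset_stage(
    m: ExpressionMatrix,
    t: SampleTable,
    stage: int | str,
    include_normals: bool = True,
) -> tuple[ExpressionMatrix, SampleTable]:
    """Restrict columns to tumor samples at ``stage`` (plus, optionally, all
    normal samples), preserving the matrix column order."""
    stage = str(stage)
    if stage not in ("1", "2", "3", "4"):
        raise ValueError(f"stage must be one of 1-4, got {stage!r}")
    info = {sid: (t.condition[i], t.stage[i]) for i, sid in enumerate(t.sample_ids)}
    keep: list[str] = []
    n_tumor = 0
    for sid in m.sample_ids:
        if sid not in info:
            continue
        cond, st = info[sid]
        if cond == "tumor" and st == stage:
            keep.append(sid)
            n_tumor += 1
        elif cond == "normal" and include_normals:
            keep.append(sid)
    if n_tumor == 0:
        raise ValueError(f"no tumor sample at stage {stage}")
    return m.subset_samples(keep), t.subset(keep)


def zscore_rows(m: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each row to mean 0, sample (n-1) standard deviation 1.

    Constant rows become all-zero rows; a warning is logged for each.
    """
    if len(m.sample_ids) < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    mean = m.values.mean(axis=1, keepdims=True)
    sd = m.values.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    for probe in np.asarray(m.probe_ids, dtype=object)[constant]:
        logger.warning("constant row %r z-scored to zeros", probe)
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (m.values - mean) / safe_sd
    z[constant, :] = 0.0
    return ExpressionMatrix(list(m.probe_ids), list(m.sample_ids), z)


def collapse_probes(m: ExpressionMatrix, probe2gene: Mapping[str, str]) -> ExpressionMatrix:
    """Collapse to one row per gene, keeping each gene's highest-variance
    probe; probes absent from the map are dropped."""
    by_gene: dict[str, list[int]] = {}
    for i, probe in enumerate(m.probe_ids):
        gene = probe2gene.get(probe)
        if gene is not None:
            by_gene.setdefault(gene, []).append(i)
    if not by_gene:
        raise ValueError("no probe in the matrix is covered by the probe-to-gene map")
    genes = sorted(by_gene)
    rows = []
    for gene in genes:
        idx = by_gene[gene]
        variances = m.values[idx].std(axis=1, ddof=1) ** 2
        # ties broken by probe id for determinism
        best = min(zip(-variances, [m.probe_ids[i] for i in idx], idx))[2]
        rows.append(best)
    return ExpressionMatrix(genes, list(m.sample_ids), m.values[rows])
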