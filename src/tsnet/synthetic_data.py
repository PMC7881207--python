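"""Seeded synthetic normal/tumor cohorts with planted gene roles.

The generative model is a single latent factor shared across the cohort.
Per sample s: latent f_s ~ Normal(0, factor_sd^2) (optionally mean-shifted
in tumors), condition indicator c_s in {0, 1}.  Per gene g:

    x_gs = mu_g + c_s * delta_g + lambda_g * f_s + Normal(0, noise_sd^2)

Roles:

* ``strong_ts``  — delta = delta_down, lambda = +loading_strong
* ``de_down``    — delta = delta_down, lambda = +loading_strong
* ``de_up``      — delta = delta_up,   lambda = -loading_strong * loading_up_scale
* ``weak_ts``    — delta = delta_down, lambda = 0 (shifted but uncorrelated)
* ``null``       — delta = 0, lambda = 0

``loading_up_scale`` (default < 1) attenuates the up-block loading so the
planted structure is positive-dominant: tumor-suppressor genes co-vary more
strongly with the down-shifted block than against the up-shifted one.
Identical configs produce bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .expression_io import ExpressionMatrix, SampleTable

ROLES = ("strong_ts", "weak_ts", "de_down", "de_up", "null")


@dataclass(frozen=True)
class SimulationConfig:
    n_normal: int = 20
    n_tumor: int = 20
    k_strong_ts: int = 4
    k_weak_ts: int = 4
    k_de_down: int = 150
    k_de_up: int = 80
    k_null: int = 1500
    delta_down: float = -3.0
    delta_up: float = 3.0
    loading_strong: float = 0.8
    loading_up_scale: float = 0.6
    factor_sd: float = 2.0
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 0.5
    factor_condition_shift: float = 0.0  # couples the latent factor to condition
    stage: str = "2"
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_normal, self.n_tumor, self.k_strong_ts, self.k_weak_ts,
            self.k_de_down, self.k_de_up, self.k_null,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        if self.n_normal == 0 or self.n_tumor == 0:
            raise ValueError("both conditions need at least one sample")
        if self.n_normal + self.n_tumor < 6:
            raise ValueError("need at least 6 samples in total")
        if self.factor_sd < 0 or self.noise_sd < 0 or self.baseline_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0 <= self.loading_strong <= 1:
            raise ValueError("loading_strong must lie in [0, 1]")

    @property
    def n_genes(self) -> int:
        return self.k_strong_ts + self.k_weak_ts + self.k_de_down + self.k_de_up + self.k_null

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class TruthTable:
    """Planted role per gene."""

    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, role in self.roles.items():
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r} for gene {g!r}")

    def genes_with(self, role: str) -> list[str]:
        return [g for g, r in self.roles.items() if r == role]

    def __getitem__(self, gene: str) -> str:
        return self.roles[gene]


def default_paper_like_config(seed: int = 0) -> SimulationConfig:
    """The documented cohort used by the acceptance suite: 20+20 samples,
    4 strong TS, 4 weak TS, 150 down- and 80 up-shifted DE genes, 1500 nulls."""
    return SimulationConfig(seed=seed)


def simulate_cohort(cfg: SimulationConfig) -> tuple[ExpressionMatrix, SampleTable, TruthTable]:
    """Draw one cohort; paired subject ids link tumor i with normal i."""
    rng = np.random.default_rng(cfg.seed)

    width = max(2, len(str(max(cfg.n_normal, cfg.n_tumor))))
    normal_ids = [f"N{i:0{width}d}" for i in range(1, cfg.n_normal + 1)]
    tumor_ids = [f"T{i:0{width}d}" for i in range(1, cfg.n_tumor + 1)]
    sample_ids = normal_ids + tumor_ids
    condition = ["normal"] * cfg.n_normal + ["tumor"] * cfg.n_tumor
    stage = ["unknown"] * cfg.n_normal + [cfg.stage] * cfg.n_tumor
    subject = [f"P{i:0{width}d}" for i in range(1, cfg.n_normal + 1)] + [
        f"P{i:0{width}d}" for i in range(1, cfg.n_tumor + 1)
    ]
    smoking = ["unknown"] * len(sample_ids)
    table = SampleTable(sample_ids, condition, stage, subject, smoking)

    gw = max(3, len(str(cfg.n_genes)))
    names, roles, delta, lam = [], [], [], []
    lam_up = -cfg.loading_strong * cfg.loading_up_scale
    blocks = (
        ("STS", "strong_ts", cfg.k_strong_ts, cfg.delta_down, cfg.loading_strong),
        ("WTS", "weak_ts", cfg.k_weak_ts, cfg.delta_down, 0.0),
        ("DND", "de_down", cfg.k_de_down, cfg.delta_down, cfg.loading_strong),
        ("DUP", "de_up", cfg.k_de_up, cfg.delta_up, lam_up),
        ("NUL", "null", cfg.k_null, 0.0, 0.0),
    )
    for prefix, role, count, d, l in blocks:
        for i in range(1, count + 1):
            names.append(f"{prefix}{i:0{gw}d}")
            roles.append(role)
            delta.append(d)
            lam.append(l)
    truth = TruthTable(dict(zip(names, roles)))

    n = len(sample_ids)
    c = np.array([1.0 if cond == "tumor" else 0.0 for cond in condition])
    mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    f = rng.normal(0.0, cfg.factor_sd, size=n) + cfg.factor_condition_shift * c
    eps = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n))
    delta_arr = np.array(delta)
    lam_arr = np.array(lam)
    values = mu[:, None] + delta_arr[:, None] * c[None, :] + lam_arr[:, None] * f[None, :] + eps

    return ExpressionMatrix(names, sample_ids, values), table, truth


def write_truth_table(truth: TruthTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\trole\n")
        for g, role in truth.roles.items():
            fh.write(f"{g}\t{role}\n")


def read_truth_table(path: str | Path) -> TruthTable:
    roles: dict[str, str] = {}
    lines = [ln for ln in Path(path).read_text(encoding="utf-8").splitlines() if ln]
    if not lines or lines[0] != "gene\trole":
        raise ValueError(f"{path}: expected header 'gene\\trole'")
    for line in lines[1:]:
        gene, role = line.split("\t")
        roles[gene] = role
    return TruthTable(roles)


def config_to_mapping(cfg: SimulationConfig) -> dict[str, object]:
    return {k: getattr(cfg, k) for k in cfg.__dataclass_fields__}


def config_from_mapping(d: Mapping[str, object]) -> SimulationConfig:
    known = set(SimulationConfig.__dataclass_fields__)
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    return SimulationConfig(**{k: v for k, v in d.items()})  # type: ignore[arg-type]
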