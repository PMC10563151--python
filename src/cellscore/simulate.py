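"""Synthetic labeled cohorts with known cell-level ground truth.

Emulates the statistical structure the scoring model assumes: every sample
shares a set of healthy cell populations (Gaussian mixture components in
transformed marker space); pathogenic populations appear only in positive
samples, mixed in at a per-sample nominal burden; per-sample mean jitter
models between-patient phenotypic heterogeneity; and positive samples carry
one pathogenic endotype each or a mixture, mirroring the endotype structure
seen clinically (e.g. CD38-positive vs CD38-negative disease variants).

Ground truth records the per-cell pathogenic indicator z_ij and the realized
burden (the fraction of pathogenic cells actually drawn), which is what the
sample record's burden is set to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import json
import numpy as np

from .cohort import Cohort, EventMatrix, SampleRecord
from .io import write_manifest, write_table
from .panel import MarkerPanel


@dataclass
class PopulationSpec:
    """One Gaussian cell population in transformed marker units."""

    mean: np.ndarray
    covariance: np.ndarray
    role: str = "healthy"  # "healthy" | "pathogenic"
    endotype_id: int = 0
    weight: float = 1.0  # relative mixing weight among populations of the same role

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.role not in ("healthy", "pathogenic"):
            raise ValueError(f"population role must be healthy|pathogenic, got {self.role!r}")
        if self.covariance.shape != (self.mean.size, self.mean.size):
            raise ValueError("covariance shape must match mean dimension")
        if not np.allclose(self.covariance, self.covariance.T):
            raise ValueError("covariance must be symmetric")
        eig = np.linalg.eigvalsh(self.covariance)
        if eig.min() <= 0:
            raise ValueError("covariance must be positive-definite")
        if self.weight <= 0:
            raise ValueError("population weight must be positive")


@dataclass
class SimConfig:
    """Configuration of one simulated cohort."""

    n_markers: int
    healthy_pops: List[PopulationSpec]
    pathogenic_pops: List[PopulationSpec]
    n_pos: int
    n_neg: int
    cells_per_sample: Tuple[int, int] = (5000, 10000)
    burden_range: Tuple[float, float] = (0.05, 0.9)
    jitter_sd: float = 0.15
    endotype_mixing: str = "single_per_sample"  # or "mixture"
    seed: int = 0
    id_prefix: str = "s"

    def __post_init__(self) -> None:
        if not self.healthy_pops:
            raise ValueError("at least one healthy population is required")
        if self.n_pos > 0 and not self.pathogenic_pops:
            raise ValueError("positive samples require at least one pathogenic population")
        for p in self.healthy_pops + self.pathogenic_pops:
            if p.mean.size != self.n_markers:
                raise ValueError("population dimension does not match n_markers")
        lo, hi = self.cells_per_sample
        if lo < 1 or hi < lo:
            raise ValueError("cells_per_sample interval must satisfy 1 <= lo <= hi")
        blo, bhi = self.burden_range
        if not (0.0 < blo <= bhi <= 1.0):
            raise ValueError("burden_range support must lie in (0, 1]")
        if self.endotype_mixing not in ("single_per_sample", "mixture"):
            raise ValueError("endotype_mixing must be single_per_sample|mixture")
        if self.n_pos + self.n_neg < 1:
            raise ValueError("cohort must contain at least one sample")


@dataclass
class GroundTruth:
    """Per-cell pathogenic indicators and realized burdens, by sample."""

    cell_labels: Dict[str, np.ndarray] = field(default_factory=dict)
    true_burden: Dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for sid, z in self.cell_labels.items():
            if not np.isclose(self.true_burden[sid], float(np.mean(z))):
                raise AssertionError(f"true_burden inconsistent with cell labels for {sid}")


def _draw_mixture(
    rng: np.random.Generator,
    pops: List[PopulationSpec],
    counts: np.ndarray,
    jitters: Dict[int, np.ndarray],
) -> np.ndarray:
    parts = []
    for pop, cnt in zip(pops, counts):
        if cnt == 0:
            continue
        mean = pop.mean + jitters[id(pop)]
        parts.append(rng.multivariate_normal(mean, pop.covariance, size=int(cnt)))
    if not parts:
        return np.empty((0, pops[0].mean.size))
    return np.vstack(parts)


def generate_cohort(config: SimConfig) -> Tuple[Cohort, GroundTruth]:
    """Draw a labeled cohort plus its cell-level ground truth.

    Negative samples contain only (jittered) healthy populations and have
    burden exactly 0; positive samples mix pathogenic cells in at a nominal
    burden drawn from `burden_range`, and the recorded burden is the realized
    fraction of pathogenic cells.  Deterministic given `config.seed`.
    """
    rng = np.random.default_rng(config.seed)
    panel = MarkerPanel.identity([f"M{d}" for d in range(config.n_markers)])
    healthy_w = np.array([p.weight for p in config.healthy_pops], dtype=float)
    healthy_w = healthy_w / healthy_w.sum()
    if config.pathogenic_pops:
        patho_w = np.array([p.weight for p in config.pathogenic_pops], dtype=float)
        patho_w = patho_w / patho_w.sum()

    samples: List[SampleRecord] = []
    truth = GroundTruth()

    statuses = [1] * config.n_pos + [0] * config.n_neg
    n_digits = max(3, len(str(len(statuses))))
    for k, is_pos in enumerate(statuses):
        sid = f"{config.id_prefix}{'pos' if is_pos else 'neg'}{k:0{n_digits}d}"
        n_cells = int(rng.integers(config.cells_per_sample[0], config.cells_per_sample[1] + 1))
        # One mean shift per (sample, population): between-sample heterogeneity.
        jitters = {
            id(p): rng.normal(0.0, config.jitter_sd, size=config.n_markers)
            for p in config.healthy_pops + config.pathogenic_pops
        }
        if is_pos:
            nominal = rng.uniform(*config.burden_range)
            n_patho = int(rng.binomial(n_cells, nominal))
            n_patho = min(max(n_patho, 1), n_cells)  # positive samples carry >= 1 pathogenic cell
        else:
            n_patho = 0
        n_healthy = n_cells - n_patho

        healthy_counts = rng.multinomial(n_healthy, healthy_w)
        X_h = _draw_mixture(rng, config.healthy_pops, healthy_counts, jitters)

        if n_patho > 0:
            if config.endotype_mixing == "single_per_sample":
                e = int(rng.choice(len(config.pathogenic_pops), p=patho_w))
                patho_counts = np.zeros(len(config.pathogenic_pops), dtype=int)
                patho_counts[e] = n_patho
            else:
                patho_counts = rng.multinomial(n_patho, patho_w)
            X_p = _draw_mixture(rng, config.pathogenic_pops, patho_counts, jitters)
            X = np.vstack([X_h, X_p]) if X_h.size else X_p
            z = np.concatenate([np.zeros(len(X_h), dtype=int), np.ones(n_patho, dtype=int)])
        else:
            X = X_h
            z = np.zeros(n_cells, dtype=int)

        perm = rng.permutation(n_cells)
        X, z = X[perm], z[perm]
        realized = float(np.mean(z))
        samples.append(
            SampleRecord(
                events=EventMatrix(sid, X),
                label=int(is_pos),
                burden=realized,
            )
        )
        truth.cell_labels[sid] = z
        truth.true_burden[sid] = realized

    truth.validate()
    return Cohort(panel=panel, samples=samples), truth


# ---------------------------------------------------------------------------
# Standard fixture: the cohort configuration used throughout the test suite
# and the worked examples.  8 transformed markers; 3 healthy populations; 2
# pathogenic endotypes each at least 2 population-SDs away from every healthy
# population on at least 2 markers (population SD 0.5).
# ---------------------------------------------------------------------------

_SD = 0.5

_HEALTHY_MEANS = [
    [1.0, 3.0, 0.5, 2.0, 1.0, 0.5, 2.0, 1.0],
    [2.0, 1.0, 1.5, 0.5, 2.0, 1.0, 1.0, 2.0],
    [3.0, 0.5, 2.0, 1.0, 0.5, 2.0, 0.5, 3.0],
]
_HEALTHY_WEIGHTS = [0.5, 0.3, 0.2]

# Pathogenic endotypes are bright on two defining markers each (M4/M5 for
# endotype 0, M6/M7 for endotype 1), shifted 3 transformed units = 6
# population SDs from their nearest healthy neighbour — the separation a
# marker-positive blast population shows against marker-negative normal cells
# on the arcsinh scale (e.g. CD19+ vs CD19-), which is what makes the
# phenotypes gateable at all.  Remaining markers match healthy population 0.
_PATHO_MEANS = [
    [1.0, 3.0, 0.5, 2.0, 4.0, 3.5, 2.0, 1.0],
    [1.0, 3.0, 0.5, 2.0, 1.0, 0.5, 5.0, 4.0],
]


def standard_populations(n_markers: int = 8) -> Tuple[List[PopulationSpec], List[PopulationSpec]]:
    cov = (_SD ** 2) * np.eye(n_markers)
    healthy = [
        PopulationSpec(mean=np.array(m), covariance=cov, role="healthy", weight=w)
        for m, w in zip(_HEALTHY_MEANS, _HEALTHY_WEIGHTS)
    ]
    patho = [
        PopulationSpec(mean=np.array(m), covariance=cov, role="pathogenic", endotype_id=e)
        for e, m in enumerate(_PATHO_MEANS)
    ]
    return healthy, patho


def standard_fixture_config(
    seed: int,
    n_pos: int = 20,
    n_neg: int = 20,
    cells_per_sample: Tuple[int, int] = (5000, 10000),
    id_prefix: str = "s",
    pathogenic: bool = True,
    endotype_mixing: str = "mixture",
    jitter_sd: float = 0.15,
) -> SimConfig:
    """The standard 8-marker benchmark cohort configuration.

    Positive samples carry a mixture of both pathogenic endotypes
    (within-sample phenotypic heterogeneity); `endotype_mixing=
    "single_per_sample"` switches to between-sample heterogeneity only.
    With `pathogenic=False` the pathogenic populations are removed and all
    samples are healthy — the negative-control cohort.
    """
    healthy, patho = standard_populations()
    if not pathogenic:
        return SimConfig(
            n_markers=8,
            healthy_pops=healthy,
            pathogenic_pops=patho,  # defined but unused: n_pos = 0
            n_pos=0,
            n_neg=n_pos + n_neg,
            cells_per_sample=cells_per_sample,
            jitter_sd=jitter_sd,
            seed=seed,
            id_prefix=id_prefix,
        )
    return SimConfig(
        n_markers=8,
        healthy_pops=healthy,
        pathogenic_pops=patho,
        n_pos=n_pos,
        n_neg=n_neg,
        cells_per_sample=cells_per_sample,
        jitter_sd=jitter_sd,
        seed=seed,
        id_prefix=id_prefix,
        endotype_mixing=endotype_mixing,
    )


def write_cohort(cohort: Cohort, ground_truth: Optional[GroundTruth], out_dir) -> Path:
    """Write one TSV per sample, a manifest, and a ground-truth sidecar.

    Returns the manifest path.  `read_manifest` round-trips the cohort.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, str] = {}
    for s in cohort.samples:
        fname = f"{s.sample_id}.tsv"
        write_table(out_dir / fname, s.events, cohort.panel)
        paths[s.sample_id] = fname
    manifest = out_dir / "manifest.json"
    write_manifest(manifest, cohort, paths)
    if ground_truth is not None:
        sidecar = {
            "cell_labels": {k: [int(v) for v in arr] for k, arr in ground_truth.cell_labels.items()},
            "true_burden": {k: float(v) for k, v in ground_truth.true_burden.items()},
        }
        (out_dir / "ground_truth.json").write_text(json.dumps(sidecar))
    return manifest


def read_ground_truth(path) -> GroundTruth:
    doc = json.loads(Path(path).read_text())
    gt = GroundTruth(
        cell_labels={k: np.asarray(v, dtype=int) for k, v in doc["cell_labels"].items()},
        true_burden={k: float(v) for k, v in doc["true_burden"].items()},
    )
    gt.validate()
    return gt
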