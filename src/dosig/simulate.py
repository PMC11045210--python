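"""Synthetic fixtures with planted structure.

Generates a two-class log-normal expression matrix with a known set of
differentially expressed genes, a disease annotation map containing one
term enriched for those genes, and exponential survival times whose
log-hazard is linear in one designated prognostic gene's expression. The
truth record makes every planted element recoverable, so each pipeline
stage can be benchmarked without external downloads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .io import AnnotationMap, ExpressionDataset, SurvivalTable


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic dataset.

    Defaults emulate a modest bulk RNA-Seq cohort: 1000 genes, 30 tumor +
    30 normal samples, 15 planted genes shifted by 2 log2 units against a
    within-class SD of 0.5, one disease term covering 80% of the planted
    genes, and exponential survival (time unit: days) for tumor samples
    with roughly a two-fold hazard ratio across the prognostic gene's
    median split.
    """

    n_genes: int = 1000
    n_tumor: int = 30
    n_normal: int = 30
    n_planted_deg: int = 15
    shift_log2: float = 2.0
    noise_sd_log2: float = 0.5
    n_terms: int = 20
    planted_term_coverage: float = 0.8
    background_annotation_rate: float = 0.05
    baseline_rate: float = np.log(2) / 730.0   # median survival ~2 years
    hazard_log2_slope: float = 1.25
    censoring_rate: float = 0.3
    scale: str = io.LINEAR
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_tumor", "n_normal", "n_terms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_planted_deg < 0 or self.n_planted_deg > self.n_genes:
            raise ValueError("n_planted_deg must lie in [0, n_genes]")
        for name in ("planted_term_coverage", "background_annotation_rate", "censoring_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd_log2 <= 0 or self.baseline_rate <= 0:
            raise ValueError("noise_sd_log2 and baseline_rate must be positive")


@dataclass
class FixtureBundle:
    dataset: ExpressionDataset
    annotation: AnnotationMap
    survival: SurvivalTable
    truth: dict


def generate_fixture(spec: FixtureSpec) -> FixtureBundle:
    """Deterministic fixture for a given spec (same seed => same bytes)."""
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:04d}" for i in range(1, spec.n_genes + 1)]
    samples = [f"T{i:03d}" for i in range(1, spec.n_tumor + 1)] + [
        f"N{i:03d}" for i in range(1, spec.n_normal + 1)
    ]
    labels = pd.Series(
        [io.TUMOR] * spec.n_tumor + [io.NORMAL] * spec.n_normal, index=samples
    )

    baseline = rng.normal(5.0, 1.5, size=spec.n_genes)
    log2_vals = baseline[:, None] + rng.normal(
        0.0, spec.noise_sd_log2, size=(spec.n_genes, spec.n_tumor + spec.n_normal)
    )
    planted_idx = np.sort(
        rng.choice(spec.n_genes, size=spec.n_planted_deg, replace=False)
    )
    signs = rng.choice([-1.0, 1.0], size=spec.n_planted_deg)
    for j, (gi, sign) in enumerate(zip(planted_idx, signs)):
        log2_vals[gi, : spec.n_tumor] += sign * spec.shift_log2
    planted_genes = [genes[i] for i in planted_idx]

    if spec.scale == io.LINEAR:
        values = pd.DataFrame(2.0 ** log2_vals, index=genes, columns=samples)
    else:
        values = pd.DataFrame(log2_vals, index=genes, columns=samples)
    dataset = ExpressionDataset(values, labels, spec.scale)

    # annotation map: one planted disease term + random background terms
    planted_set = set(planted_genes)
    n_cov = int(round(spec.planted_term_coverage * spec.n_planted_deg))
    covered = list(
        rng.choice(planted_genes, size=n_cov, replace=False)
    ) if n_cov else []
    background_pool = [g for g in genes if g not in planted_set]
    bg_mask = rng.random(len(background_pool)) < spec.background_annotation_rate
    planted_term_genes = set(covered) | {
        g for g, m in zip(background_pool, bg_mask) if m
    }
    if not planted_term_genes:
        planted_term_genes = set(covered) or {background_pool[0]}
    term_to_genes = {"DOID:0001": frozenset(planted_term_genes)}
    term_names = {"DOID:0001": "planted disease"}
    for t in range(2, spec.n_terms + 1):
        size = int(rng.integers(10, 40))
        members = rng.choice(genes, size=min(size, spec.n_genes), replace=False)
        tid = f"DOID:{t:04d}"
        term_to_genes[tid] = frozenset(members)
        term_names[tid] = f"background term {t}"
    annotation = AnnotationMap(term_to_genes, term_names)

    # survival for tumor samples, hazard linear (log2 scale) in one planted gene
    prog_gene = planted_genes[int(rng.integers(0, len(planted_genes)))] if planted_genes else genes[0]
    tumor_ids = samples[: spec.n_tumor]
    x = dataset.log2_matrix().loc[prog_gene, tumor_ids].to_numpy(float)
    rates = spec.baseline_rate * 2.0 ** (spec.hazard_log2_slope * (x - x.mean()))
    t_event = rng.exponential(1.0 / rates)
    if spec.censoring_rate > 0:
        rate_c = spec.baseline_rate * spec.censoring_rate / (1.0 - spec.censoring_rate)
        t_cens = rng.exponential(1.0 / rate_c, size=len(tumor_ids))
    else:
        t_cens = np.full(len(tumor_ids), np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    surv = SurvivalTable(
        pd.DataFrame(
            {"time": np.maximum(time, 1e-3), "event": event},
            index=pd.Index(tumor_ids, name="sample_id"),
        )
    )

    truth = {
        "planted_genes": planted_genes,
        "shift_signs": {g: float(s) for g, s in zip(planted_genes, signs)},
        "planted_term": "DOID:0001",
        "prognostic_gene": prog_gene,
        "spec": {k: (v if not isinstance(v, float) else float(v)) for k, v in asdict(spec).items()},
    }
    return FixtureBundle(dataset, annotation, surv, truth)


def write_fixture(bundle: FixtureBundle, directory) -> dict[str, Path]:
    """Write the bundle in exactly the formats the readers consume."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "labels": directory / "labels.tsv",
        "gmt": directory / "annotation.gmt",
        "survival": directory / "survival.tsv",
        "truth": directory / "truth.json",
    }
    io.write_expression(bundle.dataset, paths["expression"], labels_path=paths["labels"])
    io.write_gmt(bundle.annotation, paths["gmt"])
    io.write_survival(bundle.survival, paths["survival"])
    paths["truth"].write_text(json.dumps(bundle.truth, indent=2, sort_keys=True))
    return paths
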