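"""End-to-end orchestration: DE -> disease enrichment -> Wilks trimming ->
RBF-SVM gate -> prognostic screen.

A single global seed deterministically derives per-stage seeds through
``numpy.random.SeedSequence(seed).spawn``, so one integer reproduces the
split, the CV folds and every downstream number. Results serialize to a
directory of TSV/JSON artifacts; the report JSON is byte-stable across
reruns of the same config+seed (timings live in provenance.json only).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, diffexpr, enrichment, selection, survival as surv_mod
from .io import (
    AnnotationMap,
    ExpressionDataset,
    SurvivalTable,
    read_expression,
    read_gmt,
    read_obo_isa,
    read_survival,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables in one validated place.

    Threshold defaults: DE adjusted p < 0.05 with |log2FC| >= 1.5 and
    input size n; enrichment adjusted p < 0.05; niveau 0.10 lowered in
    0.01 steps to 0.05; 80/20 stratified split; 10-fold CV over decade
    grids gamma in [1e-6, 1e6], C in [1e-5, 1e5]; acceptance gates kappa
    and specificity > 0.80 with binomial accuracy-vs-NIR p < 0.05;
    log-rank p < 0.05 for the prognostic screen.
    """

    expression: str | None = None
    labels: str | None = None
    gmt: str | None = None
    obo: str | None = None
    survival: str | None = None
    orientation: str = "genes_in_rows"
    scale: str = "linear"

    de_p_adj: float = 0.05
    de_fc: float = 1.5
    de_n: int | None = 50
    de_epsilon: float = 0.25

    enrich_universe: str = "intersection"   # or "annotated"
    enrich_propagate: bool = False
    enrich_p: float = 0.05
    enrich_min_term_size: int = 2

    niveau_init: float = 0.1
    niveau_floor: float = 0.05
    niveau_step: float = 0.01
    trimming_mode: str = "reselect"

    train_frac: float = 0.8
    cv_folds: int = 10
    kappa_cut: float = 0.8
    spec_cut: float = 0.8
    nir_p_cut: float = 0.05
    pca_components: int = 2
    pca_coverage: float = 0.8

    survival_p: float = 0.05
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("de_p_adj", 0, 1), ("enrich_p", 0, 1), ("survival_p", 0, 1),
            ("niveau_init", 0, 1), ("niveau_floor", 0, 1),
            ("kappa_cut", -1, 1), ("spec_cut", 0, 1), ("nir_p_cut", 0, 1),
            ("pca_coverage", 0, 1),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must lie in (0, 1)")
        if self.de_fc < 0 or self.niveau_step <= 0:
            raise ValueError("de_fc must be >= 0 and niveau_step > 0")
        if self.enrich_universe not in ("intersection", "annotated"):
            raise ValueError("enrich_universe must be 'intersection' or 'annotated'")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def derive_stage_seeds(seed: int) -> dict[str, int]:
    """Per-stage 31-bit seeds spawned from the global seed."""
    children = np.random.SeedSequence(seed).spawn(3)
    names = ["split", "cv", "aux"]
    return {
        name: int(child.generate_state(1)[0] % (2 ** 31))
        for name, child in zip(names, children)
    }


@dataclass
class PipelineResult:
    status: str                                # "ok" or "empty:<stage>"
    config: PipelineConfig
    deg: diffexpr.DEGTable | None = None
    enrichment: pd.DataFrame | None = None
    filtered_genes: list[str] = field(default_factory=list)
    trace: selection.SelectionTrace | None = None
    signature: list[str] = field(default_factory=list)
    report: classify.ClassifierReport | None = None
    auc: float | None = None
    roc_points: pd.DataFrame | None = None
    pca_coverage: float | None = None
    pca_gate: bool | None = None
    prognosis: pd.DataFrame | None = None
    timings: dict = field(default_factory=dict)

    def check_containment(self) -> None:
        """Signature subseteq filtered DEGs subseteq DEGs (hard invariant)."""
        deg_set = set(self.deg.genes) if self.deg is not None else set()
        filt = set(self.filtered_genes)
        sig = set(self.signature)
        if not filt <= deg_set:
            raise AssertionError("filtered genes escape the DEG list")
        if not sig <= filt:
            raise AssertionError("signature escapes the enrichment-filtered DEG list")

    def to_report_dict(self) -> dict:
        out = {
            "status": self.status,
            "seed": self.config.seed,
            "config_hash": self.config.content_hash(),
            "n_deg": len(self.deg.genes) if self.deg is not None else 0,
            "deg_genes": self.deg.genes if self.deg is not None else [],
            "n_enriched_terms": (
                int((self.enrichment["p_adj"] < self.config.enrich_p).sum())
                if self.enrichment is not None and len(self.enrichment)
                else 0
            ),
            "filtered_genes": self.filtered_genes,
            "signature": self.signature,
            "niveau_used": self.trace.niveau_used if self.trace else None,
            "classifier": self.report.to_dict() if self.report else None,
            "auc": self.auc,
            "pca_coverage": self.pca_coverage,
            "pca_gate": self.pca_gate,
            "prognostic_genes": (
                self.prognosis.to_dict(orient="records") if self.prognosis is not None else None
            ),
        }
        return out

    def to_report_json(self) -> str:
        return json.dumps(self.to_report_dict(), indent=2, sort_keys=True)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if self.deg is not None:
            self.deg.to_tsv(outdir / "deg.tsv")
        if self.enrichment is not None:
            enrichment.write_enrichment_tsv(self.enrichment, outdir / "enrichment.tsv")
        if self.trace is not None:
            self.trace.to_tsv(outdir / "selection.tsv")
        if self.roc_points is not None:
            self.roc_points.to_csv(outdir / "roc.tsv", sep="\t", index=False)
        if self.prognosis is not None:
            surv_mod.write_prognosis_tsv(self.prognosis, outdir / "prognosis.tsv")
        (outdir / "report.json").write_text(self.to_report_json())
        provenance = {
            "config": self.config.to_dict(),
            "config_hash": self.config.content_hash(),
            "seed": self.config.seed,
            "stage_seeds": derive_stage_seeds(self.config.seed),
            "timings_s": self.timings,
        }
        (outdir / "provenance.json").write_text(
            json.dumps(provenance, indent=2, sort_keys=True, default=str)
        )


def _roc_points(scores: np.ndarray, y_true: np.ndarray) -> pd.DataFrame:
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve((y_true == "tumor").astype(int), scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def run_pipeline_data(
    ds: ExpressionDataset,
    amap: AnnotationMap,
    surv: SurvivalTable | None,
    cfg: PipelineConfig,
) -> PipelineResult:
    """Run all stages on in-memory inputs; early-exits are structured, not errors."""
    result = PipelineResult(status="ok", config=cfg)
    seeds = derive_stage_seeds(cfg.seed)
    t0 = time.perf_counter()

    # 1. differential expression
    deg = diffexpr.run_differential_expression(
        ds, p_cut=cfg.de_p_adj, fc_cut=cfg.de_fc, n=cfg.de_n, epsilon=cfg.de_epsilon
    )
    result.deg = deg
    result.timings["diffexpr"] = round(time.perf_counter() - t0, 4)
    logger.info("DE stage: %d genes retained", len(deg.genes))
    if deg.is_empty():
        result.status = "empty:diffexpr"
        return result

    # 2. disease over-representation filter
    t1 = time.perf_counter()
    amap_used = enrichment.propagate_annotations(amap) if cfg.enrich_propagate else amap
    if cfg.enrich_universe == "intersection":
        universe = frozenset(ds.gene_ids) & amap_used.all_genes
    else:
        universe = amap_used.all_genes
    query = [g for g in deg.genes if g in universe]
    enr = enrichment.enrich(
        query, amap_used, universe,
        min_term_size=cfg.enrich_min_term_size, p_cut=cfg.enrich_p,
    ) if query else pd.DataFrame(columns=enrichment.RESULT_COLUMNS)
    result.enrichment = enr
    filtered = enrichment.filter_genes_by_enrichment(deg.genes, enr, p_cut=cfg.enrich_p)
    result.filtered_genes = filtered
    result.timings["enrichment"] = round(time.perf_counter() - t1, 4)
    logger.info("enrichment stage: %d genes kept", len(filtered))
    if not filtered:
        result.status = "empty:enrichment"
        return result

    # 3. Wilks' lambda trimming
    t2 = time.perf_counter()
    X_all = ds.log2_matrix(cfg.de_epsilon).loc[filtered].T  # samples x genes
    y_all = ds.labels.to_numpy()
    try:
        signature, trace = selection.trimming_loop(
            X_all, y_all,
            niveau_init=cfg.niveau_init, niveau_floor=cfg.niveau_floor,
            step=cfg.niveau_step, mode=cfg.trimming_mode,
        )
    except selection.NoDiscriminativeSet:
        result.status = "empty:selection"
        result.timings["selection"] = round(time.perf_counter() - t2, 4)
        return result
    result.trace = trace
    result.signature = signature
    result.timings["selection"] = round(time.perf_counter() - t2, 4)
    logger.info("selection stage: signature of %d genes at niveau %.2f",
                len(signature), trace.niveau_used)
    result.check_containment()

    # 4. RBF-SVM gate + diagnostics
    t3 = time.perf_counter()
    X_sig = X_all[signature]
    train_ids, test_ids = classify.stratified_split(
        ds.labels, train_frac=cfg.train_frac, seed=seeds["split"]
    )
    grid = classify.TuneGrid(cv_folds=cfg.cv_folds, seed=seeds["cv"])
    X_train = X_sig.loc[train_ids].to_numpy(float)
    y_train = ds.labels.loc[train_ids].to_numpy()
    X_test = X_sig.loc[test_ids].to_numpy(float)
    y_test = ds.labels.loc[test_ids].to_numpy()
    gamma, C, cv_acc = classify.tune_rbf_svm(X_train, y_train, grid)
    model = classify.make_rbf_svm(gamma, C).fit(X_train, y_train)
    result.report = classify.evaluate_classifier(
        model, X_test, y_test,
        kappa_cut=cfg.kappa_cut, spec_cut=cfg.spec_cut, p_cut=cfg.nir_p_cut,
        best_gamma=gamma, best_C=C,
    )
    scores = model.decision_function(X_test)
    result.auc = classify.roc_auc(scores, y_test)
    result.roc_points = _roc_points(scores, y_test)
    k = min(cfg.pca_components, min(X_sig.shape) - 1) or 1
    result.pca_coverage = classify.pca_variance_check(X_sig.to_numpy(float), k)
    result.pca_gate = result.pca_coverage >= cfg.pca_coverage
    result.timings["classification"] = round(time.perf_counter() - t3, 4)

    # 5. prognostic screen
    if surv is not None:
        t4 = time.perf_counter()
        try:
            result.prognosis = surv_mod.prognostic_screen(
                ds, signature, surv, p_cut=cfg.survival_p
            )
        except ValueError as exc:
            logger.warning("prognostic screen skipped: %s", exc)
            result.prognosis = None
        result.timings["survival"] = round(time.perf_counter() - t4, 4)

    result.check_containment()
    return result


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Load inputs from the config paths, run all stages, write artifacts."""
    if not cfg.expression:
        raise ValueError("config must name an expression matrix")
    if not cfg.gmt:
        raise ValueError("config must name a GMT annotation file")
    ds = read_expression(
        cfg.expression, orientation=cfg.orientation, scale=cfg.scale,
        labels_path=cfg.labels,
    )
    amap = read_gmt(cfg.gmt)
    if cfg.obo:
        amap = AnnotationMap(
            dict(amap.term_to_genes), dict(amap.term_names), read_obo_isa(cfg.obo)
        )
    surv = read_survival(cfg.survival) if cfg.survival else None
    result = run_pipeline_data(ds, amap, surv, cfg)
    if cfg.outdir:
        result.write(cfg.outdir)
    return result
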