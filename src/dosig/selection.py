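"""Stepwise discriminant feature selection by Wilks' lambda.

Forward selection for two groups: at each step the candidate gene whose
addition minimizes the overall Wilks' lambda

    Lambda = det(W) / det(W + B)

(W pooled within-group, B between-group cross-products) enters the model,
provided the partial-F test of its contribution is significant at the
current entry threshold ("niveau"). An outer trimming loop lowers the
niveau from 0.10 toward 0.05 until every entered feature is individually
significant at 0.05, mirroring the adaptive gene-set trimming used ahead
of SVM classification.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_LAMBDA_FLOOR = 1e-300


class SingularWithinScatter(ValueError):
    """W is singular for the attempted feature set; the candidate must be
    skipped (collinear with features already in the model)."""


class SampleSizeExhausted(ValueError):
    """Error degrees of freedom would drop to zero; selection must stop."""


class NoDiscriminativeSet(ValueError):
    """Every trimming iteration produced an empty selection."""


@dataclass
class SelectionStep:
    gene_id: str
    lambda_overall: float
    partial_F: float
    p_enter: float
    step_index: int


@dataclass
class SelectionTrace:
    steps: list[SelectionStep] = field(default_factory=list)
    niveau_used: float = 0.1
    converged: bool = True

    @property
    def genes(self) -> list[str]:
        return [s.gene_id for s in self.steps]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (s.step_index, s.gene_id, s.lambda_overall, s.partial_F, s.p_enter)
                for s in self.steps
            ],
            columns=["step_index", "gene_id", "lambda_overall", "partial_F", "p_enter"],
        )

    def to_tsv(self, path) -> None:
        path = Path(path)
        header = json.dumps({"niveau_used": self.niveau_used, "converged": self.converged})
        with open(path, "w") as fh:
            fh.write(f"#{header}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


def _scatter_matrices(X: np.ndarray, groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Pooled within-group (W) and total (T) cross-products of deviations."""
    total = X - X.mean(axis=0)
    T = total.T @ total
    W = np.zeros_like(T)
    for idx in groups:
        sub = X[idx]
        dev = sub - sub.mean(axis=0)
        W += dev.T @ dev
    return W, T


def _group_indices(labels) -> list[np.ndarray]:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"expected exactly 2 classes, got {classes.size}")
    return [np.flatnonzero(labels == c) for c in classes]


def wilks_lambda(X, labels) -> float:
    """Overall Wilks' lambda det(W)/det(W+B) for samples x features ``X``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] <= X.shape[1] + 2:  # require N > p + g with g = 2
        raise ValueError(
            f"need N > p + 2 samples (N={X.shape[0]}, p={X.shape[1]})"
        )
    groups = _group_indices(labels)
    W, T = _scatter_matrices(X, groups)
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_w <= 0 or not np.isfinite(logdet_w):
        raise SingularWithinScatter("within-group scatter matrix is singular")
    if sign_t <= 0 or not np.isfinite(logdet_t):
        raise SingularWithinScatter("total scatter matrix is singular")
    lam = float(np.exp(logdet_w - logdet_t))
    return min(max(lam, _LAMBDA_FLOOR), 1.0)


def partial_f_enter(
    lambda_new: float, lambda_old: float, N: int, g: int, p_after: int
) -> tuple[float, float]:
    """Partial-F test for the feature just entered.

    ``p_after`` is the model size including the new feature; degrees of
    freedom are (g-1, N-g-p_after+1).
    """
    if not (0 < lambda_new <= lambda_old <= 1):
        raise ValueError(
            f"require 0 < lambda_new <= lambda_old <= 1, got {lambda_new}, {lambda_old}"
        )
    df2 = N - g - p_after + 1
    if df2 <= 0:
        raise SampleSizeExhausted(f"df2 = {df2} <= 0 at model size {p_after}")
    lam_partial = min(lambda_new / lambda_old, 1.0)
    df1 = g - 1
    F = (1.0 - lam_partial) / max(lam_partial, _LAMBDA_FLOOR) * df2 / df1
    p = float(stats.f.sf(F, df1, df2)) if F > 0 else 1.0
    return float(F), p


def greedy_forward_select(X: pd.DataFrame, labels, niveau: float) -> SelectionTrace:
    """Forward Wilks'-lambda selection at a fixed entry threshold.

    ``X`` is samples x candidate-genes. Ties at equal lambda break toward
    the larger partial F, then the lexicographically smaller gene id.
    Stops when the best candidate's entry p exceeds ``niveau``, when the
    error degrees of freedom would be exhausted, or when no candidates
    remain.
    """
    if X.shape[1] < 1:
        raise ValueError("need at least one candidate feature")
    labels = np.asarray(labels)
    groups = _group_indices(labels)
    if min(len(g) for g in groups) < 2:
        raise ValueError("both classes need >= 2 samples")
    N, g = X.shape[0], 2

    remaining = list(X.columns)
    selected: list[str] = []
    trace = SelectionTrace(niveau_used=niveau, converged=True)
    lambda_current = 1.0

    while remaining:
        p_after = len(selected) + 1
        if N - g - p_after + 1 <= 0 or N <= p_after + 2:
            break  # error degrees of freedom exhausted
        best: tuple[float, str] | None = None  # (lambda, gene)
        for gene in sorted(remaining):
            cols = selected + [gene]
            try:
                lam = wilks_lambda(X[cols].to_numpy(float), labels)
            except (SingularWithinScatter, ValueError) as exc:
                if isinstance(exc, SingularWithinScatter):
                    logger.debug("skipping collinear candidate %s: %s", gene, exc)
                    continue
                raise
            if best is None or lam < best[0] - 1e-15:
                best = (lam, gene)
            # equal lambda => equal partial F; lexicographic order of the
            # sorted scan already realizes the documented tie-break
        if best is None:
            if not selected:
                trace.converged = False
            break
        lam_new, gene = best
        F, p = partial_f_enter(min(lam_new, lambda_current), lambda_current, N, g, p_after)
        if p > niveau:
            break
        selected.append(gene)
        remaining.remove(gene)
        lambda_current = min(lam_new, lambda_current)
        trace.steps.append(
            SelectionStep(gene, lambda_current, F, p, step_index=len(selected))
        )
    if not trace.steps and trace.converged:
        # nothing met the entry threshold; still a converged (empty) outcome
        pass
    return trace


def trimming_loop(
    X: pd.DataFrame,
    labels,
    niveau_init: float = 0.1,
    niveau_floor: float = 0.05,
    step: float = 0.01,
    final_cut: float = 0.05,
    mode: str = "reselect",
) -> tuple[list[str], SelectionTrace]:
    """Adaptive trimming: lower the niveau until all entries pass 0.05.

    ``mode="reselect"`` reruns the whole forward selection at each reduced
    niveau (default); ``mode="filter"`` keeps the first-pass entry order
    and merely drops trailing steps whose entry p exceeds ``final_cut``.
    Returns the last non-empty selection and its trace.
    """
    if mode not in ("reselect", "filter"):
        raise ValueError(f"unknown trimming mode {mode!r}")
    last_nonempty: SelectionTrace | None = None
    niveau = niveau_init
    while niveau >= niveau_floor - 1e-12:
        trace = greedy_forward_select(X, labels, niveau)
        if trace.steps:
            last_nonempty = trace
            if all(s.p_enter <= final_cut for s in trace.steps):
                return trace.genes, trace
            if mode == "filter":
                keep = []
                for s in trace.steps:
                    if s.p_enter > final_cut:
                        break
                    keep.append(s)
                if keep:
                    filtered = SelectionTrace(keep, niveau_used=trace.niveau_used, converged=True)
                    return filtered.genes, filtered
        niveau = round(niveau - step, 10)
    if last_nonempty is None:
        raise NoDiscriminativeSet("no discriminative set found at any niveau")
    return last_nonempty.genes, last_nonempty
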