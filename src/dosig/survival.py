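"""Single-gene prognostic screening.

Samples are dichotomized at the median expression of each signature gene,
the two groups' survival is compared with the log-rank test, and the
hazard ratio is approximated by the Pike observed/expected estimator
(O_A/E_A)/(O_B/E_B). Genes with log-rank p < 0.05 are reported as
prognostic candidates. Ties between an event and a censoring at the same
time follow the standard convention: events precede censorings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionDataset, SurvivalTable

logger = logging.getLogger(__name__)

LOW, HIGH = "low", "high"


@dataclass
class KMCurve:
    """Kaplan-Meier estimate over the distinct event times."""

    times: np.ndarray          # ascending distinct event times
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray        # n at risk just before each event time

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    observed_a: float
    observed_b: float
    expected_a: float
    expected_b: float
    variance: float
    chi2: float
    p: float
    hazard_ratio: float
    degenerate: bool = False


def km_estimate(times, events) -> KMCurve:
    """Product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i/n_i)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    order = np.argsort(times, kind="mergesort")
    times, events = times[order], events[order]
    event_times = np.unique(times[events == 1])
    surv, at_risk = [], []
    s = 1.0
    for t in event_times:
        n_i = int((times >= t).sum())  # events at t precede censorings at t
        d_i = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
    return KMCurve(event_times, np.asarray(surv), np.asarray(at_risk, dtype=int))


def logrank_test(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Two-group log-rank test with the Pike O/E hazard-ratio estimate.

    At each distinct event time with d pooled events, N at risk and n_a at
    risk in group A: E_A accrues d*n_a/N and the variance accrues
    d*(n_a/N)*(1-n_a/N)*(N-d)/(N-1) (zero when N = 1).
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("need at least one event overall")

    pooled_event_times = np.unique(
        np.concatenate([ta[ea == 1], tb[eb == 1]])
    )
    O_a = float(ea.sum())
    O_b = float(eb.sum())
    E_a = 0.0
    V = 0.0
    for t in pooled_event_times:
        n_a = int((ta >= t).sum())
        n_b = int((tb >= t).sum())
        N = n_a + n_b
        d = int(((ta == t) & (ea == 1)).sum() + ((tb == t) & (eb == 1)).sum())
        E_a += d * n_a / N
        if N > 1:
            V += d * (n_a / N) * (1 - n_a / N) * (N - d) / (N - 1)
    E_b = (O_a + O_b) - E_a

    degenerate = V <= 0
    if degenerate:
        logger.info("log-rank variance is zero: degenerate comparison")
        chi2, p = 0.0, 1.0
    else:
        chi2 = (O_a - E_a) ** 2 / V
        p = float(stats.chi2.sf(chi2, df=1))

    if E_a > 0 and E_b > 0 and O_b > 0:
        hr = (O_a / E_a) / (O_b / E_b)
    else:
        hr = np.inf if O_a > 0 else 1.0
    return LogRankResult(O_a, O_b, E_a, E_b, V, float(chi2), p, float(hr), degenerate)


def dichotomize_by_gene(ds: ExpressionDataset, gene_id: str, samples=None) -> pd.Series:
    """Median split of samples by one gene's expression; ties go to ``low``."""
    if gene_id not in ds.values.index:
        raise KeyError(f"gene {gene_id!r} not in dataset")
    row = ds.values.loc[gene_id]
    if samples is not None:
        row = row[list(samples)]
    vals = row.to_numpy(dtype=float)
    if np.all(vals == vals[0]):
        raise ValueError(f"non-informative gene {gene_id!r}: constant expression")
    median = float(np.median(vals))
    groups = np.where(vals <= median, LOW, HIGH)
    return pd.Series(groups, index=row.index, name=gene_id)


def prognostic_screen(
    ds: ExpressionDataset,
    signature,
    surv: SurvivalTable,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Per-gene median-split log-rank screen of a signature.

    The hazard ratio reported is high-expression relative to
    low-expression. Genes whose split leaves fewer than two samples on a
    side (or is constant) are skipped with a log message. Output columns:
    gene, logrank_p, hazard_ratio; sorted by p ascending; only genes with
    p < ``p_cut`` are retained.
    """
    signature = list(signature)
    overlap = [s for s in ds.sample_ids if s in set(surv.sample_ids)]
    if not overlap:
        raise ValueError("no overlap between expression samples and survival table")
    if len(overlap) < 10:
        raise ValueError(f"need >= 10 samples with survival records, got {len(overlap)}")
    rows = []
    for gene in signature:
        try:
            groups = dichotomize_by_gene(ds, gene, samples=overlap)
        except ValueError as exc:
            logger.info("skipping %s: %s", gene, exc)
            continue
        low_ids = list(groups.index[groups == LOW])
        high_ids = list(groups.index[groups == HIGH])
        if len(low_ids) < 2 or len(high_ids) < 2:
            logger.info("skipping %s: degenerate median split", gene)
            continue
        t_hi, e_hi = surv.times_events(high_ids)
        t_lo, e_lo = surv.times_events(low_ids)
        if e_hi.sum() + e_lo.sum() == 0:
            logger.info("skipping %s: no events", gene)
            continue
        res = logrank_test(t_hi, e_hi, t_lo, e_lo)
        rows.append((gene, res.p, res.hazard_ratio))
    df = pd.DataFrame(rows, columns=["gene", "logrank_p", "hazard_ratio"])
    df = df[df["logrank_p"] < p_cut]
    return df.sort_values(["logrank_p", "gene"], kind="mergesort").reset_index(drop=True)


def write_prognosis_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(Path(path), sep="\t", index=False)
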