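import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dosig import selection
from conftest import two_class_gaussian


# --- independent oracles ----------------------------------------------


def wilks_eigen_oracle(X, y):
    """Lambda = prod 1/(1+lam_i) over eigenvalues of W^-1 B (separate route)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    classes = np.unique(y)
    grand = X.mean(axis=0)
    W = np.zeros((X.shape[1], X.shape[1]))
    B = np.zeros_like(W)
    for c in classes:
        sub = X[y == c]
        m = sub.mean(axis=0)
        W += (sub.shape[0] - 1) * np.cov(sub, rowvar=False, ddof=1).reshape(W.shape)
        B += sub.shape[0] * np.outer(m - grand, m - grand)
    eigvals = np.linalg.eigvals(np.linalg.solve(W, B))
    return float(np.prod(1.0 / (1.0 + eigvals.real)))


def oracle_stepwise(X, y, niveau):
    """Exhaustive-step reference: at every step score *all* remaining
    candidates via the eigenvalue route and apply the same entry rule."""
    N, g = X.shape[0], 2
    remaining = sorted(X.columns)
    selected = []
    lam_cur = 1.0
    while remaining:
        p_after = len(selected) + 1
        if N - g - p_after + 1 <= 0 or N <= p_after + 2:
            break
        scored = []
        for gene in remaining:
            cols = selected + [gene]
            try:
                lam = wilks_eigen_oracle(X[cols].to_numpy(), y)
            except np.linalg.LinAlgError:
                continue
            if not np.isfinite(lam) or lam <= 0:
                continue
            scored.append((lam, gene))
        if not scored:
            break
        lam_new, gene = min(scored, key=lambda t: (t[0], t[1]))
        lam_new = min(lam_new, lam_cur)
        df2 = N - g - p_after + 1
        lam_part = min(lam_new / lam_cur, 1.0)
        F = (1 - lam_part) / max(lam_part, 1e-300) * df2 / (g - 1)
        p = stats.f.sf(F, g - 1, df2) if F > 0 else 1.0
        if p > niveau:
            break
        selected.append(gene)
        remaining.remove(gene)
        lam_cur = lam_new
    return selected


# --- Wilks lambda -------------------------------------------------------


def test_wilks_lambda_scalar_toy():
    X = np.array([[1.0], [2.0], [3.0], [4.0]])
    y = ["A", "A", "B", "B"]
    assert selection.wilks_lambda(X, y) == pytest.approx(0.2, abs=1e-12)


def test_wilks_lambda_no_separation_is_one():
    X = np.array([[1.0], [3.0], [1.0], [3.0]])
    y = ["A", "A", "B", "B"]
    assert selection.wilks_lambda(X, y) == pytest.approx(1.0)


def test_wilks_lambda_matches_eigen_oracle():
    rng = np.random.default_rng(2)
    for _ in range(20):
        X, y = two_class_gaussian(rng, n_per_class=15, n_features=2, shift=0.7)
        lam = selection.wilks_lambda(X.to_numpy(), y)
        assert lam == pytest.approx(wilks_eigen_oracle(X.to_numpy(), y), abs=1e-10)


def test_wilks_lambda_singular_scatter():
    X = np.column_stack([np.arange(10.0), np.arange(10.0) * 2])  # collinear
    y = ["A"] * 5 + ["B"] * 5
    with pytest.raises(selection.SingularWithinScatter):
        selection.wilks_lambda(X, y)


# --- partial F ----------------------------------------------------------


def test_partial_f_first_entry_worked_example():
    F, p = selection.partial_f_enter(0.2, 1.0, N=4, g=2, p_after=1)
    assert F == pytest.approx(8.0, abs=1e-12)
    assert p == pytest.approx(0.1056, abs=1e-4)


def test_partial_f_no_improvement():
    F, p = selection.partial_f_enter(0.5, 0.5, N=20, g=2, p_after=3)
    assert F == 0.0 and p == 1.0


def test_partial_f_monotone_in_partial_lambda():
    F1, _ = selection.partial_f_enter(0.4, 0.8, N=30, g=2, p_after=2)
    F2, _ = selection.partial_f_enter(0.2, 0.8, N=30, g=2, p_after=2)
    assert F2 > F1


def test_partial_f_df_exhaustion():
    with pytest.raises(selection.SampleSizeExhausted):
        selection.partial_f_enter(0.1, 0.5, N=6, g=2, p_after=6)


# --- greedy forward selection -------------------------------------------


def test_dominant_feature_selected_first():
    rng = np.random.default_rng(3)
    sep = np.concatenate([rng.normal(3, 1, 20), rng.normal(-3, 1, 20)])
    noise = rng.normal(size=40)
    X = pd.DataFrame({"signal": sep, "noise": noise})
    y = np.array(["tumor"] * 20 + ["normal"] * 20)
    trace = selection.greedy_forward_select(X, y, niveau=0.1)
    assert trace.steps[0].gene_id == "signal"


def test_zero_niveau_gives_empty_trace():
    rng = np.random.default_rng(4)
    X, y = two_class_gaussian(rng, n_per_class=10, n_features=3, shift=1.0)
    trace = selection.greedy_forward_select(X, y, niveau=0.0)
    assert trace.steps == []


def test_lambda_monotone_along_trace():
    rng = np.random.default_rng(5)
    X, y = two_class_gaussian(rng, n_per_class=20, n_features=6, shift=0.8)
    trace = selection.greedy_forward_select(X, y, niveau=0.5)
    lams = [s.lambda_overall for s in trace.steps]
    assert all(b <= a + 1e-12 for a, b in zip(lams, lams[1:]))
    assert all(s.partial_F >= 0 for s in trace.steps)


def test_selection_invariant_to_candidate_order():
    rng = np.random.default_rng(6)
    X, y = two_class_gaussian(rng, n_per_class=20, n_features=5, shift=0.8)
    shuffled = X[rng.permutation(X.columns)]
    a = selection.greedy_forward_select(X, y, niveau=0.1).genes
    b = selection.greedy_forward_select(shuffled, y, niveau=0.1).genes
    assert a == b


@pytest.mark.parametrize("seed", range(10))
def test_greedy_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    n_feat = int(rng.integers(2, 7))
    X, y = two_class_gaussian(rng, n_per_class=20, n_features=n_feat, shift=0.6)
    assert selection.greedy_forward_select(X, y, 0.1).genes == oracle_stepwise(X, y, 0.1)


# --- trimming loop ------------------------------------------------------


def _trimming_toy():
    """Feature A separates strongly; B's entry p lands in (0.05, 0.1)."""
    rng = np.random.default_rng(21)
    A = np.concatenate([rng.normal(2, 1, 6), rng.normal(-2, 1, 6)])
    B = np.concatenate([rng.normal(0.8, 1, 6), rng.normal(0, 1, 6)])
    C = rng.normal(0, 1, 12)
    X = pd.DataFrame({"A": A, "B": B, "C": C})
    y = np.array(["tumor"] * 6 + ["normal"] * 6)
    return X, y


def test_trimming_single_pass_when_all_significant():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(40, 3))
    X[:20] += 2.0
    X = pd.DataFrame(X, columns=list("ABC"))
    y = np.array(["tumor"] * 20 + ["normal"] * 20)
    genes, trace = selection.trimming_loop(X, y)
    assert trace.niveau_used == pytest.approx(0.1)
    assert all(s.p_enter <= 0.05 for s in trace.steps)


def test_trimming_removes_borderline_feature():
    X, y = _trimming_toy()
    first_pass = selection.greedy_forward_select(X, y, 0.1)
    assert 0.05 < first_pass.steps[1].p_enter < 0.1  # B enters only at 0.1
    genes, trace = selection.trimming_loop(X, y)
    assert "B" not in genes
    assert all(s.p_enter <= 0.05 for s in trace.steps)
    assert trace.niveau_used < 0.1


def test_trimming_filter_mode_truncates_trace():
    X, y = _trimming_toy()
    genes, trace = selection.trimming_loop(X, y, mode="filter")
    assert genes == ["A"]


def test_trimming_all_empty_is_error():
    X = pd.DataFrame({"A": [1.0, 1.1, 0.9, 1.0, 1.05, 0.95]})
    y = np.array(["tumor"] * 3 + ["normal"] * 3)
    with pytest.raises(selection.NoDiscriminativeSet):
        selection.trimming_loop(X, y)


def test_planted_features_dominate_selection():
    """With 5 strong features among 50 null, the first entries are planted."""
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(60, 55))
        X[:30, :5] += 2.0
        cols = [f"P{i}" for i in range(5)] + [f"Z{i}" for i in range(50)]
        y = np.array(["tumor"] * 30 + ["normal"] * 30)
        genes, _ = selection.trimming_loop(pd.DataFrame(X, columns=cols), y)
        hits += all(g.startswith("P") for g in genes[:3])
    assert hits >= 18  # >= 90% of seeds


def test_permuted_labels_select_almost_nothing():
    """Pure-noise candidates: selection is empty or a singleton >= 90% of seeds."""
    small = 0
    n_seeds = 100
    for seed in range(n_seeds):
        rng = np.random.default_rng(1000 + seed)
        X = pd.DataFrame(rng.normal(size=(60, 5)), columns=list("ABCDE"))
        y = np.array(["tumor"] * 30 + ["normal"] * 30)
        try:
            genes, _ = selection.trimming_loop(X, y)
        except selection.NoDiscriminativeSet:
            genes = []
        small += len(genes) <= 1
    assert small >= 0.9 * n_seeds


def test_trace_serialization_round_trip(tmp_path):
    X, y = _trimming_toy()
    _, trace = selection.trimming_loop(X, y)
    trace.to_tsv(tmp_path / "sel.tsv")
    text = (tmp_path / "sel.tsv").read_text()
    assert text.startswith("#{") and "niveau_used" in text
    body = pd.read_csv(tmp_path / "sel.tsv", sep="\t", comment="#")
    assert list(body["gene_id"]) == trace.genes
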