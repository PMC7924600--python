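"""Greedy selection of a log-ratio balance predicting an outcome.

The algorithm searches for a single isometric log-ratio balance (two
disjoint taxon groups) whose value discriminates a binary outcome (Mann-
Whitney AUC criterion) or tracks a continuous outcome (adjusted R^2 of a
simple regression).  Step 1 evaluates every ordered taxon pair as a 1-vs-1
balance and keeps the best; each later step tries adding every unused taxon
to either side and keeps the best improving addition, stopping when no
addition improves the criterion or a maximum balance size is reached.  The
final balance size is chosen by a cross-validated criterion over the growth
trace.

Cross-validation additionally yields a per-taxon *reproducibility*: the
percentage of fold-fits in which a taxon appeared in the selected balance
(side-specifically).  An association is called *reliable* when the taxon's
reproducibility exceeds 50% and the final model R^2 exceeds 0.2 (McFadden
pseudo-R^2 of a logistic fit for binary outcomes).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .compositional import Balance, balance_value
from .tables_io import ASV_RANK, RANKS

_EPS = 1e-12

REPRODUCIBILITY_THRESHOLD = 50.0  # percent of CV fits
R2_THRESHOLD = 0.2


# ---------------------------------------------------------------------------
# criteria


def _auc_many(scores: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Mann-Whitney AUC of each row of ``scores`` against boolean ``pos``."""
    n1 = int(pos.sum())
    n0 = pos.size - n1
    r = rankdata(scores, axis=-1)
    rank_sum = r[..., pos].sum(axis=-1)
    return (rank_sum - n1 * (n1 + 1) / 2.0) / (n0 * n1)


def _adj_r2_many(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Adjusted R^2 of OLS of y on each row of ``scores``."""
    n = y.size
    yc = y - y.mean()
    sc = scores - scores.mean(axis=-1, keepdims=True)
    sy = sc @ yc
    ss = (sc * sc).sum(axis=-1)
    denom = ss * (yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(denom > 0, (sy * sy) / denom, 0.0)
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 2)


def _criterion_many(scores: np.ndarray, y: np.ndarray,
                    kind: str) -> np.ndarray:
    if kind == "AUC":
        return _auc_many(scores, y.astype(bool))
    return _adj_r2_many(scores, y)


def criterion_kind_for(y) -> str:
    """'AUC' for a binary outcome, 'adjusted R2' otherwise."""
    u = np.unique(np.asarray(y))
    return "AUC" if u.size == 2 else "adjusted R2"


def evaluate_balance(balance: Balance, X: pd.DataFrame, y,
                     kind: str | None = None) -> float:
    """Criterion of one balance: Mann-Whitney AUC (binary y) or adjusted
    R^2 of OLS of y on the balance value (continuous y)."""
    y = np.asarray(y, dtype=float)
    kind = kind or criterion_kind_for(y)
    vals = balance_value(X, balance).to_numpy()
    c = _criterion_many(vals[None, :], y, "AUC" if kind == "AUC" else "r2")
    return float(c[0])


# ---------------------------------------------------------------------------
# greedy growth


@dataclass
class SelectionTrace:
    """Greedy growth trace: the balance and training criterion per size."""

    balances: list[Balance] = field(default_factory=list)
    criteria: list[float] = field(default_factory=list)

    @property
    def sizes(self) -> list[int]:
        return [len(b.taxa) for b in self.balances]


def _taxon_key(taxa: np.ndarray, idx: int) -> str:
    return str(taxa[idx])


def _grow_greedy(L: np.ndarray, taxa: np.ndarray, y: np.ndarray,
                 kind: str, max_size: int) -> SelectionTrace:
    """Grow a balance greedily on log-part matrix L (samples x taxa)."""
    n, D = L.shape
    kk = "AUC" if kind == "AUC" else "r2"
    # --- step 1: all pairs, both orientations
    iu, ju = np.triu_indices(D, k=1)
    scores = (L[:, iu] - L[:, ju]).T * np.sqrt(0.5)  # pairs x samples
    crit = _criterion_many(scores, y, kk)
    if kind == "AUC":
        both = np.concatenate([crit, 1.0 - crit])
        num = np.concatenate([iu, ju])
        den = np.concatenate([ju, iu])
    else:
        # R^2 is orientation-symmetric; orient so the slope is positive
        yc = y - y.mean()
        slope_sign = (scores - scores.mean(axis=1, keepdims=True)) @ yc
        flip = slope_sign < 0
        both = crit
        num = np.where(flip, ju, iu)
        den = np.where(flip, iu, ju)
    best = both.max()
    cand = np.flatnonzero(both >= best - _EPS)
    pick = min(cand, key=lambda k: (_taxon_key(taxa, num[k]),
                                    _taxon_key(taxa, den[k])))
    num_idx = [int(num[pick])]
    den_idx = [int(den[pick])]
    trace = SelectionTrace()

    def _record(c: float) -> None:
        trace.balances.append(Balance(
            numerator=tuple(str(taxa[i]) for i in num_idx),
            denominator=tuple(str(taxa[i]) for i in den_idx)))
        trace.criteria.append(float(c))

    current = float(both[pick])
    _record(current)
    used = np.zeros(D, dtype=bool)
    used[num_idx + den_idx] = True
    s_num = L[:, num_idx].sum(axis=1)
    s_den = L[:, den_idx].sum(axis=1)
    while len(num_idx) + len(den_idx) < max_size and not used.all():
        free = np.flatnonzero(~used)
        r, s = len(num_idx), len(den_idx)
        c_num = np.sqrt((r + 1) * s / (r + 1 + s))
        c_den = np.sqrt(r * (s + 1) / (r + s + 1))
        add_num = c_num * ((s_num[:, None] + L[:, free]) / (r + 1)
                           - (s_den / s)[:, None])
        add_den = c_den * ((s_num / r)[:, None]
                           - (s_den[:, None] + L[:, free]) / (s + 1))
        cand_scores = np.concatenate([add_num.T, add_den.T])  # 2F x n
        crit = _criterion_many(cand_scores, y, kk)
        best = crit.max()
        if best <= current + _EPS:
            break
        F = free.size
        ties = np.flatnonzero(crit >= best - _EPS)
        # smallest taxon id wins; numerator side preferred on equal ids
        pick = min(ties, key=lambda k: (_taxon_key(taxa, free[k % F]),
                                        k // F))
        tax = int(free[pick % F])
        if pick < F:
            num_idx.append(tax)
            s_num = s_num + L[:, tax]
        else:
            den_idx.append(tax)
            s_den = s_den + L[:, tax]
        used[tax] = True
        current = float(crit[pick])
        _record(current)
    return trace


def _log_parts(X: pd.DataFrame) -> np.ndarray:
    vals = X.to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ValueError("balance selection requires strictly positive parts")
    return np.log(vals)


def select_balance(X: pd.DataFrame, y, max_size: int = 10,
                   cv_folds: int | None = None, seed: int = 0
                   ) -> tuple[Balance, SelectionTrace]:
    """Greedily select a balance on positive compositions ``X``.

    With ``cv_folds`` set, the final size is chosen as the trace size with
    the best mean held-out criterion; otherwise the natural greedy stop is
    returned.  Returns ``(balance, trace)``.
    """
    y = np.asarray(y, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("outcome is constant")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 taxa")
    if X.shape[0] < 6:
        raise ValueError("need at least 6 samples")
    kind = criterion_kind_for(y)
    taxa = np.asarray(X.columns, dtype=object)
    L = _log_parts(X)
    trace = _grow_greedy(L, taxa, y, kind, max_size)
    if cv_folds is None:
        return trace.balances[-1], trace
    folds = _make_folds(y, cv_folds, 1, np.random.default_rng(seed))
    per_size = _heldout_by_size(L, taxa, y, kind, max_size, folds, X.columns)
    size = _choose_size(per_size)
    idx = min(len(trace.balances) - 1, size - 2)
    return trace.balances[idx], trace


def _make_folds(y: np.ndarray, n_folds: int, n_repeats: int,
                rng: np.random.Generator) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded (stratified, for binary y) repeated k-fold assignments.

    Binary outcomes require every train and test fold to contain both
    classes; fold assignment is resampled up to 10 times before erroring.
    """
    from sklearn.model_selection import KFold, StratifiedKFold

    binary = np.unique(y).size == 2
    folds: list[tuple[np.ndarray, np.ndarray]] = []
    for _ in range(n_repeats):
        for attempt in range(10):
            state = int(rng.integers(0, 2**31 - 1))
            cls = StratifiedKFold if binary else KFold
            try:
                splits = list(cls(n_splits=n_folds, shuffle=True,
                                  random_state=state).split(y, y if binary else None))
            except ValueError:
                splits = None
            if splits is not None and all(
                    (not binary)
                    or (np.unique(y[tr]).size == 2 and np.unique(y[te]).size == 2)
                    for tr, te in splits):
                folds.extend(splits)
                break
        else:
            raise ValueError(
                "could not build folds containing both classes after 10 attempts")
    return folds


def _heldout_by_size(L, taxa, y, kind, max_size, folds, columns):
    """Mean held-out criterion per balance size across fold-fits."""
    kk = "AUC" if kind == "AUC" else "r2"
    per_size: dict[int, list[float]] = {}
    for tr, te in folds:
        t = _grow_greedy(L[tr], taxa, y[tr], kind, max_size)
        for bal, size in zip(t.balances, t.sizes):
            cols = [list(columns).index(c) for c in bal.taxa]
            r = len(bal.numerator)
            sc = bal.coefficient * (L[te][:, cols[:r]].mean(axis=1)
                                    - L[te][:, cols[r:]].mean(axis=1))
            c = float(_criterion_many(sc[None, :], y[te], kk)[0])
            per_size.setdefault(size, []).append(c)
    return per_size


def _choose_size(per_size: dict[int, list[float]]) -> int:
    """Smallest size within one standard error of the best mean held-out
    criterion (the usual parsimony rule for CV model-size selection)."""
    means = {s: float(np.mean(v)) for s, v in per_size.items()}
    best_size = max(means, key=lambda s: (means[s], -s))
    v = np.asarray(per_size[best_size], dtype=float)
    se = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    cutoff = means[best_size] - se
    return min(s for s, m in means.items() if m >= cutoff - _EPS)


# ---------------------------------------------------------------------------
# cross-validated selection


@dataclass
class BalanceSelectionResult:
    """Outcome of cross-validated balance selection on one rank."""

    balance: Balance
    criterion_kind: str                       # 'AUC' or 'adjusted R2'
    criterion_full: float                     # on all data
    criterion_cv: float                       # mean held-out, chosen size
    reproducibility: pd.DataFrame             # taxon, side, percent
    chosen_size: int
    final_r2: float                           # adj R2 / McFadden pseudo-R2
    rank: str | None = None
    n_fits: int = 0

    def reliable_taxa(self,
                      reproducibility_threshold: float = REPRODUCIBILITY_THRESHOLD,
                      r2_threshold: float = R2_THRESHOLD) -> pd.DataFrame:
        rep = self.reproducibility
        ok = rep["percent"] > reproducibility_threshold
        if self.final_r2 <= r2_threshold:
            ok &= False
        return rep[ok].reset_index(drop=True)

    def to_json(self, path=None) -> str:
        d = {
            "numerator": list(self.balance.numerator),
            "denominator": list(self.balance.denominator),
            "coefficient": self.balance.coefficient,
            "criterion_kind": self.criterion_kind,
            "criterion_full": self.criterion_full,
            "criterion_cv": self.criterion_cv,
            "chosen_size": self.chosen_size,
            "final_r2": self.final_r2,
            "rank": self.rank,
            "n_fits": self.n_fits,
            "reproducibility": self.reproducibility.to_dict(orient="records"),
        }
        s = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def _mcfadden_r2(bal_values: np.ndarray, y: np.ndarray) -> float:
    """McFadden pseudo-R^2 of logistic y ~ balance value; 1.0 under
    perfect separation (the likelihood is then unbounded)."""
    import statsmodels.api as sm

    X = np.column_stack([np.ones_like(bal_values), bal_values])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        return float(res.prsquared)
    except Exception:
        return 1.0


def cross_validated_selection(X: pd.DataFrame, y, folds: int = 5,
                              repeats: int = 10, seed: int = 0,
                              max_size: int = 10,
                              rank: str | None = None
                              ) -> BalanceSelectionResult:
    """Balance selection with repeated CV reproducibility.

    ``select_balance`` is re-run on each of ``folds x repeats`` training
    folds; the balance size is chosen by the mean held-out criterion over
    the growth traces, each fit's selected balance is its trace truncated
    to that size, and reproducibility is the side-specific percentage of
    fits containing each taxon.  The final balance is the full-data greedy
    trace truncated to the chosen size.  Fully seeded.
    """
    y = np.asarray(y, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("outcome is constant")
    if folds < 2:
        raise ValueError("need at least 2 folds")
    kind = criterion_kind_for(y)
    kk = "AUC" if kind == "AUC" else "r2"
    taxa = np.asarray(X.columns, dtype=object)
    L = _log_parts(X)
    rng = np.random.default_rng(seed)
    fold_list = _make_folds(y, folds, repeats, rng)

    traces = [_grow_greedy(L[tr], taxa, y[tr], kind, max_size)
              for tr, _ in fold_list]
    col_index = {c: i for i, c in enumerate(X.columns)}
    per_size: dict[int, list[float]] = {}
    for t, (_, te) in zip(traces, fold_list):
        for bal, size in zip(t.balances, t.sizes):
            cols = [col_index[c] for c in bal.taxa]
            r = len(bal.numerator)
            sc = bal.coefficient * (L[te][:, cols[:r]].mean(axis=1)
                                    - L[te][:, cols[r:]].mean(axis=1))
            per_size.setdefault(size, []).append(
                float(_criterion_many(sc[None, :], y[te], kk)[0]))
    size = _choose_size(per_size)

    counts: dict[tuple[str, str], int] = {}
    cv_scores = []
    oof_values, oof_y = [], []
    for t, (_, te) in zip(traces, fold_list):
        idx = min(len(t.balances) - 1, size - 2)
        bal = t.balances[idx]
        for tax in bal.numerator:
            counts[(tax, "numerator")] = counts.get((tax, "numerator"), 0) + 1
        for tax in bal.denominator:
            counts[(tax, "denominator")] = counts.get((tax, "denominator"), 0) + 1
        cols = [col_index[c] for c in bal.taxa]
        r = len(bal.numerator)
        sc = bal.coefficient * (L[te][:, cols[:r]].mean(axis=1)
                                - L[te][:, cols[r:]].mean(axis=1))
        cv_scores.append(float(_criterion_many(sc[None, :], y[te], kk)[0]))
        oof_values.append(sc)
        oof_y.append(y[te])
    n_fits = len(traces)
    rep = pd.DataFrame(
        [(tax, side, 100.0 * c / n_fits) for (tax, side), c in counts.items()],
        columns=["taxon", "side", "percent"],
    ).sort_values(["percent", "taxon", "side"],
                  ascending=[False, True, True]).reset_index(drop=True)

    full_trace = _grow_greedy(L, taxa, y, kind, max_size)
    final = full_trace.balances[min(len(full_trace.balances) - 1, size - 2)]
    fin_vals = balance_value(X, final).to_numpy()
    criterion_full = float(_criterion_many(fin_vals[None, :], y, kk)[0])
    # final-model R^2 from pooled out-of-fold balance values: evaluating a
    # selected balance in-sample inflates R^2 through the selection itself,
    # so the reliability gate uses held-out values
    ov = np.concatenate(oof_values)
    oy = np.concatenate(oof_y)
    if kind == "AUC":
        final_r2 = _mcfadden_r2(ov, oy.astype(int))
    else:
        final_r2 = max(0.0, float(_adj_r2_many(ov[None, :], oy)[0]))
    return BalanceSelectionResult(
        balance=final, criterion_kind=kind, criterion_full=criterion_full,
        criterion_cv=float(np.mean(cv_scores)), reproducibility=rep,
        chosen_size=len(final.taxa), final_r2=final_r2, rank=rank,
        n_fits=n_fits)


def reliability_filter(result: BalanceSelectionResult,
                       reproducibility_threshold: float = REPRODUCIBILITY_THRESHOLD,
                       r2_threshold: float = R2_THRESHOLD) -> pd.DataFrame:
    """Taxa passing both reliability thresholds, tagged with their side."""
    return result.reliable_taxa(reproducibility_threshold, r2_threshold)


def choose_rank(fdr_by_rank: dict[str, "pd.Series | np.ndarray | list"]) -> str:
    """Rank whose feature set contains the globally smallest FDR.

    Ties break toward the finer rank (species over genus over family over
    order).  Raises when every FDR is missing.
    """
    order = list(RANKS) + [ASV_RANK]
    best_rank, best_fdr = None, np.inf
    for rank, fdrs in fdr_by_rank.items():
        arr = np.asarray(pd.Series(fdrs, dtype=float).dropna())
        if arr.size == 0:
            continue
        m = arr.min()
        if m < best_fdr - _EPS or (
                abs(m - best_fdr) <= _EPS and best_rank is not None
                and order.index(rank) > order.index(best_rank)):
            best_rank, best_fdr = rank, min(m, best_fdr)
    if best_rank is None:
        raise ValueError("no FDR values available at any rank")
    return best_rank
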