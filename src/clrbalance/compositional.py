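"""Compositional data primitives: zero imputation, clr, balances, diversity.

Read counts carry only relative information, so all analyses run on closed
compositions.  Zeros are replaced by a geometric Bayesian-multiplicative
(GBM) treatment before taking logs; the centred log-ratio (clr) transform
maps each composition to a zero-sum vector in which Euclidean geometry is
the Aitchison geometry of the simplex.  A balance is a single isometric
log-ratio coordinate contrasting two disjoint taxon groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables_io import CountTable


class CompositionError(ValueError):
    pass


def impute_zeros_bm(table: CountTable) -> pd.DataFrame:
    """Geometric Bayesian-multiplicative zero replacement.

    Returns a samples x taxa DataFrame of strictly positive proportions
    closing to 1.  For sample i with depth ``n_i`` and prior strength
    ``s_i = sqrt(n_i)``, a zero part j is replaced by the posterior-expected
    proportion ``t_j * s_i / (n_i + s_i)`` where ``t_j`` is the normalized
    geometric mean of part j's nonzero observed proportions across samples
    (taxa never observed anywhere get a uniform prior weight ``1/D``); the
    nonzero parts are multiplicatively rescaled so the sample re-closes to 1.
    """
    X = table.counts.to_numpy(dtype=float).T  # samples x taxa
    n = X.sum(axis=1)
    if (n <= 0).any():
        bad = [table.sample_ids[i] for i in np.flatnonzero(n <= 0)]
        raise CompositionError(f"all-zero sample(s): {bad}")
    N, D = X.shape
    P = X / n[:, None]
    logP = np.zeros_like(P)
    np.log(P, out=logP, where=X > 0)
    nobs = (X > 0).sum(axis=0)
    t = np.full(D, 1.0 / D)
    seen = nobs > 0
    t[seen] = np.exp(logP[:, seen].sum(axis=0) / nobs[seen])
    t = t / t.sum()
    s = np.sqrt(n)
    repl = t[None, :] * (s / (n + s))[:, None]
    zero = X == 0
    out = np.where(zero, repl, P)
    # multiplicative adjustment of the observed parts
    imputed_mass = np.where(zero, repl, 0.0).sum(axis=1)
    out = np.where(zero, out, out * (1.0 - imputed_mass)[:, None])
    out = out / out.sum(axis=1, keepdims=True)
    return pd.DataFrame(out, index=table.sample_ids, columns=table.taxon_ids)


def clr_transform(comp) -> np.ndarray | pd.DataFrame:
    """Centred log-ratio: ln(x_i / geometric mean(x)) per sample (row).

    Accepts a 1-D composition or a samples x taxa array/DataFrame of
    strictly positive parts; rows of the result sum to zero.
    """
    arr = np.asarray(comp, dtype=float)
    if (arr <= 0).any():
        raise CompositionError("clr requires strictly positive parts")
    log = np.log(arr)
    if arr.ndim == 1:
        return log - log.mean()
    out = log - log.mean(axis=1, keepdims=True)
    if isinstance(comp, pd.DataFrame):
        return pd.DataFrame(out, index=comp.index, columns=comp.columns)
    return out


@dataclass(frozen=True)
class Balance:
    """An isometric log-ratio contrast between two disjoint taxon groups.

    Value on a composition x:
        c * (mean ln x[numerator] - mean ln x[denominator]),
    with the normalizing coefficient c = sqrt(r*s / (r+s)) for group sizes
    r and s, which gives the coordinate unit norm in clr space.
    """

    numerator: tuple[str, ...]
    denominator: tuple[str, ...]

    def __post_init__(self) -> None:
        num, den = set(self.numerator), set(self.denominator)
        if not num or not den:
            raise ValueError("balance sides must be non-empty")
        if num & den:
            raise ValueError(f"balance sides overlap: {sorted(num & den)}")
        object.__setattr__(self, "numerator", tuple(sorted(num)))
        object.__setattr__(self, "denominator", tuple(sorted(den)))

    @property
    def coefficient(self) -> float:
        r, s = len(self.numerator), len(self.denominator)
        return float(np.sqrt(r * s / (r + s)))

    @property
    def taxa(self) -> tuple[str, ...]:
        return self.numerator + self.denominator


def balance_value(comp, balance: Balance):
    """Evaluate a balance on composition(s) with named parts.

    ``comp`` is a Series (one sample) or DataFrame (samples x taxa) of
    strictly positive parts; returns a float or a Series per sample.
    """
    if isinstance(comp, pd.Series):
        comp = comp.to_frame().T
        scalar = True
    else:
        scalar = False
    missing = [t for t in balance.taxa if t not in comp.columns]
    if missing:
        raise KeyError(f"balance taxa missing from composition: {missing}")
    vals = comp[list(balance.taxa)].to_numpy(dtype=float)
    if (vals <= 0).any():
        raise CompositionError("balance requires strictly positive parts")
    ln = np.log(vals)
    r = len(balance.numerator)
    out = balance.coefficient * (ln[:, :r].mean(axis=1) - ln[:, r:].mean(axis=1))
    if scalar:
        return float(out[0])
    return pd.Series(out, index=comp.index)


def aitchison_distance(clr) -> pd.DataFrame:
    """Pairwise Euclidean distance between clr rows (Aitchison distance)."""
    arr = np.asarray(clr, dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    from scipy.spatial.distance import pdist, squareform

    dm = squareform(pdist(arr, metric="euclidean"))
    idx = clr.index if isinstance(clr, pd.DataFrame) else range(arr.shape[0])
    return pd.DataFrame(dm, index=idx, columns=idx)


def pca_clr(clr, n_components: int | None = None):
    """PCA of taxon-centred clr values.

    Centring per taxon makes Euclidean PCA identical to principal
    coordinates of the Aitchison distance.  Returns (scores DataFrame,
    explained-variance fractions).
    """
    arr = np.asarray(clr, dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 samples for PCA")
    from sklearn.decomposition import PCA

    k = n_components or min(arr.shape[0] - 1, arr.shape[1])
    p = PCA(n_components=k, svd_solver="full")
    scores = p.fit_transform(arr - arr.mean(axis=0))
    idx = clr.index if isinstance(clr, pd.DataFrame) else range(arr.shape[0])
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=idx, columns=cols), p.explained_variance_ratio_


def rarefy(counts, depth: int, seed) -> np.ndarray | None:
    """Subsample one sample's counts to exactly ``depth`` reads.

    Draws without replacement (multivariate hypergeometric), reproducible
    under ``seed``.  Returns None when the sample has fewer than ``depth``
    reads — callers flag such samples as excluded rather than failing.
    """
    c = np.asarray(counts)
    if not np.issubdtype(c.dtype, np.integer):
        if not np.allclose(c, np.round(c)):
            raise ValueError("rarefaction requires integer counts")
        c = c.astype(np.int64)
    if (c < 0).any():
        raise ValueError("negative counts")
    if c.sum() < depth:
        return None
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(c, depth)


def chao1(counts) -> float:
    """Chao1 richness: S_obs + F1^2 / (2 F2), with the bias-corrected
    fallback S_obs + F1 (F1 - 1) / (2 (F2 + 1)) when no doubletons exist."""
    c = np.asarray(counts)
    if (c < 0).any():
        raise ValueError("negative counts")
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def alpha_diversity_chao1(table: CountTable, depth: int = 3000,
                          seed=0) -> pd.DataFrame:
    """Per-sample Chao1 after rarefaction to ``depth`` reads.

    Samples below the rarefaction depth are excluded (``included=False``,
    chao1 NaN) rather than erroring; intended for ASV-level tables.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sid in table.sample_ids:
        c = table.counts[sid].to_numpy()
        sub = rarefy(c, depth, rng)
        if sub is None:
            rows.append((sid, np.nan, False))
        else:
            rows.append((sid, chao1(sub), True))
    return pd.DataFrame(rows, columns=["sample_id", "chao1", "included"]
                        ).set_index("sample_id")
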