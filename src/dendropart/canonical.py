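"""Constrained-ordination statistics for community matrices.

Implements the statistical core of metacommunity variation partitioning:

* Hellinger transformation of abundance matrices,
* redundancy analysis (RDA: multivariate least squares of a site-by-taxon
  response on predictor blocks) with Ezekiel-adjusted R²,
* permutation tests of the (partial) canonical pseudo-F,
* forward selection of spatial eigenfunctions with the double stopping
  criterion (per-candidate significance and the global adjusted R² cap),
* adjusted-R² variation partitioning over 2–4 predictor blocks, and
* the first-order jackknife richness estimator.

All randomised procedures take explicit seeds and are exactly
reproducible.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "hellinger",
    "RdaFit",
    "rda_fit",
    "PermutationTestResult",
    "permutation_test",
    "ForwardSelectionResult",
    "forward_select",
    "VarpartResult",
    "variation_partition",
    "jackknife1_richness",
]

_QR_TOL = 1e-8


def hellinger(y: np.ndarray) -> np.ndarray:
    """Hellinger transformation: y'_ij = sqrt(y_ij / rowsum_i).

    Rows of the result have unit sum of squares, making Euclidean-based
    ordination appropriate for count data.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("negative abundances")
    rs = y.sum(axis=1)
    zero = np.nonzero(rs == 0)[0]
    if zero.size:
        raise ValueError(f"site row(s) {zero.tolist()} have zero total abundance")
    return np.sqrt(y / rs[:, None])


def _as2d(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[:, None] if x.ndim == 1 else x


def _orthobasis(x: np.ndarray, tol: float = _QR_TOL) -> tuple[np.ndarray, int]:
    """Orthonormal basis of the column space via pivoted QR; returns (Q, rank).

    Collinear columns are pruned at relative tolerance ``tol``.
    """
    if x.size == 0:
        return np.zeros((x.shape[0], 0)), 0
    from scipy.linalg import qr

    q, r, _ = qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    if diag.size == 0 or diag[0] == 0:
        return np.zeros((x.shape[0], 0)), 0
    rank = int(np.sum(diag > tol * diag[0]))
    return q[:, :rank], rank


@dataclass
class RdaFit:
    r2: float
    adj_r2: float
    fitted: np.ndarray = field(repr=False)
    residual: np.ndarray = field(repr=False)
    rank: int
    n: int


def rda_fit(y: np.ndarray, x: np.ndarray, condition: np.ndarray | None = None) -> RdaFit:
    """Redundancy analysis of response matrix y on predictors x.

    y is column-centred and x standardised internally; with a
    ``condition`` block, both y and x are first residualised on it
    (partial RDA) and the reported R² is the semipartial fraction of the
    *total* variance of y.  Collinear predictor columns are dropped (with
    a warning) and the adjusted R² uses the post-pruning rank m:
    adj_r2 = 1 − (1 − r2)(n − 1)/(n − m − 1).
    """
    y = _as2d(y)
    x = _as2d(x)
    n = y.shape[0]
    yc = y - y.mean(axis=0)
    ss_tot = float(np.sum(yc**2))
    if ss_tot == 0:
        raise ValueError("response matrix has zero total variance")
    sd = x.std(axis=0, ddof=0)
    xs = (x - x.mean(axis=0)) / np.where(sd == 0, 1.0, sd)

    q_cond = 0
    if condition is not None:
        c = _as2d(condition)
        qc, q_cond = _orthobasis(c - c.mean(axis=0))
        yc = yc - qc @ (qc.T @ yc)
        xs = xs - qc @ (qc.T @ xs)

    q, m = _orthobasis(xs)
    if m < xs.shape[1]:
        warnings.warn(
            f"dropped {xs.shape[1] - m} collinear predictor column(s)",
            stacklevel=2,
        )
    if n <= m + q_cond + 1:
        raise ValueError(
            f"saturated model: n={n} sites cannot support m={m} predictors"
        )
    fitted = q @ (q.T @ yc)
    residual = yc - fitted
    r2 = float(np.sum(fitted**2)) / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)
    return RdaFit(r2=r2, adj_r2=adj, fitted=fitted, residual=residual, rank=m, n=n)


@dataclass
class PermutationTestResult:
    f: float
    p: float
    n_perm: int
    rank: int


def _perm_indices(rng: np.random.Generator, n: int, n_perm: int):
    """Permutation index rows; exact enumeration when n! is small."""
    if math.factorial(n) <= n_perm:
        warnings.warn(
            f"only {math.factorial(n)} distinct permutations exist for n={n}; "
            "enumerating exactly",
            stacklevel=3,
        )
        return np.array(list(itertools.permutations(range(n))))
    return np.array([rng.permutation(n) for _ in range(n_perm)])


def permutation_test(
    y: np.ndarray,
    x: np.ndarray,
    condition: np.ndarray | None = None,
    n_perm: int = 999,
    seed=0,
) -> PermutationTestResult:
    """Permutation test of the (partial) canonical pseudo-F.

    pseudo-F = (SS_explained / m) / (SS_residual / (n − m − q − 1)) where q
    is the rank of the conditioning block.  The null distribution permutes
    rows of the residuals of y on the conditioning block (reduced-model
    permutation); without a condition, raw rows of y are permuted.
    p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm).
    """
    y = _as2d(y)
    x = _as2d(x)
    n = y.shape[0]
    yc = y - y.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    xs = (x - x.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    q_cond = 0
    if condition is not None:
        c = _as2d(condition)
        qc, q_cond = _orthobasis(c - c.mean(axis=0))
        yr = yc - qc @ (qc.T @ yc)
        xs = xs - qc @ (qc.T @ xs)
    else:
        qc = None
        yr = yc
    q, m = _orthobasis(xs)
    if m == 0:
        raise ValueError("predictor block has zero rank")
    df_res = n - m - q_cond - 1
    if df_res <= 0:
        raise ValueError("saturated model: no residual degrees of freedom")

    # Under permutation the total SS of yr is invariant and, because the
    # fitted basis q is orthogonal to the conditioning basis qc, the
    # reduced-model re-residualisation only removes ||qc' yp||^2 from the
    # residual SS.  This collapses each permutation to two thin products.
    ss_yr = float(np.sum(yr**2))

    def f_from(yp: np.ndarray) -> float:
        ss_fit = float(np.sum((q.T @ yp) ** 2))
        ss_res = ss_yr - ss_fit
        if qc is not None:
            ss_res -= float(np.sum((qc.T @ yp) ** 2))
        return (ss_fit / m) / (ss_res / df_res)

    f_obs = f_from(yr)
    rng = np.random.default_rng(seed)
    perms = _perm_indices(rng, n, n_perm)
    count = 0
    for p_idx in perms:
        if f_from(yr[p_idx]) >= f_obs - 1e-12:
            count += 1
    n_eff = len(perms)
    return PermutationTestResult(
        f=f_obs, p=(1 + count) / (1 + n_eff), n_perm=n_eff, rank=m
    )


@dataclass
class ForwardSelectionResult:
    selected: list
    step_p: list
    step_adj_r2: list
    global_p: float
    global_adj_r2: float

    @property
    def any_selected(self) -> bool:
        return len(self.selected) > 0


def forward_select(
    y: np.ndarray,
    candidates: np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed=0,
) -> ForwardSelectionResult:
    """Forward selection with the double stopping criterion.

    A global permutation test with all candidates gates the procedure: a
    non-significant global model selects nothing.  Otherwise candidates
    are added greedily by added R²; the procedure stops when the incoming
    candidate's partial permutation p-value exceeds ``alpha`` or when the
    cumulative adjusted R² would exceed the global model's adjusted R²
    (the candidate triggering either criterion is not kept).  Each step
    draws its permutations from a fresh stream derived from ``seed`` and
    the step index.
    """
    y = _as2d(y)
    cands = _as2d(candidates)
    n, k = cands.shape
    # rank guard: a saturated global model is fit on its column-space basis
    if n <= k + 1:
        qg, rg = _orthobasis(cands - cands.mean(axis=0))
        glob_x = qg[:, : max(1, min(rg, n - 2))]
    else:
        glob_x = cands
    glob_test = permutation_test(y, glob_x, n_perm=n_perm, seed=np.random.SeedSequence([_seed_int(seed), 0]))
    glob_adj = rda_fit(y, glob_x).adj_r2
    if glob_test.p > alpha:
        return ForwardSelectionResult([], [], [], glob_test.p, glob_adj)

    yc = y - y.mean(axis=0)
    xc = cands - cands.mean(axis=0)
    selected: list[int] = []
    step_p: list[float] = []
    step_adj: list[float] = []
    q_sel = np.zeros((n, 0))
    for step in range(1, k + 1):
        yr = yc - q_sel @ (q_sel.T @ yc)
        xr = xc - q_sel @ (q_sel.T @ xc)
        norms = np.sum(xr**2, axis=0)
        gains = np.zeros(k)
        for j in range(k):
            if j in selected or norms[j] <= _QR_TOL:
                continue
            u = xr[:, j] / np.sqrt(norms[j])
            gains[j] = float(np.sum((u @ yr) ** 2))
        best = int(np.argmax(gains))
        if gains[best] <= 0:
            break
        trial = selected + [best]
        trial_adj = rda_fit(y, cands[:, trial]).adj_r2
        if trial_adj > glob_adj:
            break
        cond = cands[:, selected] if selected else None
        test = permutation_test(
            y, cands[:, [best]], condition=cond, n_perm=n_perm,
            seed=np.random.SeedSequence([_seed_int(seed), step]),
        )
        if test.p > alpha:
            break
        selected.append(best)
        step_p.append(test.p)
        step_adj.append(trial_adj)
        q_sel, _ = _orthobasis(xc[:, selected])
    return ForwardSelectionResult(selected, step_p, step_adj, glob_test.p, glob_adj)


def _seed_int(seed) -> int:
    if isinstance(seed, np.random.SeedSequence):
        return int(seed.generate_state(1)[0]) % (2**31)
    return int(seed) % (2**31)


@dataclass
class VarpartResult:
    """Adjusted-R² decomposition of community variation across blocks.

    ``fractions`` maps frozensets of block names to the variance fraction
    shared by exactly those blocks; ``unique`` maps each block name to
    (fraction, pseudo-F, p); ``subset_adj_r2`` stores the component fits
    from which every fraction is reproducible.
    """

    block_names: list
    fractions: dict
    unique: dict
    residual: float
    subset_adj_r2: dict
    n_perm: int

    @property
    def total_explained(self) -> float:
        return 1.0 - self.residual

    def fraction_table(self):
        import pandas as pd

        rows = []
        for t in sorted(self.fractions, key=lambda s: (len(s), sorted(s))):
            name = "+".join(sorted(t))
            val = self.fractions[t]
            if len(t) == 1:
                b = next(iter(t))
                _, f, p = self.unique[b]
                rows.append((f"unique[{name}]", val, f, p, _stars(p)))
            else:
                rows.append((f"shared[{name}]", val, np.nan, np.nan, ""))
        rows.append(("residual", self.residual, np.nan, np.nan, ""))
        return pd.DataFrame(
            rows, columns=["fraction", "adj_r2", "F", "p", "sig"]
        )


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def variation_partition(
    y: np.ndarray,
    blocks: dict,
    n_perm: int = 999,
    seed=0,
) -> VarpartResult:
    """Partition the variance of y across 2–4 named predictor blocks.

    Adjusted R² is fitted for every non-empty union of blocks; unique and
    shared fractions follow by inclusion–exclusion, the residual is
    1 − adjR²(all).  Unique fractions are tested by reduced-model
    permutation with the other blocks as condition; shared fractions are
    reported untested.  Negative fractions ("empty": explaining less than
    chance) are reported as-is.
    """
    names = list(blocks)
    if not 1 <= len(names) <= 4:
        raise ValueError("variation_partition supports 1-4 blocks")
    mats = {nm: _as2d(blocks[nm]) for nm in names}

    subset_adj: dict[frozenset, float] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            xs = np.hstack([mats[nm] for nm in combo])
            subset_adj[frozenset(combo)] = rda_fit(y, xs).adj_r2

    omega = frozenset(names)

    def inter(s: frozenset) -> float:
        # adjusted "measure" of the intersection over blocks in s
        tot = 0.0
        for r in range(1, len(s) + 1):
            for u in itertools.combinations(sorted(s), r):
                tot += (-1) ** (r + 1) * subset_adj[frozenset(u)]
        return tot

    fractions: dict[frozenset, float] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            t = frozenset(combo)
            rest = sorted(omega - t)
            val = 0.0
            for w in range(len(rest) + 1):
                for extra in itertools.combinations(rest, w):
                    val += (-1) ** w * inter(t | frozenset(extra))
            fractions[t] = val

    ss = np.random.SeedSequence(_seed_int(seed))
    child = ss.spawn(len(names))
    unique: dict = {}
    for i, nm in enumerate(names):
        others = [mats[o] for o in names if o != nm]
        cond = np.hstack(others) if others else None
        if len(names) == 1:
            res = permutation_test(y, mats[nm], n_perm=n_perm, seed=child[i])
        else:
            res = permutation_test(
                y, mats[nm], condition=cond, n_perm=n_perm, seed=child[i]
            )
        unique[nm] = (fractions[frozenset([nm])], res.f, res.p)

    return VarpartResult(
        block_names=names,
        fractions=fractions,
        unique=unique,
        residual=1.0 - subset_adj[omega],
        subset_adj_r2={tuple(sorted(k)): v for k, v in subset_adj.items()},
        n_perm=n_perm,
    )


def jackknife1_richness(incidence: np.ndarray) -> float:
    """First-order jackknife richness from m samples × taxa incidences.

    S_jack = S_obs + f1 · (m − 1)/m, with f1 the number of taxa seen in
    exactly one sample.
    """
    inc = np.asarray(incidence) > 0
    m = inc.shape[0]
    if m < 2:
        raise ValueError("jackknife requires at least 2 samples")
    occ = inc.sum(axis=0)
    s_obs = int(np.sum(occ > 0))
    f1 = int(np.sum(occ == 1))
    return s_obs + f1 * (m - 1) / m
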