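"""Fuzzy c-means clustering and the average-membership-degree (AMD) validity index.

The AMD index measures how crisply a fuzzy c-means solution partitions the
data: it is the mean, over samples, of the membership degree to the nearest
(highest-membership) cluster, minus the chance level ``1/c``.  For
structureless data memberships hover around ``1/c`` and AMD is ~0; for
perfectly crisp clusters it approaches ``1 - 1/c``.  Scanning AMD over a
range of user-defined cluster numbers, with many random restarts per count,
both detects how many well-defined clusters exist (the argmax) and
quantifies their degree of definition (the peak height).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleMatrix",
    "FuzzyPartition",
    "AMDResult",
    "AMDScanResult",
    "fit_cmeans",
    "compute_amd",
    "amd_scan",
]

# Squared distances below this are treated as a sample coinciding with a centre.
_COINCIDENT_EPS = 1e-12


@dataclass
class SampleMatrix:
    """An ``n x d`` real matrix of samples (rows) by features (columns)."""

    values: np.ndarray
    row_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("SampleMatrix requires a 2-D array")
        n, d = self.values.shape
        if n < 1 or d < 1:
            raise ValueError("SampleMatrix requires n >= 1 and d >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SampleMatrix contains missing or non-finite values")
        if self.row_ids is None:
            self.row_ids = [f"s{i}" for i in range(n)]
        elif len(self.row_ids) != n:
            raise ValueError("row_ids length does not match number of rows")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleMatrix":
        df = pd.read_csv(path, index_col=0, comment="#")
        return cls(df.to_numpy(dtype=float), [str(i) for i in df.index])

    def to_csv(self, path: str | Path, columns: Sequence[str] | None = None) -> None:
        cols = list(columns) if columns is not None else [f"x{j}" for j in range(self.d)]
        pd.DataFrame(self.values, index=self.row_ids, columns=cols).to_csv(
            path, index_label="id"
        )


@dataclass
class FuzzyPartition:
    """Result of one fuzzy c-means fit.

    ``membership`` rows sum to 1; ``objective`` is the fuzzy within-cluster
    sum of squares, sum_j sum_k u_jk^m * ||x_j - v_k||^2.
    """

    centres: np.ndarray
    membership: np.ndarray
    fuzzifier_m: float
    objective: float
    converged: bool
    seed: int
    n_iter: int = 0
    #: objective value after each sweep (monotone non-increasing)
    objective_history: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.membership.shape[0]

    @property
    def c(self) -> int:
        return self.membership.shape[1]

    def hard_labels(self) -> np.ndarray:
        """Cluster of maximal membership per sample."""
        return np.argmax(self.membership, axis=1)


@dataclass
class AMDResult:
    """AMD validity statistic for one partition: ``amd = mean_j max_k u_jk - 1/c``."""

    amd: float
    mean_nearest_md: float
    n: int
    c: int


@dataclass
class AMDScanResult:
    """Best-of-replicates AMD values over a range of cluster numbers."""

    per_c: list[dict] = field(default_factory=list)
    selected_c: int = 0

    @property
    def amd_curve(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"c": rec["c"], "best_amd": rec["best_amd"], "replicates": rec["replicates"]}
                for rec in self.per_c
            ]
        )

    def best_partition(self, c: int | None = None) -> FuzzyPartition:
        c = self.selected_c if c is None else c
        for rec in self.per_c:
            if rec["c"] == c:
                return rec["partition"]
        raise KeyError(f"c={c} not in scan range")

    def to_csv(self, path: str | Path) -> None:
        self.amd_curve.to_csv(path, index=False)


def _init_centres(X: np.ndarray, c: int, rng: np.random.Generator) -> np.ndarray:
    """Draw c distinct sample rows as initial centres."""
    idx = rng.choice(X.shape[0], size=c, replace=False)
    return X[idx].copy()


def _memberships_from_d2(d2: np.ndarray, m: float) -> np.ndarray:
    """Standard c-means membership update from squared distances.

    ``d2`` has shape (..., n, c).  Samples coincident with a centre get
    membership 1 to the first such centre and 0 elsewhere.
    """
    zero = d2 < _COINCIDENT_EPS
    with np.errstate(divide="ignore"):
        if m == 2.0:
            w = 1.0 / np.maximum(d2, 1e-300)
        else:
            w = d2 ** (-1.0 / (m - 1.0))
    if not zero.any():
        return w / w.sum(axis=-1, keepdims=True)
    w = np.where(zero, 0.0, w)
    any_zero = zero.any(axis=-1, keepdims=True)
    # crisp assignment to the first coincident centre
    first_zero = np.cumsum(zero, axis=-1) == 1
    crisp = (zero & first_zero).astype(float)
    u = np.where(any_zero, crisp, w / np.maximum(w.sum(axis=-1, keepdims=True), 1e-300))
    return u


def _sq_dists(X: np.ndarray, centres: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances; X (n,d), centres (..., c, d) -> (..., n, c).

    The cross term is computed as one GEMM over all centre sets."""
    xx = np.einsum("nd,nd->n", X, X)
    cc = np.einsum("...cd,...cd->...c", centres, centres)
    if centres.ndim == 3:
        R, c, d = centres.shape
        cross = (X @ centres.reshape(R * c, d).T).T.reshape(R, c, -1).transpose(0, 2, 1)
    else:
        cross = X @ centres.T
    d2 = xx[..., :, None] + cc[..., None, :] - 2.0 * cross
    return np.maximum(d2, 0.0)


def _cmeans_batch(
    X: np.ndarray,
    centres0: np.ndarray,
    m: float,
    tol: float,
    max_iter: int,
    history: list | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Run fuzzy c-means from a batch of R initial centre sets simultaneously.

    centres0: (R, c, d).  Returns (centres (R,c,d), membership (R,n,c),
    objective (R,), n_iter (R,), converged (R,)).  Replicates whose relative
    objective change falls below ``tol`` are frozen and skipped.
    """
    R = centres0.shape[0]
    centres = centres0.astype(float).copy()
    prev_obj = np.full(R, np.inf)
    obj = np.full(R, np.inf)
    n_iter = np.zeros(R, dtype=int)
    converged = np.zeros(R, dtype=bool)

    active = np.ones(R, dtype=bool)
    u_full = np.empty((R, X.shape[0], centres.shape[1]))
    for it in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        d2 = _sq_dists(X, centres[idx])
        u = _memberships_from_d2(d2, m)
        um = u * u if m == 2.0 else u**m
        new_obj = np.einsum("rnc,rnc->r", um, d2)
        denom = np.maximum(um.sum(axis=1), 1e-300)  # (r, c)
        r_act, n, c = um.shape
        new_centres = (um.transpose(0, 2, 1).reshape(r_act * c, n) @ X).reshape(r_act, c, -1)
        centres[idx] = new_centres / denom[:, :, None]
        u_full[idx] = u
        obj[idx] = new_obj
        n_iter[idx] += 1
        if history is not None:
            history.append(obj.copy())
        rel = np.abs(prev_obj[idx] - new_obj) / np.maximum(new_obj, 1e-300)
        done = rel < tol
        converged[idx[done]] = True
        active[idx[done]] = False
        prev_obj[idx] = new_obj
    membership = u_full
    return centres, membership, obj, n_iter, converged


def fit_cmeans(
    samples: SampleMatrix,
    c: int,
    fuzzifier_m: float = 2.0,
    tol: float = 1e-9,
    max_iter: int = 300,
    seed: int = 0,
) -> FuzzyPartition:
    """Fit fuzzy c-means with Euclidean distances.

    Initial centres are ``c`` distinct sample rows drawn with the given seed.
    Iteration stops when the relative change of the objective drops below
    ``tol`` or after ``max_iter`` sweeps.  If the data hold fewer than ``c``
    distinct rows the fit is degenerate and flagged non-converged.
    """
    X = samples.values
    n = X.shape[0]
    if not 1 <= c <= n:
        raise ValueError(f"c must satisfy 1 <= c <= n={n}, got {c}")
    if fuzzifier_m <= 1:
        raise ValueError("fuzzifier_m must be > 1")
    rng = np.random.default_rng(seed)
    centres0 = _init_centres(X, c, rng)[None]
    degenerate = c > 1 and np.unique(X, axis=0).shape[0] < c
    hist: list = []
    centres, u, obj, n_iter, conv = _cmeans_batch(
        X, centres0, fuzzifier_m, tol, max_iter, history=hist
    )
    return FuzzyPartition(
        centres=centres[0],
        membership=u[0],
        fuzzifier_m=fuzzifier_m,
        objective=float(obj[0]),
        converged=bool(conv[0]) and not degenerate,
        seed=seed,
        n_iter=int(n_iter[0]),
        objective_history=np.array([h[0] for h in hist]),
    )


def compute_amd(partition: FuzzyPartition) -> AMDResult:
    """AMD validity index of a partition: mean nearest-cluster membership minus 1/c.

    The nearest cluster of a sample is the one it holds maximal membership in
    (equivalently the closest centre under the c-means update).
    """
    u = partition.membership
    row_sums = u.sum(axis=1)
    if not np.allclose(row_sums, 1.0, atol=1e-6):
        raise ValueError("membership rows are not normalized")
    mean_nearest = float(u.max(axis=1).mean())
    c = partition.c
    return AMDResult(
        amd=mean_nearest - 1.0 / c,
        mean_nearest_md=mean_nearest,
        n=partition.n,
        c=c,
    )


def amd_scan(
    samples: SampleMatrix,
    c_min: int = 2,
    c_max: int = 10,
    replicates: int = 200,
    fuzzifier_m: float = 2.0,
    seed: int = 0,
    tol: float = 1e-9,
    max_iter: int = 300,
    max_batch_elems: int = 40_000_000,
) -> AMDScanResult:
    """Scan cluster numbers, keeping the best-AMD replicate for each.

    For each c in ``[c_min, c_max]``, runs ``replicates`` independently
    seeded c-means fits (replicate r uses seed ``seed + r``) and keeps the
    partition with the highest AMD.  ``selected_c`` is the argmax of the
    best-AMD curve; ties within 1e-12 break toward the smaller c
    (parsimony).  Replicates are batched internally for speed; results are
    identical to sequential fits.
    """
    X = samples.values
    n = X.shape[0]
    if not (2 <= c_min <= c_max <= n):
        raise ValueError(f"need 2 <= c_min <= c_max <= n={n}")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")

    result = AMDScanResult()
    for c in range(c_min, c_max + 1):
        inits = np.stack(
            [_init_centres(X, c, np.random.default_rng(seed + r)) for r in range(replicates)]
        )
        best_amd = -np.inf
        best = None
        chunk = max(1, max_batch_elems // (n * c))
        for start in range(0, replicates, chunk):
            sl = slice(start, min(start + chunk, replicates))
            centres, u, obj, n_iter, conv = _cmeans_batch(
                X, inits[sl], fuzzifier_m, tol, max_iter
            )
            amds = u.max(axis=2).mean(axis=1) - 1.0 / c
            i = int(np.argmax(amds))
            if amds[i] > best_amd:
                best_amd = float(amds[i])
                best = FuzzyPartition(
                    centres=centres[i],
                    membership=u[i],
                    fuzzifier_m=fuzzifier_m,
                    objective=float(obj[i]),
                    converged=bool(conv[i]),
                    seed=seed + start + i,
                    n_iter=int(n_iter[i]),
                )
        result.per_c.append(
            {"c": c, "best_amd": best_amd, "partition": best, "replicates": replicates}
        )

    amds = np.array([rec["best_amd"] for rec in result.per_c])
    cs = np.array([rec["c"] for rec in result.per_c])
    best_val = amds.max()
    result.selected_c = int(cs[np.flatnonzero(amds >= best_val - 1e-12)[0]])
    return result
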