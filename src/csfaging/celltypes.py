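"""Reference-free cell-type deconvolution of a methylation beta matrix.

No cell-type reference panel exists for CSF (or for blood resident in the
subarachnoid space), so putative cell-type proportions are estimated directly
from the data: the probes x samples beta matrix ``X`` is factorised as

    X  ~=  T @ W,    T in [0,1]^(P x K),   each column of W on the K-simplex,

where ``T`` holds K latent cell-type methylation profiles and ``W`` the
per-sample mixing proportions.  The factorisation is computed by alternating
projected-gradient descent (simplex projection on proportions, box projection
on profiles) with exact Lipschitz step sizes, so the squared-error objective
is non-increasing at every step; several random restarts guard against local
minima.  As with any reference-free method the K components are *putative*
cell types — identifiable only up to permutation, and not biologically
labelled.

For downstream regression adjustment the proportions live on a simplex (they
sum to one), so one component — the one with the least variance across
samples — is dropped from the covariate set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CellTypeProportions",
    "estimate_proportions",
    "select_dropped_cell",
    "project_rows_to_simplex",
]


@dataclass
class CellTypeProportions:
    """Estimated per-sample proportions of K putative cell types.

    ``proportions`` is samples x K (rows on the simplex); ``profiles`` is
    probes x K in [0, 1]; ``dropped_index`` is the 0-based index of the
    least-variable component (the one excluded from regression covariates).
    ``objective_history`` records the factorisation objective of the best
    restart at every alternating iteration (non-increasing).
    """

    proportions: pd.DataFrame
    profiles: pd.DataFrame
    variances: np.ndarray
    dropped_index: int
    objective_history: list[float] = field(default_factory=list)
    converged: bool = True

    @property
    def n_cell_types(self) -> int:
        return self.proportions.shape[1]

    def covariates(self) -> pd.DataFrame:
        """Proportions with the dropped (least-variable) component removed."""
        keep = [c for i, c in enumerate(self.proportions.columns) if i != self.dropped_index]
        return self.proportions[keep]

    def to_table(self) -> pd.DataFrame:
        """Proportions TSV shape: sample_id, cell_1..cell_K, dropped flag row."""
        out = self.proportions.copy()
        out["dropped_cell"] = self.proportions.columns[self.dropped_index]
        return out


def project_rows_to_simplex(V: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row of ``V`` onto the probability simplex."""
    n, k = V.shape
    U = np.sort(V, axis=1)[:, ::-1]
    css = np.cumsum(U, axis=1) - 1.0
    ind = np.arange(1, k + 1)
    cond = U - css / ind > 0
    rho = k - 1 - np.argmax(cond[:, ::-1], axis=1)
    theta = css[np.arange(n), rho] / (rho + 1)
    return np.maximum(V - theta[:, None], 0.0)


def select_dropped_cell(proportions: pd.DataFrame | np.ndarray) -> int:
    """Index of the component with the lowest across-sample variance.

    Ties break toward the lowest index.  Uses the population variance (ddof 0);
    the argmin is unaffected by the ddof convention.
    """
    arr = np.asarray(proportions, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 1:
        raise ValueError("proportions must be a non-empty samples x K array")
    return int(np.argmin(arr.var(axis=0)))


def _objective(X: np.ndarray, T: np.ndarray, W: np.ndarray) -> float:
    r = X - T @ W
    return float(np.sum(r * r))


def estimate_proportions(
    betas: pd.DataFrame,
    K: int = 5,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-7,
    n_restarts: int = 5,
    n_top_probes: int = 1000,
) -> CellTypeProportions:
    """Estimate K putative cell-type proportions per sample.

    Parameters
    ----------
    betas:
        Probes x samples beta matrix in [0, 1].
    K:
        Number of putative cell types (default 5).
    n_top_probes:
        The factorisation runs on the ``n_top_probes`` most variable probes
        (all probes if fewer) — standard practice that concentrates signal
        and keeps runtime modest.
    n_restarts:
        Random restarts; the solution with the best objective is kept.

    Returns
    -------
    CellTypeProportions with simplex-exact proportions (each row sums to 1
    within 1e-6 by construction of the projection).
    """
    n_probes, n_samples = betas.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n_samples:
        raise ValueError(f"K={K} exceeds the number of samples ({n_samples})")
    if n_probes < K:
        raise ValueError(f"need at least K={K} probes, have {n_probes}")
    X_full = betas.to_numpy(dtype=float)
    if not np.isfinite(X_full).all():
        raise ValueError("beta matrix contains non-finite values")

    if n_probes > n_top_probes:
        order = np.argsort(X_full.var(axis=1))[::-1][:n_top_probes]
        order = np.sort(order)
    else:
        order = np.arange(n_probes)
    X = X_full[order]
    probe_index = betas.index[order]

    if K == 1:
        # closed form: weights are identically 1, profile is the per-probe mean
        profile = X.mean(axis=1, keepdims=True)
        props = pd.DataFrame(
            np.ones((n_samples, 1)),
            index=pd.Index(betas.columns, name="sample_id"),
            columns=["cell_1"],
        )
        return CellTypeProportions(
            proportions=props,
            profiles=pd.DataFrame(profile, index=probe_index, columns=["cell_1"]),
            variances=np.zeros(1),
            dropped_index=0,
            objective_history=[_objective(X, profile, np.ones((1, n_samples)))],
        )

    ss = np.random.SeedSequence(seed).spawn(n_restarts)
    best: tuple[float, np.ndarray, np.ndarray, list[float], bool] | None = None
    for s in ss:
        rng = np.random.default_rng(s)
        T = rng.uniform(0.0, 1.0, size=(X.shape[0], K))
        W = rng.dirichlet(np.ones(K), size=n_samples).T  # K x N
        history = [_objective(X, T, W)]
        converged = False
        for _ in range(max_iter):
            # proportions step (simplex-constrained, exact Lipschitz step)
            G = T.T @ (T @ W - X)
            L = np.linalg.norm(T.T @ T, 2)
            W = project_rows_to_simplex((W - G / max(L, 1e-12)).T).T
            # profiles step (box-constrained)
            Gt = (T @ W - X) @ W.T
            Lt = np.linalg.norm(W @ W.T, 2)
            T = np.clip(T - Gt / max(Lt, 1e-12), 0.0, 1.0)
            obj = _objective(X, T, W)
            history.append(obj)
            prev = history[-2]
            if prev - obj <= tol * max(prev, 1.0):
                converged = True
                break
        if best is None or history[-1] < best[0]:
            best = (history[-1], T, W, history, converged)

    assert best is not None
    _, T, W, history, converged = best
    cols = [f"cell_{k + 1}" for k in range(K)]
    props = pd.DataFrame(W.T, index=pd.Index(betas.columns, name="sample_id"), columns=cols)
    variances = W.T.var(axis=0)
    return CellTypeProportions(
        proportions=props,
        profiles=pd.DataFrame(T, index=probe_index, columns=cols),
        variances=variances,
        dropped_index=select_dropped_cell(W.T),
        objective_history=history,
        converged=converged,
    )
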