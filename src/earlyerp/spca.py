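"""Spatial PCA: electrodes as variables, participant x condition cells as
cases. Eigen-decomposition of the channel association matrix, scree-based
factor retention, varimax rotation with Kaiser normalization, and
regression-method factor scores.

Spatial factors summarize covarying scalp regions; the posterior factor's
scores are the single-number-per-case quantity submitted to the paired
contrasts downstream. Factor sign indeterminacy is resolved by flipping
each rotated factor so its largest-magnitude loading is positive, which
keeps factor scores on the same scale direction as the underlying
amplitudes (required for one-tailed contrasts).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .layout import ChannelLayout


@dataclass
class SpatialFactorModel:
    association: str                 # 'correlation' | 'covariance'
    eigenvalues: np.ndarray          # all channel eigenvalues, descending
    loadings: np.ndarray             # channels x k, unrotated
    rotated_loadings: np.ndarray     # channels x k, varimax, sign-canonical
    explained_variance_pct: float
    scores: np.ndarray               # cases x k, regression method
    case_index: pd.MultiIndex        # (participant, category)
    channel_names: list[str]
    k: int
    mean_: np.ndarray                # per-channel centering
    scale_: np.ndarray               # per-channel scaling (1s for covariance)
    assoc_: np.ndarray               # the association matrix decomposed


def build_case_matrix(table: pd.DataFrame) -> tuple[np.ndarray, pd.MultiIndex]:
    """Case matrix (participant x condition rows, channel columns)."""
    if table.isna().any().any():
        raise ValueError("amplitude table has missing cells")
    return table.to_numpy(dtype=float), table.index


def scree_select(eigenvalues: np.ndarray, override: int | None = None) -> int:
    """Elbow selection: retain up to the point of maximum acceleration.

    With eigenvalues e_1 >= e_2 >= ..., the retained count is i-1 where
    the interior index i (1-based) maximizes the second difference
    e_{i-1} - 2 e_i + e_{i+1}. A manual override is honored as-is.
    """
    if override is not None:
        return int(override)
    e = np.asarray(eigenvalues, dtype=float)
    if len(e) < 3:
        raise ValueError("need at least three eigenvalues for the scree rule")
    acc = e[:-2] - 2.0 * e[1:-1] + e[2:]   # acc[j] corresponds to i = j+2
    i = int(np.argmax(acc)) + 2
    return i - 1


def varimax(lam: np.ndarray, kaiser: bool = True, max_iter: int = 1000, tol: float = 1e-12):
    """Varimax rotation (orthogonal), optionally with Kaiser normalization.

    Returns (rotated loadings, rotation matrix). The classic SVD-based
    iteration; Kaiser normalization divides rows by their communalities
    before rotating and restores them after.
    """
    p, k = lam.shape
    if k == 1:
        return lam.copy(), np.eye(1)
    h = np.sqrt((lam**2).sum(axis=1)) if kaiser else np.ones(p)
    h = np.where(h == 0, 1.0, h)
    a = lam / h[:, None]
    rot = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        b = a @ rot
        g = a.T @ (b**3 - b @ np.diag((b**2).sum(axis=0)) / p)
        u, s, vt = np.linalg.svd(g)
        rot = u @ vt
        d = s.sum()
        if d_old != 0 and d < d_old * (1 + tol):
            break
        d_old = d
    rotated = (a @ rot) * h[:, None]
    return rotated, rot


def _canonical_signs(loadings: np.ndarray) -> np.ndarray:
    """Flip each factor so its largest-magnitude loading is positive."""
    out = loadings.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def _regression_scores(z: np.ndarray, assoc: np.ndarray, loadings: np.ndarray) -> np.ndarray:
    """Regression (Thurstone) factor scores: Z @ assoc^+ @ loadings."""
    w, *_ = np.linalg.lstsq(assoc, loadings, rcond=None)
    return z @ w


def fit_spca(
    matrix: np.ndarray,
    case_index: pd.MultiIndex | None = None,
    channel_names: list[str] | None = None,
    k: int | str = "scree",
    association: str = "correlation",
) -> SpatialFactorModel:
    """Fit the spatial factor model.

    Parameters
    ----------
    matrix : cases x channels array (from :func:`build_case_matrix`).
    k : int or 'scree'
        Retained factor count; 'scree' applies :func:`scree_select`.
    association : {'correlation', 'covariance'}
        Matrix decomposed. Correlation matches the default of the classic
        statistics packages; covariance weights channels by amplitude.
    """
    x = np.asarray(matrix, dtype=float)
    n, p = x.shape
    if n <= 2:
        raise ValueError("need more than two cases")
    if case_index is None:
        case_index = pd.MultiIndex.from_tuples(
            [(i, "case") for i in range(n)], names=["participant", "category"]
        )
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(p)]

    mean_ = x.mean(axis=0)
    if association == "correlation":
        scale_ = x.std(axis=0, ddof=1)
        tiny = 1e-12 * max(1.0, float(np.abs(x).max()))
        if np.any(scale_ <= tiny):
            raise ValueError("zero-variance channel under correlation association")
    elif association == "covariance":
        scale_ = np.ones(p)
    else:
        raise ValueError(f"unknown association {association!r}")
    z = (x - mean_) / scale_
    assoc = (z.T @ z) / (n - 1)

    evals, evecs = np.linalg.eigh(assoc)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]

    kk = scree_select(evals) if k == "scree" else int(k)
    kk = max(1, min(kk, p))
    loadings = evecs[:, :kk] * np.sqrt(evals[:kk])[None, :]
    rotated, _ = varimax(loadings, kaiser=True)
    rotated = _canonical_signs(rotated)

    explained = 100.0 * evals[:kk].sum() / max(evals.sum(), 1e-30)
    scores = _regression_scores(z, assoc, rotated)
    return SpatialFactorModel(
        association=association,
        eigenvalues=evals,
        loadings=loadings,
        rotated_loadings=rotated,
        explained_variance_pct=float(explained),
        scores=scores,
        case_index=case_index,
        channel_names=list(channel_names),
        k=kk,
        mean_=mean_,
        scale_=scale_,
        assoc_=assoc,
    )


def factor_scores(matrix: np.ndarray, model: SpatialFactorModel) -> np.ndarray:
    """Regression-method scores for (possibly new) cases under a fitted model."""
    x = np.asarray(matrix, dtype=float)
    z = (x - model.mean_) / model.scale_
    return _regression_scores(z, model.assoc_, model.rotated_loadings)


def select_posterior_factor(
    model: SpatialFactorModel,
    layout: ChannelLayout,
    laterality: str = "bilateral",
    region_mask: np.ndarray | None = None,
) -> int:
    """Factor with maximal mean |rotated loading| over the posterior region.

    ``laterality`` restricts the region to one hemisphere (plus midline)
    for contralateral selection. Ties resolve to the factor with larger
    explained variance (sum of squared rotated loadings). The criterion
    uses absolute loadings, so it is invariant to column sign flips.
    """
    if region_mask is None:
        region_mask = layout.posterior_mask()
    mask = region_mask & layout.laterality_mask(laterality)
    idx = [
        model.channel_names.index(layout.names[i])
        for i in np.flatnonzero(mask)
        if layout.names[i] in model.channel_names
    ]
    if not idx:
        raise ValueError("empty posterior mask")
    strength = np.abs(model.rotated_loadings[idx, :]).mean(axis=0)
    ssq = (model.rotated_loadings**2).sum(axis=0)
    cand = np.flatnonzero(np.isclose(strength, strength.max()))
    return int(cand[np.argmax(ssq[cand])])


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker congruence coefficient between two loading/topography vectors."""
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def export_model(model: SpatialFactorModel, directory) -> None:
    """TSV loadings and scores plus a JSON summary."""
    import json
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cols = [f"SF{j + 1}" for j in range(model.k)]
    pd.DataFrame(model.rotated_loadings, index=model.channel_names, columns=cols).to_csv(
        d / "rotated_loadings.tsv", sep="\t"
    )
    pd.DataFrame(model.scores, index=model.case_index, columns=cols).to_csv(
        d / "scores.tsv", sep="\t"
    )
    with open(d / "summary.json", "w") as fh:
        json.dump(
            {
                "association": model.association,
                "k": model.k,
                "explained_variance_pct": model.explained_variance_pct,
                "eigenvalues": model.eigenvalues.tolist(),
            },
            fh,
        )
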