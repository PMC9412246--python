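"""Family-level multivariate structure of the nocturnal assemblage.

Site x family matrices of mean biomass or productivity are square-root
transformed, Wisconsin double-standardized (each family column divided
by its maximum, then each site row by its total), converted to
Bray-Curtis dissimilarities and ordinated by non-metric
multidimensional scaling (NMDS, Kruskal stress-1, best of several
random starts).  Family rankings report each family's share of total
productivity within the diel group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression

from .errors import ValidationError
from .productivity import family_rows


def site_family_matrix(
    summaries: pd.DataFrame,
    metric: str = "productivity",
    diel_group: str = "nocturnal",
    level: str = "site",
) -> tuple[pd.DataFrame, pd.Series]:
    """Site x family matrix of mean per-survey biomass or productivity.

    Entries are the mean over a site's surveys of the family-stratum
    value; families absent at a site enter as 0.  ``level='survey'``
    keeps one row per survey instead.  Returns ``(matrix, exposure)``
    with the exposure label per row.
    """
    col = {"biomass": "biomass_t_ha", "productivity": "prod_g_100m2_d"}[metric]
    fam = family_rows(summaries)
    fam = fam[fam["diel_group"] == diel_group]
    if len(fam) == 0:
        raise ValidationError(f"no family-level rows for diel group {diel_group!r}")
    row_key = "site_id" if level == "site" else "survey_id"
    if level == "site":
        # mean over surveys: average per-survey family totals, counting
        # surveys where the family is absent as 0
        per_survey = fam.pivot_table(
            index=["site_id", "survey_id"], columns="family", values=col,
            aggfunc="sum", fill_value=0.0,
        )
        n_surveys = summaries.groupby("site_id")["survey_id"].nunique()
        mat = per_survey.groupby(level="site_id").sum()
        mat = mat.div(n_surveys.reindex(mat.index), axis=0)
    else:
        mat = fam.pivot_table(
            index=row_key, columns="family", values=col, aggfunc="sum", fill_value=0.0
        )
    zero_cols = mat.columns[(mat <= 0).all(axis=0)]
    if len(zero_cols):
        warnings.warn(f"families with all-zero values retained: {list(zero_cols)}")
    exposure = (
        summaries.drop_duplicates(row_key).set_index(row_key)["exposure"]
        .reindex(mat.index)
    )
    return mat.sort_index(), exposure.sort_index()


def sqrt_wisconsin(matrix: pd.DataFrame) -> pd.DataFrame:
    """Square-root transform, then Wisconsin double standardization.

    Each column is divided by its maximum, then each row by its total;
    all-zero rows or columns pass through as zeros.
    """
    x = np.sqrt(np.asarray(matrix, dtype=float))
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValidationError("matrix entries must be finite and >= 0")
    colmax = x.max(axis=0)
    x = np.divide(x, colmax, out=np.zeros_like(x), where=colmax > 0)
    rowsum = x.sum(axis=1, keepdims=True)
    x = np.divide(x, rowsum, out=np.zeros_like(x), where=rowsum > 0)
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(x, index=matrix.index, columns=matrix.columns)
    return x


def bray_curtis(matrix) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity, d = sum|x-y| / sum(x+y).

    A pair of all-zero rows has an undefined dissimilarity; by
    convention it is returned as 0 with a warning.
    """
    x = np.asarray(matrix, dtype=float)
    if np.any(x < 0):
        raise ValidationError("Bray-Curtis requires non-negative entries")
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    if np.any((den == 0) & ~np.eye(len(x), dtype=bool)):
        warnings.warn("all-zero row pair: dissimilarity set to 0 by convention")
    d = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    np.fill_diagonal(d, 0.0)
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(d, index=matrix.index, columns=matrix.index)
    return d


@dataclass
class Ordination:
    coords: pd.DataFrame        # rows = sites, columns axis1..axisk
    stress: float               # Kruskal stress-1 of the best start
    start_stresses: list[float]
    n_starts: int
    seed: int
    converged: bool


def _kruskal_descent(d, x0, max_iter, eps):
    """Minimize Kruskal stress-1 from one starting configuration.

    Alternates isotonic (monotone) regression of the configuration
    distances on the rank order of the observed dissimilarities with a
    backtracking gradient step on stress-1.  Because stress-1 divides by
    the sum of squared configuration distances it does not reward the
    degenerate cluster-collapse solutions that plague raw-stress
    minimizers.
    """
    n = x0.shape[0]
    iu = np.triu_indices(n, 1)
    order = np.argsort(d[iu], kind="stable")
    x = x0.copy()

    def pair_dists(x):
        diff = x[:, None, :] - x[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1) + 1e-12)

    def stress_and_dhat(x):
        dm = pair_dists(x)
        dfit = dm[iu]
        dhat = np.empty_like(dfit)
        dhat[order] = isotonic_regression(dfit[order]).x
        num = float(((dfit - dhat) ** 2).sum())
        den = float((dfit**2).sum())
        return np.sqrt(num / den) if den > 0 else 0.0, dhat, dm

    stress, dhat, dm = stress_and_dhat(x)
    lr = 0.05
    it = 0
    for it in range(max_iter):
        dhat_m = np.zeros_like(dm)
        dhat_m[iu] = dhat
        dhat_m += dhat_m.T
        dfit = dm[iu]
        den = float((dfit**2).sum())
        # gradient of stress-1^2 w.r.t. coordinates, dhat held fixed
        w = ((dm - dhat_m) - stress**2 * dm) / np.maximum(dm, 1e-12) / den
        np.fill_diagonal(w, 0.0)
        grad = 2.0 * (w.sum(axis=1, keepdims=True) * x - w @ x)
        gnorm = np.sqrt((grad**2).sum())
        if gnorm < 1e-14:
            break
        step = lr * np.sqrt((x**2).sum()) / gnorm
        improved = False
        for _ in range(12):
            new_stress, new_dhat, new_dm = stress_and_dhat(x - step * grad)
            if new_stress < stress:
                x = x - step * grad
                improved = True
                break
            step /= 2.0
        if not improved:
            break
        if stress - new_stress < eps:
            stress, dhat, dm = new_stress, new_dhat, new_dm
            break
        stress, dhat, dm = new_stress, new_dhat, new_dm
        lr = min(lr * 1.05, 0.5)
    return stress, x, it


def nmds(
    dist,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 200,
    seed: int = 0,
    eps: float = 1e-7,
) -> Ordination:
    """Non-metric MDS of a dissimilarity matrix, best of ``n_starts``.

    Each start runs an isotonic-regression stress minimization
    (Kruskal stress-1); the first start is initialized from classical
    metric scaling, the rest from random configurations.  The
    lowest-stress solution is returned, centered and rotated to its
    principal axes.  Deterministic given ``seed``.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValidationError("distance matrix must be square and symmetric")
    if not 1 <= k < n:
        raise ValidationError(f"need 1 <= k < n_sites, got k={k}, n={n}")

    # classical (principal-coordinate) start
    j = np.eye(n) - 1.0 / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    idx = np.argsort(evals)[::-1][:k]
    pcoa = evecs[:, idx] * np.sqrt(np.maximum(evals[idx], 1e-12))

    ss = np.random.SeedSequence(seed)
    best = None
    stresses: list[float] = []
    for i, child in enumerate(ss.spawn(n_starts)):
        rng = np.random.default_rng(child)
        x0 = pcoa if i == 0 else rng.normal(size=(n, k))
        stress, coords, n_it = _kruskal_descent(d, x0, max_iter, eps)
        stresses.append(stress)
        if best is None or stress < best[0]:
            best = (stress, coords, n_it)
    stress, coords, n_it = best
    coords = coords - coords.mean(axis=0)
    # rotate to principal axes
    _, _, vt = np.linalg.svd(coords, full_matrices=False)
    coords = coords @ vt.T
    index = dist.index if isinstance(dist, pd.DataFrame) else pd.RangeIndex(n)
    cdf = pd.DataFrame(coords, index=index, columns=[f"axis{i+1}" for i in range(k)])
    return Ordination(
        coords=cdf, stress=stress, start_stresses=stresses,
        n_starts=n_starts, seed=seed, converged=n_it < max_iter,
    )


def top_families(
    summaries: pd.DataFrame,
    n: int = 10,
    metric: str = "productivity",
    diel_group: str = "nocturnal",
) -> pd.DataFrame:
    """Families ranked by their total contribution within a diel group.

    ``share`` is the family total divided by the diel group's grand
    total over all surveys; shares over all families sum to 1.
    """
    col = {"biomass": "biomass_t_ha", "productivity": "prod_g_100m2_d"}[metric]
    fam = family_rows(summaries)
    fam = fam[fam["diel_group"] == diel_group]
    totals = fam.groupby("family")[col].sum().sort_values(ascending=False)
    grand = totals.sum()
    shares = totals / grand if grand > 0 else totals * 0.0
    out = pd.DataFrame({"family": totals.index, "total": totals.values,
                        "share": shares.values})
    return out.head(n).reset_index(drop=True)
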