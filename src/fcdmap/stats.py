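"""Group-level statistics on FCD maps.

Voxel-wise comparison of case vs. control maps uses an OLS fit of each
voxel's value on {intercept, group, age, sex}; the group coefficient's
t statistic (two-tailed p, df = n - p) is the test.  Group is coded
control = 0, case = 1, so a negative t means lower values in cases.
Significance is controlled by Benjamini-Hochberg FDR over the masked
voxels at q = 0.05 plus a minimum cluster extent (default 20 voxels
under 18-neighbor connectivity).  Region-level severity analysis uses
partial Pearson correlation between per-subject regional summaries
(mean or max over a cluster) and a clinical score, controlling age and
sex, with BH correction across the tested regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

from .errors import InputError, RankDeficiencyError
from .grids import VoxelGrid

REQUIRED_COHORT_COLUMNS = ("subject_id", "group", "age", "sex")


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise InputError(f"cohort table missing column(s): {missing}")
    if cohort["subject_id"].duplicated().any():
        raise InputError("cohort table has duplicate subject ids")
    if not set(cohort["group"]) <= {"case", "control"}:
        raise InputError("group labels must be 'case' or 'control'")
    return cohort


@dataclass
class StatMaps:
    """Voxel-wise group-contrast t and two-tailed p maps."""

    t_map: np.ndarray
    p_map: np.ndarray
    df: int
    mask: np.ndarray


def _design_matrix(
    cohort: pd.DataFrame, covariates: tuple[str, ...]
) -> tuple[np.ndarray, list[str]]:
    n = len(cohort)
    cols = [np.ones(n), (cohort["group"].to_numpy() == "case").astype(float)]
    names = ["intercept", "group"]
    for cov in covariates:
        v = cohort[cov]
        x = (v == "M").astype(float).to_numpy() if cov == "sex" else v.to_numpy(float)
        if np.ptp(x) == 0:
            warnings.warn(
                f"covariate {cov!r} is constant; dropping it from the design",
                stacklevel=2,
            )
            continue
        cols.append(x)
        names.append(cov)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError(names)
    return X, names


def voxelwise_glm(
    maps: np.ndarray,
    cohort: pd.DataFrame,
    mask: np.ndarray,
    covariates: tuple[str, ...] = ("age", "sex"),
) -> StatMaps:
    """Fit the group GLM at every masked voxel.

    ``maps`` is (n_subjects, x, y, z) in the row order of ``cohort``.
    Returns t and p maps (zero / one outside the mask) with the residual
    degrees of freedom n - p.
    """
    cohort = validate_cohort(cohort)
    maps = np.asarray(maps, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if maps.shape[0] != len(cohort):
        raise InputError("number of maps != number of cohort rows")
    counts = cohort["group"].value_counts()
    if counts.get("case", 0) < 2 or counts.get("control", 0) < 2:
        raise InputError("need at least 2 subjects per group")

    X, names = _design_matrix(cohort, covariates)
    n, p = X.shape
    if n <= p:
        raise InputError(f"only {n} subjects for {p} design columns")
    Y = maps[:, mask]  # (n, n_voxels)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    g = names.index("group")
    se = np.sqrt(sigma2 * xtx_inv[g, g])
    # voxels fit exactly leave only round-off in the residuals; dividing
    # by that noise is meaningless.  No group difference -> t = 0, p = 1
    # (identical maps); an exact group difference -> t = +-inf, p = 0.
    scale = np.abs(Y).max(axis=0) + np.finfo(float).tiny
    exact_fit = sigma2 <= (1e-10 * scale) ** 2
    null_beta = np.abs(beta[g]) <= 1e-10 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where((exact_fit & null_beta) | (se == 0), 0.0, beta[g] / se)
        t = np.where(exact_fit & ~null_beta, np.sign(beta[g]) * np.inf, t)
    pvals = np.where(exact_fit, np.where(null_beta, 1.0, 0.0),
                     2.0 * sps.t.sf(np.abs(t), df))

    t_map = np.zeros(mask.shape)
    p_map = np.ones(mask.shape)
    t_map[mask] = t
    p_map[mask] = pvals
    return StatMaps(t_map=t_map, p_map=p_map, df=df, mask=mask)


# ------------------------------------------------------------ FDR correction


def bh_correct(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, input order preserved.

    adjusted p_(i) = min_{j >= i} ( m * p_(j) / j ), clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise InputError("p values must lie in [0, 1]")
    flat = p.ravel()
    m = flat.size
    order = np.argsort(flat, kind="stable")
    scaled = flat[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out.reshape(p.shape)


def fdr_correct(
    p_map: np.ndarray, mask: np.ndarray, q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """BH correction over the masked voxels.

    Returns (significance mask, corrected p volume); outside the mask the
    corrected map is 1.
    """
    mask = np.asarray(mask, dtype=bool)
    corrected = np.ones(p_map.shape)
    corrected[mask] = bh_correct(np.asarray(p_map)[mask])
    return (corrected < q) & mask, corrected


# ---------------------------------------------------------------- clustering

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class ClusterTable:
    """Significant clusters: a summary table plus the label volume.

    ``table`` columns: label, size, peak_i/j/k (voxel), peak_x/y/z (mm),
    peak_t, mean_t.  ``labels`` is 0 where no surviving cluster.
    """

    table: pd.DataFrame
    labels: np.ndarray

    def __len__(self) -> int:
        return len(self.table)

    def members(self, label: int) -> np.ndarray:
        """(n, 3) voxel indices of one cluster."""
        return np.argwhere(self.labels == label)

    def save(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def extract_clusters(
    sig_mask: np.ndarray,
    t_map: np.ndarray,
    grid: VoxelGrid,
    min_cluster_size: int = 20,
    connectivity: int = 18,
) -> ClusterTable:
    """Connected components of the significance mask, small ones dropped.

    Components are defined under the given 3D neighbor connectivity
    (6, 18 or 26; default 18) and kept only when they contain at least
    ``min_cluster_size`` voxels.  Each surviving cluster reports its
    size, its peak (the member voxel with maximum |t|) in voxel and
    world coordinates, the peak t and the mean t.
    """
    if connectivity not in _STRUCTURES:
        raise InputError("connectivity must be 6, 18 or 26")
    sig_mask = np.asarray(sig_mask, dtype=bool)
    labelled, n_comp = ndimage.label(sig_mask, structure=_STRUCTURES[connectivity])
    out_labels = np.zeros_like(labelled)
    rows = []
    next_label = 0
    for comp in range(1, n_comp + 1):
        member_idx = np.argwhere(labelled == comp)
        if len(member_idx) < min_cluster_size:
            continue
        next_label += 1
        out_labels[tuple(member_idx.T)] = next_label
        tvals = t_map[tuple(member_idx.T)]
        peak = member_idx[np.argmax(np.abs(tvals))]
        world = grid.world_coords(peak)[0]
        rows.append(
            {
                "label": next_label,
                "size": len(member_idx),
                "peak_i": int(peak[0]),
                "peak_j": int(peak[1]),
                "peak_k": int(peak[2]),
                "peak_x": world[0],
                "peak_y": world[1],
                "peak_z": world[2],
                "peak_t": float(tvals[np.argmax(np.abs(tvals))]),
                "mean_t": float(tvals.mean()),
            }
        )
    columns = ["label", "size", "peak_i", "peak_j", "peak_k",
               "peak_x", "peak_y", "peak_z", "peak_t", "mean_t"]
    return ClusterTable(pd.DataFrame(rows, columns=columns), out_labels)


def overlap_map(
    mask_g: np.ndarray, mask_c: np.ndarray, mask_i: np.ndarray
) -> np.ndarray:
    """Per-voxel count (0-3) of FCD measures flagging that voxel."""
    masks = [np.asarray(m, dtype=bool) for m in (mask_g, mask_c, mask_i)]
    if not (masks[0].shape == masks[1].shape == masks[2].shape):
        raise InputError("overlap masks must share one grid")
    return sum(m.astype(np.int8) for m in masks)


# ------------------------------------------------------ regional summaries


def regional_summary(
    maps: np.ndarray,
    cohort: pd.DataFrame,
    clusters: ClusterTable,
    mode: str = "mean",
) -> pd.DataFrame:
    """Per-subject mean (or max) of a map over each cluster's voxels.

    Returns a DataFrame indexed by subject_id with one column per cluster
    label (``cluster_<label>``).
    """
    if mode not in ("mean", "max"):
        raise InputError("mode must be 'mean' or 'max'")
    maps = np.asarray(maps, dtype=float)
    out = {}
    for label in clusters.table["label"]:
        vox = clusters.members(int(label))
        vals = maps[(slice(None), *vox.T)]  # (n_subjects, cluster size)
        out[f"cluster_{label}"] = vals.mean(axis=1) if mode == "mean" else vals.max(axis=1)
    return pd.DataFrame(out, index=pd.Index(cohort["subject_id"], name="subject_id"))


# --------------------------------------------------- partial correlation


class PartialCorrelationResult(NamedTuple):
    rho: float
    p: float
    df: int
    n: int


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> PartialCorrelationResult:
    """Pearson correlation of x and y after removing the covariates.

    Both variables are residualized on {intercept} ∪ covariates; rho is
    the Pearson correlation of the residuals, with df = n - 2 - k for k
    covariate columns and a two-tailed p from t = rho * sqrt(df / (1 -
    rho^2)).  Rows with any missing value are dropped (pairwise-complete).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        C = np.empty((len(x), 0))
    else:
        C = np.asarray(covariates, dtype=float)
        C = C[:, None] if C.ndim == 1 else C
    if not (len(x) == len(y) == len(C)):
        raise InputError("x, y and covariates must have equal length")
    complete = np.isfinite(x) & np.isfinite(y) & np.isfinite(C).all(axis=1)
    x, y, C = x[complete], y[complete], C[complete]
    n, k = len(x), C.shape[1]
    if n < k + 4:
        raise InputError(f"only {n} complete cases for {k} covariates")
    design = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise RankDeficiencyError([f"covariate_{i}" for i in range(k)])
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise InputError("residuals are constant; partial correlation undefined")
    rho = float(np.dot(rx, ry) / (np.linalg.norm(rx) * np.linalg.norm(ry)))
    df = n - 2 - k
    rho_c = min(max(rho, -1.0), 1.0)
    if abs(rho_c) == 1.0:
        p = 0.0
    else:
        t = rho_c * np.sqrt(df / (1.0 - rho_c**2))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return PartialCorrelationResult(rho=rho, p=p, df=df, n=n)


def sex_to_numeric(sex: pd.Series) -> np.ndarray:
    """Binary sex indicator (M = 1, F = 0) for covariate matrices."""
    return (sex == "M").to_numpy(float)


def correlation_report(
    summaries: pd.DataFrame,
    cohort: pd.DataFrame,
    score: str = "score",
    covariates: tuple[str, ...] = ("age", "sex"),
) -> pd.DataFrame:
    """Partial correlation of every regional summary column with a score.

    One row per region column of ``summaries`` (aligned to the cohort by
    subject_id), BH-corrected across rows.  Columns: region, rho, df, n,
    p_raw, p_bh.
    """
    cohort = validate_cohort(cohort)
    aligned = summaries.reindex(cohort["subject_id"])
    cov_cols = []
    for cov in covariates:
        cov_cols.append(
            sex_to_numeric(cohort[cov]) if cov == "sex" else cohort[cov].to_numpy(float)
        )
    C = np.column_stack(cov_cols) if cov_cols else None
    y = cohort[score].to_numpy(float)
    rows = []
    for region in aligned.columns:
        res = partial_correlation(aligned[region].to_numpy(float), y, C)
        rows.append(
            {"region": region, "rho": res.rho, "df": res.df, "n": res.n, "p_raw": res.p}
        )
    report = pd.DataFrame(rows, columns=["region", "rho", "df", "n", "p_raw"])
    report["p_bh"] = bh_correct(report["p_raw"].to_numpy()) if len(report) else []
    return report
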