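"""General linear model analysis of simulated BOLD runs.

First-level fits use ordinary least squares per voxel on a design of
HRF-convolved block or event regressors plus intercept and polynomial
drift.  Group-level maps are voxelwise one-sample t maps or the t map of
a behavioral covariate (tapping improvement) controlling for a clinical
nuisance covariate.  Suprathreshold voxels are grouped into clusters by
face connectivity and reduced to a cluster table with peak statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import scipy.stats as st

from .stats import spearman

__all__ = [
    "DesignMatrix",
    "StatMap",
    "ClusterTable",
    "canonical_hrf",
    "boxcar_from_schedule",
    "sticks_from_trs",
    "convolve_with_hrf",
    "build_design",
    "fit_first_level",
    "group_one_sample",
    "group_covariate",
    "cluster_threshold",
    "roi_summary",
]


def canonical_hrf(dt_s: float, duration_s: float = 32.0,
                  peak_delay_s: float = 6.0, undershoot_delay_s: float = 16.0,
                  peak_disp_s: float = 1.0, undershoot_disp_s: float = 1.0,
                  peak_undershoot_ratio: float = 6.0) -> np.ndarray:
    """Canonical hemodynamic response sampled every ``dt_s`` seconds.

    The kernel is the usual difference of two gamma densities: a positive
    response peaking near ``peak_delay_s - peak_disp_s`` seconds and a
    late undershoot scaled down by ``peak_undershoot_ratio``.  The kernel
    is truncated at ``duration_s`` and normalized to unit peak so planted
    amplitudes are in signal units.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")

    def raw(t):
        peak = st.gamma.pdf(t, a=peak_delay_s / peak_disp_s,
                            scale=peak_disp_s)
        under = st.gamma.pdf(t, a=undershoot_delay_s / undershoot_disp_s,
                             scale=undershoot_disp_s)
        return peak - under / peak_undershoot_ratio

    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    # normalize by the continuous-time peak so the sampled values are
    # independent of the sampling grid
    t_fine = np.arange(0.0, duration_s, 1e-3)
    return raw(t) / raw(t_fine).max()


def boxcar_from_schedule(schedule, conditions) -> np.ndarray:
    """TR-sampled indicator of ``conditions`` (a name or a set of names)."""
    if isinstance(conditions, str):
        conditions = {conditions}
    per_tr = schedule.conditions_per_tr()
    return np.array([c in conditions for c in per_tr], dtype=float)


def sticks_from_trs(tr_indices, n_trs: int) -> np.ndarray:
    """Unit impulses at the given TR indices (event-related regressor)."""
    out = np.zeros(n_trs)
    idx = np.asarray(list(tr_indices), dtype=int)
    if idx.size:
        if idx.min() < 0 or idx.max() >= n_trs:
            raise ValueError("event TR index outside the run")
        out[idx] = 1.0
    return out


def convolve_with_hrf(regressor: np.ndarray, hrf: np.ndarray) -> np.ndarray:
    """Causal convolution truncated to the run length."""
    regressor = np.asarray(regressor, dtype=float)
    return np.convolve(regressor, hrf)[: regressor.size]


@dataclass
class DesignMatrix:
    """Named design, one row per TR."""

    matrix: np.ndarray          # (n_trs, n_columns)
    names: list[str]
    tr_s: float

    @property
    def n_trs(self) -> int:
        return self.matrix.shape[0]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.names)


def build_design(regressors: dict[str, np.ndarray], tr_s: float,
                 hrf: np.ndarray | None = None, drift_order: int = 1,
                 confounds: dict[str, np.ndarray] | None = None,
                 rank_check: bool = True) -> DesignMatrix:
    """Assemble a design from TR-sampled task regressors.

    Each entry of ``regressors`` is a boxcar or stick series sampled at
    the TR; it is convolved with ``hrf`` (canonical kernel at TR
    resolution when omitted).  An intercept and Legendre-like polynomial
    drift columns up to ``drift_order`` are appended, then any
    ``confounds`` (e.g. motion series), unconvolved.  A rank-deficient
    result (for example an all-zero event regressor) is rejected with
    the offending columns named.
    """
    if not regressors:
        raise ValueError("at least one task regressor is required")
    lengths = {np.asarray(v).size for v in regressors.values()}
    if len(lengths) != 1:
        raise ValueError("task regressors must share the run length")
    n_trs = lengths.pop()
    if hrf is None:
        hrf = canonical_hrf(tr_s)

    cols, names = [], []
    for name, series in regressors.items():
        cols.append(convolve_with_hrf(np.asarray(series, float), hrf))
        names.append(name)
    cols.append(np.ones(n_trs))
    names.append("intercept")
    t = np.linspace(-1.0, 1.0, n_trs)
    for order in range(1, drift_order + 1):
        cols.append(t ** order)
        names.append(f"drift_{order}")
    for name, series in (confounds or {}).items():
        series = np.asarray(series, dtype=float)
        if series.ndim == 1:
            series = series[:, None]
        if series.shape[0] != n_trs:
            raise ValueError(f"confound {name!r} length mismatch")
        for j in range(series.shape[1]):
            cols.append(series[:, j])
            names.append(name if series.shape[1] == 1 else f"{name}_{j}")
    X = np.column_stack(cols)

    if rank_check:
        zero = [n for n, c in zip(names, X.T) if not np.any(c)]
        if zero:
            raise ValueError(f"all-zero design columns: {zero}")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(
                f"rank-deficient design (columns: {names})")
    return DesignMatrix(matrix=X, names=names, tr_s=tr_s)


def _flatten_runs(data: np.ndarray) -> tuple[np.ndarray, tuple]:
    """4D (x,y,z,t) -> (t, voxels) plus the spatial shape."""
    if data.ndim != 4:
        raise ValueError("expected a 4D (x, y, z, t) array")
    shape = data.shape[:3]
    return data.reshape(-1, data.shape[3]).T, shape


def fit_first_level(data: np.ndarray, design: DesignMatrix,
                    contrast: np.ndarray) -> np.ndarray:
    """Per-voxel OLS contrast estimate ``c @ beta_hat`` as a 3D map.

    ``contrast`` may name only the leading task columns; it is padded
    with zeros over intercept/drift columns.
    """
    Y, shape = _flatten_runs(data)
    X = design.matrix
    if Y.shape[0] != X.shape[0]:
        raise ValueError("design rows do not match run volumes")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix")
    contrast = np.asarray(contrast, dtype=float)
    if contrast.size < X.shape[1]:
        contrast = np.concatenate(
            [contrast, np.zeros(X.shape[1] - contrast.size)])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return (contrast @ beta).reshape(shape)


@dataclass
class StatMap:
    """Voxelwise t map with its degrees of freedom.

    Voxels where the test is undefined (zero residual variance) carry
    NaN rather than an infinite statistic.
    """

    t: np.ndarray               # 3D
    df: int
    model: str                  # "one_sample" | "covariate"
    extras: dict = field(default_factory=dict)


def _stack_maps(maps) -> np.ndarray:
    arr = np.stack([np.asarray(m, dtype=float) for m in maps])
    if arr.ndim != 4:
        raise ValueError("contrast maps must be 3D volumes on one grid")
    return arr


def group_one_sample(contrast_maps) -> StatMap:
    """Voxelwise one-sample t of subject contrasts against zero."""
    arr = _stack_maps(contrast_maps)
    n = arr.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), np.nan)
    return StatMap(t=t, df=n - 1, model="one_sample")


def group_covariate(contrast_maps, delta_rmse, control_covariate) -> StatMap:
    """t map of the tapping-improvement coefficient, controlling a nuisance.

    Per voxel, the subject contrasts are regressed on an intercept, the
    per-subject improvement score and the control covariate (e.g. a
    clinical severity score); the reported statistic is the improvement
    coefficient's t with n - 3 degrees of freedom.  A constant control
    covariate carries no information beyond the intercept and is
    dropped, reducing to the two-column intercept + improvement fit
    (df = n - 2); covariates that are genuinely collinear with the
    improvement scores are rejected.
    """
    arr = _stack_maps(contrast_maps)
    n = arr.shape[0]
    d = np.asarray(delta_rmse, dtype=float)
    c = np.asarray(control_covariate, dtype=float)
    if d.size != n or c.size != n:
        raise ValueError("one covariate value per subject is required")
    if np.ptp(c) == 0:
        X = np.column_stack([np.ones(n), d])
    else:
        X = np.column_stack([np.ones(n), d, c])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear covariates (including intercept)")
    shape = arr.shape[1:]
    Y = arr.reshape(n, -1)
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    df = n - X.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = (resid ** 2).sum(axis=0) / df if df > 0 \
            else np.full(Y.shape[1], np.nan)
    var_d = np.linalg.inv(X.T @ X)[1, 1]
    se = np.sqrt(sigma2 * var_d)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[1] / se, np.nan)
    return StatMap(t=t.reshape(shape), df=df, model="covariate")


_FACE_STRUCTURE = ndi.generate_binary_structure(3, 1)


@dataclass
class ClusterTable:
    """Suprathreshold clusters surviving the extent threshold."""

    clusters: pd.DataFrame      # size_voxels, peak_t, peak_x/y/z
    p_voxel: float
    k: int
    t_threshold: float
    labels: np.ndarray          # 3D int labels, 0 = background / dropped

    def __len__(self) -> int:
        return len(self.clusters)

    def cluster_mask(self, row: int) -> np.ndarray:
        label = int(self.clusters.iloc[row]["label"])
        return self.labels == label


def cluster_threshold(stat_map: StatMap, p_voxel: float = 0.001,
                      k: int = 15, two_sided: bool = False) -> ClusterTable:
    """Voxel threshold at ``p_voxel`` then drop clusters smaller than ``k``.

    One-sided positive thresholding by default (activation maps); the
    two-sided variant thresholds |t| at p/2 per tail.  Clusters are
    connected components under face (6-neighbor) connectivity.
    """
    if two_sided:
        thr = st.t.isf(p_voxel / 2, stat_map.df)
        supra = np.abs(np.nan_to_num(stat_map.t, nan=0.0)) > thr
    else:
        thr = st.t.isf(p_voxel, stat_map.df)
        supra = np.nan_to_num(stat_map.t, nan=-np.inf) > thr

    labels, n_labels = ndi.label(supra, structure=_FACE_STRUCTURE)
    rows = []
    keep = np.zeros_like(labels)
    for lab in range(1, n_labels + 1):
        members = labels == lab
        size = int(members.sum())
        if size < k:
            continue
        tvals = np.where(members, np.abs(np.nan_to_num(stat_map.t)), -np.inf)
        peak = np.unravel_index(np.argmax(tvals), tvals.shape)
        rows.append(dict(label=lab, size_voxels=size,
                         peak_t=float(stat_map.t[peak]),
                         peak_x=peak[0], peak_y=peak[1], peak_z=peak[2]))
        keep[members] = lab
    frame = pd.DataFrame(
        rows, columns=["label", "size_voxels", "peak_t",
                       "peak_x", "peak_y", "peak_z"])
    if len(frame):
        frame = frame.sort_values("size_voxels", ascending=False,
                                  ignore_index=True)
    return ClusterTable(clusters=frame, p_voxel=p_voxel, k=k,
                        t_threshold=float(thr), labels=keep)


def roi_summary(contrast_maps, cluster_mask: np.ndarray, delta_rmse):
    """Per-subject ROI means over a cluster plus their Spearman link.

    Returns ``(means, TestResult)`` where ``means[i]`` is subject *i*'s
    mean contrast over the cluster voxels and the test is the rank
    correlation of those means with the improvement scores.
    """
    cluster_mask = np.asarray(cluster_mask, dtype=bool)
    if not cluster_mask.any():
        raise ValueError("empty ROI cluster")
    arr = _stack_maps(contrast_maps)
    means = arr[:, cluster_mask].mean(axis=1)
    return means, spearman(means, np.asarray(delta_rmse, dtype=float))
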