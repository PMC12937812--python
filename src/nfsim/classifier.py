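"""Tapping-vs-rest decoding with the real-time preprocessing contract.

Training mirrors the offline step between the second tapping run and the
first imagery run: per-voxel regression of baseline, linear trend and
six motion series, spatial Gaussian smoothing, hemodynamically shifted
TR labels, and a linear maximum-margin classifier restricted to the
analysis mask (brain minus visual exclusion).  Decoding of new volumes
follows the online contract: nuisance coefficients are estimated only on
the volumes acquired earlier in the same run, then applied to the
incoming volume, so the decision for a volume never uses data from its
future.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from sklearn.svm import SVC

from .synthetic import BlockSchedule, MaskSet, VolumeSeries, TAP_CONDITIONS

__all__ = [
    "ClassifierModel",
    "Decision",
    "gaussian_blur",
    "offline_preprocess",
    "labels_from_schedule",
    "train_classifier",
    "online_preprocess",
    "replay_run_online",
    "decode",
    "evaluate_held_out",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Volumes of within-run history required before online nuisance
#: regression engages; below this the volume is passed through centered.
#: The leading practice blocks play exactly this kick-start role.
MIN_HISTORY = 8


@dataclass
class ClassifierModel:
    """Linear decision rule over analysis-mask voxels."""

    weights: np.ndarray         # 3D volume; zero outside the analysis mask
    bias: float
    masks: MaskSet
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        outside = ~self.masks.analysis_mask
        if np.any(self.weights[outside] != 0):
            raise ValueError("weights must vanish outside the analysis mask")


@dataclass
class Decision:
    tr_index: int
    decision_value: float       # signed distance-to-hyperplane surrogate
    label: str                  # "tap" | "rest"


def gaussian_blur(volume: np.ndarray, fwhm_voxels: float) -> np.ndarray:
    """Spatial Gaussian smoothing with FWHM given in voxels."""
    if fwhm_voxels <= 0:
        return volume
    return ndi.gaussian_filter(volume, sigma=fwhm_voxels * FWHM_TO_SIGMA)


def _nuisance_design(n_trs: int, motion_params: np.ndarray | None
                     ) -> np.ndarray:
    cols = [np.ones(n_trs), np.linspace(-1.0, 1.0, n_trs)]
    if motion_params is not None:
        motion_params = np.asarray(motion_params, dtype=float)
        if motion_params.shape[0] != n_trs:
            raise ValueError("motion series length must match the run")
        # constant motion series carry no information beyond the
        # intercept (e.g. a motionless subject): drop them
        for col in motion_params.T:
            if np.ptp(col) > 0:
                cols.append(col)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular nuisance design (duplicated motion "
                         "series)")
    return X


def offline_preprocess(run: VolumeSeries, motion_params: np.ndarray | None,
                       blur_fwhm_voxels: float = 1.7,
                       task_regressor: np.ndarray | None = None
                       ) -> VolumeSeries:
    """Residualize baseline/trend/motion per voxel, then smooth.

    When ``task_regressor`` (the known HRF-convolved block indicator) is
    supplied, it joins the nuisance fit so baseline and trend estimates
    do not absorb task signal, but only the nuisance components are
    subtracted — the task response stays in the output, mirroring what
    the online path sees.  Without it the residual is the plain
    projection (zero mean per voxel).

    Slice-timing correction is a deliberate no-op here: synthetic
    volumes are generated without slice offsets, and interpolation for
    real data belongs upstream of this package.
    """
    X = _nuisance_design(run.n_trs, motion_params)
    n_nuisance = X.shape[1]
    if task_regressor is not None:
        task = np.asarray(task_regressor, dtype=float)
        if task.size != run.n_trs:
            raise ValueError("task regressor length must match the run")
        X = np.column_stack([X, task])
    Y = run.data.reshape(-1, run.n_trs).T       # (t, voxels)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = (Y - X[:, :n_nuisance] @ beta[:n_nuisance]).T \
        .reshape(run.data.shape)
    if blur_fwhm_voxels > 0:
        sigma = blur_fwhm_voxels * FWHM_TO_SIGMA
        resid = ndi.gaussian_filter(resid, sigma=(sigma, sigma, sigma, 0))
    return VolumeSeries(data=resid, tr_s=run.tr_s, run_index=run.run_index)


def labels_from_schedule(schedule: BlockSchedule,
                         label_shift_trs: int = 2) -> list[str | None]:
    """Per-TR tap/rest labels shifted for hemodynamic delay.

    The BOLD response lags the task, so volume t is labeled with the
    condition at t - shift; the first ``label_shift_trs`` volumes get
    None and are dropped from training and accuracy denominators.
    """
    conds = schedule.conditions_per_tr()
    out: list[str | None] = []
    for t in range(len(conds)):
        src = t - label_shift_trs
        if src < 0:
            out.append(None)
        else:
            out.append("tap" if conds[src] in TAP_CONDITIONS else "rest")
    return out


def train_classifier(runs, schedules, masks: MaskSet,
                     label_shift_trs: int = 2, C: float = 100.0,
                     blur_fwhm_voxels: float = 1.7,
                     seed: int = 0) -> ClassifierModel:
    """Fit the linear SVM on the (preprocessed) tapping runs.

    ``runs`` are the outputs of :func:`offline_preprocess` for runs 1-2;
    TR labels come from the schedules (tap blocks of either pace = tap),
    shifted by ``label_shift_trs``.  Only analysis-mask voxels enter the
    fit; the returned weight volume is zero elsewhere, so excluded
    visual voxels can never influence a decision.
    """
    grids = {r.grid_shape for r in runs}
    if len(grids) != 1 or grids.pop() != masks.analysis_mask.shape:
        raise ValueError("runs and masks must share one grid")
    X_rows, y = [], []
    for run, schedule in zip(runs, schedules):
        labels = labels_from_schedule(schedule, label_shift_trs)
        feats = run.data[masks.analysis_mask]       # (voxels, t)
        for t, lab in enumerate(labels):
            if lab is None:
                continue
            X_rows.append(feats[:, t])
            y.append(lab)
    if len(set(y)) < 2:
        raise ValueError("training labels contain a single class")
    svm = SVC(kernel="linear", C=C, random_state=seed)
    svm.fit(np.asarray(X_rows), np.asarray(y))
    w_mask = svm.coef_.ravel()
    # sklearn orders classes alphabetically (rest, tap): positive
    # decision values mean tap already, keep orientation
    weights = np.zeros(masks.analysis_mask.shape)
    weights[masks.analysis_mask] = w_mask
    return ClassifierModel(
        weights=weights, bias=float(svm.intercept_[0]), masks=masks,
        training_meta={"label_shift_trs": label_shift_trs,
                       "blur_fwhm_voxels": blur_fwhm_voxels,
                       "C": C, "seed": seed})


def task_regressor_from_schedule(schedule: BlockSchedule) -> np.ndarray:
    """HRF-convolved indicator of the run's task-on blocks.

    Tap blocks for tapping runs, (practice-)ITAP blocks for imagery
    runs.  The display computer knows the schedule, so this regressor is
    available online; it protects the nuisance fit from absorbing task
    signal without ever being subtracted from a volume.
    """
    from .glm import boxcar_from_schedule, canonical_hrf, convolve_with_hrf
    if schedule.run_kind == "tapping":
        conds = set(TAP_CONDITIONS)
    else:
        conds = {"ITAP", "practiceITAP"}
    box = boxcar_from_schedule(schedule, conds)
    return convolve_with_hrf(box, canonical_hrf(schedule.tr_s))


def online_preprocess(new_volume: np.ndarray, new_motion,
                      history_volumes: np.ndarray | None,
                      history_motion: np.ndarray | None,
                      history_task: np.ndarray | None = None,
                      blur_fwhm_voxels: float = 1.7,
                      min_history: int = MIN_HISTORY) -> np.ndarray:
    """Residualize one incoming volume against its within-run history.

    Intercept, linear trend and motion coefficients are estimated on the
    ``history_volumes`` only (shape voxels... x t), then evaluated at
    the new volume's time point and subtracted.  When ``history_task``
    (the known task regressor over the history) is supplied it joins the
    history fit so trend estimates do not swallow task signal, but its
    component is never subtracted — the decoder must still see the task
    response.  With fewer than ``min_history`` volumes of history the
    volume is merely centered on the history mean (passthrough when
    there is no history at all).  Smoothing matches the offline training
    preprocessing.
    """
    n_hist = 0 if history_volumes is None else history_volumes.shape[-1]
    if n_hist < min_history:
        if n_hist == 0:
            resid = new_volume.copy()
        else:
            resid = new_volume - history_volumes.mean(axis=-1)
        return gaussian_blur(resid, blur_fwhm_voxels)

    t_new = n_hist                      # the incoming volume's index
    t_all = np.arange(n_hist + 1, dtype=float)
    cols = [np.ones(n_hist + 1), t_all]
    if history_motion is not None:
        motion = np.vstack([np.asarray(history_motion, dtype=float),
                            np.asarray(new_motion, dtype=float)])
        cols.extend(motion.T)
    n_nuisance = len(cols)
    if history_task is not None:
        task = np.asarray(history_task, dtype=float)
        if np.ptp(task[:n_hist]) > 0:   # constant-so-far task: skip
            cols.append(np.concatenate([task[:n_hist], [0.0]]))
    X = np.column_stack(cols)
    X_hist, x_new = X[:n_hist], X[t_new].copy()
    x_new[n_nuisance:] = 0.0            # never subtract the task component
    Y = history_volumes.reshape(-1, n_hist).T       # (t, voxels)
    beta, *_ = np.linalg.lstsq(X_hist, Y, rcond=None)
    resid = new_volume - (x_new @ beta).reshape(new_volume.shape)
    return gaussian_blur(resid, blur_fwhm_voxels)


def replay_run_online(model: ClassifierModel, run: VolumeSeries,
                      motion_params: np.ndarray | None,
                      schedule: BlockSchedule | None = None,
                      min_history: int = MIN_HISTORY) -> list[Decision]:
    """Decode every volume of a run under the online contract."""
    blur = model.training_meta.get("blur_fwhm_voxels", 1.7)
    task = task_regressor_from_schedule(schedule) \
        if schedule is not None else None
    decisions = []
    for t in range(run.n_trs):
        history = run.data[..., :t] if t else None
        h_motion = motion_params[:t] if motion_params is not None else None
        n_motion = motion_params[t] if motion_params is not None else None
        processed = online_preprocess(run.data[..., t], n_motion, history,
                                      h_motion,
                                      history_task=task[:t + 1]
                                      if task is not None else None,
                                      blur_fwhm_voxels=blur,
                                      min_history=min_history)
        decisions.append(decode(model, processed, tr_index=t))
    return decisions


def decode(model: ClassifierModel, processed_volume: np.ndarray,
           tr_index: int = 0) -> Decision:
    """Signed decision value w.x + b; ties (exactly 0) decode as rest."""
    if processed_volume.shape != model.weights.shape:
        raise ValueError("volume grid does not match the model grid")
    mask = model.masks.analysis_mask
    value = float(model.weights[mask] @ processed_volume[mask] + model.bias)
    return Decision(tr_index=tr_index, decision_value=value,
                    label="tap" if value > 0 else "rest")


def evaluate_held_out(model: ClassifierModel, runs, schedules,
                      motions=None) -> dict[str, float]:
    """Replay held-out tapping runs and score per-class accuracy.

    Labels use the same hemodynamic shift as training.  Returns the
    fraction of correctly decoded TRs within tap blocks, within rest
    blocks, and overall.
    """
    if motions is None:
        motions = [None] * len(runs)
    shift = model.training_meta.get("label_shift_trs", 2)
    hits = {"tap": 0, "rest": 0}
    totals = {"tap": 0, "rest": 0}
    for run, schedule, motion in zip(runs, schedules, motions):
        labels = labels_from_schedule(schedule, shift)
        decisions = replay_run_online(model, run, motion, schedule=schedule)
        for lab, dec in zip(labels, decisions):
            if lab is None:
                continue
            totals[lab] += 1
            hits[lab] += int(dec.label == lab)
    overall_n = totals["tap"] + totals["rest"]
    return {
        "tap_accuracy": hits["tap"] / totals["tap"] if totals["tap"]
        else float("nan"),
        "rest_accuracy": hits["rest"] / totals["rest"] if totals["rest"]
        else float("nan"),
        "overall_accuracy": (hits["tap"] + hits["rest"]) / overall_n
        if overall_n else float("nan"),
    }
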