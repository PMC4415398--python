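"""Desk-scale block-design GLM and neural differential sensitivity (NDS).

A stimulus timeline is turned into an HRF-convolved design matrix (one
boxcar regressor per modeled condition, fixation as implicit baseline,
plus intercept and linear drift), each voxel's series is fit by ordinary
least squares, and the avoidance-versus-approach contrast

    NDS contrast = mean(beta_angry, beta_fearful, beta_sad) - beta_happy

is formed per voxel with a t statistic mapped to a standard-normal z by
two-sided tail matching.  A subject's NDS is the mean contrast over
ventral-striatum/nucleus-accumbens (VS/NAc) voxels whose z exceeds a
threshold (default 1.96, i.e. p < 0.05); subjects with no surviving ROI
voxel yield an invalid result and drop out of group statistics, like
the motion-artifact exclusions of a real study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .task_design import (
    NEGATIVE_LABELS,
    POSITIVE_LABELS,
    StimulusTimeline,
)

ROI_LABELS = ("VS_NAc_left", "VS_NAc_right", "none")
DEFAULT_TR = 2.5
DEFAULT_Z_THRESHOLD = 1.96

#: canonical double-gamma HRF: response peak, undershoot peak (s), and
#: the peak-to-undershoot amplitude ratio
DEFAULT_HRF = (6.0, 16.0, 6.0)


class RankDeficientDesignError(np.linalg.LinAlgError):
    """The design matrix does not have full column rank."""


@dataclass
class VoxelTable:
    voxel_ids: list[str]
    roi_labels: list[str]
    series: np.ndarray  # (n_voxels, n_volumes)
    tr: float

    def __post_init__(self):
        self.series = np.asarray(self.series, dtype=float)
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.series.ndim != 2 or self.series.shape[0] != len(self.voxel_ids):
            raise ValueError("series must be (n_voxels, n_volumes)")
        if len(self.roi_labels) != len(self.voxel_ids):
            raise ValueError("one roi label per voxel required")

    @property
    def n_voxels(self) -> int:
        return self.series.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.series.shape[1]


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # (n_volumes, n_columns)
    columns: list[str]  # condition labels + "intercept" + "drift"
    tr: float

    @property
    def condition_columns(self) -> list[str]:
        return [c for c in self.columns if c not in ("intercept", "drift")]

    def column_index(self, name: str) -> int:
        return self.columns.index(name)


@dataclass
class GLMFit:
    betas: np.ndarray  # (n_voxels, n_columns)
    sigma2: np.ndarray  # (n_voxels,) residual variance, df-corrected
    df: int
    xtx_inv: np.ndarray
    design: DesignMatrix


@dataclass
class ContrastResult:
    voxel_id: str
    beta_neg: float
    beta_pos: float
    contrast: float
    z: float
    roi_label: str = "none"


@dataclass
class NDSResult:
    subject_id: str
    nds: float
    n_voxels_used: int
    threshold_z: float
    hemisphere: str

    @property
    def valid(self) -> bool:
        return self.n_voxels_used >= 1 and np.isfinite(self.nds)


def double_gamma_hrf(
    t: np.ndarray,
    peak: float = DEFAULT_HRF[0],
    undershoot: float = DEFAULT_HRF[1],
    ratio: float = DEFAULT_HRF[2],
) -> np.ndarray:
    """Canonical double-gamma haemodynamic response, peak-normalised.

    Difference of two gamma densities (shape = peak delay, unit scale),
    the second scaled down by ``ratio`` — the default family of the
    major fMRI packages.
    """
    t = np.asarray(t, dtype=float)
    h = stats.gamma.pdf(t, peak) - stats.gamma.pdf(t, undershoot) / ratio
    peak_val = h.max()
    return h / peak_val if peak_val > 0 else h


def build_design_matrix(
    timeline: StimulusTimeline,
    tr: float = DEFAULT_TR,
    hrf: tuple[float, float, float] = DEFAULT_HRF,
    dt: float = 0.1,
    n_volumes: int | None = None,
) -> DesignMatrix:
    """HRF-convolved boxcar regressors sampled at volume midpoints.

    Every condition present in the timeline except fixation (the
    implicit baseline) gets one column; an intercept and a linear drift
    term are appended.  Conditions absent from the timeline simply
    yield no column.  ``n_volumes`` pins the number of sampled volumes
    (e.g. to an acquired series whose final block outlasts its last
    stimulus event); by default it is ``floor(total_duration / tr)``.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if not timeline.events:
        raise ValueError("empty timeline")
    if timeline.total_duration < 2 * tr:
        raise ValueError("timeline must cover at least two volumes")
    n_vols = n_volumes if n_volumes is not None else int(np.floor(timeline.total_duration / tr))
    if n_vols < 2:
        raise ValueError("need at least two volumes")
    labels = [l for l in timeline.condition_labels() if l != "fixation"]

    grid_len = int(np.ceil(max(timeline.total_duration, n_vols * tr) / dt)) + 1
    t_grid = np.arange(grid_len) * dt
    hrf_kernel = double_gamma_hrf(np.arange(0, 32 + dt, dt), *hrf)
    sample_t = (np.arange(n_vols) + 0.5) * tr
    sample_idx = np.round(sample_t / dt).astype(int)

    cols = []
    for lbl in labels:
        box = np.zeros(grid_len)
        for ev in timeline.events:
            if ev.condition.label == lbl:
                i0 = int(np.round(ev.onset / dt))
                i1 = int(np.round((ev.onset + ev.duration) / dt))
                box[i0 : max(i1, i0 + 1)] = 1.0
        reg = np.convolve(box, hrf_kernel)[:grid_len] * dt
        cols.append(reg[sample_idx])

    X = np.column_stack(
        cols + [np.ones(n_vols), np.linspace(-0.5, 0.5, n_vols)]
    )
    return DesignMatrix(matrix=X, columns=labels + ["intercept", "drift"], tr=tr)


def fit_glm(voxels: VoxelTable, design: DesignMatrix) -> GLMFit:
    """Vectorised per-voxel ordinary least squares."""
    X = design.matrix
    if voxels.n_volumes != X.shape[0]:
        raise ValueError(
            f"series length {voxels.n_volumes} != design rows {X.shape[0]}"
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficientDesignError("design matrix is rank deficient")
    Y = voxels.series.T  # (n_volumes, n_voxels)
    xtx_inv = np.linalg.inv(X.T @ X)
    betas = xtx_inv @ X.T @ Y  # (p, n_voxels)
    resid = Y - X @ betas
    df = X.shape[0] - X.shape[1]
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = (resid**2).sum(axis=0) / df
    return GLMFit(
        betas=betas.T,
        sigma2=sigma2,
        df=df,
        xtx_inv=xtx_inv,
        design=design,
    )


def _t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Map t deviates to standard-normal deviates with the same
    two-sided tail probability."""
    t = np.asarray(t, dtype=float)
    p_half = stats.t.sf(np.abs(t), df)  # one tail
    # clip to keep isf finite for astronomically significant voxels
    z = stats.norm.isf(np.clip(p_half, 1e-300, 1.0))
    out = np.sign(t) * z
    out[np.isposinf(t)] = np.inf
    out[np.isneginf(t)] = -np.inf
    return out


def contrast_neg_minus_pos(fit: GLMFit, voxels: VoxelTable) -> list[ContrastResult]:
    """Per-voxel avoidance-minus-approach contrast:
    mean(angry, fearful, sad) betas minus the happy beta, with z from
    the OLS standard error."""
    cols = fit.design.columns
    missing = [l for l in NEGATIVE_LABELS + POSITIVE_LABELS if l not in cols]
    if missing:
        raise ValueError(f"conditions missing from design: {missing}")
    c = np.zeros(len(cols))
    for lbl in NEGATIVE_LABELS:
        c[cols.index(lbl)] = 1.0 / len(NEGATIVE_LABELS)
    c[cols.index(POSITIVE_LABELS[0])] = -1.0
    beta_neg = fit.betas[:, [cols.index(l) for l in NEGATIVE_LABELS]].mean(axis=1)
    beta_pos = fit.betas[:, cols.index(POSITIVE_LABELS[0])]
    con = fit.betas @ c
    var_c = float(c @ fit.xtx_inv @ c)
    se = np.sqrt(fit.sigma2 * var_c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, con / np.where(se > 0, se, 1.0), np.sign(con) * np.inf)
        t = np.where((se == 0) & (con == 0), 0.0, t)
    z = _t_to_z(t, fit.df)
    return [
        ContrastResult(
            voxel_id=voxels.voxel_ids[i],
            beta_neg=float(beta_neg[i]),
            beta_pos=float(beta_pos[i]),
            contrast=float(con[i]),
            z=float(z[i]),
            roi_label=voxels.roi_labels[i],
        )
        for i in range(voxels.n_voxels)
    ]


def extract_nds(
    contrasts: Sequence[ContrastResult],
    roi: str = "left",
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    subject_id: str = "",
) -> NDSResult:
    """Mean contrast over supra-threshold ROI voxels.

    ``roi`` selects the left or right VS/NAc or both ("bilateral").
    If no ROI voxel exceeds the threshold, the result is invalid
    (``n_voxels_used = 0``) and the subject is excluded downstream.
    """
    wanted = {
        "left": {"VS_NAc_left"},
        "right": {"VS_NAc_right"},
        "bilateral": {"VS_NAc_left", "VS_NAc_right"},
    }.get(roi)
    if wanted is None:
        raise ValueError(f"unknown roi {roi!r}; use left, right or bilateral")
    in_roi = [c for c in contrasts if c.roi_label in wanted]
    if not in_roi:
        raise ValueError(f"no voxels labeled for roi {roi!r}")
    supra = [c.contrast for c in in_roi if c.z > z_threshold]
    if not supra:
        return NDSResult(
            subject_id=subject_id,
            nds=float("nan"),
            n_voxels_used=0,
            threshold_z=z_threshold,
            hemisphere=roi,
        )
    return NDSResult(
        subject_id=subject_id,
        nds=float(np.mean(supra)),
        n_voxels_used=len(supra),
        threshold_z=z_threshold,
        hemisphere=roi,
    )


def subject_nds(
    voxels: VoxelTable,
    timeline: StimulusTimeline,
    roi: str = "left",
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    subject_id: str = "",
) -> NDSResult:
    """Full per-subject chain: design -> GLM -> contrast -> ROI sampling."""
    design = build_design_matrix(timeline, tr=voxels.tr, n_volumes=voxels.n_volumes)
    fit = fit_glm(voxels, design)
    contrasts = contrast_neg_minus_pos(fit, voxels)
    return extract_nds(contrasts, roi=roi, z_threshold=z_threshold, subject_id=subject_id)


# ---------------------------------------------------------------------------
# voxel-table interchange

def write_voxel_tsv(voxels: VoxelTable, path) -> None:
    df = pd.DataFrame(voxels.series, columns=[f"vol{i}" for i in range(voxels.n_volumes)])
    df.insert(0, "roi_label", voxels.roi_labels)
    df.insert(0, "voxel_id", voxels.voxel_ids)
    df.to_csv(path, sep="\t", index=False)


def read_voxel_tsv(path, tr: float = DEFAULT_TR) -> VoxelTable:
    df = pd.read_csv(path, sep="\t")
    vol_cols = [c for c in df.columns if c.startswith("vol")]
    return VoxelTable(
        voxel_ids=[str(v) for v in df["voxel_id"]],
        roi_labels=[str(v) for v in df["roi_label"]],
        series=df[vol_cols].to_numpy(dtype=float),
        tr=tr,
    )


def read_nifti_voxels(
    image_path,
    mask_path,
    tr: float = DEFAULT_TR,
    label_map: dict[int, str] | None = None,
) -> VoxelTable:
    """Read a 4D NIfTI series plus an integer-label ROI mask into the
    same table the TSV reader produces.  Voxels with label 0 are
    dropped; ``label_map`` maps the remaining integers to ROI names
    (default 1 -> left VS/NAc, 2 -> right, 3 -> unlabeled tissue)."""
    import nibabel as nib

    label_map = label_map or {1: "VS_NAc_left", 2: "VS_NAc_right", 3: "none"}
    img = np.asarray(nib.load(str(image_path)).dataobj, dtype=float)
    mask = np.asarray(nib.load(str(mask_path)).dataobj).astype(int)
    if img.ndim != 4:
        raise ValueError("expected a 4D image")
    if mask.shape != img.shape[:3]:
        raise ValueError("mask and image grids differ")
    idx = np.argwhere(mask > 0)
    series = np.stack([img[i, j, k, :] for i, j, k in idx])
    return VoxelTable(
        voxel_ids=[f"v_{i}_{j}_{k}" for i, j, k in idx],
        roi_labels=[label_map.get(int(mask[i, j, k]), "none") for i, j, k in idx],
        series=series,
        tr=tr,
    )
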