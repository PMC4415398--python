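"""Synthetic subjects with the statistical structure the analysis targets.

Each generated subject carries a ground-truth loss aversion lambda and a
ground-truth neural differential sensitivity (NDS), from which a
keypress session (counts over the affective-face picture set) and an
ROI voxel-table time series are simulated.  Cohort-level structure:

* ages uniform over a configurable range (default 20-55 years);
* lambda log-normal around 2 (the scale of published loss-aversion
  estimates), independent of age by default, with an inflated-tail
  mixture component producing the heavy outliers that exercise the
  2-standard-deviation exclusion rule;
* true NDS increasing linearly with age plus noise whose non-age
  component can be correlated with lambda (so the NDS~LA association
  is tunable while leaving the NDS~age slope unbiased).

All randomness flows from a single integer seed through per-subject
child seeds, so identical specs reproduce identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import fmri_nds, task_design
from .keypress_analysis import KeypressEvent, KeypressSession, build_session
from .task_design import Condition, StimulusTimeline

#: latent valence of each face category: approached categories positive,
#: avoided negative, neutral indifferent
CATEGORY_VALENCE = {"happy": 1.0, "angry": -1.0, "fearful": -1.0, "sad": -1.0, "neutral": 0.0}


@dataclass(frozen=True)
class Picture:
    picture_id: str
    category: str
    valence: float


@dataclass
class SubjectSpec:
    subject_id: str
    age: float
    true_lambda: float
    nds_true: float
    approach_gain: float = 10.0
    keypress_noise: float = 1.0

    def __post_init__(self):
        if self.true_lambda <= 0:
            raise ValueError("true_lambda must be positive")


@dataclass
class CohortSpec:
    """Study conditions for a simulated cohort (defaults mirror the
    17-subject, ages 20-55 design with lambda centred near 2)."""

    n_subjects: int = 17
    seed: int = 0
    age_range: tuple[float, float] = (20.0, 55.0)
    beta_age_nds: float = 0.02  # contrast units per year
    beta_age_la: float = 0.0  # per-year effect on log-lambda (0 = independent)
    noise_sd_nds: float = 0.25  # contrast units
    outlier_rate: float = 5.0 / 17.0  # inflated-tail mixture weight
    rho_nds_la: float = 0.64  # corr of NDS non-age component with lambda
    nds_intercept: float = 0.2  # contrast units at age 0
    lambda_log_mean: float = math.log(2.0)
    lambda_log_sd: float = 0.3
    outlier_log_sd: float = 1.5
    valence_jitter: float = 0.2  # per-picture Uniform(-j, +j)
    approach_gain: float = 10.0
    keypress_noise: float = 1.0
    n_presentations: int = 4  # offline task shows each picture this often
    n_voxels: int = 60
    voxel_noise_sd: float = 0.5
    tr: float = 2.5
    amp_pos: float = 1.0  # happy-condition BOLD amplitude

    def __post_init__(self):
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must satisfy low < high")
        if not 0 <= self.outlier_rate <= 1:
            raise ValueError("outlier_rate must be a probability")
        if not -1 <= self.rho_nds_la <= 1:
            raise ValueError("rho_nds_la must be in [-1, 1]")


@dataclass
class CohortData:
    spec: CohortSpec
    truth: pd.DataFrame  # subject_id, age, true_lambda, nds_true, tail_outlier
    sessions: list[KeypressSession]
    voxel_tables: list[fmri_nds.VoxelTable]
    timeline: StimulusTimeline
    pictures: list[Picture]


def make_picture_set(seed: int, jitter: float = 0.2, n_identities: int = 8) -> list[Picture]:
    """The affective-face picture set: ``n_identities`` faces per
    category, each with latent valence = category valence plus a
    per-picture uniform jitter (so within-category effort varies and
    the entropy axis is non-degenerate)."""
    rng = np.random.default_rng(seed)
    pics = []
    for cat in task_design.FACE_LABELS:
        base = CATEGORY_VALENCE[cat]
        for i in range(n_identities):
            v = base + (rng.uniform(-jitter, jitter) if jitter > 0 else 0.0)
            pics.append(Picture(picture_id=f"{cat}_f{i + 1}", category=cat, valence=v))
    return pics


def _draw_count(rng: np.random.Generator, mean: float, noise: float) -> int:
    """Keypress count with tunable dispersion: a Poisson draw shrunk or
    inflated around its mean.  noise = 1 is exact Poisson, noise = 0
    the deterministic (rounded-mean) limit, > 1 overdispersed."""
    if mean <= 0:
        return 0
    if noise == 1.0:
        return int(rng.poisson(mean))
    base = rng.poisson(mean)
    return max(0, int(round(mean + noise * (base - mean))))


def simulate_keypress_session(
    spec: SubjectSpec,
    pictures: Sequence[Picture],
    seed: int,
    n_presentations: int = 4,
    decision_window: float = 8.0,
) -> KeypressSession:
    """One subject's offline task: every picture shown
    ``n_presentations`` times in shuffled order; approach counts have
    mean ``gain * max(v, 0)`` and avoid counts mean
    ``gain * lambda * max(-v, 0)``, with the subject's dispersion."""
    if not pictures:
        raise ValueError("picture list must be non-empty")
    rng = np.random.default_rng(seed)
    order = []
    for _ in range(n_presentations):
        order.extend(rng.permutation(len(pictures)).tolist())
    events: list[KeypressEvent] = []
    trial_pictures: dict[int, tuple[str, str]] = {}
    for trial_index, pic_i in enumerate(order):
        pic = pictures[pic_i]
        trial_pictures[trial_index] = (pic.picture_id, pic.category)
        mean_app = spec.approach_gain * max(pic.valence, 0.0)
        mean_avd = spec.approach_gain * spec.true_lambda * max(-pic.valence, 0.0)
        n_app = _draw_count(rng, mean_app, spec.keypress_noise)
        n_avd = _draw_count(rng, mean_avd, spec.keypress_noise)
        for cls, n in (("approach", n_app), ("avoid", n_avd)):
            if n == 0:
                continue
            ts = np.sort(rng.uniform(0.0, decision_window, size=n))
            for t in ts:
                events.append(
                    KeypressEvent(
                        subject_id=spec.subject_id,
                        trial_index=trial_index,
                        picture_id=pic.picture_id,
                        category=pic.category,
                        key_class=cls,
                        timestamp=float(t),
                    )
                )
    return build_session(spec.subject_id, events, trial_pictures)


def simulate_voxel_table(
    spec: SubjectSpec,
    timeline: StimulusTimeline,
    n_voxels: int = 60,
    tr: float = 2.5,
    noise_sd: float = 0.5,
    seed: int = 0,
    amp_pos: float = 1.0,
    baseline: float = 100.0,
    drift_amp: float = 0.5,
) -> fmri_nds.VoxelTable:
    """ROI voxel series built from the same design-matrix model the
    analysis fits: responsive VS/NAc voxels respond to every face
    condition with (negative amplitude - positive amplitude) equal to
    the subject's true NDS; unlabeled voxels are pure noise.

    A third of the voxels are labeled left VS/NAc, a third right, the
    rest unlabeled null voxels.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    present = set(timeline.condition_labels())
    if not (present & set(task_design.NEGATIVE_LABELS) and present & set(task_design.POSITIVE_LABELS)):
        raise ValueError("timeline must include negative and positive face blocks")
    rng = np.random.default_rng(seed)
    design = fmri_nds.build_design_matrix(timeline, tr=tr)
    cols = design.columns
    n_vol = design.matrix.shape[0]

    amp_neg = amp_pos + spec.nds_true
    amplitudes = {
        "happy": amp_pos,
        "angry": amp_neg,
        "fearful": amp_neg,
        "sad": amp_neg,
        "neutral": amp_pos,
        "scrambled": 0.5 * amp_pos,
    }
    beta_resp = np.array(
        [amplitudes.get(c, 0.0) for c in cols[:-2]] + [baseline, drift_amp]
    )
    beta_null = np.zeros(len(cols))
    beta_null[-2] = baseline

    n_left = n_voxels // 3
    n_right = n_voxels // 3
    n_null = n_voxels - n_left - n_right
    labels = ["VS_NAc_left"] * n_left + ["VS_NAc_right"] * n_right + ["none"] * n_null
    series = np.empty((n_voxels, n_vol))
    for i, lbl in enumerate(labels):
        beta = beta_resp if lbl != "none" else beta_null
        clean = design.matrix @ beta
        noise = rng.normal(0.0, noise_sd, size=n_vol) if noise_sd > 0 else 0.0
        series[i] = clean + noise
    return fmri_nds.VoxelTable(
        voxel_ids=[f"{spec.subject_id}_v{i}" for i in range(n_voxels)],
        roi_labels=labels,
        series=series,
        tr=tr,
    )


def simulate_truth_table(spec: CohortSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Ages, ground-truth lambda and ground-truth NDS for a cohort
    (the lightweight core of :func:`simulate_cohort`)."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    lo, hi = spec.age_range
    ages = rng.uniform(lo, hi, size=spec.n_subjects)
    z = rng.standard_normal(spec.n_subjects)
    tail = rng.uniform(size=spec.n_subjects) < spec.outlier_rate
    log_sd = np.where(tail, spec.outlier_log_sd, spec.lambda_log_sd)
    log_lam = (
        spec.lambda_log_mean
        + log_sd * z
        + spec.beta_age_la * (ages - (lo + hi) / 2.0)
    )
    lam = np.exp(log_lam)

    # couple the non-age NDS component to lambda via the standardized
    # core log-normal, so corr(NDS, lambda) -> rho when beta_age_nds = 0
    mean_lam = math.exp(spec.lambda_log_mean + spec.lambda_log_sd**2 / 2)
    sd_lam = mean_lam * math.sqrt(math.expm1(spec.lambda_log_sd**2))
    z_lam = (np.exp(spec.lambda_log_mean + spec.lambda_log_sd * z) - mean_lam) / sd_lam
    w = rng.standard_normal(spec.n_subjects)
    rho = spec.rho_nds_la
    eps = spec.noise_sd_nds * (rho * z_lam + math.sqrt(max(0.0, 1 - rho**2)) * w)
    nds_true = spec.nds_intercept + spec.beta_age_nds * ages + eps
    return pd.DataFrame(
        {
            "subject_id": [f"sub{i + 1:02d}" for i in range(spec.n_subjects)],
            "age": ages,
            "true_lambda": lam,
            "nds_true": nds_true,
            "tail_outlier": tail,
        }
    )


def simulate_cohort(
    spec: CohortSpec,
    timeline: StimulusTimeline | None = None,
    with_voxels: bool = True,
) -> CohortData:
    """Full cohort: truth table plus per-subject keypress sessions and
    (optionally) voxel tables over a shared 25-block run timeline."""
    rng = np.random.default_rng(spec.seed)
    truth = simulate_truth_table(spec, rng)
    pictures = make_picture_set(
        int(rng.integers(2**31 - 1)), jitter=spec.valence_jitter
    )
    if timeline is None:
        seq = task_design.generate_counterbalanced_sequence(
            task_design.default_conditions(), 25, int(rng.integers(2**31 - 1))
        )
        timeline = task_design.build_timeline(seq, seed=int(rng.integers(2**31 - 1)))
    sessions = []
    voxel_tables = []
    for row in truth.itertuples():
        sub = SubjectSpec(
            subject_id=row.subject_id,
            age=float(row.age),
            true_lambda=float(row.true_lambda),
            nds_true=float(row.nds_true),
            approach_gain=spec.approach_gain,
            keypress_noise=spec.keypress_noise,
        )
        sessions.append(
            simulate_keypress_session(
                sub,
                pictures,
                seed=int(rng.integers(2**31 - 1)),
                n_presentations=spec.n_presentations,
            )
        )
        if with_voxels:
            voxel_tables.append(
                simulate_voxel_table(
                    sub,
                    timeline,
                    n_voxels=spec.n_voxels,
                    tr=spec.tr,
                    noise_sd=spec.voxel_noise_sd,
                    seed=int(rng.integers(2**31 - 1)),
                    amp_pos=spec.amp_pos,
                )
            )
    return CohortData(
        spec=spec,
        truth=truth,
        sessions=sessions,
        voxel_tables=voxel_tables,
        timeline=timeline,
        pictures=pictures,
    )
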