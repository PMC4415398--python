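"""Three-way group inference: NDS~LA, NDS~age, LA~age, plus the
end-to-end pipeline driver.

The loss-aversion/age and NDS/age tests form a family of two tests
against age, so each is held to the Bonferroni-corrected threshold
alpha = 0.05/2 = 0.025; the single NDS~LA correlation is tested at
alpha = 0.05.  Lambda outliers (the 2-SD cohort rule) are excluded from
every lambda-involving statistic; NDS outliers are excluded from the
NDS~LA correlation only, and subjects without valid imaging from every
NDS-involving statistic.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import fmri_nds, synthetic_cohort, task_design, valuation
from .keypress_analysis import category_valuation
from .valuation import flag_outliers, subject_loss_aversion

ALPHA_CORRELATION = 0.05
ALPHA_AGE_FAMILY = 0.05 / 2  # two tests against age


class DegenerateDataError(ValueError):
    """An association cannot be computed (constant predictor/response
    or too few usable subjects)."""


@dataclass
class AssociationResult:
    name: str  # "nds_la" | "nds_age" | "la_age"
    estimate: float  # Pearson r, or regression slope
    test_statistic: float  # t (correlation) or F (regression)
    p: float
    n_used: int
    alpha: float
    excluded: dict[str, str] = field(default_factory=dict)  # subject_id -> reason

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


def build_cohort_table(
    truth: pd.DataFrame,
    la_results: Sequence[valuation.LossAversionResult],
    nds_results: Sequence[fmri_nds.NDSResult],
) -> pd.DataFrame:
    """One row per subject with lambda, NDS and exclusion flags.

    ``la_outlier`` applies the 2-SD cohort rule to lambda,
    ``nds_outlier`` the same rule to NDS over valid-imaging subjects,
    and ``valid_imaging`` records whether any ROI voxel survived
    thresholding.
    """
    lam = {r.subject_id: r for r in la_results}
    nds = {r.subject_id: r for r in nds_results}
    rows = []
    for t in truth.itertuples():
        la = lam[t.subject_id]
        nd = nds.get(t.subject_id)
        rows.append(
            {
                "subject_id": t.subject_id,
                "age": float(t.age),
                "lam": la.lam,
                "s_minus": la.s_minus,
                "s_plus": la.s_plus,
                "nds": nd.nds if nd is not None else np.nan,
                "valid_imaging": bool(nd.valid) if nd is not None else False,
            }
        )
    df = pd.DataFrame(rows)
    df["la_outlier"] = flag_outliers(df["lam"].to_numpy())
    nds_flags = np.zeros(len(df), dtype=bool)
    valid = df["valid_imaging"].to_numpy()
    if valid.sum() >= 3:
        nds_flags[valid] = flag_outliers(df.loc[valid, "nds"].to_numpy())
    df["nds_outlier"] = nds_flags
    return df


def correlate_nds_la(table: pd.DataFrame, alpha: float = ALPHA_CORRELATION) -> AssociationResult:
    """Pearson correlation of NDS with lambda over the usable subset
    (no lambda outliers, no NDS outliers, valid imaging)."""
    excluded: dict[str, str] = {}
    mask = np.ones(len(table), dtype=bool)
    for i, row in enumerate(table.itertuples()):
        if not row.valid_imaging:
            excluded[row.subject_id] = "invalid imaging"
        elif row.la_outlier:
            excluded[row.subject_id] = "lambda outlier"
        elif row.nds_outlier:
            excluded[row.subject_id] = "nds outlier"
        else:
            continue
        mask[i] = False
    sub = table[mask]
    if len(sub) < 3:
        raise DegenerateDataError(f"only {len(sub)} usable subjects for nds_la")
    x = sub["lam"].to_numpy()
    y = sub["nds"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("constant lambda or NDS: correlation undefined")
    r, p = stats.pearsonr(x, y)
    n = len(sub)
    with np.errstate(divide="ignore"):
        t_stat = r * np.sqrt((n - 2) / max(1e-300, 1 - r**2))
    return AssociationResult(
        name="nds_la",
        estimate=float(r),
        test_statistic=float(t_stat),
        p=float(p),
        n_used=n,
        alpha=alpha,
        excluded=excluded,
    )


def regress_on_age(
    table: pd.DataFrame,
    measure: str,
    alpha: float = ALPHA_AGE_FAMILY,
    exclude_nds_outliers: bool = False,
) -> AssociationResult:
    """Simple linear regression of lambda or NDS on age.

    Lambda outliers are excluded for measure="lam"; invalid-imaging
    subjects (and, optionally, NDS outliers) for measure="nds".
    Reports the slope, the regression F statistic and its two-sided p.
    """
    if measure not in ("nds", "lam"):
        raise ValueError("measure must be 'nds' or 'lam'")
    excluded: dict[str, str] = {}
    mask = np.ones(len(table), dtype=bool)
    for i, row in enumerate(table.itertuples()):
        if measure == "lam":
            if row.la_outlier:
                excluded[row.subject_id] = "lambda outlier"
                mask[i] = False
        else:
            if not row.valid_imaging:
                excluded[row.subject_id] = "invalid imaging"
                mask[i] = False
            elif exclude_nds_outliers and row.nds_outlier:
                excluded[row.subject_id] = "nds outlier"
                mask[i] = False
    sub = table[mask]
    if len(sub) < 3:
        raise DegenerateDataError(f"only {len(sub)} usable subjects for {measure}_age")
    age = sub["age"].to_numpy()
    if np.ptp(age) == 0:
        raise DegenerateDataError("constant age vector")
    y = sub[measure].to_numpy()
    model = sm.OLS(y, sm.add_constant(age)).fit()
    return AssociationResult(
        name=f"{'nds' if measure == 'nds' else 'la'}_age",
        estimate=float(model.params[1]),
        test_statistic=float(model.fvalue),
        p=float(model.f_pvalue),
        n_used=len(sub),
        alpha=alpha,
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# pipeline orchestration

@dataclass
class PipelineConfig:
    seed: int = 1
    cohort: synthetic_cohort.CohortSpec | None = None
    form: str = "power"
    fraction: float = 0.10
    measure: str = "keypresses"
    roi: str = "left"
    z_threshold: float = 1.96
    exclude_nds_outliers_for_age: bool = False
    outdir: str | Path | None = None
    make_plots: bool = True

    def resolved_cohort(self) -> synthetic_cohort.CohortSpec:
        if self.cohort is not None:
            return self.cohort
        return synthetic_cohort.CohortSpec(seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort_raw = raw.pop("cohort", None)
        cfg = cls(**raw)
        if cohort_raw is not None:
            cohort_raw.setdefault("seed", cfg.seed)
            if "age_range" in cohort_raw:
                cohort_raw["age_range"] = tuple(cohort_raw["age_range"])
            cfg.cohort = synthetic_cohort.CohortSpec(**cohort_raw)
        return cfg


@dataclass
class PipelineReport:
    config: PipelineConfig
    cohort: pd.DataFrame
    associations: dict[str, AssociationResult]
    data: synthetic_cohort.CohortData

    def associations_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.associations.values():
            rows.append(
                {
                    "name": a.name,
                    "estimate": a.estimate,
                    "test_statistic": a.test_statistic,
                    "p": a.p,
                    "n_used": a.n_used,
                    "alpha": a.alpha,
                    "significant": a.significant,
                    "excluded": ";".join(f"{k}:{v}" for k, v in sorted(a.excluded.items())),
                }
            )
        return pd.DataFrame(rows)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, subject_ids, cause: Exception):
        super().__init__(f"stage {stage!r} failed for subjects {subject_ids}: {cause}")
        self.stage = stage
        self.subject_ids = subject_ids


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """behavior -> LA -> NDS -> group inference over a simulated cohort,
    with optional CSV/plot output.  Deterministic for a fixed config."""
    spec = config.resolved_cohort()
    data = synthetic_cohort.simulate_cohort(spec)

    la_results = []
    for sess in data.sessions:
        try:
            vals = category_valuation(sess, measure=config.measure)
            la_results.append(
                subject_loss_aversion(
                    vals, form=config.form, fraction=config.fraction, subject_id=sess.subject_id
                )
            )
        except Exception as exc:  # pragma: no cover - surfaced with context
            raise PipelineStageError("behavior/la", [sess.subject_id], exc) from exc

    nds_results = []
    for vox in data.voxel_tables:
        sid = vox.voxel_ids[0].rsplit("_v", 1)[0]
        try:
            nds_results.append(
                fmri_nds.subject_nds(
                    vox,
                    data.timeline,
                    roi=config.roi,
                    z_threshold=config.z_threshold,
                    subject_id=sid,
                )
            )
        except Exception as exc:  # pragma: no cover
            raise PipelineStageError("nds", [sid], exc) from exc

    table = build_cohort_table(data.truth, la_results, nds_results)
    associations = {
        "nds_la": correlate_nds_la(table),
        "nds_age": regress_on_age(
            table, "nds", exclude_nds_outliers=config.exclude_nds_outliers_for_age
        ),
        "la_age": regress_on_age(table, "lam"),
    }
    report = PipelineReport(config=config, cohort=table, associations=associations, data=data)
    if config.outdir is not None:
        _write_outputs(report, Path(config.outdir))
    return report


def _write_outputs(report: PipelineReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    report.cohort.to_csv(outdir / "cohort.csv", index=False, float_format="%.6f")
    report.associations_frame().to_csv(
        outdir / "associations.csv", index=False, float_format="%.6g"
    )
    log = {
        "seed": report.config.seed,
        "cohort_spec": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(report.config.resolved_cohort()).items()
        },
        "form": report.config.form,
        "fraction": report.config.fraction,
        "roi": report.config.roi,
        "z_threshold": report.config.z_threshold,
        "versions": _versions(),
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    if report.config.make_plots:
        _write_plots(report, outdir)


def _versions() -> dict[str, str]:
    import scipy
    import statsmodels

    import lapref

    return {
        "lapref": getattr(lapref, "__version__", "0"),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }


def _write_plots(report: PipelineReport, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # value graph of the first subject
    sess = report.data.sessions[0]
    vals = category_valuation(sess, measure=report.config.measure)
    fig, ax = plt.subplots(figsize=(5, 4))
    for v in vals:
        color = {"approach": "tab:green", "avoidance": "tab:red"}.get(v.limb, "tab:gray")
        ax.scatter(v.H, v.K, color=color)
        ax.annotate(v.category, (v.H, v.K), fontsize=8)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("H (bits)")
    ax.set_ylabel("K (mean net keypresses)")
    ax.set_title(f"value graph: {sess.subject_id}")
    fig.tight_layout()
    fig.savefig(outdir / "value_graph.png", dpi=100)
    plt.close(fig)

    # association scatters
    tbl = report.cohort
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.6))
    panels = [
        ("lam", "nds", "LA (|s-/s+|)", "NDS", "nds_la"),
        ("age", "nds", "age (years)", "NDS", "nds_age"),
        ("age", "lam", "age (years)", "LA (|s-/s+|)", "la_age"),
    ]
    for ax, (xc, yc, xl, yl, name) in zip(axes, panels):
        usable = tbl[tbl["valid_imaging"] & ~tbl["la_outlier"]]
        ax.scatter(usable[xc], usable[yc], s=18)
        a = report.associations[name]
        ax.set_xlabel(xl)
        ax.set_ylabel(yl)
        ax.set_title(f"{name}: p={a.p:.3g}{' *' if a.significant else ''}", fontsize=9)
    fig.tight_layout()
    fig.savefig(outdir / "associations.png", dpi=100)
    plt.close(fig)
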