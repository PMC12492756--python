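"""Orchestration of the full study analogue.

From one configuration this runs: cohort acquisition (synthetic or CSV),
outcome scoring, descriptives, the bivariate screen of all five HRQoL
dimensions against broad activity categories, and the PLS multivariate
pattern analysis per stratum — the total sample (adjusted for age, sex and
waist circumference), girls and boys (age, waist), and the four sex-by-
weight-status strata (age) — on the 23-band scheme, plus a 4-broad-category
model on the total sample. Results serialize deterministically to JSON and
CSV.

Significance in the per-band tables means "95% CI excludes zero"; no
multiplicity correction is applied across bands.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from . import __version__
from .adjustment import build_analysis_matrix
from .bands import BROAD_CATEGORIES
from .kidscreen import cronbach_alpha, floor_ceiling, score_cohort
from .pls_mvpa import (
    MVCorrResult, explained_variance, fit_pls, mccv_select,
    mv_correlation_ci, target_projection,
)
from .synthetic_data import CohortConfig, band_columns, broad_columns, generate_cohort

logger = logging.getLogger(__name__)

DIMENSION_COLS = ["pwb_t", "psych_t", "autonomy_t", "social_t", "school_t"]
ITEM_COLS = [f"item{j}" for j in range(1, 6)]


@dataclass(frozen=True)
class StratumSpec:
    """A subgroup and the covariates its model adjusts for.

    Covariates never include a variable the filter conditions on: sex-
    stratified models adjust for age and waist only, sex-by-weight strata
    for age only.
    """

    label: str
    sex: str | None = None          # "boy" | "girl" | None
    ow: int | None = None           # 1 | 0 | None
    covariates: tuple[str, ...] = ("age", "sex_num", "waist_cm")

    def __post_init__(self) -> None:
        if self.sex is not None and "sex_num" in self.covariates:
            raise ValueError("sex-stratified model must not adjust for sex")
        if self.ow is not None and "waist_cm" in self.covariates:
            raise ValueError("weight-status strata must not adjust for waist")

    def mask(self, df: pd.DataFrame) -> np.ndarray:
        m = np.ones(len(df), dtype=bool)
        if self.sex is not None:
            m &= (df["sex"] == self.sex).to_numpy()
        if self.ow is not None:
            m &= (df["ow_ob"] == self.ow).to_numpy()
        return m


DEFAULT_STRATA: tuple[StratumSpec, ...] = (
    StratumSpec("total", covariates=("age", "sex_num", "waist_cm")),
    StratumSpec("girls", sex="girl", covariates=("age", "waist_cm")),
    StratumSpec("boys", sex="boy", covariates=("age", "waist_cm")),
    StratumSpec("boys_normal", sex="boy", ow=0, covariates=("age",)),
    StratumSpec("boys_ow_ob", sex="boy", ow=1, covariates=("age",)),
    StratumSpec("girls_normal", sex="girl", ow=0, covariates=("age",)),
    StratumSpec("girls_ow_ob", sex="girl", ow=1, covariates=("age",)),
)


@dataclass
class AnalysisConfig:
    """Knobs of the statistical analysis (not of the data generator)."""

    reps: int = 100
    cal_frac: float = 0.5
    a_max: int = 10
    min_stratum_n: int = 50
    ci_level: float = 0.95
    outcome: str = "pwb_t"          # "pwb_t" or "scored_items"
    seed: int = 0


@dataclass
class StudyReport:
    descriptives: dict
    screen: dict
    psychometrics: dict
    strata: list
    counts: dict
    seed: int
    version: str = __version__

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2, sort_keys=True, allow_nan=True)
        if path is not None:
            Path(path).write_text(s + "\n")
        return s


def bivariate_screen(df: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations (with p-values) of each HRQoL dimension T-score
    against broad-category minutes and total cpm."""
    activity = broad_columns(df) + ["total_cpm"]
    rows = []
    for dim in DIMENSION_COLS:
        for act in activity:
            x = df[dim].to_numpy(float)
            z = df[act].to_numpy(float)
            if np.std(x) == 0 or np.std(z) == 0:
                rows.append({"dimension": dim, "activity": act,
                             "r": float("nan"), "p": float("nan")})
                continue
            r, p = pearsonr(x, z)
            rows.append({"dimension": dim, "activity": act,
                         "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


def descriptives(df: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD per analysis variable, overall and by sex."""
    cols = (["age", "waist_cm"] + DIMENSION_COLS
            + broad_columns(df) + band_columns(df) + ["total_cpm"])
    out = []
    groups = {"total": df, "boys": df[df["sex"] == "boy"],
              "girls": df[df["sex"] == "girl"]}
    for c in cols:
        row = {"variable": c}
        for g, sub in groups.items():
            row[f"{g}_mean"] = float(sub[c].mean())
            row[f"{g}_sd"] = float(sub[c].std(ddof=1))
        out.append(row)
    return pd.DataFrame(out)


def run_stratum(
    df: pd.DataFrame,
    spec: StratumSpec,
    x_cols: list[str],
    config: AnalysisConfig,
    y_col: str = "y_outcome",
    seed=None,
) -> MVCorrResult:
    """Full per-stratum analysis: filter, adjust, standardize, MCCV-select,
    fit, target-project, CI, explained variance."""
    sub = df[spec.mask(df)]
    needed = [y_col] + x_cols + list(spec.covariates)
    sub = sub.dropna(subset=needed)
    n = len(sub)
    if n < config.min_stratum_n:
        return MVCorrResult(stratum=spec.label, status="no_model", n=n,
                            selected_A=0, reason="insufficient n")
    am = build_analysis_matrix(sub, x_cols, y_col, list(spec.covariates),
                               stratum=spec.label)
    mccv = mccv_select(am.X, am.y, reps=config.reps, cal_frac=config.cal_frac,
                       A_max=config.a_max, seed=seed)
    if mccv.selected_A == 0:
        return MVCorrResult(stratum=spec.label, status="no_model", n=n,
                            selected_A=0,
                            reason="minimum median RMSEP at zero components")
    model = fit_pls(am.X, am.y, mccv.selected_A)
    _, r = target_projection(model, am.X)
    ci_low, ci_high, _ = mv_correlation_ci(
        am.X, am.y, model.A, mccv.splits, level=config.ci_level, b_full=model.b)
    r2_cal, r2_val = explained_variance(model, am.X, am.y, mccv)
    return MVCorrResult(
        stratum=spec.label, status="model", n=n, selected_A=model.A,
        band_names=am.x_names, r=r, ci_low=ci_low, ci_high=ci_high,
        significant=(ci_low > 0) | (ci_high < 0),
        r2_cal=r2_cal, r2_val=r2_val,
    )


def _result_frame(res: MVCorrResult) -> pd.DataFrame:
    return pd.DataFrame({
        "band": res.band_names,
        "r": res.r,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "significant": res.significant,
    })


def prepare_analysis_table(df: pd.DataFrame, outcome: str = "pwb_t") -> tuple[pd.DataFrame, dict]:
    """Complete-case filtering, sex encoding and outcome selection.

    Returns the analysis table plus the exclusion cascade
    (cohort -> valid accelerometry -> complete cases).
    """
    n0 = len(df)
    df = df.copy()
    if "child_valid" in df.columns:
        df = df[df["child_valid"].astype(bool)]
    n_acc = len(df)
    df["sex_num"] = (df["sex"] == "boy").astype(float)
    if outcome == "scored_items":
        scored = score_cohort(df[["child_id"] + ITEM_COLS], ITEM_COLS)
        df = df.merge(scored[["child_id", "t_score"]], on="child_id")
        df["y_outcome"] = df["t_score"]
    else:
        df["y_outcome"] = df[outcome]
    needed = (["y_outcome", "age", "waist_cm", "sex_num", "ow_ob"]
              + band_columns(df))
    df = df.dropna(subset=needed)
    counts = {
        "cohort": n0,
        "excluded_accelerometry": n0 - n_acc,
        "excluded_incomplete": n_acc - len(df),
        "analyzed": len(df),
    }
    return df, counts


def run_full_analysis(
    cohort: CohortConfig | pd.DataFrame | str | Path,
    analysis: AnalysisConfig | None = None,
    outdir: str | Path | None = None,
    strata: tuple[StratumSpec, ...] = DEFAULT_STRATA,
) -> StudyReport:
    """Run the complete study analogue and (optionally) write artifacts.

    ``cohort`` may be a generator configuration, an in-memory cohort table or
    a cohort CSV path. Artifacts written to ``outdir``: report.json,
    descriptives/screen CSVs, one per-band CSV per modelled stratum, and a
    run log; all byte-deterministic for a fixed seed.
    """
    analysis = analysis or AnalysisConfig()
    if isinstance(cohort, CohortConfig):
        df = generate_cohort(cohort)
    elif isinstance(cohort, (str, Path)):
        df = pd.read_csv(cohort)
    else:
        df = cohort.copy()

    df, counts = prepare_analysis_table(df, analysis.outcome)
    desc = descriptives(df)
    screen = bivariate_screen(df)

    items = df[ITEM_COLS].to_numpy(float)
    raw = items.sum(axis=1)
    floor_pct, ceil_pct = floor_ceiling(raw, 5, 25)
    psych = {
        "cronbach_alpha": float(cronbach_alpha(items)),
        "floor_pct": floor_pct,
        "ceiling_pct": ceil_pct,
    }

    x23 = band_columns(df)
    results = []
    root = analysis.seed
    for i, spec in enumerate(strata):
        seed = int(np.random.SeedSequence(entropy=root, spawn_key=(i,))
                   .generate_state(1)[0] % (2 ** 31))
        res = run_stratum(df, spec, x23, analysis, seed=seed)
        logger.info("stratum %s: %s (n=%d, A=%d)", spec.label, res.status,
                    res.n, res.selected_A)
        results.append(res)
    # 4-broad-category comparison model on the total sample
    broad_seed = int(np.random.SeedSequence(entropy=root, spawn_key=(len(strata),))
                     .generate_state(1)[0] % (2 ** 31))
    broad_spec = StratumSpec("total_4broad", covariates=("age", "sex_num", "waist_cm"))
    results.append(run_stratum(df, broad_spec, broad_columns(df), analysis,
                               seed=broad_seed))

    report = StudyReport(
        descriptives={r["variable"]: {k: v for k, v in r.items() if k != "variable"}
                      for r in desc.to_dict("records")},
        screen={f"{r['dimension']}|{r['activity']}": {"r": r["r"], "p": r["p"]}
                for r in screen.to_dict("records")},
        psychometrics=psych,
        strata=[r.to_dict() for r in results],
        counts=counts,
        seed=analysis.seed,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_json(outdir / "report.json")
        desc.to_csv(outdir / "descriptives.csv", index=False, float_format="%.6f")
        screen.to_csv(outdir / "bivariate_screen.csv", index=False, float_format="%.6g")
        for res in results:
            if res.status == "model":
                _result_frame(res).to_csv(
                    outdir / f"bands_{res.stratum}.csv", index=False,
                    float_format="%.6f")
        log_lines = [f"actipls {__version__}", f"seed={analysis.seed}"]
        log_lines += [f"{k}={v}" for k, v in counts.items()]
        log_lines += [f"stratum {r.stratum}: status={r.status} n={r.n} A={r.selected_A}"
                      for r in results]
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return report
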