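"""Statistical contracts on the rhythmic markers.

Four families of analyses:

* within/between association of cycle entropy H with the cycle symptom score
  SC — a gamma log-link mixed model with a participant random intercept
  (random slope kept when a likelihood-ratio test favors it), estimation
  delegated to R's lme4/glmmTMB;
* associations of each marker (mean H, MH, the nine MEHTs) with
  interviewer-rated symptom scores in the schizophrenia group — gamma
  log-link GLMs, one model per (outcome, marker), covariate-adjusted;
* group differences in each marker — linear models with control (or bipolar)
  as the reference group, covariate-adjusted;
* attrition effect sizes comparing included and excluded participants —
  Cramér's V for categorical variables, |Spearman rho| for continuous ones.

P-values are corrected with the Benjamini-Hochberg step-up procedure within
each results family; significance is p < .05 with the 95% CI excluding the
null.
"""
from __future__ import annotations

import json
import math
import subprocess
import tempfile
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .markov import STATE_LABELS

#: Marker columns of the per-participant RDM table, in reporting order.
MARKER_COLUMNS = ("mean_H", "MH") + tuple(f"MEHT_{s}" for s in STATE_LABELS)

#: Covariates of the adjusted models.
COVARIATE_COLUMNS = (
    "site",
    "age",
    "gender",
    "ethnoracial",
    "education",
    "mean_self_symptoms",
)

_COVARIATE_RHS = (
    "C(site) + age + C(gender) + C(ethnoracial) + C(education)"
    " + mean_self_symptoms"
)


class ModelSpecificationError(ValueError):
    """Raised when the data cannot support the requested model."""


@dataclass
class RegressionResult:
    """One fitted model's reportable estimate.

    ``estimate`` lives on the model's link scale; for log-link models
    ``mean_ratio`` exponentiates it (with its CI) onto the reported scale.
    """

    outcome: str
    predictor: str
    estimate: float
    conf_low: float
    conf_high: float
    p_value: float
    n: int
    scale: str = "identity"  # "identity" or "log"
    family: str = ""
    p_adjusted: float | None = None

    @property
    def mean_ratio(self) -> float | None:
        return math.exp(self.estimate) if self.scale == "log" else None

    @property
    def ratio_ci(self) -> tuple[float, float] | None:
        """95% CI of the mean ratio (log-link models only)."""
        if self.scale != "log":
            return None
        return math.exp(self.conf_low), math.exp(self.conf_high)

    @property
    def significant(self) -> bool:
        if self.p_adjusted is None:
            return False
        return self.p_adjusted < 0.05 and not (
            self.conf_low <= 0.0 <= self.conf_high
        )


def results_to_frame(results: Iterable[RegressionResult]) -> pd.DataFrame:
    """Tidy one-row-per-model table, forest-plot ready."""
    rows = []
    for r in results:
        rows.append(
            {
                "outcome": r.outcome,
                "predictor": r.predictor,
                "estimate": r.estimate,
                "conf_low": r.conf_low,
                "conf_high": r.conf_high,
                "mean_ratio": r.mean_ratio,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "n": r.n,
                "family": r.family,
                "significant": r.significant,
            }
        )
    return pd.DataFrame(rows)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Order-invariant and idempotent; adjusted values are >= the raw ones.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _apply_fdr(results: list[RegressionResult]) -> list[RegressionResult]:
    adj = bh_fdr([r.p_value for r in results])
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)
    return results


def _check_design_rank(model) -> None:
    exog = model.exog
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise ModelSpecificationError(
            f"design matrix is rank deficient "
            f"({exog.shape[0]} rows, {exog.shape[1]} columns)"
        )


def _dedup(covariates: pd.DataFrame, base: pd.DataFrame) -> pd.DataFrame:
    """Drop covariate columns already present in the base table (except the
    join key) so the merge never suffixes column names."""
    drop = [
        c for c in covariates.columns
        if c != "participant_id" and c in base.columns
    ]
    return covariates.drop(columns=drop)


def _require_columns(df: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ModelSpecificationError(f"{what} missing columns: {missing}")


def _fit_single(
    df: pd.DataFrame,
    outcome: str,
    marker: str,
    adjusted: bool,
    family: str,
    gamma: bool,
) -> RegressionResult:
    rhs = f"Q('{marker}')"
    if adjusted:
        rhs += " + " + _COVARIATE_RHS
    formula = f"Q('{outcome}') ~ {rhs}"
    if gamma:
        if (df[outcome] <= 0).any():
            raise ModelSpecificationError(
                f"gamma-family outcome {outcome!r} must be strictly positive"
            )
        model = smf.glm(
            formula, data=df, family=sm.families.Gamma(sm.families.links.Log())
        )
    else:
        model = smf.ols(formula, data=df)
    _check_design_rank(model)
    if df[marker].nunique() < 2:
        raise ModelSpecificationError(f"predictor {marker!r} is constant")
    fit = model.fit()
    term = f"Q('{marker}')"
    ci = fit.conf_int().loc[term]
    return RegressionResult(
        outcome=outcome,
        predictor=marker,
        estimate=float(fit.params[term]),
        conf_low=float(ci[0]),
        conf_high=float(ci[1]),
        p_value=float(fit.pvalues[term]),
        n=int(fit.nobs),
        scale="log" if gamma else "identity",
        family=family,
    )


def fit_rdm_symptom_models(
    rdm_table: pd.DataFrame,
    interviewer_scores: pd.DataFrame,
    covariates: pd.DataFrame,
    outcomes: Sequence[str] = (
        "positive_symptoms",
        "emotional_experience",
        "emotional_expression",
    ),
    markers: Sequence[str] = MARKER_COLUMNS,
    group: str | None = "schizophrenia",
) -> list[RegressionResult]:
    """Marker-by-marker gamma GLMs of interviewer-rated symptom scores.

    One model per (outcome, marker) pair, each adjusted for site, age,
    gender, ethnoracial group, educational attainment, and the participant's
    mean self-reported symptoms; BH-FDR is applied across the whole family
    of models.
    """
    _require_columns(rdm_table, ("participant_id",) + tuple(markers), "RDM table")
    _require_columns(covariates, COVARIATE_COLUMNS[:-1] + ("participant_id",), "covariate table")
    _require_columns(interviewer_scores, ("participant_id",) + tuple(outcomes), "score table")
    df = rdm_table.merge(interviewer_scores, on="participant_id").merge(
        _dedup(covariates, rdm_table), on="participant_id"
    )
    if group is not None:
        df = df[df["group"] == group]
    if "mean_self_symptoms" not in df.columns:
        raise ModelSpecificationError(
            "covariate column 'mean_self_symptoms' is required; derive it "
            "from the cycle table (person mean SC)"
        )
    results = [
        _fit_single(df, outcome, marker, adjusted=True,
                    family="rdm_symptom_associations", gamma=True)
        for outcome in outcomes
        for marker in markers
    ]
    return _apply_fdr(results)


def fit_group_differences(
    rdm_table: pd.DataFrame,
    covariates: pd.DataFrame,
    markers: Sequence[str] = MARKER_COLUMNS,
    reference: str = "control",
    second_reference: str = "bipolar",
    adjusted: bool = True,
) -> list[RegressionResult]:
    """Linear models of each marker on diagnostic group, per contrast.

    Contrasts mirror the reporting layout: every non-reference group versus
    control (one model per marker with control as reference level), plus
    schizophrenia versus bipolar disorder (bipolar as reference, controls
    excluded).  BH-FDR is applied within each contrast's family of markers.
    """
    _require_columns(rdm_table, ("participant_id", "group") + tuple(markers), "RDM table")
    df = rdm_table.merge(_dedup(covariates, rdm_table), on="participant_id")
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise ModelSpecificationError("group contrasts need >= 2 groups")

    def _contrast_models(sub: pd.DataFrame, ref: str) -> dict[str, list[RegressionResult]]:
        out: dict[str, list[RegressionResult]] = {}
        others = [g for g in sorted(sub["group"].unique()) if g != ref]
        for marker in markers:
            rhs = f"C(group, Treatment('{ref}'))"
            if adjusted:
                rhs += " + " + _COVARIATE_RHS
            model = smf.ols(f"Q('{marker}') ~ {rhs}", data=sub)
            _check_design_rank(model)
            fit = model.fit()
            for g in others:
                term = f"C(group, Treatment('{ref}'))[T.{g}]"
                ci = fit.conf_int().loc[term]
                out.setdefault(f"{g}_vs_{ref}", []).append(
                    RegressionResult(
                        outcome=marker,
                        predictor=f"{g}_vs_{ref}",
                        estimate=float(fit.params[term]),
                        conf_low=float(ci[0]),
                        conf_high=float(ci[1]),
                        p_value=float(fit.pvalues[term]),
                        n=int(fit.nobs),
                        scale="identity",
                        family=f"group_differences:{g}_vs_{ref}",
                    )
                )
        return out

    results: list[RegressionResult] = []
    if reference in groups:
        for fam in _contrast_models(df, reference).values():
            results.extend(_apply_fdr(fam))
    clinical = [g for g in groups if g != reference]
    if second_reference in clinical and len(clinical) >= 2:
        sub = df[df["group"] != reference]
        for fam in _contrast_models(sub, second_reference).values():
            results.extend(_apply_fdr(fam))
    if not results:
        raise ModelSpecificationError(
            f"no contrast could be formed from groups {groups}"
        )
    return results


# ---------------------------------------------------------------------------
# within/between gamma mixed model (estimation delegated to R)


def _r_script_path() -> Path:
    with resources.as_file(
        resources.files("rhythmdm.data").joinpath("wb_glmm.R")
    ) as p:
        return Path(p)


def fit_within_between_model(
    decomposed: pd.DataFrame, timeout: int = 600
) -> tuple[RegressionResult, RegressionResult, dict]:
    """Gamma log-link mixed model of SC on person-mean and centered H.

    ``decomposed`` needs columns participant_id, SC, person_mean_H,
    centered_H (one row per valid cycle of each included participant).
    Returns the between-person and within-person results (log scale, so
    ``mean_ratio`` is the reported quantity) plus a metadata dict with the
    random-slope LRT decision.

    The model contract — gamma family, log link, participant random
    intercept, ML with Laplace approximation, random slope retained when the
    LRT p < .05 — is estimated by lme4/glmmTMB through Rscript.
    """
    _require_columns(
        decomposed,
        ("participant_id", "SC", "person_mean_H", "centered_H"),
        "decomposed cycle table",
    )
    if (decomposed["SC"] <= 0).any():
        raise ModelSpecificationError(
            "gamma-family outcome SC must be strictly positive"
        )
    if decomposed["centered_H"].abs().max() < 1e-12:
        raise ModelSpecificationError(
            "centered_H is degenerate (H constant within every participant)"
        )
    with tempfile.TemporaryDirectory() as td:
        infile = Path(td) / "wb.csv"
        outfile = Path(td) / "wb.json"
        cols = ["participant_id", "SC", "person_mean_H", "centered_H"]
        decomposed[cols].to_csv(infile, index=False)
        cmd = ["Rscript", "--vanilla", str(_r_script_path()), str(infile), str(outfile)]
        proc = subprocess.run(
            cmd, capture_output=True, text=True, timeout=timeout
        )
        if proc.returncode != 0 or not outfile.exists():
            raise RuntimeError(
                f"mixed-model estimation failed:\n{proc.stderr[-2000:]}"
            )
        payload = json.loads(outfile.read_text())
    n = int(payload["n_obs"])
    out = []
    for term in ("person_mean_H", "centered_H"):
        t = payload["terms"][term]
        out.append(
            RegressionResult(
                outcome="SC",
                predictor=term,
                estimate=float(t["estimate"]),
                conf_low=float(t["conf_low"]),
                conf_high=float(t["conf_high"]),
                p_value=float(t["p_value"]),
                n=n,
                scale="log",
                family="within_between_glmm",
            )
        )
    meta = {
        "n_participants": int(payload["n_participants"]),
        "random_slope": bool(payload["random_slope"]),
        "lrt_p": payload.get("lrt_p"),
        "backend": payload.get("backend"),
    }
    return out[0], out[1], meta


# ---------------------------------------------------------------------------
# attrition effect sizes


def cramers_v(x: Sequence, y: Sequence) -> float:
    """Cramér's V between two categorical variables (0..1)."""
    table = pd.crosstab(pd.Series(x), pd.Series(y))
    if table.shape[0] < 2 or table.shape[1] < 2:
        return float("nan")
    chi2 = scipy.stats.chi2_contingency(table, correction=False)[0]
    n = table.to_numpy().sum()
    k = min(table.shape) - 1
    return float(np.sqrt(chi2 / (n * k)))


def attrition_effect_sizes(
    included: pd.DataFrame,
    excluded: pd.DataFrame,
    categorical: Sequence[str],
    continuous: Sequence[str] = (),
    threshold: float = 0.10,
) -> pd.DataFrame:
    """Effect sizes for included-vs-excluded participant differences.

    Cramér's V for categorical variables and |Spearman rho| for continuous
    ones, each computed against the inclusion indicator; effect sizes at or
    above ``threshold`` are flagged.  Constant variables yield NaN with an
    explanatory note.
    """
    for name, df in (("included", included), ("excluded", excluded)):
        _require_columns(df, tuple(categorical) + tuple(continuous), f"{name} table")
    combined = pd.concat(
        [included.assign(_included=1), excluded.assign(_included=0)],
        ignore_index=True,
    )
    rows = []
    for var in categorical:
        if combined[var].nunique() < 2:
            rows.append((var, "categorical", float("nan"), False, "constant variable"))
            continue
        v = cramers_v(combined[var], combined["_included"])
        rows.append((var, "categorical", v, bool(v >= threshold), ""))
    for var in continuous:
        if combined[var].nunique() < 2:
            rows.append((var, "continuous", float("nan"), False, "constant variable"))
            continue
        rho = scipy.stats.spearmanr(combined[var], combined["_included"]).statistic
        rows.append((var, "continuous", abs(float(rho)), bool(abs(rho) >= threshold), ""))
    return pd.DataFrame(
        rows, columns=["variable", "type", "effect_size", "flagged", "note"]
    )
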