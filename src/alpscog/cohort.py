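"""Cohort-level analysis as a Model / Results pair.

:class:`CohortStudy` wraps a cohort table (one row per participant, see
the column dictionary in the README) and ``fit()`` runs the full analysis
chain: HC-referenced normative Z-scoring, BICAMS impairment
classification, normality-gated group comparisons with per-family FDR,
the Spearman screen, covariate-adjusted linear models for screened
imaging-cognition pairs, backward stepwise logistic regression for
impairment, and ROC. The returned :class:`CohortResults` carries every
intermediate table plus ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as st
from .simulate import COGNITIVE_TESTS
from .stepwise import SeparationError, StepwiseLogit, StepwiseResults

IMAGING_VARS = (
    "alps", "ncsfv", "ngmv", "nwmv", "tiv", "cth",
    "fa", "md", "ad", "rd", "wmlv", "wmln",
)
CLINICAL_VARS = ("disease_duration", "edss")


@dataclass
class StatsConfig:
    """Analysis knobs: alpha levels, FDR family labels, variable sets."""

    bicams: tuple[str, str, str] = ("sdmt", "cvlt2", "bvmt_r")
    cognitive_tests: tuple[str, ...] = COGNITIVE_TESTS
    imaging_vars: tuple[str, ...] = IMAGING_VARS
    clinical_vars: tuple[str, ...] = CLINICAL_VARS
    covariates: tuple[str, ...] = st.DEFAULT_COVARIATES
    screen_alpha: float = 0.05
    removal_alpha: float = 0.05
    shapiro_alpha: float = 0.05
    impairment_threshold: float = st.IMPAIRMENT_Z
    #: use the generator's planted impairment label instead of the
    #: Z-score-derived one (simulation studies only)
    use_planted_label: bool = False


REQUIRED_COLUMNS = ("id", "group", "sex", "age", "education")


@dataclass
class CohortResults:
    """Everything the cohort analysis computed."""

    config: StatsConfig
    n_rrms: int
    n_hc: int
    normative: dict[str, st.NormativeModel]
    zscores: pd.DataFrame  # per-subject z_<test> columns + subgroup label
    n_impaired: int
    group_comparisons: pd.DataFrame  # per-family comparison rows
    spearman_rho: pd.DataFrame
    spearman_p: pd.DataFrame
    adjusted_models: dict[str, st.RegressionResult]  # adjusted regressions per outcome
    stepwise: StepwiseResults | None  # impairment biomarker model
    notes: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"Cohort analysis: {self.n_rrms} patients, {self.n_hc} controls; "
            f"{self.n_impaired} patients impaired (Z <= {self.config.impairment_threshold} "
            f"in >= 2 of {list(self.config.bicams)})",
            "",
            "Group comparisons (statistic, p, q, effect size):",
            self.group_comparisons.round(4).to_string(),
            "",
            "Spearman screen (rho):",
            self.spearman_rho.round(3).to_string(),
        ]
        for outcome, model in self.adjusted_models.items():
            lines += ["", model.summary()]
        if self.stepwise is not None:
            lines += ["", self.stepwise.summary()]
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)


class CohortStudy:
    """A two-group (patients vs healthy controls) cohort analysis model."""

    def __init__(self, table: pd.DataFrame, config: StatsConfig | None = None) -> None:
        self.config = config or StatsConfig()
        self.table = table.reset_index(drop=True)
        self._validate()

    @classmethod
    def from_csv(cls, path: str | Path, config: StatsConfig | None = None) -> "CohortStudy":
        return cls(pd.read_csv(path), config)

    def _validate(self) -> None:
        cfg = self.config
        problems = []
        for col in REQUIRED_COLUMNS + cfg.cognitive_tests:
            if col not in self.table.columns:
                problems.append(f"missing column {col!r}")
        if "group" in self.table.columns:
            bad = set(self.table["group"].unique()) - {"RRMS", "HC"}
            if bad:
                problems.append(f"unknown group labels {sorted(bad)}")
            elif (self.table["group"] == "HC").sum() < 5:
                problems.append("need >= 5 HC rows for normative fitting")
        for col in cfg.cognitive_tests:
            if col in self.table.columns and self.table[col].isna().any():
                problems.append(f"missing cognitive scores in {col!r}")
        if problems:
            raise ValueError("cohort table schema violations: " + "; ".join(problems))

    # -- fitting ---------------------------------------------------------

    def fit(self) -> CohortResults:
        cfg = self.config
        df = self.table.sort_values("id", kind="stable").reset_index(drop=True)
        hc = df[df["group"] == "HC"]
        rrms = df[df["group"] == "RRMS"]
        notes: list[str] = []

        normative = {t: st.fit_normative(hc, t, cfg.covariates) for t in cfg.cognitive_tests}

        z = pd.DataFrame({"id": df["id"], "group": df["group"]})
        for t in cfg.cognitive_tests:
            z[f"z_{t}"] = [st.z_transform(normative[t], row) for _, row in df.iterrows()]

        sub = []
        for _, row in z.iterrows():
            if row["group"] != "RRMS":
                sub.append("")
            else:
                label = st.classify_impairment(*(row[f"z_{t}"] for t in cfg.bicams))
                sub.append("Co-I" if label == "impaired" else "Co-P")
        z["subgroup"] = sub
        if cfg.use_planted_label and "impaired_true" in df.columns:
            planted = df["impaired_true"].astype(float)
            z["subgroup"] = np.where(
                df["group"] == "RRMS", np.where(planted > 0, "Co-I", "Co-P"), ""
            )
        n_impaired = int((z["subgroup"] == "Co-I").sum())

        merged = df.merge(z.drop(columns=["group"]), on="id")

        comparisons = self._comparisons(merged, notes)
        rho, pmat = self._spearman(merged)
        adjusted = self._adjusted_models(merged, rho, pmat, notes)
        stepwise = self._stepwise(merged, comparisons, notes)

        return CohortResults(
            config=cfg,
            n_rrms=len(rrms),
            n_hc=len(hc),
            normative=normative,
            zscores=z,
            n_impaired=n_impaired,
            group_comparisons=comparisons,
            spearman_rho=rho,
            spearman_p=pmat,
            adjusted_models=adjusted,
            stepwise=stepwise,
            notes=notes,
        )

    def _comparisons(self, df: pd.DataFrame, notes: list[str]) -> pd.DataFrame:
        cfg = self.config
        n_total = len(df)
        rows = []

        def run(sub, variable, family, order, categorical=False, grouping="group"):
            try:
                res = st.compare_groups(
                    sub, variable, grouping=grouping, family=family,
                    categorical=categorical, shapiro_alpha=cfg.shapiro_alpha,
                    n_total_for_r=n_total, order=order,
                )
                rows.append(res)
            except ValueError as err:
                notes.append(f"{family}/{variable}: {err}")

        demo = [("sex", True), ("age", False), ("education", False)]
        # lesion burden is a patient-only quantity: compared between
        # impairment subgroups but not against HC
        both_group_vars = [v for v in cfg.imaging_vars if v not in ("wmlv", "wmln")]
        for variable, cat in demo + [(v, False) for v in both_group_vars]:
            run(df, variable, "table1_rrms_vs_hc", ("RRMS", "HC"), cat)
        for t in cfg.cognitive_tests:
            run(df, t, "table2_rrms_vs_hc", ("RRMS", "HC"))

        coirows = df[df["subgroup"].isin(["Co-I", "Co-P"])]
        if coirows["subgroup"].nunique() == 2 and coirows.groupby("subgroup").size().min() >= 3:
            for variable, cat in demo + [
                (v, False) for v in cfg.imaging_vars + cfg.clinical_vars
            ]:
                run(coirows, variable, "table1_coi_vs_cop", ("Co-I", "Co-P"),
                    categorical=cat, grouping="subgroup")
        else:
            notes.append("subgroup comparison skipped: fewer than 3 per impairment class")

        out = pd.DataFrame(
            {
                "variable": [r.variable for r in rows],
                "family": [r.family for r in rows],
                "test": [r.test for r in rows],
                "statistic": [r.statistic for r in rows],
                "p": [r.p for r in rows],
                "effect_size_type": [r.effect_size_type for r in rows],
                "effect_size": [r.effect_size for r in rows],
            }
        )
        out["q"] = np.nan
        for fam in out["family"].unique():
            m = out["family"] == fam
            out.loc[m, "q"] = st.fdr_bh(out.loc[m, "p"].values, family=fam)
        return out

    def _spearman(self, df: pd.DataFrame):
        cfg = self.config
        rrms = df[df["group"] == "RRMS"]
        row_vars = list(cfg.imaging_vars) + list(cfg.clinical_vars)
        row_vars = [v for v in row_vars if v in rrms.columns]
        col_vars = [f"z_{t}" for t in cfg.cognitive_tests]
        return st.spearman_matrix(rrms, row_vars, col_vars)

    def _adjusted_models(self, df, rho, pmat, notes):
        cfg = self.config
        rrms = df[df["group"] == "RRMS"]
        models = {}
        for t in cfg.cognitive_tests:
            col = f"z_{t}"
            pcol = pmat[col].dropna()
            predictors = [v for v in pcol.index if pcol[v] < cfg.screen_alpha]
            if not predictors:
                continue
            try:
                models[col] = st.adjusted_linear_model(
                    rrms, col, predictors, cfg.covariates, family=f"table3:{col}"
                )
            except ValueError as err:
                notes.append(f"adjusted model {col}: {err}")
        return models

    def _stepwise(self, df, comparisons, notes) -> StepwiseResults | None:
        cfg = self.config
        rrms = df[df["group"] == "RRMS"].copy()
        if rrms["subgroup"].nunique() < 2:
            notes.append("stepwise skipped: only one impairment class present")
            return None
        rrms["impaired"] = (rrms["subgroup"] == "Co-I").astype(int)
        fam = comparisons[comparisons["family"] == "table1_coi_vs_cop"]
        candidates = [
            v for v in fam.loc[fam["p"] < cfg.screen_alpha, "variable"]
            if v not in ("sex",) and pd.api.types.is_numeric_dtype(rrms[v])
        ]
        if not candidates:
            notes.append("stepwise skipped: no univariate candidate with p < alpha")
            return None
        try:
            return StepwiseLogit(
                rrms, "impaired", candidates, removal_alpha=cfg.removal_alpha
            ).fit()
        except (SeparationError, ValueError) as err:
            notes.append(f"stepwise failed: {err}")
            return None
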