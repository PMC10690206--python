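"""Progression-free-interval survival stratified by signature class.

Stage reclassification (AJCC stages 0-2 -> low, 3 -> high, 4 excluded),
administrative censoring at the within-tumor-type median follow-up time,
Kaplan-Meier curves with logrank tests, and Cox proportional-hazards
models (Efron tie handling) fitted via lifelines.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from bap1sig._exceptions import InputError

log = logging.getLogger(__name__)

_ROMAN = {"0": 0, "I": 1, "II": 2, "III": 3, "IV": 4}


def parse_stage(label) -> float:
    """Numeric AJCC stage from labels like 'Stage IIIA', 'III', 'stage 2'.

    Substage suffixes (A/B/C) are ignored.  Returns NaN for labels that
    cannot be parsed.
    """
    if label is None or (isinstance(label, float) and np.isnan(label)):
        return np.nan
    s = str(label).strip().upper()
    s = re.sub(r"^STAGE\s*", "", s)
    m = re.fullmatch(r"(0|IV|III|II|I|[0-4])[ABC]?", s)
    if not m:
        return np.nan
    tok = m.group(1)
    return float(_ROMAN.get(tok, tok if not tok.isdigit() else int(tok)))


def stage_class(stage_num: float) -> str:
    """low (0-2) / high (3) / excluded (4); 'unknown' when unparseable."""
    if np.isnan(stage_num):
        return "unknown"
    if stage_num <= 2:
        return "low"
    if stage_num == 3:
        return "high"
    return "excluded"


def prepare_survival(records: pd.DataFrame, cohort: str | None = None,
                     time_col: str = "PFI.time", event_col: str = "PFI",
                     followup_col: str = "last_followup") -> pd.DataFrame:
    """Stage mapping, stage-4 exclusion and follow-up-based censoring.

    Operates on one tumor type (pass ``cohort`` to subset a multi-type
    table).  Stage-4 rows are dropped; stages 0-2 map to ``low`` and 3 to
    ``high``; unparseable stages are flagged (``stage_class='unknown'``)
    but retained.  Records with time beyond the within-type median
    follow-up (computed over all rows before exclusion, censored and
    uncensored alike) are administratively censored there: event set to 0
    and time truncated to the cut-off.  Idempotent.
    """
    df = records.copy()
    if cohort is not None and "tumor_type" in df.columns:
        df = df[df["tumor_type"] == cohort].copy()
    if df.empty:
        raise InputError(f"no survival records for cohort {cohort!r}")
    stage_num = df["stage"].map(parse_stage) if "stage" in df.columns else pd.Series(np.nan, index=df.index)
    df["stage_class"] = stage_num.map(stage_class)
    n_unknown = int((df["stage_class"] == "unknown").sum())
    if n_unknown:
        log.warning("%d records with unparseable stage labels", n_unknown)
    df = df[df["stage_class"] != "excluded"].copy()
    cutoff = float(df[followup_col].median())
    late = df[time_col] > cutoff
    df.loc[late, event_col] = 0
    df.loc[late, time_col] = cutoff
    df["followup_cutoff"] = cutoff
    log.info("prepare_survival: %d records, cutoff %.1f days, %d administratively censored",
             len(df), cutoff, int(late.sum()))
    return df


@dataclass
class KMResult:
    """Kaplan-Meier curves per group with a two-group logrank test."""

    curves: dict                 # group -> DataFrame(time, survival, ci_low, ci_high)
    risk_table: pd.DataFrame     # groups x requested time points (n at risk)
    logrank_stat: float
    logrank_p: float


def km_logrank(times: pd.Series, events: pd.Series, groups: pd.Series,
               risk_times: list[float] | None = None) -> KMResult:
    """Product-limit estimates per group plus the logrank test.

    Greenwood confidence intervals come with the lifelines estimator.
    Requires at least two non-empty groups.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    df = pd.DataFrame({"time": times, "event": events, "group": groups}).dropna()
    levels = sorted(df["group"].unique())
    if len(levels) < 2:
        raise InputError("km_logrank requires at least two non-empty groups")
    if risk_times is None:
        risk_times = list(np.linspace(0, df["time"].max(), 5))
    curves, risk_rows = {}, {}
    for lev in levels:
        sub = df[df["group"] == lev]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(lev))
        ci = kmf.confidence_interval_survival_function_
        curves[lev] = pd.DataFrame({
            "time": kmf.survival_function_.index,
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
            "ci_low": ci.iloc[:, 0].to_numpy(),
            "ci_high": ci.iloc[:, 1].to_numpy(),
        }).reset_index(drop=True)
        risk_rows[lev] = [int((sub["time"] >= t).sum()) for t in risk_times]
    risk_table = pd.DataFrame(risk_rows, index=[f"t={t:g}" for t in risk_times]).T
    lr = multivariate_logrank_test(df["time"], df["group"], df["event"])
    stat = float(lr.test_statistic)
    p = float(lr.p_value)
    if df["event"].sum() == 0:
        stat, p = 0.0, 1.0  # no events: curves identical at 1, no evidence
    return KMResult(curves, risk_table, stat, p)


def cox_fit(records: pd.DataFrame, duration_col: str = "PFI.time",
            event_col: str = "PFI", group_col: str = "signature_class",
            covariates: list[str] = ()) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron ties, Newton-Raphson).

    The primary covariate is the binary ``group_col`` (positive vs
    negative signature class); optional adjustment covariates (e.g.
    stage_class, subtype) enter as treatment-coded dummies.  Returns one
    row per coefficient with HR, Wald 95% CI and p.  Monotone-likelihood /
    separation failures are reported as a non-converged row rather than an
    estimate.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    df = records[[duration_col, event_col]].copy()
    main = records[group_col]
    if main.dtype == object or isinstance(main.dtype, pd.CategoricalDtype):
        levels = sorted(main.unique())
        if len(levels) != 2:
            raise InputError(f"{group_col} must be binary; got {levels}")
        df[group_col] = (main == levels[1]).astype(float)
        label = f"{group_col}[{levels[1]}]"
    else:
        df[group_col] = main.astype(float)
        label = group_col
    for cov in covariates:
        col = records[cov]
        if pd.api.types.is_numeric_dtype(col):
            df[cov] = col.astype(float)
        else:
            df = pd.concat([df, pd.get_dummies(col, prefix=cov, drop_first=True,
                                               dtype=float)], axis=1)
    n_params = df.shape[1] - 2
    if int(records[event_col].sum()) < n_params:
        raise InputError("fewer events than model parameters")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as err:
        log.warning("Cox model did not converge: %s", err)
        return pd.DataFrame([{"covariate": label, "hr": np.nan, "ci_low": np.nan,
                              "ci_high": np.nan, "p": np.nan, "converged": False}])
    summ = cph.summary
    if (summ["se(coef)"] > 10).any() or summ["coef"].abs().max() > 15:
        # monotone likelihood / complete separation: the partial likelihood
        # has no finite maximizer, so no estimate is reported
        log.warning("monotone partial likelihood (separation); no estimate reported")
        return pd.DataFrame([{"covariate": label, "hr": np.nan, "ci_low": np.nan,
                              "ci_high": np.nan, "p": np.nan, "converged": False,
                              "diagnostic": "monotone likelihood / separation"}])
    out = pd.DataFrame({
        "covariate": summ.index,
        "coef": summ["coef"].to_numpy(),
        "hr": summ["exp(coef)"].to_numpy(),
        "ci_low": np.exp(summ["coef lower 95%"].to_numpy()),
        "ci_high": np.exp(summ["coef upper 95%"].to_numpy()),
        "p": summ["p"].to_numpy(),
        "converged": True,
    }).reset_index(drop=True)
    out.loc[out["covariate"] == group_col, "covariate"] = label
    return out


def km_plot(km: KMResult, path, title: str = "") -> None:
    """Write a Kaplan-Meier plot (with risk-table caption) to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for lev, cur in km.curves.items():
        ax.step(cur["time"], cur["survival"], where="post", label=str(lev))
    ax.set_ylim(0, 1.05)
    ax.set_xlabel("days")
    ax.set_ylabel("progression-free survival")
    ax.legend()
    ax.set_title(f"{title} (logrank p={km.logrank_p:.2g})".strip())
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
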