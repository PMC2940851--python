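"""Reproducibility and factorial analyses of the disc metrics.

Two procedures are provided:

* :func:`reproducibility_sd` — sample standard deviations of repeated
  measurements of one disc, pooled over all repeats and per observer.
  DX, H and PSM are reported in mm; SM, being scanner-arbitrary, as a
  percent coefficient of variation.
* :func:`two_way_anova` — fixed-effects two-way ANOVA (pathology x
  severity, with interaction) on a chosen metric, using Type III sums of
  squares with sum-to-zero contrasts so unbalanced cohorts are handled
  the way classical biostatistics packages do.

:func:`cohort_report` lays out per-cell mean +/- standard error for all
four metrics, and :func:`simulate_anova_rates` estimates rejection rates
of the ANOVA under a given cohort effect model (type-I error under a null
model, power under an effect model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .core import (
    DegenerateStatisticsWarning,
    DiscMetrics,
    EmptyCellWarning,
    InsufficientDataError,
    ValidationError,
)

__all__ = [
    "CohortRecord",
    "ReproducibilityResult",
    "AnovaResult",
    "reproducibility_sd",
    "two_way_anova",
    "cohort_report",
    "simulate_anova_rates",
]

METRIC_COLUMNS = ("DX_mm", "SM", "PSM_mm", "H_mm")
PATHOLOGY_ORDER = ("spondylolisthesis", "scoliosis")


@dataclass
class CohortRecord:
    """One disc of one subject with its metrics and factor labels."""

    subject: str
    pathology: str
    severity: int
    metrics: DiscMetrics | Mapping[str, float]
    disc_level: str = ""

    def __post_init__(self) -> None:
        self.severity = int(self.severity)
        if self.severity not in (1, 2, 3):
            raise ValidationError(f"severity must be 1, 2 or 3, got {self.severity}")

    def row(self) -> dict:
        m = self.metrics.as_dict() if isinstance(self.metrics, DiscMetrics) \
            else dict(self.metrics)
        return {"subject": self.subject, "pathology": self.pathology,
                "severity": self.severity, "disc_level": self.disc_level,
                **{k: m[k] for k in METRIC_COLUMNS if k in m}}


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.row() for r in records])
    if df.empty:
        raise InsufficientDataError("no cohort records")
    for col in ("pathology", "severity"):
        if col not in df.columns:
            raise ValidationError(f"records lack a {col!r} column")
    return df


# ---------------------------------------------------------------------------
# reproducibility
# ---------------------------------------------------------------------------

def _metric_values(repeats: Sequence) -> pd.DataFrame:
    rows = []
    for m in repeats:
        d = m.as_dict() if isinstance(m, DiscMetrics) else dict(m)
        rows.append({k: float(d[k]) for k in METRIC_COLUMNS})
    return pd.DataFrame(rows)


def _sd_summary(df: pd.DataFrame) -> dict:
    """Sample SDs (n-1) per metric; SM as percent of its mean."""
    if len(df) < 2:
        return {"DX_mm": np.nan, "H_mm": np.nan, "PSM_mm": np.nan,
                "SM_pct": np.nan, "n": len(df)}
    out = {k: float(df[k].std(ddof=1)) for k in ("DX_mm", "H_mm", "PSM_mm")}
    sm_mean = float(df["SM"].mean())
    out["SM_pct"] = float(df["SM"].std(ddof=1) / sm_mean * 100.0) \
        if sm_mean != 0 else np.nan
    out["n"] = len(df)
    return out


@dataclass
class ReproducibilityResult:
    """Pooled and per-observer repeat standard deviations.

    ``pooled`` and each ``per_observer`` entry map metric names
    (``DX_mm``, ``H_mm``, ``PSM_mm`` in mm; ``SM_pct`` in percent of the
    mean) to sample standard deviations over the repeats.
    """

    pooled: dict = field(default_factory=dict)
    per_observer: dict = field(default_factory=dict)


def reproducibility_sd(
        repeats_by_observer: Mapping[str, Sequence]) -> ReproducibilityResult:
    """Repeat SDs for one disc, pooled over observers and per observer.

    Parameters
    ----------
    repeats_by_observer : mapping observer label -> sequence of
        :class:`DiscMetrics` (or metric dicts) from repeated analyses of
        the *same* disc.  At least two repeats overall are required;
        observers with a single repeat get ``NaN`` per-observer SDs.
    """
    if not repeats_by_observer or any(len(v) < 1
                                      for v in repeats_by_observer.values()):
        raise InsufficientDataError("each observer needs at least one repeat")
    frames = {obs: _metric_values(reps)
              for obs, reps in repeats_by_observer.items()}
    pooled_df = pd.concat(frames.values(), ignore_index=True)
    if len(pooled_df) < 2:
        raise InsufficientDataError(
            "at least two repeats overall are required")
    return ReproducibilityResult(
        pooled=_sd_summary(pooled_df),
        per_observer={obs: _sd_summary(df) for obs, df in frames.items()},
    )


# ---------------------------------------------------------------------------
# two-way ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """F and p for pathology, severity and their interaction on one metric.

    ``table`` is indexed by effect name; ``cell_means`` holds per-cell
    mean, standard error and n.  The interaction row is estimated but
    supplementary — cohorts of this kind are typically reported by main
    effects only.
    """

    response: str
    table: pd.DataFrame
    cell_means: pd.DataFrame
    n_obs: int
    warnings: list = field(default_factory=list)

    @property
    def p_pathology(self) -> float:
        return float(self.table.loc["pathology", "p"])

    @property
    def p_severity(self) -> float:
        return float(self.table.loc["severity", "p"])


def _cell_stats(df: pd.DataFrame, response: str) -> pd.DataFrame:
    grouped = df.groupby(["pathology", "severity"], observed=True)[response]
    out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
    out["se"] = out["sd"] / np.sqrt(out["n"])
    # single-record cells have undefined dispersion, reported as missing
    out.loc[out["n"] < 2, ["sd", "se"]] = np.nan
    return out.drop(columns="sd")[["mean", "se", "n"]]


def two_way_anova(records, response: str) -> AnovaResult:
    """Fixed-effects pathology x severity ANOVA with Type III SS.

    Unbalanced designs are allowed.  Raises if either factor has a single
    observed level; if any pathology x severity cell is empty the
    interaction is dropped with an :class:`EmptyCellWarning`.  Zero
    residual variance yields NaN statistics with a
    :class:`DegenerateStatisticsWarning`.
    """
    df = _records_frame(records)
    if response not in df.columns:
        raise ValidationError(f"records lack response column {response!r}")
    df = df[["pathology", "severity", response]].rename(columns={response: "y"})
    df["pathology"] = df["pathology"].astype(str)
    df["severity"] = df["severity"].astype(int)

    issued: list[str] = []
    for factor in ("pathology", "severity"):
        if df[factor].nunique() < 2:
            raise ValidationError(
                f"factor {factor!r} has a single level; the design is "
                "rank-deficient")
    n_cells = df.groupby(["pathology", "severity"]).size()
    full_grid = df["pathology"].nunique() * df["severity"].nunique()
    with_interaction = len(n_cells) == full_grid
    if not with_interaction:
        warnings.warn("empty pathology x severity cells: interaction "
                      "dropped", EmptyCellWarning, stacklevel=2)
        issued.append("EmptyCellWarning")

    op = "*" if with_interaction else "+"
    formula = f"y ~ C(pathology, Sum) {op} C(severity, Sum)"
    fit = smf.ols(formula, data=df).fit()

    if fit.ssr <= 1e-10 * max(float(np.abs(df["y"]).max()) ** 2, 1.0):
        warnings.warn("zero residual variance; F statistics are undefined",
                      DegenerateStatisticsWarning, stacklevel=2)
        issued.append("DegenerateStatisticsWarning")
        idx = ["pathology", "severity"] + (["interaction"] if with_interaction else [])
        table = pd.DataFrame({"F": np.nan, "p": np.nan, "df": np.nan}, index=idx)
    else:
        an = anova_lm(fit, typ=3)
        rename = {
            "C(pathology, Sum)": "pathology",
            "C(severity, Sum)": "severity",
            "C(pathology, Sum):C(severity, Sum)": "interaction",
        }
        an = an.rename(index=rename)
        keep = [r for r in ("pathology", "severity", "interaction")
                if r in an.index]
        table = pd.DataFrame({
            "F": an.loc[keep, "F"],
            "p": an.loc[keep, "PR(>F)"],
            "df": an.loc[keep, "df"],
        })
        if not table["p"].dropna().between(0, 1).all():
            raise AssertionError("p-values outside [0, 1]")

    return AnovaResult(response=response, table=table,
                       cell_means=_cell_stats(df.rename(columns={"y": response}),
                                              response),
                       n_obs=len(df), warnings=issued)


# ---------------------------------------------------------------------------
# cohort report
# ---------------------------------------------------------------------------

def _ordered_levels(values: Iterable[str]) -> list[str]:
    present = list(dict.fromkeys(values))
    known = [p for p in PATHOLOGY_ORDER if p in present]
    return known + sorted(set(present) - set(known))


def cohort_report(records) -> pd.DataFrame:
    """Per-cell mean +/- SE table for all four metrics.

    Rows: (metric, statistic in {mean, se, n}); columns: (pathology,
    severity), spondylolisthesis levels 1-3 first, then scoliosis, the
    conventional presentation.  SE = SD/sqrt(n); missing for n = 1 cells.
    """
    df = _records_frame(records)
    metrics = [m for m in METRIC_COLUMNS if m in df.columns]
    if not metrics:
        raise ValidationError("records contain no metric columns")
    pieces = {}
    for m in metrics:
        pieces[m] = _cell_stats(df, m)
    cols = []
    for p in _ordered_levels(df["pathology"]):
        for s in sorted(df.loc[df["pathology"] == p, "severity"].unique()):
            cols.append((p, int(s)))
    out = pd.DataFrame(
        index=pd.MultiIndex.from_product([metrics, ["mean", "se", "n"]],
                                         names=["metric", "stat"]),
        columns=pd.MultiIndex.from_tuples(cols, names=["pathology", "severity"]),
        dtype=float,
    )
    for m in metrics:
        st = pieces[m]
        for cell in cols:
            if cell in st.index:
                out.loc[(m, "mean"), cell] = st.loc[cell, "mean"]
                out.loc[(m, "se"), cell] = st.loc[cell, "se"]
                out.loc[(m, "n"), cell] = st.loc[cell, "n"]
    return out


def report_markdown(report: pd.DataFrame, digits: int = 2) -> str:
    """Render a cohort report as a compact 'mean +/- se' Markdown table."""
    metrics = report.index.get_level_values("metric").unique()
    cols = list(report.columns)
    header = "| metric | " + " | ".join(f"{p} {s}" for p, s in cols) + " |"
    sep = "|" + "---|" * (len(cols) + 1)
    lines = [header, sep]
    for m in metrics:
        cells = []
        for c in cols:
            mean = report.loc[(m, "mean"), c]
            se = report.loc[(m, "se"), c]
            if pd.isna(mean):
                cells.append("-")
            elif pd.isna(se):
                cells.append(f"{mean:.{digits}f}")
            else:
                cells.append(f"{mean:.{digits}f} ± {se:.{digits}f}")
        lines.append(f"| {m} | " + " | ".join(cells) + " |")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# simulation harness
# ---------------------------------------------------------------------------

def simulate_anova_rates(model, n_reps: int, responses: Sequence[str],
                         seed: int = 0, alpha: float = 0.05) -> pd.DataFrame:
    """Rejection rates of the two-way ANOVA over simulated cohorts.

    Each replication draws a metric-level cohort from ``model`` (an
    :class:`~discsig.phantom.EffectModel`) and tests each response;
    returns the fraction of replications with p < ``alpha``, indexed by
    response with columns ``pathology`` and ``severity``.  With a null
    model this estimates the type-I error; with an effect model, power.
    """
    from .phantom import sample_metric_cohort

    rng = np.random.default_rng(seed)
    hits = {r: {"pathology": 0, "severity": 0} for r in responses}
    for _ in range(n_reps):
        cohort = sample_metric_cohort(model, rng=rng)
        for r in responses:
            res = two_way_anova(cohort, r)
            if res.p_pathology < alpha:
                hits[r]["pathology"] += 1
            if res.p_severity < alpha:
                hits[r]["severity"] += 1
    return pd.DataFrame({r: {k: v / n_reps for k, v in d.items()}
                         for r, d in hits.items()}).T
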