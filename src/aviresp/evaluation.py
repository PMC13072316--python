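"""Evaluation against manual counts: error metrics, agreement, age trends.

Manual reference rates come from 10-s observation windows counted at
half-breath granularity (a completed thoracodorsal/tail undulation is one
breath, an incomplete one half) and divided by the window length to give
Hz.  Algorithm values x_i are compared to manual values y_i with:

* MAE  = (1/n)·Σ|y_i − x_i|
* MAPE = (100/n)·Σ|y_i − x_i|/y_i            (manual value in the denominator)
* RMSE = sqrt((1/n)·Σ(y_i − x_i)²)
* R²   = 1 − Σ(y_i − x_i)²/Σ(y_i − ȳ)²       — agreement with the identity
  line y = x, *not* a regression R²; a constant offset between methods
  lowers it even when the correlation is perfect.
* Pearson r, population σ (divisor n), sample SD (divisor n−1), SEM.
* Bland–Altman: bias = mean(x − y) (algorithm minus manual) with limits of
  agreement bias ± 1.96·SD of the differences.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EvaluationError


def counts_to_hz(full_cycles: float, partial: float = 0.0, window_s: float = 10.0) -> float:
    """Manual breath count over one window → rate in Hz.

    ``partial`` is 0 or 0.5 (an incomplete final undulation counts as half
    a breath).
    """
    if full_cycles < 0 or partial < 0:
        raise EvaluationError("counts must be non-negative")
    if partial not in (0, 0.5):
        raise EvaluationError(f"partial count must be 0 or 0.5, got {partial}")
    if window_s <= 0:
        raise EvaluationError("window length must be positive")
    return (full_cycles + partial) / window_s


@dataclass(frozen=True)
class PairedMeasurements:
    """Paired manual (y) and algorithm (x) rates, with cohort covariates."""

    y_manual: np.ndarray
    x_algo: np.ndarray
    ids: tuple[str, ...] = ()
    age_days: np.ndarray | None = None
    stage: tuple[str, ...] = ()
    heat_delta: np.ndarray | None = None

    def __post_init__(self) -> None:
        y = np.asarray(self.y_manual, dtype=np.float64)
        x = np.asarray(self.x_algo, dtype=np.float64)
        if y.shape != x.shape or y.ndim != 1:
            raise EvaluationError("y and x must be equal-length 1-D arrays")
        if not (np.all(np.isfinite(y)) and np.all(np.isfinite(x))):
            raise EvaluationError("non-finite measurement values")
        object.__setattr__(self, "y_manual", y)
        object.__setattr__(self, "x_algo", x)

    @property
    def n(self) -> int:
        return self.y_manual.shape[0]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PairedMeasurements":
        return cls(
            y_manual=df["y_manual"].to_numpy(float),
            x_algo=df["x_algo"].to_numpy(float),
            ids=tuple(map(str, df.get("id", pd.Series(range(len(df)))))),
            age_days=df["age_days"].to_numpy(float) if "age_days" in df else None,
            stage=tuple(map(str, df["stage"])) if "stage" in df else (),
            heat_delta=df["heat_delta"].to_numpy(float) if "heat_delta" in df else None,
        )


@dataclass(frozen=True)
class EvalReport:
    """The full metric suite for one paired comparison (units: Hz unless noted)."""

    n: int
    mae: float
    mape: float  # percent
    rmse: float
    r2: float  # identity-line coefficient of determination
    pearson_r: float
    sigma: float  # population SD of manual values (divisor n)
    sd: float  # sample SD of manual values (divisor n−1)
    sem: float
    bias: float  # mean(algorithm − manual)
    loa_low: float
    loa_high: float
    extras: dict | None = None  # optional slots (ANOVA tables, ICC, ...)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def to_markdown(self) -> str:
        rows = [
            ("n", f"{self.n}"), ("MAE (Hz)", f"{self.mae:.4f}"), ("MAPE (%)", f"{self.mape:.3f}"),
            ("RMSE (Hz)", f"{self.rmse:.4f}"), ("R² (identity)", f"{self.r2:.4f}"),
            ("Pearson r", f"{self.pearson_r:.4f}"), ("SD (Hz)", f"{self.sd:.4f}"),
            ("SEM (Hz)", f"{self.sem:.4f}"), ("bias (Hz)", f"{self.bias:.5f}"),
            ("LoA (Hz)", f"[{self.loa_low:.4f}, {self.loa_high:.4f}]"),
        ]
        lines = ["| metric | value |", "| --- | --- |"]
        lines += [f"| {k} | {v} |" for k, v in rows]
        return "\n".join(lines)


def compute_metrics(pairs: PairedMeasurements, mape: bool = True) -> EvalReport:
    """Evaluate the full metric suite on paired manual/algorithm rates."""
    if pairs.n < 2:
        raise EvaluationError(f"need at least 2 pairs for dispersion metrics, got {pairs.n}")
    y, x = pairs.y_manual, pairs.x_algo
    err = y - x
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    if mape:
        if np.any(y == 0):
            raise EvaluationError("MAPE undefined: a manual value is zero")
        mape_val = float(100.0 * np.mean(np.abs(err) / np.abs(y)))
    else:
        mape_val = float("nan")
    ss_res = float(np.sum(err**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    if np.ptp(y) > 0 and np.ptp(x) > 0:
        pearson = float(stats.pearsonr(x, y).statistic)
    else:
        pearson = float("nan")
    sigma = float(np.std(y, ddof=0))
    sd = float(np.std(y, ddof=1))
    sem = float(sd / np.sqrt(pairs.n))
    diff = x - y  # algorithm minus manual
    bias = float(diff.mean())
    diff_sd = float(np.std(diff, ddof=1))
    return EvalReport(
        n=pairs.n, mae=mae, mape=mape_val, rmse=rmse, r2=r2, pearson_r=pearson,
        sigma=sigma, sd=sd, sem=sem, bias=bias,
        loa_low=bias - 1.96 * diff_sd, loa_high=bias + 1.96 * diff_sd,
    )


def bland_altman_points(pairs: PairedMeasurements) -> pd.DataFrame:
    """Per-pair means and differences for a Bland–Altman plot."""
    return pd.DataFrame(
        {
            "mean": (pairs.x_algo + pairs.y_manual) / 2.0,
            "diff": pairs.x_algo - pairs.y_manual,
        }
    )


def fit_linear_trend(
    ages: Sequence[float], rr: Sequence[float]
) -> tuple[float, float, float]:
    """OLS trend of RR (Hz) against age (days): (slope, intercept, fit R²).

    ``fit R²`` here is the ordinary regression coefficient of
    determination — distinct from the identity-line R² of
    :func:`compute_metrics`.  Two points determine a line exactly; that
    degenerate perfect fit is flagged with a warning.
    """
    ages = np.asarray(ages, dtype=np.float64)
    rr = np.asarray(rr, dtype=np.float64)
    if ages.shape != rr.shape or ages.ndim != 1:
        raise EvaluationError("ages and rr must be equal-length 1-D arrays")
    if np.unique(ages).size < 2:
        raise EvaluationError("constant ages: trend is not identifiable")
    if np.unique(ages).size == 2:
        import warnings

        warnings.warn("only two distinct ages: trend fit is under-determined", stacklevel=2)
    res = stats.linregress(ages, rr)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def load_manual_counts(path: str | Path, window_s: float = 10.0) -> pd.DataFrame:
    """Read a manual-count CSV (id,observer,window_start_s,full_cycles,partial)
    and reduce to one rate per id: mean over observers and repeats, in Hz."""
    df = pd.read_csv(path)
    required = {"id", "full_cycles", "partial"}
    if not required <= set(df.columns):
        raise EvaluationError(f"{path}: needs columns {sorted(required)}")
    bad = ~df["partial"].isin([0, 0.5])
    if bad.any():
        raise EvaluationError(f"{path}: partial counts must be 0 or 0.5 (rows {list(df.index[bad])})")
    df = df.assign(rate_hz=(df["full_cycles"] + df["partial"]) / window_s)
    return df.groupby("id", as_index=False)["rate_hz"].mean()
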