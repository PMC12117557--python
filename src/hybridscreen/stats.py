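"""Paired model-comparison statistics.

Two models are compared on byte-identical splits, so the natural unit is
the paired difference per (data set, replicate): paired t-test, 95%
confidence interval, paired Cohen's d_z effect size, and
Benjamini-Hochberg FDR adjustment across the whole comparison family
(all model pairs x all metrics).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests


@dataclass
class PairedSample:
    """Metric values for two models over identical pairing units."""

    units: list                 # e.g. (dataset, replicate) labels
    values_a: np.ndarray
    values_b: np.ndarray

    def __post_init__(self):
        self.values_a = np.asarray(self.values_a, dtype=float)
        self.values_b = np.asarray(self.values_b, dtype=float)
        if len(self.values_a) != len(self.values_b):
            raise ValueError("paired samples must have equal length")
        if len(self.values_a) < 2:
            raise ValueError("need at least 2 pairing units")


@dataclass
class ComparisonResult:
    mean_diff: float
    ci_lo: float
    ci_hi: float
    t: float
    df: int
    p_raw: float
    effect_size: float
    degenerate: bool = False
    p_fdr: Optional[float] = None


def paired_t(ps: PairedSample) -> ComparisonResult:
    """Two-sided paired t-test on d = values_b - values_a.

    Returns t, df = k-1, raw p, 95% CI on the mean difference, and the
    paired effect size d_z = mean(d)/sd(d) (sd with ddof=1).  Identical
    differences give a degenerate result (p undefined), not an error.
    """
    d = ps.values_b - ps.values_a
    k = len(d)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        return ComparisonResult(mean_diff=mean, ci_lo=mean, ci_hi=mean,
                                t=np.nan, df=k - 1, p_raw=np.nan,
                                effect_size=np.nan, degenerate=True)
    se = sd / np.sqrt(k)
    t_stat = mean / se
    df = k - 1
    p = float(2.0 * scipy.stats.t.sf(abs(t_stat), df))
    tcrit = float(scipy.stats.t.ppf(0.975, df))
    return ComparisonResult(
        mean_diff=mean, ci_lo=mean - tcrit * se, ci_hi=mean + tcrit * se,
        t=float(t_stat), df=df, p_raw=p, effect_size=mean / sd,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    NaN entries (degenerate tests) are passed through and do not count
    toward the family size.
    """
    p = np.asarray(p_values, dtype=float)
    finite = ~np.isnan(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    if finite.sum():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


def compare_models(metric_table: pd.DataFrame, model_a: str | None = None,
                   model_b: str | None = None) -> pd.DataFrame:
    """Paired comparison of models from a long-format metric table.

    ``metric_table`` columns: dataset, model, split_kind, replicate,
    metric, value.  For every (dataset, split_kind, metric, ordered model
    pair) cell a paired t-test over replicates is run; FDR adjustment is
    applied jointly across all cells of the family.  If ``model_a`` /
    ``model_b`` are given, only that pair is compared (b minus a).
    """
    required = {"dataset", "model", "split_kind", "replicate", "metric", "value"}
    missing = required - set(metric_table.columns)
    if missing:
        raise ValueError(f"metric table lacks columns {sorted(missing)}")

    models = sorted(metric_table["model"].unique())
    if model_a is not None:
        pairs = [(model_a, model_b)]
    else:
        pairs = [(a, b) for i, a in enumerate(models) for b in models[i + 1:]]

    rows = []
    for (dataset, split_kind, metric), cell in metric_table.groupby(
            ["dataset", "split_kind", "metric"], sort=True):
        pivot = cell.pivot_table(index="replicate", columns="model",
                                 values="value", aggfunc="first")
        for a, b in pairs:
            for m in (a, b):
                if m not in pivot.columns or pivot[m].isna().any():
                    bad = (pivot.index[pivot[m].isna()].tolist()
                           if m in pivot.columns else list(pivot.index))
                    raise ValueError(
                        f"missing metric values for model {m!r} on dataset "
                        f"{dataset!r}, replicates {bad}"
                    )
            ps = PairedSample(units=list(pivot.index),
                              values_a=pivot[a].to_numpy(),
                              values_b=pivot[b].to_numpy())
            res = paired_t(ps)
            rows.append({
                "dataset": dataset, "split_kind": split_kind, "metric": metric,
                "model_a": a, "model_b": b, "mean_diff": res.mean_diff,
                "ci_lo": res.ci_lo, "ci_hi": res.ci_hi, "t": res.t,
                "df": res.df, "p_raw": res.p_raw,
                "effect_size": res.effect_size, "degenerate": res.degenerate,
            })
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_fdr(out["p_raw"].to_numpy())
    return out
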