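"""Relative qPCR quantification and actinomycin-D RNA decay kinetics.

Fold changes between groups of Ct measurements use the standard delta-delta
Ct method with a reference gene. Decay series from transcription-inhibition
assays are fit with a single exponential N(t) = N0 * exp(-k t) by least
squares on log levels, giving the decay rate k (1/h), the half-life ln2/k
and the fraction of the t = 0 level remaining at any time (4 h in the
standard readout).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CtRecord:
    sample_id: str
    gene_id: str
    reference_gene_id: str
    ct_target: float
    ct_reference: float
    condition: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        for v in (self.ct_target, self.ct_reference):
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"Ct value {v} is not finite and positive")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


class FoldChangeResult(NamedTuple):
    ddct: float
    fold_change: float
    mean_dct_treated: float
    mean_dct_control: float


def ddct_fold_change(treated: Sequence[CtRecord],
                     control: Sequence[CtRecord]) -> FoldChangeResult:
    """Delta-delta Ct fold change of treated over control.

    ddCt = mean dCt(treated) - mean dCt(control); fold = 2 ** (-ddCt).
    """
    if not treated or not control:
        raise ValueError("both groups need >= 1 replicate")
    refs = {r.reference_gene_id for r in treated} | {
        r.reference_gene_id for r in control}
    if len(refs) != 1:
        raise ValueError(f"mismatched reference genes across groups: {sorted(refs)}")
    targets = {r.gene_id for r in treated} | {r.gene_id for r in control}
    if len(targets) != 1:
        raise ValueError(f"mismatched target genes across groups: {sorted(targets)}")
    mt = float(np.mean([r.delta_ct for r in treated]))
    mc = float(np.mean([r.delta_ct for r in control]))
    ddct = mt - mc
    return FoldChangeResult(ddct, 2.0 ** (-ddct), mt, mc)


# ---------------------------------------------------------------------------
# decay fitting
# ---------------------------------------------------------------------------

@dataclass
class DecayFit:
    gene_id: str
    condition: str
    k: float                  # decay rate, 1/h
    n0: float                 # fitted level at t = 0
    rss: float                # residual sum of squares of the fitted curve
    no_decay: bool = False    # k fitted <= 0

    @property
    def half_life(self) -> float:
        return math.log(2) / self.k if self.k > 0 else math.inf

    def fraction_at(self, t: float) -> float:
        """Fraction of the t = 0 level remaining at time t (N0-normalized)."""
        return math.exp(-self.k * t)

    def level_at(self, t: float) -> float:
        return self.n0 * math.exp(-self.k * t)


def fit_decay(timepoints: Sequence[float], levels: Sequence[float],
              fix_n0: bool = False, gene_id: str = "",
              condition: str = "") -> DecayFit:
    """Fit N(t) = N0 exp(-k t) by linear least squares on log levels.

    With ``fix_n0`` the intercept is pinned to N0 = 1 (levels already
    normalized to the no-drug control); otherwise N0 is free. A fitted k < 0
    (levels rising) is returned as-is with ``no_decay`` set and an infinite
    half-life. The reported RSS is of the fitted exponential against the
    levels on the linear scale.
    """
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(levels, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("timepoints and levels must be equal-length 1-D")
    if len(t) < 3:
        raise ValueError("need >= 3 timepoints")
    if not np.any(t == 0):
        raise ValueError("series must include t = 0")
    if np.any(y <= 0):
        raise ValueError("levels must be positive (log fit)")
    ly = np.log(y)
    if fix_n0:
        denom = float(np.sum(t * t))
        slope = float(np.sum(t * ly)) / denom if denom > 0 else 0.0
        intercept = 0.0
    else:
        slope, intercept = np.polyfit(t, ly, 1)
    k = -float(slope)
    n0 = float(np.exp(intercept))
    fitted = n0 * np.exp(-k * t)
    rss = float(np.sum((y - fitted) ** 2))
    return DecayFit(gene_id, condition, k, n0, rss, no_decay=k <= 0)


def remaining_at(source: DecayFit | dict | Sequence, t: float = 4.0) -> float:
    """Fraction of the t = 0 level remaining at time ``t``.

    Fit mode (a :class:`DecayFit`) returns exp(-k t); raw mode (a mapping or
    (time, level) pairs) returns level(t) / level(0) and requires an
    observation at exactly ``t``.
    """
    if isinstance(source, DecayFit):
        return source.fraction_at(t)
    series = dict(source if isinstance(source, dict) else
                  {float(a): float(b) for a, b in source})
    if 0.0 not in series:
        raise ValueError("raw series lacks a t = 0 observation")
    if t not in series:
        raise ValueError(f"raw series has no observation at t = {t}")
    return series[t] / series[0.0]


class TwoSampleTestResult(NamedTuple):
    statistic: float
    df: int
    pvalue: float


def compare_remaining(group_a: Sequence[float],
                      group_b: Sequence[float]) -> TwoSampleTestResult:
    """Student two-tailed two-sample t-test (pooled variance) on fractions.

    Identical zero-variance groups return t = 0, p = 1; zero-variance groups
    with different means return an infinite t with p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 replicates per group")
    df = len(a) + len(b) - 2
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return TwoSampleTestResult(0.0, df, 1.0)
        return TwoSampleTestResult(math.copysign(math.inf, a.mean() - b.mean()),
                                   df, 0.0)
    res = stats.ttest_ind(a, b, equal_var=True)
    return TwoSampleTestResult(float(res.statistic), df, float(res.pvalue))


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def load_decay_series(path: str | os.PathLike) -> pd.DataFrame:
    """TSV with columns gene_id, condition, replicate, time_h, level."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "condition", "time_h", "level"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"decay series lacks columns: {sorted(missing)}")
    return df


def fit_decay_table(series: pd.DataFrame, fix_n0: bool = False) -> pd.DataFrame:
    """Fit one decay curve per (gene, condition), averaging replicate levels
    at each timepoint."""
    rows = []
    for (gid, cond), grp in series.groupby(["gene_id", "condition"]):
        mean_levels = grp.groupby("time_h")["level"].mean()
        fit = fit_decay(mean_levels.index.to_numpy(), mean_levels.to_numpy(),
                        fix_n0=fix_n0, gene_id=gid, condition=cond)
        rows.append({"gene_id": gid, "condition": cond, "k": fit.k,
                     "half_life_h": fit.half_life, "n0": fit.n0,
                     "rss": fit.rss, "fraction_at_4h": fit.fraction_at(4.0),
                     "no_decay": fit.no_decay})
    return pd.DataFrame(rows)
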