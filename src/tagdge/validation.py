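"""Wet-lab validation arithmetic: qPCR 2^-ddCT and knockdown effect sizes.

Relative expression from cycle thresholds uses the comparative CT method:
dCT = CT_target - CT_reference per sample (reference = a housekeeping gene),
ddCT = dCT_treated - mean(dCT_control), fold change = 2^-ddCT. Knockdown
efficacy is expressed as percent-of-control (100 x mean treatment / mean
control) with a two-sample Student's t-test (equal-variance by default,
Welch selectable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class FoldChangeResult:
    per_sample: pd.Series  # 2^-ddCT per treated sample
    mean: float
    se: float  # standard error over treated samples (nan for a single sample)


def ddct_fold_change(
    treated: pd.DataFrame, control: pd.DataFrame
) -> FoldChangeResult:
    """2^-ddCT fold changes of treated samples relative to the control group.

    Both frames need columns ``ct_target`` and ``ct_reference`` (cycles); the
    control dCT is the control-group mean. Adding any constant to every CT
    (target and reference alike) leaves the result unchanged.
    """
    for name, frame in (("treated", treated), ("control", control)):
        missing = {"ct_target", "ct_reference"} - set(frame.columns)
        if missing:
            raise ValueError(f"{name} table lacks columns {sorted(missing)}")
        values = frame[["ct_target", "ct_reference"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(values)) or np.any(values <= 0):
            raise ValueError(f"{name} CT values must be finite and positive")
    if len(control) == 0:
        raise ValueError("control group is empty; cannot define the reference dCT")
    dct_treated = treated["ct_target"] - treated["ct_reference"]
    dct_control = (control["ct_target"] - control["ct_reference"]).mean()
    ddct = dct_treated - dct_control
    fold = np.power(2.0, -ddct)
    n = len(fold)
    se = float(fold.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    return FoldChangeResult(per_sample=fold, mean=float(fold.mean()), se=se)


@dataclass(frozen=True)
class KnockdownResult:
    percent_of_control: Optional[float]  # None when the control mean is 0
    t_statistic: float
    p_value: float


def percent_of_control(
    treatment: Sequence[float],
    control: Sequence[float],
    equal_var: bool = True,
) -> KnockdownResult:
    """Effect size as percent of control with a two-sided two-sample t-test.

    percent = 100 * mean(treatment) / mean(control); the percent is None when
    the control mean is zero. ``equal_var=False`` switches to Welch's test.
    """
    t_arr = np.asarray(treatment, dtype=float)
    c_arr = np.asarray(control, dtype=float)
    if t_arr.size < 2 or c_arr.size < 2:
        raise ValueError("need >= 2 values per group for the t-test")
    c_mean = c_arr.mean()
    percent = float(100.0 * t_arr.mean() / c_mean) if c_mean != 0 else None
    t_stat, p = stats.ttest_ind(t_arr, c_arr, equal_var=equal_var)
    if np.isnan(p):  # zero pooled variance: identical constant groups
        p = 1.0 if t_arr.mean() == c_mean else 0.0
        t_stat = 0.0 if p == 1.0 else math.inf
    return KnockdownResult(percent, float(t_stat), float(p))
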