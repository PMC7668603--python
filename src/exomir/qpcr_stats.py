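"""Relative-quantification statistics for qPCR verification.

Expression of each target small RNA is measured relative to a housekeeping
reference assay (RNU1A by default) as dCt = Ct(target) - Ct(reference),
technical replicates averaged first.  Group comparisons run on the dCt
scale with one-way ANOVA; fold changes between conditions are the standard
2^-ddCt with amplification efficiency fixed at 2 (configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_REFERENCE = "RNU1A"


@dataclass
class CtTable:
    """Long-format Ct measurements.

    ``data`` columns: sample_id, group, target_id, ct (one row per
    technical replicate).  The reference target must be present for every
    sample; samples missing it are excluded from dCt with a warning.
    """

    data: pd.DataFrame
    reference_target: str = DEFAULT_REFERENCE

    def __post_init__(self) -> None:
        required = {"sample_id", "group", "target_id", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"CtTable missing columns: {sorted(missing)}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be > 0")

    @classmethod
    def from_tsv(cls, path: str,
                 reference_target: str = DEFAULT_REFERENCE) -> "CtTable":
        return cls(pd.read_csv(str(path), sep="\t"), reference_target)


def delta_ct(t: CtTable) -> pd.DataFrame:
    """Per-sample dCt for every non-reference target.

    Technical replicates are averaged before subtracting the sample's
    reference Ct.  Returns a long frame (sample_id, group, target_id,
    delta_ct); targets not measured in a sample are absent, not zero.
    """
    mean_ct = (t.data.groupby(["sample_id", "group", "target_id"],
                              as_index=False)["ct"].mean())
    ref = mean_ct[mean_ct["target_id"] == t.reference_target]
    ref = ref.set_index("sample_id")["ct"]
    have_ref = set(ref.index)
    dropped = sorted(set(mean_ct["sample_id"]) - have_ref)
    if dropped:
        warnings.warn(f"samples without reference {t.reference_target} "
                      f"excluded: {dropped}")
    out = mean_ct[(mean_ct["target_id"] != t.reference_target)
                  & mean_ct["sample_id"].isin(have_ref)].copy()
    out["delta_ct"] = out["ct"] - out["sample_id"].map(ref)
    return out.drop(columns="ct").reset_index(drop=True)


def relative_fold(dct_control: Sequence[float], dct_treated: Sequence[float],
                  efficiency: float = 2.0) -> float:
    """Fold change of the treated group: efficiency^-(ddCt) with
    ddCt = mean(treated dCt) - mean(control dCt)."""
    c = np.asarray(dct_control, dtype=float)
    e = np.asarray(dct_treated, dtype=float)
    if len(c) == 0 or len(e) == 0:
        raise ValueError("both groups must be non-empty")
    ddct = e.mean() - c.mean()
    return float(efficiency ** (-ddct))


@dataclass
class AnovaResult:
    target_id: str | None
    group_means: dict[str, float]
    f_stat: float
    df_between: int
    df_within: int
    p_value: float


def one_way_anova(groups: dict[str, Sequence[float]] |
                  Sequence[Sequence[float]],
                  target_id: str | None = None) -> AnovaResult:
    """Classic between/within sum-of-squares decomposition.

    With exactly two groups F equals the squared pooled t statistic and the
    p-value matches the two-sided equal-variance t test.
    """
    if isinstance(groups, dict):
        names = list(groups)
        vals = [np.asarray(groups[k], dtype=float) for k in names]
    else:
        vals = [np.asarray(g, dtype=float) for g in groups]
        names = [f"group{i + 1}" for i in range(len(vals))]
    if len(vals) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(v) < 2 for v in vals):
        raise ValueError("every group needs >= 2 values")
    n_total = sum(len(v) for v in vals)
    grand = np.concatenate(vals).mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in vals)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in vals)
    df_b = len(vals) - 1
    df_w = n_total - len(vals)
    if ss_within == 0.0:
        f = 0.0 if ss_between == 0.0 else np.inf
        p = 1.0 if ss_between == 0.0 else 0.0
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(f, df_b, df_w))
    means = {k: float(v.mean()) for k, v in zip(names, vals)}
    return AnovaResult(target_id, means, float(f), df_b, df_w, p)


def standard_error(values: Sequence[float]) -> float:
    """Standard error of the mean, sd / sqrt(n)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need n >= 2")
    return float(v.std(ddof=1) / np.sqrt(len(v)))


def qpcr_report(t: CtTable, efficiency: float = 2.0,
                baseline_group: str | None = None) -> pd.DataFrame:
    """Per-target summary: group dCt means and SEs, fold change vs the
    baseline group (when exactly two groups are present) and the one-way
    ANOVA p-value."""
    dct = delta_ct(t)
    rows = []
    for target, sub in dct.groupby("target_id"):
        groups = {g: s["delta_ct"].values for g, s in sub.groupby("group")}
        usable = {g: v for g, v in groups.items() if len(v) >= 2}
        if len(usable) < 2:
            continue
        res = one_way_anova(usable, target)
        row = {"target_id": target, "f_stat": res.f_stat,
               "p_value": res.p_value}
        for g, v in usable.items():
            row[f"mean_dct_{g}"] = float(np.mean(v))
            row[f"se_dct_{g}"] = standard_error(v)
        if len(usable) == 2:
            names = sorted(usable)
            base = (baseline_group if baseline_group in usable
                    else ("control" if "control" in usable else names[0]))
            other = [g for g in names if g != base][0]
            row["fold_change"] = relative_fold(usable[base], usable[other],
                                               efficiency)
            row["baseline"] = base
        rows.append(row)
    return pd.DataFrame(rows)
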