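"""Wet-lab-facing arithmetic: Livak 2^-ddCt relative quantification and
RNAi bioassay mortality summaries with group comparisons.

The ddCt baseline is the mean dCt of the control group, so the control
group's mean fold change is 1 by construction.  No amplification-efficiency
correction and no Abbott control-mortality correction are applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class QPCRRecord:
    sample_id: str
    condition: str  # "treatment" | "control" (or any two labels)
    target_ct: float
    reference_ct: float


def delta_delta_ct(
    records: list[QPCRRecord], control_label: str = "control"
) -> pd.DataFrame:
    """Per-replicate ddCt and fold = 2^-ddCt.

    dCt = target Ct - reference Ct per sample; ddCt subtracts the mean dCt
    of the control group.  Returns one row per sample with the fold and its
    log2 (= -ddCt); group mean/sd are obtained by grouping the result.
    """
    if not records:
        raise ValueError("no qPCR records")
    for r in records:
        if not np.isfinite(r.reference_ct):
            raise ValueError(f"missing reference Ct for sample {r.sample_id}")
        if not np.isfinite(r.target_ct):
            raise ValueError(f"missing target Ct for sample {r.sample_id}")
    conditions = {r.condition for r in records}
    if control_label not in conditions:
        raise ValueError(f"no {control_label!r} replicates present")
    if len(conditions) < 2:
        raise ValueError("need >= 1 control and >= 1 treatment replicate")

    dct = {r.sample_id: r.target_ct - r.reference_ct for r in records}
    control_mean_dct = float(
        np.mean([dct[r.sample_id] for r in records if r.condition == control_label])
    )
    rows = []
    for r in records:
        ddct = dct[r.sample_id] - control_mean_dct
        rows.append(
            {
                "sample_id": r.sample_id,
                "condition": r.condition,
                "delta_ct": dct[r.sample_id],
                "delta_delta_ct": ddct,
                "fold": 2.0 ** (-ddct),
                "log2_fold": -ddct,
            }
        )
    return pd.DataFrame(rows)


def qpcr_group_summary(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Group mean +/- sd of the per-replicate folds (linear and log2)."""
    return (
        per_replicate.groupby("condition")
        .agg(
            n=("fold", "size"),
            mean_fold=("fold", "mean"),
            sd_fold=("fold", "std"),
            mean_log2_fold=("log2_fold", "mean"),
            sd_log2_fold=("log2_fold", "std"),
        )
        .reset_index()
    )


def read_ct_table(path) -> list[QPCRRecord]:
    """TSV columns: sample, group, target_ct, reference_ct."""
    df = pd.read_csv(path, sep="\t")
    return [
        QPCRRecord(
            sample_id=str(row["sample"]),
            condition=str(row["group"]),
            target_ct=float(row["target_ct"]),
            reference_ct=float(row["reference_ct"]),
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Bioassay

@dataclass
class BioassayGroup:
    label: str
    replicates: list[tuple[int, int]]  # (n_treated, n_dead)

    def __post_init__(self) -> None:
        for n, d in self.replicates:
            if n < 1 or d < 0 or d > n:
                raise ValueError(
                    f"{self.label}: invalid replicate counts ({n} treated, {d} dead)"
                )


def mortality(group: BioassayGroup) -> tuple[np.ndarray, float]:
    """Percent mortality per replicate and the group mean over replicates."""
    per_rep = np.array([100.0 * d / n for n, d in group.replicates])
    return per_rep, float(per_rep.mean())


def read_bioassay_table(path) -> dict[tuple[str, int], BioassayGroup]:
    """TSV columns: group, replicate, day, n_treated, n_dead.

    Returns groups keyed by (group label, day).
    """
    df = pd.read_csv(path, sep="\t")
    out: dict[tuple[str, int], BioassayGroup] = {}
    for (label, day), sub in df.groupby(["group", "day"]):
        out[(str(label), int(day))] = BioassayGroup(
            label=str(label),
            replicates=[
                (int(r["n_treated"]), int(r["n_dead"])) for _, r in sub.iterrows()
            ],
        )
    return out


# ---------------------------------------------------------------------------
# Group comparisons

def compare_groups(*groups: np.ndarray, method: str = "welch_t") -> dict:
    """Welch's t for two groups, or one-way ANOVA with Tukey HSD pairwise
    p-values for two or more groups.

    Returns ``{"p": float}`` for Welch, and
    ``{"p": F-test p, "F": statistic, "tukey": {(i, j): p}}`` for ANOVA.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs >= 2 replicates")
    if method == "welch_t":
        if len(arrays) != 2:
            raise ValueError("welch_t compares exactly two groups")
        a, b = arrays
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            return {"p": 1.0 if a.mean() == b.mean() else 0.0}
        return {"p": float(stats.ttest_ind(a, b, equal_var=False).pvalue)}
    if method == "anova_tukey":
        f_res = stats.f_oneway(*arrays)
        tukey = stats.tukey_hsd(*arrays)
        pairwise = {
            (i, j): float(tukey.pvalue[i, j])
            for i in range(len(arrays))
            for j in range(i + 1, len(arrays))
        }
        return {"p": float(f_res.pvalue), "F": float(f_res.statistic),
                "tukey": pairwise}
    raise ValueError(f"unknown method {method!r}")
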