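"""FPKM normalization and differential-expression calling.

Expression is summarized as FPKM (fragments per kilobase of transcript per
million mapped fragments).  Transcripts with FPKM = 0 in every library are
pruned before testing.  Differences between the two conditions are tested
with Welch's t-test on log2(FPKM + pseudocount), p-values are adjusted by
Benjamini-Hochberg, and a transcript is called differentially expressed
when |log2FC| >= 1, p < .01 and q < .01 (all thresholds configurable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CONDITIONS = ("S", "R")


@dataclass
class ExpressionMatrix:
    """Transcript x sample raw counts with condition labels and the
    quantities needed for FPKM."""

    counts: pd.DataFrame  # transcripts x samples, non-negative
    conditions: dict[str, str]  # sample -> condition label
    lengths: pd.Series  # effective length (bp) per transcript
    library_sizes: pd.Series  # mapped fragments per sample
    fpkm: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if set(self.counts.columns) != set(self.conditions):
            raise ValueError("condition map does not match count columns")
        if not set(self.counts.index) <= set(self.lengths.index):
            raise ValueError("missing effective lengths for some transcripts")
        if set(self.counts.columns) != set(self.library_sizes.index):
            raise ValueError("missing library sizes for some samples")
        if (self.counts.values < 0).any() or not np.isfinite(
            self.counts.values
        ).all():
            raise ValueError("counts must be finite and non-negative")

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]

    def with_fpkm(self) -> "ExpressionMatrix":
        self.fpkm = compute_fpkm(
            self.counts,
            self.lengths.loc[self.counts.index],
            self.library_sizes.loc[self.counts.columns],
        )
        return self

    @classmethod
    def from_tsv(
        cls,
        counts_path,
        design_path,
        lengths: pd.Series,
        library_sizes: pd.Series | None = None,
    ) -> "ExpressionMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        design = pd.read_csv(design_path, sep="\t")
        conditions = dict(zip(design["sample"], design["condition"]))
        if library_sizes is None:
            if "library_size" in design.columns:
                library_sizes = pd.Series(
                    design["library_size"].values, index=design["sample"].values
                )
            else:
                library_sizes = counts.sum(axis=0)
        return cls(counts, conditions, lengths, library_sizes)


def compute_fpkm(
    counts: pd.DataFrame, lengths: pd.Series, library_sizes: pd.Series
) -> pd.DataFrame:
    """``fpkm = count * 1e9 / (length_bp * library_size)``."""
    lengths = lengths.loc[counts.index]
    library_sizes = library_sizes.loc[counts.columns]
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be > 0")
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be > 0")
    return (
        counts.astype(float) * 1e9
    ).div(lengths.values, axis=0).div(library_sizes.values, axis=1)


def prune_all_zero(fpkm: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop transcripts with FPKM exactly 0 in every sample."""
    mask = (fpkm == 0).all(axis=1)
    return fpkm.loc[~mask], fpkm.index[mask].tolist()


def log2_fold_change(
    mean_a: float | np.ndarray,
    mean_b: float | np.ndarray,
    pseudocount: float = 0.1,
):
    """``log2((mean_b + pc) / (mean_a + pc))`` — positive when b > a."""
    mean_a = np.asarray(mean_a, dtype=float)
    mean_b = np.asarray(mean_b, dtype=float)
    if (mean_a < 0).any() or (mean_b < 0).any():
        raise ValueError("means must be non-negative")
    out = np.log2(mean_b + pseudocount) - np.log2(mean_a + pseudocount)
    return out if out.ndim else float(out)


def welch_t_test(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Two-sided Welch p-value; 1.0 for two degenerate equal groups."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in test input")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def _welch_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized two-sided Welch p-values per row; degenerate rows with
    equal means get p = 1 (both-zero-variance convention)."""
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    degenerate = (va == 0) & (vb == 0)
    p[degenerate & (a.mean(axis=1) == b.mean(axis=1))] = 1.0
    p[degenerate & (a.mean(axis=1) != b.mean(axis=1))] = 0.0
    return p


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior for variance moderation.

    Models log sample variances as log s0^2 + log F(df, d0); returns
    (prior variance s0^2, prior df d0), with d0 = inf when the observed
    spread of log variances is no larger than expected from chi^2 noise
    alone.
    """
    from scipy.special import digamma, polygamma
    from scipy.optimize import brentq

    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 10:  # too few informative rows to estimate a prior
        return float(np.median(s2[ok])) if ok.any() else 1.0, np.inf
    z = np.log(s2[ok])
    e_mean = z.mean() - digamma(df / 2.0) + math.log(df / 2.0)
    e_var = z.var(ddof=1) - float(polygamma(1, df / 2.0))
    if e_var <= 0:
        return float(math.exp(e_mean)), np.inf

    def f(d0):
        return float(polygamma(1, d0 / 2.0)) - e_var

    # trigamma is decreasing; bracket d0 in (tiny, huge)
    lo, hi = 1e-3, 1e7
    if f(lo) < 0:
        return float(math.exp(e_mean)), np.inf
    if f(hi) > 0:
        d0 = hi
    else:
        d0 = brentq(f, lo, hi)
    s0_sq = math.exp(e_mean + digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return float(s0_sq), float(d0)


def moderated_t_test(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Row-wise two-sample t-test with empirical-Bayes variance moderation.

    Per-row pooled variances are shrunk toward a prior estimated from all
    rows (scaled-F model, method of moments), and the t statistic is
    referred to a t distribution with the augmented degrees of freedom
    ``d + d0``.  With a handful of replicates per group this restores the
    power that a per-row test loses to its tiny df, while keeping the
    type-I rate near nominal.  Returns (p-values, prior df d0, prior
    variance s0^2).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.shape[1], b.shape[1]
    df = na + nb - 2
    if df < 1:
        raise ValueError("need >= 2 replicates per group")
    ss_a = a.var(axis=1, ddof=1) * (na - 1)
    ss_b = b.var(axis=1, ddof=1) * (nb - 1)
    s2 = (ss_a + ss_b) / df
    s0_sq, d0 = _fit_f_dist(s2, df)
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_post = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_post = d0 + df
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    t = (b.mean(axis=1) - a.mean(axis=1)) / se
    if math.isinf(df_post):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_post)
    return p, d0, s0_sq


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEThresholds:
    lfc: float = 1.0
    p: float = 0.01
    q: float = 0.01


def call_de(
    matrix: ExpressionMatrix,
    thresholds: DEThresholds | None = None,
    pseudocount: float = 0.1,
    condition_a: str = "S",
    condition_b: str = "R",
    method: str = "moderated",
) -> pd.DataFrame:
    """Prune, compute fold changes, test, adjust, and call DE.

    Returns a per-transcript table with mean FPKM per condition, log2 fold
    change in both orientations, p, q, and a ``call`` column in
    ``{up_in_R, up_in_S, not_DE, pruned_all_zero}`` (labels follow the
    condition names given).  A call is made only when |log2FC| >= lfc,
    p < p-threshold and q < q-threshold simultaneously.

    ``method`` selects the per-transcript test on log2(FPKM + pseudocount):
    ``"moderated"`` (default) shares variance information across
    transcripts, which is essential for q < .01 calling at 3 replicates
    per condition; ``"welch"`` is the plain per-transcript Welch t-test.
    """
    thresholds = thresholds or DEThresholds()
    if matrix.fpkm is None:
        matrix.with_fpkm()
    fpkm, pruned = prune_all_zero(matrix.fpkm)

    a_samples = matrix.samples_of(condition_a)
    b_samples = matrix.samples_of(condition_b)
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValueError("need >= 2 replicates per condition for testing")

    mean_a = fpkm[a_samples].mean(axis=1).values
    mean_b = fpkm[b_samples].mean(axis=1).values
    lfc_b_vs_a = log2_fold_change(mean_a, mean_b, pseudocount)

    log_a = np.log2(fpkm[a_samples].values + pseudocount)
    log_b = np.log2(fpkm[b_samples].values + pseudocount)
    if method == "moderated":
        p, _, _ = moderated_t_test(log_a, log_b)
    elif method == "welch":
        p = _welch_rows(log_a, log_b)
    else:
        raise ValueError(f"unknown DE test method {method!r}")
    q = bh_fdr(p)

    sig = (np.abs(lfc_b_vs_a) >= thresholds.lfc) & (p < thresholds.p) & (
        q < thresholds.q
    )
    # a zero fold change can only be significant in the degenerate
    # lfc-threshold-0 limit; it is labeled toward condition_b by convention
    call = np.where(
        sig & (lfc_b_vs_a >= 0),
        f"up_in_{condition_b}",
        np.where(sig & (lfc_b_vs_a < 0), f"up_in_{condition_a}", "not_DE"),
    )

    table = pd.DataFrame(
        {
            "transcript_id": fpkm.index,
            f"mean_fpkm_{condition_a}": mean_a,
            f"mean_fpkm_{condition_b}": mean_b,
            f"log2fc_{condition_b}_vs_{condition_a}": lfc_b_vs_a,
            f"log2fc_{condition_a}_vs_{condition_b}": -lfc_b_vs_a,
            "p_value": p,
            "q_value": q,
            "call": call,
        }
    )
    if pruned:
        pruned_rows = pd.DataFrame(
            {
                "transcript_id": pruned,
                f"mean_fpkm_{condition_a}": 0.0,
                f"mean_fpkm_{condition_b}": 0.0,
                f"log2fc_{condition_b}_vs_{condition_a}": np.nan,
                f"log2fc_{condition_a}_vs_{condition_b}": np.nan,
                "p_value": np.nan,
                "q_value": np.nan,
                "call": "pruned_all_zero",
            }
        )
        table = pd.concat([table, pruned_rows], ignore_index=True)
    return table


def volcano_table(de_table: pd.DataFrame, path=None) -> pd.DataFrame:
    """Volcano-plot-ready export: log2FC vs -log10(p), with the DE call."""
    lfc_col = next(c for c in de_table.columns if c.startswith("log2fc_R_vs")
                   ) if any(c.startswith("log2fc_R_vs") for c in de_table.columns
                            ) else de_table.columns[3]
    out = de_table[de_table["call"] != "pruned_all_zero"][
        ["transcript_id", lfc_col, "p_value", "q_value", "call"]
    ].copy()
    out["neg_log10_p"] = -np.log10(out["p_value"])
    if path is not None:
        out.to_csv(path, sep="\t", index=False)
    return out
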