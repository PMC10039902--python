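"""Global, context- and CNV-state-stratified methylation plus cohort statistics.

Global methylation is quantified per sample as the mean beta over probes
outside CpG islands (CpG-dense island probes are excluded from global
quantifications by default); context means restrict to islands, gene
bodies or promoters.  Per-sample CNV-state means let each probe inherit
the state of its covering copy segment, quantifying the pronounced
hypomethylation of gained regions.

Cross-group statistics follow the conventions of clinical methylation
studies: Pearson chi-squared without continuity correction for
categorical contrasts (p reported at full precision and rounded to three
decimals), the Games-Howell post-hoc test (Welch t with
studentized-range reference distribution) for group means under unequal
variances, and the Pearson correlation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


def _stratum_mean(beta: pd.DataFrame, mask: np.ndarray) -> pd.Series:
    if mask.sum() == 0:
        return pd.Series(np.nan, index=beta.columns)
    return beta.loc[mask].mean(axis=0)


def global_methylation(beta: pd.DataFrame, annotation: pd.DataFrame,
                       exclude_cgi: bool = True) -> pd.Series:
    """Per-sample mean beta, excluding CpG-island probes by default."""
    ann = annotation.loc[beta.index]
    mask = (ann["cgi_relation"] != "island").to_numpy() if exclude_cgi else np.ones(len(beta), dtype=bool)
    if mask.sum() == 0:
        raise ValueError("no eligible probes for global methylation")
    return _stratum_mean(beta, mask).rename("mean_beta_global")


def context_methylation(beta: pd.DataFrame, annotation: pd.DataFrame, context: str) -> pd.Series:
    """Per-sample mean beta within one context stratum.

    ``context`` is ``island`` (CGI probes), ``body`` or ``promoter``
    (gene-region strata).  An empty stratum yields NaN (flagged
    missing), never 0.
    """
    ann = annotation.loc[beta.index]
    if context == "island":
        mask = (ann["cgi_relation"] == "island").to_numpy()
    elif context in ("body", "promoter"):
        mask = (ann["region"] == context).to_numpy()
    else:
        raise ValueError("context must be one of: island, body, promoter")
    return _stratum_mean(beta, mask).rename(f"mean_beta_{context}")


def probe_states_from_segments(annotation: pd.DataFrame, segments: pd.DataFrame) -> pd.Series:
    """Map every annotated probe to the state of its covering segment.

    ``segments`` are one sample's called segments (0-based half-open);
    they must cover every probe of every chromosome they appear on, and
    every probe's chromosome must appear.  Raises on an uncovered probe.
    """
    states = pd.Series(index=annotation.index, dtype=object)
    for chrom, sub in annotation.groupby("chrom", sort=False, observed=True):
        segs = segments[segments["chrom"] == chrom].sort_values("start")
        pos0 = sub["pos"].to_numpy() - 1  # 0-based probe coordinate
        if segs.empty:
            raise ValueError(f"no segments cover chromosome {chrom}")
        idx = np.searchsorted(segs["end"].to_numpy(), pos0, side="right")
        if (idx >= len(segs)).any() or (pos0 < segs["start"].to_numpy()[np.minimum(idx, len(segs) - 1)]).any():
            raise ValueError(f"probe outside all segments on {chrom}")
        states.loc[sub.index] = segs["state"].to_numpy()[idx]
    return states.rename("state")


def methylation_by_cnv_state(beta_sample: pd.Series, segments: pd.DataFrame,
                             annotation: pd.DataFrame, exclude_cgi: bool = True) -> dict:
    """Mean beta of one sample within gained / balanced / lost regions.

    Each probe inherits the state of its covering segment; the CGI
    exclusion switch matches the global quantification.  A state with no
    probes yields NaN.
    """
    ann = annotation.loc[beta_sample.index]
    states = probe_states_from_segments(ann, segments).to_numpy()
    eligible = (ann["cgi_relation"] != "island").to_numpy() if exclude_cgi else np.ones(len(ann), dtype=bool)
    values = beta_sample.to_numpy(dtype=float)
    out = {}
    for state in ("gain", "balanced", "loss"):
        mask = eligible & (states == state)
        out[f"mean_{state}"] = float(values[mask].mean()) if mask.any() else np.nan
        out[f"n_{state}"] = int(mask.sum())
    return out


def sample_methylation_summary(beta: pd.DataFrame, annotation: pd.DataFrame,
                               segments: pd.DataFrame | None = None,
                               exclude_cgi: bool = True) -> pd.DataFrame:
    """Per-sample methylation summary over all strata.

    Columns: global (outside-CGI) mean, island / body / promoter means,
    per-stratum probe counts, and — when a cohort segment table is
    supplied — per-CNV-state means.  The CGI-exclusion switch used for
    the global and CNV-state means is recorded in ``attrs``.
    """
    ann = annotation.loc[beta.index]
    summary = pd.DataFrame(index=beta.columns)
    summary["mean_beta_global"] = global_methylation(beta, ann, exclude_cgi=exclude_cgi)
    summary["n_global"] = int((ann["cgi_relation"] != "island").sum()) if exclude_cgi else len(ann)
    for context in ("island", "body", "promoter"):
        summary[f"mean_beta_{context}"] = context_methylation(beta, ann, context)
        if context == "island":
            summary["n_island"] = int((ann["cgi_relation"] == "island").sum())
        else:
            summary[f"n_{context}"] = int((ann["region"] == context).sum())
    if segments is not None:
        for sample in beta.columns:
            by_state = methylation_by_cnv_state(
                beta[sample], segments[segments["sample_id"] == sample], ann, exclude_cgi=exclude_cgi
            )
            for key, value in by_state.items():
                summary.loc[sample, f"{key.replace('mean_', 'mean_beta_')}"] = value
    summary.attrs["exclude_cgi"] = exclude_cgi
    return summary


# ---------------------------------------------------------------------------
# cohort statistics

def pearson_r(x, y) -> float:
    """Pearson correlation coefficient (lengths >= 3, nonzero variances)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must share length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class ChiSquaredResult:
    statistic: float
    df: int
    p: float

    @property
    def p_rounded(self) -> float:
        """p rounded to three decimal places (the reporting convention)."""
        return round(self.p, 3)


def chi_squared_test(table) -> ChiSquaredResult:
    """Pearson chi-squared on a contingency table of counts.

    No continuity correction; df = (r-1)(c-1); upper-tail p.  Raises on
    negative counts or a zero row/column marginal.
    """
    table = np.asarray(table, dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    res = stats.chi2_contingency(table, correction=False)
    return ChiSquaredResult(statistic=float(res.statistic), df=int(res.dof), p=float(res.pvalue))


def games_howell(groups: list, labels: list[str] | None = None) -> pd.DataFrame:
    """Games-Howell pairwise comparisons for k groups with unequal variances.

    For each pair: ``t = (mean2 - mean1) / sqrt(s1^2/n1 + s2^2/n2)`` with
    Welch-Satterthwaite degrees of freedom; the p-value is the upper tail
    of the studentized-range distribution with k groups evaluated at
    ``q = |t| * sqrt(2)``.  Each group needs n >= 2 and nonzero variance.
    """
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if len(g) < 2:
            raise ValueError("every group needs at least two observations")
        if np.var(g, ddof=1) == 0:
            raise ValueError("zero-variance group")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(arrays))]
    k = len(arrays)
    rows = []
    for i, j in combinations(range(k), 2):
        a, b = arrays[i], arrays[j]
        n1, n2 = len(a), len(b)
        v1, v2 = np.var(a, ddof=1), np.var(b, ddof=1)
        se2 = v1 / n1 + v2 / n2
        diff = b.mean() - a.mean()
        t = diff / np.sqrt(se2)
        df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = float(np.clip(stats.studentized_range.sf(abs(t) * np.sqrt(2), k, df), 0.0, 1.0))
        rows.append(
            {"group1": labels[i], "group2": labels[j], "mean_diff": float(diff),
             "t": float(t), "df": float(df), "p": p, "p_rounded": round(p, 3)}
        )
    return pd.DataFrame(rows)
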