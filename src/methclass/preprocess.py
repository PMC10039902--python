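"""Probe-level preparation of beta-value matrices.

Beta matrices are probes x samples DataFrames of methylation fractions
in [0, 1] (the field convention and the on-disk layout); the sklearn
estimator :class:`ProbeFilter` follows the sklearn samples x features
orientation instead.  Raw-intensity normalization (background and
dye-bias correction) is upstream of this package: the pipeline ingests
normalized betas.

Filtering removes probes that cannot be compared across samples or
sexes: sex-chromosome probes, SNP-overlapping probes, cross-reactive
("multi hit") probes and probes that could not be uniquely mapped.
Probes failing several rules are attributed to the first matching rule
(fixed order) for reporting; the removal outcome is order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from methclass.annotation import SEX_CHROMOSOMES

#: reporting order for probes failing several rules
FILTER_RULES = ("sex_chromosome", "snp_overlap", "multi_hit", "non_unique")


@dataclass
class FilterReport:
    """Per-rule removal counts; removed + retained sums to the input count."""

    removed: dict[str, int] = field(default_factory=dict)
    retained: int = 0

    @property
    def total_removed(self) -> int:
        return sum(self.removed.values())


def _validate_beta(beta: pd.DataFrame) -> None:
    if beta.index.has_duplicates:
        raise ValueError("duplicated probe ids in beta matrix")
    if beta.columns.has_duplicates:
        raise ValueError("duplicated sample ids in beta matrix")
    values = beta.to_numpy(dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("beta values must lie in [0, 1]")


def merge_platforms(beta_a: pd.DataFrame, beta_b: pd.DataFrame) -> pd.DataFrame:
    """Merge two platforms on the intersection of their probe sets.

    Returns a matrix over the common probes (in ``beta_a``'s row order)
    carrying all samples from both inputs.  Raises if the probe
    intersection is empty or any sample id appears in both inputs.
    """
    _validate_beta(beta_a)
    _validate_beta(beta_b)
    shared_samples = beta_a.columns.intersection(beta_b.columns)
    if len(shared_samples):
        raise ValueError(f"sample ids present on both platforms: {list(shared_samples[:5])}")
    common = beta_a.index.intersection(beta_b.index, sort=False)
    if common.empty:
        raise ValueError("platforms share no probes")
    return pd.concat([beta_a.loc[common], beta_b.loc[common]], axis=1)


def filter_probes(beta: pd.DataFrame, annotation: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Remove sex-chromosome and flagged probes; return matrix + report."""
    missing = beta.index.difference(annotation.index)
    if not missing.empty:
        raise ValueError(f"probes without annotation: {list(missing[:5])}")
    ann = annotation.loc[beta.index]
    rule_masks = {
        "sex_chromosome": ann["chrom"].isin(SEX_CHROMOSOMES).to_numpy(),
        "snp_overlap": ann["snp_overlap"].to_numpy(),
        "multi_hit": ann["multi_hit"].to_numpy(),
        "non_unique": ann["non_unique"].to_numpy(),
    }
    removed = np.zeros(len(beta), dtype=bool)
    report = FilterReport()
    for rule in FILTER_RULES:
        newly = rule_masks[rule] & ~removed
        report.removed[rule] = int(newly.sum())
        removed |= rule_masks[rule]
    report.retained = int((~removed).sum())
    return beta.loc[~removed], report


def drop_incomplete_probes(beta: pd.DataFrame, max_missing_rate: float = 0.0) -> pd.DataFrame:
    """Drop probes whose missing-value rate exceeds ``max_missing_rate``.

    Variance ranking and per-probe t-statistics need complete rows, so
    the default drops any probe with a missing value.
    """
    if not 0 <= max_missing_rate <= 1:
        raise ValueError("max_missing_rate must lie in [0, 1]")
    rates = beta.isna().mean(axis=1)
    return beta.loc[rates <= max_missing_rate]


def beta_to_m(beta, offset: float = 1e-6):
    """Logit2 transform: M = log2((beta + offset) / (1 - beta + offset)).

    The offset guards betas of exactly 0 or 1; :func:`m_to_beta` inverts
    the transform exactly (up to float precision).
    """
    if offset <= 0:
        raise ValueError("offset must be positive")
    values = np.asarray(beta, dtype=float) if not isinstance(beta, (pd.DataFrame, pd.Series)) else beta
    return np.log2((values + offset) / (1 - values + offset))


def m_to_beta(m, offset: float = 1e-6):
    """Inverse of :func:`beta_to_m`."""
    if offset <= 0:
        raise ValueError("offset must be positive")
    r = np.power(2.0, np.asarray(m, dtype=float) if not isinstance(m, (pd.DataFrame, pd.Series)) else m)
    return (r * (1 + offset) - offset) / (1 + r)


class ProbeFilter(BaseEstimator, TransformerMixin):
    """Sklearn transformer dropping sex-chromosome and flagged probes.

    Operates on samples x probes input (probe ids as DataFrame columns).
    Fitted attributes: ``retained_probe_ids_`` and ``report_``.
    """

    def __init__(self, annotation: pd.DataFrame | None = None):
        self.annotation = annotation

    def fit(self, X: pd.DataFrame, y=None):
        if self.annotation is None:
            raise ValueError("ProbeFilter requires an annotation frame")
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a samples x probes DataFrame with probe-id columns")
        filtered, report = filter_probes(X.T, self.annotation)
        self.retained_probe_ids_ = filtered.index.to_numpy()
        self.report_ = report
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "retained_probe_ids_"):
            raise ValueError("ProbeFilter is not fitted")
        return X[list(self.retained_probe_ids_)]
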