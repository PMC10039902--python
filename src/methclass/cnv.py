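"""Copy-number inference from array intensity and genomic-index scoring.

Per-probe log2 copy ratios are computed against the per-probe median of
an explicit reference panel and median-centered per sample.  Segments
are found by recursive binary segmentation: at each step the candidate
split maximizing the two-sample Welch t statistic is accepted iff the
mean difference exceeds ``min_delta`` AND the split p-value (t
distribution, Bonferroni-corrected over candidate positions) is below
``alpha`` AND both children retain ``min_probes`` probes.  Segment
states are called against fixed log2 thresholds (+0.1 gain / -0.1 loss,
strict exceedance: boundary values are balanced).

The genomic index summarizes chromosomal complexity:
``GI = A^2 / C`` where A is the number of gained+lost segments and C
the number of distinct chromosomes carrying them; a fully balanced
genome scores 0.  Coordinates are 0-based half-open internally; the SEG
writer converts to that format's 1-based inclusive convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "n_probes", "mean_log2"]

GAIN_THRESHOLD = 0.1
LOSS_THRESHOLD = -0.1


# ---------------------------------------------------------------------------
# log2 ratios

def probe_log2_ratios(sample_intensity: pd.Series, reference_panel: pd.DataFrame) -> pd.Series:
    """log2(sample / per-probe median of reference panel), median-centered.

    ``sample_intensity`` and ``reference_panel`` are linear-scale total
    intensities over the same probes; at least 3 reference samples are
    required and all intensities must be positive.
    """
    if reference_panel.shape[1] < 3:
        raise ValueError("reference panel needs at least 3 samples")
    if not sample_intensity.index.equals(reference_panel.index):
        reference_panel = reference_panel.reindex(sample_intensity.index)
        if reference_panel.isna().any().any():
            raise ValueError("sample and reference panel must share probes")
    sample = sample_intensity.to_numpy(dtype=float)
    ref = reference_panel.to_numpy(dtype=float)
    if (sample <= 0).any() or (ref <= 0).any():
        raise ValueError("intensities must be positive")
    ratios = np.log2(sample / np.median(ref, axis=1))
    ratios -= np.median(ratios)
    return pd.Series(ratios, index=sample_intensity.index, name=sample_intensity.name)


def cohort_log2_ratios(intensity: pd.DataFrame, reference_panel: pd.DataFrame) -> pd.DataFrame:
    """Per-probe log2 ratios for every sample column of ``intensity``."""
    return pd.DataFrame(
        {s: probe_log2_ratios(intensity[s], reference_panel) for s in intensity.columns}
    )


# ---------------------------------------------------------------------------
# recursive binary segmentation

def _welch_split_scan(values, lo, hi, min_probes):
    """Welch t statistic for every admissible split of values[lo:hi].

    Returns (split_positions, t, delta, df) arrays; empty when the
    window admits no split with both children >= min_probes.
    """
    v = values[lo:hi]
    n = len(v)
    ks = np.arange(min_probes, n - min_probes + 1)
    if len(ks) == 0:
        return ks, ks.astype(float), ks.astype(float), ks.astype(float)
    cs = np.cumsum(v)
    css = np.cumsum(v * v)
    n1 = ks.astype(float)
    n2 = n - n1
    s1, s2 = cs[ks - 1], cs[-1] - cs[ks - 1]
    q1, q2 = css[ks - 1], css[-1] - css[ks - 1]
    m1, m2 = s1 / n1, s2 / n2
    var1 = np.maximum(q1 - n1 * m1 * m1, 0.0) / np.maximum(n1 - 1, 1)
    var2 = np.maximum(q2 - n2 * m2 * m2, 0.0) / np.maximum(n2 - 1, 1)
    delta = m2 - m1
    se2 = var1 / n1 + var2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se2 > 0, delta / np.sqrt(se2), np.where(delta == 0, 0.0, np.inf * np.sign(delta)))
        df_num = se2 * se2
        df_den = (var1 / n1) ** 2 / np.maximum(n1 - 1, 1) + (var2 / n2) ** 2 / np.maximum(n2 - 1, 1)
        df = np.where(df_den > 0, df_num / df_den, n - 2)
    return lo + ks, t, delta, df


def _segment_one_chromosome(values, min_probes, min_delta, alpha):
    """Breakpoint indices (within the chromosome) by recursive splitting."""
    breaks: list[int] = []

    def recurse(lo, hi):
        ks, t, delta, df = _welch_split_scan(values, lo, hi, min_probes)
        if len(ks) == 0:
            return
        best = int(np.argmax(np.abs(t)))
        t_best = abs(t[best])
        if not np.isfinite(t_best):
            p = 0.0
        else:
            p = 2.0 * stats.t.sf(t_best, df[best]) * len(ks)
        if abs(delta[best]) >= min_delta and p < alpha:
            k = int(ks[best])
            breaks.append(k)
            recurse(lo, k)
            recurse(k, hi)

    recurse(0, len(values))
    return sorted(breaks)


def segment_log2(ratios: pd.Series, annotation: pd.DataFrame, *,
                 min_probes: int = 5, min_delta: float = 0.1,
                 alpha: float = 0.01, sample_id: str | None = None) -> pd.DataFrame:
    """Segment one sample's log2 ratios per chromosome (states unset).

    ``ratios`` is indexed by probe id; ``annotation`` supplies ``chrom``
    and ``pos``.  Positions must be sorted within each chromosome.
    Returns a frame with columns ``sample_id, chrom, start, end,
    n_probes, mean_log2`` where segments of one chromosome partition its
    probes in order.
    """
    ann = annotation.loc[ratios.index]
    if sample_id is None:
        sample_id = str(ratios.name) if ratios.name is not None else "sample"
    rows = []
    for chrom, sub in ann.groupby("chrom", sort=False, observed=True):
        pos = sub["pos"].to_numpy()
        if not np.all(np.diff(pos) > 0):
            raise ValueError(f"probe positions unsorted on {chrom}")
        values = ratios.loc[sub.index].to_numpy(dtype=float)
        breaks = _segment_one_chromosome(values, min_probes, min_delta, alpha)
        bounds = [0, *breaks, len(values)]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            rows.append(
                {
                    "sample_id": sample_id,
                    "chrom": chrom,
                    "start": int(pos[lo] - 1),
                    "end": int(pos[hi - 1]),
                    "n_probes": hi - lo,
                    "mean_log2": float(values[lo:hi].mean()),
                }
            )
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def call_segment_states(segments: pd.DataFrame, gain_thr: float = GAIN_THRESHOLD,
                        loss_thr: float = LOSS_THRESHOLD) -> pd.DataFrame:
    """Attach gain/loss/balanced states (strict exceedance of thresholds)."""
    if not gain_thr > 0 > loss_thr:
        raise ValueError("thresholds must satisfy gain_thr > 0 > loss_thr")
    out = segments.copy()
    mean = out["mean_log2"].to_numpy(dtype=float)
    out["state"] = np.where(mean > gain_thr, "gain", np.where(mean < loss_thr, "loss", "balanced"))
    return out


def segment_cohort(ratios: pd.DataFrame, annotation: pd.DataFrame, *,
                   min_probes: int = 5, min_delta: float = 0.1, alpha: float = 0.01,
                   gain_thr: float = GAIN_THRESHOLD, loss_thr: float = LOSS_THRESHOLD) -> pd.DataFrame:
    """Segment every sample column and call states; one stacked frame."""
    parts = [
        segment_log2(ratios[s], annotation, min_probes=min_probes,
                     min_delta=min_delta, alpha=alpha, sample_id=s)
        for s in ratios.columns
    ]
    return call_segment_states(pd.concat(parts, ignore_index=True), gain_thr, loss_thr)


# ---------------------------------------------------------------------------
# genomic index

def genomic_index(segments: pd.DataFrame) -> dict:
    """Genomic index of one sample: GI = A^2 / C.

    A = number of segments with state gain or loss, C = number of
    distinct chromosomes carrying them; GI = 0 (with C = 0) when A = 0.
    """
    if "state" not in segments.columns:
        raise ValueError("segments need called states; run call_segment_states first")
    altered = segments[segments["state"] != "balanced"]
    a = len(altered)
    c = altered["chrom"].nunique()
    return {
        "n_altered_segments": a,
        "n_involved_chromosomes": c,
        "genomic_index": (a * a / c) if a else 0.0,
    }


def cohort_genomic_index(segments: pd.DataFrame) -> pd.DataFrame:
    """Genomic-index record per sample (index: sample_id)."""
    records = {
        sample: genomic_index(sub)
        for sample, sub in segments.groupby("sample_id", sort=False)
    }
    return pd.DataFrame.from_dict(records, orient="index").rename_axis("sample_id")


# ---------------------------------------------------------------------------
# cohort summaries

def cohort_cnv_frequency(segments: pd.DataFrame, bin_size: int,
                         chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Per-bin fraction of samples with a gain / with a loss.

    The genome is tiled with ``bin_size`` bins per chromosome; a sample
    counts once per bin and direction if any overlapping segment carries
    that state.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    samples = segments["sample_id"].unique()
    if len(samples) == 0:
        raise ValueError("no samples in segment table")
    if chrom_sizes is None:
        chrom_sizes = segments.groupby("chrom", sort=False)["end"].max().to_dict()
    rows = []
    for chrom, size in chrom_sizes.items():
        edges = np.arange(0, size + bin_size, bin_size)
        n_bins = len(edges) - 1
        gain = np.zeros(n_bins)
        loss = np.zeros(n_bins)
        sub = segments[(segments["chrom"] == chrom) & (segments["state"] != "balanced")]
        for sample in samples:
            ssub = sub[sub["sample_id"] == sample]
            for direction, acc in (("gain", gain), ("loss", loss)):
                hit = np.zeros(n_bins, dtype=bool)
                for _, seg in ssub[ssub["state"] == direction].iterrows():
                    first = int(seg["start"] // bin_size)
                    last = int(min((seg["end"] - 1) // bin_size, n_bins - 1))
                    hit[first:last + 1] = True
                acc += hit
        for b in range(n_bins):
            rows.append(
                {"chrom": chrom, "start": int(edges[b]), "end": int(min(edges[b + 1], size)),
                 "gain_fraction": gain[b] / len(samples), "loss_fraction": loss[b] / len(samples)}
            )
    return pd.DataFrame(rows)


def detect_focal_events(segments: pd.DataFrame, amp_thr: float = 1.0,
                        del_thr: float = -1.0, max_len: int = 1_000_000,
                        gene_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Focal high-level events: short segments beyond amplification /
    deep-deletion thresholds.

    ``amp_thr`` must exceed the gain threshold and ``del_thr`` undercut
    the loss threshold; segments longer than ``max_len`` bp (e.g. arm or
    chromosome level) are not focal.  When a ``gene_table`` (``chrom,
    start, end, gene_id``) is supplied, overlapping gene ids are listed.
    """
    if amp_thr <= GAIN_THRESHOLD or del_thr >= LOSS_THRESHOLD:
        raise ValueError("focal thresholds must exceed the gain/loss call thresholds")
    length = segments["end"] - segments["start"]
    mean = segments["mean_log2"]
    is_amp = (mean > amp_thr) & (length <= max_len)
    is_del = (mean < del_thr) & (length <= max_len)
    out = segments.loc[is_amp | is_del, ["sample_id", "chrom", "start", "end", "mean_log2"]].copy()
    out["type"] = np.where(out["mean_log2"] > 0, "amplification", "deep_deletion")
    if gene_table is not None:
        genes = []
        for _, row in out.iterrows():
            sub = gene_table[
                (gene_table["chrom"] == row["chrom"])
                & (gene_table["start"] < row["end"])
                & (gene_table["end"] > row["start"])
            ]
            genes.append(";".join(sub["gene_id"].astype(str)) or ".")
        out["genes"] = genes
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# output formats

def write_seg(segments: pd.DataFrame, path) -> None:
    """Write segments in SEG format (1-based inclusive coordinates)."""
    out = pd.DataFrame(
        {
            "sample": segments["sample_id"],
            "chrom": segments["chrom"],
            "loc.start": segments["start"] + 1,
            "loc.end": segments["end"],
            "num.mark": segments["n_probes"],
            "seg.mean": segments["mean_log2"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_segments_bed(segments: pd.DataFrame, path) -> None:
    """Write segments as BED (0-based half-open; name = sample:state)."""
    name = segments["sample_id"].astype(str)
    if "state" in segments.columns:
        name = name + ":" + segments["state"].astype(str)
    out = pd.DataFrame(
        {
            "chrom": segments["chrom"],
            "start": segments["start"],
            "end": segments["end"],
            "name": name,
            "score": segments["mean_log2"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


class CopyNumberSegmenter(BaseEstimator):
    """Sklearn-style wrapper: segment log2 ratios and score complexity.

    ``fit`` takes a samples x probes frame of log2 ratios (probe-id
    columns matching the annotation) and exposes ``segments_`` (stacked
    per-sample segments with called states) and ``genomic_index_`` (per
    sample A, C and GI).
    """

    def __init__(self, annotation: pd.DataFrame | None = None, min_probes: int = 5,
                 min_delta: float = 0.1, alpha: float = 0.01,
                 gain_threshold: float = GAIN_THRESHOLD, loss_threshold: float = LOSS_THRESHOLD):
        self.annotation = annotation
        self.min_probes = min_probes
        self.min_delta = min_delta
        self.alpha = alpha
        self.gain_threshold = gain_threshold
        self.loss_threshold = loss_threshold

    def fit(self, X: pd.DataFrame, y=None):
        if self.annotation is None:
            raise ValueError("CopyNumberSegmenter requires an annotation frame")
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a samples x probes DataFrame of log2 ratios")
        self.segments_ = segment_cohort(
            X.T, self.annotation, min_probes=self.min_probes, min_delta=self.min_delta,
            alpha=self.alpha, gain_thr=self.gain_threshold, loss_thr=self.loss_threshold,
        )
        self.genomic_index_ = cohort_genomic_index(self.segments_)
        self.n_features_in_ = X.shape[1]
        return self
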