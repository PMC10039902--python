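"""Differential methylation: DMPs, window-based DMRs, signed intersection,
and gene-set enrichment.

Per-probe differential methylation is tested with a two-sided Welch t
test on beta values with Benjamini-Hochberg adjustment across all tested
probes; the effect size is the difference in group mean betas
(delta = mean(group B) - mean(group A)), banded into hyper (> 0.1), mid
and hypo (< -0.1) categories.

Region calling follows a probe-lasso-style rule: a window ("lasso") of
configurable radius is drawn around every significant probe, windows
capturing at least ``min_significant`` significant probes are retained,
overlapping retained windows merge, and each region is trimmed to its
outermost member significant probes.  Regions from different class
comparisons only count as intersecting when they overlap genomically AND
their delta signs match.  Enrichment of DMR-overlapping genes against a
gene-set collection uses the one-sided hypergeometric upper tail with BH
adjustment across sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DELTA_BAND = 0.1


def dmp_test(beta: pd.DataFrame, samples_a: list[str], samples_b: list[str]) -> pd.DataFrame:
    """Per-probe Welch t test between two sample groups.

    Returns a frame indexed by probe id with ``delta_beta`` (mean B -
    mean A), ``t``, ``p``, ``fdr`` (BH across all tested probes) and the
    delta ``category``.  Probes with zero variance in both groups get
    p = 1 when means are equal (and p = 0 on an exact mean difference).
    """
    samples_a, samples_b = list(samples_a), list(samples_b)
    overlap = set(samples_a) & set(samples_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each group needs at least two samples")
    a = beta[samples_a].to_numpy(dtype=float)
    b = beta[samples_b].to_numpy(dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    delta = m2 - m1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se2 > 0, delta / np.sqrt(se2), 0.0)
        df = np.where(
            se2 > 0,
            se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)),
            n1 + n2 - 2,
        )
    p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0
    p[degenerate & (delta == 0)] = 1.0
    p[degenerate & (delta != 0)] = 0.0
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "delta_beta": delta,
            "t": t,
            "p": p,
            "fdr": fdr,
            "category": categorize_delta(delta),
        },
        index=beta.index,
    )


def categorize_delta(delta):
    """Band a beta difference: hyper (> 0.1), hypo (< -0.1), else mid.

    Boundary values of exactly +/-0.1 are mid.  Accepts scalars or
    arrays; deltas outside [-1, 1] raise.
    """
    arr = np.asarray(delta, dtype=float)
    if (np.abs(arr) > 1).any():
        raise ValueError("delta_beta must lie in [-1, 1]")
    cats = np.where(arr > DELTA_BAND, "hyper", np.where(arr < -DELTA_BAND, "hypo", "mid"))
    return cats.item() if np.isscalar(delta) else cats


def call_dmrs_probelasso(dmps: pd.DataFrame, annotation: pd.DataFrame, *,
                         radius_bp: int = 1000, min_significant: int = 5,
                         adj_p_thr: float = 0.05,
                         gene_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Call differentially methylated regions by the probe-lasso window rule.

    A probe is significant when ``fdr < adj_p_thr``.  Around each
    significant probe a window of ``+/- radius_bp`` is drawn; windows
    capturing >= ``min_significant`` significant probes are retained,
    overlapping retained windows merge per chromosome, and each region
    is trimmed to its outermost member significant probes.  The region
    delta is the mean ``delta_beta`` over member significant probes;
    regions averaging exactly zero are discarded.  Coordinates are
    0-based half-open.
    """
    if radius_bp <= 0:
        raise ValueError("radius_bp must be positive")
    ann = annotation.loc[dmps.index]
    sig = dmps["fdr"].to_numpy() < adj_p_thr
    rows = []
    for chrom, sub in ann.groupby("chrom", sort=False, observed=True):
        sig_mask = sig[ann.index.get_indexer(sub.index)]
        sig_probes = sub.index.to_numpy()[sig_mask]
        pos = sub["pos"].to_numpy()[sig_mask]
        if len(pos) == 0:
            continue
        order = np.argsort(pos, kind="mergesort")
        pos, sig_probes = pos[order], sig_probes[order]
        counts = np.searchsorted(pos, pos + radius_bp, side="right") - np.searchsorted(
            pos, pos - radius_bp, side="left"
        )
        kept = counts >= min_significant
        if not kept.any():
            continue
        intervals = np.column_stack([pos[kept] - radius_bp, pos[kept] + radius_bp])
        merged = []
        for lo, hi in intervals:
            if merged and lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        for lo, hi in merged:
            inside = (pos >= lo) & (pos <= hi)
            members = sig_probes[inside]
            member_pos = pos[inside]
            mean_delta = float(dmps.loc[members, "delta_beta"].mean())
            if mean_delta == 0.0:
                continue
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(member_pos.min() - 1),
                    "end": int(member_pos.max()),
                    "probe_ids": ";".join(members),
                    "n_significant": int(inside.sum()),
                    "mean_delta_beta": mean_delta,
                    "direction": "+" if mean_delta > 0 else "-",
                }
            )
    dmrs = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "probe_ids", "n_significant", "mean_delta_beta", "direction"],
    )
    if gene_table is not None and len(dmrs):
        genes = []
        for _, row in dmrs.iterrows():
            sub = gene_table[
                (gene_table["chrom"] == row["chrom"])
                & (gene_table["start"] < row["end"])
                & (gene_table["end"] > row["start"])
            ]
            genes.append(";".join(sub["gene_id"].astype(str)) or ".")
        dmrs["genes"] = genes
    return dmrs


def intersect_dmrs_signed(dmrs_a: pd.DataFrame, dmrs_b: pd.DataFrame) -> pd.DataFrame:
    """Matched DMR pairs: >= 1 bp genomic overlap AND matching delta sign.

    A region may appear in multiple pairs; the returned frame carries
    the row indices of both inputs plus the shared interval.
    """
    rows = []
    for ia, a in dmrs_a.iterrows():
        sub = dmrs_b[
            (dmrs_b["chrom"] == a["chrom"])
            & (dmrs_b["start"] < a["end"])
            & (dmrs_b["end"] > a["start"])
            & (dmrs_b["direction"] == a["direction"])
        ]
        for ib, b in sub.iterrows():
            rows.append(
                {
                    "index_a": ia,
                    "index_b": ib,
                    "chrom": a["chrom"],
                    "start": int(max(a["start"], b["start"])),
                    "end": int(min(a["end"], b["end"])),
                    "direction": a["direction"],
                }
            )
    return pd.DataFrame(rows, columns=["index_a", "index_b", "chrom", "start", "end", "direction"])


def go_enrichment(gene_ids, gene_sets: dict[str, set], universe) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in each set.

    ``p`` is the one-sided upper tail P(X >= overlap) for drawing
    ``len(gene_ids)`` genes from the universe; ``fdr`` is BH across
    sets.  Query genes outside the universe raise, listing offenders.
    """
    universe = set(universe)
    query = set(gene_ids)
    outside = query - universe
    if outside:
        raise ValueError(f"query genes outside the universe: {sorted(outside)[:10]}")
    if not gene_sets:
        raise ValueError("gene_sets is empty")
    n_universe, n_query = len(universe), len(query)
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        overlap = len(query & members)
        p = float(stats.hypergeom.sf(overlap - 1, n_universe, len(members), n_query))
        rows.append({"set": name, "set_size": len(members), "overlap": overlap, "p": p})
    out = pd.DataFrame(rows).set_index("set")
    out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_dmrs_bed(dmrs: pd.DataFrame, path) -> None:
    """Write DMRs as BED (name = direction, score = mean delta)."""
    out = pd.DataFrame(
        {
            "chrom": dmrs["chrom"],
            "start": dmrs["start"],
            "end": dmrs["end"],
            "name": dmrs["direction"],
            "score": dmrs["mean_delta_beta"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)
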