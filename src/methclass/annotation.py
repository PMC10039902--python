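"""Probe annotation: genomic coordinates and feature context for array probes.

The annotation frame is the backbone for every stratified statistic.  It is
a :class:`pandas.DataFrame` indexed by ``probe_id`` with columns

``chrom``
    chromosome name (``chr1`` ... ``chr22``, ``chrX``, ``chrY``).
``pos``
    1-based probe coordinate (the interrogated CpG).
``cgi_relation``
    ``island`` or ``open_sea`` (shores/shelves are folded into open sea).
``region``
    ``promoter``, ``body`` or ``intergenic``.
``platform``
    ``A``, ``B`` or ``both`` — membership on the two array designs.
``snp_overlap``, ``multi_hit``, ``non_unique``
    boolean exclusion flags (SNP-containing, cross-reactive, ambiguously
    mapped probes).

On disk the annotation is a BED-like TSV with 0-based half-open intervals.
"""

from __future__ import annotations

import pandas as pd

SEX_CHROMOSOMES = ("chrX", "chrY")
CGI_RELATIONS = ("island", "open_sea")
REGIONS = ("promoter", "body", "intergenic")
PLATFORMS = ("A", "B", "both")
FLAG_COLUMNS = ("snp_overlap", "multi_hit", "non_unique")

REQUIRED_COLUMNS = ("chrom", "pos", "cgi_relation", "region", "platform") + FLAG_COLUMNS

_BED_COLUMNS = ["chrom", "start", "end", "probe_id", "cgi_relation", "region", "platform", "flags"]


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate an annotation frame, returning it unchanged.

    Raises ``ValueError`` on missing columns, duplicated probe ids,
    non-positive coordinates, unknown category levels, or positions that
    are not strictly increasing within a chromosome.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation is missing columns: {missing}")
    if ann.index.has_duplicates:
        dup = ann.index[ann.index.duplicated()][:5].tolist()
        raise ValueError(f"duplicated probe ids in annotation: {dup}")
    if (ann["pos"] < 1).any():
        raise ValueError("probe positions must be 1-based positive integers")
    for col, levels in (("cgi_relation", CGI_RELATIONS), ("region", REGIONS), ("platform", PLATFORMS)):
        bad = set(ann[col].unique()) - set(levels)
        if bad:
            raise ValueError(f"unknown {col} levels: {sorted(bad)}")
    for chrom, sub in ann.groupby("chrom", sort=False, observed=True):
        if not sub["pos"].is_monotonic_increasing or sub["pos"].duplicated().any():
            raise ValueError(f"probe positions not strictly increasing on {chrom}")
    return ann


def write_annotation_bed(ann: pd.DataFrame, path) -> None:
    """Write the annotation as a BED-like TSV (0-based half-open intervals)."""
    flags = ann[list(FLAG_COLUMNS)].apply(
        lambda row: ";".join(name for name in FLAG_COLUMNS if row[name]) or ".", axis=1
    )
    out = pd.DataFrame(
        {
            "chrom": ann["chrom"],
            "start": ann["pos"] - 1,
            "end": ann["pos"],
            "probe_id": ann.index,
            "cgi_relation": ann["cgi_relation"],
            "region": ann["region"],
            "platform": ann["platform"],
            "flags": flags,
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_annotation_bed(path) -> pd.DataFrame:
    """Read an annotation written by :func:`write_annotation_bed`."""
    raw = pd.read_csv(path, sep="\t", dtype={"chrom": str, "flags": str})
    ann = pd.DataFrame(
        {
            "chrom": raw["chrom"].to_numpy(),
            "pos": raw["end"].to_numpy(dtype=int),
            "cgi_relation": raw["cgi_relation"].to_numpy(),
            "region": raw["region"].to_numpy(),
            "platform": raw["platform"].to_numpy(),
        },
        index=pd.Index(raw["probe_id"].to_numpy(), name="probe_id"),
    )
    for flag in FLAG_COLUMNS:
        ann[flag] = raw["flags"].str.split(";").apply(lambda parts: flag in parts).to_numpy()
    return validate_annotation(ann)
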