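"""Synthetic methylation-array cohorts with known ground truth.

The generator emulates the statistical structure that every downstream
stage assumes: a probes x samples beta matrix in [0, 1] with CGI /
open-sea bimodality on two partially overlapping platform probe sets,
three tumor classes with graded global hypomethylation and graded
copy-number complexity, a recurrent whole-chromosome-8 gain in the
intermediate class, extra hypomethylation inside gained regions, locally
clustered class-specific differential probe blocks (DMR signal),
per-sample log2 total-intensity signal consistent with the simulated
copy state, clinical metadata, and class-dependent censored survival
times.  Every quantity that a recovery test needs is returned in a
:class:`TruthBundle`.

The reduced genome (~20k probes over 22 autosomes + X + Y at 1/20 of
physical scale) stands in for 450k/850k arrays; all downstream statistics
are scale-free.  A fraction of probes is laid down in tight clusters
(~100-250 bp spacing), mirroring the concentration of array probes at
CpG islands and promoters; DMR signal is injected into such clusters so
that window-based region calling has realistic local density to work on.
Sex-chromosome probes are generated (so the exclusion filter has work to
do) but carry no class signal.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

from methclass.annotation import validate_annotation

# hg-like chromosome lengths scaled to 1/20 (bp)
_DEFAULT_CHROMOSOMES: tuple[tuple[str, int], ...] = tuple(
    (f"chr{name}", length)
    for name, length in [
        ("1", 12462000), ("2", 12160000), ("3", 9901000), ("4", 9557000),
        ("5", 9046000), ("6", 8556000), ("7", 7957000), ("8", 7318000),
        ("9", 7061000), ("10", 6777000), ("11", 6750000), ("12", 6693000),
        ("13", 5758000), ("14", 5367000), ("15", 5127000), ("16", 4517000),
        ("17", 4060000), ("18", 3904000), ("19", 2956000), ("20", 3151000),
        ("21", 2406000), ("22", 2565000), ("X", 7763000), ("Y", 2968000),
    ]
)


@dataclass
class GenomeModel:
    """Reduced-genome layout for the simulated array manifest.

    Parameters
    ----------
    chromosomes
        ``(name, length_bp)`` pairs.  Default: 22 autosomes + X + Y at
        1/20 physical scale.
    probe_count
        Total number of probes across the genome.
    cgi_fraction
        Fraction of probes annotated as CpG island.
    platform_overlap
        Fraction of probes present on both simulated platforms; the
        remainder is split evenly between platform A only and B only.
    cluster_fraction
        Fraction of probes placed in tight local clusters (6-12 probes,
        100-250 bp apart) rather than scattered uniformly.
    snp_rate, multi_hit_rate, non_unique_rate
        Per-probe rates of the exclusion flags.
    """

    chromosomes: tuple[tuple[str, int], ...] = _DEFAULT_CHROMOSOMES
    probe_count: int = 20000
    cgi_fraction: float = 0.30
    platform_overlap: float = 0.80
    cluster_fraction: float = 0.30
    snp_rate: float = 0.02
    multi_hit_rate: float = 0.02
    non_unique_rate: float = 0.01

    def validate(self) -> "GenomeModel":
        if len(self.chromosomes) == 0:
            raise ValueError("at least one chromosome is required")
        if self.probe_count < len(self.chromosomes):
            raise ValueError("probe_count must be >= number of chromosomes")
        if not 0 < self.cgi_fraction < 1:
            raise ValueError("cgi_fraction must lie in (0, 1)")
        if not 0 < self.platform_overlap <= 1:
            raise ValueError("platform_overlap must lie in (0, 1]")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        return self


@dataclass
class ClassSpec:
    """Generative parameters of one tumor class.

    ``open_sea_beta_mean`` / ``cgi_beta_mean`` set the target mean beta
    outside / inside CpG islands; ``cnv_rate`` is the expected number of
    altered segments per sample (Poisson); ``chr8_gain_prob`` the
    probability of a whole-chromosome-8 gain; ``gain_hypo_shift`` the
    extra beta decrease applied inside gained regions; ``dmr_block_count``
    and ``dmr_delta`` the number and effect size of locally clustered
    class-specific probe blocks; ``survival_event_rate`` the exponential
    event hazard per month and ``censor_rate`` the independent censoring
    hazard.
    """

    label: str
    n_samples: int = 30
    open_sea_beta_mean: float = 0.60
    cgi_beta_mean: float = 0.15
    cnv_rate: float = 2.0
    chr8_gain_prob: float = 0.1
    gain_hypo_shift: float = 0.10
    dmr_block_count: int = 0
    dmr_delta: float = -0.20
    survival_event_rate: float = 0.002
    censor_rate: float = 0.005
    median_age_years: float = 10.0
    diagnoses: tuple[str, ...] = ("NOS",)
    locations: tuple[str, ...] = ("NOS",)

    def validate(self) -> "ClassSpec":
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not 0 <= self.open_sea_beta_mean <= 1 or not 0 <= self.cgi_beta_mean <= 1:
            raise ValueError("target beta means must lie in [0, 1]")
        for name in ("cnv_rate", "chr8_gain_prob", "gain_hypo_shift", "survival_event_rate", "censor_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.chr8_gain_prob > 1:
            raise ValueError("chr8_gain_prob must be <= 1")
        if self.dmr_block_count < 0:
            raise ValueError("dmr_block_count must be >= 0")
        return self


def default_class_specs() -> list[ClassSpec]:
    """The three default tumor classes.

    A low-grade class (``LG``, high methylation, near-balanced genomes),
    a sarcoma class (``SARC``, intermediate hypomethylation, moderate
    copy-number complexity, recurrent chromosome-8 gain) and an
    intracranial-sarcoma-like class (``PIS``, strongest hypomethylation,
    most complex genomes).  Open-sea means 0.60 / 0.52 / 0.45 with 30
    samples per class; event hazards are graded so progression-free
    survival orders LG > SARC > PIS.
    """
    return [
        ClassSpec(
            label="LG", n_samples=30, open_sea_beta_mean=0.60, cnv_rate=2.0,
            chr8_gain_prob=0.10, dmr_block_count=0, survival_event_rate=0.002,
            median_age_years=1.5,
            diagnoses=("CN", "PPB I", "NCMH"), locations=("Kidney", "Lungs", "Head and Neck"),
        ),
        ClassSpec(
            label="SARC", n_samples=30, open_sea_beta_mean=0.52, cnv_rate=8.0,
            chr8_gain_prob=0.80, dmr_block_count=10, dmr_delta=-0.20,
            survival_event_rate=0.010, median_age_years=23.6,
            diagnoses=("ERMS", "PPB III", "ASK", "PB"), locations=("Uterus", "Lungs", "Kidney"),
        ),
        ClassSpec(
            label="PIS", n_samples=30, open_sea_beta_mean=0.45, cnv_rate=20.0,
            chr8_gain_prob=0.30, dmr_block_count=10, dmr_delta=-0.20,
            survival_event_rate=0.020, median_age_years=11.0,
            diagnoses=("PIS",), locations=("CNS",),
        ),
    ]


@dataclass
class TruthBundle:
    """Ground truth of a simulated cohort.

    ``classes`` maps sample_id -> class label; ``segments`` holds the
    altered (gain/loss) intervals actually injected per sample (0-based
    half-open bp coordinates plus the probe-index range); ``dmr_blocks``
    the clustered class-specific differential probe blocks; ``log2`` the
    noise-free per-probe copy-number signal per sample.
    """

    classes: pd.Series
    segments: pd.DataFrame
    dmr_blocks: pd.DataFrame
    log2: pd.DataFrame


@dataclass
class SimulatedCohort:
    """Output bundle of :func:`simulate_cohort`."""

    beta: pd.DataFrame
    log2_intensity: pd.DataFrame
    reference_log2_intensity: pd.DataFrame
    samples: pd.DataFrame
    truth: TruthBundle


def build_genome_annotation(model: GenomeModel, seed: int) -> pd.DataFrame:
    """Build a deterministic probe annotation for the reduced genome.

    Probes are apportioned to chromosomes proportionally to length (at
    least one per chromosome).  Within each chromosome a
    ``cluster_fraction`` of probes is placed in tight clusters and the
    rest scattered uniformly; positions are strictly increasing.
    CGI relation, gene region, platform membership and exclusion flags
    are drawn at the configured rates.
    """
    model.validate()
    rng = np.random.default_rng(seed)
    names = [name for name, _ in model.chromosomes]
    lengths = np.array([length for _, length in model.chromosomes], dtype=float)

    counts = np.maximum(1, np.round(model.probe_count * lengths / lengths.sum()).astype(int))
    # nudge rounding so the total matches exactly
    while counts.sum() != model.probe_count:
        i = int(rng.integers(len(counts)))
        if counts.sum() > model.probe_count and counts[i] > 1:
            counts[i] -= 1
        elif counts.sum() < model.probe_count:
            counts[i] += 1

    chroms: list[str] = []
    positions: list[np.ndarray] = []
    for name, length, n_probes in zip(names, lengths.astype(int), counts):
        pos = _chromosome_positions(rng, length, n_probes, model.cluster_fraction)
        chroms.extend([name] * n_probes)
        positions.append(pos)
    pos_all = np.concatenate(positions)

    n = model.probe_count
    probe_ids = np.array([f"cg{i:08d}" for i in range(n)])
    platform_draw = rng.random(n)
    half_excl = (1 - model.platform_overlap) / 2
    platform = np.where(
        platform_draw < model.platform_overlap, "both",
        np.where(platform_draw < model.platform_overlap + half_excl, "A", "B"),
    )
    ann = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos_all,
            "cgi_relation": np.where(rng.random(n) < model.cgi_fraction, "island", "open_sea"),
            "region": rng.choice(["promoter", "body", "intergenic"], size=n, p=[0.20, 0.45, 0.35]),
            "platform": platform,
            "snp_overlap": rng.random(n) < model.snp_rate,
            "multi_hit": rng.random(n) < model.multi_hit_rate,
            "non_unique": rng.random(n) < model.non_unique_rate,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return validate_annotation(ann)


def _chromosome_positions(rng, length, n_probes, cluster_fraction):
    """Strictly increasing probe positions: clustered runs + uniform scatter."""
    cluster_sizes: list[int] = []
    remaining = int(round(n_probes * cluster_fraction))
    while remaining >= 6:
        size = int(rng.integers(6, 13))
        size = min(size, remaining)
        cluster_sizes.append(size)
        remaining -= size
    n_scatter = n_probes - sum(cluster_sizes)

    pieces = []
    for size in cluster_sizes:
        anchor = rng.integers(1, max(2, length - 5000))
        offsets = np.cumsum(rng.integers(100, 251, size=size))
        pieces.append(anchor + offsets)
    if n_scatter:
        pieces.append(rng.integers(1, length + 1, size=n_scatter))
    pos = np.sort(np.concatenate(pieces)) if pieces else np.array([], dtype=int)
    pos = np.minimum(pos, length)
    # enforce strict monotonicity after sorting/clipping
    for i in range(1, len(pos)):
        if pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    return pos.astype(int)


def simulate_cohort(
    annotation: pd.DataFrame,
    specs: list[ClassSpec],
    seed: int,
    *,
    probe_effect_sd: float = 0.05,
    beta_noise_sd: float = 0.04,
    gain_log2: float = 0.3,
    loss_log2: float = -0.3,
    log2_noise_sd: float = 0.025,
    n_reference: int = 20,
    missing_rate: float = 0.0,
    admin_censor_months: float = 240.0,
) -> SimulatedCohort:
    """Simulate a multi-class methylation cohort with ground truth.

    Per-probe baseline betas are drawn bimodally (CGI low, open sea
    high) as a shared probe effect around each class's target means;
    class shifts act outside CGIs.  Per-sample copy segments are drawn
    (count ~ Poisson(``cnv_rate``), equal-probability gain/loss states,
    whole-chr8 gain with ``chr8_gain_prob``); the log2 intensity signal
    is per-probe noise around the segment level (``gain_log2`` /
    ``loss_log2`` / 0).  Betas inside gained segments are additionally
    decreased by ``gain_hypo_shift``; DMR-block probes are shifted by
    ``dmr_delta``; survival times are exponential with the class hazard
    under independent censoring; betas are clamped to [0, 1].
    """
    if not specs:
        raise ValueError("at least one ClassSpec is required")
    for spec in specs:
        spec.validate()
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError("class labels must be unique")
    validate_annotation(annotation)

    rng = np.random.default_rng(seed)
    probe_ids = annotation.index.to_numpy()
    n_probes = len(probe_ids)
    is_cgi = (annotation["cgi_relation"] == "island").to_numpy()
    chrom = annotation["chrom"].to_numpy()
    pos = annotation["pos"].to_numpy()
    autosomes = [c for c in pd.unique(chrom) if c not in ("chrX", "chrY")]

    probe_effect = rng.normal(0.0, probe_effect_sd, size=n_probes)
    # sex-chromosome probes carry no class signal: pin them to the first
    # class's means for every class
    sex_mask = np.isin(chrom, ("chrX", "chrY"))

    dmr_blocks = _assign_dmr_blocks(rng, specs, chrom, pos, autosomes)

    sample_ids: list[str] = []
    beta_cols: list[np.ndarray] = []
    log2_cols: list[np.ndarray] = []
    true_log2_cols: list[np.ndarray] = []
    seg_rows: list[dict] = []
    meta_rows: list[dict] = []

    for spec in specs:
        class_mean = np.where(is_cgi, spec.cgi_beta_mean, spec.open_sea_beta_mean)
        base_mean = np.where(is_cgi, specs[0].cgi_beta_mean, specs[0].open_sea_beta_mean)
        class_mean = np.where(sex_mask, base_mean, class_mean)
        probe_mean = class_mean + probe_effect

        block_shift = np.zeros(n_probes)
        for block in dmr_blocks:
            if block["class_label"] == spec.label:
                block_shift[block["probe_start"]:block["probe_stop"]] += block["delta"]

        for j in range(spec.n_samples):
            sample_id = f"{spec.label}_{j:02d}"
            sample_ids.append(sample_id)

            true_log2 = np.zeros(n_probes)
            segments = _draw_sample_segments(rng, spec, chrom, autosomes)
            for seg in segments:
                sl = slice(seg["probe_start"], seg["probe_stop"])
                true_log2[sl] = gain_log2 if seg["state"] == "gain" else loss_log2
                seg_rows.append(
                    {
                        "sample_id": sample_id,
                        "chrom": seg["chrom"],
                        "start": int(pos[seg["probe_start"]] - 1),
                        "end": int(pos[seg["probe_stop"] - 1]),
                        "probe_start": seg["probe_start"],
                        "probe_stop": seg["probe_stop"],
                        "n_probes": seg["probe_stop"] - seg["probe_start"],
                        "state": seg["state"],
                    }
                )

            mean = probe_mean + block_shift - spec.gain_hypo_shift * (true_log2 > 0)
            beta = np.clip(mean + rng.normal(0.0, beta_noise_sd, size=n_probes), 0.0, 1.0)
            if missing_rate > 0:
                beta[rng.random(n_probes) < missing_rate] = np.nan
            beta_cols.append(beta)
            true_log2_cols.append(true_log2)
            log2_cols.append(true_log2 + rng.normal(0.0, log2_noise_sd, size=n_probes))

            event_time = rng.exponential(1.0 / spec.survival_event_rate) if spec.survival_event_rate > 0 else np.inf
            censor_time = rng.exponential(1.0 / spec.censor_rate) if spec.censor_rate > 0 else np.inf
            censor_time = min(censor_time, admin_censor_months)
            time = min(event_time, censor_time)
            meta_rows.append(
                {
                    "sample_id": sample_id,
                    "true_class": spec.label,
                    "sex": "F" if rng.random() < 0.5 else "M",
                    "age_years": round(float(spec.median_age_years * np.exp(rng.normal(0.0, 0.5))), 1),
                    "diagnosis": str(rng.choice(list(spec.diagnoses))),
                    "location": str(rng.choice(list(spec.locations))),
                    "pfs_time_months": max(float(time), 1e-3),
                    "pfs_event": int(event_time <= censor_time),
                }
            )

    # intensity scale: per-probe baseline around 2^11 with biological spread
    log2_baseline = rng.normal(11.0, 0.5, size=n_probes)
    log2_intensity = pd.DataFrame(
        log2_baseline[:, None] + np.column_stack(log2_cols),
        index=annotation.index, columns=sample_ids,
    )
    reference = pd.DataFrame(
        log2_baseline[:, None] + rng.normal(0.0, log2_noise_sd, size=(n_probes, n_reference)),
        index=annotation.index, columns=[f"REF_{j:02d}" for j in range(n_reference)],
    )

    beta = pd.DataFrame(np.column_stack(beta_cols), index=annotation.index, columns=sample_ids)
    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    truth = TruthBundle(
        classes=samples["true_class"].rename("true_class"),
        segments=pd.DataFrame(
            seg_rows,
            columns=["sample_id", "chrom", "start", "end", "probe_start", "probe_stop", "n_probes", "state"],
        ),
        dmr_blocks=pd.DataFrame(
            dmr_blocks,
            columns=["class_label", "chrom", "start", "end", "probe_start", "probe_stop", "delta"],
        ),
        log2=pd.DataFrame(np.column_stack(true_log2_cols), index=annotation.index, columns=sample_ids),
    )
    return SimulatedCohort(beta, log2_intensity, reference, samples, truth)


def _candidate_probe_clusters(chrom, pos, autosomes, max_gap=400, min_size=6):
    """Runs of >= min_size consecutive autosomal probes spaced <= max_gap bp."""
    clusters = []
    for c in autosomes:
        idx = np.flatnonzero(chrom == c)
        if len(idx) < min_size:
            continue
        gaps = np.diff(pos[idx])
        run_start = 0
        for i, gap in enumerate(np.append(gaps, np.inf)):
            if gap > max_gap:
                if i + 1 - run_start >= min_size:
                    clusters.append((idx[run_start], idx[i] + 1))
                run_start = i + 1
    return clusters


def _assign_dmr_blocks(rng, specs, chrom, pos, autosomes):
    """Assign non-overlapping probe clusters to classes as DMR truth blocks."""
    clusters = _candidate_probe_clusters(chrom, pos, autosomes)
    rng.shuffle(clusters)
    blocks = []
    cursor = 0
    for spec in specs:
        for _ in range(spec.dmr_block_count):
            if cursor >= len(clusters):
                raise ValueError(
                    "not enough probe clusters for the requested DMR blocks; "
                    "increase cluster_fraction or probe_count"
                )
            start_idx, stop_idx = clusters[cursor]
            cursor += 1
            blocks.append(
                {
                    "class_label": spec.label,
                    "chrom": str(chrom[start_idx]),
                    "start": int(pos[start_idx] - 1),
                    "end": int(pos[stop_idx - 1]),
                    "probe_start": int(start_idx),
                    "probe_stop": int(stop_idx),
                    "delta": float(spec.dmr_delta),
                }
            )
    return blocks


def _draw_sample_segments(rng, spec, chrom, autosomes, min_len=30, max_len=150, max_tries=50):
    """Non-overlapping altered segments for one sample, as probe-index ranges."""
    segments = []

    def overlaps(start, stop):
        return any(not (stop <= s["probe_start"] or start >= s["probe_stop"]) for s in segments)

    if "chr8" in autosomes and rng.random() < spec.chr8_gain_prob:
        idx = np.flatnonzero(chrom == "chr8")
        segments.append(
            {"chrom": "chr8", "probe_start": int(idx[0]), "probe_stop": int(idx[-1] + 1), "state": "gain"}
        )
    n_extra = rng.poisson(spec.cnv_rate)
    for _ in range(n_extra):
        for _try in range(max_tries):
            c = autosomes[int(rng.integers(len(autosomes)))]
            idx = np.flatnonzero(chrom == c)
            if len(idx) < min_len:
                continue
            length = int(rng.integers(min_len, min(max_len, len(idx)) + 1))
            offset = int(rng.integers(0, len(idx) - length + 1))
            start, stop = int(idx[offset]), int(idx[offset + length - 1] + 1)
            if not overlaps(start, stop):
                segments.append(
                    {"chrom": c, "probe_start": start, "probe_stop": stop,
                     "state": "gain" if rng.random() < 0.5 else "loss"}
                )
                break
    segments.sort(key=lambda s: s["probe_start"])
    return segments


# ---------------------------------------------------------------------------
# fixture round-trip I/O

def write_fixture_bundle(cohort: SimulatedCohort, directory) -> dict[str, str]:
    """Write a cohort to plain-text files; returns the path map.

    Matrices go to TSV (probes as rows, ``probe_id`` first column), the
    annotation is not re-derivable from the cohort and must be written
    separately with :func:`methclass.annotation.write_annotation_bed`.
    """
    from pathlib import Path

    if cohort.beta.shape[1] == 0 or cohort.beta.shape[0] == 0:
        raise ValueError("refusing to write an empty cohort")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": directory / "beta.tsv",
        "log2_intensity": directory / "log2_intensity.tsv",
        "reference_log2_intensity": directory / "reference_log2_intensity.tsv",
        "samples": directory / "samples.csv",
        "truth_segments": directory / "truth_segments.tsv",
        "truth_dmr_blocks": directory / "truth_dmr_blocks.tsv",
        "truth_log2": directory / "truth_log2.tsv",
    }
    cohort.beta.to_csv(paths["beta"], sep="\t", index_label="probe_id")
    cohort.log2_intensity.to_csv(paths["log2_intensity"], sep="\t", index_label="probe_id")
    cohort.reference_log2_intensity.to_csv(
        paths["reference_log2_intensity"], sep="\t", index_label="probe_id"
    )
    cohort.samples.to_csv(paths["samples"], index_label="sample_id")
    cohort.truth.segments.to_csv(paths["truth_segments"], sep="\t", index=False)
    cohort.truth.dmr_blocks.to_csv(paths["truth_dmr_blocks"], sep="\t", index=False)
    cohort.truth.log2.to_csv(paths["truth_log2"], sep="\t", index_label="probe_id")
    return {k: str(v) for k, v in paths.items()}


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a probes x samples TSV written by :func:`write_fixture_bundle`."""
    return pd.read_csv(path, sep="\t", index_col="probe_id")


def read_fixture_bundle(directory) -> SimulatedCohort:
    """Read a cohort previously written with :func:`write_fixture_bundle`."""
    from pathlib import Path

    directory = Path(directory)
    samples = pd.read_csv(directory / "samples.csv", index_col="sample_id")
    truth = TruthBundle(
        classes=samples["true_class"].rename("true_class"),
        segments=pd.read_csv(directory / "truth_segments.tsv", sep="\t"),
        dmr_blocks=pd.read_csv(directory / "truth_dmr_blocks.tsv", sep="\t"),
        log2=read_matrix_tsv(directory / "truth_log2.tsv"),
    )
    return SimulatedCohort(
        beta=read_matrix_tsv(directory / "beta.tsv"),
        log2_intensity=read_matrix_tsv(directory / "log2_intensity.tsv"),
        reference_log2_intensity=read_matrix_tsv(directory / "reference_log2_intensity.tsv"),
        samples=samples,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# config round-trip

def save_cohort_config(model: GenomeModel, specs: list[ClassSpec], path) -> None:
    """Write generator configuration as YAML (`genome:` block + `classes:` list)."""
    payload = {
        "genome": {**asdict(model), "chromosomes": [list(c) for c in model.chromosomes]},
        "classes": [
            {**asdict(s), "diagnoses": list(s.diagnoses), "locations": list(s.locations)}
            for s in specs
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_cohort_config(path) -> tuple[GenomeModel, list[ClassSpec]]:
    """Read a configuration written by :func:`save_cohort_config`."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    genome = dict(payload["genome"])
    genome["chromosomes"] = tuple((str(n), int(l)) for n, l in genome["chromosomes"])
    model = GenomeModel(**genome).validate()
    specs = []
    for entry in payload["classes"]:
        entry = dict(entry)
        entry["diagnoses"] = tuple(entry.get("diagnoses", ("NOS",)))
        entry["locations"] = tuple(entry.get("locations", ("NOS",)))
        specs.append(ClassSpec(**entry).validate())
    return model, specs
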