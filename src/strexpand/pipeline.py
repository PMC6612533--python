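"""End-to-end discovery workflow: profile -> case-control -> annotate -> screen.

`run_discovery` binds the stages into the discovery workflow driven by a
single configuration: per-sample anchored-IRR profiles are built from
alignments, candidate loci are ranked by the label-permutation test,
candidates are annotated with named genomic intervals (e.g. a linkage
region), and optionally each candidate locus is screened per sample.
`run_demo` simulates a complete cohort and runs the same workflow on it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import io as sio
from .casecontrol import (
    DEFAULT_N_PERM,
    DEFAULT_P_THRESHOLD,
    adjust_genomewide,
    intersect_candidates,
    rank_candidates,
)
from .exceptions import ConfigurationError, DataError, StrexpandError
from .profiling import (
    DEFAULT_CLUSTER_GAP,
    DEFAULT_MIN_ANCHOR_MAPQ,
    DEFAULT_REFERENCE_DEPTH,
    SampleProfile,
    build_profile,
    estimate_depth,
    find_anchored_irrs,
)
from .motifs import DEFAULT_PURITY_THRESHOLD
from .screening import STRLocus, call_expansion, screen_locus
from .simulate import ReadSimConfig, simulate_case_control_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_discovery", "run_demo"]


@dataclass
class PipelineConfig:
    """Paths and parameters for the discovery workflow."""

    alignments: dict[str, str] = field(default_factory=dict)  # sample -> SAM path
    labels: str = ""  # two-column sample/status TSV
    reference: Optional[str] = None  # FASTA
    catalog: Optional[str] = None  # BED (chrom, start, end, motif)
    intervals: Optional[str] = None  # named BED intervals for annotation
    depth_windows: Optional[str] = None  # BED windows for depth estimation
    output_dir: str = "strexpand_out"
    min_anchor_mapq: int = DEFAULT_MIN_ANCHOR_MAPQ
    purity_threshold: float = DEFAULT_PURITY_THRESHOLD
    cluster_gap: int = DEFAULT_CLUSTER_GAP
    reference_depth: float = DEFAULT_REFERENCE_DEPTH
    n_perm: int = DEFAULT_N_PERM
    p_threshold: float = DEFAULT_P_THRESHOLD
    seed: int = 0
    screen_candidates: bool = False

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"{path}: unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_metadata(self) -> dict:
        meta = dataclasses.asdict(self)
        # paths vary between runs without affecting the analysis
        for key in ("alignments", "output_dir", "labels", "reference", "catalog",
                    "intervals", "depth_windows"):
            meta.pop(key, None)
        return meta


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StrexpandError):
                raise DataError(f"stage '{name}' failed: {exc}") from exc
            if isinstance(exc, StrexpandError) and not getattr(exc, "_staged", False):
                exc._staged = True
                exc.args = (f"stage '{name}': {exc}",)
            return False

    return _Ctx()


def run_discovery(config: PipelineConfig):
    """Execute the discovery workflow from files on disk.

    Returns a dict with the profiles, the ranked candidate table (annotated
    and Bonferroni-adjusted) and, when requested, per-sample screening calls
    at each cataloged locus. All tables are also written under
    ``config.output_dir`` with seed/parameter headers.
    """
    if not config.alignments:
        raise ConfigurationError("no alignment files configured")
    if not config.labels:
        raise ConfigurationError("no label file configured")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    with _stage("labels"):
        labels = sio.read_labels(config.labels)
    n_cases = sum(1 for s in config.alignments if labels.get(s) == "case")
    n_controls = sum(1 for s in config.alignments if labels.get(s) == "control")
    if n_cases < 1 or n_controls < 1:
        raise ConfigurationError(
            f"need >=1 case and >=1 control (got {n_cases} cases, {n_controls} controls)"
        )

    depth_windows = None
    if config.depth_windows:
        with _stage("depth-windows"):
            depth_windows = [
                (chrom, int(start), int(end))
                for chrom, start, end, *_ in sio.read_bed(config.depth_windows)
            ]

    profiles: list[SampleProfile] = []
    pairs_by_sample = {}
    with _stage("profile"):
        for sample in sorted(config.alignments):
            pairs = sio.read_sam_pairs(config.alignments[sample])
            pairs_by_sample[sample] = pairs
            if depth_windows:
                depth = estimate_depth(pairs, depth_windows)
                if depth <= 0:
                    raise DataError(f"{sample}: zero coverage in depth windows")
            else:
                depth = config.reference_depth
            irrs = find_anchored_irrs(
                pairs,
                min_anchor_mapq=config.min_anchor_mapq,
                purity_threshold=config.purity_threshold,
                sample=sample,
            )
            profile = build_profile(
                irrs,
                depth=depth,
                cluster_gap=config.cluster_gap,
                reference_depth=config.reference_depth,
                sample=sample,
            )
            profiles.append(profile)
            sio.write_profile(
                profile, outdir / f"{sample}.profile.tsv", {"seed": config.seed}
            )

    with _stage("casecontrol"):
        candidates = rank_candidates(
            profiles,
            labels,
            n_perm=config.n_perm,
            seed=config.seed,
            p_threshold=config.p_threshold,
            harmonize_gap=config.cluster_gap,
        )

    if config.intervals:
        with _stage("intersect"):
            named = [
                (str(rest[0]) if rest else f"interval{i + 1}", chrom, start + 1, end)
                for i, (chrom, start, end, *rest) in enumerate(
                    sio.read_bed(config.intervals)
                )
            ]
            candidates = intersect_candidates(candidates, named)

    with _stage("adjust"):
        candidates = adjust_genomewide(candidates)

    screen_results = None
    if config.screen_candidates and config.catalog:
        with _stage("screen"):
            screen_results = {}
            catalog = [
                STRLocus(chrom=chrom, start=start + 1, end=end, ref_motif=rest[0],
                         alt_motifs=tuple(rest[1].split(",")) if len(rest) > 1 else ())
                for chrom, start, end, *rest in sio.read_bed(config.catalog)
            ]
            for locus in catalog:
                cohort = {
                    sample: screen_locus(
                        pairs_by_sample[sample], locus,
                        purity_threshold=config.purity_threshold,
                        min_anchor_mapq=config.min_anchor_mapq,
                        sample=sample,
                    )
                    for sample in sorted(config.alignments)
                }
                calls = {}
                for sample in cohort:
                    try:
                        calls[sample] = call_expansion(cohort, sample)
                    except StrexpandError:
                        calls[sample] = cohort[sample].call
                key = f"{locus.chrom}:{locus.start}-{locus.end}"
                screen_results[key] = calls

    sio.write_candidates(
        candidates, outdir / "candidates.tsv", config.to_metadata()
    )
    bed_rows = [
        (row.chrom, row.start - 1, row.end, f"{row.motif}|rank{row.rank}")
        for row in candidates.itertuples()
    ]
    sio.write_bed(outdir / "candidates.bed", bed_rows)
    if screen_results is not None:
        with open(outdir / "screen_calls.json", "w") as fh:
            json.dump(screen_results, fh, indent=2, sort_keys=True)

    logger.info(
        "discovery complete: %d candidate loci (%d cases vs %d controls)",
        len(candidates), n_cases, n_controls,
    )
    return {"profiles": profiles, "candidates": candidates, "screen": screen_results}


def run_demo(
    output_dir: str,
    seed: int = 0,
    n_cases: int = 2,
    n_controls: int = 31,
    coverage: float = 30.0,
    n_perm: int = DEFAULT_N_PERM,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> dict:
    """Simulate the discovery design end-to-end and run the workflow on it.

    Writes the simulated FASTA/SAM/BED/labels under ``output_dir`` and then
    runs :func:`run_discovery` on those files, exactly as a user would on
    real data. Deterministic for a fixed seed.
    """
    outdir = Path(output_dir)
    (outdir / "data").mkdir(parents=True, exist_ok=True)
    sim = ReadSimConfig(coverage=coverage, seed=seed)
    reference, locus, reads, labels = simulate_case_control_cohort(
        sim, n_cases=n_cases, n_controls=n_controls
    )
    sio.write_fasta(outdir / "data" / "reference.fa", {sim.chrom: reference})
    sio.write_bed(
        outdir / "data" / "catalog.bed",
        [(locus.chrom, locus.start - 1, locus.end, locus.ref_motif, "AAGGG,AAAGG")],
    )
    # depth windows: flanks away from the locus
    sio.write_bed(
        outdir / "data" / "depth_windows.bed",
        [
            (sim.chrom, 0, max(0, locus.start - 1001)),
            (sim.chrom, locus.end + 1000, sim.reference_length),
        ],
    )
    sio.write_labels(outdir / "data" / "labels.tsv", labels)
    alignments = {}
    for sample, pairs in reads.items():
        path = outdir / "data" / f"{sample}.sam"
        sio.write_sam(path, pairs, {sim.chrom: sim.reference_length}, sample=sample)
        alignments[sample] = str(path)
    config = PipelineConfig(
        alignments=alignments,
        labels=str(outdir / "data" / "labels.tsv"),
        catalog=str(outdir / "data" / "catalog.bed"),
        depth_windows=str(outdir / "data" / "depth_windows.bed"),
        output_dir=str(outdir),
        n_perm=n_perm,
        p_threshold=p_threshold,
        seed=seed,
    )
    result = run_discovery(config)
    result["locus"] = locus
    result["config"] = config
    return result
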