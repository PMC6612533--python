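"""Readers and writers binding the pipeline stages to standard file formats.

Conventions: coordinates are 0-based half-open internally wherever BED
interoperability matters and 1-based inclusive in every human-readable
report (``chr4:38887351-40463592`` style). Chromosome names are taken as
written; comparison helpers normalise "chr4" and "4". SAM is read and
written through pysam, FASTA read through Biopython; VCF is written as plain
text and read back through pysam.

Carrier-haplotype VCF convention: one diploid sample per carrier, phased GT,
with the expansion-bearing haplotype as the *first* allele of each genotype.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from . import __version__
from .dating import HaplotypeMatrix
from .exceptions import DataError
from .profiling import AlignedRead, ReadPair, SampleProfile

logger = logging.getLogger(__name__)

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_sam",
    "read_sam_pairs",
    "read_bed",
    "write_bed",
    "read_labels",
    "write_labels",
    "read_genetic_map",
    "write_genetic_map",
    "write_carrier_vcf",
    "read_carrier_haplotypes",
    "format_region",
    "write_profile",
    "read_profile",
    "write_candidates",
]

PathLike = Union[str, Path]


# ---------------------------------------------------------------- FASTA / SAM

def read_fasta(path: PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: PathLike, sequences: Mapping[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_sam(
    path: PathLike,
    pairs: Iterable[ReadPair],
    reference_lengths: Mapping[str, int],
    sample: str = "sample",
) -> None:
    """Write read pairs as a plain-text SAM file with proper mate pointers."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in reference_lengths.items()],
        "RG": [{"ID": sample, "SM": sample}],
        "PG": [{"ID": "strexpand", "PN": "strexpand", "VN": __version__}],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        tid = {name: i for i, name in enumerate(reference_lengths)}
        for pair in pairs:
            for read, mate, first in (
                (pair.mate1, pair.mate2, True),
                (pair.mate2, pair.mate1, False),
            ):
                a = pysam.AlignedSegment(out.header)
                a.query_name = pair.name
                flag = 0x1  # paired
                flag |= 0x40 if first else 0x80
                if read.is_aligned:
                    a.reference_id = tid[read.chrom]
                    a.reference_start = read.pos - 1
                    a.cigarstring = read.cigar or f"{len(read.seq)}M"
                else:
                    flag |= 0x4
                if read.is_reverse:
                    flag |= 0x10
                if mate.is_reverse:
                    flag |= 0x20
                if mate.is_aligned:
                    a.next_reference_id = tid[mate.chrom]
                    a.next_reference_start = mate.pos - 1
                else:
                    flag |= 0x8
                if read.is_aligned and mate.is_aligned and read.chrom == mate.chrom:
                    flag |= 0x2
                    a.template_length = (
                        (mate.pos + len(mate.seq) - read.pos)
                        if mate.pos >= read.pos
                        else -(read.pos + len(read.seq) - mate.pos)
                    )
                a.flag = flag
                a.mapping_quality = read.mapq
                a.query_sequence = read.seq
                out.write(a)


def read_sam_pairs(path: PathLike) -> list[ReadPair]:
    """Read primary alignments and collate them into pairs by read name.

    Secondary and supplementary records are ignored; unpaired records are
    skipped with a logged count.
    """
    by_name: dict[str, dict[int, AlignedRead]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            read = AlignedRead(
                chrom=None if rec.is_unmapped else rec.reference_name,
                pos=None if rec.is_unmapped else rec.reference_start + 1,
                mapq=rec.mapping_quality,
                seq=rec.query_sequence or "",
                cigar=(rec.cigarstring or "") if not rec.is_unmapped else "",
                is_reverse=rec.is_reverse,
            )
            slot = 1 if rec.is_read1 or not rec.is_paired else 2
            by_name.setdefault(rec.query_name, {})[slot] = read
    pairs = []
    n_unpaired = 0
    for name in sorted(by_name):
        mates = by_name[name]
        if len(mates) != 2:
            n_unpaired += 1
            continue
        pairs.append(ReadPair(name=name, mate1=mates[1], mate2=mates[2]))
    if n_unpaired:
        logger.warning("%s: skipped %d unpaired records", path, n_unpaired)
    return pairs


# ------------------------------------------------------------------ BED & TSV

def read_bed(path: PathLike) -> list[tuple]:
    """Read a BED file (0-based half-open); returns (chrom, start, end[, name...])."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"{path}:{lineno}: BED line has {len(fields)} fields, need >=3")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if start < 0 or end < start:
                raise DataError(f"{path}:{lineno}: invalid BED interval {start}-{end}")
            rows.append((fields[0], start, end, *fields[3:]))
    return rows


def write_bed(path: PathLike, intervals: Iterable[Sequence]) -> None:
    with open(path, "w") as fh:
        for interval in intervals:
            fh.write("\t".join(str(v) for v in interval) + "\n")


def read_labels(path: PathLike) -> dict[str, str]:
    """Two-column sample/status table; status must be case or control."""
    labels = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise DataError(f"{path}:{lineno}: expected 'sample<TAB>status'")
            sample, status = fields
            if status not in ("case", "control"):
                raise DataError(f"{path}:{lineno}: status must be case/control, got {status!r}")
            labels[sample] = status
    return labels


def write_labels(path: PathLike, labels: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for sample, status in labels.items():
            fh.write(f"{sample}\t{status}\n")


def read_genetic_map(path: PathLike) -> pd.DataFrame:
    """Three-column genetic map: chrom, bp position, cM position."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["chrom", "bp", "cm"]
    )
    if df.empty:
        raise DataError(f"{path}: empty genetic map")
    if not np.issubdtype(df["bp"].dtype, np.integer):
        try:
            df["bp"] = df["bp"].astype(int)
        except (ValueError, TypeError) as exc:
            raise DataError(f"{path}: non-integer bp column") from exc
    df["cm"] = df["cm"].astype(float)
    return df


def write_genetic_map(path: PathLike, markers: pd.DataFrame) -> None:
    markers[["chrom", "bp", "cm"]].to_csv(path, sep="\t", header=False, index=False)


# ----------------------------------------------------------------------- VCF

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=strexpand-{version}
##FORMAT=<ID=GT,Number=1,Type=String,Description="Phased genotype; first allele is the expansion-bearing haplotype">
##contig=<ID={chrom}>
"""


def write_carrier_vcf(matrix: HaplotypeMatrix, path: PathLike) -> None:
    """Write carrier haplotypes as a phased VCF (first GT allele = carrier).

    Allele codes map to REF=A (0) and ALT=G (1); the partner haplotype is
    written as 0 (it carries no information in this representation).
    """
    chroms = matrix.markers["chrom"].unique()
    if len(chroms) != 1:
        raise DataError("carrier VCF expects markers on a single chromosome")
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(version=__version__, chrom=chroms[0]))
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        hap = matrix.haplotypes
        for j, row in enumerate(matrix.markers.itertuples()):
            gts = "\t".join(f"{int(hap[i, j])}|0" for i in range(hap.shape[0]))
            fh.write(
                f"{row.chrom}\t{int(row.bp)}\t.\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_carrier_haplotypes(
    vcf_path: PathLike, genetic_map: Union[PathLike, pd.DataFrame], focal_bp: int
) -> HaplotypeMatrix:
    """Load phased carrier haplotypes plus the genetic map into a matrix.

    The first allele of each phased genotype is the expansion-bearing
    haplotype. Unphased genotypes are rejected — haplotype sharing is only
    defined on phased chromosomes. Every VCF site must appear in the map.
    """
    if not isinstance(genetic_map, pd.DataFrame):
        genetic_map = read_genetic_map(genetic_map)
    cm_by_pos = {
        (row.chrom, int(row.bp)): float(row.cm) for row in genetic_map.itertuples()
    }
    rows = []
    haplotype_cols: list[list[int]] = []
    samples: list[str] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            key = (rec.chrom, rec.pos)
            if key not in cm_by_pos:
                raise DataError(
                    f"{vcf_path}: site {rec.chrom}:{rec.pos} missing from the genetic map"
                )
            alleles = []
            for sample in samples:
                call = rec.samples[sample]
                if not call.phased:
                    raise DataError(
                        f"{vcf_path}: unphased genotype for {sample} at "
                        f"{rec.chrom}:{rec.pos}; carrier haplotypes must be phased "
                        "(first allele = expansion-bearing chromosome)"
                    )
                gt = call["GT"]
                if gt is None or gt[0] is None:
                    raise DataError(
                        f"{vcf_path}: missing genotype for {sample} at {rec.chrom}:{rec.pos}"
                    )
                alleles.append(int(gt[0]))
            rows.append((rec.chrom, rec.pos, cm_by_pos[key]))
            haplotype_cols.append(alleles)
    if not rows:
        raise DataError(f"{vcf_path}: no variant records")
    markers = pd.DataFrame(rows, columns=["chrom", "bp", "cm"])
    order = np.argsort(markers["bp"].to_numpy(), kind="mergesort")
    markers = markers.iloc[order].reset_index(drop=True)
    hap = np.asarray(haplotype_cols, dtype=np.int8).T[:, order]
    focal_hits = np.nonzero(markers["bp"].to_numpy() == focal_bp)[0]
    if focal_hits.size == 0:
        raise DataError(f"focal position {focal_bp} not present in {vcf_path}")
    return HaplotypeMatrix(
        markers=markers,
        haplotypes=hap,
        focal_index=int(focal_hits[0]),
        samples=samples,
    )


# ------------------------------------------------------------------- reports

def format_region(chrom: str, start0: int, end0: int) -> str:
    """1-based inclusive report of a 0-based half-open interval.

    >>> format_region("chr4", 38887350, 40463592)
    'chr4:38887351-40463592'
    """
    return f"{chrom}:{start0 + 1}-{end0}"


def _header_lines(metadata: Mapping[str, object]) -> str:
    items = {"tool": "strexpand", "version": __version__, **metadata}
    blob = json.dumps(items, sort_keys=True, default=str)
    digest = hashlib.sha256(blob.encode()).hexdigest()[:12]
    lines = [f"# {k} = {v}" for k, v in items.items()]
    lines.append(f"# config_hash = {digest}")
    return "\n".join(lines) + "\n"


def write_profile(
    profile: SampleProfile, path: PathLike, metadata: Optional[Mapping] = None
) -> None:
    """Profile as TSV: sample, motif, chrom, start, end, raw_count, norm_count."""
    with open(path, "w") as fh:
        fh.write(
            _header_lines(
                {
                    "sample": profile.sample,
                    "depth": round(profile.depth, 4),
                    "reference_depth": profile.reference_depth,
                    **(metadata or {}),
                }
            )
        )
        df = profile.counts.copy()
        df.insert(0, "sample", profile.sample)
        df.to_csv(fh, sep="\t", index=False)


def read_profile(path: PathLike) -> SampleProfile:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            pos = fh.tell()
            if "=" in line:
                key, value = line[1:].split("=", 1)
                meta[key.strip()] = value.strip()
        df = pd.read_csv(fh, sep="\t")
    if "sample" not in df.columns:
        raise DataError(f"{path}: not a profile table")
    sample = meta.get("sample", df["sample"].iloc[0] if len(df) else "sample")
    depth = float(meta.get("depth", "30"))
    reference_depth = float(meta.get("reference_depth", "30"))
    return SampleProfile(
        sample=sample,
        depth=depth,
        counts=df.drop(columns=["sample"]),
        reference_depth=reference_depth,
    )


def write_candidates(
    candidates: pd.DataFrame, path: PathLike, metadata: Optional[Mapping] = None
) -> None:
    """Candidate table as TSV with header metadata (n_perm, seed, threshold)."""
    meta = {
        key: candidates.attrs[key]
        for key in ("n_perm", "seed", "p_threshold", "n_tested_regions")
        if key in candidates.attrs
    }
    meta.update(metadata or {})
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        df = candidates.copy()
        df["region"] = [
            format_region(c, s - 1, e)
            for c, s, e in zip(df["chrom"], df["start"], df["end"])
        ]
        df.to_csv(fh, sep="\t", index=False)
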