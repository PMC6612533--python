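"""Permutation-based case-control ranking of candidate expansion loci.

For each (motif, region) the statistic is the difference of group means of
depth-normalised anchored-IRR counts, cases minus controls; the alternative
is one-sided because an expansion can only inflate IRR counts. With a tiny
case group the permutation null is enumerated exhaustively — with 2 cases and
31 controls there are only C(33,2) = 528 distinct label assignments, so the
smallest attainable p-value is 1/528 and genome-wide significance is
structurally out of reach at that design, however strong the signal.
"""

from __future__ import annotations

import logging
from math import comb
from itertools import combinations, islice
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InvalidParameterError
from .profiling import DEFAULT_CLUSTER_GAP, SampleProfile

logger = logging.getLogger(__name__)

__all__ = [
    "permutation_test",
    "rank_candidates",
    "intersect_candidates",
    "adjust_genomewide",
    "DEFAULT_N_PERM",
    "DEFAULT_P_THRESHOLD",
]

DEFAULT_N_PERM = 1_000_000
DEFAULT_P_THRESHOLD = 0.005

_SAMPLE_CHUNK = 50_000


def permutation_test(
    case_counts: Sequence[float],
    control_counts: Sequence[float],
    n_perm: int = DEFAULT_N_PERM,
    seed: Union[int, np.random.Generator, None] = None,
) -> float:
    """One-sided permutation p-value for mean(case) - mean(control).

    When the number of distinct case-label assignments C(n_case+n_ctrl,
    n_case) does not exceed ``n_perm`` the null is enumerated exhaustively and
    p = (# assignments with statistic >= observed) / (total assignments).
    Otherwise ``n_perm`` random assignments are drawn and the add-one
    correction p = (1 + exceedances) / (1 + n_perm) avoids p = 0.
    """
    case = np.asarray(case_counts, dtype=float)
    ctrl = np.asarray(control_counts, dtype=float)
    if case.size == 0 or ctrl.size == 0:
        raise InvalidParameterError("both groups must be non-empty")
    if n_perm < 1:
        raise InvalidParameterError("n_perm must be >= 1")
    pool = np.concatenate([case, ctrl])
    n, k = pool.size, case.size
    # mean(case) - mean(control) is monotone increasing in the case-subset sum,
    # so permutations are compared on subset sums alone.
    s_obs = float(case.sum())
    eps = 1e-9 * (1.0 + abs(s_obs))
    if comb(n, k) <= n_perm:
        exceed = 0
        total = 0
        gen = combinations(range(n), k)
        while True:
            block = np.fromiter(
                (i for idx in islice(gen, _SAMPLE_CHUNK) for i in idx),
                dtype=np.intp,
            ).reshape(-1, k)
            if block.size == 0:
                break
            sums = pool[block].sum(axis=1)
            exceed += int((sums >= s_obs - eps).sum())
            total += block.shape[0]
        return exceed / total
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exceed = 0
    remaining = n_perm
    while remaining > 0:
        chunk = min(remaining, _SAMPLE_CHUNK)
        tiles = np.tile(pool, (chunk, 1))
        rng.permuted(tiles, axis=1, out=tiles)
        sums = tiles[:, :k].sum(axis=1)
        exceed += int((sums >= s_obs - eps).sum())
        remaining -= chunk
    return (1 + exceed) / (1 + n_perm)


def _union_regions(
    intervals: list[tuple[int, int]], gap: int
) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals, merging those within ``gap``."""
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + gap + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def rank_candidates(
    profiles: Sequence[SampleProfile],
    labels: Mapping[str, str],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    harmonize_gap: int = DEFAULT_CLUSTER_GAP,
) -> pd.DataFrame:
    """Rank candidate (motif, region) loci by permutation p-value.

    Regions are harmonised across samples by motif-wise interval union (so a
    locus whose per-sample regions differ slightly in extent is tested once);
    samples lacking a region contribute count 0. All regions with
    p < ``p_threshold`` are returned ranked by ascending p, ties broken by
    descending statistic.
    """
    missing = [p.sample for p in profiles if p.sample not in labels]
    if missing:
        raise ConfigurationError(f"no case/control label for samples: {missing}")
    statuses = {labels[p.sample] for p in profiles}
    bad = statuses - {"case", "control"}
    if bad:
        raise ConfigurationError(f"labels must be 'case' or 'control', got {sorted(bad)}")
    case_samples = [p.sample for p in profiles if labels[p.sample] == "case"]
    ctrl_samples = [p.sample for p in profiles if labels[p.sample] == "control"]
    if not case_samples or not ctrl_samples:
        raise ConfigurationError(
            f"need >=1 case and >=1 control profile "
            f"(got {len(case_samples)} cases, {len(ctrl_samples)} controls)"
        )

    per_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for prof in profiles:
        for row in prof.counts.itertuples():
            per_key.setdefault((row.motif, row.chrom), []).append((row.start, row.end))

    ss = np.random.SeedSequence(seed)
    rows = []
    keys = sorted(per_key)
    region_list: list[tuple[str, str, int, int]] = []
    for motif, chrom in keys:
        for start, end in _union_regions(per_key[(motif, chrom)], harmonize_gap):
            region_list.append((motif, chrom, start, end))
    child_seeds = ss.spawn(len(region_list)) if region_list else []
    for (motif, chrom, start, end), child in zip(region_list, child_seeds):
        counts = {}
        for prof in profiles:
            sub = prof.counts
            mask = (
                (sub["motif"] == motif)
                & (sub["chrom"] == chrom)
                & (sub["start"] <= end)
                & (sub["end"] >= start)
            )
            counts[prof.sample] = float(sub.loc[mask, "norm_count"].sum())
        case = [counts[s] for s in case_samples]
        ctrl = [counts[s] for s in ctrl_samples]
        p = permutation_test(
            case, ctrl, n_perm=n_perm, seed=np.random.default_rng(child)
        )
        rows.append(
            {
                "motif": motif,
                "chrom": chrom,
                "start": start,
                "end": end,
                "case_mean": float(np.mean(case)),
                "control_mean": float(np.mean(ctrl)),
                "statistic": float(np.mean(case) - np.mean(ctrl)),
                "p_value": p,
            }
        )
    columns = [
        "motif", "chrom", "start", "end",
        "case_mean", "control_mean", "statistic", "p_value", "rank",
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=columns)
    df.attrs["n_tested_regions"] = len(df)
    df = df[df["p_value"] < p_threshold]
    df = df.sort_values(
        ["p_value", "statistic"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df.attrs["n_perm"] = n_perm
    df.attrs["seed"] = seed
    df.attrs["p_threshold"] = p_threshold
    return df


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def intersect_candidates(
    candidates: pd.DataFrame,
    intervals: Iterable[tuple[str, str, int, int]],
) -> pd.DataFrame:
    """Annotate candidates with names of overlapping genomic intervals.

    ``intervals`` yields ``(name, chrom, start, end)`` with 1-based inclusive
    coordinates. Overlap uses half-open arithmetic internally (any-overlap
    rule): a candidate that merely abuts an interval end does not annotate.
    Chromosome names are normalised ("chr4" == "4"), and normalisation is
    logged when it changes a name.
    """
    intervals = list(intervals)
    for name, chrom, _s, _e in intervals:
        if _norm_chrom(chrom) != chrom:
            logger.debug("normalised interval chromosome %s -> %s (%s)", chrom, _norm_chrom(chrom), name)
    out = candidates.copy()
    annotations = []
    for row in out.itertuples():
        c0, s0, e0 = _norm_chrom(row.chrom), row.start - 1, row.end
        hits = [
            name
            for name, chrom, start, end in intervals
            if _norm_chrom(chrom) == c0 and s0 < end and (start - 1) < e0
        ]
        annotations.append(";".join(hits))
    out["annotations"] = annotations
    return out


def adjust_genomewide(
    candidates: pd.DataFrame, n_tested_regions: Optional[int] = None
) -> pd.DataFrame:
    """Bonferroni adjustment: p_adjusted = min(1, p * n_tested_regions)."""
    if n_tested_regions is None:
        n_tested_regions = candidates.attrs.get("n_tested_regions", len(candidates))
    if n_tested_regions < len(candidates):
        raise InvalidParameterError(
            "n_tested_regions must be at least the number of candidates"
        )
    out = candidates.copy()
    out["p_adjusted"] = np.minimum(1.0, out["p_value"] * n_tested_regions)
    return out
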