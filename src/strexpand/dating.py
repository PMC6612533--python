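"""Core-haplotype extraction and haplotype-sharing MRCA age estimation.

Carriers of a mutation that arose once in history share an ancestral
haplotype around it, eroded by recombination each generation. Under a star
genealogy — every carrier descends independently from the most recent common
ancestor (MRCA) — the genetic length shared on one side of the focal locus is
exponentially distributed with rate g per Morgan, where g is the number of
generations to the MRCA. With m uncensored one-sided lengths summing to S
Morgans, 2gS ~ chi-squared with 2m degrees of freedom, giving the maximum
likelihood estimate g_hat = m / S and the exact pivot 95% interval
[chi2(0.025, 2m) / 2S, chi2(0.975, 2m) / 2S].

Observed lengths are interval-censored by the marker grid; the breakpoint is
taken at the midpoint between the last matching and first mismatching
marker. Lengths running to the edge of the map — or to the point where the
ancestral haplotype can no longer be reconstructed — are right-censored:
their magnitude still contributes to the total time on test in the
denominator (the standard censored-exponential likelihood, which keeps the
chi-squared pivot exact under type-II censoring), but only uncensored
lengths count toward m. These modelling choices — star genealogy, midpoint
correction, censored handling — are surfaced in the output metadata.

The ancestral haplotype beyond the core is reconstructed by peeling: moving
outward from the focal marker, the consensus allele is taken among the
carriers that still match the consensus at every marker so far. Carriers
that have recombined away drop out, so the consensus tracks the ancestral
chromosome far beyond the point where a plain per-marker majority would be
swamped by background alleles; once fewer than two carriers remain the
ancestral allele is undefined and the surviving run is censored there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    CannotEstimateError,
    DegenerateCoreError,
    InvalidParameterError,
)

__all__ = [
    "HaplotypeMatrix",
    "CoreHaplotype",
    "MRCAEstimate",
    "core_haplotype",
    "shared_lengths",
    "estimate_mrca",
    "cluster_subhaplotypes",
    "allele_frequency",
    "DEFAULT_GENERATION_TIME",
    "DEFAULT_MAJORITY",
    "DEFAULT_CLUSTER_MARGIN_CM",
]

DEFAULT_GENERATION_TIME = 25.0  # years; configurable, not an empirical claim
DEFAULT_MAJORITY = 0.5
DEFAULT_CLUSTER_MARGIN_CM = 0.5


@dataclass
class HaplotypeMatrix:
    """Phased carrier haplotypes on an ordered marker map.

    ``markers`` has columns ``chrom, bp, cm`` (cM non-decreasing with bp);
    ``haplotypes`` is an (n_haplotypes, n_markers) integer allele matrix, one
    row per expansion-bearing carrier chromosome; ``focal_index`` is the
    marker index of the STR locus.
    """

    markers: pd.DataFrame
    haplotypes: np.ndarray
    focal_index: int
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes)
        n_hap, n_markers = self.haplotypes.shape
        if len(self.markers) != n_markers:
            raise InvalidParameterError(
                f"{n_markers} haplotype columns but {len(self.markers)} markers"
            )
        if not (0 <= self.focal_index < n_markers):
            raise InvalidParameterError("focal_index outside marker range")
        cm = np.asarray(self.markers["cm"], dtype=float)
        if np.any(np.diff(cm) < 0):
            raise InvalidParameterError("cM positions must be non-decreasing")
        if not self.samples:
            self.samples = [f"hap{i + 1}" for i in range(n_hap)]

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def cm(self) -> np.ndarray:
        return np.asarray(self.markers["cm"], dtype=float)


@dataclass
class CoreHaplotype:
    """Maximal marker interval around the focal locus shared by a majority.

    ``alleles`` is the peeled consensus estimate of the ancestral haplotype,
    defined on ``consensus_left..consensus_right`` (outside that range the
    ancestral allele cannot be reconstructed from the carriers and the value
    is meaningless); ``left_index..right_index`` delimit the core interval
    over which the sharing fraction stays at or above the majority
    threshold.
    """

    left_index: int
    right_index: int
    alleles: np.ndarray
    bp_span: int
    cm_length: float
    share_fraction: np.ndarray
    consensus_left: int = 0
    consensus_right: int = -1

    @property
    def n_markers(self) -> int:
        return self.right_index - self.left_index + 1


@dataclass
class MRCAEstimate:
    """Generations to the MRCA with its 95% confidence interval."""

    g_hat: float
    ci_low: float
    ci_high: float
    years: float
    years_ci_low: float
    years_ci_high: float
    n_haplotypes: int
    n_uncensored: int
    n_censored: int
    total_shared_morgans: float
    generation_time: float
    model: str = (
        "star-genealogy exponential; midpoint breakpoint correction; "
        "censored lengths enter the total time on test only"
    )

    def summary(self) -> str:
        lines = [
            "MRCA age estimate (haplotype sharing)",
            "-" * 44,
            f"generations to MRCA    {self.g_hat:12.1f}",
            f"95% CI (generations)   [{self.ci_low:.1f}, {self.ci_high:.1f}]",
            f"years (x{self.generation_time:g}/gen)      {self.years:12.0f}",
            f"95% CI (years)         [{self.years_ci_low:.0f}, {self.years_ci_high:.0f}]",
            f"carrier haplotypes     {self.n_haplotypes:12d}",
            f"one-sided lengths used {self.n_uncensored:12d}",
            f"censored lengths       {self.n_censored:12d}",
            f"total shared (Morgan)  {self.total_shared_morgans:12.4f}",
            f"model: {self.model}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "g_hat": self.g_hat,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "years": self.years,
            "years_ci_low": self.years_ci_low,
            "years_ci_high": self.years_ci_high,
            "n_haplotypes": self.n_haplotypes,
            "n_uncensored": self.n_uncensored,
            "n_censored": self.n_censored,
            "total_shared_morgans": self.total_shared_morgans,
            "generation_time": self.generation_time,
            "model": self.model,
        }


def core_haplotype(
    matrix: HaplotypeMatrix, majority: float = DEFAULT_MAJORITY
) -> CoreHaplotype:
    """Identify the core shared haplotype around the focal marker.

    The modal allele is taken per marker (ties to the smallest allele code);
    the interval extends left and right from the focal marker while the
    fraction of carrier haplotypes matching the modal allele strictly
    exceeds ``majority`` (unanimity always qualifies, so ``majority=1.0``
    demands complete sharing). The strict comparison matters on biallelic
    markers, where the modal fraction can never drop below one half.
    """
    if matrix.n_haplotypes < 2:
        raise InvalidParameterError("need >=2 carrier haplotypes")
    if not (0 < majority <= 1):
        raise InvalidParameterError("majority must be in (0, 1]")
    hap = matrix.haplotypes
    n_hap, n_markers = hap.shape
    lo, hi = int(hap.min()), int(hap.max())
    if hi - lo < 64:
        # small allele alphabet: vectorise per-allele counts across markers
        counts = np.stack([(hap == a).sum(axis=0) for a in range(lo, hi + 1)])
        best = counts.argmax(axis=0)  # first (smallest) allele wins ties
        modal = (best + lo).astype(hap.dtype)
        frac = counts.max(axis=0) / n_hap
    else:
        modal = np.empty(n_markers, dtype=hap.dtype)
        frac = np.empty(n_markers, dtype=float)
        for j in range(n_markers):
            values, cnt = np.unique(hap[:, j], return_counts=True)
            b = np.argmax(cnt)  # np.unique sorts, so ties go to smallest value
            modal[j] = values[b]
            frac[j] = cnt[b] / n_hap
    focal = matrix.focal_index
    focal_matches = int((hap[:, focal] == modal[focal]).sum())
    if focal_matches < 2:
        raise DegenerateCoreError(
            "no carrier shares the modal allele at the focal marker with any other"
        )
    def _shared(j: int) -> bool:
        return frac[j] > majority or frac[j] == 1.0

    left = focal
    while left > 0 and _shared(left - 1):
        left -= 1
    right = focal
    while right < n_markers - 1 and _shared(right + 1):
        right += 1
    bp = np.asarray(matrix.markers["bp"], dtype=int)
    cm = matrix.cm
    ancestral, cons_left, cons_right = _peel_ancestral(hap, focal, modal[focal])
    return CoreHaplotype(
        left_index=left,
        right_index=right,
        alleles=ancestral,
        bp_span=int(bp[right] - bp[left] + 1),
        cm_length=float(cm[right] - cm[left]),
        share_fraction=frac,
        consensus_left=cons_left,
        consensus_right=cons_right,
    )


def _column_modal(column: np.ndarray) -> int:
    values, counts = np.unique(column, return_counts=True)
    return int(values[np.argmax(counts)])  # ties to the smallest allele code


def _peel_ancestral(
    hap: np.ndarray, focal: int, focal_allele: int
) -> tuple[np.ndarray, int, int]:
    """Peeling reconstruction of the ancestral haplotype.

    Moving outward from the focal marker, the consensus allele is the modal
    allele among carriers that still match the consensus at every marker
    visited so far; mismatching carriers drop out. Reconstruction stops in
    each direction once fewer than two carriers remain. Returns the
    consensus vector and the index range on which it is defined.
    """
    n_hap, n_markers = hap.shape
    anc = np.array(hap[0], copy=True)  # values outside the defined range are meaningless
    anc[focal] = focal_allele
    cons_right = focal
    alive = hap[:, focal] == focal_allele
    for j in range(focal + 1, n_markers):
        if int(alive.sum()) < 2:
            break
        anc[j] = _column_modal(hap[alive, j])
        alive = alive & (hap[:, j] == anc[j])
        cons_right = j
    cons_left = focal
    alive = hap[:, focal] == focal_allele
    for j in range(focal - 1, -1, -1):
        if int(alive.sum()) < 2:
            break
        anc[j] = _column_modal(hap[alive, j])
        alive = alive & (hap[:, j] == anc[j])
        cons_left = j
    return anc, cons_left, cons_right


def shared_lengths(
    matrix: HaplotypeMatrix,
    ancestral_alleles: Union[np.ndarray, CoreHaplotype],
) -> pd.DataFrame:
    """Per-haplotype shared genetic lengths left and right of the focal locus.

    Each carrier haplotype is extended from the focal marker while it matches
    the ancestral allele; the breakpoint is placed at the midpoint of the
    interval between the last matching and first mismatching marker. Lengths
    reaching the map edge — or, when a :class:`CoreHaplotype` is supplied,
    the edge of its defined consensus — are flagged right-censored at that
    point. Columns: ``sample, left_cm, right_cm, left_censored,
    right_censored`` (lengths in cM).
    """
    if isinstance(ancestral_alleles, CoreHaplotype):
        ancestral = np.asarray(ancestral_alleles.alleles)
        lo, hi = ancestral_alleles.consensus_left, ancestral_alleles.consensus_right
    else:
        ancestral = np.asarray(ancestral_alleles)
        lo, hi = 0, ancestral.shape[0] - 1
    hap = matrix.haplotypes
    if ancestral.shape[0] != hap.shape[1]:
        raise InvalidParameterError("ancestral allele vector length mismatch")
    cm = matrix.cm
    focal = matrix.focal_index
    if not (lo <= focal <= hi):
        raise InvalidParameterError("focal marker outside the defined consensus range")
    rows = []
    for i in range(hap.shape[0]):
        match = hap[i] == ancestral
        if not match[focal]:
            rows.append(
                {
                    "sample": matrix.samples[i],
                    "left_cm": 0.0, "right_cm": 0.0,
                    "left_censored": False, "right_censored": False,
                }
            )
            continue
        # right side: consensus defined on focal..hi
        mism = np.nonzero(~match[focal + 1 : hi + 1])[0]
        if mism.size == 0:
            right = cm[hi] - cm[focal]
            right_cens = True
        else:
            j = focal + 1 + mism[0]  # first mismatching marker
            right = (cm[j - 1] + cm[j]) / 2.0 - cm[focal]
            right_cens = False
        # left side: consensus defined on lo..focal
        mism = np.nonzero(~match[lo:focal][::-1])[0]
        if mism.size == 0:
            left = cm[focal] - cm[lo]
            left_cens = True
        else:
            j = focal - 1 - mism[0]
            left = cm[focal] - (cm[j] + cm[j + 1]) / 2.0
            left_cens = False
        rows.append(
            {
                "sample": matrix.samples[i],
                "left_cm": float(left),
                "right_cm": float(right),
                "left_censored": left_cens,
                "right_censored": right_cens,
            }
        )
    return pd.DataFrame(rows)


def estimate_mrca(
    lengths: Union[pd.DataFrame, Sequence[tuple[float, float]]],
    generation_time: float = DEFAULT_GENERATION_TIME,
    lengths_in_cm: Optional[bool] = None,
) -> MRCAEstimate:
    """Estimate generations to the MRCA from one-sided shared lengths.

    ``lengths`` is either the DataFrame from :func:`shared_lengths` (cM, with
    censor flags) or a sequence of ``(left, right)`` pairs in Morgans. The
    estimator is the censored-exponential MLE: g_hat = m / S where m counts
    the uncensored one-sided lengths and S is the total time on test (all
    lengths, censored magnitudes included). At least one uncensored length
    is required; under type-II censoring 2gS is exactly chi-squared with 2m
    degrees of freedom, which the 95% interval inverts.
    """
    if generation_time <= 0:
        raise InvalidParameterError("generation_time must be positive")
    if isinstance(lengths, pd.DataFrame):
        if lengths_in_cm is None:
            lengths_in_cm = True
        observed, censored = [], []
        for row in lengths.itertuples():
            (censored if row.left_censored else observed).append(row.left_cm)
            (censored if row.right_censored else observed).append(row.right_cm)
        n_hap = len(lengths)
    else:
        pairs = list(lengths)
        if lengths_in_cm is None:
            lengths_in_cm = False
        observed = [v for pair in pairs for v in pair]
        censored = []
        n_hap = len(pairs)
    obs = np.asarray(observed, dtype=float)
    cens = np.asarray(censored, dtype=float)
    if lengths_in_cm:
        obs, cens = obs / 100.0, cens / 100.0
    if obs.size == 0:
        raise CannotEstimateError("no uncensored one-sided lengths")
    if np.any(obs < 0) or np.any(cens < 0):
        raise InvalidParameterError("shared lengths must be non-negative")
    m = obs.size
    n_censored = cens.size
    total = float(obs.sum() + cens.sum())
    if total <= 0:
        raise CannotEstimateError("total shared length is zero")
    g_hat = m / total
    ci_low = float(stats.chi2.ppf(0.025, 2 * m) / (2 * total))
    ci_high = float(stats.chi2.ppf(0.975, 2 * m) / (2 * total))
    return MRCAEstimate(
        g_hat=float(g_hat),
        ci_low=ci_low,
        ci_high=ci_high,
        years=float(g_hat * generation_time),
        years_ci_low=float(ci_low * generation_time),
        years_ci_high=float(ci_high * generation_time),
        n_haplotypes=n_hap,
        n_uncensored=m,
        n_censored=n_censored,
        total_shared_morgans=total,
        generation_time=float(generation_time),
    )


def _pairwise_extent(
    hap: np.ndarray, i: int, j: int, focal: int
) -> tuple[int, int]:
    """Maximal marker interval around focal on which haplotypes i and j agree."""
    match = hap[i] == hap[j]
    if not match[focal]:
        return focal, focal - 1  # empty
    mism = np.nonzero(~match[focal + 1 :])[0]
    right = hap.shape[1] - 1 if mism.size == 0 else focal + mism[0]
    mism = np.nonzero(~match[:focal][::-1])[0]
    left = 0 if mism.size == 0 else focal - mism[0]
    return left, right


def cluster_subhaplotypes(
    matrix: HaplotypeMatrix,
    core: CoreHaplotype,
    margin_cm: float = DEFAULT_CLUSTER_MARGIN_CM,
    generation_time: float = DEFAULT_GENERATION_TIME,
) -> tuple[pd.DataFrame, dict[str, Optional[MRCAEstimate]]]:
    """Group carriers whose pairwise sharing extends beyond the core.

    Two carriers link when their pairwise shared segment extends at least
    ``margin_cm`` beyond the core interval on either side; groups are the
    connected components (greedy single linkage), labelled A, B, ... in
    order of first member. Carriers without any extended sharing are
    labelled "N". Each group with >=2 members is re-dated on its own
    consensus haplotype.

    Returns the per-carrier assignment table and a mapping from group label
    to its :class:`MRCAEstimate` (None when a group cannot be dated).
    """
    hap = matrix.haplotypes
    n = hap.shape[0]
    cm = matrix.cm
    focal = matrix.focal_index
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            li, ri = _pairwise_extent(hap, i, j, focal)
            if ri < li:
                continue
            left_ext = cm[core.left_index] - cm[li]
            right_ext = cm[ri] - cm[core.right_index]
            if left_ext >= margin_cm or right_ext >= margin_cm:
                parent[find(i)] = find(j)
    components: dict[int, list[int]] = {}
    for i in range(n):
        components.setdefault(find(i), []).append(i)
    groups = sorted(
        (members for members in components.values() if len(members) >= 2),
        key=lambda members: members[0],
    )
    labels = [""] * n
    estimates: dict[str, Optional[MRCAEstimate]] = {}
    for gi, members in enumerate(groups):
        label = chr(ord("A") + gi)
        for i in members:
            labels[i] = label
        sub = HaplotypeMatrix(
            markers=matrix.markers,
            haplotypes=hap[members],
            focal_index=focal,
            samples=[matrix.samples[i] for i in members],
        )
        try:
            sub_core = core_haplotype(sub)
            lens = shared_lengths(sub, sub_core)
            estimates[label] = estimate_mrca(lens, generation_time=generation_time)
        except (DegenerateCoreError, CannotEstimateError):
            estimates[label] = None
    for i in range(n):
        if not labels[i]:
            labels[i] = "N"
    assignment = pd.DataFrame({"sample": matrix.samples, "group": labels})
    return assignment, estimates


def allele_frequency(
    n_het: int, n_hom: int, n_individuals: int, decimals: int = 3
) -> float:
    """Carrier allele frequency (n_het + 2 n_hom) / (2 n_individuals)."""
    if n_individuals <= 0:
        raise InvalidParameterError("n_individuals must be positive")
    if n_het < 0 or n_hom < 0:
        raise InvalidParameterError("carrier counts must be non-negative")
    if n_het + n_hom > n_individuals:
        raise InvalidParameterError("more carriers than individuals")
    return round((n_het + 2 * n_hom) / (2 * n_individuals), decimals)
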