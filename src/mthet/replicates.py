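"""Triplicate-PCR concordance: consensus truth sets, confusion matrices,
per-sample sensitivity and specificity.

Because no orthogonal method resolves heteroplasmy down to 0.2% MAF, a site
is taken as "true heteroplasmic" in a sample when it is called in at least
``k`` of the sample's replicate PCR libraries (default k = 2 of 3).  Each
replicate is then scored against that consensus over all 853 fragment
positions: tp + fp + fn + tn always equals the fragment length.

Sensitivity = tp / (tp + fn) and specificity = tn / (tn + fp); ratios with a
zero denominator are undefined and are excluded from cohort means (never
imputed), with the number of skipped values reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coords import default_coords
from .errors import CoordinateError, DegenerateStatisticError, ParameterError

__all__ = [
    "ReplicateSet",
    "ConfusionSummary",
    "consensus_truth",
    "replicate_confusion",
    "cohort_replicate_report",
    "replicate_maf_dispersion",
]


@dataclass(frozen=True)
class ReplicateSet:
    """Call-site sets from >= 2 replicate libraries of one sample."""

    sample_id: str
    replicate_sites: tuple[frozenset[int], ...]

    def __post_init__(self) -> None:
        if len(self.replicate_sites) < 2:
            raise ParameterError("at least 2 replicates are required")

    @classmethod
    def from_sets(cls, sample_id: str, sets: Sequence[Iterable[int]]) -> "ReplicateSet":
        return cls(sample_id, tuple(frozenset(int(s) for s in rep) for rep in sets))


@dataclass(frozen=True)
class ConfusionSummary:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def sensitivity(self) -> float | None:
        denom = self.tp + self.fn
        return self.tp / denom if denom > 0 else None

    @property
    def specificity(self) -> float | None:
        denom = self.tn + self.fp
        return self.tn / denom if denom > 0 else None


def consensus_truth(replicates: ReplicateSet, k: int = 2) -> frozenset[int]:
    """Sites present in at least ``k`` replicate call sets.

    k = 1 gives the union, k = n_replicates the intersection.
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if k > len(replicates.replicate_sites):
        raise ParameterError(
            f"k = {k} exceeds replicate count {len(replicates.replicate_sites)}"
        )
    counts: dict[int, int] = {}
    for rep in replicates.replicate_sites:
        for site in rep:
            counts[site] = counts.get(site, 0) + 1
    return frozenset(site for site, n in counts.items() if n >= k)


def replicate_confusion(
    replicate_sites: Iterable[int],
    truth: Iterable[int],
    all_sites: Sequence[int] | np.ndarray | None = None,
) -> ConfusionSummary:
    """Confusion cells of one replicate against the consensus truth set."""
    if all_sites is None:
        all_sites = default_coords().positions
    universe = set(int(p) for p in all_sites)
    rep = set(int(p) for p in replicate_sites)
    tru = set(int(p) for p in truth)
    for label, s in (("replicate", rep), ("truth", tru)):
        stray = s - universe
        if stray:
            raise CoordinateError(f"{label} sites outside the assessed positions: {sorted(stray)[:5]}")
    tp = len(rep & tru)
    fp = len(rep - tru)
    fn = len(tru - rep)
    tn = len(universe) - tp - fp - fn
    return ConfusionSummary(tp=tp, fp=fp, fn=fn, tn=tn)


def cohort_replicate_report(
    replicate_sets: Iterable[ReplicateSet],
    k: int = 2,
    all_sites: Sequence[int] | np.ndarray | None = None,
    aggregation: str = "per_sample",
) -> tuple[pd.DataFrame, dict]:
    """Score every replicate of every sample against its sample consensus.

    ``aggregation='per_sample'`` averages replicate-level sensitivities and
    specificities within each sample first, then reports the cohort mean and
    sd over samples; ``'pooled'`` averages directly over all replicate-level
    values.  Undefined ratios are skipped and counted.

    Returns the per-replicate table
    (``sample_id replicate tp fp fn tn sensitivity specificity``) and a
    summary dict.
    """
    if aggregation not in ("per_sample", "pooled"):
        raise ParameterError(f"unknown aggregation {aggregation!r}")
    if all_sites is None:
        all_sites = default_coords().positions

    rows = []
    per_sample_sens: list[float] = []
    per_sample_spec: list[float] = []
    pooled_sens: list[float] = []
    pooled_spec: list[float] = []
    skipped_sens = skipped_spec = 0

    for rs in replicate_sets:
        truth = consensus_truth(rs, k)
        sample_sens: list[float] = []
        sample_spec: list[float] = []
        for i, rep in enumerate(rs.replicate_sites, start=1):
            cm = replicate_confusion(rep, truth, all_sites)
            rows.append(
                {
                    "sample_id": rs.sample_id,
                    "replicate": i,
                    "tp": cm.tp,
                    "fp": cm.fp,
                    "fn": cm.fn,
                    "tn": cm.tn,
                    "sensitivity": cm.sensitivity if cm.sensitivity is not None else np.nan,
                    "specificity": cm.specificity if cm.specificity is not None else np.nan,
                }
            )
            if cm.sensitivity is None:
                skipped_sens += 1
            else:
                sample_sens.append(cm.sensitivity)
                pooled_sens.append(cm.sensitivity)
            if cm.specificity is None:
                skipped_spec += 1
            else:
                sample_spec.append(cm.specificity)
                pooled_spec.append(cm.specificity)
        if sample_sens:
            per_sample_sens.append(float(np.mean(sample_sens)))
        if sample_spec:
            per_sample_spec.append(float(np.mean(sample_spec)))

    sens_values = per_sample_sens if aggregation == "per_sample" else pooled_sens
    spec_values = per_sample_spec if aggregation == "per_sample" else pooled_spec
    if not sens_values and not spec_values:
        raise DegenerateStatisticError(
            "sensitivity and specificity undefined for every sample"
        )

    def _ms(values: list[float]) -> tuple[float, float]:
        if not values:
            return float("nan"), float("nan")
        return float(np.mean(values)), float(np.std(values, ddof=1)) if len(values) > 1 else 0.0

    mean_sens, sd_sens = _ms(sens_values)
    mean_spec, sd_spec = _ms(spec_values)
    summary = {
        "aggregation": aggregation,
        "k": k,
        "mean_sensitivity": mean_sens,
        "sd_sensitivity": sd_sens,
        "mean_specificity": mean_spec,
        "sd_specificity": sd_spec,
        "n_undefined_sensitivity": skipped_sens,
        "n_undefined_specificity": skipped_spec,
    }
    return pd.DataFrame(rows), summary


def replicate_maf_dispersion(maf_by_replicate: Sequence[Mapping[int, float]]) -> float:
    """Supplementary diagnostic: mean pairwise absolute MAF difference.

    Computed over the union of called sites of each replicate pair, with a
    replicate lacking the site contributing MAF 0.  Site-identity concordance
    (the confusion matrix) is the primary readout; this quantifies how well
    the *levels* agree.
    """
    if len(maf_by_replicate) < 2:
        raise ParameterError("need >= 2 replicates")
    diffs: list[float] = []
    for a, b in combinations(maf_by_replicate, 2):
        union = set(a) | set(b)
        if not union:
            diffs.append(0.0)
            continue
        diffs.append(
            float(np.mean([abs(a.get(s, 0.0) - b.get(s, 0.0)) for s in sorted(union)]))
        )
    return float(np.mean(diffs))
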