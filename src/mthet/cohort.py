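"""Cohort-level heteroplasmy statistics.

Works on the MAF matrix: rows are QC-passing samples, columns the 853
fragment positions in canonical order, entries the called minor allele
frequency (0 where the sample carries no call at the site).  Provides

* per-group occurrence counts and mean levels per position,
* Fisher-exact region enrichment of heteroplasmic positions (HV1 /
  intermediate / HV2) with Woolf log-OR confidence intervals,
* Pearson correlation between per-position occurrence and a user-supplied
  relative mutation-rate table,
* Mann-Whitney comparison of mutation rates at heteroplasmic vs all sites,
* per-position one-way ANOVA of MAF across groups with Tukey HSD contrasts
  and family-wide multiple-testing adjustment,
* per-position age correlations, and
* complete-linkage hierarchical clustering of samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .calling import SampleProfile
from .coords import GenomeCoords, RegionMap, default_coords
from .errors import CoordinateError, DegenerateStatisticError, ParameterError

__all__ = [
    "build_maf_matrix",
    "occurrence_counts",
    "EnrichmentResult",
    "fisher_exact_2x2",
    "region_enrichment",
    "mr_correlation",
    "mean_rate_comparison",
    "per_site_anova",
    "age_correlations",
    "ClusterResult",
    "cluster_samples",
]


def build_maf_matrix(
    profiles: Iterable[SampleProfile], coords: GenomeCoords | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """MAF matrix (samples x 853 positions) plus sample metadata frame.

    QC-failed profiles are dropped.  Column order follows the canonical
    fragment ordering; metadata carries group, family_id and age.
    """
    coords = coords or default_coords()
    positions = [int(p) for p in coords.positions]
    rows, meta = [], []
    for p in profiles:
        if not p.qc_pass:
            continue
        vec = np.zeros(len(positions))
        for call in p.calls:
            vec[coords.require(call.site)] = call.maf
        rows.append(vec)
        meta.append(
            {"sample_id": p.sample_id, "group": p.group, "family_id": p.family_id, "age": p.age}
        )
    if not rows:
        raise ParameterError("no QC-passing profiles")
    ids = [m["sample_id"] for m in meta]
    if len(set(ids)) != len(ids):
        raise ParameterError("duplicate sample ids")
    matrix = pd.DataFrame(np.vstack(rows), index=ids, columns=positions)
    meta_df = pd.DataFrame(meta).set_index("sample_id")
    return matrix, meta_df


def occurrence_counts(
    matrix: pd.DataFrame,
    groups: pd.Series,
    group: str,
    threshold: float = 0.002,
) -> pd.DataFrame:
    """Per-position occurrence count and mean MAF within one group.

    The mean is taken over heteroplasmic samples only and is NaN (absent)
    for positions with zero occurrences.
    """
    if group not in set(groups):
        raise ParameterError(f"unknown group {group!r}")
    sub = matrix.loc[groups[matrix.index] == group]
    het = sub.to_numpy() >= threshold
    counts = het.sum(axis=0)
    with np.errstate(invalid="ignore"):
        sums = np.where(het, sub.to_numpy(), 0.0).sum(axis=0)
        mean_maf = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({"count": counts, "mean_maf": mean_maf}, index=matrix.columns)


@dataclass(frozen=True)
class EnrichmentResult:
    """Fisher 2x2 result for one region vs the rest of the fragment."""

    region: str
    het_in: int
    non_het_in: int
    het_out: int
    non_het_out: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    degenerate: bool = False


def _woolf_ci(a: int, b: int, c: int, d: int, alpha: float = 0.05) -> tuple[float, float, float]:
    """Cross-product OR with Woolf (log-OR normal) CI.

    Applies the Haldane-Anscombe 0.5 continuity correction to every cell
    when any cell is zero.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    orr = (a_ * d_) / (b_ * c_)
    se = np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    z = stats.norm.ppf(1 - alpha / 2)
    return float(orr), float(np.exp(np.log(orr) - z * se)), float(np.exp(np.log(orr) + z * se))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on one 2x2 table.

    Returns the sample (cross-product) odds ratio and the exact two-sided p
    summed over hypergeometric outcomes no more probable than the observed
    table.  This is the primitive behind :func:`region_enrichment`.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ParameterError("table cells must be non-negative")
    orr, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(orr), float(p)


def region_enrichment(
    het_sites: Iterable[int],
    region_map: RegionMap | None = None,
) -> list[EnrichmentResult]:
    """Per-region Fisher exact test of heteroplasmic-site enrichment.

    Each region is compared against the remainder of the fragment on the 2x2
    table (het in / non-het in / het out / non-het out); cells always sum to
    the fragment length.  Two-sided exact p from the hypergeometric
    distribution; OR and CI per :func:`_woolf_ci`.
    """
    region_map = region_map or RegionMap()
    coords = region_map.coords
    het = set(int(s) for s in het_sites)
    stray = het - set(int(p) for p in coords.positions)
    if stray:
        raise CoordinateError(f"het sites outside the fragment: {sorted(stray)[:5]}")
    sizes = region_map.sizes()
    total = coords.fragment_length
    degenerate_all = len(het) == 0 or len(het) == total
    results = []
    for name in region_map.names:
        in_region = set(int(p) for p in region_map.positions(name))
        a = len(het & in_region)
        b = sizes[name] - a
        c = len(het) - a
        d = (total - sizes[name]) - c
        if degenerate_all:
            # no heteroplasmic/non-heteroplasmic contrast exists: report the
            # null odds ratio with an undefined interval, flagged
            p, orr, lo, hi = 1.0, 1.0, float("nan"), float("nan")
        else:
            _, p = fisher_exact_2x2(a, b, c, d)
            orr, lo, hi = _woolf_ci(a, b, c, d)
        results.append(
            EnrichmentResult(
                region=name,
                het_in=a,
                non_het_in=b,
                het_out=c,
                non_het_out=d,
                odds_ratio=orr,
                ci_low=lo,
                ci_high=hi,
                p_value=float(p),
                degenerate=degenerate_all,
            )
        )
    return results


def mr_correlation(
    occurrences: pd.Series | np.ndarray, rates: pd.Series
) -> tuple[float, float]:
    """Pearson correlation between per-position occurrence counts and rates."""
    occ = np.asarray(occurrences, dtype=float)
    if isinstance(occurrences, pd.Series):
        r = rates.reindex(occurrences.index).to_numpy(dtype=float)
        if np.isnan(r).any():
            raise ParameterError("rate table does not cover every position")
    else:
        r = rates.to_numpy(dtype=float)
    if len(occ) != len(r):
        raise ParameterError("occurrences and rates differ in length")
    if len(occ) < 3:
        raise ParameterError("need >= 3 positions")
    if np.std(occ) == 0 or np.std(r) == 0:
        raise DegenerateStatisticError("zero variance in occurrences or rates")
    res = stats.pearsonr(occ, r)
    return float(res.statistic), float(res.pvalue)


def mean_rate_comparison(
    het_sites: Iterable[int],
    rates: pd.Series,
    region_map: RegionMap | None = None,
) -> pd.DataFrame:
    """Mean mutation rate over all vs heteroplasmic sites, per stratum.

    Strata are the entire fragment plus each region.  A two-sided
    Mann-Whitney test compares the het-site rates against the all-site rates
    of the stratum (overlapping sets, matching the published comparison).
    Strata without heteroplasmic sites get NaN means and p (flagged).
    """
    region_map = region_map or RegionMap()
    het = set(int(s) for s in het_sites)
    if not het:
        raise ParameterError("het_sites must be non-empty")
    strata: dict[str, np.ndarray] = {"ALL": region_map.coords.positions}
    for name in region_map.names:
        strata[name] = region_map.positions(name)
    rows = []
    for name, positions in strata.items():
        pos = [int(p) for p in positions]
        all_rates = rates.reindex(pos).to_numpy(dtype=float)
        het_pos = [p for p in pos if p in het]
        het_rates = rates.reindex(het_pos).to_numpy(dtype=float) if het_pos else np.array([])
        if het_pos:
            if np.ptp(all_rates) == 0 and np.ptp(het_rates) == 0:
                p = 1.0
            else:
                p = float(
                    stats.mannwhitneyu(het_rates, all_rates, alternative="two-sided").pvalue
                )
            mean_het = float(het_rates.mean())
        else:
            p, mean_het = np.nan, np.nan
        rows.append(
            {
                "stratum": name,
                "n_sites": len(pos),
                "n_het_sites": len(het_pos),
                "mean_rate_all": float(all_rates.mean()),
                "mean_rate_het": mean_het,
                "mannwhitney_p": p,
            }
        )
    return pd.DataFrame(rows).set_index("stratum")


def per_site_anova(
    matrix: pd.DataFrame,
    groups: pd.Series,
    adjust: str = "bonferroni",
    contrasts: bool = True,
    contrast_alpha: float = 0.05,
    het_only: bool = False,
    threshold: float = 0.002,
) -> pd.DataFrame:
    """One-way ANOVA of MAF across groups at every fragment position.

    By default all samples enter each position's ANOVA, with MAF 0 for
    samples without a call there (excluding zeros would leave most positions
    untestable); ``het_only=True`` restricts to samples called at the
    position.  Positions with zero total variance report F = 0, p = 1.
    Family-wide adjustment over the 853 positions is Bonferroni by default
    (``adjust='bh'`` for Benjamini-Hochberg).  Where the nominal p falls
    below ``contrast_alpha``, pairwise Tukey HSD contrasts significant at
    that level are listed as e.g. ``"CENT-ONLL"``.
    """
    if adjust not in ("bonferroni", "bh"):
        raise ParameterError(f"unknown adjustment {adjust!r}")
    labels = sorted(set(groups[matrix.index]))
    if len(labels) < 2:
        raise ParameterError("need >= 2 groups")
    by_group = {g: matrix.loc[groups[matrix.index] == g] for g in labels}
    for g, sub in by_group.items():
        if len(sub) < 2:
            raise ParameterError(f"group {g} has fewer than 2 samples")

    data = matrix.to_numpy(dtype=float)
    n_sites = data.shape[1]
    F = np.zeros(n_sites)
    p = np.ones(n_sites)

    arrays = [by_group[g].to_numpy(dtype=float) for g in labels]
    variable = np.ptp(data, axis=0) > 0
    if het_only:
        # positions are tested one by one on their called samples only
        for j in range(n_sites):
            samples = [a[:, j][a[:, j] >= threshold] for a in arrays]
            samples = [s for s in samples if len(s) >= 2]
            if len(samples) < 2 or np.ptp(np.concatenate(samples)) == 0:
                continue
            res = stats.f_oneway(*samples)
            F[j], p[j] = res.statistic, res.pvalue
    else:
        idx = np.nonzero(variable)[0]
        if len(idx):
            res = stats.f_oneway(*[a[:, idx] for a in arrays], axis=0)
            fj = np.asarray(res.statistic, dtype=float)
            pj = np.asarray(res.pvalue, dtype=float)
            # a column can vary yet be constant within the F test's reach
            fj = np.where(np.isfinite(fj), fj, 0.0)
            pj = np.where(np.isfinite(pj), pj, 1.0)
            F[idx], p[idx] = fj, pj

    method = "bonferroni" if adjust == "bonferroni" else "fdr_bh"
    p_adj = multipletests(p, method=method)[1]

    contrast_col = [""] * n_sites
    if contrasts and len(labels) >= 2:
        for j in np.nonzero(p < contrast_alpha)[0]:
            samples = [a[:, j] for a in arrays]
            res = stats.tukey_hsd(*samples)
            sig = []
            for i1 in range(len(labels)):
                for i2 in range(i1 + 1, len(labels)):
                    if res.pvalue[i1, i2] < contrast_alpha:
                        sig.append(f"{labels[i1]}-{labels[i2]}")
            contrast_col[j] = ",".join(sig)

    return pd.DataFrame(
        {"F": F, "p": p, "p_adj": p_adj, "significant_contrasts": contrast_col},
        index=matrix.columns,
    )


def _pearson_columns(data: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-column Pearson r against y, with two-sided t-test p."""
    n = len(y)
    yc = y - y.mean()
    xc = data - data.mean(axis=0)
    sy = np.sqrt((yc**2).sum())
    sx = np.sqrt((xc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, np.finfo(float).tiny))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return r, p


def age_correlations(
    matrix: pd.DataFrame, ages: pd.Series
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Pearson correlation of per-position MAF with age, plus the correlation
    between each sample's heteroplasmic-site count and age.

    Constant MAF columns are undefined and reported as NaN (flagged in the
    ``defined`` column).  Ages must be available for every sample.
    """
    age = ages.reindex(matrix.index).to_numpy(dtype=float)
    if np.isnan(age).any():
        raise ParameterError("missing age for some samples")
    if np.ptp(age) == 0:
        raise DegenerateStatisticError("ages are constant")
    data = matrix.to_numpy(dtype=float)
    r, p = _pearson_columns(data, age)
    defined = np.ptp(data, axis=0) > 0
    r = np.where(defined, r, np.nan)
    p = np.where(defined, p, np.nan)
    per_site = pd.DataFrame({"r": r, "p": p, "defined": defined}, index=matrix.columns)

    counts = (data >= 0.002).sum(axis=1).astype(float)
    if np.ptp(counts) == 0:
        count_rp = (float("nan"), float("nan"))
    else:
        res = stats.pearsonr(counts, age)
        count_rp = (float(res.statistic), float(res.pvalue))
    return per_site, count_rp


@dataclass(frozen=True)
class ClusterResult:
    """Complete-linkage dendrogram over samples."""

    linkage: np.ndarray
    labels: tuple[str, ...]

    @property
    def leaf_order(self) -> tuple[str, ...]:
        return tuple(self.labels[i] for i in hierarchy.leaves_list(self.linkage))

    def cut(self, n_clusters: int) -> dict[str, int]:
        flat = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return {lab: int(c) for lab, c in zip(self.labels, flat)}

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_dist: float) -> str:
            length = max(parent_dist - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


def cluster_samples(
    matrix: pd.DataFrame, method: str = "complete", metric: str = "euclidean"
) -> ClusterResult:
    """Agglomerative clustering of sample MAF vectors (complete linkage,
    Euclidean distance by default).  Samples are processed in sorted-id
    order so that distance ties resolve deterministically.
    """
    if len(matrix) < 2:
        raise ParameterError("need >= 2 samples")
    if matrix.index.duplicated().any():
        raise ParameterError("duplicate sample ids")
    ordered = matrix.sort_index()
    Z = hierarchy.linkage(ordered.to_numpy(dtype=float), method=method, metric=metric)
    return ClusterResult(linkage=Z, labels=tuple(str(i) for i in ordered.index))
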