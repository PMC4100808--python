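"""Mother-offspring transmission statistics and reshuffling nulls.

Quantifies familial maintenance of low-level heteroplasmy over a set of
mother-offspring pairs (centenarian mothers, their offspring) plus an
unrelated control group:

* **total heteroplasmy** — per individual, the sum of minor allele
  frequencies over all called sites, expressed in percent;
* **pair correlation** — Pearson r of a per-individual statistic between
  mothers and their own offspring;
* **TNCS** — total number of common sites: summed over pairs, the number of
  positions heteroplasmic in both members;
* **site distance** — for positions heteroplasmic in both members,
  ``100 * |m1 - m2| / max(m1, m2)``;
* **public/private classification** of shared positions across families;
* **reshuffling nulls** — the observed statistic is compared with its
  distribution over replicates in which offspring are randomly re-matched to
  mothers (uniform random permutations, default 2000 replicates).  The
  empirical p uses the add-one convention
  ``p = (1 + #{replicate >= observed}) / (1 + R)`` for these upper-tail
  statistics, so p is never exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import SampleProfile
from .coords import GenomeCoords, default_coords
from .errors import DegenerateStatisticError, ParameterError

__all__ = [
    "PairSet",
    "NullDistribution",
    "total_heteroplasmy",
    "pair_correlation",
    "reshuffle_null",
    "cross_group_null",
    "tncs",
    "site_distance",
    "pair_site_distances",
    "classify_sites",
]

logger = logging.getLogger(__name__)

DEFAULT_RESHUFFLES = 2000


@dataclass(frozen=True)
class PairSet:
    """Mother-offspring pairs (matched by family id) plus unrelated controls."""

    pairs: tuple[tuple[SampleProfile, SampleProfile], ...]
    onll: tuple[SampleProfile, ...] = ()

    def __post_init__(self) -> None:
        fams = [m.family_id for m, _ in self.pairs]
        if len(set(fams)) != len(fams):
            raise ParameterError("a family_id appears in more than one pair")
        for m, o in self.pairs:
            if m.family_id != o.family_id:
                raise ParameterError(
                    f"pair members have different family ids: {m.family_id} vs {o.family_id}"
                )
            if not (m.qc_pass and o.qc_pass):
                raise ParameterError(f"family {m.family_id}: both members must pass QC")

    @classmethod
    def from_profiles(cls, profiles: Iterable[SampleProfile]) -> "PairSet":
        """Pair CENT with CO by family id; QC-failed members drop the pair."""
        mothers: dict[str, SampleProfile] = {}
        offspring: dict[str, SampleProfile] = {}
        onll = []
        for p in profiles:
            if not p.qc_pass:
                continue
            if p.group == "CENT" and p.family_id:
                mothers[p.family_id] = p
            elif p.group == "CO" and p.family_id:
                offspring[p.family_id] = p
            elif p.group == "ONLL":
                onll.append(p)
        shared = sorted(set(mothers) & set(offspring))
        pairs = tuple((mothers[f], offspring[f]) for f in shared)
        return cls(pairs=pairs, onll=tuple(onll))

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def mother_values(self, statistic: Callable[[SampleProfile], float]) -> np.ndarray:
        return np.array([statistic(m) for m, _ in self.pairs], dtype=float)

    def offspring_values(self, statistic: Callable[[SampleProfile], float]) -> np.ndarray:
        return np.array([statistic(o) for _, o in self.pairs], dtype=float)


@dataclass(frozen=True)
class NullDistribution:
    """Observed statistic, reshuffled replicate values and empirical p."""

    observed: float | None
    replicates: np.ndarray
    p: float | None
    seed: int | None
    statistic: str = ""
    n_degenerate_resampled: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicates))

    @property
    def sd(self) -> float:
        return float(np.std(self.replicates, ddof=1))

    def summary(self) -> dict:
        return {
            "statistic": self.statistic,
            "observed": self.observed,
            "null_mean": self.mean,
            "null_sd": self.sd,
            "empirical_p": self.p,
            "n_reshuffles": int(len(self.replicates)),
            "seed": self.seed,
            "n_degenerate_resampled": self.n_degenerate_resampled,
        }


def total_heteroplasmy(profile: SampleProfile) -> float:
    """Sum of MAFs over all called sites, in percent (0 for no calls)."""
    if not profile.qc_pass:
        raise ParameterError(f"sample {profile.sample_id} failed QC")
    return 100.0 * float(sum(c.maf for c in profile.calls))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc @ xc) * (yc @ yc))
    return float((xc @ yc) / den)


def pair_correlation(
    mother_values: Sequence[float], offspring_values: Sequence[float]
) -> tuple[float, float]:
    """Pearson r (with two-sided p) between mother and offspring statistics."""
    x = np.asarray(mother_values, dtype=float)
    y = np.asarray(offspring_values, dtype=float)
    if len(x) != len(y):
        raise ParameterError("value vectors differ in length")
    if len(x) < 3:
        raise ParameterError("need >= 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateStatisticError("zero variance on one side of the pairing")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _permutation_pearson(x: np.ndarray, y: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Pearson r of x against every row-permutation of y.  perms: (R, n)."""
    xc = x - x.mean()
    Y = y[perms]
    Yc = Y - Y.mean(axis=1, keepdims=True)
    num = Yc @ xc
    den = np.sqrt((xc @ xc) * (Yc**2).sum(axis=1))
    return num / den


def _shared_site_matrix(
    mothers: Sequence[frozenset[int]], offspring: Sequence[frozenset[int]]
) -> np.ndarray:
    """S[i, j] = number of sites heteroplasmic in mother i and offspring j."""
    n = len(mothers)
    S = np.zeros((n, n), dtype=np.int64)
    for i, m in enumerate(mothers):
        for j, o in enumerate(offspring):
            S[i, j] = len(m & o)
    return S


def reshuffle_null(
    mother_items: Sequence,
    offspring_items: Sequence,
    statistic: str = "pearson_r",
    n_reshuffles: int = DEFAULT_RESHUFFLES,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    exclude_identity: bool = False,
) -> NullDistribution:
    """Null distribution of a pairing statistic under random re-matching.

    ``statistic='pearson_r'`` takes per-individual float values on both
    sides; ``'tncs'`` takes per-individual heteroplasmic-site sets.  Each
    replicate applies an independent uniform random permutation to the
    offspring side and recomputes the statistic; the identity permutation is
    allowed unless ``exclude_identity`` is set (its probability is 1/n!).
    Non-finite replicate values are resampled with fresh permutations and
    counted.
    """
    if n_reshuffles < 1:
        raise ParameterError("n_reshuffles must be >= 1")
    if len(mother_items) != len(offspring_items):
        raise ParameterError("sides differ in length")
    n = len(mother_items)
    if rng is None:
        rng = np.random.default_rng(seed)

    def draw_perms(count: int) -> np.ndarray:
        perms = np.empty((count, n), dtype=np.int64)
        for i in range(count):
            perm = rng.permutation(n)
            while exclude_identity and np.array_equal(perm, np.arange(n)):
                perm = rng.permutation(n)
            perms[i] = perm
        return perms

    if statistic == "pearson_r":
        x = np.asarray(mother_items, dtype=float)
        y = np.asarray(offspring_items, dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise DegenerateStatisticError("zero variance: correlation undefined")
        observed = _pearson(x, y)
        values = _permutation_pearson(x, y, draw_perms(n_reshuffles))
    elif statistic == "tncs":
        mothers = [frozenset(s) for s in mother_items]
        offspring = [frozenset(s) for s in offspring_items]
        S = _shared_site_matrix(mothers, offspring)
        observed = float(np.trace(S))
        perms = draw_perms(n_reshuffles)
        values = S[np.arange(n), perms].sum(axis=1).astype(float)
    else:
        raise ParameterError(f"unknown statistic {statistic!r}")

    n_resampled = 0
    bad = ~np.isfinite(values)
    while bad.any():  # unreachable for the built-in statistics, kept defensive
        n_resampled += int(bad.sum())
        logger.warning("resampling %d degenerate reshuffle replicates", int(bad.sum()))
        perms = draw_perms(int(bad.sum()))
        if statistic == "pearson_r":
            values[bad] = _permutation_pearson(x, y, perms)
        else:
            values[bad] = S[np.arange(n), perms].sum(axis=1)
        bad = ~np.isfinite(values)

    p = (1.0 + float(np.sum(values >= observed))) / (1.0 + n_reshuffles)
    return NullDistribution(
        observed=observed,
        replicates=np.asarray(values, dtype=float),
        p=p,
        seed=seed,
        statistic=statistic,
        n_degenerate_resampled=n_resampled,
    )


def cross_group_null(
    values_a: Sequence[float],
    values_b: Sequence[float],
    n_reshuffles: int = DEFAULT_RESHUFFLES,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> NullDistribution:
    """Correlation null between two groups with no true pairing.

    Each replicate pairs the two groups uniformly at random without
    replacement, truncating to the smaller group size; only the distribution
    (mean, sd) is meaningful, so ``observed`` and ``p`` are None.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    k = min(len(a), len(b))
    if k < 3:
        raise ParameterError("need >= 3 individuals per group")
    if rng is None:
        rng = np.random.default_rng(seed)
    values = np.empty(n_reshuffles)
    for i in range(n_reshuffles):
        ai = a[rng.permutation(len(a))[:k]]
        bi = b[rng.permutation(len(b))[:k]]
        if np.ptp(ai) == 0 or np.ptp(bi) == 0:
            values[i] = np.nan
        else:
            values[i] = _pearson(ai, bi)
    bad = ~np.isfinite(values)
    n_resampled = 0
    while bad.any():
        n_resampled += int(bad.sum())
        for i in np.nonzero(bad)[0]:
            ai = a[rng.permutation(len(a))[:k]]
            bi = b[rng.permutation(len(b))[:k]]
            values[i] = _pearson(ai, bi) if np.ptp(ai) > 0 and np.ptp(bi) > 0 else np.nan
        bad = ~np.isfinite(values)
    return NullDistribution(
        observed=None,
        replicates=values,
        p=None,
        seed=seed,
        statistic="cross_group_pearson_r",
        n_degenerate_resampled=n_resampled,
    )


def tncs(pairs: PairSet) -> int:
    """Total number of common sites over all mother-offspring pairs."""
    return int(sum(len(m.sites & o.sites) for m, o in pairs.pairs))


def site_distance(maf_mother: float, maf_offspring: float, threshold: float = 0.002) -> float:
    """Site-level distance in percent: 100 * |m1 - m2| / max(m1, m2).

    Defined only for sites heteroplasmic in both individuals (both MAFs at
    or above the detection threshold).
    """
    if maf_mother < threshold or maf_offspring < threshold:
        raise ParameterError("site distance requires heteroplasmy in both individuals")
    return 100.0 * abs(maf_mother - maf_offspring) / max(maf_mother, maf_offspring)


def pair_site_distances(
    pairs: PairSet, threshold: float = 0.002, coords: GenomeCoords | None = None
) -> pd.DataFrame:
    """Distance matrix: families x fragment positions, NaN where not jointly
    heteroplasmic."""
    coords = coords or default_coords()
    positions = [int(p) for p in coords.positions]
    data = np.full((pairs.n_pairs, len(positions)), np.nan)
    families = []
    for i, (m, o) in enumerate(pairs.pairs):
        families.append(m.family_id)
        m_maf, o_maf = m.maf_by_site, o.maf_by_site
        for site in m.sites & o.sites:
            data[i, coords.require(site)] = site_distance(m_maf[site], o_maf[site], threshold)
    return pd.DataFrame(data, index=families, columns=positions)


def classify_sites(
    pairs: PairSet, public_fraction: float = 0.5, coords: GenomeCoords | None = None
) -> pd.Series:
    """Label each fragment position public / private / absent.

    A position is *public* when jointly heteroplasmic in at least
    ``public_fraction`` of pairs, *private* when shared by at least one but
    fewer pairs, and *absent* otherwise.
    """
    if pairs.n_pairs < 1:
        raise ParameterError("need >= 1 pair")
    if not 0.0 < public_fraction <= 1.0:
        raise ParameterError("public_fraction must be in (0, 1]")
    coords = coords or default_coords()
    counts: dict[int, int] = {}
    for m, o in pairs.pairs:
        for site in m.sites & o.sites:
            counts[site] = counts.get(site, 0) + 1
    cutoff = public_fraction * pairs.n_pairs
    labels = []
    for pos in coords.positions:
        c = counts.get(int(pos), 0)
        labels.append("public" if c >= cutoff and c > 0 else ("private" if c >= 1 else "absent"))
    return pd.Series(labels, index=[int(p) for p in coords.positions], name="class")
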