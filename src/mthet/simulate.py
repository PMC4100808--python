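"""Synthetic cohort generator with full truth bookkeeping.

Emulates the statistical structure the downstream analysis assumes: paired
mother-offspring samples with inherited plus de novo low-level
heteroplasmies, an unrelated control group, mutation-rate hotspots with
public sites (146, 204, 16129 by default), ultra-deep strand-resolved
coverage (~50,000x combined) and strand-specific sequencing error.  Every
output is a pure function of (config, seed).

Generative model
----------------
* A per-position relative mutation-rate table is gamma-distributed with
  region-level means matching the hypervariable regions (elevated in
  HV1/HV2, low in the origin-crossing intermediate stretch); designated
  hotspot positions are forced into the top decile.
* Mothers and unrelated controls carry each public site independently with
  probability ``public_prob`` and additionally a Poisson(``de_novo_rate``)
  number of de novo sites placed proportionally to the mutation rate.  De
  novo MAFs are exponential (scale ``maf_scale``) truncated to
  ``[maf_min, maf_max]``; public-site MAFs use their own, higher-level
  truncated exponential (``public_maf_scale``, ``public_maf_min``) since
  public positions are recurrent hotspots that sit well above the detection
  threshold in essentially every individual.
* Offspring inherit each maternal site with probability ``retention``; the
  inherited MAF is multiplied by a mean-one lognormal jitter (sd
  ``maf_jitter_sd`` on the log scale, modelling germline drift
  phenomenologically rather than via an explicit bottleneck).  Offspring
  then draw their own public sites (if not inherited) and their own de novo
  sites.
* Read counts per site and strand: depth is Poisson around half the mean
  combined depth (negative-binomial when ``overdispersion`` > 0); minor
  reads are binomial at the true MAF; error reads are binomial at the
  per-strand error rate, split uniformly over the three non-major bases.
  Sites with true MAF 0 receive error reads only.

The reference sequence is synthetic (a deterministic position-derived base,
with the minor allele its transition partner); calling is reference-free so
only cosmetic realism is affected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

from .calling import BASES, StrandCountTable
from .coords import GenomeCoords, RegionMap, default_coords
from .errors import ParameterError

__all__ = [
    "GeneratorConfig",
    "TruthProfile",
    "TruthCohort",
    "generate_rate_table",
    "generate_truth_cohort",
    "simulate_strand_counts",
    "simulate_cohort_counts",
    "simulate_replicates",
]

DEFAULT_PUBLIC_SITES = (146, 204, 16129)

# group-level age distributions (years): mean, sd
AGE_DISTRIBUTIONS = {"CENT": (101.6, 2.8), "CO": (69.9, 6.6), "ONLL": (70.7, 4.8)}

# all-site mean relative mutation rate targeted per region
REGION_RATE_MEANS = {"HV1": 4.7, "INTERMEDIATE": 1.6, "HV2": 6.2}


@dataclass(frozen=True)
class GeneratorConfig:
    """Tunable knobs of the synthetic cohort; defaults emulate the study."""

    n_pairs: int = 29
    n_onll: int = 28
    retention: float = 0.8          # probability a maternal site is inherited
    maf_jitter_sd: float = 0.3      # lognormal sd (log scale) on inherited MAFs
    de_novo_rate: float = 2.0       # Poisson mean of de novo sites per individual
    public_sites: tuple[int, ...] = DEFAULT_PUBLIC_SITES
    public_prob: float = 1.0        # per-individual presence probability of a public site
    maf_scale: float = 0.004        # exponential scale of de novo site MAFs
    maf_min: float = 0.002
    maf_max: float = 0.5
    public_maf_scale: float = 0.02  # public sites are recurrent, higher-level
    public_maf_min: float = 0.01
    mean_depth: float = 50_000.0    # combined over both strands
    error_rate: float = 5e-4        # per-strand per-base error rate (plus strand)
    error_rate_minus: float | None = None  # set for strand-asymmetric error
    overdispersion: float = 0.0     # depth variance = mu * (1 + phi * mu)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("retention", "public_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} = {v} outside [0, 1]")
        if self.mean_depth <= 0:
            raise ParameterError("mean_depth must be positive")
        if self.n_pairs < 1 or self.n_onll < 0:
            raise ParameterError("cohort sizes invalid")
        if not 0.0 < self.maf_min < self.maf_max <= 0.5:
            raise ParameterError("require 0 < maf_min < maf_max <= 0.5")
        if not 0.0 < self.public_maf_min < self.maf_max:
            raise ParameterError("require 0 < public_maf_min < maf_max")
        for name in ("maf_jitter_sd", "de_novo_rate", "maf_scale", "public_maf_scale",
                     "error_rate", "overdispersion"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.error_rate_minus is not None and self.error_rate_minus < 0:
            raise ParameterError("error_rate_minus must be >= 0")


@dataclass(frozen=True)
class TruthProfile:
    """Ground-truth heteroplasmy state of one simulated individual."""

    sample_id: str
    group: str
    family_id: str | None
    age: float
    maf: dict[int, float] = field(default_factory=dict)

    @property
    def sites(self) -> frozenset[int]:
        return frozenset(self.maf)

    @property
    def total_heteroplasmy(self) -> float:
        return 100.0 * float(sum(self.maf.values()))


@dataclass(frozen=True)
class TruthCohort:
    """All truth profiles plus planted-statistic bookkeeping."""

    profiles: tuple[TruthProfile, ...]
    rate_table: pd.Series
    config: GeneratorConfig

    @property
    def pairs(self) -> tuple[tuple[TruthProfile, TruthProfile], ...]:
        mothers = {p.family_id: p for p in self.profiles if p.group == "CENT"}
        offspring = {p.family_id: p for p in self.profiles if p.group == "CO"}
        return tuple((mothers[f], offspring[f]) for f in sorted(mothers))

    @property
    def planted_shared_sites(self) -> dict[str, int]:
        return {m.family_id: len(m.sites & o.sites) for m, o in self.pairs}

    @property
    def planted_tncs(self) -> int:
        return int(sum(self.planted_shared_sites.values()))

    @property
    def planted_totals(self) -> dict[str, float]:
        return {p.sample_id: p.total_heteroplasmy for p in self.profiles}

    @property
    def planted_occurrence(self) -> pd.Series:
        coords = default_coords()
        counts = pd.Series(0, index=[int(p) for p in coords.positions], dtype=int)
        for p in self.profiles:
            for site in p.sites:
                counts[site] += 1
        return counts


def generate_rate_table(
    seed: int | np.random.Generator,
    coords: GenomeCoords | None = None,
    region_map: RegionMap | None = None,
    hotspots: Sequence[int] = DEFAULT_PUBLIC_SITES,
    shape: float = 0.4,
) -> pd.Series:
    """Gamma-distributed relative mutation rates over the fragment.

    Rates are drawn per region with the region's target mean (hypervariable
    regions elevated); ``hotspots`` are then raised above the largest drawn
    rate (recurrent public positions are the fastest-mutating sites), so
    they always rank in the top decile.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    coords = coords or default_coords()
    region_map = region_map or RegionMap(coords=coords)
    rates = pd.Series(0.0, index=[int(p) for p in coords.positions])
    for name in region_map.names:
        mean = REGION_RATE_MEANS.get(name, 3.6)
        pos = [int(p) for p in region_map.positions(name)]
        rates[pos] = rng.gamma(shape, scale=mean / shape, size=len(pos))
    top = float(rates.max())
    for h in hotspots:
        rates[int(h)] = top * (1.1 + 0.5 * rng.random())
    rates.name = "rate"
    return rates


def _truncated_exponential_maf(
    rng: np.random.Generator, scale: float, lo_bound: float, hi_bound: float, size: int
) -> np.ndarray:
    """Exp(scale) conditioned on [lo_bound, hi_bound], via inverse CDF."""
    lo = 1.0 - np.exp(-lo_bound / scale)
    hi = 1.0 - np.exp(-hi_bound / scale)
    u = rng.uniform(lo, hi, size=size)
    return -scale * np.log1p(-u)


def _draw_base_sites(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    rates: pd.Series,
    exclude: frozenset[int] = frozenset(),
) -> dict[int, float]:
    """Public-site draws plus Poisson de novo sites placed proportional to rate."""
    maf: dict[int, float] = {}
    publics = [s for s in cfg.public_sites if s not in exclude]
    present = rng.random(len(publics)) < cfg.public_prob
    public_mafs = _truncated_exponential_maf(
        rng, cfg.public_maf_scale, cfg.public_maf_min, cfg.maf_max, len(publics)
    )
    for site, keep, m in zip(publics, present, public_mafs):
        if keep:
            maf[int(site)] = float(m)
    n_new = int(rng.poisson(cfg.de_novo_rate))
    if n_new > 0:
        taken = set(maf) | set(cfg.public_sites) | set(exclude)
        candidates = np.array([p for p in rates.index if p not in taken])
        weights = rates.reindex(candidates).to_numpy(dtype=float)
        weights = weights / weights.sum()
        n_new = min(n_new, len(candidates))
        chosen = rng.choice(candidates, size=n_new, replace=False, p=weights)
        mafs = _truncated_exponential_maf(rng, cfg.maf_scale, cfg.maf_min, cfg.maf_max, n_new)
        for site, m in zip(chosen, mafs):
            maf[int(site)] = float(m)
    return maf


def _age(rng: np.random.Generator, group: str) -> float:
    mean, sd = AGE_DISTRIBUTIONS[group]
    return float(np.clip(rng.normal(mean, sd), 40.0, 120.0))


def generate_truth_cohort(
    config: GeneratorConfig | None = None,
    seed: int | None = None,
    rate_table: pd.Series | None = None,
    coords: GenomeCoords | None = None,
) -> TruthCohort:
    """Simulate the full cohort truth: paired CENT/CO families plus ONLL."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    coords = coords or default_coords()
    rates = rate_table if rate_table is not None else generate_rate_table(rng, coords)

    profiles: list[TruthProfile] = []
    for i in range(1, cfg.n_pairs + 1):
        fam = f"F{i:02d}"
        mother_maf = _draw_base_sites(rng, cfg, rates)
        profiles.append(
            TruthProfile(f"CENT{i:02d}", "CENT", fam, _age(rng, "CENT"), mother_maf)
        )
        child_maf: dict[int, float] = {}
        sites = sorted(mother_maf)
        inherited = rng.random(len(sites)) < cfg.retention
        jitter = np.exp(
            rng.normal(-0.5 * cfg.maf_jitter_sd**2, cfg.maf_jitter_sd, size=len(sites))
        )
        for site, keep, j in zip(sites, inherited, jitter):
            if keep:
                child_maf[site] = float(np.clip(mother_maf[site] * j, 1e-6, cfg.maf_max))
        # own public draws for sites not inherited, then own de novo sites
        extra = _draw_base_sites(rng, cfg, rates, exclude=frozenset(child_maf))
        for site, m in extra.items():
            child_maf.setdefault(site, m)
        profiles.append(
            TruthProfile(f"CO{i:02d}", "CO", fam, _age(rng, "CO"), child_maf)
        )
    for i in range(1, cfg.n_onll + 1):
        profiles.append(
            TruthProfile(
                f"ONLL{i:02d}", "ONLL", None, _age(rng, "ONLL"),
                _draw_base_sites(rng, cfg, rates),
            )
        )
    return TruthCohort(profiles=tuple(profiles), rate_table=rates, config=cfg)


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _reference_base(position: int) -> str:
    # deterministic synthetic reference in place of the real fragment sequence
    return BASES[(position * 2654435761) % 4]


@lru_cache(maxsize=4)
def _reference_indices(coords: GenomeCoords) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(major, minor, other-two) base column indices per fragment position."""
    positions = coords.positions
    major = np.array([BASES.index(_reference_base(int(p))) for p in positions])
    minor = np.array([BASES.index(_TRANSITION[_reference_base(int(p))]) for p in positions])
    other = np.array([sorted(set(range(4)) - {ma, mi}) for ma, mi in zip(major, minor)])
    return major, minor, other


def _draw_depth(rng: np.random.Generator, cfg: GeneratorConfig, size: int) -> np.ndarray:
    mu = cfg.mean_depth / 2.0  # per strand
    if cfg.overdispersion > 0:
        lam = rng.gamma(1.0 / cfg.overdispersion, cfg.overdispersion * mu, size=size)
        return rng.poisson(lam)
    return rng.poisson(mu, size=size)


def simulate_strand_counts(
    truth: TruthProfile,
    config: GeneratorConfig | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    coords: GenomeCoords | None = None,
) -> StrandCountTable:
    """Draw a strand-resolved count table from a truth profile."""
    cfg = config or GeneratorConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
    coords = coords or default_coords()
    positions = coords.positions
    n = len(positions)

    maf = np.zeros(n)
    for site, m in truth.maf.items():
        maf[coords.require(site)] = m
    major_idx, minor_idx, other_idx = _reference_indices(coords)

    error_rates = {"plus": cfg.error_rate, "minus": cfg.error_rate if cfg.error_rate_minus is None else cfg.error_rate_minus}
    strands = {}
    rows = np.arange(n)
    for strand in ("plus", "minus"):
        depth = _draw_depth(rng, cfg, n)
        k_minor = rng.binomial(depth, maf)
        k_err = rng.binomial(depth - k_minor, error_rates[strand])
        # split error reads uniformly over the three non-major bases
        e1 = rng.binomial(k_err, 1.0 / 3.0)
        e2 = rng.binomial(k_err - e1, 0.5)
        e3 = k_err - e1 - e2
        counts = np.zeros((n, 4), dtype=np.int64)
        counts[rows, major_idx] = depth - k_minor - k_err
        counts[rows, minor_idx] += k_minor + e1
        counts[rows, other_idx[:, 0]] += e2
        counts[rows, other_idx[:, 1]] += e3
        strands[strand] = counts
    return StrandCountTable(truth.sample_id, strands["plus"], strands["minus"], coords)


def simulate_cohort_counts(
    cohort: TruthCohort,
    seed: int | None = None,
    coords: GenomeCoords | None = None,
) -> dict[str, StrandCountTable]:
    """Count tables for every profile of a cohort, deterministically seeded."""
    rng = np.random.default_rng(cohort.config.seed if seed is None else seed)
    return {
        p.sample_id: simulate_strand_counts(p, cohort.config, rng=rng, coords=coords)
        for p in cohort.profiles
    }


def simulate_replicates(
    truth: TruthProfile,
    n: int = 3,
    config: GeneratorConfig | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    pcr_jitter_sd: float = 0.0,
    coords: GenomeCoords | None = None,
) -> list[StrandCountTable]:
    """n independent count realisations of one truth profile (replicate PCRs).

    Fresh depth and error draws per replicate; ``pcr_jitter_sd`` > 0 adds a
    per-replicate lognormal perturbation of the true MAFs (PCR drift,
    default off).
    """
    if n < 2:
        raise ParameterError("need >= 2 replicates")
    cfg = config or GeneratorConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
    out = []
    for _ in range(n):
        t = truth
        if pcr_jitter_sd > 0:
            jitter = {
                s: float(np.clip(m * np.exp(rng.normal(-0.5 * pcr_jitter_sd**2, pcr_jitter_sd)), 1e-6, cfg.maf_max))
                for s, m in truth.maf.items()
            }
            t = replace(truth, maf=jitter)
        out.append(simulate_strand_counts(t, cfg, rng=rng, coords=coords))
    return out
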