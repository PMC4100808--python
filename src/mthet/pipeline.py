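"""End-to-end orchestration of the synthetic study.

``run_full_study`` composes the stages in analysis order — simulate counts,
call heteroplasmies, score PCR replicates, cohort statistics, transmission
statistics with reshuffling nulls — writing tab-separated reports plus a
run manifest, and returns the in-memory results.  All randomness derives
from one seed via independent child seeds per stage, so two runs with the
same seed produce byte-identical statistics tables.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .calling import SampleProfile, build_profile, call_sample
from .cohort import (
    age_correlations,
    build_maf_matrix,
    cluster_samples,
    mean_rate_comparison,
    mr_correlation,
    occurrence_counts,
    per_site_anova,
    region_enrichment,
)
from .coords import RegionMap, default_coords
from .errors import QCEmptyError
from .replicates import ReplicateSet, cohort_replicate_report
from .simulate import (
    GeneratorConfig,
    TruthCohort,
    generate_rate_table,
    generate_truth_cohort,
    simulate_cohort_counts,
    simulate_replicates,
)
from .transmission import (
    NullDistribution,
    PairSet,
    classify_sites,
    cross_group_null,
    pair_correlation,
    pair_site_distances,
    reshuffle_null,
    tncs,
    total_heteroplasmy,
)

__all__ = ["StudyResult", "run_full_study"]

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


def _child_seeds(seed: int, n: int) -> list[int]:
    """Independent stage seeds derived from one master seed (each < 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


@dataclass
class StudyResult:
    """Everything the full synthetic study computes."""

    seed: int
    config: GeneratorConfig
    truth: TruthCohort
    profiles: tuple[SampleProfile, ...]
    maf_matrix: pd.DataFrame
    metadata: pd.DataFrame
    replicate_table: pd.DataFrame
    replicate_summary: dict
    enrichment: list
    anova: pd.DataFrame
    mr_correlations: dict[str, tuple[float, float]]
    rate_comparison: pd.DataFrame
    age_per_site: pd.DataFrame
    age_count_corr: tuple[float, float]
    newick: str
    pairs: PairSet
    pair_table: pd.DataFrame
    pearson_null: NullDistribution
    tncs_null: NullDistribution
    cross_nulls: dict[str, NullDistribution]
    distances: pd.DataFrame
    site_classes: pd.Series
    summary: dict = field(default_factory=dict)


def run_full_study(
    config: GeneratorConfig | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
    n_reshuffles: int = 2000,
    n_replicate_samples: int = 12,
    threshold: float = 0.002,
    coverage_floor: float = 10_000.0,
    write_counts: bool = True,
) -> StudyResult:
    """Run the complete synthetic study and write its report directory."""
    t0 = time.time()
    cfg = config or GeneratorConfig()
    coords = default_coords()
    region_map = RegionMap(coords=coords)
    seeds = _child_seeds(seed, 5)
    s_rates, s_cohort, s_counts, s_reps, s_null = seeds

    # --- simulate -----------------------------------------------------------
    rates = generate_rate_table(s_rates, coords, region_map, hotspots=cfg.public_sites)
    truth = generate_truth_cohort(cfg, seed=s_cohort, rate_table=rates, coords=coords)
    counts = simulate_cohort_counts(truth, seed=s_counts, coords=coords)
    logger.info("simulated %d samples x %d sites", len(counts), coords.fragment_length)

    # --- call ---------------------------------------------------------------
    profiles = []
    for p in truth.profiles:
        profiles.append(
            build_profile(
                counts[p.sample_id], p.group, p.family_id, p.age,
                threshold=threshold, coverage_floor=coverage_floor,
            )
        )
    n_pass = sum(p.qc_pass for p in profiles)
    logger.info(
        "calling: %d/%d samples pass QC (floor %.0f), %d calls total (threshold %.4f)",
        n_pass, len(profiles), coverage_floor,
        sum(len(p.calls) for p in profiles), threshold,
    )
    if n_pass == 0:
        raise QCEmptyError("no QC-passing samples")
    profiles = tuple(profiles)

    # --- replicates ---------------------------------------------------------
    rep_rng = np.random.default_rng(s_reps)
    qc_ids = [p.sample_id for p in profiles if p.qc_pass]
    rep_ids = qc_ids[:n_replicate_samples]
    truth_by_id = {p.sample_id: p for p in truth.profiles}
    replicate_sets = []
    for sid in rep_ids:
        reps = simulate_replicates(truth_by_id[sid], n=3, config=cfg, rng=rep_rng, coords=coords)
        sets = [frozenset(c.site for c in call_sample(t, threshold)) for t in reps]
        replicate_sets.append(ReplicateSet.from_sets(sid, sets))
    replicate_table, replicate_summary = cohort_replicate_report(
        replicate_sets, k=2, all_sites=coords.positions
    )

    # --- cohort statistics --------------------------------------------------
    matrix, meta = build_maf_matrix(profiles, coords)
    het_sites = set(int(c) for c in matrix.columns[(matrix.to_numpy() >= threshold).any(axis=0)])
    enrichment = region_enrichment(het_sites, region_map)
    anova = per_site_anova(matrix, meta["group"])
    mr_corr = {}
    for group in ("CENT", "CO", "ONLL"):
        occ = occurrence_counts(matrix, meta["group"], group, threshold)["count"]
        mr_corr[group] = mr_correlation(occ, rates)
    rate_cmp = mean_rate_comparison(het_sites, rates, region_map)
    age_site, age_count = age_correlations(matrix, meta["age"])
    newick = cluster_samples(matrix).to_newick()

    # --- transmission -------------------------------------------------------
    pairs = PairSet.from_profiles(profiles)
    th_m = pairs.mother_values(total_heteroplasmy)
    th_o = pairs.offspring_values(total_heteroplasmy)
    r, p = pair_correlation(th_m, th_o)
    null_rng = np.random.default_rng(s_null)
    pearson_null = reshuffle_null(th_m, th_o, "pearson_r", n_reshuffles, rng=null_rng, seed=s_null)
    tncs_null = reshuffle_null(
        [m.sites for m, _ in pairs.pairs], [o.sites for _, o in pairs.pairs],
        "tncs", n_reshuffles, rng=null_rng, seed=s_null,
    )
    th_onll = [total_heteroplasmy(p_) for p_ in pairs.onll]
    cross_nulls = {}
    if len(th_onll) >= 3:
        cross_nulls["CENT-ONLL"] = cross_group_null(th_m, th_onll, n_reshuffles, rng=null_rng, seed=s_null)
        cross_nulls["CO-ONLL"] = cross_group_null(th_o, th_onll, n_reshuffles, rng=null_rng, seed=s_null)
    pair_table = pd.DataFrame(
        {
            "family_id": [m.family_id for m, _ in pairs.pairs],
            "th_mother": th_m,
            "th_offspring": th_o,
            "shared_sites": [len(m.sites & o.sites) for m, o in pairs.pairs],
        }
    ).set_index("family_id")
    distances = pair_site_distances(pairs, threshold, coords)
    site_classes = classify_sites(pairs, coords=coords)

    summary = {
        "seed": seed,
        "n_samples": len(profiles),
        "n_qc_pass": n_pass,
        "n_pairs": pairs.n_pairs,
        "n_het_positions": len(het_sites),
        "mean_sensitivity": replicate_summary["mean_sensitivity"],
        "sd_sensitivity": replicate_summary["sd_sensitivity"],
        "mean_specificity": replicate_summary["mean_specificity"],
        "sd_specificity": replicate_summary["sd_specificity"],
        "tncs": tncs(pairs),
        "planted_tncs": truth.planted_tncs,
        "total_heteroplasmy_r": r,
        "total_heteroplasmy_p": p,
        "reshuffle_empirical_p": pearson_null.p,
        "tncs_empirical_p": tncs_null.p,
        "odds_ratio": {e.region: e.odds_ratio for e in enrichment},
        "mr_correlation_r": {g: rp[0] for g, rp in mr_corr.items()},
        "age_count_r": age_count[0],
        "n_public_sites": int((site_classes == "public").sum()),
    }

    result = StudyResult(
        seed=seed, config=cfg, truth=truth, profiles=profiles,
        maf_matrix=matrix, metadata=meta,
        replicate_table=replicate_table, replicate_summary=replicate_summary,
        enrichment=enrichment, anova=anova, mr_correlations=mr_corr,
        rate_comparison=rate_cmp, age_per_site=age_site, age_count_corr=age_count,
        newick=newick, pairs=pairs, pair_table=pair_table,
        pearson_null=pearson_null, tncs_null=tncs_null, cross_nulls=cross_nulls,
        distances=distances, site_classes=site_classes, summary=summary,
    )

    if outdir is not None:
        _write_reports(result, Path(outdir), counts, rates, write_counts, t0)
    return result


def _write_reports(
    result: StudyResult,
    outdir: Path,
    counts: dict,
    rates: pd.Series,
    write_counts: bool,
    t0: float,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    region_map = RegionMap()

    mio.dump_config(cfg, outdir / "config.yaml")
    mio.write_rate_table(rates, outdir / "rates.tsv")
    mio.write_metadata(result.truth, outdir / "metadata.tsv")
    mio.write_truth(result.truth, outdir / "truth.tsv")
    if write_counts:
        mio.write_count_tables(counts.values(), outdir / "counts.tsv")
    mio.write_calls({p.sample_id: p.calls for p in result.profiles}, outdir / "calls.tsv")

    result.replicate_table.to_csv(outdir / "replicates.tsv", sep="\t", index=False, float_format="%.6f")

    per_site = pd.DataFrame(index=result.maf_matrix.columns)
    per_site.index.name = "site"
    per_site["region"] = [region_map.assign(int(s)) for s in per_site.index]
    groups = result.metadata["group"]
    for g in ("CENT", "CO", "ONLL"):
        occ = occurrence_counts(result.maf_matrix, groups, g)
        per_site[f"occ_{g}"] = occ["count"]
        per_site[f"mean_maf_{g}"] = occ["mean_maf"]
    per_site["anova_F"] = result.anova["F"]
    per_site["anova_p"] = result.anova["p"]
    per_site["anova_p_adj"] = result.anova["p_adj"]
    per_site["contrasts"] = result.anova["significant_contrasts"]
    per_site.to_csv(outdir / "per_site_stats.tsv", sep="\t", float_format="%.6g")

    pd.DataFrame([vars(e) for e in result.enrichment]).to_csv(
        outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g"
    )
    result.rate_comparison.to_csv(outdir / "rate_comparison.tsv", sep="\t", float_format="%.6g")
    (outdir / "clustering.nwk").write_text(result.newick + "\n")

    result.pair_table.to_csv(outdir / "pairs.tsv", sep="\t", float_format="%.6f")
    result.distances.to_csv(outdir / "distances.tsv", sep="\t", float_format="%.4f")
    result.site_classes.rename_axis("site").to_frame().to_csv(outdir / "site_classes.tsv", sep="\t")

    null_rows = [result.pearson_null.summary(), result.tncs_null.summary()]
    null_rows[0]["comparison"] = "CENT-CO"
    null_rows[1]["comparison"] = "CENT-CO"
    for name, nd in result.cross_nulls.items():
        row = nd.summary()
        row["comparison"] = name
        null_rows.append(row)
    pd.DataFrame(null_rows).to_csv(outdir / "null_distributions.tsv", sep="\t", index=False, float_format="%.6g")

    manifest = {
        "tool": "mthet",
        "version": __version__,
        "seed": result.seed,
        "config_hash": mio.config_hash(cfg),
        "n_reshuffles": int(len(result.pearson_null.replicates)),
        "stages": ["simulate", "call", "replicates", "cohort-stats", "transmission"],
        "outputs": sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"),
        "elapsed_s": round(time.time() - t0, 2),
        "summary": result.summary,
    }
    mio.write_json(manifest, outdir / "manifest.json")
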