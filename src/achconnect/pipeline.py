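"""End-to-end scaled-down studies: dispersal → network and genetics → verdict.

These orchestrate the full chain the way the field study was run, at desk
scale: a ~300-km synthetic coast with two cross-shore flow discontinuities
takes the place of a ~2750-km coastline forced by an eddy-resolving ocean
model, and a few dozen coastal points with one particle per point per day
take the place of millions of particles.  The qualitative target is
structural: regions separated by flow discontinuities should emerge as
distinct modularity clusters of the stepping-stone network, and a genetic
ACH effect switched on in the generator should be recovered by the
centre-vs-edge verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ach, connectivity, gen_synth, lagrangian, ocean, popgen


@dataclass
class DispersalStudy:
    domain: ocean.CoastalDomain
    matrix: connectivity.ConnectivityMatrix
    stepping: connectivity.SteppingStoneResult
    stepping_W: np.ndarray
    partition: connectivity.ClusterPartition
    sampled_ids: np.ndarray
    region_labels: dict
    summaries: list
    ari_vs_regions: float


def dispersal_study(
    seed: int = 0,
    coast_length_km: float = 300.0,
    point_spacing_km: float = 5.0,
    n_years: int = 2,
    days_per_year: int = 45,
    release_days_per_year: int = 12,
    pld_days: float = 30.0,
    jet_speed: float = 0.18,
    barrier_speed: float = 0.4,
    capture_radius_km: float = 2.5,
    min_competency_days: float = 1.5,
    diffusion_km_sqrt_day: float = 6.0,
    sampled_km=(15, 45, 75, 115, 145, 175, 215, 245, 275),
) -> DispersalStudy:
    """Simulate dispersal along a three-region coast and cluster it.

    The coast runs east-west with land to the south; the alongshore jet
    flows westward and two Gaussian cross-shore barrier jets (at 1/3 and
    2/3 of the coast) deflect drifters offshore, partitioning the coast
    into a western, a central and an eastern region.  Nine sampled
    locations (three per region by default) are queried for stepping-stone
    connectivity and clustered by exhaustive modularity maximisation.
    """
    domain = ocean.straight_coast_domain(
        length_km=coast_length_km,
        point_spacing_km=point_spacing_km,
        grid_spacing_deg=0.02,
    )
    lon0 = float(domain.points["lon"].iloc[0])
    lon1 = float(domain.points["lon"].iloc[-1])
    barrier_lons = (lon0 + (lon1 - lon0) / 3.0, lon0 + 2.0 * (lon1 - lon0) / 3.0)
    recipe = ocean.FlowRecipe(
        name="three-region-coast-v1",
        jet_speed=jet_speed,
        jet_direction_deg=180.0,  # westward
        eddy_amplitude=0.05,
        eddy_wavelength_km=60.0,
        eddy_period_days=10.0,
        noise_sd=0.01,
        barriers=tuple((lon, 0.15, barrier_speed) for lon in barrier_lons),
        offshore_direction_deg=90.0,  # north, away from the southern land
    )

    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=2 * n_years)
    yearly = []
    summaries = []
    for y in range(n_years):
        fields = ocean.generate_fields(
            domain,
            recipe,
            years=1,
            days_per_year=days_per_year,
            seed=int(sub_seeds[2 * y]),
        )
        ts = lagrangian.run_release(
            domain,
            fields,
            release_days=range(release_days_per_year),
            pld_days=pld_days,
            capture_radius_km=capture_radius_km,
            min_competency_days=min_competency_days,
            diffusion_km_sqrt_day=diffusion_km_sqrt_day,
            seed=int(sub_seeds[2 * y + 1]),
            year=str(y),
        )
        yearly.append(connectivity.build_matrix(ts))
        summaries.append(lagrangian.summarize_dispersal(ts))
    avg = connectivity.average_matrices(yearly) if n_years > 1 else yearly[0]

    spacing = domain.point_spacing_km
    sampled_ids = np.array([int(round(km / spacing)) for km in sampled_km])
    stepping = connectivity.stepping_stone(avg, sampled_ids)
    W = connectivity.stepping_stone_matrix(avg, sampled_ids)
    partition = connectivity.cluster_modularity(W, ids=sampled_ids)

    thirds = coast_length_km / 3.0
    region_labels = {
        int(pid): int(min(km // thirds, 2)) for pid, km in zip(sampled_ids, sampled_km)
    }
    agreement = ach.compare_clusterings(region_labels, partition)
    return DispersalStudy(
        domain=domain,
        matrix=avg,
        stepping=stepping,
        stepping_W=W,
        partition=partition,
        sampled_ids=sampled_ids,
        region_labels=region_labels,
        summaries=summaries,
        ari_vs_regions=agreement["ari"],
    )


@dataclass
class GeneticsStudy:
    scenario: gen_synth.PopulationScenario
    diversity: list
    diffs: list
    diversity_tests: dict
    verdicts: list
    supported: bool


def genetics_study(
    scenario: gen_synth.PopulationScenario | None = None,
    seed: int = 0,
    diff_permutations: int = 0,
    test_iterations: int = 1000,
    bootstraps: int = 1000,
) -> GeneticsStudy:
    """Generate genetic data for a scenario and run the centre-vs-edge test.

    Sequence diversity (h, π) is compared within lineages with permutation
    diversity-difference tests (Bonferroni over within-lineage pairs);
    allelic richness uses bootstrap CIs at a standardised sample size.
    Differentiation matrices (Φ_PT, F_ST, G″_ST) supply the elevated-edge-
    divergence condition; their own permutation p-values are optional
    (``diff_permutations=0`` skips them, which the verdict does not need).
    """
    sc = scenario if scenario is not None else gen_synth.default_scenario()
    rng = np.random.default_rng(seed)
    s_hap, s_gen, s_ar, s_test, s_phi, s_fst = rng.integers(0, 2**31 - 1, size=6)

    haps = gen_synth.simulate_haplotypes(sc, seed=int(s_hap))
    gt = gen_synth.simulate_genotypes(sc, seed=int(s_gen))
    sites = sc.sites_table()

    diversity: list[popgen.DiversityEstimate] = []
    for code, hs in haps.items():
        diversity.append(popgen.haplotype_diversity(hs))
        diversity.append(popgen.nucleotide_diversity(hs))
    diversity.extend(
        popgen.allelic_richness(gt, bootstraps=bootstraps, seed=int(s_ar))
    )

    # within-lineage pairwise diversity-difference tests, Bonferroni over
    # all tested pairs per statistic
    tests: dict = {}
    pair_list = []
    for lineage, grp in sites.groupby("lineage"):
        codes = list(grp["code"])
        for i in range(len(codes)):
            for j in range(i + 1, len(codes)):
                pair_list.append((codes[i], codes[j]))
    m = len(pair_list)
    for a_code, b_code in pair_list:
        res = popgen.diversity_diff_test(
            haps[a_code],
            haps[b_code],
            iterations=test_iterations,
            seed=int(s_test) + hash((a_code, b_code)) % 10_000,
        )
        tests[("h", a_code, b_code)] = min(1.0, m * res["h"])
        tests[("pi", a_code, b_code)] = min(1.0, m * res["pi"])

    diffs = [
        popgen.phi_pt(list(haps.values()), permutations=diff_permutations, seed=int(s_phi)),
        popgen.fst_microsat(gt, permutations=diff_permutations, seed=int(s_fst)),
        popgen.g_double_prime_st(gt, permutations=0),
    ]

    verdicts = ach.evaluate_ach(
        diversity, diffs, sites, diversity_tests=tests, alpha=0.05
    )
    return GeneticsStudy(
        scenario=sc,
        diversity=diversity,
        diffs=diffs,
        diversity_tests=tests,
        verdicts=verdicts,
        supported=ach.overall_verdict(verdicts),
    )
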