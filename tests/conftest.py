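import numpy as np
import pytest

import steppescan as ss


@pytest.fixture(scope="session")
def scan_study():
    """Geography for the injected-gene-flow scan study: 12 focal populations,
    two dedicated neighbors each, one distant source and 9 extra references."""
    rng = np.random.default_rng(2024)
    records = [("SRC", 50.0, 95.0, "reference")]
    neighbor_sets = {}
    for k in range(12):
        lat = 45 + rng.normal(0, 2)
        lon = 40 + 4 * k + rng.normal(0, 2)
        records.append((f"F{k}", lat, lon, "focal"))
        ns = []
        for j in range(2):
            records.append(
                (f"N{k}_{j}", lat + rng.normal(0, 1), lon + rng.normal(0, 1),
                 "neighbor")
            )
            ns.append(f"N{k}_{j}")
        neighbor_sets[f"F{k}"] = ns
    for r in range(9):
        records.append(
            (f"R{r}", 40 + rng.normal(0, 5), 30 + rng.normal(0, 30), "reference")
        )
    pops = ss.PopulationTable.from_records(records, neighbor_sets)
    sizes = {p: 25 for p in pops.population_ids}
    return pops, sizes, neighbor_sets


def make_scan_config(pops, sizes, seed, delta=2.0):
    bins = [ss.LengthBin(1, 2)]
    edges = [ss.GeneFlowEdge("SRC", f"F{k}", delta) for k in range(12)]
    return ss.SharingSimConfig(
        populations=pops,
        sample_sizes=sizes,
        baseline_rate_cM=1.0,
        decay_scale_km=2000.0,
        gene_flow_edges=edges if delta > 0 else [],
        bins=bins,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_trio():
    """Admixed trio panel (alpha = 0.5) shared across f3 tests."""
    return ss.simulate_frequency_trio(0.5, F=0.2, n_snps=5000, n_per_pop=25, seed=11)


@pytest.fixture(scope="session")
def admixture_sim_g20():
    """One default-scale admixture simulation at g = 20, shared by dating tests."""
    cfg = ss.AdmixtureSimConfig(g=20, seed=77)
    geno, tracts = ss.simulate_admixed_haplotypes(cfg)
    return cfg, geno, tracts


def exchangeable_permtest_populations(n_neighbors=5, pool_size=100):
    """Focal + pooled neighbors at identical coordinates (exact exchangeability)
    with a distant source: the permutation-test null scenario."""
    records = [("F", 50.0, 40.0, "focal"), ("S", 50.0, 90.0, "source")]
    for j in range(n_neighbors):
        records.append((f"N{j}", 50.0, 40.0, "neighbor"))
    pops = ss.PopulationTable.from_records(records)
    sizes = {"F": 10, "S": 25, **{f"N{j}": pool_size for j in range(n_neighbors)}}
    return pops, sizes, [f"N{j}" for j in range(n_neighbors)]
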