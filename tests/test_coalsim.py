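"""Coalescent simulator: closed-form calibration, conditioning, determinism."""

import numpy as np
import pytest

from ratpopgen.coalsim import (
    CoalescentReplicate,
    DemographicModel,
    drop_mutations,
    fixed_s_tajima_null,
    simulate_fixed_s,
    simulate_genealogy,
)
from ratpopgen.diversity import harmonic
from ratpopgen.errors import ModelError


def test_model_validation():
    with pytest.raises(ModelError):
        DemographicModel("single", (1,))
    with pytest.raises(ModelError):
        DemographicModel("split", (4,))
    with pytest.raises(ModelError):
        DemographicModel("single", (4,), theta_locus=-1)
    with pytest.raises(ModelError):
        DemographicModel("bogus", (4,))


def test_pairwise_tmrca_expectation(rng):
    """E[TMRCA] = 1 for n = 2 in units of 2N generations."""
    model = DemographicModel("single", (2,))
    t = np.array([simulate_genealogy(model, rng).tmrca for _ in range(5000)])
    se = t.std(ddof=1) / np.sqrt(len(t))
    assert abs(t.mean() - 1.0) < 3 * se


def test_total_branch_length_expectation(rng):
    """E[total length] = 2 * a_n; a_10 gives 5.658."""
    model = DemographicModel("single", (10,))
    tot = np.array([simulate_genealogy(model, rng).total_branch_length() for _ in range(5000)])
    expected = 2 * harmonic(10)
    assert expected == pytest.approx(5.658, abs=1e-3)
    se = tot.std(ddof=1) / np.sqrt(len(tot))
    assert abs(tot.mean() - expected) < 3 * se


def test_split_without_migration_separates_populations(rng):
    """Between-population pairs cannot coalesce before the split."""
    model = DemographicModel("split", (2, 2), split_time=10.0, migration_rate=0.0)
    for _ in range(50):
        gen = simulate_genealogy(model, rng)
        for i in (0, 1):
            for j in (2, 3):
                assert gen.pair_tmrca(i, j) >= 10.0
        # within-population coalescence is allowed earlier
    gen = simulate_genealogy(DemographicModel("split", (1, 1), split_time=10.0), rng)
    assert gen.tmrca >= 10.0


def test_zero_theta_gives_monomorphic_replicate(rng):
    gen = simulate_genealogy(DemographicModel("single", (6,)), rng)
    rep = drop_mutations(gen, 0.0, 100, rng)
    assert rep.S == 0 and rep.alleles.shape == (6, 0)


def test_segregating_sites_expectation(rng):
    """E[S] = theta * a_n at the Table-1 scale (theta ~ 6.27, n = 58)."""
    theta, n, L = 6.27, 58, 2893
    model = DemographicModel("single", (n,), theta_locus=theta, L=L)
    S = np.array(
        [drop_mutations(simulate_genealogy(model, rng), theta, L, rng).S for _ in range(3000)]
    )
    expected = theta * harmonic(n)
    assert expected == pytest.approx(29.0, abs=0.1)
    se = S.std(ddof=1) / np.sqrt(len(S))
    assert abs(S.mean() - expected) < 3 * se


def test_single_mutation_carriers_form_a_clade(rng):
    gen = simulate_genealogy(DemographicModel("single", (8,)), rng)
    rep = simulate_fixed_s(DemographicModel("single", (8,)), 1, rng)
    assert rep.S == 1
    carriers = set(np.flatnonzero(rep.alleles[:, 0]))
    node = rep.mutations[0][1]
    assert carriers == set(rep.genealogy.leaves_under(node))
    assert 1 <= len(carriers) <= 7  # derived allele is polymorphic


def test_fixed_s_conditioning_and_determinism():
    model = DemographicModel("single", (10,), L=500)
    a = simulate_fixed_s(model, 7, seed=3)
    b = simulate_fixed_s(model, 7, seed=3)
    c = simulate_fixed_s(model, 7, seed=4)
    assert a.S == b.S == c.S == 7
    assert np.array_equal(a.alleles, b.alleles) and np.array_equal(a.positions, b.positions)
    assert not np.array_equal(a.alleles, c.alleles) or not np.array_equal(
        a.positions, c.positions
    )


def test_identical_seed_gives_bit_identical_genealogies():
    model = DemographicModel("split", (6, 4), split_time=0.5, migration_rate=1.0)
    g1 = simulate_genealogy(model, seed=99)
    g2 = simulate_genealogy(model, seed=99)
    assert np.array_equal(g1.parent, g2.parent)
    assert np.array_equal(g1.time, g2.time)


def test_fixed_s_null_distribution_brackets_zero(rng):
    d = fixed_s_tajima_null(n=44, S=50, n_reps=3000, seed=rng)
    assert -0.6 < d.mean() < 0.0  # slightly negative null mean
    lo, hi = np.quantile(d, [0.025, 0.975])
    assert lo < 0 < hi


def test_mean_pairwise_diversity_matches_theta(rng):
    """Sample mean of per-site theta_pi over replicates converges to
    theta_locus / L."""
    theta, n, L = 4.0, 16, 800
    model = DemographicModel("single", (n,), theta_locus=theta, L=L)
    vals = []
    for _ in range(2000):
        rep = drop_mutations(simulate_genealogy(model, rng), theta, L, rng)
        vals.append(rep.mean_pairwise_differences() / L)
    vals = np.array(vals)
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean() - theta / L) < 3 * se


def test_tmrca_distribution_against_msprime(rng):
    """Independent-engine cross-check: TMRCA and total length moments for
    n = 10 match msprime (same units: time in 2N generations with Ne = 0.5
    coalescent scaling)."""
    msprime = pytest.importorskip("msprime")
    ours_t, ours_len = [], []
    model = DemographicModel("single", (10,))
    for _ in range(3000):
        g = simulate_genealogy(model, rng)
        ours_t.append(g.tmrca)
        ours_len.append(g.total_branch_length())
    ts_t, ts_len = [], []
    for ts in msprime.sim_ancestry(
        samples=10, ploidy=1, population_size=1.0, num_replicates=3000, random_seed=5
    ):
        tree = ts.first()
        ts_t.append(tree.time(tree.root))
        ts_len.append(tree.total_branch_length)
    for ours, ref in ((ours_t, ts_t), (ours_len, ts_len)):
        ours, ref = np.array(ours), np.array(ref)
        se = np.sqrt(ours.var() / len(ours) + ref.var() / len(ref))
        assert abs(ours.mean() - ref.mean()) < 3.5 * se


def test_island_model_fst_scale(rng):
    """With 4Nm = 1 between two demes (long-standing split), Hudson Fst over
    many loci sits in the band around 1/(1 + 4Nm-ish) expectations; the
    check pins the simulator to a fixed tolerance band."""
    from ratpopgen.popstruct import hudson_fst

    model = DemographicModel(
        "split", (20, 20), split_time=20.0, migration_rate=1.0, L=1000
    )
    sites = []
    for _ in range(300):
        rep = drop_mutations(simulate_genealogy(model, rng), 2.0, 1000, rng)
        for col in range(rep.S):
            c1 = int(rep.alleles[:20, col].sum())
            c2 = int(rep.alleles[20:, col].sum())
            sites.append(
                ({"A": 20 - c1, "T": c1}, {"A": 20 - c2, "T": c2})
            )
    _, fst = hudson_fst(sites)
    # island-model expectation ~ 1/(1+4Nm+...) ; generous fixed band
    assert 0.2 < fst < 0.55
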