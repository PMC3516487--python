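"""Fst, polymorphism sharing, clustering export, Evanno delta-K."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ratpopgen.errors import ExportError
from ratpopgen.popstruct import (
    bootstrap_fst,
    classify_sharing,
    dataset_fst,
    evanno_delta_k,
    export_structure_input,
    hudson_fst,
    locus_site_counts,
    tally_sharing,
)

from conftest import make_alignment


def site(c1, k1, c2, k2):
    """Biallelic site record from derived counts and totals."""
    return ({"A": k1 - c1, "T": c1}, {"A": k2 - c2, "T": c2})


def test_fixed_difference_gives_fst_one():
    _, fst = hudson_fst([site(100, 100, 0, 100)])
    assert fst == pytest.approx(1.0)


def test_no_differentiation_gives_fst_near_zero():
    # the k/(k-1) correction leaves an O(1/k) negative bias at p1 = p2
    _, fst = hudson_fst([site(500, 1000, 500, 1000)])
    assert abs(fst) < 2e-3


def test_fst_direct_evaluation():
    # p1=0.9, p2=0.1 with 10 alleles each: Hw = 0.2 (unbiased), Hb = 0.82
    per_site, fst = hudson_fst([site(9, 10, 1, 10)])
    assert fst == pytest.approx(1 - 0.2 / 0.82)
    assert fst == pytest.approx(0.756, abs=5e-4)
    assert per_site[0] == pytest.approx(fst)


def test_monomorphic_sites_are_excluded():
    with pytest.raises(ValueError):
        hudson_fst([site(0, 10, 0, 10)])
    per_site, fst = hudson_fst([site(0, 10, 0, 10), site(9, 10, 1, 10)])
    assert len(per_site) == 1


def test_bootstrap_distribution_on_two_locus_toy(rng):
    """All resample combinations of two loci are enumerable; every bootstrap
    replicate value must be one of the attainable ratio-of-sums values."""
    locus_a = [site(9, 10, 1, 10)]
    locus_b = [site(6, 10, 4, 10)]
    attainable = set()
    for combo in itertools.product([locus_a, locus_b], repeat=2):
        _, f = hudson_fst([s for locus in combo for s in locus])
        attainable.add(round(f, 12))
    assert len(attainable) == 3  # aa, bb, and the mixed draw
    res = bootstrap_fst([locus_a, locus_b], n_boot=200, seed=0)
    eps = 1e-9
    assert min(attainable) - eps <= res.ci_low <= res.ci_high <= max(attainable) + eps

    # degenerate bootstrap: all loci identical -> zero-width CI
    res = bootstrap_fst([locus_a, locus_a, locus_a], n_boot=50, seed=1)
    assert res.ci_low == pytest.approx(res.ci_high)
    assert res.ci_low == pytest.approx(res.fst)


def test_bootstrap_is_deterministic_under_seed():
    loci = [[site(9, 10, 1, 10)], [site(6, 10, 4, 10)], [site(2, 10, 8, 10)]]
    a = bootstrap_fst(loci, n_boot=300, seed=42)
    b = bootstrap_fst(loci, n_boot=300, seed=42)
    assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)


@pytest.mark.parametrize(
    "c1,k1,c2,k2,expected",
    [
        (3, 10, 0, 10, "private_pop1"),
        (0, 10, 3, 10, "private_pop2"),
        (3, 10, 6, 10, "shared"),
        (10, 10, 0, 10, "fixed_diff"),
    ],
)
def test_sharing_classification(c1, k1, c2, k2, expected):
    assert classify_sharing(site(c1, k1, c2, k2)) == expected


def test_sharing_tallies_sum_to_analyzed_sites():
    sites = [site(3, 10, 0, 10), site(1, 10, 1, 10), site(10, 10, 0, 10), site(5, 10, 0, 0)]
    tally = tally_sharing(sites)
    assert tally.total == 3  # the all-missing-in-pop2 site is excluded
    assert tally.fixed_diff == 1 and tally.shared == 1 and tally.private_pop1 == 1


def test_fst_near_zero_for_unstructured_data(rng):
    """Data simulated without structure: multilocus Fst averages ~0."""
    from ratpopgen.coalsim import DemographicModel, drop_mutations, simulate_genealogy

    model = DemographicModel("single", (20,), L=500)
    vals = []
    for _ in range(500):
        rep = drop_mutations(simulate_genealogy(model, rng), 3.0, 500, rng)
        sites = []
        for col in range(rep.S):
            c1 = int(rep.alleles[:10, col].sum())
            c2 = int(rep.alleles[10:, col].sum())
            sites.append(site(c1, 10, c2, 10))
        if sites:
            try:
                _, f = hudson_fst(sites)
                vals.append(f)
            except ValueError:
                pass
    vals = np.array(vals)
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean()) < 3 * se + 0.01


def test_fst_increases_with_split_time(rng):
    from ratpopgen.coalsim import DemographicModel, drop_mutations, simulate_genealogy

    estimates = []
    for split_time in (0.1, 0.5, 2.0):
        model = DemographicModel(
            "split", (12, 12), split_time=split_time, migration_rate=0.0, L=500
        )
        sites = []
        sub_rng = np.random.default_rng(1000)  # same seed stream per grid point
        for _ in range(400):
            rep = drop_mutations(simulate_genealogy(model, sub_rng), 2.0, 500, sub_rng)
            for col in range(rep.S):
                c1 = int(rep.alleles[:12, col].sum())
                c2 = int(rep.alleles[12:, col].sum())
                sites.append(site(c1, 12, c2, 12))
        _, f = hudson_fst(sites)
        estimates.append(f)
    assert estimates[0] < estimates[1] < estimates[2]


def test_structure_export_modes_and_determinism(default_corpus):
    alignments, _, _ = default_corpus
    out1 = export_structure_input(alignments, "one-snp-per-locus", seed=5)
    out2 = export_structure_input(alignments, "one-snp-per-locus", seed=5)
    assert out1 == out2  # byte-identical under a fixed seed
    out3 = export_structure_input(alignments, "one-snp-per-locus", seed=6)
    assert out1 != out3  # the random SNP draw depends on the seed

    # two rows per individual, constant column count
    lines = out1.strip().split("\n")
    rows = [l.split("\t") for l in lines[1:]]
    assert len({len(r) for r in rows}) == 1
    assert len(rows) % 2 == 0


def test_structure_export_singleton_locus_omitted():
    # the only SNP is a singleton -> locus unusable in SNP mode
    aln = make_alignment(["AAA", "AAA", "AAA", "AAC"], pops=["P1", "P1", "P2", "P2"])
    with pytest.raises(ExportError):
        export_structure_input([aln], "one-snp-per-locus", seed=0)


def test_structure_export_haplotype_coding():
    # after masking the singleton (position 5), haplotypes are defined on the
    # informative positions 0 and 2; codes must preserve individual pairing
    seqs = ["TAAAAA", "TATAAA", "CAAAAA", "CATAAC"]
    aln = make_alignment(seqs, pops=["P1"] * 4)
    text = export_structure_input([aln], "haplotypes-as-alleles", seed=0)
    lines = [l.split("\t") for l in text.strip().split("\n")[1:]]
    # four distinct haplotypes (TA, TT, CA, CT) coded in order of appearance,
    # rows paired per individual
    assert [lines[0][2], lines[1][2]] == ["1", "2"]
    assert [lines[2][2], lines[3][2]] == ["3", "4"]

    # masking removes the singleton: identical on informative sites -> same code
    seqs = ["TAAAAA", "TAAAAC", "CATAAA", "CATAAA"]
    text = export_structure_input(
        [make_alignment(seqs, pops=["P1"] * 4)], "haplotypes-as-alleles", seed=0
    )
    lines = [l.split("\t") for l in text.strip().split("\n")[1:]]
    assert lines[0][2] == lines[1][2] == "1"
    assert lines[2][2] == lines[3][2] == "2"


def test_evanno_delta_k_worked_example():
    rows = []
    for k, mean in ((1, -100.0), (2, -50.0), (3, -45.0)):
        # two replicates per K, symmetric so the mean is exact
        for r, eps in ((0, +1.0), (1, -1.0)):
            sd_scale = {2: np.sqrt(2)}.get(k, 1.0)  # sd(L(2)) = 2
            rows.append({"K": k, "replicate": r, "log_prob": mean + eps * sd_scale})
    table = evanno_delta_k(pd.DataFrame(rows))
    dk2 = table.loc[table.K == 2, "delta_k"].item()
    assert dk2 == pytest.approx(abs(-45 - 2 * (-50) + (-100)) / 2.0)
    assert dk2 == pytest.approx(22.5)
    assert table.loc[table.K == 2, "is_best"].item()


def test_evanno_linear_log_probs_give_zero():
    rows = [
        {"K": k, "replicate": r, "log_prob": -10.0 * k + (r - 0.5)}
        for k in (1, 2, 3, 4)
        for r in (0, 1)
    ]
    table = evanno_delta_k(pd.DataFrame(rows))
    interior = table[table.K.isin([2, 3])]
    assert (interior["delta_k"].abs() < 1e-9).all()


def test_evanno_zero_sd_is_nan_and_ties_are_reported():
    rows = [
        {"K": k, "replicate": r, "log_prob": v}
        for k, v in ((1, -100.0), (2, -50.0), (3, -25.0), (4, -12.5))
        for r, v in ((0, v), (1, v))
    ]
    table = evanno_delta_k(pd.DataFrame(rows))
    assert table["delta_k"].dropna().empty  # sd = 0 -> undefined, not inf
    assert not table["is_best"].any()


def test_dataset_fst_on_synthetic_corpus(default_corpus):
    alignments, _, truth = default_corpus
    fst, per_locus = dataset_fst(alignments, "China", "UK")
    assert 0.0 < fst < 0.6
    res = bootstrap_fst(per_locus, n_boot=200, seed=3)
    assert res.ci_low <= res.fst <= res.ci_high
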