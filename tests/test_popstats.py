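"""Distances, Hudson Fst, diversity estimators and the isolation-model
moment estimator, each checked against enumeration or coalescent oracles."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import radsweep as rs
from radsweep import popstats
from radsweep.stackasm import (Assembly, AssemblyParams, CatalogLocus,
                               IndividualLocus, Stack)

from conftest import locus_copies_by_pop


def mk_locus(genotype_alleles: dict[str, list[str]], cid=0) -> CatalogLocus:
    genos = {ind: IndividualLocus(ind, [Stack(a, 10, ind) for a in alleles],
                                  len(alleles))
             for ind, alleles in genotype_alleles.items()}
    some = next(iter(genotype_alleles.values()))[0]
    return CatalogLocus(catalog_id=cid, genotypes=genos, consensus=some)


def mk_asm(loci, L):
    return Assembly(AssemblyParams(similarity_s=93, locus_length=L), loci)


def test_p_distance():
    assert rs.p_distance("ACGT", "ACGT") == 0.0
    assert rs.p_distance("A" * 99 + "C", "A" * 100) == pytest.approx(0.01)
    rng = np.random.default_rng(0)
    for _ in range(50):
        a = "".join(rng.choice(list("ACGT"), 30))
        b = "".join(rng.choice(list("ACGT"), 30))
        assert rs.p_distance(a, b) == sum(
            x != y for x, y in zip(a, b)) / 30
    with pytest.raises(ValueError):
        rs.p_distance("AC", "ACG")


def test_jc_distance_values_and_saturation():
    assert rs.jc_distance(0.0) == 0.0
    assert rs.jc_distance(0.01) == pytest.approx(0.010067265249105515,
                                                 abs=1e-12)
    assert math.isnan(rs.jc_distance(0.75))
    assert math.isnan(rs.jc_distance(0.9))


@settings(derandomize=True, max_examples=80)
@given(p=st.floats(min_value=0.0, max_value=0.74))
def test_jc_correction_never_below_p(p):
    d = rs.jc_distance(p)
    assert d >= p * (1 - 1e-12)
    if p > 1e-9:
        assert d > p
    assert (d == 0) == (p == 0)


def test_individual_pair_distance_enumeration():
    locus = mk_locus({"i": ["AAAA"], "j": ["AAAA"]})
    assert rs.individual_pair_distance(locus, "i", "j") == 0.0
    # het {A,B} vs hom {A}: mean of {0, d(A,B)} twice = d(A,B)/2
    locus = mk_locus({"i": ["AAAA", "AATT"], "j": ["AAAA"]})
    assert rs.individual_pair_distance(locus, "i", "j") == pytest.approx(
        rs.p_distance("AAAA", "AATT") / 2)
    rng = np.random.default_rng(1)
    for _ in range(30):
        seqs = ["".join(rng.choice(list("ACGT"), 12)) for _ in range(4)]
        locus = mk_locus({"i": seqs[:2], "j": seqs[2:]})
        copies_i, copies_j = seqs[:2], seqs[2:]
        expected = np.mean([rs.p_distance(a, b)
                            for a in copies_i for b in copies_j])
        assert rs.individual_pair_distance(locus, "i", "j") == pytest.approx(
            expected)
    assert rs.individual_pair_distance(locus, "i", "missing") is None


POPMAP8 = {f"p1_i{k}": "pop1" for k in range(1, 5)} | \
          {f"p2_i{k}": "pop2" for k in range(1, 5)}


def test_hudson_fst_fixed_difference():
    """Populations fixed for alleles differing at one site: Hw=0, Hb=1,
    Fst=1."""
    locus = mk_locus({ind: ["A" * 10] for ind in POPMAP8 if "p1" in ind}
                     | {ind: ["A" * 9 + "C"] for ind in POPMAP8 if "p2" in ind})
    r = rs.hudson_fst(locus, POPMAP8)
    assert (r.hw, r.hb, r.fst) == (0.0, 1.0, 1.0)


def test_hudson_fst_identical_compositions_is_zero():
    alleles = {"p1_i1": ["AAAA", "AATT"], "p1_i2": ["AAAA", "AATT"],
               "p2_i1": ["AAAA", "AATT"], "p2_i2": ["AAAA", "AATT"]}
    popmap = {"p1_i1": "pop1", "p1_i2": "pop1",
              "p2_i1": "pop2", "p2_i2": "pop2"}
    r = rs.hudson_fst(mk_locus(alleles), popmap, with_replacement=True)
    assert r.hw == pytest.approx(r.hb)
    assert r.fst == pytest.approx(0.0)
    # the distinct-pair estimator carries the usual small-sample offset
    r2 = rs.hudson_fst(mk_locus(alleles), popmap)
    assert abs(r2.fst) < 0.5


def _oracle_fst(copies_by_pop):
    labeled = [(pop, c) for pop, cs in copies_by_pop.items() for c in cs]
    within, between = [], []
    for (pa, a), (pb, b) in combinations(labeled, 2):
        d = sum(x != y for x, y in zip(a, b))
        (within if pa == pb else between).append(d)
    hw, hb = np.mean(within), np.mean(between)
    return 1 - hw / hb if hb > 0 else None


def test_hudson_fst_matches_exhaustive_pair_enumeration():
    """4+4 diploids with random biallelic genotypes: Fst equals the
    brute-force mean over all C(16,2) allele-copy pairs."""
    rng = np.random.default_rng(2)
    a, b = "A" * 8, "A" * 4 + "C" * 4
    for _ in range(40):
        genos = {}
        for ind in POPMAP8:
            pick = rng.integers(3)
            genos[ind] = [[a], [a, b], [b]][pick]
        locus = mk_locus(genos)
        r = rs.hudson_fst(locus, POPMAP8)
        copies = {"pop1": [], "pop2": []}
        for ind, alleles in genos.items():
            cs = alleles * 2 if len(alleles) == 1 else alleles
            copies[POPMAP8[ind]].extend(cs)
        expected = _oracle_fst(copies)
        if expected is None or len({*copies["pop1"], *copies["pop2"]}) == 1:
            assert r is None or r.fst is None
        else:
            assert r.fst == pytest.approx(expected)


def test_fst_invariances():
    """Relabeling populations leaves Fst unchanged exactly; duplicating
    every allele copy leaves Hb unchanged exactly and Hw at the known
    pair-count factor 2(n-1)/(2n-1)."""
    genos = {"p1_i1": ["AAAA", "AATT"], "p1_i2": ["AAAA"],
             "p2_i1": ["TTTT"], "p2_i2": ["TTAA", "TTTT"]}
    popmap = {"p1_i1": "pop1", "p1_i2": "pop1",
              "p2_i1": "pop2", "p2_i2": "pop2"}
    swapped = {k: ("pop2" if v == "pop1" else "pop1")
               for k, v in popmap.items()}
    locus = mk_locus(genos)
    r1, r2 = rs.hudson_fst(locus, popmap), rs.hudson_fst(locus, swapped)
    assert r1.fst == pytest.approx(r2.fst)
    # duplicate every copy: represent each individual twice
    genos_dup = dict(genos)
    popmap_dup = dict(popmap)
    for ind in genos:
        genos_dup[ind + "_b"] = genos[ind]
        popmap_dup[ind + "_b"] = popmap[ind]
    r_dup = rs.hudson_fst(mk_locus(genos_dup), popmap_dup)
    assert r_dup.hb == pytest.approx(r1.hb)
    n = 4  # copies per population before duplication
    factor = 2 * (n - 1) / (2 * n - 1)
    assert r_dup.hw == pytest.approx(r1.hw * factor)
    # the frequency-weighted estimator is exactly duplication-invariant
    rw = rs.hudson_fst(locus, popmap, with_replacement=True)
    rw_dup = rs.hudson_fst(mk_locus(genos_dup), popmap_dup,
                           with_replacement=True)
    assert rw_dup.hw == pytest.approx(rw.hw)
    assert rw_dup.fst == pytest.approx(rw.fst)


def test_mean_fst_methods(shallow_dataset):
    asm = rs.assemble(shallow_dataset.reads_by_individual,
                      rs.AssemblyParams(similarity_s=93, min_depth_m=3))
    popmap = shallow_dataset.populations
    m1 = rs.mean_fst(asm, popmap, method="mean_of_ratios")
    m2 = rs.mean_fst(asm, popmap, method="ratio_of_sums")
    assert 0 < m1 <= 1 and 0 < m2 <= 1
    with pytest.raises(ValueError):
        rs.mean_fst(asm, popmap, method="nope")


def test_segregating_sites_and_watterson():
    assert rs.segregating_sites(["AAAA", "AAAA", "AAAA"]) == 0
    assert rs.segregating_sites(["AAAA", "AATA", "CAAA"]) == 2
    # n=2 copies: harmonic sum is 1, theta_W = S / (L * n_loci)
    loci = [["AAAA", "AATA"], ["CCCC", "CCCC"]]
    assert rs.watterson_theta(loci, 2) == pytest.approx(1 / (4 * 2))
    with pytest.raises(ValueError):
        rs.watterson_theta(loci, 1)


def test_diversity_estimators_match_coalescent_expectation():
    """tau=0, theta=0.005: pi and Watterson's estimator each within 3
    Monte-Carlo SE of theta (800 loci)."""
    theta = 0.005
    params = rs.SimParams(n_loci=800, tau=0.0, theta1=theta, theta2=theta,
                          theta_a=theta, seed=31)
    loci = [locus_copies_by_pop(loc, 4)[0]
            for loc in rs.simulate_true_loci(params)]
    pis = []
    for copies in loci:
        pis.append(np.mean([rs.p_distance(a, b)
                            for a, b in combinations(copies, 2)]))
    se_pi = np.std(pis, ddof=1) / math.sqrt(len(pis))
    assert abs(np.mean(pis) - theta) <= 3 * se_pi
    assert rs.nucleotide_diversity(loci) == pytest.approx(np.mean(pis))
    a7 = sum(1 / k for k in range(1, 8))
    svals = [rs.segregating_sites(c) for c in loci]
    se_w = np.std(svals, ddof=1) / math.sqrt(len(svals)) / (a7 * 100)
    assert abs(rs.watterson_theta(loci, 8) - theta) <= 3 * se_w


def test_moment_inversion_trivial_identities():
    """Infinite-sites closed form: zero counts give zero estimates; a pure
    Poisson variance (v = mean) gives theta_A=0 and tau = mean/(2L)."""
    th, tau, fl = popstats._invert_infinite_sites(0.0, 0.0, 100)
    assert (th, tau) == (0.0, 0.0)
    th, tau, fl = popstats._invert_infinite_sites(2.0, 2.0, 100)
    assert th == 0.0 and tau == pytest.approx(0.01)
    th, tau, fl = popstats._invert_infinite_sites(1.5, 1.75, 100)
    assert th == pytest.approx(0.005) and tau == pytest.approx(0.005)


def test_finite_sites_inversion_agrees_at_low_divergence():
    """The exact finite-sites inversion converges to the infinite-sites
    closed form as divergence -> 0 and recovers exact moments."""
    for tau, th_a in [(0.002, 0.001), (0.005, 0.005), (0.01, 0.008)]:
        L = 100
        # forward moments under the finite-sites model
        a = math.exp(-8 * tau / 3)
        u = 1 / (1 + 4 * th_a / 3)
        w = 1 / (1 + 8 * th_a / 3)
        eq = 0.75 * (1 - a * u)
        eq2 = (9 / 16) * (1 - 2 * a * u + a * a * w)
        mean_k = L * eq
        var_k = L * (eq - eq2) + L * L * (eq2 - eq * eq)
        th_hat, tau_hat, _ = popstats._invert_finite_sites(mean_k, var_k, L)
        assert th_hat == pytest.approx(th_a, rel=1e-9)
        assert tau_hat == pytest.approx(tau, rel=1e-9)
        th_inf, tau_inf, _ = popstats._invert_infinite_sites(mean_k, var_k, L)
        assert th_inf == pytest.approx(th_a, rel=0.15)
        assert tau_inf == pytest.approx(tau, rel=0.15)


def test_isolation_moments_all_identical_sequences():
    loci = [(["A" * 100] * 2, ["A" * 100] * 2)] * 60
    est = rs.isolation_moments_from_loci(loci, 100, np.random.default_rng(0))
    assert est.theta_a == 0.0 and est.tau == 0.0
    assert not est.low_confidence


def test_isolation_moments_low_confidence_flag():
    loci = [(["A" * 100], ["A" * 100])] * 10
    est = rs.isolation_moments_from_loci(loci, 100, np.random.default_rng(0))
    assert est.low_confidence


def test_isolation_moments_recovery_smoke():
    """Moderate-size recovery from true haplotypes (1,500 loci): estimates
    land within 30% of the generating parameters."""
    params = rs.SimParams(n_loci=1500, tau=0.005, theta1=0.005,
                          theta2=0.005, theta_a=0.005, seed=41)
    loci = [locus_copies_by_pop(loc, 4)
            for loc in rs.simulate_true_loci(params)]
    est = rs.isolation_moments_from_loci(loci, 100, np.random.default_rng(2))
    assert est.theta_a == pytest.approx(0.005, rel=0.30)
    assert est.tau == pytest.approx(0.005, rel=0.30)
    assert est.theta1 == pytest.approx(0.005, rel=0.20)


def test_threshold_bias_reproduction(moderate_sweep):
    """Stringent thresholds depress mean JC distance and ancestral theta;
    the liberal 93% values sit closer to the generating truth."""
    t = moderate_sweep.table.set_index("threshold")
    jc93, jc99 = t.loc[93, "mean_jc_distance"], t.loc[99, "mean_jc_distance"]
    th93, th99 = t.loc[93, "theta_a"], t.loc[99, "theta_a"]
    assert jc99 < jc93
    assert th99 < th93
    true_theta_a = moderate_sweep.dataset.params.theta_a
    assert abs(th93 - true_theta_a) < abs(th99 - true_theta_a)
    # truth-based mean JC between individuals for comparison
    loci = moderate_sweep.dataset.loci[:400]
    import itertools
    inds = sorted(loci[0].haplotypes)
    vals = []
    for i, j in itertools.combinations(inds, 2):
        ds_pair = []
        for loc in loci:
            ps = [rs.p_distance(a, b) for a in loc.haplotypes[i]
                  for b in loc.haplotypes[j]]
            ds_pair.append(np.mean([rs.jc_distance(p) for p in ps]))
        vals.append(np.mean(ds_pair))
    true_jc = np.mean(vals)
    assert abs(jc93 - true_jc) < abs(jc99 - true_jc)


def test_fst_stability_diagnostic(moderate_sweep):
    """Fst is far less threshold-sensitive than ancestral theta (reported
    range check, not a fixed tolerance)."""
    t = moderate_sweep.table.set_index("threshold")
    fst_rel = abs(t.loc[99, "mean_fst"] - t.loc[93, "mean_fst"]) \
        / t.loc[93, "mean_fst"]
    assert 0 < t.loc[93, "mean_fst"] <= 1
    assert fst_rel < 0.5
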