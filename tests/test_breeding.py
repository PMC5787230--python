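"""Breeding loop, BLUP solver and GBLUP prediction."""

import numpy as np
import pytest

from rohsim import inbreeding as ib
from rohsim.breeding import (
    SimConfig,
    blup_ebv,
    gblup_gebv,
    henderson_a_inverse,
    run_simulation,
    score_candidates,
)


def small_config(**kw):
    base = dict(
        n_sires=8, n_dams=40, n_cycles=8, n_chrom=3, total_cm=300.0,
        n_snp=400, n_qtl=40, snapshot_cycles=(8,), selection="random",
    )
    base.update(kw)
    return SimConfig(**base)


class TestSimulationContract:
    def test_pedigree_size_and_founder_inbreeding(self):
        res = run_simulation(small_config(), rng=np.random.default_rng(0))
        assert res.n_animals == 48 + 8 * 80
        assert np.all(res.f_true[:48] == 0.0)
        assert np.all(res.f_ped[:48] == 0.0)
        ped = res.pedigree_frame()
        # parents precede offspring; sires male, dams female
        off = ped[ped.sire > 0]
        assert (off.sire < off.id).all() and (off.dam < off.id).all()
        sex = ped.set_index("id").sex
        assert (sex.loc[off.sire].to_numpy() == "M").all()
        assert (sex.loc[off.dam].to_numpy() == "F").all()

    def test_deterministic_replay(self):
        a = run_simulation(small_config(), rng=np.random.default_rng(3))
        b = run_simulation(small_config(), rng=np.random.default_rng(3))
        assert np.array_equal(a.f_true, b.f_true)
        assert np.array_equal(a.sire, b.sire)
        assert np.array_equal(a.snapshots[8].dose, b.snapshots[8].dose)

    def test_inbreeding_rises_under_random_mating(self):
        res = run_simulation(small_config(), rng=np.random.default_rng(1))
        means = [res.f_true[res.cohort(c)].mean() for c in (2, 5, 8)]
        assert means[0] < means[1] < means[2]

    def test_phenotype_selection_gains_and_inbreeds_faster(self):
        r_rand = run_simulation(small_config(), rng=np.random.default_rng(2))
        r_phen = run_simulation(
            small_config(selection="phenotype"), rng=np.random.default_rng(2)
        )
        founders_mean = r_phen.tbv[:48].mean()
        assert r_phen.tbv[r_phen.cohort(8)].mean() > founders_mean + 0.5
        assert (
            r_phen.f_true[r_phen.cohort(8)].mean()
            > r_rand.f_true[r_rand.cohort(8)].mean()
        )

    def test_unknown_criterion_rejected(self):
        with pytest.raises(ValueError):
            run_simulation(small_config(selection="magic"))

    def test_random_selection_no_differential(self):
        res = run_simulation(small_config(n_cycles=4, snapshot_cycles=()), rng=np.random.default_rng(4))
        # selected parents of cycle-4 offspring are an unbiased TBV sample
        sel = np.unique(res.sire[res.cohort(4)])
        pool = res.cohort(3)
        assert abs(res.tbv[sel].mean() - res.tbv[pool].mean()) < 0.5


class TestBlup:
    def test_matches_dense_mixed_model_solve(self):
        rng = np.random.default_rng(5)
        n, nf = 30, 6
        sire = np.full(n, -1)
        dam = np.full(n, -1)
        for i in range(nf, n):
            sire[i], dam[i] = rng.integers(0, i), rng.integers(0, i)
        y = rng.normal(0, 1, n)
        sa2, se2 = 0.4, 0.6
        mu, ebv = blup_ebv(sire, dam, y, sa2, se2)
        A = ib.tabular_relationship_matrix(sire, dam)
        C = np.zeros((n + 1, n + 1))
        C[0, 0] = n
        C[0, 1:] = 1
        C[1:, 0] = 1
        C[1:, 1:] = np.eye(n) + (se2 / sa2) * np.linalg.inv(A)
        sol = np.linalg.solve(C, np.concatenate([[y.sum()], y]))
        assert abs(mu - sol[0]) < 1e-6
        assert np.abs(ebv - sol[1:]).max() < 1e-6

    def test_unrelated_single_record_regression(self):
        y = np.array([2.0, 0.0, 1.0])
        s = np.full(3, -1)
        mu, ebv = blup_ebv(s, s, y, 0.3, 0.7)
        assert np.allclose(ebv, 0.3 * (y - mu), atol=1e-9)

    def test_heritability_one_limit(self):
        y = np.array([2.0, -1.0, 0.5, 1.5])
        s = np.full(4, -1)
        _, ebv = blup_ebv(s, s, y, 1.0, 1e-4)
        assert np.allclose(ebv, y - y.mean(), atol=1e-2)

    def test_all_missing_rejected(self):
        s = np.full(3, -1)
        with pytest.raises(ValueError):
            blup_ebv(s, s, np.full(3, np.nan), 0.3, 0.7)

    def test_accuracy_increases_with_heritability(self):
        rng = np.random.default_rng(6)
        res = {}
        for h2 in (0.1, 0.9):
            r = run_simulation(
                small_config(selection="blup_ebv", h2=h2, n_cycles=4, snapshot_cycles=()),
                rng=np.random.default_rng(7),
            )
            idx = r.cohort(4)
            mu, ebv = blup_ebv(
                r.sire, r.dam, r.phen, h2, 1 - h2, F=r.f_ped
            )
            res[h2] = np.corrcoef(ebv[idx], r.tbv[idx])[0, 1]
        assert res[0.9] > res[0.1]
        del rng

    def test_a_inverse_inverts_tabular_a(self):
        rng = np.random.default_rng(8)
        n, nf = 40, 6
        sire = np.full(n, -1)
        dam = np.full(n, -1)
        for i in range(nf, n):
            sire[i], dam[i] = rng.integers(0, i), rng.integers(0, i)
        F = ib.f_ped(sire, dam)
        Ainv = henderson_a_inverse(sire, dam, F).toarray()
        A = ib.tabular_relationship_matrix(sire, dam)
        assert np.allclose(Ainv @ A, np.eye(n), atol=1e-8)


class TestGblup:
    def test_single_marker_rank_order(self):
        rng = np.random.default_rng(9)
        dose_r = rng.integers(0, 3, (30, 1)).astype(np.int8)
        y = dose_r[:, 0] * 1.0  # noise-free single-predictor trait
        dose_c = np.array([[0], [1], [2]], np.int8)
        _, g = gblup_gebv(dose_r, y, dose_c, 0.3, 0.7)
        assert g[0] < g[1] < g[2]

    def test_marker_space_equals_grm_space(self):
        """SNP-BLUP and G-space GBLUP are the same predictor."""
        rng = np.random.default_rng(10)
        dose_r = rng.integers(0, 3, (20, 100)).astype(np.int8)
        dose_c = rng.integers(0, 3, (7, 100)).astype(np.int8)
        y = rng.normal(0, 1, 20)
        mu_m, gm = gblup_gebv(dose_r, y, dose_c, 0.3, 0.7, method="markers")
        mu_g, gg = gblup_gebv(dose_r, y, dose_c, 0.3, 0.7, method="grm")
        assert abs(mu_m - mu_g) < 1e-8
        assert np.abs(gm - gg).max() < 1e-8

    def test_monomorphic_reference_rejected(self):
        dose = np.full((5, 10), 2, np.int8)
        with pytest.raises(ValueError):
            gblup_gebv(dose, np.zeros(5), dose, 0.3, 0.7)


def test_score_candidates_dispatch():
    rng = np.random.default_rng(11)
    phen = np.arange(5.0)
    cand = np.array([0, 2, 4])
    assert np.array_equal(score_candidates("phenotype", cand, phen, rng), [0.0, 2.0, 4.0])
    r = score_candidates("random", cand, phen, rng)
    assert r.shape == (3,)
    with pytest.raises(ValueError):
        score_candidates("blup_ebv", cand, phen, rng)
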