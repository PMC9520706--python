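"""Two-stage detection: Phase I filtering/ordering and Phase II search."""

import itertools

import numpy as np
import pytest

from stsbn.data import GenotypeMatrix
from stsbn.detect import STSBNConfig, phase1_candidates, phase2_select, run_sts_bn
from stsbn.scoring import local_score
from stsbn.simulate import SimParams, sample_dataset

from conftest import make_noise_matrix


def matrix_from_columns(columns, pheno):
    cols = [np.asarray(c, dtype=np.int8) for c in columns]
    return GenotypeMatrix(
        genotypes=np.column_stack(cols),
        phenotype=np.asarray(pheno, dtype=np.int8),
        marker_ids=[f"m{j}" for j in range(len(cols))],
        sample_ids=[f"s{i}" for i in range(len(pheno))],
    )


def exhaustive_best_subset(g, candidates, kappa=0.17):
    """Oracle: maximise the local score over all subsets of the candidates."""
    best, best_set = local_score(g.phenotype, [], kappa).score, frozenset()
    for k in range(1, len(candidates) + 1):
        for sub in itertools.combinations(candidates, k):
            s = local_score(g.phenotype, [g.column(j) for j in sub], kappa).score
            if s > best:
                best, best_set = s, frozenset(sub)
    return best_set, best


class TestPhase1:
    def test_strong_marker_among_noise_survives(self, rng):
        hits = 0
        for _ in range(30):
            g = make_noise_matrix(rng, n=2000, m=50)
            geno = g.genotypes.copy()
            geno[:, 17] = np.where(
                rng.random(2000) < 0.9, g.phenotype * 2, rng.integers(0, 3, 2000)
            )
            g2 = GenotypeMatrix(geno, g.phenotype, g.marker_ids, g.sample_ids)
            hits += phase1_candidates(g2) == [17]
        assert hits / 30 >= 0.95

    def test_noisy_copy_evicted_by_conditional_test(self, rng):
        """Chain X' <- X -> D: the shadow X' is screened off given X."""
        evictions = 0
        reps = 50
        for _ in range(reps):
            n = 2000
            x = rng.integers(0, 3, n)
            x_shadow = np.where(rng.random(n) < 0.85, x, rng.integers(0, 3, n))
            p_d = 1 / (1 + np.exp(-(x - 1.0) * 1.5))
            d = (rng.random(n) < p_d).astype(np.int8)
            g = matrix_from_columns([x_shadow, x], d)
            cand = phase1_candidates(g)
            evictions += 0 not in cand and 1 in cand
        assert evictions / reps >= 0.9

    def test_all_noise_marginal_survivor_rate_uncorrected(self, rng):
        """Without familywise correction, ~alpha1 * m markers pass the screen."""
        cfg = STSBNConfig(alpha1=0.01, max_cond=0, bonferroni=False)
        survivors = [
            len(phase1_candidates(make_noise_matrix(rng, m=100), cfg)) for _ in range(20)
        ]
        assert 0.2 < np.mean(survivors) < 3.0  # binomial mean 1, loose MC band

    def test_constant_phenotype_rejected(self, rng):
        g = make_noise_matrix(rng, n=100, m=5)
        g.phenotype[:] = 1
        with pytest.raises(ValueError):
            phase1_candidates(g)

    def test_zero_markers_gives_empty_list(self):
        g = GenotypeMatrix(
            np.zeros((10, 0), dtype=np.int8),
            np.tile([0, 1], 5),
            [],
            [f"s{i}" for i in range(10)],
        )
        assert phase1_candidates(g) == []


class TestPhase2:
    def test_empty_candidates_select_nothing(self, noise_matrix):
        res = phase2_select([], noise_matrix)
        assert res.selected == set()
        assert res.final_score == pytest.approx(
            local_score(noise_matrix.phenotype, []).score
        )

    def test_single_improving_candidate_selected(self, rng):
        n = 1000
        x = rng.integers(0, 3, n)
        d = (x + rng.integers(0, 2, n) >= 2).astype(np.int8)
        g = matrix_from_columns([x], d)
        res = phase2_select([0], g)
        assert res.selected == {0}
        assert res.score_trace == [("add", 0, pytest.approx(res.final_score))]

    def test_two_causal_plus_ld_shadows_recovered(self, rng):
        """Greedy selection matches the exhaustive-score oracle and keeps
        only the causal pair when each causal marker has an LD shadow."""
        agree = both = 0
        reps = 20
        for _ in range(reps):
            n = 2000
            a = rng.integers(0, 3, n)
            b = rng.integers(0, 3, n)
            sh_a = np.where(rng.random(n) < 0.8, a, rng.integers(0, 3, n))
            sh_b = np.where(rng.random(n) < 0.8, b, rng.integers(0, 3, n))
            logit = -2.0 + 1.0 * a + 1.0 * b
            d = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(np.int8)
            g = matrix_from_columns([a, b, sh_a, sh_b], d)
            res = phase2_select([0, 1, 2, 3], g)
            oracle, _ = exhaustive_best_subset(g, [0, 1, 2, 3])
            agree += res.selected == set(oracle)
            both += res.selected == {0, 1}
        assert agree / reps >= 0.9
        assert both / reps >= 0.9

    def test_max_parents_cap_respected(self, rng):
        n = 2000
        xs = [rng.integers(0, 3, n) for _ in range(4)]
        logit = -3.0 + sum(1.0 * x for x in xs)
        d = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(np.int8)
        g = matrix_from_columns(xs, d)
        res = phase2_select([0, 1, 2, 3], g, STSBNConfig(max_parents=2))
        assert len(res.selected) <= 2


class TestRunStsBn:
    def test_deterministic(self, rng):
        g = sample_dataset(SimParams(seed=5, maf_a=0.5, maf_b=0.5), model=1)
        r1 = run_sts_bn(g)
        r2 = run_sts_bn(g)
        assert r1.selected == r2.selected
        assert r1.candidates == r2.candidates
        assert r1.final_score == r2.final_score
        assert r1.score_trace == r2.score_trace

    def test_selected_subset_of_candidates_and_score_no_worse_than_empty(self):
        g = sample_dataset(SimParams(seed=11, maf_a=0.5, maf_b=0.5), model=1)
        res = run_sts_bn(g)
        assert res.selected <= set(res.candidates)
        assert res.final_score >= local_score(g.phenotype, []).score

    def test_column_permutation_invariance(self):
        """Selected marker identities do not depend on column order."""
        g = sample_dataset(SimParams(seed=2, maf_a=0.5, maf_b=0.5), model=1)
        base = run_sts_bn(g).selected_ids(g)
        rng = np.random.default_rng(0)
        for _ in range(3):
            order = rng.permutation(g.n_markers)
            gp = g.permute_markers(order)
            assert run_sts_bn(gp).selected_ids(gp) == base

    def test_permuted_phenotype_selects_nothing(self, rng):
        g = sample_dataset(SimParams(seed=3, maf_a=0.5, maf_b=0.5), model=1)
        empties = 0
        reps = 10
        for _ in range(reps):
            gp = GenotypeMatrix(
                g.genotypes,
                rng.permutation(g.phenotype),
                g.marker_ids,
                g.sample_ids,
            )
            empties += len(run_sts_bn(gp).selected) == 0
        assert empties / reps >= 0.9
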