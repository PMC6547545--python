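import numpy as np
import pytest

from diplohmm.hmm import (
    CallConfig,
    CoverageCapError,
    assign_phase_sets,
    build_hmm,
    call_diplotype,
    forward_backward,
    genotype_posteriors,
)
from diplohmm.matrix import AlignmentMatrix
from diplohmm.simulate import SimulationConfig, simulate
from diplohmm.substitution import SubstitutionModel

from conftest import make_matrix
from oracles import brute_force_inference, random_matrix


@pytest.fixture(scope="module")
def model():
    return SubstitutionModel()


class TestConstruction:
    def test_emitting_state_count_is_2_pow_cov_times_pairs(self, rng, model):
        m = random_matrix(rng, 5, 4)
        hmm = build_hmm(m, model)
        for j, col in enumerate(hmm.columns):
            n_states = len(col.bparts) * col.n_alleles**2
            assert n_states == 2 ** len(m.active_rows(j)) * len(
                m.site_alleles[j]
            ) ** 2

    def test_staggered_reads_silent_states_cover_shared_reads(self, model):
        # three columns; read 0 covers 1-2, read 1 covers 2-3
        m = make_matrix(["GG-", "-GG", "GGG"])
        hmm = build_hmm(m, model)
        shared_01 = np.intersect1d(hmm.columns[0].active, hmm.columns[1].active)
        shared_12 = np.intersect1d(hmm.columns[1].active, hmm.columns[2].active)
        assert set(shared_01.tolist()) == m.active_nonterminal_rows(0)
        assert set(shared_12.tolist()) == m.active_nonterminal_rows(1)

    def test_cap_exceeded_names_pruned_alternative(self, rng, model):
        m = random_matrix(rng, 6, 3)
        with pytest.raises(CoverageCapError, match="compute_pruned_hmm"):
            build_hmm(m, model, exact_cap=3)


class TestForwardBackward:
    def test_concordant_column_concentrates_posterior(self, model):
        m = make_matrix(["A", "A"], site_alleles=[("A", "C")])
        hmm = build_hmm(m, model)
        gl = genotype_posteriors(forward_backward(hmm), hmm, 0)
        assert gl.best == (0, 0)
        assert gl.posteriors[(0, 0)] > 0.99

    def test_matches_brute_force_enumeration(self, rng, model):
        for _ in range(20):
            m = random_matrix(
                rng, int(rng.integers(1, 7)), int(rng.integers(1, 6))
            )
            total, posts = brute_force_inference(m, model)
            hmm = build_hmm(m, model)
            tables = forward_backward(hmm)
            assert np.exp(tables.log_likelihood) == pytest.approx(
                total, rel=1e-9
            )
            for j in range(m.n):
                gl = genotype_posteriors(tables, hmm, j)
                for g, p in posts[j].items():
                    assert abs(gl.posteriors.get(g, 0.0) - p) < 1e-9

    def test_alpha_beta_column_sums_constant(self, rng, model):
        m = random_matrix(rng, 6, 5)
        tables = forward_backward(build_hmm(m, model))
        for j in range(m.n):
            assert (tables.alphas[j] * tables.betas[j]).sum() == pytest.approx(
                1.0, abs=1e-9
            )

    def test_row_permutation_leaves_posteriors_unchanged(self, rng, model):
        m = random_matrix(rng, 5, 4)
        perm = rng.permutation(m.m)
        permuted = AlignmentMatrix(
            m.entries[perm],
            m.weights[perm],
            m.site_positions,
            m.site_alleles,
            [m.read_ids[i] for i in perm],
        )
        t1 = forward_backward(build_hmm(m, model))
        h2 = build_hmm(permuted, model)
        t2 = forward_backward(h2)
        assert t1.log_likelihood == pytest.approx(t2.log_likelihood, rel=1e-9)
        h1 = build_hmm(m, model)
        for j in range(m.n):
            g1 = genotype_posteriors(t1, h1, j).posteriors
            g2 = genotype_posteriors(t2, h2, j).posteriors
            for g in g1:
                assert g1[g] == pytest.approx(g2.get(g, 0.0), abs=1e-9)

    def test_uninformative_column_returns_prior(self, model):
        # near-zero weights carry no information: posterior = transition prior
        m = make_matrix(["G", "T"], site_alleles=[("G", "T")], weight=1e-9)
        hmm = build_hmm(m, model)
        gl = genotype_posteriors(forward_backward(hmm), hmm, 0)
        table = model.pair_table(("G", "T"))
        assert gl.posteriors[(0, 0)] == pytest.approx(table[0, 0], abs=1e-6)
        assert gl.posteriors[(0, 1)] == pytest.approx(
            table[0, 1] + table[1, 0], abs=1e-6
        )


class TestCallDiplotype:
    def test_discordant_middle_site_has_lower_genotype_quality(self, model):
        # three het sites; the middle column's reads disagree with the
        # haplotype structure implied by the flanking sites
        rows = [
            "GGG", "GGG", "GTG",   # haplotype 1 reads, one discordant middle
            "TTT", "TTT", "TGT",   # haplotype 2 reads, one discordant middle
        ]
        m = make_matrix(rows, site_alleles=[("G", "T")] * 3)
        res = call_diplotype(m, model)
        gq = [gl.quality for gl in res.likelihoods]
        assert gq[1] < gq[0]
        assert gq[1] < gq[2]

    def test_noiseless_simulation_recovered_exactly(self, model):
        cfg = SimulationConfig(
            n_sites=30, coverage=10, substitution_error_rate=0.0, seed=7
        )
        truth, matrix, labels = simulate(cfg)
        res = call_diplotype(matrix, model)
        assert res.diplotype.genotypes == truth.genotypes
        # phasing matches truth up to a global flip per phase set
        d = res.diplotype
        for ps in np.unique(d.phase_sets[d.het_mask]):
            sel = (d.phase_sets == ps) & d.het_mask
            same = np.array_equal(d.hap1[sel], truth.hap1[sel])
            flip = np.array_equal(d.hap1[sel], truth.hap2[sel])
            assert same or flip

    def test_reads_assigned_consistently_with_truth(self, model):
        cfg = SimulationConfig(
            n_sites=20, coverage=8, substitution_error_rate=0.0, seed=13
        )
        truth, matrix, labels = simulate(cfg)
        res = call_diplotype(matrix, model)
        # within a phase set, reads from the same true haplotype that cover
        # a het site must land on the same called haplotype
        het_cols = np.flatnonzero(res.diplotype.het_mask)
        for ps in np.unique(res.diplotype.phase_sets[het_cols]):
            by_truth: dict[int, set[int]] = {1: set(), 2: set()}
            for i, rid in enumerate(matrix.read_ids):
                cols = [
                    j
                    for j in het_cols
                    if res.diplotype.phase_sets[j] == ps
                    and matrix.first_nongap(i) <= j <= matrix.last_nongap(i)
                ]
                if cols and rid in res.assignments:
                    by_truth[labels[i]].add(res.assignments[rid])
            if by_truth[1] and by_truth[2]:
                assert len(by_truth[1]) == 1 and len(by_truth[2]) == 1
                assert by_truth[1] != by_truth[2]

    def test_genotype_posteriors_sum_to_one(self, rng, model):
        m = random_matrix(rng, 6, 4)
        res = call_diplotype(m, model)
        for gl in res.likelihoods:
            assert sum(gl.posteriors.values()) == pytest.approx(1.0, abs=1e-9)


class TestPhaseSets:
    def test_connected_sites_share_one_set(self):
        m = make_matrix(["GGG", "TTT"])
        labels = assign_phase_sets(m, [0, 1, 2])
        assert len(set(labels.values())) == 1

    def test_coverage_gap_splits_block(self):
        m = make_matrix(["GG--", "--TT"])
        labels = assign_phase_sets(m, [0, 1, 2, 3])
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert labels[1] != labels[2]

    def test_matches_union_find_on_random_instances(self, rng):
        for _ in range(10):
            m = random_matrix(rng, 6, 6)
            het = sorted(rng.choice(m.n, size=4, replace=False).tolist())
            labels = assign_phase_sets(m, het, min_span_reads=1)
            # oracle: union consecutive het sites spanned by >= 1 read
            parent = {j: j for j in het}

            def find(x):
                while parent[x] != x:
                    x = parent[x]
                return x

            for a, b in zip(het, het[1:]):
                if m.active_rows(a) & m.active_rows(b):
                    parent[find(b)] = find(a)
            for a in het:
                for b in het:
                    assert (find(a) == find(b)) == (labels[a] == labels[b])
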