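import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr
from sklearn.metrics import roc_auc_score

from petmine.errors import DegenerateInputError, EvaluationError
from petmine.io import Alignment, CANONICAL_AA
from petmine.phmm import (
    PHMMConfig,
    ProfileHMM,
    build_phmm,
    discriminate_difference_method,
    discriminate_score_method,
    forward_score,
    hmm_search,
    roc_auc,
    spearman_rho,
    viterbi_score,
)
from petmine.synthetic import SyntheticConfig, gen_homolog_family

from _oracles import oracle_bits, random_profile_hmm


class TestBuild:
    def test_identical_ungapped_rows(self):
        aln = Alignment(["a", "b", "c"], ["ACDEFGHIKL"] * 3)
        model = build_phmm(aln)
        assert model.M == 10
        idx = {a: i for i, a in enumerate(model.alphabet)}
        for k, consensus in enumerate("ACDEFGHIKL"):
            assert model.match_emis[k].argmax() == idx[consensus]

    def test_gap_heavy_column_not_a_match_state(self):
        rows = ["A-CDE", "A-CDE", "AMCDE", "A-CDE", "A-CDE"]  # col 2: 80% gaps
        model = build_phmm(Alignment(list("abcde"), rows))
        assert model.M == 4
        assert model.column_map == [0, 2, 3, 4]

    def test_all_gap_heavy_rejected(self):
        rows = ["A---", "-C--", "--D-", "---E", "----"]
        with pytest.raises(DegenerateInputError):
            build_phmm(Alignment(list("abcde"), rows),
                       PHMMConfig(match_threshold=0.1))

    @settings(max_examples=200, deadline=None)
    @given(data=st.data())
    def test_random_alignments_stay_normalized(self, data):
        n = data.draw(st.integers(2, 6))
        L = data.draw(st.integers(2, 12))
        rows = [
            "".join(data.draw(st.sampled_from(list("ACDEFG-"))) for _ in range(L))
            for _ in range(n)
        ]
        if all(set(r) == {"-"} for r in rows):
            rows[0] = "A" * L
        try:
            model = build_phmm(Alignment([f"s{i}" for i in range(n)], rows))
        except DegenerateInputError:
            return
        model.validate()  # emission/transition rows sum to 1, all positive

    def test_serialization_round_trip(self, tmp_path):
        aln = Alignment(["a", "b", "c"], ["ACD-FGHIKL", "ACDEFG-IKL", "ACDEFGHIKL"])
        model = build_phmm(aln)
        path = tmp_path / "model.json"
        model.save(path)
        back = ProfileHMM.load(path)
        seq = "ACDEFGHIKL"
        assert forward_score(back, seq) == forward_score(model, seq)


class TestScoringOracle:
    """Forward/Viterbi vs exhaustive path enumeration on toy models."""

    @pytest.mark.parametrize("M", [1, 2, 3])
    def test_forward_matches_enumeration(self, M):
        rng = np.random.default_rng(100 + M)
        model = random_profile_hmm(M, "AC", rng)
        for L in range(1, 5):
            for seq in map("".join, itertools.product("AC", repeat=L)):
                got = forward_score(model, seq)
                want = oracle_bits(model, seq, "sum")
                assert got == pytest.approx(want, rel=1e-9)

    @pytest.mark.parametrize("M", [1, 2, 4])
    def test_viterbi_matches_enumeration(self, M):
        rng = np.random.default_rng(200 + M)
        model = random_profile_hmm(M, "AC", rng)
        for L in range(1, 5):
            for seq in map("".join, itertools.product("AC", repeat=L)):
                got, _ = viterbi_score(model, seq)
                want = oracle_bits(model, seq, "max")
                assert got == pytest.approx(want, rel=1e-9)

    def test_forward_at_least_viterbi(self):
        rng = np.random.default_rng(3)
        for M in (1, 3, 5):
            model = random_profile_hmm(M, "ACDE", rng)
            for _ in range(20):
                seq = "".join(rng.choice(list("ACDE"), rng.integers(1, 12)))
                f = forward_score(model, seq)
                v, _ = viterbi_score(model, seq)
                assert f >= v - 1e-9

    def test_single_path_limit_scores_by_hand(self):
        # M=1, one-residue sequence: exactly one viable path, so forward and
        # viterbi coincide and the score is computable by hand.  With
        # eta = 1/2, uniform background over 4 letters, deterministic
        # emission and exit, P(model) = (1-eta)*1*1*(1-eta) = 1/4 and
        # P(null) = (1-eta)*eta*bg = 1/16, i.e. exactly 2 bits.
        eps = 1e-13
        alphabet = "ACDE"
        K = len(alphabet)
        emis = np.full((1, K), eps)
        emis[0, 0] = 1.0 - (K - 1) * eps
        model = ProfileHMM(
            M=1, column_map=[0], match_emis=emis,
            insert_emis=np.full((1, K), 1.0 / K),
            t_m=np.array([[0.0, eps, 0.0, 1.0 - eps]]),
            t_i=np.array([[1.0 - eps, eps, 0.0]]),
            t_d=np.array([[1.0 - eps, eps, 0.0]]),
            background=np.full(K, 1.0 / K), alphabet=alphabet,
        )
        f = forward_score(model, "A")
        v, _ = viterbi_score(model, "A")
        assert f == pytest.approx(v, abs=1e-9)
        assert f == pytest.approx(2.0, abs=1e-6)

    def test_consensus_beats_reversal(self):
        aln = Alignment(["a", "b", "c"], ["ACDEFGHIKL"] * 3)
        model = build_phmm(aln)
        assert forward_score(model, "ACDEFGHIKL") > forward_score(model, "LKIHGFEDCA")

    def test_viterbi_path_is_architecturally_valid(self):
        rng = np.random.default_rng(9)
        model = random_profile_hmm(3, "ACDE", rng)
        for _ in range(100):
            seq = "".join(rng.choice(list("ACDE"), rng.integers(1, 10)))
            _, path = viterbi_score(model, seq)
            emitted = [p for p in path if p[0] in ("N", "M", "I", "C")]
            assert len(emitted) == len(seq)
            core = [(s, k) for s, k, _ in path if s in ("M", "I", "D")]
            for (s1, k1), (s2, k2) in zip(core, core[1:]):
                if s2 == "I":
                    assert k2 == k1
                else:
                    assert k2 == k1 + 1

    def test_consensus_score_rises_as_mutation_rate_falls(self):
        for seed in range(1, 6):
            scores = []
            for rate in (0.3, 0.1, 0.02):
                cfg = SyntheticConfig(seed=seed, length=(60, 80), n_active=15,
                                      n_inactive=0, mutation_rate=rate)
                _, aln, truth = gen_homolog_family(cfg)
                model = build_phmm(aln)
                scores.append(forward_score(model, truth.ancestor))
            assert scores[0] < scores[1] < scores[2], (seed, scores)


class TestSearch:
    def test_threshold_semantics(self):
        aln = Alignment(["a", "b", "c"], ["ACDEFGHIKL"] * 3)
        model = build_phmm(aln)
        from petmine.io import SequenceRecord
        records = [SequenceRecord(id=f"s{i}", residues="ACDEFGHIKL") for i in range(3)]
        all_hits = hmm_search(model, records)
        assert [h.id for h in all_hits] == ["s0", "s1", "s2"]   # ties by id
        assert [h.rank for h in all_hits] == [1, 2, 3]
        top = max(h.score for h in all_hits)
        assert hmm_search(model, records, score_threshold=top + 1) == []

    def test_family_ranks_above_random(self):
        cfg = SyntheticConfig(seed=2, length=(60, 90), n_active=20, n_inactive=0,
                              mutation_rate=0.05)
        records, aln, _ = gen_homolog_family(cfg)
        model = build_phmm(aln)
        rng = np.random.default_rng(2)
        from petmine.io import SequenceRecord
        decoys = [
            SequenceRecord(id=f"rand{i}",
                           residues="".join(rng.choice(list(CANONICAL_AA), 75)))
            for i in range(20)
        ]
        fam_scores = [forward_score(model, r) for r in records]
        decoy_scores = [forward_score(model, r) for r in decoys]
        assert roc_auc(fam_scores, decoy_scores) == 1.0


class TestRankStats:
    @pytest.mark.parametrize("pos,neg,expected", [
        ([2, 3], [0, 1], 1.0),
        ([1, 3], [2, 4], 0.25),
        ([1, 1, 2], [1, 1, 2], 0.5),
        ([5, 5, 5], [5, 5, 5], 0.5),
    ])
    def test_auc_examples(self, pos, neg, expected):
        assert roc_auc(pos, neg) == pytest.approx(expected)

    def test_auc_cross_check_sklearn(self, rng):
        for _ in range(20):
            pos = rng.normal(0.5, 1, 15)
            neg = rng.normal(0, 1, 10)
            ours = roc_auc(pos, neg)
            ref = roc_auc_score([1] * 15 + [0] * 10, np.concatenate([pos, neg]))
            assert ours == pytest.approx(ref)

    def test_auc_invariant_under_monotone_transform(self, rng):
        pos = rng.normal(1, 1, 12)
        neg = rng.normal(0, 1, 12)
        base = roc_auc(pos, neg)
        assert roc_auc(np.exp(pos), np.exp(neg)) == pytest.approx(base)
        assert roc_auc(3 * pos + 7, 3 * neg + 7) == pytest.approx(base)

    def test_auc_empty_class_rejected(self):
        with pytest.raises(EvaluationError):
            roc_auc([], [1.0])

    @pytest.mark.parametrize("x,y,expected", [
        ([1, 2, 3, 4], [1, 2, 3, 4], 1.0),
        ([1, 2, 3, 4], [-1, -2, -3, -4], -1.0),
        ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),
    ])
    def test_spearman_examples(self, x, y, expected):
        assert spearman_rho(x, y) == pytest.approx(expected)

    def test_spearman_cross_check_scipy(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        assert spearman_rho(x, y) == pytest.approx(spearmanr(x, y).statistic)

    def test_spearman_zero_variance_warns_nan(self):
        with pytest.warns(UserWarning):
            assert np.isnan(spearman_rho([1, 1, 1], [1, 2, 3]))


class TestDiscrimination:
    def test_separable_family_high_auc(self, separable_family):
        records, aln, _ = separable_family
        actives = [r.id for r in records if r.activity_label == "active"]
        inactives = [r.id for r in records if r.activity_label == "inactive"]
        activity = {r.id: r.activity_value for r in records}
        res = discriminate_score_method(actives, inactives, aln, folds=5, seed=1,
                                        activity_values=activity)
        assert res.pooled_auc >= 0.95
        assert res.rho > 0.5
        res_d = discriminate_difference_method(actives, inactives, aln,
                                               folds=5, seed=1)
        assert res_d.pooled_auc >= res.pooled_auc - 0.05

    def test_identical_training_sets_give_zero_difference(self):
        row = "ACDEFGHIKLMNPQRSTVWY"
        ids = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        aln = Alignment(ids, [row] * 8)
        res = discriminate_difference_method(
            [f"a{i}" for i in range(4)], [f"b{i}" for i in range(4)],
            aln, folds=2, seed=0,
        )
        assert all(abs(s) < 1e-9 for s in res.scores.values())
        assert res.pooled_auc == pytest.approx(0.5)

    def test_deterministic_under_fixed_seed(self, separable_family):
        records, aln, _ = separable_family
        actives = [r.id for r in records if r.activity_label == "active"][:10]
        inactives = [r.id for r in records if r.activity_label == "inactive"][:10]
        r1 = discriminate_score_method(actives, inactives, aln, folds=5, seed=4)
        r2 = discriminate_score_method(actives, inactives, aln, folds=5, seed=4)
        assert r1.scores == r2.scores and r1.pooled_auc == r2.pooled_auc

    def test_fold_without_inactives_rejected(self):
        cfg = SyntheticConfig(seed=6, length=(60, 80), n_active=6, n_inactive=1)
        records, aln, _ = gen_homolog_family(cfg)
        actives = [r.id for r in records if r.activity_label == "active"]
        inactives = [r.id for r in records if r.activity_label == "inactive"]
        with pytest.raises(EvaluationError):
            discriminate_score_method(actives, inactives, aln, folds=3, seed=0)
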