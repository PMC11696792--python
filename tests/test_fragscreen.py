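"""Fragment delimitation, MSA filtering/pairing, score aggregation and ranking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cellmig import synthetic as syn
from cellmig.fragscreen import (
    FragmentScheme,
    MsaRow,
    ScoreSet,
    SpeciesMSA,
    aggregate_scores,
    filter_msa,
    make_fragments,
    pair_msas,
    read_a3m,
    screen,
    write_a3m,
    MockPredictor,
)


class TestMakeFragments:
    def test_fifteen_fragments_of_a_1046_residue_protein(self):
        s = make_fragments(1046, 15, 100)
        assert s.n_fragments == 15
        assert s.fragments[0] == (1, 100)
        assert s.fragments[-1] == (947, 1046)
        starts = np.array([f[0] for f in s.fragments])
        diffs = np.diff(starts)
        assert set(diffs.tolist()) <= {67, 68}
        overlaps = [e1 - s2 + 1 for (_, e1), (s2, _) in zip(s.fragments, s.fragments[1:])]
        assert set(overlaps) <= {32, 33}

    def test_single_fragment_when_length_equals_target(self):
        s = make_fragments(100, 1, 100)
        assert s.fragments == ((1, 100),)

    def test_explicit_domain_delimitations_validate(self):
        # four overlapping domains of a short 143-residue protein
        s = FragmentScheme("i3S", 143, ((1, 41), (32, 95), (86, 115), (106, 142)))
        assert s.n_fragments == 4
        assert s.covered_end == 142

    def test_gap_between_fragments_rejected(self):
        with pytest.raises(ValueError):
            FragmentScheme("p", 200, ((1, 50), (60, 120)))

    def test_cannot_cover_rejected(self):
        with pytest.raises(ValueError, match="cannot cover"):
            make_fragments(500, 4, 100)

    def test_auto_count_gives_min_overlap(self):
        s = make_fragments(1046, target_len=100, min_overlap=20)
        overlaps = [e1 - s2 + 1 for (_, e1), (s2, _) in zip(s.fragments, s.fragments[1:])]
        assert min(overlaps) >= 20
        # one fewer fragment could not keep the required overlap
        n = s.n_fragments
        step = (1046 - 100) / (n - 2)
        assert 100 - step < 20

    @settings(deadline=None, max_examples=40)
    @given(length=st.integers(100, 3000), target=st.integers(50, 150))
    def test_coverage_exact_and_lengths_on_target(self, length, target):
        if length < target:
            length = target
        n = max(2, int(np.ceil((length - target) / max(target - 20, 1))) + 1) \
            if length > target else 1
        s = make_fragments(length, n, target)
        covered = np.zeros(length + 1, dtype=bool)
        for a, b in s.fragments:
            assert (b - a + 1) == target
            covered[a: b + 1] = True
        assert covered[1:].all()
        assert s.fragments[-1][1] == length


def _msa(rows):
    return SpeciesMSA(rows=tuple(MsaRow(*r) for r in rows))


class TestFilterMsa:
    BASE = [
        ("q", "query", "ACDEFGHIKL"),
        ("h", "human", "ACDEFGHIKL"),
        ("m", "mouse", "ACDEFGHIKW"),
        ("f", "fly", "WWDEFGHIKL"),
    ]

    def test_low_identity_row_removed(self):
        rows = self.BASE + [("x", "yeast", "WWWWWWWWWW")]  # 0% identity
        out = filter_msa(_msa(rows), qid=25)
        assert "x" not in [r.row_id for r in out.rows]

    def test_exact_duplicates_collapse(self):
        rows = self.BASE + [("h2", "human2", "ACDEFGHIKL")]
        out = filter_msa(_msa(rows))
        seqs = [r.seq for r in out.rows]
        assert len(seqs) == len(set(seqs))

    def test_best_row_per_species_kept(self):
        rows = [
            ("q", "query", "ACDEFGHIKL"),
            ("m1", "mouse", "ACDEWWWWWL"),   # 50%
            ("m2", "mouse", "ACDEFGWWWL"),   # 70%
        ]
        out = filter_msa(_msa(rows), qid=25)
        kept = [r.row_id for r in out.rows]
        assert kept == ["q", "m2"]

    def test_low_coverage_row_removed(self):
        rows = self.BASE + [("g", "gap", "ACD-------")]  # 30% coverage
        out = filter_msa(_msa(rows), cov=50)
        assert "g" not in [r.row_id for r in out.rows]

    def test_query_always_kept(self):
        out = filter_msa(_msa(self.BASE), qid=99, cov=99)
        assert out.rows[0].row_id == "q"


class TestPairMsas:
    def test_enumerated_four_row_example(self):
        a = _msa([("qa", "query", "AAAA"), ("a_h", "human", "AAAC"), ("a_m", "mouse", "AACC")])
        b = _msa([("qb", "query", "GGG"), ("b_m", "mouse", "GGT"), ("b_f", "fly", "GTT")])
        out = pair_msas(a, b)
        assert len(out.rows) == 4
        assert out.width == 7
        assert out.rows[0].seq == "AAAAGGG"          # paired queries
        assert out.rows[1].seq == "AACCGGT"          # mouse paired
        assert out.rows[2].seq == "AAAC---"          # human, partner gap-padded
        assert out.rows[3].seq == "----GTT"          # fly, partner gap-padded

    def test_disjoint_species_only_queries_paired(self):
        a = _msa([("qa", "query", "AA"), ("a_h", "human", "AC")])
        b = _msa([("qb", "query", "GG"), ("b_f", "fly", "GT")])
        out = pair_msas(a, b)
        paired = [r for r in out.rows[1:] if "-" not in r.seq]
        assert paired == []
        assert out.rows[0].seq == "AAGG"

    def test_identical_species_sets_all_paired(self):
        species = ["human", "mouse", "rat"]
        a = _msa([("qa", "query", "AAA")] + [(f"a_{s}", s, "AAC") for s in species])
        b = _msa([("qb", "query", "GG")] + [(f"b_{s}", s, "GT") for s in species])
        out = pair_msas(a, b)
        assert len(out.rows) == 1 + len(species)
        assert all("-" not in r.seq for r in out.rows)

    def test_row_and_width_accounting(self):
        a = _msa([("qa", "query", "AAAA"), ("a_h", "human", "AAAC"), ("a_m", "mouse", "AACC")])
        b = _msa([("qb", "query", "GGG"), ("b_m", "mouse", "GGT"), ("b_f", "fly", "GTT")])
        out = pair_msas(a, b)
        common = a.species_set & b.species_set
        expected_rows = 1 + len(common) + len(a.species_set - common) + len(b.species_set - common)
        assert len(out.rows) == expected_rows
        assert out.width == a.width + b.width

    def test_a3m_roundtrip(self, tmp_path):
        rows = syn.gen_toy_msa(["HUMAN", "MOUSE"], width=12, seed=0)
        msa = _msa([(r[0] if i == 0 else f"sp|{r[0]}_{r[1]}", r[1], r[2])
                    for i, r in enumerate(rows)])
        write_a3m(msa, tmp_path / "m.a3m")
        back = read_a3m(tmp_path / "m.a3m")
        assert [r.seq for r in back.rows] == [r.seq for r in msa.rows]
        assert back.rows[1].species == "HUMAN"


class TestScores:
    def test_equal_scores_aggregate_trivially(self):
        s = aggregate_scores({"bait": "f1", "prey": "p1",
                              "models": [{"plddt": 70, "ptm": 0.7, "iptm": 0.7}] * 5})
        assert s.avg_iptm == pytest.approx(0.7)
        assert s.best_confidence == pytest.approx(0.7)
        assert s.plddt[0] == pytest.approx(0.7)

    def test_confidence_is_20_80_weighting(self):
        s = aggregate_scores({"bait": "f", "prey": "p",
                              "models": [{"plddt": 80, "ptm": 0.5, "iptm": 0.75}]})
        assert s.confidence[0] == pytest.approx(0.70)

    def test_average_iptm(self):
        models = [{"plddt": 50, "ptm": 0.5, "iptm": v} for v in (0.1, 0.2, 0.3, 0.4, 0.5)]
        s = aggregate_scores({"bait": "f", "prey": "p", "models": models})
        assert s.avg_iptm == pytest.approx(0.3)

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError):
            ScoreSet("f", "p", (0.5,), (1.2,), (0.5,))

    def test_model_order_permutation_invariant(self):
        rng = np.random.default_rng(0)
        models = [{"plddt": 60, "ptm": rng.uniform(), "iptm": rng.uniform()}
                  for _ in range(5)]
        s1 = aggregate_scores({"bait": "f", "prey": "p", "models": models})
        s2 = aggregate_scores({"bait": "f", "prey": "p", "models": models[::-1]})
        assert s1.avg_iptm == pytest.approx(s2.avg_iptm)
        assert s1.best_confidence == pytest.approx(s2.best_confidence)


class TestScreen:
    def _set(self, prey, conf):
        # all five models identical: best_confidence == conf, avg_iptm == conf
        return ScoreSet("bait", prey, (0.7,) * 5, (conf,) * 5, (conf,) * 5)

    def test_strictly_above_threshold_boundary(self):
        table = screen([self._set("in", 0.66), self._set("edge", 0.65),
                        self._set("out", 0.64)])
        assert list(table["prey"]) == ["in"]

    def test_all_below_threshold_gives_empty_table(self):
        table = screen([self._set("a", 0.2), self._set("b", 0.5)])
        assert len(table) == 0

    def test_ranking_matches_naive_sort_oracle(self):
        raws = syn.gen_score_tables(10, seed=4)
        sets = [aggregate_scores(r) for r in raws]
        table = screen(sets, threshold=0.0)
        oracle = sorted(sets, key=lambda s: (-s.avg_iptm, -s.best_confidence,
                                             f"{s.bait}|{s.prey}"))
        assert list(table["prey"]) == [s.prey for s in oracle]

    def test_raising_iptm_never_lowers_rank(self):
        raws = syn.gen_score_tables(6, seed=9)
        sets = [aggregate_scores(r) for r in raws]
        base = screen(sets, threshold=0.0)
        target = sets[3]
        boosted = ScoreSet(target.bait, target.prey, target.plddt, target.ptm,
                           tuple(min(1.0, v + 0.2) for v in target.iptm))
        new = screen([boosted if s is target else s for s in sets], threshold=0.0)
        old_rank = base.index[base["prey"] == target.prey][0]
        new_rank = new.index[new["prey"] == target.prey][0]
        assert new_rank <= old_rank
        assert boosted.avg_iptm >= target.avg_iptm


def test_mock_predictor_serves_fixture_scores():
    table = {("f1", "p1"): {"bait": "f1", "prey": "p1",
                            "models": [{"plddt": 80, "ptm": 0.6, "iptm": 0.8}]}}
    pred = MockPredictor(table)
    s = pred.predict("f1", "p1")
    assert s.best_confidence == pytest.approx(0.2 * 0.6 + 0.8 * 0.8)
    with pytest.raises(KeyError):
        pred.predict("f1", "p2")
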