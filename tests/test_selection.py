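"""Threshold methods, promiscuity grouping and cluster detection."""

import numpy as np
import pytest

from epitopescan.selection import (
    ThresholdSpec,
    compute_quantile_table,
    detect_clusters,
    promiscuous_binders,
    rank_records,
    select_binders,
)
from tests.conftest import make_record, random_peptide


class TestRankRecords:
    def test_simple_sort_higher_better(self):
        recs = [make_record(pos=i + 1, score=s)
                for i, s in enumerate([10, 30, 20])]
        rank_records(recs, "higher")
        assert [r.rank for r in recs] == [3, 1, 2]

    def test_ties_follow_position_order(self):
        recs = [make_record(pos=p, score=5.0) for p in (3, 1, 2)]
        rank_records(recs, "higher")
        assert {r.pos: r.rank for r in recs} == {1: 1, 2: 2, 3: 3}

    def test_against_group_sort_oracle(self, rng):
        alleles = ["HLA-DRB1*01:01", "HLA-DRB1*03:01", "HLA-DRB1*04:01"]
        recs = [
            make_record(peptide=random_peptide(rng, 15),
                        pos=int(rng.integers(1, 100)),
                        sequence_id=f"s{rng.integers(1, 4)}",
                        allele=alleles[rng.integers(3)],
                        score=float(np.round(rng.normal(), 2)))
            for _ in range(200)
        ]
        rank_records(recs, "higher")
        groups = {}
        for r in recs:
            groups.setdefault((r.sequence_id, r.allele), []).append(r)
        for grp in groups.values():
            expected = sorted(grp, key=lambda r: (-r.score, r.pos, r.peptide))
            assert [r.rank for r in expected] == list(range(1, len(grp) + 1))


class TestSelectBinders:
    def test_affinity_cutoff_keeps_boundary(self):
        recs = [make_record(pos=i + 1, score=s)
                for i, s in enumerate([100.0, 500.0, 900.0])]
        spec = ThresholdSpec("score", 500, better="lower")
        assert [r.score for r in select_binders(recs, spec)] == [100.0, 500.0]

    def test_rank_cutoff_keeps_top_two(self, rng):
        recs = [make_record(pos=i + 1, score=float(s))
                for i, s in enumerate(rng.permutation(10))]
        out = select_binders(recs, ThresholdSpec("rank", 2, better="higher"))
        assert sorted(r.score for r in out) == [8.0, 9.0]

    def test_global_requires_table(self):
        with pytest.raises(ValueError, match="quantile"):
            select_binders([make_record()], ThresholdSpec("global", 0.05))

    def test_global_missing_allele_named(self):
        recs = [make_record(allele="HLA-DRB1*01:01", score=1.0)]
        qt = compute_quantile_table(
            [make_record(allele="HLA-DRB1*03:01", score=float(i))
             for i in range(30)],
            [0.05],
        )
        with pytest.raises(KeyError, match="HLA-DRB1\\*01:01"):
            select_binders(recs, ThresholdSpec("global", 0.05), qt)

    def test_global_self_selection_fraction(self, rng):
        # selecting on the same reference the table was built from should
        # pick ~t per allele
        recs = []
        for a in ("HLA-DRB1*01:01", "HLA-DRB1*03:01"):
            offset = 0.0 if a.endswith("01:01") else 30.0
            recs += [make_record(pos=i + 1, allele=a,
                                 score=float(rng.normal(offset, 1)))
                     for i in range(500)]
        for t in (0.05, 0.1, 0.25):
            qt = compute_quantile_table(recs, [t])
            out = select_binders(recs, ThresholdSpec("global", t), qt)
            for a in ("HLA-DRB1*01:01", "HLA-DRB1*03:01"):
                frac = sum(r.allele == a for r in out) / 500
                assert abs(frac - t) <= 0.02

    def test_order_preserved(self, rng):
        recs = [make_record(pos=i + 1, score=float(rng.normal()))
                for i in range(50)]
        out = select_binders(recs, ThresholdSpec("score", 0.0, "higher"))
        assert [r.pos for r in out] == sorted(r.pos for r in out)


class TestQuantileTable:
    def test_uniform_scores_interpolated_cutoff(self):
        recs = [make_record(pos=i, score=float(i)) for i in range(1, 101)]
        qt = compute_quantile_table(recs, [0.05], better="higher")
        cut = qt.cutoff("HLA-DRB1*01:01", 0.05)
        assert 95.0 < cut < 96.0

    def test_constant_scores(self):
        recs = [make_record(pos=i + 1, score=7.5) for i in range(30)]
        qt = compute_quantile_table(recs, [0.05, 0.5])
        assert qt.cutoff("HLA-DRB1*01:01", 0.05) == 7.5
        assert qt.cutoff("HLA-DRB1*01:01", 0.5) == 7.5

    def test_per_allele_isolation(self):
        recs = [make_record(pos=i + 1, allele="HLA-DRB1*01:01",
                            score=float(i)) for i in range(1, 31)]
        recs += [make_record(pos=i + 1, allele="HLA-DRB1*03:01",
                             score=float(1000 + i)) for i in range(1, 31)]
        qt = compute_quantile_table(recs, [0.1])
        assert qt.cutoff("HLA-DRB1*01:01", 0.1) <= 30
        assert qt.cutoff("HLA-DRB1*03:01", 0.1) >= 1000

    def test_better_lower_direction(self):
        recs = [make_record(pos=i, score=float(i)) for i in range(1, 101)]
        qt = compute_quantile_table(recs, [0.05], better="lower")
        assert 5.0 < qt.cutoff("HLA-DRB1*01:01", 0.05) < 6.0

    def test_sparse_allele_warns(self):
        recs = [make_record(pos=i + 1, score=float(i)) for i in range(5)]
        with pytest.warns(UserWarning, match="5"):
            compute_quantile_table(recs, [0.5])


def brute_force_promiscuity(records, spec, min_alleles):
    """Exhaustive per-peptide counting oracle."""
    selected = select_binders(records, spec)
    table = {}
    for r in selected:
        table.setdefault((r.sequence_id, r.pos, r.peptide), set()).add(r.allele)
    return {k: v for k, v in table.items() if len(v) >= min_alleles}


class TestPromiscuity:
    def test_below_min_alleles_excluded(self):
        recs = [make_record(allele=a, score=10.0)
                for a in ("HLA-DRB1*01:01", "HLA-DRB1*03:01", "HLA-DRB1*04:01")]
        rows = promiscuous_binders(recs, ThresholdSpec("score", 1, "higher"),
                                   min_alleles=5)
        assert rows == []

    def test_min_one_lists_each_peptide_once(self, rng):
        peptides = [random_peptide(rng, 15) for _ in range(10)]
        recs = [make_record(peptide=p, pos=i + 1, allele=a, score=5.0)
                for i, p in enumerate(peptides)
                for a in ("HLA-DRB1*01:01", "HLA-DRB1*03:01")]
        rows = promiscuous_binders(recs, ThresholdSpec("score", 1, "higher"),
                                   min_alleles=1)
        assert len(rows) == 10
        assert all(r.allele_count == 2 for r in rows)

    def test_against_brute_force_oracle(self, rng):
        alleles = [f"HLA-DRB1*{i:02d}:01" for i in range(1, 9)]
        peptides = [random_peptide(rng, 15) for _ in range(50)]
        recs = [make_record(peptide=p, pos=i + 1,
                            sequence_id=f"s{1 + i % 3}", allele=a,
                            score=float(np.round(rng.normal(), 1)))
                for i, p in enumerate(peptides) for a in alleles]
        spec = ThresholdSpec("score", 0.5, "higher")
        for m in (1, 2, 3, 5):
            rows = promiscuous_binders(recs, spec, min_alleles=m)
            oracle = brute_force_promiscuity(recs, spec, m)
            assert {(r.sequence_id, r.pos, r.peptide) for r in rows} == set(
                oracle
            )
            for r in rows:
                assert set(r.alleles) == oracle[(r.sequence_id, r.pos,
                                                 r.peptide)]
                assert r.allele_count == len(r.alleles)

    def test_sorted_by_count_then_best_score(self, rng):
        recs = []
        for i, n_all in enumerate([2, 5, 3]):
            for j in range(n_all):
                recs.append(make_record(peptide=f"PEP{i}" + "A" * 11,
                                        pos=10 * i + 1,
                                        allele=f"HLA-DRB1*{j + 1:02d}:01",
                                        score=float(10 - i)))
        rows = promiscuous_binders(recs, ThresholdSpec("score", 0, "higher"),
                                   min_alleles=1)
        assert [r.allele_count for r in rows] == [5, 3, 2]

    def test_cap_per_sequence(self, rng):
        recs = [make_record(peptide=random_peptide(rng, 15), pos=i + 1,
                            score=float(i)) for i in range(30)]
        rows = promiscuous_binders(recs, ThresholdSpec("score", 0, "higher"),
                                   min_alleles=1, cap_per_sequence=7)
        assert len(rows) == 7
        # the cap keeps the best-sorted rows
        assert min(r.best_score for r in rows) == 23.0

    def test_loosening_is_superset(self, rng):
        alleles = [f"HLA-DRB1*{i:02d}:01" for i in range(1, 6)]
        recs = [make_record(peptide=random_peptide(rng, 15), pos=i + 1,
                            allele=a, score=float(rng.normal()))
                for i in range(40) for a in alleles]
        spec_tight = ThresholdSpec("score", 1.0, "higher")
        spec_loose = ThresholdSpec("score", 0.0, "higher")
        tight = {(r.pos, r.peptide) for r in
                 promiscuous_binders(recs, spec_tight, min_alleles=3)}
        loose = {(r.pos, r.peptide) for r in
                 promiscuous_binders(recs, spec_loose, min_alleles=2)}
        assert tight <= loose


class TestDetectClusters:
    def test_dense_run_merges_to_one_cluster(self):
        recs = [make_record(peptide="A" * 15, pos=p) for p in range(1, 11)]
        out = detect_clusters(recs, window=25, min_binders=3)
        assert len(out) == 1
        c = out[0]
        assert (c.start, c.end, c.n_binders) == (1, 24, 10)
        assert c.density == pytest.approx(10 / 24)

    def test_below_minimum_yields_nothing(self):
        recs = [make_record(peptide="A" * 15, pos=p) for p in (1, 5)]
        assert detect_clusters(recs, min_binders=3) == []

    def test_empty_input(self):
        assert detect_clusters([]) == []

    def test_two_separated_regions_ordered_by_density(self):
        dense = [make_record(peptide="A" * 15, pos=p) for p in range(1, 9)]
        sparse = [make_record(peptide="A" * 15, pos=p)
                  for p in range(200, 212, 4)]
        out = detect_clusters(dense + sparse, window=25, min_binders=3)
        assert len(out) == 2
        assert out[0].density > out[1].density
        assert out[0].start == 1 and out[1].start == 200

    def test_clusters_never_overlap_and_density_law(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            recs = [make_record(peptide="A" * 15, pos=int(p))
                    for p in sorted(r.integers(1, 400, 40))]
            out = detect_clusters(recs, window=25, min_binders=3)
            spans = sorted((c.start, c.end) for c in out)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 < s2
            for c in out:
                assert c.density == pytest.approx(
                    c.n_binders / (c.end - c.start + 1)
                )

    def test_multiple_sequences_rejected(self):
        recs = [make_record(pos=1, sequence_id="a"),
                make_record(pos=2, sequence_id="b")]
        with pytest.raises(ValueError, match="one sequence"):
            detect_clusters(recs)


class TestCutoffMonotonicity:
    def test_superset_under_loosening(self, rng):
        alleles = [f"HLA-DRB1*{i:02d}:01" for i in range(1, 5)]
        recs = [make_record(peptide=random_peptide(rng, 15), pos=i + 1,
                            sequence_id=f"s{1 + i % 2}", allele=a,
                            score=float(rng.normal()))
                for i in range(60) for a in alleles]
        qt = compute_quantile_table(recs, [0.02, 0.05, 0.1, 0.2, 0.3, 0.5])
        for _ in range(50):
            method = ("rank", "score", "global")[rng.integers(3)]
            if method == "rank":
                v1, v2 = sorted(rng.integers(1, 30, 2))
                s1 = ThresholdSpec("rank", int(v1), "higher")
                s2 = ThresholdSpec("rank", int(v2), "higher")
            elif method == "score":
                v1, v2 = sorted(rng.normal(0, 1, 2))
                s1 = ThresholdSpec("score", float(v2), "higher")  # stricter
                s2 = ThresholdSpec("score", float(v1), "higher")
            else:
                levels = [0.02, 0.05, 0.1, 0.2, 0.3, 0.5]
                i1, i2 = sorted(rng.integers(0, 6, 2))
                s1 = ThresholdSpec("global", levels[i1], "higher")
                s2 = ThresholdSpec("global", levels[i2], "higher")
            tight = {id(r) for r in select_binders(recs, s1, qt)}
            loose = {id(r) for r in select_binders(recs, s2, qt)}
            assert tight <= loose


def test_threshold_spec_validation():
    with pytest.raises(ValueError):
        ThresholdSpec("rank", 0)
    with pytest.raises(ValueError):
        ThresholdSpec("global", 1.5)
    with pytest.raises(ValueError):
        ThresholdSpec("bogus", 1)
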