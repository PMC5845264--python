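"""Dataset curation pipeline: filters, clustering, pair enumeration, audit."""

import itertools

import numpy as np
import pytest

from pocketbench import chem
from pocketbench import fixtures as fx
from pocketbench.curation import (
    CurationConfig,
    cluster_sequences,
    enumerate_pairs,
    filter_complexes,
    pocket_quality_filter,
    run_pipeline,
    select_representatives,
    sequence_identity,
    verify_manifest,
)
from pocketbench.structures import ResidueId


@pytest.fixture(scope="module")
def filter_fixture():
    return fx.make_filter_fixture(seed=40)


@pytest.fixture(scope="module")
def cfg():
    return CurationConfig()


class TestConfig:
    def test_defaults(self, cfg):
        assert (cfg.min_len, cfg.max_len) == (50, 999)
        assert cfg.drug_tc == 0.5
        assert cfg.seq_cluster == 0.40
        assert cfg.multi_ligand_tc == 0.5
        assert cfg.site_separation == 8.0
        assert cfg.pocket_mcc == 0.4
        assert cfg.ligand_cluster_tc == 0.7
        assert cfg.tm_max == 0.4

    def test_yaml_round_trip(self, cfg):
        assert CurationConfig.from_yaml(cfg.to_yaml()) == cfg

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            CurationConfig(tm_max=1.5)


class TestFilterComplexes:
    def test_drug_identical_ligand_kept(self, cfg):
        rec = fx.make_complex(fx.FixtureSpec(seed=1, n_residues=55))
        drug = chem.path_fingerprint(chem.perceive_molecule(rec.ligand))
        kept, log = filter_complexes([rec], [drug], cfg)
        assert kept == [rec]

    def test_long_chain_rejected_with_rule_tag(self, filter_fixture, cfg):
        records, drugs, _, tags = filter_fixture
        long_ids = [rid for rid, t in tags.items() if t == "length"]
        _, log = filter_complexes(records, drugs, cfg)
        decisions = {rid: d for rid, _, d in log}
        for rid in long_ids:
            assert decisions[rid] == "length"

    def test_planted_violations_recovered_exactly(self, filter_fixture, cfg):
        records, drugs, expected_kept, tags = filter_fixture
        kept, log = filter_complexes(records, drugs, cfg)
        assert sorted(r.record_id for r in kept) == sorted(expected_kept)
        decisions = {rid: d for rid, _, d in log}
        assert decisions == tags

    def test_every_record_logged_once(self, filter_fixture, cfg):
        records, drugs, _, _ = filter_fixture
        _, log = filter_complexes(records, drugs, cfg)
        assert sorted(rid for rid, _, _ in log) \
            == sorted(r.record_id for r in records)

    def test_empty_input_warns_not_raises(self, cfg):
        fp = chem.Fingerprint(frozenset({1}))
        assert filter_complexes([], [fp], cfg) == ([], [])


class TestClusterSequences:
    def test_identical_sequences_one_cluster(self, cfg):
        recs = [fx.make_stub_record(f"r{i}_A_LIG", "ACDEFGHIKLMNPQRSTVWY" * 3)
                for i in range(2)]
        assert len(set(cluster_sequences(recs, cfg).values())) == 1

    def test_disjoint_sequences_two_clusters(self, cfg):
        recs = [fx.make_stub_record("r1_A_LIG", "AAAAAAAAAAAAAAA"),
                fx.make_stub_record("r2_A_LIG", "WWWWWWWWWWWWWWW")]
        assert len(set(cluster_sequences(recs, cfg).values())) == 2

    def test_planted_families_recovered(self, cfg):
        seqs, labels = fx.make_sequence_families(
            3, 4, length=80, mutation_rate=0.2, seed=8)
        # confirm the planted structure with the pairwise identity oracle
        for (i, si), (j, sj) in itertools.combinations(enumerate(seqs), 2):
            ident = sequence_identity(si, sj, cfg)
            if labels[i] == labels[j]:
                assert ident >= cfg.seq_cluster
            else:
                assert ident < cfg.seq_cluster
        recs = [fx.make_stub_record(f"f{i}_A_LIG", s)
                for i, s in enumerate(seqs)]
        assignment = cluster_sequences(recs, cfg)
        clusters = [assignment[r.record_id] for r in recs]
        assert len(set(clusters)) == 3
        mapping = {}
        for c, lbl in zip(clusters, labels):
            mapping.setdefault(c, lbl)
            assert mapping[c] == lbl


class TestSelectRepresentatives:
    def test_same_ligand_same_site_collapses(self, cfg):
        rec = fx.make_complex(fx.FixtureSpec(seed=13, n_residues=55))
        reps, log = select_representatives([rec, rec], cfg)
        assert len(reps) == 1

    def test_different_ligand_far_site_both_kept(self, cfg):
        a = fx.make_complex(fx.FixtureSpec(seed=14, n_residues=55),
                            ligand_elements="C")
        b = fx.make_complex(fx.FixtureSpec(seed=15, n_residues=55),
                            ligand_elements="NO")
        # independent folds start at the origin; separate them explicitly
        for atom in b.ligand.atoms:
            atom.coords = atom.coords + np.array([100.0, 0, 0])
        reps, _ = select_representatives([a, b], cfg)
        assert len(reps) == 2

    def test_planted_keep_set(self, cfg):
        base = fx.make_complex(fx.FixtureSpec(seed=16, n_residues=55))
        import copy

        # 5 records: original + 2 site copies (drop) + 2 shifted sites (keep)
        near1, near2 = copy.deepcopy(base), copy.deepcopy(base)
        far1, far2 = copy.deepcopy(base), copy.deepcopy(base)
        for i, rec in enumerate((near1, near2, far1, far2)):
            rec.pdb_id = f"cp{i}"
        for rec, dx in ((far1, 50.0), (far2, -50.0)):
            for atom in rec.ligand.atoms:
                atom.coords = atom.coords + np.array([dx, 0, 0])
        reps, _ = select_representatives([base, near1, near2, far1, far2], cfg)
        assert {r.record_id for r in reps} \
            == {base.record_id, far1.record_id, far2.record_id}


class TestPocketQuality:
    def test_exact_prediction_kept(self, cfg, small_complex):
        pred = {small_complex.record_id: set(small_complex.binding_residues)}
        kept, log = pocket_quality_filter([small_complex], pred, cfg)
        assert kept == [small_complex]

    def test_disjoint_prediction_rejected(self, cfg, small_complex):
        truth = set(small_complex.binding_residues)
        universe = {r.rid for r in small_complex.residues}
        pred = {small_complex.record_id: set(list(universe - truth)[:10])}
        kept, log = pocket_quality_filter([small_complex], pred, cfg)
        assert kept == []

    def test_partial_overlap_matches_count_oracle(self, cfg, small_complex):
        from pocketbench.metrics import ConfusionCounts, binary_mcc

        truth = list(small_complex.binding_residues)
        universe = {r.rid for r in small_complex.residues}
        others = sorted(universe - set(truth))[:4]
        pred = set(truth[: int(0.6 * len(truth)) + 1]) | set(others)
        tp = len(pred & set(truth))
        fp = len(pred - set(truth))
        fn = len(set(truth) - pred)
        tn = len(universe) - tp - fp - fn
        mcc = binary_mcc(ConfusionCounts(tp, fp, tn, fn))
        kept, _ = pocket_quality_filter(
            [small_complex], {small_complex.record_id: pred}, cfg)
        assert bool(kept) == (mcc >= cfg.pocket_mcc)

    def test_missing_prediction_distinct_tag(self, cfg, small_complex):
        kept, log = pocket_quality_filter([small_complex], {}, cfg)
        assert kept == []
        assert log[0][2] == "no_prediction"


def _recs(n, seed0=60):
    return [fx.make_complex(fx.FixtureSpec(seed=seed0 + i, n_residues=55),
                            pdb_id=f"e{i}") for i in range(n)]


class TestEnumeratePairs:
    def test_single_cluster_all_positive(self, cfg):
        recs = _recs(3)
        ids = [r.record_id for r in recs]
        clusters = {rid: 0 for rid in ids}
        tm = {frozenset(p): 0.2 for p in itertools.combinations(ids, 2)}
        pos, neg, missing = enumerate_pairs(recs, clusters, tm, cfg)
        assert len(pos) == 3 and neg == [] and missing == 0

    def test_tm_max_excludes_similar_structures(self, cfg):
        recs = _recs(2)
        ids = [r.record_id for r in recs]
        clusters = {ids[0]: 0, ids[1]: 1}
        tm = {frozenset(ids): 0.9}
        pos, neg, _ = enumerate_pairs(recs, clusters, tm, cfg)
        assert pos == [] and neg == []

    def test_matches_brute_force_enumeration(self, cfg, rng):
        recs = _recs(7)
        ids = [r.record_id for r in recs]
        clusters = {rid: i % 3 for i, rid in enumerate(ids)}
        tm = {frozenset(p): float(rng.random())
              for p in itertools.combinations(ids, 2)}
        pos, neg, missing = enumerate_pairs(recs, clusters, tm, cfg)
        expect_pos = sorted(
            (min(a, b), max(a, b), tm[frozenset((a, b))])
            for a, b in itertools.combinations(ids, 2)
            if clusters[a] == clusters[b]
            and tm[frozenset((a, b))] < cfg.tm_max)
        assert pos == expect_pos
        rep = {}
        for rid, c in clusters.items():
            rec = next(r for r in recs if r.record_id == rid)
            cur = rep.get(c)
            if cur is None or (-len(rec.binding_residues), rid) < \
                    (-len(cur.binding_residues), cur.record_id):
                rep[c] = rec
        rep_ids = sorted(r.record_id for r in rep.values())
        expect_neg = sorted(
            (min(a, b), max(a, b), tm[frozenset((a, b))])
            for a, b in itertools.combinations(rep_ids, 2)
            if tm[frozenset((a, b))] < cfg.tm_max)
        assert neg == expect_neg
        assert missing == 0

    def test_missing_tm_counted(self, cfg):
        recs = _recs(2)
        ids = [r.record_id for r in recs]
        clusters = {rid: 0 for rid in ids}
        pos, neg, missing = enumerate_pairs(recs, clusters, {}, cfg)
        assert pos == [] and missing == 1


@pytest.fixture(scope="module")
def pipeline_output():
    # two chemistry groups -> two ligand clusters
    recs = [
        fx.make_complex(fx.FixtureSpec(seed=70 + i, n_residues=55),
                        pdb_id=f"p{i}",
                        ligand_elements="C" if i < 3 else "NO")
        for i in range(6)
    ]
    drugs = [chem.path_fingerprint(chem.perceive_molecule(r.ligand))
             for r in recs]
    ids = [r.record_id for r in recs]
    tm = {frozenset(p): 0.2 for p in itertools.combinations(ids, 2)}
    cfg = CurationConfig()
    manifest = run_pipeline(recs, drugs, tm, cfg)
    return recs, drugs, tm, cfg, manifest


class TestPipelineAndAudit:

    def test_manifest_passes_audit(self, pipeline_output):
        *_, cfg, manifest = pipeline_output
        assert verify_manifest(manifest, cfg) == []

    def test_pipeline_idempotent(self, pipeline_output):
        recs, drugs, tm, cfg, manifest = pipeline_output
        survivors = [r for r in recs if r.record_id in manifest.complexes]
        again = run_pipeline(survivors, drugs, tm, cfg)
        assert again.complexes == manifest.complexes
        assert again.positive_pairs == manifest.positive_pairs
        assert again.negative_pairs == manifest.negative_pairs

    def test_every_record_in_survivors_or_log(self, pipeline_output):
        recs, _, _, _, manifest = pipeline_output
        logged = {rid for rid, _, _ in manifest.filter_log}
        for rec in recs:
            assert rec.record_id in set(manifest.complexes) | logged

    def test_injected_high_tm_pair_flagged(self, pipeline_output):
        import copy

        *_, cfg, manifest = pipeline_output
        bad = copy.deepcopy(manifest)
        a, b = bad.complexes[0], bad.complexes[1]
        bad.positive_pairs = bad.positive_pairs + [(a, b, 0.6)]
        report = verify_manifest(bad, cfg)
        assert sum("TM-score" in v for v in report) == 1

    def test_duplicate_pair_flagged(self, pipeline_output):
        import copy

        *_, cfg, manifest = pipeline_output
        bad = copy.deepcopy(manifest)
        bad.positive_pairs = bad.positive_pairs + [bad.positive_pairs[0]]
        report = verify_manifest(bad, cfg)
        assert any("duplicate" in v for v in report)

    def test_pair_sets_disjoint_and_correctly_clustered(self, pipeline_output):
        *_, manifest = pipeline_output
        lc = manifest.ligand_clusters
        pos = {(a, b) for a, b, _ in manifest.positive_pairs}
        neg = {(a, b) for a, b, _ in manifest.negative_pairs}
        assert pos.isdisjoint(neg)
        assert all(lc[a] == lc[b] for a, b in pos)
        assert all(lc[a] != lc[b] for a, b in neg)
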