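import numpy as np
import pytest

from stagewise.config import PipelineConfig
from stagewise.diffexpr import call_de
from stagewise.enrichment import enrich_set
from stagewise.normalize import normalize_counts
from stagewise.simulate import (
    ARCHETYPES,
    SimConfig,
    simulate_counts,
    simulate_go_annotation,
    simulate_srna_libraries,
    simulate_target_pairs,
)
from stagewise.srna import build_count_matrix, collapse, target_anticorrelation_filter


def small_cfg(**kw) -> SimConfig:
    defaults = dict(n_features=300, srna_n_distinct=120, n_target_pairs=20, seed=0)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestSimulateCounts:
    def test_deterministic(self):
        cfg = small_cfg(seed=5)
        a, _ = simulate_counts(cfg)
        b, _ = simulate_counts(cfg)
        assert a == b

    def test_no_de_when_fractions_zero(self):
        cfg = small_cfg(frac_de_t1=0, frac_de_t2=0)
        _, truth = simulate_counts(cfg)
        assert truth.de_features == {"T1": {}, "T2": {}}
        assert truth.archetype_of == {}

    def test_truth_references_generated_features(self):
        counts, truth = simulate_counts(small_cfg())
        ids = set(counts.feature_ids)
        for trans in truth.de_features.values():
            assert set(trans) <= ids

    def test_frac_zero_forces_zeros(self):
        cfg = small_cfg(frac_zero=0.3)
        counts, _ = simulate_counts(cfg)
        frac = (counts.values.to_numpy() == 0).mean()
        assert frac >= 0.25

    def test_overplanting_rejected(self):
        with pytest.raises(ValueError):
            simulate_counts(small_cfg(frac_de_t1=0.7, frac_de_t2=0.7))

    def test_planted_folds_realized(self):
        cfg = SimConfig(n_features=1000, seed=3, frac_de_t2=0.1,
                        de_fold_range=(4, 4), lib_size_mean=500_000)
        counts, truth = simulate_counts(cfg)
        design = counts.design
        s2 = design.samples_of("S2")
        s3 = design.samples_of("S3")
        rel_errors = []
        for fid, (direction, fold) in truth.de_features["T2"].items():
            m2 = counts.values.loc[fid, s2].mean()
            m3 = counts.values.loc[fid, s3].mean()
            if min(m2, m3) < 10:
                continue
            observed = m3 / m2 if direction == "up" else m2 / m3
            rel_errors.append((abs(observed - fold) / fold, min(m2, m3)))
            # replicate noise at mean ~10 makes per-feature ratios wobble;
            # the strict bound applies where sampling noise is negligible
            if min(m2, m3) >= 100:
                assert observed == pytest.approx(fold, rel=0.25)
        assert len(rel_errors) > 10
        assert np.mean([e for e, _ in rel_errors]) <= 0.25

    def test_recovery_by_de_caller(self):
        # planted 4-fold T2 features with adequate expression are recovered
        sens = []
        fdp = []
        for seed in range(10):
            cfg = SimConfig(n_features=2000, seed=seed, frac_de_t2=0.1,
                            de_fold_range=(4, 4), nb_dispersion=0.05)
            counts, truth = simulate_counts(cfg)
            expr = normalize_counts(counts)
            de = {c.feature_id for c in call_de(expr, ("S2", "S3")) if c.is_de}
            planted = set(truth.de_features["T2"])
            cols = [s for s in counts.design.samples
                    if counts.design.stage_of[s] in ("S2", "S3")]
            means = counts.values[cols].mean(axis=1)
            planted_hi = {f for f in planted if means[f] >= 50}
            sens.append(len(de & planted_hi) / len(planted_hi))
            fdp.append(len(de - planted) / max(1, len(de)))
        assert np.mean(sens) >= 0.85
        assert np.mean(fdp) <= 0.10


class TestSimulateGO:
    def test_factor_one_matches_base_rate(self):
        cfg = small_cfg(n_features=2000, frac_de_t2=0.2, n_go_terms=5,
                        go_base_rate=0.1,
                        planted_enriched=[(2, "GO:0000001", 1.0)])
        _, truth = simulate_counts(cfg)
        annotation = simulate_go_annotation(truth, cfg)
        cluster = [f for f, a in truth.archetype_of.items() if a == 2]
        k = sum(1 for f in cluster if "GO:0000001" in annotation.get(f, ()))
        n = len(cluster)
        sd = np.sqrt(n * 0.1 * 0.9)
        assert abs(k - n * 0.1) <= 3 * sd

    def test_planted_enrichment_recovered(self):
        hits = 0
        for seed in range(10):
            cfg = SimConfig(n_features=2000, seed=seed, frac_de_t2=0.2,
                            n_go_terms=20, go_base_rate=0.02,
                            planted_enriched=[(2, "GO:0000001", 10.0)])
            _, truth = simulate_counts(cfg)
            annotation = simulate_go_annotation(truth, cfg)
            cluster = {f for f, a in truth.archetype_of.items() if a == 2}
            results = enrich_set(
                cluster, annotation, cfg=PipelineConfig(), runs=100_000, seed=seed
            )
            if any(r.go_term == "GO:0000001" and r.q_significant for r in results):
                hits += 1
        assert hits >= 9

    def test_null_mostly_clean(self):
        clean = 0
        for seed in range(10):
            cfg = SimConfig(n_features=1500, seed=seed, frac_de_t2=0.2,
                            n_go_terms=15, go_base_rate=0.05)
            _, truth = simulate_counts(cfg)
            annotation = simulate_go_annotation(truth, cfg)
            cluster = {f for f, a in truth.archetype_of.items() if a == 2}
            results = enrich_set(
                cluster, annotation, cfg=PipelineConfig(), runs=20_000, seed=seed
            )
            if not any(r.q_significant for r in results):
                clean += 1
        assert clean >= 9

    def test_bad_factor_rejected(self):
        cfg = small_cfg(planted_enriched=[(0, "GO:0000001", -1.0)])
        _, truth = simulate_counts(cfg)
        with pytest.raises(ValueError):
            simulate_go_annotation(truth, cfg)


class TestSimulateSRNA:
    def test_length_mode_follows_weights(self):
        cfg = small_cfg(srna_n_distinct=400)
        reads, _, _ = simulate_srna_libraries(cfg)
        lengths = [len(s) for lib in reads.values() for s in lib]
        values, counts = np.unique(lengths, return_counts=True)
        assert values[counts.argmax()] == 24

    def test_planted_mirnas_are_substrings_of_reference(self):
        cfg = small_cfg()
        _, truth, mature = simulate_srna_libraries(cfg)
        assert len(truth.mirna_srnas) == cfg.n_planted_mirnas
        mature_seqs = {mseq for _, mseq in mature}
        for seq in truth.mirna_srnas:
            assert any(seq in m for m in mature_seqs)

    def test_distinct_bound(self):
        cfg = small_cfg()
        reads, _, _ = simulate_srna_libraries(cfg)
        distinct = {s for lib in reads.values() for s in lib}
        assert len(distinct) <= cfg.srna_n_distinct

    def test_deterministic(self):
        a = simulate_srna_libraries(small_cfg(seed=9))[0]
        b = simulate_srna_libraries(small_cfg(seed=9))[0]
        assert a == b

    def test_weights_outside_window_rejected(self):
        cfg = small_cfg(srna_len_weights={14: 1.0, 24: 1.0})
        with pytest.raises(ValueError):
            simulate_srna_libraries(cfg)


class TestSimulateTargetPairs:
    def _matrices(self, cfg):
        counts, truth = simulate_counts(cfg)
        reads, truth, _ = simulate_srna_libraries(cfg, truth)
        libs = [collapse(r, library_id=s) for s, r in reads.items()]
        srna_expr = normalize_counts(build_count_matrix(libs, counts.design))
        tx_expr = normalize_counts(counts)
        return srna_expr, tx_expr, truth

    def test_planted_pairs_pass_filter(self):
        cfg = small_cfg(n_features=400, frac_de_t2=0.3, srna_n_distinct=300)
        srna_expr, tx_expr, truth = self._matrices(cfg)
        pairs, truth = simulate_target_pairs(cfg, srna_expr, tx_expr, truth)
        results = target_anticorrelation_filter(
            pairs, srna_expr, tx_expr, PipelineConfig()
        )
        retained = {(r.srna_seq, r.transcript_id) for r in results if r.retained}
        planted = set(truth.anticorrelated_pairs)
        assert planted
        assert planted <= retained  # sensitivity 1.0 by construction

    def test_deterministic(self):
        cfg = small_cfg(n_features=400, frac_de_t2=0.3, srna_n_distinct=300)
        srna_expr, tx_expr, truth = self._matrices(cfg)
        a, _ = simulate_target_pairs(cfg, srna_expr, tx_expr)
        b, _ = simulate_target_pairs(cfg, srna_expr, tx_expr)
        assert a == b

    def test_too_many_pairs_rejected(self):
        cfg = small_cfg(n_features=400, frac_de_t2=0.3, srna_n_distinct=300)
        srna_expr, tx_expr, truth = self._matrices(cfg)
        sub = srna_expr.subset(srna_expr.feature_ids[:2])
        txsub = tx_expr.subset(tx_expr.feature_ids[:2])
        bad = small_cfg(n_target_pairs=100)
        with pytest.raises(ValueError):
            simulate_target_pairs(bad, sub, txsub)

    def test_null_retention_near_monte_carlo_rate(self):
        # with no planted pairs, retention matches the null rate of
        # r <= -0.9 among random 3-point profiles
        rng = np.random.default_rng(0)
        null_hits = 0
        trials = 20_000
        for _ in range(trials):
            x = rng.normal(size=3)
            y = rng.normal(size=3)
            r = np.corrcoef(x, y)[0, 1]
            if r <= -0.9:
                null_hits += 1
        null_rate = null_hits / trials

        cfg = small_cfg(
            n_features=400, frac_de_t2=0.0, frac_de_t1=0.0,
            srna_frac_trend=0.0, srna_n_distinct=300,
            frac_anticorrelated_pairs=0.0, n_target_pairs=400, seed=4,
        )
        srna_expr, tx_expr, truth = self._matrices(cfg)
        pairs, _ = simulate_target_pairs(cfg, srna_expr, tx_expr)
        results = target_anticorrelation_filter(
            pairs, srna_expr, tx_expr, PipelineConfig()
        )
        observed = sum(r.retained for r in results) / len(results)
        se = np.sqrt(null_rate * (1 - null_rate) / len(results))
        assert observed <= null_rate + 3 * se + 0.02
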