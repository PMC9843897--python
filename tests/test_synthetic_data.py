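import numpy as np
import pytest
from scipy import stats

from convexpr.errors import ValidationError
from convexpr.io_formats import write_hit_table
from convexpr.methylation import promoter_methylation, promoter_regions
from convexpr.orthology import select_longest_isoform
from convexpr.synthetic_data import (
    MethylationConfig,
    SimConfig,
    simulate_counts,
    simulate_hit_tables,
    simulate_methylation,
)


def small_config(**kw):
    defaults = dict(
        n_species=4,
        n_genes=200,
        n_convergent_up=5,
        n_convergent_down=5,
        seed=77,
        samples_per_species=3,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestSimulateCounts:
    def test_shapes_and_labels(self):
        cfg = small_config()
        mats, genes, truth = simulate_counts(cfg)
        assert len(mats) == 4
        assert mats[0].shape == (200, 3)
        assert all(len(genes[sp]) == 200 for sp in cfg.species_ids)
        assert len(truth.convergent_up_ids) == 5
        assert truth.orthology.shape == (200, 4)

    def test_same_seed_identical(self):
        a = simulate_counts(small_config())
        b = simulate_counts(small_config())
        for ma, mb in zip(a[0], b[0]):
            np.testing.assert_array_equal(ma.counts, mb.counts)
        assert a[2].convergent_up_ids == b[2].convergent_up_ids

    def test_different_seed_differs(self):
        a = simulate_counts(small_config(seed=1))
        b = simulate_counts(small_config(seed=2))
        assert (a[0][0].counts != b[0][0].counts).any()

    def test_planted_effect_visible_in_means(self):
        cfg = small_config(
            n_genes=400, effect_log2fc=2.0, samples_per_species=4,
            species_effect_sd=0.0, dispersion=0.05, seed=5,
        )
        mats, genes, truth = simulate_counts(cfg)
        by_sp = {m.species: m for m in mats}
        lens = {sp: {r.gene_id: r.length for r in genes[sp]} for sp in cfg.species_ids}
        for gid in sorted(truth.convergent_up_ids)[:3]:
            idx = int(gid.split("_g")[1])
            # compare focal sp1 vs background sp3 on a per-length, per-library basis
            def rel(sp):
                m = by_sp[sp]
                col = m.counts[idx].astype(float)
                libs = m.counts.sum(axis=0)
                gl = lens[sp][f"{sp}_g{idx:05d}"]
                return (col / libs / gl).mean()

            ratio = rel("sp1") / rel("sp3")
            assert 4.0 * 0.8 / 1.2 < ratio < 4.0 * 1.2 / 0.8 * 1.5

    def test_null_config_gives_uniform_pvalues(self, rng):
        cfg = small_config(
            n_genes=2000, n_convergent_up=0, n_convergent_down=0,
            effect_log2fc=0.0, species_effect_sd=0.0, dispersion=0.0,
            samples_per_species=4, seed=13, gene_length_range=(1000, 1000),
        )
        mats, genes, _ = simulate_counts(cfg)
        from convexpr.diffexp import exact_test_nb

        a, b = mats[0], mats[2]
        # length-correct per species as the pipeline does before testing
        len_a = np.array([r.length for r in genes[a.species]])[:, None]
        len_b = np.array([r.length for r in genes[b.species]])[:, None]
        rpk_a = a.counts / (len_a / 1000.0)
        rpk_b = b.counts / (len_b / 1000.0)
        de = exact_test_nb(
            rpk_a, rpk_b, 0.0, rpk_a.sum(axis=0), rpk_b.sum(axis=0)
        )
        ks = stats.kstest(de["p_value"], "uniform").statistic
        assert ks < 0.05

    def test_truth_sets_disjoint(self):
        _, _, truth = simulate_counts(small_config())
        assert truth.convergent_up_ids.isdisjoint(truth.convergent_down_ids)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            SimConfig(n_genes=5, n_convergent_up=4, n_convergent_down=4)
        with pytest.raises(ValidationError):
            SimConfig(n_focal=1)


class TestSimulateHitTables:
    def test_rbh_recovers_truth_without_decoys(self):
        from itertools import combinations

        from convexpr.orthology import one_to_one_orthologues, reciprocal_best_hits

        cfg = small_config()
        _, _, truth = simulate_counts(cfg)
        hits = simulate_hit_tables(truth, cfg, decoy_fraction=0.0)
        rbh = {
            (a, b): reciprocal_best_hits(hits[(a, b)], hits[(b, a)])
            for a, b in combinations(cfg.species_ids, 2)
        }
        omap = one_to_one_orthologues(rbh, cfg.species_ids)
        assert set(omap.rows) == {tuple(r) for r in truth.orthology.itertuples(index=False)}

    def test_rbh_recovers_truth_with_decoys(self):
        from itertools import combinations

        from convexpr.orthology import one_to_one_orthologues, reciprocal_best_hits

        cfg = small_config()
        _, _, truth = simulate_counts(cfg)
        hits = simulate_hit_tables(truth, cfg, decoy_fraction=1.0)
        rbh = {
            (a, b): reciprocal_best_hits(hits[(a, b)], hits[(b, a)])
            for a, b in combinations(cfg.species_ids, 2)
        }
        omap = one_to_one_orthologues(rbh, cfg.species_ids)
        assert set(omap.rows) == {tuple(r) for r in truth.orthology.itertuples(index=False)}

    def test_weak_decoys_filtered_at_read_time(self, tmp_path):
        from convexpr.io_formats import read_hit_table

        cfg = small_config()
        _, _, truth = simulate_counts(cfg)
        hits = simulate_hit_tables(truth, cfg, decoy_fraction=1.0)
        path = tmp_path / "hits.tsv"
        write_hit_table(hits[("sp1", "sp2")], path)
        kept = read_hit_table(path, evalue_cutoff=1e-5)
        assert all(r.evalue <= 1e-5 for r in kept)
        assert len(kept) < len(hits[("sp1", "sp2")])  # some decoys dropped
        assert len(kept) >= cfg.n_genes  # every true hit survives


class TestSimulateMethylation:
    def _promoters(self, cfg):
        _, genes, _ = simulate_counts(cfg)
        recs = genes[cfg.species_ids[0]]
        iso = select_longest_isoform(recs)
        reps = [r for r in recs if iso[r.gene_id] == r.isoform_id]
        return promoter_regions(reps)

    def test_estimated_level_near_truth(self):
        cfg = small_config(
            methylation=MethylationConfig(
                n_promoters=20, cpgs_per_promoter=10, depth_mean=30.0,
                level_high=0.9, n_differential=20,
            )
        )
        promoters = self._promoters(cfg)
        reports, truth = simulate_methylation(cfg, promoters)
        sample = sorted(reports)[0]
        reported, _ = promoter_methylation(reports[sample], promoters[:20])
        merged = reported.merge(truth, on="gene_id")
        high = merged[merged["differential"]]
        assert len(high) == 20
        assert (abs(high["level"] - 0.9) < 0.05).all()

    def test_low_depth_mostly_unreported(self):
        cfg = small_config(
            methylation=MethylationConfig(n_promoters=30, depth_mean=3.0)
        )
        promoters = self._promoters(cfg)
        reports, _ = simulate_methylation(cfg, promoters)
        sample = sorted(reports)[0]
        reported, excluded = promoter_methylation(reports[sample], promoters[:30])
        assert len(excluded) > len(reported)

    def test_null_differential_calibrated(self):
        from convexpr.methylation import differential_methylation

        cfg = small_config(
            seed=31,
            methylation=MethylationConfig(
                n_promoters=300, n_differential=0, depth_mean=30.0,
                level_low=0.3, samples_per_group=4,
            ),
        )
        promoters = self._promoters(cfg)
        # 300 promoters needs only 200 genes; recycle the list
        proms = (promoters * 2)[:300]
        seen = set()
        proms = [p for p in promoters if not (p.gene_id in seen or seen.add(p.gene_id))]
        reports, _ = simulate_methylation(cfg, proms)
        import pandas as pd

        frames = {"a": [], "b": []}
        for sample_id, recs in reports.items():
            grp = "a" if sample_id.startswith("methA") else "b"
            reported, _ = promoter_methylation(recs, proms)
            reported["sample_id"] = sample_id
            frames[grp].append(reported)
        res, _ = differential_methylation(
            pd.concat(frames["a"]), pd.concat(frames["b"])
        )
        frac = (res["p_value"] < 0.05).mean()
        assert 0.01 <= frac <= 0.1

    def test_determinism(self):
        cfg = small_config()
        promoters = self._promoters(cfg)
        r1, t1 = simulate_methylation(cfg, promoters)
        r2, t2 = simulate_methylation(cfg, promoters)
        assert r1 == r2
        assert t1.equals(t2)
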