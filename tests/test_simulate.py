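"""Generator contracts: determinism, planted-truth consistency, monotone effects."""

import numpy as np
import pytest

from paleoreg.core import GenomicInterval, overlaps
from paleoreg import io as pio
from paleoreg.enrichment.motifs import make_example_pwm, scan_pwm
from paleoreg.simulate import (
    DEFAULT_GENOME,
    CapacityError,
    GenomeSpec,
    simulate_counts,
    simulate_feature_sets,
    simulate_peaks,
    simulate_regions,
    simulate_sequences_with_motif,
    simulate_sncs,
)


class TestRegions:
    def test_empty_request_yields_empty_valid_outputs(self, tmp_path):
        regions, linkage = simulate_regions(n_enh=0, n_prom=0, rng_seed=0)
        assert regions == [] and linkage.empty
        pio.write_linkage_tsv(linkage, tmp_path / "l.tsv")
        assert pio.read_linkage_tsv(tmp_path / "l.tsv").empty

    def test_regions_pairwise_disjoint_with_min_gap(self):
        genome = GenomeSpec((("1", 5_000_000),))
        regions, _ = simulate_regions(genome, n_enh=100, n_prom=0, min_gap=100, rng_seed=1)
        assert len(regions) == 100
        ivs = sorted((r.interval.start, r.interval.end) for r in regions)
        gaps = [b[0] - a[1] for a, b in zip(ivs, ivs[1:])]
        assert min(gaps) >= 100

    def test_same_seed_byte_identical_files(self, tmp_path):
        paths = []
        for name in ("a", "b"):
            regions, linkage = simulate_regions(rng_seed=42)
            sncs, _ = simulate_sncs(regions, rng_seed=43)
            d = tmp_path / name
            d.mkdir()
            pio.write_bed(pio.regions_to_bed(regions), d / "r.bed")
            pio.write_linkage_tsv(linkage, d / "l.tsv")
            pio.write_snc_tsv(sncs, d / "s.tsv")
            paths.append(d)
        for f in ("r.bed", "l.tsv", "s.tsv"):
            assert (paths[0] / f).read_bytes() == (paths[1] / f).read_bytes()

    def test_capacity_error_on_overfull_genome(self):
        with pytest.raises(CapacityError):
            simulate_regions(GenomeSpec((("1", 10_000),)), n_enh=50, n_prom=0, rng_seed=0)

    def test_every_region_linked_to_one_to_three_genes(self, small_dataset):
        regions, linkage, _, _ = small_dataset
        per_region = linkage.groupby("region_id").size()
        assert per_region.between(1, 3).all()
        assert set(per_region.index) == {r.region_id for r in regions}


class TestSncs:
    def test_extreme_status_probabilities(self, small_dataset):
        regions = small_dataset[0]
        _, man_all = simulate_sncs(regions, p_modern_only=1.0, p_archaic=0.0, rng_seed=0)
        assert man_all.candidate_region_ids == {r.region_id for r in regions}
        _, man_none = simulate_sncs(regions, p_modern_only=0.0, rng_seed=0)
        assert man_none.candidate_region_ids == set()

    def test_manifest_matches_recount_from_emitted_records(self, small_dataset):
        """Brute-force recount oracle over the emitted SNC records."""
        regions, _, sncs, manifest = small_dataset
        recounted = set()
        for r in regions:
            n_modern = n_archaic = 0
            for s in sncs:
                if s.chrom == r.interval.chrom and r.interval.start <= s.pos - 1 < r.interval.end:
                    if s.lineage == "modern":
                        n_modern += 1
                    else:
                        n_archaic += 1
            if n_modern >= 1 and n_archaic == 0:
                recounted.add(r.region_id)
        assert recounted == manifest.candidate_region_ids

    def test_frequencies_fixed_or_above_ninety_percent(self, small_dataset):
        sncs = small_dataset[2]
        freqs = np.array([s.frequency for s in sncs if s.lineage == "modern"])
        assert ((freqs == 1.0) | ((freqs >= 0.90) & (freqs < 1.0))).all()

    def test_manifest_json_round_trip(self, small_dataset, tmp_path):
        from paleoreg.simulate import TruthManifest

        manifest = small_dataset[3]
        manifest.to_json(tmp_path / "m.json")
        back = TruthManifest.from_json(tmp_path / "m.json")
        assert back.candidate_region_ids == manifest.candidate_region_ids
        assert back.both_genes == manifest.both_genes


class TestFeatureSets:
    def test_rho_one_forces_overlap_for_every_feature(self, small_dataset):
        regions, _, _, manifest = small_dataset
        cand = [r for r in regions if r.region_id in manifest.candidate_region_ids]
        feats = simulate_feature_sets(DEFAULT_GENOME, cand, rho=1.0, n_features=50, rng_seed=3)
        assert len(feats) == 50
        for f in feats:
            assert any(overlaps(f, c.interval) for c in cand)

    def test_rho_half_forces_at_least_half(self, small_dataset):
        regions, _, _, manifest = small_dataset
        cand = [r for r in regions if r.region_id in manifest.candidate_region_ids]
        feats = simulate_feature_sets(DEFAULT_GENOME, cand, rho=0.5, n_features=100, rng_seed=4)
        n_olap = sum(any(overlaps(f, c.interval) for c in cand) for f in feats)
        assert n_olap >= 50

    def test_overlap_statistic_monotone_in_rho(self, small_dataset):
        """Planted effect grows with rho (averaged over a small seed grid)."""
        regions, _, _, manifest = small_dataset
        cand = [r for r in regions if r.region_id in manifest.candidate_region_ids]

        def mean_observed(rho):
            obs = []
            for seed in range(5):
                feats = simulate_feature_sets(
                    DEFAULT_GENOME, cand, rho=rho, n_features=50, rng_seed=seed
                )
                obs.append(
                    sum(any(overlaps(c.interval, f) for f in feats) for c in cand)
                )
            return np.mean(obs)

        stats = [mean_observed(r) for r in (0.0, 0.5, 1.0)]
        assert stats[0] < stats[1] < stats[2]


class TestPeaks:
    def test_truth_ids_subset_of_enhancers(self, small_dataset):
        regions = [r for r in small_dataset[0] if r.region_class == "enhancer"]
        k27, me3, passing = simulate_peaks(regions, rng_seed=5)
        assert passing <= {r.region_id for r in regions}
        assert 0 < len(passing) < len(regions)
        assert k27 and me3


class TestSequences:
    def test_planted_fraction_zero_and_exact_count(self):
        pwm = make_example_pwm()
        ids = [(f"r{i}", 120) for i in range(40)]
        _, planted0 = simulate_sequences_with_motif(ids, pwm, 0.0, rng_seed=0)
        assert planted0 == set()
        _, planted = simulate_sequences_with_motif(ids, pwm, 0.3, rng_seed=0)
        assert len(planted) == round(0.3 * 40)

    def test_fraction_one_length_equals_motif_gives_pure_draws(self):
        pwm = make_example_pwm()
        ids = [(f"r{i}", pwm.length) for i in range(20)]
        seqs, planted = simulate_sequences_with_motif(ids, pwm, 1.0, rng_seed=1)
        assert planted == set(seqs)
        # every sequence is a motif draw (possibly reverse-complemented):
        # a permissive scan must find a full-length hit in each
        for s in seqs.values():
            assert len(s) == pwm.length
            assert scan_pwm(s, pwm, threshold=-1e9)

    def test_region_shorter_than_motif_rejected(self):
        pwm = make_example_pwm()
        with pytest.raises(ValueError):
            simulate_sequences_with_motif([("r0", pwm.length - 1)], pwm, 0.0, rng_seed=0)


class TestCounts:
    def test_same_seed_identical_matrix(self):
        a1, _ = simulate_counts(rng_seed=3)
        a2, _ = simulate_counts(rng_seed=3)
        assert np.array_equal(np.asarray(a1.X), np.asarray(a2.X))

    def test_column_sums_track_library_sizes_without_overdispersion(self):
        adata, _ = simulate_counts(
            n_cells=60, n_genes=300, n_modules=0, n_clusters=1,
            nb_dispersion=0.0, phase_effect=0.0, cluster_effect=0.0, rng_seed=4,
        )
        totals = np.asarray(adata.X).sum(axis=1)
        # Poisson totals around the drawn library sizes: relative spread small
        assert 2000 < np.median(totals) < 10000

    def test_no_modules_means_no_excess_correlation(self):
        from paleoreg.coexpression import bicor_matrix, log_normalize

        adata, _ = simulate_counts(
            n_cells=80, n_genes=150, n_modules=0, n_clusters=1,
            cluster_effect=0.0, phase_effect=0.0, rng_seed=5,
        )
        X = np.asarray(adata.X).T.astype(float)
        keep = (X > 0).mean(axis=1) > 0.2
        norm = log_normalize(X[keep])
        c = bicor_matrix(norm)
        off = c[np.triu_indices_from(c, k=1)]
        # independent genes: correlations are sampling noise around 0
        assert abs(np.mean(off)) < 0.05
        assert np.quantile(np.abs(off), 0.99) < 0.45

    def test_manifest_module_sizes(self, counts_dataset):
        adata, manifest = counts_dataset
        labels = list(manifest.module_assignment.values())
        assert len(labels) == 4 * 250
        assert {labels.count(f"M{i}") for i in range(1, 5)} == {250}
        assert set(manifest.module_assignment) <= set(adata.var_names)

    def test_module_capacity_validated(self):
        with pytest.raises(ValueError):
            simulate_counts(n_genes=100, n_modules=4, module_size=100)
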