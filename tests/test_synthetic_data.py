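import numpy as np
import pytest

from viropop.microdiversity import filter_snvs
from viropop.synthetic_data import (
    SimulationConfig,
    simulate_abundance_matrix,
    simulate_contig_population,
    simulate_coverage,
    simulate_presence_tracks,
    simulate_snvs,
)


def hamming_identity(seq_a: str, seq_b: str) -> float:
    """Oracle: identity over the shared prefix by direct position count."""
    span = min(len(seq_a), len(seq_b))
    mismatches = sum(a != b for a, b in zip(seq_a[:span], seq_b[:span]))
    return 1 - mismatches / span


class TestContigPopulations:
    def test_determinism(self):
        config = SimulationConfig(seed=5, n_populations=3, n_decoys=1)
        a = simulate_contig_population(config)
        b = simulate_contig_population(config)
        assert [c.sequence for c in a[0]] == [c.sequence for c in b[0]]
        assert a[1].equals(b[1])
        assert a[2] == b[2]

    def test_singleton_population(self):
        config = SimulationConfig(seed=1, n_populations=1, contigs_per_population=1)
        contigs, truth, alignments = simulate_contig_population(config)
        assert len(contigs) == 1
        assert truth.iloc[0]["is_representative"]
        assert alignments == []

    def test_pairwise_ani_at_least_095(self):
        config = SimulationConfig(seed=2, n_populations=1, contigs_per_population=3)
        contigs, _, alignments = simulate_contig_population(config)
        seqs = {c.contig_id: c.sequence for c in contigs}
        assert len(alignments) == 3
        for rec in alignments:
            # emitted ANI is exact: matches the direct mutated-position count
            oracle = hamming_identity(seqs[rec.query_id], seqs[rec.target_id])
            assert rec.pct_identity == pytest.approx(oracle, abs=1e-12)
            assert rec.pct_identity >= 0.95

    def test_member_rep_identity_near_configured(self):
        config = SimulationConfig(seed=3, n_populations=2, contigs_per_population=3,
                                  within_pop_identity=0.97)
        contigs, truth, alignments = simulate_contig_population(config)
        reps = set(truth.loc[truth["is_representative"], "contig_id"])
        for rec in alignments:
            if rec.target_id in reps and not rec.query_id.endswith("C00"):
                assert rec.pct_identity == pytest.approx(0.97, abs=0.005)

    def test_no_cross_population_alignments(self):
        config = SimulationConfig(seed=4, n_populations=3, contigs_per_population=2)
        _, truth, alignments = simulate_contig_population(config)
        pop_of = dict(zip(truth["contig_id"], truth["population_id"]))
        assert all(pop_of[r.query_id] == pop_of[r.target_id] for r in alignments)

    def test_decoys_below_cluster_threshold(self):
        config = SimulationConfig(seed=6, n_populations=2, n_decoys=2, decoy_identity=0.90)
        _, truth, alignments = simulate_contig_population(config)
        decoy_ids = set(truth.loc[truth["population_id"].str.startswith("D"), "contig_id"])
        decoy_alns = [r for r in alignments if r.query_id in decoy_ids or r.target_id in decoy_ids]
        assert decoy_alns
        for rec in decoy_alns:
            assert rec.pct_identity == pytest.approx(0.90, abs=0.01)
            assert rec.pct_identity < 0.95

    def test_identity_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(within_pop_identity=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(within_pop_identity=1.2)


class TestCoverage:
    def test_null_case_no_dips(self):
        config = SimulationConfig(seed=1, hvr_spec=())
        tracks, truth = simulate_coverage(config, lengths={"c1": 5000})
        (track,) = tracks
        assert truth.empty
        median = np.median(track.depth)
        assert median >= 20  # within the configured mean range, no collapse
        assert (track.depth > 0.2 * median).mean() > 0.99

    def test_engineered_dip_recorded_as_truth(self):
        config = SimulationConfig(seed=2, hvr_spec=(("c1", 2000, 2700, 0.0),))
        tracks, truth = simulate_coverage(config, lengths={"c1": 10_000})
        (track,) = tracks
        row = truth.iloc[0]
        assert row["is_true_hvr"]
        region = track.depth[2000:2700]
        assert (region == 0).any()
        assert region.max() < 0.2 * np.median(track.depth)

    def test_short_dip_marked_decoy(self):
        config = SimulationConfig(seed=3, hvr_spec=(("c1", 2000, 2500, 0.0),))
        _, truth = simulate_coverage(config, lengths={"c1": 10_000})
        assert not truth.iloc[0]["is_true_hvr"]

    def test_nonzero_floor_dip_has_no_zeros(self):
        config = SimulationConfig(seed=4, hvr_spec=(("c1", 2000, 2700, 4.0),))
        tracks, truth = simulate_coverage(config, lengths={"c1": 10_000})
        assert not truth.iloc[0]["is_true_hvr"]
        assert (tracks[0].depth[2000:2700] >= 1).all()

    def test_overlapping_dips_rejected(self):
        config = SimulationConfig(
            seed=5, hvr_spec=(("c1", 2000, 2700, 0.0), ("c1", 2500, 3300, 0.0))
        )
        with pytest.raises(ValueError, match="overlap"):
            simulate_coverage(config, lengths={"c1": 10_000})

    def test_out_of_bounds_dip_rejected(self):
        config = SimulationConfig(seed=6, hvr_spec=(("c1", 500, 1200, 0.0),))
        with pytest.raises(ValueError):
            simulate_coverage(config, lengths={"c1": 1000})


class TestSnvs:
    def test_monomorphic_at_f_zero(self):
        config = SimulationConfig(seed=1, snv_spec=(("c1", 50, 0.0),))
        records, truth = simulate_snvs(config, lengths={"c1": 10_000})
        assert all(len(r.allele_counts) == 1 for r in records)
        assert (truth["truth_pi_site"] == 0).all()

    def test_truth_closed_form(self):
        config = SimulationConfig(seed=2, snv_spec=(("c1", 10, 0.5),))
        _, truth = simulate_snvs(config, lengths={"c1": 10_000})
        assert truth["truth_pi_site"].iloc[0] == pytest.approx(2 * 0.25 * 10 / 9)

    def test_depth_is_configured(self):
        config = SimulationConfig(seed=3, snv_spec=(("c1", 20, 0.3),), snv_depth=80)
        records, _ = simulate_snvs(config, lengths={"c1": 10_000})
        assert all(r.depth == 80 for r in records)

    def test_rare_alleles_fail_frequency_filter(self):
        config = SimulationConfig(seed=4, snv_spec=(("c1", 200, 0.005),), snv_depth=100)
        records, _ = simulate_snvs(config, lengths={"c1": 10_000})
        kept = filter_snvs(records)
        # at f=0.005 and 100X, >1% AND >=4 reads is (almost) never met
        assert len(kept) <= 2

    def test_invalid_frequency(self):
        config = SimulationConfig(seed=5, snv_spec=(("c1", 10, 1.0),))
        with pytest.raises(ValueError):
            simulate_snvs(config, lengths={"c1": 1000})

    def test_invalid_depth(self):
        with pytest.raises(ValueError):
            SimulationConfig(snv_depth=0)


class TestAbundance:
    def test_null_effect_exchangeable(self):
        config = SimulationConfig(seed=1, effect_size=0.0)
        matrix, truth = simulate_abundance_matrix(config)
        assert truth["multiplier"].iloc[0] == 1.0

    def test_effect_taxa_shifted(self):
        config = SimulationConfig(seed=2, effect_size=2.0, n_effect_taxa=3)
        matrix, truth = simulate_abundance_matrix(config)
        groups = matrix.sample_meta["group"]
        g2 = groups[groups == config.group_labels[1]].index
        g1 = groups[groups == config.group_labels[0]].index
        for taxon in truth["taxon_id"]:
            assert matrix.values.loc[taxon, g2].mean() > matrix.values.loc[taxon, g1].mean()

    def test_single_sample_per_group_rejected(self):
        config = SimulationConfig(seed=3, n_samples=2)
        with pytest.raises(ValueError):
            simulate_abundance_matrix(config)

    def test_negative_effect_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(effect_size=-1.0)


class TestPresenceTracks:
    def test_breadth_structure(self):
        from viropop.abundance import breadth

        config = SimulationConfig(seed=7)
        tracks, truth = simulate_presence_tracks(config, n_present=3, n_decoy=2)
        present = set(truth.loc[truth["present"], "population_id"])
        for (pop, _sample), track in tracks.items():
            if pop in present:
                assert breadth(track) == 1.0
            else:
                assert breadth(track) == pytest.approx(0.5, abs=0.01)
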