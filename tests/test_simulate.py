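"""The synthetic-data generators: determinism, calibration and truth files."""

import numpy as np
import pytest

from paleofoam import fixtures
from paleofoam.consensus import identify_duplicate_sets
from paleofoam.cophylogeny import (
    codivergence_test,
    extract_branch_pairs,
    map_congruent_branches,
    parse_newick,
)
from paleofoam.dating import RatePrior
from paleofoam.distances import k2p_from_pair
from paleofoam.records import SequenceRecord
from paleofoam.simulate import (
    SimulationConfig,
    evolve_sequence,
    k2p_change_probs,
    make_provirus,
    random_sequence,
    simulate_codivergence,
    simulate_endogenization,
)


class TestEvolveSequence:
    def test_zero_duration_identity(self, rng):
        anc = random_sequence(500, rng)
        assert evolve_sequence(anc, 0.0, 2.2e-9, seed=1).residues == anc.residues

    def test_same_seed_same_output(self, rng):
        anc = random_sequence(500, rng)
        a = evolve_sequence(anc, 1e7, 2.2e-9, seed=42)
        b = evolve_sequence(anc, 1e7, 2.2e-9, seed=42)
        assert a.residues == b.residues

    def test_gaps_and_n_carried_through(self):
        anc = SequenceRecord(id="a", residues="AC-GTN" * 20)
        out = evolve_sequence(anc, 1e8, 1e-8, seed=0)
        assert all(
            o == i for o, i in zip(out.residues, anc.residues) if i in "-N"
        )

    def test_change_probs_sum_to_one(self):
        for d in (0.0, 0.05, 0.5, 3.0):
            p_ts, p_tv, p_same = k2p_change_probs(d, kappa=2.0)
            assert p_ts + 2 * p_tv + p_same == pytest.approx(1.0)
            assert min(p_ts, p_tv, p_same) >= 0

    def test_expected_distance_matches_rate_times_time(self, rng):
        """E[K2P distance] = rate x duration, checked by Monte Carlo."""
        anc = random_sequence(10000, rng)
        target = 2.2e-9 * 9.3e6  # single-lineage expectation
        ds = [
            k2p_from_pair(anc, evolve_sequence(anc, 9.3e6, 2.2e-9, seed=s)).d
            for s in range(40)
        ]
        se = np.std(ds, ddof=1) / np.sqrt(len(ds))
        assert abs(np.mean(ds) - target) < 3 * se + 1e-6


class TestSimulateCodivergence:
    def test_topology_mirrors_host(self):
        host = fixtures.host_tree()
        virus, seqs = simulate_codivergence(
            host, 1.5e-9, seed=0, tip_map=fixtures.tip_map()
        )
        assert map_congruent_branches(host, virus, fixtures.tip_map()).congruent
        assert set(seqs) == set(fixtures.tip_map())

    def test_zero_noise_branch_lengths_exactly_clocklike(self):
        host = fixtures.host_tree()
        virus, _ = simulate_codivergence(host, 1.5e-9, seed=0,
                                         tip_map=fixtures.tip_map())
        res = map_congruent_branches(host, virus, fixtures.tip_map())
        pairs = extract_branch_pairs(res, host, virus)
        np.testing.assert_allclose(
            pairs["virus_length"], 1.5e-9 * 1e6 * pairs["host_duration"]
        )

    def test_equal_durations_equal_expected_lengths(self):
        host = parse_newick("(A:50,B:50);")
        virus, _ = simulate_codivergence(host, 2e-9, seed=0)
        lengths = sorted(
            l.edge.length for l in virus.leaf_node_iter()
        )
        assert lengths[0] == pytest.approx(lengths[1])

    def test_r2_decreases_monotonically_with_rate_noise(self):
        host = fixtures.host_tree()
        mean_r2 = []
        for sd in (0.0, 0.4, 1.0):
            r2s = []
            for s in range(8):
                virus, _ = simulate_codivergence(
                    host, 1.5e-9, seed=300 + s, rate_noise_sd=sd,
                    tip_map=fixtures.tip_map(),
                )
                res = map_congruent_branches(host, virus, fixtures.tip_map())
                pairs = extract_branch_pairs(res, host, virus)
                r2s.append(codivergence_test(pairs).r_squared)
            mean_r2.append(np.mean(r2s))
        assert mean_r2[0] > mean_r2[1] > mean_r2[2]

    def test_undated_host_rejected(self):
        with pytest.raises(ValueError, match="dated"):
            simulate_codivergence(parse_newick("((A,B),C);"), 1e-9)


class TestMakeProvirus:
    def test_orf_is_intact(self, rng):
        pro, start, end = make_provirus(3000, rng)
        orf = pro.residues[start:end]
        assert orf.startswith("ATG")
        assert orf[-3:] == "TAG"
        codons = [orf[i: i + 3] for i in range(0, len(orf) - 3, 3)]
        assert not any(c in {"TAA", "TAG", "TGA"} for c in codons)


BASE_CFG = dict(
    genome_length=2000,
    endogenization_time=10.0,
    duplication_times=[9.0, 5.0],
    flank_length=200,
    seed=5,
)


class TestSimulateEndogenization:
    def test_deterministic_given_seed(self):
        a = simulate_endogenization(SimulationConfig(**BASE_CFG))
        b = simulate_endogenization(SimulationConfig(**BASE_CFG))
        assert [r.residues for r in a.locus_alignment.records] == [
            r.residues for r in b.locus_alignment.records
        ]
        assert a.truth.to_dict() == b.truth.to_dict()

    def test_zero_rate_copies_identical(self):
        cfg = SimulationConfig(
            **{**BASE_CFG, "seed": 2},
            host_neutral_rate=RatePrior(1e-30, 0.0),
            indel_rate=0.0,
        )
        sim = simulate_endogenization(cfg)
        seqs = {r.residues for r in sim.element_alignment.records}
        assert len(seqs) == 1

    def test_truth_consistent_with_outputs(self):
        sim = simulate_endogenization(SimulationConfig(**BASE_CFG))
        names = sorted(r.id for r in sim.element_alignment.records)
        assert sim.truth.duplicate_sets == [names]
        assert sorted(sim.truth.defects) == names
        # genealogy parses and spans the copies with the configured ages
        tree = parse_newick(sim.truth.genealogy_newick)
        labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
        assert labels == names
        # the copy genealogy coalesces at the oldest duplication, not at
        # endogenization (a single lineage exists before the first split)
        depths = {l.taxon.label: l.distance_from_root() for l in tree.leaf_node_iter()}
        assert max(depths.values()) == pytest.approx(max(BASE_CFG["duplication_times"]))
        # ungapped alignment rows equal the contig element sequences
        for contig, rec in zip(sim.contigs, sim.element_alignment.records):
            elem = contig.record.residues[contig.element_start: contig.element_end]
            assert elem == rec.residues.replace("-", "")

    def test_pairwise_distance_calibration(self):
        """Copies duplicated t years apart diverge by ~2 r t."""
        ds = []
        for seed in range(30):
            cfg = SimulationConfig(
                genome_length=4000,
                endogenization_time=9.3,
                duplication_times=[9.3],
                flank_length=0,
                indel_rate=0.0,
                seed=seed,
            )
            sim = simulate_endogenization(cfg)
            a, b = sim.element_alignment.records
            ds.append(k2p_from_pair(a, b).d)
        target = 2 * 2.2e-9 * 9.3e6
        se = np.std(ds, ddof=1) / np.sqrt(len(ds))
        assert abs(np.mean(ds) - target) < 3 * se + 1e-6

    def test_recent_duplicates_recovered_by_flank_clustering(self):
        # flank divergence ~0.4% << the 10% identity margin
        cfg = SimulationConfig(
            genome_length=1500,
            endogenization_time=5.0,
            duplication_times=[1.0, 1.0],
            flank_length=300,
            seed=11,
        )
        sim = simulate_endogenization(cfg)
        sets = identify_duplicate_sets(sim.contigs)
        assert sets == sim.truth.duplicate_sets

    def test_fragmentation_covers_contigs(self):
        cfg = SimulationConfig(**{**BASE_CFG, "n_fragments": 3})
        sim = simulate_endogenization(cfg)
        frag_names = {f.id for f in sim.fragments}
        for copy_id, spans in sim.truth.fragments.items():
            contig = next(c for c in sim.contigs if c.record.id == copy_id)
            covered = np.zeros(len(contig.record), dtype=bool)
            for name, s, e in spans:
                assert name in frag_names
                covered[s:e] = True
            assert covered.all()

    def test_decay_produces_defects(self):
        cfg = SimulationConfig(
            genome_length=6000,
            endogenization_time=40.0,
            duplication_times=[20.0],
            indel_rate=5e-11,
            seed=3,
        )
        sim = simulate_endogenization(cfg)
        total_stops = sum(d["stops"] for d in sim.truth.defects.values())
        assert total_stops > 0

    def test_invalid_times_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(endogenization_time=5.0, duplication_times=[6.0])
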