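"""Generator ground truth: planted features, determinism, read sampling."""

import io

import numpy as np
import pandas as pd
import pytest

from stratovir.config import CommunityConfig, STRATIFIED_MONTHS
from stratovir.io import write_fasta
from stratovir.synthetic import (abundance_to_reads,
                                 covered_fraction_from_depth,
                                 generate_genomes, mutate_polb,
                                 random_sequence, reverse_complement,
                                 simulate_dynamics)


def _fasta_bytes(contigs):
    buf = io.StringIO()
    for name, seq in contigs.items():
        buf.write(f">{name}\n")
        for i in range(0, len(seq), 80):
            buf.write(seq[i:i + 80] + "\n")
    return buf.getvalue().encode()


class TestGenerateGenomes:
    def test_empty_community_rejected(self):
        cfg = CommunityConfig(n_epi_specialists=0, n_hypo_specialists=0,
                              n_generalists=0, n_cellular_decoys=0)
        with pytest.raises(ValueError, match="empty community"):
            generate_genomes(cfg)

    def test_gv_genomes_carry_gv_signal(self, small_config):
        comm = generate_genomes(small_config, with_sequences=False)
        seven = {"MCP", "PolB", "TFIIB", "TopoII", "A32", "SFII", "VLTF3"}
        for spec in comm.specs:
            genes = {g for g, _ in spec.planted_markers}
            if spec.true_guild == "cellular":
                assert not genes & (seven | {"HK97_MCP"})
                assert spec.bac_completeness > 15
            else:
                hk97 = [s for g, s in spec.planted_markers if g == "HK97_MCP"]
                assert genes & seven or any(s > 100 for s in hk97)

    def test_planted_tir_is_literal(self, small_config):
        cfg = CommunityConfig(**{**small_config.__dict__, "tir_prob": 1.0})
        comm = generate_genomes(cfg)
        planted = [s for s in comm.specs if s.planted_tir is not None]
        assert planted, "expected at least one planted TIR in the fixture"
        for spec in planted:
            tir_len, n_mm = spec.planted_tir
            seq = comm.contigs[f"{spec.mag_id}_c1"]
            mism = sum(a != b for a, b in
                       zip(seq[:tir_len],
                           reverse_complement(seq[-tir_len:])))
            assert mism == n_mm

    def test_same_seed_byte_identical_fasta(self, small_config):
        a = generate_genomes(small_config)
        b = generate_genomes(small_config)
        assert _fasta_bytes(a.contigs) == _fasta_bytes(b.contigs)
        pd.testing.assert_frame_equal(a.markers, b.markers)

    def test_marker_table_matches_specs(self, small_config):
        comm = generate_genomes(small_config, with_sequences=False)
        by_mag = comm.markers.groupby("seq_id")["gene"].apply(list).to_dict()
        for spec in comm.specs:
            assert by_mag.get(spec.mag_id, []) == \
                [g for g, _ in spec.planted_markers]


class TestSimulateDynamics:
    def test_epi_specialist_single_contiguous_peak(self, small_config):
        ab, _ = simulate_dynamics(small_config)
        truth = {f"MAG_{i:04d}": "epi"
                 for i in range(1, small_config.n_epi_specialists + 1)}
        dur = small_config.epi_peak_duration_months
        for mag in truth:
            epi = ab.loc[mag].xs("epilimnion", level="layer")
            strat = (epi[list(STRATIFIED_MONTHS)] > 0).astype(int).tolist()
            runs = [len(r) for r in "".join(map(str, strat)).split("0") if r]
            assert runs == [dur]

    def test_hypo_specialist_epilimnion_leakage_small(self, small_config):
        ab, _ = simulate_dynamics(small_config)
        n_epi = small_config.n_epi_specialists
        for i in range(n_epi + 1, n_epi + small_config.n_hypo_specialists + 1):
            row = ab.loc[f"MAG_{i:04d}"]
            epi = row.xs("epilimnion", level="layer")[list(STRATIFIED_MONTHS)]
            hypo = row.xs("hypolimnion", level="layer")[list(STRATIFIED_MONTHS)]
            assert epi.sum() < 0.05 * (epi.sum() + hypo.sum())

    def test_zero_sigma_gives_deterministic_template(self, small_config):
        cfg = CommunityConfig(**{**small_config.__dict__,
                                 "abundance_lognormal_sigma": 0.0})
        ab, _ = simulate_dynamics(cfg)
        epi = ab.loc["MAG_0001"].xs("epilimnion", level="layer")
        peak = epi[list(STRATIFIED_MONTHS)][epi[list(STRATIFIED_MONTHS)] > 0]
        assert np.allclose(peak.values, cfg.epi_peak_amplitude)

    def test_true_p_epi_separates_guilds(self, small_config):
        """Noise-free abundances recover the planted guilds exactly."""
        cfg = CommunityConfig(**{**small_config.__dict__,
                                 "abundance_lognormal_sigma": 0.0})
        ab, _ = simulate_dynamics(cfg)
        n_e, n_h = cfg.n_epi_specialists, cfg.n_hypo_specialists
        for i, row in enumerate(ab.index):
            epi = ab.loc[row].xs("epilimnion", level="layer")
            hypo = ab.loc[row].xs("hypolimnion", level="layer")
            e = epi[list(STRATIFIED_MONTHS)].sum()
            h = hypo[list(STRATIFIED_MONTHS)].sum()
            p = e / (e + h)
            if i < n_e:
                assert p > 0.95
            elif i < n_e + n_h:
                assert p < 0.05
            else:
                assert 0.05 < p < 0.95

    def test_sample_grid_is_two_layers_by_months(self, small_config):
        ab, meta = simulate_dynamics(small_config)
        assert ab.shape[1] == 24
        assert len(meta) == 24
        assert meta["stratified"].sum() == 16  # 8 months x 2 layers


class TestAbundanceToReads:
    def test_zero_abundance_zero_counts(self, small_config):
        ab, _ = simulate_dynamics(small_config)
        comm = generate_genomes(small_config, with_sequences=False)
        counts, depth, covfrac = abundance_to_reads(
            ab, comm.genome_lengths, small_config)
        zero = ab.values == 0
        assert (counts.values[zero] == 0).all()
        assert (covfrac.values[zero] == 0).all()

    def test_lander_waterman_closed_form(self):
        assert covered_fraction_from_depth(0.2231) == \
            pytest.approx(0.2, abs=1e-4)
        assert covered_fraction_from_depth(0.0) == 0.0

    def test_covered_fraction_monotone_in_depth(self):
        d = np.linspace(0, 20, 200)
        f = covered_fraction_from_depth(d)
        assert (np.diff(f) > 0).all()
        assert f[-1] > 1 - 1e-8

    def test_total_counts_near_target(self, small_config):
        ab, _ = simulate_dynamics(small_config)
        comm = generate_genomes(small_config, with_sequences=False)
        counts, _, _ = abundance_to_reads(ab, comm.genome_lengths,
                                          small_config)
        target = small_config.reads_per_sample
        totals = counts.sum(axis=0).values
        assert (np.abs(totals - target) <= 3 * np.sqrt(target)).all()

    def test_reproducible_from_seed(self, small_config):
        ab, _ = simulate_dynamics(small_config)
        comm = generate_genomes(small_config, with_sequences=False)
        c1, _, _ = abundance_to_reads(ab, comm.genome_lengths, small_config)
        c2, _, _ = abundance_to_reads(ab, comm.genome_lengths, small_config)
        pd.testing.assert_frame_equal(c1, c2)


class TestMutatePolb:
    def test_zero_divergence_identity(self, rng):
        ref = {"g1": random_sequence(rng, 300)}
        (var,) = mutate_polb(ref, 0.0, seed=1)
        assert var.identity == 1.0
        assert var.sequence == ref["g1"]

    def test_recorded_identity_is_exact(self, rng):
        refs = {f"g{i}": random_sequence(rng, 100) for i in range(20)}
        for var in mutate_polb(refs, 0.03, seed=2):
            ref = refs[var.source_id]
            hamming = sum(a != b for a, b in zip(ref, var.sequence))
            assert var.identity == pytest.approx(1.0 - hamming / 100)

    def test_realized_divergence_near_nominal(self, rng):
        ref = {"g": random_sequence(rng, 1000)}
        div = 0.1
        (var,) = mutate_polb(ref, div, seed=3)
        se = np.sqrt(div * (1 - div) / 1000)
        assert abs((1 - var.identity) - div) < 4 * se

    def test_divergence_out_of_range(self, rng):
        with pytest.raises(ValueError):
            mutate_polb({"g": "ACGT"}, 0.6, seed=0)
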