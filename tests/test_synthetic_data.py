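"""The cohort generator: germlines, lineages, peptide intensities, ground truth."""

import numpy as np
import pandas as pd
import pytest

from igtrace import ig_proteome as ip
from igtrace import synthetic_data as sd
from igtrace.clonotyping import junction_distance
from igtrace.errors import ConfigurationError, InputError
from igtrace.repertoire_io import translate_frame1


class TestSimConfig:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            sd.SimConfig(cell_type_proportions=(0.5, 0.4, 0.2)).validate()

    def test_shm_rate_bounds(self):
        with pytest.raises(ConfigurationError):
            sd.SimConfig(shm_rate=0.3).validate()

    def test_yaml_round_trip(self, tmp_path):
        cfg = sd.SimConfig(n_patients=2, seed=9)
        cfg.to_yaml(tmp_path / "c.yaml")
        assert sd.SimConfig.from_yaml(tmp_path / "c.yaml") == cfg


class TestMakeGermlineSet:
    def test_fixed_seed_is_deterministic(self):
        assert sd.make_germline_set(1, 4, 3) == sd.make_germline_set(1, 4, 3)

    def test_different_seeds_differ(self):
        a = sd.make_germline_set(1, 2, 2)
        b = sd.make_germline_set(2, 2, 2)
        assert a != b

    def test_segment_lengths_and_open_reading_frames(self):
        g = sd.make_germline_set(5, 6, 4)
        for locus, lg in g.by_locus.items():
            for seg in lg.v:
                assert 270 <= len(seg.seq) <= 300
                assert "*" not in translate_frame1(seg.seq)
                assert seg.name.startswith(f"IG{locus[2]}V") and "*01" in seg.name
            for seg in lg.j:
                assert 45 <= len(seg.seq) <= 60
            assert len(lg.constant_extension) == 24

    def test_v_names_are_unique(self):
        g = sd.make_germline_set(5, 30, 4)
        names = [s.name for s in g.by_locus["IGH"].v]
        assert len(set(names)) == len(names)

    def test_too_few_segments_rejected(self):
        with pytest.raises(ConfigurationError):
            sd.make_germline_set(1, 1, 2)


class TestSimulateLineage:
    def test_zero_mutation_rate_gives_identical_cells(self, rng):
        g = sd.make_germline_set(2, 4, 3)
        cells = sd.simulate_lineage(g, 3, 0.0, rng)
        seqs = {(c["heavy"].sequence_nt, c["light"].sequence_nt) for c in cells}
        assert len(seqs) == 1

    def test_singleton_lineage(self, rng):
        g = sd.make_germline_set(2, 4, 3)
        cells = sd.simulate_lineage(g, 1, 0.1, rng)
        assert len(cells) == 1

    def test_members_share_vj_picks_and_junction_length(self, rng):
        g = sd.make_germline_set(2, 6, 4)
        cells = sd.simulate_lineage(g, 6, 0.05, rng)
        assert len({c["heavy"].v_call for c in cells}) == 1
        assert len({c["heavy"].j_call for c in cells}) == 1
        assert len({len(c["heavy"].junction_nt) for c in cells}) == 1
        assert len({c["light"].locus for c in cells}) == 1

    def test_pairwise_junction_distances_stay_below_threshold(self, rng):
        g = sd.make_germline_set(3, 4, 3)
        cells = sd.simulate_lineage(g, 5, 0.05, rng)
        for chain in ("heavy", "light"):
            js = [c[chain].junction_nt for c in cells]
            for a in js:
                for b in js:
                    assert junction_distance(a, b) < 0.2

    def test_mutated_chains_remain_productive(self, rng):
        g = sd.make_germline_set(4, 4, 3)
        for cell in sd.simulate_lineage(g, 10, 0.2, rng):
            for chain in cell.values():
                aa = translate_frame1(chain.sequence_nt)
                assert "*" not in aa[:-1]
                assert chain.junction_nt in chain.sequence_nt

    def test_zero_cells_rejected(self, rng):
        g = sd.make_germline_set(2, 4, 3)
        with pytest.raises(InputError):
            sd.simulate_lineage(g, 0, 0.0, rng)


class TestSimulatePeptides:
    CFG = sd.SimConfig(noise_floor=0.0)

    def test_serum_level_zero_gives_no_serum_rows(self, rng):
        chain = "AAAAAAAKCCCCCCCKDDDDDDD"
        table = sd.simulate_peptides([chain], [sd.SecretionLevel(csf=1.0)],
                                     self.CFG, rng)
        assert (table.compartment == "serum").sum() == 0
        assert (table.compartment == "CSF").sum() > 0

    def test_all_observable_peptides_appear_in_csf(self, rng):
        chain = "AAAAAAAKCCCCCCCKDDDDDDDKEEEEEEE"
        table = sd.simulate_peptides([chain], [sd.SecretionLevel(csf=1.0)],
                                     self.CFG, rng)
        expected = set(ip.digest(chain, missed_cleavages=0))
        assert set(table.peptide_sequence) == expected

    def test_shared_peptide_intensities_are_summed(self, rng):
        # both chains contain AAAAAAAK; the toy's expected value is the sum of
        # the two independent draws, recovered by rerunning the rng stream
        chains = ["AAAAAAAKCCCCCCC", "AAAAAAAKDDDDDDD"]
        levels = [sd.SecretionLevel(csf=1.0)] * 2
        table = sd.simulate_peptides(chains, levels, self.CFG,
                                     np.random.default_rng(0))
        ref = np.random.default_rng(0)
        draws = {}
        for chain in chains:
            for pep in sorted(set(ip.digest(chain, missed_cleavages=0))):
                draws[pep] = draws.get(pep, 0.0) + float(
                    np.exp(ref.normal(self.CFG.csf_intensity_mu,
                                      self.CFG.csf_intensity_sigma))
                )
        shared = table.set_index("peptide_sequence").intensity["AAAAAAAK"]
        assert float(shared) == pytest.approx(draws["AAAAAAAK"])
        assert (table.peptide_sequence == "AAAAAAAK").sum() == 1

    def test_noise_floor_drops_low_draws(self, rng):
        cfg = sd.SimConfig(csf_intensity_mu=1.0, csf_intensity_sigma=0.1,
                           noise_floor=1e9)
        table = sd.simulate_peptides(["AAAAAAAKCCCCCCC"],
                                     [sd.SecretionLevel(csf=1.0)], cfg, rng)
        assert table.empty

    def test_empty_chain_rejected(self, rng):
        with pytest.raises(InputError):
            sd.simulate_peptides([""], [sd.SecretionLevel(csf=1.0)],
                                 self.CFG, rng)


class TestGenerateCohort:
    def test_no_secretors_means_no_csf_signal_from_cells(self):
        cfg = sd.SimConfig(n_patients=1, cells_per_patient=30,
                           n_secretor_clonotypes=0, serum_background_chains=0,
                           seed=1)
        cohort = sd.generate_cohort(cfg)
        assert cohort.truth.secretor_clones == {"P1": []}
        assert cohort.peptides_csf.empty and cohort.peptides_serum.empty

    def test_fixed_seed_output_files_are_byte_identical(self, tmp_path):
        cfg = sd.SimConfig(n_patients=2, cells_per_patient=40, seed=8,
                           n_secretor_clonotypes=3)
        p1 = sd.write_cohort(sd.generate_cohort(cfg), tmp_path / "a")
        p2 = sd.write_cohort(sd.generate_cohort(cfg), tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_truth_clone_count_matches_emitted_clone_ids(self, small_cohort):
        truth = small_cohort.truth
        for patient, n in truth.n_clones.items():
            ids = {cid for cell, cid in truth.clone_of_cell.items()
                   if cell.startswith(patient + "_")}
            assert len(ids) == n

    def test_every_cell_belongs_to_exactly_one_clone(self, small_cohort):
        cells = set(small_cohort.cells.cell_id)
        assert cells == set(small_cohort.truth.clone_of_cell)

    def test_cell_type_counts_match_proportions_within_rounding(self, small_cohort):
        cfg = small_cohort.config
        counts = pd.Series(small_cohort.truth.cell_type).value_counts()
        for prop, name in zip(cfg.cell_type_proportions, ("ASC", "memory", "naive")):
            assert abs(counts.get(name, 0) / cfg.n_patients
                       - prop * cfg.cells_per_patient) <= 1

    def test_secretor_clones_exist_and_decoys_are_absent_from_cells(self, small_cohort):
        truth = small_cohort.truth
        clone_ids = set(truth.clone_of_cell.values())
        for ids in truth.secretor_clones.values():
            assert set(ids) <= clone_ids
        cell_ids = set(small_cohort.cells.cell_id)
        for decoys in truth.decoy_chains.values():
            assert not set(decoys) & cell_ids

    def test_asc_ig_fractions_straddle_the_threshold(self, small_cohort):
        df = small_cohort.cells.drop_duplicates("cell_id").set_index("cell_id")
        for cell, ctype in small_cohort.truth.cell_type.items():
            frac = float(df.loc[cell, "ig_read_fraction"])
            if ctype == "ASC":
                assert frac > 0.10
            else:
                assert frac < 0.10

    def test_decoy_csf_serum_ratio_stays_below_threshold(self, small_cohort):
        csf = small_cohort.peptides_csf.set_index("peptide_sequence").intensity
        serum = small_cohort.peptides_serum.set_index("peptide_sequence").intensity
        # serum-only peptides come from decoys; where both exist and the
        # peptide is decoy-derived the ratio must sit in [0.5, 1.1]
        both = csf.index.intersection(serum.index)
        secretor_peps = set(csf.index) - set(serum.index)
        assert len(secretor_peps) > 0
        for pep in both:
            ratio = float(np.atleast_1d(csf[pep]).sum()) / float(
                np.atleast_1d(serum[pep]).sum()
            )
            assert ratio <= 1.1 + 1e-9

    def test_inconsistent_secretor_count_fails_before_output(self):
        cfg = sd.SimConfig(n_patients=1, cells_per_patient=10,
                           n_secretor_clonotypes=50, seed=1)
        with pytest.raises(ConfigurationError):
            sd.generate_cohort(cfg)
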