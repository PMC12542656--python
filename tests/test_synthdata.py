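"""The synthetic world: panels, genomes, spatial communities, reads."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from genetarget import ecodiv, synthdata as sd
from genetarget.core_io import ConfigError, revcomp
from genetarget.recruit import translate


class TestConfig:
    def test_error_rate_bounds(self):
        with pytest.raises(ConfigError):
            sd.SynthConfig(error_rate=0.2)

    def test_background_fraction_bounds(self):
        with pytest.raises(ConfigError):
            sd.SynthConfig(background_fraction=1.0)

    def test_divergence_ordering_enforced(self):
        with pytest.raises(ConfigError):
            sd.SynthConfig(member_divergence=(0.1, 0.6),
                           paralog_divergence=0.5)


class TestPanel:
    def test_same_seed_identical_panels(self):
        cfg = sd.SynthConfig(seed=42)
        p1 = sd.make_reference_panel(cfg)
        p2 = sd.make_reference_panel(cfg)
        assert [(r.id, r.aa_sequence, r.clade_label) for r in p1] == \
            [(r.id, r.aa_sequence, r.clade_label) for r in p2]

    def test_zero_pmo_members(self):
        cfg = sd.SynthConfig(seed=1)
        cfg.n_ref_families = dict(cfg.n_ref_families,
                                  pmoA=0, pmoB=0, pmoC=0)
        panel = sd.make_reference_panel(cfg)
        assert not any(r.family.startswith("pmo") for r in panel)

    def test_within_family_identity_exceeds_paralog_identity(self, panel):
        """Mean pairwise identity within amoA is higher than between
        amoA and pmoA (checked with the global-alignment oracle)."""
        amoA = [r.aa_sequence for r in panel.by_family("amoA")][:6]
        pmoA = [r.aa_sequence for r in panel.by_family("pmoA")][:4]
        within = [ecodiv.global_identity(a, b)
                  for i, a in enumerate(amoA) for b in amoA[i + 1:]]
        between = [ecodiv.global_identity(a, p)
                   for a in amoA for p in pmoA]
        assert np.mean(within) > np.mean(between)
        assert np.mean(between) < 0.6

    def test_clade_labels_on_archaeal_amoA_only(self, panel):
        for r in panel:
            if r.clade_label is not None:
                assert r.family == "amoA"
                assert r.domain_label == "archaea"
        labels = {r.clade_label for r in panel if r.clade_label}
        assert len(labels) >= 4


class TestGenomes:
    def test_layout_and_gap_construction(self):
        cfg = sd.SynthConfig(seed=2, n_genomes=1,
                             operon_layouts=("amoC,amoA,amoB",),
                             intergenic_gap_bp=(50, 50))
        panel = sd.make_reference_panel(cfg)
        genomes, truth = sd.plant_genomes(panel, cfg)
        genes = genomes[0].genes
        assert [g.family for g in genes] == ["amoC", "amoA", "amoB"]
        # gap between stop codon of one gene and start of the next:
        # planted end excludes the stop codon, so the spacing is 3+50
        assert genes[1].start - genes[0].end == 53
        assert genes[2].start - genes[1].end == 53

    def test_reverse_translation_inverse(self):
        cfg = sd.SynthConfig(seed=3, n_genomes=3)
        panel = sd.make_reference_panel(cfg)
        genomes, _ = sd.plant_genomes(panel, cfg)
        for g in genomes:
            for gene in g.genes:
                cds = g.sequence[gene.start:gene.end]
                assert translate(cds) == gene.aa_sequence

    def test_amoX_layout_fourth_cds_downstream_of_amoB(self):
        cfg = sd.SynthConfig(seed=4, n_genomes=1,
                             operon_layouts=("amoC,amoA,amoB,amoX",))
        panel = sd.make_reference_panel(cfg)
        genomes, _ = sd.plant_genomes(panel, cfg)
        fams = [g.family for g in genomes[0].genes]
        assert fams == ["amoC", "amoA", "amoB", "amoX"]
        b = next(g for g in genomes[0].genes if g.family == "amoB")
        x = next(g for g in genomes[0].genes if g.family == "amoX")
        assert x.start > b.end

    def test_unique_kmer_guarantee(self):
        cfg = sd.SynthConfig(seed=5, n_genomes=4)
        panel = sd.make_reference_panel(cfg)
        genomes, _ = sd.plant_genomes(panel, cfg)
        for g in genomes:
            assert not sd._has_repeated_kmer(g.sequence, 21)


class TestRingDesign:
    def test_default_25_samples(self):
        design = sd.ring_design(sd.SynthConfig(seed=0))
        assert len(design) == 25
        radii = design.table["ring_radius"].value_counts()
        assert radii[0.0] == 1
        for r in (1.0, 5.0, 10.0, 20.0, 50.0, 100.0):
            assert radii[r] == 4

    def test_points_on_their_rings(self):
        design = sd.ring_design(sd.SynthConfig(seed=0))
        t = design.table
        r = np.hypot(t["x"], t["y"])
        assert np.allclose(r, t["ring_radius"])


class TestAbundances:
    def test_deterministic(self):
        cfg = sd.SynthConfig(seed=9)
        design = sd.ring_design(cfg)
        a = sd.simulate_abundances(design, cfg)
        b = sd.simulate_abundances(design, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_single_replicate_ddr_near_planted(self):
        cfg = sd.SynthConfig(seed=10)
        design = sd.ring_design(cfg)
        ab = sd.simulate_abundances(design, cfg)
        fit = ecodiv.fit_ddr(ab, design)
        assert fit.slope == pytest.approx(-0.045, abs=0.01)

    def test_calibration_mean_over_replicates(self):
        """Across seeded replicates the mean fitted slope matches the
        planted slope closely (the acceptance suite runs 20 replicates;
        a smaller sweep here)."""
        cfg = sd.SynthConfig(seed=0)
        design = sd.ring_design(cfg)
        slopes = []
        for s in range(8):
            c = dataclasses.replace(cfg, seed=500 + s)
            ab = sd.simulate_abundances(design, c)
            slopes.append(ecodiv.fit_ddr(ab, design).slope)
        assert np.mean(slopes) == pytest.approx(-0.045, abs=0.005)

    def test_tar_endemics_plant_power_law(self):
        cfg = sd.SynthConfig(seed=12)
        design = sd.ring_design(cfg)
        ab = sd.simulate_abundances(design, cfg)
        fit = ecodiv.fit_tar(ab, design)
        assert fit.slope == pytest.approx(0.016, abs=0.002)
        assert fit.r2 > 0.99


class TestReads:
    def test_byte_identical_under_same_seed(self):
        from conftest import make_world
        r1 = make_world(33, n_genomes=2, ring_radii=(1.0, 5.0),
                        samples_per_ring=2, coverage_per_sample=2.0)
        r2 = make_world(33, n_genomes=2, ring_radii=(1.0, 5.0),
                        samples_per_ring=2, coverage_per_sample=2.0)
        assert [(x.id, x.sequence) for x in r1[3]] == \
            [(x.id, x.sequence) for x in r2[3]]

    def test_error_free_reads_are_genome_substrings(self):
        from conftest import make_world
        cfg, panel, genomes, reads, truth = make_world(
            34, n_genomes=1, error_rate=0.0, background_fraction=0.0,
            coverage_per_sample=3.0, ring_radii=(1.0,), samples_per_ring=0)
        g = genomes[0].sequence
        for r in reads:
            assert r.sequence in g or revcomp(r.sequence) in g

    def test_read_counts_conserved_in_truth(self):
        from conftest import make_world
        cfg, panel, genomes, reads, truth = make_world(
            35, n_genomes=2, background_fraction=0.4,
            coverage_per_sample=2.0, ring_radii=(1.0, 5.0),
            samples_per_ring=2)
        assert len(truth.read_origin) == len(reads)
        assert {r.id for r in reads} == set(truth.read_origin)
        n_back = sum(1 for o in truth.read_origin.values()
                     if o == "background")
        assert 0 < n_back < len(reads)

    def test_background_fraction_binomial_band(self):
        """At a 0.9 background fraction nearly all reads are background
        (checked against the recorded origins at n in the thousands)."""
        from conftest import make_world
        cfg, panel, genomes, reads, truth = make_world(
            36, n_genomes=1, background_fraction=0.9,
            coverage_per_sample=20.0, ring_radii=(1.0,),
            samples_per_ring=3)
        frac = sum(1 for o in truth.read_origin.values()
                   if o == "background") / len(truth.read_origin)
        assert frac >= 0.85

    def test_paired_mode_emits_mate_pairs(self):
        from conftest import make_world
        cfg, panel, genomes, reads, truth = make_world(
            37, n_genomes=1, paired=True, coverage_per_sample=2.0,
            background_fraction=0.0, ring_radii=(1.0,), samples_per_ring=0)
        mates = [r.mate for r in reads]
        assert mates.count("1") == mates.count("2")
        assert set(mates) == {"1", "2"}
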