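"""Contiguity metrics, community matrices, slope fits, clades, trees."""

import math
import random

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from genetarget import ecodiv, synthdata as sd
from genetarget.core_io import Read, ReadSet, ReferencePanel, ReferenceRecord


def brute_force_stats(lengths):
    """Independent enumeration straight from the definitions."""
    ls = sorted(lengths, reverse=True)
    total = sum(ls)
    cum = 0
    out = {}
    for i, x in enumerate(ls, 1):
        cum += x
        if "N50" not in out and cum >= total / 2:
            out["N50"], out["L50"] = x, i
        if "N90" not in out and cum >= 0.9 * total:
            out["N90"], out["L90"] = x, i
    return out


class TestAssemblyStats:
    @pytest.mark.parametrize("lengths,expect", [
        ([100], dict(N50=100, L50=1, N90=100, L90=1)),
        ([80, 70, 50, 30, 20], dict(N50=70, L50=2, N90=30, L90=4)),
        ([50, 50, 50, 50], dict(N50=50, L50=2, N90=50, L90=4)),
    ])
    def test_known_values(self, lengths, expect):
        s = ecodiv.assembly_stats(lengths)
        assert (s.N50, s.L50, s.N90, s.L90) == \
            (expect["N50"], expect["L50"], expect["N90"], expect["L90"])

    def test_oracle_equivalence_random_multisets(self):
        rng = random.Random(0)
        for _ in range(1000):
            lengths = [rng.randint(1, 5000)
                       for _ in range(rng.randint(1, 60))]
            s = ecodiv.assembly_stats(lengths)
            o = brute_force_stats(lengths)
            assert (s.N50, s.L50, s.N90, s.L90) == \
                (o["N50"], o["L50"], o["N90"], o["L90"])

    def test_invariants(self):
        s = ecodiv.assembly_stats([500, 400, 100, 50])
        assert s.N90 <= s.N50
        assert s.L50 <= s.L90 <= s.n_contigs

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ecodiv.assembly_stats([])


class TestBrayCurtis:
    def test_identical_nonzero_is_zero(self):
        assert ecodiv.bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint_supports_is_one(self):
        assert ecodiv.bray_curtis([1, 0, 2], [0, 3, 0]) == 1.0

    def test_hand_computed_value(self):
        assert ecodiv.bray_curtis([1, 2], [3, 0]) == pytest.approx(4 / 6)

    @given(st.lists(st.integers(min_value=0, max_value=100),
                    min_size=2, max_size=10))
    @settings(max_examples=60, deadline=None)
    def test_symmetric_and_bounded(self, x):
        rng = random.Random(sum(x) + len(x))
        y = [rng.randint(0, 100) for _ in x]
        if not any(x) and not any(y):
            return
        d1 = ecodiv.bray_curtis(x, y)
        d2 = ecodiv.bray_curtis(y, x)
        assert d1 == pytest.approx(d2)
        assert 0.0 <= d1 <= 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ecodiv.bray_curtis([0, 0], [0, 0])


class TestMapReads:
    def _panel_reads(self):
        rng = np.random.default_rng(0)
        reps = {"g1": sd._random_dna(rng, 400),
                "g2": sd._random_dna(rng, 400)}
        return rng, reps

    def test_exact_substring_counted(self):
        rng, reps = self._panel_reads()
        reads = ReadSet([Read(id="r", sample_id="s",
                              sequence=reps["g1"][50:150])])
        m = ecodiv.map_reads(reads, reps)
        assert m.loc["s", "g1"] == 1
        assert m.loc["s", "g2"] == 0

    def test_ambiguous_read_dropped(self):
        rng = np.random.default_rng(1)
        shared = sd._random_dna(rng, 200)
        reps = {"a": shared + sd._random_dna(rng, 200),
                "b": shared + sd._random_dna(rng, 200)}
        reads = ReadSet([Read(id="r", sample_id="s",
                              sequence=shared[10:110])])
        m = ecodiv.map_reads(reads, reps)
        assert m.loc["s"].sum() == 0

    def test_row_sums_equal_mapped_counts(self):
        rng, reps = self._panel_reads()
        reads = [Read(id=f"r{i}", sample_id="s",
                      sequence=reps["g1"][i * 3:i * 3 + 120])
                 for i in range(20)]
        reads += [Read(id="b", sample_id="s",
                       sequence=sd._random_dna(rng, 100))]
        m = ecodiv.map_reads(ReadSet(reads), reps)
        assert m.loc["s"].sum() == 20

    def test_abundance_recovery_correlation(self):
        """Error-free reads drawn at planted proportions give matrix
        columns matching the truth."""
        rng = np.random.default_rng(2)
        reps = {f"g{i}": sd._random_dna(rng, 600) for i in range(4)}
        planted = {"g0": 200, "g1": 100, "g2": 50, "g3": 10}
        reads = []
        for gid, n in planted.items():
            for j in range(n):
                start = int(rng.integers(0, 500))
                reads.append(Read(id=f"{gid}_{j}", sample_id="s",
                                  sequence=reps[gid][start:start + 100]))
        m = ecodiv.map_reads(ReadSet(reads), reps)
        got = m.loc["s"].reindex(planted.keys()).to_numpy(float)
        want = np.array(list(planted.values()), float)
        r = np.corrcoef(got, want)[0, 1]
        assert r >= 0.99


class TestSlopeFits:
    def test_exact_decay_line_recovered(self):
        """Similarities constructed exactly on 0.8 - 0.045*log10(d)."""
        dists = np.array([1, 5, 10, 20, 50, 100, 200], float)
        sims = 0.8 - 0.045 * np.log10(dists)
        fit = ecodiv.fit_decay(sims, dists)
        assert fit.slope == pytest.approx(-0.045)
        assert fit.intercept == pytest.approx(0.8)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_similarity_zero_slope(self):
        fit = ecodiv.fit_decay([0.5] * 6, [1, 2, 4, 8, 16, 32])
        assert fit.slope == pytest.approx(0.0)

    def test_insufficient_pairs_rejected(self):
        with pytest.raises(ValueError):
            ecodiv.fit_decay([0.5, 0.4], [1, 10])

    def test_zero_distance_pairs_excluded(self):
        dists = [0, 1, 10, 100, 1000]
        sims = [1.0, 0.8, 0.7, 0.6, 0.5]
        fit = ecodiv.fit_decay(sims, dists)
        assert fit.n_points == 4

    def test_ddr_from_matrix_matches_manual(self):
        """fit_ddr equals Bray-Curtis + OLS assembled by hand."""
        from scipy import stats as sps
        design = sd.ring_design(sd.SynthConfig(seed=0))
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.integers(0, 50, size=(25, 30)).astype(float),
                         index=design.sample_ids)
        fit = ecodiv.fit_ddr(m, design, relative=False)
        d = design.pairwise_distances().to_numpy()
        sims, dists = [], []
        vals = m.to_numpy(float)
        for i in range(25):
            for j in range(i + 1, 25):
                if d[i, j] <= 0:
                    continue
                num = np.abs(vals[i] - vals[j]).sum()
                den = (vals[i] + vals[j]).sum()
                sims.append(1 - num / den)
                dists.append(d[i, j])
        res = sps.linregress(np.log10(dists), sims)
        assert fit.slope == pytest.approx(res.slope)
        assert fit.p_value == pytest.approx(res.pvalue)

    def test_tar_exact_power_law(self):
        """Pooled richness planted exactly as a power law in ring area
        recovers z with r2 = 1 (doublings of richness at computed radii)."""
        z = 0.016
        richness = [100, 200, 400, 800, 1600]
        a1 = math.pi  # area at r=1
        radii = [math.sqrt((n / richness[0]) ** (1 / z) * a1 / math.pi)
                 for n in richness]
        rows = []
        cols = sum(richness)
        counts = np.zeros((len(radii), cols))
        c0 = 0
        for k, (r, n_new) in enumerate(zip(
                radii, [richness[0]] + list(np.diff(richness)))):
            rows.append({"sample_id": f"S{k}", "x": r, "y": 0.0,
                         "ring_radius": r})
            counts[k, c0:c0 + n_new] = 1
            c0 += n_new
        from genetarget.core_io import SampleDesign
        design = SampleDesign(pd.DataFrame(rows))
        matrix = pd.DataFrame(counts, index=[f"S{k}" for k in
                                             range(len(radii))])
        fit = ecodiv.fit_tar(matrix, design)
        assert fit.slope == pytest.approx(z, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_tar_constant_richness_zero_slope(self):
        design = sd.ring_design(sd.SynthConfig(seed=0))
        matrix = pd.DataFrame(1, index=design.sample_ids,
                              columns=[f"v{i}" for i in range(10)])
        fit = ecodiv.fit_tar(matrix, design)
        assert fit.slope == pytest.approx(0.0)

    def test_tar_single_ring_rejected(self):
        design = sd.ring_design(sd.SynthConfig(seed=0, ring_radii=(5.0,)))
        matrix = pd.DataFrame(1, index=design.sample_ids,
                              columns=["v0", "v1"])
        with pytest.raises(ValueError):
            ecodiv.fit_tar(matrix, design)


class TestCladeAssignment:
    def _panel(self):
        rng = np.random.default_rng(4)
        anc = sd._random_protein(rng, 220)
        clades = {}
        records = []
        for i, label in enumerate(("NP-gamma", "NT-alpha", "NP-zeta")):
            seq = sd._mutate_protein(rng, anc, 0.3)
            clades[label] = seq
            records.append(ReferenceRecord(
                id=f"ref{i}", family="amoA", domain_label="archaea",
                clade_label=label, aa_sequence=seq))
        return ReferencePanel(records), clades, rng

    def test_exact_reference_gets_its_clade(self):
        panel, clades, _ = self._panel()
        got = ecodiv.assign_clade(clades["NP-gamma"], panel)
        assert got.label == "NP-gamma"
        assert got.identity == 1.0

    def test_distant_query_unclassified(self):
        panel, _, rng = self._panel()
        got = ecodiv.assign_clade(sd._random_protein(rng, 220), panel)
        assert got.label == "unclassified"

    def test_mutant_assigned_to_nearest_clade(self):
        panel, clades, rng = self._panel()
        query = sd._mutate_protein(rng, clades["NT-alpha"], 0.2)
        got = ecodiv.assign_clade(query, panel)
        assert got.label == "NT-alpha"
        assert got.identity >= 0.7
        assert got.ambiguous is False


class TestNjTree:
    def test_three_taxa_closed_form(self):
        """Three-taxon NJ branch lengths solve the three-point formulas:
        la = (dab + dac - dbc) / 2 etc."""
        import skbio
        dm = {"a": {"b": 0.4, "c": 0.6}, "b": {"c": 0.8}}
        nwk = ecodiv.nj_from_distances(
            ["a", "b", "c"],
            np.array([[0, .4, .6], [.4, 0, .8], [.6, .8, 0]]))
        tree = skbio.TreeNode.read([nwk])
        tips = {t.name: t.length for t in tree.tips()}
        assert tips["a"] == pytest.approx((0.4 + 0.6 - 0.8) / 2)
        assert tips["b"] == pytest.approx((0.4 + 0.8 - 0.6) / 2)
        assert tips["c"] == pytest.approx((0.6 + 0.8 - 0.4) / 2)

    def test_additive_four_taxa_topology(self):
        # additive matrix for ((a,b),(c,d)) with internal branch 0.3
        ids = ["a", "b", "c", "d"]
        d = {("a", "b"): 0.2, ("c", "d"): 0.2,
             ("a", "c"): 0.6, ("a", "d"): 0.6,
             ("b", "c"): 0.6, ("b", "d"): 0.6}
        mat = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = ids.index(x), ids.index(y)
            mat[i, j] = mat[j, i] = v
        import skbio
        tree = skbio.TreeNode.read([ecodiv.nj_from_distances(ids, mat)])
        # a and b form a cherry
        a = tree.find("a")
        sibs = {t.name for t in a.parent.tips()}
        assert sibs == {"a", "b"}

    def test_duplicate_sequences_zero_cherry(self):
        rng = np.random.default_rng(5)
        s = sd._random_protein(rng, 120)
        other = sd._mutate_protein(rng, s, 0.4)
        import skbio
        nwk = ecodiv.nj_tree({"x1": s, "x2": s, "y": other})
        tree = skbio.TreeNode.read([nwk])
        assert tree.find("x1").length == pytest.approx(0.0, abs=1e-9)
        assert tree.find("x2").length == pytest.approx(0.0, abs=1e-9)

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            ecodiv.nj_tree({"a": "MKV", "b": "MKV"})


class TestPoissonDistance:
    def test_identical_zero(self):
        assert ecodiv.poisson_distance("MKVL", "MKVL") == 0.0

    def test_correction_formula(self):
        # two sequences differing in 1 of 10 residues: p = 0.1
        a = "MKVLWAALLV"
        b = "MKVLWAALLA"
        assert ecodiv.poisson_distance(a, b) == \
            pytest.approx(-math.log(0.9))

    def test_cap_keeps_distance_finite(self):
        rng = np.random.default_rng(6)
        a = sd._random_protein(rng, 100)
        b = sd._random_protein(rng, 100)
        d = ecodiv.poisson_distance(a, b)
        assert np.isfinite(d)
        assert d <= -math.log(1 - 0.95) + 1e-9


class TestMantelOption:
    def test_permutation_p_value_reported(self):
        design = sd.ring_design(sd.SynthConfig(seed=0))
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.integers(1, 50, size=(25, 20)).astype(float),
                         index=design.sample_ids)
        fit = ecodiv.fit_ddr(m, design, mantel_permutations=99, seed=1)
        assert fit.mantel_p is not None
        assert 0.0 < fit.mantel_p <= 1.0
        # seeded: identical reruns agree
        fit2 = ecodiv.fit_ddr(m, design, mantel_permutations=99, seed=1)
        assert fit.mantel_p == fit2.mantel_p
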