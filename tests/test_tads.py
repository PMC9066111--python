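"""TAD calling: DI arithmetic, HMM decoding, domain assembly rules,
boundary strength calibration and condition comparisons."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import chromarch as ca
from chromarch.contact import BinTable, ContactMatrix, ice_balance, oe_transform
from chromarch.genome_sim import structural_oe_matrix
from chromarch import tads as tz


def uniform_matrix(n=200, res=40_000, value=5.0):
    m = ContactMatrix(BinTable({"c": n * res}, res),
                      {"c": np.full((n, n), value)})
    m.balanced = {"c": np.full((n, n), value)}
    return m


def oe_only_matrix(Z, res=40_000, chrom="chr1"):
    n = Z.shape[0]
    m = ContactMatrix(BinTable({chrom: n * res}, res), {chrom: np.ones((n, n))})
    m.oe = {chrom: Z}
    return m


class TestDirectionalityIndex:
    def test_uniform_matrix_interior_di_is_zero(self):
        div = ca.directionality_index(uniform_matrix(), window=2_000_000)
        interior = ~div.partial["c"]
        assert np.allclose(div.di["c"][interior], 0.0)
        assert interior.sum() > 0

    def test_hand_computed_formula(self):
        # A=2, B=8 -> E=5, DI = +((2-5)^2/5 + (8-5)^2/5) = +3.6
        A, B = 2.0, 8.0
        E = (A + B) / 2
        di = np.sign(B - A) * ((A - E) ** 2 / E + (B - E) ** 2 / E)
        assert di == pytest.approx(3.6)
        # engine agrees: 3 bins, window = 1 bin
        M = np.array([[0.0, 0, 0], [2.0, 0, 8.0], [0, 0, 0]])
        M = (M + M.T) / 2 * 2  # symmetric with M[1,0]=2, M[1,2]=8
        m = ContactMatrix(BinTable({"c": 3000}, 1000), {"c": M})
        m.balanced = {"c": M}
        div = ca.directionality_index(m, window=1000)
        assert div.di["c"][1] == pytest.approx(3.6)
        assert div.upstream["c"][1] == 2.0 and div.downstream["c"][1] == 8.0

    def test_bin_count_at_40kb(self, strong_boundary_sim):
        *_, m = strong_boundary_sim
        div = ca.directionality_index(m)
        assert len(div.di["chr1"]) == 500  # 20 Mb / 40 kb

    def test_window_must_be_multiple_of_resolution(self):
        with pytest.raises(ValueError, match="multiple"):
            ca.directionality_index(uniform_matrix(), window=30_000)

    def test_antisymmetry_under_bin_reversal(self, strong_boundary_sim):
        *_, m = strong_boundary_sim
        div = ca.directionality_index(m)
        rev = ContactMatrix(m.bins, {c: v[::-1, ::-1].copy() for c, v in m.raw.items()})
        rev.balanced = {c: v[::-1, ::-1].copy() for c, v in m.balanced.items()}
        div_r = ca.directionality_index(rev)
        for c in m.raw:
            assert np.allclose(div_r.di[c], -div.di[c][::-1])


class TestHmm:
    def test_constant_di_gives_all_unbiased(self):
        z = np.zeros(120)
        bins = BinTable({"c": 120 * 40_000}, 40_000)
        div = tz.DIVector(bins, 2_000_000, {"c": z}, {"c": z}, {"c": z},
                          {"c": z}, {"c": np.zeros(120, bool)})
        states = ca.fit_hmm_and_decode(div)
        assert np.all(states["c"] == tz.STATE_NONE)

    def test_long_runs_decoded_exactly(self):
        rng = np.random.default_rng(0)
        pattern = np.concatenate([
            np.full(30, 5.0), np.full(30, -5.0), np.full(40, 5.0),
            np.full(40, -5.0), np.full(30, 5.0), np.full(30, -5.0)])
        di = pattern + rng.normal(0, 0.3, len(pattern))
        bins = BinTable({"c": len(di) * 40_000}, 40_000)
        div = tz.DIVector(bins, 2_000_000, {"c": di}, {"c": di}, {"c": di},
                          {"c": di}, {"c": np.zeros(len(di), bool)})
        states = ca.fit_hmm_and_decode(div, seed=13)
        want = np.where(pattern > 0, tz.STATE_DOWN, tz.STATE_UP)
        assert np.array_equal(states["c"], want)

    def test_same_seed_same_path(self, strong_boundary_sim):
        *_, m = strong_boundary_sim
        div = ca.directionality_index(m)
        a = ca.fit_hmm_and_decode(div, seed=13)
        b = ca.fit_hmm_and_decode(div, seed=13)
        for c in a:
            assert np.array_equal(a[c], b[c])


class TestAssembleDomains:
    def _assemble(self, states, res=40_000):
        bins = BinTable({"c": len(states) * res}, res)
        return ca.assemble_domains({"c": np.asarray(states, dtype=np.int8)}, bins)

    def test_small_gap_is_boundary(self):
        # domains separated by a 200-kb unbiased gap (5 bins at 40 kb)
        states = [2] * 5 + [0] * 5 + [1] * 5 + [2] * 5 + [0] * 5
        ts = self._assemble(states)
        assert len(ts.domains) == 2
        bnd = ts.boundaries
        assert list(bnd["kind"]) == ["boundary"]
        assert (bnd["end"] - bnd["start"]).iloc[0] == 200_000

    def test_large_gap_is_unorganized(self):
        states = [2] * 5 + [0] * 5 + [1] * 15 + [2] * 5 + [0] * 5
        ts = self._assemble(states)
        assert list(ts.boundaries["kind"]) == ["unorganized"]
        assert len(ts.boundary_regions()) == 0

    def test_zero_gap_gives_one_bp_boundary(self):
        states = [2] * 5 + [0] * 5 + [2] * 5 + [0] * 5
        ts = self._assemble(states)
        bnd = ts.boundaries
        assert len(ts.domains) == 2
        assert (bnd["end"] - bnd["start"]).iloc[0] == 1
        assert bnd["start"].iloc[0] == 10 * 40_000

    def test_invariant_to_flanking_unbiased_runs(self):
        core = [2] * 5 + [0] * 5 + [2] * 6 + [1, 0, 0, 0]
        a = self._assemble(core + [1] * 10)
        b = self._assemble([1] * 10 + core + [1] * 10)
        shift = 10 * 40_000
        assert np.array_equal(a.domains["start"].to_numpy() + shift,
                              b.domains["start"].to_numpy())
        assert len(a.boundaries) == len(b.boundaries)

    def test_empty_path_gives_empty_tadset(self):
        ts = ca.assemble_domains({}, BinTable({"c": 400_000}, 40_000))
        assert ts.domains.empty and ts.boundaries.empty

    def test_planted_boundary_recovery(self, strong_boundary_sim):
        genome, truth, cfg, m = strong_boundary_sim
        div = ca.directionality_index(m)
        states = ca.fit_hmm_and_decode(div, seed=13)
        ts = ca.assemble_domains(states, m.bins)
        assert ca.boundary_recall(ts, truth.boundary_insulation) >= 0.90


class TestBoundaryStrength:
    def test_structureless_oe_scores_zero(self):
        Z = np.ones((100, 100))
        m = oe_only_matrix(Z)
        doms = pd.DataFrame({"chrom": ["chr1", "chr1"],
                             "start": [0, 2_000_000], "end": [2_000_000, 4_000_000]})
        ts = tz.tadset_from_domains(doms)
        ts = ca.boundary_strength(m, ts)
        assert ts.boundaries["strength"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("f", [0.2, 0.5, 0.8])
    def test_noise_free_calibration(self, f):
        # isolated boundary, gamma=1, delta=0: S = -log2(f) exactly
        cfg = replace(ca.SimulationConfig(), tad_enrichment=1.0,
                      compartment_contrast=0.0, n_chroms=1,
                      chrom_length=4_000_000)
        g, t = ca.simulate_genome(cfg, seed=5)
        t.tad_domains = pd.DataFrame({"chrom": ["chr1"] * 2,
                                      "start": [0, 2_000_000],
                                      "end": [2_000_000, 4_000_000]})
        t.boundary_insulation = pd.DataFrame({"chrom": ["chr1"],
                                              "pos": [2_000_000], "f": [f]})
        Z = structural_oe_matrix(g, t, cfg, 40_000)
        m = oe_only_matrix(Z["chr1"])
        ts = ca.boundary_strength(m, tz.tadset_from_domains(t.tad_domains))
        assert ts.boundaries["strength"].iloc[0] == pytest.approx(-np.log2(f),
                                                                  abs=1e-6)

    def test_mean_strength_monotone_in_insulation(self):
        means = {}
        for f in (0.2, 0.5, 0.8):
            cfg = replace(ca.SimulationConfig(), insulation=f)
            g, t = ca.simulate_genome(cfg, seed=2)
            m = ca.simulate_contact_map(g, t, cfg, 40_000, seed=3)
            ice_balance(m)
            oe_transform(m)
            ts = ca.boundary_strength(m, tz.tadset_from_domains(t.tad_domains))
            means[f] = np.nanmean(ts.boundaries["strength"])
        assert means[0.2] > means[0.5] > means[0.8]

    def test_edge_boundaries_unscored(self):
        Z = np.ones((30, 30))
        m = oe_only_matrix(Z)
        doms = pd.DataFrame({"chrom": ["chr1", "chr1"],
                             "start": [0, 120_000], "end": [120_000, 1_200_000]})
        ts = ca.boundary_strength(m, tz.tadset_from_domains(doms), flank_bins=10)
        assert np.isnan(ts.boundaries["strength"].iloc[0])


class TestIntraTad:
    def test_unit_oe_gives_unit_means_and_null_comparison(self):
        Z = np.ones((100, 100))
        m = oe_only_matrix(Z)
        doms = pd.DataFrame({"chrom": ["chr1"] * 2, "start": [0, 2_000_000],
                             "end": [2_000_000, 4_000_000]})
        ts = tz.tadset_from_domains(doms)
        means = ca.intra_tad_interaction(m, ts)
        assert np.allclose(means["mean_oe"], 1.0)
        shift, p = ca.compare_conditions(means["mean_oe"], means["mean_oe"])
        assert shift == 0.0 and p > 0.9

    def test_small_domains_skipped(self):
        Z = np.ones((100, 100))
        m = oe_only_matrix(Z)
        doms = pd.DataFrame({"chrom": ["chr1"] * 2, "start": [0, 80_000],
                             "end": [80_000, 4_000_000]})
        means = ca.intra_tad_interaction(m, tz.tadset_from_domains(doms))
        assert len(means) == 1

    def test_mean_matches_enumerated_pairs_on_toy_domain(self):
        rng = np.random.default_rng(4)
        Z = rng.uniform(0.5, 2.0, (12, 12))
        Z = (Z + Z.T) / 2
        m = oe_only_matrix(Z)
        doms = pd.DataFrame({"chrom": ["chr1"], "start": [80_000],
                             "end": [280_000]})  # bins 2..6
        means = ca.intra_tad_interaction(m, tz.tadset_from_domains(doms))
        vals = [Z[i, j] for i in range(2, 7) for j in range(i + 1, 7)]
        assert means["mean_oe"].iloc[0] == pytest.approx(np.mean(vals))

    def test_reduced_enrichment_lowers_intra_tad_oe(self):
        cfg = ca.SimulationConfig()
        g, t = ca.simulate_genome(cfg, seed=1)
        means = {}
        for tag, gamma, seed in (("control", 3.0, 41), ("treated", 2.0, 43)):
            c = replace(cfg, tad_enrichment=gamma)
            m = ca.simulate_contact_map(g, t, c, 40_000, seed=seed)
            m2 = ca.simulate_contact_map(g, t, c, 40_000, seed=seed + 1)
            for ch in m.raw:  # pool the two replicates, the study design
                m.raw[ch] += m2.raw[ch]
            ice_balance(m)
            oe_transform(m)
            div = ca.directionality_index(m)
            ts = ca.assemble_domains(ca.fit_hmm_and_decode(div, seed=13), m.bins)
            means[tag] = ca.intra_tad_interaction(m, ts)["mean_oe"]
        shift, p = ca.compare_conditions(means["control"], means["treated"])
        assert shift < 0 and p < 0.01


class TestTadCompartment:
    def _track(self, pc1):
        from chromarch.compartments import CompartmentTrack
        pc1 = np.asarray(pc1, dtype=float)
        bins = BinTable({"chr1": len(pc1) * 500_000}, 500_000)
        labels = np.where(np.isnan(pc1), "masked",
                          np.where(pc1 > 0, "A",
                                   np.where(pc1 < 0, "B", "masked")))
        return CompartmentTrack(bins, np.asarray(pc1, float),
                                labels.astype(object))

    def test_positive_mean_is_a_compartment(self):
        track = self._track([0.5, 0.5, -0.2, -0.2])
        doms = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1_000_000]})
        scores = ca.tad_compartment_scores(tz.tadset_from_domains(doms), track)
        assert scores["score"].iloc[0] == pytest.approx(0.5)
        assert scores["label"].iloc[0] == "A"

    def test_zero_mean_is_masked(self):
        track = self._track([0.3, -0.3, 0.1, 0.1])
        doms = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1_000_000]})
        scores = ca.tad_compartment_scores(tz.tadset_from_domains(doms), track)
        assert scores["label"].iloc[0] == "masked"

    def test_identical_conditions_never_switch(self):
        track = self._track([0.5, 0.5, -0.4, -0.4, 0.2, 0.2])
        doms = pd.DataFrame({"chrom": ["chr1"] * 3,
                             "start": [0, 1_000_000, 2_000_000],
                             "end": [1_000_000, 2_000_000, 3_000_000]})
        scores = ca.tad_compartment_scores(tz.tadset_from_domains(doms), track)
        frac, n = ca.tad_switch(scores, scores)
        assert frac == 0.0 and n == 3


class TestStrata:
    def _scored(self, strengths, start=0):
        rows = []
        bnds = []
        pos = start
        for s in strengths:
            rows.append(("chr1", pos, pos + 1_000_000))
            pos += 1_000_000
        doms = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        ts = tz.tadset_from_domains(doms)
        ts.boundaries["strength"] = strengths[:-1]
        return ts

    def test_identical_sets_fully_overlap(self):
        ts = self._scored([1.0, 2.0, 3.0, 4.0])
        out = ca.boundary_strength_strata(ts, ts, pd.DataFrame(
            columns=["chrom", "start", "end"]))
        assert out["a"]["n_overlapping"] == 3 and out["a"]["n_specific"] == 0

    def test_all_bound_skips_comparison(self):
        ts = self._scored([1.0, 2.0, 3.0])
        peaks = pd.DataFrame({"chrom": ["chr1"] * 2,
                              "start": [999_000, 1_999_000],
                              "end": [1_001_000, 2_001_000]})
        out = ca.boundary_strength_strata(ts, ts, peaks)
        assert np.isnan(out["a"]["p_bound_vs_unbound"])
        assert len(out["a"]["unbound"]) == 0

    def test_planted_bound_unbound_stratification(self):
        # peak-bound boundaries get f=0.2, unbound f=0.6
        cfg = ca.SimulationConfig()
        g, t = ca.simulate_genome(cfg, seed=3)
        rng = np.random.default_rng(8)
        nb = len(t.boundary_insulation)
        bound_mask = np.zeros(nb, bool)
        bound_mask[rng.choice(nb, nb // 2, replace=False)] = True
        t.boundary_insulation["f"] = np.where(bound_mask, 0.2, 0.6)
        m = ca.simulate_contact_map(g, t, cfg, 40_000, seed=9)
        ice_balance(m)
        oe_transform(m)
        ts = ca.boundary_strength(m, tz.tadset_from_domains(t.tad_domains))
        peaks = t.boundary_insulation[bound_mask].assign(
            start=lambda d: d["pos"] - 150, end=lambda d: d["pos"] + 150)[
            ["chrom", "start", "end"]]
        out = ca.boundary_strength_strata(ts, ts, peaks)
        assert np.mean(out["a"]["bound"]) > np.mean(out["a"]["unbound"])
        assert out["a"]["p_bound_vs_unbound"] < 0.01
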