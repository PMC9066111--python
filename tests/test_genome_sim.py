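"""Simulator: planted-structure intensities, Poisson sampling properties,
determinism and truth round-trips."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import chromarch as ca
from chromarch.genome_sim import (expected_intensity, medip_intensity,
                                  write_truth, read_truth)


def structureless_config(**kw):
    return replace(ca.SimulationConfig(), tad_enrichment=1.0,
                   compartment_contrast=0.0, insulation=1.0, bias_sigma=0.0,
                   n_chroms=1, chrom_length=10_000_000, **kw)


class TestContactMap:
    def test_structureless_distance_bands_are_flat(self):
        cfg = structureless_config()
        g, t = ca.simulate_genome(cfg, seed=0)
        m = ca.simulate_contact_map(g, t, cfg, 500_000, seed=1)
        lam = expected_intensity(g, t, cfg, 500_000)["chr1"]
        M = m.raw["chr1"]
        for s in (1, 3, 7):
            d = np.diagonal(M, offset=s)
            mu = np.diagonal(lam, offset=s)
            assert np.allclose(mu, mu[0], rtol=1e-12)  # flat expectation
            # observed band mean within 4 Poisson SE of the expectation
            se = np.sqrt(mu.sum()) / len(d)
            assert abs(d.mean() - mu[0]) < 4 * se

    def test_domain_enrichment_matches_brute_force_lambda(self):
        # one planted 2-Mb domain with gamma=3; compare sampled within/outside
        # means per distance band against an independently built lambda table
        cfg = replace(structureless_config(), tad_enrichment=3.0)
        g, t = ca.simulate_genome(cfg, seed=0)
        t.tad_domains = pd.DataFrame(
            {"chrom": ["chr1"], "start": [4_000_000], "end": [6_000_000]})
        t.boundary_insulation = t.boundary_insulation.iloc[0:0]
        res = 40_000
        m = ca.simulate_contact_map(g, t, cfg, res, seed=3)
        # brute-force lambda, built directly from the model definition
        n = 10_000_000 // res
        centers = (np.arange(n) + 0.5) * res
        inside = (centers >= 4_000_000) & (centers < 6_000_000)
        i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        s = np.abs(i - j) * res
        with np.errstate(divide="ignore"):
            lam_bf = np.where(s > 0, s.astype(float) ** -1.0,
                              2.0 * float(res) ** -1.0)
        lam_bf *= np.where(inside[:, None] & inside[None, :], 3.0, 1.0)
        lam_bf *= cfg.sequencing_depth / np.triu(lam_bf).sum()
        M = m.raw["chr1"]
        for dist in (5, 15, 30):
            ii, jj = np.arange(n - dist), np.arange(dist, n)
            pair_in = inside[ii] & inside[jj]
            pair_out = ~(inside[ii] | inside[jj])
            obs_ratio = M[ii, jj][pair_in].mean() / M[ii, jj][pair_out].mean()
            exp_ratio = lam_bf[ii, jj][pair_in].mean() / lam_bf[ii, jj][pair_out].mean()
            assert exp_ratio == pytest.approx(1.0 * 3.0 / 1.0, rel=1e-12)
            assert obs_ratio == pytest.approx(3.0, rel=0.10)

    def test_replicates_agree_within_poisson_error(self):
        cfg = ca.SimulationConfig()
        g, t = ca.simulate_genome(cfg, seed=1)
        m1 = ca.simulate_contact_map(g, t, cfg, 500_000, seed=10)
        m2 = ca.simulate_contact_map(g, t, cfg, 500_000, seed=11)
        for s in (1, 5, 10):
            a = np.concatenate([np.diagonal(m1.raw[c], s) for c in m1.raw])
            b = np.concatenate([np.diagonal(m2.raw[c], s) for c in m2.raw])
            se = np.sqrt(a.sum() + b.sum()) / len(a)
            assert abs(a.mean() - b.mean()) < 3 * se

    def test_symmetry_exact(self, strong_boundary_sim):
        *_, m = strong_boundary_sim
        for c in m.raw:
            assert np.array_equal(m.raw[c], m.raw[c].T)

    def test_total_counts_conserved(self, default_sim):
        genome, truth, cfg = default_sim
        m = ca.simulate_contact_map(genome, truth, cfg, 500_000, seed=9)
        total = sum(np.triu(v).sum() for v in m.raw.values())
        assert abs(total - cfg.sequencing_depth) < 3 * np.sqrt(cfg.sequencing_depth)

    def test_determinism(self, default_sim):
        genome, truth, cfg = default_sim
        a = ca.simulate_contact_map(genome, truth, cfg, 500_000, seed=7)
        b = ca.simulate_contact_map(genome, truth, cfg, 500_000, seed=7)
        for c in a.raw:
            assert np.array_equal(a.raw[c], b.raw[c])

    def test_misaligned_domain_rejected(self, default_sim):
        genome, truth, cfg = default_sim
        bad = truth.tad_domains.copy()
        bad.loc[0, "end"] = bad.loc[0, "end"] + 13_000
        bad.loc[1, "start"] = bad.loc[1, "start"] + 13_000
        t2 = ca.SyntheticTruth(truth.compartment_labels, bad,
                               truth.boundary_insulation, truth.planted_dmrs,
                               truth.bias_profile)
        with pytest.raises(ValueError, match="chr1"):
            ca.simulate_contact_map(genome, t2, cfg, 40_000, seed=1)


class TestMedip:
    def test_flat_without_genes_and_dmrs(self):
        cfg = structureless_config()
        g, t = ca.simulate_genome(cfg, seed=0)
        g.genes = g.genes.iloc[0:0]
        t.planted_dmrs = t.planted_dmrs.iloc[0:0]
        inten = medip_intensity(g, t, cfg, 1000)
        assert np.allclose(inten["control"]["chr1"], 1.0)
        track = ca.simulate_medip_tracks(g, t, cfg, 1000, seed=2)
        counts = track.counts["control"][0]
        mu = cfg.medip_depth / len(counts)
        assert abs(counts.mean() - mu) < 4 * np.sqrt(mu / len(counts))

    def test_planted_hyper_dmr_fold_recovered(self, default_sim, medip_track):
        genome, truth, cfg = default_sim
        hyper = truth.planted_dmrs[truth.planted_dmrs["direction"] == "hyper"]
        track = medip_track
        wf = track.window_frame()
        xt = np.sum(track.counts["treated"], axis=0).astype(float)
        xc = np.sum(track.counts["control"], axis=0).astype(float)
        ratios = []
        for _, r in hyper.iterrows():
            sel = ((wf["chrom"] == r["chrom"]) & (wf["start"] >= r["start"])
                   & (wf["end"] <= r["end"])).to_numpy()
            ratios.append(xt[sel].mean() / xc[sel].mean())
        assert np.mean(ratios) == pytest.approx(cfg.dmr_fold_change, rel=0.15)

    def test_metagene_dip_and_rise_in_simulated_control(self, default_sim,
                                                        medip_track):
        genome, *_ = default_sim
        prof = ca.metagene_profile(medip_track, genome.genes, "control")
        assert 45 <= int(np.argmin(prof)) <= 60      # TSS-adjacent minimum
        assert 140 <= int(np.argmax(prof)) <= 155    # TES-adjacent maximum


class TestPeaks:
    def test_empty_request_gives_empty_valid_narrowpeak(self, default_sim, tmp_path):
        genome, truth, cfg = default_sim
        cfg0 = replace(cfg, peak_count=(0, 0, 0))
        pk = ca.simulate_peaks(genome, truth, cfg0, seed=5)
        assert len(pk) == 0
        from chromarch import io as cio
        cio.write_narrowpeak(pk, tmp_path / "p.narrowPeak")
        assert cio.read_narrowpeak(tmp_path / "p.narrowPeak").empty

    def test_boundary_peaks_are_within_one_bin(self, default_sim):
        genome, truth, cfg = default_sim
        cfg1 = replace(cfg, peak_count=(100, 0, 0))
        pk = ca.simulate_peaks(genome, truth, cfg1, seed=6)
        from chromarch.io import peak_summits
        summits = peak_summits(pk)
        for k in range(len(pk)):
            bnd = truth.boundary_insulation
            pos = bnd[bnd["chrom"] == pk["chrom"].iloc[k]]["pos"].to_numpy()
            assert np.min(np.abs(pos - summits[k])) <= 40_000 + 250

    def test_class_composition_matches_config(self, default_sim):
        genome, truth, cfg = default_sim
        pk = ca.simulate_peaks(genome, truth, cfg, seed=7)
        comp = truth.peak_truth["class"].value_counts().to_dict()
        assert comp["boundary"] == cfg.peak_count[0]
        assert comp["promoter"] == cfg.peak_count[1]
        assert comp["random"] == cfg.peak_count[2]
        assert len(pk) == sum(cfg.peak_count)

    def test_boundary_peaks_without_boundaries_rejected(self):
        cfg = structureless_config()
        g, t = ca.simulate_genome(cfg, seed=0)
        t.boundary_insulation = t.boundary_insulation.iloc[0:0]
        with pytest.raises(ValueError, match="boundar"):
            ca.simulate_peaks(g, t, cfg, seed=0)


def test_truth_round_trip(default_sim, default_peaks, tmp_path):
    genome, truth, cfg = default_sim
    write_truth(genome, truth, tmp_path)
    sizes, t2 = read_truth(tmp_path)
    assert sizes == genome.chromsizes
    pd.testing.assert_frame_equal(truth.tad_domains, t2.tad_domains)
    pd.testing.assert_frame_equal(truth.compartment_labels, t2.compartment_labels)
    pd.testing.assert_frame_equal(truth.planted_dmrs, t2.planted_dmrs,
                                  check_dtype=False)
    assert np.allclose(truth.boundary_insulation["f"], t2.boundary_insulation["f"])


def test_gene_bodies_within_bounds_and_tss_strandedness(default_sim):
    genome, *_ = default_sim
    g = genome.genes
    for c, length in genome.chromosomes:
        sub = g[g["chrom"] == c]
        assert (sub["start"] >= 0).all() and (sub["end"] <= length).all()
    from chromarch.io import gene_tss
    tss = gene_tss(g)
    plus = g["strand"] == "+"
    assert np.array_equal(tss[plus], g["start"][plus])
    assert np.array_equal(tss[~plus], g["end"][~plus])


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        replace(ca.SimulationConfig(), decay_exponent=0.0).validate()
    with pytest.raises(ValueError):
        replace(ca.SimulationConfig(), compartment_contrast=1.0).validate()
    with pytest.raises(ValueError):
        replace(ca.SimulationConfig(), dmr_fold_change=1.5).validate()
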