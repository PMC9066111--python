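"""End-to-end driver: simulate -> balance -> compartments -> TADs ->
differential interactions -> methylation -> peak integration, with a single
JSON report.

Configuration is a strict-schema YAML document: unknown keys are errors and
every effective parameter is echoed into the report (silent defaults are
forbidden there). The report carries no timestamps, so two runs with the
same seed produce byte-identical reports; stage timers go to the log.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml

from . import io as cio
from . import genome_sim as sim
from .contact import ice_balance, oe_transform, write_matrix, expected_profile
from .compartments import (compartment_pc1, switch_classify, pc1_correlation,
                           peaks_by_compartment, COMPARTMENT_RESOLUTION)
from . import tads as tadmod
from . import diffint as dimod
from . import methylation as methmod
from . import peaks as peakmod

log = logging.getLogger("chromarch")


@dataclass
class RunConfig:
    seed: int = 1
    outdir: str = "chromarch_out"
    simulate: dict = field(default_factory=dict)   # SimulationConfig overrides
    resolutions: dict = field(default_factory=lambda: {
        "compartment": 500_000, "tad": 40_000, "diff": 20_000})
    ice: dict = field(default_factory=lambda: {
        "tol": 1e-5, "max_iter": 200, "mask_fraction": 0.02})
    tads: dict = field(default_factory=lambda: {
        "di_window": 2_000_000, "flank_bins": 10, "hmm_seed": 13})
    diffint: dict = field(default_factory=lambda: {
        "min_count": 10, "fdr": 0.05, "lfc": 1.0})
    dmr: dict = field(default_factory=lambda: {
        "window": 1_000, "fdr": 0.05, "lfc": 1.0, "merge_gap": 1_000,
        "flank": 2_000})
    peaks: dict = field(default_factory=lambda: {
        "promoter_bp": 2_000, "proximal_bp": 10_000,
        "boundary_span": 500_000, "boundary_step": 25_000})

    def validate(self) -> None:
        if self.resolutions["compartment"] != COMPARTMENT_RESOLUTION:
            raise ValueError(
                f"compartment analysis runs at 500 kb; got "
                f"{self.resolutions['compartment']} bp")
        defaults = RunConfig()
        for section in ("resolutions", "ice", "tads", "diffint", "dmr", "peaks"):
            allowed = set(getattr(defaults, section))
            extra = set(getattr(self, section)) - allowed
            if extra:
                raise ValueError(f"unknown keys in config section "
                                 f"'{section}': {sorted(extra)}")
        sim_fields = set(sim.SimulationConfig.__dataclass_fields__)
        extra = set(self.simulate) - sim_fields
        if extra:
            raise ValueError(f"unknown keys in config section 'simulate': "
                             f"{sorted(extra)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        allowed = set(cls.__dataclass_fields__)
        extra = set(raw) - allowed
        if extra:
            raise ValueError(f"unknown top-level config keys: {sorted(extra)}")
        cfg = cls()
        for k, v in raw.items():
            if isinstance(getattr(cfg, k), dict) and isinstance(v, dict):
                merged = dict(getattr(cfg, k))
                merged.update(v)
                setattr(cfg, k, merged)
            else:
                setattr(cfg, k, v)
        cfg.validate()
        return cfg


def _seed(master: int, k: int) -> int:
    return (master * 100_003 + k) % (2 ** 31)


def _stage(name):
    class _Timer:
        def __enter__(self):
            self.t0 = time.time()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: done in %.1fs", name, time.time() - self.t0)
            return False
    return _Timer()


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages in dependency order and write every artifact plus a
    ``report.json`` under the output directory."""
    config.validate()
    out = Path(config.outdir)
    (out / "inputs").mkdir(parents=True, exist_ok=True)
    (out / "results").mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed,
                    "parameters": {k: v for k, v in asdict(config).items()
                                   if k != "outdir"}}

    simcfg = sim.SimulationConfig(**config.simulate)
    master = config.seed

    with _stage("simulate"):
        genome, truth = sim.simulate_genome(simcfg, seed=_seed(master, 0))
        truth_t, simcfg_t, diff_blocks = sim.treated_condition(
            genome, truth, simcfg, seed=_seed(master, 1))
        peaks = sim.simulate_peaks(genome, truth, simcfg, seed=_seed(master, 2))
        medip = sim.simulate_medip_tracks(genome, truth_t, simcfg,
                                          window=config.dmr["window"],
                                          seed=_seed(master, 3))
        sim.write_truth(genome, truth, out / "inputs")
        cio.write_narrowpeak(peaks, out / "inputs" / "peaks.narrowPeak")
        methmod.tracks_to_bedgraphs(medip, out / "inputs")
        cio.write_table(diff_blocks, out / "inputs" / "truth_diff_blocks.tsv")
        report["simulate"] = {"parameters": sim.config_echo(simcfg),
                              "n_genes": int(len(genome.genes)),
                              "n_planted_boundaries": int(len(truth.boundary_insulation)),
                              "n_planted_dmrs": int(len(truth.planted_dmrs)),
                              "n_peaks": int(len(peaks))}

    conditions = {"control": (truth, simcfg, None),
                  "treated": (truth_t, simcfg_t, diff_blocks)}
    mats: dict = {}
    with _stage("contact-maps"):
        for res_name, res in (("compartment", config.resolutions["compartment"]),
                              ("tad", config.resolutions["tad"]),
                              ("diff", config.resolutions["diff"])):
            for ci, (cond, (tr, cf, blocks)) in enumerate(conditions.items()):
                reps = []
                for r in range(simcfg.replicate_count):
                    m = sim.simulate_contact_map(
                        genome, tr, cf, res,
                        seed=_seed(master, 10 + 10 * ci + r + {"compartment": 0, "tad": 100, "diff": 200}[res_name]),
                        extra_blocks=blocks)
                    reps.append(m)
                mats[(res_name, cond)] = reps
        # pooled per condition for compartment/TAD analyses
        for res_name in ("compartment", "tad"):
            for cond in conditions:
                reps = mats[(res_name, cond)]
                pooled = reps[0].copy()
                for m in reps[1:]:
                    for c in pooled.raw:
                        pooled.raw[c] += m.raw[c]
                mats[(res_name, cond, "pooled")] = pooled

    with _stage("ice"):
        ice_kw = dict(max_iter=config.ice["max_iter"], tol=config.ice["tol"],
                      mask_fraction=config.ice["mask_fraction"])
        ice_cv = {}
        for res_name in ("compartment", "tad"):
            for cond in conditions:
                m = mats[(res_name, cond, "pooled")]
                ice_balance(m, **ice_kw)
                oe_transform(m)
                cv = {}
                for c in m.bins.chroms:
                    s = m.balanced[c].sum(axis=1)[~m.mask[c]]
                    cv[c] = float(s.std() / s.mean())
                ice_cv[f"{res_name}/{cond}"] = cv
                write_matrix(m, out / "results" / f"{res_name}_{cond}_balanced.matrix",
                             out / "results" / f"{res_name}_{cond}_bins.bed",
                             layer="balanced")
        prof = expected_profile(mats[("tad", "control", "pooled")])
        cio.write_table(prof.density, out / "results" / "distance_density.tsv")
        report["ice"] = {"row_sum_cv": ice_cv,
                         "decay_slope_control": prof.slope()}

    with _stage("compartments"):
        tracks = {}
        for cond in conditions:
            tr = compartment_pc1(mats[("compartment", cond, "pooled")],
                                 genome.genes, condition=cond)
            tracks[cond] = tr
            cio.write_bedgraph(tr.frame().rename(columns={"pc1": "value"})
                               [["chrom", "start", "end", "value"]].fillna(0.0),
                               out / "results" / f"pc1_{cond}.bedGraph")
        r, scatter = pc1_correlation(tracks["control"], tracks["treated"])
        switch = switch_classify(tracks["control"], tracks["treated"])
        cio.write_table(scatter, out / "results" / "pc1_scatter.tsv")
        cio.write_bed(switch.frame()[["chrom", "start", "end", "class"]],
                      out / "results" / "compartment_switch.bed")
        comp_peaks, bound_frac = peaks_by_compartment(peaks, switch)
        report["compartments"] = {
            "pc1_correlation_r": r,
            "switch_fractions": switch.fractions,
            "peak_composition_by_class": comp_peaks,
            "class_bound_fraction": bound_frac}

    with _stage("tads"):
        tadsets = {}
        for cond in conditions:
            m = mats[("tad", cond, "pooled")]
            div = tadmod.directionality_index(m, window=config.tads["di_window"])
            states = tadmod.fit_hmm_and_decode(div, seed=config.tads["hmm_seed"])
            ts = tadmod.assemble_domains(states, m.bins, condition=cond)
            ts = tadmod.boundary_strength(m, ts, flank_bins=config.tads["flank_bins"])
            tadsets[cond] = ts
            cio.write_bedgraph(div.frame().rename(columns={"di": "value"})
                               [["chrom", "start", "end", "value"]],
                               out / "results" / f"di_{cond}.bedGraph")
            tadmod.write_tadset(ts, out / "results" / f"domains_{cond}.bed",
                                out / "results" / f"boundaries_{cond}.bed")
        intra = {cond: tadmod.intra_tad_interaction(mats[("tad", cond, "pooled")],
                                                    tadsets[cond])
                 for cond in conditions}
        shift, p_intra = tadmod.compare_conditions(
            intra["control"]["mean_oe"], intra["treated"]["mean_oe"])
        scores = {cond: tadmod.tad_compartment_scores(tadsets[cond], tracks[cond])
                  for cond in conditions}
        sw_frac, n_matched = tadmod.tad_switch(scores["control"], scores["treated"])
        strata = tadmod.boundary_strength_strata(tadsets["control"],
                                                 tadsets["treated"], peaks)
        report["tads"] = {
            "n_domains": {c: int(len(tadsets[c].domains)) for c in conditions},
            "n_boundaries": {c: int(len(tadsets[c].boundary_regions()))
                             for c in conditions},
            "intra_tad_median_shift": shift,
            "intra_tad_mw_p": p_intra,
            "tad_switch_fraction": sw_frac,
            "tad_switch_n_matched": n_matched,
            "boundary_strata": {
                cond: {k: (float(np.mean(v)) if isinstance(v, np.ndarray) and len(v)
                           else (None if isinstance(v, np.ndarray)
                                 else (None if isinstance(v, float) and np.isnan(v)
                                       else v)))
                       for k, v in strata[tag].items()}
                for tag, cond in (("a", "control"), ("b", "treated"))}}

    with _stage("differential-interactions"):
        table = dimod.call_differential(mats[("diff", "control")],
                                        mats[("diff", "treated")],
                                        min_count=config.diffint["min_count"],
                                        fdr=config.diffint["fdr"],
                                        lfc=config.diffint["lfc"])
        dimod.write_table_bedpe(table, out / "results" / "differential_interactions.tsv")
        dbins = dimod.differential_bins(table)
        cio.write_bed(dbins.assign(name="diff_bin"),
                      out / "results" / "differential_bins.bed")
        venn = dimod.overlap_with_peaks(dbins, peaks)
        binding = dimod.counts_by_binding(table, peaks)
        report["differential_interactions"] = {
            "n_tested": int(len(table.records)),
            "n_significant": int(table.records["significant"].sum()),
            "n_differential_bins": int(len(dbins)),
            "replicate_correlation": table.replicate_correlation,
            "peak_overlap": venn,
            "binding_mw_p": None if np.isnan(binding["p"]) else float(binding["p"])}

    with _stage("methylation"):
        prof_c = methmod.metagene_profile(medip, genome.genes, "control",
                                          flank_bp=config.dmr["flank"])
        prof_t = methmod.metagene_profile(medip, genome.genes, "treated",
                                          flank_bp=config.dmr["flank"])
        import pandas as pd
        cio.write_table(pd.DataFrame({"bin": np.arange(len(prof_c)),
                                      "control": prof_c, "treated": prof_t}),
                        out / "results" / "metagene_profile.tsv")
        dmrs = methmod.call_dmrs(medip, fdr=config.dmr["fdr"],
                                 lfc=config.dmr["lfc"],
                                 merge_gap=config.dmr["merge_gap"])
        annotated = methmod.annotate_dmrs(dmrs, genome.genes)
        methmod.write_dmrs(annotated, out / "results" / "dmrs.bed")
        dmr_venn = methmod.dmr_peak_overlap(dmrs, peaks)
        report["methylation"] = {
            "metagene_min_bin": int(np.argmin(prof_c)),
            "metagene_max_bin": int(np.argmax(prof_c)),
            "n_dmrs": int(len(dmrs)),
            "n_hyper": int((dmrs["direction"] == "hyper").sum()) if len(dmrs) else 0,
            "n_hypo": int((dmrs["direction"] == "hypo").sum()) if len(dmrs) else 0,
            "feature_composition": methmod.feature_composition(annotated),
            "dmr_peak_overlap": dmr_venn}

    with _stage("peak-integration"):
        annot, fractions = peakmod.annotate_peaks(
            peaks, genome.genes, promoter_bp=config.peaks["promoter_bp"],
            proximal_bp=config.peaks["proximal_bp"])
        cio.write_table(annot, out / "results" / "peak_annotation.tsv")
        profile, offsets = peakmod.boundary_enrichment_profile(
            peaks, tadsets["treated"], genome.chromsizes,
            span_bp=config.peaks["boundary_span"],
            step_bp=config.peaks["boundary_step"])
        import pandas as pd
        cio.write_table(pd.DataFrame({"offset": offsets, "peaks_per_boundary": profile}),
                        out / "results" / "boundary_enrichment.tsv")
        at_bnd = peakmod.peaks_at_boundaries(peaks, tadsets["treated"])
        report["peak_integration"] = {
            "class_fractions": fractions,
            "boundary_profile_peak_bin": int(np.argmax(profile)),
            "peaks_at_boundaries": at_bnd}

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True,
                                      allow_nan=False, default=_jsonify) + "\n")
    return report


def _jsonify(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    raise TypeError(f"not JSON serializable: {type(v)}")
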