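"""Stage orchestration and the run manifest.

A pipeline run generates (or loads) every modality, executes the
scoring stages in dependency order and writes one RunManifest recording
the package version, the configuration snapshot, input checksums, seeds
and per-stage summary statistics, so that a rerun with the same
manifest inputs reproduces identical deterministic outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path

from . import __version__, io
from .atac import AtacPairCaller
from .imaging import ImagingPairClassifier
from .niche import NicheClusterer
from .synthetic import (ScenarioConfig, default_genome, gen_centroids,
                        gen_chimerism, gen_expression, gen_imaging_pairs,
                        gen_peaksets, gen_transition_observations)
from .transcriptome import PairConcordance
from .transition import TransitionMLE
from .transplant import ChimerismScorer

log = logging.getLogger("hscpolarity")

STAGES = ("generate", "fit-transition", "score-imaging", "score-transplants",
          "score-rna-pairs", "score-atac-pairs", "niche-cluster")


def generate_scenario(cfg: ScenarioConfig, out_dir: Path) -> dict:
    """Write every synthetic modality in the formats the scoring
    commands read; returns the file map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome = default_genome()
    paths = {}

    pairs, truth = gen_imaging_pairs(cfg)
    paths["imaging"] = out_dir / "imaging_pairs.csv"
    io.write_imaging_csv(paths["imaging"], pairs)
    io.write_json(out_dir / "imaging_truth.json", truth)

    series, truth_df = gen_chimerism(cfg)
    paths["chimerism"] = out_dir / "chimerism.csv"
    io.write_chimerism_csv(paths["chimerism"], series)
    truth_df.to_csv(out_dir / "chimerism_truth.csv", index=False)

    matrix, rna_truth = gen_expression(cfg)
    paths["expression"] = out_dir / "expression.tsv"
    paths["expression_meta"] = out_dir / "expression_meta.csv"
    io.write_expression(paths["expression"], paths["expression_meta"], matrix)
    rna_truth.to_csv(out_dir / "expression_truth.csv", index=False)

    peak_pairs, atac_truth = gen_peaksets(cfg, genome)
    paths["beds"] = out_dir / "beds"
    paths["atac_meta"] = out_dir / "atac_meta.tsv"
    io.write_peaksets(paths["beds"], paths["atac_meta"], peak_pairs)
    atac_truth.to_csv(out_dir / "atac_truth.csv", index=False)
    paths["genome"] = out_dir / "genome.chrom.sizes"
    io.write_chrom_sizes(paths["genome"], genome)

    fields, frac = gen_centroids(cfg)
    paths["centroids"] = out_dir / "centroids.csv"
    io.write_centroid_csv(paths["centroids"], fields)
    io.write_json(out_dir / "centroid_truth.json", {"clustered_fraction": frac})

    obs = gen_transition_observations(cfg)
    paths["observations"] = out_dir / "transition_obs.tsv"
    io.write_observations_table(paths["observations"], obs)
    return {k: str(v) for k, v in paths.items()}


def run_pipeline(cfg: ScenarioConfig, out_dir, stages=STAGES,
                 n_permutations: int = 2000, n_iter: int = 500) -> dict:
    """Run the requested stages on a synthetic scenario end-to-end.

    Stage failures are recorded in the manifest (partial completion);
    the manifest is always written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = list(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    if any(s != "generate" for s in stages) and "generate" not in stages:
        # scoring stages depend on generated inputs
        stages = ["generate"] + stages

    manifest = {
        "tool": "hscpolarity", "version": __version__,
        "config": dataclasses.asdict(cfg), "seed": cfg.master_seed,
        "stages": {}, "inputs": {},
    }
    data_dir = out_dir / "data"
    ok = True
    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.perf_counter()
        entry = {"status": "ok"}
        try:
            entry.update(_run_stage(stage, cfg, data_dir, out_dir,
                                    n_permutations, n_iter, manifest))
        except Exception as err:  # recorded, not raised: partial manifest
            log.exception("stage %s failed", stage)
            entry = {"status": "failed", "error": str(err)}
            ok = False
        entry["seconds"] = round(time.perf_counter() - t0, 3)
        manifest["stages"][stage] = entry
        log.info("stage %s: %s (%.2fs)", stage, entry["status"], entry["seconds"])
    manifest["status"] = "ok" if ok else "partial"
    io.write_json(out_dir / "manifest.json", manifest)
    return manifest


def _run_stage(stage, cfg, data_dir, out_dir, n_permutations, n_iter, manifest):
    if stage == "generate":
        paths = generate_scenario(cfg, data_dir)
        manifest["inputs"] = {k: io.file_sha256(v) for k, v in paths.items()
                              if Path(v).is_file()}
        return {"outputs": paths}
    if stage == "fit-transition":
        obs = io.read_observations_table(data_dir / "transition_obs.tsv")
        est = TransitionMLE().fit(obs)
        result = {"d_a": est.d_a_, "d_s": est.d_s_, "loglik": est.loglik_,
                  "ci_d_a": est.ci_d_a_, "ci_d_s": est.ci_d_s_}
        io.write_json(out_dir / "transition_fit.json", result)
        return result
    if stage == "score-imaging":
        pairs = io.read_imaging_csv(data_dir / "imaging_pairs.csv")
        summary = ImagingPairClassifier().summarize(pairs)
        summary["per_pair"].to_csv(out_dir / "imaging_calls.tsv", sep="\t",
                                   index=False)
        io.write_json(out_dir / "imaging_summary.json",
                      {k: v for k, v in summary.items() if k != "per_pair"})
        return {"per_condition": summary["per_condition"]}
    if stage == "score-transplants":
        series = io.read_chimerism_csv(data_dir / "chimerism.csv")
        res = ChimerismScorer().score_cohort(series)
        res["per_daughter"].to_csv(out_dir / "daughter_calls.tsv", sep="\t",
                                   index=False)
        res["per_pair"].to_csv(out_dir / "pair_outcomes.tsv", sep="\t",
                               index=False)
        io.write_json(out_dir / "transplant_summary.json",
                      {"true_hsc_fraction": res["true_hsc_fraction"],
                       "per_condition": res["per_condition"]})
        return {"true_hsc_fraction": res["true_hsc_fraction"]}
    if stage == "score-rna-pairs":
        matrix = io.read_expression(data_dir / "expression.tsv",
                                    data_dir / "expression_meta.csv")
        est = PairConcordance(n_permutations=n_permutations,
                              random_state=cfg.master_seed).fit(matrix)
        est.summary_.to_csv(out_dir / "rna_concordance.tsv", sep="\t", index=False)
        return {"n_pairs": len(est.summary_),
                "n_concordant": int((est.summary_["call"] == "concordant").sum())}
    if stage == "score-atac-pairs":
        pairs = io.read_peaksets(data_dir / "beds", data_dir / "atac_meta.tsv")
        genome = io.read_chrom_sizes(data_dir / "genome.chrom.sizes")
        caller = AtacPairCaller(n_iter=n_iter, random_state=cfg.master_seed)
        caller.fit(pairs, genome)
        import pandas as pd
        pd.DataFrame([{"pair_id": c.pair_id, "adjusted_ratio": c.adjusted_ratio,
                       "observed_overlap": c.observed_overlap,
                       "null_mean_overlap": c.null_mean_overlap,
                       "empirical_p": c.empirical_p, "call": c.call}
                      for c in caller.calls_]).to_csv(
            out_dir / "atac_calls.tsv", sep="\t", index=False)
        return {"n_pairs": len(caller.calls_),
                "fraction_asymmetric": caller.fraction_asymmetric_}
    if stage == "niche-cluster":
        fields = io.read_centroid_csv(data_dir / "centroids.csv")
        total = clustered = 0
        for cs in fields:
            m = NicheClusterer().fit(cs)
            total += cs.n
            clustered += int(round(m.clustered_fraction_ * cs.n))
        frac = clustered / total if total else float("nan")
        io.write_json(out_dir / "niche_summary.json",
                      {"n_points": total, "clustered_fraction": frac})
        return {"clustered_fraction": frac}
    raise AssertionError(stage)
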