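"""End-to-end orchestration: candidates (or map) + FASTA -> backbone PDB.

``run_trace`` wires extraction, clustering, HMM construction, sequential
chain alignment, and model writing together, and records per-stage counts
in a JSON-serializable run summary. Deep-model inference is pluggable: a
precomputed (or synthetic) candidate table replaces the classifier, so the
full pipeline runs without trained weights.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from .candidates import (CaCandidate, cluster_candidates,
                         extract_ca_candidates, read_candidate_table)
from .config import ModelConfig, PipelineConfig
from .evaluation import EvalReport, evaluate_models
from .hmm import (InsufficientStatesError, Observation, TransitionParams,
                  align_chains, build_hmm, traces_to_model)
from .map_io import (read_ca_model, read_density_map, read_fasta_chains,
                     stitch_predictions, tile_map, write_pdb)
from .voxnet import build_voxel_classifier, predict_subgrid

logger = logging.getLogger("catrace")


def predict_map_probabilities(map_path, config: PipelineConfig,
                              model_seed: int = 0):
    """Run the (randomly initialized) classifier over a map by tiling.

    Without trained weights the output is not biologically meaningful;
    this path exercises the full inference plumbing and is the hook where
    trained checkpoints would plug in.
    """
    dmap = read_density_map(map_path)
    atom_net = build_voxel_classifier(ModelConfig(out_channels=4),
                                      seed=model_seed)
    aa_net = build_voxel_classifier(ModelConfig(out_channels=21),
                                    seed=model_seed + 1)
    tiles = tile_map(dmap, edge=32, stride=config.tile_stride)
    atom_tiles, aa_tiles = [], []
    for tile in tiles:
        atom_tiles.append(
            (predict_subgrid(atom_net, tile.data).values, tile.index_offset))
        aa_tiles.append(
            (predict_subgrid(aa_net, tile.data).values, tile.index_offset))
    atom_grid = stitch_predictions(atom_tiles, dmap.grid.shape,
                                   dmap.voxel_size, dmap.origin)
    aa_grid = stitch_predictions(aa_tiles, dmap.grid.shape,
                                 dmap.voxel_size, dmap.origin)
    return atom_grid, aa_grid


def run_trace(
    fasta_path,
    out_path,
    config: PipelineConfig | None = None,
    candidates_path=None,
    candidates: list[CaCandidate] | None = None,
    map_path=None,
    summary_path=None,
):
    """Trace chain sequences through C-alpha candidates; write a PDB model.

    Exactly one of ``candidates``, ``candidates_path`` or ``map_path`` must
    supply the C-alpha evidence. Returns ``(BackboneModel, summary dict)``.
    """
    config = config or PipelineConfig()
    t0 = time.time()
    sources = [s is not None for s in (candidates, candidates_path, map_path)]
    if sum(sources) != 1:
        raise ValueError(
            "provide exactly one of candidates, candidates_path, map_path")

    chains_fa = read_fasta_chains(fasta_path)
    observations = [Observation.from_sequence(seq, name=rid)
                    for rid, seq in chains_fa]

    if candidates_path is not None:
        candidates = read_candidate_table(candidates_path)
        logger.info("read %d candidates from %s", len(candidates),
                    candidates_path)
    elif map_path is not None:
        atom_grid, aa_grid = predict_map_probabilities(
            map_path, config, model_seed=config.seed)
        candidates = extract_ca_candidates(atom_grid, aa_grid,
                                           threshold=config.ca_threshold)
        logger.info("extracted %d candidate voxels from map", len(candidates))

    n_raw = len(candidates)
    above = [c for c in candidates if c.p_ca > config.ca_threshold]
    clusters = cluster_candidates(above, radius=config.cluster_radius)
    reps = [cl.representative for cl in clusters]
    logger.info("threshold %.2f: %d/%d candidates; %d clusters",
                config.ca_threshold, len(above), n_raw, len(reps))

    total_res = sum(len(o) for o in observations)
    if len(reps) < total_res:
        raise InsufficientStatesError(
            f"{total_res} residues to place but only {len(reps)} clustered "
            f"candidates above threshold {config.ca_threshold} "
            f"(shortfall {total_res - len(reps)})")

    params = TransitionParams(mu=config.mu, sigma=config.sigma,
                              lambda_scale=config.lambda_scale)
    model_hmm = build_hmm(reps, background=config.background, params=params)
    traces = align_chains(model_hmm, observations, order=config.chain_order)
    backbone = traces_to_model(traces)
    written = write_pdb(backbone, out_path)

    summary = {
        "config": config.summary_dict(),
        "n_candidates_input": n_raw,
        "n_candidates_above_threshold": len(above),
        "n_clusters": len(reps),
        "n_chains": len(observations),
        "chain_log_scores": {t.name or str(i): round(t.log_score, 6)
                             for i, t in enumerate(traces)},
        "n_residues_placed": backbone.n_residues,
        "output": str(written),
        "runtime_s": round(time.time() - t0, 3),
    }
    if summary_path is not None:
        with open(summary_path, "w") as fh:
            json.dump(summary, fh, indent=2)
    return backbone, summary


def run_eval(model_path, reference_path, out_csv=None,
             cutoff: float = 3.0) -> EvalReport:
    """Score a built model against a reference structure; optional CSV row."""
    predicted = read_ca_model(model_path)
    reference = read_ca_model(reference_path)
    report = evaluate_models(predicted, reference, cutoff=cutoff)
    if out_csv is not None:
        report.to_row(label=str(Path(model_path).name)).to_csv(
            out_csv, index=False)
    return report
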