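"""End-to-end orchestration: preprocess -> align -> embed -> cluster -> stats.

A :class:`RunConfig` collects every stage parameter (defaults follow the
standard settings documented per stage); :func:`run_pipeline` executes
the full analysis over a set of sessions and writes labels, module
assignments, dendrograms, metric curves and a statistics report plus a
reproducibility manifest to a run directory.  :func:`make_demo`
generates a small synthetic multi-session dataset with ground truth.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .align import align_to_reference
from .embedding import density_map, umap_embed, watershed_postures
from .features import compute_features, concat_features, normalize_features, pca_reduce
from .hierarchy import ami, best_cut, dasgupta_score, paris_dendrogram
from .preprocess import (
    DEFAULT_CAGE_BOUNDS,
    PoseSequence,
    interpolate_gaps,
    normalize_pose,
    qc_filter,
    read_pose_table,
    write_pose_table,
)
from .simulate import (
    corrupt_session,
    generate_markov_labels,
    make_repertoire,
    render_poses,
    write_ground_truth,
    write_manifest,
)
from .skeleton import SkeletonModel, default_skeleton
from .timescales import fit_half_life, metric_curve, shuffle_null, two_way_anova
from .transitions import compress_runs, transition_matrix

logger = logging.getLogger("ethokit")


@dataclass
class RunConfig:
    """All tunable stage parameters of one pipeline run."""

    session_files: list = field(default_factory=list)
    cage_bounds: tuple = DEFAULT_CAGE_BOUNDS
    min_mean_limb: float = 0.10
    max_gap_frames: int = 10
    align_K: int = 100
    align_filter_order: int = 15
    align_weighting: str = "kernel"
    do_alignment: bool = True
    var_fraction: float = 0.95
    min_dist: float = 0.001
    n_neighbors: int = 20
    grid_n: int = 200
    cut_range: tuple = (0.4, 1.4)
    n_cuts: int = 51
    lags: list = field(default_factory=lambda: [1, 2, 3, 5, 8, 12, 20, 35, 60, 100])
    n_permutations: int = 100
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _stage_seed(master: int, stage: str) -> int:
    """Named substream of the master seed (stable across runs)."""
    h = np.uint32(master)
    for ch in stage:
        h = np.uint32(h * np.uint32(31) + np.uint32(ord(ch)))
    return int(h % np.uint32(2**31 - 1))


def preprocess_session(seq: PoseSequence, skeleton: SkeletonModel, config: RunConfig):
    """QC -> gap interpolation -> normalization for one session."""
    seq, report = qc_filter(
        seq, skeleton, cage_bounds=config.cage_bounds, min_mean_limb=config.min_mean_limb
    )
    seq = interpolate_gaps(seq, max_gap_frames=config.max_gap_frames)
    norm = normalize_pose(seq, skeleton)
    return seq, norm, report


def run_pipeline(
    config: RunConfig,
    out_dir,
    sessions: list[PoseSequence] | None = None,
    skeleton: SkeletonModel | None = None,
) -> dict:
    """Execute the full analysis; returns the metrics report dict.

    ``sessions`` may be passed in memory; otherwise they are read from
    ``config.session_files``.
    """
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    skeleton = skeleton or default_skeleton()
    if sessions is None:
        sessions = [read_pose_table(p, skeleton) for p in config.session_files]
    if not sessions:
        raise ValueError("no sessions to analyze")

    # --- preprocess ---------------------------------------------------
    qc_reports, fms, cleaned = {}, [], []
    for seq in sessions:
        seq2, norm, report = preprocess_session(seq, skeleton, config)
        qc_reports[seq.session_id] = report.to_dict()
        fms.append(compute_features(norm, seq2, skeleton))
        cleaned.append(seq2)
        logger.info(
            "preprocessed %s: %d frames, %.2f%% removed",
            seq.session_id,
            seq.n_frames,
            100 * report.fraction_removed,
        )

    # --- per-subject feature normalization ----------------------------
    pooled = normalize_features(concat_features(fms))

    # --- cross-session alignment to the largest session ---------------
    sess_names = [s.session_id for s in sessions]
    feats = pooled.features.copy()
    if config.do_alignment and len(sessions) > 1:
        sizes = {nm: int(np.sum(pooled.session_id == nm)) for nm in sess_names}
        ref = max(sizes, key=sizes.get)
        ref_rows = pooled.session_id == ref
        for nm in sess_names:
            if nm == ref:
                continue
            rows = pooled.session_id == nm
            aligned, corr = align_to_reference(
                feats[ref_rows],
                feats[rows],
                K=config.align_K,
                filter_order=config.align_filter_order,
                weighting=config.align_weighting,
            )
            feats[rows] = aligned
            logger.info(
                "aligned %s to %s: %d/%d samples paired, mean |c| = %.4f",
                nm,
                ref,
                corr.n_paired,
                int(rows.sum()),
                float(np.nanmean(np.linalg.norm(corr.C, axis=1))),
            )

    # --- embed + segment (single global embedding) ---------------------
    scores, pca = pca_reduce(
        type(pooled)(
            features=feats,
            frame_index=pooled.frame_index,
            subject_id=pooled.subject_id,
            session_id=pooled.session_id,
            normalized=True,
        ),
        var_fraction=config.var_fraction,
    )
    logger.info("PCA kept %d components", scores.shape[1])
    points = umap_embed(
        scores,
        min_dist=config.min_dist,
        n_neighbors=config.n_neighbors,
        seed=_stage_seed(config.seed, "umap"),
    )
    grid = density_map(points, grid_n=config.grid_n)
    emb = watershed_postures(grid, points)
    n_postures = emb.n_postures
    logger.info("watershed found %d postures", n_postures)

    labels_df = pd.DataFrame(
        {
            "session": pooled.session_id,
            "frame": pooled.frame_index,
            "posture": emb.posture_labels,
        }
    )
    labels_df.to_csv(out / "posture_labels.csv", index=False)

    # --- per-session transition analysis -------------------------------
    heights = np.linspace(config.cut_range[0], config.cut_range[1], config.n_cuts)
    report: dict = {"sessions": {}, "qc": qc_reports, "n_postures": n_postures}
    assignments = {}
    rows = []
    for seq in sessions:
        nm = seq.session_id
        mask = pooled.session_id == nm
        frame_labels = emb.posture_labels[mask]
        runs = compress_runs(frame_labels, fps=seq.fps)
        g = transition_matrix(runs, T=1, n_postures=n_postures).active_subgraph()
        dend = paris_dendrogram(g)
        part = best_cut(dend, g)
        dscore = dasgupta_score(dend, g)
        null = shuffle_null(
            runs,
            metric="modularity",
            n=config.n_permutations,
            seed=_stage_seed(config.seed, f"null-{nm}"),
            n_postures=n_postures,
        )
        curve = metric_curve(runs, config.lags, metric="modularity", n_postures=n_postures)
        fit = fit_half_life(curve) if len(curve.lags) >= 4 else None
        assignments[nm] = part.modules
        (out / f"dendrogram_{nm}.nwk").write_text(dend.to_newick())
        pd.DataFrame(
            {"posture": list(part.modules), "module": list(part.modules.values())}
        ).to_csv(out / f"modules_{nm}.csv", index=False)
        pd.DataFrame({"lag": curve.lags, "modularity": curve.values}).to_csv(
            out / f"modularity_curve_{nm}.csv", index=False
        )
        sess_report = {
            "subject": seq.subject_id,
            "task": seq.task_condition,
            "n_runs": int(runs.n_runs),
            "mean_dwell_s": runs.mean_dwell(),
            "n_modules": part.n_modules,
            "modularity": part.Q,
            "dasgupta": dscore,
            "modularity_p": null.p_value,
            "null_n": null.n_permutations,
            "half_life": None if fit is None or fit.degenerate else fit.half_life,
            "fit_adj_r2": None if fit is None else fit.adj_r2,
        }
        report["sessions"][nm] = sess_report
        rows.append(
            {
                "session": nm,
                "subject": seq.subject_id,
                "task": seq.task_condition,
                "value": part.Q,
            }
        )
        logger.info(
            "session %s: %d modules, Q=%.3f, Dasgupta=%.3f, p=%.4f",
            nm,
            part.n_modules,
            part.Q,
            dscore,
            null.p_value,
        )
        _ = heights  # cut grid recorded via manifest

    # --- cross-session statistics --------------------------------------
    metrics_df = pd.DataFrame(rows)
    stats_report: dict = {}
    if metrics_df["subject"].nunique() >= 2 and metrics_df["task"].nunique() >= 2:
        try:
            tbl = two_way_anova(metrics_df)
            stats_report["modularity_anova"] = {
                str(k): {"F": float(tbl.loc[k, "F"]), "p": float(tbl.loc[k, "PR(>F)"])}
                for k in tbl.index
                if k != "Residual"
            }
        except ValueError as e:
            stats_report["modularity_anova"] = {"error": str(e)}
    if len(assignments) > 1:
        pairs = {}
        names = sorted(assignments)
        for i, s1 in enumerate(names):
            for s2 in names[i + 1 :]:
                pairs[f"{s1}|{s2}"] = ami(assignments[s1], assignments[s2])
        stats_report["pairwise_session_ami"] = pairs
    report["stats"] = stats_report

    manifest = {
        "config": config.to_dict(),
        "ethokit_version": __version__,
        "n_sessions": len(sessions),
        "wall_time_s": time.time() - t0,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


DEMO_TASKS = ("OFF", "ON_controlled", "ON_random")


def make_demo(
    seed: int,
    out_dir=None,
    n_frames: int = 20000,
    n_postures: int = 12,
    n_modules: int = 4,
    subjects: tuple = (("subjA", 1.0), ("subjB", 1.15)),
    noise_sd: float = 0.01,
    skeleton: SkeletonModel | None = None,
):
    """Synthetic 2-subject x 3-condition dataset with ground truth.

    Both subjects share one behavior repertoire; subjects differ by limb
    scale and each session gets its own small additive batch offset plus
    a few tracking dropouts and outlier frames.  Returns (sessions,
    ground_truths, repertoire); when ``out_dir`` is given, pose tables,
    ground-truth label tables and a parameter manifest are written.
    """
    skeleton = skeleton or default_skeleton()
    rng = np.random.default_rng(seed)
    rep = make_repertoire(
        n_postures=n_postures, n_modules=n_modules, seed=int(rng.integers(2**31 - 1))
    )
    sessions, truths = [], {}
    for subj, scale in subjects:
        for task in DEMO_TASKS:
            nm = f"{subj}_{task}"
            s = int(rng.integers(2**31 - 1))
            labels, gt = generate_markov_labels(rep, n_frames, seed=s)
            seq = render_poses(
                labels,
                skeleton,
                rep,
                noise_sd=noise_sd,
                seed=s + 1,
                subject_scale=scale,
                subject_id=subj,
                session_id=nm,
                task_condition=task,
            )
            offset = rng.normal(0.0, 0.01, 3)
            n_drop = int(rng.integers(2, 5))
            drops = [
                (int(rng.integers(100, n_frames - 100)), int(rng.integers(2, 12)))
                for _ in range(n_drop)
            ]
            outliers = [int(rng.integers(n_frames)), (int(rng.integers(n_frames)), "collapse")]
            seq = corrupt_session(seq, offset=offset, dropout_runs=drops, outlier_frames=outliers)
            gt.session_offsets[nm] = offset
            gt.subject_scale[subj] = scale
            sessions.append(seq)
            truths[nm] = gt
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for seq in sessions:
            write_pose_table(seq, out / f"{seq.session_id}.csv")
            write_ground_truth(truths[seq.session_id], out / f"{seq.session_id}.truth.csv")
        write_manifest(
            {
                "seed": seed,
                "n_frames": n_frames,
                "n_postures": n_postures,
                "n_modules": n_modules,
                "subjects": list(subjects),
                "noise_sd": noise_sd,
            },
            out / "demo_manifest.json",
        )
    return sessions, truths, rep
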