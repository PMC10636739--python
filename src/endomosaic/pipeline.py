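"""End-to-end mosaicking runs: sources -> fusion -> panorama -> metrics.

``run_mosaic`` executes one configuration (fusion mode, enabled sources,
loop closure on/off) on a frame sequence and returns the panorama, the
estimated states and a JSON-serialisable run report.  ``run_benchmark``
runs the three single-source baselines, the naive average, and the
fused graph with and without loop closure on the same per-pair
estimates, mirroring the standard ablation table.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .affine_estimation import ransac_affine
from .config import RunConfig
from .correspondence_sources import (
    compute_dense_flow,
    detect_and_match_features,
    flow_to_correspondences,
    match_keypoints,
    to_gray,
)
from .direct_registration import register_direct
from .evaluation import SsimReport, pairwise_ssim, summarize
from .geometry import AffineTransform
from .loop_closure import extract_features, find_loop_closures
from .panorama import Panorama, anchor_to_middle, blend, middle_index
from .pose_graph import (
    average_fusion,
    build_graph,
    chain_single_source,
    optimize,
)
from .uncertainty import (
    Diagnostics,
    RegistrationEstimate,
    finalize_estimate,
    information_from_inliers,
    information_from_residual,
)

__all__ = [
    "MosaicResult",
    "load_frames",
    "estimate_pairs",
    "states_for_mode",
    "run_mosaic",
    "run_benchmark",
    "save_run",
]

logger = logging.getLogger(__name__)


@dataclass
class MosaicResult:
    panorama: Panorama
    states: list                  # anchor-relative per-frame AffineTransforms
    middle_states: list           # middle-anchored transforms used for blending
    ssim: SsimReport
    report: dict = field(default_factory=dict)


def load_frames(input_dir: str | Path) -> list:
    """Read a PNG/JPEG/TIFF directory in lexicographic (= temporal) order."""
    import imageio.v3 as iio

    paths = sorted(
        p
        for p in Path(input_dir).iterdir()
        if p.suffix.lower() in (".png", ".jpg", ".jpeg", ".tif", ".tiff")
    )
    if not paths:
        raise ValueError(f"no image files found in {input_dir}")
    frames = [np.asarray(iio.imread(p), dtype=float) for p in paths]
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise ValueError(f"frames have mismatched shapes: {sorted(shapes)}")
    return [f / 255.0 if f.max() > 1.5 else f for f in frames]


def _estimate_one(frames, i, source, cfg: RunConfig, features=None) -> RegistrationEstimate:
    """One consecutive-pair estimate; z maps frame i+1 coords into frame i."""
    j = i + 1
    if source == "direct":
        res = register_direct(frames[i], frames[j], params=cfg.direct)
        return RegistrationEstimate(
            frame_i=i,
            frame_j=j,
            source="direct",
            transform=res.transform,
            info=information_from_residual(res.residual if res.converged else 0.0),
            diagnostics=Diagnostics(
                residual=res.residual, converged=res.converged,
                n_correspondences=res.n_valid,
            ),
        )
    if source == "feature":
        if features is not None:
            corr = match_keypoints(
                features[j].keypoints, features[j].descriptors,
                features[i].keypoints, features[i].descriptors, cfg.feature,
            )
        else:
            corr = detect_and_match_features(frames[j], frames[i], cfg.feature)
    else:  # flow
        field_ = compute_dense_flow(
            frames[j], frames[i], cfg.flow, pair_key=f"{j:05d}_{i:05d}"
        )
        corr = flow_to_correspondences(field_, cfg.flow.stride, cfg.flow.border_margin)
    res = ransac_affine(
        corr,
        eps=cfg.estimation.eps,
        max_iters=cfg.estimation.max_iters,
        min_inliers=cfg.estimation.min_inliers,
        seed=cfg.seed + 1000 * i + (0 if source == "feature" else 1),
        sample_size=cfg.estimation.sample_size,
    )
    return RegistrationEstimate(
        frame_i=i,
        frame_j=j,
        source=source,
        transform=res.transform,
        info=information_from_inliers(res.n_inliers if res.converged else 0),
        diagnostics=Diagnostics(
            n_inliers=res.n_inliers,
            n_correspondences=len(corr),
            converged=res.converged,
        ),
    )


def estimate_pairs(frames: list, cfg: RunConfig, sources=None, features=None) -> list:
    """All consecutive-pair estimates for the enabled sources.

    ``features`` may carry per-frame FrameFeatures so SIFT runs once
    per frame instead of once per pair.
    """
    sources = list(sources or cfg.sources)
    if features is None and "feature" in sources:
        features = [extract_features(f, cfg.feature) for f in frames]
    estimates = []
    for i in range(len(frames) - 1):
        for source in sources:
            est = _estimate_one(frames, i, source, cfg, features)
            finalize_estimate(est, cfg.uncertainty)
            estimates.append(est)
            d = est.diagnostics
            logger.info(
                "pair (%d,%d) %s: n_inl=%d n_corr=%d res=%.3g omega_tr=%.3g failed=%s",
                i, i + 1, source, d.n_inliers, d.n_correspondences,
                d.residual, float(np.trace(est.info)), est.failed,
            )
    return estimates


def states_for_mode(
    estimates: list,
    n_frames: int,
    mode: str,
    loop_edges: list | None = None,
    cfg: RunConfig | None = None,
) -> tuple:
    """Per-frame states under a fusion mode; returns (states, report dict)."""
    cfg = cfg or RunConfig()
    info: dict = {"mode": mode}
    if mode.startswith("single:"):
        return chain_single_source(estimates, n_frames, mode.split(":", 1)[1]), info
    if mode == "average":
        return average_fusion(estimates, n_frames), info
    if mode != "graph":
        raise ValueError(f"unknown fusion mode {mode!r}")
    graph = build_graph(list(estimates) + list(loop_edges or []), n_frames)
    graph, opt = optimize(graph, cfg=cfg.graph)
    info.update(
        iterations=opt.iteration,
        final_cost=opt.cost,
        converged=opt.converged,
        cost_history=opt.cost_history,
        n_loop_edges=len(loop_edges or []),
    )
    return graph.vertices, info


def run_mosaic(frames: list, cfg: RunConfig | None = None) -> MosaicResult:
    """Full pipeline on an in-memory frame sequence."""
    cfg = cfg or RunConfig()
    n = len(frames)
    if n == 0:
        raise ValueError("empty frame sequence")
    if n == 1:
        g = to_gray(frames[0])
        pano = Panorama(
            canvas=np.asarray(frames[0], dtype=float),
            offset=np.zeros(2),
            filled_mask=np.ones(g.shape, dtype=bool),
        )
        return MosaicResult(
            pano,
            [AffineTransform.identity()],
            [AffineTransform.identity()],
            SsimReport(),
            {"n_frames": 1, "mode": cfg.fusion_mode},
        )

    if cfg.fusion_mode.startswith("single:"):
        sources = [cfg.fusion_mode.split(":", 1)[1]]
    else:
        sources = cfg.sources
    need_loops = cfg.fusion_mode == "graph" and cfg.loop_closure.enabled
    features = (
        [extract_features(f, cfg.feature) for f in frames]
        if ("feature" in sources or need_loops)
        else None
    )
    estimates = estimate_pairs(frames, cfg, sources, features)

    loop_edges: list = []
    if need_loops:
        provisional, _ = states_for_mode(estimates, n, "average", cfg=cfg)
        loop_edges = find_loop_closures(
            frames, provisional, cfg.loop_closure, cfg.feature,
            cfg.estimation, cfg.uncertainty, seed=cfg.seed, features=features,
        )
    states, mode_info = states_for_mode(
        estimates, n, cfg.fusion_mode, loop_edges, cfg
    )
    middle_states = anchor_to_middle(states)
    pano = blend(frames, middle_states, cfg.panorama.interpolation)
    ssim = pairwise_ssim(
        frames, states, cfg.evaluation.d_max, cfg.evaluation.min_overlap_frac
    )
    report = {
        "n_frames": n,
        "middle_index": middle_index(n),
        "offset": [float(x) for x in pano.offset],
        "transforms_middle_anchored": [t.to_list() for t in middle_states],
        "ssim_means": {str(k): v for k, v in ssim.means.items()},
        "edges": [
            {
                "i": e.frame_i,
                "j": e.frame_j,
                "source": e.source,
                "loop": e.is_loop,
                "n_inliers": e.diagnostics.n_inliers,
                "n_correspondences": e.diagnostics.n_correspondences,
                "residual": None
                if not np.isfinite(e.diagnostics.residual)
                else e.diagnostics.residual,
                "omega_diag": [float(x) for x in np.diag(e.info)],
                "failed": e.failed,
            }
            for e in list(estimates) + loop_edges
        ],
        **mode_info,
    }
    return MosaicResult(pano, states, middle_states, ssim, report)


BENCHMARK_MODES = (
    "single:feature",
    "single:direct",
    "single:flow",
    "average",
    "fusion_no_lc",
    "fusion",
)


def run_benchmark(frames: list, cfg: RunConfig | None = None) -> dict:
    """All fusion modes on one input, sharing the per-pair estimates.

    Returns ``{"table": method -> distance means, "states": method ->
    states, "reports": method -> SsimReport}``.
    """
    cfg = cfg or RunConfig()
    n = len(frames)
    features = [extract_features(f, cfg.feature) for f in frames]
    estimates = estimate_pairs(frames, cfg, ("feature", "flow", "direct"), features)
    provisional, _ = states_for_mode(estimates, n, "average", cfg=cfg)
    loop_edges = find_loop_closures(
        frames, provisional, cfg.loop_closure, cfg.feature,
        cfg.estimation, cfg.uncertainty, seed=cfg.seed, features=features,
    ) if cfg.loop_closure.enabled else []

    states_by_mode = {}
    for mode in BENCHMARK_MODES:
        if mode == "fusion":
            states, _ = states_for_mode(estimates, n, "graph", loop_edges, cfg)
        elif mode == "fusion_no_lc":
            states, _ = states_for_mode(estimates, n, "graph", [], cfg)
        else:
            states, _ = states_for_mode(estimates, n, mode, cfg=cfg)
        states_by_mode[mode] = states

    reports = {
        mode: pairwise_ssim(
            frames, states, cfg.evaluation.d_max, cfg.evaluation.min_overlap_frac
        )
        for mode, states in states_by_mode.items()
    }
    return {
        "table": summarize(reports, cfg.evaluation.d_max),
        "states": states_by_mode,
        "reports": reports,
        "estimates": estimates,
        "loop_edges": loop_edges,
    }


def save_run(result: MosaicResult, out_dir: str | Path) -> None:
    """Write panorama PNG, transforms/report JSON and SSIM CSV."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    canvas = np.clip(result.panorama.canvas, 0, 1)
    iio.imwrite(out / "panorama.png", (canvas * 255).round().astype(np.uint8))
    (out / "report.json").write_text(json.dumps(result.report, indent=2))
    with open(out / "ssim.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["distance", "mean_ssim", "n_pairs"])
        for d in sorted(result.ssim.per_distance):
            vals = result.ssim.per_distance[d]
            writer.writerow([d, result.ssim.mean(d), len(vals)])


def save_benchmark(bench: dict, out_dir: str | Path, d_max: int = 5) -> None:
    """Write the method-by-distance mean-SSIM table as CSV + JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = bench["table"]
    with open(out / "benchmark.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["method"] + [f"d{d}" for d in range(1, d_max + 1)] + ["overall"])
        for method, row in table.items():
            writer.writerow(
                [method]
                + [row.get(d, float("nan")) for d in range(1, d_max + 1)]
                + [row["overall"]]
            )
    dists = {
        m: {str(d): v for d, v in r.per_distance.items()}
        for m, r in bench["reports"].items()
    }
    (out / "benchmark.json").write_text(json.dumps({"table": {m: {str(k): v for k, v in row.items()} for m, row in table.items()}, "distributions": dists}, indent=2))
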