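"""End-to-end pipeline: read -> crop -> filter -> segment -> track -> analyze.

The pipeline is deterministic for fixed inputs and configuration; every
run writes a manifest (configuration echo + library versions) sufficient
to reproduce it bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from . import __version__
from .filters import GuidedFilterParams
from .gearshift import GearReport, analyze_trial
from .io import ImageSequence, read_frames, read_torque_csv
from .lbf import LBFParams, RoiRect, segment_sequence
from .tracking import CentroidTrack, dwell_map, fill_missing, track_from_masks


@dataclass
class PipelineConfig:
    """Configuration of one analysis run.

    Defaults follow the nominal acquisition (25 frames/s, 0.1 mm/px) and
    the published algorithm parameters carried by
    :class:`~femurshift.filters.GuidedFilterParams` and
    :class:`~femurshift.lbf.LBFParams`.
    """

    frames: str = ""
    torque: str = ""
    outdir: str = "femurshift_out"
    roi: tuple = (0, 0, 0, 0)  # (top, left, bottom, right), half-open
    init_rects: tuple = ()  # ROI-local rectangles
    pixel_spacing: float = 0.1
    frame_rate: float = 25.0
    use_filter: bool = True
    guided: GuidedFilterParams = field(default_factory=GuidedFilterParams)
    lbf: LBFParams = field(default_factory=LBFParams)
    k: int = 3
    rest_threshold: float = 0.05
    max_gap: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        guided = GuidedFilterParams(**raw.pop("guided", {}))
        lbf = LBFParams(**raw.pop("lbf", {}))
        if "roi" in raw:
            raw["roi"] = tuple(raw["roi"])
        if "init_rects" in raw:
            raw["init_rects"] = tuple(tuple(r) for r in raw["init_rects"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(guided=guided, lbf=lbf, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["roi"] = list(self.roi)
        d["init_rects"] = [list(r) for r in self.init_rects]
        return d


@dataclass
class RunResult:
    """In-memory artifacts of one pipeline run."""

    report: GearReport
    track: CentroidTrack
    masks: list
    frame_meta: list
    dwell: np.ndarray


def run_arrays(
    sequence: ImageSequence,
    torque: np.ndarray,
    config: PipelineConfig,
) -> RunResult:
    """Run the analysis on in-memory arrays (no file I/O)."""
    if len(sequence) != np.asarray(torque).size:
        raise ValueError(
            f"sequence has {len(sequence)} frames but torque has "
            f"{np.asarray(torque).size} samples"
        )
    gf = config.guided if config.use_filter else None
    masks, meta = segment_sequence(
        sequence.frames, config.roi, config.init_rects, gf, config.lbf
    )
    track = track_from_masks(
        masks, pixel_spacing=config.pixel_spacing, frame_rate=config.frame_rate
    )
    track = fill_missing(track, max_gap=config.max_gap)
    report = analyze_trial(track, torque, k=config.k, rest_threshold=config.rest_threshold)
    dwell = dwell_map(masks)
    return RunResult(report=report, track=track, masks=masks, frame_meta=meta, dwell=dwell)


def _write_report_json(report: GearReport, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_overlay_plot(report: GearReport, track: CentroidTrack, torque, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_t, ax_xy) = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
    frames = np.arange(len(torque))
    ax_t.plot(frames, torque, color="k", lw=1)
    ax_t.set_ylabel("torque (MVC fraction)")
    ax_t.axvline(report.stages.peak_frame, color="tab:red", ls="--", label="peak")
    if report.stages.rest_onset is not None:
        ax_t.axvline(report.stages.rest_onset, color="tab:blue", ls="--", label="rest onset")
    for stage, cps in report.change_points.items():
        for cp in cps:
            ax_t.axvline(cp, color="tab:gray", ls=":", lw=0.8)
    ax_t.legend(loc="upper right", fontsize=8)

    ax_xy.plot(track.frames, track.x, label="x (mm)")
    ax_xy.plot(track.frames, track.y, label="y (mm)")
    for stage, cps in report.change_points.items():
        for cp in cps:
            ax_xy.axvline(cp, color="tab:gray", ls=":", lw=0.8)
    ax_xy.set_xlabel("frame")
    ax_xy.set_ylabel("centroid (mm)")
    ax_xy.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _write_dwell_images(dwell: np.ndarray, outdir: Path) -> None:
    iio.imwrite(outdir / "dwell_map.png", dwell.astype(np.uint16))
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(dwell, cmap="inferno")
    fig.colorbar(im, ax=ax, label="frames of femur occupancy")
    ax.set_title("femur dwell map")
    fig.tight_layout()
    fig.savefig(outdir / "dwell_map_colormap.png", dpi=120)
    plt.close(fig)


def write_artifacts(
    result: RunResult,
    torque: np.ndarray,
    config: PipelineConfig,
    outdir: str | Path,
) -> Path:
    """Write masks, track CSV, dwell map, gear report, tables, plots and
    the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    masks_dir = outdir / "masks"
    masks_dir.mkdir(exist_ok=True)
    for i, mask in enumerate(result.masks):
        if mask is not None:
            iio.imwrite(masks_dir / f"mask_{i:04d}.png", (mask * 255).astype(np.uint8))
    result.track.to_dataframe().to_csv(outdir / "track.csv", index=False)
    _write_dwell_images(result.dwell, outdir)
    _write_report_json(result.report, outdir / "gear_report.json")
    result.report.variance_table().to_csv(outdir / "cluster_variances.csv", index=False)
    result.report.distance_table().to_csv(outdir / "pair_distances.csv", index=False)
    with open(outdir / "convergence.csv", "w") as fh:
        fh.write("frame,n_iter,converged,final_energy,missing\n")
        for m in result.frame_meta:
            fh.write(
                f"{m.frame},{m.n_iter},{int(m.converged)},"
                f"{float(m.final_energy)!r},{int(m.missing)}\n"
            )
    _write_overlay_plot(result.report, result.track, torque, outdir / "overlay.png")

    manifest = {
        "config": config.to_dict(),
        "versions": {
            "femurshift": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir


def run(config: PipelineConfig) -> RunResult:
    """Run the full pipeline from files and write all artifacts."""
    sequence = read_frames(
        config.frames, frame_rate=config.frame_rate, pixel_spacing=config.pixel_spacing
    )
    torque = read_torque_csv(config.torque, n_frames=len(sequence))
    result = run_arrays(sequence, torque, config)
    write_artifacts(result, torque, config, config.outdir)
    return result
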