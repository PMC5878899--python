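"""Synthetic B-mode trial generator with known ground truth.

Emulates the statistical structure the downstream analysis assumes: a
triangular torque ramp up to 0.9 MVC, a femur centroid that dwells at
three gear positions during contraction and three during relaxation, and
grayscale frames with a bright bone interface, posterior acoustic shadow,
smooth intensity inhomogeneity, and multiplicative gamma speckle.  Every
generator is reproducible from its seed, and masks / centroids / change
points are returned as ground truth so each pipeline stage can be scored.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .tracking import CentroidTrack

#: temporal cluster order over the whole trial
GEAR_ORDER = ("#A", "#B", "#C", "#C'", "#B'", "#A'")


@dataclass
class TrialDesign:
    """Design of one isometric contraction-relaxation trial.

    The defaults describe the nominal study conditions: 240 frames at
    25 frames/s, a triangular torque ramp to 0.9 MVC, three contraction
    gear positions and three relaxation gear positions (given in temporal
    order: the relaxation sequence is #C', #B', #A'), with per-gear
    positional jitter in mm.  The default relaxation end (#A') sits 2 mm
    away from the contraction start (#A), modelling incomplete return of
    the muscle to its initial configuration, while #B'/#C' return exactly
    to the #B/#C positions.
    """

    n_frames: int = 240
    frame_rate: float = 25.0
    peak_torque: float = 0.9
    ramp_up_frames: int = 100
    ramp_down_frames: int = 100
    rest_frames: int = 40
    gear_positions_contraction: tuple = ((4.0, 6.0), (7.0, 4.5), (9.2, 3.5))
    gear_positions_relaxation: tuple = ((9.2, 3.5), (7.0, 4.5), (5.2, 7.6))
    dwell_noise_sd: tuple = (0.2, 0.2, 0.2, 0.2, 0.4, 0.1)
    transition_frames: int = 4
    torque_noise_sd: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.ramp_up_frames + self.ramp_down_frames + self.rest_frames != self.n_frames:
            raise ValueError(
                f"frame budget mismatch: ramp_up ({self.ramp_up_frames}) + "
                f"ramp_down ({self.ramp_down_frames}) + rest ({self.rest_frames}) "
                f"!= n_frames ({self.n_frames})"
            )
        if not 0 < self.peak_torque <= 1:
            raise ValueError("peak_torque must be in (0, 1]")
        if len(self.gear_positions_contraction) != 3 or len(self.gear_positions_relaxation) != 3:
            raise ValueError("exactly 3 gear positions per stage are required")
        if len(self.dwell_noise_sd) != 6:
            raise ValueError("dwell_noise_sd needs 6 values (3 contraction + 3 relaxation)")
        for stage_len, name in (
            (self.ramp_up_frames + 1, "contraction"),
            (self.ramp_down_frames, "relaxation"),
        ):
            n_gears = 3
            if stage_len - 2 * self.transition_frames < 3 * n_gears:
                raise ValueError(
                    f"{name} stage too short for {n_gears} dwells of >= 3 frames "
                    f"with {self.transition_frames}-frame transitions"
                )
        for positions in (self.gear_positions_contraction, self.gear_positions_relaxation):
            pts = [tuple(p) for p in positions]
            if len(set(pts)) != len(pts):
                raise ValueError("gear positions within a stage must be pairwise distinct")


@dataclass
class PhantomParams:
    """Rendering parameters of the B-mode phantom.

    The femur appears as a bright dome (the upper half-disk of radius
    ``femur_arc_radius`` mm, its curved boundary being the bone
    interface) with an attenuated acoustic shadow strictly below it.  A
    linear intensity ramp across the image emulates field inhomogeneity,
    and multiplicative unit-mean gamma noise with shape ``speckle_shape``
    emulates speckle (variance 1/shape; the default shape of 25 gives the
    ~20% contrast typical of log-compressed display speckle);
    ``speckle_shape`` of None or 0 disables speckle.
    """

    image_height: int = 96
    image_width: int = 128
    pixel_spacing: float = 0.1
    femur_arc_radius: float = 3.0
    interface_brightness: float = 190.0
    shadow_attenuation: float = 0.35
    background_level: float = 70.0
    speckle_shape: float | None = 25.0
    inhomogeneity_amplitude: float = 20.0

    def validate(self) -> None:
        for name in ("interface_brightness", "background_level"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name} must lie in [0, 255], got {v}")
        if not 0 < self.shadow_attenuation < 1:
            raise ValueError("shadow_attenuation must lie in (0, 1)")
        if self.speckle_shape is not None and self.speckle_shape < 0:
            raise ValueError("speckle_shape must be >= 0 or None")


@dataclass
class GroundTruth:
    """Per-trial ground truth for scoring every pipeline stage."""

    true_masks: np.ndarray | None
    true_centroids: np.ndarray  # (n, 2) mm, (x, y)
    true_change_points: dict  # stage -> absolute after-index frame indices
    true_stage_boundaries: tuple  # (peak frame, rest-onset frame)


def ideal_torque(design: TrialDesign) -> np.ndarray:
    """Noiseless piecewise-linear torque trace (MVC fraction per frame)."""
    f = np.arange(design.n_frames, dtype=float)
    up, down = design.ramp_up_frames, design.ramp_down_frames
    trace = np.where(
        f <= up,
        design.peak_torque * f / up,
        np.where(f <= up + down, design.peak_torque * (up + down - f) / down, 0.0),
    )
    return np.maximum(trace, 0.0)


def generate_torque_trace(design: TrialDesign) -> np.ndarray:
    """Torque trace: triangular ramp 0 -> peak -> 0 then rest, with
    additive Gaussian noise of sd ``torque_noise_sd``, clipped to [0, 1]."""
    design.validate()
    trace = ideal_torque(design)
    if design.torque_noise_sd > 0:
        rng = np.random.default_rng([design.seed, 1])
        trace = trace + rng.normal(0.0, design.torque_noise_sd, size=trace.shape)
    return np.clip(trace, 0.0, 1.0)


def design_stage_boundaries(design: TrialDesign, rest_threshold: float = 0.05) -> tuple[int, int]:
    """(peak frame, rest-onset frame) implied by the noiseless torque."""
    trace = ideal_torque(design)
    peak = int(np.argmax(trace))
    below = np.nonzero(trace[peak + 1 :] < rest_threshold)[0]
    rest_onset = peak + 1 + int(below[0]) if below.size else design.n_frames
    return peak, rest_onset


def _stage_layout(length: int, transition: int) -> np.ndarray:
    """Per-frame gear id (0/1/2) for one stage; transition frames are
    attributed half to the earlier gear, half to the later."""
    dwell_total = length - 2 * transition
    base, extra = divmod(dwell_total, 3)
    dwells = [base + (1 if i < extra else 0) for i in range(3)]
    ids = []
    for g in range(3):
        ids.extend([g] * dwells[g])
        if g < 2:
            first_half = (transition + 1) // 2
            ids.extend([g] * first_half)
            ids.extend([g + 1] * (transition - first_half))
    return np.asarray(ids, dtype=int)


def _stage_positions(
    length: int,
    transition: int,
    gears: np.ndarray,
    sds: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[int]]:
    """Noisy dwelling trajectory for one stage plus local change points
    (after-index of the last frame of each of the first two gears)."""
    dwell_total = length - 2 * transition
    base, extra = divmod(dwell_total, 3)
    dwells = [base + (1 if i < extra else 0) for i in range(3)]
    pos = np.empty((length, 2))
    sd = np.empty(length)
    cursor = 0
    for g in range(3):
        pos[cursor : cursor + dwells[g]] = gears[g]
        sd[cursor : cursor + dwells[g]] = sds[g]
        cursor += dwells[g]
        if g < 2:
            for t in range(transition):
                frac = (t + 1) / (transition + 1)
                pos[cursor + t] = gears[g] * (1 - frac) + gears[g + 1] * frac
                sd[cursor + t] = 0.5 * (sds[g] + sds[g + 1])
            cursor += transition
    ids = _stage_layout(length, transition)
    change_points = [int(np.nonzero(ids == g)[0][-1]) for g in (0, 1)]
    noisy = pos + rng.normal(size=pos.shape) * sd[:, None]
    return noisy, change_points


def generate_gear_trajectory(
    design: TrialDesign, rest_threshold: float = 0.05
) -> tuple[CentroidTrack, GroundTruth]:
    """Piecewise-dwelling centroid trajectory plus its ground truth.

    The centroid dwells at the three contraction gears over frames
    [0, peak], at the three relaxation gears over (peak, rest onset), and
    stays at the last relaxation gear during rest.  Motion between gears
    is linear over ``transition_frames`` frames; each dwell adds isotropic
    Gaussian jitter with its configured sd.  True change points are the
    after-index frame of the last frame attributed to each gear
    (transition frames split evenly between neighbours).
    """
    design.validate()
    rng = np.random.default_rng([design.seed, 2])
    peak, rest_onset = design_stage_boundaries(design, rest_threshold)
    gc = np.asarray(design.gear_positions_contraction, dtype=float)
    gr = np.asarray(design.gear_positions_relaxation, dtype=float)
    sds = np.asarray(design.dwell_noise_sd, dtype=float)

    len_con = peak + 1
    len_rel = rest_onset - peak - 1
    pos_con, cp_con = _stage_positions(len_con, design.transition_frames, gc, sds[:3], rng)
    pos_rel, cp_rel = _stage_positions(len_rel, design.transition_frames, gr, sds[3:], rng)
    len_rest = design.n_frames - rest_onset
    pos_rest = gr[2] + rng.normal(size=(len_rest, 2)) * sds[5]

    pos = np.concatenate([pos_con, pos_rel, pos_rest], axis=0)
    track = CentroidTrack(
        frames=np.arange(design.n_frames),
        x=pos[:, 0],
        y=pos[:, 1],
        missing=np.zeros(design.n_frames, dtype=bool),
        frame_rate=design.frame_rate,
    )
    truth = GroundTruth(
        true_masks=None,
        true_centroids=pos.copy(),
        true_change_points={
            "contraction": [c for c in cp_con],
            "relaxation": [peak + 1 + c for c in cp_rel],
        },
        true_stage_boundaries=(peak, rest_onset),
    )
    return track, truth


def _dome_geometry(phantom: PhantomParams) -> tuple[float, float]:
    """(radius in px, row offset of the dome's flat-side center above which
    the half-disk centroid sits).  The half-disk centroid lies 4R/(3 pi)
    above the flat side, so the flat-side row is placed that far below the
    requested centroid row."""
    r_px = phantom.femur_arc_radius / phantom.pixel_spacing
    return r_px, 4.0 * r_px / (3.0 * math.pi)


def render_frame(
    x_mm: float,
    y_mm: float,
    phantom: PhantomParams,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one frame and its femur mask for a centroid at (x, y) mm."""
    phantom.validate()
    H, W = phantom.image_height, phantom.image_width
    r_px, centroid_drop = _dome_geometry(phantom)
    c0 = x_mm / phantom.pixel_spacing
    r0 = y_mm / phantom.pixel_spacing + centroid_drop
    if r0 - r_px < -0.5 or r0 > H - 0.5 or c0 - r_px < -0.5 or c0 + r_px > W - 0.5:
        raise ValueError("femur leaves the field of view")

    rr, cc = np.mgrid[0:H, 0:W]
    dome = ((rr - r0) ** 2 + (cc - c0) ** 2 <= r_px**2) & (rr <= r0)
    shadow = (rr > r0) & (np.abs(cc - c0) <= r_px)

    img = np.full((H, W), phantom.background_level)
    img[shadow] = phantom.background_level * phantom.shadow_attenuation
    img[dome] = phantom.interface_brightness
    if phantom.inhomogeneity_amplitude:
        img = img + phantom.inhomogeneity_amplitude * (cc / max(W - 1, 1))
    if phantom.speckle_shape and rng is not None:
        img = img * rng.gamma(phantom.speckle_shape, 1.0 / phantom.speckle_shape, size=img.shape)
    return np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8), dome


def render_sequence(
    track: CentroidTrack,
    phantom: PhantomParams,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render every frame of a trajectory.

    Returns (frames uint8 (n, H, W), masks bool (n, H, W)).  Raises with
    the offending frame index if the femur leaves the field of view.
    """
    phantom.validate()
    rng = np.random.default_rng([seed, 3])
    frames = np.empty((len(track), phantom.image_height, phantom.image_width), dtype=np.uint8)
    masks = np.empty((len(track), phantom.image_height, phantom.image_width), dtype=bool)
    for i in range(len(track)):
        try:
            frames[i], masks[i] = render_frame(track.x[i], track.y[i], phantom, rng)
        except ValueError as exc:
            raise ValueError(f"frame {i}: {exc}") from exc
    return frames, masks


@dataclass
class SyntheticTrial:
    """One fully rendered synthetic trial with its ground truth."""

    design: TrialDesign
    phantom: PhantomParams
    torque: np.ndarray
    track: CentroidTrack
    truth: GroundTruth
    frames: np.ndarray | None = None
    masks: np.ndarray | None = None


def generate_trial(
    design: TrialDesign | None = None,
    phantom: PhantomParams | None = None,
    render: bool = True,
) -> SyntheticTrial:
    """Generate torque, trajectory and (optionally) rendered frames."""
    design = design or TrialDesign()
    phantom = phantom or PhantomParams()
    torque = generate_torque_trace(design)
    track, truth = generate_gear_trajectory(design)
    frames = masks = None
    if render:
        frames, masks = render_sequence(track, phantom, seed=design.seed)
        truth = GroundTruth(
            true_masks=masks,
            true_centroids=truth.true_centroids,
            true_change_points=truth.true_change_points,
            true_stage_boundaries=truth.true_stage_boundaries,
        )
    return SyntheticTrial(
        design=design,
        phantom=phantom,
        torque=torque,
        track=track,
        truth=truth,
        frames=frames,
        masks=masks,
    )


def write_fixture(trial: SyntheticTrial, outdir: str | Path) -> Path:
    """Write a trial to disk as a pipeline-ready fixture.

    Layout: ``frames/frame_0000.png`` ..., ``masks/mask_0000.png`` ...,
    ``torque.csv`` (frame_index, torque_mvc_fraction) and
    ``ground_truth.json`` (change points, stage boundaries, design echo).
    """
    outdir = Path(outdir)
    (outdir / "frames").mkdir(parents=True, exist_ok=True)
    if trial.frames is None:
        raise ValueError("trial was generated without rendering; nothing to write")
    for i, frame in enumerate(trial.frames):
        iio.imwrite(outdir / "frames" / f"frame_{i:04d}.png", frame)
    (outdir / "masks").mkdir(exist_ok=True)
    for i, mask in enumerate(trial.masks):
        iio.imwrite(outdir / "masks" / f"mask_{i:04d}.png", (mask * 255).astype(np.uint8))
    with open(outdir / "torque.csv", "w") as fh:
        fh.write("frame_index,torque_mvc_fraction\n")
        for i, t in enumerate(trial.torque):
            fh.write(f"{i},{float(t)!r}\n")
    truth = {
        "true_change_points": trial.truth.true_change_points,
        "true_stage_boundaries": list(trial.truth.true_stage_boundaries),
        "true_centroids_mm": [[float(x), float(y)] for x, y in trial.truth.true_centroids],
        "design": asdict(trial.design),
        "phantom": asdict(trial.phantom),
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return outdir
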