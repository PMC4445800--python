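"""Synthetic circadian traces and oscillating-blob image sequences.

Two generators make every downstream stage testable without real plant
imagery:

* :func:`simulate_trace` draws 1-D decaying noisy cosines — the standard
  parameter-recovery design for rhythm estimators: a cosine of known
  period with one of three amplitude-decay trends (decay rates 0, 0.001,
  0.002 per sample) and one of three additive white-noise levels (sd 0.2,
  0.6, 1.0 in units of the initial amplitude).
* :func:`simulate_image_sequence` renders a smooth Gaussian-profile blob
  whose vertical center oscillates with known period, with subpixel
  accuracy, standing in for a computer-generated plant with precisely
  known motion.  Per-step displacement is kept inside the small-motion
  regime that the differential motion estimator's linearization assumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .cropgrid import ImageStack
from .trace import Trace

__all__ = [
    "TREND_DECAY",
    "NOISE_SD",
    "SimulationSpec",
    "BlobSceneSpec",
    "simulate_trace",
    "simulate_image_sequence",
    "simulation_grid",
    "write_image_sequence",
]

#: Amplitude-trend decay rates, per sample (exponential envelope).
TREND_DECAY = {"I": 0.0, "II": 0.001, "III": 0.002}

#: Noise standard deviations in units of the initial amplitude.
NOISE_SD = {"A": 0.2, "B": 0.6, "C": 1.0}

_SEED_MASK = 0x7FFFFFFF  # keep derived seeds below 2**31


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated-trace condition.

    ``true_period`` is in hours; ``amplitude_trend`` is one of I/II/III
    (envelope decay rates 0 / 0.001 / 0.002 per sample); ``noise_level``
    one of A/B/C (noise sd 0.2 / 0.6 / 1.0 x initial amplitude).
    """

    true_period: float
    amplitude_trend: str = "I"
    noise_level: str = "A"
    sampling_interval: float = 20.0  # minutes
    duration: float = 120.0  # hours
    n_replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_trend not in TREND_DECAY:
            raise ValueError(
                f"amplitude_trend must be one of {sorted(TREND_DECAY)}, "
                f"got {self.amplitude_trend!r}"
            )
        if self.noise_level not in NOISE_SD:
            raise ValueError(
                f"noise_level must be one of {sorted(NOISE_SD)}, "
                f"got {self.noise_level!r}"
            )
        if self.true_period <= 0:
            raise ValueError("true_period must be positive")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.duration < 2 * self.true_period:
            raise ValueError(
                "duration must cover at least 2 full periods "
                f"({self.duration} h < 2 x {self.true_period} h); period "
                "estimation is unreliable below two cycles"
            )
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    @property
    def decay_rate(self) -> float:
        return TREND_DECAY[self.amplitude_trend]

    @property
    def noise_sd(self) -> float:
        return NOISE_SD[self.noise_level]

    @property
    def condition_label(self) -> str:
        """Compact label, e.g. ``24I_A`` for 24 h, trend I, noise A."""
        return f"{self.true_period:g}{self.amplitude_trend}_{self.noise_level}"


def _time_grid(duration: float, sampling_interval: float) -> np.ndarray:
    step_h = sampling_interval / 60.0
    n = int(np.floor(duration / step_h + 1e-9)) + 1
    return np.arange(n) * step_h


def simulate_trace(spec: SimulationSpec, replicate_index: int = 0) -> Trace:
    """Draw one replicate trace.

    The signal is ``env(i) * cos(2*pi*t_i / period) + eps_i`` where
    ``env(i) = exp(-r*i)`` with the trend's per-sample decay rate ``r``
    and ``eps`` is iid zero-mean Gaussian noise with the level's sd
    (initial amplitude = 1).  Deterministic given ``(spec.seed,
    replicate_index)``: each replicate uses its own independent stream.
    """
    if replicate_index < 0:
        raise ValueError("replicate_index must be non-negative")
    t = _time_grid(spec.duration, spec.sampling_interval)
    idx = np.arange(t.size)
    env = np.exp(-spec.decay_rate * idx)
    signal = env * np.cos(2 * np.pi * t / spec.true_period)
    rng = np.random.default_rng([spec.seed, replicate_index])
    noise = rng.normal(0.0, spec.noise_sd, size=t.size) if spec.noise_sd > 0 else 0.0
    return Trace(
        t,
        signal + noise,
        spec.sampling_interval,
        plant_id=f"{spec.condition_label}_rep{replicate_index}",
    )


def simulation_grid(
    periods: list[float],
    trends: list[str] = ("I", "II", "III"),
    noise_levels: list[str] = ("A", "B", "C"),
    *,
    n_replicates: int = 10,
    sampling_interval: float = 20.0,
    duration: float = 120.0,
    base_seed: int = 0,
) -> list[SimulationSpec]:
    """Build the full condition grid with decorrelated per-condition seeds.

    Condition order is (period, trend, noise), row-major.  Each condition
    receives a seed drawn deterministically from ``base_seed`` so that
    noise realizations are independent across conditions yet reproducible.
    """
    combos = [(p, tr, nz) for p in periods for tr in trends for nz in noise_levels]
    seeds = np.random.SeedSequence(base_seed).generate_state(len(combos)) & _SEED_MASK
    return [
        SimulationSpec(
            true_period=float(p),
            amplitude_trend=tr,
            noise_level=nz,
            sampling_interval=sampling_interval,
            duration=duration,
            n_replicates=n_replicates,
            seed=int(s),
        )
        for (p, tr, nz), s in zip(combos, seeds)
    ]


@dataclass(frozen=True)
class BlobSceneSpec:
    """A plant-like Gaussian blob oscillating vertically with known period.

    The blob's vertical center follows ``y0 + A*cos(2*pi*t/period)``; the
    frame is rendered analytically at pixel centers so subpixel positions
    are exact.  The per-step center displacement implied by amplitude,
    period and frame interval must stay <= 2 px — the small-motion regime
    in which the one-shot linearized translation solve is valid.
    """

    frame_size: tuple[int, int] = (120, 120)  # (height, width) px
    blob_sigma: tuple[float, float] = (12.0, 8.0)  # (sigma_y, sigma_x) px
    center: tuple[float, float] | None = None  # (y, x); default frame center
    oscillation_amplitude: float = 6.0  # px
    true_period: float = 24.0  # hours
    background_level: float = 0.05
    foreground_level: float = 0.9
    noise_sd: float = 0.0
    sampling_interval: float = 20.0  # minutes
    duration: float = 120.0  # hours
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.frame_size
        if h < 16 or w < 16:
            raise ValueError("frame_size too small to render a blob")
        if self.true_period <= 0 or self.sampling_interval <= 0:
            raise ValueError("true_period and sampling_interval must be positive")
        if self.oscillation_amplitude < 0:
            raise ValueError("oscillation_amplitude must be >= 0")
        step_h = self.sampling_interval / 60.0
        max_step = 2 * self.oscillation_amplitude * np.sin(
            np.pi * min(step_h / self.true_period, 0.5)
        )
        if max_step > 2.0:
            raise ValueError(
                f"per-step displacement {max_step:.2f} px exceeds the 2 px "
                "small-motion limit of the linearized translation model; "
                "reduce amplitude or frame interval"
            )
        if not (0 <= self.background_level < self.foreground_level <= 1):
            raise ValueError("need 0 <= background < foreground <= 1")
        if self.noise_sd > 0 and (
            self.foreground_level - self.background_level <= 5 * self.noise_sd
        ):
            raise ValueError(
                "foreground/background contrast must exceed 5x noise_sd"
            )

    @property
    def center_yx(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        h, w = self.frame_size
        return ((h - 1) / 2.0, (w - 1) / 2.0)


def render_blob_frame(scene: BlobSceneSpec, center_y: float, center_x: float) -> np.ndarray:
    """Render one noise-free frame with the blob at a subpixel position."""
    h, w = scene.frame_size
    yy = np.arange(h, dtype=float)[:, None]
    xx = np.arange(w, dtype=float)[None, :]
    sy, sx = scene.blob_sigma
    profile = np.exp(
        -((yy - center_y) ** 2) / (2 * sy**2) - ((xx - center_x) ** 2) / (2 * sx**2)
    )
    return scene.background_level + (
        scene.foreground_level - scene.background_level
    ) * profile


def simulate_image_sequence(scene: BlobSceneSpec) -> ImageStack:
    """Render the full oscillating-blob frame sequence.

    Deterministic given ``scene.seed``.  Frames are float images in [0, 1]
    at the stated frame interval; optional iid Gaussian pixel noise is
    added and clipped to the valid intensity range.
    """
    t = _time_grid(scene.duration, scene.sampling_interval)
    cy0, cx0 = scene.center_yx
    centers_y = cy0 + scene.oscillation_amplitude * np.cos(
        2 * np.pi * t / scene.true_period
    )
    rng = np.random.default_rng(scene.seed)
    frames = np.empty((t.size, *scene.frame_size), dtype=float)
    for i, cy in enumerate(centers_y):
        frame = render_blob_frame(scene, cy, cx0)
        if scene.noise_sd > 0:
            frame = np.clip(frame + rng.normal(0, scene.noise_sd, frame.shape), 0, 1)
        frames[i] = frame
    source_ids = [f"frame_{i:04d}" for i in range(t.size)]
    return ImageStack(frames, scene.sampling_interval, source_ids)


def write_image_sequence(
    stack: ImageStack,
    directory: str | Path,
    *,
    fmt: str = "png",
    metadata: dict | None = None,
) -> Path:
    """Write a stack as numbered 8-bit image files plus a JSON sidecar."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(stack.frames):
        img = np.clip(np.round(frame * 255.0), 0, 255).astype(np.uint8)
        iio.imwrite(directory / f"frame_{i:04d}.{fmt}", img)
    meta = {"sampling_interval_min": stack.sampling_interval, "n_frames": len(stack)}
    if metadata:
        meta.update(metadata)
    with open(directory / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return directory
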