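"""Moving-bar stimuli and the camera-emulation pipeline.

A stimulus "direction step" is a binary 6 x 1000 frame: each of the 6 rows
feeds one unit of the microcircuit and each of the 1000 columns is one
millisecond of the step. A black pixel (1) at row j, column t delivers a
presynaptic spike to unit j at time t ms, so the number of spikes a unit
receives equals the number of 1s in its row -- a wider bar means a higher
input frequency, and shifting the bar shifts spike timing.

The default experiment is a bidirectional sweep of a full-height vertical
bar: 200 steps, the first 100 moving rightward and the last 100 leftward.
Each step also carries a pair of initial release probabilities (one per
subpopulation) drawn from a mirrored direction-dependent schedule; this
schedule is what makes the two subpopulations direction selective.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .synapses import validate_spike_train

__all__ = [
    "N_ROWS",
    "N_COLS",
    "BinaryFrame",
    "DirectionSequence",
    "make_bar_frame",
    "make_direction_sequence",
    "u_schedule",
    "downsample_camera",
    "frame_to_spikes",
]

N_ROWS = 6
N_COLS = 1000
#: native rows of the (emulated) camera before the 100 -> 6 reduction
CAMERA_ROWS = 100


@dataclass(frozen=True)
class BinaryFrame:
    """One binary stimulus frame of exactly 6 x 1000 {0, 1} pixels."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.shape != (N_ROWS, N_COLS):
            raise ValueError(f"frame must be {N_ROWS} x {N_COLS}, got {p.shape}")
        if not np.isin(p, (0, 1)).all():
            raise ValueError("frame entries must be 0 or 1")
        object.__setattr__(self, "pixels", p.astype(np.uint8))

    @property
    def n_pixels(self) -> int:
        return self.pixels.size

    @property
    def n_ones(self) -> int:
        return int(self.pixels.sum())

    def to_csv(self, path) -> None:
        np.savetxt(path, self.pixels, fmt="%d", delimiter=",")

    @classmethod
    def from_csv(cls, path) -> "BinaryFrame":
        return cls(np.loadtxt(path, delimiter=",", dtype=int))

    def to_pgm(self, path) -> None:
        """Write as a portable graymap (1 = black pixel = value 0)."""
        from PIL import Image

        img = Image.fromarray(((1 - self.pixels) * 255).astype(np.uint8), mode="L")
        img.save(path, format="PPM")

    @classmethod
    def from_pgm(cls, path, threshold: float = 0.5) -> "BinaryFrame":
        """Read a graymap; intensities below ``threshold`` (of max) are 1."""
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("L"), dtype=float) / 255.0
        return cls((arr < threshold).astype(np.uint8))


@dataclass
class DirectionSequence:
    """An ordered bidirectional stimulus sweep.

    Attributes
    ----------
    frames : list[BinaryFrame]
        One frame per direction step.
    directions : list[str]
        Per-step motion label, ``"right"`` or ``"left"``.
    u_pairs : list[tuple[float, float]]
        Per-step initial release probabilities ``(U1, U2)`` recruited by
        subpopulation 1 and subpopulation 2 respectively.
    step_duration : float
        Duration of each step in ms (the frame's column axis), default 1000.
    """

    frames: list
    directions: list
    u_pairs: list
    step_duration: float = 1000.0

    def __post_init__(self) -> None:
        if not (len(self.frames) == len(self.directions) == len(self.u_pairs)):
            raise ValueError("frames, directions and u_pairs must have equal length")
        for d in self.directions:
            if d not in ("right", "left"):
                raise ValueError(f"direction must be 'right' or 'left', got {d!r}")
        for u1, u2 in self.u_pairs:
            if not (0 < u1 <= 1 and 0 < u2 <= 1):
                raise ValueError("release probabilities must lie in (0, 1]")
        if self.step_duration <= 0:
            raise ValueError("step_duration must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    def save(self, directory) -> None:
        """Write frames as CSV plus a JSON manifest into ``directory``."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        names = []
        for i, frame in enumerate(self.frames):
            name = f"frame_{i:04d}.csv"
            frame.to_csv(d / name)
            names.append(name)
        manifest = {
            "frames": names,
            "directions": list(self.directions),
            "u_pairs": [[float(a), float(b)] for a, b in self.u_pairs],
            "step_duration": self.step_duration,
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory) -> "DirectionSequence":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        frames = [BinaryFrame.from_csv(d / name) for name in manifest["frames"]]
        return cls(
            frames=frames,
            directions=manifest["directions"],
            u_pairs=[tuple(p) for p in manifest["u_pairs"]],
            step_duration=manifest["step_duration"],
        )


def make_bar_frame(
    bar_position: int,
    bar_width: int,
    noise_prob: float = 0.0,
    rng_seed: int = 0,
    wrap: bool = False,
) -> BinaryFrame:
    """Render a full-height vertical bar into a binary frame.

    Columns ``[bar_position, bar_position + bar_width)`` are set to 1 in
    every row; by default the bar is clipped at the right edge, with
    ``wrap=True`` it wraps around the 1000-column axis (keeping the pixel
    count constant for any position). Every remaining pixel is flipped to 1
    independently with probability ``noise_prob``, reproducibly for a given
    ``rng_seed``.
    """
    if not 0 <= bar_position < N_COLS:
        raise ValueError(f"bar_position must lie in [0, {N_COLS}), got {bar_position}")
    if bar_width < 1:
        raise ValueError("bar_width must be >= 1")
    if not 0 <= noise_prob < 1:
        raise ValueError("noise_prob must lie in [0, 1)")
    pixels = np.zeros((N_ROWS, N_COLS), dtype=np.uint8)
    cols = np.arange(bar_position, bar_position + bar_width)
    cols = cols[cols < N_COLS] if not wrap else cols % N_COLS
    pixels[:, cols] = 1
    if noise_prob > 0:
        rng = np.random.default_rng(rng_seed)
        flips = rng.random((N_ROWS, N_COLS)) < noise_prob
        pixels[flips & (pixels == 0)] = 1
    return BinaryFrame(pixels)


def u_schedule(n_steps: int = 200, U_min: float = 0.05, U_max: float = 0.6) -> list:
    """Direction-dependent schedule of initial release probability pairs.

    The first half of the steps is rightward motion, the second half
    leftward. Subpopulation 1 recruits an ascending ramp through the upper
    half-range ``(mid, U_max]`` on right steps and through the lower
    half-range ``[U_min, mid)`` on left steps, where ``mid`` is the
    midpoint; subpopulation 2 recruits the same two ramps with the blocks
    swapped. Consequences, by construction:

    * mean U1 over right steps > mean U1 over left steps (and vice versa
      for U2) -- the source of the opposite direction preferences;
    * the per-step values of subpop 1 during right motion are identical,
      step for step, to those of subpop 2 during left motion (mirror
      symmetry), so the two preferred-direction release-probability
      trajectories coincide exactly.
    """
    if n_steps % 2:
        raise ValueError("n_steps must be even")
    if not 0 < U_min < U_max <= 1:
        raise ValueError("need 0 < U_min < U_max <= 1")
    half = n_steps // 2
    mid = 0.5 * (U_min + U_max)
    preferred = np.linspace(mid, U_max, half + 1)[1:]   # (mid, U_max]
    null = np.linspace(U_min, mid, half + 1)[:-1]       # [U_min, mid)
    u1 = np.concatenate([preferred, null])
    u2 = np.concatenate([null, preferred])
    return [(float(a), float(b)) for a, b in zip(u1, u2)]


def make_direction_sequence(
    n_steps: int = 200,
    bar_width: int = 50,
    shift_per_step: int = 5,
    noise_prob: float = 0.0,
    rng_seed: int = 0,
    U_min: float = 0.05,
    U_max: float = 0.6,
    step_duration: float = 1000.0,
) -> DirectionSequence:
    """Build the default bidirectional moving-bar sweep.

    The bar starts at column 0 and moves rightward by ``shift_per_step``
    columns per step for the first ``n_steps / 2`` steps, then retraces
    leftward for the second half; positions wrap around the frame edge so
    every step delivers the same number of spikes. Per-step noise pixels
    (if any) are seeded independently per step from ``rng_seed``.
    """
    if n_steps % 2:
        raise ValueError("n_steps must be even")
    if shift_per_step < 1:
        raise ValueError("shift_per_step must be >= 1")
    half = n_steps // 2
    positions = []
    pos = 0
    for _ in range(half):
        positions.append(pos % N_COLS)
        pos += shift_per_step
    pos -= shift_per_step
    for _ in range(half):
        pos -= shift_per_step
        positions.append(pos % N_COLS)
    directions = ["right"] * half + ["left"] * half
    rng = np.random.default_rng(rng_seed)
    step_seeds = rng.integers(0, 2**31 - 1, size=n_steps)
    frames = [
        make_bar_frame(p, bar_width, noise_prob, rng_seed=int(s), wrap=True)
        for p, s in zip(positions, step_seeds)
    ]
    return DirectionSequence(
        frames=frames,
        directions=directions,
        u_pairs=u_schedule(n_steps, U_min, U_max),
        step_duration=step_duration,
    )


def downsample_camera(raw) -> BinaryFrame:
    """Reduce a 100 x 1000 binary camera image to the 6 x 1000 network input.

    The 100 camera rows are partitioned into 6 nearly equal contiguous
    blocks (17/17/17/17/16/16); each output row is the logical OR of its
    block, so a black pixel anywhere in a unit's receptive strip triggers
    a spike for that unit.
    """
    raw = np.asarray(raw)
    if raw.shape != (CAMERA_ROWS, N_COLS):
        raise ValueError(f"raw image must be {CAMERA_ROWS} x {N_COLS}, got {raw.shape}")
    if not np.isin(raw, (0, 1)).all():
        raise ValueError("raw image entries must be 0 or 1")
    sizes = np.full(N_ROWS, CAMERA_ROWS // N_ROWS)
    sizes[: CAMERA_ROWS % N_ROWS] += 1  # 17/17/17/17/16/16
    edges = np.concatenate([[0], np.cumsum(sizes)])
    pixels = np.stack(
        [raw[edges[i]:edges[i + 1]].any(axis=0) for i in range(N_ROWS)]
    ).astype(np.uint8)
    return BinaryFrame(pixels)


def frame_to_spikes(frame: BinaryFrame) -> list:
    """Convert a frame to one presynaptic spike train per row.

    Unit j receives a spike at time t ms iff ``pixels[j, t] == 1``, so each
    train's length equals its row sum (pixel/spike conservation).
    """
    return [
        validate_spike_train(np.flatnonzero(frame.pixels[j]).astype(float))
        for j in range(N_ROWS)
    ]
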