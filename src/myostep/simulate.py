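"""Stochastic simulators for processive-motor experiments.

Everything the analysis chain consumes can be generated here:

* :func:`simulate_stepping` - continuous-time Markov (Gillespie)
  realizations of load-dependent stepping: three competing exponential
  clocks (forward step, backward step, detachment) whose rates follow
  Bell-type exponentials on the branch matching the force sign;
* :func:`simulate_clamp_record` - ultrafast force-clamp dumbbell
  records: triangular oscillation of the unbound dumbbell inside a
  window [0, D], stochastic attachment, staircase stepping while bound,
  window-edge truncation of assistive runs, Gaussian position noise;
* :func:`simulate_motility_trajectory` - unloaded 2-D trajectories of a
  labeled motor walking a straight filament, sampled at the camera
  frame interval with localization noise;
* :func:`simulate_image_stack` - TIRF-like image stacks with integrated
  Gaussian point-spread functions and Poisson shot noise;
* :func:`sample_truncated_run_lengths` - direct i.i.d. draws from the
  window-censored run-length density (inverse-CDF sampling), the
  Monte-Carlo oracle for the run-length correction.

Sign conventions: motor plus-end motion is the positive position
direction; assistive force is negative, resistive positive.  All
randomness flows through a single numpy Generator per call, so results
are reproducible bit-for-bit given the same seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import erf

from .clamp import PositionRecord
from .localize import Trajectory
from .models import KBT_ROOM

__all__ = [
    "MotorModel",
    "ClampConfig",
    "StateTrajectory",
    "ImageStack",
    "simulate_stepping",
    "simulate_clamp_record",
    "simulate_motility_trajectory",
    "simulate_image_stack",
    "sample_truncated_run_lengths",
]


def _as_rng(seed=None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# kinetic model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotorModel:
    """Generative kinetic parameters of a processive stepper under load.

    Stepping rates follow ``k = k0 * exp(F * d / kBT)`` with the signed
    force (assistive < 0), on the branch (+/-) matching the force sign;
    detachment follows ``k_d = kd0 * exp(|F| * d_k / kBT)``.  Defaults
    are the myosin-5B values recovered in this package's own fits:
    forward/backward stepping, detachment, a 36-nm forward and 30-nm
    backward step, and thermal energy at room temperature.

    ``short_step_prob_scale`` enables an optional inchworm-like mixture:
    under resistive load the forward step is 20 nm with a probability
    that rises sigmoidally toward stall, emulating the trail head
    binding one actin monomer short of the next pseudo-repeat.  Off by
    default.
    """

    k0f_plus: float = 6.5
    df_plus: float = 2.2
    k0b_plus: float = 10.0
    db_plus: float = 2.0
    k0f_minus: float = 14.6
    df_minus: float = 0.05
    k0b_minus: float = 54.1
    db_minus: float = 2.4
    kd0_plus: float = 0.64
    dk_plus: float = 4.2
    kd0_minus: float = 2.3
    dk_minus: float = 1.9
    step_fwd: float = 36.0
    step_bwd: float = 30.0
    short_step_prob_scale: float = 0.0
    attach_rate: float = 1.0
    kBT: float = KBT_ROOM

    def __post_init__(self):
        rates = (self.k0f_plus, self.k0b_plus, self.k0f_minus, self.k0b_minus,
                 self.kd0_plus, self.kd0_minus)
        dists = (self.df_plus, self.db_plus, self.df_minus, self.db_minus,
                 self.dk_plus, self.dk_minus)
        if any(r <= 0 for r in rates):
            raise ValueError("all rates must be positive")
        if any(d < 0 for d in dists):
            raise ValueError("distance parameters must be non-negative")
        if self.kBT <= 0:
            raise ValueError("kBT must be positive")
        for s in (self.step_fwd, self.step_bwd):
            if not 0 < s < 90:
                raise ValueError("step sizes must lie in (0, 90) nm")

    def rates(self, force: float) -> tuple[float, float, float]:
        """(forward, backward, detachment) rates at signed force (pN).

        Zero force uses the mean of the two branch rates (the branches
        are independent empirical fits and need not meet at F = 0).
        """
        e = np.exp
        kBT = self.kBT

        def plus(F):
            return (self.k0f_plus * e(F * self.df_plus / kBT),
                    self.k0b_plus * e(F * self.db_plus / kBT),
                    self.kd0_plus * e(abs(F) * self.dk_plus / kBT))

        def minus(F):
            return (self.k0f_minus * e(F * self.df_minus / kBT),
                    self.k0b_minus * e(F * self.db_minus / kBT),
                    self.kd0_minus * e(abs(F) * self.dk_minus / kBT))

        with np.errstate(over="ignore"):
            if force > 0:
                out = plus(force)
            elif force < 0:
                out = minus(force)
            else:
                out = tuple(0.5 * (a + b) for a, b in zip(plus(0.0), minus(0.0)))
        if not all(np.isfinite(out)):
            raise ValueError(f"non-finite rates at force {force} pN: {out}")
        return out

    def short_step_prob(self, force: float) -> float:
        """Probability that a forward step is the short (20 nm) variant."""
        if self.short_step_prob_scale <= 0 or force <= 0:
            return 0.0
        return self.short_step_prob_scale / (1.0 + np.exp(-(force - 2.0) / 0.5))

    def to_dict(self) -> dict:
        return asdict(self)


SHORT_STEP_NM = 20.0


@dataclass(frozen=True)
class ClampConfig:
    """Geometry and acquisition settings of the force-clamp assay."""

    force_magnitude: float
    oscillation_range_D: float
    sample_rate: float = 200_000.0
    noise_sigma: float = 8.0
    drag_velocity: float = 10_000.0
    seed: int | None = None

    def __post_init__(self):
        if self.oscillation_range_D <= 0:
            raise ValueError("oscillation_range_D must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.drag_velocity <= 0:
            raise ValueError("drag_velocity must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class StateTrajectory:
    """Ground-truth event sequence of one attachment.

    ``events`` is an ordered list of ``(time_s, kind, position_nm)``
    with kind in {attach, step_fwd, step_bwd, detach}; the position
    changes only at step events.  ``censored`` marks realizations cut at
    the simulation horizon rather than by detachment.
    """

    events: list[tuple[float, str, float]]
    censored: bool = False

    def __post_init__(self):
        if not self.events:
            raise ValueError("empty event list")
        times = [t for t, _, _ in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if self.events[0][1] != "attach" or self.events[-1][1] != "detach":
            raise ValueError("trajectory must start with attach and end with detach")

    @property
    def duration(self) -> float:
        return self.events[-1][0] - self.events[0][0]

    @property
    def run_length(self) -> float:
        return self.events[-1][2] - self.events[0][2]

    @property
    def n_fwd(self) -> int:
        return sum(1 for _, k, _ in self.events if k == "step_fwd")

    @property
    def n_bwd(self) -> int:
        return sum(1 for _, k, _ in self.events if k == "step_bwd")

    @property
    def steps(self) -> list[tuple[float, float]]:
        """(time, signed size) of each step."""
        out = []
        prev = self.events[0][2]
        for t, kind, pos in self.events[1:]:
            if kind.startswith("step"):
                out.append((t, pos - prev))
            prev = pos
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=["time_s", "kind", "position_nm"])


# ---------------------------------------------------------------------------
# Gillespie stepping
# ---------------------------------------------------------------------------

def simulate_stepping(
    model: MotorModel,
    force: float,
    max_duration: float,
    seed=None,
) -> StateTrajectory:
    """One Gillespie realization of stepping under constant signed force.

    Three competing exponential clocks (forward, backward, detach) are
    sampled until detachment or ``max_duration`` (the latter yields a
    censored trajectory, closed by a detach event at the horizon).
    """
    rng = _as_rng(seed)
    kf, kb, kd = model.rates(force)
    total = kf + kb + kd
    t, pos = 0.0, 0.0
    events: list[tuple[float, str, float]] = [(0.0, "attach", 0.0)]
    p_short = model.short_step_prob(force)
    while True:
        t += rng.exponential(1.0 / total)
        if t >= max_duration:
            events.append((max_duration, "detach", pos))
            return StateTrajectory(events, censored=True)
        u = rng.random() * total
        if u < kf:
            size = SHORT_STEP_NM if (p_short > 0 and rng.random() < p_short) \
                else model.step_fwd
            pos += size
            events.append((t, "step_fwd", pos))
        elif u < kf + kb:
            pos -= model.step_bwd
            events.append((t, "step_bwd", pos))
        else:
            events.append((t, "detach", pos))
            return StateTrajectory(events, censored=False)


# ---------------------------------------------------------------------------
# force-clamp record
# ---------------------------------------------------------------------------

def simulate_clamp_record(
    model: MotorModel,
    cfg: ClampConfig,
    duration: float = 10.0,
    seed=None,
    attach: bool = True,
) -> PositionRecord:
    """Simulate a full dumbbell position record with embedded ground truth.

    While unbound the dumbbell ramps at ``drag_velocity`` between the
    window edges [0, D], the clamp force flipping at each edge; the
    motor attaches after an exponential waiting time (``attach_rate`` of
    the model; ``attach=False`` disables attachment for motor-free
    records).  While bound the record follows the stepping staircase at
    the signed force set by the oscillation phase: force toward the
    plus end is assistive (negative by convention).  An assistive run
    that carries the dumbbell to the upper window edge is terminated
    there (truncated) and the force reverses - the censoring corrected
    downstream by the run-length inversion.  Gaussian noise of
    ``noise_sigma`` is added per sample.

    The 200-kHz force feedback is emulated as instantaneous clamping:
    no bead-relaxation physics, steps are rendered as instantaneous
    plateau changes.
    """
    if cfg.oscillation_range_D < model.step_fwd:
        raise ValueError(
            f"oscillation range D={cfg.oscillation_range_D} nm smaller than one "
            f"forward step ({model.step_fwd} nm): no run observable")
    rng = _as_rng(cfg.seed if seed is None else seed)
    fs, D = cfg.sample_rate, cfg.oscillation_range_D
    vd, F = cfg.drag_velocity, cfg.force_magnitude
    N = int(round(duration * fs))
    position = np.empty(N)
    force = np.empty(N)

    def fill(t0, t1, p0, slope, f_signed):
        k0 = max(int(np.ceil(t0 * fs - 1e-9)), 0)
        k1 = min(int(np.ceil(t1 * fs - 1e-9)), N)
        if k1 > k0:
            tt = np.arange(k0, k1) / fs
            position[k0:k1] = p0 + slope * (tt - t0)
            force[k0:k1] = f_signed

    t, p, dirn = 0.0, 0.0, +1
    truth: list[dict] = []
    rate = model.attach_rate if attach else 0.0
    while t < duration:
        t_attach = t + rng.exponential(1.0 / rate) if rate > 0 else np.inf
        # unbound triangular ramp until attachment (or end of record)
        while t < min(t_attach, duration) - 1e-12:
            t_edge = t + ((D - p) / vd if dirn > 0 else p / vd)
            t_next = min(t_edge, t_attach, duration)
            fill(t, t_next, p, dirn * vd, -dirn * F)
            p += dirn * vd * (t_next - t)
            if t_next == t_edge and t_next < min(t_attach, duration):
                dirn = -dirn
            t = t_next
        if t >= duration or not np.isfinite(t_attach):
            break
        # attached: signed force in motor convention
        f_signed = -dirn * F
        traj = simulate_stepping(model, f_signed, duration - t, seed=rng)
        steps: list[list[float]] = []
        truncated = False
        t0_run, p0_run = t, p
        t_prev = t0_run
        t_detach = t0_run + traj.duration
        for t_step, size in traj.steps:
            t_abs = t0_run + t_step
            new_p = p + size
            fill(t_prev, t_abs, p, 0.0, f_signed)
            t_prev = t_abs
            if f_signed < 0 and new_p >= D:  # assistive run hits upper edge
                p = D
                truncated = True
                t_detach = t_abs
                dirn = -1
                break
            if f_signed > 0 and new_p <= 0:  # backed into lower edge
                p = 0.0
                truncated = True
                t_detach = t_abs
                dirn = +1
                break
            p = new_p
            steps.append([t_abs, size])
        else:
            fill(t_prev, t_detach, p, 0.0, f_signed)
        truth.append({
            "t_attach": t0_run,
            "t_detach": t_detach,
            "pos_attach": p0_run,
            "pos_detach": p,
            "force": f_signed,
            "truncated": truncated,
            "censored": bool(traj.censored and not truncated),
            "steps": steps,
        })
        t = t_detach
    if cfg.noise_sigma > 0:
        position += rng.normal(0.0, cfg.noise_sigma, N)
    meta = cfg.to_dict() | {"duration": duration, "model": model.to_dict()}
    return PositionRecord(position, force, fs, meta=meta, ground_truth=truth)


# ---------------------------------------------------------------------------
# unloaded motility
# ---------------------------------------------------------------------------

def simulate_motility_trajectory(
    velocity: float,
    run_length_mean: float,
    frame_interval: float,
    loc_noise: float,
    seed=None,
    step_size: float = 36.0,
    angle: float = 0.0,
) -> Trajectory:
    """Unloaded 2-D trajectory of a stepping motor on a straight filament.

    Steps of ``step_size`` occur at rate ``velocity / step_size``; the
    number of steps is geometric so the total run length has mean
    ``run_length_mean`` (the 36-nm-quantized analog of an exponential
    run length); detachment closes the run after one further dwell.
    Positions are sampled every ``frame_interval`` with isotropic
    Gaussian localization noise.  Ground truth (step times/sizes, true
    run length) is kept in ``meta``.
    """
    if min(velocity, run_length_mean, frame_interval) <= 0 or loc_noise < 0:
        raise ValueError("velocity, run_length_mean, frame_interval must be > 0 "
                         "and loc_noise >= 0")
    rng = _as_rng(seed)
    p_detach = min(step_size / run_length_mean, 1.0)
    n_steps = int(rng.geometric(p_detach))
    rate = velocity / step_size
    dwells = rng.exponential(1.0 / rate, n_steps + 1)
    step_times = np.cumsum(dwells[:-1])
    t_detach = float(dwells.sum())
    times = np.arange(0.0, t_detach, frame_interval)
    s = step_size * np.searchsorted(step_times, times, side="right")
    ca, sa = np.cos(angle), np.sin(angle)
    x = s * ca
    y = s * sa
    if loc_noise > 0:
        x = x + rng.normal(0.0, loc_noise, times.size)
        y = y + rng.normal(0.0, loc_noise, times.size)
    return Trajectory(
        frames=np.arange(times.size),
        times=times,
        x=x,
        y=y,
        meta={
            "true_steps": list(zip(step_times.tolist(),
                                   [step_size] * n_steps)),
            "true_run_length": n_steps * step_size,
            "velocity": velocity,
            "frame_interval": frame_interval,
        },
    )


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

@dataclass
class ImageStack:
    """Simulated TIRF movie with per-frame ground-truth spot centers."""

    frames: np.ndarray  # (frame, row, col), counts
    pixel_size: float
    frame_interval: float
    psf_sigma: float  # nm
    ground_truth: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_tiff(self, path, truth_path=None) -> None:
        import tifffile

        tifffile.imwrite(path, self.frames.astype(np.float32))
        if truth_path is not None:
            self.ground_truth.to_csv(truth_path, index=False)


def _integrated_gaussian_patch(x0, y0, sigma_px, half):
    """Expected photon fraction per pixel of a unit-flux emitter."""
    cx, cy = int(round(x0)), int(round(y0))
    cols = np.arange(cx - half, cx + half + 1)
    rows = np.arange(cy - half, cy + half + 1)
    s = sigma_px * np.sqrt(2.0)
    fx = 0.5 * (erf((cols + 0.5 - x0) / s) - erf((cols - 0.5 - x0) / s))
    fy = 0.5 * (erf((rows + 0.5 - y0) / s) - erf((rows - 0.5 - y0) / s))
    return rows, cols, np.outer(fy, fx)


def simulate_image_stack(
    trajectories: list[Trajectory],
    psf_sigma: float = 130.0,
    photons_per_frame: float = 1000.0,
    background: float = 10.0,
    pixel_size: float = 91.0,
    shape: tuple[int, int] = (64, 64),
    frame_interval: float = 0.1,
    seed=None,
    poisson: bool = True,
) -> ImageStack:
    """Render trajectories (nm coordinates) as a noisy TIRF stack.

    Each spot is an integrated symmetric Gaussian at its true sub-pixel
    center; Poisson shot noise applies to spot + background counts.
    Spots falling outside the field are dropped with a warning.
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be positive")
    rng = _as_rng(seed)
    n_frames = max((int(tr.frames[-1]) + 1 for tr in trajectories), default=1)
    ny, nx = shape
    expected = np.full((n_frames, ny, nx), float(background))
    sigma_px = psf_sigma / pixel_size
    half = max(int(np.ceil(4 * sigma_px)), 3)
    rows_out = []
    dropped = 0
    for spot_id, tr in enumerate(trajectories):
        for f, x_nm, y_nm in zip(tr.frames, tr.x, tr.y):
            x_px, y_px = x_nm / pixel_size, y_nm / pixel_size
            if not (0 <= x_px < nx and 0 <= y_px < ny):
                dropped += 1
                continue
            rr, cc, patch = _integrated_gaussian_patch(x_px, y_px, sigma_px, half)
            rsel = (rr >= 0) & (rr < ny)
            csel = (cc >= 0) & (cc < nx)
            expected[int(f), rr[rsel][0]:rr[rsel][-1] + 1,
                     cc[csel][0]:cc[csel][-1] + 1] += (
                photons_per_frame * patch[np.ix_(rsel, csel)])
            rows_out.append((int(f), spot_id, x_nm, y_nm, x_px, y_px))
    if dropped:
        warnings.warn(f"{dropped} spot positions outside the field were dropped")
    frames = rng.poisson(expected).astype(float) if poisson else expected
    truth = pd.DataFrame(rows_out,
                         columns=["frame", "spot", "x_nm", "y_nm", "x_px", "y_px"])
    return ImageStack(frames, pixel_size, frame_interval, psf_sigma, truth)


# ---------------------------------------------------------------------------
# censored run-length sampling
# ---------------------------------------------------------------------------

def sample_truncated_run_lengths(L: float, D: float, n: int, seed=None) -> np.ndarray:
    """I.i.d. draws from the window-censored run-length density on [0, D].

    Inverse-CDF sampling by vectorized bisection of
    ``F(x) = 1 - exp(-x/L) (1 - x/D)``, which is continuous and strictly
    increasing on [0, D].
    """
    if L <= 0 or D <= 0:
        raise ValueError("L and D must be positive")
    rng = _as_rng(seed)
    u = rng.random(n)
    lo = np.zeros(n)
    hi = np.full(n, float(D))
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        cdf = 1.0 - np.exp(-mid / L) * (1.0 - mid / D)
        below = cdf < u
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 0.5 * (lo + hi)
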