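"""Parameter-recovery experiments at the package's reference conditions.

Each function simulates data from the reference myosin-5B parameter set
(the same values the :class:`~myostep.simulate.MotorModel` defaults
use), runs the corresponding detection/fitting chain, and returns the
recovered model.  They serve as end-to-end self-consistency checks:
generate from the model, analyze blind, and compare the recovered
parameters with the generating ones.
"""

from __future__ import annotations

import numpy as np

from . import models, motility, simulate

__all__ = [
    "REFERENCE",
    "recover_runlength_bell",
    "recover_detachment_bell",
    "recover_step_ratio",
    "recover_michaelis_menten",
    "recover_step_size",
    "recover_unloaded_run_length",
]

#: Reference parameter set: resistive-branch run-length and detachment
#: Bell models, forward/backward step-ratio model, unloaded
#: Michaelis-Menten kinetics, lattice step and mean run length.
REFERENCE: dict = {
    "L0_resistive": 890.0,     # nm
    "dL_resistive": 6.3,       # nm
    "k0_resistive": 0.64,      # 1/s
    "dk_resistive": 4.2,       # nm
    "R0": 54.0,                # forward/backward ratio at zero force
    "d_ratio": 8.2,            # nm
    "vmax": 691.0,             # nm/s
    "Kapp": 22.0,              # µM
    "step_nm": 36.0,
    "run_length_nm": 780.0,
    "loc_noise_nm": 4.0,
    "kBT": models.KBT_ROOM,
}

_RESISTIVE_FORCES = np.linspace(0.5, 3.0, 6)  # pN


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def recover_runlength_bell(seed, runs_per_level: int = 125) -> models.BellFit:
    """Run-length force dependence on the resistive branch.

    Exponentially distributed run lengths with force-dependent mean
    ``L(F) = L0 exp(-F dL / kBT)`` at six force levels between 0.5 and
    3 pN; per-level means (with s.e.m. weights) fitted with the Bell
    decay model.
    """
    rng = _rng(seed)
    p, kBT = REFERENCE, REFERENCE["kBT"]
    F, y, sem = [], [], []
    for f in _RESISTIVE_FORCES:
        mean_L = p["L0_resistive"] * np.exp(-f * p["dL_resistive"] / kBT)
        draws = rng.exponential(mean_L, runs_per_level)
        F.append(f)
        y.append(draws.mean())
        sem.append(draws.std(ddof=1) / np.sqrt(runs_per_level))
    return models.fit_bell(F, y, sem, sign="decay", branch="resistive", kBT=kBT)


def recover_detachment_bell(seed, runs_per_level: int = 125) -> models.BellFit:
    """Detachment-rate force dependence on the resistive branch.

    Exponential run durations with rate ``k(F) = k0 exp(F dk / kBT)``;
    per-level ``k = 1/<tau>`` with the propagated error
    ``sigma_k = sigma_tau <tau>^-2`` as weight; Bell growth fit.
    """
    rng = _rng(seed)
    p, kBT = REFERENCE, REFERENCE["kBT"]
    F, k, sk = [], [], []
    for f in _RESISTIVE_FORCES:
        rate = p["k0_resistive"] * np.exp(f * p["dk_resistive"] / kBT)
        tau = rng.exponential(1.0 / rate, runs_per_level)
        mean_tau = tau.mean()
        sem_tau = tau.std(ddof=1) / np.sqrt(runs_per_level)
        F.append(f)
        k.append(1.0 / mean_tau)
        sk.append(sem_tau / mean_tau**2)
    return models.fit_bell(F, k, sk, sign="growth", branch="resistive", kBT=kBT)


def recover_step_ratio(seed, total_steps: int = 3418) -> models.BellFit:
    """Forward/backward step-count ratio below stall.

    At six resistive force levels below the stall force, step
    directions are Bernoulli with odds given by the ratio model
    ``R(F) = R0 exp(-F d / kBT)``; per-level count ratios (with
    propagated errors) fitted with the Bell decay model.  The total
    step count matches the reference data set (2729 forward + 689
    backward).
    """
    rng = _rng(seed)
    p, kBT = REFERENCE, REFERENCE["kBT"]
    forces = np.linspace(0.5, 1.8, 6)
    base, extra = divmod(total_steps, len(forces))
    F, y, sem = [], [], []
    for i, f in enumerate(forces):
        n = base + (1 if i < extra else 0)
        R = p["R0"] * np.exp(-f * p["d_ratio"] / kBT)
        n_fwd = rng.binomial(n, R / (1.0 + R))
        n_bwd = n - n_fwd
        if n_bwd == 0:
            continue
        ratio = n_fwd / n_bwd
        F.append(f)
        y.append(ratio)
        sem.append(ratio * np.sqrt(1.0 / n_fwd + 1.0 / n_bwd))
    return models.fit_bell(F, y, sem, sign="decay", branch="resistive", kBT=kBT)


def recover_michaelis_menten(seed, n_runs: int = 127,
                             noise_cv: float = 0.15) -> models.MMFit:
    """Unloaded velocity versus [ATP] at the reference design.

    ``n_runs`` per-run velocities spread over six ATP levels between
    0.3 and 1000 µM, drawn around the Michaelis-Menten curve with
    multiplicative noise, then refitted.
    """
    rng = _rng(seed)
    p = REFERENCE
    atp_levels = np.array([0.3, 1.0, 5.0, 22.0, 100.0, 1000.0])
    counts = np.full(len(atp_levels), n_runs // len(atp_levels))
    counts[: n_runs - counts.sum()] += 1
    atp = np.repeat(atp_levels, counts)
    v_true = models.michaelis_menten(atp, p["vmax"], p["Kapp"])
    v = v_true * (1.0 + noise_cv * rng.standard_normal(atp.size))
    return models.fit_michaelis_menten(atp, v)


def recover_step_size(seed, atp_uM: float = 0.3, frame_interval: float = 0.1,
                      min_steps: int = 42, max_trajectories: int = 40,
                      ) -> tuple[float, float, int]:
    """Plateau-detector step size on simulated low-ATP trajectories.

    Trajectories step on the 36-nm lattice with dwell times set by the
    Michaelis-Menten velocity at ``atp_uM`` (long dwells at 0.3 µM),
    sampled at the camera frame interval with 4-nm localization noise;
    the change-point detector's single-step mean/s.e.m. over at least
    ``min_steps`` detected steps is returned as (mean, sem, n).
    """
    rng = _rng(seed)
    p = REFERENCE
    v = models.michaelis_menten(atp_uM, p["vmax"], p["Kapp"])
    steps: list[motility.UnloadedStep] = []
    n_traj = 0
    while n_traj < max_trajectories:
        traj = simulate.simulate_motility_trajectory(
            v, p["run_length_nm"], frame_interval, p["loc_noise_nm"],
            seed=rng, step_size=p["step_nm"])
        n_traj += 1
        if len(traj) < 10:
            continue
        steps.extend(motility.detect_steps_unloaded(traj))
        if len(steps) >= 2 * min_steps:  # sizes above the double-step gate drop out
            mean, sem, n = motility.step_statistics(steps)
            if n >= min_steps:
                return mean, sem, n
    return motility.step_statistics(steps)


def recover_unloaded_run_length(
    seed,
    atp_levels=(0.3, 1.0, 2.0),
    trajectories_per_level: int = 800,
    frame_interval: float = 0.05,
    min_frames: int = 10,
) -> tuple[float, int]:
    """Pooled mean run length of a simulated motility ensemble.

    Exponential-mean run lengths on the 36-nm lattice at low ATP levels
    (where a 10-frame minimum track length censors only a few tens of
    nm, keeping the truncation bias of the conditional mean small),
    4-nm localization noise, the >= ``min_frames`` filter, and the
    interpolated-path run-length estimator.  Returns (mean, n_kept).
    """
    rng = _rng(seed)
    p = REFERENCE
    lengths = []
    for atp in atp_levels:
        v = models.michaelis_menten(atp, p["vmax"], p["Kapp"])
        for _ in range(trajectories_per_level):
            traj = simulate.simulate_motility_trajectory(
                v, p["run_length_nm"], frame_interval, p["loc_noise_nm"],
                seed=rng, step_size=p["step_nm"])
            if len(traj) >= min_frames:
                lengths.append(motility.compute_run_length(traj))
    return float(np.mean(lengths)), len(lengths)
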