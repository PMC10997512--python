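"""Diffusion and treatment-response calibration from observed trajectories.

The diffusion coefficient beta is estimated from the slope of the mean
squared displacement (MSD) of observed state-space trajectories about
their cohort mean path (1-D convention MSD = 2 beta t, so beta =
slope / 2; the factor is stated explicitly since conventions differ).

Treatment parameters (gamma, beta) are fitted by grid search: for each
candidate pair, the treatment model is simulated from each subject's
first observed time point and the ensemble-and-time averaged squared
deviation from the observed path is minimized.  Common random numbers
across grid cells keep the surface smooth at modest replicate counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dynamics import TrajectoryEnsemble, simulate_langevin
from .potentials import PotentialModel
from .treatment import TreatmentSchedule

__all__ = [
    "MSDResult",
    "msd_between",
    "estimate_beta_from_slope",
    "calibrate_amplitude",
    "grid_search",
    "GAMMA_RANGE",
    "BETA_RANGE",
]

# search ranges of the treatment-response and diffusion parameters
GAMMA_RANGE = (0.1, 2.0)
BETA_RANGE = (0.001, 0.1)


@dataclass
class MSDResult:
    gamma_grid: np.ndarray
    beta_grid: np.ndarray
    msd: np.ndarray                    # (n_gamma, n_beta) mean MSD surface
    gamma_opt: float
    beta_opt: float
    msd_curve: np.ndarray | None = None   # per-time MSD at the optimum
    curve_times: np.ndarray | None = None
    beta_slope_estimate: float | None = None
    on_boundary: bool = False


def msd_between(simulated: TrajectoryEnsemble, obs_times, obs_path):
    """Per-time and mean MSD between a simulated ensemble and one path.

    The observed path is linearly interpolated onto the simulation's
    recorded time grid (restricted to the overlap).  Returns
    ``(times, msd_t, mean_msd)`` where ``msd_t`` averages over
    replicates and ``mean_msd`` additionally over time.
    """
    obs_times = np.asarray(obs_times, dtype=float)
    obs_path = np.asarray(obs_path, dtype=float)
    t = simulated.times
    lo, hi = max(t[0], obs_times.min()), min(t[-1], obs_times.max())
    if lo > hi:
        raise ValueError("simulated and observed time ranges do not overlap")
    mask = (t >= lo) & (t <= hi)
    ti = t[mask]
    obs_i = np.interp(ti, obs_times, obs_path)
    dev = simulated.paths[:, mask] - obs_i[None, :]
    msd_t = np.mean(dev ** 2, axis=0)
    return ti, msd_t, float(np.mean(msd_t))


def estimate_beta_from_slope(trajectories: dict):
    """beta from the OLS slope of MSD(t) about the cohort mean path.

    ``trajectories`` maps subject -> (weeks, coords).  The MSD at each
    common time point is the across-subject mean squared deviation from
    the cohort mean path; a line is fitted through the MSD-vs-time
    points and beta = slope / 2 (1-D diffusion).  Slopes that come out
    negative are clipped at zero.
    """
    series = {k: (np.asarray(w, dtype=float), np.asarray(x, dtype=float))
              for k, (w, x) in trajectories.items()}
    all_weeks = np.array(sorted(set().union(*(set(w) for w, _ in
                                              series.values()))))
    times, msd = [], []
    for t in all_weeks:
        vals = [x[np.nonzero(w == t)[0][0]] for w, x in series.values()
                if t in w]
        if len(vals) >= 2:
            vals = np.asarray(vals)
            times.append(t)
            msd.append(np.mean((vals - vals.mean()) ** 2))
    if len(times) < 3:
        raise ValueError("need >= 3 time points with >= 2 subjects "
                         "for the MSD fit")
    slope = np.polyfit(times, msd, 1)[0]
    return max(0.0, float(slope) / 2.0)


def calibrate_amplitude(observed: dict, potential: PotentialModel,
                        beta: float, a_range=(1e0, 1e7), n_points=22,
                        reps=100, seed=0,
                        max_steps=40000) -> tuple[PotentialModel, float]:
    """Fit the free landscape amplitude ``a`` jointly with a fixed beta.

    The polynomial landscape fixes only the critical-point *locations*;
    its amplitude (the gradient scale, hence the transition kinetics) is
    a free parameter.  It is fitted by minimizing the mean MSD between
    untreated Langevin ensembles started from each subject's first
    observed point and the observed trajectories, over a log-spaced
    amplitude grid with common random numbers.  Returns the rescaled
    potential and the fitted amplitude.
    """
    a_grid = np.logspace(np.log10(a_range[0]), np.log10(a_range[1]), n_points)
    subjects = {k: (np.asarray(w, dtype=float), np.asarray(x, dtype=float))
                for k, (w, x) in observed.items()}
    pts = np.concatenate([potential.critical_points]
                         + [x for _, x in subjects.values()])
    margin = min(0.4, 0.3 * np.ptp(pts))
    scores = []
    for a in a_grid:
        pot = PotentialModel(kind=potential.kind, a=float(a),
                             critical_points=potential.critical_points,
                             c_h=potential.c_h)
        grid = np.linspace(pts.min() - margin, pts.max() + margin, 512)
        dt = min(0.01, 0.4 / np.max(np.abs(pot.curvature(grid))))
        horizon = max(w[-1] - w[0] for w, _ in subjects.values())
        if horizon / dt > max_steps:
            # amplitude so stiff relative to the coordinate scale that the
            # integrator budget is exceeded; such scales never win the fit
            scores.append(np.inf)
            continue
        total = 0.0
        for s_idx, (w, x) in enumerate(subjects.values()):
            ens = simulate_langevin(pot, x0=x[0], t_max=w[-1] - w[0], dt=dt,
                                    beta=beta, n_reps=reps,
                                    seed=seed + 1000 * s_idx, record_dt=1.0,
                                    t0=w[0], margin=margin)
            total += msd_between(ens, w, x)[2]
        scores.append(total / len(subjects))
    i = int(np.argmin(scores))
    a_opt = float(a_grid[i])
    fitted = PotentialModel(kind=potential.kind, a=a_opt,
                            critical_points=potential.critical_points,
                            c_h=potential.c_h)
    return fitted, a_opt


def grid_search(observed: dict, potential: PotentialModel,
                schedule_template: TreatmentSchedule,
                gamma_range=GAMMA_RANGE, beta_range=BETA_RANGE,
                resolution=(20, 20), reps=200, seed=0, dt=0.005,
                beta_pre=None) -> MSDResult:
    """Minimize mean MSD over a (gamma, beta) grid.

    ``observed`` maps subject -> (weeks, coords).  For each grid pair the
    treatment model is simulated from every subject's first observed
    point over that subject's observation window (``beta`` sets the
    treated diffusion plateaus; ``beta_pre`` the pre-treatment plateau,
    defaulting to the grid value).  Gamma is sampled linearly over its
    range, beta logarithmically.  The same random seed is reused in each
    cell (common random numbers).  A warning is issued when the argmin
    lands on the range boundary.
    """
    n_g, n_b = resolution
    gammas = np.linspace(*gamma_range, n_g)
    betas = np.logspace(np.log10(beta_range[0]), np.log10(beta_range[1]), n_b)
    surface = np.zeros((n_g, n_b))
    subjects = {k: (np.asarray(w, dtype=float), np.asarray(x, dtype=float))
                for k, (w, x) in observed.items()}
    if not subjects:
        raise ValueError("no observed subjects to calibrate against")
    pts = np.concatenate([potential.critical_points]
                         + [x for _, x in subjects.values()])
    margin = min(0.4, 0.3 * np.ptp(pts))
    for i, g in enumerate(gammas):
        for j, b in enumerate(betas):
            total = 0.0
            for s_idx, (w, x) in enumerate(subjects.values()):
                sched = TreatmentSchedule(
                    kind=schedule_template.kind, gamma=g,
                    t_on=schedule_template.t_on, t_off=schedule_template.t_off,
                    lam=schedule_template.lam,
                    beta_pre=beta_pre if beta_pre is not None else b,
                    beta_on=b, beta_post=b)
                ens = simulate_langevin(
                    potential, x0=x[0], t_max=w[-1] - w[0], dt=dt,
                    schedule=sched, n_reps=reps, margin=margin,
                    seed=seed + 1000 * s_idx, record_dt=1.0, t0=w[0])
                _, _, m = msd_between(ens, w, x)
                total += m
            surface[i, j] = total / len(subjects)
    i_opt, j_opt = np.unravel_index(np.argmin(surface), surface.shape)
    on_boundary = i_opt in (0, n_g - 1) or j_opt in (0, n_b - 1)
    if on_boundary:
        warnings.warn("grid-search argmin lies on the search-range boundary")
    # per-time curve at the optimum for the first subject set
    g, b = gammas[i_opt], betas[j_opt]
    pairs = []
    for s_idx, (w, x) in enumerate(subjects.values()):
        sched = TreatmentSchedule(
            kind=schedule_template.kind, gamma=g,
            t_on=schedule_template.t_on, t_off=schedule_template.t_off,
            lam=schedule_template.lam,
            beta_pre=beta_pre if beta_pre is not None else b,
            beta_on=b, beta_post=b)
        ens = simulate_langevin(potential, x0=x[0], t_max=w[-1] - w[0],
                                dt=dt, schedule=sched, n_reps=reps,
                                seed=seed + 1000 * s_idx, record_dt=1.0,
                                t0=w[0], margin=margin)
        ti, msd_t, _ = msd_between(ens, w, x)
        pairs.append((ti, msd_t))
    tgrid = min((ti for ti, _ in pairs), key=len)
    curves = [np.interp(tgrid, ti, c) for ti, c in pairs]
    return MSDResult(gamma_grid=gammas, beta_grid=betas, msd=surface,
                     gamma_opt=float(g), beta_opt=float(b),
                     msd_curve=np.mean(curves, axis=0), curve_times=tgrid,
                     on_boundary=on_boundary)
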