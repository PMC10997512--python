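"""Stochastic dynamics on the disease landscape.

The transcriptome is modeled as an overdamped Brownian particle in the
potential ``U(x)``:

    dX_t = (-dU/dx + F(x, t)) dt + sqrt(2 R(t)) dB_t

where ``F`` is the treatment force and ``R`` the (possibly piecewise
constant) diffusion coefficient.  The matching Fokker-Planck equation

    dp/dt = -d/dx[(-dU/dx + F) p] + R d^2p/dx^2

is discretized with a conservative finite-volume scheme using
Scharfetter-Gummel (Chang-Cooper) flux weighting, which is positivity
preserving and reproduces the discrete Boltzmann stationary state
exactly.  Time stepping is implicit Euler.  An optional absorbing
boundary at the late-disease critical point turns the absorbed mass into
the time-to-disease probability ``P(t)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded

from lifelines.statistics import logrank_test

from .potentials import PotentialModel
from .treatment import TreatmentSchedule

__all__ = [
    "TrajectoryEnsemble",
    "FPSolution",
    "SurvivalComparison",
    "simulate_langevin",
    "solve_fokker_planck",
    "time_to_disease_probability",
    "predicted_time_from_curve",
    "observed_first_crossing",
    "concordance_index",
    "compare_survival",
]


# ---------------------------------------------------------------------------
# Langevin simulation
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryEnsemble:
    """Sampled paths x(t): ``paths[r, k]`` is replicate r at ``times[k]``."""

    times: np.ndarray
    paths: np.ndarray
    seed: int | None = None
    subject_ids: list | None = None
    crossing_times: np.ndarray | None = None  # first passage per replicate (nan = none)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.paths = np.atleast_2d(np.asarray(self.paths, dtype=float))
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def n_reps(self):
        return self.paths.shape[0]


def _stability_domain(potential: PotentialModel, x0, margin=0.4):
    pts = np.atleast_1d(potential.critical_points).astype(float)
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    lo = min(pts.min(), x0.min()) - margin
    hi = max(pts.max(), x0.max()) + margin
    return lo, hi


def simulate_langevin(potential: PotentialModel, x0, t_max, dt, beta=None,
                      schedule: TreatmentSchedule | None = None,
                      n_reps=1, seed=None, rng=None, record_dt=None,
                      crossing_threshold=None, crossing_direction=None,
                      t0=0.0, margin=0.4) -> TrajectoryEnsemble:
    """Euler-Maruyama integration of the Langevin equation.

    ``beta`` is the constant diffusion coefficient when no schedule is
    given; with a schedule, F(x, t) and R(t) come from it.  ``x0`` may be
    a scalar (all replicates identical) or an array of length ``n_reps``.

    The step size must satisfy ``dt * max|U''| < 0.5`` over the domain
    spanned by the critical points and the initial conditions plus
    ``margin``; positions are reflected at that domain's edges so a rare
    excursion cannot enter the stiffer exterior of the polynomial.

    When ``crossing_threshold`` is given, the first time each replicate
    moves beyond it (in ``crossing_direction``, default the potential's
    disease direction) is recorded at full step resolution.
    """
    if schedule is None:
        if beta is None:
            raise ValueError("provide beta or a treatment schedule")
        schedule = TreatmentSchedule.none(beta=beta)
    elif beta is not None:
        raise ValueError("give either beta or a schedule, not both")
    lo, hi = _stability_domain(potential, x0, margin=margin)
    grid = np.linspace(lo, hi, 512)
    max_curv = float(np.max(np.abs(potential.curvature(grid))))
    if dt * max_curv >= 0.5:
        raise ValueError(
            f"dt={dt} too large for this landscape: dt*max|U''| = "
            f"{dt * max_curv:.2f} >= 0.5; use dt < {0.5 / max_curv:.2g}")

    if rng is None:
        rng = np.random.default_rng(seed)
    n_steps = int(round(t_max / dt))
    if record_dt is None:
        record_dt = dt
    every = max(1, int(round(record_dt / dt)))

    x = np.full(n_reps, np.nan)
    x[:] = np.asarray(x0, dtype=float)
    direction = crossing_direction
    if crossing_threshold is not None and direction is None:
        direction = potential.disease_direction
    crossed = np.full(n_reps, np.nan)
    if crossing_threshold is not None:
        already = direction * (x - crossing_threshold) >= 0
        crossed[already] = t0

    times = [t0]
    snaps = [x.copy()]
    for k in range(n_steps):
        t = t0 + k * dt
        drift = -potential.gradient(x) + schedule.force(potential, x, t)
        R = schedule.diffusion(t)
        x = x + drift * dt + np.sqrt(2.0 * R * dt) * rng.standard_normal(n_reps)
        np.clip(x, lo, hi, out=x)
        if crossing_threshold is not None:
            new = np.isnan(crossed) & (direction * (x - crossing_threshold) >= 0)
            crossed[new] = t + dt
        if (k + 1) % every == 0 or k == n_steps - 1:
            times.append(t0 + (k + 1) * dt)
            snaps.append(x.copy())
    return TrajectoryEnsemble(
        times=np.asarray(times), paths=np.column_stack(snaps), seed=seed,
        crossing_times=crossed if crossing_threshold is not None else None)


# ---------------------------------------------------------------------------
# Fokker-Planck solver
# ---------------------------------------------------------------------------

@dataclass
class FPSolution:
    """Density p(x, t) on a uniform cell-centered grid with a mass ledger.

    ``p[k]`` is the density at ``times[k]``; ``absorbed[k]`` the mass that
    has left through the absorbing boundary by then.  The invariant
    ``sum(p) dx + absorbed == 1`` holds to solver tolerance at all times.
    """

    x: np.ndarray
    dx: float
    times: np.ndarray
    p: np.ndarray
    absorbed: np.ndarray
    boundary: str = "no-flux"
    absorbing_at: float | None = None

    def mass(self, k=None):
        tot = self.p.sum(axis=1) * self.dx
        return tot if k is None else float(tot[k])

    def density_at(self, t):
        k = int(np.argmin(np.abs(self.times - t)))
        return self.p[k]

    def absorbed_at(self, t):
        return float(np.interp(t, self.times, self.absorbed))


def _bernoulli(w):
    """B(w) = w / (e^w - 1), with the w -> 0 limit handled."""
    w = np.asarray(w, dtype=float)
    out = np.empty_like(w)
    small = np.abs(w) < 1e-10
    out[small] = 1.0 - 0.5 * w[small]
    ws = np.clip(w[~small], -700, 700)
    out[~small] = ws / np.expm1(ws)
    return out


def solve_fokker_planck(potential: PotentialModel, x0=None, init_density=None,
                        grid=None, n_cells=1024, t_max=18.0, dt=0.01,
                        beta=None, schedule: TreatmentSchedule | None = None,
                        absorbing_at=None, record_dt=0.1,
                        margin=2.0) -> FPSolution:
    """Solve the 1-D Fokker-Planck equation with conservative fluxes.

    The spatial grid defaults to the span of the critical points plus
    ``margin`` on each side; pass ``grid=(lo, hi)`` to override.  The
    initial condition is a point mass at ``x0`` or an arbitrary density
    sampled at the cell centers (``init_density`` callable or array).

    Outer boundaries are no-flux.  With ``absorbing_at`` set, the domain
    is truncated at that coordinate on the potential's disease side and
    mass leaving through it accumulates in the ledger — the first-passage
    (time-to-disease) probability.
    """
    if schedule is None:
        if beta is None:
            raise ValueError("provide beta or a treatment schedule")
        schedule = TreatmentSchedule.none(beta=beta)
    elif beta is not None:
        raise ValueError("give either beta or a schedule, not both")

    pts = np.atleast_1d(potential.critical_points).astype(float)
    if grid is None:
        lo, hi = pts.min() - margin, pts.max() + margin
        if x0 is not None:
            lo, hi = min(lo, x0 - margin), max(hi, x0 + margin)
    else:
        lo, hi = grid
    direction = potential.disease_direction
    boundary = "no-flux"
    absorb_left = False
    if absorbing_at is not None:
        if not lo < absorbing_at < hi:
            raise ValueError(f"absorbing boundary {absorbing_at} outside grid "
                             f"[{lo:.3g}, {hi:.3g}]")
        if direction < 0:
            lo = absorbing_at
            absorb_left = True
        else:
            hi = absorbing_at
        boundary = "absorbing"

    dx = (hi - lo) / n_cells
    xc = lo + (np.arange(n_cells) + 0.5) * dx
    faces = lo + np.arange(n_cells + 1) * dx

    # mass starting at/beyond the absorbing boundary is absorbed immediately
    if (absorbing_at is not None and x0 is not None
            and direction * (x0 - absorbing_at) >= 0):
        dx = (hi - lo) / n_cells
        xc = lo + (np.arange(n_cells) + 0.5) * dx
        times = np.arange(0.0, t_max + 1e-9, record_dt)
        return FPSolution(x=xc, dx=dx, times=times,
                          p=np.zeros((len(times), n_cells)),
                          absorbed=np.ones(len(times)),
                          boundary=boundary, absorbing_at=absorbing_at)

    p = np.zeros(n_cells)
    if init_density is not None:
        vals = init_density(xc) if callable(init_density) else np.asarray(init_density)
        if np.any(vals < 0):
            raise ValueError("initial density must be nonnegative")
        p = vals / (vals.sum() * dx)
    elif x0 is not None:
        if not lo <= x0 <= hi:
            raise ValueError(f"x0={x0} outside grid [{lo:.3g}, {hi:.3g}]")
        i = min(n_cells - 1, max(0, int((x0 - lo) / dx)))
        p[i] = 1.0 / dx
    else:
        raise ValueError("provide x0 or init_density")

    n_steps = int(round(t_max / dt))
    every = max(1, int(round(record_dt / dt)))

    def banded_matrix(t):
        """(I - dt*M) in banded (3, n) form for solve_banded."""
        R = schedule.diffusion(t)
        v = -potential.gradient(faces) + schedule.force(potential, faces, t)
        w = v * dx / R
        Bm = _bernoulli(-w)   # weight of the left cell
        Bp = _bernoulli(w)    # weight of the right cell
        r = dt * R / dx**2
        lower = np.zeros(n_cells)   # coupling to cell i-1 via face i
        upper = np.zeros(n_cells)   # coupling to cell i+1 via face i+1
        diag = np.zeros(n_cells)
        # interior faces f = 1..n-1 between cells f-1 and f
        fB_m, fB_p = Bm[1:-1], Bp[1:-1]
        # cell i gains from face i (inflow) and loses via face i+1
        # dp_i/dt = (J_i - J_{i+1}) / dx, J_f = (R/dx)(B(-w_f) p_{f-1} - B(w_f) p_f)
        diag[:] = 0.0
        # J_i contribution to cell i: +(R/dx^2)(Bm_i p_{i-1} - Bp_i p_i)
        lower[1:] = r * fB_m
        diag[1:] += -r * fB_p
        # -J_{i+1} contribution to cell i: -(R/dx^2)(Bm_{i+1} p_i - Bp_{i+1} p_{i+1})
        diag[:-1] += -r * fB_m
        upper[:-1] = r * fB_p
        # boundaries: no-flux faces contribute nothing; absorbing left face:
        if absorb_left:
            w0 = v[0] * dx / R
            diag[0] += -dt * R / dx**2 * float(_bernoulli(np.array([w0]))[0])
        elif absorbing_at is not None:
            wN = v[-1] * dx / R
            diag[-1] += -dt * R / dx**2 * float(_bernoulli(np.array([-wN]))[0])
        ab = np.zeros((3, n_cells))
        ab[0, 1:] = -upper[:-1]
        ab[1, :] = 1.0 - diag
        ab[2, :-1] = -lower[1:]
        return ab

    static = schedule.kind == "none"
    times = [0.0]
    history = [p.copy()]
    absorbed = [1.0 - p.sum() * dx]
    ab = banded_matrix(0.0)
    mass_prev = p.sum() * dx
    abs_total = absorbed[0]
    for k in range(n_steps):
        t = k * dt
        if not static:
            ab = banded_matrix(t)
        p = solve_banded((1, 1), ab, p)
        if np.any(p < -1e-12):
            raise RuntimeError("Fokker-Planck solver produced negative density")
        np.clip(p, 0.0, None, out=p)
        mass = p.sum() * dx
        abs_total += max(0.0, mass_prev - mass)
        mass_prev = mass
        if (k + 1) % every == 0 or k == n_steps - 1:
            times.append((k + 1) * dt)
            history.append(p.copy())
            absorbed.append(abs_total)
    return FPSolution(x=xc, dx=dx, times=np.asarray(times),
                      p=np.asarray(history), absorbed=np.asarray(absorbed),
                      boundary=boundary, absorbing_at=absorbing_at)


# ---------------------------------------------------------------------------
# Time to disease
# ---------------------------------------------------------------------------

def time_to_disease_probability(fp: FPSolution, weeks=None):
    """Disease-progression probability P(t) at weekly observation times.

    P(t) is the probability mass absorbed beyond the late-disease
    critical point by time t; requires an FP solution computed with an
    absorbing boundary.  Returns (weeks, P) with P nondecreasing,
    P(0) >= 0 and P <= 1.
    """
    if fp.boundary != "absorbing":
        raise ValueError("time-to-disease needs an absorbing-boundary solution")
    if weeks is None:
        weeks = np.arange(0.0, fp.times[-1] + 1e-9, 1.0)
    weeks = np.asarray(weeks, dtype=float)
    P = np.interp(weeks, fp.times, fp.absorbed)
    return weeks, P


def predicted_time_from_curve(weeks, P, threshold=0.5):
    """First weekly time point with P(t) >= threshold; None if never."""
    hit = np.nonzero(np.asarray(P) >= threshold)[0]
    if len(hit) == 0:
        return None
    return float(np.asarray(weeks)[hit[0]])


def observed_first_crossing(weeks, coords, threshold, direction=-1):
    """First observed week at/beyond the disease threshold.

    Returns ``(time, event)``: the first week whose coordinate lies at or
    beyond ``threshold`` in the disease ``direction`` (default health-high,
    disease toward smaller coordinates), or the last observed week with
    ``event=False`` when the subject never crosses.
    """
    weeks = np.asarray(weeks, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if len(weeks) == 0:
        raise ValueError("empty coordinate series")
    order = np.argsort(weeks)
    weeks, coords = weeks[order], coords[order]
    beyond = direction * (coords - threshold) >= 0
    idx = np.nonzero(beyond)[0]
    if len(idx) == 0:
        return float(weeks[-1]), False
    return float(weeks[idx[0]]), True


# ---------------------------------------------------------------------------
# Survival comparison
# ---------------------------------------------------------------------------

@dataclass
class SurvivalComparison:
    table: pd.DataFrame
    logrank_stat: float
    logrank_p: float
    c_index: float


def concordance_index(pred_times, obs_times, obs_events):
    """Concordance between predicted and observed orderings, ties at 1/2.

    A pair is comparable when the observed times differ and the earlier
    observed time is an uncensored event.  It is concordant when the
    predicted ordering agrees with the observed one.
    """
    pred = np.asarray(pred_times, dtype=float)
    obs = np.asarray(obs_times, dtype=float)
    ev = np.asarray(obs_events, dtype=bool)
    num = den = 0.0
    n = len(pred)
    for i in range(n):
        for j in range(i + 1, n):
            if obs[i] == obs[j]:
                continue
            first, second = (i, j) if obs[i] < obs[j] else (j, i)
            if not ev[first]:
                continue
            den += 1
            if pred[first] == pred[second]:
                num += 0.5
            elif pred[first] < pred[second]:
                num += 1
    if den == 0:
        raise ValueError("no comparable pairs (all observations censored?)")
    return num / den


def compare_survival(predicted, observed, scores=None) -> SurvivalComparison:
    """Compare predicted and observed time-to-disease across subjects.

    ``predicted`` and ``observed`` map subject id -> (time, event); a
    ``None`` time in ``predicted`` means the model never reaches the
    event probability threshold and is treated as censored at the longest
    observed horizon.  The pooled predicted-vs-observed curves are
    compared with the two-sample log-rank test, and subject orderings
    with the concordance index.

    ``scores`` optionally maps subject -> a continuous predicted-time
    surrogate (e.g. the restricted mean first-passage time) used for the
    concordance ordering instead of the weekly discretized predicted
    times, which are tie-prone at small cohort sizes.
    """
    subjects = sorted(observed)
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    horizon = max(t for t, _ in observed.values())
    rows = []
    for s in subjects:
        pt, pe = predicted[s]
        if pt is None:
            pt, pe = horizon, False
        ot, oe = observed[s]
        rows.append((s, pt, bool(pe), ot, bool(oe)))
    tab = pd.DataFrame(rows, columns=["subject", "predicted_time",
                                      "predicted_event", "observed_time",
                                      "observed_event"])
    if not tab.observed_event.any():
        raise ValueError("all observations censored: no survival comparison")
    lr = logrank_test(tab.predicted_time, tab.observed_time,
                      event_observed_A=tab.predicted_event,
                      event_observed_B=tab.observed_event)
    order_stat = (np.array([scores[s] for s in subjects], dtype=float)
                  if scores is not None else tab.predicted_time)
    c = concordance_index(order_stat, tab.observed_time, tab.observed_event)
    return SurvivalComparison(table=tab, logrank_stat=float(lr.test_statistic),
                              logrank_p=float(lr.p_value), c_index=float(c))
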