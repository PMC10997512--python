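"""Potential landscapes for transcriptome state-transition models.

Two routes produce the landscape:

* **Mechanistic** — a double-negative-feedback gene circuit (DNFL-B) in
  which the oncogenic signal S acts on a cell compartment A, and A and the
  observable transcriptome coordinate B mutually repress each other while B
  weakly self-activates.  Eliminating A at quasi-steady state yields an
  effective 1-D force ``F(B, S)`` whose sign changes are the critical
  points of the landscape; the potential is ``V(B, S) = -∫ F dx``.

* **Empirical** — kernel density estimation of observed sample coordinates
  in the disease state-space.  Density maxima are taken as the stable
  critical points, the minima between them as the unstable ones, and the
  landscape is represented by the quintic-gradient polynomial

      dU/dx = a (x - c1)(x - c2)(x - c3)(x - c4)(x - c5)

Critical points are stored in *label order* ``c1 .. c5`` running from the
health side toward the disease side of the axis (under the health-high
orientation of the state-space this is decreasing coordinate order).  The
stability pattern — c1, c3, c5 stable, c2, c4 unstable — depends only on
the root set, not on the label direction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq
from scipy.stats import gaussian_kde

__all__ = [
    "hill_minus",
    "hill_plus",
    "CircuitParams",
    "rate_GA",
    "rate_GB",
    "steady_state_A",
    "effective_force",
    "circuit_potential",
    "find_critical_points",
    "CriticalPointSet",
    "PotentialModel",
    "circuit_potential_model",
    "empirical_potential_from_density",
    "evaluate_potential",
]


# ---------------------------------------------------------------------------
# Hill switching functions
# ---------------------------------------------------------------------------

def hill_minus(x, x0, n):
    """Repressive Hill function ``H-(x) = 1 / (1 + (x/x0)^n)``.

    Monotone decreasing from 1 at ``x = 0`` to 0 as ``x -> inf``, equal to
    1/2 at ``x = x0``.  ``x0`` must be positive and ``n >= 1``.
    """
    if x0 <= 0:
        raise ValueError(f"Hill threshold x0 must be positive, got {x0}")
    if n < 1:
        raise ValueError(f"Hill coefficient n must be >= 1, got {n}")
    x = np.asarray(x, dtype=float)
    out = 1.0 / (1.0 + (x / x0) ** n)
    return out if out.ndim else float(out)


def hill_plus(x, x0, n):
    """Activating Hill function ``H+(x) = 1 - H-(x)``."""
    return 1.0 - hill_minus(x, x0, n)


# ---------------------------------------------------------------------------
# Circuit model
# ---------------------------------------------------------------------------

@dataclass
class CircuitParams:
    """Rate constants and Hill parameters of the DNFL-B circuit.

    Production-rate subscripts name the occupancy corner they dominate:
    for ``g_a_*`` the first letter refers to the signal S, the second to
    the transcriptome B; for ``g_b_*`` the first letter refers to the cell
    compartment A, the second to B.  ``m`` means the regulator is low
    (H- weight), ``p`` that it is high (H+ weight).

    ``gamma_circuit`` is the treatment response modifier: it multiplies
    the transcriptome production rates under regulated (A-high)
    conditions, ``g_b_pm`` and ``g_b_pp``.  The untreated circuit has
    ``gamma_circuit = 1``; TOTO uses 1.1 and TKI 1.4.
    """

    g_a_mm: float = 3.0
    g_a_pm: float = 1.0
    g_a_mp: float = 3.0
    g_a_pp: float = 0.15
    g_b_mm: float = 0.4
    g_b_pm: float = 0.8
    g_b_mp: float = 6.5
    g_b_pp: float = 1.2
    k_a: float = 1.0
    k_b: float = 1.0
    x0_s: float = 0.5
    n_s: float = 4
    x0_a: float = 0.93
    n_a: float = 6
    x0_b_on_a: float = 5.0
    n_b_on_a: float = 12
    x0_b: float = 2.0
    n_b: float = 6
    s: float = 0.0
    s_max: float = 2.0
    gamma_circuit: float = 1.0

    def __post_init__(self):
        for name in ("g_a_mm", "g_a_pm", "g_a_mp", "g_a_pp",
                     "g_b_mm", "g_b_pm", "g_b_mp", "g_b_pp"):
            if getattr(self, name) < 0:
                raise ValueError(f"production rate {name} must be >= 0")
        if self.k_a <= 0 or self.k_b <= 0:
            raise ValueError("degradation rates k_a, k_b must be positive")
        for name in ("n_s", "n_a", "n_b_on_a", "n_b"):
            if getattr(self, name) < 1:
                raise ValueError(f"Hill coefficient {name} must be >= 1")
        if self.s < 0:
            raise ValueError("signal level s must be nonnegative")

    @classmethod
    def reference(cls) -> "CircuitParams":
        """Load the packaged reference parameter set."""
        text = (resources.files("cmlstate.data") / "dnflb_reference.yaml").read_text()
        return cls(**yaml.safe_load(text))

    @classmethod
    def from_yaml(cls, path) -> "CircuitParams":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def with_(self, **kwargs) -> "CircuitParams":
        return replace(self, **kwargs)


def rate_GA(S, B, params: CircuitParams):
    """Production rate of the cell compartment A given signal S and state B.

    A convex combination of the four corner rates weighted by the Hill
    occupancy partition; weights sum to one at any (S, B).
    """
    p = params
    hs_m = hill_minus(S, p.x0_s, p.n_s)
    hs_p = 1.0 - hs_m
    hb_m = hill_minus(B, p.x0_b_on_a, p.n_b_on_a)
    hb_p = 1.0 - hb_m
    return (p.g_a_mm * hs_m * hb_m + p.g_a_pm * hs_p * hb_m
            + p.g_a_mp * hs_m * hb_p + p.g_a_pp * hs_p * hb_p)


def rate_GB(A, B, params: CircuitParams):
    """Production rate of the transcriptome coordinate B given A and B.

    The treatment response modifier ``gamma_circuit`` multiplies the
    A-high (regulated) production rates.
    """
    p = params
    ha_m = hill_minus(A, p.x0_a, p.n_a)
    ha_p = 1.0 - ha_m
    hb_m = hill_minus(B, p.x0_b, p.n_b)
    hb_p = 1.0 - hb_m
    g = p.gamma_circuit
    return (p.g_b_mm * ha_m * hb_m + g * p.g_b_pm * ha_p * hb_m
            + p.g_b_mp * ha_m * hb_p + g * p.g_b_pp * ha_p * hb_p)


def steady_state_A(S, B, params: CircuitParams):
    """Quasi-steady-state level of A: ``A* = G_A(S, B) / k_A``."""
    return rate_GA(S, B, params) / params.k_a


def effective_force(B, S, params: CircuitParams):
    """Effective 1-D force on B after eliminating A at steady state.

    ``F(B, S) = G_B(A*(S, B), B) - k_B B``.
    """
    A = steady_state_A(S, B, params)
    return rate_GB(A, B, params) - params.k_b * np.asarray(B, dtype=float)


def circuit_potential(B, S, params: CircuitParams, b_max=None):
    """Effective potential ``V(B, S) = -∫_0^B F(x, S) dx``.

    Evaluated by adaptive quadrature per requested point; ``V(0, S) = 0``.
    ``B`` may be a scalar or array and must lie inside ``[0, b_max]``.
    """
    from scipy.integrate import quad
    if b_max is None:
        b_max = 2.0 * params.x0_b_on_a
    B = np.asarray(B, dtype=float)
    if np.any(B < 0) or np.any(B > b_max):
        raise ValueError(f"B outside the quadrature grid [0, {b_max}]")
    flat = np.atleast_1d(B)
    out = np.empty_like(flat)
    for i, b in enumerate(flat):
        val, _ = quad(lambda x: effective_force(x, S, params), 0.0, b,
                      limit=200, epsabs=1e-11, epsrel=1e-11)
        out[i] = -val
    return out.reshape(B.shape) if B.ndim else float(out[0])


# ---------------------------------------------------------------------------
# Critical points
# ---------------------------------------------------------------------------

@dataclass
class CriticalPointSet:
    """Zeros of a 1-D force with stability labels.

    ``locations`` are sorted in increasing coordinate order; ``stable[i]``
    is True where the force crosses from positive to negative (a potential
    minimum).  ``signal`` records the signal level S at which the force
    was evaluated, when applicable.
    """

    locations: np.ndarray
    stable: np.ndarray
    signal: float | None = None

    def __len__(self):
        return len(self.locations)

    @property
    def n_stable(self):
        return int(np.sum(self.stable))

    @property
    def stable_points(self):
        return self.locations[self.stable]

    @property
    def unstable_points(self):
        return self.locations[~self.stable]


def find_critical_points(force, grid, signal=None, tol=1e-8,
                         refine_levels=2) -> CriticalPointSet:
    """Locate the roots of ``force`` on ``grid`` with bisection refinement.

    Roots are bracketed by sign changes on the grid (adaptively refined
    ``refine_levels`` times so closely spaced roots are separated) and
    polished with Brent's method to ``tol``.  Stability follows the force
    slope: a root is stable when the force passes from + to - along
    increasing x (for dynamics ``dx = F dt``, i.e. U'' > 0).

    Returns an empty set (with no error) when the force has no sign
    change on the grid.
    """
    grid = np.asarray(grid, dtype=float)
    for _ in range(refine_levels):
        fine = np.linspace(grid[0], grid[-1], 2 * len(grid) - 1)
        grid = fine
    f = np.asarray(force(grid), dtype=float)
    sign = np.sign(f)
    # treat exact zeros as part of the following interval
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    locs, stab = [], []
    for i in idx:
        root = brentq(force, grid[i], grid[i + 1], xtol=tol)
        h = max(tol * 100, 1e-7 * (grid[-1] - grid[0]))
        stable = force(root - h) > 0 and force(root + h) < 0
        locs.append(root)
        stab.append(stable)
    # exact grid-point zeros (rare; e.g. constructed polynomials)
    zero_idx = np.nonzero(f == 0.0)[0]
    for i in zero_idx:
        x = grid[i]
        if any(abs(x - l) < 10 * tol for l in locs):
            continue
        h = max(tol * 100, 1e-7 * (grid[-1] - grid[0]))
        locs.append(x)
        stab.append(force(x - h) > 0 and force(x + h) < 0)
    order = np.argsort(locs)
    return CriticalPointSet(
        locations=np.asarray(locs)[order],
        stable=np.asarray(stab, dtype=bool)[order],
        signal=signal,
    )


# ---------------------------------------------------------------------------
# Polynomial potential model
# ---------------------------------------------------------------------------

_KINDS = ("quintic", "cubic", "linear", "circuit-derived")


@dataclass
class PotentialModel:
    """A 1-D landscape with polynomial gradient ``dU/dx = a prod(x - c_i)``.

    ``critical_points`` are stored in label order c1 .. c5 (health side
    first); ``c_h`` optionally records the healthy-state location from the
    control-sample density.  ``kind`` is "quintic" (5 points), "cubic"
    (3) or "linear" (1), degrading gracefully when fewer density modes
    are resolvable; "circuit-derived" models wrap a numeric force instead
    (see :func:`circuit_potential_model`).

    The potential is the exact polynomial antiderivative of the gradient,
    gauged so that ``U = 0`` at the middle critical point (``gauge``).
    """

    kind: str
    a: float
    critical_points: np.ndarray
    c_h: float | None = None
    gauge: float | None = None
    _force: object = field(default=None, repr=False, compare=False)
    _numeric: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown potential kind {self.kind!r}")
        self.critical_points = np.asarray(self.critical_points, dtype=float)
        expected = {"quintic": 5, "cubic": 3, "linear": 1}
        if self.kind in expected and len(self.critical_points) != expected[self.kind]:
            raise ValueError(
                f"{self.kind} potential needs {expected[self.kind]} critical "
                f"points, got {len(self.critical_points)}")
        if self.kind != "circuit-derived" and self.a <= 0:
            raise ValueError("amplitude a must be positive")
        if self.gauge is None and self.kind != "circuit-derived":
            mid = len(self.critical_points) // 2
            self.gauge = float(self.critical_points[mid])

    # -- labeled accessors (label order: c1 = health side) ------------------
    def c(self, i: int) -> float:
        """Critical point by 1-based label index (c1 ... c5)."""
        return float(self.critical_points[i - 1])

    @property
    def disease_direction(self) -> int:
        """+1 if disease lies toward larger coordinates, else -1."""
        if len(self.critical_points) > 1:
            return int(np.sign(self.critical_points[-1] - self.critical_points[0]))
        if self.c_h is not None:
            d = self.critical_points[0] - self.c_h
            if d != 0:
                return int(np.sign(d))
        return -1  # health-high convention

    @property
    def sorted_points(self) -> np.ndarray:
        return np.sort(self.critical_points)

    @property
    def stable_points(self) -> np.ndarray:
        """Minima of U: every other sorted critical point, outermost included."""
        return self.sorted_points[::2]

    @property
    def unstable_points(self) -> np.ndarray:
        return self.sorted_points[1::2]

    # -- evaluators ----------------------------------------------------------
    def gradient(self, x):
        """dU/dx at x."""
        if self.kind == "circuit-derived":
            return -np.asarray(self._force(x), dtype=float)
        x = np.asarray(x, dtype=float)
        out = self.a * np.prod(
            [x - c for c in self.critical_points], axis=0)
        return out if out.ndim else float(out)

    def potential(self, x):
        """U(x), gauged to zero at ``gauge``."""
        if self.kind == "circuit-derived":
            xg, Vg = self._numeric
            out = np.interp(np.asarray(x, dtype=float), xg, Vg)
            return out if np.ndim(out) else float(out)
        coeffs = self.a * np.poly(self.critical_points)  # highest power first
        # antiderivative coefficients
        n = len(coeffs)
        anti = np.append(coeffs / np.arange(n, 0, -1), 0.0)
        x = np.asarray(x, dtype=float)
        out = np.polyval(anti, x) - np.polyval(anti, self.gauge)
        return out if out.ndim else float(out)

    def curvature(self, x):
        """U''(x) by exact polynomial derivative (finite diff for circuit)."""
        if self.kind == "circuit-derived":
            h = 1e-5
            return (self.gradient(x + h) - self.gradient(x - h)) / (2 * h)
        coeffs = self.a * np.poly(self.critical_points)
        d = np.polyder(coeffs)
        out = np.polyval(d, np.asarray(x, dtype=float))
        return out if np.ndim(out) else float(out)

    # -- serialization -------------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "kind": self.kind,
            "a": self.a,
            "critical_points": self.critical_points.tolist(),
            "c_h": self.c_h,
            "gauge": self.gauge,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PotentialModel":
        if isinstance(source, (str, Path)) and Path(source).exists():
            source = Path(source).read_text()
        payload = json.loads(source)
        return cls(**payload)


def circuit_potential_model(params: CircuitParams, b_max=None,
                            n_grid=4097) -> PotentialModel:
    """Wrap the circuit's effective force as a (numeric) PotentialModel.

    The gradient is ``-F(B, s)`` at the parameter set's signal level; the
    potential is the quadrature antiderivative.  Critical points are the
    force roots in increasing B order.
    """
    if b_max is None:
        b_max = 2.0 * params.x0_b_on_a
    grid = np.linspace(0.0, b_max, n_grid)

    def force(x):
        return effective_force(x, params.s, params)

    cps = find_critical_points(force, np.linspace(0.0, b_max, 2049),
                               signal=params.s)
    V = -cumulative_trapezoid(force(grid), grid, initial=0.0)
    model = PotentialModel(
        kind="circuit-derived", a=1.0,
        critical_points=cps.locations, gauge=0.0,
        _force=force, _numeric=(grid, V),
    )
    return model


# ---------------------------------------------------------------------------
# Empirical potential from sample density
# ---------------------------------------------------------------------------

def _refine_extremum(xg, yg, i):
    """Parabolic refinement of a grid extremum at index i."""
    if i == 0 or i == len(xg) - 1:
        return xg[i]
    x0, x1, x2 = xg[i - 1], xg[i], xg[i + 1]
    y0, y1, y2 = yg[i - 1], yg[i], yg[i + 1]
    num = (x1 - x0) ** 2 * (y1 - y2) - (x1 - x2) ** 2 * (y1 - y0)
    den = (x1 - x0) * (y1 - y2) - (x1 - x2) * (y1 - y0)
    if den == 0:
        return x1
    return x1 - 0.5 * num / den


def _density_extrema(values, n_grid=2048):
    """KDE (Silverman bandwidth) and its interior maxima/minima."""
    values = np.asarray(values, dtype=float)
    kde = gaussian_kde(values, bw_method="silverman")
    bw = np.sqrt(kde.covariance[0, 0])
    lo, hi = values.min() - 3 * bw, values.max() + 3 * bw
    xg = np.linspace(lo, hi, n_grid)
    yg = kde(xg)
    maxima, minima = [], []
    for i in range(1, n_grid - 1):
        if yg[i] > yg[i - 1] and yg[i] >= yg[i + 1]:
            maxima.append((_refine_extremum(xg, yg, i), yg[i]))
        elif yg[i] < yg[i - 1] and yg[i] <= yg[i + 1]:
            minima.append((_refine_extremum(xg, yg, i), yg[i]))
    return kde, bw, maxima, minima


def empirical_potential_from_density(cml_coords, control_coords=None,
                                     a=1.0, n_grid=2048) -> PotentialModel:
    """Build a polynomial landscape from observed sample coordinates.

    A Gaussian KDE (Silverman's rule) is fitted to the disease-cohort
    coordinates.  Density maxima become the stable critical points, the
    minima between consecutive maxima the unstable ones, and the model is
    returned with the quintic gradient ``a prod(x - c_i)``.  When fewer
    than three maxima are resolved the model degrades to "cubic" (one
    barrier) or "linear" (single well), labeled explicitly in ``kind``.

    The control-sample density mode, when given, is stored as ``c_h``.
    Critical points are stored in label order c1 .. c5 from the health
    side (the side of ``c_h``, or the highest-coordinate mode under the
    health-high convention) toward the disease side.
    """
    cml_coords = np.asarray(cml_coords, dtype=float)
    if len(cml_coords) < 10:
        raise ValueError("need at least 10 disease-cohort samples for the KDE")
    _, bw, maxima, minima = _density_extrema(cml_coords, n_grid=n_grid)
    if len(maxima) > 3:  # keep the three strongest modes
        maxima = sorted(maxima, key=lambda t: -t[1])[:3]
    modes = sorted(x for x, _ in maxima)

    c_h = None
    if control_coords is not None:
        control_coords = np.asarray(control_coords, dtype=float)
        _, _, cmax, _ = _density_extrema(control_coords, n_grid=n_grid)
        if cmax:
            c_h = float(max(cmax, key=lambda t: t[1])[0])

    # antimodes between consecutive retained modes
    anti = []
    for left, right in zip(modes[:-1], modes[1:]):
        inside = [(x, y) for x, y in minima if left < x < right]
        if inside:
            anti.append(min(inside, key=lambda t: t[1])[0])
        else:  # ties/flat density: fall back to the midpoint
            anti.append(0.5 * (left + right))

    pts = np.sort(np.concatenate([modes, anti]))
    kind = {5: "quintic", 3: "cubic", 1: "linear"}[len(pts)]

    # orient labels: c1 nearest health
    if c_h is not None:
        health_high = abs(pts[-1] - c_h) <= abs(pts[0] - c_h)
    else:
        health_high = True  # health-high convention by default
    labeled = pts[::-1] if health_high else pts
    return PotentialModel(kind=kind, a=a, critical_points=labeled, c_h=c_h)


def evaluate_potential(model: PotentialModel, x):
    """U(x) for a potential model (polynomial antiderivative, gauged)."""
    return model.potential(x)
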