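"""Synthetic four-cohort time-series RNA-seq generator.

Emulates the experimental design the analysis assumes: weekly peripheral
blood sampling of control, untreated-disease (CML), signal-silencing
(TOTO) and kinase-inhibitor (TKI) cohorts over weeks 0-18, with a
low-rank disease signal planted along a latent Langevin trajectory
through a multiwell landscape.

Each mouse carries a latent state-space coordinate ``x_m(t)`` simulated
under its cohort's potential and treatment schedule.  Gene-level
log-mean expression is

    mu_gs = b_g + sigma_d * v2_g * x_s + sigma_n * v1_g * z_s (+ sex term)

with planted orthonormal loading vectors ``v1`` (nuisance) and ``v2``
(disease) and per-sample nuisance factor ``z_s``; counts are negative
binomial with shared dispersion (variance mu + phi mu^2).  The oncogene
transcript rises only after an induction latency; the myeloid fraction
is a monotone logistic function of the latent coordinate; subjects whose
coordinate crosses the endpoint threshold stop contributing samples
after the crossing week.

The count-noise family of the real assay is not stated by the source
experiment; negative binomial is an explicit modeling assumption here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .dynamics import simulate_langevin
from .potentials import PotentialModel
from .treatment import TreatmentSchedule

__all__ = [
    "SyntheticConfig",
    "TiltedSchedule",
    "default_true_potential",
    "generate_cohort",
    "write_dataset",
    "read_dataset",
]


def default_true_potential() -> PotentialModel:
    """The planted tri-stable landscape, in health-high coordinates.

    Critical points c1..c5 run from the early-disease well (1.4) down to
    the late-disease well (-0.9); the control well sits at c_h = 1.5.
    The spacing keeps the transition barriers of order the diffusion
    coefficient; combined with the per-subject aggressiveness tilt this
    yields a median first passage to the disease well of roughly seven
    to ten weeks with most, but not all, subjects progressing.
    """
    return PotentialModel(kind="quintic", a=2.2,
                          critical_points=[1.4, 1.1, 0.65, 0.35, -0.9],
                          c_h=1.5)


@dataclass
class SyntheticConfig:
    """Study-design and noise parameters of the generator.

    Defaults mirror the emulated experiment: cohort sizes 3/6/4/7
    (control/CML/TOTO/TKI), weekly sampling over weeks 0-18, treatment
    from week 6 (TKI dosing 4 weeks), an oncogene induction latency of
    4.5 weeks, and a diffusion coefficient inside the plausible range of
    the trajectory calibration (0.001-0.1 state units^2/week).
    """

    n_genes: int = 20000
    cohort_sizes: dict = field(default_factory=lambda: {
        "control": 3, "CML": 6, "TOTO": 4, "TKI": 7})
    weeks: tuple = (0, 18)
    true_potential: PotentialModel = field(default_factory=default_true_potential)
    control_curvature: float = 2.0
    true_gamma: dict = field(default_factory=lambda: {"TOTO": 1.1, "TKI": 1.4})
    true_beta: float = 0.02
    loading_scale_disease: float = 34.0
    loading_scale_nuisance: float = 50.0
    nb_dispersion: float = 0.1
    bcrabl_latency_weeks: float = 4.5
    seed: int = 0
    endpoint_threshold: float | None = None  # default: the late-disease point c5
    endpoint_delay_weeks: int = 2            # moribund delay after crossing
    # per-subject disease aggressiveness: a constant disease-ward tilt force
    # drawn log-normally; the week-0 coordinate is shifted proportionally so
    # the baseline transcriptome carries prognostic information
    frailty_tilt_mean: float = 0.08
    frailty_tilt_sd: float = 0.8
    frailty_coupling: float = 4.0
    baseline_noise_sd: float = 0.1
    aging_drift_per_week: float = 0.015
    baseline_log_mean: float = 2.0
    baseline_log_sd: float = 1.2
    sex_effect: float = 0.1
    t_on: float = 6.0
    t_off: float = 10.0
    langevin_dt: float = 0.003
    bcrabl_scale: float = 100.0

    def __post_init__(self):
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if any(n < 1 for n in self.cohort_sizes.values()):
            raise ValueError("every cohort needs at least one subject")
        lo, hi = self.weeks
        if hi - lo + 1 < 2:
            raise ValueError("need at least 2 weekly time points")
        if self.true_beta <= 0:
            raise ValueError("true_beta must be positive")
        if self.bcrabl_latency_weeks < 0:
            raise ValueError("latency must be nonnegative")


_PREFIX = {"control": "C", "CML": "M", "TOTO": "T", "TKI": "K"}


def _signal_curve(t, cfg: SyntheticConfig, cohort: str):
    """Relative oncogene signal in [0, 1] vs time for one cohort.

    A soft-plus ramp delayed by the induction latency; silencing decays
    it exponentially after t_on (TOTO), inhibitor dosing scales it down
    during [t_on, t_off] (TKI, rebounding afterwards).
    """
    t = np.asarray(t, dtype=float)
    if cohort == "control":
        return np.zeros_like(t)
    lat, tau = cfg.bcrabl_latency_weeks, 1.5
    ramp = np.log1p(np.exp((t - lat) / tau))
    ramp = ramp / np.log1p(np.exp((cfg.weeks[1] - lat) / tau))
    if cohort == "TOTO":
        off = t >= cfg.t_on
        ramp_at_on = (np.log1p(np.exp((cfg.t_on - lat) / tau))
                      / np.log1p(np.exp((cfg.weeks[1] - lat) / tau)))
        ramp = np.where(off, ramp_at_on * np.exp(-2.0 * (t - cfg.t_on)), ramp)
    elif cohort == "TKI":
        dosing = (t >= cfg.t_on) & (t <= cfg.t_off)
        ramp = np.where(dosing, 0.35 * ramp, ramp)
    return np.clip(ramp, 0.0, 1.0)


def _myeloid_mean(x):
    return 0.1 + 0.75 / (1.0 + np.exp(2.0 * (np.asarray(x, dtype=float) - 0.35)))


class TiltedSchedule:
    """A cohort schedule plus a constant per-subject disease-ward force."""

    def __init__(self, base: TreatmentSchedule, tilt_force: float):
        self.base = base
        self.tilt_force = tilt_force
        self.kind = base.kind

    def force(self, potential, x, t):
        return self.base.force(potential, x, t) + self.tilt_force

    def diffusion(self, t):
        return self.base.diffusion(t)


def _cohort_schedule(cfg: SyntheticConfig, cohort: str) -> TreatmentSchedule:
    b = cfg.true_beta
    if cohort == "TOTO":
        return TreatmentSchedule.toto(gamma=cfg.true_gamma["TOTO"],
                                      t_on=cfg.t_on, beta_pre=b, beta_on=b,
                                      beta_post=b)
    if cohort == "TKI":
        return TreatmentSchedule.tki(gamma=cfg.true_gamma["TKI"],
                                     t_on=cfg.t_on, t_off=cfg.t_off,
                                     beta_pre=b, beta_on=b, beta_post=b)
    return TreatmentSchedule.none(beta=b)


def generate_cohort(config: SyntheticConfig):
    """Generate (counts, sample table, latent truth record).

    Counts are a genes x samples integer DataFrame; the sample table has
    one row per (mouse, week); the truth record stores every planted
    quantity: latent trajectories, loading vectors, nuisance factors and
    the generator parameters.  A fixed seed makes the output
    bit-identical.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    w0, w1 = cfg.weeks
    weeks = np.arange(w0, w1 + 1)
    pot = cfg.true_potential
    control_pot = PotentialModel(kind="linear", a=cfg.control_curvature,
                                 critical_points=[pot.c_h], c_h=pot.c_h)
    endpoint = cfg.endpoint_threshold
    if endpoint is None:
        endpoint = pot.critical_points[-1]
    direction = pot.disease_direction

    # ---- latent trajectories ------------------------------------------------
    latent = {}       # mouse -> (weeks kept, x values)
    tilts = {}
    mice = []
    sex_cycle = ["M", "F"]
    mouse_counter = 0
    for cohort in ("control", "CML", "TOTO", "TKI"):
        n = cfg.cohort_sizes.get(cohort, 0)
        if n == 0:
            continue
        sim_pot = control_pot if cohort == "control" else pot
        schedule = _cohort_schedule(cfg, cohort)
        for i in range(n):
            mouse = f"{_PREFIX[cohort]}{i + 1}"
            if cohort == "control":
                tilt = 0.0
                x0 = pot.c_h + cfg.baseline_noise_sd * rng.standard_normal()
            else:
                tilt = float(np.exp(np.log(cfg.frailty_tilt_mean)
                                    + cfg.frailty_tilt_sd
                                    * np.clip(rng.standard_normal(), -2, 2))) \
                    if cfg.frailty_tilt_mean > 0 else 0.0
                lo_clip, hi_clip = sorted((
                    pot.critical_points[-2] + 0.25 * (-direction),
                    pot.c_h + 0.5 * (-direction)))
                x0 = float(np.clip(
                    pot.c_h + direction * cfg.frailty_coupling * tilt
                    + cfg.baseline_noise_sd * rng.standard_normal(),
                    lo_clip, hi_clip))
            ens = simulate_langevin(
                sim_pot, x0=x0, t_max=float(w1 - w0), dt=cfg.langevin_dt,
                schedule=TiltedSchedule(schedule, direction * tilt),
                n_reps=1, rng=rng, record_dt=1.0, t0=float(w0))
            path = np.interp(weeks, ens.times, ens.paths[0])
            path = path + direction * cfg.aging_drift_per_week * (weeks - w0)
            beyond = direction * (path - endpoint) >= 0
            if cohort != "control" and beyond.any():
                # sampled through the crossing week plus a short moribund delay
                last = min(int(np.argmax(beyond)) + cfg.endpoint_delay_weeks,
                           len(weeks) - 1)
            else:
                last = len(weeks) - 1
            latent[mouse] = (weeks[: last + 1].copy(), path[: last + 1].copy())
            tilts[mouse] = tilt
            mice.append((mouse, cohort, sex_cycle[mouse_counter % 2]))
            mouse_counter += 1

    # ---- sample table -------------------------------------------------------
    rows = []
    for mouse, cohort, sex in mice:
        wk, xs = latent[mouse]
        sig = _signal_curve(wk, cfg, cohort)
        bcr = cfg.bcrabl_scale * sig * np.exp(0.15 * rng.standard_normal(len(wk)))
        bcr[sig == 0] = 0.0
        mye = np.clip(_myeloid_mean(xs)
                      + 0.02 * rng.standard_normal(len(xs)), 0.0, 1.0)
        for j, w in enumerate(wk):
            rows.append({
                "sample": f"{mouse}_w{int(w):02d}", "mouse": mouse,
                "cohort": cohort, "week": int(w), "sex": sex,
                "bcrabl_abundance": float(bcr[j]),
                "myeloid_fraction": float(mye[j]),
            })
    table = pd.DataFrame(rows).set_index("sample")

    # ---- expression ---------------------------------------------------------
    G = cfg.n_genes
    genes = pd.Index([f"g{i:05d}" for i in range(G)], name="gene")
    b = cfg.baseline_log_mean + cfg.baseline_log_sd * rng.standard_normal(G)
    raw = rng.standard_normal((G, 2))
    q, _ = np.linalg.qr(raw)
    v1, v2 = q[:, 0], q[:, 1]
    x_s = np.array([latent[m][1][list(latent[m][0]).index(w)]
                    for m, w in zip(table.mouse, table.week)])
    # nuisance factor: a shared aging/technical trend plus sample noise, so
    # the first principal axis carries a coherent non-disease signal
    week_arr = table.week.to_numpy(dtype=float)
    z_s = (week_arr - week_arr.mean()) / max(week_arr.std(), 1.0) \
        + 0.4 * rng.standard_normal(len(table))
    sex_genes = rng.choice(G, size=G // 20, replace=False)
    sex_vec = np.zeros(G)
    sex_vec[sex_genes] = cfg.sex_effect
    is_f = (table.sex == "F").to_numpy(dtype=float)

    mu_log = (b[:, None]
              + cfg.loading_scale_disease * np.outer(v2, x_s)
              + cfg.loading_scale_nuisance * np.outer(v1, z_s)
              + np.outer(sex_vec, is_f))
    mu = np.exp(np.clip(mu_log, None, 30.0))  # overflow guard at tiny n_genes
    phi = cfg.nb_dispersion
    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    counts = rng.poisson(lam).astype(np.int64)
    counts = pd.DataFrame(counts, index=genes, columns=table.index)

    truth = {
        "latent": {m: {"weeks": wk.tolist(), "x": xs.tolist()}
                   for m, (wk, xs) in latent.items()},
        "v1": v1.tolist(), "v2": v2.tolist(),
        "z": z_s.tolist(), "baseline_log": b.tolist(),
        "x_per_sample": dict(zip(table.index, x_s.tolist())),
        "tilts": tilts,
        "endpoint_threshold": float(endpoint),
        "critical_points": pot.critical_points.tolist(),
        "c_h": pot.c_h,
        "params": {
            "n_genes": G, "true_beta": cfg.true_beta,
            "true_gamma": cfg.true_gamma,
            "loading_scale_disease": cfg.loading_scale_disease,
            "loading_scale_nuisance": cfg.loading_scale_nuisance,
            "nb_dispersion": phi, "seed": cfg.seed,
            "bcrabl_latency_weeks": cfg.bcrabl_latency_weeks,
        },
    }
    return counts, table, truth


# ---------------------------------------------------------------------------
# Disk round-trip
# ---------------------------------------------------------------------------

def write_dataset(counts: pd.DataFrame, table: pd.DataFrame, path,
                  truth=None, fmt="tsv"):
    """Write counts + metadata (+ optional truth record) to a directory.

    ``fmt="tsv"`` writes a dense TSV (genes as rows, sample-id header);
    ``fmt="mtx"`` writes sparse triplet MatrixMarket with separate gene
    and sample id files.
    """
    if counts.shape[0] == 0:
        raise ValueError("empty gene set")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if fmt == "tsv":
        counts.to_csv(path / "counts.tsv", sep="\t")
    elif fmt == "mtx":
        scipy.io.mmwrite(path / "counts.mtx",
                         scipy.sparse.csr_matrix(counts.to_numpy()))
        (path / "genes.txt").write_text("\n".join(counts.index) + "\n")
        (path / "samples.txt").write_text("\n".join(counts.columns) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    table.to_csv(path / "metadata.tsv", sep="\t")
    if truth is not None:
        (path / "truth.json").write_text(json.dumps(truth))


def read_dataset(path):
    """Read a dataset directory back into (counts, table).

    Validates the count invariants; a negative entry raises a parse
    error naming the offending gene and sample.
    """
    path = Path(path)
    if (path / "counts.tsv").exists():
        counts = pd.read_csv(path / "counts.tsv", sep="\t", index_col=0)
    elif (path / "counts.mtx").exists():
        mat = scipy.io.mmread(path / "counts.mtx").toarray()
        genes = (path / "genes.txt").read_text().splitlines()
        samples = (path / "samples.txt").read_text().splitlines()
        counts = pd.DataFrame(mat, index=pd.Index(genes, name="gene"),
                              columns=samples)
    else:
        raise FileNotFoundError(f"no counts.tsv or counts.mtx under {path}")
    if counts.shape[0] == 0:
        raise ValueError("empty gene set in counts file")
    neg = counts.lt(0)
    if neg.any().any():
        col = neg.any(axis=0).idxmax()
        gene = neg[col].idxmax()
        raise ValueError(
            f"negative count at gene {gene!r}, sample {col!r}")
    counts = counts.astype(np.int64)
    table = pd.read_csv(path / "metadata.tsv", sep="\t", index_col=0)
    bad = set(table.cohort) - {"control", "CML", "TOTO", "TKI"}
    if bad:
        raise ValueError(f"unknown cohorts in metadata: {sorted(bad)}")
    if table.duplicated(subset=["mouse", "week"]).any():
        raise ValueError("duplicate (mouse, week) rows in metadata")
    return counts, table
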