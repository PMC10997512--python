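"""Disease state-space construction from time-series expression.

The state-space is built by singular value decomposition of
log-normalized, gene-centered expression of the control and untreated
disease cohorts (all time points).  The (PC1, PC2) plane is then rotated
so the least-squares fit of the control samples is parallel to the first
axis, the disease axis is selected as the one best separating control
from disease-endpoint samples, and its sign is fixed so that health maps
to larger coordinates than disease.  Held-out (treatment) samples are
projected with ``U_T = X_T V S^-1`` using the stored transform.

The rotated loading column of the disease axis is the *eigengene*
vector: each gene's directional pull on a sample's coordinate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "normalize_expression",
    "log_cpm",
    "StateSpaceModel",
    "fit_state_space",
    "build_state_space",
    "rotate_axes",
    "select_disease_axis",
    "orient_axis",
    "project_samples",
    "coordinate_series",
]

COHORTS = ("control", "CML", "TOTO", "TKI")
TRAIN_COHORTS = ("control", "CML")


def log_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(CPM + 1) per sample (columns are samples, rows genes)."""
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = list(lib.index[lib == 0])
        raise ValueError(f"samples with zero library size: {bad}")
    return np.log2(counts / lib * 1e6 + 1.0)


def normalize_expression(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(CPM + 1) followed by per-gene mean-centering.

    Returns a genes x samples real matrix; the centering means are those
    of the given matrix (a fitted model stores its own training means for
    projection reuse).
    """
    lc = log_cpm(counts)
    return lc.sub(lc.mean(axis=1), axis=0)


def _rotation_matrix(theta_deg: float) -> np.ndarray:
    """Axis rotation by theta (counter-clockwise, degrees) acting on
    row-vector (pc1, pc2) scores from the right."""
    th = np.deg2rad(theta_deg)
    return np.array([[np.cos(th), -np.sin(th)],
                     [np.sin(th), np.cos(th)]])


@dataclass
class StateSpaceModel:
    """SVD factors plus rotation/selection/orientation of the disease axis."""

    genes: pd.Index
    center: pd.Series              # per-gene training mean of log2(CPM+1)
    sample_ids: pd.Index           # training samples (control + disease)
    U: np.ndarray                  # samples x k scores (unrotated)
    S: np.ndarray                  # singular values
    V: np.ndarray                  # genes x k loadings (unrotated)
    rotation_angle_degrees: float = 0.0
    disease_axis_index: int | None = None
    orientation_sign: int = 1
    axis_diagnostics: pd.DataFrame | None = None
    selection_reliable: bool = True

    @property
    def k(self) -> int:
        return len(self.S)

    # -- transforms ----------------------------------------------------------
    def normalize(self, counts: pd.DataFrame) -> pd.DataFrame:
        """log2(CPM+1) on the model's gene set, centered by the stored
        training means (genes x samples in and out)."""
        missing = self.genes.difference(counts.index)
        if len(missing):
            raise ValueError(
                f"{len(missing)} model genes missing from input, e.g. "
                f"{list(missing[:5])}")
        lc = log_cpm(counts.loc[self.genes])
        return lc.sub(self.center, axis=0)

    def scores(self) -> np.ndarray:
        """Training-sample scores after rotation and orientation."""
        return self._transform_scores(self.U.copy())

    def _transform_scores(self, u: np.ndarray) -> np.ndarray:
        u[:, :2] = u[:, :2] @ _rotation_matrix(self.rotation_angle_degrees)
        if self.disease_axis_index is not None:
            u[:, self.disease_axis_index] *= self.orientation_sign
        return u

    def loadings(self) -> np.ndarray:
        """Gene loadings after rotation and orientation (genes x k)."""
        v = self.V.copy()
        v[:, :2] = v[:, :2] @ _rotation_matrix(self.rotation_angle_degrees)
        if self.disease_axis_index is not None:
            v[:, self.disease_axis_index] *= self.orientation_sign
        return v

    @property
    def eigengene(self) -> pd.Series:
        """Rotated, oriented loading on the disease axis per gene."""
        if self.disease_axis_index is None:
            raise ValueError("disease axis not selected yet")
        return pd.Series(self.loadings()[:, self.disease_axis_index],
                         index=self.genes, name="eigengene")

    @property
    def v1(self) -> pd.Series:
        """Rotated loading on the first (non-disease) axis per gene."""
        return pd.Series(self.loadings()[:, 0], index=self.genes, name="v1")

    def coordinates(self) -> pd.Series:
        if self.disease_axis_index is None:
            raise ValueError("disease axis not selected yet")
        return pd.Series(self.scores()[:, self.disease_axis_index],
                         index=self.sample_ids, name="coordinate")

    # -- serialization -------------------------------------------------------
    def to_dir(self, path):
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        load = self.loadings()
        pd.DataFrame({"gene": self.genes, "v1": load[:, 0],
                      "v2": load[:, 1]}).to_csv(
            path / "loadings.tsv", sep="\t", index=False)
        self.center.rename("center").to_csv(path / "centering.tsv", sep="\t")
        meta = {
            "singular_values": self.S.tolist(),
            "rotation_angle_degrees": self.rotation_angle_degrees,
            "disease_axis_index": self.disease_axis_index,
            "orientation_sign": self.orientation_sign,
            "selection_reliable": self.selection_reliable,
        }
        (path / "model.json").write_text(json.dumps(meta, indent=2))


def fit_state_space(normed: pd.DataFrame, table: pd.DataFrame,
                    k_max: int = 20,
                    center: pd.Series | None = None) -> StateSpaceModel:
    """SVD of centered expression (genes x samples) on the training cohorts.

    ``normed`` must already be log-normalized and gene-centered (see
    :func:`normalize_expression`); ``table`` supplies cohorts.  Only
    control and untreated-disease samples enter the factorization; the
    reconstruction ``U S V^T`` equals the input to numerical tolerance.
    Column signs are fixed deterministically (largest-magnitude loading
    positive) before orientation.
    """
    samples = [s for s in normed.columns
               if table.loc[s, "cohort"] in TRAIN_COHORTS]
    if len(samples) < 2:
        raise ValueError("need at least 2 training samples for the SVD")
    X = normed[samples].to_numpy().T  # samples x genes
    k = min(k_max, min(X.shape))
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    V = Vt.T
    for j in range(k):  # deterministic sign gauge
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] *= -1
            U[:, j] *= -1
    if center is None:
        center = pd.Series(0.0, index=normed.index)
    return StateSpaceModel(
        genes=normed.index, center=center,
        sample_ids=pd.Index(samples), U=U, S=S, V=V)


def build_state_space(counts: pd.DataFrame,
                      table: pd.DataFrame) -> StateSpaceModel:
    """Full state-space construction from raw counts.

    Restricts to genes expressed (count > 0) in at least one training
    sample, log-normalizes and centers on the training cohorts, fits the
    SVD, rotates the plane flat on the controls, selects the disease
    axis and orients it health-high.  The stored centering means make
    :func:`project_samples` consistent for held-out cohorts.
    """
    train = [s for s in counts.columns
             if table.loc[s, "cohort"] in TRAIN_COHORTS]
    tcounts = counts[train]
    expressed = tcounts.index[(tcounts > 0).any(axis=1)]
    lc = log_cpm(tcounts.loc[expressed])
    center = lc.mean(axis=1)
    normed = lc.sub(center, axis=0)
    model = fit_state_space(normed, table, center=center)
    rotate_axes(model, table)
    select_disease_axis(model, table)
    orient_axis(model, table)
    return model


def rotate_axes(model: StateSpaceModel, table: pd.DataFrame) -> StateSpaceModel:
    """Rotate the (PC1, PC2) plane so the control fit line is flat.

    The least-squares slope of control-sample PC2 on PC1 defines the
    rotation angle theta = atan(slope) (counter-clockwise axis rotation,
    stored in degrees); after rotation the control slope is zero to
    within 1e-8.
    """
    ctrl = [s for s in model.sample_ids if table.loc[s, "cohort"] == "control"]
    if len(ctrl) < 2:
        raise ValueError("need at least 2 control samples to rotate")
    idx = [model.sample_ids.get_loc(s) for s in ctrl]
    x, y = model.U[idx, 0], model.U[idx, 1]
    if np.ptp(x) == 0:
        raise ValueError("control samples vertically collinear: slope undefined")
    slope = np.polyfit(x, y, 1)[0]
    model.rotation_angle_degrees = float(np.rad2deg(np.arctan(slope)))
    return model


def select_disease_axis(model: StateSpaceModel, table: pd.DataFrame,
                        reliability_threshold: float = 1.0) -> StateSpaceModel:
    """Pick the rotated axis separating controls from disease endpoints.

    The separation statistic per axis is the standardized distance
    |mean(control) - mean(endpoint)| / pooled SD, where endpoints are
    each untreated-disease mouse's last sample.  Ties are broken by the
    R^2 of the axis coordinate against oncogene transcript abundance.
    Per-axis R^2 against raw and log abundance and against the myeloid
    fraction are reported as diagnostics.  When no axis reaches
    ``reliability_threshold`` the selection is flagged unreliable.
    """
    u = model.U.copy()
    u[:, :2] = u[:, :2] @ _rotation_matrix(model.rotation_angle_degrees)
    sub = table.loc[model.sample_ids]
    ctrl_mask = (sub.cohort == "control").to_numpy()
    cml = sub[sub.cohort == "CML"]
    if len(cml) == 0:
        raise ValueError("no untreated-disease samples")
    endpoint_ids = cml.sort_values("week").groupby("mouse").tail(1).index
    end_mask = np.asarray(sub.index.isin(endpoint_ids))
    if end_mask.sum() == 0:
        raise ValueError("no disease endpoint samples")

    def r2(xcol, ycol):
        ok = np.isfinite(ycol)
        if ok.sum() < 3 or np.std(ycol[ok]) == 0 or np.std(xcol[ok]) == 0:
            return 0.0
        return float(np.corrcoef(xcol[ok], ycol[ok])[0, 1] ** 2)

    cml_mask = (sub.cohort == "CML").to_numpy()
    bcr = sub.bcrabl_abundance.to_numpy(dtype=float)
    mye = sub.myeloid_fraction.to_numpy(dtype=float)
    rows = []
    for j in range(model.k):
        a, b = u[ctrl_mask, j], u[end_mask, j]
        pooled = np.sqrt(0.5 * (a.var(ddof=1) + b.var(ddof=1)))
        sep = np.abs(a.mean() - b.mean()) / pooled if pooled > 0 else 0.0
        rows.append({
            "axis": j,
            "separation": sep,
            "r2_bcrabl": r2(u[cml_mask, j], bcr[cml_mask]),
            "r2_bcrabl_log": r2(u[cml_mask, j], np.log1p(bcr[cml_mask])),
            "r2_myeloid": r2(u[cml_mask, j], mye[cml_mask]),
        })
    diag = pd.DataFrame(rows)
    best = diag.sort_values(["separation", "r2_bcrabl"],
                            ascending=False).iloc[0]
    model.disease_axis_index = int(best.axis)
    model.axis_diagnostics = diag
    model.selection_reliable = bool(best.separation >= reliability_threshold)
    return model


def orient_axis(model: StateSpaceModel, table: pd.DataFrame) -> StateSpaceModel:
    """Fix the disease-axis sign: health high, disease low.

    The sign is chosen so control samples have a larger mean coordinate
    than the untreated-disease endpoint samples, making the pro/anti
    disease quadrant rule read directly off loading and fold-change
    signs.
    """
    if model.disease_axis_index is None:
        raise ValueError("select the disease axis before orienting")
    j = model.disease_axis_index
    u = model.U.copy()
    u[:, :2] = u[:, :2] @ _rotation_matrix(model.rotation_angle_degrees)
    sub = table.loc[model.sample_ids]
    ctrl = u[(sub.cohort == "control").to_numpy(), j]
    cml = sub[sub.cohort == "CML"]
    endpoint_ids = cml.sort_values("week").groupby("mouse").tail(1).index
    end = u[np.asarray(sub.index.isin(endpoint_ids)), j]
    model.orientation_sign = 1 if ctrl.mean() >= end.mean() else -1
    return model


def project_samples(model: StateSpaceModel, counts: pd.DataFrame,
                    table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Project new samples into the state-space: ``U_T = X_T V S^-1``.

    ``counts`` are raw counts (genes x samples) on the model's gene set;
    they are normalized with the stored transform, multiplied by the
    loadings and inverse singular values, then rotated and oriented.
    Projecting the training matrix reproduces the training coordinates.
    Returns a coordinate table (sample, coordinate, plus metadata when
    ``table`` is given).
    """
    Xc = model.normalize(counts).to_numpy().T  # samples x genes
    u = Xc @ model.V @ np.diag(1.0 / model.S)
    u = model._transform_scores(u)
    j = model.disease_axis_index if model.disease_axis_index is not None else 1
    out = pd.DataFrame({"sample": counts.columns,
                        "coordinate": u[:, j]}).set_index("sample")
    if table is not None:
        out = out.join(table[["mouse", "cohort", "week"]])
    return out


def coordinate_series(model: StateSpaceModel,
                      table: pd.DataFrame) -> pd.DataFrame:
    """Training-sample coordinates with metadata (one row per sample)."""
    coords = model.coordinates()
    out = pd.DataFrame({"coordinate": coords})
    return out.join(table[["mouse", "cohort", "week"]])
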