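"""Disease-state grouping, eigengene contributions, modules and drivers.

Samples are grouped into disease states by the unstable critical points
(c2, c4) of the landscape.  Each differentially expressed gene (DEG) is
classified pro- or anti-disease by combining its eigengene loading v2
with its fold change: with the health-high orientation a positive
loading with downregulation (or negative loading with upregulation)
pushes samples toward disease, so the contribution scalar is
``-(v2 * log2FC)`` with positive = pro-disease.

Co-regulated gene modules are detected by hierarchical clustering of the
gene-gene correlation matrix over disease-cohort samples (distance
1 - r, average linkage), retaining clusters whose median pairwise
correlation exceeds 0.25.  Transition-driver genes are those whose
expression across samples near an unstable critical point tracks the
potential (|r| > 0.5, regression p < 0.05).

The differential-expression engine is pluggable: the internal default is
a per-gene negative-binomial regression with a log library-size offset
and a sex covariate (Wald test, Benjamini-Hochberg adjustment); an
externally produced DE table with the same columns can be supplied
instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .potentials import PotentialModel
from .statespace import StateSpaceModel

__all__ = [
    "assign_disease_states",
    "differential_expression",
    "validate_de_table",
    "eigengene_contribution",
    "gene_set_contribution",
    "read_gmt",
    "GeneModule",
    "detect_gene_modules",
    "find_transition_drivers",
    "age_adjust",
    "expand_driver_network",
]

STATE_LABELS = ("Hs", "Es", "Ts", "Ls")


# ---------------------------------------------------------------------------
# Disease-state assignment
# ---------------------------------------------------------------------------

def assign_disease_states(coords: pd.DataFrame, potential: PotentialModel,
                          table: pd.DataFrame,
                          allow_degraded: bool = False) -> pd.DataFrame:
    """Label each sample Hs/Es/Ts/Ls by its basin in the landscape.

    The unstable critical points c2 and c4 are the basin boundaries;
    samples exactly on a boundary go to the more diseased state.
    Control samples are always Hs.  ``coords`` must have a
    ``coordinate`` column indexed by sample.

    A landscape with fewer than five critical points is an error unless
    ``allow_degraded`` is set, in which case a cubic (two-well) landscape
    yields only Es and Ls separated by its single unstable point.
    """
    n_pts = len(potential.critical_points)
    if n_pts < 5 and not (allow_degraded and n_pts == 3):
        raise ValueError("state assignment needs all five critical points")
    d = potential.disease_direction
    if n_pts == 5:
        c2, c4 = potential.c(2), potential.c(4)
    else:
        c2 = c4 = potential.c(2)  # single barrier: Es | Ls
    out = coords.copy()
    cohorts = table.loc[out.index, "cohort"]

    def label(row):
        x = row.coordinate
        if d * (x - c4) >= 0:
            return "Ls"
        if d * (x - c2) >= 0:
            return "Ts"
        return "Es"

    out["state"] = [label(r) for r in out.itertuples()]
    out.loc[cohorts == "control", "state"] = "Hs"
    out["boundaries"] = [(c2, c4)] * len(out)
    return out


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def _nb_dispersion_moment(y, mu):
    """Method-of-moments NB dispersion alpha (var = mu + alpha mu^2)."""
    resid = (y - mu) ** 2 - mu
    denom = np.sum(mu ** 2)
    if denom == 0:
        return 1e-8
    return float(np.clip(np.sum(resid) / denom, 1e-8, 10.0))


def differential_expression(counts: pd.DataFrame, table: pd.DataFrame,
                            group_a, group_b, covariates=("sex",),
                            comparison: str = "A_vs_B",
                            min_count: int = 1) -> pd.DataFrame:
    """Per-gene NB regression of group B vs group A (log2FC of B over A).

    ``group_a`` / ``group_b`` are sample-id lists.  The model per gene is
    NB GLM with log library-size offset, group indicator and the listed
    covariates (sex is coded F = 1).  Wald p-values are BH-adjusted.
    Genes with zero counts in all selected samples are excluded.
    """
    group_a, group_b = list(group_a), list(group_b)
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 samples per group")
    samples = group_a + group_b
    sub = counts[samples]
    lib = sub.sum(axis=0).to_numpy(dtype=float)
    offset = np.log(lib)
    indicator = np.array([0.0] * len(group_a) + [1.0] * len(group_b))
    design = [np.ones(len(samples)), indicator]
    for cov in covariates:
        vals = table.loc[samples, cov]
        design.append((vals == "F").to_numpy(dtype=float)
                      if cov == "sex" else vals.to_numpy(dtype=float))
    X = np.column_stack(design)

    keep = sub.sum(axis=1) >= min_count
    rows = []
    for gene, y in sub.loc[keep].iterrows():
        y = y.to_numpy(dtype=float)
        try:
            pois = sm.GLM(y, X, family=sm.families.Poisson(),
                          offset=offset).fit()
            alpha = _nb_dispersion_moment(y, pois.fittedvalues)
            nb = sm.GLM(y, X,
                        family=sm.families.NegativeBinomial(alpha=alpha),
                        offset=offset).fit()
            coef, pval = nb.params[1], nb.pvalues[1]
        except Exception:
            continue
        rows.append((gene, coef / np.log(2.0), float(pval)))
    res = pd.DataFrame(rows, columns=["gene", "log2FC", "p"]).set_index("gene")
    res["p"] = res["p"].fillna(1.0).clip(0.0, 1.0)
    res["padj"] = multipletests(res["p"], method="fdr_bh")[1]
    res["comparison"] = comparison
    return res


def validate_de_table(df: pd.DataFrame) -> pd.DataFrame:
    """Adapter for externally produced DE tables (e.g. DESeq2 exports).

    Requires columns log2FC, p, padj indexed by gene (or a 'gene'
    column); validates finiteness and the padj >= p invariant direction.
    """
    df = df.copy()
    if "gene" in df.columns:
        df = df.set_index("gene")
    missing = {"log2FC", "p", "padj"} - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    if not np.isfinite(df["log2FC"]).all():
        raise ValueError("non-finite log2FC in DE table")
    if ((df["p"] < 0) | (df["p"] > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    return df


def significant_genes(de: pd.DataFrame, alpha=0.05, lfc=0.0):
    mask = (de["padj"] < alpha) & (de["log2FC"].abs() > lfc)
    return set(de.index[mask])


# ---------------------------------------------------------------------------
# Eigengene contributions
# ---------------------------------------------------------------------------

def eigengene_contribution(de: pd.DataFrame,
                           model: StateSpaceModel) -> tuple[pd.DataFrame, tuple]:
    """Pro/anti-disease contribution of each DEG, plus the mean vector.

    The contribution scalar is ``-(v2 * log2FC)``; under the health-high
    orientation positive values are pro-disease (positive loading with
    downregulation, or negative loading with upregulation) and negative
    values anti-disease.  Each gene is also given the 2-D vector
    (v1 loading, contribution); the mean vector over the DEG set is the
    set's net contribution.
    """
    missing = de.index.difference(model.genes)
    if len(missing):
        raise ValueError(f"DEGs absent from the state-space gene set: "
                         f"{list(missing[:5])}")
    v1 = model.v1.loc[de.index]
    v2 = model.eigengene.loc[de.index]
    contribution = -(v2 * de["log2FC"])
    cls = np.where(contribution > 0, "pro-CML",
                   np.where(contribution < 0, "anti-CML", "neutral"))
    rec = pd.DataFrame({
        "v1": v1, "v2": v2, "log2FC": de["log2FC"],
        "contribution": contribution, "class": cls,
    })
    mean_vector = (float(rec["v1"].mean()), float(rec["contribution"].mean()))
    return rec, mean_vector


def read_gmt(path) -> dict:
    """Parse a GMT gene-set file: name <tab> description <tab> genes..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def gene_set_contribution(records: pd.DataFrame, gene_sets: dict) -> pd.DataFrame:
    """Mean contribution vector of each gene set over its DEG members."""
    rows = []
    for name, genes in gene_sets.items():
        members = records.index.intersection(genes)
        if len(members) == 0:
            continue
        sub = records.loc[members]
        rows.append((name, len(members), sub["v1"].mean(),
                     sub["contribution"].mean()))
    return pd.DataFrame(rows, columns=["gene_set", "n_degs", "v1_mean",
                                       "contribution_mean"]).set_index("gene_set")


# ---------------------------------------------------------------------------
# Gene modules
# ---------------------------------------------------------------------------

@dataclass
class GeneModule:
    genes: list
    origin: str
    median_r: float
    direction: str                 # "increasing" / "decreasing" vs coordinate
    dynamics: pd.DataFrame         # columns: coordinate, mean_expression


def detect_gene_modules(normed: pd.DataFrame, coords: pd.DataFrame,
                        gene_sets: dict, min_median_r: float = 0.25,
                        min_size: int = 3) -> list[GeneModule]:
    """Find co-regulated modules inside each state-unique DEG set.

    ``normed`` is log-normalized mean-centered expression (genes x
    samples); ``coords`` the disease-cohort coordinate table (indexed by
    sample).  Within each DEG set, genes are clustered by average
    linkage on distance 1 - r (Pearson across the disease-cohort
    samples); the dendrogram is cut at the largest number of clusters
    <= ``max_clusters`` whose clusters all have >= ``min_size`` members,
    and clusters with median pairwise r > ``min_median_r`` are retained.
    Constant-expression genes are dropped with a warning.

    Module dynamics are the per-sample mean of member expression paired
    with the sample coordinate; the direction is the sign of the
    Spearman trend.
    """
    samples = coords.index
    modules = []
    for origin, genes in gene_sets.items():
        genes = [g for g in genes if g in normed.index]
        if len(genes) < min_size:
            raise ValueError(f"gene set {origin!r} has fewer than "
                             f"{min_size} usable genes")
        expr = normed.loc[genes, samples]
        sd = expr.std(axis=1)
        if (sd == 0).any():
            warnings.warn(f"dropping {(sd == 0).sum()} constant genes "
                          f"from {origin!r}")
            expr = expr.loc[sd > 0]
        if len(expr) < min_size:
            continue
        r = np.corrcoef(expr.to_numpy())
        dist = ssd.squareform(np.clip(1.0 - r, 0.0, 2.0), checks=False)
        link = sch.linkage(dist, method="average")
        # cut at the correlation threshold's distance height: subtrees whose
        # average mutual correlation exceeds the retention threshold stay
        # together, so a single co-regulated set is not oversplit
        chosen = sch.fcluster(link, t=1.0 - min_median_r,
                              criterion="distance")
        for cl in np.unique(chosen):
            idx = np.nonzero(chosen == cl)[0]
            if len(idx) < min_size:
                continue
            sub_r = r[np.ix_(idx, idx)]
            med = float(np.median(sub_r[np.triu_indices(len(idx), k=1)]))
            if med <= min_median_r:
                continue
            member_genes = list(expr.index[idx])
            curve = pd.DataFrame({
                "coordinate": coords["coordinate"].to_numpy(),
                "mean_expression": expr.iloc[idx].mean(axis=0).to_numpy(),
            }, index=samples)
            rho = scipy.stats.spearmanr(curve.coordinate,
                                        curve.mean_expression).statistic
            modules.append(GeneModule(
                genes=member_genes, origin=origin, median_r=med,
                direction="increasing" if rho >= 0 else "decreasing",
                dynamics=curve))
    return modules


# ---------------------------------------------------------------------------
# Transition drivers
# ---------------------------------------------------------------------------

def find_transition_drivers(normed: pd.DataFrame, coords: pd.DataFrame,
                            potential: PotentialModel, degs,
                            r_threshold: float = 0.5,
                            p_threshold: float = 0.05,
                            min_samples: int = 4) -> pd.DataFrame:
    """Genes whose expression tracks the potential near c2 or c4.

    For each transition window — T-Es: coordinates between c1 and c3;
    T-Ls: between c3 and c5 — each DEG's log-normalized mean-centered
    expression is correlated with U(coordinate) over the disease-cohort
    samples inside the window.  Drivers have |r| > ``r_threshold`` and
    regression p < ``p_threshold``; the signed r is reported.
    """
    if len(potential.critical_points) < 5:
        raise ValueError("driver analysis needs all five critical points")
    degs = [g for g in degs if g in normed.index]
    windows = {
        "T-Es": sorted((potential.c(1), potential.c(3))),
        "T-Ls": sorted((potential.c(3), potential.c(5))),
    }
    frames = []
    for name, (lo, hi) in windows.items():
        mask = (coords["coordinate"] >= lo) & (coords["coordinate"] <= hi)
        samples = coords.index[mask]
        n = len(samples)
        if n < min_samples:
            raise ValueError(f"only {n} samples in window {name}; "
                             f"need >= {min_samples}")
        u = potential.potential(coords.loc[samples, "coordinate"].to_numpy())
        E = normed.loc[degs, samples].to_numpy()
        sd = E.std(axis=1)
        ok = sd > 0
        Ez = (E[ok] - E[ok].mean(axis=1, keepdims=True)) / sd[ok][:, None]
        uz = (u - u.mean()) / u.std()
        r = Ez @ uz / n
        r = np.clip(r, -1.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
        p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
        p = np.where(np.isnan(p), 0.0, p)  # |r| == 1 exactly
        frames.append(pd.DataFrame({
            "gene": np.asarray(degs)[ok], "window": name, "r": r, "p": p,
            "driver": (np.abs(r) > r_threshold) & (p < p_threshold),
            "n_samples": n,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Aging control and network expansion
# ---------------------------------------------------------------------------

def age_adjust(target_degs, counts: pd.DataFrame, table: pd.DataFrame,
               n_points: int = 5, alpha: float = 0.05):
    """Remove age-associated DEGs found in early-vs-late controls.

    The first ``n_points`` and last ``n_points`` control time points are
    compared with the internal DE engine; significant genes are
    subtracted from ``target_degs``.
    """
    ctrl = table[table.cohort == "control"]
    weeks = sorted(ctrl.week.unique())
    if len(weeks) < 2 * n_points:
        raise ValueError(f"need >= {2 * n_points} control time points, "
                         f"have {len(weeks)}")
    early = ctrl[ctrl.week.isin(weeks[:n_points])].index
    late = ctrl[ctrl.week.isin(weeks[-n_points:])].index
    de = differential_expression(counts, table, early, late,
                                 comparison="late_vs_early_control")
    aging = significant_genes(de, alpha=alpha)
    return set(target_degs) - aging


def expand_driver_network(drivers, edges: pd.DataFrame,
                          min_score: float = 900) -> set:
    """Drivers plus high-confidence interaction partners (score > min).

    ``edges`` needs columns geneA, geneB, score; the threshold is
    strict (score must exceed ``min_score``).
    """
    missing = {"geneA", "geneB", "score"} - set(edges.columns)
    if missing:
        raise ValueError(f"edge list missing columns: {sorted(missing)}")
    drivers = set(drivers)
    strong = edges[edges["score"] > min_score]
    out = set(drivers)
    for _, e in strong.iterrows():
        if e.geneA in drivers:
            out.add(e.geneB)
        if e.geneB in drivers:
            out.add(e.geneA)
    return out
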