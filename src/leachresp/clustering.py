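"""Responder-cluster identification and absolute abundance scaling.

Abundant ASVs (those above the relative-abundance screen) are
centred-log-ratio transformed per sample, then hierarchically clustered
by the Euclidean distance between their across-sample profiles, so ASVs
that rise and fall together across treatments end up in one cluster —
generalists responding everywhere, treatment-specific responders, and
inoculum-only taxa that collapse in every incubation. Cluster
proportions are scaled to absolute cell abundances with flow-cytometry
totals.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as _linkage
from scipy.spatial.distance import pdist
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

__all__ = [
    "clr_transform",
    "default_pseudocount",
    "cluster_responders",
    "silhouette_profile",
    "cluster_contribution",
    "cluster_cell_abundance",
    "cardfish_vs_16s_agreement",
    "PROBE_TO_TAXON",
]


def default_pseudocount(rel: pd.DataFrame) -> float:
    """Half the smallest nonzero relative abundance in the table."""
    vals = np.asarray(rel, dtype=float)
    nz = vals[vals > 0]
    if nz.size == 0:
        raise ValueError("table has no nonzero entries")
    return float(nz.min() / 2.0)


def clr_transform(rel: pd.DataFrame, pseudocount: float | None = None) -> pd.DataFrame:
    """Centred log-ratio transform per sample column.

    clr_i = ln((x_i + delta) / g) with g the geometric mean of (x + delta)
    over the included ASVs, so every column has mean zero and Euclidean
    distances between rows are invariant to per-sample rescaling.
    A zero anywhere with delta = 0 is an error.
    """
    x = np.asarray(rel, dtype=float)
    if pseudocount is None:
        pseudocount = default_pseudocount(rel)
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and (x <= 0).any():
        raise ValueError("zeros present: a positive pseudocount is required")
    shifted = x + pseudocount
    logx = np.log(shifted)
    clr = logx - logx.mean(axis=0, keepdims=True)
    return pd.DataFrame(clr, index=rel.index, columns=rel.columns)


def cluster_responders(
    clr: pd.DataFrame, k: int = 7, linkage: str = "complete"
) -> pd.Series:
    """Cut an agglomerative tree over ASV rows into k response clusters.

    Rows are sorted by ASV id before clustering so the outcome is
    deterministic under input reordering. Labels are arbitrary 1..k;
    any scoring against ground truth must be label-permutation
    invariant (adjusted Rand index).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(clr):
        raise ValueError(f"k={k} exceeds the {len(clr)} available ASVs")
    ordered = clr.sort_index()
    if k == 1:
        return pd.Series(1, index=ordered.index, name="cluster")
    z = _linkage(ordered.to_numpy(), method=linkage, metric="euclidean")
    labels = fcluster(z, t=k, criterion="maxclust")
    return pd.Series(labels, index=ordered.index, name="cluster")


def silhouette_profile(
    clr: pd.DataFrame, k_range=range(2, 13), linkage: str = "complete"
) -> pd.DataFrame:
    """Mean silhouette width across candidate cluster counts.

    A quantitative stand-in for choosing the cut height by eye: report
    the silhouette at each k so the chosen k can be judged against the
    alternatives.
    """
    ordered = clr.sort_index().to_numpy()
    z = _linkage(ordered, method=linkage, metric="euclidean")
    d = pdist(ordered)
    rows = []
    for k in k_range:
        if k >= len(ordered):
            break
        labels = fcluster(z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        rows.append({"k": k, "mean_silhouette": float(
            silhouette_score(ordered, labels, metric="euclidean"))})
    return pd.DataFrame(rows)


def cluster_contribution(
    assignment: pd.Series, rel: pd.DataFrame
) -> pd.DataFrame:
    """Summed relative abundance per cluster per sample; the ASVs outside
    the filtered set are pooled as ``other (rare)`` so columns close to 1."""
    missing = set(assignment.index) - set(rel.index)
    if missing:
        raise ValueError(f"assigned ASVs absent from the table: {sorted(missing)[:5]}")
    rows = {}
    for cl in sorted(assignment.unique()):
        members = assignment.index[assignment == cl]
        rows[f"cluster_{cl}"] = rel.loc[members].sum(axis=0)
    unassigned = rel.index.difference(assignment.index)
    rows["other (rare)"] = (
        rel.loc[unassigned].sum(axis=0)
        if len(unassigned)
        else pd.Series(0.0, index=rel.columns)
    )
    return pd.DataFrame(rows).T


def cluster_cell_abundance(
    contributions: pd.DataFrame,
    flow_totals: pd.Series,
    design: pd.DataFrame | None = None,
) -> dict:
    """Scale cluster proportions to absolute cells per mL.

    Per sample: cells = proportion x flow-cytometry total, so summed
    over clusters (incl. the rare pool) the flow total is conserved
    exactly. If a design table is given, replicate mean and SD per
    treatment are also returned.
    """
    samples = [s for s in contributions.columns if s in flow_totals.index]
    skipped = [s for s in contributions.columns if s not in flow_totals.index]
    for s in skipped:
        logger.warning("no flow-cytometry total for sample %s: excluded", s)
    absolute = contributions[samples] * flow_totals[samples]
    out = {"cells_per_sample": absolute}
    if design is not None:
        meta = design.loc[samples]
        treatment = meta["plastic"].astype(str) + ":" + meta["light"].astype(str)
        grouped = absolute.T.groupby(treatment.to_numpy())
        out["treatment_mean"] = grouped.mean().T
        out["treatment_sd"] = grouped.std(ddof=1).T
    return out


#: probe -> taxonomy group used when comparing CARD-FISH with sequencing
PROBE_TO_TAXON = {
    "GAM42a": ("class", "Gammaproteobacteria"),
    "Alf968": ("class", "Alphaproteobacteria"),
    "CF319a": ("phylum", "Bacteroidota"),
    "ALT1413": ("order", "Alteromonadales"),
    "ROS537": ("order", "Rhodobacterales"),
}


def cardfish_vs_16s_agreement(
    per_probe_abundance: pd.DataFrame,
    rel: pd.DataFrame,
    taxonomy: pd.DataFrame,
    probe_map: dict = PROBE_TO_TAXON,
    n_perm: int = 999,
    seed: int | None = 0,
) -> dict:
    """Compare probe-based group fractions with sequencing-based fractions.

    ``per_probe_abundance`` is long-format (sample_id, probe_id,
    contribution_abundance). For each mapped probe the 16S fraction is
    the summed corrected relative abundance of ASVs matching the probe's
    target taxon at the declared rank. Returns the paired table plus a
    permutation-tested Spearman correlation across all pairs.
    """
    from .stats_core import spearman

    rows = []
    for _, r in per_probe_abundance.iterrows():
        probe = r["probe_id"]
        if probe not in probe_map:
            logger.info("probe %s has no taxonomy mapping: skipped", probe)
            continue
        rank, taxon = probe_map[probe]
        if r["sample_id"] not in rel.columns:
            continue
        members = taxonomy.index[taxonomy[rank] == taxon]
        frac_16s = float(rel.loc[rel.index.intersection(members), r["sample_id"]].sum())
        rows.append(
            {
                "sample_id": r["sample_id"],
                "probe_id": probe,
                "group": taxon,
                "cardfish_fraction": float(r["contribution_abundance"]),
                "fraction_16s": frac_16s,
                "difference": float(r["contribution_abundance"]) - frac_16s,
            }
        )
    paired = pd.DataFrame(rows)
    result = {"paired": paired}
    if len(paired) >= 3 and paired["cardfish_fraction"].nunique() > 1 and paired["fraction_16s"].nunique() > 1:
        test = spearman(
            paired["cardfish_fraction"].to_numpy(),
            paired["fraction_16s"].to_numpy(),
            n_perm=n_perm,
            seed=seed,
        )
        result["spearman_rho"] = test.statistic
        result["spearman_p"] = test.p_value
    return result
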