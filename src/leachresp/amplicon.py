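"""Post-denoising ASV table processing.

Consumes an ASV count table (ASVs x samples), a SILVA-style taxonomy
table, and a mean 16S rRNA gene copy-number lookup; produces copy-number
corrected relative abundances, rarefaction-averaged counts and alpha
diversity (richness, Shannon H, Pielou J), the >1 %-in-any-sample
abundance screen, and mixed-rank taxonomic aggregation.

Copy-number correction divides each ASV's reads by the mean 16S gene
copy number of its lowest available taxonomic rank among genus, family
and order (species entries are treated at genus level); ASVs resolved
only to class or above are left uncorrected, because copy-number
prediction at coarse ranks is too unreliable to de-bias with.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats_core import DegenerateInputError, pielou_evenness, shannon_index

logger = logging.getLogger(__name__)

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
#: ranks eligible for copy-number lookup, most resolved first
CORRECTION_LADDER = ("species", "genus", "family", "order")

__all__ = [
    "RANKS",
    "CopyNumberTable",
    "copy_number_correct",
    "closure",
    "rarefy_once",
    "rarefy_mean",
    "diversity",
    "abundant_asv_filter",
    "aggregate_taxa",
]


@dataclass(frozen=True)
class CopyNumberTable:
    """(taxon name, rank) -> mean 16S rRNA gene copy number (>= 1)."""

    table: pd.DataFrame  # columns: taxon, rank, mean_copies

    def __post_init__(self) -> None:
        required = {"taxon", "rank", "mean_copies"}
        if not required <= set(self.table.columns):
            raise ValueError(f"copy-number table needs columns {sorted(required)}")
        if (self.table["mean_copies"] < 1).any():
            raise ValueError("mean 16S copy numbers must be >= 1")

    def lookup(self, taxon: str, rank: str) -> float | None:
        hit = self.table[(self.table["taxon"] == taxon) & (self.table["rank"] == rank)]
        if hit.empty:
            return None
        return float(hit["mean_copies"].iloc[0])


def closure(table: pd.DataFrame) -> pd.DataFrame:
    """Close each sample column to sum 1 (columns = samples)."""
    totals = table.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise DegenerateInputError(f"samples with zero total reads: {bad}")
    return table / totals


def _lowest_available_rank(tax_row: pd.Series) -> str | None:
    """Most resolved non-missing rank for an ASV, or None if fully unknown."""
    for rank in reversed(RANKS):
        val = tax_row.get(rank)
        if isinstance(val, str) and val.strip():
            return rank
    return None


def copy_number_correct(
    counts: pd.DataFrame, taxonomy: pd.DataFrame, copy_numbers: CopyNumberTable
) -> pd.DataFrame:
    """Copy-number corrected relative abundances (columns close to 1).

    Per ASV the divisor is found by walking the ladder
    species -> genus -> family -> order from the ASV's lowest available
    rank upward (species lookups use the genus-level table entry when a
    species entry is absent); a miss at every eligible rank, or
    resolution only to class or above, leaves the ASV uncorrected
    (divisor 1).
    """
    if not set(counts.index) <= set(taxonomy.index):
        missing = sorted(set(counts.index) - set(taxonomy.index))
        raise ValueError(f"ASVs missing from taxonomy: {missing[:5]}...")
    if (np.asarray(counts) < 0).any():
        raise ValueError("counts must be non-negative")

    divisors = pd.Series(1.0, index=counts.index)
    for asv in counts.index:
        row = taxonomy.loc[asv]
        lowest = _lowest_available_rank(row)
        if lowest is None or lowest not in CORRECTION_LADDER:
            continue  # class or above: no correction
        start = CORRECTION_LADDER.index(lowest)
        for rank in CORRECTION_LADDER[start:]:
            name = row.get(rank)
            if not (isinstance(name, str) and name.strip()):
                continue
            # species names are looked up as their genus-level entry
            query_rank = "genus" if rank == "species" else rank
            cn = copy_numbers.lookup(name, query_rank)
            if cn is None and rank == "species":
                cn = copy_numbers.lookup(row.get("genus", ""), "genus")
            if cn is not None:
                divisors[asv] = cn
                break
        else:
            logger.warning("no copy-number entry for %s at any eligible rank", asv)
    weighted = counts.div(divisors, axis=0)
    return closure(weighted)


def rarefy_once(counts, depth: int, seed=None, rng=None) -> np.ndarray:
    """Subsample one sample's counts to ``depth`` reads without replacement.

    Multivariate-hypergeometric draw: exact sampling of reads without
    replacement, so the output sums to depth and never exceeds the input
    per ASV.
    """
    c = np.asarray(counts, dtype=np.int64)
    if (c < 0).any():
        raise ValueError("counts must be non-negative integers")
    total = int(c.sum())
    if depth > total:
        raise ValueError(f"rarefaction depth {depth} exceeds sample total {total}")
    if rng is None:
        rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(c, depth)


def rarefy_mean(
    table: pd.DataFrame, depth: int | None = None, n_reps: int = 100, seed=None
) -> pd.DataFrame:
    """Average of repeated rarefactions, rounded half-away-from-zero.

    Default depth is the minimum sample total. Each sample column is
    drawn ``n_reps`` times independently; the per-cell mean is rounded
    to the nearest integer (ties away from zero), so columns may miss
    the exact depth by the rounding residue.
    """
    if depth is None:
        depth = int(table.sum(axis=0).min())
    rng = np.random.default_rng(seed)
    out = {}
    for sample in table.columns:
        draws = np.stack(
            [rarefy_once(table[sample].to_numpy(), depth, rng=rng) for _ in range(n_reps)]
        )
        mean = draws.mean(axis=0)
        out[sample] = np.floor(mean + 0.5).astype(np.int64)  # half-away-from-zero, values >= 0
    return pd.DataFrame(out, index=table.index)


def diversity(table_rarefied: pd.DataFrame) -> pd.DataFrame:
    """Per-sample richness, Shannon H and Pielou J on a rarefied table.

    Samples whose richness is < 2 get ``NaN`` evenness and are flagged
    rather than dropped.
    """
    rows = []
    for sample in table_rarefied.columns:
        c = table_rarefied[sample].to_numpy(dtype=float)
        if c.sum() <= 0:
            raise DegenerateInputError(f"sample {sample!r} has no reads")
        richness = int((c >= 1).sum())
        h = shannon_index(c)
        try:
            j = pielou_evenness(c)
            flagged = False
        except DegenerateInputError:
            j, flagged = np.nan, True
        rows.append(
            {
                "sample_id": sample,
                "richness": richness,
                "shannon": h,
                "pielou": j,
                "evenness_undefined": flagged,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def abundant_asv_filter(rel: pd.DataFrame, threshold: float = 0.01) -> list:
    """ASVs whose relative abundance exceeds ``threshold`` in >= 1 sample.

    The inequality is strict, so an ASV sitting exactly at the threshold
    everywhere is excluded. Input order is preserved.
    """
    keep = rel.max(axis=1) > threshold
    return list(rel.index[keep])


def aggregate_taxa(
    rel: pd.DataFrame,
    taxonomy: pd.DataFrame,
    level: str = "phylum",
    order_level_overrides: tuple = (),
) -> pd.DataFrame:
    """Aggregate ASV relative abundances to a (possibly mixed) rank scheme.

    Default is one row per ``level`` group; any group named in
    ``order_level_overrides`` (matched at phylum or class rank) is split
    to order level instead — the scheme used to show Proteobacteria
    classes and Bacteroidota at order resolution while the rest stays at
    phylum. Columns still close to their input totals.
    """
    if level not in RANKS:
        raise ValueError(f"unknown rank {level!r}; choose from {RANKS}")
    groups = []
    for asv in rel.index:
        row = taxonomy.loc[asv]
        label = row.get(level) or "Unclassified"
        override = None
        for cand in order_level_overrides:
            if row.get("phylum") == cand or row.get("class") == cand:
                override = cand
        if override is not None:
            label = row.get("order") or f"Unclassified {override}"
        groups.append(label)
    agg = rel.groupby(pd.Index(groups, name="group")).sum()
    return agg.sort_index()
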