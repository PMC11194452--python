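"""Single-cell activity quantification from epifluorescence micrographs.

Each field of view (FOV) is imaged three times on the same filter
section: a DAPI channel (all cells), a BONCAT channel (click-labelled
newly synthesised protein; intensity is proportional to per-cell
translational activity), and a CARD-FISH channel (one taxonomic probe
per filter section). Cells are segmented on DAPI, so every retained cell
is DAPI-positive by construction; a cell counts as BONCAT+ only if it is
DAPI+ and its BONCAT mean grey value (MGV) clears the positivity
threshold. Group contributions to activity divide the summed BONCAT MGV
of probe-positive cells by the summed BONCAT MGV of all BONCAT+ cells.

Because each probe is hybridised on its own filter section, probes are
quantified on independent FOV sets of the same community; nested probes
(Alteromonadales within Gammaproteobacteria, Roseobacter within
Alphaproteobacteria) are resolved by subtraction afterwards.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

logger = logging.getLogger(__name__)

CHANNELS = ("dapi", "boncat", "fish")

__all__ = [
    "Micrograph",
    "ProbePanel",
    "default_probe_panel",
    "segment_cells",
    "mean_grey_value",
    "gate_cells",
    "sample_activity",
    "group_activity_contribution",
    "group_abundance_contribution",
    "resolve_nested_groups",
    "abundance_vs_activity",
    "boncat_positive_density",
    "load_fov_triplet",
    "quantify_fov_directory",
]


@dataclass(frozen=True)
class Micrograph:
    """One grayscale channel of one field of view."""

    pixels: np.ndarray
    channel: str
    fov_id: str
    sample_id: str
    probe_id: str | None = None
    bit_depth: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("micrograph must be a 2-D pixel grid")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")
        if px.min() < 0 or px.max() > 2**self.bit_depth - 1:
            raise ValueError("pixel values exceed the stated bit depth")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class ProbePanel:
    """CARD-FISH probes, their target groups and nesting relations."""

    targets: dict  # probe_id -> target group name
    nesting: dict  # child probe -> parent probe
    universal: str  # probe covering most Bacteria

    def __post_init__(self) -> None:
        for child, parent in self.nesting.items():
            if child not in self.targets or parent not in self.targets:
                raise ValueError(f"nesting refers to unknown probe {child}/{parent}")
        # acyclicity: walking parents must terminate
        for probe in self.nesting:
            seen = set()
            node = probe
            while node in self.nesting:
                if node in seen:
                    raise ValueError(f"nesting cycle at probe {node!r}")
                seen.add(node)
                node = self.nesting[node]

    @property
    def group_probes(self) -> list:
        return [p for p in self.targets if p != self.universal]


def default_probe_panel() -> ProbePanel:
    """The six-probe panel used for marine bacterioplankton groups."""
    return ProbePanel(
        targets={
            "EUB338": "Bacteria",
            "GAM42a": "Gammaproteobacteria",
            "ALT1413": "Alteromonadales",
            "Alf968": "Alphaproteobacteria",
            "ROS537": "Rhodobacterales",
            "CF319a": "Bacteroidetes",
        },
        nesting={"ALT1413": "GAM42a", "ROS537": "Alf968"},
        universal="EUB338",
    )


# ---------------------------------------------------------------------------
# segmentation and per-cell statistics


def segment_cells(
    dapi: Micrograph, min_area_px: int = 5, threshold_method: str = "otsu"
) -> np.ndarray:
    """Label map from the DAPI channel: global threshold + 8-connected components.

    Components below ``min_area_px`` are dropped and labels re-packed to
    1..K. A blank image yields an all-zero map (with a logged warning)
    rather than an error, since empty FOVs occur in dilute samples.
    """
    if dapi.channel != "dapi":
        raise ValueError("segmentation runs on the DAPI channel")
    px = dapi.pixels.astype(float)
    if threshold_method != "otsu":
        raise ValueError(f"unknown threshold method {threshold_method!r}")
    if px.max() == px.min():
        logger.warning("blank DAPI image %s/%s: no cells", dapi.sample_id, dapi.fov_id)
        return np.zeros(px.shape, dtype=np.int32)
    tau = threshold_otsu(px)
    labels = cc_label(px > tau, connectivity=2)
    if labels.max() == 0:
        logger.warning("no foreground in %s/%s after threshold", dapi.sample_id, dapi.fov_id)
        return labels.astype(np.int32)
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts >= min_area_px)
    keep = keep[keep != 0]
    remap = np.zeros(counts.size, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1)
    return remap[labels]


def mean_grey_value(label_map: np.ndarray, image: np.ndarray, cell_id: int) -> float:
    """Arithmetic mean of the grey values over one cell's pixel set."""
    if label_map.shape != np.asarray(image).shape:
        raise ValueError("image and label map shapes differ")
    mask = label_map == cell_id
    n = int(mask.sum())
    if cell_id <= 0 or n == 0:
        raise KeyError(f"cell id {cell_id} not present in label map")
    return float(np.asarray(image, dtype=float)[mask].sum() / n)


@dataclass(frozen=True)
class BackgroundThreshold:
    """Positivity threshold: background mean + k * background SD."""

    k: float = 3.0

    def __call__(self, image: np.ndarray, label_map: np.ndarray) -> float:
        bg = np.asarray(image, dtype=float)[label_map == 0]
        if bg.size == 0:
            raise ValueError("no background pixels to estimate the threshold from")
        return float(bg.mean() + self.k * bg.std())


@dataclass(frozen=True)
class FixedThreshold:
    value: float = 0.0

    def __call__(self, image, label_map) -> float:
        return float(self.value)


def gate_cells(
    label_map: np.ndarray,
    dapi: Micrograph,
    boncat: Micrograph,
    fish: Micrograph | None = None,
    boncat_threshold_policy=None,
    fish_threshold_policy=None,
) -> pd.DataFrame:
    """Per-cell records with MGVs and DAPI/BONCAT/probe positivity flags.

    Segmented cells are DAPI+ by construction; BONCAT positivity
    additionally requires the BONCAT MGV to exceed the policy threshold,
    so ``boncat_pos`` implies ``dapi_pos`` on every output row.
    """
    for ch in (boncat, fish):
        if ch is not None and ch.pixels.shape != label_map.shape:
            raise ValueError("channel/label-map shape mismatch")
    if boncat is None:
        raise ValueError("BONCAT channel is required")
    boncat_threshold_policy = boncat_threshold_policy or BackgroundThreshold()
    fish_threshold_policy = fish_threshold_policy or BackgroundThreshold()

    n_cells = int(label_map.max())
    ids = np.arange(1, n_cells + 1)
    tau_b = boncat_threshold_policy(boncat.pixels, label_map)
    tau_f = (
        fish_threshold_policy(fish.pixels, label_map) if fish is not None else np.inf
    )

    if n_cells == 0:
        cols = [
            "cell_id", "fov_id", "sample_id", "probe_id", "area_px",
            "mgv_dapi", "mgv_boncat", "mgv_fish",
            "dapi_pos", "boncat_pos", "fish_pos",
        ]
        return pd.DataFrame(columns=cols)

    area = ndi.sum_labels(np.ones_like(label_map), label_map, ids)
    mgv_d = ndi.mean(dapi.pixels.astype(float), label_map, ids)
    mgv_b = ndi.mean(boncat.pixels.astype(float), label_map, ids)
    mgv_f = (
        ndi.mean(fish.pixels.astype(float), label_map, ids)
        if fish is not None
        else np.full(n_cells, np.nan)
    )
    dapi_pos = np.ones(n_cells, dtype=bool)
    boncat_pos = dapi_pos & (mgv_b > tau_b)
    fish_pos = (mgv_f > tau_f) if fish is not None else np.zeros(n_cells, dtype=bool)
    return pd.DataFrame(
        {
            "cell_id": ids,
            "fov_id": dapi.fov_id,
            "sample_id": dapi.sample_id,
            "probe_id": fish.probe_id if fish is not None else None,
            "area_px": area.astype(int),
            "mgv_dapi": mgv_d,
            "mgv_boncat": mgv_b,
            "mgv_fish": mgv_f,
            "dapi_pos": dapi_pos,
            "boncat_pos": boncat_pos,
            "fish_pos": fish_pos,
        }
    )


# ---------------------------------------------------------------------------
# sample- and group-level summaries


def sample_activity(cells: pd.DataFrame, n_fov: int) -> float:
    """Total activity proxy: summed BONCAT MGV of BONCAT+ cells per FOV."""
    if n_fov < 1:
        raise ValueError("n_fov must be >= 1")
    return float(cells.loc[cells["boncat_pos"], "mgv_boncat"].sum() / n_fov)


def group_activity_contribution(cells: pd.DataFrame) -> float:
    """Fraction of total BONCAT intensity carried by probe-positive cells.

    sum MGV_BONCAT over (BONCAT+ and probe+) / sum over all BONCAT+.
    Undefined (raises) when the sample has no BONCAT+ cell — reported
    upstream as missing, never as zero.
    """
    pos = cells[cells["boncat_pos"]]
    denom = pos["mgv_boncat"].sum()
    if len(pos) == 0 or denom <= 0:
        raise ZeroDivisionError("no BONCAT+ cells: activity contribution undefined")
    num = pos.loc[pos["fish_pos"], "mgv_boncat"].sum()
    return float(num / denom)


def group_abundance_contribution(cells: pd.DataFrame) -> float:
    """Fraction of DAPI+ cells hybridised by the probe."""
    dapi = cells[cells["dapi_pos"]]
    if len(dapi) == 0:
        raise ZeroDivisionError("no DAPI+ cells: abundance contribution undefined")
    return float((dapi["fish_pos"] & dapi["dapi_pos"]).sum() / len(dapi))


def resolve_nested_groups(
    per_probe: pd.DataFrame, panel: ProbePanel, tolerance: float = 0.05
) -> pd.DataFrame:
    """Exclusive displayed categories from overlapping probe measurements.

    ``per_probe`` is long-format with columns ``sample_id``, ``probe_id``,
    ``contribution_activity``, ``contribution_abundance`` (one row per
    probe per sample). Each nesting pair (child ⊂ parent) yields an
    "other parent-target" category as parent − child; the residual
    "Other" category is 1 minus the top-level probes' total. Negative
    differences — possible because probes are counted on different
    filter sections — are clipped to 0 with a warning, and categories
    are re-closed to sum exactly 1.
    """
    out_rows = []
    children_of = {}
    for child, parent in panel.nesting.items():
        children_of.setdefault(parent, []).append(child)
    top_level = [
        p for p in panel.group_probes if p not in panel.nesting
    ]
    for sample, sub in per_probe.groupby("sample_id"):
        sub = sub.set_index("probe_id")
        for kind in ("contribution_activity", "contribution_abundance"):
            if kind not in sub.columns:
                raise ValueError(f"per-probe table lacks column {kind!r}")
        cats: dict[str, dict[str, float]] = {}
        for kind in ("contribution_activity", "contribution_abundance"):
            vals = {}
            top_total = 0.0
            for parent in top_level:
                if parent not in sub.index:
                    raise ValueError(f"sample {sample!r} lacks probe {parent!r}")
                pv = float(sub.loc[parent, kind])
                top_total += pv
                kids = children_of.get(parent, [])
                child_sum = 0.0
                for child in kids:
                    cv = float(sub.loc[child, kind])
                    vals[panel.targets[child]] = cv
                    child_sum += cv
                if kids:
                    diff = pv - child_sum
                    if diff < -tolerance:
                        logger.warning(
                            "sample %s: children of %s exceed parent by %.3f",
                            sample, parent, -diff,
                        )
                    vals[f"Other {panel.targets[parent]}"] = max(diff, 0.0)
                else:
                    vals[panel.targets[parent]] = pv
            vals["Other"] = max(1.0 - top_total, 0.0)
            total = sum(vals.values())
            if total <= 0:
                raise ZeroDivisionError(f"sample {sample!r}: all categories zero")
            cats[kind] = {k: v / total for k, v in vals.items()}
        for group in cats["contribution_activity"]:
            out_rows.append(
                {
                    "sample_id": sample,
                    "group": group,
                    "contribution_activity": cats["contribution_activity"][group],
                    "contribution_abundance": cats["contribution_abundance"][group],
                }
            )
    return pd.DataFrame(out_rows)


def abundance_vs_activity(activity_table: pd.DataFrame) -> pd.DataFrame:
    """Paired abundance/activity contributions with deviation from 1:1.

    A group lying below the identity line (negative deviation) is
    present but under-active — the signature of a taxon that bloomed
    earlier and has since shut down protein synthesis.
    """
    required = {"sample_id", "group", "contribution_abundance", "contribution_activity"}
    if not required <= set(activity_table.columns):
        raise ValueError(f"need columns {sorted(required)}")
    paired = activity_table.dropna(
        subset=["contribution_abundance", "contribution_activity"]
    ).copy()
    dropped = len(activity_table) - len(paired)
    if dropped:
        logger.info("abundance_vs_activity: skipped %d unpaired rows", dropped)
    paired["deviation"] = (
        paired["contribution_activity"] - paired["contribution_abundance"]
    )
    return paired


def boncat_positive_density(
    cells: pd.DataFrame,
    n_fov: int,
    volume_mL: float | None = None,
    filter_area: float | None = None,
    fov_area: float | None = None,
) -> dict:
    """BONCAT+ cells per FOV, optionally scaled to cells per mL.

    Scaling multiplies by (filter area / FOV area) to go from one FOV to
    the whole filter, then divides by the filtered volume.
    """
    if n_fov < 1:
        raise ValueError("n_fov must be >= 1")
    count = int(cells["boncat_pos"].sum())
    out = {"boncat_pos_count": count, "per_fov": count / n_fov}
    meta = (volume_mL, filter_area, fov_area)
    if any(m is not None for m in meta):
        if any(m is None or m <= 0 for m in meta):
            raise ValueError("volume_mL, filter_area and fov_area must all be positive")
        out["per_mL"] = (count / n_fov) * (filter_area / fov_area) / volume_mL
    return out


# ---------------------------------------------------------------------------
# file-based entry points

_FNAME = re.compile(r"^(?P<sample>.+)_(?P<probe>[^_]+)_(?P<fov>[^_]+)_(?P<chan>dapi|boncat|fish)\.tiff?$")


def load_fov_triplet(directory: Path, sample: str, probe: str, fov: str,
                     bit_depth: int = 8) -> dict:
    """Read the DAPI/BONCAT/FISH TIFFs of one FOV by filename convention.

    Files are named ``<sample>_<probe>_<fov>_{dapi|boncat|fish}.tif``.
    """
    directory = Path(directory)
    out = {}
    for chan in CHANNELS:
        path = directory / f"{sample}_{probe}_{fov}_{chan}.tif"
        if not path.exists():
            raise FileNotFoundError(path)
        out[chan] = Micrograph(
            tifffile.imread(path), chan, fov, sample,
            probe_id=probe if chan == "fish" else None, bit_depth=bit_depth,
        )
    return out


def quantify_fov_directory(
    directory: Path,
    min_area_px: int = 5,
    boncat_k: float = 3.0,
    fish_k: float = 3.0,
    bit_depth: int = 8,
) -> pd.DataFrame:
    """Segment and gate every FOV triplet found in a directory."""
    directory = Path(directory)
    triplets: dict[tuple, set] = {}
    for path in sorted(directory.glob("*.tif")):
        m = _FNAME.match(path.name)
        if not m:
            logger.warning("skipping unrecognised file name %s", path.name)
            continue
        triplets.setdefault(
            (m["sample"], m["probe"], m["fov"]), set()
        ).add(m["chan"])
    frames = []
    for (sample, probe, fov), chans in sorted(triplets.items()):
        if set(CHANNELS) - chans:
            raise FileNotFoundError(
                f"FOV {sample}/{probe}/{fov} is missing channels {sorted(set(CHANNELS) - chans)}"
            )
        trip = load_fov_triplet(directory, sample, probe, fov, bit_depth=bit_depth)
        labels = segment_cells(trip["dapi"], min_area_px=min_area_px)
        frames.append(
            gate_cells(
                labels, trip["dapi"], trip["boncat"], trip["fish"],
                BackgroundThreshold(boncat_k), BackgroundThreshold(fish_k),
            )
        )
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
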