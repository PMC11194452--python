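"""Synthetic data with the statistical structure of a leachate incubation.

Two generators cover the two data streams of the study design:

* ``simulate_fov_set`` renders DAPI/BONCAT/CARD-FISH micrograph triplets
  of planted cell communities (hard disks on a noisy background, BONCAT
  amplitude proportional to each cell's activity, one independent FOV
  set per probe since every probe is hybridised on its own filter
  section), together with a ground-truth manifest per cell.

* ``simulate_asv_experiment`` draws an ASV count table for the
  six-treatment (3 plastic levels x 2 light levels) x 3 replicate
  design plus the inoculum, around planted responder clusters:
  generalists growing everywhere, treatment-specific responders,
  inoculum-only taxa that collapse after the 9:1 dilution into
  leachate, and a rare tail. Counts follow a compound multinomial whose
  composition is gamma-perturbed at constant coefficient of variation;
  flow-cytometry totals and DOC/FDOM covariates are calibrated to the
  measured end-point values of the incubation (aged-plastic leachates
  reaching ~4x the control's cell density under irradiation).

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage.draw import disk as _disk

from .image_quant import Micrograph, ProbePanel, default_probe_panel

__all__ = [
    "CellGroupSpec",
    "FovParams",
    "default_image_community",
    "simulate_fov_set",
    "treatment_fov_scenario",
    "write_fov_set",
    "ClusterSpec",
    "AsvExperimentParams",
    "default_cluster_specs",
    "TREATMENTS",
    "FLOW_TOTALS_1e6",
    "FLOW_TOTALS_SD_1e6",
    "COVARIATES",
    "simulate_asv_experiment",
    "write_asv_experiment",
    "write_manifest",
    "read_manifest",
]


# ===========================================================================
# micrograph simulation


@dataclass(frozen=True)
class CellGroupSpec:
    """One planted taxonomic group in the imaged community."""

    name: str
    fraction: float  # of total cells
    probes: tuple  # probe ids whose target set includes this group
    activity_level: float  # expected in-cell BONCAT mean grey value (absolute)
    active_fraction: float = 1.0  # share of the group's cells synthesising protein


@dataclass(frozen=True)
class FovParams:
    shape: tuple = (256, 256)
    bit_depth: int = 8
    n_cells: int = 80
    radius_range: tuple = (2, 4)
    background: float = 20.0
    noise_sd: float = 2.0
    dapi_amplitude: float = 120.0
    fish_amplitude: float = 100.0
    min_gap_px: int = 2
    exact_fractions: bool = True  # largest-remainder group counts instead of a draw
    probe_sensitivity: dict = field(default_factory=dict)  # probe -> [0,1]


def default_image_community() -> list:
    """Groups mirroring the probe panel's coverage of a bloom community."""
    return [
        CellGroupSpec("Alteromonadales", 0.25, ("ALT1413", "GAM42a", "EUB338"), 90.0),
        CellGroupSpec("OtherGamma", 0.20, ("GAM42a", "EUB338"), 70.0),
        CellGroupSpec("Rhodobacterales", 0.20, ("ROS537", "Alf968", "EUB338"), 80.0),
        CellGroupSpec("OtherAlpha", 0.15, ("Alf968", "EUB338"), 55.0),
        CellGroupSpec("Bacteroidetes", 0.10, ("CF319a", "EUB338"), 45.0),
        CellGroupSpec("Other", 0.10, ("EUB338",), 40.0),
    ]


def _group_counts(groups: list, n_cells: int, exact: bool, rng) -> np.ndarray:
    fracs = np.array([g.fraction for g in groups], dtype=float)
    fracs = fracs / fracs.sum()
    if exact:
        raw = fracs * n_cells
        counts = np.floor(raw).astype(int)
        remainder = n_cells - counts.sum()
        order = np.argsort(-(raw - counts))
        counts[order[:remainder]] += 1
        return counts
    return rng.multinomial(n_cells, fracs)


def _place_cells(shape, radii, min_gap, rng, max_tries=20000):
    """Rejection-sample non-overlapping disk centres inside the frame."""
    centers = []
    for r in radii:
        for attempt in range(max_tries):
            c = (
                rng.uniform(r + 1, shape[0] - r - 1),
                rng.uniform(r + 1, shape[1] - r - 1),
            )
            ok = all(
                np.hypot(c[0] - c2[0], c[1] - c2[1]) > r + r2 + min_gap
                for c2, r2 in centers
            )
            if ok:
                centers.append((c, r))
                break
        else:
            raise RuntimeError(
                f"cannot place {len(radii)} non-overlapping cells of radius ~{r} "
                f"in a {shape} frame"
            )
    return [c for c, _ in centers]


def _render(shape, background, noise_sd, disks, bit_depth, rng):
    """Disks of given (center, radius, amplitude) over noisy background."""
    img = np.full(shape, background, dtype=float)
    for center, radius, amplitude in disks:
        rr, cc = _disk(center, radius, shape=shape)
        img[rr, cc] = background + amplitude
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=shape)
    return np.clip(np.round(img), 0, 2**bit_depth - 1).astype(
        np.uint8 if bit_depth <= 8 else np.uint16
    )


def simulate_fov_set(
    params: FovParams,
    n_fov: int,
    sample_id: str = "S1",
    groups: list | None = None,
    panel: ProbePanel | None = None,
    probes: list | None = None,
    seed: int | None = 0,
):
    """Render per-probe FOV sets with a per-cell ground-truth manifest.

    Returns ``(fovs, truth)`` where ``fovs[probe]`` is a list of
    ``{"dapi": Micrograph, "boncat": ..., "fish": ...}`` dicts and
    ``truth`` is a DataFrame with one row per planted cell (probe set,
    FOV, position, radius, group, activity, expected positivity).
    """
    rng = np.random.default_rng(seed)
    groups = groups if groups is not None else default_image_community()
    panel = panel or default_probe_panel()
    probes = probes if probes is not None else list(panel.targets)
    unknown = set(probes) - set(panel.targets)
    if unknown:
        raise ValueError(f"probes not in panel: {sorted(unknown)}")

    fovs: dict[str, list] = {p: [] for p in probes}
    truth_rows = []
    for probe in probes:
        sens = params.probe_sensitivity.get(probe, 1.0)
        for i_fov in range(n_fov):
            fov_id = f"fov{i_fov:02d}"
            counts = _group_counts(groups, params.n_cells, params.exact_fractions, rng)
            cell_groups = [g for g, c in zip(groups, counts) for _ in range(c)]
            rng.shuffle(cell_groups)
            radii = rng.integers(
                params.radius_range[0], params.radius_range[1] + 1, len(cell_groups)
            )
            centers = (
                _place_cells(params.shape, radii, params.min_gap_px, rng)
                if cell_groups
                else []
            )
            dapi_disks, boncat_disks, fish_disks = [], [], []
            for center, radius, g in zip(centers, radii, cell_groups):
                active = rng.random() < g.active_fraction
                hybridised = (probe in g.probes) and (rng.random() < sens)
                dapi_disks.append((center, radius, params.dapi_amplitude))
                if active:
                    if g.activity_level <= params.background:
                        raise ValueError(
                            f"activity level {g.activity_level} of group {g.name!r} "
                            f"must exceed the background {params.background} to be "
                            "an in-cell mean grey value"
                        )
                    # activity_level is the absolute in-cell BONCAT grey value
                    boncat_disks.append((center, radius, g.activity_level - params.background))
                if hybridised:
                    fish_disks.append((center, radius, params.fish_amplitude))
                truth_rows.append(
                    {
                        "sample_id": sample_id,
                        "probe_id": probe,
                        "fov_id": fov_id,
                        "row": center[0],
                        "col": center[1],
                        "radius_px": int(radius),
                        "group": g.name,
                        "is_active": bool(active),
                        "activity_level": g.activity_level if active else 0.0,
                        "hybridised": bool(hybridised),
                    }
                )
            chans = {
                "dapi": _render(params.shape, params.background, params.noise_sd,
                                dapi_disks, params.bit_depth, rng),
                "boncat": _render(params.shape, params.background, params.noise_sd,
                                  boncat_disks, params.bit_depth, rng),
                "fish": _render(params.shape, params.background, params.noise_sd,
                                fish_disks, params.bit_depth, rng),
            }
            fovs[probe].append(
                {
                    chan: Micrograph(
                        chans[chan], chan, fov_id, sample_id,
                        probe_id=probe if chan == "fish" else None,
                        bit_depth=params.bit_depth,
                    )
                    for chan in chans
                }
            )
    truth = pd.DataFrame(truth_rows)
    return fovs, truth


def treatment_fov_scenario(
    plastic: str,
    light: str,
    timepoint: str = "t4",
    cells_per_fov_per_1e6: float = 10.0,
) -> tuple:
    """FOV parameters and community for one treatment at one timepoint.

    Cell density per FOV scales with the treatment's end-point
    flow-cytometry total, so aged-plastic leachates carry ~4x the
    control's cells per field. At t1 every group is near-uniformly
    active (abundance tracks activity); at t4 the Alteromonadales-like
    early responders are largely inactivated (abundant but with a low
    active fraction and dim BONCAT signal), reproducing the
    below-the-1:1-line signature of a group that bloomed early and shut
    down.
    """
    total_1e6 = FLOW_TOTALS_1e6[(plastic, light)]
    n_cells = max(int(round(cells_per_fov_per_1e6 * total_1e6)), 5)
    params = FovParams(n_cells=n_cells)
    if timepoint == "t1":
        groups = [
            CellGroupSpec("Alteromonadales", 0.35, ("ALT1413", "GAM42a", "EUB338"), 90.0, 0.9),
            CellGroupSpec("OtherGamma", 0.15, ("GAM42a", "EUB338"), 80.0, 0.9),
            CellGroupSpec("Rhodobacterales", 0.20, ("ROS537", "Alf968", "EUB338"), 85.0, 0.9),
            CellGroupSpec("OtherAlpha", 0.12, ("Alf968", "EUB338"), 75.0, 0.9),
            CellGroupSpec("Bacteroidetes", 0.08, ("CF319a", "EUB338"), 70.0, 0.85),
            CellGroupSpec("Other", 0.10, ("EUB338",), 70.0, 0.85),
        ]
    elif timepoint == "t4":
        groups = [
            CellGroupSpec("Alteromonadales", 0.30, ("ALT1413", "GAM42a", "EUB338"), 45.0, 0.2),
            CellGroupSpec("OtherGamma", 0.18, ("GAM42a", "EUB338"), 95.0, 0.85),
            CellGroupSpec("Rhodobacterales", 0.25, ("ROS537", "Alf968", "EUB338"), 85.0, 0.75),
            CellGroupSpec("OtherAlpha", 0.10, ("Alf968", "EUB338"), 80.0, 0.7),
            CellGroupSpec("Bacteroidetes", 0.07, ("CF319a", "EUB338"), 75.0,
                          0.6 if plastic == "aged" and light == "irradiated" else 0.15),
            CellGroupSpec("Other", 0.10, ("EUB338",), 60.0, 0.5),
        ]
    else:
        raise ValueError(f"unknown timepoint {timepoint!r}")
    return params, groups


def write_fov_set(fovs: dict, truth: pd.DataFrame, directory: Path) -> None:
    """Serialise a simulated FOV set as TIFFs plus a truth manifest TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for probe, fov_list in fovs.items():
        for fov in fov_list:
            for chan, mg in fov.items():
                name = f"{mg.sample_id}_{probe}_{mg.fov_id}_{chan}.tif"
                tifffile.imwrite(directory / name, mg.pixels)
    truth.to_csv(directory / "image_truth.tsv", sep="\t", index=False)


# ===========================================================================
# ASV experiment simulation

#: treatment keys are (plastic, light)
TREATMENTS = [
    ("control", "irradiated"),
    ("control", "non_irradiated"),
    ("LDPE", "irradiated"),
    ("LDPE", "non_irradiated"),
    ("aged", "irradiated"),
    ("aged", "non_irradiated"),
]

#: end-point flow-cytometry totals, 1e6 cells/mL (mean, SD across replicates)
FLOW_TOTALS_1e6 = {
    ("control", "irradiated"): 3.06,
    ("control", "non_irradiated"): 2.71,
    ("LDPE", "irradiated"): 3.15,
    ("LDPE", "non_irradiated"): 2.78,
    ("aged", "irradiated"): 13.4,
    ("aged", "non_irradiated"): 9.79,
}
FLOW_TOTALS_SD_1e6 = {
    ("control", "irradiated"): 0.34,
    ("control", "non_irradiated"): 0.23,
    ("LDPE", "irradiated"): 0.31,
    ("LDPE", "non_irradiated"): 0.19,
    ("aged", "irradiated"): 2.75,
    ("aged", "non_irradiated"): 0.88,
}

#: start-of-experiment leachate chemistry per treatment:
#: total DOC (umol/L), protein-like FDOM, humic-like FDOM (R.U. nm^2)
COVARIATES = {
    ("control", "irradiated"): (81.36, 41.75, 71.98),
    ("control", "non_irradiated"): (73.62, 45.21, 110.56),
    ("LDPE", "irradiated"): (94.50, 51.67, 64.57),
    ("LDPE", "non_irradiated"): (79.56, 50.54, 117.71),
    ("aged", "irradiated"): (665.87, 972.84, 309.66),
    ("aged", "non_irradiated"): (492.53, 1695.00, 573.92),
}


@dataclass(frozen=True)
class ClusterSpec:
    """One planted responder cluster of ASVs.

    ``weights`` gives the cluster's expected share of the community in
    each of the six treatments (order of ``TREATMENTS``); ``inoculum``
    its share in the untreated inoculum sample.
    """

    name: str
    n_asvs: int
    weights: tuple  # len 6, order of TREATMENTS
    inoculum: float
    taxa_pool: str  # key into the taxonomy pools


def default_cluster_specs() -> list:
    """Seven response archetypes plus a rare tail.

    Effect sizes between preferred and non-preferred treatments are
    >= 4-fold; shares echo the published cluster contributions
    (generalists 40-90 % depending on treatment, irradiated-aged
    specialists ~40 %+12 %, non-irradiated-aged responders ~15 %,
    irradiated-LDPE responders ~8 %, inoculum dominated by taxa that
    never grow in any treatment).
    """
    return [
        ClusterSpec("generalist", 12, (0.86, 0.60, 0.78, 0.62, 0.38, 0.44), 0.05, "generalist"),
        ClusterSpec("non_irradiated_pref", 8, (0.04, 0.28, 0.04, 0.20, 0.0002, 0.02), 0.02, "mixed"),
        ClusterSpec("irradiated_aged", 8, (0.0002, 0.0002, 0.0002, 0.0002, 0.38, 0.10), 0.01, "aged_responders"),
        ClusterSpec("aged_specific_pseudoalteromonas", 7, (0.0002, 0.0002, 0.0002, 0.0002, 0.12, 0.0015), 0.002, "pseudoalteromonas"),
        ClusterSpec("irradiated_ldpe", 4, (0.0002, 0.0002, 0.09, 0.0002, 0.0002, 0.0002), 0.005, "ldpe_responders"),
        ClusterSpec("non_irradiated_aged", 8, (0.0002, 0.01, 0.0002, 0.01, 0.015, 0.18), 0.01, "mixed2"),
        ClusterSpec("inoculum_only", 8, (0.0002, 0.0002, 0.0002, 0.0002, 0.0002, 0.0002), 0.70, "oligotrophs"),
        ClusterSpec("rare", 120, (0.099, 0.109, 0.089, 0.169, 0.104, 0.258), 0.211, "rare"),
    ]


# taxonomy pools: (phylum, class, order, family, genus) with optional gaps
_TAX_POOLS = {
    "generalist": [
        ("Proteobacteria", "Alphaproteobacteria", "Rhodobacterales", "Rhodobacteraceae", "Leisingera"),
        ("Proteobacteria", "Alphaproteobacteria", "Rhodobacterales", "Rhodobacteraceae", "Phaeobacter"),
        ("Proteobacteria", "Alphaproteobacteria", "Sphingomonadales", "Sphingomonadaceae", "Sphingomonas"),
        ("Proteobacteria", "Gammaproteobacteria", "Alteromonadales", "Alteromonadaceae", "Alteromonas"),
        ("Proteobacteria", "Gammaproteobacteria", "Alteromonadales", "Marinobacteraceae", "Marinobacter"),
        ("Proteobacteria", "Gammaproteobacteria", "Oceanospirillales", "Alcanivoracaceae", "Alcanivorax"),
        ("Proteobacteria", "Gammaproteobacteria", "Nitrosococcales", "Methylophagaceae", "Methylophaga"),
    ],
    "mixed": [
        ("Bacteroidota", "Bacteroidia", "Flavobacteriales", "Flavobacteriaceae", "Winogradskyella"),
        ("Proteobacteria", "Gammaproteobacteria", "Nitrosococcales", "Methylophagaceae", "Methylophaga"),
        ("Proteobacteria", "Gammaproteobacteria", "Alteromonadales", "Alteromonadaceae", "Glaciecola"),
        ("Proteobacteria", "Gammaproteobacteria", "Oceanospirillales", "Oceanospirillaceae", "Marinomonas"),
        ("Proteobacteria", "Alphaproteobacteria", "Rhodobacterales", "Rhodobacteraceae", "Sulfitobacter"),
        ("Proteobacteria", "Alphaproteobacteria", "Caulobacterales", "Hyphomonadaceae", "Hyphomonas"),
        ("Proteobacteria", "Alphaproteobacteria", "Parvibaculales", "Parvibaculaceae", "Parvibaculum"),
        ("Proteobacteria", "Alphaproteobacteria", "Sneathiellales", "Sneathiellaceae", "Sneathiella"),
    ],
    "aged_responders": [
        ("Proteobacteria", "Gammaproteobacteria", "Alteromonadales", "Pseudoalteromonadaceae", "Pseudoalteromonas"),
        ("Proteobacteria", "Gammaproteobacteria", "Oceanospirillales", "Oceanospirillaceae", "Marinomonas"),
        ("Bacteroidota", "Bacteroidia", "Flavobacteriales", "Flavobacteriaceae", "Allomuricauda"),
        ("Bacteroidota", "Rhodothermia", "Balneolales", "Balneolaceae", "Balneola"),
        ("Proteobacteria", "Alphaproteobacteria", "Rhodobacterales", "Rhodobacteraceae", "Antarctobacter"),
        ("Proteobacteria", "Alphaproteobacteria", "Rhodospirillales", "Thalassospiraceae", "Thalassospira"),
    ],
    "pseudoalteromonas": [
        ("Proteobacteria", "Gammaproteobacteria", "Alteromonadales", "Pseudoalteromonadaceae", "Pseudoalteromonas"),
        ("Planctomycetota", "Planctomycetes", "Isosphaerales", "Isosphaeraceae", "Paludisphaera"),
    ],
    "ldpe_responders": [
        ("Proteobacteria", "Gammaproteobacteria", "Alteromonadales", "Marinobacteraceae", "Marinobacter"),
        ("Proteobacteria", "Gammaproteobacteria", "Cellvibrionales", "Spongiibacteraceae", "Spongiibacter"),
        ("Proteobacteria", "Alphaproteobacteria", "Rhodobacterales", "Rhodobacteraceae", "Leisingera"),
    ],
    "mixed2": [
        ("Proteobacteria", "Gammaproteobacteria", "Alteromonadales", "Marinobacteraceae", "Marinobacter"),
        ("Proteobacteria", "Gammaproteobacteria", "Oceanospirillales", "Pseudohongiellaceae", "Pseudohongiella"),
        ("Bacteroidota", "Bacteroidia", "Flavobacteriales", "Crocinitomicaceae", "Crocinitomix"),
        ("Bacteroidota", "Bacteroidia", "Flavobacteriales", "Cryomorphaceae", ""),
        ("Bacteroidota", "Bacteroidia", "Sphingobacteriales", "Lentimicrobiaceae", ""),
        ("Proteobacteria", "Alphaproteobacteria", "Rhodobacterales", "Rhodobacteraceae", "Leisingera"),
        ("Proteobacteria", "Alphaproteobacteria", "Rhodobacterales", "Rhodobacteraceae", ""),
        ("Proteobacteria", "Alphaproteobacteria", "Sneathiellales", "Sneathiellaceae", "Sneathiella"),
    ],
    "oligotrophs": [
        ("Proteobacteria", "Alphaproteobacteria", "Pelagibacterales", "Pelagibacteraceae", "Pelagibacter"),
        ("Crenarchaeota", "Nitrososphaeria", "Nitrosopumilales", "Nitrosopumilaceae", "Nitrosopumilus"),
        ("Actinobacteriota", "Acidimicrobiia", "Actinomarinales", "Actinomarinaceae", "Actinomarina"),
        ("Cyanobacteria", "Cyanobacteriia", "Synechococcales", "Cyanobiaceae", "Synechococcus"),
    ],
    "rare": [
        ("Proteobacteria", "Gammaproteobacteria", "", "", ""),
        ("Proteobacteria", "Gammaproteobacteria", "Vibrionales", "Vibrionaceae", "Vibrio"),
        ("Bacteroidota", "Bacteroidia", "Flavobacteriales", "", ""),
        ("Verrucomicrobiota", "Verrucomicrobiae", "Verrucomicrobiales", "", ""),
        ("Planctomycetota", "Planctomycetes", "Pirellulales", "Pirellulaceae", ""),
        ("Proteobacteria", "Gammaproteobacteria", "Pseudomonadales", "Pseudomonadaceae", "Pseudomonas"),
    ],
}

#: mean 16S rRNA gene copy numbers; (name, rank) -> copies. Genus entries
#: dominate, a few taxa resolve only through family/order fallbacks.
_COPY_NUMBERS = [
    ("Leisingera", "genus", 2.0), ("Phaeobacter", "genus", 3.0),
    ("Sulfitobacter", "genus", 4.0), ("Antarctobacter", "genus", 2.0),
    ("Sphingomonas", "genus", 2.0), ("Hyphomonas", "genus", 2.0),
    ("Parvibaculum", "genus", 2.0), ("Sneathiella", "genus", 2.0),
    ("Alteromonas", "genus", 5.0), ("Glaciecola", "genus", 4.0),
    ("Marinobacter", "genus", 3.0), ("Pseudoalteromonas", "genus", 9.0),
    ("Alcanivorax", "genus", 3.0), ("Marinomonas", "genus", 8.0),
    ("Pseudohongiella", "genus", 2.0), ("Methylophaga", "genus", 3.0),
    ("Spongiibacter", "genus", 2.0), ("Winogradskyella", "genus", 2.0),
    ("Allomuricauda", "genus", 2.0), ("Crocinitomix", "genus", 2.0),
    ("Balneola", "genus", 2.0), ("Thalassospira", "genus", 2.0),
    ("Pelagibacter", "genus", 1.0), ("Nitrosopumilus", "genus", 1.0),
    ("Actinomarina", "genus", 1.0), ("Synechococcus", "genus", 2.0),
    ("Paludisphaera", "genus", 2.0), ("Pseudomonas", "genus", 4.5),
    ("Vibrio", "genus", 9.0),
    ("Cryomorphaceae", "family", 2.0), ("Lentimicrobiaceae", "family", 1.5),
    ("Rhodobacteraceae", "family", 2.5), ("Pirellulaceae", "family", 1.5),
    ("Flavobacteriales", "order", 2.0), ("Verrucomicrobiales", "order", 1.5),
]


@dataclass(frozen=True)
class AsvExperimentParams:
    cluster_specs: tuple = tuple(default_cluster_specs())
    n_replicates: int = 3
    depth_range: tuple = (4436, 8000)
    cv: float = 0.20  # replicate coefficient of variation of abundant taxa
    timepoint: str = "t4"
    effect_scale: float = 1.0  # 0 => all treatments share the inoculum profile


def _asv_taxonomy(params: AsvExperimentParams) -> tuple[pd.DataFrame, pd.Series]:
    """Fixed taxonomy and cluster membership for every planted ASV."""
    rows, membership = [], {}
    i = 0
    for spec in params.cluster_specs:
        pool = _TAX_POOLS[spec.taxa_pool]
        for j in range(spec.n_asvs):
            asv = f"asv{i:04d}"
            phylum, cls, order, family, genus = pool[j % len(pool)]
            domain = "Archaea" if phylum == "Crenarchaeota" else "Bacteria"
            rows.append(
                {
                    "asv_id": asv, "domain": domain, "phylum": phylum,
                    "class": cls, "order": order, "family": family,
                    "genus": genus, "species": "",
                }
            )
            membership[asv] = spec.name
            i += 1
    tax = pd.DataFrame(rows).set_index("asv_id")
    return tax, pd.Series(membership, name="cluster")


def _expected_compositions(params: AsvExperimentParams, rng) -> pd.DataFrame:
    """Expected relative abundance per ASV per treatment (+ inoculum).

    Within a responder cluster the weight is spread over member ASVs on
    a geometric ladder (ratio 0.9), echoing the dominance of a few lead
    responders; the rare tail is spread flat so each member stays below
    the abundance screen. The ladder is drawn once so all treatments
    share it.
    ``effect_scale`` < 1 shrinks every treatment profile toward the
    across-treatment mean; 0 makes treatments exchangeable (null case).
    """
    cols = [f"{p}:{l}" for p, l in TREATMENTS] + ["inoculum"]
    blocks = []
    for spec in params.cluster_specs:
        base = np.ones(spec.n_asvs) if spec.name == "rare" else 0.90 ** np.arange(spec.n_asvs)
        ladder = base * rng.lognormal(0.0, 0.12, spec.n_asvs)
        ladder /= ladder.sum()
        w = np.array(list(spec.weights) + [spec.inoculum])
        blocks.append(np.outer(ladder, w))
    exp = np.vstack(blocks)
    exp /= exp.sum(axis=0, keepdims=True)
    if params.effect_scale != 1.0:
        treat = exp[:, :6]
        mean = treat.mean(axis=1, keepdims=True)
        exp[:, :6] = mean + params.effect_scale * (treat - mean)
        exp[:, :6] = np.clip(exp[:, :6], 1e-12, None)
        exp[:, :6] /= exp[:, :6].sum(axis=0, keepdims=True)
    n_asv = exp.shape[0]
    index = [f"asv{i:04d}" for i in range(n_asv)]
    return pd.DataFrame(exp, index=index, columns=cols)


def simulate_asv_experiment(
    params: AsvExperimentParams | None = None, seed: int | None = 0
) -> dict:
    """Draw one full synthetic sequencing experiment.

    Returns a dict with ``counts`` (ASV x sample), ``taxonomy``,
    ``copy_numbers``, ``design``, ``flow_totals`` (cells/mL),
    ``covariates`` and ``truth`` (cluster membership, expected
    compositions, parameters, seed).
    """
    params = params or AsvExperimentParams()
    rng = np.random.default_rng(seed)
    tax, membership = _asv_taxonomy(params)
    expected = _expected_compositions(params, rng)

    def _draw_composition(expected_col: np.ndarray) -> np.ndarray:
        """Replicate-to-replicate compositional noise with constant CV.

        Each taxon's expected share is perturbed by an independent
        gamma factor of mean 1 and coefficient of variation ``cv``
        before re-closure, so abundant responders fluctuate by ~cv
        across replicates while the planted rare tail stays rare
        (a shared-concentration Dirichlet would make rare taxa orders
        of magnitude noisier than abundant ones).
        """
        if params.cv <= 0:
            return expected_col / expected_col.sum()
        shape = 1.0 / params.cv**2
        w = expected_col * rng.gamma(shape, 1.0 / shape, size=expected_col.size)
        total = w.sum()
        return w / total if total > 0 else expected_col / expected_col.sum()

    design_rows, count_cols, flow_rows, cov_rows = [], {}, [], []
    for (plastic, light) in TREATMENTS:
        tkey = f"{plastic}:{light}"
        doc, fdom_prot, fdom_hum = COVARIATES[(plastic, light)]
        for rep in range(1, params.n_replicates + 1):
            sid = f"{plastic}_{light}_r{rep}"
            design_rows.append(
                {"sample_id": sid, "plastic": plastic, "light": light,
                 "replicate": rep, "timepoint": params.timepoint}
            )
            p = _draw_composition(expected[tkey].to_numpy())
            depth = int(rng.integers(params.depth_range[0], params.depth_range[1] + 1))
            count_cols[sid] = rng.multinomial(depth, p)
            total = max(
                rng.normal(FLOW_TOTALS_1e6[(plastic, light)],
                           FLOW_TOTALS_SD_1e6[(plastic, light)]),
                0.05,
            ) * 1e6
            flow_rows.append({"sample_id": sid, "cells_per_mL": total})
            cov_rows.append(
                {"sample_id": sid, "doc_umol_L": doc,
                 "fdom_protein_like": fdom_prot, "fdom_humic_like": fdom_hum}
            )
    # the inoculum: one unreplicated community sample at t0
    sid = "inoculum"
    design_rows.append(
        {"sample_id": sid, "plastic": "inoculum", "light": "none",
         "replicate": 1, "timepoint": "t0"}
    )
    depth = int(rng.integers(params.depth_range[0], params.depth_range[1] + 1))
    count_cols[sid] = rng.multinomial(depth, _draw_composition(expected["inoculum"].to_numpy()))

    counts = pd.DataFrame(count_cols, index=expected.index)
    design = pd.DataFrame(design_rows).set_index("sample_id")
    flow_totals = pd.DataFrame(flow_rows).set_index("sample_id")["cells_per_mL"]
    covariates = pd.DataFrame(cov_rows).set_index("sample_id")
    copy_numbers = pd.DataFrame(_COPY_NUMBERS, columns=["taxon", "rank", "mean_copies"])

    truth = {
        "seed": seed,
        "cluster_membership": membership.to_dict(),
        "expected_composition": expected.to_dict(),
        "params": {
            "n_replicates": params.n_replicates,
            "depth_range": list(params.depth_range),
            "cv": params.cv,
            "effect_scale": params.effect_scale,
            "clusters": [asdict(s) for s in params.cluster_specs],
        },
    }
    return {
        "counts": counts,
        "taxonomy": tax,
        "copy_numbers": copy_numbers,
        "design": design,
        "flow_totals": flow_totals,
        "covariates": covariates,
        "truth": truth,
    }


def write_asv_experiment(experiment: dict, directory: Path) -> None:
    """Serialise a simulated experiment in the formats the pipeline reads."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    experiment["counts"].rename_axis("asv_id").to_csv(directory / "counts.tsv", sep="\t")
    experiment["taxonomy"].to_csv(directory / "taxonomy.tsv", sep="\t")
    experiment["copy_numbers"].to_csv(directory / "copy_numbers.tsv", sep="\t", index=False)
    experiment["design"].to_csv(directory / "design.tsv", sep="\t")
    experiment["flow_totals"].rename_axis("sample_id").to_frame().to_csv(
        directory / "flow_totals.tsv", sep="\t"
    )
    experiment["covariates"].to_csv(directory / "covariates.tsv", sep="\t")
    write_manifest(experiment["truth"], directory / "manifest.json")


def write_manifest(truth: dict, path: Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1, sort_keys=True))


def read_manifest(path: Path) -> dict:
    return json.loads(Path(path).read_text())
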