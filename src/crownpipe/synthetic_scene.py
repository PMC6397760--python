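"""Seeded generator of complete synthetic forest plots.

Each generated scene carries everything the pipeline stages consume plus
the ground truth they are scored against: a canopy height model rendered
from conical crowns, a co-registered hyperspectral cube built from
per-species reflectance signatures over a low-NDVI ground background, stem
records with positional jitter and a plot-wide systematic offset, crown
records derived from the true label grid, and the true stem-crown pairing
and species labels.

Model of a tree
---------------
Trees are placed by rejection sampling with a minimum apex spacing.  A
tree of height ``H`` and crown radius ``R`` contributes the cone

    h(d) = H * max(0, 1 - d / R)

at distance ``d`` from its apex; the CHM is the pixelwise maximum over
trees (ground = 0), and the true crown label of a canopy pixel is the
tree attaining that maximum (ties to the earlier tree index).  Crown
radius follows a linear allometry on height with Gaussian noise, and the
stem diameter is generated by inverting a linear crown-diameter-on-stem-
diameter relation with residual noise, so the regression the alignment
stage fits on training pairs is well-posed by construction.

Randomness is driven by one global seed spawning per-purpose substreams
(placement, spectra, stem jitter, stem allometry), so subsystems can be
varied independently while staying fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import (
    CanopyHeightModel,
    CrownRecord,
    PixelObservation,
    SpectralCube,
    StemRecord,
    write_chm,
    write_crowns,
    write_cube,
    write_label_raster,
    write_stems,
)
from .segmentation import CrownLabelGrid, TreeTop

__all__ = [
    "SpeciesSpec",
    "SceneConfig",
    "TreeTruth",
    "SceneTruth",
    "SyntheticScene",
    "default_wavelengths",
    "default_species_list",
    "default_ground_signature",
    "separated_species",
    "generate_scene",
    "degrade_scene",
    "sample_pixel_observations",
    "write_scene",
]

N_BANDS_DEFAULT = 426
WAVELENGTH_MIN_NM = 350.0
WAVELENGTH_MAX_NM = 2500.0


def default_wavelengths(n_bands: int = N_BANDS_DEFAULT) -> np.ndarray:
    """Evenly spaced band-centre wavelengths spanning 350-2500 nm."""
    return np.linspace(WAVELENGTH_MIN_NM, WAVELENGTH_MAX_NM, n_bands)


def _vegetation_base(w: np.ndarray) -> np.ndarray:
    """A smooth green-vegetation reflectance curve: red-edge step at ~710 nm,
    NIR plateau, gentle shortwave-infrared decline with two water-absorption
    dips.  NDVI of this curve is ~0.75, comfortably above the 0.5 mask cut."""
    red_edge = 1.0 / (1.0 + np.exp(-(w - 710.0) / 15.0))
    swir = np.clip(1.0 - (w - 1300.0) / 2400.0, 0.35, 1.0)
    refl = 0.05 + 0.40 * red_edge * swir
    for centre, depth, width in ((1450.0, 0.25, 60.0), (1940.0, 0.35, 80.0)):
        refl = refl * (1.0 - depth * np.exp(-0.5 * ((w - centre) / width) ** 2))
    return refl


@dataclass
class SpeciesSpec:
    """One species: name, mean reflectance signature, within-species sigma."""

    name: str
    signature: np.ndarray
    sigma: float = 0.01

    def __post_init__(self) -> None:
        self.signature = np.asarray(self.signature, dtype=float)
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def default_species_list(
    names: tuple[str, ...] = ("PIPA", "QULA", "ACRU"),
    n_bands: int = N_BANDS_DEFAULT,
    sigma: float = 0.01,
) -> list[SpeciesSpec]:
    """Vegetation signatures differing by NIR/SWIR bumps per species.

    The bumps sit away from the red/near-infrared NDVI bands so every
    species passes the vegetation mask, while remaining well separated in
    the spectral feature space.
    """
    w = default_wavelengths(n_bands)
    base = _vegetation_base(w)
    species = []
    for i, name in enumerate(names):
        bump = 0.05 * np.exp(-0.5 * ((w - (900.0 + 180.0 * i)) / 60.0) ** 2)
        tilt = 0.02 * np.sin(2.0 * np.pi * (w - 350.0) / (700.0 + 150.0 * i))
        tilt = np.where(w > 1500.0, tilt, 0.0)
        species.append(SpeciesSpec(name=name, signature=base + bump + tilt, sigma=sigma))
    return species


def default_ground_signature(n_bands: int = N_BANDS_DEFAULT) -> np.ndarray:
    """Flat soil-like background; NDVI ~ 0, well below the 0.5 mask cut."""
    w = default_wavelengths(n_bands)
    return 0.20 + 2e-5 * (w - WAVELENGTH_MIN_NM)


def separated_species(
    n_species: int = 3,
    n_bands: int = N_BANDS_DEFAULT,
    sigma: float = 0.01,
    separation: float = 5.0,
    block_bands: int = 30,
) -> list[SpeciesSpec]:
    """Species signatures with controlled between-class separation.

    Class ``i`` is offset by ``separation * sigma`` on its own disjoint
    block of ``block_bands`` bands, giving a mean separation of
    ``separation`` within-class standard deviations per informative band.
    Intended for classification-only experiments (the signatures are flat,
    so they are not meant to pass an NDVI mask).
    """
    if n_species * block_bands > n_bands:
        raise ValueError("not enough bands for disjoint class blocks")
    base = np.full(n_bands, 0.30)
    out = []
    for i in range(n_species):
        sig = base.copy()
        sig[i * block_bands : (i + 1) * block_bands] += separation * sigma
        out.append(SpeciesSpec(name=f"SP{i + 1:02d}", signature=sig, sigma=sigma))
    return out


@dataclass
class SceneConfig:
    """Parameters of a synthetic plot.

    Defaults emulate the survey geometry the pipeline targets: an 80 x 80 m
    plot gridded at 1 m pixels, 426 spectral bands spanning 350-2500 nm,
    stem positions jittered by 1 m plus a plot-wide systematic offset of a
    few metres (typical hand-held GPS bias).
    """

    plot_size_m: float = 80.0
    pixel_size_m: float = 1.0
    n_trees: int = 10
    min_spacing_m: float = 10.0
    height_range_m: tuple[float, float] = (8.0, 20.0)
    #: crown radius = slope * height + intercept + N(0, noise), metres
    crown_radius_allometry: tuple[float, float, float] = (0.2, 1.0, 0.25)
    species_list: list[SpeciesSpec] = field(default_factory=default_species_list)
    ground_signature: np.ndarray = field(default_factory=default_ground_signature)
    ground_sigma: float = 0.01
    #: crown diameter = slope * stem diameter (cm) + intercept + N(0, noise) m,
    #: inverted to generate stem diameters from the rendered crown radii
    stem_diameter_model: tuple[float, float, float] = (0.114, 0.882, 0.5)
    stem_jitter_sigma_m: float = 1.0
    plot_offset_m: tuple[float, float] = (3.2, -1.7)
    plot_id: str = "P1"
    seed: int = 0

    def __post_init__(self) -> None:
        self.ground_signature = np.asarray(self.ground_signature, dtype=float)
        if self.min_spacing_m <= 0:
            raise ValueError("min_spacing_m must be > 0")
        if self.stem_jitter_sigma_m < 0 or self.ground_sigma < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not self.species_list:
            raise ValueError("at least one species is required")
        n_bands = self.ground_signature.size
        for sp in self.species_list:
            if sp.signature.size != n_bands:
                raise ValueError(
                    f"species {sp.name}: signature length {sp.signature.size} "
                    f"does not match ground signature length {n_bands}"
                )

    @property
    def n_bands(self) -> int:
        return self.ground_signature.size


@dataclass
class TreeTruth:
    """Ground truth for one planted tree."""

    apex_xy: tuple[float, float]
    height_m: float
    crown_radius_m: float
    species: str


@dataclass
class SceneTruth:
    """Everything the evaluation stage scores against."""

    trees: list[TreeTruth]
    labels: CrownLabelGrid
    pairs: list[tuple[str, str]]  # (stem_id, crown_id)
    species_by_crown: dict[str, str]


@dataclass
class SyntheticScene:
    """A generated plot: pipeline inputs plus ground truth."""

    chm: CanopyHeightModel
    cube: SpectralCube
    stems: list[StemRecord]
    crowns: list[CrownRecord]
    truth: SceneTruth
    config: SceneConfig


def _place_trees(
    cfg: SceneConfig, rng: np.random.Generator, max_attempts_per_tree: int = 500
) -> list[TreeTruth]:
    slope, intercept, noise = cfg.crown_radius_allometry
    h_lo, h_hi = cfg.height_range_m
    trees: list[TreeTruth] = []
    names = [sp.name for sp in cfg.species_list]
    attempts = 0
    budget = max_attempts_per_tree * cfg.n_trees
    while len(trees) < cfg.n_trees:
        if attempts >= budget:
            raise ValueError(
                f"could not place {cfg.n_trees} trees at spacing "
                f"{cfg.min_spacing_m} m in a {cfg.plot_size_m} m plot "
                f"({attempts} attempts)"
            )
        attempts += 1
        height = float(rng.uniform(h_lo, h_hi))
        radius = float(
            max(cfg.pixel_size_m, slope * height + intercept + rng.normal(0.0, noise))
        )
        if 2 * radius >= cfg.plot_size_m:
            continue
        # snap apexes to pixel centres so the apex pixel carries exactly H
        s = cfg.pixel_size_m
        x = float(rng.uniform(radius, cfg.plot_size_m - radius))
        y = float(rng.uniform(radius, cfg.plot_size_m - radius))
        x = (np.floor(x / s) + 0.5) * s
        y = (np.floor(y / s) + 0.5) * s
        if any(
            (t.apex_xy[0] - x) ** 2 + (t.apex_xy[1] - y) ** 2 < cfg.min_spacing_m**2
            for t in trees
        ):
            continue
        trees.append(
            TreeTruth(
                apex_xy=(x, y),
                height_m=height,
                crown_radius_m=radius,
                species=names[len(trees) % len(names)],
            )
        )
    return trees


def _render_chm(
    cfg: SceneConfig, trees: list[TreeTruth]
) -> tuple[np.ndarray, np.ndarray]:
    """Render (heights, owner) grids; owner is -1 for ground, else tree index."""
    n = int(round(cfg.plot_size_m / cfg.pixel_size_m))
    s = cfg.pixel_size_m
    xs = (np.arange(n) + 0.5) * s
    ys = cfg.plot_size_m - (np.arange(n) + 0.5) * s
    gx, gy = np.meshgrid(xs, ys)  # gy decreases with row index (row 0 = north)
    heights = np.zeros((n, n))
    owner = np.full((n, n), -1, dtype=int)
    for i, tree in enumerate(trees):
        d = np.hypot(gx - tree.apex_xy[0], gy - tree.apex_xy[1])
        cone = tree.height_m * np.maximum(0.0, 1.0 - d / tree.crown_radius_m)
        taller = cone > heights  # strict: ties stay with the earlier tree
        heights = np.where(taller, cone, heights)
        owner = np.where(taller, i, owner)
    return heights, owner


def _apex_pixel(cfg: SceneConfig, tree: TreeTruth) -> tuple[int, int]:
    s = cfg.pixel_size_m
    col = min(int(tree.apex_xy[0] / s), int(round(cfg.plot_size_m / s)) - 1)
    row = min(int((cfg.plot_size_m - tree.apex_xy[1]) / s), int(round(cfg.plot_size_m / s)) - 1)
    return row, col


def _render_cube_noise(
    cfg: SceneConfig,
    labels: np.ndarray,
    trees: list[TreeTruth],
    rng: np.random.Generator,
) -> np.ndarray:
    n_bands = cfg.n_bands
    shape = labels.shape
    refl = cfg.ground_signature[:, None, None] + rng.normal(
        0.0, cfg.ground_sigma, (n_bands, *shape)
    )
    by_name = {sp.name: sp for sp in cfg.species_list}
    for i, tree in enumerate(trees):
        mask = labels == i + 1
        count = int(mask.sum())
        if count == 0:
            continue
        sp = by_name[tree.species]
        refl[:, mask] = sp.signature[:, None] + rng.normal(
            0.0, sp.sigma, (n_bands, count)
        )
    return refl


def generate_scene(cfg: SceneConfig) -> SyntheticScene:
    """Generate a complete synthetic plot; bit-identical for a given seed."""
    streams = np.random.SeedSequence(cfg.seed).spawn(4)
    place_rng, spectra_rng, jitter_rng, allometry_rng = (
        np.random.default_rng(s) for s in streams
    )
    trees = _place_trees(cfg, place_rng)
    heights, owner = _render_chm(cfg, trees)
    labels = owner + 1

    counts = [int((labels == i + 1).sum()) for i in range(len(trees))]
    if any(c == 0 for c in counts):
        raise ValueError("a planted tree owns no CHM pixel; relax the configuration")

    s = cfg.pixel_size_m
    origin = (0.0, cfg.plot_size_m)
    tops = []
    for i, tree in enumerate(trees):
        r, c = _apex_pixel(cfg, tree)
        if labels[r, c] != i + 1:
            raise ValueError(
                f"tree {i} apex pixel is overtopped by a neighbour; increase "
                "min_spacing_m"
            )
        cx = origin[0] + (c + 0.5) * s
        cy = origin[1] - (r + 0.5) * s
        tops.append(TreeTop(row=r, col=c, height_m=float(heights[r, c]), apex_xy=(cx, cy)))
    label_grid = CrownLabelGrid(labels=labels, treetops=tops)

    chm = CanopyHeightModel(
        heights=heights, origin=origin, pixel_size=s, crs_label="local-metric"
    )
    cube = SpectralCube(
        reflectance=_render_cube_noise(cfg, labels, trees, spectra_rng),
        wavelengths_nm=default_wavelengths(cfg.n_bands),
        origin=origin,
        pixel_size=s,
        crs_label="local-metric",
    )

    d_slope, d_intercept, d_noise = cfg.stem_diameter_model
    stems: list[StemRecord] = []
    crowns: list[CrownRecord] = []
    pairs: list[tuple[str, str]] = []
    species_by_crown: dict[str, str] = {}
    dx_off, dy_off = cfg.plot_offset_m
    for i, tree in enumerate(trees):
        stem_id, crown_id = f"S{i + 1:04d}", f"C{i + 1:04d}"
        crown_diam = 2.0 * tree.crown_radius_m + allometry_rng.normal(0.0, d_noise)
        diameter_cm = max(1.0, (crown_diam - d_intercept) / d_slope)
        jx, jy = jitter_rng.normal(0.0, cfg.stem_jitter_sigma_m, 2)
        stems.append(
            StemRecord(
                stem_id=stem_id,
                x_pos=tree.apex_xy[0] + jx + dx_off,
                y_pos=tree.apex_xy[1] + jy + dy_off,
                stem_height_m=tree.height_m,
                stem_diameter_cm=float(diameter_cm),
                species=tree.species,
                plot_id=None,
            )
        )
        rows, cols = np.nonzero(labels == i + 1)
        cx = float(np.mean(origin[0] + (cols + 0.5) * s))
        cy = float(np.mean(origin[1] - (rows + 0.5) * s))
        crowns.append(
            CrownRecord(
                crown_id=crown_id,
                x_pos=cx,
                y_pos=cy,
                area_m2=float(rows.size) * s * s,
                plot_id=cfg.plot_id,
            )
        )
        pairs.append((stem_id, crown_id))
        species_by_crown[crown_id] = tree.species

    truth = SceneTruth(
        trees=trees, labels=label_grid, pairs=pairs, species_by_crown=species_by_crown
    )
    return SyntheticScene(
        chm=chm, cube=cube, stems=stems, crowns=crowns, truth=truth, config=cfg
    )


def degrade_scene(
    scene: SyntheticScene,
    extra_jitter_sigma: float = 0.0,
    signature_mixing: float = 0.0,
    seed: int | None = None,
) -> SyntheticScene:
    """Stress a scene: extra stem jitter and spectral signature collapse.

    ``signature_mixing`` in [0, 1] blends every species signature toward
    the across-species mean (1 makes all species spectrally identical, so
    classification degrades to chance); the pixel noise already drawn is
    preserved, so mixing 0 and jitter 0 return the scene unchanged.
    """
    if not 0.0 <= signature_mixing <= 1.0:
        raise ValueError("signature_mixing must lie in [0, 1]")
    if extra_jitter_sigma < 0:
        raise ValueError("extra_jitter_sigma must be >= 0")
    rng = np.random.default_rng(
        scene.config.seed + 1_000_003 if seed is None else seed
    )
    stems = []
    for stem in scene.stems:
        jx, jy = rng.normal(0.0, extra_jitter_sigma, 2)
        stems.append(replace(stem, x_pos=stem.x_pos + jx, y_pos=stem.y_pos + jy))

    cfg = scene.config
    mean_sig = np.mean([sp.signature for sp in cfg.species_list], axis=0)
    refl = scene.cube.reflectance.copy()
    by_name = {sp.name: sp for sp in cfg.species_list}
    labels = scene.truth.labels.labels
    for i, tree in enumerate(scene.truth.trees):
        shift = signature_mixing * (mean_sig - by_name[tree.species].signature)
        mask = labels == i + 1
        refl[:, mask] += shift[:, None]
    new_species = [
        replace(
            sp, signature=(1.0 - signature_mixing) * sp.signature + signature_mixing * mean_sig
        )
        for sp in cfg.species_list
    ]
    new_cfg = replace(cfg, species_list=new_species)
    cube = SpectralCube(
        reflectance=refl,
        wavelengths_nm=scene.cube.wavelengths_nm.copy(),
        origin=scene.cube.origin,
        pixel_size=scene.cube.pixel_size,
        crs_label=scene.cube.crs_label,
    )
    return SyntheticScene(
        chm=scene.chm,
        cube=cube,
        stems=stems,
        crowns=scene.crowns,
        truth=scene.truth,
        config=new_cfg,
    )


def sample_pixel_observations(
    species: list[SpeciesSpec],
    n_crowns_per_species: int,
    pixels_per_crown: int,
    seed: int,
    height_range_m: tuple[float, float] = (8.0, 20.0),
    id_prefix: str = "T",
) -> tuple[list[PixelObservation], dict[str, str]]:
    """Draw labelled per-pixel crown tables directly (no raster rendering).

    Each crown gets a base height drawn uniformly, per-pixel heights with
    0.5 m spread, and per-pixel spectra = species signature + N(0, sigma).
    Returns the pixel list and the crown-to-species truth map.
    """
    rng = np.random.default_rng(seed)
    pixels: list[PixelObservation] = []
    truth: dict[str, str] = {}
    counter = 0
    for sp in species:
        for _ in range(n_crowns_per_species):
            counter += 1
            crown_id = f"{id_prefix}{counter:04d}"
            truth[crown_id] = sp.name
            base_h = rng.uniform(*height_range_m)
            for _ in range(pixels_per_crown):
                pixels.append(
                    PixelObservation(
                        crown_id=crown_id,
                        height_m=float(max(0.0, base_h + rng.normal(0.0, 0.5))),
                        reflectances=sp.signature + rng.normal(0.0, sp.sigma, sp.signature.size),
                    )
                )
    return pixels, truth


def write_scene(scene: SyntheticScene, out_dir: str | Path) -> dict[str, Path]:
    """Write a scene to disk in the pipeline's external formats.

    Produces chm.tif, cube.tif (+ wavelength sidecar), stems.csv,
    crowns.csv, truth_labels.tif, truth_pairs.csv and truth_species.csv;
    returns the path of each artefact by name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "chm": out / "chm.tif",
        "cube": out / "cube.tif",
        "stems": out / "stems.csv",
        "crowns": out / "crowns.csv",
        "truth_labels": out / "truth_labels.tif",
        "truth_pairs": out / "truth_pairs.csv",
        "truth_species": out / "truth_species.csv",
    }
    write_chm(scene.chm, paths["chm"])
    write_cube(scene.cube, paths["cube"])
    write_stems(scene.stems, paths["stems"])
    write_crowns(scene.crowns, paths["crowns"])
    write_label_raster(
        scene.truth.labels.labels,
        scene.chm.origin,
        scene.chm.pixel_size,
        paths["truth_labels"],
        crs_label=scene.chm.crs_label,
    )
    pd.DataFrame(scene.truth.pairs, columns=["stem_id", "crown_id"]).to_csv(
        paths["truth_pairs"], index=False
    )
    pd.DataFrame(
        sorted(scene.truth.species_by_crown.items()), columns=["crown_id", "species"]
    ).to_csv(paths["truth_species"], index=False)
    return paths
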