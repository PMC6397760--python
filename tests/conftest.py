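"""Shared fixtures: small rasters, lightweight synthetic plots, and a full
pre-generated scene written to disk once per session."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from crownpipe.io_core import CanopyHeightModel, SpectralCube
from crownpipe.segmentation import SegmentationConfig
from crownpipe.synthetic_scene import (
    SceneConfig,
    SpeciesSpec,
    generate_scene,
    write_scene,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_chm(heights, origin=(0.0, None), pixel_size=1.0) -> CanopyHeightModel:
    """CHM from a nested list; default origin puts (0, 0) at the lower-left."""
    heights = np.asarray(heights, dtype=float)
    oy = origin[1] if origin[1] is not None else heights.shape[0] * pixel_size
    return CanopyHeightModel(
        heights=heights, origin=(origin[0], oy), pixel_size=pixel_size
    )


def make_cube(red, nir, red_nm=628.1, nir_nm=728.3, **kw) -> SpectralCube:
    """Two-band cube with given red and NIR reflectance grids."""
    red = np.asarray(red, dtype=float)
    nir = np.asarray(nir, dtype=float)
    return SpectralCube(
        reflectance=np.stack([red, nir]),
        wavelengths_nm=np.array([red_nm, nir_nm]),
        origin=kw.get("origin", (0.0, red.shape[0] * 1.0)),
        pixel_size=kw.get("pixel_size", 1.0),
    )


def light_species(n_species: int = 3, n_bands: int = 4) -> list[SpeciesSpec]:
    """Tiny flat signatures for tests that never touch the spectral stage."""
    return [
        SpeciesSpec(name=f"SP{i + 1:02d}", signature=np.full(n_bands, 0.3), sigma=0.01)
        for i in range(n_species)
    ]


def light_scene_config(**overrides) -> SceneConfig:
    """Scene config with a 4-band cube: cheap CHM/stem/crown generation."""
    defaults = dict(
        species_list=light_species(),
        ground_signature=np.full(4, 0.2),
    )
    defaults.update(overrides)
    return SceneConfig(**defaults)


@pytest.fixture(scope="session")
def default_seg_config() -> SegmentationConfig:
    return SegmentationConfig()


@pytest.fixture(scope="session")
def easy_scene():
    """A well-separated full-band scene the whole pipeline should nail:
    apex spacing about three crown diameters, 1 m stem jitter, strongly
    separated species signatures."""
    cfg = SceneConfig(
        seed=7,
        plot_size_m=160.0,
        n_trees=18,
        min_spacing_m=22.0,
        height_range_m=(8.0, 14.0),
    )
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def easy_scene_dir(easy_scene, tmp_path_factory):
    """The easy scene written to disk in the pipeline's external formats."""
    out = tmp_path_factory.mktemp("scene")
    paths = write_scene(easy_scene, out)
    return paths
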