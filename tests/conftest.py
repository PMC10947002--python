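import numpy as np
import pytest
import trimesh

from fetalmorpho.surface_io import LabelVolume, SurfaceMesh


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_icosphere(radius: float = 2.0, subdivisions: int = 4) -> SurfaceMesh:
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh.from_trimesh(tm, structure_label=1)


def make_ball_volume(
    radius_mm: float, spacing: float, label: int = 1, pad: int = 3,
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> LabelVolume:
    """Digitized ball: voxel labelled iff its centre lies inside the sphere."""
    n = int(2 * (radius_mm / spacing + pad)) + 1
    ax = (np.arange(n) - (n - 1) / 2) * spacing
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    ox, oy, oz = offset
    mask = (X - ox) ** 2 + (Y - oy) ** 2 + (Z - oz) ** 2 <= radius_mm**2
    data = np.where(mask, np.int16(label), np.int16(0))
    return LabelVolume(data=data, spacing=spacing, origin=np.array([ax[0]] * 3))


@pytest.fixture
def icosphere():
    return make_icosphere()


@pytest.fixture
def ball_volume():
    return make_ball_volume(10.0, 0.8)
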