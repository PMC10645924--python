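"""Shared fixtures: synthetic anatomies and reconstructions are expensive,
so they are built once per session and treated as read-only."""

import numpy as np
import pytest

np.seterr(all="ignore")

from carotidfem import (
    StenosisSpec,
    default_centerlines,
    make_anatomy,
    reconstruct_wall,
    tube_wall_mesh,
)


def stenotic_spec(**kw):
    base = dict(
        branch="CCA",
        center=12.0,
        extent=8.0,
        area_reduction=0.5,
        angle=0.0,
        calcific_fraction=0.25,
        lipid_fraction=0.15,
    )
    base.update(kw)
    return StenosisSpec(**base)


@pytest.fixture(scope="session")
def tube_anatomy():
    return make_anatomy(
        1, centerlines=default_centerlines("tube"), stenoses=[stenotic_spec()]
    )


@pytest.fixture(scope="session")
def tube_wall(tube_anatomy):
    return reconstruct_wall(
        tube_anatomy.lumen, tube_anatomy.components, tube_anatomy.centerlines
    )


@pytest.fixture(scope="session")
def healthy_tube_anatomy():
    return make_anatomy(3, centerlines=default_centerlines("tube"))


@pytest.fixture(scope="session")
def bif_anatomy():
    spec = StenosisSpec(
        branch="ICA",
        center=5.5,
        extent=6.0,
        area_reduction=0.45,
        angle=1.0,
        calcific_fraction=0.2,
        lipid_fraction=0.2,
    )
    return make_anatomy(2, stenoses=[spec])


@pytest.fixture(scope="session")
def bif_wall(bif_anatomy):
    return reconstruct_wall(
        bif_anatomy.lumen, bif_anatomy.components, bif_anatomy.centerlines
    )


@pytest.fixture(scope="session")
def lame_mesh_coarse():
    # inner 3 mm, outer 3.9 mm: the 30% outer-wall rule
    return tube_wall_mesh(3.0, 3.9, 6.0, size=0.45)
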