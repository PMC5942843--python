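"""Shared fixtures: analytic tube scalar-map fields and small noiseless
phantom datasets used across the tracking and analysis tests."""

import numpy as np
import pytest

from plexusdti.dti import ScalarMaps, fit_tensor_wlls, scalar_maps
from plexusdti.phantom import (
    AcquisitionSpec,
    TissueParams,
    make_nerve_centerlines,
    rasterize_tensor_field,
    simulate_dwi,
)

NERVE_EVALS = (1.85e-3, 1.12e-3, 1.12e-3)


def tube_maps(
    grid=(21, 16, 16),
    voxel=3.0,
    x_range_mm=None,
    radius_mm=7.0,
    fa_nerve=None,
    md_gradient=0.0,
):
    """Analytic straight-tube ScalarMaps along +x, centered in the y/z plane.

    ``x_range_mm=None`` spans the whole grid (tracks then terminate by grid
    exit at the tube ends); otherwise only voxel centers inside the range are
    nerve.  ``md_gradient`` adds a linear MD ramp (per mm of x) to exercise
    monotone-sampling checks.
    """
    ad, rd_ = NERVE_EVALS[0], NERVE_EVALS[1]
    lam = np.array([ad, rd_, rd_])
    fa_true = np.sqrt(1.5 * np.sum((lam - lam.mean()) ** 2) / np.sum(lam**2))
    fa_nerve = fa_true if fa_nerve is None else fa_nerve
    shape = tuple(grid)
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    x = ii * voxel
    yc = (shape[1] - 1) / 2.0 * voxel
    zc = (shape[2] - 1) / 2.0 * voxel
    r = np.sqrt((jj * voxel - yc) ** 2 + (kk * voxel - zc) ** 2)
    nerve = r <= radius_mm
    if x_range_mm is not None:
        nerve &= (x >= x_range_mm[0]) & (x <= x_range_mm[1])
    fa = np.where(nerve, fa_nerve, 0.0)
    md = np.where(nerve, lam.mean() + md_gradient * x, 2.0e-3)
    admap = np.where(nerve, ad + md_gradient * x, 2.0e-3)
    rdmap = np.where(nerve, rd_ + md_gradient * x, 2.0e-3)
    ev = np.zeros(shape + (3,))
    ev[..., 0] = 1.0
    evals = np.stack([admap, rdmap, rdmap], axis=-1)
    affine = np.diag([voxel, voxel, voxel, 1.0])
    return (
        ScalarMaps(
            fa=fa,
            md=md,
            ad=admap,
            rd=rdmap,
            eigenvalues=evals,
            principal_direction=ev,
            mask=np.ones(shape, bool),
            affine=affine,
        ),
        nerve,
    )


@pytest.fixture(scope="session")
def full_span_tube():
    """60 mm straight tube spanning the whole x-extent of a 21-voxel grid."""
    maps, nerve = tube_maps()
    return maps, nerve


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default-geometry noiseless phantom with fitted scalar maps."""
    acq = AcquisitionSpec(snr_target=None)
    tissue = TissueParams()
    centerlines = make_nerve_centerlines(1, "low")
    field, s0, labels = rasterize_tensor_field(centerlines, tissue, acq)
    dwi, scheme = simulate_dwi(field, s0, acq)
    maps = scalar_maps(fit_tensor_wlls(dwi, scheme, affine=acq.affine))
    return {
        "acq": acq,
        "tissue": tissue,
        "centerlines": centerlines,
        "field": field,
        "s0": s0,
        "labels": labels,
        "dwi": dwi,
        "scheme": scheme,
        "maps": maps,
    }
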