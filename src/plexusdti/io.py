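"""File formats: NIfTI + FSL bval/bvec gradient tables, TCK bundles with JSON
sidecars, nerve sample tables as CSV (diffusivities serialized ×10⁻³ mm²/s)."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .dti import GradientScheme
from .tracking import Streamline, TractBundle, TrackingParams

__all__ = [
    "read_dwi",
    "write_dwi",
    "read_bundle",
    "write_bundle",
    "write_nifti",
    "write_sample_table",
    "read_sample_table",
]

DIFFUSIVITY_SCALE = 1e3  # stored mm²/s -> serialized ×10⁻³ mm²/s
DIFFUSIVITY_COLS = ("md", "ad", "rd")


def write_dwi(prefix, dwi: np.ndarray, scheme: GradientScheme, affine: np.ndarray):
    """Write a 4-D volume as ``<prefix>.nii.gz`` with FSL-style ``.bval`` /
    ``.bvec`` text tables (bvec: 3 rows of x, y, z components)."""
    prefix = Path(prefix)
    nib.save(nib.Nifti1Image(np.asarray(dwi, np.float32), affine), f"{prefix}.nii.gz")
    np.savetxt(f"{prefix}.bval", scheme.b_values[None], fmt="%.1f")
    np.savetxt(f"{prefix}.bvec", scheme.directions.T, fmt="%.8f")


def read_dwi(path_nifti, path_bval, path_bvec):
    """Load a 4-D DWI plus gradient table; returns ``(data, affine, scheme)``.

    Volume and gradient counts must agree.  Slightly non-unit directions
    (|‖g‖−1| < 0.01) are renormalised with a warning; worse ones are errors.
    """
    img = nib.load(str(path_nifti))
    data = np.asarray(img.dataobj, float)
    bvals = np.loadtxt(path_bval).ravel()
    bvecs = np.loadtxt(path_bvec)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    if data.shape[-1] != len(bvals) or len(bvals) != len(bvecs):
        raise ValueError(
            f"count mismatch: {data.shape[-1]} volumes, {len(bvals)} b-values, "
            f"{len(bvecs)} directions"
        )
    nz = bvals > 0
    norms = np.linalg.norm(bvecs[nz], axis=1)
    if np.any(np.abs(norms - 1.0) >= 0.01):
        raise ValueError("gradient directions deviate from unit norm by >= 1%")
    if np.any(np.abs(norms - 1.0) > 1e-6):
        import warnings

        warnings.warn("renormalising slightly non-unit gradient directions")
        bvecs = bvecs.copy()
        bvecs[nz] /= norms[:, None]
    return data, img.affine, GradientScheme(b_values=bvals, directions=bvecs)


def write_nifti(path, data: np.ndarray, affine: np.ndarray):
    nib.save(nib.Nifti1Image(np.asarray(data, np.float32), affine), str(path))


def write_bundle(path_tck, bundle: TractBundle):
    """TCK streamlines (world mm) plus a JSON sidecar with the tracking
    parameters, seed label and termination-cause histogram."""
    path_tck = Path(path_tck)
    tractogram = nib.streamlines.Tractogram(
        [sl.points.astype(np.float32) for sl in bundle.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    nib.streamlines.save(tractogram, str(path_tck))
    sidecar = {
        "label": bundle.label,
        "side": bundle.side,
        "params": None if bundle.params is None else vars(bundle.params),
        "termination_counts": bundle.termination_counts,
    }
    path_tck.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_bundle(path_tck) -> TractBundle:
    """Load a TCK bundle; a missing sidecar leaves the params unknown."""
    path_tck = Path(path_tck)
    tck = nib.streamlines.load(str(path_tck))
    streamlines = [Streamline(points=np.asarray(s, float)) for s in tck.streamlines]
    meta = {"label": "", "side": "", "params": None, "termination_counts": {}}
    sidecar = path_tck.with_suffix(".json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    params = TrackingParams(**meta["params"]) if meta["params"] else None
    return TractBundle(
        streamlines=streamlines,
        label=meta["label"],
        side=meta["side"],
        params=params,
        termination_counts=meta["termination_counts"],
    )


def write_sample_table(path, table: pd.DataFrame):
    """Nerve sample table as CSV: diffusivities in ×10⁻³ mm²/s, with an
    explicit units column to prevent scale bugs."""
    out = table.copy()
    for c in DIFFUSIVITY_COLS:
        if c in out.columns:
            out[c] = out[c] * DIFFUSIVITY_SCALE
    out["diffusivity_units"] = "1e-3 mm^2/s"
    out.to_csv(path, index=False)


def read_sample_table(path) -> pd.DataFrame:
    """Read a sample-table CSV back into internal units (mm²/s)."""
    df = pd.read_csv(path)
    units = df.pop("diffusivity_units").iloc[0] if "diffusivity_units" in df else None
    if units is not None and units != "1e-3 mm^2/s":
        raise ValueError(f"unexpected diffusivity units: {units}")
    for c in DIFFUSIVITY_COLS:
        if c in df.columns:
            df[c] = df[c] / DIFFUSIVITY_SCALE
    return df
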