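"""Diffusion-tensor core: signal conditioning, WLLS fitting, scalar maps, SNR.

The estimation chain mirrors standard peripheral-nerve DTI post-processing:
optional moment-based Rician bias correction, registration of the weighted
volumes to the b=0 reference with the matching b-matrix rotation, a two-pass
weighted linear least squares (WLLS) tensor fit on log-signals, and
eigenvalue-derived scalar maps (FA, MD, AD, RD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

__all__ = [
    "GradientScheme",
    "TensorField",
    "ScalarMaps",
    "SNRResult",
    "suppress_rician_noise",
    "register_to_b0",
    "fit_tensor_wlls",
    "scalar_maps",
    "compute_snr",
]


@dataclass(frozen=True)
class GradientScheme:
    """Per-volume b-values (s/mm²) and unit gradient directions.

    The b-matrix is b·ggᵀ per volume; any rotation applied to a volume must
    be conjugated into its b-matrix (R B Rᵀ).
    """

    b_values: np.ndarray  # (n,)
    directions: np.ndarray  # (n, 3)

    def __post_init__(self):
        b = np.asarray(self.b_values, float)
        g = np.asarray(self.directions, float)
        if b.ndim != 1 or g.shape != (len(b), 3):
            raise ValueError("need matching b_values (n,) and directions (n,3)")
        if not np.any(b == 0):
            raise ValueError("scheme must contain at least one b=0 volume")
        nz = b > 0
        norms = np.linalg.norm(g[nz], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("non-zero-b directions must be unit-norm (tol 1e-6)")
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "directions", g)

    def __len__(self) -> int:
        return len(self.b_values)

    @property
    def b_matrix(self) -> np.ndarray:
        """(n, 3, 3) array of b·ggᵀ."""
        return self.b_values[:, None, None] * np.einsum(
            "ni,nj->nij", self.directions, self.directions
        )

    def rotated(self, rotations: np.ndarray) -> "GradientScheme":
        """Scheme with per-volume rotations applied to the directions
        (equivalently R B Rᵀ on each b-matrix)."""
        R = np.asarray(rotations, float)
        if R.shape == (3, 3):
            R = np.broadcast_to(R, (len(self), 3, 3))
        g = np.einsum("nij,nj->ni", R, self.directions)
        return GradientScheme(b_values=self.b_values.copy(), directions=g)


@dataclass(frozen=True)
class TensorField:
    """Per-voxel symmetric diffusion tensor (mm²/s), ln-S0 and validity mask."""

    tensors: np.ndarray  # (..., 3, 3)
    ln_s0: np.ndarray  # (...)
    mask: np.ndarray  # (...) bool
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    flagged: np.ndarray | None = None  # voxels whose signal needed clamping

    def __post_init__(self):
        t = np.asarray(self.tensors, float)
        if t.shape[-2:] != (3, 3):
            raise ValueError("tensors must be (..., 3, 3)")
        asym = np.abs(t - np.swapaxes(t, -1, -2)).max()
        if asym > 1e-10:
            raise ValueError("tensors must be symmetric")


@dataclass(frozen=True)
class ScalarMaps:
    """Eigenvalue-derived maps.  Eigenvalues sorted descending; diffusivities
    in mm²/s, FA dimensionless in [0, 1] where defined."""

    fa: np.ndarray
    md: np.ndarray
    ad: np.ndarray
    rd: np.ndarray
    eigenvalues: np.ndarray  # (..., 3) descending
    principal_direction: np.ndarray  # (..., 3)
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    n_negative_eig: int = 0


@dataclass(frozen=True)
class SNRResult:
    sigma: float
    snr_mean: float
    snr_sd: float
    per_roi: dict


def suppress_rician_noise(dwi: np.ndarray, sigma: float) -> np.ndarray:
    """Moment-based Rician bias correction: M → √(max(M² − 2σ², 0)).

    For M ≫ σ this is a vanishing correction (idempotent in the limit); at
    M ≤ σ√2 the corrected magnitude clamps to zero.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    m = np.asarray(dwi, float)
    return np.sqrt(np.maximum(m**2 - 2.0 * sigma**2, 0.0))


def _rigid_transform_cost(params, moving, fixed, center, interior):
    """1 − NCC between the resampled moving volume and the reference,
    evaluated on an interior region so boundary fill-in cannot anchor the
    optimum at the identity.  NCC is contrast-insensitive, which matters when
    aligning b=800 volumes to the b=0 reference."""
    R = Rotation.from_euler("xyz", params[:3], degrees=True).as_matrix()
    offset = center - R @ center + params[3:]
    res = ndimage.affine_transform(moving, R, offset=offset, order=1, mode="constant")
    a = res[interior] - res[interior].mean()
    b = fixed[interior] - fixed[interior].mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 1.0
    return 1.0 - float((a * b).sum() / denom)


def register_to_b0(
    dwi: np.ndarray,
    scheme: GradientScheme,
    mode: str = "identity",
) -> tuple[np.ndarray, GradientScheme, list[int]]:
    """Align weighted volumes to the (first) b=0 reference.

    ``mode='identity'`` is a strict pass-through for motion-free data.
    ``mode='rigid'`` estimates a rotation + translation per weighted volume by
    least-squares intensity matching (Powell search, trilinear resampling) and
    conjugates each recovered rotation into the stored b-matrix (R B Rᵀ).

    Returns ``(aligned_dwi, rotated_scheme, flagged_volumes)``; flagged
    volumes are those whose registration did not converge (never silent).
    """
    if mode == "identity":
        return dwi, scheme, []
    if mode != "rigid":
        raise ValueError("mode must be 'identity' or 'rigid'")
    b0_idx = int(np.flatnonzero(scheme.b_values == 0)[0])
    fixed = ndimage.gaussian_filter(dwi[..., b0_idx].astype(float), 1.0)
    center = (np.asarray(fixed.shape, float) - 1) / 2.0
    margin = 4
    interior = np.zeros(fixed.shape, bool)
    interior[margin:-margin, margin:-margin, margin:-margin] = True
    out = np.array(dwi, dtype=float, copy=True)
    rotations = np.broadcast_to(np.eye(3), (len(scheme), 3, 3)).copy()
    flagged = []
    for v in range(dwi.shape[-1]):
        if scheme.b_values[v] == 0:
            continue
        moving = dwi[..., v].astype(float)
        moving_s = ndimage.gaussian_filter(moving, 1.0)
        res = minimize(
            _rigid_transform_cost,
            np.zeros(6),
            args=(moving_s, fixed, center, interior),
            method="Powell",
            options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 5000},
        )
        if not res.success:
            flagged.append(v)
            continue
        R = Rotation.from_euler("xyz", res.x[:3], degrees=True).as_matrix()
        offset = center - R @ center + res.x[3:]
        out[..., v] = ndimage.affine_transform(moving, R, offset=offset, order=1)
        # image was resampled by R⁻¹ in index space; gradient frame follows
        rotations[v] = R.T
    return out, scheme.rotated(rotations), flagged


def _design_matrix(scheme: GradientScheme) -> np.ndarray:
    B = scheme.b_matrix
    return np.column_stack(
        [
            np.ones(len(scheme)),
            -B[:, 0, 0],
            -B[:, 1, 1],
            -B[:, 2, 2],
            -2.0 * B[:, 0, 1],
            -2.0 * B[:, 0, 2],
            -2.0 * B[:, 1, 2],
        ]
    )


def _beta_to_tensors(beta: np.ndarray) -> np.ndarray:
    """(n, 7) parameter rows -> (n, 3, 3) symmetric tensors."""
    D = np.empty(beta.shape[:-1] + (3, 3))
    D[..., 0, 0] = beta[..., 1]
    D[..., 1, 1] = beta[..., 2]
    D[..., 2, 2] = beta[..., 3]
    D[..., 0, 1] = D[..., 1, 0] = beta[..., 4]
    D[..., 0, 2] = D[..., 2, 0] = beta[..., 5]
    D[..., 1, 2] = D[..., 2, 1] = beta[..., 6]
    return D


def fit_tensor_wlls(
    dwi: np.ndarray,
    scheme: GradientScheme,
    mask: np.ndarray | None = None,
    affine: np.ndarray | None = None,
    signal_floor_eps: float = 1e-6,
) -> TensorField:
    """Two-pass weighted linear least squares tensor fit.

    Solves ln Sᵢ = ln S0 − Σⱼₖ Bᵢⱼₖ Dⱼₖ per voxel: pass 1 is ordinary least
    squares on log-signals; pass 2 re-solves with weights wᵢ = Ŝᵢ² from the
    pass-1 predicted signals (the standard log-linear heteroscedasticity
    correction).  Non-positive signals are clamped to ``eps·S0_proxy`` (the
    voxel's maximum signal) and the voxel flagged.
    """
    dwi = np.asarray(dwi, float)
    if dwi.shape[-1] != len(scheme):
        raise ValueError(
            f"volume count {dwi.shape[-1]} does not match scheme length {len(scheme)}"
        )
    if len(scheme) < 7:
        raise ValueError("need >= 7 volumes (6 directions + b=0)")
    A = _design_matrix(scheme)
    if np.linalg.matrix_rank(A) < 7:
        raise ValueError("singular design: gradient directions are coplanar/degenerate")

    shape = dwi.shape[:-1]
    if mask is None:
        mask = np.ones(shape, bool)
    vox = dwi[mask]  # (nv, n)
    s0_proxy = vox.max(axis=1, keepdims=True)
    floor = signal_floor_eps * np.maximum(s0_proxy, np.finfo(float).tiny)
    clamped = vox <= 0
    flagged_v = clamped.any(axis=1)
    y = np.log(np.maximum(vox, floor))

    beta = np.linalg.lstsq(A, y.T, rcond=None)[0].T  # (nv, 7) OLS pass
    w = np.exp(A @ beta.T).T ** 2  # predicted signals squared
    AtWA = np.einsum("ni,vn,nj->vij", A, w, A)
    AtWy = np.einsum("ni,vn,vn->vi", A, w, y)
    beta = np.linalg.solve(AtWA, AtWy[..., None])[..., 0]

    tensors = np.zeros(shape + (3, 3))
    ln_s0 = np.zeros(shape)
    flagged = np.zeros(shape, bool)
    tensors[mask] = _beta_to_tensors(beta)
    ln_s0[mask] = beta[:, 0]
    flagged[mask] = flagged_v
    return TensorField(
        tensors=tensors,
        ln_s0=ln_s0,
        mask=np.asarray(mask, bool),
        affine=np.eye(4) if affine is None else affine,
        flagged=flagged,
    )


def scalar_maps(field: TensorField) -> ScalarMaps:
    """Eigen-decompose the tensor field into FA/MD/AD/RD and the principal
    direction.  FA = √(3 Σ(λᵢ−λ̄)² / (2 Σλᵢ²)).

    Negative eigenvalues are kept (not clipped) but counted; all-zero tensors
    have undefined FA and are masked out.
    """
    t = field.tensors[field.mask]
    evals, evecs = np.linalg.eigh(t)  # ascending
    evals = evals[:, ::-1]
    e1 = evecs[:, :, ::-1][:, :, 0]
    md = evals.mean(axis=1)
    ad = evals[:, 0]
    rd = evals[:, 1:].mean(axis=1)
    ssq = np.sum(evals**2, axis=1)
    dev = np.sum((evals - md[:, None]) ** 2, axis=1)
    defined = ssq > 0
    fa = np.zeros_like(md)
    fa[defined] = np.sqrt(1.5 * dev[defined] / ssq[defined])

    shape = field.mask.shape
    out = {k: np.zeros(shape) for k in ("fa", "md", "ad", "rd")}
    out["fa"][field.mask] = fa
    out["md"][field.mask] = md
    out["ad"][field.mask] = ad
    out["rd"][field.mask] = rd
    ev = np.zeros(shape + (3,))
    ev[field.mask] = evals
    pd_ = np.zeros(shape + (3,))
    pd_[field.mask] = e1
    mask = field.mask.copy()
    mask[field.mask] &= defined
    return ScalarMaps(
        fa=out["fa"],
        md=out["md"],
        ad=out["ad"],
        rd=out["rd"],
        eigenvalues=ev,
        principal_direction=pd_,
        mask=mask,
        affine=field.affine,
        n_negative_eig=int(np.sum(evals.min(axis=1) < 0)),
    )


def compute_snr(
    b0_volume: np.ndarray,
    roi_mask: np.ndarray,
    noise_volume: np.ndarray | None = None,
    sigma: float | None = None,
    roi_labels: np.ndarray | None = None,
) -> SNRResult:
    """SNR = mean(b0 over ROI) / σ.

    σ comes either from a noise-only magnitude acquisition (RF off) via the
    Rayleigh mean identity σ = mean(|noise|)/√(π/2), or is supplied directly.
    If ``roi_labels`` is given, per-label SNRs are reported and the summary is
    their mean ± SD; otherwise the ROI is treated as one region.
    """
    roi_mask = np.asarray(roi_mask, bool)
    if not roi_mask.any():
        raise ValueError("ROI is empty")
    if (noise_volume is None) == (sigma is None):
        raise ValueError("provide exactly one of noise_volume or sigma")
    if noise_volume is not None:
        sigma = float(np.mean(np.abs(noise_volume)) / np.sqrt(np.pi / 2.0))
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    per_roi = {}
    if roi_labels is not None:
        for code in np.unique(roi_labels[roi_mask & (roi_labels > 0)]):
            sel = roi_mask & (roi_labels == code)
            per_roi[int(code)] = float(b0_volume[sel].mean() / sigma)
        vals = np.array(list(per_roi.values()))
        return SNRResult(
            sigma=sigma,
            snr_mean=float(vals.mean()),
            snr_sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            per_roi=per_roi,
        )
    snr = float(b0_volume[roi_mask].mean() / sigma)
    return SNRResult(sigma=sigma, snr_mean=snr, snr_sd=0.0, per_roi={0: snr})
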