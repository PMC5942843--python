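"""Along-tract analysis: mean fiber path, outlier exclusion, fiber cutting,
equal arc-length sections and evenly weighted nerve means.

Sampling happens along the *average path* of the bundle rather than over
member voxels: the mean path runs through the middle of the nerve, so values
interpolated at fiber points assigned to arc-length sections are largely free
of partial-volume contamination at the tube edge, and averaging section means
(instead of raw points) weights the whole nerve course evenly instead of
over-counting the dense region near the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .dti import ScalarMaps
from .tracking import Streamline, TractBundle

__all__ = [
    "MeanPath",
    "SectionScheme",
    "DEFAULT_SECTIONS",
    "compute_mean_path",
    "exclude_outlier_fibers",
    "cut_fibers",
    "sample_sections",
    "nerve_means",
    "SAMPLE_COLUMNS",
]

#: per-root section counts used for along-nerve sampling
DEFAULT_SECTIONS = {"C5": 8, "C6": 8, "C7": 6, "C8": 4}

SAMPLE_COLUMNS = [
    "subject",
    "session",
    "rater",
    "side",
    "root",
    "section",
    "n_points",
    "fa",
    "md",
    "ad",
    "rd",
]


@dataclass(frozen=True)
class MeanPath:
    """The bundle-average polyline (proximal→distal) with its arc length."""

    points: np.ndarray  # (K, 3) mm

    def __post_init__(self):
        pts = np.asarray(self.points, float)
        if len(pts) < 2:
            raise ValueError("mean path needs >= 2 points")
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(steps <= 0):
            raise ValueError("mean-path arc length must be strictly increasing")
        object.__setattr__(self, "points", pts)

    @property
    def arc_length(self) -> np.ndarray:
        return np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(self.points, axis=0), axis=1))]
        )

    @property
    def length_mm(self) -> float:
        return float(self.arc_length[-1])


@dataclass(frozen=True)
class SectionScheme:
    """Number of equal arc-length sections per root."""

    sections: dict

    def __post_init__(self):
        if any(v < 1 for v in self.sections.values()):
            raise ValueError("every root needs >= 1 section")

    def n_sections(self, root: str) -> int:
        return self.sections[root]


def _resample_polyline(points: np.ndarray, k: int) -> np.ndarray:
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(points, axis=0), axis=1))])
    si = np.linspace(0.0, s[-1], k)
    return np.column_stack([np.interp(si, s, points[:, c]) for c in range(3)])


def _oriented_fibers(bundle: TractBundle, k: int) -> np.ndarray:
    """(n_fibers, k, 3) resampled fibers, all pointing along the bundle's
    dominant endpoint axis."""
    disp = np.array([sl.points[-1] - sl.points[0] for sl in bundle.streamlines])
    # dominant axis: principal direction of the endpoint displacements
    _, _, vt = np.linalg.svd(disp, full_matrices=False)
    axis = vt[0]
    if np.sum(disp @ axis) < 0:  # majority orientation defines "distal"
        axis = -axis
    out = np.empty((len(bundle.streamlines), k, 3))
    for i, sl in enumerate(bundle.streamlines):
        pts = sl.points if disp[i] @ axis >= 0 else sl.points[::-1]
        out[i] = _resample_polyline(pts, k)
    return out


def compute_mean_path(bundle: TractBundle, k: int = 100) -> MeanPath:
    """Point-wise average of all fibers after consistent orientation and
    resampling to ``k`` equidistant arc-length points.

    Sampling along this path covers the complete nerve course evenly, so the
    many short fibers near the seed cannot dominate the summary.
    """
    if len(bundle) == 0:
        raise ValueError("cannot average an empty bundle")
    fibers = _oriented_fibers(bundle, k)
    return MeanPath(points=fibers.mean(axis=0))


def exclude_outlier_fibers(
    bundle: TractBundle, mean_path: MeanPath, dist_threshold_mm: float = 5.0
) -> tuple[TractBundle, MeanPath]:
    """Drop aberrant fibers whose mean distance to the mean path exceeds the
    threshold, then recompute the mean path once.

    Returns ``(clean_bundle, updated_mean_path)``.
    """
    if dist_threshold_mm <= 0:
        raise ValueError("distance threshold must be positive")
    tree = cKDTree(mean_path.points)
    kept = []
    for sl in bundle.streamlines:
        d, _ = tree.query(_resample_polyline(sl.points, 50))
        if d.mean() <= dist_threshold_mm:
            kept.append(sl)
    if not kept:
        raise ValueError(
            "all fibers classified as outliers — review dist_threshold_mm "
            f"({dist_threshold_mm} mm) against the bundle geometry"
        )
    clean = TractBundle(
        streamlines=kept,
        label=bundle.label,
        side=bundle.side,
        params=bundle.params,
        termination_counts=bundle.termination_counts,
    )
    return clean, compute_mean_path(clean)


def _project_arc_fraction(points: np.ndarray, mean_path: MeanPath) -> np.ndarray:
    """Arc-length fraction along the mean path of each point's nearest
    mean-path sample."""
    tree = cKDTree(mean_path.points)
    _, idx = tree.query(points)
    s = mean_path.arc_length
    return s[idx] / s[-1]


def cut_fibers(
    bundle: TractBundle,
    mean_path: MeanPath,
    proximal_bound=0.0,
    distal_bound=1.0,
    planes: tuple | None = None,
) -> TractBundle:
    """Truncate fibers to the retained nerve segment.

    Bounds are either arc-length fractions of the mean path (default), or two
    oriented planes ``((point, normal), (point, normal))`` whose normals point
    *into* the retained region.  Fibers with fewer than two points in the
    region are dropped.
    """
    kept = []
    if planes is not None:
        (p1, n1), (p2, n2) = planes
        p1, n1, p2, n2 = map(np.asarray, (p1, n1, p2, n2))
        for sl in bundle.streamlines:
            inside = ((sl.points - p1) @ n1 >= 0) & ((sl.points - p2) @ n2 >= 0)
            seg = _longest_run(sl.points, inside)
            if seg is not None:
                kept.append(Streamline(points=seg))
    else:
        if not 0.0 <= proximal_bound < distal_bound <= 1.0:
            raise ValueError("need 0 <= proximal_bound < distal_bound <= 1")
        for sl in bundle.streamlines:
            frac = _project_arc_fraction(sl.points, mean_path)
            inside = (frac >= proximal_bound) & (frac <= distal_bound)
            seg = _longest_run(sl.points, inside)
            if seg is not None:
                kept.append(Streamline(points=seg))
    return TractBundle(
        streamlines=kept,
        label=bundle.label,
        side=bundle.side,
        params=bundle.params,
        termination_counts=bundle.termination_counts,
    )


def _longest_run(points: np.ndarray, inside: np.ndarray):
    """Longest contiguous in-region segment with >= 2 points, else None."""
    if not inside.any():
        return None
    idx = np.flatnonzero(inside)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, breaks + 1)
    best = max(runs, key=len)
    if len(best) < 2:
        return None
    return points[best]


def _interp_world(vol: np.ndarray, affine: np.ndarray, pts_world: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(affine)
    hom = np.column_stack([pts_world, np.ones(len(pts_world))])
    vox = (inv @ hom.T).T[:, :3]
    vox = np.clip(vox, 0, np.asarray(vol.shape) - 1)
    p0 = np.floor(vox).astype(int)
    f = vox - p0
    out = np.zeros(len(pts_world))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                q = np.clip(p0 + (dx, dy, dz), 0, np.asarray(vol.shape) - 1)
                w = (
                    (f[:, 0] if dx else 1 - f[:, 0])
                    * (f[:, 1] if dy else 1 - f[:, 1])
                    * (f[:, 2] if dz else 1 - f[:, 2])
                )
                out += w * vol[q[:, 0], q[:, 1], q[:, 2]]
    return out


def sample_sections(
    bundle: TractBundle,
    maps: ScalarMaps,
    scheme: SectionScheme,
    root: str,
    mean_path: MeanPath | None = None,
    subject: str = "S01",
    session: int = 1,
    rater: int = 1,
    side: str | None = None,
) -> pd.DataFrame:
    """Per-section means of FA/MD/AD/RD along the nerve.

    The mean-path arc is divided into ``n`` equal sections; every fiber point
    joins the section of its nearest-arc-length projection, and the section
    value is the mean of the scalar maps trilinearly interpolated at those
    fiber points.  Empty sections yield a flagged row (n_points 0, NaN
    values) so the section index stays contiguous.
    """
    if len(bundle) == 0:
        raise ValueError("cannot sample an empty bundle")
    if mean_path is None:
        mean_path = compute_mean_path(bundle)
    n_sec = scheme.n_sections(root)
    pts = np.concatenate([sl.points for sl in bundle.streamlines])
    frac = _project_arc_fraction(pts, mean_path)
    sec = np.minimum((frac * n_sec).astype(int), n_sec - 1)
    vals = {
        m: _interp_world(getattr(maps, m), maps.affine, pts)
        for m in ("fa", "md", "ad", "rd")
    }
    rows = []
    for s in range(n_sec):
        sel = sec == s
        row = {
            "subject": subject,
            "session": session,
            "rater": rater,
            "side": side if side is not None else bundle.side,
            "root": root,
            "section": s + 1,
            "n_points": int(sel.sum()),
        }
        for m in ("fa", "md", "ad", "rd"):
            row[m] = float(vals[m][sel].mean()) if sel.any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=SAMPLE_COLUMNS)


def nerve_means(table: pd.DataFrame) -> pd.DataFrame:
    """Evenly weighted per-nerve means: each section contributes equally to
    its root's mean regardless of how many fiber points it contains."""
    if len(table) == 0:
        raise ValueError("empty sample table")
    keys = ["subject", "session", "rater", "side", "root"]
    out = (
        table.dropna(subset=["fa", "md", "ad", "rd"])
        .groupby(keys, as_index=False)[["fa", "md", "ad", "rd"]]
        .mean()
    )
    return out
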