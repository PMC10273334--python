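"""Generalized Procrustes superimposition, semilandmark sliding, and shape PCA.

The morphospace pipeline for endosseous-labyrinth curve semilandmarks:

1. :func:`gpa` — iterative Generalized Procrustes Analysis: every
   configuration is centred, scaled to unit centroid size, and rotated onto
   the evolving consensus (rotations proper, determinant +1, since labyrinths
   are chirally consistent), until the consensus stabilises.
2. :func:`slide_semilandmarks` — optional minimised-Procrustes-distance
   sliding of semilandmarks along discrete curve tangents (endpoints fixed),
   accepted only when it lowers the total Procrustes sum of squares.
3. :func:`pca_shapes` — covariance PCA of the aligned coordinates in the
   tangent space at the consensus, with a deterministic eigenvector sign
   convention.
4. :func:`morphospace_summary` — per-group centroids, score ranges, pairwise
   centroid distances, and 1D overlap fractions in morphospace.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_model import LandmarkConfiguration, SpecimenRecord, ValidationError

__all__ = [
    "AlignedShapeSet",
    "PCAResult",
    "MorphospaceSummary",
    "gpa",
    "procrustes_ss",
    "slide_semilandmarks",
    "pca_shapes",
    "morphospace_summary",
]


@dataclass
class AlignedShapeSet:
    """Procrustes-aligned configurations and their consensus.

    Every aligned configuration has its centroid at the origin and unit
    centroid size; the consensus is the coordinate-wise mean of the aligned
    configurations.
    """

    specimen_ids: list[str]
    consensus: np.ndarray  # (k, 3)
    aligned: np.ndarray  # (n, k, 3)
    centroid_sizes: np.ndarray  # (n,)
    iterations: int
    converged: bool
    curve_ids: Optional[list[str]] = None
    is_semilandmark: Optional[np.ndarray] = None

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]


def _center_and_scale(x: np.ndarray) -> tuple[np.ndarray, float]:
    c = x - x.mean(axis=0)
    cs = float(np.sqrt((c**2).sum()))
    if cs == 0.0:
        raise ValidationError("degenerate configuration: all landmarks coincident")
    return c / cs, cs


def _optimal_rotation(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation (det +1) minimising ||x R - target||_F (Kabsch)."""
    u, _, vt = np.linalg.svd(x.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    s = np.diag([1.0, 1.0, d])
    return u @ s @ vt


def _canonical_orientation(consensus: np.ndarray) -> np.ndarray:
    """Proper rotation mapping the consensus to a canonical frame.

    Aligns the consensus inertia axes with the coordinate axes (descending
    variance), fixing each axis sign so the consensus coordinate of largest
    magnitude along it is positive, and forcing determinant +1. This removes
    the arbitrary global orientation of a GPA solution so downstream scores
    are reproducible under rigid motions of the inputs.
    """
    cov = consensus.T @ consensus
    eigvals, v = np.linalg.eigh(cov)
    v = v[:, ::-1]  # descending variance
    proj = consensus @ v
    for j in range(3):
        pivot = np.argmax(np.abs(proj[:, j]))
        if proj[pivot, j] < 0:
            v[:, j] = -v[:, j]
    if np.linalg.det(v) < 0:
        v[:, 2] = -v[:, 2]
    return v


def gpa(
    configs: Sequence[LandmarkConfiguration],
    tol: float = 1e-10,
    max_iter: int = 100,
) -> AlignedShapeSet:
    """Generalized Procrustes Analysis of homologous 3D configurations.

    Removes translation (centroid to origin), scale (unit centroid size),
    and rotation (proper orthogonal Procrustes against the evolving
    consensus). Iterates until the consensus root-mean-square change falls
    below ``tol`` or ``max_iter`` is reached; non-convergence is reported via
    ``converged=False``, never an exception.
    """
    if not configs:
        raise ValidationError("gpa needs at least one configuration")
    k0 = configs[0].k
    curves0 = list(configs[0].curve_ids)
    for c in configs[1:]:
        if c.k != k0 or list(c.curve_ids) != curves0:
            raise ValidationError("configurations are not homologous")
    shapes, sizes = [], []
    for c in configs:
        c.validate()
        s, cs = _center_and_scale(c.coordinates)
        if np.linalg.matrix_rank(s, tol=1e-12) < 2:
            raise ValidationError(
                f"{c.specimen_id}: degenerate (collinear) configuration"
            )
        shapes.append(s)
        sizes.append(cs)
    x = np.stack(shapes)  # (n, k, 3)
    n = x.shape[0]

    consensus = x[0].copy()
    iterations, converged = 0, n == 1
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            x[i] = x[i] @ _optimal_rotation(x[i], consensus)
        new_consensus = x.mean(axis=0)
        # re-standardise the consensus so scale cannot drift
        new_consensus, _ = _center_and_scale(new_consensus)
        rms = float(np.sqrt(((new_consensus - consensus) ** 2).mean()))
        consensus = new_consensus
        if rms < tol:
            converged = True
            break
    # final rotation pass so every shape is aligned to the final consensus
    for i in range(n):
        x[i] = x[i] @ _optimal_rotation(x[i], consensus)
    # canonical global orientation (GPA is otherwise unique only up to rotation)
    r = _canonical_orientation(x.mean(axis=0))
    x = x @ r
    return AlignedShapeSet(
        specimen_ids=[c.specimen_id for c in configs],
        consensus=x.mean(axis=0),
        aligned=x,
        centroid_sizes=np.array(sizes),
        iterations=iterations,
        converged=converged,
        curve_ids=curves0,
        is_semilandmark=np.asarray(configs[0].is_semilandmark, bool).copy(),
    )


def procrustes_ss(aligned: AlignedShapeSet) -> float:
    """Total Procrustes sum of squares about the consensus."""
    return float(((aligned.aligned - aligned.consensus) ** 2).sum())


def _curve_tangents(points: np.ndarray) -> np.ndarray:
    """Unit tangents along an ordered curve via central differences."""
    t = np.empty_like(points)
    t[0] = points[1] - points[0]
    t[-1] = points[-1] - points[-2]
    t[1:-1] = points[2:] - points[:-2]
    norms = np.linalg.norm(t, axis=1, keepdims=True)
    norms[norms == 0.0] = 1.0
    return t / norms


def slide_semilandmarks(
    aligned: AlignedShapeSet,
    curves: Optional[Sequence[str]] = None,
    mode: str = "procrustes_distance",
) -> AlignedShapeSet:
    """Slide semilandmarks along discrete curve tangents toward the consensus.

    With ``mode="procrustes_distance"`` each interior semilandmark of each
    curve moves along its local tangent by the projection of its residual to
    the consensus (the 1D minimiser of squared distance along that
    direction); curve endpoints and non-semilandmarks stay put, and the set
    is then re-superimposed. The slid result is kept only when it does not
    increase the total Procrustes sum of squares; otherwise the input is
    returned unchanged. ``mode="off"`` is the identity.
    """
    if mode == "off":
        return aligned
    if mode != "procrustes_distance":
        raise ValidationError(f"unknown sliding mode {mode!r}")
    curve_ids = list(curves) if curves is not None else aligned.curve_ids
    if curve_ids is None:
        raise ValidationError("curve labels required for sliding")
    if len(curve_ids) != aligned.k:
        raise ValidationError("curve label count does not match landmark count")
    semi = (
        aligned.is_semilandmark
        if aligned.is_semilandmark is not None
        else np.ones(aligned.k, bool)
    )
    # index runs per curve, preserving landmark order
    curve_runs: dict[str, list[int]] = {}
    for idx, cid in enumerate(curve_ids):
        curve_runs.setdefault(cid, []).append(idx)
    for cid, idxs in curve_runs.items():
        if len(idxs) < 3:
            raise ValidationError(f"curve {cid!r} has fewer than 3 landmarks")

    before = procrustes_ss(aligned)
    slid = aligned.aligned.copy()
    for i in range(aligned.n):
        for idxs in curve_runs.values():
            pts = slid[i, idxs]
            tangents = _curve_tangents(pts)
            residual = aligned.consensus[idxs] - pts
            step = (residual * tangents).sum(axis=1, keepdims=True) * tangents
            step[0] = 0.0  # curve endpoints are fixed
            step[-1] = 0.0
            movable = semi[idxs]
            step[~movable] = 0.0
            slid[i, idxs] = pts + step

    configs = [
        LandmarkConfiguration(
            specimen_id=sid,
            coordinates=slid[i],
            curve_ids=curve_ids,
            is_semilandmark=semi,
        )
        for i, sid in enumerate(aligned.specimen_ids)
    ]
    out = gpa(configs)
    out.centroid_sizes = aligned.centroid_sizes.copy()
    if procrustes_ss(out) > before:
        return aligned
    return out


@dataclass
class PCAResult:
    """Shape PCA: eigenvalues, variance fractions, scores, and loadings."""

    specimen_ids: list[str]
    eigenvalues: np.ndarray  # non-increasing, >= 0
    variance_fraction: np.ndarray  # sums to 1 over non-zero components
    scores: np.ndarray  # (n, n_components)
    loadings: np.ndarray  # (n_components, k, 3)
    n_components: int
    consensus: np.ndarray  # (k, 3)

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.n_components)]
        return pd.DataFrame(self.scores, index=self.specimen_ids, columns=cols)

    def variance_frame(self) -> pd.DataFrame:
        frac = self.variance_fraction
        return pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(self.n_components)],
                "eigenvalue": self.eigenvalues,
                "fraction": frac,
                "cumulative": np.cumsum(frac),
            }
        )


def pca_shapes(aligned: AlignedShapeSet) -> PCAResult:
    """Covariance PCA of aligned shapes in the tangent space at the consensus.

    Eigen-decomposes the covariance of the flattened aligned coordinates
    about the consensus; scores are the centred data projected on the
    eigenvectors. Eigenvector signs follow a deterministic convention: the
    largest-magnitude entry of each eigenvector is made positive.
    """
    if aligned.n < 3:
        raise ValidationError("shape PCA needs at least 3 specimens")
    n, k = aligned.n, aligned.k
    flat = aligned.aligned.reshape(n, 3 * k)
    centered = flat - aligned.consensus.reshape(1, 3 * k)
    # SVD route: eigenvalues of the covariance are s^2 / (n - 1)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigvals = s**2 / (n - 1)
    # deterministic sign: largest-|entry| of each eigenvector positive
    for j in range(vt.shape[0]):
        pivot = np.argmax(np.abs(vt[j]))
        if vt[j, pivot] < 0:
            vt[j] = -vt[j]
    scores = centered @ vt.T
    total = eigvals.sum()
    frac = eigvals / total if total > 0 else np.zeros_like(eigvals)
    m = len(eigvals)
    return PCAResult(
        specimen_ids=list(aligned.specimen_ids),
        eigenvalues=eigvals,
        variance_fraction=frac,
        scores=scores,
        loadings=vt.reshape(m, k, 3),
        n_components=m,
        consensus=aligned.consensus.copy(),
    )


@dataclass
class MorphospaceSummary:
    """Group structure in morphospace on the first PCs."""

    centroids: pd.DataFrame  # group x PC centroid coordinates
    ranges: pd.DataFrame  # group x (PC, min, max)
    pairwise_distances: pd.DataFrame  # group_a, group_b, distance
    overlap: pd.DataFrame  # group_a, group_b, PC, overlap_fraction


def _interval_overlap(a: tuple[float, float], b: tuple[float, float]) -> float:
    """1D overlap fraction: intersection length / union length (0 when disjoint)."""
    lo, hi = max(a[0], b[0]), min(a[1], b[1])
    inter = max(0.0, hi - lo)
    union = max(a[1], b[1]) - min(a[0], b[0])
    if union == 0.0:
        return 1.0 if inter == 0.0 and a == b else 0.0
    return inter / union


def morphospace_summary(
    p: PCAResult,
    records: Sequence[SpecimenRecord],
    grouping: str = "skull_class",
    n_axes: int = 3,
) -> MorphospaceSummary:
    """Summarise group structure on the first ``n_axes`` PCs.

    ``grouping`` is ``"skull_class"`` or ``"ecology"``; every scored specimen
    must carry the grouping label.
    """
    if grouping not in ("ecology", "skull_class"):
        raise ValidationError(f"unknown grouping {grouping!r}")
    by_id = {r.specimen_id: r for r in records}
    labels = []
    for sid in p.specimen_ids:
        rec = by_id.get(sid)
        value = getattr(rec, grouping, None) if rec is not None else None
        if value is None:
            raise ValidationError(f"{sid}: missing {grouping} label")
        labels.append(value.value if hasattr(value, "value") else str(value))
    n_axes = min(n_axes, p.n_components)
    cols = [f"PC{i + 1}" for i in range(n_axes)]
    df = pd.DataFrame(p.scores[:, :n_axes], columns=cols)
    df["group"] = labels

    centroids = df.groupby("group").mean()
    range_rows, overlap_rows, dist_rows = [], [], []
    groups = sorted(centroids.index)
    for g in groups:
        sub = df[df["group"] == g]
        for c in cols:
            range_rows.append(
                {"group": g, "component": c, "min": sub[c].min(), "max": sub[c].max()}
            )
    for ga, gb in combinations(groups, 2):
        dist_rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "distance": float(
                    np.linalg.norm(centroids.loc[ga] - centroids.loc[gb])
                ),
            }
        )
        for c in cols:
            a = df[df["group"] == ga][c]
            b = df[df["group"] == gb][c]
            overlap_rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "component": c,
                    "overlap_fraction": _interval_overlap(
                        (a.min(), a.max()), (b.min(), b.max())
                    ),
                }
            )
    return MorphospaceSummary(
        centroids=centroids,
        ranges=pd.DataFrame(range_rows),
        pairwise_distances=pd.DataFrame(
            dist_rows, columns=["group_a", "group_b", "distance"]
        ),
        overlap=pd.DataFrame(
            overlap_rows, columns=["group_a", "group_b", "component", "overlap_fraction"]
        ),
    )
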