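"""Regression-voting constrained-local-model landmark detection.

A deliberately compact single-stage take on the random-forest
regression-voting constrained local model (RFRV-CLM) family of landmark
detectors.  The two ingredients are

1. a *statistical shape model*: the mean landmark configuration and the
   principal modes of variation of Procrustes-aligned training shapes,
   with mode coefficients clamped to ``|b_i| <= c * sqrt(lambda_i)``; and
2. one *regression-voting forest per landmark*: random-forest regressors
   mapping a normalised square intensity patch to the 2D displacement from
   the patch centre to the true landmark.  At search time the forest is
   evaluated over a grid around the current estimate; every grid sample
   votes for a corrected position, the vote accumulator's peak becomes the
   candidate, and a similarity + constrained-shape fit to the candidates
   regularises the configuration.  The loop alternates voting and shape
   fitting for a fixed number of iterations.

The estimator follows scikit-learn conventions: hyperparameters in
``__init__``, state learned by :meth:`RegressionVotingDetector.fit` stored
in trailing-underscore attributes, inference via
:meth:`RegressionVotingDetector.predict`.

Displacements are learned and voted in image pixels; the shape-model pose
scale modulates the sampling and search ranges.  This assumes roughly
standardised image scale across the dataset (true for the synthetic
renders this detector is benchmarked on) and is the main simplification
relative to multi-resolution reference-frame implementations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor
from sklearn.utils import check_random_state

from .landmarks import LandmarkSet, SchemaId, get_schema

__all__ = [
    "ShapeModel",
    "RegressionVotingDetector",
    "procrustes_align",
    "build_shape_model",
    "constrain",
    "place_mean_shape_in_bbox",
]

FORMAT_VERSION = 1


# --------------------------------------------------------------------------
# generalised Procrustes analysis and the shape model

def _similarity_align(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """Least-squares similarity transform mapping ``src`` onto ``dst``.

    Returns ``(R, s, t, aligned)`` with ``aligned = s * src @ R.T + t``.
    """
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    a, b = src - mu_s, dst - mu_d
    cov = b.T @ a
    u, sv, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    D = np.diag([1.0, d])
    R = u @ D @ vt
    denom = float(np.sum(a * a))
    if denom == 0.0:
        raise ValueError("degenerate shape: all points coincide")
    s = float(np.sum(sv * np.diag(D))) / denom
    t = mu_d - s * (mu_s @ R.T)
    return R, s, t, s * src @ R.T + t


def _normalise(shape: np.ndarray) -> np.ndarray:
    c = shape - shape.mean(axis=0)
    n = np.linalg.norm(c)
    if n == 0.0:
        raise ValueError("degenerate shape: all points coincide")
    return c / n


def procrustes_align(shapes: Sequence[np.ndarray], tol: float = 1e-8,
                     max_iter: int = 100) -> tuple[list[np.ndarray], np.ndarray]:
    """Generalised Procrustes alignment of a set of (n, 2) point arrays.

    Removes translation, rotation and isotropic scale; iterates aligning
    every shape to the current mean and re-estimating the mean (zero
    centroid, unit Frobenius norm) until the mean moves less than ``tol``.
    Returns (aligned shapes, converged mean).
    """
    if len(shapes) < 2:
        raise ValueError("need at least 2 shapes")
    shapes = [np.asarray(s, dtype=float) for s in shapes]
    mean = _normalise(shapes[0])
    aligned = list(shapes)
    for _ in range(max_iter):
        aligned = [_similarity_align(s, mean)[3] for s in shapes]
        new_mean = _normalise(np.mean(aligned, axis=0))
        delta = float(np.linalg.norm(new_mean - mean))
        mean = new_mean
        if delta < tol:
            break
    aligned = [_similarity_align(s, mean)[3] for s in shapes]
    return aligned, mean


@dataclass
class ShapeModel:
    """Point-distribution model: mean shape + principal modes of variation.

    ``mean_shape`` is (n, 2), zero-centroid, unit-norm; ``modes`` is
    (n_modes, 2n) orthonormal; ``eigenvalues`` are the per-mode variances in
    non-increasing order.  ``reference_scale`` is the average Frobenius norm
    of the centred training shapes in image pixels, mapping the normalised
    frame back to image scale.
    """

    mean_shape: np.ndarray
    modes: np.ndarray
    eigenvalues: np.ndarray
    reference_scale: float

    @property
    def n_modes(self) -> int:
        return int(self.modes.shape[0])

    def fit_points(self, points: np.ndarray, limit: float = 3.0
                   ) -> tuple[np.ndarray, tuple[np.ndarray, float, np.ndarray]]:
        """Constrained fit of the model to image-frame points.

        Returns the regularised points in the image frame and the
        similarity pose (R, s, t) mapping model frame -> image frame.
        """
        R, s, t, _ = _similarity_align(self.mean_shape, points)
        # residual in the model frame
        Rin, sin_, tin, in_frame = _similarity_align(points, self.mean_shape)
        b = self.modes @ (in_frame - self.mean_shape).ravel()
        b = constrain(b, self.eigenvalues, limit)
        model_pts = self.mean_shape + (b @ self.modes).reshape(-1, 2)
        return s * model_pts @ R.T + t, (R, s, t)


def build_shape_model(aligned: Sequence[np.ndarray], variance_fraction: float = 0.95,
                      reference_scale: float = 1.0,
                      n_modes: int | None = None) -> ShapeModel:
    """PCA shape model from Procrustes-aligned shapes.

    Retains the smallest number of modes whose cumulative explained
    variance reaches ``variance_fraction`` (or exactly ``n_modes`` if
    given; 0 keeps the mean shape only).
    """
    if not 0.0 < variance_fraction <= 1.0:
        raise ValueError("variance_fraction must be in (0, 1]")
    if len(aligned) < 3:
        raise ValueError("need at least 3 shapes")
    X = np.stack([np.asarray(s, dtype=float).ravel() for s in aligned])
    mean = X.mean(axis=0)
    max_modes = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=max_modes, svd_solver="full")
    pca.fit(X)
    if n_modes is None:
        ratio = np.cumsum(pca.explained_variance_ratio_)
        n_modes = int(np.searchsorted(ratio, variance_fraction - 1e-12) + 1)
        n_modes = min(n_modes, max_modes)
    if n_modes > 0:
        modes = pca.components_[:n_modes]
        eigvals = pca.explained_variance_[:n_modes]
    else:
        modes = np.zeros((0, X.shape[1]))
        eigvals = np.zeros(0)
    return ShapeModel(mean_shape=mean.reshape(-1, 2), modes=modes,
                      eigenvalues=np.asarray(eigvals, dtype=float),
                      reference_scale=float(reference_scale))


def constrain(b: np.ndarray, eigenvalues: np.ndarray, limit: float = 3.0) -> np.ndarray:
    """Clamp mode coefficients to ``|b_i| <= limit * sqrt(lambda_i)``."""
    b = np.asarray(b, dtype=float)
    lam = np.asarray(eigenvalues, dtype=float)
    if b.shape != lam.shape:
        raise ValueError("b and eigenvalues must have matching shapes")
    bound = limit * np.sqrt(lam)
    return np.clip(b, -bound, bound)


def place_mean_shape_in_bbox(model: ShapeModel, bbox: Sequence[float]) -> np.ndarray:
    """Initial points: mean shape translated/scaled into (x0, y0, x1, y1)."""
    x0, y0, x1, y1 = bbox
    m = model.mean_shape
    mx0, my0 = m.min(axis=0)
    mx1, my1 = m.max(axis=0)
    s = min((x1 - x0) / (mx1 - mx0), (y1 - y0) / (my1 - my0))
    centre = np.array([(x0 + x1) / 2.0, (y0 + y1) / 2.0])
    return (m - m.mean(axis=0)) * s + centre


# --------------------------------------------------------------------------
# patch sampling

def _extract_patches(img: np.ndarray, centres: np.ndarray, hw: int) -> np.ndarray:
    """Normalised intensity patches (one row per centre).

    Centres are rounded to the pixel grid and clipped so the patch stays
    inside the image; each patch is mean/variance normalised.
    """
    h, w = img.shape
    cx = np.clip(np.rint(centres[:, 0]).astype(int), hw, w - 1 - hw)
    cy = np.clip(np.rint(centres[:, 1]).astype(int), hw, h - 1 - hw)
    offs = np.arange(-hw, hw + 1)
    rows = cy[:, None, None] + offs[None, :, None]
    cols = cx[:, None, None] + offs[None, None, :]
    patches = img[rows, cols].reshape(len(centres), -1)
    patches = patches - patches.mean(axis=1, keepdims=True)
    sd = patches.std(axis=1, keepdims=True)
    return patches / np.maximum(sd, 1e-8)


class RegressionVotingDetector(BaseEstimator):
    """Per-landmark regression-voting search under a shape-model constraint.

    Parameters
    ----------
    patch_halfwidth : int
        Half-width of the square intensity patch (feature window), pixels.
    d_max : float
        Maximum training offset from the true landmark, reference pixels;
        also bounds how far a single vote can move a point.
    n_offsets_per_image : int
        Random patch offsets sampled per landmark per training image.
    n_trees, max_depth : int
        Regression-forest size per landmark.
    search_halfwidth : float
        Half-width of the voting grid around the current estimate,
        reference pixels.
    grid_spacing : float
        Voting-grid step, pixels.
    n_iterations : int
        Vote / shape-fit alternations per image.
    variance_fraction : float
        Shape-model variance retained.
    shape_limit : float
        Mode-coefficient clamp ``c`` in ``|b_i| <= c * sqrt(lambda_i)``.
    random_state : int or None
        Seed for every source of randomness (offsets, forest bootstrap).
    """

    def __init__(self, patch_halfwidth: int = 6, d_max: float = 12.0,
                 n_offsets_per_image: int = 15, n_trees: int = 10,
                 max_depth: int = 12, search_halfwidth: float = 8.0,
                 grid_spacing: float = 1.0, n_iterations: int = 3,
                 variance_fraction: float = 0.95, shape_limit: float = 3.0,
                 random_state: int | None = None):
        self.patch_halfwidth = patch_halfwidth
        self.d_max = d_max
        self.n_offsets_per_image = n_offsets_per_image
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.search_halfwidth = search_halfwidth
        self.grid_spacing = grid_spacing
        self.n_iterations = n_iterations
        self.variance_fraction = variance_fraction
        self.shape_limit = shape_limit
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def fit(self, images: Sequence[np.ndarray],
            landmark_sets: Sequence[LandmarkSet]) -> "RegressionVotingDetector":
        """Train the shape model and one voting forest per landmark."""
        if len(images) != len(landmark_sets):
            raise ValueError("images and landmark_sets must have equal length")
        if len(images) < 10:
            raise ValueError("need at least 10 training pairs")
        sids = {ls.schema_id for ls in landmark_sets}
        if len(sids) != 1:
            raise ValueError("training landmark sets must share one schema")
        self.schema_id_ = sids.pop()
        n_points = get_schema(self.schema_id_).n_points

        rng = check_random_state(self.random_state)
        shapes = [ls.points for ls in landmark_sets]
        aligned, _ = procrustes_align(shapes)
        ref_scale = float(np.mean([
            np.linalg.norm(s - s.mean(axis=0)) for s in shapes]))
        self.shape_model_ = build_shape_model(
            aligned, variance_fraction=self.variance_fraction,
            reference_scale=ref_scale)

        # image-frame sampling radius per image: d_max scaled by pose scale
        scales = [np.linalg.norm(s - s.mean(axis=0)) / ref_scale for s in shapes]
        imgs = [np.asarray(im, dtype=float) for im in images]

        self.forests_ = []
        for l in range(n_points):
            feats, targets = [], []
            for im, ls, sc in zip(imgs, landmark_sets, scales):
                truth = ls.points[l]
                r = self.d_max * sc
                offs = rng.uniform(-r, r, size=(self.n_offsets_per_image, 2))
                centres = truth[None, :] + offs
                feats.append(_extract_patches(im, centres, self.patch_halfwidth))
                # displacement from (rounded, clipped) patch centre to truth
                h, w = im.shape
                cx = np.clip(np.rint(centres[:, 0]), self.patch_halfwidth,
                             w - 1 - self.patch_halfwidth)
                cy = np.clip(np.rint(centres[:, 1]), self.patch_halfwidth,
                             h - 1 - self.patch_halfwidth)
                targets.append(truth[None, :] - np.column_stack([cx, cy]))
            forest = RandomForestRegressor(
                n_estimators=self.n_trees, max_depth=self.max_depth,
                random_state=rng.randint(0, 2**31 - 1), n_jobs=1)
            forest.fit(np.vstack(feats), np.vstack(targets))
            self.forests_.append(forest)
        return self

    # -------------------------------------------------------------- predict
    def _vote_landmark(self, img: np.ndarray, l: int, centre: np.ndarray,
                       scale: float, hw_mult: float = 1.0,
                       step_mult: float = 1.0) -> np.ndarray:
        """Accumulator peak for one landmark around ``centre``."""
        hw = self.search_halfwidth * scale * hw_mult
        step = self.grid_spacing * step_mult
        g = np.arange(-hw, hw + step / 2, step)
        gx, gy = np.meshgrid(g, g)
        positions = centre[None, :] + np.column_stack([gx.ravel(), gy.ravel()])
        h, w = img.shape
        phw = self.patch_halfwidth
        px = np.clip(np.rint(positions[:, 0]), phw, w - 1 - phw)
        py = np.clip(np.rint(positions[:, 1]), phw, h - 1 - phw)
        grid = np.column_stack([px, py])
        feats = _extract_patches(img, grid, phw)
        disp = self.forests_[l].predict(feats)
        norm = np.linalg.norm(disp, axis=1)
        keep = norm <= self.d_max * scale
        votes = (grid + disp)[keep] if np.any(keep) else grid + disp
        # 1 px accumulator bins over the vote cloud; candidate = mean of
        # the votes falling in the fullest bin.  Votes are rounded to 1e-6
        # px first so bin membership is immune to float dust (keeps
        # predictions stable across model reload / BLAS alignment).
        binned = np.floor(np.round(votes, 6)).astype(int)
        uniq, inv, counts = np.unique(binned, axis=0, return_inverse=True,
                                      return_counts=True)
        best = int(np.argmax(counts))
        return votes[inv == best].mean(axis=0)

    def predict(self, images: Sequence[np.ndarray],
                init: "Sequence[np.ndarray] | None" = None,
                bboxes: "Sequence[Sequence[float]] | None" = None,
                ) -> list[LandmarkSet]:
        """Detect landmarks in each image.

        Initialisation: explicit ``init`` point arrays, or the mean shape
        placed into per-image ``bboxes`` (x0, y0, x1, y1), or the mean shape
        at reference scale centred in the image.
        """
        if not hasattr(self, "forests_"):
            raise RuntimeError("detector is not fitted")
        out = []
        for i, im in enumerate(images):
            img = np.asarray(im, dtype=float)
            h, w = img.shape
            if init is not None:
                pts = np.asarray(init[i], dtype=float).copy()
            elif bboxes is not None:
                pts = place_mean_shape_in_bbox(self.shape_model_, bboxes[i])
            else:
                m = self.shape_model_.mean_shape
                pts = (m - m.mean(axis=0)) * self.shape_model_.reference_scale \
                    + np.array([w / 2.0, h / 2.0])
            if np.any(pts < 0) or np.any(pts[:, 0] >= w) or np.any(pts[:, 1] >= h):
                raise ValueError("initialisation outside the image frame")
            for it in range(self.n_iterations):
                _, (R, s, t) = self.shape_model_.fit_points(pts, self.shape_limit)
                scale = s / self.shape_model_.reference_scale \
                    if self.shape_model_.reference_scale else 1.0
                # first pass searches wider on a coarser grid to absorb a
                # rough initialisation; later passes refine at grid_spacing
                hw_mult, step_mult = (2.5, 2.0) if it == 0 else (1.0, 1.0)
                cand = np.stack([
                    self._vote_landmark(img, l, pts[l], scale, hw_mult, step_mult)
                    for l in range(pts.shape[0])])
                pts, _ = self.shape_model_.fit_points(cand, self.shape_limit)
            pts[:, 0] = np.clip(pts[:, 0], 0, w - 1)
            pts[:, 1] = np.clip(pts[:, 1], 0, h - 1)
            out.append(LandmarkSet(self.schema_id_, pts,
                                   image_id=f"detected_{i:04d}",
                                   source="automatic"))
        return out

    # -------------------------------------------------------- serialization
    def save(self, path: "str | Path") -> None:
        """Serialise the fitted detector (single-archive model file)."""
        payload = {
            "format_version": FORMAT_VERSION,
            "params": self.get_params(),
            "schema_id": self.schema_id_.value,
            "shape_model": self.shape_model_,
            "forests": self.forests_,
        }
        joblib.dump(payload, path)

    @classmethod
    def load(cls, path: "str | Path") -> "RegressionVotingDetector":
        payload = joblib.load(path)
        if payload.get("format_version") != FORMAT_VERSION:
            raise ValueError("unsupported model file format version")
        det = cls(**payload["params"])
        det.schema_id_ = SchemaId(payload["schema_id"])
        det.shape_model_ = payload["shape_model"]
        det.forests_ = payload["forests"]
        return det
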