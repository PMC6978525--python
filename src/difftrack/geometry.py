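"""Planar region masks used for simulation, detection and spatial statistics.

A mask describes the cell contact zone (the region inside the cell contour).
All masks work in physical units (micrometres) and provide point-membership
tests, uniform sampling (for complete-spatial-randomness references) and a
reflection rule used by the trajectory simulator to keep particles inside.
"""

from __future__ import annotations

import numpy as np
from numpy.random import Generator
from scipy import ndimage

__all__ = ["Mask", "DiskMask", "RectMask", "PolygonMask", "ImageMask"]


class Mask:
    """Abstract planar region."""

    #: (xmin, ymin, xmax, ymax) in um
    bounds: tuple[float, float, float, float]

    def contains(self, xy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def area(self) -> float:
        raise NotImplementedError

    def centroid(self) -> np.ndarray:
        raise NotImplementedError

    def reflect(self, xy: np.ndarray) -> np.ndarray:
        """Map points outside the region back inside (mirror at the boundary)."""
        raise NotImplementedError

    def sample(self, n: int, rng: Generator) -> np.ndarray:
        """Uniform points inside the region via rejection from the bounding box."""
        xmin, ymin, xmax, ymax = self.bounds
        out = np.empty((0, 2))
        while out.shape[0] < n:
            m = max(4 * (n - out.shape[0]), 64)
            cand = rng.uniform([xmin, ymin], [xmax, ymax], size=(m, 2))
            out = np.vstack([out, cand[self.contains(cand)]])
        return out[:n]


class DiskMask(Mask):
    """Disk of given radius; the default footprint for simulated cells."""

    def __init__(self, radius: float, center: tuple[float, float] = (0.0, 0.0)):
        if radius <= 0:
            raise ValueError("radius must be positive")
        self.radius = float(radius)
        self.center = np.asarray(center, dtype=float)
        cx, cy = self.center
        self.bounds = (cx - radius, cy - radius, cx + radius, cy + radius)

    def contains(self, xy):
        xy = np.atleast_2d(xy)
        return np.hypot(*(xy - self.center).T) <= self.radius

    def area(self):
        return np.pi * self.radius**2

    def centroid(self):
        return self.center.copy()

    def reflect(self, xy):
        xy = np.atleast_2d(np.asarray(xy, dtype=float)).copy()
        d = xy - self.center
        r = np.hypot(d[:, 0], d[:, 1])
        # mirror radially: r -> 2R - r, repeated for large excursions
        for _ in range(16):
            out = r > self.radius
            if not out.any():
                break
            r = np.where(out, 2 * self.radius - r, r)
            r = np.abs(r)
        r = np.minimum(r, self.radius * (1 - 1e-12))
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(
                np.hypot(d[:, 0], d[:, 1])[:, None] > 0,
                d / np.maximum(np.hypot(d[:, 0], d[:, 1])[:, None], 1e-300),
                0.0,
            )
        return self.center + unit * r[:, None]


class RectMask(Mask):
    def __init__(self, xmin: float, ymin: float, xmax: float, ymax: float):
        if xmax <= xmin or ymax <= ymin:
            raise ValueError("degenerate rectangle")
        self.bounds = (float(xmin), float(ymin), float(xmax), float(ymax))

    def contains(self, xy):
        xy = np.atleast_2d(xy)
        xmin, ymin, xmax, ymax = self.bounds
        return (
            (xy[:, 0] >= xmin) & (xy[:, 0] <= xmax)
            & (xy[:, 1] >= ymin) & (xy[:, 1] <= ymax)
        )

    def area(self):
        xmin, ymin, xmax, ymax = self.bounds
        return (xmax - xmin) * (ymax - ymin)

    def centroid(self):
        xmin, ymin, xmax, ymax = self.bounds
        return np.array([(xmin + xmax) / 2, (ymin + ymax) / 2])

    def reflect(self, xy):
        xy = np.atleast_2d(np.asarray(xy, dtype=float)).copy()
        xmin, ymin, xmax, ymax = self.bounds
        for k, (lo, hi) in enumerate([(xmin, xmax), (ymin, ymax)]):
            w = hi - lo
            # fold coordinate into [lo, hi] (triangle-wave reflection)
            t = np.mod(xy[:, k] - lo, 2 * w)
            xy[:, k] = lo + np.where(t > w, 2 * w - t, t)
        return xy


class PolygonMask(Mask):
    """Arbitrary simple polygon (irregular cell contour)."""

    def __init__(self, vertices: np.ndarray):
        from shapely.geometry import Polygon

        self.vertices = np.asarray(vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[0] < 3:
            raise ValueError("need >= 3 vertices")
        self._poly = Polygon(self.vertices)
        if not self._poly.is_valid:
            raise ValueError("invalid (self-intersecting?) polygon")
        xmin, ymin, xmax, ymax = self._poly.bounds
        self.bounds = (xmin, ymin, xmax, ymax)

    def contains(self, xy):
        from shapely import points, contains

        xy = np.atleast_2d(xy)
        return contains(self._poly, points(xy))

    def area(self):
        return self._poly.area

    def centroid(self):
        c = self._poly.centroid
        return np.array([c.x, c.y])

    def reflect(self, xy):
        # Mirror across the nearest boundary point; fall back to snapping just
        # inside if the mirror lands outside (sharp corners).
        from shapely import points, shortest_line

        xy = np.atleast_2d(np.asarray(xy, dtype=float)).copy()
        inside = self.contains(xy)
        for i in np.flatnonzero(~inside):
            p = xy[i]
            for _ in range(8):
                seg = shortest_line(points(p[None, :])[0], self._poly.exterior)
                b = np.array(seg.coords[1])
                p = 2 * b - p
                if self.contains(p[None, :])[0]:
                    break
            else:
                seg = shortest_line(points(xy[i][None, :])[0], self._poly.exterior)
                b = np.array(seg.coords[1])
                c = self.centroid()
                p = b + 1e-6 * (c - b)
            xy[i] = p
        return xy


class ImageMask(Mask):
    """Binary mask image (nonzero = inside), as exported from contour imaging."""

    def __init__(self, image: np.ndarray, pixel_size: float, origin: tuple[float, float] = (0.0, 0.0)):
        self.image = np.asarray(image) != 0
        if self.image.ndim != 2 or not self.image.any():
            raise ValueError("mask image must be 2-D with at least one inside pixel")
        self.pixel_size = float(pixel_size)
        self.origin = np.asarray(origin, dtype=float)
        h, w = self.image.shape
        self.bounds = (
            self.origin[0], self.origin[1],
            self.origin[0] + w * pixel_size, self.origin[1] + h * pixel_size,
        )
        # nearest-inside-pixel lookup for reflection
        self._nearest = None

    def _to_px(self, xy):
        xy = np.atleast_2d(xy)
        col = np.floor((xy[:, 0] - self.origin[0]) / self.pixel_size).astype(int)
        row = np.floor((xy[:, 1] - self.origin[1]) / self.pixel_size).astype(int)
        return row, col

    def contains(self, xy):
        row, col = self._to_px(xy)
        h, w = self.image.shape
        ok = (row >= 0) & (row < h) & (col >= 0) & (col < w)
        out = np.zeros(ok.shape, bool)
        out[ok] = self.image[row[ok], col[ok]]
        return out

    def area(self):
        return self.image.sum() * self.pixel_size**2

    def centroid(self):
        rows, cols = np.nonzero(self.image)
        return self.origin + (np.array([cols.mean(), rows.mean()]) + 0.5) * self.pixel_size

    def sample(self, n, rng):
        rows, cols = np.nonzero(self.image)
        idx = rng.integers(0, rows.size, size=n)
        jit = rng.uniform(0, 1, size=(n, 2))
        x = self.origin[0] + (cols[idx] + jit[:, 0]) * self.pixel_size
        y = self.origin[1] + (rows[idx] + jit[:, 1]) * self.pixel_size
        return np.column_stack([x, y])

    def reflect(self, xy):
        # snap to the centre of the nearest inside pixel
        if self._nearest is None:
            ind = ndimage.distance_transform_edt(
                ~self.image, return_distances=False, return_indices=True
            )
            self._nearest = ind
        xy = np.atleast_2d(np.asarray(xy, dtype=float)).copy()
        inside = self.contains(xy)
        if inside.all():
            return xy
        row, col = self._to_px(xy[~inside])
        h, w = self.image.shape
        row = np.clip(row, 0, h - 1)
        col = np.clip(col, 0, w - 1)
        nr = self._nearest[0][row, col]
        nc = self._nearest[1][row, col]
        xy[~inside, 0] = self.origin[0] + (nc + 0.5) * self.pixel_size
        xy[~inside, 1] = self.origin[1] + (nr + 0.5) * self.pixel_size
        return xy
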