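"""Panel geometry for membrane surfaces.

Surfaces are composed of infinitely thin, locally smooth *panels*: axis-aligned
rectangles, triangles, spheres, cylinders, hemispheres, and disks.  Every panel
has a distinct *front* and *back* side.  The conventions are:

* rectangle -- front is the side its stated normal (``+x`` / ``-z`` ...) points to;
* triangle  -- front follows the right-hand rule on the vertex order;
* sphere / cylinder / hemisphere -- front is outside (away from center/axis)
  unless the panel is constructed with ``front_outside=False``;
* disk      -- front is the side of its normal vector.

All vectorized operations take ``(n, 3)`` position arrays; for 1-D and 2-D
systems the unused trailing coordinates are zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

NO_HIT = np.inf
#: crossings with |signed distance| below this (relative to panel scale) are
#: treated as tangent grazes and ignored: they are measure-zero events and
#: ignoring them avoids double-processing a molecule sitting on a plane.
GRAZE_RTOL = 1e-12


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector where a direction is required")
    return v / n


# ---------------------------------------------------------------------------
# panels
# ---------------------------------------------------------------------------


class Panel:
    """Base class.  Subclasses implement the vectorized geometric kernel."""

    name: str = ""
    shape: str = ""

    # -- interface -----------------------------------------------------------
    def intersect(self, p0: np.ndarray, p1: np.ndarray):
        """First crossing of segments ``p0->p1`` with the panel.

        Returns ``(frac, side)``: ``frac[i]`` is the parametric fraction of the
        first crossing in ``(0, 1]`` or ``inf`` if segment *i* does not cross;
        ``side[i]`` is ``+1`` when the approach is from the front, ``-1`` from
        the back.
        """
        raise NotImplementedError

    def normal_at(self, points: np.ndarray) -> np.ndarray:
        """Unit front normal at points assumed on (or near) the panel."""
        raise NotImplementedError

    def project(self, points: np.ndarray) -> np.ndarray:
        """Closest point on the (finite) panel; used to re-deposit
        surface-bound molecules after a free Gaussian step."""
        raise NotImplementedError

    def bounding_sphere(self):
        """(center, radius) enclosing the panel; used as a broad-phase cull."""
        raise NotImplementedError

    def sample_points(self, n: int, rng) -> np.ndarray:
        raise NotImplementedError

    def area(self) -> float:
        raise NotImplementedError

    def ref_point(self) -> np.ndarray:
        c, _ = self.bounding_sphere()
        return c


def _plane_cross(p0, p1, origin, normal):
    """Shared plane-crossing kernel: signed distances and strict sign change."""
    d0 = (p0 - origin) @ normal
    d1 = (p1 - origin) @ normal
    hit = (d0 * d1) < 0.0  # strict: grazing endpoints are no-hits
    denom = d0 - d1
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(hit, d0 / np.where(denom == 0.0, 1.0, denom), NO_HIT)
    side = np.where(d0 > 0.0, 1, -1).astype(np.int8)
    return frac, side, hit


@dataclass
class Rectangle(Panel):
    """Axis-aligned rectangle (3-D), segment (2-D) or point-plane (1-D).

    ``axis``/``sign`` give the front normal (e.g. axis=2, sign=+1 is ``+z``);
    the panel spans ``lengths`` along the other axes in cyclic order starting
    at ``(axis+1) % 3``.
    """

    axis: int
    sign: int
    origin: np.ndarray
    lengths: tuple  # () in 1-D, (Lu,) in 2-D, (Lu, Lv) in 3-D
    name: str = ""
    shape: str = "rectangle"

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).copy()
        if self.origin.shape != (3,):
            o = np.zeros(3)
            o[: self.origin.size] = self.origin
            self.origin = o
        if any(l <= 0 for l in self.lengths):
            raise ValueError("rectangle edge lengths must be positive")
        self._n = np.zeros(3)
        self._n[self.axis] = float(self.sign)
        self._uaxes = [(self.axis + 1) % 3, (self.axis + 2) % 3][: len(self.lengths)]

    def intersect(self, p0, p1):
        frac, side, hit = _plane_cross(p0, p1, self.origin, self._n)
        if hit.any():
            fr = np.where(np.isfinite(frac), frac, 0.0)
            q = p0 + fr[:, None] * (p1 - p0)
            ok = hit.copy()
            for ax, L in zip(self._uaxes, self.lengths):
                u = q[:, ax] - self.origin[ax]
                ok &= (u >= 0.0) & (u <= L)
            frac = np.where(ok, frac, NO_HIT)
        return frac, side

    def normal_at(self, points):
        return np.broadcast_to(self._n, (len(points), 3))

    def project(self, points):
        q = np.array(points, dtype=float, copy=True)
        q[:, self.axis] = self.origin[self.axis]
        for ax, L in zip(self._uaxes, self.lengths):
            q[:, ax] = np.clip(q[:, ax], self.origin[ax], self.origin[ax] + L)
        return q

    def bounding_sphere(self):
        c = self.origin.copy()
        r = 0.0
        for ax, L in zip(self._uaxes, self.lengths):
            c[ax] += L / 2.0
            r += (L / 2.0) ** 2
        return c, math.sqrt(r)

    def sample_points(self, n, rng):
        q = np.tile(self.origin, (n, 1))
        for ax, L in zip(self._uaxes, self.lengths):
            q[:, ax] += rng.uniform(0.0, L, size=n)
        return q

    def area(self):
        return float(np.prod(self.lengths)) if self.lengths else 1.0


@dataclass
class Triangle(Panel):
    verts: np.ndarray  # (3, 3); front normal by right-hand rule
    name: str = ""
    shape: str = "triangle"

    def __post_init__(self):
        self.verts = np.asarray(self.verts, dtype=float).reshape(3, 3).copy()
        e1 = self.verts[1] - self.verts[0]
        e2 = self.verts[2] - self.verts[0]
        nvec = np.cross(e1, e2)
        a2 = np.linalg.norm(nvec)
        if a2 == 0:
            raise ValueError("triangle vertices are collinear")
        self._n = nvec / a2
        self._area = a2 / 2.0
        self._e1, self._e2 = e1, e2

    def intersect(self, p0, p1):
        frac, side, hit = _plane_cross(p0, p1, self.verts[0], self._n)
        if hit.any():
            fr = np.where(np.isfinite(frac), frac, 0.0)
            q = p0 + fr[:, None] * (p1 - p0)
            w = q - self.verts[0]
            # barycentric via the 2x2 Gram system
            d11 = self._e1 @ self._e1
            d12 = self._e1 @ self._e2
            d22 = self._e2 @ self._e2
            det = d11 * d22 - d12 * d12
            w1 = w @ self._e1
            w2 = w @ self._e2
            u = (d22 * w1 - d12 * w2) / det
            v = (d11 * w2 - d12 * w1) / det
            ok = hit & (u >= 0.0) & (v >= 0.0) & (u + v <= 1.0)
            frac = np.where(ok, frac, NO_HIT)
        return frac, side

    def normal_at(self, points):
        return np.broadcast_to(self._n, (len(points), 3))

    def project(self, points):
        return _closest_point_triangle(np.asarray(points, float), self.verts)

    def bounding_sphere(self):
        c = self.verts.mean(axis=0)
        r = float(np.max(np.linalg.norm(self.verts - c, axis=1)))
        return c, r

    def sample_points(self, n, rng):
        r1 = np.sqrt(rng.uniform(size=n))
        r2 = rng.uniform(size=n)
        a, b, c = self.verts
        return (1 - r1)[:, None] * a + (r1 * (1 - r2))[:, None] * b + (r1 * r2)[:, None] * c

    def area(self):
        return self._area


def _closest_point_triangle(p, tri):
    """Vectorized closest point on a triangle (Ericson's region test)."""
    a, b, c = tri
    ab, ac = b - a, c - a
    ap = p - a
    d1 = ap @ ab
    d2 = ap @ ac
    bp = p - b
    d3 = bp @ ab
    d4 = bp @ ac
    cp = p - c
    d5 = cp @ ab
    d6 = cp @ ac
    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b
    done |= m
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = d1 / (d1 - d3)
    out[m] = a + v[m, None] * ab
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c
    done |= m
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = d2 / (d2 - d6)
    out[m] = a + w[m, None] * ac
    done |= m
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    out[m] = b + w[m, None] * (c - b)
    done |= m
    m = ~done
    if m.any():
        denom = va + vb + vc
        v = vb / denom
        w = vc / denom
        out[m] = a + v[m, None] * ab + w[m, None] * ac
    return out


@dataclass
class Sphere(Panel):
    center: np.ndarray
    radius: float
    front_outside: bool = True
    dim: int = 3
    name: str = ""
    shape: str = "sphere"

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).copy()
        if self.center.shape != (3,):
            c = np.zeros(3)
            c[: self.center.size] = self.center
            self.center = c
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")

    def intersect(self, p0, p1):
        u = p1 - p0
        w = p0 - self.center
        a = np.einsum("ij,ij->i", u, u)
        b = 2.0 * np.einsum("ij,ij->i", u, w)
        c = np.einsum("ij,ij->i", w, w) - self.radius**2
        disc = b * b - 4.0 * a * c
        frac = np.full(len(p0), NO_HIT)
        graze = self.radius**2 * GRAZE_RTOL
        ok = (disc > graze) & (a > 0)
        if ok.any():
            sq = np.sqrt(np.maximum(disc[ok], 0.0))
            t1 = (-b[ok] - sq) / (2 * a[ok])
            t2 = (-b[ok] + sq) / (2 * a[ok])
            tiny = 1e-12
            t1 = np.where((t1 > tiny) & (t1 <= 1.0), t1, NO_HIT)
            t2 = np.where((t2 > tiny) & (t2 <= 1.0), t2, NO_HIT)
            frac[ok] = np.minimum(t1, t2)
        outside = np.einsum("ij,ij->i", w, w) > self.radius**2
        side = np.where(outside == self.front_outside, 1, -1).astype(np.int8)
        return frac, side

    def normal_at(self, points):
        v = points - self.center
        nrm = np.linalg.norm(v, axis=1, keepdims=True)
        nrm[nrm == 0] = 1.0
        s = 1.0 if self.front_outside else -1.0
        return s * v / nrm

    def project(self, points):
        v = points - self.center
        nrm = np.linalg.norm(v, axis=1, keepdims=True)
        zero = nrm[:, 0] == 0
        if zero.any():  # degenerate: point at center -> arbitrary pole
            v[zero] = 0.0
            v[zero, 0] = 1.0
            nrm[zero] = 1.0
        return self.center + self.radius * v / nrm

    def bounding_sphere(self):
        return self.center.copy(), self.radius

    def sample_points(self, n, rng):
        v = rng.normal(size=(n, 3))
        if self.dim == 2:
            v[:, 2] = 0.0
        elif self.dim == 1:
            v[:, 1:] = 0.0
        nrm = np.linalg.norm(v, axis=1, keepdims=True)
        return self.center + self.radius * v / nrm

    def area(self):
        if self.dim == 3:
            return 4.0 * math.pi * self.radius**2
        if self.dim == 2:
            return 2.0 * math.pi * self.radius
        return 2.0


@dataclass
class Cylinder(Panel):
    """Finite open cylinder (no end caps), 3-D only."""

    a: np.ndarray
    b: np.ndarray
    radius: float
    front_outside: bool = True
    name: str = ""
    shape: str = "cylinder"

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float).copy()
        self.b = np.asarray(self.b, dtype=float).copy()
        if self.radius <= 0:
            raise ValueError("cylinder radius must be positive")
        self._L = float(np.linalg.norm(self.b - self.a))
        if self._L == 0:
            raise ValueError("cylinder endpoints coincide")
        self._e = (self.b - self.a) / self._L

    def _perp(self, p):
        w = p - self.a
        h = w @ self._e
        return w - h[:, None] * self._e, h

    def intersect(self, p0, p1):
        u = p1 - p0
        u_perp = u - (u @ self._e)[:, None] * self._e
        w_perp, _ = self._perp(p0)
        a = np.einsum("ij,ij->i", u_perp, u_perp)
        b = 2.0 * np.einsum("ij,ij->i", u_perp, w_perp)
        c = np.einsum("ij,ij->i", w_perp, w_perp) - self.radius**2
        disc = b * b - 4.0 * a * c
        frac = np.full(len(p0), NO_HIT)
        ok = (disc > self.radius**2 * GRAZE_RTOL) & (a > 0)
        if ok.any():
            sq = np.sqrt(np.maximum(disc[ok], 0.0))
            for troot in ((-b[ok] - sq) / (2 * a[ok]), (-b[ok] + sq) / (2 * a[ok])):
                valid = (troot > 1e-12) & (troot <= 1.0)
                q = p0[ok] + troot[:, None] * u[ok]
                _, h = self._perp(q)
                valid &= (h >= 0.0) & (h <= self._L)
                cand = np.where(valid, troot, NO_HIT)
                sub = frac[ok]
                frac[ok] = np.minimum(sub, cand)
        rad2 = np.einsum("ij,ij->i", w_perp, w_perp)
        outside = rad2 > self.radius**2
        side = np.where(outside == self.front_outside, 1, -1).astype(np.int8)
        return frac, side

    def normal_at(self, points):
        w_perp, _ = self._perp(points)
        nrm = np.linalg.norm(w_perp, axis=1, keepdims=True)
        nrm[nrm == 0] = 1.0
        s = 1.0 if self.front_outside else -1.0
        return s * w_perp / nrm

    def project(self, points):
        w_perp, h = self._perp(points)
        nrm = np.linalg.norm(w_perp, axis=1, keepdims=True)
        zero = nrm[:, 0] == 0
        if zero.any():
            w_perp[zero] = _any_perp(self._e)
            nrm[zero] = 1.0
        h = np.clip(h, 0.0, self._L)
        return self.a + h[:, None] * self._e + self.radius * w_perp / nrm

    def bounding_sphere(self):
        c = (self.a + self.b) / 2.0
        return c, math.sqrt((self._L / 2.0) ** 2 + self.radius**2)

    def sample_points(self, n, rng):
        h = rng.uniform(0.0, self._L, size=n)
        phi = rng.uniform(0.0, 2 * math.pi, size=n)
        u = _any_perp(self._e)
        v = np.cross(self._e, u)
        ring = np.cos(phi)[:, None] * u + np.sin(phi)[:, None] * v
        return self.a + h[:, None] * self._e + self.radius * ring

    def area(self):
        return 2.0 * math.pi * self.radius * self._L


def _any_perp(e):
    t = np.array([1.0, 0.0, 0.0]) if abs(e[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    v = np.cross(e, t)
    return v / np.linalg.norm(v)


@dataclass
class Hemisphere(Panel):
    """Spherical cap covering the half with ``(q - center) . pole >= 0``."""

    center: np.ndarray
    radius: float
    pole: np.ndarray
    front_outside: bool = True
    name: str = ""
    shape: str = "hemisphere"

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).copy()
        self.pole = _unit(self.pole)
        if self.radius <= 0:
            raise ValueError("hemisphere radius must be positive")
        self._sph = Sphere(self.center, self.radius, self.front_outside)

    def intersect(self, p0, p1):
        # both sphere roots must be screened against the cap
        u = p1 - p0
        w = p0 - self.center
        a = np.einsum("ij,ij->i", u, u)
        b = 2.0 * np.einsum("ij,ij->i", u, w)
        c = np.einsum("ij,ij->i", w, w) - self.radius**2
        disc = b * b - 4.0 * a * c
        frac = np.full(len(p0), NO_HIT)
        ok = (disc > self.radius**2 * GRAZE_RTOL) & (a > 0)
        if ok.any():
            sq = np.sqrt(np.maximum(disc[ok], 0.0))
            for troot in ((-b[ok] - sq) / (2 * a[ok]), (-b[ok] + sq) / (2 * a[ok])):
                valid = (troot > 1e-12) & (troot <= 1.0)
                q = p0[ok] + troot[:, None] * u[ok]
                valid &= (q - self.center) @ self.pole >= 0.0
                frac[ok] = np.minimum(frac[ok], np.where(valid, troot, NO_HIT))
        outside = np.einsum("ij,ij->i", w, w) > self.radius**2
        side = np.where(outside == self.front_outside, 1, -1).astype(np.int8)
        return frac, side

    def normal_at(self, points):
        return self._sph.normal_at(points)

    def project(self, points):
        q = self._sph.project(points)
        h = (q - self.center) @ self.pole
        below = h < 0.0
        if below.any():  # clamp to the rim circle
            v = q[below] - self.center
            v -= (v @ self.pole)[:, None] * self.pole
            nrm = np.linalg.norm(v, axis=1, keepdims=True)
            nrm[nrm == 0] = 1.0
            q[below] = self.center + self.radius * v / nrm
        return q

    def bounding_sphere(self):
        return self.center.copy(), self.radius

    def sample_points(self, n, rng):
        out = np.empty((0, 3))
        while len(out) < n:
            v = rng.normal(size=(2 * n, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            v = v[v @ self.pole >= 0.0]
            out = np.vstack([out, self.center + self.radius * v])
        return out[:n]

    def area(self):
        return 2.0 * math.pi * self.radius**2


@dataclass
class Disk(Panel):
    center: np.ndarray
    radius: float
    normal: np.ndarray
    name: str = ""
    shape: str = "disk"

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).copy()
        self.normal = _unit(self.normal)
        if self.radius <= 0:
            raise ValueError("disk radius must be positive")

    def intersect(self, p0, p1):
        frac, side, hit = _plane_cross(p0, p1, self.center, self.normal)
        if hit.any():
            fr = np.where(np.isfinite(frac), frac, 0.0)
            q = p0 + fr[:, None] * (p1 - p0)
            ok = hit & (np.linalg.norm(q - self.center, axis=1) <= self.radius)
            frac = np.where(ok, frac, NO_HIT)
        return frac, side

    def normal_at(self, points):
        return np.broadcast_to(self.normal, (len(points), 3))

    def project(self, points):
        v = points - self.center
        v_in = v - (v @ self.normal)[:, None] * self.normal
        r = np.linalg.norm(v_in, axis=1, keepdims=True)
        scale = np.minimum(1.0, self.radius / np.where(r == 0, 1.0, r))
        return self.center + v_in * scale

    def bounding_sphere(self):
        return self.center.copy(), self.radius

    def sample_points(self, n, rng):
        u = _any_perp(self.normal)
        v = np.cross(self.normal, u)
        r = self.radius * np.sqrt(rng.uniform(size=n))
        phi = rng.uniform(0.0, 2 * math.pi, size=n)
        return self.center + (r * np.cos(phi))[:, None] * u + (r * np.sin(phi))[:, None] * v

    def area(self):
        return math.pi * self.radius**2


# ---------------------------------------------------------------------------
# free functions required by the simulation core
# ---------------------------------------------------------------------------


def intersect_segment(p0, p1, panel: Panel):
    """Scalar convenience wrapper: first crossing of one segment with a panel.

    Returns ``(hit_point, frac, side)`` or ``None`` when the segment misses.
    ``side`` is ``'front'`` or ``'back'`` (side of approach).
    """
    p0 = np.atleast_2d(np.asarray(p0, dtype=float))
    p1 = np.atleast_2d(np.asarray(p1, dtype=float))
    if p0.shape[1] < 3:
        p0 = np.pad(p0, ((0, 0), (0, 3 - p0.shape[1])))
        p1 = np.pad(p1, ((0, 0), (0, 3 - p1.shape[1])))
    if np.allclose(p0, p1):
        return None
    frac, side = panel.intersect(p0, p1)
    if not np.isfinite(frac[0]):
        return None
    q = p0[0] + frac[0] * (p1[0] - p0[0])
    return q, float(frac[0]), ("front" if side[0] > 0 else "back")


def reflect(p0, p1, panel: Panel):
    """Ballistic reflection of the endpoint across the tangent plane at the hit.

    ``p0 -> p1`` must cross the panel; the mirrored endpoint lies on the same
    side as ``p0``.  For curved panels the tangent plane at the hit point is
    used.
    """
    res = intersect_segment(p0, p1, panel)
    if res is None:
        raise ValueError("segment does not cross the panel")
    q, _, _ = res
    p1 = np.asarray(p1, dtype=float)
    pad = 3 - p1.shape[-1] if p1.shape[-1] < 3 else 0
    if pad:
        p1 = np.pad(p1, (0, pad))
    n = panel.normal_at(q[None, :])[0]
    out = p1 - 2.0 * np.dot(p1 - q, n) * n
    return out if not pad else out[: 3 - pad]


def reflect_endpoints(hits, endpoints, normals):
    """Vectorized mirror of ``endpoints`` across tangent planes at ``hits``."""
    d = np.einsum("ij,ij->i", endpoints - hits, normals)
    return endpoints - 2.0 * d[:, None] * normals


def jump(hit_point, panel: Panel, partner: Panel, residual=None):
    """Teleport a crossing point from ``panel`` to ``partner``.

    The rigid transform implemented is the translation between the panels'
    reference points, which covers the jump-surface uses in this package
    (periodic/toroidal boundaries and holes between congruent panels).  The
    remaining displacement of the step, if given, is continued from the mapped
    point.
    """
    hit_point = np.asarray(hit_point, dtype=float)
    shift = partner.ref_point() - panel.ref_point()
    mapped = hit_point + shift
    if residual is not None:
        mapped = mapped + np.asarray(residual, dtype=float)
    return mapped


def project_to_panel(p, panel: Panel):
    """Closest point on the panel (clamped into finite panels)."""
    p = np.atleast_2d(np.asarray(p, dtype=float))
    squeeze = p.shape[0] == 1
    if p.shape[1] < 3:
        p = np.pad(p, ((0, 0), (0, 3 - p.shape[1])))
    q = panel.project(p)
    return q[0] if squeeze else q


# ---------------------------------------------------------------------------
# surfaces and compartments
# ---------------------------------------------------------------------------

ACTIONS = ("reflect", "transmit", "absorb", "adsorb", "jump", "port")


@dataclass
class Emitter:
    pos: np.ndarray
    rate: float  # molecules / time


@dataclass
class Surface:
    """A named set of panels with per-(species, side) interaction rules.

    ``actions`` maps ``(species_name, side)`` with side in ``{'front','back'}``
    to one of :data:`ACTIONS`.  Rate coefficients:

    * ``adsorb_kappa[(species, side)]`` -- adsorption coefficient, length/time;
      adsorbed molecules enter ``adsorb_state[(species, side)]``;
    * ``desorb_rate[(species, state)]`` -- desorption rate, 1/time, with
      ``desorb_reversible`` flags;
    * ``permeability[(species, side)]`` -- permeability coefficient,
      length/time (action must be ``transmit`` to be partial; a plain
      ``transmit`` with no coefficient is fully transparent);
    * ``conversion[(species, from_state)] = [(to_state, rate), ...]``.
    """

    name: str
    panels: list = field(default_factory=list)
    actions: dict = field(default_factory=dict)
    adsorb_kappa: dict = field(default_factory=dict)
    adsorb_state: dict = field(default_factory=dict)
    desorb_rate: dict = field(default_factory=dict)
    desorb_reversible: dict = field(default_factory=dict)
    permeability: dict = field(default_factory=dict)
    conversion: dict = field(default_factory=dict)
    jump_partner: dict = field(default_factory=dict)  # panel name -> panel name
    emitters: dict = field(default_factory=dict)  # species -> list[Emitter]
    enabled: bool = True
    # derived at init_sim time:
    adsorb_prob: dict = field(default_factory=dict)
    perm_prob: dict = field(default_factory=dict)
    emit_absorb_prob: dict = field(default_factory=dict)  # species -> (n_panels,)
    port_ledger: dict = field(default_factory=dict)

    def action_for(self, species: str, side: str) -> str:
        if (species, side) in self.actions:
            return self.actions[(species, side)]
        if ("all", side) in self.actions:
            return self.actions[("all", side)]
        return "reflect"  # undeclared pairs default to reflection

    def clear_radius(self):
        """Radius of the largest panel-free ball around the panel centroid.

        Non-zero only for closed, roughly spherical surfaces; used to skip
        crossing tests for molecules that stay deep inside.
        """
        if not self.panels:
            return np.zeros(3), 0.0
        centers = np.array([p.bounding_sphere()[0] for p in self.panels])
        c = centers.mean(axis=0)
        r = math.inf
        for p in self.panels:
            q = p.project(c[None, :])[0]
            r = min(r, float(np.linalg.norm(q - c)))
        return c, max(r, 0.0)


@dataclass
class Compartment:
    """Region bounded by the panels of one or more surfaces.

    Membership is decided by ray-crossing parity against an interior
    reference point.
    """

    name: str
    surfaces: list  # list[Surface]
    interior_point: np.ndarray

    def __post_init__(self):
        self.interior_point = np.asarray(self.interior_point, dtype=float).copy()
        if self.interior_point.shape != (3,):
            p = np.zeros(3)
            p[: self.interior_point.size] = self.interior_point
            self.interior_point = p

    def panels(self):
        for s in self.surfaces:
            yield from s.panels

    def contains(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if points.shape[1] < 3:
            points = np.pad(points, ((0, 0), (0, 3 - points.shape[1])))
        # a fixed irrational-direction jitter keeps parity rays off panel
        # vertices and edges (degenerate hits are measure zero but common for
        # symmetric queries such as points on a mesh axis)
        jitter = 1e-6 * np.array([0.6180339887, 0.3819660113, 0.2360679775])
        ref = np.broadcast_to(self.interior_point + jitter,
                              points.shape).copy()
        crossings = np.zeros(len(points), dtype=int)
        for panel in self.panels():
            crossings += count_crossings(panel, points, ref)
        return (crossings % 2) == 0

    # membership for a single point
    def contains_point(self, p) -> bool:
        return bool(self.contains(np.asarray(p, dtype=float)[None, :])[0])


def count_crossings(panel: Panel, p0: np.ndarray, p1: np.ndarray, max_iter: int = 4):
    """Number of times each segment crosses the panel (0..max_iter).

    Plane-like panels cross at most once; quadrics at most twice.  Implemented
    by advancing the segment start just past each successive hit.
    """
    start = np.array(p0, dtype=float, copy=True)
    total = np.zeros(len(start), dtype=int)
    live = np.ones(len(start), dtype=bool)
    for _ in range(max_iter):
        frac, _ = panel.intersect(start[live], p1[live])
        hit = np.isfinite(frac)
        if not hit.any():
            break
        idx = np.flatnonzero(live)[hit]
        total[idx] += 1
        q = start[idx] + frac[hit][:, None] * (p1[idx] - start[idx])
        start[idx] = q + 1e-9 * (p1[idx] - q)
        newlive = np.zeros_like(live)
        newlive[idx] = True
        live = newlive
    return total


def in_compartment(p, c: Compartment) -> bool:
    """True iff the segment from ``p`` to the interior reference point crosses
    the compartment's bounding panels an even number of times."""
    return c.contains_point(p)


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------


def icosphere(center, radius, subdivisions: int = 1, name_prefix="ico"):
    """Triangulated sphere: subdivided icosahedron with outward front sides."""
    t = (1.0 + math.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
            [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
            [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = list(verts)
    for _ in range(subdivisions):
        cache = {}

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = verts[i] + verts[j]
                m /= np.linalg.norm(m)
                verts.append(m)
                cache[key] = len(verts) - 1
            return cache[key]

        new_faces = []
        for (i, j, k) in faces:
            a, b, c = midpoint(i, j), midpoint(j, k), midpoint(k, i)
            new_faces += [(i, a, c), (j, b, a), (k, c, b), (a, b, c)]
        faces = new_faces
    center = np.asarray(center, dtype=float)
    panels = []
    for idx, (i, j, k) in enumerate(faces):
        tri = center + radius * np.array([verts[i], verts[j], verts[k]])
        panel = Triangle(tri, name=f"{name_prefix}{idx}")
        # ensure the front side points outward
        if (panel._n @ (tri.mean(axis=0) - center)) < 0:
            panel = Triangle(tri[::-1], name=f"{name_prefix}{idx}")
        panels.append(panel)
    return panels


def read_triangle_mesh(path, name_prefix="tri"):
    """Plain triangle-list mesh: one triangle per line, 9 whitespace-separated
    floats (x1 y1 z1 x2 y2 z2 x3 y3 z3); ``#`` comments and blank lines
    allowed."""
    panels = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            vals = line.split()
            if len(vals) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 floats, got {len(vals)}")
            v = np.array([float(x) for x in vals]).reshape(3, 3)
            panels.append(Triangle(v, name=f"{name_prefix}{len(panels)}"))
    return panels


def write_triangle_mesh(path, panels):
    with open(path, "w") as fh:
        for p in panels:
            fh.write(" ".join(f"{x:.9g}" for x in np.asarray(p.verts).ravel()) + "\n")
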