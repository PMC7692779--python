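"""Knot identification for open 3D chains.

Pipeline: close the open curve far outside its convex bulk, simplify the
closed polygon with topology-preserving triangle moves, project onto a
generic plane, extract the signed over/under crossing code, and evaluate
the Alexander polynomial at t = -1 and t = -2 by exact integer
arithmetic.  The invariant pair separates the unknot and the (2, p) torus
knots 3_1, 5_1, 7_1, which is all the disentanglement chain ever visits.

The minimal knotted arc of a chain — the shortest subchain whose closure
still carries the reference knot type — is located by a shrinking search
from both ends, which is how the knot's chemical coordinates (kymograph
bounds) are measured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

__all__ = [
    "PolylineCurve",
    "Crossing",
    "CrossingDiagram",
    "KnotArc",
    "close_curve",
    "simplify_polygon",
    "project_crossings",
    "alexander_determinant",
    "invariant_pair",
    "classify",
    "minimal_knotted_arc",
    "contour_length",
    "INVARIANT_TABLE",
]

#: (|Delta(-1)|, odd part of |det at t=-2|) -> knot label.  For (2, p) torus
#: knots Delta(-1) = p and Delta(t) = sum_{j} (-t)^j over |j| <= (p-1)/2.
INVARIANT_TABLE: dict[tuple[int, int], str] = {
    (1, 1): "unknot",
    (3, 7): "3_1",
    (5, 31): "5_1",
    (7, 127): "7_1",
}


@dataclass
class PolylineCurve:
    """Ordered 3D polyline; ``closed`` curves wrap around without a
    duplicated terminal vertex."""

    vertices: np.ndarray      # (M, 3), sigma units
    closed: bool = False

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (M, 3)")
        d = np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)
        if np.any(d < 1e-12):
            raise ValueError("consecutive vertices must be distinct")
        if self.closed and np.linalg.norm(self.vertices[0] - self.vertices[-1]) < 1e-12:
            raise ValueError("closed curves must not duplicate the terminal vertex")

    def __len__(self) -> int:
        return len(self.vertices)


@dataclass(frozen=True)
class Crossing:
    """One transversal crossing of the projected diagram."""

    over_pos: float     # arclength-order key of the over passage
    under_pos: float
    sign: int           # +1 / -1 from the 2D orientation of (over, under)


@dataclass
class CrossingDiagram:
    """Signed crossing code of a projected closed curve."""

    crossings: list[Crossing]

    @property
    def n(self) -> int:
        return len(self.crossings)


@dataclass(frozen=True)
class KnotArc:
    """Inclusive 0-based bead bounds of a knotted arc."""

    start: int
    end: int

    @property
    def n_beads(self) -> int:
        return self.end - self.start + 1

    def length(self, sigma: float = 1.0) -> float:
        """Knot contour length in chemical-coordinate units.

        The particle model books contour length as bead count times the
        bead diameter (a chain of N beads has L = N sigma), so a knotted
        arc of n beads carries n sigma of contour.
        """
        return self.n_beads * sigma


def contour_length(vertices: np.ndarray, start: int = 0, end: Optional[int] = None) -> float:
    """Backbone contour length between two beads (inclusive), in sigma."""
    v = np.asarray(vertices, dtype=float)
    if end is None:
        end = len(v) - 1
    return float(np.linalg.norm(np.diff(v[start:end + 1], axis=0), axis=1).sum())


# --------------------------------------------------------------------------
# closure
# --------------------------------------------------------------------------

def close_curve(curve: PolylineCurve, arc_step: float = 0.45,
                rng: Optional[np.random.Generator] = None) -> PolylineCurve:
    """Close an open curve far outside its bulk.

    Both endpoints are extended radially outward from the chain centroid
    to a sphere of radius twice the maximal chain extent, then joined by a
    great-circle arc on that sphere.  Every added segment stays at radius
    >= 2 x extent while the chain lies within 1 x extent, so the closure
    cannot pierce the chain.
    """
    if curve.closed:
        return curve
    v = curve.vertices
    centroid = v.mean(axis=0)
    extent = float(np.linalg.norm(v - centroid, axis=1).max())
    if extent < 1e-9:
        raise ValueError("degenerate curve: zero extent")
    R = 2.0 * extent + 1.0

    def radial(point: np.ndarray) -> np.ndarray:
        d = point - centroid
        n = np.linalg.norm(d)
        if n < 1e-9:
            if rng is None:
                raise ValueError("endpoint at centroid; pass an rng to jitter")
            d = rng.standard_normal(3)
            n = np.linalg.norm(d)
        return centroid + d / n * R

    a = radial(v[-1])
    b = radial(v[0])
    ua = (a - centroid) / R
    ub = (b - centroid) / R
    dot = float(np.clip(ua @ ub, -1.0, 1.0))
    ang = math.acos(dot)
    # chords of the great-circle arc stay at radius >= R cos(step/2), far
    # outside the chain, so the angular step can be coarse
    n_arc = max(2, int(math.ceil(ang / arc_step)))
    if ang < 1e-9:
        arc_pts = [centroid + ua * R]
    elif abs(dot + 1.0) < 1e-9:
        # antipodal: pick any perpendicular to define the half great circle
        perp = np.cross(ua, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(ua, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        arc_pts = []
        for k in range(n_arc + 1):
            th = ang * k / n_arc
            arc_pts.append(centroid + R * (math.cos(th) * ua + math.sin(th) * perp))
    else:
        arc_pts = []
        for k in range(n_arc + 1):
            th = ang * k / n_arc
            w = (math.sin(ang - th) * ua + math.sin(th) * ub) / math.sin(ang)
            arc_pts.append(centroid + R * w)
    extra = np.array(arc_pts)
    allv = np.vstack([v, extra])
    # drop near-duplicate consecutive points
    keep = [0]
    for i in range(1, len(allv)):
        if np.linalg.norm(allv[i] - allv[keep[-1]]) > 1e-9:
            keep.append(i)
    allv = allv[keep]
    if np.linalg.norm(allv[0] - allv[-1]) < 1e-9:
        allv = allv[:-1]
    return PolylineCurve(allv, closed=True)


# --------------------------------------------------------------------------
# topology-preserving polygon simplification (triangle elimination)
# --------------------------------------------------------------------------

@njit(cache=True)
def _tri_seg_blocked(a, b, c, p, q) -> bool:
    """Does segment p-q intersect triangle a-b-c (conservative on degeneracy)?"""
    e1 = b - a
    e2 = c - a
    d = q - p
    h = np.cross(d, e2)
    det = e1[0] * h[0] + e1[1] * h[1] + e1[2] * h[2]
    scale = (abs(e1[0]) + abs(e1[1]) + abs(e1[2]) +
             abs(e2[0]) + abs(e2[1]) + abs(e2[2]) +
             abs(d[0]) + abs(d[1]) + abs(d[2]) + 1e-30)
    if abs(det) < 1e-12 * scale**3:
        nrm = np.cross(e1, e2)
        nn = math.sqrt(nrm[0]**2 + nrm[1]**2 + nrm[2]**2) + 1e-30
        dp = abs((p[0]-a[0])*nrm[0] + (p[1]-a[1])*nrm[1] + (p[2]-a[2])*nrm[2]) / nn
        dq = abs((q[0]-a[0])*nrm[0] + (q[1]-a[1])*nrm[1] + (q[2]-a[2])*nrm[2]) / nn
        if dp > 1e-9 and dq > 1e-9:
            return False
        return True   # coplanar or touching: be conservative, keep vertex
    f = 1.0 / det
    s = p - a
    u = f * (s[0] * h[0] + s[1] * h[1] + s[2] * h[2])
    if u < -1e-12 or u > 1.0 + 1e-12:
        return False
    qv = np.cross(s, e1)
    v = f * (d[0] * qv[0] + d[1] * qv[1] + d[2] * qv[2])
    if v < -1e-12 or u + v > 1.0 + 1e-12:
        return False
    tt = f * (e2[0] * qv[0] + e2[1] * qv[1] + e2[2] * qv[2])
    if tt < -1e-12 or tt > 1.0 + 1e-12:
        return False
    return True


@njit(cache=True)
def _kmt_pass(r, alive, nxt, prv):
    """One sweep of triangle eliminations; returns number removed."""
    M = r.shape[0]
    removed = 0
    i = 0
    count = 0
    for idx in range(M):
        if not alive[idx]:
            continue
        count += 1
    for i in range(M):
        if not alive[i] or count <= 3:
            continue
        a = prv[i]
        c = nxt[i]
        # a degenerate (collinear) elimination triangle is always safe
        e1 = r[i] - r[a]
        e2 = r[c] - r[a]
        ar = np.cross(e1, e2)
        area2 = ar[0]**2 + ar[1]**2 + ar[2]**2
        sc = e1[0]**2 + e1[1]**2 + e1[2]**2 + e2[0]**2 + e2[1]**2 + e2[2]**2
        if area2 < 1e-16 * sc * sc:
            alive[i] = False
            nxt[a] = c
            prv[c] = a
            removed += 1
            count -= 1
            continue
        blocked = False
        j = nxt[c]
        while j != a:
            j2 = nxt[j]
            if j != i and j2 != i and j != a and j != c and j2 != a and j2 != c:
                if _tri_seg_blocked(r[a], r[i], r[c], r[j], r[j2]):
                    blocked = True
                    break
            j = j2
        if not blocked:
            alive[i] = False
            nxt[a] = c
            prv[c] = a
            removed += 1
            count -= 1
    return removed


def simplify_polygon(curve: PolylineCurve, max_passes: int = 100) -> PolylineCurve:
    """Reduce a closed polygon by removing vertices whose elimination
    triangle is uncrossed (knot type preserved)."""
    if not curve.closed:
        raise ValueError("simplify_polygon expects a closed curve")
    r = np.ascontiguousarray(curve.vertices)
    M = len(r)
    alive = np.ones(M, dtype=np.bool_)
    nxt = np.roll(np.arange(M), -1)
    prv = np.roll(np.arange(M), 1)
    for _ in range(max_passes):
        if _kmt_pass(r, alive, nxt, prv) == 0:
            break
    return PolylineCurve(r[alive], closed=True)


# --------------------------------------------------------------------------
# projection and crossing code
# --------------------------------------------------------------------------

class ProjectionDegeneracyError(RuntimeError):
    pass


def _basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2, d


def project_crossings(curve: PolylineCurve, direction: Sequence[float],
                      tol: float = 1e-9) -> CrossingDiagram:
    """Crossing code of a closed curve viewed along ``direction``.

    Raises :class:`ProjectionDegeneracyError` for non-generic views
    (near-parallel overlaps, endpoint hits, ambiguous depth); callers
    perturb the direction and retry.
    """
    if not curve.closed:
        raise ValueError("project_crossings expects a closed curve")
    e1, e2, d = _basis(np.asarray(direction, dtype=float))
    v = curve.vertices
    M = len(v)
    P = np.column_stack([v @ e1, v @ e2])
    depth = v @ d
    crossings: list[Crossing] = []
    for i in range(M):
        i2 = (i + 1) % M
        pi, pj = P[i], P[i2]
        for j in range(i + 1, M):
            j2 = (j + 1) % M
            if j == i or j2 == i or j == i2:
                continue
            qi, qj = P[j], P[j2]
            r1 = pj - pi
            r2 = qj - qi
            den = r1[0] * r2[1] - r1[1] * r2[0]
            diff = qi - pi
            if abs(den) < tol * (np.abs(r1).sum() * np.abs(r2).sum() + 1e-30):
                # parallel in projection: degenerate only if they overlap
                cross_off = diff[0] * r1[1] - diff[1] * r1[0]
                if abs(cross_off) < tol * (np.abs(r1).sum()**2 + 1e-30):
                    raise ProjectionDegeneracyError("collinear overlap in projection")
                continue
            s = (diff[0] * r2[1] - diff[1] * r2[0]) / den
            u = (diff[0] * r1[1] - diff[1] * r1[0]) / den
            if -tol < s < tol or 1 - tol < s < 1 + tol or \
               -tol < u < tol or 1 - tol < u < 1 + tol:
                if -tol < s < 1 + tol and -tol < u < 1 + tol:
                    raise ProjectionDegeneracyError("crossing at a projected vertex")
                continue
            if not (0 < s < 1 and 0 < u < 1):
                continue
            z1 = depth[i] + s * (depth[i2] - depth[i])
            z2 = depth[j] + u * (depth[j2] - depth[j])
            if abs(z1 - z2) < 1e-9:
                raise ProjectionDegeneracyError("ambiguous depth at crossing")
            # viewer looks along -direction from +infinity: larger depth is over
            first_over = z1 > z2
            over_dir, under_dir = (r1, r2) if first_over else (r2, r1)
            sgn = 1 if over_dir[0] * under_dir[1] - over_dir[1] * under_dir[0] > 0 else -1
            pos_i, pos_j = i + s, j + u
            over_pos, under_pos = (pos_i, pos_j) if first_over else (pos_j, pos_i)
            crossings.append(Crossing(over_pos, under_pos, sgn))
    return CrossingDiagram(crossings)


# --------------------------------------------------------------------------
# Alexander invariant
# --------------------------------------------------------------------------

def _bareiss_det(m: list[list[int]]) -> int:
    """Exact integer determinant (fraction-free Gaussian elimination)."""
    n = len(m)
    if n == 0:
        return 1
    m = [row[:] for row in m]
    sign = 1
    prev = 1
    for k in range(n - 1):
        if m[k][k] == 0:
            for r in range(k + 1, n):
                if m[r][k] != 0:
                    m[k], m[r] = m[r], m[k]
                    sign = -sign
                    break
            else:
                return 0
        for i in range(k + 1, n):
            for j in range(k + 1, n):
                m[i][j] = (m[i][j] * m[k][k] - m[i][k] * m[k][j]) // prev
        prev = m[k][k]
    return sign * m[n - 1][n - 1]


def _diagram_arcs(diag: CrossingDiagram):
    """Arc incidence of the diagram: for each crossing, the over arc and the
    incoming/outgoing under arcs, with arcs delimited by under-passages."""
    events = []
    for cid, c in enumerate(diag.crossings):
        events.append((c.under_pos, cid, False))
        events.append((c.over_pos, cid, True))
    events.sort()
    # arcs are numbered by traversal order; arc k ends at the k-th
    # under-passage event
    under_order = [cid for pos, cid, over in events if not over]
    n = diag.n
    arc_of_under_in = {}
    arc_of_under_out = {}
    for k, cid in enumerate(under_order):
        arc_of_under_in[cid] = k
        arc_of_under_out[cid] = (k + 1) % n
    # over event at position p lies on the arc that is active there
    under_positions = sorted(c.under_pos for c in diag.crossings)
    arc_of_over = {}
    for cid, c in enumerate(diag.crossings):
        k = int(np.searchsorted(under_positions, c.over_pos))
        # arc index: arc (k mod n) is the one beginning after the k-th
        # under event (arc 0 starts after the last/0th boundary)
        arc_of_over[cid] = k % n
    return arc_of_over, arc_of_under_in, arc_of_under_out


def alexander_determinant(diag: CrossingDiagram, t_eval: int = -1) -> int:
    """|det| of the Alexander matrix (one row/column deleted) at ``t_eval``.

    Exact integer arithmetic.  At t = -1 the value is the knot determinant
    itself; at other integer arguments it equals |t^k Delta(t)| for some
    power k, so callers normalise (e.g. take the odd part at t = -2).
    A 0-crossing diagram returns 1.
    """
    n = diag.n
    if n == 0:
        return 1
    arc_over, arc_in, arc_out = _diagram_arcs(diag)
    t = int(t_eval)
    mat = [[0] * n for _ in range(n)]
    for cid, c in enumerate(diag.crossings):
        o, ain, aout = arc_over[cid], arc_in[cid], arc_out[cid]
        if c.sign > 0:
            mat[cid][ain] += -t
            mat[cid][aout] += 1
            mat[cid][o] += t - 1
        else:
            mat[cid][ain] += -1
            mat[cid][aout] += t
            mat[cid][o] += 1 - t
    minor = [row[:-1] for row in mat[:-1]]
    return abs(_bareiss_det(minor))


def _odd_part(v: int) -> int:
    if v == 0:
        return 0
    while v % 2 == 0:
        v //= 2
    return v


def invariant_pair(curve: PolylineCurve, direction: Sequence[float],
                   max_retries: int = 20,
                   rng: Optional[np.random.Generator] = None) -> tuple[int, int]:
    """(|Delta(-1)|, odd part of |det(-2)|) for one (retried) projection."""
    rng = rng or np.random.default_rng(0)
    d = np.asarray(direction, dtype=float)
    for attempt in range(max_retries):
        try:
            diag = project_crossings(curve, d)
            return alexander_determinant(diag, -1), _odd_part(alexander_determinant(diag, -2))
        except ProjectionDegeneracyError:
            d = d + 1e-4 * (attempt + 1) * rng.standard_normal(3)
    raise ProjectionDegeneracyError("no generic projection found after retries")


_DEFAULT_DIRECTIONS = np.array([
    [0.276, 0.583, 0.764],
    [0.811, -0.332, 0.481],
    [-0.402, 0.718, -0.568],
])


def classify(curve: PolylineCurve, n_directions: int = 3,
             seed: int = 0, simplify: bool = True) -> str:
    """Knot label of a closed curve by majority vote over projections.

    Returns "unknot", "3_1", "5_1", "7_1", "other" (consistent but
    unregistered invariants) or "unresolved" (conflicting votes).
    """
    if not curve.closed:
        raise ValueError("classify expects a closed curve; use close_curve first")
    if simplify:
        curve = simplify_polygon(curve)
    rng = np.random.default_rng(seed)
    votes: list[str] = []
    for k in range(n_directions):
        if k < len(_DEFAULT_DIRECTIONS):
            d = _DEFAULT_DIRECTIONS[k]
        else:
            d = rng.standard_normal(3)
        pair = invariant_pair(curve, d, rng=rng)
        votes.append(INVARIANT_TABLE.get(pair, "other"))
    best = max(set(votes), key=votes.count)
    if votes.count(best) * 2 > len(votes):
        return best
    return "unresolved"


# --------------------------------------------------------------------------
# minimal knotted arc
# --------------------------------------------------------------------------

def _arc_is_knotted(vertices: np.ndarray, s: int, e: int, label: str,
                    seed: int) -> bool:
    if e - s < 3:
        return False
    sub = PolylineCurve(vertices[s:e + 1])
    closed = close_curve(sub)
    return classify(closed, seed=seed) == label


def _window_scan(v: np.ndarray, s_range, e_range, reference: str,
                 seed: int) -> Optional[KnotArc]:
    """Shortest knotted subarc with bounds inside the given index windows."""
    best: Optional[tuple[float, int, int]] = None
    N = len(v)
    for s in s_range:
        if s < 0:
            continue
        for e in e_range:
            if e >= N or e - s < 3:
                continue
            L = contour_length(v, s, e)
            if best is not None and L >= best[0]:
                continue
            if _arc_is_knotted(v, s, e, reference, seed):
                best = (L, s, e)
                break   # larger e only lengthens the arc for this s
    return KnotArc(best[1], best[2]) if best else None


def minimal_knotted_arc(
    chain: PolylineCurve | np.ndarray,
    reference: str,
    seed: int = 0,
    exhaustive: bool = False,
    hint: Optional[KnotArc] = None,
    hint_pad: int = 4,
    pad: int = 8,
) -> Optional[KnotArc]:
    """Shortest subchain whose closure still carries ``reference``.

    Default search: the knot core is bracketed from both ends (largest
    start keeping the full-tail arc knotted, smallest end likewise, each
    by bisection — the one-sided property is monotone for a localized
    knot), then every subarc within ``pad`` beads of the bracket is
    checked and the shortest knotted one returned.  ``hint`` (e.g. the
    previous trajectory frame's arc) restricts the scan to a ``hint_pad``
    neighbourhood first, which makes kymograph extraction cheap.
    ``exhaustive`` checks every subarc of the whole chain (validation
    mode, O(N^2) closures).  Returns None when no subarc carries the
    label.
    """
    v = chain.vertices if isinstance(chain, PolylineCurve) else np.asarray(chain, float)
    N = len(v)
    if exhaustive:
        best = None
        for s in range(N):
            for e in range(s + 3, N):
                if best is not None and contour_length(v, s, e) >= best[0]:
                    continue
                if _arc_is_knotted(v, s, e, reference, seed):
                    best = (contour_length(v, s, e), s, e)
        return KnotArc(best[1], best[2]) if best else None
    if hint is not None:
        found = _window_scan(
            v, range(hint.start - hint_pad, hint.start + hint_pad + 1),
            range(max(hint.end - hint_pad, 0), hint.end + hint_pad + 1),
            reference, seed)
        if found is not None:
            return found
    if not _arc_is_knotted(v, 0, N - 1, reference, seed):
        return None

    # outer bracket: largest s with (s, N-1) knotted, smallest e with (0, e)
    lo, hi = 0, N - 4
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if _arc_is_knotted(v, mid, N - 1, reference, seed):
            lo = mid
        else:
            hi = mid - 1
    s_out = lo
    lo, hi = 3, N - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if _arc_is_knotted(v, 0, mid, reference, seed):
            hi = mid
        else:
            lo = mid + 1
    e_out = hi

    for p in (pad, 2 * pad):
        found = _window_scan(v, range(s_out - p, s_out + p + 1),
                             range(max(e_out - p, 0), e_out + p + 1),
                             reference, seed)
        if found is not None:
            return found
    # bracket disagrees with any joint arc (rare, fluctuating closure):
    # report the bracket itself as the best available localization
    return KnotArc(max(s_out - 1, 0), min(e_out + 1, N - 1))
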