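"""Low-level numerical kernels (numba-compiled).

All kernels operate on raw arrays in the global fibril frame
(axis 0 = W, axis 1 = T, axis 2 = L).  A box is given by its centroid
``c`` (3,), rotation matrix ``R`` (3,3) whose *columns* are the box local
axes expressed in the global frame, and half-dimensions ``h`` (3,).

Corner ordering convention (used everywhere a vertex array appears):
corner ``k`` (0..7) has local coordinates ``(sx*h0, sy*h1, sz*h2)`` with
``sx = -1 if (k>>2)&1 == 0 else +1`` and likewise ``sy`` from bit 1 and
``sz`` from bit 0.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Maximum faces / vertices-per-face of a box clipped by another box.
_MAXF = 16
_MAXV = 24


@njit(cache=True)
def box_vertices(c, R, h):
    """Return the 8 corners of an oriented box, fixed corner order."""
    out = np.empty((8, 3))
    for k in range(8):
        sx = -1.0 if (k >> 2) & 1 == 0 else 1.0
        sy = -1.0 if (k >> 1) & 1 == 0 else 1.0
        sz = -1.0 if k & 1 == 0 else 1.0
        for r in range(3):
            out[k, r] = (
                c[r]
                + R[r, 0] * sx * h[0]
                + R[r, 1] * sy * h[1]
                + R[r, 2] * sz * h[2]
            )
    return out


@njit(cache=True)
def box_aabb(c, R, h):
    """Axis-aligned bounds (lo[3], hi[3]) of an oriented box."""
    lo = np.empty(3)
    hi = np.empty(3)
    for r in range(3):
        e = abs(R[r, 0]) * h[0] + abs(R[r, 1]) * h[1] + abs(R[r, 2]) * h[2]
        lo[r] = c[r] - e
        hi[r] = c[r] + e
    return lo, hi


@njit(cache=True)
def all_aabbs(centroids, orients, half_dims):
    n = centroids.shape[0]
    out = np.empty((n, 2, 3))
    for i in range(n):
        lo, hi = box_aabb(centroids[i], orients[i], half_dims[i])
        out[i, 0] = lo
        out[i, 1] = hi
    return out


@njit(cache=True)
def sat_separated(c1, R1, h1, c2, R2, h2):
    """True iff a strictly separating axis exists (touching => False).

    Standard 15-axis oriented-bounding-box test; cross-product axes with
    near-zero norm (parallel edges) are skipped.
    """
    # A[i,j] = dot(axis1_i, axis2_j); T = c2-c1 in box1 frame
    A = np.empty((3, 3))
    absA = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            s = 0.0
            for r in range(3):
                s += R1[r, i] * R2[r, j]
            A[i, j] = s
            absA[i, j] = abs(s) + 1e-12
    T = np.empty(3)
    for i in range(3):
        s = 0.0
        for r in range(3):
            s += R1[r, i] * (c2[r] - c1[r])
        T[i] = s
    # box1 face axes
    for i in range(3):
        ra = h1[i]
        rb = h2[0] * absA[i, 0] + h2[1] * absA[i, 1] + h2[2] * absA[i, 2]
        if abs(T[i]) > ra + rb:
            return True
    # box2 face axes
    for j in range(3):
        ra = h1[0] * absA[0, j] + h1[1] * absA[1, j] + h1[2] * absA[2, j]
        rb = h2[j]
        t = T[0] * A[0, j] + T[1] * A[1, j] + T[2] * A[2, j]
        if abs(t) > ra + rb:
            return True
    # edge-edge cross axes a1_i x a2_j
    for i in range(3):
        i1 = (i + 1) % 3
        i2 = (i + 2) % 3
        for j in range(3):
            j1 = (j + 1) % 3
            j2 = (j + 2) % 3
            # norm^2 of cross product = 1 - A[i,j]^2 (unit axes)
            if 1.0 - A[i, j] * A[i, j] < 1e-12:
                continue
            ra = h1[i1] * absA[i2, j] + h1[i2] * absA[i1, j]
            rb = h2[j1] * absA[i, j2] + h2[j2] * absA[i, j1]
            t = T[i2] * A[i1, j] - T[i1] * A[i2, j]
            if abs(t) > ra + rb:
                return True
    return False


@njit(cache=True)
def penetration_depth_kernel(c1, R1, h1, c2, R2, h2):
    """Penetration depth of two oriented boxes (0 when disjoint/touching).

    Minimum translation distance estimated as the smallest overlap
    extent over the 15 candidate separating axes (face normals of both
    boxes and normalized edge-edge cross products); exact for face
    contacts, the standard tight estimate otherwise.
    """
    A = np.empty((3, 3))
    absA = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            s = 0.0
            for r in range(3):
                s += R1[r, i] * R2[r, j]
            A[i, j] = s
            absA[i, j] = abs(s) + 1e-12
    T = np.empty(3)
    for i in range(3):
        s = 0.0
        for r in range(3):
            s += R1[r, i] * (c2[r] - c1[r])
        T[i] = s
    depth = 1e300
    for i in range(3):
        ra = h1[i]
        rb = h2[0] * absA[i, 0] + h2[1] * absA[i, 1] + h2[2] * absA[i, 2]
        ov = ra + rb - abs(T[i])
        if ov <= 0.0:
            return 0.0
        if ov < depth:
            depth = ov
    for j in range(3):
        ra = h1[0] * absA[0, j] + h1[1] * absA[1, j] + h1[2] * absA[2, j]
        rb = h2[j]
        t = T[0] * A[0, j] + T[1] * A[1, j] + T[2] * A[2, j]
        ov = ra + rb - abs(t)
        if ov <= 0.0:
            return 0.0
        if ov < depth:
            depth = ov
    for i in range(3):
        i1 = (i + 1) % 3
        i2 = (i + 2) % 3
        for j in range(3):
            norm2 = 1.0 - A[i, j] * A[i, j]
            if norm2 < 1e-12:
                continue
            norm = np.sqrt(norm2)
            j1 = (j + 1) % 3
            j2 = (j + 2) % 3
            ra = h1[i1] * absA[i2, j] + h1[i2] * absA[i1, j]
            rb = h2[j1] * absA[i, j2] + h2[j2] * absA[i, j1]
            t = T[i2] * A[i1, j] - T[i1] * A[i2, j]
            ov = (ra + rb - abs(t)) / norm
            if ov <= 0.0:
                return 0.0
            if ov < depth:
                depth = ov
    return depth


@njit(cache=True)
def _project_box(p, c, R, h):
    """Closest point of the (closed) box to p."""
    out = np.empty(3)
    u = np.empty(3)
    for i in range(3):
        s = 0.0
        for r in range(3):
            s += R[r, i] * (p[r] - c[r])
        if s > h[i]:
            s = h[i]
        elif s < -h[i]:
            s = -h[i]
        u[i] = s
    for r in range(3):
        out[r] = c[r] + R[r, 0] * u[0] + R[r, 1] * u[1] + R[r, 2] * u[2]
    return out


@njit(cache=True)
def min_distance_kernel(c1, R1, h1, c2, R2, h2):
    """Minimum Euclidean distance between two oriented boxes.

    Alternating nearest-point projection between the two convex sets
    (globally convergent for convex bodies), multi-started from the
    centre and the 8 corners of the first box.  Returns 0 for touching
    or interpenetrating boxes.
    """
    if not sat_separated(c1, R1, h1, c2, R2, h2):
        return 0.0
    starts = np.empty((9, 3))
    starts[0] = c1
    verts = box_vertices(c1, R1, h1)
    for k in range(8):
        starts[k + 1] = verts[k]
    best = 1e300
    for s in range(9):
        p = starts[s].copy()
        d_prev = 1e300
        for _ in range(600):
            q = _project_box(p, c2, R2, h2)
            p = _project_box(q, c1, R1, h1)
            dx = p[0] - q[0]
            dy = p[1] - q[1]
            dz = p[2] - q[2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if d_prev - d < 1e-13:
                d_prev = d
                break
            d_prev = d
        if d_prev < best:
            best = d_prev
        if best < 1e-12:
            return 0.0
    return best


@njit(cache=True)
def overlap_volume_kernel(c1, R1, h1, c2, R2, h2):
    """Intersection volume of two oriented boxes by half-space clipping.

    Box 2 is expressed in box 1's local frame and clipped successively by
    the 6 slab planes of box 1; the running convex polytope is kept as a
    list of outward-wound polygon faces and each clip adds a cap face.
    Volume via the divergence theorem.  Degenerate slivers return 0.
    """
    if sat_separated(c1, R1, h1, c2, R2, h2):
        return 0.0
    # box2 in box1 frame
    t = np.empty(3)
    M = np.empty((3, 3))
    for i in range(3):
        s = 0.0
        for r in range(3):
            s += R1[r, i] * (c2[r] - c1[r])
        t[i] = s
        for j in range(3):
            s = 0.0
            for r in range(3):
                s += R1[r, i] * R2[r, j]
            M[i, j] = s
    verts = box_vertices(t, M, h2)

    faces = np.zeros((_MAXF, _MAXV, 3))
    nv = np.zeros(_MAXF, dtype=np.int64)
    # outward-wound quads of a box in the fixed corner order
    idx = np.array(
        [
            [4, 6, 7, 5],  # +x
            [0, 1, 3, 2],  # -x
            [2, 3, 7, 6],  # +y
            [0, 4, 5, 1],  # -y
            [1, 5, 7, 3],  # +z
            [0, 2, 6, 4],  # -z
        ],
        dtype=np.int64,
    )
    for f in range(6):
        for v in range(4):
            faces[f, v] = verts[idx[f, v]]
        nv[f] = 4
    nf = 6

    scale = max(h1[0], max(h1[1], h1[2])) + max(h2[0], max(h2[1], h2[2]))
    eps = 1e-12 * scale

    newfaces = np.zeros((_MAXF, _MAXV, 3))
    newnv = np.zeros(_MAXF, dtype=np.int64)
    cap = np.zeros((4 * _MAXV, 3))

    for axis in range(3):
        for side in range(2):
            sign = 1.0 if side == 0 else -1.0
            off = h1[axis]
            # keep sign*x[axis] <= off
            nnf = 0
            ncap = 0
            for f in range(nf):
                m = nv[f]
                if m < 3:
                    continue
                cnt = 0
                for v in range(m):
                    w = (v + 1) % m
                    pv = faces[f, v]
                    pw = faces[f, w]
                    dv = sign * pv[axis] - off
                    dw = sign * pw[axis] - off
                    if dv <= eps:
                        if cnt < _MAXV:
                            newfaces[nnf, cnt] = pv
                            cnt += 1
                    if (dv > eps and dw < -eps) or (dv < -eps and dw > eps):
                        s = dv / (dv - dw)
                        if cnt < _MAXV:
                            for r in range(3):
                                newfaces[nnf, cnt, r] = pv[r] + s * (
                                    pw[r] - pv[r]
                                )
                            if ncap < 4 * _MAXV:
                                cap[ncap] = newfaces[nnf, cnt]
                                ncap += 1
                            cnt += 1
                if cnt >= 3:
                    newnv[nnf] = cnt
                    nnf += 1
            # cap polygon: convex, sort by angle around its centroid in
            # the clip plane; wind so its normal is the outward +sign*axis
            if ncap >= 3 and nnf < _MAXF:
                mx = 0.0
                my = 0.0
                a1 = (axis + 1) % 3
                a2 = (axis + 2) % 3
                for k in range(ncap):
                    mx += cap[k, a1]
                    my += cap[k, a2]
                mx /= ncap
                my /= ncap
                ang = np.empty(ncap)
                for k in range(ncap):
                    ang[k] = np.arctan2(cap[k, a2] - my, cap[k, a1] - mx)
                order = np.argsort(ang)
                cnt = 0
                for k in range(min(ncap, _MAXV)):
                    newfaces[nnf, cnt] = cap[order[k]]
                    cnt += 1
                # (e_{a1}, e_{a2}, e_axis) is right-handed, so increasing
                # angle in (a1, a2) winds about +axis; flip for -axis side.
                if sign < 0.0:
                    for k in range(cnt // 2):
                        tmp = newfaces[nnf, k].copy()
                        newfaces[nnf, k] = newfaces[nnf, cnt - 1 - k]
                        newfaces[nnf, cnt - 1 - k] = tmp
                newnv[nnf] = cnt
                nnf += 1
            nf = nnf
            for f in range(nf):
                nv[f] = newnv[f]
                for v in range(nv[f]):
                    faces[f, v] = newfaces[f, v]
            if nf == 0:
                return 0.0

    vol = 0.0
    for f in range(nf):
        m = nv[f]
        v0 = faces[f, 0]
        for v in range(1, m - 1):
            v1 = faces[f, v]
            v2 = faces[f, v + 1]
            cx = v1[1] * v2[2] - v1[2] * v2[1]
            cy = v1[2] * v2[0] - v1[0] * v2[2]
            cz = v1[0] * v2[1] - v1[1] * v2[0]
            vol += v0[0] * cx + v0[1] * cy + v0[2] * cz
    vol /= 6.0
    if vol < 1e-12:
        return 0.0
    return vol


@njit(cache=True)
def inside_cylinder_kernel(c, R, h, radius, l_lo, l_hi):
    """All 8 box corners inside the closed cylinder (radius, [l_lo, l_hi])."""
    eps = 1e-9 * max(1.0, radius)
    verts = box_vertices(c, R, h)
    r2 = (radius + eps) * (radius + eps)
    for k in range(8):
        if verts[k, 0] ** 2 + verts[k, 1] ** 2 > r2:
            return False
        if verts[k, 2] < l_lo - eps or verts[k, 2] > l_hi + eps:
            return False
    return True


@njit(cache=True)
def _gram_schmidt(R):
    out = np.empty((3, 3))
    n0 = np.sqrt(R[0, 0] ** 2 + R[1, 0] ** 2 + R[2, 0] ** 2)
    for r in range(3):
        out[r, 0] = R[r, 0] / n0
    d = out[0, 0] * R[0, 1] + out[1, 0] * R[1, 1] + out[2, 0] * R[2, 1]
    v1 = np.empty(3)
    for r in range(3):
        v1[r] = R[r, 1] - d * out[r, 0]
    n1 = np.sqrt(v1[0] ** 2 + v1[1] ** 2 + v1[2] ** 2)
    for r in range(3):
        out[r, 1] = v1[r] / n1
    out[0, 2] = out[1, 0] * out[2, 1] - out[2, 0] * out[1, 1]
    out[1, 2] = out[2, 0] * out[0, 1] - out[0, 0] * out[2, 1]
    out[2, 2] = out[0, 0] * out[1, 1] - out[1, 0] * out[0, 1]
    return out


@njit(cache=True)
def compose_rotation(R, aw, at, al):
    """Apply world-frame rotations about W, T, L (in that order) to R."""
    cw = np.cos(aw)
    sw = np.sin(aw)
    ct = np.cos(at)
    st = np.sin(at)
    cl = np.cos(al)
    sl = np.sin(al)
    # Rl @ Rt @ Rw
    P = np.empty((3, 3))
    P[0, 0] = cl * ct
    P[0, 1] = cl * st * sw - sl * cw
    P[0, 2] = cl * st * cw + sl * sw
    P[1, 0] = sl * ct
    P[1, 1] = sl * st * sw + cl * cw
    P[1, 2] = sl * st * cw - cl * sw
    P[2, 0] = -st
    P[2, 1] = ct * sw
    P[2, 2] = ct * cw
    out = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            s = 0.0
            for r in range(3):
                s += P[i, r] * R[r, j]
            out[i, j] = s
    return out


@njit(cache=True)
def rotation_from_angles(aw, at, al):
    """Rotation matrix R = R_L(al) @ R_T(at) @ R_W(aw) (world axes)."""
    return compose_rotation(np.eye(3), aw, at, al)


@njit(cache=True)
def candidate_acceptable(
    i,
    cand_c,
    cand_R,
    centroids,
    orients,
    half_dims,
    volumes,
    min_dims,
    aabbs,
    radius_tol,
    l_lo,
    l_hi,
    max_overlap_frac,
    max_depth_frac,
    min_cos_incl,
):
    """Legality of a trial pose for platelet i against all others.

    Checks (in order): inclination cap, tolerance-cylinder containment,
    and the pairwise interpenetration bounds against AABB-prescreened
    neighbours: penetration depth at most max_depth_frac of the smaller
    platelet's thinnest dimension (shallow surface fusion) and overlap
    volume at most max_overlap_frac of the smaller platelet volume.
    Negative max_depth_frac disables the depth bound; min_cos_incl < 0
    disables the inclination cap.
    """
    h = half_dims[i]
    if min_cos_incl >= 0.0 and abs(cand_R[2, 2]) < min_cos_incl:
        return False
    if not inside_cylinder_kernel(cand_c, cand_R, h, radius_tol, l_lo, l_hi):
        return False
    lo, hi = box_aabb(cand_c, cand_R, h)
    n = centroids.shape[0]
    for j in range(n):
        if j == i:
            continue
        if (
            lo[0] > aabbs[j, 1, 0]
            or hi[0] < aabbs[j, 0, 0]
            or lo[1] > aabbs[j, 1, 1]
            or hi[1] < aabbs[j, 0, 1]
            or lo[2] > aabbs[j, 1, 2]
            or hi[2] < aabbs[j, 0, 2]
        ):
            continue
        if max_depth_frac >= 0.0:
            depth = penetration_depth_kernel(
                cand_c, cand_R, h, centroids[j], orients[j], half_dims[j]
            )
            if depth > max_depth_frac * min(min_dims[i], min_dims[j]) + 1e-12:
                return False
            if depth == 0.0:
                continue
        vol = overlap_volume_kernel(
            cand_c, cand_R, h, centroids[j], orients[j], half_dims[j]
        )
        if vol > max_overlap_frac * min(volumes[i], volumes[j]) + 1e-12:
            return False
    return True


@njit(cache=True)
def run_cycle_kernel(
    centroids,
    orients,
    angles,
    half_dims,
    volumes,
    min_dims,
    aabbs,
    trans,
    dangles,
    mh_uniforms,
    angle_cap,
    texture_sigma,
    radius_tol,
    l_lo,
    l_hi,
    max_overlap_frac,
    max_depth_frac,
    min_cos_incl,
):
    """One Monte Carlo cycle: every platelet attempted once, in index order.

    Orientation state is the bounded world-axis angle triple ``angles``
    (n,3); a trial adds the Gaussian step ``dangles[i]`` and is rejected
    outright if any resulting angle leaves [-angle_cap, angle_cap]
    (negative angle_cap disables the bound).  With texture_sigma > 0 the
    stationary orientation measure carries the Gaussian c-axis texture
    prior exp(-sum a^2 / (2 sigma^2)): the angle step is accepted with
    the Metropolis-Hastings probability min(1, prior_cand/prior_cur)
    using the pre-drawn uniform mh_uniforms[i].  The rotation matrix is
    rebuilt from the angles, so orientations stay exactly orthonormal.
    trans (n,3) carries the uniform translation steps.  Arrays are
    updated in place for accepted moves; returns the accepted count.
    """
    n = centroids.shape[0]
    accepted = 0
    for i in range(n):
        a0 = angles[i, 0] + dangles[i, 0]
        a1 = angles[i, 1] + dangles[i, 1]
        a2 = angles[i, 2] + dangles[i, 2]
        if angle_cap >= 0.0 and (
            abs(a0) > angle_cap or abs(a1) > angle_cap or abs(a2) > angle_cap
        ):
            continue
        if texture_sigma > 0.0:
            cur = (
                angles[i, 0] ** 2 + angles[i, 1] ** 2 + angles[i, 2] ** 2
            )
            cand = a0 * a0 + a1 * a1 + a2 * a2
            if cand > cur:
                w = np.exp(-(cand - cur) / (2.0 * texture_sigma**2))
                if mh_uniforms[i] > w:
                    continue
        cand_c = centroids[i] + trans[i]
        cand_R = rotation_from_angles(a0, a1, a2)
        if candidate_acceptable(
            i,
            cand_c,
            cand_R,
            centroids,
            orients,
            half_dims,
            volumes,
            min_dims,
            aabbs,
            radius_tol,
            l_lo,
            l_hi,
            max_overlap_frac,
            max_depth_frac,
            min_cos_incl,
        ):
            centroids[i] = cand_c
            orients[i] = cand_R
            angles[i, 0] = a0
            angles[i, 1] = a1
            angles[i, 2] = a2
            lo, hi = box_aabb(cand_c, cand_R, half_dims[i])
            aabbs[i, 0] = lo
            aabbs[i, 1] = hi
            accepted += 1
    return accepted


@njit(cache=True)
def pair_table_kernel(centroids, orients, half_dims, aabbs, reach):
    """Distances for all pairs whose AABB gap is within reach on every axis.

    Returns (i, j, d, vol) arrays: d is the exact minimum box distance,
    vol the interpenetration volume (0 when disjoint or merely touching).
    Conservative prescreen: a pair at true distance <= reach always has
    per-axis AABB gaps <= reach, so no qualifying pair is lost.
    """
    n = centroids.shape[0]
    maxp = n * (n - 1) // 2
    ii = np.empty(maxp, dtype=np.int64)
    jj = np.empty(maxp, dtype=np.int64)
    dd = np.empty(maxp)
    vv = np.empty(maxp)
    cnt = 0
    for i in range(n):
        for j in range(i + 1, n):
            ok = True
            for r in range(3):
                gap = max(
                    aabbs[i, 0, r] - aabbs[j, 1, r],
                    aabbs[j, 0, r] - aabbs[i, 1, r],
                )
                if gap > reach:
                    ok = False
                    break
            if not ok:
                continue
            if sat_separated(
                centroids[i],
                orients[i],
                half_dims[i],
                centroids[j],
                orients[j],
                half_dims[j],
            ):
                d = min_distance_kernel(
                    centroids[i],
                    orients[i],
                    half_dims[i],
                    centroids[j],
                    orients[j],
                    half_dims[j],
                )
                v = 0.0
            else:
                d = 0.0
                v = overlap_volume_kernel(
                    centroids[i],
                    orients[i],
                    half_dims[i],
                    centroids[j],
                    orients[j],
                    half_dims[j],
                )
            if d <= reach:
                ii[cnt] = i
                jj[cnt] = j
                dd[cnt] = d
                vv[cnt] = v
                cnt += 1
    return ii[:cnt], jj[:cnt], dd[:cnt], vv[:cnt]
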