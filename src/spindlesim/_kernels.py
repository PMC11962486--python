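"""Numba kernels for the inner mechanics loop.

All kernels operate on flat struct-of-arrays state: vertex positions ``X``
(V, 3) with per-fiber offsets ``off`` (F+1,), so fiber ``f`` owns vertices
``X[off[f]:off[f+1]]`` with vertex 0 at the minus end.  Per-fiber segment
length is ``length[f] / (nv[f]-1)``.  No RNG is used inside kernels; any
random numbers are drawn by the caller and passed in, keeping runs
reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# fiber geometry


@njit(cache=True)
def resample_fibers(Xold, off_old, Xnew, off_new, lengths):
    """Arc-length reparametrization of every fiber, anchored at the minus end.

    Fiber f is resampled to off_new[f+1]-off_new[f] vertices equally spaced
    along its current polyline with total arc length lengths[f]; targets
    beyond the old arc length are extrapolated along the terminal tangent
    (this is where plus-end growth is applied).
    """
    nf = off_old.shape[0] - 1
    for f in range(nf):
        a0, a1 = off_old[f], off_old[f + 1]
        m = a1 - a0
        b0, b1 = off_new[f], off_new[f + 1]
        n = b1 - b0
        # cumulative arc length of old polyline
        ctot = 0.0
        s_new = lengths[f] / (n - 1)
        # terminal tangent (last non-degenerate segment)
        tx, ty, tz = 1.0, 0.0, 0.0
        for j in range(m - 1, 0, -1):
            dx = Xold[a0 + j, 0] - Xold[a0 + j - 1, 0]
            dy = Xold[a0 + j, 1] - Xold[a0 + j - 1, 1]
            dz = Xold[a0 + j, 2] - Xold[a0 + j - 1, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if d > 1e-12:
                tx, ty, tz = dx / d, dy / d, dz / d
                break
        # march along old polyline
        Xnew[b0, 0] = Xold[a0, 0]
        Xnew[b0, 1] = Xold[a0, 1]
        Xnew[b0, 2] = Xold[a0, 2]
        j = 0  # current old segment
        cj = 0.0  # arc length at old vertex j
        dj = 0.0
        for i in range(1, n):
            t = i * s_new
            # advance j until cum length at j+1 >= t or last segment
            while j < m - 1:
                dx = Xold[a0 + j + 1, 0] - Xold[a0 + j, 0]
                dy = Xold[a0 + j + 1, 1] - Xold[a0 + j, 1]
                dz = Xold[a0 + j + 1, 2] - Xold[a0 + j, 2]
                dj = np.sqrt(dx * dx + dy * dy + dz * dz)
                if cj + dj >= t or j == m - 2:
                    break
                cj += dj
                j += 1
            if j >= m - 1 or (cj + dj < t and j == m - 2):
                pass
            if cj + dj >= t and dj > 1e-12:
                w = (t - cj) / dj
                Xnew[b0 + i, 0] = Xold[a0 + j, 0] + w * (Xold[a0 + j + 1, 0] - Xold[a0 + j, 0])
                Xnew[b0 + i, 1] = Xold[a0 + j, 1] + w * (Xold[a0 + j + 1, 1] - Xold[a0 + j, 1])
                Xnew[b0 + i, 2] = Xold[a0 + j, 2] + w * (Xold[a0 + j + 1, 2] - Xold[a0 + j, 2])
            else:
                # beyond old arc length: extrapolate from old plus end
                excess = t - (cj + dj)
                Xnew[b0 + i, 0] = Xold[a1 - 1, 0] + excess * tx
                Xnew[b0 + i, 1] = Xold[a1 - 1, 1] + excess * ty
                Xnew[b0 + i, 2] = Xold[a1 - 1, 2] + excess * tz
        ctot = 0.0  # silence unused warning


@njit(cache=True)
def shake_segments(X, off, seglen, rtol, max_sweeps):
    """Minimal-displacement inextensibility projection (SHAKE-style).

    Gauss-Seidel sweeps move each bond's two vertices symmetrically along
    the bond until every segment length matches the fiber's spacing to
    relative ``rtol``.  Unlike an arc-length resampling this does not cut
    corners, so thermal bending fluctuations are preserved; interior
    corrections are pairwise symmetric, leaving the center of mass
    essentially unchanged.
    """
    nf = off.shape[0] - 1
    for f in range(nf):
        a0, a1 = off[f], off[f + 1]
        m = a1 - a0
        s = seglen[f]
        tol = rtol * s
        for sweep in range(max_sweeps):
            worst = 0.0
            for j in range(a0, a1 - 1):
                dx = X[j + 1, 0] - X[j, 0]
                dy = X[j + 1, 1] - X[j, 1]
                dz = X[j + 1, 2] - X[j, 2]
                ell = np.sqrt(dx * dx + dy * dy + dz * dz)
                if ell < 1e-12:
                    continue
                err = ell - s
                if abs(err) > worst:
                    worst = abs(err)
                c = 0.5 * err / ell
                X[j, 0] += c * dx
                X[j, 1] += c * dy
                X[j, 2] += c * dz
                X[j + 1, 0] -= c * dx
                X[j + 1, 1] -= c * dy
                X[j + 1, 2] -= c * dz
            if worst <= tol:
                break


@njit(cache=True)
def bending_forces(X, off, seglen, kappa, F):
    """Linearized bending elasticity: E = kappa/(2 s^3) sum |x_{j+1}-2x_j+x_{j-1}|^2.

    Adds forces into F.  Net force and net torque per fiber are zero by
    construction (the energy is invariant to rigid motions).
    """
    nf = off.shape[0] - 1
    for f in range(nf):
        a0, a1 = off[f], off[f + 1]
        m = a1 - a0
        if m < 3:
            continue
        k = kappa / (seglen[f] ** 3)
        for j in range(1, m - 1):
            for c in range(3):
                b = X[a0 + j + 1, c] - 2.0 * X[a0 + j, c] + X[a0 + j - 1, c]
                F[a0 + j - 1, c] -= k * b
                F[a0 + j, c] += 2.0 * k * b
                F[a0 + j + 1, c] -= k * b


# ---------------------------------------------------------------------------
# segment-segment geometry


@njit(cache=True, inline="always")
def _closest_params(p1x, p1y, p1z, d1x, d1y, d1z, p2x, p2y, p2z, d2x, d2y, d2z):
    """Closest-point parameters (s, t) in [0,1]^2 between two segments
    p1+s*d1 and p2+t*d2 (clamped)."""
    rx, ry, rz = p1x - p2x, p1y - p2y, p1z - p2z
    a = d1x * d1x + d1y * d1y + d1z * d1z
    e = d2x * d2x + d2y * d2y + d2z * d2z
    fdr = d2x * rx + d2y * ry + d2z * rz
    cdr = d1x * rx + d1y * ry + d1z * rz
    b = d1x * d2x + d1y * d2y + d1z * d2z
    denom = a * e - b * b
    if denom > 1e-18:
        s = (b * fdr - cdr * e) / denom
    else:
        s = 0.0
    if s < 0.0:
        s = 0.0
    elif s > 1.0:
        s = 1.0
    if e > 1e-18:
        t = (b * s + fdr) / e
    else:
        t = 0.0
    if t < 0.0:
        t = 0.0
        if a > 1e-18:
            s = -cdr / a
            if s < 0.0:
                s = 0.0
            elif s > 1.0:
                s = 1.0
    elif t > 1.0:
        t = 1.0
        if a > 1e-18:
            s = (b - cdr) / a
            if s < 0.0:
                s = 0.0
            elif s > 1.0:
                s = 1.0
    return s, t


@njit(cache=True)
def steric_forces(
    X,
    seg_v0,
    seg_fib,
    mids,
    seg_len,
    cell_of_seg,
    order,
    cell_start,
    ncx,
    ncy,
    ncz,
    d0,
    reject_pad,
    stiffness,
    fallback_normal,
    F,
    Kv,
    el_v,
    el_w,
    el_u,
    el_k,
    el_n,
):
    """Short-range repulsion between segments of distinct fibers.

    Segments are binned by midpoint into a uniform grid (built by the caller);
    each segment scans its 27 neighboring cells and interacts once with every
    segment of higher index from a different fiber at center-line distance
    d < d0, with a Hookean force stiffness*(d0-d) along the mutual normal,
    distributed to the four segment vertices.  Active contacts are appended
    as elastic elements for the implicit solver.  Returns the number of
    degenerate (coincident) pairs, which use ``fallback_normal``.
    """
    nseg = seg_v0.shape[0]
    ncells = ncx * ncy * ncz
    degenerate = 0
    for i in range(nseg):
        ci = cell_of_seg[i]
        cz = ci % ncz
        cy = (ci // ncz) % ncy
        cx = ci // (ncz * ncy)
        vi = seg_v0[i]
        p1x, p1y, p1z = X[vi, 0], X[vi, 1], X[vi, 2]
        d1x = X[vi + 1, 0] - p1x
        d1y = X[vi + 1, 1] - p1y
        d1z = X[vi + 1, 2] - p1z
        for ox in range(-1, 2):
            gx = cx + ox
            if gx < 0 or gx >= ncx:
                continue
            for oy in range(-1, 2):
                gy = cy + oy
                if gy < 0 or gy >= ncy:
                    continue
                for oz in range(-1, 2):
                    gz = cz + oz
                    if gz < 0 or gz >= ncz:
                        continue
                    cell = (gx * ncy + gy) * ncz + gz
                    for k in range(cell_start[cell], cell_start[cell + 1]):
                        j = order[k]
                        if j <= i or seg_fib[j] == seg_fib[i]:
                            continue
                        # quick reject: closest distance is at least the
                        # midpoint distance minus both half-lengths; the pad
                        # covers motion since the (cached) hash was built
                        mdx = mids[j, 0] - mids[i, 0]
                        mdy = mids[j, 1] - mids[i, 1]
                        mdz = mids[j, 2] - mids[i, 2]
                        reach = 0.5 * (seg_len[i] + seg_len[j]) + d0 + reject_pad
                        if mdx * mdx + mdy * mdy + mdz * mdz > reach * reach:
                            continue
                        vj = seg_v0[j]
                        p2x, p2y, p2z = X[vj, 0], X[vj, 1], X[vj, 2]
                        d2x = X[vj + 1, 0] - p2x
                        d2y = X[vj + 1, 1] - p2y
                        d2z = X[vj + 1, 2] - p2z
                        s, t = _closest_params(
                            p1x, p1y, p1z, d1x, d1y, d1z, p2x, p2y, p2z, d2x, d2y, d2z
                        )
                        qx = p1x + s * d1x - (p2x + t * d2x)
                        qy = p1y + s * d1y - (p2y + t * d2y)
                        qz = p1z + s * d1z - (p2z + t * d2z)
                        d = np.sqrt(qx * qx + qy * qy + qz * qz)
                        if d >= d0:
                            continue
                        if d > 1e-9:
                            nx, ny, nz = qx / d, qy / d, qz / d
                        else:
                            degenerate += 1
                            nx, ny, nz = (
                                fallback_normal[0],
                                fallback_normal[1],
                                fallback_normal[2],
                            )
                        fmag = stiffness * (d0 - d)
                        fx, fy, fz = fmag * nx, fmag * ny, fmag * nz
                        F[vi, 0] += (1.0 - s) * fx
                        F[vi, 1] += (1.0 - s) * fy
                        F[vi, 2] += (1.0 - s) * fz
                        F[vi + 1, 0] += s * fx
                        F[vi + 1, 1] += s * fy
                        F[vi + 1, 2] += s * fz
                        F[vj, 0] -= (1.0 - t) * fx
                        F[vj, 1] -= (1.0 - t) * fy
                        F[vj, 2] -= (1.0 - t) * fz
                        F[vj + 1, 0] -= t * fx
                        F[vj + 1, 1] -= t * fy
                        F[vj + 1, 2] -= t * fz
                        Kv[vi] += (1.0 - s) * stiffness
                        Kv[vi + 1] += s * stiffness
                        Kv[vj] += (1.0 - t) * stiffness
                        Kv[vj + 1] += t * stiffness
                        m = el_n[0]
                        if m < el_v.shape[0]:
                            el_v[m, 0] = vi
                            el_v[m, 1] = vj
                            el_w[m, 0] = s
                            el_w[m, 1] = t
                            el_u[m, 0] = nx
                            el_u[m, 1] = ny
                            el_u[m, 2] = nz
                            el_k[m] = stiffness
                            el_n[0] = m + 1
    if ncells < 0:  # pragma: no cover - keep ncells "used" for numba
        return -1
    return degenerate


# ---------------------------------------------------------------------------
# attachment interpolation and crosslink spring forces


@njit(cache=True, inline="always")
def _interp(X, off, seglen, fib, absc):
    """Position and unit tangent (minus->plus) at arc position absc on fiber."""
    a0 = off[fib]
    a1 = off[fib + 1]
    m = a1 - a0
    s = seglen[fib]
    j = int(absc / s)
    if j > m - 2:
        j = m - 2
    if j < 0:
        j = 0
    w = absc / s - j
    if w < 0.0:
        w = 0.0
    elif w > 1.0:
        w = 1.0
    px = X[a0 + j, 0] + w * (X[a0 + j + 1, 0] - X[a0 + j, 0])
    py = X[a0 + j, 1] + w * (X[a0 + j + 1, 1] - X[a0 + j, 1])
    pz = X[a0 + j, 2] + w * (X[a0 + j + 1, 2] - X[a0 + j, 2])
    tx = X[a0 + j + 1, 0] - X[a0 + j, 0]
    ty = X[a0 + j + 1, 1] - X[a0 + j, 1]
    tz = X[a0 + j + 1, 2] - X[a0 + j, 2]
    tn = np.sqrt(tx * tx + ty * ty + tz * tz)
    if tn > 1e-12:
        tx, ty, tz = tx / tn, ty / tn, tz / tn
    return px, py, pz, tx, ty, tz, j, w


@njit(cache=True)
def attachment_points(X, off, seglen, fibs, abscs, out_pos, out_tan):
    for i in range(fibs.shape[0]):
        f = fibs[i]
        if f < 0:
            continue
        px, py, pz, tx, ty, tz, j, w = _interp(X, off, seglen, f, abscs[i])
        out_pos[i, 0], out_pos[i, 1], out_pos[i, 2] = px, py, pz
        out_tan[i, 0], out_tan[i, 1], out_tan[i, 2] = tx, ty, tz


@njit(cache=True)
def crosslink_forces(
    X,
    off,
    seglen,
    fib_a,
    absc_a,
    fib_b,
    absc_b,
    stiffness,
    rest_length,
    F,
    Kv,
    tension,
    ftan_a,
    ftan_b,
    el_v,
    el_w,
    el_u,
    el_k,
    el_n,
):
    """Hookean spring force of every doubly-bound complex, scattered to fiber
    vertices.  Also records |spring force| (tension[i], for Bell unbinding)
    and the tangential force component on each unit (for motor load / biased
    diffusion), signed along the local minus->plus tangent.  ``Kv``
    accumulates the per-vertex spring stiffness (diagonal preconditioner),
    and each active link appends an elastic-element record (first vertex
    index and weight per side, unit connector, written at el_n[0]...) used by
    the implicit solver.
    """
    n = fib_a.shape[0]
    for i in range(n):
        fa, fb = fib_a[i], fib_b[i]
        if fa < 0 or fb < 0:
            tension[i] = 0.0
            ftan_a[i] = 0.0
            ftan_b[i] = 0.0
            continue
        pax, pay, paz, tax, tay, taz, ja, wa = _interp(X, off, seglen, fa, absc_a[i])
        pbx, pby, pbz, tbx, tby, tbz, jb, wb = _interp(X, off, seglen, fb, absc_b[i])
        dx, dy, dz = pbx - pax, pby - pay, pbz - paz
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        fmag = stiffness * (d - rest_length)
        tension[i] = abs(fmag)
        if d < 1e-9:
            ftan_a[i] = 0.0
            ftan_b[i] = 0.0
            continue
        ux, uy, uz = dx / d, dy / d, dz / d
        # force on unit a (and its fiber) points toward b when stretched
        fx, fy, fz = fmag * ux, fmag * uy, fmag * uz
        ftan_a[i] = fx * tax + fy * tay + fz * taz
        ftan_b[i] = -(fx * tbx + fy * tby + fz * tbz)
        a0 = off[fa]
        F[a0 + ja, 0] += (1.0 - wa) * fx
        F[a0 + ja, 1] += (1.0 - wa) * fy
        F[a0 + ja, 2] += (1.0 - wa) * fz
        F[a0 + ja + 1, 0] += wa * fx
        F[a0 + ja + 1, 1] += wa * fy
        F[a0 + ja + 1, 2] += wa * fz
        b0 = off[fb]
        F[b0 + jb, 0] -= (1.0 - wb) * fx
        F[b0 + jb, 1] -= (1.0 - wb) * fy
        F[b0 + jb, 2] -= (1.0 - wb) * fz
        F[b0 + jb + 1, 0] -= wb * fx
        F[b0 + jb + 1, 1] -= wb * fy
        F[b0 + jb + 1, 2] -= wb * fz
        Kv[a0 + ja] += (1.0 - wa) * stiffness
        Kv[a0 + ja + 1] += wa * stiffness
        Kv[b0 + jb] += (1.0 - wb) * stiffness
        Kv[b0 + jb + 1] += wb * stiffness
        m = el_n[0]
        if m < el_v.shape[0]:
            el_v[m, 0] = a0 + ja
            el_v[m, 1] = b0 + jb
            el_w[m, 0] = wa
            el_w[m, 1] = wb
            el_u[m, 0] = ux
            el_u[m, 1] = uy
            el_u[m, 2] = uz
            el_k[m] = stiffness
            el_n[0] = m + 1


# ---------------------------------------------------------------------------
# per-species unit kinetics (Bell unbinding + motor stepping + biased
# lattice diffusion in its damped diffusion limit)


@njit(cache=True)
def unbind_and_move(
    fib,
    absc,
    kind,  # (2,) 0 MOTOR / 1 DIFFUSIVE / 2 END_BINDER
    vm,  # (2,) um/s signed
    koff,
    fstall,
    funbind,
    D,
    kT,
    stiffness,
    flen,
    tension,
    ftan_a,
    ftan_b,
    dt,
    u_unbind,  # (n,2) uniforms
    z_move,  # (n,2) standard normals
    release,  # (n,2) uint8 out
):
    n = fib.shape[0]
    for i in range(n):
        doubly = fib[i, 0] >= 0 and fib[i, 1] >= 0
        for u in range(2):
            f = fib[i, u]
            release[i, u] = 0
            if f < 0:
                continue
            # Bell unbinding (load only when doubly bound)
            rate = koff[u]
            if doubly and tension[i] > 0.0:
                x = tension[i] / funbind[u]
                if x > 30.0:
                    x = 30.0
                rate = koff[u] * np.exp(x)
            if u_unbind[i, u] < 1.0 - np.exp(-rate * dt):
                release[i, u] = 1
                continue
            ft = ftan_a[i] if u == 0 else ftan_b[i]
            L = flen[f]
            if kind[u] == 0:  # MOTOR
                vabs = abs(vm[u])
                if vabs > 0.0:
                    sgn = 1.0 if vm[u] >= 0.0 else -1.0
                    v = vabs * (1.0 + ft * sgn / fstall[u])
                    if v < 0.0:
                        v = 0.0
                    elif v > vabs:
                        v = vabs
                    a = absc[i, u] + sgn * v * dt
                    if a < 0.0:
                        a = 0.0
                    elif a > L:
                        a = L
                    absc[i, u] = a
            elif kind[u] == 1:  # DIFFUSIVE
                # exact Ornstein-Uhlenbeck update of lattice diffusion
                # (drift D f/kT) against the crosslink spring along the
                # fiber: the tangential load relaxes within the step
                # (relaxation time kT/(D k) << dt), which is what makes
                # this unit a slippery anchor
                if doubly and stiffness > 0.0:
                    omega = D[u] * stiffness / kT
                    e = np.exp(-omega * dt)
                    drift = (ft / stiffness) * (1.0 - e)
                    sd = np.sqrt((kT / stiffness) * (1.0 - e * e))
                else:
                    drift = D[u] * ft * dt / kT
                    sd = np.sqrt(2.0 * D[u] * dt)
                a = absc[i, u] + drift + sd * z_move[i, u]
                if a < 0.0:
                    a = 0.0
                elif a > L:
                    a = L
                absc[i, u] = a
            # END_BINDER: static


# ---------------------------------------------------------------------------
# spatial hash (counting sort)


@njit(cache=True)
def counting_sort(lin, ncells):
    """Stable counting sort of cell ids; returns (order, cell_start)."""
    n = lin.shape[0]
    cell_start = np.zeros(ncells + 1, dtype=np.int64)
    for i in range(n):
        cell_start[lin[i] + 1] += 1
    for c in range(ncells):
        cell_start[c + 1] += cell_start[c]
    fill = cell_start.copy()
    order = np.empty(n, dtype=np.int64)
    for i in range(n):
        c = lin[i]
        order[fill[c]] = i
        fill[c] += 1
    return order, cell_start


# ---------------------------------------------------------------------------
# implicit overdamped step (matrix-free conjugate gradient)


@njit(cache=True, inline="always")
def _apply_operator(v, out, off, seglen, kappa, gdt, diagK, el_v, el_w, el_u, el_k, n_el):
    """out = (diag(gamma/dt + diagK) + A_bend + sum_el k (u u^T)) v.

    A_bend is the exact bending stiffness (per fiber, SPD); each elastic
    element (crosslink spring or steric contact) contributes its linearized
    rank-one stiffness along the current connector/normal direction.
    """
    V = v.shape[0]
    for i in range(V):
        d = gdt[i] + diagK[i]
        out[i, 0] = d * v[i, 0]
        out[i, 1] = d * v[i, 1]
        out[i, 2] = d * v[i, 2]
    nf = off.shape[0] - 1
    for f in range(nf):
        a0, a1 = off[f], off[f + 1]
        m = a1 - a0
        if m < 3:
            continue
        c = kappa / (seglen[f] ** 3)
        for j in range(1, m - 1):
            for comp in range(3):
                b = v[a0 + j + 1, comp] - 2.0 * v[a0 + j, comp] + v[a0 + j - 1, comp]
                out[a0 + j - 1, comp] += c * b
                out[a0 + j, comp] -= 2.0 * c * b
                out[a0 + j + 1, comp] += c * b
    for e in range(n_el):
        ia, ib = el_v[e, 0], el_v[e, 1]
        wa, wb = el_w[e, 0], el_w[e, 1]
        ux, uy, uz = el_u[e, 0], el_u[e, 1], el_u[e, 2]
        k = el_k[e]
        # interpolated displacements at the two attachment points
        dax = (1.0 - wa) * v[ia, 0] + wa * v[ia + 1, 0]
        day = (1.0 - wa) * v[ia, 1] + wa * v[ia + 1, 1]
        daz = (1.0 - wa) * v[ia, 2] + wa * v[ia + 1, 2]
        dbx = (1.0 - wb) * v[ib, 0] + wb * v[ib + 1, 0]
        dby = (1.0 - wb) * v[ib, 1] + wb * v[ib + 1, 1]
        dbz = (1.0 - wb) * v[ib, 2] + wb * v[ib + 1, 2]
        s = ux * (dbx - dax) + uy * (dby - day) + uz * (dbz - daz)
        g = k * s
        gx, gy, gz = g * ux, g * uy, g * uz
        out[ia, 0] -= (1.0 - wa) * gx
        out[ia, 1] -= (1.0 - wa) * gy
        out[ia, 2] -= (1.0 - wa) * gz
        out[ia + 1, 0] -= wa * gx
        out[ia + 1, 1] -= wa * gy
        out[ia + 1, 2] -= wa * gz
        out[ib, 0] += (1.0 - wb) * gx
        out[ib, 1] += (1.0 - wb) * gy
        out[ib, 2] += (1.0 - wb) * gz
        out[ib + 1, 0] += wb * gx
        out[ib + 1, 1] += wb * gy
        out[ib + 1, 2] += wb * gz


@njit(cache=True)
def implicit_cg_step(
    off,
    seglen,
    kappa,
    gamma,
    diagK,
    precondK,
    F,
    noise,
    dt,
    el_v,
    el_w,
    el_u,
    el_k,
    n_el,
    rtol,
    maxiter,
    delta,
):
    """Linearized backward-Euler displacement solve.

    Solves (diag(gamma/dt + diagK) + A) delta = F + (gamma/dt) * noise with
    A the assembled bending + spring-element stiffness (SPD), by conjugate
    gradients preconditioned with the exact per-fiber (diagonal + bending)
    operator (banded LDL^T, factored once per call).  This restores the
    correct collective mobility of crosslinked fiber clusters, which a
    purely diagonal treatment would overdamp, while remaining
    unconditionally stable.  Returns the iteration count.
    """
    V = F.shape[0]
    gdt = np.empty(V)
    diag_all = np.empty(V)
    for i in range(V):
        gdt[i] = gamma[i] / dt
        diag_all[i] = gdt[i] + diagK[i] + precondK[i]
    # --- factor the per-fiber preconditioner: diag_all + A_bend (bw 2)
    nf = off.shape[0] - 1
    Df = np.empty(V)
    L1 = np.zeros(V)
    L2 = np.zeros(V)
    a0b = np.empty(V)
    a1b = np.zeros(V)
    a2b = np.zeros(V)
    for f in range(nf):
        v0, v1 = off[f], off[f + 1]
        n = v1 - v0
        c = kappa / (seglen[f] ** 3)
        for i in range(v0, v1):
            a0b[i] = diag_all[i]
            a1b[i] = 0.0
            a2b[i] = 0.0
        if n >= 3:
            for r in range(n - 2):
                a0b[v0 + r] += c
                a0b[v0 + r + 1] += 4.0 * c
                a0b[v0 + r + 2] += c
                a1b[v0 + r] += -2.0 * c
                a1b[v0 + r + 1] += -2.0 * c
                a2b[v0 + r] += c
        for jj in range(n):
            j = v0 + jj
            d = a0b[j]
            if jj >= 1:
                d -= L1[j - 1] * L1[j - 1] * Df[j - 1]
            if jj >= 2:
                d -= L2[j - 2] * L2[j - 2] * Df[j - 2]
            Df[j] = d
            if jj + 1 < n:
                t = a1b[j]
                if jj >= 1:
                    t -= L2[j - 1] * L1[j - 1] * Df[j - 1]
                L1[j] = t / d
            else:
                L1[j] = 0.0
            if jj + 2 < n:
                L2[j] = a2b[j] / d
            else:
                L2[j] = 0.0
    # --- rhs
    b = np.empty((V, 3))
    bnorm2 = 0.0
    for i in range(V):
        for comp in range(3):
            b[i, comp] = F[i, comp] + gdt[i] * noise[i, comp]
            bnorm2 += b[i, comp] * b[i, comp]
    for i in range(V):
        for comp in range(3):
            delta[i, comp] = 0.0
    if bnorm2 == 0.0:
        return 0
    r = b.copy()
    z = np.empty((V, 3))
    _precond_solve(r, z, off, Df, L1, L2)
    p = z.copy()
    Ap = np.empty((V, 3))
    rz = 0.0
    for i in range(V):
        for comp in range(3):
            rz += r[i, comp] * z[i, comp]
    tol2 = rtol * rtol * bnorm2
    it = 0
    while it < maxiter:
        _apply_operator(p, Ap, off, seglen, kappa, gdt, diagK, el_v, el_w, el_u, el_k, n_el)
        pAp = 0.0
        for i in range(V):
            for comp in range(3):
                pAp += p[i, comp] * Ap[i, comp]
        if pAp <= 0.0:
            break
        alpha = rz / pAp
        rnorm2 = 0.0
        for i in range(V):
            for comp in range(3):
                delta[i, comp] += alpha * p[i, comp]
                r[i, comp] -= alpha * Ap[i, comp]
                rnorm2 += r[i, comp] * r[i, comp]
        it += 1
        if rnorm2 <= tol2:
            break
        _precond_solve(r, z, off, Df, L1, L2)
        rz_new = 0.0
        for i in range(V):
            for comp in range(3):
                rz_new += r[i, comp] * z[i, comp]
        beta = rz_new / rz
        rz = rz_new
        for i in range(V):
            for comp in range(3):
                p[i, comp] = z[i, comp] + beta * p[i, comp]
    return it


@njit(cache=True, inline="always")
def _precond_solve(r, z, off, Df, L1, L2):
    """Apply the per-fiber banded LDL^T preconditioner: z = P^{-1} r."""
    nf = off.shape[0] - 1
    for f in range(nf):
        v0, v1 = off[f], off[f + 1]
        n = v1 - v0
        for comp in range(3):
            for jj in range(n):
                j = v0 + jj
                val = r[j, comp]
                if jj >= 1:
                    val -= L1[j - 1] * z[j - 1, comp]
                if jj >= 2:
                    val -= L2[j - 2] * z[j - 2, comp]
                z[j, comp] = val
            for jj in range(n):
                z[v0 + jj, comp] /= Df[v0 + jj]
            for jj in range(n - 1, -1, -1):
                j = v0 + jj
                if jj + 1 < n:
                    z[j, comp] -= L1[j] * z[j + 1, comp]
                if jj + 2 < n:
                    z[j, comp] -= L2[j] * z[j + 2, comp]


# ---------------------------------------------------------------------------
# per-species unit kinetics (Bell unbinding + motor stepping + biased
# lattice diffusion in its damped diffusion limit)



# ---------------------------------------------------------------------------
# binding search


@njit(cache=True)
def nearest_segment(
    P,
    X,
    seg_v0,
    seg_fib,
    seg_off_in_fiber,
    cell_of_seg,
    order,
    cell_start,
    ncx,
    ncy,
    ncz,
    origin,
    cell_size,
    max_range,
    exclude_fib,
    out_fib,
    out_absc,
    out_dist,
):
    """For each query point, the nearest fiber point within ``max_range``.

    Writes fiber index (-1 if none), arc-length abscissa of the closest point,
    and its distance.  ``exclude_fib[i]`` (or -1) is skipped, so a partially
    bound complex never binds both units to the same fiber.
    """
    npts = P.shape[0]
    for i in range(npts):
        best = max_range
        bf = -1
        babsc = 0.0
        cx = int((P[i, 0] - origin[0]) / cell_size)
        cy = int((P[i, 1] - origin[1]) / cell_size)
        cz = int((P[i, 2] - origin[2]) / cell_size)
        for ox in range(-1, 2):
            gx = cx + ox
            if gx < 0 or gx >= ncx:
                continue
            for oy in range(-1, 2):
                gy = cy + oy
                if gy < 0 or gy >= ncy:
                    continue
                for oz in range(-1, 2):
                    gz = cz + oz
                    if gz < 0 or gz >= ncz:
                        continue
                    cell = (gx * ncy + gy) * ncz + gz
                    for k in range(cell_start[cell], cell_start[cell + 1]):
                        j = order[k]
                        if seg_fib[j] == exclude_fib[i]:
                            continue
                        v = seg_v0[j]
                        ax, ay, az = X[v, 0], X[v, 1], X[v, 2]
                        dx = X[v + 1, 0] - ax
                        dy = X[v + 1, 1] - ay
                        dz = X[v + 1, 2] - az
                        L2 = dx * dx + dy * dy + dz * dz
                        if L2 > 1e-18:
                            t = (
                                (P[i, 0] - ax) * dx
                                + (P[i, 1] - ay) * dy
                                + (P[i, 2] - az) * dz
                            ) / L2
                            if t < 0.0:
                                t = 0.0
                            elif t > 1.0:
                                t = 1.0
                        else:
                            t = 0.0
                        qx = ax + t * dx - P[i, 0]
                        qy = ay + t * dy - P[i, 1]
                        qz = az + t * dz - P[i, 2]
                        d = np.sqrt(qx * qx + qy * qy + qz * qz)
                        if d < best:
                            best = d
                            bf = seg_fib[j]
                            babsc = (seg_off_in_fiber[j] + t) * np.sqrt(L2)
        out_fib[i] = bf
        out_absc[i] = babsc
        out_dist[i] = best
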