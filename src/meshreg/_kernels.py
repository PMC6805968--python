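"""Numba closest-point-on-mesh kernel.

Scalar Ericson point-triangle closest-point evaluated per (point, face)
pair with a centroid+circumradius lower-bound rejection test; exact to
floating point, no spatial index needed at the mesh sizes this package
works with.
"""

import numba
import numpy as np

@numba.njit(cache=True, fastmath=False)
def _query_kernel(points, tri, cent, circum):
    n = points.shape[0]
    m = tri.shape[0]
    out_pt = np.empty((n, 3))
    out_d = np.empty(n)
    out_f = np.empty(n, dtype=np.int64)
    for i in range(n):
        px, py, pz = points[i, 0], points[i, 1], points[i, 2]
        best = 1e300
        bf = -1
        bx = by = bz = 0.0
        for j in range(m):
            dx = px - cent[j, 0]; dy = py - cent[j, 1]; dz = pz - cent[j, 2]
            lb = np.sqrt(dx*dx + dy*dy + dz*dz) - circum[j]
            if lb > 0 and lb*lb >= best:
                continue
            ax, ay, az = tri[j,0,0], tri[j,0,1], tri[j,0,2]
            abx, aby, abz = tri[j,1,0]-ax, tri[j,1,1]-ay, tri[j,1,2]-az
            acx, acy, acz = tri[j,2,0]-ax, tri[j,2,1]-ay, tri[j,2,2]-az
            apx, apy, apz = px-ax, py-ay, pz-az
            d1 = abx*apx + aby*apy + abz*apz
            d2 = acx*apx + acy*apy + acz*apz
            if d1 <= 0.0 and d2 <= 0.0:
                qx, qy, qz = ax, ay, az
            else:
                bpx, bpy, bpz = px-tri[j,1,0], py-tri[j,1,1], pz-tri[j,1,2]
                d3 = abx*bpx + aby*bpy + abz*bpz
                d4 = acx*bpx + acy*bpy + acz*bpz
                if d3 >= 0.0 and d4 <= d3:
                    qx, qy, qz = tri[j,1,0], tri[j,1,1], tri[j,1,2]
                else:
                    cpx, cpy, cpz = px-tri[j,2,0], py-tri[j,2,1], pz-tri[j,2,2]
                    d5 = abx*cpx + aby*cpy + abz*cpz
                    d6 = acx*cpx + acy*cpy + acz*cpz
                    if d6 >= 0.0 and d5 <= d6:
                        qx, qy, qz = tri[j,2,0], tri[j,2,1], tri[j,2,2]
                    else:
                        vc = d1*d4 - d3*d2
                        if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
                            v = d1 / (d1 - d3)
                            qx, qy, qz = ax + v*abx, ay + v*aby, az + v*abz
                        else:
                            vb = d5*d2 - d1*d6
                            if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
                                w = d2 / (d2 - d6)
                                qx, qy, qz = ax + w*acx, ay + w*acy, az + w*acz
                            else:
                                va = d3*d6 - d5*d4
                                if va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
                                    w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
                                    qx = tri[j,1,0] + w*(tri[j,2,0]-tri[j,1,0])
                                    qy = tri[j,1,1] + w*(tri[j,2,1]-tri[j,1,1])
                                    qz = tri[j,1,2] + w*(tri[j,2,2]-tri[j,1,2])
                                else:
                                    denom = 1.0 / (va + vb + vc)
                                    v = vb * denom
                                    w = vc * denom
                                    qx = ax + v*abx + w*acx
                                    qy = ay + v*aby + w*acy
                                    qz = az + v*abz + w*acz
            ddx, ddy, ddz = px-qx, py-qy, pz-qz
            dd = ddx*ddx + ddy*ddy + ddz*ddz
            if dd < best:
                best = dd; bf = j; bx, by, bz = qx, qy, qz
        out_pt[i,0], out_pt[i,1], out_pt[i,2] = bx, by, bz
        out_d[i] = np.sqrt(best)
        out_f[i] = bf
    return out_pt, out_d, out_f

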