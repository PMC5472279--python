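"""Independent brute-force reference implementations used by the tests.

Each oracle deliberately uses the most naive correct algorithm (sliding
windows, exhaustive search, flood fill, quaternion eigenproblem, finite
differences) so that agreement with the package's vectorized or
library-backed implementations is a meaningful cross-check.
"""

from __future__ import annotations

import numpy as np


def naive_median_filter(img: np.ndarray, k: int) -> np.ndarray:
    """O(N k^2) sliding-window median with edge replication."""
    pad = k // 2
    padded = np.pad(img, pad, mode="edge")
    out = np.empty_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = np.median(padded[i : i + k, j : j + k])
    return out


def exhaustive_otsu(img: np.ndarray, nbins: int = 256) -> float:
    """Between-class-variance maximization by trying every histogram bin."""
    counts, edges = np.histogram(img.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    total = counts.sum()
    best_t, best_var = centers[0], -1.0
    for split in range(1, nbins):
        w0 = counts[:split].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (counts[:split] * centers[:split]).sum() / w0
        m1 = (counts[split:] * centers[split:]).sum() / w1
        var = w0 * w1 * (m0 - m1) ** 2
        if var > best_var:
            best_var, best_t = var, centers[split - 1]
    return best_t


def pixel_between_class_variance(img: np.ndarray, thr: float) -> float:
    """Between-class variance of the actual pixel split at ``thr``."""
    vals = np.asarray(img, dtype=float).ravel()
    lo, hi = vals[vals <= thr], vals[vals > thr]
    if lo.size == 0 or hi.size == 0:
        return 0.0
    return lo.size * hi.size * (lo.mean() - hi.mean()) ** 2


def flood_fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill via explicit 4-connected flood fill of background from the border."""
    mask = np.asarray(mask, dtype=bool)
    reachable = np.zeros_like(mask)
    stack = []
    h, w = mask.shape
    for i in range(h):
        for j in (0, w - 1):
            if not mask[i, j]:
                stack.append((i, j))
    for j in range(w):
        for i in (0, h - 1):
            if not mask[i, j]:
                stack.append((i, j))
    while stack:
        i, j = stack.pop()
        if reachable[i, j] or mask[i, j]:
            continue
        reachable[i, j] = True
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = i + di, j + dj
            if 0 <= ni < h and 0 <= nj < w and not mask[ni, nj] and not reachable[ni, nj]:
                stack.append((ni, nj))
    return mask | ~reachable


def component_areas_bruteforce(mask: np.ndarray) -> list[int]:
    """8-connected component pixel counts via explicit flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    areas = []
    h, w = mask.shape
    for si in range(h):
        for sj in range(w):
            if mask[si, sj] and not seen[si, sj]:
                count = 0
                stack = [(si, sj)]
                seen[si, sj] = True
                while stack:
                    i, j = stack.pop()
                    count += 1
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            ni, nj = i + di, j + dj
                            if (
                                0 <= ni < h and 0 <= nj < w
                                and mask[ni, nj] and not seen[ni, nj]
                            ):
                                seen[ni, nj] = True
                                stack.append((ni, nj))
                areas.append(count)
    return sorted(areas)


def quaternion_superpose_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Optimal-superposition RMSD via Horn's quaternion eigen method."""
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)
    s = x.T @ y
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    e0 = float(np.sum(x**2) + np.sum(y**2))
    msd = max(0.0, (e0 - 2.0 * lam) / mobile.shape[0])
    return float(np.sqrt(msd))


def anm_energy(coords_flat: np.ndarray, ref: np.ndarray, cutoff: float) -> float:
    """Harmonic network energy, for finite-difference Hessian checks."""
    coords = coords_flat.reshape(ref.shape)
    n = ref.shape[0]
    e = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            d0 = np.linalg.norm(ref[i] - ref[j])
            if 0 < d0 <= cutoff:
                d = np.linalg.norm(coords[i] - coords[j])
                e += 0.5 * (d - d0) ** 2
    return e


def finite_difference_hessian(ref: np.ndarray, cutoff: float, h: float = 1e-5) -> np.ndarray:
    """Numerical Hessian of the network energy at the reference state."""
    x0 = ref.ravel().astype(float)
    m = x0.size
    hess = np.zeros((m, m))
    for a in range(m):
        for b in range(a, m):
            xpp = x0.copy(); xpp[a] += h; xpp[b] += h
            xpm = x0.copy(); xpm[a] += h; xpm[b] -= h
            xmp = x0.copy(); xmp[a] -= h; xmp[b] += h
            xmm = x0.copy(); xmm[a] -= h; xmm[b] -= h
            val = (
                anm_energy(xpp, ref, cutoff)
                - anm_energy(xpm, ref, cutoff)
                - anm_energy(xmp, ref, cutoff)
                + anm_energy(xmm, ref, cutoff)
            ) / (4 * h * h)
            hess[a, b] = hess[b, a] = val
    return hess


def pooled_t_statistic(a, b) -> tuple[float, float]:
    """Textbook pooled-variance two-sample t with its degrees of freedom."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return float(t), float(na + nb - 2)
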