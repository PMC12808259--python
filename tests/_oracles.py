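"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately naive (loops, BFS, O(N^4) transforms) and
shares no code with the package's implementation paths.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def direct_dft_filter(pixels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Frequency filtering via an O(N^4) direct discrete Fourier transform."""
    h, w = pixels.shape
    fwd = np.zeros((h, w), dtype=complex)
    for k in range(h):
        for l in range(w):
            acc = 0.0 + 0.0j
            for m in range(h):
                for n in range(w):
                    acc += pixels[m, n] * np.exp(-2j * np.pi * (k * m / h + l * n / w))
            fwd[k, l] = acc
    fwd *= mask
    out = np.zeros((h, w), dtype=complex)
    for m in range(h):
        for n in range(w):
            acc = 0.0 + 0.0j
            for k in range(h):
                for l in range(w):
                    acc += fwd[k, l] * np.exp(2j * np.pi * (k * m / h + l * n / w))
            out[m, n] = acc / (h * w)
    return out.real


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[int]:
    """Sizes of connected foreground components via breadth-first search."""
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                 if (dy, dx) != (0, 0)]
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    sizes = []
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                q = deque([(i, j)])
                seen[i, j] = True
                size = 0
                while q:
                    y, x = q.popleft()
                    size += 1
                    for dy, dx in steps:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] \
                                and not seen[ny, nx]:
                            seen[ny, nx] = True
                            q.append((ny, nx))
                sizes.append(size)
    return sorted(sizes)


def exhaustive_otsu(pixels: np.ndarray, nbins: int = 256):
    """All cut points maximizing between-class variance, plus the criterion.

    Returns (list of candidate threshold edges on the maximizing plateau,
    maximum criterion value); the search enumerates every histogram cut.
    """
    px = pixels.ravel()
    hist, edges = np.histogram(px, bins=nbins, range=(px.min(), px.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    best, plateau = -1.0, []
    for cut in range(1, nbins):
        n0, n1 = hist[:cut].sum(), hist[cut:].sum()
        if n0 == 0 or n1 == 0:
            continue
        mu0 = (hist[:cut] * centers[:cut]).sum() / n0
        mu1 = (hist[cut:] * centers[cut:]).sum() / n1
        crit = n0 * n1 * (mu0 - mu1) ** 2
        if crit > best * (1 + 1e-12):
            best, plateau = crit, [edges[cut]]
        elif crit >= best * (1 - 1e-12):
            plateau.append(edges[cut])
    return plateau, best


def anova_icc31(x: np.ndarray) -> float:
    """ICC(3,1) from explicit ANOVA sums of squares, all loops."""
    n, k = x.shape
    grand = sum(x[i, j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(x[i, j] for j in range(k)) / k for i in range(n)]
    col = [sum(x[i, j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((r - grand) ** 2 for r in row)
    ss_cols = n * sum((c - grand) ** 2 for c in col)
    ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)


def pooled_t_test(a: np.ndarray, b: np.ndarray):
    """Closed-form pooled-variance two-sided t-test (Student)."""
    from scipy.stats import t as tdist

    na, nb = len(a), len(b)
    va = sum((v - np.mean(a)) ** 2 for v in a) / (na - 1)
    vb = sum((v - np.mean(b)) ** 2 for v in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p
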