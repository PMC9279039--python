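"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a statistic from its definition by direct enumeration
(double loops, rank sums, bin enumeration, breadth-first flood fill), staying
deliberately independent of the vectorized implementation paths it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata


def pearson_two_pass(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook two-pass Pearson correlation."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    mx, my = x.mean(), y.mean()
    num = float(((x - mx) * (y - my)).sum())
    den = float(np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum()))
    return num / den


def region_means_loop(data: np.ndarray, labels: np.ndarray) -> dict[int, np.ndarray]:
    """Per-label mean series via an explicit voxel loop."""
    out: dict[int, list] = {}
    for idx in np.ndindex(labels.shape):
        lab = int(labels[idx])
        if lab > 0:
            out.setdefault(lab, []).append(data[idx])
    return {lab: np.mean(series, axis=0) for lab, series in out.items()}


def dc_bruteforce(data: np.ndarray, threshold: float = 0.25) -> np.ndarray:
    """All-pairs signed-correlation threshold count per voxel."""
    shape = data.shape[:3]
    X = data.reshape(-1, data.shape[3])
    V = X.shape[0]
    sd = X.std(axis=1)
    counts = np.zeros(V, dtype=np.int64)
    for i in range(V):
        if sd[i] == 0:
            continue
        for j in range(V):
            if i == j or sd[j] == 0:
                continue
            if pearson_two_pass(X[i], X[j]) > threshold:
                counts[i] += 1
    return counts.reshape(shape)


def _neighbor_offsets(neighborhood: int):
    max_l1 = {7: 1, 19: 2, 27: 3}[neighborhood]
    return [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if abs(dx) + abs(dy) + abs(dz) <= max_l1
    ]


def kendall_w(series: np.ndarray) -> float:
    """Kendall's coefficient of concordance over K series (midranks, no
    tie correction): W = 12 * sum_t (R_t - Rbar)^2 / (K^2 (T^3 - T))."""
    K, T = series.shape
    ranks = np.stack([rankdata(s) for s in series])
    R = ranks.sum(axis=0)
    ss = float(((R - R.mean()) ** 2).sum())
    return 12.0 * ss / (K**2 * (T**3 - T))


def reho_bruteforce(data: np.ndarray, neighborhood: int = 27) -> np.ndarray:
    """Per-voxel Kendall's W over the truncated spatial neighborhood."""
    X, Y, Z, _ = data.shape
    out = np.zeros((X, Y, Z))
    offsets = _neighbor_offsets(neighborhood)
    for x in range(X):
        for y in range(Y):
            for z in range(Z):
                block = [
                    data[x + dx, y + dy, z + dz]
                    for dx, dy, dz in offsets
                    if 0 <= x + dx < X and 0 <= y + dy < Y and 0 <= z + dz < Z
                ]
                out[x, y, z] = kendall_w(np.stack(block))
    return out


def alff_bin_enumeration(
    series: np.ndarray, fs: float, low: float, high: float, power: bool = False
) -> float:
    """Sum one-sided DFT amplitudes over in-band bins, enumerated one by one."""
    T = series.size
    total = 0.0
    for h in range(T // 2 + 1):
        f = h * fs / T
        if low <= f <= high:
            amp = abs(np.fft.fft(series)[h])
            total += amp**2 if power else amp
    return total


def falff_bin_enumeration(
    series: np.ndarray, fs: float, low: float, high: float, exclude_dc: bool = True
) -> float:
    T = series.size
    spec = np.fft.fft(series)
    numer = 0.0
    denom = 0.0
    for h in range(T // 2 + 1):
        amp = abs(spec[h])
        f = h * fs / T
        if low <= f <= high:
            numer += amp
        if h > 0 or not exclude_dc:
            denom += amp
    return numer / denom


def pooled_t(a: np.ndarray, b: np.ndarray) -> float:
    """Closed-form pooled-variance two-sample t for two 1D samples."""
    na, nb = a.size, b.size
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    return float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb)))


def flood_fill_components(mask: np.ndarray, connectivity: int = 26) -> list[set]:
    """Connected components of a binary 3D mask via breadth-first search."""
    conn_rank = {6: 1, 18: 2, 26: 3}[connectivity]
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0) and abs(dx) + abs(dy) + abs(dz) <= conn_rank
    ]
    seen = np.zeros(mask.shape, dtype=bool)
    comps = []
    X, Y, Z = mask.shape
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        queue = [start]
        seen[start] = True
        comp = set()
        while queue:
            vox = queue.pop()
            comp.add(vox)
            x, y, z = vox
            for dx, dy, dz in offsets:
                nx, ny, nz = x + dx, y + dy, z + dz
                if 0 <= nx < X and 0 <= ny < Y and 0 <= nz < Z:
                    if mask[nx, ny, nz] and not seen[nx, ny, nz]:
                        seen[nx, ny, nz] = True
                        queue.append((nx, ny, nz))
        comps.append(comp)
    return comps


def route_direct(votes: np.ndarray, iters: int) -> np.ndarray:
    """Direct re-statement of agreement routing used as a fixed-point oracle."""
    P, C, D = votes.shape
    b = np.zeros((P, C))
    for _ in range(iters):
        c = np.exp(b) / np.exp(b).sum(axis=1, keepdims=True)
        s = np.einsum("pc,pcd->cd", c, votes)
        n2 = (s**2).sum(axis=1, keepdims=True)
        v = s * n2 / (1 + n2) / np.sqrt(n2 + 1e-12)
        b = b + np.einsum("pcd,cd->pc", votes, v)
    return v


def margin_loss_closed_form(scores, true_class, m_plus=0.9, m_minus=0.1, lam=0.5):
    total = 0.0
    for p, v in enumerate(scores):
        if p == true_class:
            total += max(0.0, m_plus - v) ** 2
        else:
            total += lam * max(0.0, v - m_minus) ** 2
    return total


def margin_loss_grad_closed_form(scores, true_class, m_plus=0.9, m_minus=0.1, lam=0.5):
    g = np.zeros(len(scores))
    for p, v in enumerate(scores):
        if p == true_class:
            g[p] = -2.0 * max(0.0, m_plus - v)
        else:
            g[p] = 2.0 * lam * max(0.0, v - m_minus)
    return g
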