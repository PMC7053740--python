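"""Independent brute-force oracles: literal per-pixel / per-cell loops.

Deliberately unvectorized (or at most region-slice sums) and kept free of
any prefix-sum machinery, so they can stand as independent references for
the fast implementations.
"""

import math

import numpy as np

# same near-tie tolerance as the package: mathematically tied (s, t) cells
# can differ by float-summation noise between implementations
TIE_RTOL = 1e-12


def _better(new, best, maximize):
    if best is None:
        return True
    tol = TIE_RTOL * max(1.0, abs(best))
    return new > best + tol if maximize else new < best - tol


def _border_index(k: int, size: int, border: str) -> int:
    if border == "replicate":
        return min(max(k, 0), size - 1)
    # mirror: reflect without repeating the edge sample (numpy 'reflect')
    if size == 1:
        return 0
    period = 2 * size - 2
    k = k % period
    return k if k < size else period - k


def naive_lre(image: np.ndarray, n: int, border: str = "replicate") -> np.ndarray:
    """Per-pixel double loop over the n x n window."""
    M, N = image.shape
    r = (n - 1) // 2
    out = np.zeros((M, N))
    for x in range(M):
        for y in range(N):
            vals = []
            for i in range(-r, r + 1):
                for j in range(-r, r + 1):
                    vals.append(
                        image[_border_index(x + i, M, border),
                              _border_index(y + j, N, border)]
                    )
            mean = sum(vals) / n**2
            acc = 0.0
            for v in vals:
                if v > 0 and mean > 0:
                    acc += v * abs(math.log(v / mean))
            out[x, y] = acc
    return out


def naive_class_stats(p: np.ndarray, s: int, t: int):
    """Literal double sums for P0, P1, mu0, mu1."""
    L = p.shape[0]
    P0 = sum(p[i][j] for i in range(s) for j in range(t))
    P1 = sum(p[i][j] for i in range(s, L) for j in range(t))
    mu0 = mu1 = None
    if P0 > 0:
        mu0 = (
            sum(i * p[i][j] for i in range(s) for j in range(t)) / P0,
            sum(j * p[i][j] for i in range(s) for j in range(t)) / P0,
        )
    if P1 > 0:
        mu1 = (
            sum(i * p[i][j] for i in range(s, L) for j in range(t)) / P1,
            sum(j * p[i][j] for i in range(s, L) for j in range(t)) / P1,
        )
    return P0, P1, mu0, mu1


def naive_criterion(p: np.ndarray, s: int, t: int):
    """Literal cell-by-cell evaluation of the 2-D relative entropy D.

    Returns None when either class is empty.  Terms with i = 0 or j = 0, or
    with a zero mean coordinate (all in-class mass at coordinate 0), are 0.
    """
    L = p.shape[0]
    P0, P1, mu0, mu1 = naive_class_stats(p, s, t)
    if P0 == 0 or P1 == 0:
        return None
    D = 0.0
    for i in range(s):
        for j in range(t):
            if p[i][j] == 0:
                continue
            if i > 0 and mu0[0] > 0:
                D += i * p[i][j] * math.log(i / mu0[0])
            if j > 0 and mu0[1] > 0:
                D += j * p[i][j] * math.log(j / mu0[1])
    for i in range(s, L):
        for j in range(t):
            if p[i][j] == 0:
                continue
            if i > 0 and mu1[0] > 0:
                D += i * p[i][j] * math.log(i / mu1[0])
            if j > 0 and mu1[1] > 0:
                D += j * p[i][j] * math.log(j / mu1[1])
    return D


def _region_criterion(p: np.ndarray, s: int, t: int, charge_excluded: bool = True):
    """Slice-sum version of D for the brute search (no prefix sums).

    With ``charge_excluded`` the high-LRE region (all i, j >= t) contributes
    its own dispersion term, mirroring the package's default objective.
    """
    L = p.shape[0]
    i = np.arange(L, dtype=float)
    c0, c1 = p[:s, :t], p[s:, :t]
    P0, P1 = c0.sum(), c1.sum()
    if P0 == 0 or P1 == 0:
        return None
    with np.errstate(divide="ignore"):
        ilogi = np.where(i > 0, i * np.log(np.where(i > 0, i, 1)), 0.0)
    regions = [
        (c0, slice(None, s), slice(None, t)),
        (c1, slice(s, None), slice(None, t)),
    ]
    if charge_excluded:
        regions.append((p[:, t:], slice(None), slice(t, None)))
    D = 0.0
    for sub, rows, cols in regions:
        P = sub.sum()
        if P == 0:
            continue
        si = (i[rows, None] * sub).sum()
        sj = (i[None, cols] * sub).sum()
        D += (ilogi[rows, None] * sub).sum() + (ilogi[None, cols] * sub).sum()
        if si > 0:
            D -= si * math.log(si / P)
        if sj > 0:
            D -= sj * math.log(sj / P)
    return D


def brute_select_min_re(p: np.ndarray, charge_excluded: bool = True):
    """O(L^4)-style exhaustive search; tie-aware '<' keeps the lexicographic first."""
    L = p.shape[0]
    best, best_tv = None, None
    for s in range(1, L):
        for t in range(1, L):
            D = _region_criterion(p, s, t, charge_excluded)
            if D is None:
                continue
            if _better(D, best, maximize=False):
                best, best_tv = D, (s, t)
    return best_tv


def brute_otsu_gllre(p: np.ndarray):
    L = p.shape[0]
    i = np.arange(L, dtype=float)
    best, best_tv = None, None
    for s in range(1, L):
        for t in range(1, L):
            c0, c1 = p[:s, :t], p[s:, :t]
            P0, P1 = c0.sum(), c1.sum()
            if P0 == 0 or P1 == 0:
                continue
            mu0 = ((i[:s, None] * c0).sum() / P0, (i[None, :t] * c0).sum() / P0)
            mu1 = ((i[s:, None] * c1).sum() / P1, (i[None, :t] * c1).sum() / P1)
            Pt = P0 + P1
            muT = (
                ((i[:, None] * p[:, :t]).sum()) / Pt,
                ((i[None, :t] * p[:, :t]).sum()) / Pt,
            )
            score = P0 * ((mu0[0] - muT[0]) ** 2 + (mu0[1] - muT[1]) ** 2) + P1 * (
                (mu1[0] - muT[0]) ** 2 + (mu1[1] - muT[1]) ** 2
            )
            if _better(score, best, maximize=True):
                best, best_tv = score, (s, t)
    return best_tv


def brute_kapur_gllre(p: np.ndarray):
    L = p.shape[0]
    best, best_tv = None, None
    for s in range(1, L):
        for t in range(1, L):
            c0, c1 = p[:s, :t], p[s:, :t]
            P0, P1 = c0.sum(), c1.sum()
            if P0 == 0 or P1 == 0:
                continue
            score = 0.0
            for sub, P in ((c0, P0), (c1, P1)):
                q = sub[sub > 0] / P
                score += -(q * np.log(q)).sum()
            if _better(score, best, maximize=True):
                best, best_tv = score, (s, t)
    return best_tv


def brute_otsu_1d(hist):
    w = np.asarray(hist, dtype=float)
    w = w / w.sum()
    L = w.size
    i = np.arange(L, dtype=float)
    best, best_s = None, None
    for s in range(1, L):
        P0, P1 = w[:s].sum(), w[s:].sum()
        if P0 == 0 or P1 == 0:
            continue
        mu0 = (i[:s] * w[:s]).sum() / P0
        mu1 = (i[s:] * w[s:]).sum() / P1
        score = P0 * P1 * (mu0 - mu1) ** 2
        if _better(score, best, maximize=True):
            best, best_s = score, s
    return best_s


def brute_kapur_1d(hist):
    w = np.asarray(hist, dtype=float)
    w = w / w.sum()
    L = w.size
    best, best_s = None, None
    for s in range(1, L):
        P0, P1 = w[:s].sum(), w[s:].sum()
        if P0 == 0 or P1 == 0:
            continue
        score = 0.0
        for seg, P in ((w[:s], P0), (w[s:], P1)):
            q = seg[seg > 0] / P
            score += -(q * np.log(q)).sum()
        if _better(score, best, maximize=True):
            best, best_s = score, s
    return best_s


def random_histogram(rng: np.random.Generator, L: int = 16, sparsity: float = 0.5):
    """Random normalized L x L histogram with a random support pattern."""
    p = rng.random((L, L)) * (rng.random((L, L)) < sparsity)
    if p.sum() == 0:
        p[rng.integers(L), rng.integers(L)] = 1.0
        p[rng.integers(L), rng.integers(L)] += 1.0
    return p / p.sum()
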