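"""Threshold selection on 1-D gray histograms and 2-D GLLRE histograms.

A threshold vector ``(s, t)`` cuts the L x L joint histogram into four
quadrants: the low-LRE strip ``j < t`` holds object and background mass,
split at gray level ``s`` into class C0 (``i < s``) and class C1
(``i >= s``); the high-LRE quadrants (``j >= t``) are edge/noise mass and
are excluded from every criterion.

Five selectors are provided:

* :func:`select_threshold_min_re` -- the minimum-relative-entropy criterion
  on the GLLRE histogram (the method of interest),
* :func:`otsu_gllre`, :func:`kapur_gllre` -- the classical between-class
  variance and maximum-entropy criteria restricted to the same class
  regions (reconstructions: the comparison methods are named in the source
  literature but their quadrant conventions are not spelled out; we reuse
  the C0/C1 regions above for consistency),
* :func:`otsu_1d`, :func:`kapur_1d` -- the 1-D classics on the gray-level
  histogram.

All 2-D searches are exhaustive over ``(s, t)`` in ``[1, L-1]^2`` using 2-D
prefix sums, so each candidate is scored in O(1) and a full L = 256 search
runs in O(L^2).  Ties are broken by the lexicographically smallest ``(s, t)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .exceptions import InvalidInputError, InvalidParameterError, NoThresholdError
from .histogram import GLLREHistogram

__all__ = [
    "ThresholdVector",
    "ClassStatistics",
    "CriterionValue",
    "class_statistics",
    "relative_entropy_criterion",
    "select_threshold_min_re",
    "otsu_1d",
    "kapur_1d",
    "otsu_gllre",
    "kapur_gllre",
    "apply_threshold",
]


class ThresholdVector(NamedTuple):
    """Gray-level cut ``s`` and LRE cut ``t``, each in [1, L-1]."""

    s: int
    t: int


@dataclass(frozen=True)
class ClassStatistics:
    """Probabilities and mean vectors of the two classes under ``(s, t)``.

    ``P0 + P1 <= 1``: mass in the high-LRE quadrants is excluded.  A mean
    vector is ``None`` when its class is empty.
    """

    P0: float
    P1: float
    mu0: tuple[float, float] | None
    mu1: tuple[float, float] | None


@dataclass(frozen=True)
class CriterionValue:
    """Two-dimensional relative entropy D at a threshold vector.

    ``defined`` is False when either class is empty, in which case ``D`` is
    meaningless (reported as nan).
    """

    D: float
    defined: bool


def _as_p(hist) -> np.ndarray:
    """Accept a GLLREHistogram or a raw probability matrix."""
    if isinstance(hist, GLLREHistogram):
        return hist.p
    p = np.asarray(hist, dtype=np.float64)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise InvalidInputError(f"expected a square L x L histogram, got {p.shape}")
    if p.min() < 0:
        raise InvalidInputError("histogram frequencies must be nonnegative")
    return p


def _check_tv(s: int, t: int, L: int) -> None:
    if not (1 <= s <= L - 1 and 1 <= t <= L - 1):
        raise InvalidParameterError(
            f"threshold vector ({s}, {t}) outside [1, {L - 1}]^2"
        )


def class_statistics(hist, tv: tuple[int, int]) -> ClassStatistics:
    """Class probabilities and mean vectors for a threshold vector.

    C0 collects cells with ``i < s, j < t``; C1 cells with ``i >= s, j < t``.
    """
    p = _as_p(hist)
    L = p.shape[0]
    s, t = int(tv[0]), int(tv[1])
    _check_tv(s, t, L)

    i = np.arange(L, dtype=np.float64)
    c0 = p[:s, :t]
    c1 = p[s:, :t]
    P0 = float(c0.sum())
    P1 = float(c1.sum())

    mu0 = mu1 = None
    if P0 > 0:
        mu0 = (
            float((i[:s, None] * c0).sum() / P0),
            float((i[None, :t] * c0).sum() / P0),
        )
    if P1 > 0:
        mu1 = (
            float((i[s:, None] * c1).sum() / P1),
            float((i[None, :t] * c1).sum() / P1),
        )
    return ClassStatistics(P0=P0, P1=P1, mu0=mu0, mu1=mu1)


def relative_entropy_criterion(hist, tv: tuple[int, int]) -> CriterionValue:
    """Two-dimensional relative entropy between the image and its two-class summary.

    D = sum_{i<s, j<t} [ i p_ij log(i / mu0_i) + j p_ij log(j / mu0_j) ]
      + sum_{i>=s, j<t} [ i p_ij log(i / mu1_i) + j p_ij log(j / mu1_j) ]

    Terms with i = 0 or j = 0 contribute nothing (0 log 0 := 0); a zero mean
    coordinate only occurs when every in-class pixel sits at coordinate 0,
    and those terms vanish by the same convention.  Computed literally over
    the low-LRE strip without renormalizing by P0 + P1.
    """
    p = _as_p(hist)
    L = p.shape[0]
    s, t = int(tv[0]), int(tv[1])
    _check_tv(s, t, L)

    stats = class_statistics(p, (s, t))
    if stats.P0 == 0 or stats.P1 == 0:
        return CriterionValue(D=float("nan"), defined=False)

    i = np.arange(L, dtype=np.float64)
    with np.errstate(divide="ignore"):
        ilogi = np.where(i > 0, i * np.log(np.where(i > 0, i, 1.0)), 0.0)

    def block(sub: np.ndarray, rows: np.ndarray, mu: tuple[float, float]) -> float:
        cols = i[:t]
        wi = rows[:, None] * sub  # i * p_ij
        wj = cols[None, :] * sub  # j * p_ij
        d = float((ilogi[rows.astype(int), None] * sub).sum()) + float(
            (ilogi[: t][None, :] * sub).sum()
        )
        si, sj = wi.sum(), wj.sum()
        if si > 0:
            d -= si * np.log(mu[0])
        if sj > 0:
            d -= sj * np.log(mu[1])
        return d

    d0 = block(p[:s, :t], i[:s], stats.mu0)
    d1 = block(p[s:, :t], i[s:], stats.mu1)
    return CriterionValue(D=d0 + d1, defined=True)


# ---------------------------------------------------------------------------
# prefix-sum machinery for the exhaustive (s, t) searches


def _cum2d(a: np.ndarray) -> np.ndarray:
    """Padded 2-D prefix sum: C[s, t] = sum over i < s, j < t."""
    L = a.shape[0]
    c = np.zeros((L + 1, L + 1), dtype=np.float64)
    c[1:, 1:] = a.cumsum(axis=0).cumsum(axis=1)
    return c


def _region_grids(a: np.ndarray):
    """For every (s, t) in [1, L-1]^2, return sums of ``a`` over C0 and C1.

    Output arrays are indexed [s-1, t-1].
    """
    c = _cum2d(a)
    L = a.shape[0]
    c0 = c[1:L, 1:L]
    strip = c[L, 1:L][None, :]
    return c0, strip - c0


# Criterion values at distinct (s, t) can be mathematically identical (e.g.
# an unoccupied gray level between the cuts), yet differ by ~1e-16 between
# summation orders.  Values within this relative tolerance of the optimum are
# treated as exact ties so the lexicographic tie-break is reproducible.
_TIE_RTOL = 1e-12


def _lex_argbest(score: np.ndarray, maximize: bool) -> ThresholdVector:
    """Lexicographically smallest (s, t) among near-ties for the optimum."""
    if maximize:
        score = -score
    m = score.min()
    ties = score <= m + _TIE_RTOL * max(1.0, abs(m))
    flat = int(np.argmax(ties))  # first True in row-major order
    w = score.shape[1]
    return ThresholdVector(s=flat // w + 1, t=flat % w + 1)


def _lex_argbest_1d(score: np.ndarray, maximize: bool) -> int:
    if maximize:
        score = -score
    m = score.min()
    return int(np.argmax(score <= m + _TIE_RTOL * max(1.0, abs(m)))) + 1


def _criterion_grids(p: np.ndarray):
    """Admissibility mask and the shared region sums used by the 2-D selectors."""
    L = p.shape[0]
    i = np.arange(L, dtype=np.float64)
    with np.errstate(divide="ignore"):
        logi = np.where(i > 0, np.log(np.where(i > 0, i, 1.0)), 0.0)

    P0, P1 = _region_grids(p)
    Si0, Si1 = _region_grids(i[:, None] * p)
    Sj0, Sj1 = _region_grids(i[None, :] * p)
    adm = (P0 > 0) & (P1 > 0)
    return i, logi, P0, P1, Si0, Si1, Sj0, Sj1, adm


def _f_dispersion(S, P):
    """S * log(S / P): the -sum(w) log(mean) part of a class dispersion.

    Zero when S = 0 (all class mass at coordinate 0, the 0 log 0 convention).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        out = S * np.log(S / P)
    return np.where(S > 0, out, 0.0)


def select_threshold_min_re(hist, charge_excluded: bool = True) -> ThresholdVector:
    """Exhaustive minimum-relative-entropy threshold search.

    Evaluates every admissible ``(s, t)`` (both classes nonempty) via prefix
    sums and returns the minimizer; exact ties go to the smallest ``(s, t)``
    lexicographically.

    Parameters
    ----------
    hist : GLLREHistogram or (L, L) array
    charge_excluded : bool
        The per-class terms of D are nonnegative dispersions, so minimizing
        the strip-only sum alone is degenerate: it always shrinks the strip
        to the smallest admissible sliver of mass and the selected ``s``
        carries no information.  By default the high-LRE region ``j >= t``
        is therefore charged its own dispersion term (same functional form,
        its own mean vector) -- it is treated as the edge/noise class the
        quadrant semantics describe, total mass is conserved, and the search
        becomes well-posed: ``t*`` settles where the LRE tail separates from
        the bulk and ``s*`` at the gray-level valley.  Set False for the
        literal strip-only objective.

    Raises
    ------
    NoThresholdError
        If no ``(s, t)`` leaves both classes nonempty (constant image).
    """
    p = _as_p(hist)
    i, logi, P0, P1, Si0, Si1, Sj0, Sj1, adm = _criterion_grids(p)
    if not adm.any():
        raise NoThresholdError("no admissible (s, t): need two occupied gray levels")

    ipli = (i * logi)[:, None] * p  # i p_ij log i
    jplj = (i * logi)[None, :] * p  # j p_ij log j
    Sil0, Sil1 = _region_grids(ipli)
    Sjl0, Sjl1 = _region_grids(jplj)

    f = _f_dispersion
    with np.errstate(invalid="ignore"):
        D = (
            Sil0 - f(Si0, P0)
            + Sjl0 - f(Sj0, P0)
            + Sil1 - f(Si1, P1)
            + Sjl1 - f(Sj1, P1)
        )

    if charge_excluded:
        # suffix sums over the excluded region (all i, j >= t), per t
        L = p.shape[0]

        def suffix(a: np.ndarray) -> np.ndarray:
            cols = a.sum(axis=0)
            return cols[::-1].cumsum()[::-1][1:L]  # index [t-1] = sum_{j>=t}

        Q = suffix(p)
        Qi = suffix(i[:, None] * p)
        Qj = suffix(i[None, :] * p)
        Qil = suffix(ipli)
        Qjl = suffix(jplj)
        with np.errstate(invalid="ignore"):
            g = Qil - f(Qi, Q) + Qjl - f(Qj, Q)
        g = np.where(Q > 0, g, 0.0)
        D = D + g[None, :]

    D = np.where(adm, D, np.inf)
    return _lex_argbest(D, maximize=False)


def otsu_gllre(hist) -> ThresholdVector:
    """2-D Otsu on the GLLRE histogram over the C0/C1 regions.

    Maximizes ``P0 ||mu0 - muT||^2 + P1 ||mu1 - muT||^2`` where ``muT`` is
    the mean vector of the renormalized low-LRE strip.
    """
    p = _as_p(hist)
    _, _, P0, P1, Si0, Si1, Sj0, Sj1, adm = _criterion_grids(p)
    if not adm.any():
        raise NoThresholdError("no admissible (s, t): need two occupied gray levels")

    Pt = P0 + P1
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0i, mu0j = Si0 / P0, Sj0 / P0
        mu1i, mu1j = Si1 / P1, Sj1 / P1
        muTi, muTj = (Si0 + Si1) / Pt, (Sj0 + Sj1) / Pt
        score = P0 * ((mu0i - muTi) ** 2 + (mu0j - muTj) ** 2) + P1 * (
            (mu1i - muTi) ** 2 + (mu1j - muTj) ** 2
        )
    score = np.where(adm, score, -np.inf)
    return _lex_argbest(score, maximize=True)


def kapur_gllre(hist) -> ThresholdVector:
    """2-D maximum-entropy (Kapur) criterion over the C0/C1 regions.

    Maximizes the sum of Shannon entropies of the two renormalized class
    distributions: H_c = log P_c - (1/P_c) * sum_c p log p.
    """
    p = _as_p(hist)
    _, _, P0, P1, _, _, _, _, adm = _criterion_grids(p)
    if not adm.any():
        raise NoThresholdError("no admissible (s, t): need two occupied gray levels")

    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    Spl0, Spl1 = _region_grids(plogp)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.log(P0) - Spl0 / P0 + np.log(P1) - Spl1 / P1
    score = np.where(adm, score, -np.inf)
    return _lex_argbest(score, maximize=True)


# ---------------------------------------------------------------------------
# 1-D baselines


def _as_hist1d(gray_hist) -> np.ndarray:
    h = np.asarray(gray_hist, dtype=np.float64)
    if h.ndim != 1 or h.size < 2:
        raise InvalidInputError(f"expected a 1-D histogram of length >= 2, got {h.shape}")
    if h.min() < 0 or h.sum() == 0:
        raise InvalidInputError("histogram must be nonnegative with positive mass")
    return h / h.sum()


def otsu_1d(gray_hist) -> int:
    """Classical Otsu threshold: maximize between-class variance.

    Classes are ``i < s`` and ``i >= s``; returns the smallest maximizing s.
    """
    w = _as_hist1d(gray_hist)
    L = w.size
    i = np.arange(L, dtype=np.float64)
    P0 = np.cumsum(w)[: L - 1]  # P0[s-1] = sum_{i<s} w_i
    M0 = np.cumsum(i * w)[: L - 1]
    P1 = 1.0 - P0
    M1 = (i * w).sum() - M0
    adm = (P0 > 0) & (P1 > 0)
    if not adm.any():
        raise NoThresholdError("constant histogram: no threshold separates two classes")
    with np.errstate(divide="ignore", invalid="ignore"):
        score = P0 * P1 * (M0 / P0 - M1 / P1) ** 2
    score = np.where(adm, score, -np.inf)
    return _lex_argbest_1d(score, maximize=True)


def kapur_1d(gray_hist) -> int:
    """Kapur maximum-entropy threshold: maximize H(C0) + H(C1).

    Class distributions are renormalized before the Shannon entropy; same
    class convention and tie-break as :func:`otsu_1d`.
    """
    w = _as_hist1d(gray_hist)
    L = w.size
    with np.errstate(divide="ignore", invalid="ignore"):
        wlogw = np.where(w > 0, w * np.log(np.where(w > 0, w, 1.0)), 0.0)
    P0 = np.cumsum(w)[: L - 1]
    E0 = np.cumsum(wlogw)[: L - 1]
    P1 = 1.0 - P0
    E1 = wlogw.sum() - E0
    adm = (P0 > 0) & (P1 > 0)
    if not adm.any():
        raise NoThresholdError("constant histogram: no threshold separates two classes")
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.log(P0) - E0 / P0 + np.log(P1) - E1 / P1
    score = np.where(adm, score, -np.inf)
    return _lex_argbest_1d(score, maximize=True)


def apply_threshold(image: np.ndarray, tv, invert: bool = False) -> np.ndarray:
    """Label pixels by the gray-level cut alone: foreground iff I < s.

    The LRE cut ``t`` shapes the criterion during selection but plays no
    role at labeling time.  ``invert`` flips the polarity, for images whose
    objects are brighter than the background.
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise InvalidInputError(f"expected a non-empty 2-D image, got {image.shape}")
    s = int(tv[0]) if isinstance(tv, (tuple, ThresholdVector, list, np.ndarray)) else int(tv)
    mask = (image < s).astype(np.uint8)
    if invert:
        mask = 1 - mask
    return mask
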