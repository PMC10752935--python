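"""Group-level inference: paired t maps, TFCE, sign-flip permutation tests.

Tests compare a per-subject quantity (TRF amplitude over lags, or prediction
accuracy over voxels) against its circular-shift noise floor with a one-tailed
paired design.  Threshold-free cluster enhancement (TFCE) integrates cluster
extent^E × height^H over an ascending ladder of thresholds, boosting
contiguous effects without a fixed cluster-forming threshold; family-wise
error is controlled by the max-statistic permutation distribution over
per-subject sign flips of the paired differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats as sps

T_CAP = 1e6

__all__ = [
    "GridAdjacency",
    "EdgeAdjacency",
    "chain_adjacency",
    "grid_adjacency",
    "StatResult",
    "paired_t_map",
    "tfce",
    "tfce_bruteforce",
    "permutation_test",
    "extract_peaks",
    "compare_peaks_wilcoxon",
    "WilcoxonResult",
]


@dataclass(frozen=True)
class GridAdjacency:
    """Orthogonal (chain / 6-connectivity) neighborhood on a regular grid."""

    shape: tuple[int, ...]

    @property
    def n_elements(self) -> int:
        return int(np.prod(self.shape))

    def edges(self) -> np.ndarray:
        idx = np.arange(self.n_elements).reshape(self.shape)
        pairs = []
        for ax in range(len(self.shape)):
            a = np.moveaxis(idx, ax, 0)
            pairs.append(np.stack([a[:-1].ravel(), a[1:].ravel()], axis=1))
        return np.concatenate(pairs, axis=0)


@dataclass(frozen=True)
class EdgeAdjacency:
    """Explicit neighbor graph over arbitrary elements."""

    n_elements: int
    edge_list: np.ndarray  # (E, 2)

    def edges(self) -> np.ndarray:
        return self.edge_list


def chain_adjacency(n: int) -> GridAdjacency:
    return GridAdjacency((n,))


def grid_adjacency(shape: tuple[int, ...]) -> GridAdjacency:
    return GridAdjacency(tuple(shape))


def voxel_adjacency(coords_mm: np.ndarray, spacing_mm: float) -> EdgeAdjacency:
    """6-connectivity from physical coordinates: neighbors one spacing apart."""
    coords = np.asarray(coords_mm, dtype=np.float64)
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    i, j = np.nonzero(np.isclose(d, spacing_mm))
    keep = i < j
    return EdgeAdjacency(coords.shape[0], np.stack([i[keep], j[keep]], axis=1))


@dataclass
class StatResult:
    t_map: np.ndarray
    tfce_map: np.ndarray
    p_map: np.ndarray
    sig_mask: np.ndarray
    t_max: float
    n_permutations: int
    alpha: float
    tail: str = "one_tailed"
    degenerate_t: bool = False
    extra: dict = field(default_factory=dict)

    def sig_ranges(self, grid: np.ndarray) -> list[tuple[float, float]]:
        """Contiguous significant runs, as (start, stop) values of ``grid``."""
        mask = np.asarray(self.sig_mask, dtype=bool)
        if mask.ndim != 1:
            raise ValueError("ranges are defined for 1-D element sets")
        ranges = []
        in_run = False
        for i, m in enumerate(mask):
            if m and not in_run:
                start = grid[i]
                in_run = True
            if not m and in_run:
                ranges.append((float(start), float(grid[i - 1])))
                in_run = False
        if in_run:
            ranges.append((float(start), float(grid[-1])))
        return ranges


def paired_t_map(values_a: np.ndarray, values_b: np.ndarray) -> np.ndarray:
    """Elementwise paired t over the subject axis (axis 0), sd-zero guarded.

    t = mean(d) / (sd(d)/√n) with the sample sd (ddof 1).  Constant nonzero
    differences give ±T_CAP; all-zero differences give t = 0.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape or a.shape[0] < 2:
        raise ValueError("paired samples must match and contain n >= 2 subjects")
    d = a - b
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(sd == 0, np.sign(mean) * T_CAP, t)
    return t


def _component_extent(values: np.ndarray, adjacency, threshold: float) -> np.ndarray:
    """Size of the suprathreshold connected component of each element (0 if sub)."""
    mask = values >= threshold
    if isinstance(adjacency, GridAdjacency):
        m = mask.reshape(adjacency.shape)
        labels, _ = ndimage.label(m)  # orthogonal connectivity by default
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        return sizes[labels].ravel().astype(np.float64)
    # generic graph: union-find over the masked subgraph
    n = adjacency.n_elements
    parent = np.arange(n)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in adjacency.edges():
        if mask[i] and mask[j]:
            ri, rj = find(int(i)), find(int(j))
            if ri != rj:
                parent[rj] = ri
    roots = np.array([find(int(i)) if mask[i] else -1 for i in range(n)])
    sizes = np.zeros(n)
    for i in range(n):
        if roots[i] >= 0:
            sizes[roots[i]] += 1
    return np.where(roots >= 0, sizes[np.maximum(roots, 0)], 0.0)


def tfce(
    values: np.ndarray,
    adjacency,
    e: float = 0.5,
    h: float = 2.0,
    dh: float | None = None,
    n_steps: int = 100,
) -> np.ndarray:
    """Threshold-free cluster enhancement (one-tailed: negatives contribute 0).

    TFCE(p) = Σ_{hh = dh, 2dh, … ≤ v(p)} extent(p, hh)^e · hh^h · dh, where
    extent is the size of the suprathreshold connected component containing p.
    ``dh`` defaults to max(values)/``n_steps``.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if not np.isfinite(v).all():
        raise ValueError("non-finite map values")
    vmax = v.max(initial=0.0)
    if vmax <= 0:
        return np.zeros_like(v)
    if dh is None:
        dh = vmax / n_steps
    out = np.zeros_like(v)
    hh = dh
    while hh <= vmax + 1e-12:
        ext = _component_extent(v, adjacency, hh)
        sup = ext > 0
        out[sup] += ext[sup] ** e * hh**h * dh
        hh += dh
    return out


def tfce_bruteforce(
    values: np.ndarray,
    adjacency,
    e: float = 0.5,
    h: float = 2.0,
    dh: float | None = None,
    n_steps: int = 100,
) -> np.ndarray:
    """Slow reference TFCE: per-threshold breadth-first component search.

    Independent of the fast path (no scipy labeling, no union-find); intended
    for verification on small maps.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    n = v.size
    vmax = v.max(initial=0.0)
    if vmax <= 0:
        return np.zeros(n)
    if dh is None:
        dh = vmax / n_steps
    nbr: list[list[int]] = [[] for _ in range(n)]
    for i, j in adjacency.edges():
        nbr[int(i)].append(int(j))
        nbr[int(j)].append(int(i))
    out = np.zeros(n)
    hh = dh
    while hh <= vmax + 1e-12:
        seen = [False] * n
        for start in range(n):
            if seen[start] or v[start] < hh:
                continue
            queue = [start]
            seen[start] = True
            comp = []
            while queue:
                x = queue.pop()
                comp.append(x)
                for y in nbr[x]:
                    if not seen[y] and v[y] >= hh:
                        seen[y] = True
                        queue.append(y)
            bump = len(comp) ** e * hh**h * dh
            for x in comp:
                out[x] += bump
        hh += dh
    return out


def _sign_flip_matrix(n_subjects: int, n_permutations: int, seed: int) -> np.ndarray:
    if 2**n_subjects <= n_permutations:
        bits = np.arange(2**n_subjects)
        signs = 1 - 2 * ((bits[:, None] >> np.arange(n_subjects)) & 1)
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1, 1], size=(n_permutations, n_subjects))
        signs[0] = 1  # the identity permutation anchors p >= 1/n
    return signs.astype(np.float64)


def permutation_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    adjacency,
    n_permutations: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
    e: float = 0.5,
    h: float = 2.0,
    n_steps: int = 100,
) -> StatResult:
    """One-tailed paired test (a > b) with TFCE and max-statistic permutations.

    The observed statistic is TFCE of the paired-t map; the null distribution
    is the maximum TFCE value under per-subject sign flips of the differences
    (full enumeration when 2^n ≤ ``n_permutations``, else Monte Carlo with the
    identity flip included).  p(element) is the fraction of null maxima ≥ the
    observed TFCE, so min p = 1/n_permutations > 0.  ``t_max`` is the largest
    t value within the significant mask (NaN when nothing is significant).
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    orig_shape = a.shape[1:]
    a = a.reshape(a.shape[0], -1)
    b = b.reshape(b.shape[0], -1)
    n_sub = a.shape[0]
    if n_sub < 5:
        import warnings

        warnings.warn("fewer than 5 subjects: permutation p resolution is coarse",
                      stacklevel=2)
    d = a - b
    t_obs = paired_t_map(a, b)
    degenerate = bool(np.any(np.abs(t_obs) >= T_CAP))

    signs = _sign_flip_matrix(n_sub, n_permutations, seed)
    k = signs.shape[0]
    means = signs @ d / n_sub
    m2 = (d**2).mean(axis=0)
    var = (m2 - means**2) * (n_sub / (n_sub - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = means / np.sqrt(var / n_sub)
    t_null = np.where(var <= 0, np.sign(means) * T_CAP, t_null)

    # one threshold ladder for every map (observed and permuted): dh from the
    # global maximum keeps the enhancement function identical across maps and
    # bounds the work at n_steps thresholds per map
    global_max = max(float(t_obs.max(initial=0.0)), float(t_null.max(initial=0.0)))
    dh = max(global_max, 1e-12) / n_steps
    tfce_obs = tfce(t_obs, adjacency, e=e, h=h, dh=dh)
    null_max = np.empty(k)
    for i in range(k):
        null_max[i] = tfce(t_null[i], adjacency, e=e, h=h, dh=dh).max(initial=0.0)
    p = (null_max[None, :] >= tfce_obs[:, None]).mean(axis=1)
    sig = p <= alpha
    t_max = float(t_obs[sig].max()) if sig.any() else float("nan")
    return StatResult(
        t_map=t_obs.reshape(orig_shape),
        tfce_map=tfce_obs.reshape(orig_shape),
        p_map=p.reshape(orig_shape),
        sig_mask=sig.reshape(orig_shape),
        t_max=t_max,
        n_permutations=k,
        alpha=alpha,
        degenerate_t=degenerate,
        extra={"seed": seed, "dh": dh},
    )


def extract_peaks(
    corrected_amplitudes: np.ndarray,
    lag_grid_ms: np.ndarray,
    window_ms: tuple[float, float] = (20.0, 50.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Peak (max) of noise-floor-corrected amplitude within a lag window.

    ``corrected_amplitudes``: (..., L); a voxel axis, if present, must be
    averaged by the caller beforehand (region-of-interest averaging).  Returns
    (peak values, peak latencies in ms), shapes (...,).  Peaks may be
    negative — no clipping.
    """
    amp = np.asarray(corrected_amplitudes, dtype=np.float64)
    lags = np.asarray(lag_grid_ms, dtype=np.float64)
    lo, hi = window_ms
    sel = (lags >= lo) & (lags <= hi)
    if not sel.any():
        raise ValueError("peak window lies outside the lag grid")
    windowed = amp[..., sel]
    idx = windowed.argmax(axis=-1)
    peaks = np.take_along_axis(windowed, idx[..., None], axis=-1)[..., 0]
    lat = lags[sel][idx]
    return peaks, lat


@dataclass
class WilcoxonResult:
    w: float          # sum of the ranks of negative differences
    p: float
    n_used: int
    no_test: bool = False


def compare_peaks_wilcoxon(
    peaks_attend: np.ndarray, peaks_ignore: np.ndarray
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired peak amplitudes.

    Zero differences are dropped.  The reported statistic follows the
    W = Σ ranks of *negative* differences convention (so uniformly positive
    attend−ignore differences give W = 0); p-values are exact for n ≤ 25 when
    no rank ties occur, normal-approximate otherwise.
    """
    d = np.asarray(peaks_attend, dtype=np.float64) - np.asarray(
        peaks_ignore, dtype=np.float64
    )
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(float("nan"), float("nan"), 0, no_test=True)
    ranks = sps.rankdata(np.abs(d))
    w_neg = float(ranks[d < 0].sum())
    ties = np.unique(np.abs(d)).size < n
    method = "exact" if (n <= 25 and not ties) else "approx"
    res = sps.wilcoxon(d, alternative="two-sided", method=method)
    return WilcoxonResult(w_neg, float(res.pvalue), n)
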