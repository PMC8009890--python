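"""ERP microstate analysis: topographic clustering, template fitting, features.

A *microstate* is a brief period during which the scalp potential field keeps
a quasi-stable topography while only its strength (global field power, GFP)
varies. For event-related potentials the analysis is polarity-sensitive:
time-locked averages carry component identity in their sign (an Nc is a
frontal negativity), so spatial correlations are signed by default, unlike
resting-state microstate practice which rectifies them.

The pipeline implemented here:

1. cluster the GFP-normalised topographies of a reference grand average with
   atomize-and-agglomerate hierarchical clustering (AAHC);
2. select the number of maps by cross-validated explained variance with a
   randomization test on the per-map improvement;
3. fit the resulting template maps to individual ERPs by per-sample spatial
   correlation;
4. extract per-map total duration and mean GFP inside a feature window.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .erp import ErpWaveform, average_reference, grand_average

logger = logging.getLogger(__name__)

#: Samples whose GFP falls below this (in µV) are treated as flat and
#: cannot be normalised or correlated.
FLAT_TOL = 1e-12


def gfp(sample: np.ndarray) -> float | np.ndarray:
    """Global field power: std across channels of one (or many) samples.

    GFP(v) = sqrt(mean_i (v_i - mean(v))^2), the population standard
    deviation of the potentials over the scalp — the strength of the field.
    Accepts a 1-D channel vector or a channel x sample matrix (in which
    case a per-sample GFP series is returned).
    """
    v = np.asarray(sample, dtype=float)
    if v.shape[0] < 2:
        raise ValueError("GFP requires at least 2 channels")
    return np.std(v, axis=0, ddof=0)


def normalize_topography(sample: np.ndarray) -> np.ndarray:
    """Average-reference a channel vector and scale it to unit GFP.

    Raises on flat (zero-GFP) input; callers decide whether a flat sample
    is skipped or label-carried.
    """
    v = np.asarray(sample, dtype=float)
    v = v - v.mean()
    g = np.sqrt(np.mean(v**2))
    if g < FLAT_TOL:
        raise ValueError("flat topography: zero GFP")
    return v / g


def spatial_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two topographies across channels.

    Equals the cosine similarity of the average-referenced vectors.
    Polarity-sensitive: no absolute value is taken.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("inputs must be equal-length channel vectors (>=2 channels)")
    return float(np.dot(normalize_topography(a), normalize_topography(b)) / a.size)


@dataclass
class MicrostateMaps:
    """k prototypical topographies, each average-referenced with unit GFP."""

    maps: np.ndarray  # (k, n_channels)
    source: str = ""

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2 or self.maps.shape[0] < 2:
            raise ValueError("need a k x channels matrix with k >= 2")
        means = self.maps.mean(axis=1)
        gfps = np.sqrt(np.mean((self.maps - means[:, None]) ** 2, axis=1))
        if np.max(np.abs(means)) > 1e-6 or np.max(np.abs(gfps - 1)) > 1e-6:
            raise ValueError("maps must be average-referenced with unit GFP")

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


@dataclass
class Segmentation:
    """Per-sample microstate labelling of one ERP over an analysis window."""

    labels: np.ndarray  # 1-based map index per in-window sample
    gfp: np.ndarray  # raw (un-normalised) GFP per sample, µV
    spatial_corr: np.ndarray  # correlation with the winning map
    times: np.ndarray  # ms, same length
    window: tuple[float, float]
    k: int


@dataclass
class MicrostateFeatures:
    """Per-map duration and mean GFP inside a feature window, one condition.

    ``duration_ms[m]`` is the total time labelled map m (contiguous or not),
    so durations over maps always sum to the window length.  ``mean_gfp[m]``
    is NaN and ``present[m]`` False for a map never expressed in the window.
    """

    duration_ms: np.ndarray  # (k,)
    mean_gfp: np.ndarray  # (k,), NaN where absent
    present: np.ndarray  # (k,) bool
    feature_window: tuple[float, float]
    condition: str = ""


# ---------------------------------------------------------------------------
# AAHC clustering
# ---------------------------------------------------------------------------


def _corr_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Correlations between rows of two matrices of normalised topographies."""
    return x @ y.T / x.shape[1]


def _refine_centroids(
    x: np.ndarray,
    w2: np.ndarray,
    centroids: np.ndarray,
    n_iter: int,
    ignore_polarity: bool,
) -> np.ndarray:
    """Correlation k-means polish: full reassignment + centroid update.

    Runs until the labelling stabilises or ``n_iter`` passes; empty clusters
    keep their centroid. Output is ordered by assigned GEV, descending.
    """
    cents = centroids.copy()
    prev: np.ndarray | None = None
    for _ in range(n_iter):
        c = _corr_matrix(x, cents)
        if ignore_polarity:
            c = np.abs(c)
        lab = np.argmax(c, axis=1)
        if prev is not None and np.array_equal(lab, prev):
            break
        prev = lab
        for j in range(cents.shape[0]):
            sel = lab == j
            if not sel.any():
                continue
            sub = x[sel]
            if ignore_polarity:
                signs = np.sign(sub @ cents[j])
                signs[signs == 0] = 1.0
                sub = sub * signs[:, None]
            m = sub.mean(axis=0)
            if np.sqrt(np.mean((m - m.mean()) ** 2)) > FLAT_TOL:
                cents[j] = normalize_topography(m)
    c = _corr_matrix(x, cents)
    if ignore_polarity:
        c = np.abs(c)
    lab = np.argmax(c, axis=1)
    contrib = np.array(
        [float(np.sum(w2[lab == j] * c[lab == j, j] ** 2)) for j in range(cents.shape[0])]
    )
    order = np.argsort(-contrib, kind="stable")
    return cents[order]


def aahc_cluster(
    samples: np.ndarray | Sequence[np.ndarray],
    k_target: int,
    weights: np.ndarray | None = None,
    *,
    ignore_polarity: bool = False,
    capture: Sequence[int] = (),
    refine: int = 0,
    refine_below: int | None = None,
) -> MicrostateMaps | tuple[MicrostateMaps, dict[int, np.ndarray]]:
    """Atomize-and-agglomerate hierarchical clustering of topographies.

    Each normalised sample starts as its own cluster. At every step the
    cluster contributing least to the global explained variance (GEV) is
    dissolved and its members are reassigned to the remaining cluster whose
    centroid correlates best with them; affected centroids are recomputed as
    the polarity-aligned mean renormalised to unit GFP. Stops at ``k_target``
    clusters.

    Parameters
    ----------
    samples : array (n, channels)
        Normalised topographies (zero-mean, unit GFP rows).
    k_target : int
        Number of clusters to stop at (>= 2).
    weights : array (n,), optional
        Per-sample GFP weights entering GEV; defaults to 1.
    ignore_polarity : bool
        Rectified correlations (resting-state convention). Off by default:
        ERP analysis is polarity-sensitive.
    capture : sequence of int
        Additional cluster counts at which to snapshot the centroids, for
        reusing one agglomeration run across several k.
    refine : int
        After reaching a requested cluster count, run up to this many
        full-reassignment iterations (correlation k-means) to polish the
        centroids. Greedy agglomeration can strand boundary samples in
        the wrong cluster; refinement locally maximises GEV. 0 = pure AAHC.
    refine_below : int, optional
        Also interleave the polish into the agglomeration itself whenever
        the live cluster count is at or below this value (default:
        2 + twice the largest requested count). Greedy dissolution can
        destroy a genuine low-GFP cluster early; re-sorting samples at each
        low level keeps the hierarchy honest. Ignored when ``refine`` is 0.

    Returns
    -------
    MicrostateMaps ordered by total assigned GEV (descending), or a pair
    ``(maps, snapshots)`` when ``capture`` is non-empty, where ``snapshots``
    maps each captured k to its centroid matrix (same ordering rule).
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 2:
        raise ValueError("samples must be an n x channels matrix")
    n, nch = x.shape
    if not (2 <= k_target <= n):
        raise ValueError("need len(samples) >= k_target >= 2")
    # defensive renormalisation (also rejects flat rows)
    x = np.apply_along_axis(normalize_topography, 1, x)
    w2 = np.ones(n) if weights is None else np.asarray(weights, dtype=float) ** 2
    if w2.shape != (n,):
        raise ValueError("weights must match the number of samples")
    denom = w2.sum()

    members: list[list[int]] = [[i] for i in range(n)]
    centroids = x.copy()
    alive = np.ones(n, dtype=bool)
    contrib = w2.copy()  # each singleton: (w * corr(sample, itself))^2 = w^2

    def _centroid_of(idx: list[int]) -> np.ndarray:
        sub = x[idx]
        if ignore_polarity and len(idx) > 1:
            ref = sub[0]
            signs = np.sign(sub @ ref)
            signs[signs == 0] = 1.0
            sub = sub * signs[:, None]
        return normalize_topography(sub.mean(axis=0))

    def _contrib_of(ci: int) -> float:
        idx = members[ci]
        c = _corr_matrix(x[idx], centroids[ci][None, :])[:, 0]
        if ignore_polarity:
            c = np.abs(c)
        return float(np.sum(w2[idx] * c**2))

    snapshots: dict[int, np.ndarray] = {}
    want = set(capture)

    def _ordered_centroids() -> np.ndarray:
        live = np.nonzero(alive)[0]
        order = live[np.argsort(-contrib[live], kind="stable")]
        cents = centroids[order].copy()
        if refine > 0 and cents.shape[0] < n:
            cents = _refine_centroids(x, w2, cents, refine, ignore_polarity)
        return cents

    if refine_below is None:
        refine_below = 2 + 2 * max([k_target, *want] or [k_target])

    def _interleaved_refine() -> None:
        """Re-sort every sample among the live centroids and rebuild state."""
        live = np.nonzero(alive)[0]
        cents = centroids[live].copy()
        prev_lab: np.ndarray | None = None
        for _ in range(refine):
            c = _corr_matrix(x, cents)
            if ignore_polarity:
                c = np.abs(c)
            lab = np.argmax(c, axis=1)
            if prev_lab is not None and np.array_equal(lab, prev_lab):
                break
            prev_lab = lab
            for j in range(len(live)):
                sel = lab == j
                if not sel.any():
                    continue
                sub = x[sel]
                if ignore_polarity:
                    signs = np.sign(sub @ cents[j])
                    signs[signs == 0] = 1.0
                    sub = sub * signs[:, None]
                m = sub.mean(axis=0)
                if np.sqrt(np.mean((m - m.mean()) ** 2)) > FLAT_TOL:
                    cents[j] = normalize_topography(m)
        for j, ci in enumerate(live):
            members[ci] = list(np.nonzero(prev_lab == j)[0]) if prev_lab is not None else members[ci]
            centroids[ci] = cents[j]
            contrib[ci] = _contrib_of(ci) if members[ci] else 0.0

    n_alive = n
    if n_alive in want:
        snapshots[n_alive] = _ordered_centroids()
    while n_alive > k_target:
        live = np.nonzero(alive)[0]
        if refine > 0 and n_alive <= refine_below:
            # near the interesting cluster counts, dissolve the cluster whose
            # loss of explained variance is smallest once its members are
            # re-homed: a twin of another cluster costs nothing to dissolve,
            # while a weak-field but unique state costs its full contribution.
            # (The plain minimum-contribution rule used higher up would
            # sacrifice unique low-GFP states and keep duplicates.)
            c_all = _corr_matrix(x, centroids[live])
            if ignore_polarity:
                c_all = np.abs(c_all)
            losses = np.empty(len(live))
            for j, ci in enumerate(live):
                idx = members[ci]
                if not idx:
                    losses[j] = 0.0
                    continue
                others = np.delete(c_all[idx], j, axis=1)
                best_other = others.max(axis=1) if others.size else np.zeros(len(idx))
                losses[j] = contrib[ci] - float(np.sum(w2[idx] * best_other**2))
            victim = live[int(np.argmin(losses))]
        else:
            # dissolve the cluster with the smallest GEV contribution;
            # ties break toward the lowest cluster index (argmin is first-min)
            victim = live[int(np.argmin(contrib[live]))]
        alive[victim] = False
        n_alive -= 1
        orphans = members[victim]
        members[victim] = []
        live = np.nonzero(alive)[0]
        c = _corr_matrix(x[orphans], centroids[live])
        if ignore_polarity:
            c = np.abs(c)
        dest = live[np.argmax(c, axis=1)]
        touched = set()
        for t, d in zip(orphans, dest):
            members[d].append(t)
            touched.add(int(d))
        for d in touched:
            centroids[d] = _centroid_of(members[d])
            contrib[d] = _contrib_of(d)
        if refine > 0 and n_alive <= refine_below:
            _interleaved_refine()
        if n_alive in want:
            snapshots[n_alive] = _ordered_centroids()

    final = MicrostateMaps(_ordered_centroids())
    if capture:
        return final, snapshots
    return final


# ---------------------------------------------------------------------------
# Template fitting and features
# ---------------------------------------------------------------------------


def fit_templates(
    erp: ErpWaveform,
    maps: MicrostateMaps,
    window: tuple[float, float],
    *,
    ignore_polarity: bool = False,
) -> Segmentation:
    """Label every in-window sample with its best-correlating template map.

    Each sample topography is GFP-normalised and correlated with every map;
    the winning (1-based) map index is the argmax of the signed correlation
    (rectified if ``ignore_polarity``). Ties go to the lowest map index.
    Flat samples carry the previous label forward (a leading flat run takes
    the first non-flat label), keeping the duration bookkeeping conserved.
    """
    if erp.n_channels != maps.n_channels:
        raise ValueError("channel count mismatch between ERP and maps")
    idx = erp.window_indices(window)
    if idx.size == 0:
        raise ValueError("window contains no samples")
    data = erp.data[:, idx]
    data = data - data.mean(axis=0, keepdims=True)
    g = np.sqrt(np.mean(data**2, axis=0))
    flat = g < FLAT_TOL
    labels = np.zeros(idx.size, dtype=int)
    win_corr = np.zeros(idx.size)
    if np.all(flat):
        raise ValueError("all samples in the window are flat")
    normed = np.where(flat, 1.0, g)
    topo = (data / normed).T  # (n_samples, n_channels), unit GFP where non-flat
    corr = _corr_matrix(topo, maps.maps)
    if ignore_polarity:
        corr = np.abs(corr)
    best = np.argmax(corr, axis=1)  # first max -> lowest index on ties
    labels = best + 1
    win_corr = corr[np.arange(idx.size), best]
    if flat.any():
        nonflat = np.nonzero(~flat)[0]
        labels = labels.copy()
        # leading flats take the first non-flat label
        labels[: nonflat[0]] = labels[nonflat[0]]
        win_corr[: nonflat[0]] = np.nan
        for i in np.nonzero(flat)[0]:
            if i >= nonflat[0]:
                labels[i] = labels[i - 1]
                win_corr[i] = np.nan
    return Segmentation(
        labels=labels,
        gfp=g.astype(float),
        spatial_corr=win_corr,
        times=erp.times[idx],
        window=window,
        k=maps.k,
    )


def extract_features(
    seg: Segmentation,
    k: int,
    feature_window: tuple[float, float],
    fs: float,
) -> MicrostateFeatures:
    """Per-map total duration (ms) and mean raw GFP inside the feature window.

    Duration counts every in-window sample labelled m, contiguous or not,
    times the sample period — so durations over maps sum exactly to the
    window length. A map with zero duration gets NaN mean GFP and a False
    presence flag.
    """
    lo, hi = feature_window
    if lo < seg.window[0] - 1e-9 or hi > seg.window[1] + 1e-9:
        raise ValueError("feature window must lie inside the segmentation window")
    mask = (seg.times >= lo - 1e-9) & (seg.times <= hi + 1e-9)
    labels = seg.labels[mask]
    g = seg.gfp[mask]
    dt = 1000.0 / fs
    duration = np.zeros(k)
    mean_gfp = np.full(k, np.nan)
    present = np.zeros(k, dtype=bool)
    for m in range(1, k + 1):
        sel = labels == m
        cnt = int(sel.sum())
        duration[m - 1] = cnt * dt
        if cnt:
            mean_gfp[m - 1] = float(g[sel].mean())
            present[m - 1] = True
    return MicrostateFeatures(
        duration_ms=duration,
        mean_gfp=mean_gfp,
        present=present,
        feature_window=feature_window,
    )


def explained_variance(
    erp: ErpWaveform,
    maps: MicrostateMaps,
    window: tuple[float, float],
    *,
    ignore_polarity: bool = False,
) -> float:
    """Global explained variance of an ERP under a set of template maps.

    GEV = sum_t (gfp_t * corr(sample_t, winning map))^2 / sum_t gfp_t^2,
    a GFP-weighted squared correlation in [0, 1].
    """
    seg = fit_templates(erp, maps, window, ignore_polarity=ignore_polarity)
    return _gev_from_segmentation(seg)


def _gev_from_segmentation(seg: Segmentation) -> float:
    g2 = np.sum(seg.gfp**2)
    if g2 <= 0:
        raise ValueError("all-flat window: GEV undefined")
    c = np.nan_to_num(seg.spatial_corr, nan=0.0)
    return float(np.sum((seg.gfp * c) ** 2) / g2)


# ---------------------------------------------------------------------------
# Map-count selection by cross-validated explained variance
# ---------------------------------------------------------------------------


@dataclass
class CvParams:
    """Cross-validation settings for map-count selection.

    ``n_splits`` random half splits of the reference subjects; the per-step
    improvement in mean test explained variance is tested against a null in
    which the added map is an arbitrary random topography (``n_randomizations``
    draws), one-sided at level ``alpha``.
    """

    n_splits: int = 10
    train_fraction: float = 0.5
    n_randomizations: int = 200
    alpha: float = 0.05
    refine_iter: int = 20  # correlation k-means polish after agglomeration
    seed: int = 0


class MapSelection(NamedTuple):
    k_opt: int
    maps: MicrostateMaps
    test_ev: dict[int, float]  # mean test EV per k
    p_values: dict[int, float]  # p for the step (k-1) -> k
    warnings: tuple[str, ...]


def _normalized_window(erp: ErpWaveform, window: tuple[float, float]):
    """Normalised in-window topographies and their raw GFPs for one ERP."""
    idx = erp.window_indices(window)
    data = erp.data[:, idx]
    data = data - data.mean(axis=0, keepdims=True)
    g = np.sqrt(np.mean(data**2, axis=0))
    keep = g >= FLAT_TOL
    return (data[:, keep] / g[keep]).T, g[keep]


def select_n_maps(
    reference_erps: list[ErpWaveform],
    k_range: Sequence[int],
    cv: CvParams | None = None,
    *,
    window: tuple[float, float] = (0.0, 794.0),
    ignore_polarity: bool = False,
) -> MapSelection:
    """Choose the number of microstate maps by cross-validated explained variance.

    For each random split of the reference subjects, template maps for every
    k in ``k_range`` are learned from the training grand average (one AAHC
    agglomeration run captures all k, each snapshot polished by correlation
    k-means). Test explained variance is the mean GEV of the held-out
    subjects' ERPs under those maps.

    Because argmax fitting makes test EV weakly monotone in k, the step from
    k-1 to k maps is judged by a randomization test on the residuals: with
    the k-1 assignment of each held-out sample fixed, the GEV gain of the
    genuinely new k-th topography (the candidate least correlated with the
    k-1 templates) is compared against the same gain after randomly
    re-orienting the residuals about the k-1 model (one shared channel
    permutation and sign flip per draw). Under the null that k-1 maps fully
    describe the topographic structure, the residual orientation is
    exchangeable and the real gain looks like a null draw;
    p = (1 + #{null >= observed}) / (n_randomizations + 1). Walking k upward,
    the optimum is the last k in an unbroken chain of significant steps; if
    the first step already fails, the floor of ``k_range`` is returned with
    a warning. The returned maps are refit on the full reference grand
    average at the selected k.
    """
    cv = cv or CvParams()
    k_range = sorted(set(int(k) for k in k_range))
    if len(k_range) < 2 or k_range[0] < 2:
        raise ValueError("k_range must contain at least two values, all >= 2")
    n_sub = len(reference_erps)
    n_train = max(2, int(round(cv.train_fraction * n_sub)))
    if n_sub - n_train < 1:
        raise ValueError("degenerate split: no test subjects")
    rng = np.random.default_rng(cv.seed)
    nch = reference_erps[0].n_channels

    erps = [average_reference(e) for e in reference_erps]
    sub_topo = [_normalized_window(e, window) for e in erps]

    # Per split: learn snapshots at every k from the training grand average,
    # stack the held-out subjects' normalised topographies with GEV weights
    # normalised per subject (so each test subject contributes equally).
    splits = []
    ev = np.zeros((cv.n_splits, len(k_range)))
    for s in range(cv.n_splits):
        perm = rng.permutation(n_sub)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        ga = grand_average([erps[i] for i in train_idx])
        topo, g = _normalized_window(ga, window)
        _, snaps = aahc_cluster(
            topo, min(k_range), weights=g, ignore_polarity=ignore_polarity,
            capture=k_range, refine=cv.refine_iter,
        )
        blocks, wblocks = [], []
        for ti in test_idx:
            t_topo, t_g = sub_topo[ti]
            blocks.append(t_topo)
            wblocks.append(t_g**2 / np.sum(t_g**2) / len(test_idx))
        S = np.vstack(blocks)
        w = np.concatenate(wblocks)
        corr_by_k = {}
        for j, k in enumerate(k_range):
            c = _corr_matrix(S, snaps[k])
            if ignore_polarity:
                c = np.abs(c)
            corr_by_k[k] = c
            ev[s, j] = float(np.sum(w * c.max(axis=1) ** 2))
        splits.append((snaps, S, w, corr_by_k))

    # Walk k upward. The step k_prev -> k is significant when the GEV gain
    # attributable to the best candidate map (added to the k_prev templates
    # with assignments held fixed) exceeds the same gain after randomising
    # the orientation of the residuals about the k_prev model (shared channel
    # permutation + sign flip per draw) — the exchangeable-residual null.
    warns: list[str] = []
    p_values: dict[int, float] = {}
    k_opt = k_range[0]
    chain_alive = True
    for j in range(1, len(k_range)):
        if not chain_alive:
            break
        k_prev, k = k_range[j - 1], k_range[j]
        obs_split = np.zeros(cv.n_splits)
        null_split = np.zeros((cv.n_splits, cv.n_randomizations))
        for si, (snaps, S, w, corr_by_k) in enumerate(splits):
            prev_maps = snaps[k_prev]
            cand = snaps[k]
            c_prev = corr_by_k[k_prev]
            widx = np.argmax(c_prev, axis=1)
            c0 = c_prev[np.arange(len(S)), widx]
            cross = _corr_matrix(prev_maps, cand)  # (k_prev, k) corr among maps
            # the genuinely new topography: the candidate least explained by
            # the k_prev templates (gains of the others merely re-estimate
            # existing states and are not evidence for more of them)
            new_i = int(np.argmin(np.max(np.abs(cross), axis=0)))
            c_new = corr_by_k[k][:, new_i]
            obs_split[si] = float(
                w @ np.where(c_new > c0, c_new**2 - c0**2, 0.0)
            )
            # residuals about the fixed k_prev assignment (rows of S are
            # unit-GFP, so the residual is orthogonal to the winning map)
            R = S - c0[:, None] * prev_maps[widx]
            base = c0[:, None] * cross[widx, new_i : new_i + 1]  # (n, 1)
            n_rows, kc, kp = len(S), 1, prev_maps.shape[0]
            both = np.vstack([cand[new_i : new_i + 1], prev_maps])
            chunk = 50
            for start in range(0, cv.n_randomizations, chunk):
                nd = min(chunk, cv.n_randomizations - start)
                tilde = np.empty((nd, kc + kp, nch))
                for a in range(nd):
                    pi = rng.permutation(nch)
                    sg = rng.choice([-1.0, 1.0], size=nch)
                    tilde[a][:, pi] = sg * both
                G = (R @ tilde.reshape(-1, nch).T / nch).reshape(n_rows, nd, kc + kp)
                # surrogate corr of each candidate, with the unit-norm
                # correction from the winning-map / permuted-residual overlap
                cr = np.take_along_axis(
                    G[:, :, kc:], widx[:, None, None] + 0, axis=2
                )[:, :, 0]
                denom = np.sqrt(np.maximum(1e-12, 1.0 + 2.0 * c0[:, None] * cr))
                c_null = (base[:, None, :] + G[:, :, :kc]) / denom[:, :, None]
                if ignore_polarity:
                    c_null = np.abs(c_null)
                ng = np.where(
                    c_null > c0[:, None, None],
                    c_null**2 - c0[:, None, None] ** 2,
                    0.0,
                )
                null_split[si, start : start + nd] = np.max(
                    np.einsum("t,tdm->dm", w, ng), axis=1
                )
        # median across splits: robust to a minority of degenerate
        # training clusterings within the split ensemble
        obs = float(np.median(obs_split))
        null = np.median(null_split, axis=0)
        p = float((1 + np.sum(null >= obs)) / (cv.n_randomizations + 1))
        p_values[k] = p
        if p < cv.alpha:
            k_opt = k
        else:
            chain_alive = False
    if k_opt == k_range[0]:
        msg = (
            f"no significant explained-variance gain beyond k={k_range[0]}; "
            "returning the floor of k_range"
        )
        warns.append(msg)
        warnings.warn(msg, stacklevel=2)

    ga_all = grand_average(erps)
    topo, g = _normalized_window(ga_all, window)
    maps = aahc_cluster(
        topo, k_opt, weights=g, ignore_polarity=ignore_polarity, refine=cv.refine_iter
    )
    maps.source = f"reference grand average, window {window[0]}-{window[1]} ms, k={k_opt}"
    return MapSelection(
        k_opt=k_opt,
        maps=maps,
        test_ev={k: float(np.mean(ev[:, j])) for j, k in enumerate(k_range)},
        p_values=p_values,
        warnings=tuple(warns),
    )


def match_maps(estimated: MicrostateMaps, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Greedy one-to-one matching of estimated maps to reference topographies.

    Returns (permutation, |correlations|): ``permutation[i]`` is the index of
    the estimated map matched to reference row i. Used for recovery checks.
    """
    ref = np.apply_along_axis(normalize_topography, 1, np.asarray(reference, float))
    corr = np.abs(_corr_matrix(ref, estimated.maps))
    n = ref.shape[0]
    perm = np.full(n, -1)
    cors = np.zeros(n)
    c = corr.copy()
    for _ in range(min(n, estimated.k)):
        i, j = np.unravel_index(np.argmax(c), c.shape)
        perm[i] = j
        cors[i] = corr[i, j]
        c[i, :] = -1
        c[:, j] = -1
    return perm, cors
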