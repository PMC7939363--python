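"""Genotype-phenotype map statistics over screen outputs.

The *GPM regression* quantifies how fast morphological distance grows with
genetic distance within the IS one-mutant neighborhood of a parent: per
parameter, the nine perturbation levels (parent at 0%, mutants at -80..+80%)
define pairwise genetic distances x in {0, 20, ..., 160}%, the mean
morphological distance between the twin sets at two levels gives y, and the
ordinary least-squares slope beta is the GPM complexity of that parameter.
A large beta means small genetic changes produce large morphological
changes (a complex GPM); a flat but noisy plot -- high developmental
instability with no distance trend -- still yields a small beta.

All functions here are pure functions of their input tables; no simulation
happens in this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .core import Morphology
from .morphometrics import hmd as _hmd, mean_morphology
from .screens import (MutationRecord, mean_cross_distance,
                      mean_pairwise_distance)


@dataclass
class GPMRegression:
    parent_id: int
    descriptor: tuple
    metric: str
    points: list[tuple[float, float]]
    beta: float
    n_aberrant_excluded: int = 0


def gpm_regression(parent_twins: list[Morphology],
                   is_records: list[MutationRecord], metric: str = "cmd",
                   parent_id: int = 0) -> list[GPMRegression]:
    """One GPM regression per mutated parameter.

    The parent (0% perturbation) is included as a ninth level.  For EMD and
    CMD each point is the mean distance between all twins of one level and
    all twins of another (twin-twin pairs within a level give the x = 0
    points, i.e. developmental instability); for HMD each point is the
    distance between two mean morphologies and there is no x = 0 level.
    Mutants whose twins were all aberrant drop out with their pairs.
    """
    if metric not in ("emd", "cmd", "hmd"):
        raise ValueError(metric)
    by_param: dict[tuple, dict[float, MutationRecord]] = {}
    for rec in is_records:
        if rec.kind != "IS":
            continue
        by_param.setdefault(rec.descriptor, {})[rec.magnitude] = rec

    out = []
    for desc, by_mag in sorted(by_param.items()):
        levels: dict[float, list[Morphology]] = {0.0: parent_twins}
        n_excluded = 0
        for mag, rec in by_mag.items():
            if rec.twins:
                levels[float(mag)] = rec.twins
            else:
                n_excluded += 1
        points: list[tuple[float, float]] = []
        mags = sorted(levels)
        if metric == "hmd":
            means = {mg: mean_morphology(tw) for mg, tw in levels.items()}
            for a, b in combinations(mags, 2):
                points.append((abs(a - b), _hmd(means[a], means[b])))
        else:
            for mg in mags:
                if len(levels[mg]) >= 2:
                    points.append(
                        (0.0, mean_pairwise_distance(levels[mg], metric)))
            for a, b in combinations(mags, 2):
                points.append((abs(a - b),
                               mean_cross_distance(levels[a], levels[b],
                                                   metric)))
        xs = np.array([p[0] for p in points])
        ys = np.array([p[1] for p in points])
        if len(points) < 2 or np.ptp(xs) == 0:
            beta = 0.0
        else:
            beta = float(np.polyfit(xs, ys, 1)[0])
        out.append(GPMRegression(parent_id=parent_id, descriptor=desc,
                                 metric=metric, points=points, beta=beta,
                                 n_aberrant_excluded=n_excluded))
    return out


# ---------------------------------------------------------------------------
# histograms and spectra
# ---------------------------------------------------------------------------

@dataclass
class AsymmetryHistogram:
    """Column-normalized 2D histogram of offspring complexity change.

    ``log_rel_abundance[iy, ix]`` is the natural log of the share of a
    column's offspring falling in that (parent complexity, offspring minus
    parent complexity) bin; empty cells are NaN (absent), never -inf.
    Before the log every non-empty column sums to exactly one.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray  # (ny, nx)
    log_rel_abundance: np.ndarray  # (ny, nx), NaN where empty


def asymmetry_histogram(parent_scores, offspring_scores,
                        bin_size: float) -> AsymmetryHistogram:
    """Mutational-asymmetry histogram (complexity change vs parent level).

    ``parent_scores`` and ``offspring_scores`` are matched arrays: one entry
    per mutant offspring, carrying its parent's complexity and its own.
    Bin size: 0.03 for AV, 1 for OPC.
    """
    parent_scores = np.asarray(parent_scores, dtype=float)
    offspring_scores = np.asarray(offspring_scores, dtype=float)
    if parent_scores.shape != offspring_scores.shape or parent_scores.size == 0:
        raise ValueError("matched, non-empty score arrays required")
    delta = offspring_scores - parent_scores
    x0 = np.floor(parent_scores.min() / bin_size) * bin_size
    x1 = parent_scores.max() + bin_size
    y_abs = max(abs(delta.min()), abs(delta.max())) + bin_size
    x_edges = np.arange(x0, x1 + bin_size, bin_size)
    ny = int(np.ceil(y_abs / bin_size))
    y_edges = np.arange(-ny, ny + 1) * bin_size
    counts, _, _ = np.histogram2d(delta, parent_scores,
                                  bins=(y_edges, x_edges))
    col_tot = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = counts / np.where(col_tot > 0, col_tot, np.nan)[None, :]
        logrel = np.where(counts > 0, np.log(rel), np.nan)
    return AsymmetryHistogram(x_edges=x_edges, y_edges=y_edges,
                              counts=counts, log_rel_abundance=logrel)


def frequency_spectrum(scores, bins=20):
    """Complexity histogram over the ensemble: (counts, bin_edges)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("at least one score required")
    return np.histogram(scores, bins=bins)


def degeneracy_heatmap(morphologies: list[Morphology], scores,
                       interval_edges, per_interval: int,
                       rng: np.random.Generator,
                       align: bool = True):
    """Mean HMD between morphologies grouped by complexity interval.

    Samples up to ``per_interval`` morphologies per complexity interval and
    returns (matrix, counts): entry (a, b) is the mean HMD over all sampled
    cross-interval pairs (within-interval pairs on the diagonal); intervals
    with no morphologies, or diagonal cells with a single one, are NaN.
    """
    scores = np.asarray(scores, dtype=float)
    edges = np.asarray(interval_edges, dtype=float)
    k = len(edges) - 1
    groups: list[list[Morphology]] = []
    for a in range(k):
        lo, hi = edges[a], edges[a + 1]
        sel = np.flatnonzero((scores >= lo) & (scores < hi))
        if len(sel) > per_interval:
            sel = rng.choice(sel, size=per_interval, replace=False)
        groups.append([morphologies[int(i)] for i in sel])
    mat = np.full((k, k), np.nan)
    counts = np.zeros((k, k), dtype=int)
    for a in range(k):
        for b in range(a, k):
            if a == b:
                pairs = list(combinations(groups[a], 2))
            else:
                pairs = [(x, y) for x in groups[a] for y in groups[b]]
            if pairs:
                mat[a, b] = mat[b, a] = float(np.mean(
                    [_hmd(x, y, align=align) for x, y in pairs]))
                counts[a, b] = counts[b, a] = len(pairs)
    return mat, counts
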