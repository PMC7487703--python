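"""Pedigree kinship and cohort-representativeness analysis.

The kinship (coancestry) coefficient phi(i, j) is the probability that two
alleles drawn at random, one from each individual, are identical by
descent. Under this convention a non-inbred individual has self-kinship
0.5, full siblings of unrelated parents 0.25 and half siblings 0.125.

The module computes phi by the standard recursion over the pedigree,
builds a resampling null for the mean pairwise kinship of a test cohort
against a registration-database pool, embeds the kinship matrix with
classical MDS, flags percentile outliers on the leading components, and
groups flagged dogs into families through shared recent ancestry.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import PedigreeTable


@dataclass
class KinshipMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, phi(i,i) on the diagonal

    def loc(self, i: str, j: str) -> float:
        return float(self.values[self.ids.index(i), self.ids.index(j)])


@dataclass(frozen=True)
class ResamplingConfig:
    sample_size: int = 261
    replicates: int = 1500
    seed: int = 0
    birth_year_range: tuple[int, int] | None = (2009, 2017)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass(frozen=True)
class OutlierRule:
    n_components: int = 3
    lower_percentile: float = 0.5
    upper_percentile: float = 99.5

    def __post_init__(self) -> None:
        # (0, 100) is allowed and vacuous: nothing lies strictly outside
        # the full range
        if not 0 <= self.lower_percentile < self.upper_percentile <= 100:
            raise ValueError("need 0 <= lower < upper <= 100")


class _KinshipCalculator:
    """Memoized recursion shared across all pairs of one pedigree."""

    def __init__(self, pedigree: PedigreeTable):
        self.ped = pedigree
        self.cache: dict[frozenset, float] = {}
        self.depth: dict[str, int] = {}
        for d in pedigree.ids:
            self._depth(d)

    def _depth(self, d: str | None) -> int:
        if d is None or d not in self.ped._parents:
            return 0
        if d in self.depth:
            return self.depth[d]
        s, dam = self.ped.parents(d)
        out = 1 + max(self._depth(s), self._depth(dam))
        self.depth[d] = out
        return out

    def phi(self, i: str | None, j: str | None) -> float:
        # an unknown parent acts as a unique unrelated founder
        if i is None or j is None:
            return 0.0
        key = frozenset((i, j))
        if key in self.cache:
            return self.cache[key]
        if i == j:
            s, d = self.ped.parents(i)
            out = 0.5 * (1.0 + self.phi(s, d))
        else:
            # recurse on the deeper individual: it cannot be an ancestor
            # of the shallower one
            if self._depth(i) < self._depth(j):
                i, j = j, i
            s, d = self.ped.parents(i)
            if s is None and d is None:
                out = 0.0  # distinct founders are unrelated
            else:
                out = 0.5 * (self.phi(s, j) + self.phi(d, j))
        self.cache[key] = out
        return out


def kinship_pair(pedigree: PedigreeTable, i: str, j: str) -> float:
    """phi(i, j) by the recursive algorithm (memoized per call)."""
    for d in (i, j):
        if d not in pedigree._parents:
            raise KeyError(f"dog {d!r} not in pedigree")
    return _KinshipCalculator(pedigree).phi(i, j)


def kinship_matrix(pedigree: PedigreeTable, ids: list[str] | None = None) -> KinshipMatrix:
    """All pairwise phi for ``ids`` (default: every dog), shared memoization."""
    if ids is None:
        ids = pedigree.ids
    missing = [d for d in ids if d not in pedigree._parents]
    if missing:
        raise KeyError(f"dogs not in pedigree: {missing}")
    calc = _KinshipCalculator(pedigree)
    n = len(ids)
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a, n):
            out[a, b] = out[b, a] = calc.phi(ids[a], ids[b])
    return KinshipMatrix(list(ids), out)


def mean_pairwise_kinship(matrix: KinshipMatrix, ids: list[str] | None = None) -> tuple[float, float]:
    """Mean and sample SD over the n(n-1)/2 off-diagonal unordered pairs."""
    if ids is None:
        ids = matrix.ids
    if len(ids) < 2:
        raise ValueError("need at least two individuals")
    idx = [matrix.ids.index(d) for d in ids]
    sub = matrix.values[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    vals = sub[iu]
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return float(np.mean(vals)), sd


@dataclass
class ResamplingResult:
    replicate_means: np.ndarray
    observed_mean: float
    p_value: float
    ci_low: float
    ci_high: float
    replicate_min: float
    replicate_max: float
    exceeds_replicate_max: bool


def resample_null(
    pedigree: PedigreeTable,
    pool_ids: list[str],
    config: ResamplingConfig,
    observed_mean: float,
) -> ResamplingResult:
    """Null distribution of mean pairwise kinship under random sampling.

    Each replicate draws ``sample_size`` dogs without replacement from the
    (birth-year-filtered) pool and records the mean pairwise kinship.
    The empirical p-value is upper-tail with the +1 correction,
    ``(1 + #{replicate >= observed}) / (replicates + 1)``. The 2.5/97.5
    percentile band and the replicate range are reported alongside, and
    ``exceeds_replicate_max`` records the confidence-interval-style check
    of the observed mean against the whole replicate range.
    """
    pool = list(pool_ids)
    if config.birth_year_range is not None:
        lo, hi = config.birth_year_range
        pool = [
            d
            for d in pool
            if (y := pedigree.birth_year(d)) is not None and lo <= y <= hi
        ]
    if len(pool) < config.sample_size:
        raise ValueError(
            f"pool of {len(pool)} after birth-year filtering is smaller than "
            f"sample size {config.sample_size}"
        )
    calc_matrix = kinship_matrix(pedigree, pool)
    rng = np.random.default_rng(config.seed)
    means = np.empty(config.replicates)
    for r in range(config.replicates):
        take = rng.choice(len(pool), size=config.sample_size, replace=False)
        sub = calc_matrix.values[np.ix_(take, take)]
        iu = np.triu_indices(config.sample_size, k=1)
        means[r] = sub[iu].mean()
    p = (1 + int(np.sum(means >= observed_mean))) / (config.replicates + 1)
    lo_ci, hi_ci = np.percentile(means, [2.5, 97.5])
    return ResamplingResult(
        replicate_means=means,
        observed_mean=observed_mean,
        p_value=float(p),
        ci_low=float(lo_ci),
        ci_high=float(hi_ci),
        replicate_min=float(means.min()),
        replicate_max=float(means.max()),
        exceeds_replicate_max=bool(observed_mean > means.max()),
    )


def mds_components(matrix: KinshipMatrix, k: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical MDS of the kinship matrix.

    Squared distances use the Gower transform
    ``d2(i,j) = phi(i,i) + phi(j,j) - 2 phi(i,j)``; the double-centered
    matrix is eigendecomposed, components are ordered by descending
    eigenvalue and scaled by sqrt(eigenvalue), and each component's sign
    is fixed so its largest-magnitude loading is positive. If fewer than
    ``k`` positive eigenvalues exist, the result is truncated.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    phi = matrix.values
    diag = np.diag(phi)
    d2 = diag[:, None] + diag[None, :] - 2 * phi
    n = len(matrix.ids)
    j_mat = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j_mat @ d2 @ j_mat
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    positive = evals > 1e-10
    k_eff = min(k, int(positive.sum()))
    if k_eff < k:
        import warnings

        warnings.warn(
            f"only {k_eff} positive eigenvalues; returning {k_eff} components"
        )
    coords = evecs[:, :k_eff] * np.sqrt(evals[:k_eff])
    for c in range(k_eff):
        if coords[np.argmax(np.abs(coords[:, c])), c] < 0:
            coords[:, c] = -coords[:, c]
    df = pd.DataFrame(
        coords, index=matrix.ids, columns=[f"C{c + 1}" for c in range(k_eff)]
    )
    return df, evals[:k_eff]


def detect_outliers(components: pd.DataFrame, rule: OutlierRule) -> list[str]:
    """Flag ids lying strictly outside the percentile band on any leading
    component (linear-interpolation quantiles; values exactly at a
    percentile are not flagged)."""
    flagged: set[str] = set()
    for c in components.columns[: rule.n_components]:
        vals = components[c].to_numpy()
        lo = np.percentile(vals, rule.lower_percentile)
        hi = np.percentile(vals, rule.upper_percentile)
        mask = (vals < lo) | (vals > hi)
        flagged.update(np.asarray(components.index)[mask])
    return [d for d in components.index if d in flagged]


def family_groups(
    pedigree: PedigreeTable, flagged_ids: list[str], max_depth: int = 3
) -> list[list[str]]:
    """Partition flagged dogs into family groups via shared recent ancestry.

    Two flagged dogs share a group iff they are connected in the graph
    linking each dog to its ancestors; ``max_depth`` counts generations
    beyond the parents (0 = parents only, 1 = grandparents too, ...).
    """
    g = nx.Graph()
    g.add_nodes_from(flagged_ids)
    levels = max_depth + 1
    for dog in flagged_ids:
        frontier = [dog]
        for _ in range(levels):
            nxt = []
            for d in frontier:
                for p in pedigree.parents(d):
                    if p is not None:
                        g.add_edge(d, p)
                        nxt.append(p)
            frontier = nxt
    flagged = set(flagged_ids)
    groups = []
    for comp in nx.connected_components(g):
        members = sorted(comp & flagged)
        if members:
            groups.append(members)
    groups.sort(key=lambda grp: grp[0])
    return groups


@dataclass
class GroupKinshipSummary:
    labels: list[str]
    means: pd.DataFrame  # symmetric; NaN within-group mean for singletons


def group_summary(
    matrix: KinshipMatrix, groups: dict[str, list[str]]
) -> GroupKinshipSummary:
    """Mean pairwise kinship within and between labeled groups.

    Within-group means average over distinct unordered pairs (NaN for a
    singleton group); between-group means average over all cross pairs.
    """
    labels = list(groups)
    n = len(labels)
    out = np.full((n, n), np.nan)
    idx = {lab: [matrix.ids.index(d) for d in members] for lab, members in groups.items()}
    for a in range(n):
        ia = idx[labels[a]]
        if len(ia) >= 2:
            sub = matrix.values[np.ix_(ia, ia)]
            iu = np.triu_indices(len(ia), k=1)
            out[a, a] = sub[iu].mean()
        for b in range(a + 1, n):
            ib = idx[labels[b]]
            cross = matrix.values[np.ix_(ia, ib)]
            out[a, b] = out[b, a] = cross.mean()
    return GroupKinshipSummary(
        labels, pd.DataFrame(out, index=labels, columns=labels)
    )
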