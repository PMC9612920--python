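"""Spatiotemporal cluster-based permutation tests.

Sample-wise t statistics over a sensor-pair x time grid are thresholded at
the two-tailed critical value of the cluster-forming alpha; supra-threshold
samples of equal sign that are neighbours in time (same pair, adjacent
samples) and/or space (same sample, neighbouring pairs) are joined into
clusters; assemblies without at least two mutually neighbouring pairs are
discarded.  Each cluster is summarized by the sum of its t values (maxsum),
and the observed per-sign maxima are compared against a Monte Carlo null
built by permuting group labels (independent design) or flipping the signs
of paired differences (dependent design).  Monte Carlo p-values use the
(b + 1)/(m + 1) estimator, so they are never zero and remain valid for any
number of permutations.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace
from math import comb
from typing import Sequence

import numpy as np
from scipy.stats import t as t_dist

from .mmn import MMNmWave, SensorSelection, additivity_difference, stack_maps
from .paradigm import DeviantType
from .preprocess import Evoked
from .simulate import SensorLayout

#: Pairwise validity-check comparisons (larger, smaller): triple > double and
#: double > single deviants.
ORDERING_PAIRS: tuple[tuple[str, str], ...] = (
    ("FIL", "FI"), ("FIL", "IL"), ("FIL", "LF"),
    ("FI", "F"), ("FI", "I"),
    ("IL", "I"), ("IL", "L"),
    ("LF", "L"), ("LF", "F"),
)


def bonferroni_alpha(base_two_sided: float = 0.05, n_tests: int = 4) -> float:
    """Per-tail alpha after Bonferroni correction: (base/2)/n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    return (base_two_sided / 2.0) / n_tests


@dataclass
class Adjacency:
    """Neighbourhood structure over the selected sensor pairs."""

    pair_indices: np.ndarray  # layout pair indices, in analysis order
    matrix: np.ndarray  # boolean (m, m), symmetric, irreflexive
    distance_threshold_m: float

    @property
    def n_pairs(self) -> int:
        return len(self.pair_indices)

    @property
    def edges(self) -> list[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.matrix, 1))
        return list(zip(i.tolist(), j.tolist()))

    def neighbor_counts(self) -> np.ndarray:
        return self.matrix.sum(axis=1)


def build_adjacency(
    layout: SensorLayout,
    selection: SensorSelection | Sequence[int],
    distance_threshold_m: float | None = None,
) -> Adjacency:
    """Neighbourhood from linear inter-sensor distance, within the selection.

    If no threshold is given, the smallest distance giving a mean of at least
    3 neighbours per selected pair is used.
    """
    if isinstance(selection, SensorSelection):
        idx = np.asarray(selection.all_pairs)
    else:
        idx = np.asarray(list(selection))
    d = layout.distances()[np.ix_(idx, idx)]
    if distance_threshold_m is None:
        cands = np.unique(d[np.triu_indices(len(idx), 1)])
        for thr in cands:
            mat = (d > 0) & (d <= thr)
            if mat.sum(axis=1).mean() >= 3.0:
                distance_threshold_m = float(thr)
                break
        else:
            distance_threshold_m = float(cands[-1])
    if distance_threshold_m <= 0:
        raise ValueError("distance threshold must be positive")
    mat = (d > 0) & (d <= distance_threshold_m)
    if (mat.sum(axis=1) == 0).any():
        isolated = idx[mat.sum(axis=1) == 0]
        raise ValueError(
            f"isolated selected pairs {isolated.tolist()}; increase the distance threshold"
        )
    return Adjacency(idx, mat, distance_threshold_m)


def samplewise_t(
    data_a: np.ndarray, data_b: np.ndarray | None, design: str
) -> np.ndarray:
    """Sample-wise t map over the pair x time grid.

    independent: pooled-variance two-sample t (df = n1 + n2 - 2);
    dependent: one-sample t on the paired differences (df = n - 1); pass the
    difference stack as ``data_a`` (or both stacks, matched by row).
    """
    if design == "independent":
        a, b = np.asarray(data_a, float), np.asarray(data_b, float)
        na, nb = a.shape[0], b.shape[0]
        if na < 2 or nb < 2:
            raise ValueError("need at least two subjects per group")
        va = a.var(axis=0, ddof=1)
        vb = b.var(axis=0, ddof=1)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (a.mean(axis=0) - b.mean(axis=0)) / denom
        return np.nan_to_num(t)
    if design == "dependent":
        d = np.asarray(data_a, float)
        if data_b is not None:
            d = d - np.asarray(data_b, float)
        n = d.shape[0]
        if n < 2:
            raise ValueError("need at least two paired observations")
        with np.errstate(divide="ignore", invalid="ignore"):
            t = d.mean(axis=0) / (d.std(axis=0, ddof=1) / np.sqrt(n))
        return np.nan_to_num(t)
    raise ValueError(f"unknown design: {design!r}")


@dataclass
class Cluster:
    """A connected set of supra-threshold (pair, time) samples."""

    samples: np.ndarray  # (k, 2) of (pair index within grid, time index)
    sign: int  # +1 or -1
    sum_t: float
    p_value: float | None = None

    @property
    def pair_set(self) -> set[int]:
        return set(int(p) for p in self.samples[:, 0])


def form_clusters(
    t_map: np.ndarray,
    df: int,
    alpha_forming: float,
    adjacency: Adjacency,
) -> list[Cluster]:
    """Threshold the t map and join neighbouring supra-threshold samples.

    The threshold is the two-tailed t critical value at ``alpha_forming``.
    Components whose pair set does not contain at least two mutually
    neighbouring pairs are discarded.
    """
    if df < 1:
        raise ValueError("degrees of freedom must be at least 1")
    thr = float(t_dist.ppf(1.0 - alpha_forming / 2.0, df))
    return _clusters_from_threshold(t_map, thr, adjacency)


def _clusters_from_threshold(
    t_map: np.ndarray, thr: float, adjacency: Adjacency
) -> list[Cluster]:
    clusters: list[Cluster] = []
    adj_edges = adjacency.edges
    adj_mat = adjacency.matrix
    for sign in (1, -1):
        mask = t_map > thr if sign > 0 else t_map < -thr
        n_sup = int(mask.sum())
        if n_sup == 0:
            continue
        ids = -np.ones(mask.shape, dtype=np.int64)
        ids[mask] = np.arange(n_sup)
        rows: list[np.ndarray] = [ids[:, :-1][mask[:, :-1] & mask[:, 1:]]]
        cols: list[np.ndarray] = [ids[:, 1:][mask[:, :-1] & mask[:, 1:]]]
        for i, j in adj_edges:
            m_s = mask[i] & mask[j]
            rows.append(ids[i][m_s])
            cols.append(ids[j][m_s])
        parent = np.arange(n_sup)

        def find(x: int) -> int:
            root = x
            while parent[root] != root:
                root = parent[root]
            while parent[x] != root:
                parent[x], x = root, parent[x]
            return root

        for r, c in zip(np.concatenate(rows), np.concatenate(cols)):
            ra, rb = find(int(r)), find(int(c))
            if ra != rb:
                parent[rb] = ra
        labels = np.fromiter((find(i) for i in range(n_sup)), np.int64, n_sup)
        pcoord, tcoord = np.nonzero(mask)
        tvals = t_map[mask]
        for lab in np.unique(labels):
            node_mask = labels == lab
            pairs = np.unique(pcoord[node_mask])
            if len(pairs) < 2 or not adj_mat[np.ix_(pairs, pairs)].any():
                continue
            clusters.append(
                Cluster(
                    samples=np.column_stack([pcoord[node_mask], tcoord[node_mask]]),
                    sign=sign,
                    sum_t=float(tvals[node_mask].sum()),
                )
            )
    return clusters


def cluster_stat(clusters: Sequence[Cluster]) -> dict[str, float | None]:
    """Per-sign extreme cluster statistic: max positive sum, min negative sum."""
    pos = [c.sum_t for c in clusters if c.sign > 0]
    neg = [c.sum_t for c in clusters if c.sign < 0]
    return {"pos": max(pos) if pos else None, "neg": min(neg) if neg else None}


@dataclass
class TestSpec:
    """Parameters of one cluster-based permutation test."""

    design: str = "independent"  # or "dependent"
    tails: str = "two"  # "two" | "pos" | "neg"
    alpha_cluster_forming: float = 0.05
    alpha_inference: float = 0.025  # per-tail inference level
    n_perm: int = 10_000
    window_s: tuple[float, float] = (0.100, 0.300)
    seed: int = 0

    __test__ = False  # not a pytest collectable despite the name

    def __post_init__(self) -> None:
        if self.n_perm < 100:
            raise ValueError("n_perm must be at least 100")
        if self.tails not in ("two", "pos", "neg"):
            raise ValueError(f"unknown tails: {self.tails!r}")


@dataclass
class ClusterResult:
    """Observed clusters, Monte Carlo null and p-values of one test."""

    clusters: list[Cluster]
    observed: dict[str, float | None]
    null_max: dict[str, np.ndarray]
    n_perm: int
    seed: int
    alpha_cluster_forming: float
    tails: str
    design: str
    method: str = "montecarlo"  # or "exhaustive"

    def min_p(self) -> float:
        """Smallest cluster p (1.0 when no cluster formed)."""
        ps = [c.p_value for c in self.clusters if c.p_value is not None]
        return min(ps) if ps else 1.0

    def significant(self, alpha_per_tail: float) -> bool:
        return any(
            c.p_value is not None and c.p_value <= alpha_per_tail for c in self.clusters
        )

    def to_dict(self) -> dict:
        return {
            "design": self.design,
            "tails": self.tails,
            "method": self.method,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "alpha_cluster_forming": self.alpha_cluster_forming,
            "observed": {k: v for k, v in self.observed.items()},
            "clusters": [
                {
                    "sign": c.sign,
                    "sum_t": c.sum_t,
                    "p_value": c.p_value,
                    "samples": c.samples.tolist(),
                }
                for c in self.clusters
            ],
        }


def _score_permutation(
    t_map: np.ndarray, thr: float, adjacency: Adjacency
) -> tuple[float, float]:
    stat = cluster_stat(_clusters_from_threshold(t_map, thr, adjacency))
    return (stat["pos"] if stat["pos"] is not None else 0.0,
            stat["neg"] if stat["neg"] is not None else 0.0)


def _finalize_result(
    observed_clusters: list[Cluster],
    null_pos: np.ndarray,
    null_neg: np.ndarray,
    spec: TestSpec,
    method: str,
) -> ClusterResult:
    m = len(null_pos)
    for c in observed_clusters:
        if c.sign > 0:
            b = int(np.sum(null_pos >= c.sum_t))
        else:
            b = int(np.sum(null_neg <= c.sum_t))
        if method == "exhaustive":
            # the enumeration contains the observed labeling, so b/m is the
            # exact p; the +1 guard is only needed for Monte Carlo draws
            c.p_value = b / m
        else:
            c.p_value = (b + 1) / (m + 1)
    if spec.tails == "pos":
        observed_clusters = [c for c in observed_clusters if c.sign > 0]
    elif spec.tails == "neg":
        observed_clusters = [c for c in observed_clusters if c.sign < 0]
    return ClusterResult(
        clusters=observed_clusters,
        observed=cluster_stat(observed_clusters),
        null_max={"pos": null_pos, "neg": null_neg},
        n_perm=m,
        seed=spec.seed,
        alpha_cluster_forming=spec.alpha_cluster_forming,
        tails=spec.tails,
        design=spec.design,
        method=method,
    )


def permutation_test(
    data_a: np.ndarray,
    data_b: np.ndarray,
    spec: TestSpec,
    adjacency: Adjacency,
) -> ClusterResult:
    """Monte Carlo cluster permutation test on subject-level maps.

    independent design: ``data_a``/``data_b`` are the two groups' maps and
    permutations shuffle group membership; dependent design: the rows are
    paired and permutations flip the signs of the paired differences.  Falls
    back to exhaustive enumeration when ``n_perm`` covers all distinct
    relabelings.
    """
    a = np.asarray(data_a, float)
    b = np.asarray(data_b, float)
    if spec.design == "independent":
        n_distinct = comb(a.shape[0] + b.shape[0], a.shape[0])
    else:
        if a.shape != b.shape:
            raise ValueError("dependent design requires paired stacks of equal shape")
        n_distinct = 2 ** a.shape[0]
    if spec.n_perm >= n_distinct:
        warnings.warn(
            f"n_perm={spec.n_perm} covers all {n_distinct} relabelings; "
            "switching to exhaustive enumeration",
            stacklevel=2,
        )
        return exhaustive_permutation(data_a, data_b, spec, adjacency)

    rng = np.random.default_rng(spec.seed)
    grid_shape = a.shape[1:]
    if spec.design == "independent":
        na, nb = a.shape[0], b.shape[0]
        n = na + nb
        X = np.concatenate([a, b], axis=0).reshape(n, -1)
        df = n - 2
        t_obs = samplewise_t(a, b, "independent")
        # all permutation t maps from three gemms over a 0/1 selection matrix
        sel = np.zeros((spec.n_perm, n))
        for k in range(spec.n_perm):
            sel[k, rng.permutation(n)[:na]] = 1.0
        sum_all = X.sum(axis=0)
        sq_all = (X**2).sum(axis=0)
        sa = sel @ X
        sa2 = sel @ X**2
        ma, mb = sa / na, (sum_all - sa) / nb
        va = (sa2 - na * ma**2) / (na - 1)
        vb = (sq_all - sa2 - nb * mb**2) / (nb - 1)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        with np.errstate(divide="ignore", invalid="ignore"):
            t_all = (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    else:
        d = (a - b).reshape(a.shape[0], -1)
        n = d.shape[0]
        df = n - 1
        t_obs = samplewise_t(a, b, "dependent")
        signs = rng.integers(0, 2, (spec.n_perm, n)) * 2.0 - 1.0
        mean = (signs @ d) / n
        var = ((d**2).sum(axis=0) - n * mean**2) / df  # sign flips keep d^2
        with np.errstate(divide="ignore", invalid="ignore"):
            t_all = mean / np.sqrt(var / n)
    t_all = np.nan_to_num(t_all)
    thr = float(t_dist.ppf(1.0 - spec.alpha_cluster_forming / 2.0, df))
    observed = _clusters_from_threshold(t_obs, thr, adjacency)

    null_pos = np.empty(spec.n_perm)
    null_neg = np.empty(spec.n_perm)
    for k in range(spec.n_perm):
        null_pos[k], null_neg[k] = _score_permutation(
            t_all[k].reshape(grid_shape), thr, adjacency
        )
    return _finalize_result(observed, null_pos, null_neg, spec, "montecarlo")


def exhaustive_permutation(
    data_a: np.ndarray,
    data_b: np.ndarray,
    spec: TestSpec,
    adjacency: Adjacency,
) -> ClusterResult:
    """Exact test by enumerating every group partition / sign pattern."""
    a = np.asarray(data_a, float)
    b = np.asarray(data_b, float)
    if spec.design == "independent":
        n = a.shape[0] + b.shape[0]
        if n > 14:
            raise ValueError("exhaustive enumeration limited to 14 subjects total")
        na = a.shape[0]
        X = np.concatenate([a, b], axis=0)
        df = n - 2
        thr = float(t_dist.ppf(1.0 - spec.alpha_cluster_forming / 2.0, df))
        observed = _clusters_from_threshold(samplewise_t(a, b, "independent"), thr, adjacency)
        scores = []
        all_idx = frozenset(range(n))
        for subset in itertools.combinations(range(n), na):
            rest = sorted(all_idx - set(subset))
            t_perm = samplewise_t(X[list(subset)], X[rest], "independent")
            scores.append(_score_permutation(t_perm, thr, adjacency))
    else:
        if a.shape != b.shape:
            raise ValueError("dependent design requires paired stacks of equal shape")
        d = a - b
        n = d.shape[0]
        if n > 16:
            raise ValueError("exhaustive enumeration limited to 16 pairs")
        df = n - 1
        thr = float(t_dist.ppf(1.0 - spec.alpha_cluster_forming / 2.0, df))
        observed = _clusters_from_threshold(samplewise_t(d, None, "dependent"), thr, adjacency)
        scores = []
        for pattern in itertools.product((1.0, -1.0), repeat=n):
            signs = np.array(pattern)
            t_perm = samplewise_t(signs[:, None, None] * d, None, "dependent")
            scores.append(_score_permutation(t_perm, thr, adjacency))
    null_pos = np.array([s[0] for s in scores])
    null_neg = np.array([s[1] for s in scores])
    return _finalize_result(observed, null_pos, null_neg, spec, "exhaustive")


# ---------------------------------------------------------------------------
# High-level tests on wave collections
# ---------------------------------------------------------------------------

def _by_subject(waves: Sequence[MMNmWave], group: str | None = None) -> dict[str, list[MMNmWave]]:
    out: dict[str, list[MMNmWave]] = {}
    for w in waves:
        if group is None or w.group == group:
            out.setdefault(w.subject_id, []).append(w)
    return out


def _pick(waves: Sequence, **attrs):
    found = [w for w in waves if all(getattr(w, k) == v for k, v in attrs.items())]
    if len(found) != 1:
        raise ValueError(f"expected exactly one wave with {attrs}, found {len(found)}")
    return found[0]


def interaction_test(
    waves: Sequence[MMNmWave],
    deviant_type: DeviantType,
    spec: TestSpec,
    selection: SensorSelection,
    adjacency: Adjacency,
    groups: tuple[str, str] = ("musician", "nonmusician"),
) -> ClusterResult:
    """Additivity-by-expertise interaction for one double/triple deviant.

    Per subject, the empirical-minus-modeled difference map is computed; the
    two groups' difference maps are then compared with an independent-design
    permutation test over the selection x window grid.
    """
    stacks = []
    for g in groups:
        maps = []
        per_subject = _by_subject(waves, g)
        for sid in sorted(per_subject):
            sw = per_subject[sid]
            emp = _pick(sw, deviant_type=deviant_type, kind="empirical")
            mod = _pick(sw, deviant_type=deviant_type, kind="modeled")
            maps.append(additivity_difference(emp, mod))
        stacks.append(stack_maps(maps, selection, times=waves[0].times()))
    return permutation_test(
        stacks[0], stacks[1], replace(spec, design="independent"), adjacency
    )


def simple_effect_test(
    waves: Sequence[MMNmWave],
    deviant_type: DeviantType,
    group: str,
    spec: TestSpec,
    selection: SensorSelection,
    adjacency: Adjacency,
) -> ClusterResult:
    """Within-group paired test of empirical vs. modeled MMNm."""
    emp_maps, mod_maps = [], []
    per_subject = _by_subject(waves, group)
    for sid in sorted(per_subject):
        sw = per_subject[sid]
        emp_maps.append(_pick(sw, deviant_type=deviant_type, kind="empirical").data)
        mod_maps.append(_pick(sw, deviant_type=deviant_type, kind="modeled").data)
    t = waves[0].times()
    return permutation_test(
        stack_maps(emp_maps, selection, times=t),
        stack_maps(mod_maps, selection, times=t),
        replace(spec, design="dependent"),
        adjacency,
    )


def presence_test(
    evokeds: Sequence[Evoked],
    deviant_type: DeviantType,
    group: str,
    spec: TestSpec,
    selection: SensorSelection,
    adjacency: Adjacency,
) -> ClusterResult:
    """Paired deviant-vs-standard test establishing that an MMNm is present."""
    dev_maps, std_maps = [], []
    per_subject = _by_subject(evokeds, group)
    for sid in sorted(per_subject):
        sw = per_subject[sid]
        dev_maps.append(_pick(sw, condition=deviant_type).data)
        std_maps.append(_pick(sw, condition=DeviantType.STD).data)
    t = evokeds[0].times()
    return permutation_test(
        stack_maps(dev_maps, selection, times=t),
        stack_maps(std_maps, selection, times=t),
        replace(spec, design="dependent"),
        adjacency,
    )


def ordering_test(
    waves: Sequence[MMNmWave],
    larger: DeviantType,
    smaller: DeviantType,
    spec: TestSpec,
    selection: SensorSelection,
    adjacency: Adjacency,
) -> ClusterResult:
    """Directional paired test that one empirical MMNm exceeds another.

    Run across all subjects regardless of group, one-sided (positive tail) by
    default.
    """
    hi_maps, lo_maps = [], []
    per_subject = _by_subject([w for w in waves if w.kind == "empirical"])
    for sid in sorted(per_subject):
        sw = per_subject[sid]
        hi_maps.append(_pick(sw, deviant_type=larger).data)
        lo_maps.append(_pick(sw, deviant_type=smaller).data)
    t = waves[0].times()
    tails = spec.tails if spec.tails != "two" else "pos"
    return permutation_test(
        stack_maps(hi_maps, selection, times=t),
        stack_maps(lo_maps, selection, times=t),
        replace(spec, design="dependent", tails=tails),
        adjacency,
    )
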