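"""Group-level inference for predictive-power and TRF maps.

Univariate paired (related-measures) t-tests, and mass-univariate tests
with permutation-based family-wise-error control: an element-wise t map
is thresholded, suprathreshold elements are grouped into clusters that
are connected under the sensor adjacency graph (and temporally
contiguous when a time axis is present), and each cluster's summed t
(cluster mass) is compared against the null distribution of the maximum
cluster mass obtained by randomly sign-flipping the subject difference
maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats as spstats
from scipy.sparse.csgraph import connected_components

__all__ = [
    "GroupTable",
    "ClusterResult",
    "paired_t",
    "cluster_permutation_test",
    "average_sensors",
    "build_adjacency",
    "adjacency_from_edges",
]


@dataclass
class GroupTable:
    """Per-subject outcome maps for a paired two-condition design.

    ``outcomes`` maps condition label -> array of shape
    ``(n_subjects, n_sensors[, n_times])``; rows are paired across
    conditions by subject.
    """

    subjects: list[str]
    outcomes: dict
    sensor_labels: list[str]

    def __post_init__(self):
        shapes = {k: np.asarray(v).shape for k, v in self.outcomes.items()}
        first = next(iter(shapes.values()))
        if any(s != first for s in shapes.values()):
            raise ValueError(f"condition outcome shapes differ: {shapes}")
        if first[0] != len(self.subjects):
            raise ValueError("outcome rows must match subject count")
        if first[1] != len(self.sensor_labels):
            raise ValueError("outcome sensor dimension must match sensor_labels")
        self.outcomes = {k: np.asarray(v, dtype=float) for k, v in
                         self.outcomes.items()}

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "GroupTable":
        """Build from a long-format table (subject, condition, sensor[, time], value)."""
        required = {"subject", "condition", "sensor", "value"}
        if not required <= set(df.columns):
            raise ValueError(f"long table needs columns {sorted(required)}")
        has_time = "time" in df.columns
        subjects = sorted(df["subject"].astype(str).unique())
        sensors = sorted(df["sensor"].astype(str).unique())
        outcomes = {}
        for cond, g in df.groupby("condition"):
            if has_time:
                times = sorted(g["time"].unique())
                arr = np.full((len(subjects), len(sensors), len(times)), np.nan)
                ti = {t: i for i, t in enumerate(times)}
            else:
                arr = np.full((len(subjects), len(sensors)), np.nan)
            si = {s: i for i, s in enumerate(subjects)}
            ci = {s: i for i, s in enumerate(sensors)}
            for row in g.itertuples():
                if has_time:
                    arr[si[str(row.subject)], ci[str(row.sensor)],
                        ti[row.time]] = row.value
                else:
                    arr[si[str(row.subject)], ci[str(row.sensor)]] = row.value
            if np.isnan(arr).any():
                raise ValueError(f"incomplete design for condition {cond!r}")
            outcomes[str(cond)] = arr
        return cls(subjects, outcomes, sensors)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for cond, arr in self.outcomes.items():
            for si, subj in enumerate(self.subjects):
                if arr.ndim == 2:
                    for ci, sens in enumerate(self.sensor_labels):
                        rows.append((subj, cond, sens, arr[si, ci]))
                else:
                    for ci, sens in enumerate(self.sensor_labels):
                        for ti in range(arr.shape[2]):
                            rows.append((subj, cond, sens, ti, arr[si, ci, ti]))
        cols = ["subject", "condition", "sensor", "value"]
        if next(iter(self.outcomes.values())).ndim == 3:
            cols = ["subject", "condition", "sensor", "time", "value"]
        return pd.DataFrame(rows, columns=cols)


@dataclass
class ClusterResult:
    """Element-wise t map with clusters and family-wise-error corrected p-values."""

    t_map: np.ndarray
    cluster_labels: np.ndarray  # int map, 0 = no cluster
    cluster_masses: np.ndarray  # per cluster (signed)
    cluster_p: np.ndarray
    n_permutations: int
    exhaustive: bool
    threshold: float
    warnings: list[str] = field(default_factory=list)

    @property
    def min_p(self) -> float:
        return float(self.cluster_p.min()) if self.cluster_p.size else 1.0


def paired_t(values_a: np.ndarray, values_b: np.ndarray):
    """Related-measures t-test on paired per-subject values.

    Returns ``(t, df, p)`` with df = n - 1 and a two-tailed p.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 subjects")
    d = a - b
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        t = 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
    else:
        t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2 * spstats.t.sf(abs(t), df) if np.isfinite(t) else 0.0
    return float(t), df, float(p)


# ---------------------------------------------------------------------------
# adjacency helpers


def build_adjacency(coords: np.ndarray, threshold: float) -> sparse.csr_matrix:
    """Sensor adjacency from coordinates: neighbors within ``threshold`` distance."""
    coords = np.asarray(coords, dtype=float)
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    adj = (d <= threshold) & ~np.eye(len(coords), dtype=bool)
    return sparse.csr_matrix(adj)


def adjacency_from_edges(edges, sensor_labels: list[str]) -> sparse.csr_matrix:
    """Adjacency from an explicit neighbor (edge) list of label pairs."""
    n = len(sensor_labels)
    idx = {s: i for i, s in enumerate(sensor_labels)}
    mat = sparse.lil_matrix((n, n), dtype=bool)
    for a, b in edges:
        if a not in idx or b not in idx:
            raise ValueError(f"edge ({a}, {b}) names unknown sensor")
        mat[idx[a], idx[b]] = True
        mat[idx[b], idx[a]] = True
    return mat.tocsr()


def _element_graph(adjacency: sparse.spmatrix, n_times: int) -> sparse.csr_matrix:
    """Connectivity over (sensor, time) elements: sensor graph x time contiguity."""
    n_sens = adjacency.shape[0]
    if n_times == 1:
        return sparse.csr_matrix(adjacency)
    eye_t = sparse.eye(n_times, dtype=bool)
    time_chain = sparse.diags([np.ones(n_times - 1)] * 2, [-1, 1], dtype=bool)
    g = sparse.kron(adjacency, eye_t) + sparse.kron(
        sparse.eye(n_sens, dtype=bool), time_chain
    )
    return g.tocsr()


def _neighbor_lists(graph: sparse.spmatrix) -> list[np.ndarray]:
    g = sparse.csr_matrix(graph)
    return [g.indices[g.indptr[i]: g.indptr[i + 1]] for i in range(g.shape[0])]


def _clusters(mask: np.ndarray, nbrs: list[np.ndarray]):
    """Connected components of the suprathreshold set (BFS on neighbor lists)."""
    seen = np.zeros(mask.size, dtype=bool)
    for start in np.flatnonzero(mask):
        if seen[start]:
            continue
        seen[start] = True
        stack = [start]
        members = [start]
        while stack:
            node = stack.pop()
            for nb in nbrs[node]:
                if mask[nb] and not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
                    members.append(nb)
        yield members


def _max_cluster_mass(t_flat, mask_pos, mask_neg, nbrs):
    """Maximum |cluster mass| over positive and negative suprathreshold clusters."""
    best = 0.0
    for mask, sgn in ((mask_pos, 1.0), (mask_neg, -1.0)):
        if not mask.any():
            continue
        for members in _clusters(mask, nbrs):
            best = max(best, float(sgn * t_flat[members].sum()))
    return best


def cluster_permutation_test(
    table: GroupTable,
    adjacency: sparse.spmatrix,
    condition_a: str | None = None,
    condition_b: str | None = None,
    alpha: float = 0.05,
    n_permutations: int = 10000,
    cluster_threshold: float | None = None,
    seed: int = 0,
) -> ClusterResult:
    """Mass-univariate related-measures test with max-cluster-mass correction.

    The null distribution is built from random sign flips of the
    subject difference maps; all ``2^n`` sign patterns are enumerated
    when that is no larger than ``n_permutations``, otherwise Monte
    Carlo sampling with the given seed is used. Cluster p-values are the
    proportion of null maxima at least as large as the observed cluster
    mass, controlling family-wise error at ``alpha``.
    """
    warnings: list[str] = []
    conds = list(table.outcomes)
    if condition_a is None or condition_b is None:
        if len(conds) == 1:
            diffs = table.outcomes[conds[0]]
        elif len(conds) == 2:
            diffs = table.outcomes[conds[0]] - table.outcomes[conds[1]]
        else:
            raise ValueError("specify condition_a and condition_b")
    else:
        diffs = table.outcomes[condition_a] - table.outcomes[condition_b]

    n_subj = diffs.shape[0]
    map_shape = diffs.shape[1:]
    n_times = map_shape[1] if len(map_shape) == 2 else 1
    if adjacency.shape[0] != map_shape[0]:
        raise ValueError("adjacency must cover all sensors")
    n_comp_graph, _ = connected_components(sparse.csr_matrix(adjacency),
                                           directed=False)
    if n_comp_graph > 1:
        warnings.append(f"adjacency graph has {n_comp_graph} disconnected components")
    if n_permutations < 100:
        warnings.append(f"n_permutations={n_permutations} is very small")

    df = n_subj - 1
    if cluster_threshold is None:
        cluster_threshold = float(spstats.t.ppf(1 - alpha / 2, df))

    D = diffs.reshape(n_subj, -1)
    sq = (D**2).sum(axis=0)  # invariant under sign flips

    def t_of(signs):
        """t maps for a batch of sign patterns (rows)."""
        means = signs @ D / n_subj
        var = (sq[None, :] - n_subj * means**2) / (n_subj - 1)
        var = np.maximum(var, 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = means / np.sqrt(var / n_subj)
        t[~np.isfinite(t)] = 0.0
        return t

    t_obs = t_of(np.ones((1, n_subj)))[0]

    graph = _element_graph(adjacency, n_times)
    nbrs = _neighbor_lists(graph)
    mask_pos = t_obs > cluster_threshold
    mask_neg = t_obs < -cluster_threshold

    # observed clusters
    cluster_labels = np.zeros(t_obs.size, dtype=int)
    masses = []
    next_label = 1
    for mask in (mask_pos, mask_neg):
        if not mask.any():
            continue
        for members in _clusters(mask, nbrs):
            members = np.asarray(members)
            cluster_labels[members] = next_label
            masses.append(float(t_obs[members].sum()))
            next_label += 1
    masses = np.asarray(masses)

    exhaustive = 2**n_subj <= n_permutations
    if exhaustive:
        m = 2**n_subj
        bits = (np.arange(m)[:, None] >> np.arange(n_subj)) & 1
        signs = 1.0 - 2.0 * bits
    else:
        m = n_permutations
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(m, n_subj))

    null_max = np.empty(m)
    t_null = t_of(signs)
    pos_all = t_null > cluster_threshold
    neg_all = t_null < -cluster_threshold
    for i in range(m):
        null_max[i] = _max_cluster_mass(t_null[i], pos_all[i], neg_all[i], nbrs)

    if masses.size:
        exceed = (null_max[None, :] >= np.abs(masses)[:, None]).sum(axis=1)
        if exhaustive:
            p = exceed / m
        else:
            p = (exceed + 1) / (m + 1)
    else:
        p = np.empty(0)

    return ClusterResult(
        t_map=t_obs.reshape(map_shape),
        cluster_labels=cluster_labels.reshape(map_shape),
        cluster_masses=masses,
        cluster_p=p,
        n_permutations=m,
        exhaustive=exhaustive,
        threshold=cluster_threshold,
        warnings=warnings,
    )


def average_sensors(map_values: np.ndarray, sensor_labels: list[str],
                    sensor_subset: list[str]) -> float:
    """Unweighted mean of a sensor map over a pre-specified sensor group."""
    if not sensor_subset:
        raise ValueError("sensor_subset must be non-empty")
    idx = []
    for s in sensor_subset:
        if s not in sensor_labels:
            raise ValueError(f"unknown sensor label {s!r}")
        idx.append(sensor_labels.index(s))
    return float(np.mean(np.asarray(map_values)[idx]))
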