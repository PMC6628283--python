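"""Induce a fuzzy knowledge base from a training table.

The knowledge *database* (fuzzy variables and their membership functions) is
derived by clustering each variable independently in one dimension: Ward
agglomerative clustering for small tables, k-means for large ones.  Each
cluster's minimum and maximum in the raw data become the plateau edges
``b`` and ``c`` of a membership function; a cluster whose minimum equals its
maximum yields a triangle peaked there.  The feet are placed at the nearest
extreme of the neighbouring cluster (``a_i = M_{i-1}``, ``d_i = m_{i+1}``),
which makes the family a Ruspini partition: degrees sum to one across the
variable's range, so the inference engine always has full coverage.

The knowledge *rule base* is the set of sorted unique rows of the
cluster-index table: every training row is mapped to the vector of cluster
indices of its values, duplicates are dropped, and each surviving row reads
as an IF-THEN rule (antecedent = input columns, consequent = output columns,
weight 1, AND connector).

Sizing heuristic: a variable with ``u`` distinct values gets ``u`` fuzzy
sets when ``u <= 20``; above that the rounded square root of ``u`` is used
instead, and never fewer than two.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from .fuzzy_core import (
    TRAPEZOIDAL,
    TRIANGULAR,
    FuzzyRule,
    FuzzySystem,
    FuzzyVariable,
    MembershipFunction,
)

__all__ = [
    "ClusterModel",
    "KnowledgeBase",
    "ContradictoryRulesWarning",
    "unique_value_count",
    "optimal_cluster_count",
    "cluster_variable",
    "cluster_nominal",
    "mfs_from_cluster_model",
    "extract_rule_base",
    "enumerate_feature_subsets",
    "build_knowledge_base",
    "WARD_ROW_LIMIT",
]

#: above this many training rows the auto method switches from Ward to k-means
WARD_ROW_LIMIT = 10_000


class ContradictoryRulesWarning(UserWarning):
    """Several unique rows share an antecedent but disagree on the consequent."""


@dataclass(frozen=True)
class ClusterModel:
    """One-dimensional clustering of a single variable's training values.

    Labels are 1-based and canonical: cluster ``i``'s minimum value is below
    cluster ``i+1``'s, so cluster index order matches value order.
    """

    variable_name: str
    method: str  # "ward" | "kmeans" | "nominal"
    k: int
    labels: np.ndarray  # (n_rows,), int, 1-based
    summaries: tuple[tuple[float, float, int], ...]  # per cluster (min, max, count)

    def __post_init__(self) -> None:
        if self.k != len(self.summaries):
            raise ValueError("k must equal the number of cluster summaries")
        mins = [s[0] for s in self.summaries]
        if any(m2 <= m1 for m1, m2 in zip(mins, mins[1:])):
            raise ValueError("cluster summaries must be ordered by ascending minimum")
        if any(cnt < 1 for _, _, cnt in self.summaries):
            raise ValueError("every cluster must be non-empty")


@dataclass
class KnowledgeBase:
    """Cluster models, fuzzy variables and the extracted rule table."""

    input_vars: list[FuzzyVariable]
    output_vars: list[FuzzyVariable]
    cluster_models: list[ClusterModel]
    rule_table: list[FuzzyRule]
    feature_subset: tuple[int, ...]  # positions of the inputs in the source table

    @property
    def output_class_codes(self) -> list[list[float]]:
        """Per output variable, the class code represented by each MF.

        The code is the cluster minimum, which for singleton (nominal or
        per-class) clusters is the category code itself.
        """
        n_in = len(self.input_vars)
        return [
            [s[0] for s in cm.summaries]
            for cm in self.cluster_models[n_in:]
        ]


def unique_value_count(values) -> int:
    """Number of distinct values in a non-empty vector (pivot-table row count)."""
    arr = np.asarray(values)
    if arr.size == 0:
        raise ValueError("cannot count unique values of an empty vector")
    return int(np.unique(arr).size)


def optimal_cluster_count(values) -> int:
    """Recommended number of fuzzy sets for one variable.

    Equal to the distinct-value count ``u`` when ``u <= 20``; otherwise the
    square root of ``u`` rounded half away from zero.  Never below two, so a
    variable always gets at least a low/high pair of fuzzy sets.
    """
    u = unique_value_count(values)
    k = u if u <= 20 else int(math.floor(math.sqrt(u) + 0.5))
    return max(k, 2)


def _canonicalise(
    values: np.ndarray, raw_labels: np.ndarray, method: str, name: str
) -> ClusterModel:
    """Relabel arbitrary cluster ids so index order follows ascending minima."""
    ids = np.unique(raw_labels)
    stats = []
    for cid in ids:
        member = values[raw_labels == cid]
        stats.append((float(member.min()), float(member.max()), int(member.size), cid))
    stats.sort(key=lambda s: s[0])
    remap = {cid: rank + 1 for rank, (_, _, _, cid) in enumerate(stats)}
    labels = np.array([remap[cid] for cid in raw_labels], dtype=int)
    summaries = tuple((mn, mx, cnt) for mn, mx, cnt, _ in stats)
    return ClusterModel(name, method, len(summaries), labels, summaries)


def cluster_variable(
    values, k: int, method: str = "ward", seed: int = 0, name: str = "x"
) -> ClusterModel:
    """Cluster one variable's values into ``k`` groups.

    ``ward`` runs agglomerative clustering with Ward linkage on the 1-D
    Euclidean distances and cuts the dendrogram at ``k`` groups; ``kmeans``
    fits ``k`` seeded centres with 10 restarts.  If fewer than ``k`` distinct
    values exist, ``k`` is reduced to the distinct count with a warning.
    Labels are canonicalised by ascending cluster minimum.
    """
    if k < 2:
        raise ValueError("at least two clusters must be requested")
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("cannot cluster an empty vector")
    n_unique = unique_value_count(arr)
    if n_unique < k:
        warnings.warn(
            f"variable {name!r}: only {n_unique} distinct values; "
            f"reducing cluster count from {k}",
            stacklevel=2,
        )
        k = n_unique
    if k == 1:
        labels = np.ones(arr.size, dtype=int)
        return _canonicalise(arr, labels, method, name)
    if method == "ward":
        Z = linkage(arr.reshape(-1, 1), method="ward")
        raw = fcluster(Z, t=k, criterion="maxclust")
    elif method == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=seed % (2**31))
        raw = km.fit_predict(arr.reshape(-1, 1))
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    return _canonicalise(arr, raw, method, name)


def cluster_nominal(values, name: str = "x") -> ClusterModel:
    """Singleton cluster per category code, bypassing distance-based methods.

    Category codes are arbitrary labels, so treating each as its own cluster
    (a triangle peaked at the code) is the only meaningful fuzzification.
    """
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("cannot cluster an empty vector")
    codes = np.unique(arr)
    remap = {v: i + 1 for i, v in enumerate(codes)}
    labels = np.array([remap[v] for v in arr], dtype=int)
    summaries = tuple(
        (float(v), float(v), int((arr == v).sum())) for v in codes
    )
    return ClusterModel(name, "nominal", codes.size, labels, summaries)


def mfs_from_cluster_model(cm: ClusterModel) -> FuzzyVariable:
    """Build a fuzzy variable from cluster extrema.

    Cluster ``i`` with raw-data extrema ``(m_i, M_i)`` yields plateau edges
    ``b = m_i`` and ``c = M_i``; the shape is triangular when they coincide.
    Feet go to the neighbouring cluster's nearest extreme (``a_i = M_{i-1}``,
    ``d_i = m_{i+1}``; the first/last MF keeps its foot at its own plateau
    edge), so adjacent MFs cross linearly and degrees sum to one everywhere
    in the range ``[m_1, M_K]``.
    """
    if cm.k == 0:
        raise ValueError("empty cluster model")
    mins = [s[0] for s in cm.summaries]
    maxs = [s[1] for s in cm.summaries]
    mfs = []
    for i in range(cm.k):
        a = mins[0] if i == 0 else maxs[i - 1]
        b, c = mins[i], maxs[i]
        d = maxs[-1] if i == cm.k - 1 else mins[i + 1]
        if b == c:
            mfs.append(MembershipFunction(f"MF{i + 1}", TRIANGULAR, a, b, d))
        else:
            mfs.append(MembershipFunction(f"MF{i + 1}", TRAPEZOIDAL, a, b, c, d))
    return FuzzyVariable(cm.variable_name, mins[0], maxs[-1], tuple(mfs))


def extract_rule_base(
    clustered_rows,
    n_inputs: int,
    resolve_contradictions: bool = False,
) -> list[FuzzyRule]:
    """Turn a table of cluster indices into the unique-row rule base.

    The sorted unique rows of the table become rules: the first ``n_inputs``
    columns form the antecedent, the rest the consequent (weight 1, AND).
    Rows sharing an antecedent but differing in consequent are contradictory;
    both are retained by default (they are distinct observations) with a
    warning, or resolved to the majority consequent (ties toward the lower
    index) when ``resolve_contradictions`` is set.
    """
    arr = np.asarray(clustered_rows, dtype=int)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("clustered_rows must be a non-empty 2-D table")
    if not 1 <= n_inputs < arr.shape[1]:
        raise ValueError("need at least one input and one output column")
    unique_rows = np.unique(arr, axis=0)  # sorted lexicographically
    by_antecedent: dict[tuple[int, ...], list[tuple[int, ...]]] = {}
    for row in unique_rows:
        ant = tuple(int(v) for v in row[:n_inputs])
        by_antecedent.setdefault(ant, []).append(tuple(int(v) for v in row[n_inputs:]))
    contradictory = {a for a, cons in by_antecedent.items() if len(cons) > 1}
    if contradictory:
        warnings.warn(
            f"{len(contradictory)} antecedent(s) map to multiple consequents "
            "(contradictory rules)",
            ContradictoryRulesWarning,
            stacklevel=2,
        )
    if not resolve_contradictions:
        return [
            FuzzyRule(tuple(int(v) for v in row[:n_inputs]),
                      tuple(int(v) for v in row[n_inputs:]))
            for row in unique_rows
        ]
    # majority vote over the original (non-deduplicated) rows per antecedent
    counts: dict[tuple[int, ...], dict[tuple[int, ...], int]] = {}
    for row in arr:
        ant = tuple(int(v) for v in row[:n_inputs])
        con = tuple(int(v) for v in row[n_inputs:])
        counts.setdefault(ant, {}).setdefault(con, 0)
        counts[ant][con] += 1
    rules = []
    for ant in sorted(counts):
        cons = counts[ant]
        best = max(sorted(cons), key=lambda c: (cons[c], tuple(-v for v in c)))
        rules.append(FuzzyRule(ant, best))
    return rules


def enumerate_feature_subsets(n: int, k: int) -> list[tuple[int, ...]]:
    """All C(n, k) sorted k-subsets of {1..n}, in lexicographic order."""
    if not 1 <= k <= n:
        raise ValueError(f"subset size {k} must lie in [1, {n}]")
    return list(itertools.combinations(range(1, n + 1), k))


def build_knowledge_base(
    train: pd.DataFrame,
    input_cols: list[str],
    output_cols: list[str],
    ks: list[int],
    method: str = "auto",
    seed: int = 0,
    nominal: set[str] | frozenset[str] = frozenset(),
    resolution: int = 1001,
    name: str = "mamfis",
    resolve_contradictions: bool = False,
) -> tuple[KnowledgeBase, FuzzySystem]:
    """Cluster the selected columns, extract rules and assemble a system.

    ``ks`` is aligned to ``input_cols + output_cols``; entries for nominal
    columns (and output columns, which are treated as nominal class labels)
    are ignored because each category forms its own singleton cluster.
    Returns the knowledge base together with a ready-to-run Mamdani system
    (min/max operators, centroid defuzzification).
    """
    if train.empty:
        raise ValueError("training table is empty")
    cols = list(input_cols) + list(output_cols)
    if len(ks) != len(cols):
        raise ValueError("ks must align to input columns followed by output columns")
    if method == "auto":
        method = "ward" if len(train) <= WARD_ROW_LIMIT else "kmeans"
    cluster_models: list[ClusterModel] = []
    label_cols = []
    for col, k in zip(cols, ks):
        values = train[col].to_numpy(dtype=float)
        if np.unique(values).size < 2:
            raise ValueError(f"column {col!r} is constant on the training rows")
        if col in nominal or col in output_cols:
            cm = cluster_nominal(values, name=col)
        else:
            cm = cluster_variable(values, k, method=method, seed=seed, name=col)
        cluster_models.append(cm)
        label_cols.append(cm.labels)
    variables = [mfs_from_cluster_model(cm) for cm in cluster_models]
    input_vars = variables[: len(input_cols)]
    output_vars = variables[len(input_cols):]
    rule_table = extract_rule_base(
        np.column_stack(label_cols),
        n_inputs=len(input_cols),
        resolve_contradictions=resolve_contradictions,
    )
    positions = tuple(list(train.columns).index(c) for c in input_cols)
    kb = KnowledgeBase(input_vars, output_vars, cluster_models, rule_table, positions)
    system = FuzzySystem(
        name=name,
        inputs=input_vars,
        outputs=output_vars,
        rules=rule_table,
        resolution=resolution,
    )
    system.validate()
    return kb, system
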