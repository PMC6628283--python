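"""Iterative model construction: partitioning, candidate sweep, selection.

The search enumerates candidate models — a feature subset paired with a
per-variable cluster count vector — and evaluates each under one of two
partition schemes: a single random training/validation split (70/30 by
default) or k-fold cross-validation (k = 10 by default) with fold-averaged
metrics.  Candidates are streamed in order of increasing complexity: subset
size first, then total cluster count, with a seeded shuffle inside each
stratum, so a tight iteration budget (3000 by default) is spent on
parsimonious models first.  Within every candidate, clustering, membership
ranges and rules are derived from that candidate's training rows only.

Selection maximises a configurable metric (accuracy by default); ties break
toward fewer input variables, then fewer rules, then the earlier iteration,
so the whole procedure is deterministic for a given seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .data_io import Dataset, DatasetSchema
from .evaluation import MetricSet, compute_metrics
from .fuzzy_core import FuzzySystem, classify_batch, infer_batch
from .kb_builder import KnowledgeBase, build_knowledge_base, optimal_cluster_count

__all__ = [
    "SearchConfig",
    "Provenance",
    "SearchResult",
    "permute_rows",
    "random_split",
    "kfold_partitions",
    "predict",
    "search",
    "select_best",
]

logger = logging.getLogger("mamfis.search")

_METRIC_NAMES = (
    "accuracy", "sensitivity", "specificity", "precision", "recall",
    "f_measure", "kappa", "auc",
)


@dataclass
class SearchConfig:
    """Knobs of the iterative design loop; defaults follow common practice.

    ``subset_sizes`` of ``None`` means every size from 2 (or 1 when only one
    input exists) up to the number of inputs.  ``cluster_max`` of ``None``
    sizes each variable's sweep by the distinct-value heuristic
    (:func:`mamfis.kb_builder.optimal_cluster_count`).
    """

    partition: str = "random_sampling"  # or "cross_validation"
    train_frac: float = 0.7
    val_frac: float = 0.3
    test_frac: float = 0.0
    k_folds: int = 10
    max_iterations: int = 3000
    subset_sizes: tuple[int, ...] | None = None
    cluster_min: int = 2
    cluster_max: int | None = None
    method: str = "auto"  # "ward" | "kmeans" | "auto"
    seed: int = 0
    selection_metric: str = "accuracy"
    stratify: bool = False
    positive_class: float | None = None  # default: highest class code
    resolution: int = 1001

    def __post_init__(self) -> None:
        fracs = (self.train_frac, self.val_frac, self.test_frac)
        if any(not 0.0 <= f <= 1.0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("train/val/test fractions must lie in [0,1] and sum to 1")
        if self.partition not in ("random_sampling", "cross_validation"):
            raise ValueError(f"unknown partition scheme {self.partition!r}")
        if self.k_folds < 2:
            raise ValueError("k_folds must be at least 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be at least 1")
        if self.selection_metric not in _METRIC_NAMES:
            raise ValueError(f"unknown selection metric {self.selection_metric!r}")


@dataclass(frozen=True)
class Provenance:
    """Where a candidate came from: enough to rebuild it exactly."""

    subset: tuple[str, ...]
    ks: tuple[int, ...]
    method: str
    seed: int
    partition: str
    iteration: int


@dataclass
class SearchResult:
    """One evaluated candidate: system, knowledge base, metrics, provenance."""

    system: FuzzySystem
    kb: KnowledgeBase
    metrics: MetricSet
    provenance: Provenance
    fold_metrics: list[MetricSet] | None = None


def permute_rows(table: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Seeded uniform permutation of the rows; content unchanged."""
    if table.empty:
        raise ValueError("cannot permute an empty table")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(table))
    return table.iloc[perm].reset_index(drop=True)


def _stratified_take(table, labels, count, rng):
    """Indices of ``count`` rows drawn proportionally from each class."""
    idx = np.arange(len(table))
    chosen: list[int] = []
    classes = np.unique(labels)
    per = {c: int(round(count * np.mean(labels == c))) for c in classes}
    # fix rounding drift deterministically on the largest class
    drift = count - sum(per.values())
    per[classes[np.argmax([np.sum(labels == c) for c in classes])]] += drift
    for c in classes:
        pool = idx[labels == c]
        pool = rng.permutation(pool)
        chosen.extend(pool[: per[c]])
    return np.sort(np.array(chosen, dtype=int))


def random_split(
    table: pd.DataFrame,
    fractions: tuple[float, ...],
    seed: int,
    stratify_labels=None,
) -> tuple[pd.DataFrame, ...]:
    """Disjoint exhaustive train/validation(/test) split by rounded fractions.

    The non-training subsets get ``round(n * frac)`` rows each and training
    the remainder.  Optional stratification keeps class proportions per
    subset.  Deterministic for a given seed.
    """
    fracs = tuple(fractions)
    if len(fracs) not in (2, 3):
        raise ValueError("fractions must be (train, val) or (train, val, test)")
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(table)
    if n < 2:
        raise ValueError("need at least two rows to split")
    rng = np.random.default_rng(seed)
    sizes = [int(round(n * f)) for f in fracs[1:]]
    n_train = n - sum(sizes)
    for f, s in zip(fracs, [n_train] + sizes):
        if f > 0 and s == 0:
            raise ValueError(f"fraction {f} yields an empty subset for n={n}")
        if f == 0 and s != 0:
            raise ValueError("zero fraction received rows; check the fractions")
    if stratify_labels is not None:
        labels = np.asarray(stratify_labels)
        remaining = np.arange(n)
        parts = []
        for s in sizes:
            mask = np.isin(np.arange(n), remaining)
            take = _stratified_take(table.iloc[remaining], labels[remaining], s, rng)
            parts.append(remaining[take])
            remaining = np.setdiff1d(remaining, remaining[take])
        order = [remaining] + parts
    else:
        perm = rng.permutation(n)
        cuts = np.cumsum([n_train] + sizes)[:-1]
        order = np.split(perm, cuts)
    out = tuple(table.iloc[np.sort(ix)].reset_index(drop=True) for ix in order)
    return out if len(fracs) == 3 else out[:2]


def kfold_partitions(
    table: pd.DataFrame, k: int, seed: int
) -> list[tuple[pd.DataFrame, pd.DataFrame]]:
    """k shuffled folds with sizes differing by at most one row."""
    if k > len(table):
        raise ValueError(f"k={k} exceeds the {len(table)} available rows")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    return [
        (table.iloc[tr].reset_index(drop=True), table.iloc[te].reset_index(drop=True))
        for tr, te in kf.split(table)
    ]


def predict(
    system: FuzzySystem, kb: KnowledgeBase, X
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Predicted class codes, continuous scores and no-rule flags for rows ``X``.

    The score is the crisp defuzzified value of the first output, which is
    monotone in class code because output MFs sit at the codes themselves.
    """
    crisp, flags = infer_batch(system, X, warn=False)
    codes = kb.output_class_codes[0]
    pred = classify_batch(system.outputs[0], crisp[:, 0], codes)
    return pred, crisp[:, 0], flags[:, 0]


def _bounded_compositions(
    total: int, bounds: list[int], lo: int
) -> Iterator[tuple[int, ...]]:
    """All vectors with ``lo <= v_i <= bounds[i]`` summing to ``total``."""
    if len(bounds) == 1:
        if lo <= total <= bounds[0]:
            yield (total,)
        return
    head_max = min(bounds[0], total - lo * (len(bounds) - 1))
    for v in range(lo, head_max + 1):
        for rest in _bounded_compositions(total - v, bounds[1:], lo):
            yield (v,) + rest


def _candidate_stream(
    input_cols: list[str],
    kmax: dict[str, int],
    kmin: int,
    sizes: tuple[int, ...],
    rng: np.random.Generator,
) -> Iterator[tuple[tuple[str, ...], tuple[int, ...]]]:
    """(subset, ks) pairs by ascending subset size, then ascending total
    cluster count, seeded-shuffled within each stratum."""
    from itertools import combinations

    for s in sorted(sizes):
        subs = list(combinations(input_cols, s))
        hi = max(sum(sorted((kmax[c] for c in sub), reverse=True)) for sub in subs)
        for total in range(kmin * s, hi + 1):
            stratum = []
            for sub in subs:
                bounds = [kmax[c] for c in sub]
                if sum(bounds) < total:
                    continue
                for ks in _bounded_compositions(total, bounds, kmin):
                    stratum.append((sub, ks))
            if not stratum:
                continue
            rng.shuffle(stratum)
            yield from stratum


def _rank_key(res: SearchResult, metric: str):
    v = res.metrics.value(metric)
    v = -np.inf if not np.isfinite(v) else v
    return (-v, len(res.provenance.subset), len(res.kb.rule_table),
            res.provenance.iteration)


def search(data: Dataset | pd.DataFrame, config: SearchConfig) -> list[SearchResult]:
    """Run the candidate sweep and return results ranked best-first.

    ``data`` is a preprocessed :class:`~mamfis.data_io.Dataset` (or a plain
    DataFrame whose last column is the class).  Random-sampling mode
    evaluates every candidate on one shared validation split; cross-
    validation mode reports fold-averaged metrics and rebuilds each
    candidate's delivered system on the full table.
    """
    if isinstance(data, Dataset):
        df = data.df
        schema = data.schema
    else:
        df = data
        cols = list(df.columns)
        schema = DatasetSchema.from_columns(cols[:-1], [cols[-1]])
    if df.isna().any().any():
        raise ValueError("table contains missing values; run preprocess first")
    input_cols = [c for c in schema.input_cols if df[c].nunique() > 1]
    dropped = set(schema.input_cols) - set(input_cols)
    if dropped:
        logger.warning("dropping constant column(s): %s", sorted(dropped))
    output_cols = schema.output_cols
    nominal = schema.nominal_cols
    if not input_cols:
        raise ValueError("no usable (non-constant) input columns")

    rng = np.random.default_rng(config.seed)
    df = permute_rows(df, int(rng.integers(2**31)))

    n_in = len(input_cols)
    if config.subset_sizes is None:
        lo = 2 if n_in >= 2 else 1
        sizes = tuple(range(lo, n_in + 1))
    else:
        sizes = tuple(s for s in sorted(set(config.subset_sizes)) if 1 <= s <= n_in)
        if not sizes:
            raise ValueError("no feasible subset size")
    kmax = {}
    for c in input_cols:
        if c in nominal:
            kmax[c] = df[c].nunique()
        else:
            k = optimal_cluster_count(df[c].to_numpy())
            kmax[c] = min(k, config.cluster_max) if config.cluster_max else k
        kmax[c] = max(kmax[c], config.cluster_min)
    output_ks = [df[c].nunique() for c in output_cols]
    labels = df[output_cols[0]].to_numpy()
    positive = (
        config.positive_class
        if config.positive_class is not None
        else float(np.max(labels))
    )

    if config.partition == "random_sampling":
        fracs = (config.train_frac, config.val_frac, config.test_frac)
        fracs = fracs if config.test_frac > 0 else fracs[:2]
        split_seed = int(rng.integers(2**31))
        parts = random_split(
            df, fracs, split_seed,
            stratify_labels=labels if config.stratify else None,
        )
        train_df, val_df = parts[0], parts[1]
        folds = None
    else:
        fold_seed = int(rng.integers(2**31))
        folds = kfold_partitions(df, config.k_folds, fold_seed)
        train_df = val_df = None

    stream_rng = np.random.default_rng(int(rng.integers(2**31)))
    results: list[SearchResult] = []
    iteration = 0
    for subset, ks in _candidate_stream(input_cols, kmax, config.cluster_min,
                                        sizes, stream_rng):
        if iteration >= config.max_iterations:
            break
        all_ks = list(ks) + output_ks
        try:
            # contradictions and cluster-count reductions are routine during
            # a sweep; keep them out of the user's face
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                metrics, fold_metrics, kb, system = _evaluate_candidate(
                    subset, all_ks, config, nominal, output_cols, positive,
                    train_df, val_df, folds, df,
                )
        except ValueError as exc:
            logger.debug("candidate %s/%s skipped: %s", subset, ks, exc)
            iteration += 1
            continue
        results.append(
            SearchResult(
                system=system,
                kb=kb,
                metrics=metrics,
                provenance=Provenance(
                    subset=subset,
                    ks=tuple(ks),
                    method=config.method,
                    seed=config.seed,
                    partition=config.partition,
                    iteration=iteration,
                ),
                fold_metrics=fold_metrics,
            )
        )
        iteration += 1
    if not results:
        raise ValueError("no feasible candidate configuration was evaluated")
    results.sort(key=lambda r: _rank_key(r, config.selection_metric))
    return results


def _evaluate_candidate(subset, all_ks, config, nominal, output_cols, positive,
                        train_df, val_df, folds, full_df):
    """Build and score one (subset, ks) candidate under the active partition."""
    if folds is None:
        kb, system = build_knowledge_base(
            train_df, list(subset), output_cols, all_ks,
            method=config.method, seed=config.seed, nominal=nominal,
            resolution=config.resolution,
        )
        pred, scores, _ = predict(
            system, kb, val_df[list(subset)].to_numpy(dtype=float)
        )
        truth = val_df[output_cols[0]].to_numpy(dtype=float)
        return _safe_metrics(truth, pred, scores, positive), None, kb, system
    fold_metrics = []
    for tr, te in folds:
        kb_f, sys_f = build_knowledge_base(
            tr, list(subset), output_cols, all_ks,
            method=config.method, seed=config.seed, nominal=nominal,
            resolution=config.resolution,
        )
        pred, scores, _ = predict(
            sys_f, kb_f, te[list(subset)].to_numpy(dtype=float)
        )
        truth = te[output_cols[0]].to_numpy(dtype=float)
        fold_metrics.append(_safe_metrics(truth, pred, scores, positive))
    metrics = MetricSet.mean(fold_metrics)
    # the delivered model is rebuilt on the full table
    kb, system = build_knowledge_base(
        full_df, list(subset), output_cols, all_ks,
        method=config.method, seed=config.seed, nominal=nominal,
        resolution=config.resolution,
    )
    return metrics, fold_metrics, kb, system


def _safe_metrics(truth, pred, scores, positive) -> MetricSet:
    """Metric suite that degrades gracefully when a class is missing."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return compute_metrics(truth, pred, scores, positive)
        except ValueError:
            # e.g. validation fold lacks one class: fall back to accuracy only
            ms = MetricSet()
            ms.accuracy = float(np.mean(np.asarray(truth) == np.asarray(pred)))
            return ms


def select_best(results: list[SearchResult],
                metric: str = "accuracy") -> SearchResult:
    """Best result by the metric; ties break toward fewer variables, then
    fewer rules, then the earlier iteration."""
    if not results:
        raise ValueError("empty result list")
    return min(results, key=lambda r: _rank_key(r, metric))
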