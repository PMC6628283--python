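"""Synthetic classification tables with known per-class band structure.

Every other module is testable offline against these generators: each
informative feature draws its values from a class-specific band (a run of
integer codes, or a clipped-normal interval for continuous biomarkers),
noise features draw identically for every class, and the ground truth
records which features are informative, where the bands sit and how many
IF-THEN rules a perfect per-band clustering would need.

Band geometry: with within-band spread ``s`` (half-width of a band), the
edge-to-edge gap between consecutive class bands is ``separation * s``, so
bands are disjoint whenever ``separation > 0`` and a nearest-band classifier
is exact.  ``separation = 0`` is the null case: all classes share one band,
so informative features carry no class signal at all.  An optional
``band_leak`` fraction of informative cells is drawn from the full-range
class-independent distribution instead, mimicking the measurement spillover
that makes real clinical tables imperfectly separable (and making integer
features span their whole code range, as the public tumour datasets do).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ColumnSpec, Dataset, DatasetSchema

__all__ = ["GeneratorSpec", "GroundTruth", "generate", "generate_wbcd_like",
           "implied_rules"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Shape of a synthetic classification table.

    ``separation`` is the gap between class-conditional value bands in units
    of the within-band spread; ``clusters_per_feature`` splits each class
    band into that many sub-bands (multi-modal classes).  ``missing_rate``
    replaces that fraction of informative cells with the missing token
    (restricted to ``missing_columns`` when given).
    """

    n_rows: int
    n_informative: int = 2
    n_noise: int = 3
    n_classes: int = 2
    clusters_per_feature: int = 1
    separation: float = 3.0
    feature_kind: str = "integer_code"  # "integer_code" | "continuous" | "nominal"
    code_range: tuple[int, int] = (1, 10)
    missing_rate: float = 0.0
    missing_columns: tuple[int, ...] | None = None  # informative-feature offsets
    band_leak: float = 0.0
    class_probs: tuple[float, ...] | None = None  # None = balanced
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < self.n_classes:
            raise ValueError("need at least one row per class")
        if self.n_informative < 1:
            raise ValueError("need at least one informative feature")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.band_leak < 1.0:
            raise ValueError("band_leak must lie in [0, 1)")
        if self.feature_kind not in ("integer_code", "continuous", "nominal"):
            raise ValueError(f"unknown feature kind {self.feature_kind!r}")
        if self.class_probs is not None:
            if len(self.class_probs) != self.n_classes:
                raise ValueError("class_probs must have one entry per class")
            if abs(sum(self.class_probs) - 1.0) > 1e-9:
                raise ValueError("class_probs must sum to 1")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually planted in the table."""

    informative: tuple[int, ...]  # column positions in the feature table
    bands: dict  # class code -> list per informative feature of [(lo, hi), ...]
    row_bands: np.ndarray  # (n_rows, n_informative) global band ids, -1 = leak
    labels: np.ndarray  # (n_rows,) class codes 1..C
    minimal_rules: int = field(default=0)


def _class_labels(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    n, C = spec.n_rows, spec.n_classes
    if spec.class_probs is None:
        counts = [n // C] * C
        for i in range(n - sum(counts)):
            counts[i] += 1
    else:
        counts = [int(round(n * p)) for p in spec.class_probs]
        counts[0] += n - sum(counts)
    labels = np.repeat(np.arange(1, C + 1), counts)
    return labels[rng.permutation(n)]


def _integer_bands(spec: GeneratorSpec) -> list[list[tuple[float, float]]]:
    """Per class, the list of sub-band (lo, hi) code runs for one feature."""
    lo, hi = spec.code_range
    span = hi - lo + 1
    C = spec.n_classes
    if spec.separation == 0:
        return [[(lo, hi)] * spec.clusters_per_feature for _ in range(C)]
    gap = int(math.ceil(spec.separation))
    width = (span - (C - 1) * gap) // C
    if width < spec.clusters_per_feature:
        raise ValueError(
            f"infeasible separation: class bands of width {width} cannot hold "
            f"{spec.clusters_per_feature} sub-band(s) within codes {lo}..{hi}"
        )
    bands = []
    for c in range(C):
        b_lo = lo + c * (width + gap)
        b_hi = b_lo + width - 1
        edges = np.linspace(b_lo, b_hi + 1, spec.clusters_per_feature + 1)
        bands.append(
            [(int(math.ceil(edges[j])), int(math.ceil(edges[j + 1]) - 1))
             for j in range(spec.clusters_per_feature)]
        )
    return bands


def _continuous_bands(spec: GeneratorSpec) -> list[list[tuple[float, float]]]:
    C = spec.n_classes
    half = 2.0  # band half-width = 2 within-band SDs (sigma = 1)
    if spec.separation == 0:
        return [[(-half, half)] * spec.clusters_per_feature for _ in range(C)]
    step = 2 * half + spec.separation  # edge gap = separation * sigma
    bands = []
    for c in range(C):
        b_lo = c * step - half
        b_hi = c * step + half
        edges = np.linspace(b_lo, b_hi, spec.clusters_per_feature + 1)
        bands.append(
            [(edges[j], edges[j + 1]) for j in range(spec.clusters_per_feature)]
        )
    return bands


def _draw_in_band(kind, band, size, rng):
    lo, hi = band
    if kind == "continuous":
        mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
        return np.clip(rng.normal(mid, max(half / 2.0, 1e-9), size), lo, hi)
    return rng.integers(int(lo), int(hi) + 1, size).astype(float)


def generate(spec: GeneratorSpec) -> tuple[Dataset, GroundTruth]:
    """Build the table and its ground truth; fully seeded and deterministic."""
    rng = np.random.default_rng(spec.seed)
    labels = _class_labels(spec, rng)
    n = spec.n_rows
    n_feat = spec.n_informative + spec.n_noise
    positions = rng.permutation(n_feat)
    informative = tuple(sorted(int(p) for p in positions[: spec.n_informative]))

    if spec.feature_kind == "continuous":
        per_class = _continuous_bands(spec)
        full_lo = min(b[0] for cls in per_class for b in cls)
        full_hi = max(b[1] for cls in per_class for b in cls)
    else:
        per_class = _integer_bands(spec)
        full_lo, full_hi = spec.code_range

    # global band ids: enumerate (class, sub-band) pairs by ascending lo
    flat = sorted(
        {(cls_bands[j][0], cls_bands[j][1])
         for cls_bands in per_class for j in range(spec.clusters_per_feature)}
    )
    band_id = {b: i for i, b in enumerate(flat)}

    X = np.empty((n, n_feat))
    row_bands = np.full((n, spec.n_informative), -1, dtype=int)
    kind = "continuous" if spec.feature_kind == "continuous" else "integer"
    for fi, col in enumerate(informative):
        for c in range(1, spec.n_classes + 1):
            mask = labels == c
            cls_bands = per_class[c - 1]
            choice = rng.integers(0, spec.clusters_per_feature, mask.sum())
            vals = np.empty(mask.sum())
            for j in range(spec.clusters_per_feature):
                sub = choice == j
                vals[sub] = _draw_in_band(kind, cls_bands[j], sub.sum(), rng)
            X[mask, col] = vals
            row_bands[mask, fi] = [band_id[cls_bands[j]] for j in choice]
        if spec.band_leak > 0:
            leak = rng.random(n) < spec.band_leak
            X[leak, col] = _draw_in_band(kind, (full_lo, full_hi), leak.sum(), rng)
            row_bands[leak, fi] = -1
    noise_cols = [c for c in range(n_feat) if c not in informative]
    for col in noise_cols:
        X[:, col] = _draw_in_band(kind, (full_lo, full_hi), n, rng)

    if spec.missing_rate > 0:
        targets = (
            list(informative)
            if spec.missing_columns is None
            else [informative[i] for i in spec.missing_columns]
        )
        for col in targets:
            miss = rng.random(n) < spec.missing_rate
            X[miss, col] = np.nan

    feature_names = [f"f{i + 1}" for i in range(n_feat)]
    df = pd.DataFrame(X, columns=feature_names)
    df["class"] = labels.astype(float)
    nominal_kind = spec.feature_kind == "nominal"
    # class codes are already integers, so the output column stays numeric;
    # the rule builder treats output columns as class labels regardless
    specs = tuple(
        [ColumnSpec(name, "input", "nominal" if nominal_kind else "numeric")
         for name in feature_names]
        + [ColumnSpec("class", "output", "numeric")]
    )
    schema = DatasetSchema(specs)
    ds = Dataset(df, schema)

    bands = {
        c: [per_class[c - 1][j] for j in range(spec.clusters_per_feature)]
        for c in range(1, spec.n_classes + 1)
    }
    gt = GroundTruth(
        informative=informative,
        bands=bands,
        row_bands=row_bands,
        labels=labels,
        minimal_rules=0,
    )
    object.__setattr__(gt, "minimal_rules", implied_rules(gt))
    return ds, gt


def generate_wbcd_like(
    n_rows: int = 699, seed: int = 0, missing_rate: float = 0.02
) -> tuple[Dataset, GroundTruth]:
    """Tumour-grading style table: 9 integer-coded 1-10 features, binary class.

    Five features are informative (low codes for the majority/benign class,
    high codes for the minority/malignant one, ~65/35 prevalence), four are
    noise, and exactly one informative feature carries missing cells — the
    usual shape of cytology tables with an incompletely recorded marker.
    A small band leak makes every feature span the full 1-10 code range.
    """
    if n_rows < 10:
        raise ValueError("need at least 10 rows")
    spec = GeneratorSpec(
        n_rows=n_rows,
        n_informative=5,
        n_noise=4,
        n_classes=2,
        separation=2.0,
        feature_kind="integer_code",
        code_range=(1, 10),
        missing_rate=missing_rate,
        missing_columns=(2,),
        band_leak=0.08,
        class_probs=(0.655, 0.345),
        seed=seed,
    )
    return generate(spec)


def implied_rules(gt: GroundTruth, ks=None) -> int:
    """Distinct (band combination -> class) patterns present in the table.

    This is the rule count a perfect per-band clustering would extract.
    Rows with leaked (out-of-band) cells are excluded because their pattern
    is undefined.  ``ks``, when given, must align to the informative
    features and is validated only (the pattern count is a property of the
    planted bands, not of a requested clustering).
    """
    if ks is not None and len(ks) != len(gt.informative):
        raise ValueError("ks must align to the informative features")
    clean = (gt.row_bands >= 0).all(axis=1)
    rows = np.column_stack([gt.row_bands[clean], gt.labels[clean]])
    if rows.size == 0:
        return 0
    return int(np.unique(rows, axis=0).shape[0])
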