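"""Mamdani-type fuzzy inference.

A Mamdani system maps crisp inputs to crisp outputs through four stages:
fuzzification (crisp value -> membership degrees), rule firing (min for AND,
max for OR, scaled by a rule weight), implication and aggregation (min-clip
each rule's consequent set, pointwise max across rules), and defuzzification
(collapse the aggregated output set to one number, by default its centroid

    z* = integral mu(z) z dz / integral mu(z) dz

discretised on an even grid over the output range).  Membership functions are
piecewise-linear triangles and trapezoids, which is all the rule-induction
pipeline in :mod:`mamfis.kb_builder` ever produces.

Conventions chosen here (and relied on elsewhere in the package):

* membership degree is upper semi-continuous at vertical edges: a zero-width
  ramp (``a == b`` or ``c == d``) evaluates to 1 at the breakpoint, so
  touching cluster-derived sets never leave a measure-zero gap;
* out-of-range inputs are clamped to the variable range before fuzzification;
* an input that fires no rule defuzzifies to the midpoint of the output range
  and raises a diagnostic flag instead of aborting batch evaluation;
* the centroid integrals treat the sampled aggregate as piecewise linear
  between grid points and integrate each segment in closed form, so the
  result is exact for the interpolant (no quadrature error on top of the
  grid discretisation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MembershipFunction",
    "FuzzyVariable",
    "FuzzyRule",
    "FuzzySystem",
    "AggregatedOutput",
    "ZeroAggregateError",
    "NoRuleFiredWarning",
    "membership_degree",
    "rule_fire_strength",
    "infer",
    "infer_batch",
    "defuzzify",
    "classify",
    "classify_batch",
]

TRIANGULAR = "triangular"
TRAPEZOIDAL = "trapezoidal"

DEFUZZ_METHODS = ("centroid", "som", "mom", "lom")


class ZeroAggregateError(ValueError):
    """Raised by :func:`defuzzify` when no rule contributed any membership."""


class NoRuleFiredWarning(UserWarning):
    """Emitted when an input fires no rule and the midpoint fallback is used."""


@dataclass(frozen=True)
class MembershipFunction:
    """Triangular or trapezoidal fuzzy set with ordered breakpoints.

    For a trapezoid the plateau is ``[b, c]`` with feet ``a`` and ``d``.
    For a triangle the peak is ``b`` and the feet are ``a`` and ``c``
    (``d`` is unused and must be ``None``).
    """

    label: str
    shape: str
    a: float
    b: float
    c: float
    d: float | None = None

    def __post_init__(self) -> None:
        if self.shape not in (TRIANGULAR, TRAPEZOIDAL):
            raise ValueError(f"unknown membership shape {self.shape!r}")
        if self.shape == TRIANGULAR:
            if self.d is not None:
                raise ValueError("triangular MF takes three breakpoints")
            if not (self.a <= self.b <= self.c):
                raise ValueError(
                    f"triangular breakpoints must be ordered: {(self.a, self.b, self.c)}"
                )
        else:
            if self.d is None:
                raise ValueError("trapezoidal MF needs a fourth breakpoint")
            if not (self.a <= self.b <= self.c <= self.d):
                raise ValueError(
                    "trapezoidal breakpoints must be ordered: "
                    f"{(self.a, self.b, self.c, self.d)}"
                )

    def _trapezoid_params(self) -> tuple[float, float, float, float]:
        """Return ``(a, b, c, d)`` treating a triangle as a zero-plateau trapezoid."""
        if self.shape == TRIANGULAR:
            return self.a, self.b, self.b, self.c
        return self.a, self.b, self.c, self.d  # type: ignore[return-value]

    @property
    def support_hi(self) -> float:
        return self.c if self.shape == TRIANGULAR else self.d  # type: ignore[return-value]

    def degree(self, x):
        """Membership degree of ``x`` (scalar or array), always in [0, 1]."""
        a, b, c, d = self._trapezoid_params()
        xv = np.asarray(x, dtype=float)
        out = np.zeros(xv.shape)
        left = (xv >= a) & (xv < b)
        right = (xv > c) & (xv <= d)
        # masks are empty when the corresponding ramp has zero width, so the
        # divisions below never see b == a or d == c
        if left.any():
            out[left] = (xv[left] - a) / (b - a)
        if right.any():
            out[right] = (d - xv[right]) / (d - c)
        out[(xv >= b) & (xv <= c)] = 1.0
        if np.isscalar(x) or xv.ndim == 0:
            return float(out)
        return out


@dataclass(frozen=True)
class FuzzyVariable:
    """Named variable with a range and an ordered family of membership functions."""

    name: str
    range_lo: float
    range_hi: float
    mfs: tuple[MembershipFunction, ...]

    def __post_init__(self) -> None:
        if not self.range_lo < self.range_hi:
            raise ValueError(
                f"variable {self.name!r}: range [{self.range_lo}, {self.range_hi}] "
                "has zero or negative width"
            )
        if not self.mfs:
            raise ValueError(f"variable {self.name!r} has no membership functions")
        peaks = [mf.b for mf in self.mfs]
        if any(p2 < p1 for p1, p2 in zip(peaks, peaks[1:])):
            raise ValueError(f"variable {self.name!r}: MFs not ordered by peak")
        for mf in self.mfs:
            if mf.a < self.range_lo - 1e-12 or mf.support_hi > self.range_hi + 1e-12:
                raise ValueError(
                    f"variable {self.name!r}: MF {mf.label!r} exceeds the range"
                )

    def validate_coverage(self, n_points: int = 257) -> None:
        """Check that every point of the range has positive membership somewhere."""
        grid = np.linspace(self.range_lo, self.range_hi, n_points)
        total = np.max([mf.degree(grid) for mf in self.mfs], axis=0)
        if np.any(total <= 0):
            hole = grid[int(np.argmin(total))]
            raise ValueError(
                f"variable {self.name!r}: no membership covers x={hole:g}"
            )

    def degrees(self, x) -> np.ndarray:
        """Stack of membership degrees, shape ``(n_mfs,) + shape(x)``."""
        return np.stack([np.atleast_1d(mf.degree(x)) for mf in self.mfs])


@dataclass(frozen=True)
class FuzzyRule:
    """IF-THEN rule over MF indices (1-based; 0 marks an unused variable)."""

    antecedent: tuple[int, ...]
    consequent: tuple[int, ...]
    weight: float = 1.0
    connector: str = "AND"

    def __post_init__(self) -> None:
        if not 0.0 < self.weight <= 1.0:
            raise ValueError(f"rule weight {self.weight} outside (0, 1]")
        if self.connector not in ("AND", "OR"):
            raise ValueError(f"unknown connector {self.connector!r}")


@dataclass
class FuzzySystem:
    """Assembled Mamdani system: variables, rules and operator configuration."""

    name: str
    inputs: list[FuzzyVariable]
    outputs: list[FuzzyVariable]
    rules: list[FuzzyRule]
    and_method: str = "min"
    or_method: str = "max"
    implication: str = "min"
    aggregation: str = "max"
    defuzz_method: str = "centroid"
    resolution: int = 1001
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.defuzz_method not in DEFUZZ_METHODS:
            raise ValueError(f"unknown defuzzification method {self.defuzz_method!r}")
        if self.resolution < 2:
            raise ValueError("resolution must be at least 2 grid points")

    def validate(self) -> None:
        """Full consistency check: rule shapes, index ranges, MF coverage."""
        if not self.rules:
            raise ValueError("rule base is empty")
        for var in (*self.inputs, *self.outputs):
            var.validate_coverage()
        for i, rule in enumerate(self.rules):
            if len(rule.antecedent) != len(self.inputs):
                raise ValueError(f"rule {i}: antecedent length != number of inputs")
            if len(rule.consequent) != len(self.outputs):
                raise ValueError(f"rule {i}: consequent length != number of outputs")
            for j, idx in enumerate(rule.antecedent):
                if not 0 <= idx <= len(self.inputs[j].mfs):
                    raise ValueError(
                        f"rule {i}: antecedent index {idx} out of range for "
                        f"input {self.inputs[j].name!r}"
                    )
            for j, idx in enumerate(rule.consequent):
                if not 0 <= idx <= len(self.outputs[j].mfs):
                    raise ValueError(
                        f"rule {i}: consequent index {idx} out of range for "
                        f"output {self.outputs[j].name!r}"
                    )

    def with_defuzz(self, method: str) -> "FuzzySystem":
        return replace(self, defuzz_method=method, diagnostics={})

    def clamp(self, X: np.ndarray) -> np.ndarray:
        lo = np.array([v.range_lo for v in self.inputs])
        hi = np.array([v.range_hi for v in self.inputs])
        return np.clip(X, lo, hi)


@dataclass(frozen=True)
class AggregatedOutput:
    """Aggregated output fuzzy set sampled on a strictly increasing grid."""

    grid: np.ndarray
    mu: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        mu = np.asarray(self.mu, dtype=float)
        if grid.shape != mu.shape or grid.ndim != 1:
            raise ValueError("grid and mu must be 1-D arrays of equal length")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(mu < -1e-12) or np.any(mu > 1 + 1e-12):
            raise ValueError("membership values must lie in [0, 1]")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "mu", mu)


def membership_degree(mf: MembershipFunction, x):
    """Degree of membership of ``x`` in ``mf``; total function on the reals."""
    return mf.degree(x)


def rule_fire_strength(system: FuzzySystem, rule: FuzzyRule, x) -> float:
    """Firing strength of one rule for a single (already clamped) input vector.

    AND rules take the minimum over the referenced antecedent degrees, OR
    rules the maximum; either is scaled by the rule weight.  Antecedent
    entries of 0 (unused variable) are skipped; a rule with no referenced
    antecedent fires fully.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (len(system.inputs),):
        raise ValueError(
            f"input vector has {x.size} values but the system has "
            f"{len(system.inputs)} inputs"
        )
    degs = [
        system.inputs[j].mfs[idx - 1].degree(x[j])
        for j, idx in enumerate(rule.antecedent)
        if idx > 0
    ]
    if not degs:
        return rule.weight
    combined = min(degs) if rule.connector == "AND" else max(degs)
    return rule.weight * combined


def _fire_strengths(system: FuzzySystem, X: np.ndarray) -> np.ndarray:
    """Firing strengths for a batch, shape ``(n_rules, n_samples)``."""
    degrees = [var.degrees(X[:, j]) for j, var in enumerate(system.inputs)]
    n = X.shape[0]
    strengths = np.empty((len(system.rules), n))
    for r, rule in enumerate(system.rules):
        used = [degrees[j][idx - 1] for j, idx in enumerate(rule.antecedent) if idx > 0]
        if not used:
            s = np.ones(n)
        elif rule.connector == "AND":
            s = np.min(used, axis=0)
        else:
            s = np.max(used, axis=0)
        strengths[r] = rule.weight * s
    return strengths


def _centroid_moments(grid: np.ndarray, mu: np.ndarray):
    """Exact area and first moment of the piecewise-linear interpolant.

    On a segment [z0, z0+h] with end degrees (m0, m1):
    integral of mu dz = h (m0 + m1) / 2 and
    integral of z mu dz = h [ z0 (m0 + m1) / 2 + h (m0/6 + m1/3) ].
    ``mu`` may be 1-D or (n_samples, resolution); reduction is on the last axis.
    """
    h = np.diff(grid)
    m0, m1 = mu[..., :-1], mu[..., 1:]
    pair = 0.5 * (m0 + m1)
    area = (h * pair).sum(axis=-1)
    moment = (h * (grid[:-1] * pair + h * (m0 / 6.0 + m1 / 3.0))).sum(axis=-1)
    return area, moment


def defuzzify(agg: AggregatedOutput, method: str = "centroid") -> float:
    """Collapse an aggregated output set to a crisp value.

    ``centroid`` integrates the piecewise-linear interpolant of the sampled
    aggregate exactly (closed-form segment moments); ``som``/``lom`` return
    the smallest/largest grid point attaining the maximum and ``mom`` their
    mean (within a 1e-12 tolerance of the maximum).
    """
    if method not in DEFUZZ_METHODS:
        raise ValueError(f"unknown defuzzification method {method!r}")
    grid, mu = agg.grid, agg.mu
    if method == "centroid":
        area, moment = _centroid_moments(grid, mu)
        if area <= 0.0:
            raise ZeroAggregateError("no rule fired: aggregate is identically zero")
        return float(moment / area)
    peak = float(mu.max())
    if method == "mom" and peak <= 0.0:
        raise ZeroAggregateError("no rule fired: aggregate is identically zero")
    at_max = grid[mu >= peak - 1e-12]
    if method == "som":
        return float(at_max[0])
    if method == "lom":
        return float(at_max[-1])
    return float(at_max.mean())


def _defuzzify_batch(
    grid: np.ndarray, agg: np.ndarray, method: str
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised defuzzification of ``agg`` (n_samples x resolution).

    Returns crisp values and a boolean flag per sample marking all-zero
    aggregates, for which the midpoint of the range is substituted.
    """
    mid = 0.5 * (grid[0] + grid[-1])
    if method == "centroid":
        area, moment = _centroid_moments(grid, agg)
        flags = area <= 0.0
        crisp = np.where(flags, mid, moment / np.where(flags, 1.0, area))
        return crisp, flags
    peak = agg.max(axis=1)
    flags = peak <= 0.0
    at_max = agg >= (peak[:, None] - 1e-12)
    if method == "som":
        crisp = grid[at_max.argmax(axis=1)]
    elif method == "lom":
        crisp = grid[agg.shape[1] - 1 - at_max[:, ::-1].argmax(axis=1)]
    else:  # mom
        weights = at_max.astype(float)
        crisp = (weights @ grid) / weights.sum(axis=1)
    return np.where(flags, mid, crisp), flags


def infer_batch(
    system: FuzzySystem, X, warn: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Crisp outputs for a batch of input rows.

    Parameters
    ----------
    X : array-like, shape (n_samples, n_inputs)
        Input rows; values outside a variable's range are clamped to it.
    warn : bool
        Emit a :class:`NoRuleFiredWarning` summarising midpoint fallbacks.

    Returns
    -------
    crisp : ndarray, shape (n_samples, n_outputs)
    flags : boolean ndarray, same shape, True where no rule fired and the
        output-range midpoint was substituted.
    """
    if not system.rules:
        raise ValueError("cannot run inference with an empty rule base")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(system.inputs):
        raise ValueError(
            f"input has {X.shape[1]} columns but the system has "
            f"{len(system.inputs)} inputs"
        )
    Xc = system.clamp(X)
    strengths = _fire_strengths(system, Xc)
    n = X.shape[0]
    crisp = np.empty((n, len(system.outputs)))
    flags = np.zeros((n, len(system.outputs)), dtype=bool)
    for j, var in enumerate(system.outputs):
        grid = np.linspace(var.range_lo, var.range_hi, system.resolution)
        mf_grid = var.degrees(grid)  # (n_mfs, resolution)
        agg = np.zeros((n, system.resolution))
        for r, rule in enumerate(system.rules):
            idx = rule.consequent[j]
            if idx == 0:
                continue
            np.maximum(
                agg, np.minimum(strengths[r][:, None], mf_grid[idx - 1][None, :]), out=agg
            )
        crisp[:, j], flags[:, j] = _defuzzify_batch(grid, agg, system.defuzz_method)
    n_flagged = int(flags.any(axis=1).sum())
    if n_flagged:
        system.diagnostics["no_rule_fired"] = (
            system.diagnostics.get("no_rule_fired", 0) + n_flagged
        )
        if warn:
            warnings.warn(
                f"{n_flagged} of {n} inputs fired no rule; "
                "output-range midpoint substituted",
                NoRuleFiredWarning,
                stacklevel=2,
            )
    return crisp, flags


def infer(system: FuzzySystem, x) -> np.ndarray:
    """Crisp output vector for a single input row (see :func:`infer_batch`)."""
    crisp, _ = infer_batch(system, np.atleast_2d(np.asarray(x, dtype=float)))
    return crisp[0]


def classify(output_var: FuzzyVariable, crisp: float, class_codes) -> float:
    """Decode a crisp output value to a class code.

    The code of the MF with maximal membership at ``crisp`` is returned;
    ties break toward the lower MF index so decoding is deterministic.
    """
    codes = list(class_codes)
    if len(codes) != len(output_var.mfs):
        raise ValueError("need exactly one class code per output MF")
    degs = np.array([mf.degree(crisp) for mf in output_var.mfs])
    return codes[int(np.argmax(degs))]


def classify_batch(output_var: FuzzyVariable, crisp, class_codes) -> np.ndarray:
    """Vectorised :func:`classify` over an array of crisp values."""
    codes = np.asarray(list(class_codes), dtype=float)
    if codes.size != len(output_var.mfs):
        raise ValueError("need exactly one class code per output MF")
    degs = output_var.degrees(np.asarray(crisp, dtype=float))
    return codes[np.argmax(degs, axis=0)]
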