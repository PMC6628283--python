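"""Tabular dataset I/O, preprocessing and the ``.fis`` text serialisation.

Datasets are delimited text files with a header row; the delimiter is
auto-detected among comma, semicolon and tab.  A :class:`DatasetSchema`
assigns each column a role (input / output / ignore) and a kind (numeric /
nominal).  Nominal categories are encoded as 1-based integer codes in
first-appearance order and remembered in a bijective code book.  Missing
tokens (``"?"`` by default) become NaN on read and are imputed (default 0)
by :func:`preprocess`, which also applies any explicit value recoding of
numeric columns (e.g. a 2/4 class column recoded to 1/2).

Fuzzy systems are serialised in the de-facto fuzzy-toolbox ``.fis`` dialect:
a ``[System]`` block, one ``[InputN]`` / ``[OutputN]`` block per variable
with ``'trimf'`` / ``'trapmf'`` membership entries, and a ``[Rules]`` block
whose lines list antecedent indices, consequent indices, a parenthesised
weight and the connector code (1 = AND, 2 = OR); index 0 marks a variable
unused by a rule.  Writing is canonical, so write-read-write is byte-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import MetricSet
from .fuzzy_core import (
    TRAPEZOIDAL,
    TRIANGULAR,
    FuzzyRule,
    FuzzySystem,
    FuzzyVariable,
    MembershipFunction,
)

__all__ = [
    "ColumnSpec",
    "DatasetSchema",
    "Dataset",
    "read_dataset",
    "write_dataset",
    "preprocess",
    "write_fis",
    "read_fis",
    "write_report",
    "FisFormatError",
]


class FisFormatError(ValueError):
    """Malformed ``.fis`` file; the message carries the offending line number."""


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    role: str = "input"  # "input" | "output" | "ignore"
    kind: str = "numeric"  # "numeric" | "nominal"

    def __post_init__(self) -> None:
        if self.role not in ("input", "output", "ignore"):
            raise ValueError(f"unknown column role {self.role!r}")
        if self.kind not in ("numeric", "nominal"):
            raise ValueError(f"unknown column kind {self.kind!r}")


@dataclass(frozen=True)
class DatasetSchema:
    """Column roles and kinds plus preprocessing directives."""

    columns: tuple[ColumnSpec, ...]
    missing_token: str = "?"
    impute_value: float = 0.0
    recode: dict = field(default_factory=dict)  # column -> {old value: new value}

    def __post_init__(self) -> None:
        if not any(c.role == "input" for c in self.columns):
            raise ValueError("schema needs at least one input column")
        if not any(c.role == "output" for c in self.columns):
            raise ValueError("schema needs at least one output column")

    @staticmethod
    def from_columns(
        inputs: list[str],
        outputs: list[str],
        nominal: list[str] | None = None,
        ignore: list[str] | None = None,
        **kwargs,
    ) -> "DatasetSchema":
        nominal = set(nominal or [])
        specs = []
        for name in inputs:
            specs.append(ColumnSpec(name, "input",
                                    "nominal" if name in nominal else "numeric"))
        for name in outputs:
            specs.append(ColumnSpec(name, "output",
                                    "nominal" if name in nominal else "numeric"))
        for name in ignore or []:
            specs.append(ColumnSpec(name, "ignore"))
        return DatasetSchema(tuple(specs), **kwargs)

    def names(self, role: str) -> list[str]:
        return [c.name for c in self.columns if c.role == role]

    @property
    def input_cols(self) -> list[str]:
        return self.names("input")

    @property
    def output_cols(self) -> list[str]:
        return self.names("output")

    @property
    def nominal_cols(self) -> set[str]:
        return {c.name for c in self.columns if c.kind == "nominal"}


@dataclass
class Dataset:
    """Numeric table (NaN marks still-unimputed missing cells) plus metadata."""

    df: pd.DataFrame
    schema: DatasetSchema
    codebooks: dict = field(default_factory=dict)  # column -> [category strings]

    def decode(self, column: str, codes) -> list[str]:
        """Map integer codes of a nominal column back to category strings."""
        book = self.codebooks[column]
        return [book[int(c) - 1] for c in np.asarray(codes).ravel()]


def _detect_delimiter(header: str) -> str:
    counts = {sep: header.count(sep) for sep in (",", ";", "\t")}
    best = max(counts, key=counts.get)
    if counts[best] == 0:
        raise ValueError("could not detect a delimiter (comma/semicolon/tab)")
    return best


def read_dataset(
    path, schema: DatasetSchema, delimiter: str | None = None
) -> Dataset:
    """Read a delimited text file and type its columns per the schema."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    if delimiter is None:
        delimiter = _detect_delimiter(header)
    raw = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    if raw.empty:
        raise ValueError(f"{path}: empty dataset (header only)")
    declared = [c.name for c in schema.columns]
    missing_cols = [c for c in declared if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"{path}: declared column(s) missing: {missing_cols}")
    out = {}
    codebooks: dict[str, list[str]] = {}
    for spec in schema.columns:
        if spec.role == "ignore":
            continue
        col = raw[spec.name].astype(str).str.strip()
        is_missing = col == schema.missing_token
        if spec.kind == "nominal":
            categories: list[str] = []
            codes = np.full(len(col), np.nan)
            for i, (val, miss) in enumerate(zip(col, is_missing)):
                if miss:
                    continue
                if val not in categories:
                    categories.append(val)
                codes[i] = categories.index(val) + 1
            out[spec.name] = codes
            codebooks[spec.name] = categories
        else:
            values = np.full(len(col), np.nan)
            for i, (val, miss) in enumerate(zip(col, is_missing)):
                if miss:
                    continue
                try:
                    values[i] = float(val)
                except ValueError:
                    raise ValueError(
                        f"{path}: column {spec.name!r}, row {i + 2}: "
                        f"cannot parse {val!r} as a number"
                    ) from None
            out[spec.name] = values
    df = pd.DataFrame(out)
    return Dataset(df, schema, codebooks)


def write_dataset(ds: Dataset, path) -> None:
    """Write the (possibly still-missing) table to CSV, NaN as the token."""
    token = ds.schema.missing_token

    def fmt(col: pd.Series) -> pd.Series:
        values = col.dropna()
        as_int = values.size and np.allclose(values % 1, 0)
        return col.map(
            lambda v: token if pd.isna(v)
            else (str(int(v)) if as_int else repr(float(v)))
        )

    out = pd.DataFrame({name: fmt(ds.df[name]) for name in ds.df.columns})
    out.to_csv(path, index=False)


def preprocess(ds: Dataset) -> Dataset:
    """Impute missing cells and apply the schema's recode map.

    Missing cells (NaN after reading) become ``schema.impute_value``; the
    recode map rewrites listed values of listed columns simultaneously (so
    ``{2: 1, 4: 2}`` never chains).  A source value that is also a recode
    target (the 2 above) is ambiguous on its own, so the map is only applied
    while at least one unambiguous source value is present — this is what
    keeps ``preprocess`` idempotent on already-recoded data.  A mapping whose
    source values never occur at all triggers a warning, not an error.
    """
    import warnings

    df = ds.df.copy()
    df = df.fillna(ds.schema.impute_value)
    for col, mapping in ds.schema.recode.items():
        if col not in df.columns:
            raise ValueError(f"recode references unknown column {col!r}")
        fmap = {float(k): float(v) for k, v in mapping.items()}
        present = set(np.unique(df[col].to_numpy()))
        targets = set(fmap.values())
        pure_sources = [k for k in fmap if k not in targets]
        sources_here = [k for k in fmap if k in present]
        if not sources_here:
            if not targets <= present:
                warnings.warn(
                    f"recode for column {col!r}: value(s) "
                    f"{sorted(fmap)} not present",
                    stacklevel=2,
                )
            continue
        if pure_sources and not any(k in present for k in pure_sources):
            # only chain-ambiguous values remain: the map was already applied
            continue
        df[col] = df[col].replace(fmap)
    return Dataset(df, ds.schema, dict(ds.codebooks))


# --------------------------------------------------------------------------
# .fis serialisation
# --------------------------------------------------------------------------

def _fmt(v: float) -> str:
    """Canonical number formatting: integers bare, floats via shortest repr."""
    f = float(v)
    if f.is_integer():
        return str(int(f))
    return repr(f)


def _mf_line(i: int, mf: MembershipFunction) -> str:
    if mf.shape == TRIANGULAR:
        kind, params = "trimf", (mf.a, mf.b, mf.c)
    else:
        kind, params = "trapmf", (mf.a, mf.b, mf.c, mf.d)
    joined = " ".join(_fmt(p) for p in params)
    return f"MF{i}='{mf.label}':'{kind}',[{joined}]"


def _var_block(tag: str, var: FuzzyVariable) -> list[str]:
    lines = [
        f"[{tag}]",
        f"Name='{var.name}'",
        f"Range=[{_fmt(var.range_lo)} {_fmt(var.range_hi)}]",
        f"NumMFs={len(var.mfs)}",
    ]
    lines += [_mf_line(i + 1, mf) for i, mf in enumerate(var.mfs)]
    return lines


def write_fis(system: FuzzySystem, path) -> None:
    """Serialise a system to the sectioned ``.fis`` text format."""
    lines = [
        "[System]",
        f"Name='{system.name}'",
        "Type='mamdani'",
        "Version=2.0",
        f"NumInputs={len(system.inputs)}",
        f"NumOutputs={len(system.outputs)}",
        f"NumRules={len(system.rules)}",
        f"AndMethod='{system.and_method}'",
        f"OrMethod='{system.or_method}'",
        f"ImpMethod='{system.implication}'",
        f"AggMethod='{system.aggregation}'",
        f"DefuzzMethod='{system.defuzz_method}'",
    ]
    for i, var in enumerate(system.inputs):
        lines.append("")
        lines += _var_block(f"Input{i + 1}", var)
    for i, var in enumerate(system.outputs):
        lines.append("")
        lines += _var_block(f"Output{i + 1}", var)
    lines.append("")
    lines.append("[Rules]")
    for rule in system.rules:
        ant = " ".join(str(i) for i in rule.antecedent)
        con = " ".join(str(i) for i in rule.consequent)
        conn = 1 if rule.connector == "AND" else 2
        lines.append(f"{ant}, {con} ({_fmt(rule.weight)}) : {conn}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _parse_kv(line: str, lineno: int) -> tuple[str, str]:
    if "=" not in line:
        raise FisFormatError(f"line {lineno}: expected key=value, got {line!r}")
    key, val = line.split("=", 1)
    return key.strip(), val.strip()


def _unquote(val: str) -> str:
    return val[1:-1] if len(val) >= 2 and val[0] == val[-1] == "'" else val


def _parse_mf(val: str, lineno: int) -> MembershipFunction:
    try:
        name_part, rest = val.split(":", 1)
        kind_part, params_part = rest.split(",", 1)
        label = _unquote(name_part.strip())
        kind = _unquote(kind_part.strip())
        params = [float(p) for p in params_part.strip().strip("[]").split()]
    except (ValueError, IndexError):
        raise FisFormatError(f"line {lineno}: malformed MF entry {val!r}") from None
    if kind == "trimf":
        if len(params) != 3:
            raise FisFormatError(f"line {lineno}: trimf needs 3 parameters")
        return MembershipFunction(label, TRIANGULAR, *params)
    if kind == "trapmf":
        if len(params) != 4:
            raise FisFormatError(f"line {lineno}: trapmf needs 4 parameters")
        return MembershipFunction(label, TRAPEZOIDAL, *params)
    raise FisFormatError(f"line {lineno}: unknown MF shape {kind!r}")


def read_fis(path) -> FuzzySystem:
    """Parse a ``.fis`` file back into a :class:`FuzzySystem`."""
    text = Path(path).read_text(encoding="utf-8")
    blocks: list[tuple[str, int, list[tuple[int, str]]]] = []
    current = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "%", "//")):
            continue
        if line.startswith("["):
            if not line.endswith("]"):
                raise FisFormatError(f"line {lineno}: malformed block header {line!r}")
            current = (line[1:-1], lineno, [])
            blocks.append(current)
        else:
            if current is None:
                raise FisFormatError(f"line {lineno}: content before any block")
            current[2].append((lineno, line))

    sys_fields: dict[str, str] = {}
    inputs: dict[int, FuzzyVariable] = {}
    outputs: dict[int, FuzzyVariable] = {}
    rules: list[FuzzyRule] = []
    for header, hline, entries in blocks:
        if header == "System":
            for lineno, line in entries:
                k, v = _parse_kv(line, lineno)
                sys_fields[k] = v
        elif header.startswith("Input") or header.startswith("Output"):
            is_input = header.startswith("Input")
            try:
                idx = int(header[5 if is_input else 6:])
            except ValueError:
                raise FisFormatError(
                    f"line {hline}: malformed block header [{header}]"
                ) from None
            fields_: dict[str, str] = {}
            mfs: list[MembershipFunction] = []
            for lineno, line in entries:
                k, v = _parse_kv(line, lineno)
                if k.startswith("MF"):
                    mfs.append(_parse_mf(v, lineno))
                else:
                    fields_[k] = v
            try:
                lo, hi = (float(t) for t in fields_["Range"].strip("[]").split())
            except (KeyError, ValueError):
                raise FisFormatError(
                    f"line {hline}: block [{header}] lacks a valid Range"
                ) from None
            var = FuzzyVariable(_unquote(fields_.get("Name", header)), lo, hi,
                                tuple(mfs))
            (inputs if is_input else outputs)[idx] = var
        elif header == "Rules":
            for lineno, line in entries:
                try:
                    main, conn_part = line.rsplit(":", 1)
                    body, weight_part = main.rsplit("(", 1)
                    weight = float(weight_part.strip().rstrip(")").strip())
                    ant_part, con_part = body.split(",", 1)
                    ant = tuple(int(t) for t in ant_part.split())
                    con = tuple(int(t) for t in con_part.split())
                    connector = "AND" if int(conn_part.strip()) == 1 else "OR"
                except (ValueError, IndexError):
                    raise FisFormatError(
                        f"line {lineno}: malformed rule {line!r}"
                    ) from None
                rules.append(FuzzyRule(ant, con, weight, connector))
        else:
            raise FisFormatError(f"line {hline}: unknown block [{header}]")

    input_vars = [inputs[i] for i in sorted(inputs)]
    output_vars = [outputs[i] for i in sorted(outputs)]
    system = FuzzySystem(
        name=_unquote(sys_fields.get("Name", "fis")),
        inputs=input_vars,
        outputs=output_vars,
        rules=rules,
        and_method=_unquote(sys_fields.get("AndMethod", "'min'")),
        or_method=_unquote(sys_fields.get("OrMethod", "'max'")),
        implication=_unquote(sys_fields.get("ImpMethod", "'min'")),
        aggregation=_unquote(sys_fields.get("AggMethod", "'max'")),
        defuzz_method=_unquote(sys_fields.get("DefuzzMethod", "'centroid'")),
    )
    for i, rule in enumerate(rules):
        for j, idx in enumerate(rule.antecedent):
            if not 0 <= idx <= len(input_vars[j].mfs):
                raise FisFormatError(
                    f"rule {i + 1} references MF {idx} of input {j + 1}, "
                    f"which has {len(input_vars[j].mfs)} MFs"
                )
        for j, idx in enumerate(rule.consequent):
            if not 0 <= idx <= len(output_vars[j].mfs):
                raise FisFormatError(
                    f"rule {i + 1} references MF {idx} of output {j + 1}, "
                    f"which has {len(output_vars[j].mfs)} MFs"
                )
    return system


# --------------------------------------------------------------------------
# search reports
# --------------------------------------------------------------------------

_METRIC_COLS = [
    "accuracy", "sensitivity", "specificity", "precision", "recall",
    "f_measure", "kappa", "auc", "auc_category",
]


def _metric_row(ms: MetricSet) -> dict:
    return {name: getattr(ms, name) for name in _METRIC_COLS}


def write_report(results, path) -> pd.DataFrame:
    """Write a delimited table of search results (one row per model/fold).

    Cross-validated results get one row per fold plus a ``mean`` row; the
    returned DataFrame is what was written.
    """
    if not results:
        raise ValueError("no results to report")
    rows = []
    for res in results:
        base = {
            "iteration": res.provenance.iteration,
            "subset": "|".join(str(c) for c in res.provenance.subset),
            "ks": "|".join(str(k) for k in res.provenance.ks),
            "method": res.provenance.method,
            "partition": res.provenance.partition,
            "seed": res.provenance.seed,
            "n_vars": len(res.provenance.subset),
            "n_rules": len(res.kb.rule_table) if res.kb is not None else len(
                res.system.rules),
        }
        if res.fold_metrics:
            for fold_id, ms in enumerate(res.fold_metrics, start=1):
                rows.append({**base, "fold": str(fold_id), **_metric_row(ms)})
            rows.append({**base, "fold": "mean", **_metric_row(res.metrics)})
        else:
            rows.append({**base, "fold": "", **_metric_row(res.metrics)})
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
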