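"""Read, validate, and write the delimited tracer data tables.

Column-naming dialect follows the MixSIAR CSV convention so published
example datasets can be reused directly:

* mixture file: one row per consumer, one column per tracer, plus
  optional covariate columns;
* source summary file: one row per source with ``Mean<tracer>``,
  ``SD<tracer>``, optional ``Conc<tracer>``, and ``n`` columns;
* source raw file: one row per source *sample* with a ``Source`` column;
* discrimination file: one row per source with ``Mean<tracer>`` and
  ``SD<tracer>`` columns.

Only comma and tab delimiters are auto-detected, and the decimal
separator is always ``.``.  Factor levels are ordered by first
appearance in the file so design matrices are reproducible regardless
of locale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Factor",
    "MixtureData",
    "SourceData",
    "DiscriminationData",
    "SchemaError",
    "read_mixture_table",
    "read_source_table",
    "read_discrimination_table",
    "as_fixed_sources",
    "write_mixture_table",
    "write_source_table",
    "zero_discrimination",
    "cross_factors",
]


class SchemaError(ValueError):
    """A required column is missing or malformed in an input table."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Factor:
    """A categorical covariate: integer level codes plus level labels.

    Level codes index into ``levels``; levels are ordered by first
    appearance in the input file.
    """

    name: str
    codes: np.ndarray  # int codes, shape (N,)
    levels: list[str]

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=int)
        if self.codes.size and (self.codes.min() < 0 or self.codes.max() >= len(self.levels)):
            raise ValueError(f"factor {self.name!r}: codes out of range")


@dataclass
class MixtureData:
    """Consumer-by-tracer matrix with attached covariates."""

    values: np.ndarray  # (N, J)
    tracer_names: list[str]
    fixed_factors: list[Factor] = field(default_factory=list)
    random_factors: list[Factor] = field(default_factory=list)
    continuous_covariates: list[tuple[str, np.ndarray]] = field(default_factory=list)
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        n, j = self.values.shape
        if n < 1 or j < 1:
            raise ValueError("mixture data needs at least one row and one tracer")
        if len(self.tracer_names) != j:
            raise ValueError("tracer_names length does not match value columns")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(f"missing/non-finite tracer value at row {bad[0]}, tracer {self.tracer_names[bad[1]]!r}")
        for fac in list(self.fixed_factors) + list(self.random_factors):
            if fac.codes.shape[0] != n:
                raise ValueError(f"factor {fac.name!r} length mismatch")
            if fac.n_levels < 2:
                raise ValueError(f"factor {fac.name!r} needs >=2 levels to be used as an effect")
        for fac in self.random_factors:
            # with only two groups the group-level SD is unidentifiable
            if fac.n_levels == 2:
                raise ValueError(
                    f"factor {fac.name!r} has exactly 2 levels and must be used as a fixed effect"
                )
        for name, vals in self.continuous_covariates:
            if np.asarray(vals).shape[0] != n:
                raise ValueError(f"continuous covariate {name!r} length mismatch")
        if self.ids is None:
            self.ids = [str(i) for i in range(n)]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_tracers(self) -> int:
        return self.values.shape[1]

    def factor(self, name: str) -> Factor:
        for fac in list(self.fixed_factors) + list(self.random_factors):
            if fac.name == name:
                return fac
        raise KeyError(f"no factor named {name!r}")

    def covariate(self, name: str) -> np.ndarray:
        for cov_name, vals in self.continuous_covariates:
            if cov_name == name:
                return np.asarray(vals, dtype=float)
        raise KeyError(f"no continuous covariate named {name!r}")


@dataclass
class SourceData:
    """Per-source tracer information under one of three treatments.

    ``raw`` carries the per-sample matrices (summaries are derived);
    ``summary`` carries mean/SD/sample-size only; ``fixed`` pins the
    means and SDs so the model will not update them.
    """

    treatment: str  # raw | summary | fixed
    source_names: list[str]
    means: np.ndarray  # (K, J)
    sds: np.ndarray  # (K, J)
    sample_sizes: np.ndarray  # (K,)
    tracer_names: list[str]
    raw_samples: list[np.ndarray] | None = None  # per source (n_k, J)
    concentrations: np.ndarray | None = None  # (K, J), strictly positive

    def __post_init__(self) -> None:
        if self.treatment not in ("raw", "summary", "fixed"):
            raise ValueError(f"unknown source treatment {self.treatment!r}")
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.sds = np.atleast_2d(np.asarray(self.sds, dtype=float))
        self.sample_sizes = np.asarray(self.sample_sizes, dtype=int)
        k, j = self.means.shape
        if k < 2:
            raise ValueError("need at least 2 sources")
        if self.sds.shape != (k, j):
            raise ValueError("sds shape does not match means")
        if len(self.source_names) != k or len(self.tracer_names) != j:
            raise ValueError("source/tracer name lengths do not match matrices")
        if self.treatment in ("summary", "fixed") and np.any(self.sds <= 0):
            raise ValueError("source SDs must be strictly positive")
        if self.treatment == "raw":
            if self.raw_samples is None or len(self.raw_samples) != k:
                raise ValueError("raw treatment requires raw_samples per source")
            for name, samp in zip(self.source_names, self.raw_samples):
                samp = np.atleast_2d(np.asarray(samp, dtype=float))
                if samp.shape[0] < 2:
                    raise ValueError(f"source {name!r}: raw treatment needs >=2 samples")
                if samp.shape[1] != j:
                    raise ValueError(f"source {name!r}: sample tracer count mismatch")
        if self.concentrations is not None:
            self.concentrations = np.atleast_2d(np.asarray(self.concentrations, dtype=float))
            if self.concentrations.shape != (k, j):
                raise ValueError("concentrations shape does not match means")
            if np.any(self.concentrations <= 0):
                raise ValueError("concentrations must be strictly positive")
            if np.any(self.concentrations > 1):
                raise ValueError(
                    "concentrations must lie in (0, 1]; divide percentages by 100"
                )

    @property
    def n_sources(self) -> int:
        return self.means.shape[0]

    @property
    def n_tracers(self) -> int:
        return self.means.shape[1]


@dataclass
class DiscriminationData:
    """Per-source, per-tracer discrimination (trophic enrichment) shift and its SD."""

    means: np.ndarray  # (K, J)
    sds: np.ndarray  # (K, J), >= 0

    def __post_init__(self) -> None:
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.sds = np.atleast_2d(np.asarray(self.sds, dtype=float))
        if self.means.shape != self.sds.shape:
            raise ValueError("discrimination means/sds shape mismatch")
        if np.any(self.sds < 0):
            raise ValueError("discrimination SDs must be >= 0")


def zero_discrimination(n_sources: int, n_tracers: int) -> DiscriminationData:
    """All-zero discrimination (non-isotope tracers may need none)."""
    z = np.zeros((n_sources, n_tracers))
    return DiscriminationData(means=z, sds=z.copy())


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _sniff_sep(path: str | Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") > first.count(",") else ","


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path: str | Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _numeric_column(df: pd.DataFrame, col: str, path: str | Path) -> np.ndarray:
    out = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
    bad = np.nonzero(~np.isfinite(out))[0]
    if bad.size:
        raise SchemaError(
            f"{path}: non-numeric or missing value in column {col!r} at row {bad[0]}"
        )
    return out


def _factor_from_series(name: str, series: pd.Series) -> Factor:
    levels: list[str] = []
    codes = np.empty(len(series), dtype=int)
    for i, raw in enumerate(series.astype(str)):
        if raw not in levels:
            levels.append(raw)
        codes[i] = levels.index(raw)
    return Factor(name=name, codes=codes, levels=levels)


def read_mixture_table(
    path: str | Path,
    tracer_columns: Sequence[str],
    factor_columns: Sequence[str] = (),
    continuous_columns: Sequence[str] = (),
    random_flags: Sequence[bool] | None = None,
    id_column: str | None = None,
) -> MixtureData:
    """Read a consumer table into :class:`MixtureData`, preserving row order.

    ``random_flags`` is parallel to ``factor_columns``; a True entry
    declares that factor a random effect.
    """
    df = _read_table(path)
    _require_columns(df, list(tracer_columns) + list(factor_columns) + list(continuous_columns), path)
    values = np.column_stack([_numeric_column(df, c, path) for c in tracer_columns])
    if random_flags is None:
        random_flags = [False] * len(factor_columns)
    if len(random_flags) != len(factor_columns):
        raise ValueError("random_flags must parallel factor_columns")
    fixed, random = [], []
    for col, is_random in zip(factor_columns, random_flags):
        fac = _factor_from_series(col, df[col])
        (random if is_random else fixed).append(fac)
    continuous = [(c, _numeric_column(df, c, path)) for c in continuous_columns]
    ids = df[id_column].astype(str).tolist() if id_column else None
    return MixtureData(
        values=values,
        tracer_names=list(tracer_columns),
        fixed_factors=fixed,
        random_factors=random,
        continuous_covariates=continuous,
        ids=ids,
    )


def read_source_table(
    path: str | Path,
    mode: str,
    tracer_columns: Sequence[str],
    source_column: str = "Source",
) -> SourceData:
    """Read a source table in ``raw`` or ``summary`` mode.

    Summary files carry ``Mean<tracer>``, ``SD<tracer>``, ``n`` and
    optional ``Conc<tracer>`` columns, one row per source.  Raw files
    carry one row per source sample with the tracers as plain columns.
    """
    if mode not in ("raw", "summary"):
        raise ValueError("mode must be 'raw' or 'summary'")
    df = _read_table(path)
    _require_columns(df, [source_column], path)

    if mode == "summary":
        mean_cols = [f"Mean{t}" for t in tracer_columns]
        sd_cols = [f"SD{t}" for t in tracer_columns]
        _require_columns(df, mean_cols + sd_cols + ["n"], path)
        means = np.column_stack([_numeric_column(df, c, path) for c in mean_cols])
        sds = np.column_stack([_numeric_column(df, c, path) for c in sd_cols])
        n = _numeric_column(df, "n", path).astype(int)
        conc = None
        conc_cols = [f"Conc{t}" for t in tracer_columns]
        if all(c in df.columns for c in conc_cols):
            conc = np.column_stack([_numeric_column(df, c, path) for c in conc_cols])
        return SourceData(
            treatment="summary",
            source_names=df[source_column].astype(str).tolist(),
            means=means,
            sds=sds,
            sample_sizes=n,
            tracer_names=list(tracer_columns),
            concentrations=conc,
        )

    _require_columns(df, list(tracer_columns), path)
    fac = _factor_from_series(source_column, df[source_column])
    values = np.column_stack([_numeric_column(df, c, path) for c in tracer_columns])
    raw_samples, means, sds, sizes = [], [], [], []
    conc_cols = [f"Conc{t}" for t in tracer_columns]
    has_conc = all(c in df.columns for c in conc_cols)
    conc_rows = []
    for code, name in enumerate(fac.levels):
        mask = fac.codes == code
        samp = values[mask]
        raw_samples.append(samp)
        means.append(samp.mean(axis=0))
        sds.append(samp.std(axis=0, ddof=1))
        sizes.append(int(mask.sum()))
        if has_conc:
            conc_rows.append(
                np.array([_numeric_column(df, c, path)[mask][0] for c in conc_cols])
            )
    return SourceData(
        treatment="raw",
        source_names=list(fac.levels),
        means=np.array(means),
        sds=np.array(sds),
        sample_sizes=np.array(sizes),
        tracer_names=list(tracer_columns),
        raw_samples=raw_samples,
        concentrations=np.array(conc_rows) if has_conc else None,
    )


def read_discrimination_table(
    path: str | Path | None,
    tracer_columns: Sequence[str],
    source_names: Sequence[str],
    source_column: str = "Source",
) -> DiscriminationData:
    """Read a discrimination table; ``path=None`` yields all zeros.

    Rows are aligned to ``source_names`` by the source column.
    """
    if path is None:
        return zero_discrimination(len(source_names), len(tracer_columns))
    df = _read_table(path)
    mean_cols = [f"Mean{t}" for t in tracer_columns]
    sd_cols = [f"SD{t}" for t in tracer_columns]
    _require_columns(df, [source_column] + mean_cols + sd_cols, path)
    df = df.set_index(df[source_column].astype(str))
    missing = [s for s in source_names if s not in df.index]
    if missing:
        raise SchemaError(f"{path}: no discrimination row for source(s) {missing}")
    rows = df.loc[list(source_names)]
    means = np.column_stack([pd.to_numeric(rows[c]).to_numpy() for c in mean_cols])
    sds = np.column_stack([pd.to_numeric(rows[c]).to_numpy() for c in sd_cols])
    return DiscriminationData(means=means, sds=sds)


def as_fixed_sources(source_data: SourceData) -> SourceData:
    """Copy with treatment=fixed: the model will not update source moments.

    Idempotent; for raw data the sample means/SDs are used.
    """
    if source_data.treatment == "fixed":
        return source_data
    return SourceData(
        treatment="fixed",
        source_names=list(source_data.source_names),
        means=source_data.means.copy(),
        sds=source_data.sds.copy(),
        sample_sizes=source_data.sample_sizes.copy(),
        tracer_names=list(source_data.tracer_names),
        concentrations=None if source_data.concentrations is None else source_data.concentrations.copy(),
    )


# ---------------------------------------------------------------------------
# writing (round-trip support)
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"  # enough digits for bit-identical text round trips


def write_mixture_table(mixture: MixtureData, path: str | Path, sep: str = ",") -> None:
    cols: dict[str, object] = {"ID": mixture.ids}
    for j, name in enumerate(mixture.tracer_names):
        cols[name] = mixture.values[:, j]
    for fac in mixture.fixed_factors + mixture.random_factors:
        cols[fac.name] = [fac.levels[c] for c in fac.codes]
    for name, vals in mixture.continuous_covariates:
        cols[name] = vals
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)


def write_source_table(source: SourceData, path: str | Path, sep: str = ",") -> None:
    """Write the summary dialect for summary/fixed data, raw dialect for raw."""
    if source.treatment == "raw":
        rows = []
        for name, samp in zip(source.source_names, source.raw_samples):
            for row in samp:
                rows.append([name] + list(row))
        df = pd.DataFrame(rows, columns=["Source"] + list(source.tracer_names))
    else:
        cols: dict[str, object] = {"Source": source.source_names}
        for j, t in enumerate(source.tracer_names):
            cols[f"Mean{t}"] = source.means[:, j]
            cols[f"SD{t}"] = source.sds[:, j]
        if source.concentrations is not None:
            for j, t in enumerate(source.tracer_names):
                cols[f"Conc{t}"] = source.concentrations[:, j]
        cols["n"] = source.sample_sizes
        df = pd.DataFrame(cols)
    df.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def cross_factors(a: Factor, b: Factor, name: str | None = None) -> Factor:
    """Cross two factors into their interaction (e.g., ``Size class:Sex``).

    Level order follows first appearance of the combination.
    """
    if a.codes.shape != b.codes.shape:
        raise ValueError("factors must have equal length")
    name = name or f"{a.name}:{b.name}"
    labels = [f"{a.levels[ca]}:{b.levels[cb]}" for ca, cb in zip(a.codes, b.codes)]
    return _factor_from_series(name, pd.Series(labels))


def replace_factors(mixture: MixtureData, fixed: list[Factor] | None = None,
                    random: list[Factor] | None = None) -> MixtureData:
    """Return a copy of ``mixture`` with factors swapped out."""
    return dataclasses.replace(
        mixture,
        fixed_factors=mixture.fixed_factors if fixed is None else fixed,
        random_factors=mixture.random_factors if random is None else random,
    )
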