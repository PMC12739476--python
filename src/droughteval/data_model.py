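"""Domain types and tidy CSV I/O for multi-indicator stress-phenotype tables.

The central container is the :class:`IndicatorTable`: a long-form table of
replicate-level measurements keyed by ``(genotype, stage, replicate,
indicator)``.  Stages are ordered labels bound to day offsets of the stress
time course (e.g. ``control`` = day 0, ``T1`` = day 4, ...).  Aggregating
replicates produces the :class:`SampleMatrix` — one row per genotype x stage
sample, one column per indicator — which is the input to correlation-matrix
PCA in :mod:`droughteval.evaluation`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    CompletenessError,
    IntegrityError,
    SchemaError,
    TableParseError,
)

__all__ = [
    "Direction",
    "Indicator",
    "IndicatorRegistry",
    "default_registry",
    "DEFAULT_STAGES",
    "IndicatorTable",
    "SampleMatrix",
    "read_indicator_table",
    "aggregate_to_samples",
]


class Direction(str, enum.Enum):
    """How an indicator relates to drought resistance.

    ``HIGHER_IS_RESISTANT``: larger values indicate better water status /
    intact structure (declines under drought).  ``HIGHER_IS_STRESSED``:
    larger values indicate stronger stress response (rises under drought).
    """

    HIGHER_IS_RESISTANT = "higher_is_resistant"
    HIGHER_IS_STRESSED = "higher_is_stressed"
    NEUTRAL = "neutral"


@dataclass(frozen=True)
class Indicator:
    code: str
    name: str
    direction: Direction = Direction.NEUTRAL
    units: str = ""


#: The 18 standard leaf-anatomy / stomatal / physiological indicator codes.
_STANDARD_INDICATORS = [
    ("Lth", "Leaf thickness", Direction.HIGHER_IS_RESISTANT, "mm"),
    ("UET", "Upper epidermis thickness", Direction.HIGHER_IS_RESISTANT, "mm"),
    ("LET", "Lower epidermis thickness", Direction.HIGHER_IS_RESISTANT, "mm"),
    ("PT", "Palisade tissue thickness", Direction.HIGHER_IS_RESISTANT, "mm"),
    ("ST", "Spongy tissue thickness", Direction.HIGHER_IS_RESISTANT, "mm"),
    ("SD", "Stomatal density", Direction.HIGHER_IS_RESISTANT, "n/mm^2"),
    ("SA", "Stomatal aperture", Direction.HIGHER_IS_RESISTANT, "um^2"),
    ("SL", "Stomatal length", Direction.HIGHER_IS_RESISTANT, "um"),
    ("SW", "Stomatal width", Direction.HIGHER_IS_RESISTANT, "um"),
    ("SOC", "Stomatal opening count", Direction.HIGHER_IS_RESISTANT, "n/mm^2"),
    ("CRC", "Chlorophyll relative content", Direction.HIGHER_IS_RESISTANT, "SPAD"),
    ("MDA", "Malondialdehyde", Direction.HIGHER_IS_STRESSED, "nmol/g"),
    ("CAT", "Catalase", Direction.HIGHER_IS_STRESSED, "U/g"),
    ("POD", "Peroxidase", Direction.HIGHER_IS_STRESSED, "U/g"),
    ("SOD", "Superoxide dismutase", Direction.HIGHER_IS_STRESSED, "U/g"),
    ("Pro", "Proline", Direction.HIGHER_IS_STRESSED, "ug/g"),
    ("SS", "Soluble sugar", Direction.HIGHER_IS_STRESSED, "mg/g"),
    ("SP", "Soluble protein", Direction.HIGHER_IS_STRESSED, "mg/g"),
]


class IndicatorRegistry:
    """Ordered registry of indicator codes with direction tags and units.

    Column order of every :class:`SampleMatrix` follows registry order, so
    downstream outputs are deterministic.
    """

    def __init__(self, indicators: list[Indicator] | None = None):
        self._by_code: dict[str, Indicator] = {}
        for ind in indicators or []:
            self.register(ind)

    def register(self, indicator: Indicator) -> Indicator:
        if indicator.code in self._by_code:
            raise IntegrityError(f"indicator code already registered: {indicator.code}")
        self._by_code[indicator.code] = indicator
        return indicator

    def register_code(
        self,
        code: str,
        name: str | None = None,
        direction: Direction = Direction.NEUTRAL,
        units: str = "",
    ) -> Indicator:
        return self.register(Indicator(code, name or code, direction, units))

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __getitem__(self, code: str) -> Indicator:
        try:
            return self._by_code[code]
        except KeyError:
            raise IntegrityError(f"unknown indicator code: {code}") from None

    def __iter__(self):
        return iter(self._by_code.values())

    def __len__(self) -> int:
        return len(self._by_code)

    @property
    def codes(self) -> list[str]:
        return list(self._by_code)

    def direction(self, code: str) -> Direction:
        return self[code].direction


def default_registry() -> IndicatorRegistry:
    """Registry of the 18 standard indicators plus room for derived codes."""
    return IndicatorRegistry([Indicator(*row) for row in _STANDARD_INDICATORS])


#: Stage label -> day offset of the default drought time course.
DEFAULT_STAGES: dict[str, int] = {"control": 0, "T1": 4, "T2": 8, "T3": 12, "T4": 16}

_KEY_COLS = ["genotype", "stage", "replicate", "indicator"]
_ALL_COLS = _KEY_COLS + ["value"]


class IndicatorTable:
    """Validated long-form table of replicate-level indicator measurements.

    Parameters
    ----------
    df
        Frame with columns ``genotype, stage, replicate, indicator, value``.
    registry
        Indicator registry; defaults to the 18 standard codes.
    stages
        Mapping of stage label to day offset; defines the strict stage order.
    unknown
        ``"register"`` to add unseen indicator codes with neutral direction,
        ``"error"`` to reject them.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        registry: IndicatorRegistry | None = None,
        stages: dict[str, int] | None = None,
        unknown: str = "register",
    ):
        self.registry = registry if registry is not None else default_registry()
        self.stages = dict(stages) if stages is not None else dict(DEFAULT_STAGES)
        if len(set(self.stages.values())) != len(self.stages):
            raise SchemaError("stage day offsets must be unique (strict total order)")
        missing = [c for c in _ALL_COLS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        df = df.loc[:, _ALL_COLS].copy()
        df["replicate"] = df["replicate"].astype(int)
        df["value"] = df["value"].astype(float)
        self.df = df.reset_index(drop=True)
        self._validate(unknown)

    def _validate(self, unknown: str) -> None:
        df = self.df
        if (df["replicate"] < 1).any():
            raise IntegrityError("replicate indices must be positive integers")
        bad_stage = set(df["stage"]) - set(self.stages)
        if bad_stage:
            raise IntegrityError(f"stages not in the stage order: {sorted(bad_stage)}")
        if not np.isfinite(df["value"].to_numpy()).all():
            rows = df.index[~np.isfinite(df["value"].to_numpy())].tolist()
            raise IntegrityError(f"non-finite values at rows {rows[:5]}")
        dup = df.duplicated(subset=_KEY_COLS)
        if dup.any():
            key = df.loc[dup.idxmax(), _KEY_COLS].tolist()
            raise IntegrityError(f"duplicate (genotype, stage, replicate, indicator) key: {key}")
        for code in pd.unique(df["indicator"]):
            if code not in self.registry:
                if unknown == "register":
                    self.registry.register_code(str(code))
                else:
                    raise IntegrityError(f"unknown indicator code: {code}")

    # -- basic introspection ------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def genotypes(self) -> list[str]:
        return sorted(pd.unique(self.df["genotype"]).tolist())

    @property
    def stage_order(self) -> list[str]:
        present = set(self.df["stage"])
        return [s for s, _ in sorted(self.stages.items(), key=lambda kv: kv[1]) if s in present]

    @property
    def indicator_order(self) -> list[str]:
        present = set(self.df["indicator"])
        return [c for c in self.registry.codes if c in present]

    def day(self, stage: str) -> int:
        return self.stages[stage]

    # -- I/O ----------------------------------------------------------------
    def write_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def read_indicator_table(
    path,
    schema: dict[str, str] | None = None,
    registry: IndicatorRegistry | None = None,
    stages: dict[str, int] | None = None,
    unknown: str = "register",
) -> IndicatorTable:
    """Read a long-form indicator CSV into a validated :class:`IndicatorTable`.

    ``schema`` maps the canonical column names (``genotype``, ``stage``,
    ``replicate``, ``indicator``, ``value``) to the file's column names.
    """
    schema = schema or {}
    raw = pd.read_csv(path, dtype=str)
    colmap = {schema.get(c, c): c for c in _ALL_COLS}
    missing = [src for src in colmap if src not in raw.columns]
    if missing:
        raise SchemaError(f"columns not found in {path}: {missing}")
    df = raw.rename(columns=colmap).loc[:, _ALL_COLS]
    for col, caster in (("replicate", int), ("value", float)):
        parsed = []
        for i, raw_val in enumerate(df[col]):
            try:
                parsed.append(caster(raw_val))
            except (TypeError, ValueError):
                # +2: header line plus 1-based numbering
                raise TableParseError(
                    f"could not parse {col} value {raw_val!r}", row=i + 2
                ) from None
        df[col] = parsed
    return IndicatorTable(df, registry=registry, stages=stages, unknown=unknown)


class SampleMatrix:
    """Stage-mean matrix: rows = (genotype, stage) samples, cols = indicators."""

    def __init__(self, df: pd.DataFrame, registry: IndicatorRegistry | None = None):
        if df.isna().any().any():
            raise IntegrityError("sample matrix contains missing cells")
        if not np.isfinite(df.to_numpy(dtype=float)).all():
            raise IntegrityError("sample matrix contains non-finite values")
        if df.shape[1] < 2:
            raise IntegrityError("need at least 2 indicators")
        self.df = df.astype(float)
        self.registry = registry

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    @property
    def row_labels(self) -> list[tuple[str, str]]:
        return list(self.df.index)

    @property
    def indicators(self) -> list[str]:
        return list(self.df.columns)

    @property
    def n_samples(self) -> int:
        return self.df.shape[0]

    def genotype_of_rows(self) -> list[str]:
        return [g for g, _ in self.row_labels]

    def write_csv(self, path) -> None:
        out = self.df.copy()
        out.index = pd.MultiIndex.from_tuples(self.row_labels, names=["genotype", "stage"])
        out.to_csv(path)


def aggregate_to_samples(
    table: IndicatorTable,
    statistic: str = "mean",
    indicators: list[str] | None = None,
) -> SampleMatrix:
    """Collapse replicates to genotype x stage means.

    Row order is genotype-major with stages ascending by day offset; column
    order follows the registry.  Raises :class:`CompletenessError` if any
    (genotype, stage, indicator) cell has no replicate.
    """
    if statistic != "mean":
        raise ValueError(f"unsupported aggregation statistic: {statistic}")
    cols = indicators if indicators is not None else table.indicator_order
    genotypes = table.genotypes
    stage_order = table.stage_order
    grouped = table.df.groupby(["genotype", "stage", "indicator"])["value"].mean()
    rows, missing = [], []
    index = []
    for g in genotypes:
        for s in stage_order:
            row = []
            for c in cols:
                try:
                    row.append(grouped.loc[(g, s, c)])
                except KeyError:
                    missing.append((g, s, c))
            rows.append(row)
            index.append((g, s))
    if missing:
        raise CompletenessError(missing)
    df = pd.DataFrame(rows, index=pd.Index(index), columns=cols, dtype=float)
    return SampleMatrix(df, registry=table.registry)
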