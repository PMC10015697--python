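"""Typed readers/writers for women-level outcome tables, zone adjacency, and point samples.

The package's central container is :class:`Dataset`: a validated rectangular
table of women-level records carrying two binary outcomes — attendance of the
recommended four or more antenatal-care visits (``anc``) and delivery at a
health facility rather than at home (``dc``) — together with an administrative
zone identifier, a survey-year label, an optional positive sampling weight,
and any number of declared categorical covariates.

Spatial structure is carried by :class:`SpatialWeights`, a symmetric binary
zone-adjacency relation with a zero diagonal, read from a plain two-column
edge list so that no GIS geometry is ever required.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("anc", "dc", "zone", "year")


class SchemaError(ValueError):
    """A required column or declared covariate is missing or malformed."""


class ValidationError(ValueError):
    """A cell value violates the dataset's declared schema or an invariant."""


@dataclass(frozen=True)
class WomanRecord:
    """One woman's record: outcome pair, covariates, zone, survey year, weight."""

    anc: int
    dc: int
    zone: str
    year: str
    weight: float = 1.0
    covariates: Mapping[str, str] = field(default_factory=dict)


@dataclass
class Dataset:
    """Validated women-level table with a categorical covariate schema.

    Parameters
    ----------
    df:
        Table with columns ``anc``, ``dc``, ``zone``, ``year``, ``weight``
        plus one column per declared covariate.
    schema:
        Mapping covariate name -> ordered category labels. The first label of
        each covariate is its reference level in any downstream regression.
    drop_report:
        Counts of rows discarded during reading (missing outcome/zone,
        undeclared-missing covariates). Empty for programmatically built data.
    """

    df: pd.DataFrame
    schema: dict[str, list[str]] = field(default_factory=dict)
    drop_report: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.df
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"dataset is missing required column {col!r}")
        if "weight" not in df.columns:
            df = df.copy()
            df["weight"] = 1.0
        df = df.copy()
        for out in ("anc", "dc"):
            vals = pd.to_numeric(df[out], errors="coerce")
            bad = ~vals.isin([0, 1])
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValidationError(
                    f"column {out!r} must be 0/1; offending value "
                    f"{df[out].iloc[row]!r} at row {row}"
                )
            df[out] = vals.astype(np.int8)
        df["zone"] = df["zone"].astype(str)
        df["year"] = df["year"].astype(str)
        w = pd.to_numeric(df["weight"], errors="coerce")
        if not np.all(np.isfinite(w)) or (w <= 0).any():
            raise ValidationError("weights must be finite and > 0")
        df["weight"] = w.astype(float)
        for cov, labels in self.schema.items():
            if cov not in df.columns:
                raise SchemaError(f"declared covariate {cov!r} absent from data")
            col = df[cov].astype(str)
            unknown = ~col.isin(labels)
            if unknown.any():
                row = int(np.flatnonzero(unknown.to_numpy())[0])
                raise ValidationError(
                    f"value {col.iloc[row]!r} at row {row} is not among the "
                    f"declared labels of covariate {cov!r}: {labels}"
                )
            df[cov] = pd.Categorical(col, categories=labels, ordered=True)
        self.df = df.reset_index(drop=True)

    # -- views ------------------------------------------------------------
    @property
    def zones(self) -> list[str]:
        return sorted(self.df["zone"].unique())

    @property
    def years(self) -> list[str]:
        return sorted(self.df["year"].unique())

    @property
    def n(self) -> int:
        return len(self.df)

    def records(self) -> Iterator[WomanRecord]:
        covs = list(self.schema)
        for row in self.df.itertuples(index=False):
            d = row._asdict()
            yield WomanRecord(
                anc=int(d["anc"]),
                dc=int(d["dc"]),
                zone=d["zone"],
                year=d["year"],
                weight=float(d["weight"]),
                covariates={c: str(d[c]) for c in covs},
            )

    def filter_year(self, year: str) -> "Dataset":
        sub = self.df[self.df["year"] == str(year)]
        if sub.empty:
            raise ValidationError(f"no records for survey year {year!r}")
        return Dataset(sub.reset_index(drop=True), schema=dict(self.schema))


class SpatialWeights:
    """Symmetric binary zone adjacency with zero diagonal.

    Stored as a neighbor map; :meth:`to_dense` materializes the 0/1 matrix in
    ``zone_order``.
    """

    def __init__(self, zone_order: Sequence[str], neighbors: Mapping[str, Iterable[str]]):
        self.zone_order: list[str] = [str(z) for z in zone_order]
        index = set(self.zone_order)
        if len(index) != len(self.zone_order):
            raise ValidationError("duplicate zone ids in zone_order")
        nb: dict[str, frozenset[str]] = {z: frozenset() for z in self.zone_order}
        for z, ns in neighbors.items():
            z = str(z)
            if z not in index:
                raise ValidationError(f"neighbor map names unknown zone {z!r}")
            ns = frozenset(str(m) for m in ns)
            if z in ns:
                raise ValidationError(f"zone {z!r} listed as its own neighbor (diagonal must be zero)")
            missing = ns - index
            if missing:
                raise ValidationError(f"neighbors of {z!r} include unknown zones {sorted(missing)}")
            nb[z] = ns
        # enforce symmetry
        for z, ns in nb.items():
            for m in ns:
                if z not in nb[m]:
                    raise ValidationError(f"asymmetric adjacency: {z!r}->{m!r} but not the reverse")
        self.neighbors: dict[str, frozenset[str]] = nb

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]], zone_order: Sequence[str] | None = None) -> "SpatialWeights":
        """Build from an undirected edge list; symmetric closure and dedup applied."""
        pairs = [(str(a), str(b)) for a, b in edges]
        for a, b in pairs:
            if a == b:
                raise ValidationError(f"self-loop edge ({a!r},{a!r}): diagonal must be zero")
        if zone_order is None:
            zone_order = sorted({z for e in pairs for z in e})
        else:
            known = set(map(str, zone_order))
            for a, b in pairs:
                if a not in known or b not in known:
                    raise ValidationError(f"edge ({a!r},{b!r}) names a zone absent from the registry")
        nb: dict[str, set[str]] = {str(z): set() for z in zone_order}
        for a, b in pairs:
            nb[a].add(b)
            nb[b].add(a)
        return cls(zone_order, nb)

    def to_dense(self) -> np.ndarray:
        idx = {z: i for i, z in enumerate(self.zone_order)}
        n = len(self.zone_order)
        w = np.zeros((n, n))
        for z, ns in self.neighbors.items():
            for m in ns:
                w[idx[z], idx[m]] = 1.0
        return w

    def degree(self, zone: str) -> int:
        return len(self.neighbors[str(zone)])

    @property
    def n_zones(self) -> int:
        return len(self.zone_order)

    def edges(self) -> list[tuple[str, str]]:
        out = []
        for z in self.zone_order:
            for m in sorted(self.neighbors[z]):
                if z < m:
                    out.append((z, m))
        return out

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, SpatialWeights)
            and self.zone_order == other.zone_order
            and self.neighbors == other.neighbors
        )


@dataclass(frozen=True)
class PointSample:
    """A planar sample: projected coordinates and the value observed there."""

    x: float
    y: float
    value: float


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_dataset(path, schema: Mapping[str, Sequence[str]] | None = None) -> Dataset:
    """Read a women-level CSV into a validated :class:`Dataset`.

    Rows with missing outcome or zone are dropped and counted in the returned
    dataset's ``drop_report``. Covariate values outside the declared labels
    raise :class:`ValidationError` unless the schema declares an explicit
    ``"missing"`` level, in which case blanks map to it; undeclared blanks drop
    the row with a count.
    """
    schema = {k: list(v) for k, v in (schema or {}).items()}
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"input file lacks required column {col!r}")
    report: dict[str, int] = {}
    bad = df["anc"].isna() | df["dc"].isna() | df["zone"].isna()
    if bad.any():
        report["missing_outcome_or_zone"] = int(bad.sum())
        df = df[~bad]
    for cov, labels in schema.items():
        if cov not in df.columns:
            raise SchemaError(f"declared covariate {cov!r} absent from file")
        blank = df[cov].isna()
        if blank.any():
            if "missing" in labels:
                df = df.copy()
                df.loc[blank, cov] = "missing"
            else:
                report[f"missing_{cov}"] = int(blank.sum())
                df = df[~blank]
    if report:
        logger.warning("read_dataset dropped rows: %s", report)
    if "weight" in df.columns:
        df = df.copy()
        df["weight"] = pd.to_numeric(df["weight"], errors="raise")
    return Dataset(df.reset_index(drop=True), schema=schema, drop_report=report)


def write_dataset(dataset: Dataset, path) -> None:
    cols = list(REQUIRED_COLUMNS) + ["weight"] + list(dataset.schema)
    out = dataset.df[cols].copy()
    out.to_csv(path, index=False)


def read_adjacency(path, zone_order: Sequence[str] | None = None) -> SpatialWeights:
    """Read a two-column zone edge list; symmetric closure and dedup applied."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise SchemaError("adjacency file must have two zone columns (zone_i,zone_j)")
    edges = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
    return SpatialWeights.from_edges(edges, zone_order=zone_order)


def write_adjacency(weights: SpatialWeights, path) -> None:
    pd.DataFrame(weights.edges(), columns=["zone_i", "zone_j"]).to_csv(path, index=False)


def read_points(path) -> list[PointSample]:
    """Read x,y,value samples; exact-duplicate coordinates are averaged with a warning."""
    df = pd.read_csv(path)
    if df.empty:
        return []
    for col in ("x", "y", "value"):
        if col not in df.columns:
            raise SchemaError(f"points file lacks required column {col!r}")
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any() or vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise ValidationError(f"non-numeric or missing {col!r} at row {row}")
        df[col] = vals.astype(float)
    if not np.all(np.isfinite(df[["x", "y", "value"]].to_numpy())):
        raise ValidationError("point coordinates and values must be finite")
    grouped = df.groupby(["x", "y"], as_index=False, sort=False)["value"].mean()
    if len(grouped) < len(df):
        warnings.warn(
            f"{len(df) - len(grouped)} duplicate coordinate row(s) averaged", stacklevel=2
        )
    return [PointSample(r.x, r.y, r.value) for r in grouped.itertuples(index=False)]


def write_points(points: Sequence[PointSample], path) -> None:
    pd.DataFrame([(p.x, p.y, p.value) for p in points], columns=["x", "y", "value"]).to_csv(
        path, index=False
    )
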