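"""Weighted contingency-table machinery for the paired ANC/DC outcomes.

Joint 2x2 tables, cell and marginal probabilities, the dependency odds ratio
psi = (n11*n00)/(n10*n01), Pearson chi-square association tests, and
covariate-by-outcome-combination frequency tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import Dataset, ValidationError


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Weighted counts of the four (outcome1, outcome2) combinations.

    Cell (g,h) counts women with outcome1 = g, outcome2 = h; n11 is the
    both-services cell, n00 the neither-service cell.
    """

    n11: float
    n10: float
    n01: float
    n00: float

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValidationError("contingency cells must be nonnegative")

    @property
    def n(self) -> float:
        return self.n11 + self.n10 + self.n01 + self.n00

    def as_array(self) -> np.ndarray:
        return np.array([[self.n11, self.n10], [self.n01, self.n00]], dtype=float)


@dataclass(frozen=True)
class JointSummary:
    """Cell probabilities, marginals, dependency OR and chi-square test of a 2x2 table."""

    p11: float
    p10: float
    p01: float
    p00: float
    p1_marg: float  # P(outcome1 = 1), row marginal
    p2_marg: float  # P(outcome2 = 1), column marginal
    odds_ratio: float
    chi_square: float
    p_value: float

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


def build_2x2(
    data: Dataset, year: str | None = None, use_weights: bool = True
) -> ContingencyTable2x2:
    """Tabulate (weighted) counts of the four outcome combinations, optionally per survey year."""
    df = data.df
    if year is not None:
        df = df[df["year"] == str(year)]
        if df.empty:
            raise ValidationError(f"no records for survey year {year!r}")
    w = df["weight"].to_numpy() if use_weights else np.ones(len(df))
    a = df["anc"].to_numpy()
    d = df["dc"].to_numpy()
    return ContingencyTable2x2(
        n11=float(w[(a == 1) & (d == 1)].sum()),
        n10=float(w[(a == 1) & (d == 0)].sum()),
        n01=float(w[(a == 0) & (d == 1)].sum()),
        n00=float(w[(a == 0) & (d == 0)].sum()),
    )


def odds_ratio_2x2(table: ContingencyTable2x2, continuity: bool = False) -> float:
    """Cross-product (dependency) odds ratio n11*n00 / (n10*n01).

    A zero off-diagonal cell yields +inf with a warning unless ``continuity``
    requests the Haldane-Anscombe +0.5 correction to every cell.
    """
    n11, n10, n01, n00 = table.n11, table.n10, table.n01, table.n00
    if continuity:
        n11, n10, n01, n00 = n11 + 0.5, n10 + 0.5, n01 + 0.5, n00 + 0.5
    if n10 * n01 == 0:
        warnings.warn("zero off-diagonal cell: odds ratio is infinite", stacklevel=2)
        return float("inf")
    return (n11 * n00) / (n10 * n01)


def chi_square_test(counts) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c table of (weighted) counts.

    Returns (statistic, degrees of freedom, upper-tail p-value). A zero row or
    column sum leaves the test undefined and raises.
    """
    obs = np.asarray(counts, dtype=float)
    if obs.ndim != 2:
        raise ValidationError("chi_square_test expects a 2-D table")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValidationError("zero row/column sum: chi-square test undefined")
    stat, p, dof, _ = stats.chi2_contingency(obs, correction=False)
    return float(stat), int(dof), float(p)


def joint_marginal_summary(table: ContingencyTable2x2) -> JointSummary:
    """Cell probabilities, marginal utilization, OR and chi-square of a 2x2 table."""
    n = table.n
    if n <= 0:
        raise ValidationError("empty table: probabilities undefined")
    stat, _, p = chi_square_test(table.as_array())
    return JointSummary(
        p11=table.n11 / n,
        p10=table.n10 / n,
        p01=table.n01 / n,
        p00=table.n00 / n,
        p1_marg=(table.n11 + table.n10) / n,
        p2_marg=(table.n11 + table.n01) / n,
        odds_ratio=odds_ratio_2x2(table),
        chi_square=stat,
        p_value=p,
    )


COMBO_LABELS = ["anc1_dc1", "anc1_dc0", "anc0_dc1", "anc0_dc0"]


def combo_distribution(
    data: Dataset,
    covariate: str,
    year: str | None = None,
    use_weights: bool = True,
    percentages: bool = False,
) -> pd.DataFrame:
    """Counts of the four (ANC, DC) combinations per level of one covariate.

    Rows are covariate levels, columns the four combinations. With
    ``percentages`` the counts are replaced by within-column percentages
    (each combination column sums to 100).
    """
    if covariate not in data.schema:
        raise ValidationError(f"covariate {covariate!r} not declared in the schema")
    df = data.df
    if year is not None:
        df = df[df["year"] == str(year)]
        if df.empty:
            raise ValidationError(f"no records for survey year {year!r}")
    w = df["weight"] if use_weights else pd.Series(1.0, index=df.index)
    combo = df["anc"].astype(int) * 2 + df["dc"].astype(int)
    names = {3: "anc1_dc1", 2: "anc1_dc0", 1: "anc0_dc1", 0: "anc0_dc0"}
    out = pd.DataFrame(
        0.0, index=pd.Index(data.schema[covariate], name=covariate), columns=COMBO_LABELS
    )
    grouped = w.groupby([df[covariate].astype(str), combo.map(names)]).sum()
    for (level, cname), val in grouped.items():
        out.loc[level, cname] = val
    if percentages:
        tot = out.sum(axis=0)
        tot = tot.replace(0, np.nan)
        out = 100.0 * out / tot
    return out
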