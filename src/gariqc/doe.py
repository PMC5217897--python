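"""Two-way balanced 2x2 factorial decomposition and ANOVA.

Used for the grain-size x moisture -> acidity correlation study: each
response y_ijk (i, j = factor levels, k = replicate) is decomposed into

    y_ijk = grand mean + a_i + b_j + (ab)_ij + e_ijk

by cell/marginal means, with the usual zero-sum constraints.  The ANOVA
table partitions the total sum of squares into the two main effects,
the interaction and the replication error, and tests each against the
error mean square with an F statistic.

Only balanced 2x2 designs are supported; the module is agnostic to what
the response is (here: moisture-corrected acidity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UnbalancedDesignError

_RECON_TOL = 1e-9


@dataclass(frozen=True)
class FactorialDataset:
    """Responses of a balanced 2x2 design with r >= 2 replicates.

    ``responses`` has shape (2, 2, r), indexed [a_level, b_level,
    replicate].  ``response_scale`` is a display multiplier only (the
    acidity study plots responses x 100); all statistics are computed
    on the raw scale.
    """

    responses: np.ndarray
    factor_a_name: str = "A"
    factor_a_levels: tuple[str, str] = ("level 1", "level 2")
    factor_b_name: str = "B"
    factor_b_levels: tuple[str, str] = ("level 1", "level 2")
    response_scale: float = 1.0

    def __post_init__(self) -> None:
        resp = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "responses", resp)
        if resp.ndim != 3 or resp.shape[:2] != (2, 2):
            raise UnbalancedDesignError(
                f"expected a (2, 2, r) response array, got {resp.shape}"
            )
        if resp.shape[2] < 2:
            raise UnbalancedDesignError("need r >= 2 replicates per cell")
        if len(self.factor_a_levels) != 2 or len(self.factor_b_levels) != 2:
            raise UnbalancedDesignError("exactly 2 levels per factor")

    @property
    def n_replicates(self) -> int:
        return self.responses.shape[2]

    @classmethod
    def from_long(cls, df: pd.DataFrame, **kwargs) -> "FactorialDataset":
        """Build from long-format columns
        (factor_a_level, factor_b_level, replicate, response)."""
        a_levels = tuple(pd.unique(df["factor_a_level"]))
        b_levels = tuple(pd.unique(df["factor_b_level"]))
        if len(a_levels) != 2 or len(b_levels) != 2:
            raise UnbalancedDesignError("exactly 2 levels per factor required")
        counts = df.groupby(["factor_a_level", "factor_b_level"]).size()
        if counts.nunique() != 1 or len(counts) != 4:
            raise UnbalancedDesignError("unequal replication across cells")
        r = int(counts.iloc[0])
        resp = np.empty((2, 2, r))
        for i, a in enumerate(a_levels):
            for j, b in enumerate(b_levels):
                cell = df[(df["factor_a_level"] == a)
                          & (df["factor_b_level"] == b)]
                resp[i, j] = cell.sort_values("replicate")["response"].values
        return cls(responses=resp,
                   factor_a_levels=(str(a_levels[0]), str(a_levels[1])),
                   factor_b_levels=(str(b_levels[0]), str(b_levels[1])),
                   **kwargs)


@dataclass(frozen=True)
class Decomposition:
    """Additive decomposition of a 2x2xr response array."""

    grand_mean: float
    effect_a: np.ndarray      # (2,)
    effect_b: np.ndarray      # (2,)
    interaction_ab: np.ndarray  # (2, 2)
    residuals: np.ndarray     # (2, 2, r)

    def reconstruct(self) -> np.ndarray:
        """Rebuild the observations from the decomposition terms."""
        return (self.grand_mean
                + self.effect_a[:, None, None]
                + self.effect_b[None, :, None]
                + self.interaction_ab[:, :, None]
                + self.residuals)


@dataclass(frozen=True)
class GroupedMeans:
    """Cell, marginal and grand means for the interaction graph."""

    cell_means: np.ndarray    # (2, 2)
    marginal_a: np.ndarray    # (2,)
    marginal_b: np.ndarray    # (2,)
    grand_mean: float


def decompose(data: FactorialDataset) -> Decomposition:
    """Least-squares decomposition by cell and marginal means.

    Zero-sum constraints hold by construction and the terms reconstruct
    every observation exactly.
    """
    y = data.responses
    cell = y.mean(axis=2)
    grand = float(y.mean())
    a = cell.mean(axis=1) - grand
    b = cell.mean(axis=0) - grand
    ab = cell - grand - a[:, None] - b[None, :]
    resid = y - cell[:, :, None]
    return Decomposition(grand_mean=grand, effect_a=a, effect_b=b,
                         interaction_ab=ab, residuals=resid)


def grouped_means(data: FactorialDataset) -> GroupedMeans:
    """Cell and marginal means, consistent with :func:`decompose`."""
    cell = data.responses.mean(axis=2)
    return GroupedMeans(
        cell_means=cell,
        marginal_a=cell.mean(axis=1),
        marginal_b=cell.mean(axis=0),
        grand_mean=float(data.responses.mean()),
    )


def anova(dec: Decomposition) -> pd.DataFrame:
    """ANOVA table for a balanced 2x2 design with replication.

    Rows: the two main effects, the interaction and the error; columns:
    sum of squares, degrees of freedom, mean square, F, p and the
    complementary significance probability in percent (100 x (1 - p)).
    A zero error mean square (constant replicates) yields infinite F
    and p = 0 for sources with positive SS, and F = NaN otherwise.
    """
    r = dec.residuals.shape[2]
    ss_a = 2 * r * float(np.sum(dec.effect_a ** 2))
    ss_b = 2 * r * float(np.sum(dec.effect_b ** 2))
    ss_ab = r * float(np.sum(dec.interaction_ab ** 2))
    ss_e = float(np.sum(dec.residuals ** 2))
    df_a = df_b = df_ab = 1
    df_e = 4 * (r - 1)
    ms = np.array([ss_a / df_a, ss_b / df_b, ss_ab / df_ab, ss_e / df_e])
    if ms[3] > 0:
        f_stats = ms[:3] / ms[3]
        p = stats.f.sf(f_stats, 1, df_e)
    else:
        f_stats = np.array([math.inf if s > 0 else math.nan
                            for s in (ss_a, ss_b, ss_ab)])
        p = np.array([0.0 if s > 0 else math.nan
                      for s in (ss_a, ss_b, ss_ab)])
    table = pd.DataFrame({
        "source": ["A", "B", "AxB", "error"],
        "sum_sq": [ss_a, ss_b, ss_ab, ss_e],
        "df": [df_a, df_b, df_ab, df_e],
        "mean_sq": list(ms),
        "F": [*f_stats, math.nan],
        "p_value": [*p, math.nan],
    })
    table["probability_percent"] = 100.0 * (1.0 - table["p_value"])
    return table
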