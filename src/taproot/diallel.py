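"""Griffing Method IV, Model I analysis of a half-diallel.

A half-diallel crosses p parents in all p(p−1)/2 unordered pairs, with no
selfs and no reciprocals; Method IV, Model I fits fixed general (GCA) and
specific (SCA) combining-ability effects to the F1 cross means:

    y_ijk = μ + g_i + g_j + s_ij + ε_ijk,   Σ g_i = 0,  Σ_j s_ij = 0.

Roots are first aggregated to plot means so the replicate count r is the
number of field plots per cross. Mean squares are reported on the
entry-mean (cross-mean) basis, matching the expected-mean-square
equations used to extract variance components:

    EMS_GCA = Vε + V_SCA + (p−2)·V_GCA
    EMS_SCA = Vε + V_SCA

with Vε the error variance on the entry-mean basis. Additive and
dominance variances follow from the parental inbreeding coefficient F:
V_A = 4/(1+F)·V_GCA and V_D = 4/(1+F)²·V_SCA; total genetic variance is
V_G = V_A + V_D. Broad- and narrow-sense heritabilities divide V_G and
V_A by V_G + Vε/r, and Baker's ratio 2·MS_GCA/(2·MS_GCA + MS_SCA)
summarises the share of combining-ability variation that is additive.

Negative variance-component estimates are reported as-is with a warning
flag, never truncated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SingularDesignError, UnbalancedDesignError

__all__ = [
    "DiallelTable",
    "DiallelConfig",
    "DiallelResult",
    "fit_griffing",
    "variance_components",
    "genetic_components",
    "heritabilities",
    "bakers_ratio",
    "analyze",
    "read_diallel_csv",
]

REQUIRED_COLUMNS = ("parent_i", "parent_j", "rep", "root_id", "value")


@dataclass
class DiallelTable:
    """Validated half-diallel records: one row per root, crosses i < j only."""

    df: pd.DataFrame
    parents: list = field(default_factory=list)

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"table missing columns {missing}")
        if (self.df["parent_i"] == self.df["parent_j"]).any():
            raise ValueError("self crosses (i == j) are not allowed in Method IV")
        bad = self.df["parent_i"] >= self.df["parent_j"]
        if bad.any():
            raise ValueError(
                "crosses must be stored with parent_i < parent_j (no reciprocals)"
            )
        if not self.parents:
            self.parents = sorted(
                set(self.df["parent_i"]).union(set(self.df["parent_j"]))
            )


@dataclass(frozen=True)
class DiallelConfig:
    """p parents, r replicate plots per cross, parental inbreeding F."""

    p: int
    r: int
    F: float = 1.0

    def __post_init__(self):
        if self.p < 4:
            raise SingularDesignError(
                f"Method IV needs at least 4 parents, got p={self.p}"
            )
        if self.r < 2:
            raise ValueError("need at least 2 replicates")
        if not 0.0 <= self.F <= 1.0:
            raise ValueError("F must lie in [0, 1]")

    @property
    def df_gca(self) -> int:
        return self.p - 1

    @property
    def df_sca(self) -> int:
        return self.p * (self.p - 3) // 2

    @property
    def df_error(self) -> int:
        return (self.r - 1) * self.p * (self.p - 1) // 2


@dataclass
class DiallelResult:
    """Combining-ability ANOVA and variance-component chain for one trait.

    ``ms_gca``/``ms_sca`` and ``v_eps`` are on the entry-mean basis (the
    scale on which the EMS equations are written); ``v_eps_root`` is the
    raw per-root residual variance, reported separately. Heritabilities
    are raw values; ``report()`` clamps them to [0, 1].
    """

    trait: str
    config: DiallelConfig
    ms_gca: float
    ms_sca: float
    v_eps: float
    v_eps_root: float
    v_gca: float
    v_sca: float
    v_a: float
    v_d: float
    v_g: float
    H2: float
    h2: float
    bakers_ratio: float
    gca_effects: pd.Series
    sca_effects: pd.DataFrame
    flags: list = field(default_factory=list)

    @property
    def df_gca(self) -> int:
        return self.config.df_gca

    @property
    def df_sca(self) -> int:
        return self.config.df_sca

    def report(self) -> dict:
        clamp = lambda v: float(np.clip(v, 0.0, 1.0))
        return {
            "trait": self.trait,
            "MS_GCA": self.ms_gca,
            "V_A": self.v_a,
            "MS_SCA": self.ms_sca,
            "V_D": self.v_d,
            "V_eps": self.v_eps,
            "H2": clamp(self.H2),
            "h2": clamp(self.h2),
            "BR": self.bakers_ratio,
            "df_GCA": self.df_gca,
            "df_SCA": self.df_sca,
            "flags": ";".join(self.flags),
        }


def _check_balance(plot_means: pd.DataFrame, config: DiallelConfig, parents) -> None:
    expected = {
        (i, j, rep)
        for a, i in enumerate(parents)
        for j in parents[a + 1 :]
        for rep in sorted(plot_means["rep"].unique())
    }
    have = set(map(tuple, plot_means[["parent_i", "parent_j", "rep"]].to_numpy()))
    missing = sorted(expected - have)
    if missing:
        raise UnbalancedDesignError(
            f"missing {len(missing)} cross/replicate cells, e.g. {missing[:5]}",
            missing=missing,
        )
    n_reps = plot_means["rep"].nunique()
    if n_reps != config.r:
        raise UnbalancedDesignError(
            f"table has {n_reps} replicates but config.r={config.r}"
        )
    if len(parents) != config.p:
        raise UnbalancedDesignError(
            f"table has {len(parents)} parents but config.p={config.p}"
        )


def fit_griffing(table: DiallelTable, config: DiallelConfig, trait: str = "value"):
    """Combining-ability ANOVA of a balanced half-diallel.

    Roots are aggregated to plot means, then cross means over replicates.
    GCA effects are the least-squares solution under Σg = 0 (closed form
    for the balanced design); SCA effects are the cross-mean residuals.
    Sums of squares use df p−1 (GCA) and p(p−3)/2 (SCA); mean squares are
    on the entry-mean basis. Returns
    (ms_gca, ms_sca, v_eps, v_eps_root, gca_effects, sca_effects).
    """
    df = table.df
    parents = table.parents
    p, r = config.p, config.r

    plot_means = (
        df.groupby(["parent_i", "parent_j", "rep"], sort=True)[trait]
        .mean()
        .reset_index()
    )
    _check_balance(plot_means, config, parents)
    cross_means = (
        plot_means.groupby(["parent_i", "parent_j"], sort=True)[trait].mean()
    )

    mu = float(cross_means.mean())
    totals = pd.Series(0.0, index=parents)
    for (i, j), y in cross_means.items():
        totals[i] += y
        totals[j] += y
    grand = float(cross_means.sum())
    gca = (p * totals - 2.0 * grand) / (p * (p - 2.0))

    sca = pd.DataFrame(np.nan, index=parents, columns=parents)
    ss_sca = 0.0
    for (i, j), y in cross_means.items():
        s_ij = y - mu - gca[i] - gca[j]
        sca.loc[i, j] = s_ij
        sca.loc[j, i] = s_ij
        ss_sca += s_ij**2
    ss_gca = (p - 2.0) * float((gca**2).sum())

    ms_gca = ss_gca / config.df_gca
    ms_sca = ss_sca / config.df_sca

    # plot-mean error MS, then the entry-mean basis error variance
    merged = plot_means.merge(
        cross_means.rename("cross_mean"), on=["parent_i", "parent_j"]
    )
    ss_err = float(((merged[trait] - merged["cross_mean"]) ** 2).sum())
    ms_err_plot = ss_err / config.df_error
    v_eps = ms_err_plot / r

    # raw per-root residual variance (within plots)
    resid = df[trait] - df.groupby(["parent_i", "parent_j", "rep"])[trait].transform(
        "mean"
    )
    counts = df.groupby(["parent_i", "parent_j", "rep"])[trait].transform("count")
    dof = float((df.groupby(["parent_i", "parent_j", "rep"])[trait].count() - 1).sum())
    v_eps_root = float((resid**2).sum() / dof) if dof > 0 else float("nan")
    del counts

    return ms_gca, ms_sca, v_eps, v_eps_root, gca, sca


def variance_components(ms_gca: float, ms_sca: float, v_eps: float, config: DiallelConfig):
    """GCA/SCA variance components from the expected mean squares:
    V_GCA = (MS_GCA − MS_SCA)/(p−2), V_SCA = MS_SCA − Vε. Negative
    estimates are returned as-is."""
    v_gca = (ms_gca - ms_sca) / (config.p - 2.0)
    v_sca = ms_sca - v_eps
    return v_gca, v_sca


def genetic_components(v_gca: float, v_sca: float, F: float = 1.0):
    """Additive and dominance variances from the combining-ability
    components: V_A = 4/(1+F)·V_GCA, V_D = 4/(1+F)²·V_SCA."""
    if not 0.0 <= F <= 1.0:
        raise ValueError("F must lie in [0, 1]")
    v_a = 4.0 / (1.0 + F) * v_gca
    v_d = 4.0 / (1.0 + F) ** 2 * v_sca
    return v_a, v_d


def heritabilities(v_a: float, v_d: float, v_eps: float, r: int):
    """Broad- and narrow-sense heritability with V_G = V_A + V_D:
    H² = V_G/(V_G + Vε/r), h² = V_A/(V_G + Vε/r). Raw (unclamped) values."""
    v_g = v_a + v_d
    denom = v_g + v_eps / r
    if denom == 0:
        raise ZeroDivisionError("zero phenotypic variance")
    return v_g / denom, v_a / denom


def bakers_ratio(ms_gca: float, ms_sca: float) -> float:
    """2·MS_GCA / (2·MS_GCA + MS_SCA): 1 when all combining-ability
    variation is additive (GCA), 0 when all of it is SCA."""
    if ms_gca < 0 or ms_sca < 0:
        raise ValueError("mean squares must be non-negative")
    if ms_gca == 0 and ms_sca == 0:
        raise ZeroDivisionError("both mean squares are zero")
    return 2.0 * ms_gca / (2.0 * ms_gca + ms_sca)


def analyze(table: DiallelTable, config: DiallelConfig, trait: str = "value") -> DiallelResult:
    """Full chain: ANOVA → variance components → V_A/V_D → H², h², BR."""
    ms_gca, ms_sca, v_eps, v_eps_root, gca, sca = fit_griffing(table, config, trait)
    flags = []
    if ms_gca < 1e-12 and ms_sca < 1e-12:
        flags.append("degenerate: all mean squares zero")
        v_gca = v_sca = v_a = v_d = v_g = 0.0
        h2_broad = h2_narrow = float("nan")
        br = float("nan")
    else:
        v_gca, v_sca = variance_components(ms_gca, ms_sca, v_eps, config)
        if v_gca < 0:
            flags.append("negative V_GCA estimate")
        if v_sca < 0:
            flags.append("negative V_SCA estimate")
        v_a, v_d = genetic_components(v_gca, v_sca, config.F)
        v_g = v_a + v_d
        h2_broad, h2_narrow = heritabilities(v_a, v_d, v_eps, config.r)
        br = bakers_ratio(ms_gca, ms_sca)
    return DiallelResult(
        trait=trait,
        config=config,
        ms_gca=ms_gca,
        ms_sca=ms_sca,
        v_eps=v_eps,
        v_eps_root=v_eps_root,
        v_gca=v_gca,
        v_sca=v_sca,
        v_a=v_a,
        v_d=v_d,
        v_g=v_g,
        H2=h2_broad,
        h2=h2_narrow,
        bakers_ratio=br,
        gca_effects=gca,
        sca_effects=sca,
        flags=flags,
    )


def read_diallel_csv(path: str | Path) -> DiallelTable:
    """Read a ``parent_i,parent_j,rep,root_id,value`` CSV into a table."""
    return DiallelTable(pd.read_csv(path, comment="#"))
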