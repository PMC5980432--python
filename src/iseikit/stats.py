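"""Comparative statistics over the egg-records table.

Three analysis families, applied per descriptor:

1. within a species, across developmental stages — one-way ANOVA;
2. between species, at a fixed developmental stage — one-way ANOVA;
3. parental vs. reciprocal-hybrid crosses — two-way ANOVA with effects in
   the fixed order female origin, male origin, female x male interaction,
   using sequential (Type I) sums of squares, the classical default for
   unbalanced designs in base R-style workflows.

Post hoc, significant one-way results get Tukey's Honest Significant
Difference test, with the Tukey-Kramer standard error for unequal group
sizes and p-values from the studentized range distribution.  No
multiple-testing correction is applied across descriptors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols

from iseikit.pipeline import SHAPE_DESCRIPTORS, PN_ONLY

log = logging.getLogger(__name__)

__all__ = ["AnovaResult", "EffectTest", "TukeyResult", "anova_oneway",
           "anova_twoway", "tukey_hsd", "run_paper_design"]

TINY_P = np.nextafter(0.0, 1.0)


@dataclass
class EffectTest:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float


@dataclass
class AnovaResult:
    effects: list[EffectTest]
    flags: list[str] = field(default_factory=list)

    @property
    def F(self) -> float:
        return self.effects[0].F

    @property
    def p(self) -> float:
        return self.effects[0].p

    def as_rows(self) -> list[dict]:
        return [{"effect": e.effect, "F": e.F, "df_num": e.df_num,
                 "df_den": e.df_den, "p": e.p} for e in self.effects]


def _as_groups(values, labels=None) -> dict:
    if isinstance(values, dict):
        return {k: np.asarray(v, float) for k, v in values.items()}
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    return {k: values[labels == k] for k in pd.unique(labels)}


def anova_oneway(values, labels=None) -> AnovaResult:
    """Classical one-way ANOVA: F = MS_between / MS_within.

    ``values`` may be a dict {level: array} or an array with ``labels``.
    Requires at least two groups with n >= 2 each and finite values.
    With zero within-group variance the F statistic is unbounded: p is
    reported at the machine minimum (or as F = 0 when all values are
    identical) with an explanatory flag.
    """
    groups = _as_groups(values, labels)
    _check_groups(groups)
    df = pd.DataFrame({
        "value": np.concatenate(list(groups.values())),
        "g": np.concatenate([[k] * len(v) for k, v in groups.items()]),
    })
    k = len(groups)
    n = len(df)
    degenerate = _degenerate_oneway(groups)
    if degenerate is not None:
        return AnovaResult([EffectTest("group", *degenerate, )],
                           flags=["zero_within_variance"])
    fit = ols("value ~ C(g)", data=df).fit()
    tbl = sm.stats.anova_lm(fit, typ=1)
    F = float(tbl.loc["C(g)", "F"])
    p = float(tbl.loc["C(g)", "PR(>F)"])
    return AnovaResult([EffectTest("group", F, k - 1, n - k, p)])


def _check_groups(groups):
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs at least two groups")
    for name, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group '{name}' has n < 2")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"group '{name}' contains non-finite values")


def _degenerate_oneway(groups):
    """Handle zero within-group variance explicitly; returns an effect tuple
    (F, df_num, df_den, p) or None for the regular path."""
    ssw = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    allv = np.concatenate(list(groups.values()))
    sst = ((allv - allv.mean()) ** 2).sum()
    if ssw > 1e-12 * max(sst, 1.0):
        return None
    k, n = len(groups), len(allv)
    if sst <= 1e-12 * max(abs(allv).max() ** 2, 1.0) * n:
        return (0.0, k - 1, n - k, 1.0)       # every value identical
    return (float("inf"), k - 1, n - k, TINY_P)


def anova_twoway(table: pd.DataFrame, value: str = "value",
                 female: str = "female", male: str = "male") -> AnovaResult:
    """Two-way ANOVA, sequential (Type I) SS, effect order female, male,
    female x male; each F tested against the residual mean square.

    Requires a complete 2x2 (or larger) layout with at least two
    observations per cell; an empty cell is an error naming the cell.
    """
    df = table[[value, female, male]].dropna().copy()
    counts = df.groupby([female, male], observed=True).size()
    f_levels = df[female].unique()
    m_levels = df[male].unique()
    if len(f_levels) < 2 or len(m_levels) < 2:
        raise ValueError("two-way ANOVA needs >= 2 levels of each factor")
    for fl in f_levels:
        for ml in m_levels:
            n_cell = counts.get((fl, ml), 0)
            if n_cell < 2:
                raise ValueError(f"cell (female={fl}, male={ml}) has n={n_cell} < 2")
    df = df.rename(columns={value: "value", female: "female", male: "male"})
    fit = ols("value ~ C(female) + C(male) + C(female):C(male)", data=df).fit()
    tbl = sm.stats.anova_lm(fit, typ=1)
    df_den = int(tbl.loc["Residual", "df"])
    order = [("C(female)", "female"), ("C(male)", "male"),
             ("C(female):C(male)", "female:male")]
    effects = []
    flags = []
    for key, name in order:
        F = float(tbl.loc[key, "F"])
        p = float(tbl.loc[key, "PR(>F)"])
        if not np.isfinite(F):
            F, p = float("inf"), TINY_P
            flags.append("zero_residual_variance")
        effects.append(EffectTest(name, F, int(tbl.loc[key, "df"]), df_den, p))
    return AnovaResult(effects, flags=flags)


@dataclass
class TukeyResult:
    table: pd.DataFrame     # group1, group2, diff, se, q, p_adj, lo, hi
    alpha: float
    df_den: int
    n_groups: int


def tukey_hsd(values, labels=None, alpha: float = 0.05) -> TukeyResult:
    """All-pairs Tukey HSD with the Tukey-Kramer SE for unequal n.

    For each pair (i, j): q = |mean_i - mean_j| / sqrt(MSW/2 (1/n_i + 1/n_j));
    the adjusted p is the studentized-range survival function at q with k
    groups and N - k error degrees of freedom, and the confidence bounds use
    the alpha-level studentized-range quantile.
    """
    groups = _as_groups(values, labels)
    if len(groups) < 2:
        raise ValueError("Tukey HSD needs at least two groups")
    names = list(groups)
    k = len(names)
    n = {g: len(groups[g]) for g in names}
    mean = {g: groups[g].mean() for g in names}
    N = sum(n.values())
    dfd = N - k
    msw = sum(((groups[g] - mean[g]) ** 2).sum() for g in names) / dfd
    qdist = sps.studentized_range(k, dfd)
    qcrit = qdist.ppf(1.0 - alpha)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = names[i], names[j]
            diff = mean[b] - mean[a]
            se = np.sqrt(msw / 2.0 * (1.0 / n[a] + 1.0 / n[b]))
            if se == 0:
                q = 0.0 if diff == 0 else float("inf")
                p = 1.0 if diff == 0 else TINY_P
            else:
                q = abs(diff) / se
                p = float(np.clip(qdist.sf(q), TINY_P, 1.0))
            rows.append({"group1": a, "group2": b, "diff": diff, "se": se,
                         "q": q, "p_adj": p,
                         "lo": diff - qcrit * se, "hi": diff + qcrit * se})
    return TukeyResult(pd.DataFrame(rows), alpha, dfd, k)


# ---------------------------------------------------------------------------
# the full comparison design


def run_paper_design(table: pd.DataFrame, alpha: float = 0.05,
                     min_n: int = 2) -> dict:
    """Run the three comparison families over an egg-records table.

    ``table`` is the long-format output of ``pipeline.build_table``.  Cells
    that cannot support a test (missing stage/species combinations, groups
    below ``min_n``) are skipped and listed in the result, never imputed.

    Returns ``{"anova": DataFrame, "tukey": {key: TukeyResult},
    "skipped": list}``; Tukey tables are produced only for significant
    one-way rows, gated at ``alpha``.
    """
    rows, tukeys, skipped = [], {}, []
    consp = table[table.female_species == table.male_species]

    # 1) within species, across stages
    for species, sub in consp.groupby("female_species", observed=True):
        for desc in SHAPE_DESCRIPTORS:
            groups = _valid_groups(sub, "stage", desc, min_n)
            if len(groups) < 2:
                skipped.append(("within_species", species, desc, "fewer than 2 stages"))
                continue
            res = anova_oneway(groups)
            rows.append(_row("within_species", species, "stage", desc, res))
            if res.p <= alpha:
                tukeys[("within_species", species, desc)] = tukey_hsd(groups, alpha=alpha)

    # 2) between species, per stage
    for stage, sub in consp.groupby("stage", observed=True):
        descs = SHAPE_DESCRIPTORS + (PN_ONLY if stage == "PN" else ())
        for desc in descs:
            groups = _valid_groups(sub, "female_species", desc, min_n)
            if len(groups) < 2:
                skipped.append(("between_species", stage, desc, "fewer than 2 species"))
                continue
            res = anova_oneway(groups)
            rows.append(_row("between_species", stage, "species", desc, res))
            if res.p <= alpha:
                tukeys[("between_species", stage, desc)] = tukey_hsd(groups, alpha=alpha)

    # 3) parental vs reciprocal hybrids: every species pair with a complete
    #    2x2 cross layout at a stage
    pairs = _complete_pairs(table, min_n)
    for (sp_a, sp_b, stage) in pairs:
        sub = table[(table.stage == stage)
                    & table.female_species.isin([sp_a, sp_b])
                    & table.male_species.isin([sp_a, sp_b])]
        descs = SHAPE_DESCRIPTORS + (PN_ONLY if stage == "PN" else ())
        for desc in descs:
            if desc not in sub.columns:
                skipped.append(("hybrid", f"{sp_a}-{sp_b}@{stage}", desc,
                                "descriptor not measured"))
                continue
            cell = sub.dropna(subset=[desc])
            counts = cell.groupby(["female_species", "male_species"], observed=True).size()
            if len(counts) < 4 or counts.min() < min_n:
                skipped.append(("hybrid", f"{sp_a}-{sp_b}@{stage}", desc, "incomplete 2x2"))
                continue
            res = anova_twoway(cell, value=desc,
                               female="female_species", male="male_species")
            for eff in res.effects:
                rows.append({"family": "hybrid", "context": f"{sp_a}-{sp_b}@{stage}",
                             "factor": eff.effect, "descriptor": desc,
                             "F": eff.F, "df_num": eff.df_num,
                             "df_den": eff.df_den, "p": eff.p,
                             "significant": eff.p <= alpha})

    anova_df = pd.DataFrame(rows, columns=["family", "context", "factor",
                                           "descriptor", "F", "df_num",
                                           "df_den", "p", "significant"])
    return {"anova": anova_df, "tukey": tukeys, "skipped": skipped}


def _valid_groups(sub, by, desc, min_n):
    if desc not in sub.columns:
        return {}
    cell = sub.dropna(subset=[desc])
    return {lvl: g[desc].to_numpy(float)
            for lvl, g in cell.groupby(by, observed=True) if len(g) >= min_n}


def _row(family, context, factor, desc, res: AnovaResult):
    e = res.effects[0]
    return {"family": family, "context": context, "factor": factor,
            "descriptor": desc, "F": e.F, "df_num": e.df_num,
            "df_den": e.df_den, "p": e.p, "significant": e.p <= 0.05}


def _complete_pairs(table, min_n):
    """Species pairs with parental + both reciprocal crosses at a stage."""
    out = []
    species = sorted(set(table.female_species) | set(table.male_species))
    counts = table.groupby(["female_species", "male_species", "stage"],
                           observed=True).size()
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            for stage in table.stage.unique():
                need = [(a, a, stage), (a, b, stage), (b, a, stage), (b, b, stage)]
                if all(counts.get(cell, 0) >= min_n for cell in need):
                    out.append((a, b, stage))
    return out
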