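"""Cross-species and phylogenetic statistics for leaf trait tables.

Implements the statistical layer used for the 36-species comparison:

* a normality screen (Shapiro–Wilk) that decides whether a trait is
  log10-transformed before parametric analysis,
* one-way ANOVA across functional groups with Bonferroni-corrected
  pairwise comparisons,
* standardized major axis (SMA) regression for symmetric bivariate
  allometries,
* Felsenstein's phylogenetically independent contrasts (PICs) under
  Brownian motion on a rooted tree with branch lengths,
* Moran's I with phylogenetic proximity weights (inverse patristic
  distance) as a test of phylogenetic autocorrelation,

plus a report routine that aggregates the summaries for a full trait table.
Trees are dendropy objects; trait tables are pandas DataFrames with one row
per species.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FUNCTIONAL_GROUPS",
    "REQUIRED_COLUMNS",
    "ContrastSet",
    "GroupComparison",
    "SMAResult",
    "MoranResult",
    "validate_trait_table",
    "transform_screen",
    "group_compare",
    "sma_slope",
    "pic",
    "pic_correlation",
    "morans_I",
    "analysis_report",
]

FUNCTIONAL_GROUPS = ("H/D", "H/E", "W/D", "W/E")

#: minimum schema for a species-level trait table
REQUIRED_COLUMNS = (
    "species",
    "family",
    "functional_group",
    "E_T",
    "E_B",
    "ratio",
    "thickness",
    "alpha",
    "E_f",
    "E_c",
    "EB_I",
)


def validate_trait_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the species-level schema; returns the table unchanged."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trait table missing columns: {missing}")
    if table["species"].duplicated().any():
        dups = table.loc[table["species"].duplicated(), "species"].tolist()
        raise ValueError(f"duplicate species: {dups}")
    bad_fg = set(table["functional_group"]) - set(FUNCTIONAL_GROUPS)
    if bad_fg:
        raise ValueError(f"unknown functional groups: {sorted(bad_fg)}")
    return table


# ---------------------------------------------------------------------------
# transform screening


def transform_screen(
    values: Sequence[float], labels: Optional[Sequence[str]] = None, p_threshold: float = 0.05
) -> tuple[np.ndarray, int]:
    """Log10-transform a trait iff Shapiro–Wilk rejects normality at P < 0.05.

    Returns ``(transformed values, flag)`` with flag 1 when the log branch
    was taken (the "Trans" column convention).  Raises when the log branch
    is required but some values are non-positive, naming the offenders.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 values for the normality screen")
    if np.any(~np.isfinite(x)):
        raise ValueError("non-finite trait values")
    _, p = stats.shapiro(x)
    if p >= p_threshold:
        return x, 0
    if np.any(x <= 0):
        bad = np.flatnonzero(x <= 0)
        names = (
            [str(labels[i]) for i in bad] if labels is not None else bad.tolist()
        )
        raise ValueError(
            f"log transform required (Shapiro–Wilk P={p:.3g}) but non-positive "
            f"values present: {names}"
        )
    return np.log10(x), 1


# ---------------------------------------------------------------------------
# group comparison


@dataclass(frozen=True)
class GroupComparison:
    F: float
    p: float
    pairwise_p: dict[tuple[str, str], float]
    groups: tuple[str, ...]
    transformed: int


def group_compare(
    table: pd.DataFrame,
    trait: str,
    grouping: str = "functional_group",
    min_group_size: int = 2,
    screen: bool = True,
) -> GroupComparison:
    """One-way ANOVA of ``trait`` across ``grouping`` + Bonferroni pairwise tests.

    Groups smaller than ``min_group_size`` are reported as degenerate and
    rejected.  When ``screen`` is set the trait passes through
    :func:`transform_screen` first and the ANOVA runs on the chosen scale.
    """
    if trait not in table.columns or grouping not in table.columns:
        raise ValueError(f"missing column: {trait!r} or {grouping!r}")
    vals = table[trait].to_numpy(dtype=float)
    labels = table["species"] if "species" in table.columns else None
    flag = 0
    if screen:
        vals, flag = transform_screen(vals, labels)
    groups = sorted(table[grouping].unique())
    samples = {g: vals[(table[grouping] == g).to_numpy()] for g in groups}
    degenerate = [g for g, s in samples.items() if len(s) < min_group_size]
    if degenerate:
        raise ValueError(f"degenerate groups (n < {min_group_size}): {degenerate}")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    F, p = stats.f_oneway(*samples.values())
    pairs = list(itertools.combinations(groups, 2))
    pairwise: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        _, raw = stats.ttest_ind(samples[a], samples[b], equal_var=True)
        pairwise[(a, b)] = min(1.0, float(raw) * len(pairs))
    return GroupComparison(
        F=float(F), p=float(p), pairwise_p=pairwise,
        groups=tuple(groups), transformed=flag,
    )


# ---------------------------------------------------------------------------
# standardized major axis regression


@dataclass(frozen=True)
class SMAResult:
    slope: float
    ci: tuple[float, float]
    r: float
    intercept: float
    n: int


def sma_slope(x: Sequence[float], y: Sequence[float], alpha: float = 0.05) -> SMAResult:
    """Standardized major axis line through (x, y).

    slope = sign(r) * sd(y)/sd(x); the confidence interval follows the
    standard construction from the F distribution of the correlation:
    with B = F_{1,n-2}(1-alpha) * (1 - r^2)/(n - 2), the limits are
    slope * (sqrt(B + 1) +/- sqrt(B)).  Symmetric in x and y in the sense
    that swapping them inverts the slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must be equal length, n >= 3")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = math.copysign(sy / sx, r if r != 0 else 1.0)
    n = len(x)
    B = stats.f.ppf(1 - alpha, 1, n - 2) * (1 - r * r) / (n - 2)
    lo = slope * (math.sqrt(B + 1) - math.sqrt(B))
    hi = slope * (math.sqrt(B + 1) + math.sqrt(B))
    intercept = float(y.mean() - slope * x.mean())
    return SMAResult(slope=slope, ci=(min(lo, hi), max(lo, hi)), r=r,
                     intercept=intercept, n=n)


# ---------------------------------------------------------------------------
# phylogenetically independent contrasts


@dataclass(frozen=True)
class ContrastSet:
    """Standardized contrasts in postorder over the resolved tree's internal
    nodes, with the subtending tip sets recorded for traceability."""

    contrasts: np.ndarray
    node_tips: tuple[tuple[str, ...], ...] = field(default=())

    def __len__(self) -> int:
        return len(self.contrasts)


def _resolved_copy(tree: dendropy.Tree) -> dendropy.Tree:
    """Binary deep copy: polytomies broken with zero-length internal edges,
    children ordered alphabetically by their smallest tip label (fixes
    contrast signs deterministically)."""
    t = tree.clone(depth=1)
    t.resolve_polytomies(limit=2, update_bipartitions=False)
    for nd in t.preorder_node_iter():
        if nd.edge.length is None:
            nd.edge.length = 0.0
    def min_tip(nd: dendropy.Node) -> str:
        return min(lf.taxon.label for lf in nd.leaf_iter())
    for nd in t.preorder_node_iter():
        if not nd.is_leaf():
            nd.set_child_nodes(sorted(nd.child_nodes(), key=min_tip))
    return t


def pic(tree: dendropy.Tree, trait: Mapping[str, float]) -> ContrastSet:
    """Felsenstein's standardized independent contrasts of one trait.

    ``trait`` maps tip labels to values and must cover every tip.  The tree
    is resolved to binary form first (zero-length internal branches), so a
    tree with n tips yields n - 1 contrasts.  Each contrast is
    (x_left - x_right)/sqrt(v_left' + v_right') with the usual pruning
    branch-length adjustment; "left" is the child whose smallest tip label
    sorts first.
    """
    tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = sorted(tips - set(trait))
    if missing:
        raise ValueError(f"trait values missing for tips: {missing}")
    t = _resolved_copy(tree)
    contrasts: list[float] = []
    node_tips: list[tuple[str, ...]] = []
    for nd in t.postorder_node_iter():
        if nd.is_leaf():
            nd.pic_value = float(trait[nd.taxon.label])
            nd.pic_var = float(nd.edge.length)
            continue
        c1, c2 = nd.child_nodes()
        v1, v2 = c1.pic_var, c2.pic_var
        vsum = v1 + v2
        if vsum <= 0:
            raise ValueError(
                "zero expected contrast variance at an internal node "
                "(all-zero branch lengths?)"
            )
        contrasts.append((c1.pic_value - c2.pic_value) / math.sqrt(vsum))
        node_tips.append(tuple(sorted(lf.taxon.label for lf in nd.leaf_iter())))
        nd.pic_value = (c1.pic_value / v1 + c2.pic_value / v2) / (1 / v1 + 1 / v2) \
            if v1 > 0 and v2 > 0 else (
                c2.pic_value if v1 > 0 else c1.pic_value
                if v2 > 0 else 0.5 * (c1.pic_value + c2.pic_value)
            )
        nd.pic_var = float(nd.edge.length or 0.0) + v1 * v2 / vsum
    return ContrastSet(np.asarray(contrasts), tuple(node_tips))


def pic_correlation(tree: dendropy.Tree, trait_x: Mapping[str, float],
                    trait_y: Mapping[str, float]) -> tuple[float, float]:
    """PIC correlation of two traits: through-the-origin r over contrasts.

    Returns ``(r, p)`` with p from the t distribution on n_contrasts - 1
    degrees of freedom.
    """
    u = pic(tree, trait_x).contrasts
    v = pic(tree, trait_y).contrasts
    denom = math.sqrt(float(u @ u) * float(v @ v))
    if denom == 0:
        raise ValueError("zero contrast variance (constant trait?)")
    r = float(u @ v) / denom
    df = len(u) - 1
    if abs(r) >= 1.0:
        return r, 0.0
    tstat = r * math.sqrt(df / (1 - r * r))
    p = 2 * stats.t.sf(abs(tstat), df)
    return r, float(p)


# ---------------------------------------------------------------------------
# Moran's I


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected: float
    sd: float
    p: float
    p_permutation: Optional[float] = None


def _inverse_distance_weights(tree: dendropy.Tree, labels: Sequence[str]) -> np.ndarray:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    W = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i == j:
                continue
            d = pdm.patristic_distance(taxa[a], taxa[b])
            if d <= 0:
                raise ValueError(f"non-positive patristic distance {a} – {b}")
            W[i, j] = 1.0 / d
    return W


def morans_I(
    tree: dendropy.Tree,
    trait: Mapping[str, float],
    n_permutations: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> MoranResult:
    """Moran's autocorrelation index of a trait on a phylogeny.

    Weights are inverse patristic distances (diagonal zero, unnormalized).
    Expectation under no autocorrelation is -1/(n-1); the two-sided P uses
    the Gaussian approximation with the randomization-assumption variance
    (kurtosis-corrected, the standard choice for trait data).  Setting
    ``n_permutations`` adds a permutation P (trait shuffled across tips).
    """
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    missing = sorted(set(labels) - set(trait))
    if missing:
        raise ValueError(f"trait values missing for tips: {missing}")
    x = np.array([trait[s] for s in labels], dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 tips")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("constant trait: Moran's I undefined (zero variance)")
    W = _inverse_distance_weights(tree, labels)
    S0 = W.sum()
    if S0 == 0:
        raise ValueError("zero weight matrix")

    def stat(zv: np.ndarray) -> float:
        return float(n / S0 * (zv @ W @ zv) / (zv @ zv))

    I = stat(z)
    EI = -1.0 / (n - 1)
    Wsym = W + W.T
    S1 = 0.5 * float((Wsym**2).sum())
    S2 = float(((W.sum(axis=0) + W.sum(axis=1)) ** 2).sum())
    s_sq = S0 * S0
    kurt = (float((z**4).sum()) / n) / (denom / n) ** 2
    varI = (
        n * ((n * n - 3 * n + 3) * S1 - n * S2 + 3 * s_sq)
        - kurt * (n * (n - 1) * S1 - 2 * n * S2 + 6 * s_sq)
    ) / ((n - 1) * (n - 2) * (n - 3) * s_sq) - 1.0 / ((n - 1) ** 2)
    sd = math.sqrt(max(varI, 0.0))
    p = 2 * stats.norm.sf(abs(I - EI) / sd) if sd > 0 else float("nan")
    p_perm = None
    if n_permutations > 0:
        rng = rng or np.random.default_rng()
        hits = 1
        for _ in range(n_permutations):
            if abs(stat(rng.permutation(z)) - EI) >= abs(I - EI):
                hits += 1
        p_perm = hits / (n_permutations + 1)
    return MoranResult(I=I, expected=EI, sd=sd, p=float(p), p_permutation=p_perm)


# ---------------------------------------------------------------------------
# aggregated report


_REPORT_TRAITS = ("E_T", "E_B", "ratio", "thickness", "alpha", "E_f", "E_c", "EB_I")


def analysis_report(
    table: pd.DataFrame,
    tree: Optional[dendropy.Tree] = None,
    traits: Sequence[str] = _REPORT_TRAITS,
) -> dict:
    """Standard summary of a species-level trait table.

    Produces overall and per-functional-group means ± SD of the bending:
    tensile ratio, alpha and thickness; a cross-species Pearson correlation
    matrix over ``traits`` (log10 scale where the normality screen says so);
    the matching PIC correlation matrix when a tree is supplied; the SMA fit
    of log10 E_B on log10 E_T; and the species whose ratio exceeds the
    sandwich bound 1 + alpha + alpha^2.
    """
    validate_trait_table(table)
    missing = [t for t in traits if t not in table.columns]
    if missing:
        raise ValueError(f"missing trait columns: {missing}")

    def mean_sd(series: pd.Series) -> dict:
        return {"mean": float(series.mean()), "sd": float(series.std(ddof=1)),
                "n": int(series.count())}

    report: dict = {
        "overall": {k: mean_sd(table[k]) for k in ("ratio", "alpha", "thickness", "E_f", "E_c")},
        "by_group": {
            g: {k: mean_sd(sub[k]) for k in ("ratio", "alpha", "thickness")}
            for g, sub in table.groupby("functional_group")
        },
    }
    woody = table[table["functional_group"].isin(["W/D", "W/E"])]
    herb = table[table["functional_group"].isin(["H/D", "H/E"])]
    report["woody_vs_herbaceous_ratio"] = {
        "woody": mean_sd(woody["ratio"]),
        "herbaceous": mean_sd(herb["ratio"]),
    }

    # transform screen per trait, then Pearson matrix on the chosen scales
    scaled: dict[str, np.ndarray] = {}
    trans_flags: dict[str, int] = {}
    for t in traits:
        vals = table[t].to_numpy(dtype=float)
        try:
            scaled[t], trans_flags[t] = transform_screen(vals, table["species"])
        except ValueError:
            scaled[t], trans_flags[t] = vals, 0  # log impossible (negatives): raw scale
    report["transform_flags"] = trans_flags

    k = len(traits)
    pearson = np.eye(k)
    pearson_p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            r, p = stats.pearsonr(scaled[traits[i]], scaled[traits[j]])
            pearson[i, j] = pearson[j, i] = r
            pearson_p[i, j] = pearson_p[j, i] = p
    report["pearson"] = pd.DataFrame(pearson, index=traits, columns=traits)
    report["pearson_p"] = pd.DataFrame(pearson_p, index=traits, columns=traits)

    # SMA of log10 E_B on log10 E_T (both screen as log traits on real data)
    logET, logEB = np.log10(table["E_T"]), np.log10(table["E_B"])
    fit = sma_slope(logET, logEB)
    report["sma_logEB_on_logET"] = {
        "slope": fit.slope, "ci": fit.ci, "r": fit.r, "r_squared": fit.r**2,
    }

    bound = 1 + table["alpha"] + table["alpha"] ** 2
    report["exceeds_bound_species"] = table.loc[
        table["ratio"] > bound, "species"
    ].tolist()

    if tree is not None:
        pic_r = np.eye(k)
        pic_p = np.zeros((k, k))
        species = table["species"].tolist()
        for i in range(k):
            for j in range(i + 1, k):
                tx = dict(zip(species, scaled[traits[i]]))
                ty = dict(zip(species, scaled[traits[j]]))
                r, p = pic_correlation(tree, tx, ty)
                pic_r[i, j] = pic_r[j, i] = r
                pic_p[i, j] = pic_p[j, i] = p
        report["pic"] = pd.DataFrame(pic_r, index=traits, columns=traits)
        report["pic_p"] = pd.DataFrame(pic_p, index=traits, columns=traits)
        report["moran"] = {
            t: morans_I(tree, dict(zip(species, scaled[t]))) for t in traits
        }
    return report
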