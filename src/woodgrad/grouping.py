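"""Guild, site and taxonomic structure of vertical-profile scores.

Three questions about the axis-1 ordination scores are answered here:

* do regeneration guilds (pioneer / nonpioneer light-demanding /
  shade-tolerant) differ in profile shape? -- one-way ANOVA with a Tukey
  HSD post hoc and a compact letter display;
* how much profile variance sits between species vs. between sites? --
  sequential (type-I) two-way ANOVA with interaction, restricted to
  species observed at several sites so the two factors are crossed;
* is the profile evolutionarily conserved? -- Blomberg's K on species mean
  scores over a phylogeny, with a tip-randomization p-value. K is the
  ratio of the observed (MSE0/MSE) contrast -- trait variance around the
  phylogenetic GLS mean over phylogenetically corrected variance -- to its
  Brownian-motion expectation, so K ~ 1 under Brownian evolution and K ~ 0
  when relatives are no more similar than chance.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult",
    "PhyloSignal",
    "oneway_anova",
    "tukey_hsd",
    "variance_partition",
    "phylo_vcv",
    "blomberg_k",
    "blomberg_k_pvalue",
    "simulate_brownian",
]


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    ss_between: float = float("nan")
    ss_within: float = float("nan")
    #: for the two-way partition: variance fraction (SS_term/SS_total) per term
    variance_fractions: dict | None = None
    terms: pd.DataFrame | None = None
    n: int = 0


@dataclass
class PhyloSignal:
    K: float
    p: float
    n_randomizations: int
    tail: str
    K_random: np.ndarray | None = None


# ---------------------------------------------------------------------------
# One-way ANOVA and Tukey HSD
# ---------------------------------------------------------------------------

def _check_groups(values, groups) -> tuple[np.ndarray, list, list[np.ndarray]]:
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if y.shape != g.shape:
        raise ValueError("values and groups must have the same length")
    levels = sorted(pd.unique(g).tolist())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    split = [y[g == lv] for lv in levels]
    for lv, arr in zip(levels, split):
        if arr.size < 2:
            raise ValueError(f"group {lv!r} has fewer than 2 values")
    return y, levels, split


def oneway_anova(values, groups) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA (between/within decomposition)."""
    y, levels, split = _check_groups(values, groups)
    grand = y.mean()
    ssb = sum(arr.size * (arr.mean() - grand) ** 2 for arr in split)
    ssw = sum(((arr - arr.mean()) ** 2).sum() for arr in split)
    dfb = len(levels) - 1
    dfw = y.size - len(levels)
    if ssw == 0.0:
        F = 0.0 if ssb == 0.0 else float("inf")
    else:
        F = (ssb / dfb) / (ssw / dfw)
    p = float(stats.f.sf(F, dfb, dfw)) if np.isfinite(F) else 0.0
    return AnovaResult(
        F=float(F), df_between=dfb, df_within=dfw, p=p,
        ss_between=float(ssb), ss_within=float(ssw), n=y.size,
    )


def tukey_hsd(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey's honestly-significant-difference pairwise comparisons.

    Adjusted p-values and confidence intervals come from the studentized
    range distribution with the pooled within-group variance
    (Tukey-Kramer for unequal group sizes). The returned frame carries one
    row per pair (difference = mean2 - mean1, CI, adjusted p, reject flag)
    and a ``letters`` attribute mapping each group to its compact letter
    display for plot annotation.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    y, levels, split = _check_groups(values, groups)
    k = len(levels)
    dfw = y.size - k
    msw = sum(((arr - arr.mean()) ** 2).sum() for arr in split) / dfw
    means = {lv: arr.mean() for lv, arr in zip(levels, split)}
    sizes = {lv: arr.size for lv, arr in zip(levels, split)}

    rows = []
    for g1, g2 in itertools.combinations(levels, 2):
        diff = means[g2] - means[g1]
        se = np.sqrt(msw / 2.0 * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        if se == 0.0:
            q = 0.0 if diff == 0 else float("inf")
            p_adj = 1.0 if diff == 0 else 0.0
            half = 0.0
        else:
            q = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q, k, dfw))
            half = float(stats.studentized_range.ppf(1 - alpha, k, dfw)) * se
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "difference": float(diff),
                "ci_low": float(diff - half),
                "ci_high": float(diff + half),
                "p_adj": min(p_adj, 1.0),
                "reject": bool(p_adj < alpha),
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["letters"] = _compact_letters(levels, table)
    return table


def _compact_letters(levels: list, pairs: pd.DataFrame) -> dict:
    """Insert-and-absorb compact letter display from a pairwise table."""
    distinct = {
        (r.group1, r.group2) for r in pairs.itertuples(index=False) if r.reject
    }
    # each letter set is a set of groups not significantly different
    letter_sets: list[set] = [set(levels)]
    for g1, g2 in distinct:
        new_sets: list[set] = []
        for s in letter_sets:
            if g1 in s and g2 in s:
                new_sets.extend((s - {g1}, s - {g2}))
            else:
                new_sets.append(s)
        # absorb subsets
        letter_sets = [
            s for s in new_sets
            if not any(s < t for t in new_sets)
        ]
        # deduplicate
        uniq = []
        for s in letter_sets:
            if s not in uniq:
                uniq.append(s)
        letter_sets = uniq
    letters = {lv: "" for lv in levels}
    for i, s in enumerate(sorted(letter_sets, key=lambda s: sorted(map(str, s)))):
        ch = chr(ord("a") + i)
        for lv in s:
            letters[lv] += ch
    return {lv: "".join(sorted(v)) for lv, v in letters.items()}


# ---------------------------------------------------------------------------
# Species x site variance partitioning
# ---------------------------------------------------------------------------

def _rss(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and rank of the OLS projection on X."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def _dummies(labels: np.ndarray) -> np.ndarray:
    levels = pd.unique(labels)
    return (labels[:, None] == levels[None, :]).astype(float)


def variance_partition(
    values, species, site, *, min_sites: int = 3
) -> AnovaResult:
    """Sequential (type-I) two-way ANOVA: species, then site, then their
    interaction, on trees of species found in at least ``min_sites`` sites.

    Variance fractions are SS_term / SS_total. If the species-by-site
    design leaves no degrees of freedom for the interaction it is dropped
    with a warning.
    """
    df = pd.DataFrame(
        {
            "y": np.asarray(values, dtype=float),
            "species": np.asarray(species),
            "site": np.asarray(site),
        }
    )
    n_sites_of = df.groupby("species")["site"].nunique()
    keep = n_sites_of[n_sites_of >= min_sites].index
    df = df[df["species"].isin(keep)]
    if df["species"].nunique() < 2 or df["site"].nunique() < 2:
        raise ValueError(
            f"after the >= {min_sites}-sites filter, need >= 2 species and >= 2 sites "
            f"(kept {df['species'].nunique()} species, {df['site'].nunique()} sites)"
        )

    y = df["y"].to_numpy()
    n = y.size
    one = np.ones((n, 1))
    A = _dummies(df["species"].to_numpy())
    B = _dummies(df["site"].to_numpy())
    AB = (A[:, :, None] * B[:, None, :]).reshape(n, -1)

    ss_total = float(((y - y.mean()) ** 2).sum())
    rss0, r0 = _rss(y, one)
    rss1, r1 = _rss(y, np.hstack([one, A]))
    rss2, r2 = _rss(y, np.hstack([one, A, B]))
    rss3, r3 = _rss(y, np.hstack([one, A, B, AB]))

    terms = [
        ("species", rss0 - rss1, r1 - r0),
        ("site", rss1 - rss2, r2 - r1),
        ("species:site", rss2 - rss3, r3 - r2),
    ]
    if terms[-1][2] == 0:
        warnings.warn(
            "species-by-site interaction inestimable (no crossed cells); dropped",
            stacklevel=2,
        )
        terms = terms[:2]
        rss3, r3 = rss2, r2
    df_resid = n - r3
    ms_resid = rss3 / df_resid if df_resid > 0 else float("nan")

    rows = []
    fractions = {}
    for name, ss, dof in terms:
        F = (ss / dof) / ms_resid if dof > 0 and ms_resid > 0 else float("nan")
        p = float(stats.f.sf(F, dof, df_resid)) if np.isfinite(F) else float("nan")
        fractions[name] = ss / ss_total if ss_total > 0 else float("nan")
        rows.append({"term": name, "ss": ss, "df": dof, "F": F, "p": p,
                     "frac": fractions[name]})
    rows.append(
        {"term": "residual", "ss": rss3, "df": df_resid, "F": np.nan, "p": np.nan,
         "frac": rss3 / ss_total if ss_total > 0 else np.nan}
    )
    sp = rows[0]
    return AnovaResult(
        F=float(sp["F"]),
        df_between=int(sp["df"]),
        df_within=int(df_resid),
        p=float(sp["p"]),
        ss_between=float(sp["ss"]),
        ss_within=float(rss3),
        variance_fractions=fractions,
        terms=pd.DataFrame(rows),
        n=n,
    )


# ---------------------------------------------------------------------------
# Blomberg's K
# ---------------------------------------------------------------------------

def _as_tree(phylogeny) -> dendropy.Tree:
    if isinstance(phylogeny, dendropy.Tree):
        return phylogeny
    return dendropy.Tree.get(data=str(phylogeny), schema="newick")


def phylo_vcv(phylogeny) -> tuple[np.ndarray, list[str]]:
    """Phylogenetic variance-covariance matrix (shared root-to-MRCA branch
    length between each pair of tips) and the tip labels in matrix order."""
    tree = _as_tree(phylogeny)
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    pdm = tree.phylogenetic_distance_matrix()
    n = len(leaves)
    C = np.empty((n, n))
    for i, li in enumerate(leaves):
        C[i, i] = li.root_distance
        for j in range(i + 1, n):
            lj = leaves[j]
            d = pdm.patristic_distance(li.taxon, lj.taxon)
            C[i, j] = C[j, i] = (li.root_distance + lj.root_distance - d) / 2.0
    return C, labels


def _k_statistic(x: np.ndarray, Cinv: np.ndarray, expected_ratio: float) -> float:
    n = x.size
    ones = np.ones(n)
    a_hat = (ones @ Cinv @ x) / (ones @ Cinv @ ones)
    dev = x - a_hat
    mse0 = (dev @ dev) / (n - 1)
    mse = (dev @ Cinv @ dev) / (n - 1)
    return float((mse0 / mse) / expected_ratio)


def _prepare_k(trait, phylogeny) -> tuple[np.ndarray, np.ndarray, float]:
    C, labels = phylo_vcv(phylogeny)
    if isinstance(trait, pd.Series):
        trait = trait.to_dict()
    if isinstance(trait, dict):
        missing = [lb for lb in labels if lb not in trait]
        extra = sorted(set(trait) - set(labels))
        if missing or extra:
            raise ValueError(
                f"trait/tip mismatch; tips without trait: {missing[:10]}, "
                f"trait labels not in tree: {extra[:10]}"
            )
        x = np.array([float(trait[lb]) for lb in labels])
    else:
        x = np.asarray(trait, dtype=float)
        if x.size != len(labels):
            raise ValueError("trait vector length does not match tip count")
    if np.allclose(x, x[0]):
        raise ValueError("trait has zero variance across tips")
    n = x.size
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    expected_ratio = (np.trace(C) - n / (ones @ Cinv @ ones)) / (n - 1)
    return x, Cinv, expected_ratio


def blomberg_k(trait, phylogeny) -> float:
    """Blomberg's K of a tip trait on a branch-length phylogeny.

    ``trait`` is a mapping/Series keyed by tip label (or a vector in tip
    order). K = (MSE0/MSE) / E[MSE0/MSE | Brownian motion], where MSE0 is
    the trait mean square around the phylogenetic GLS mean and MSE the
    phylogenetically corrected mean square; invariant to rescaling the
    branch lengths or the trait.
    """
    x, Cinv, expected = _prepare_k(trait, phylogeny)
    return _k_statistic(x, Cinv, expected)


def blomberg_k_pvalue(
    trait,
    phylogeny,
    n_rand: int = 999,
    seed: int | None = None,
    tail: str = "lower",
) -> PhyloSignal:
    """Tip-randomization significance test for Blomberg's K.

    The trait values are shuffled across tips ``n_rand`` times and the
    rank-based p-value is (1 + #{K_rand at least as extreme}) / (n_rand+1).
    ``tail="lower"`` asks whether K is *smaller* than random (phylogenetic
    overdispersion), ``"upper"`` whether it is larger (conservatism),
    ``"two_sided"`` doubles the smaller tail.
    """
    if n_rand < 99:
        raise ValueError(f"n_rand must be >= 99, got {n_rand}")
    if tail not in ("lower", "upper", "two_sided"):
        raise ValueError(f"tail must be lower|upper|two_sided, got {tail!r}")
    x, Cinv, expected = _prepare_k(trait, phylogeny)
    k_obs = _k_statistic(x, Cinv, expected)
    rng = np.random.default_rng(seed)
    k_rand = np.empty(n_rand)
    for i in range(n_rand):
        k_rand[i] = _k_statistic(rng.permutation(x), Cinv, expected)
    p_lower = (1 + np.sum(k_rand <= k_obs)) / (n_rand + 1)
    p_upper = (1 + np.sum(k_rand >= k_obs)) / (n_rand + 1)
    if tail == "lower":
        p = p_lower
    elif tail == "upper":
        p = p_upper
    else:
        p = min(1.0, 2.0 * min(p_lower, p_upper))
    return PhyloSignal(
        K=k_obs, p=float(p), n_randomizations=n_rand, tail=tail, K_random=k_rand
    )


def simulate_brownian(
    phylogeny, rng: np.random.Generator, sigma: float = 1.0, mean: float = 0.0
) -> dict[str, float]:
    """Simulate one Brownian-motion trait on a phylogeny (tip label -> value)."""
    C, labels = phylo_vcv(phylogeny)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(len(labels)))
    x = mean + sigma * (L @ rng.standard_normal(len(labels)))
    return dict(zip(labels, x.tolist()))
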