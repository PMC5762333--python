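"""Statistical kernels: combined hypergeometric enrichment, BH
correction, Wilcoxon rank-sum differential activity, per-type mean
correlation, and signature-overlap comparison.

The combined enrichment test treats genes and lncRNAs as one urn: with
m_g measured genes and m_lnc measured lncRNAs, of which t_g + t_lnc sit
in a subpathway, and n_g + n_lnc significant features, the p-value is
the upper tail P(X >= r_g + r_lnc) of the hypergeometric distribution
with population m_g + m_lnc, successes t_g + t_lnc and draws
n_g + n_lnc. With all lncRNA counts zero this reduces exactly to the
classical gene-only pathway enrichment test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from subspa.errors import InputError


@dataclass(frozen=True)
class EnrichmentInput:
    """Counts for the combined gene + lncRNA hypergeometric test."""

    m_g: int
    m_lnc: int
    n_g: int
    n_lnc: int
    t_g: int
    t_lnc: int
    r_g: int
    r_lnc: int

    def __post_init__(self):
        checks = [
            (0 <= self.r_g <= min(self.t_g, self.n_g), "0 <= r_g <= min(t_g, n_g)"),
            (0 <= self.r_lnc <= min(self.t_lnc, self.n_lnc), "0 <= r_lnc <= min(t_lnc, n_lnc)"),
            (self.t_g <= self.m_g, "t_g <= m_g"),
            (self.t_lnc <= self.m_lnc, "t_lnc <= m_lnc"),
            (self.n_g <= self.m_g, "n_g <= m_g"),
            (self.n_lnc <= self.m_lnc, "n_lnc <= m_lnc"),
        ]
        for ok, name in checks:
            if not ok:
                raise InputError(f"enrichment counts violate {name}: {self}")


@dataclass(frozen=True)
class EnrichmentResult:
    subpathway_id: str
    p: float
    p_adjusted: float
    counts: EnrichmentInput


def combined_hypergeometric(inp: EnrichmentInput) -> float:
    """Upper-tail P(X >= r_g + r_lnc) of the pooled hypergeometric."""
    r = inp.r_g + inp.r_lnc
    n = inp.n_g + inp.n_lnc
    if r > n:
        raise InputError(f"r_g + r_lnc = {r} exceeds draws n_g + n_lnc = {n}")
    # survival function at r-1 is numerically stable for the small tails
    return float(sps.hypergeom.sf(r - 1, inp.m_g + inp.m_lnc, inp.t_g + inp.t_lnc, n))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

_EXACT_MAX = 10  # per-group size bound for the enumeration path


def wilcoxon_rank_sum(a, b) -> float:
    """Two-sided rank-sum p-value.

    With both groups of size <= 10 the exact permutation distribution of
    the rank sum is enumerated over all group assignments of the pooled
    (mid-ranked) values, which handles ties exactly; larger groups use
    the normal approximation with tie-corrected variance and continuity
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs >= 2 observations")
    if a.size <= _EXACT_MAX and b.size <= _EXACT_MAX:
        return _exact_rank_sum_p(a, b)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                           use_continuity=True)
    return float(res.pvalue)


def _exact_rank_sum_p(a, b) -> float:
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n1, n = len(a), len(pooled)
    w_obs = ranks[:n1].sum()
    # mid-ranks preserve the total rank sum, so E[W] is the tie-free value
    expected = n1 * (n + 1) / 2.0
    dev = abs(w_obs - expected)
    hits = total = 0
    for idx in combinations(range(n), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - expected) >= dev - 1e-9:
            hits += 1
    return hits / total


def differential_activity(
    spa_norm: pd.DataFrame,
    group_a,
    group_b,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-subpathway two-sided Wilcoxon comparison of two sample groups.

    Returns a frame with the rank-sum ``p``, BH-adjusted ``p_adjusted``,
    ``direction`` (sign of median A minus median B) and a categorical
    ``call``: ``higher_in_A`` / ``higher_in_B`` / ``ns`` at level
    ``alpha`` on the raw p-value.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise InputError("groups overlap")
    missing = [s for s in group_a + group_b if s not in spa_norm.columns]
    if missing:
        raise InputError(f"unknown sample id(s): {missing[:5]}")
    rows = []
    for sub_id, row in spa_norm.iterrows():
        va, vb = row[group_a].to_numpy(), row[group_b].to_numpy()
        p = wilcoxon_rank_sum(va, vb)
        direction = int(np.sign(np.median(va) - np.median(vb)))
        rows.append((sub_id, direction, p))
    out = pd.DataFrame(rows, columns=["subpathway_id", "direction", "p"])
    out["p_adjusted"] = bh_adjust(out["p"].to_numpy())
    out["call"] = "ns"
    sig = out["p"] < alpha
    out.loc[sig & (out["direction"] > 0), "call"] = "higher_in_A"
    out.loc[sig & (out["direction"] < 0), "call"] = "higher_in_B"
    return out.set_index("subpathway_id")


def type_mean_correlation(spa_norm: pd.DataFrame, type_labels: pd.Series):
    """Pearson correlation of per-type mean activity vectors.

    ``type_labels`` maps sample id -> tumor type. Returns ``(r, p)``
    square frames; p-values are two-sided from the t distribution with
    (#subpathways - 2) degrees of freedom; the diagonal of ``r`` is 1.
    """
    type_labels = pd.Series(type_labels)
    types = sorted(type_labels.unique())
    if len(types) < 2:
        raise InputError("need >= 2 tumor types")
    if spa_norm.shape[0] < 3:
        raise InputError("need >= 3 subpathways for a correlation p-value")
    means = {}
    for t in types:
        samples = type_labels.index[type_labels == t]
        samples = [s for s in samples if s in spa_norm.columns]
        if not samples:
            raise InputError(f"tumor type {t!r} has no samples in the profile")
        means[t] = spa_norm[samples].mean(axis=1).to_numpy()
    r = pd.DataFrame(np.eye(len(types)), index=types, columns=types)
    p = pd.DataFrame(np.zeros((len(types), len(types))), index=types, columns=types)
    for t1, t2 in combinations(types, 2):
        res = sps.pearsonr(means[t1], means[t2])
        r.loc[t1, t2] = r.loc[t2, t1] = res.statistic
        p.loc[t1, t2] = p.loc[t2, t1] = res.pvalue
    return r, p


def signature_overlap(set_a, set_b, universe_size: int) -> float:
    """Upper-tail hypergeometric p for the overlap of two signatures."""
    set_a, set_b = frozenset(set_a), frozenset(set_b)
    if universe_size < len(set_a | set_b):
        raise InputError("universe smaller than the union of the two sets")
    inp = EnrichmentInput(
        m_g=universe_size, m_lnc=0,
        n_g=len(set_a), n_lnc=0,
        t_g=len(set_b), t_lnc=0,
        r_g=len(set_a & set_b), r_lnc=0,
    )
    return combined_hypergeometric(inp)


def enrich_subpathways(
    subpathways,
    significant_features,
    universe_genes,
    universe_lncrnas,
) -> pd.DataFrame:
    """Combined hypergeometric enrichment of every subpathway, with BH.

    The universe defaults to the measured features handed in (the only
    self-consistent choice when the input cohort varies); significant
    features outside the universe are ignored.
    """
    universe_genes = frozenset(universe_genes)
    universe_lncrnas = frozenset(universe_lncrnas)
    if universe_genes & universe_lncrnas:
        raise InputError("gene and lncRNA universes overlap")
    sig = frozenset(significant_features)
    sig_g = sig & universe_genes
    sig_l = sig & universe_lncrnas
    rows = []
    for sub in subpathways:
        t_g = sub.genes & universe_genes
        t_l = sub.lncrnas & universe_lncrnas
        inp = EnrichmentInput(
            m_g=len(universe_genes), m_lnc=len(universe_lncrnas),
            n_g=len(sig_g), n_lnc=len(sig_l),
            t_g=len(t_g), t_lnc=len(t_l),
            r_g=len(t_g & sig_g), r_lnc=len(t_l & sig_l),
        )
        rows.append((sub.subpathway_id, combined_hypergeometric(inp),
                     inp.t_g, inp.t_lnc, inp.r_g, inp.r_lnc))
    out = pd.DataFrame(
        rows, columns=["subpathway_id", "p", "t_g", "t_lnc", "r_g", "r_lnc"]
    ).set_index("subpathway_id")
    out["p_adjusted"] = bh_adjust(out["p"].to_numpy())
    return out
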