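"""Cohort-level tumor analyses over an activity profile.

Covers the three downstream analyses: hierarchical clustering of
samples or subpathways (uncentered correlation, complete linkage),
tumor-vs-normal stratification support, and the prognosis pipeline —
random equal train/test split, univariate Cox screening of subpathway
activities on the training half, signature selection at a Wald-p
threshold, K-means risk grouping on the testing half, and Kaplan-Meier
/ log-rank evaluation of the risk groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans

from subspa.errors import InputError
from subspa.stats import bh_adjust, signature_overlap

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------

def uncentered_correlation_distance(matrix: np.ndarray) -> np.ndarray:
    """Condensed distance vector d(x, y) = 1 - sum(xy)/sqrt(sum(x^2) sum(y^2)).

    The similarity is cosine-like, computed without mean-centering;
    all-zero vectors have no defined distance and are rejected.
    """
    x = np.asarray(matrix, dtype=float)
    norms = np.sqrt((x ** 2).sum(axis=1))
    if np.any(norms == 0):
        raise InputError("all-zero vector: uncentered correlation undefined")
    sim = (x @ x.T) / np.outer(norms, norms)
    np.clip(sim, -1.0, 1.0, out=sim)
    n = x.shape[0]
    iu = np.triu_indices(n, k=1)
    return 1.0 - sim[iu]


@dataclass(eq=False)
class ClusteringResult:
    linkage: np.ndarray       # scipy linkage matrix
    labels: list              # item labels in input (sorted) order
    leaf_order: list          # labels in dendrogram leaf order

    def cut(self, n_clusters: int) -> pd.Series:
        flat = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return pd.Series(flat, index=self.labels, name="cluster")


def hierarchical_cluster(profile: pd.DataFrame, axis: str = "samples") -> ClusteringResult:
    """Complete-linkage agglomeration under uncentered-correlation distance.

    ``axis`` selects whether samples (columns) or subpathways (rows) are
    clustered. Items are processed in sorted label order so ties in the
    merge heights resolve deterministically.
    """
    if axis not in ("samples", "subpathways"):
        raise InputError(f"axis must be 'samples' or 'subpathways', got {axis!r}")
    mat = profile.T if axis == "samples" else profile
    if mat.isna().any().any():
        raise InputError("profile contains missing values")
    if mat.shape[0] < 2:
        raise InputError("need >= 2 items to cluster")
    mat = mat.sort_index()
    dist = uncentered_correlation_distance(mat.to_numpy())
    link = hierarchy.linkage(dist, method="complete")
    order = hierarchy.leaves_list(link)
    labels = list(mat.index)
    return ClusteringResult(
        linkage=link, labels=labels, leaf_order=[labels[i] for i in order]
    )


def to_newick(result: ClusteringResult) -> str:
    """Serialize the dendrogram as a Newick string with branch heights."""
    tree = hierarchy.to_tree(result.linkage)

    def render(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{result.labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"


# ---------------------------------------------------------------------------
# Train/test split
# ---------------------------------------------------------------------------

def split_cohort(
    sample_ids,
    clinical: pd.DataFrame,
    seed: int,
    stratify_event: bool = False,
) -> tuple:
    """Random equal-sized train/test halves of the samples with survival data.

    Samples missing from the clinical table are excluded with a warning.
    With an odd count the training half receives the extra sample. With
    ``stratify_event`` the split balances event/censored status.
    """
    sample_ids = list(sample_ids)
    with_data = [s for s in sample_ids if s in clinical.index]
    dropped = len(sample_ids) - len(with_data)
    if dropped:
        warnings.warn(f"{dropped} sample(s) lack survival data and were excluded",
                      stacklevel=2)
    if len(with_data) < 4:
        raise InputError("need >= 4 samples with survival data to split")
    rng = np.random.default_rng(seed)

    def halve(ids):
        ids = list(ids)
        perm = rng.permutation(len(ids))
        n_train = (len(ids) + 1) // 2
        return ([ids[i] for i in perm[:n_train]], [ids[i] for i in perm[n_train:]])

    if stratify_event:
        train, test = [], []
        for flag in (1, 0):
            ids = [s for s in with_data if clinical.loc[s, "event"] == flag]
            if ids:
                tr, te = halve(ids)
                train += tr
                test += te
    else:
        train, test = halve(with_data)
    return sorted(train), sorted(test)


# ---------------------------------------------------------------------------
# Univariate Cox screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoxResult:
    subpathway_id: str
    coefficient: float
    hazard_ratio: float
    wald_p: float
    available: bool = True
    reason: str = ""


def univariate_cox(values: pd.Series, clinical: pd.DataFrame,
                   subpathway_id: str = "") -> CoxResult:
    """Proportional-hazards fit with one continuous covariate.

    Ties in event times are handled with the Efron approximation
    (lifelines' default); the p-value is the two-sided Wald test.
    Degenerate inputs (constant covariate, < 2 events) yield a result
    flagged unavailable instead of an estimate.
    """
    common = [s for s in values.index if s in clinical.index]
    if len(common) < 3:
        return CoxResult(subpathway_id, np.nan, np.nan, np.nan, False, "too few samples")
    frame = pd.DataFrame({
        "x": values[common].astype(float),
        "time": clinical.loc[common, "time"].astype(float),
        "event": clinical.loc[common, "event"].astype(int),
    })
    if frame["event"].sum() < 2:
        return CoxResult(subpathway_id, np.nan, np.nan, np.nan, False, "fewer than 2 events")
    if frame["x"].std(ddof=0) == 0:
        return CoxResult(subpathway_id, np.nan, np.nan, np.nan, False, "constant covariate")
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(frame, duration_col="time", event_col="event")
    except Exception as exc:  # convergence failure on pathological inputs
        return CoxResult(subpathway_id, np.nan, np.nan, np.nan, False, f"fit failed: {exc}")
    coef = float(fitter.params_["x"])
    return CoxResult(
        subpathway_id=subpathway_id,
        coefficient=coef,
        hazard_ratio=float(np.exp(coef)),
        wald_p=float(fitter.summary.loc["x", "p"]),
    )


def cox_screen(spa_norm: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Univariate Cox per subpathway row; flagged rows carry NaN estimates."""
    rows = []
    for sub_id, row in spa_norm.iterrows():
        res = univariate_cox(row, clinical, subpathway_id=sub_id)
        rows.append((sub_id, res.coefficient, res.hazard_ratio, res.wald_p,
                     res.available, res.reason))
    return pd.DataFrame(
        rows,
        columns=["subpathway_id", "coefficient", "hazard_ratio", "wald_p",
                 "available", "reason"],
    ).set_index("subpathway_id")


def select_signature(cox_results: pd.DataFrame, threshold: float = 0.01) -> list:
    """Subpathways with Wald p below the threshold (default 0.01)."""
    ok = cox_results["available"] & (cox_results["wald_p"] < threshold)
    return sorted(cox_results.index[ok])


# ---------------------------------------------------------------------------
# Risk groups and survival comparison
# ---------------------------------------------------------------------------

def kmeans_risk_groups(signature_profile: pd.DataFrame, k: int = 2,
                       seed: int = 0, n_init: int = 25) -> pd.Series:
    """Euclidean K-means over per-sample signature-activity vectors.

    Rows of ``signature_profile`` are signature subpathways; columns are
    samples. Labels are renumbered so group 1 is the cluster whose first
    (sorted) sample comes first — stable under a fixed seed.
    """
    if k < 1:
        raise InputError("k must be >= 1")
    samples = list(signature_profile.columns)
    if k > len(samples):
        raise InputError(f"k={k} exceeds sample count {len(samples)}")
    x = signature_profile.T.to_numpy()
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(x)
    # renumber clusters by order of first appearance over sorted samples
    order = {}
    for s in sorted(samples):
        lab = raw[samples.index(s)]
        if lab not in order:
            order[lab] = len(order) + 1
    return pd.Series([order[l] for l in raw], index=samples, name="risk_group")


@dataclass(eq=False)
class LogrankResult:
    statistic: float
    df: int
    p: float
    curves: dict  # group label -> survival-function DataFrame


def km_logrank(groups: pd.Series, clinical: pd.DataFrame) -> LogrankResult:
    """Kaplan-Meier curves per group and the k-group log-rank test."""
    common = [s for s in groups.index if s in clinical.index]
    groups = groups[common]
    counts = groups.value_counts()
    if len(counts) < 2:
        raise InputError("need >= 2 non-empty groups")
    time = clinical.loc[common, "time"].astype(float)
    event = clinical.loc[common, "event"].astype(int)
    res = multivariate_logrank_test(time, groups, event)
    curves = {}
    for label in sorted(counts.index):
        mask = groups == label
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask], label=str(label))
        curves[label] = kmf.survival_function_
    return LogrankResult(
        statistic=float(res.test_statistic),
        df=int(len(counts) - 1),
        p=float(res.p_value),
        curves=curves,
    )


# ---------------------------------------------------------------------------
# Full prognosis pipeline
# ---------------------------------------------------------------------------

def prognosis_pipeline(
    spa_norm: pd.DataFrame,
    clinical: pd.DataFrame,
    split_seed: int = 17,
    cox_p: float = 0.01,
    k_groups: int = 2,
    kmeans_seed: int = 0,
    stratify_event: bool = False,
    enrichment: pd.DataFrame | None = None,
    overlap_cutoffs: tuple = (0.01, 0.001, 0.0001),
) -> dict:
    """Train/test prognostic signature discovery over an activity profile.

    Splits the cohort into equal halves, screens every subpathway with
    univariate Cox on the training half, selects the signature at the
    Wald-p threshold, forms K-means risk groups on the testing half
    restricted to the signature, and evaluates them by log-rank. When an
    enrichment table (from :func:`subspa.stats.enrich_subpathways`) is
    supplied, the signature is compared against the enrichment-derived
    sets at each adjusted-p cutoff with an overlap hypergeometric test.

    Returns a JSON-serializable report.
    """
    usable = spa_norm.dropna(axis=0, how="any")
    dropped = sorted(set(spa_norm.index) - set(usable.index))
    if dropped:
        logger.warning("dropped %d subpathway(s) with missing activities", len(dropped))
    train, test = split_cohort(usable.columns, clinical, split_seed,
                               stratify_event=stratify_event)
    cox = cox_screen(usable[train], clinical)
    signature = select_signature(cox, threshold=cox_p)
    report = {
        "split_seed": int(split_seed),
        "n_train": len(train),
        "n_test": len(test),
        "train": train,
        "test": test,
        "cox_p_threshold": float(cox_p),
        "signature": signature,
        "signature_parents": sorted({s.rsplit("_", 1)[0] for s in signature}),
        "dropped_subpathways": dropped,
    }
    if enrichment is not None:
        universe = len(usable.index)
        overlaps = {}
        for cutoff in overlap_cutoffs:
            enriched = sorted(enrichment.index[enrichment["p_adjusted"] < cutoff])
            enriched = [e for e in enriched if e in usable.index]
            shared = sorted(set(signature) & set(enriched))
            if signature and enriched:
                p = signature_overlap(signature, enriched, universe)
            else:
                p = 1.0
            overlaps[str(cutoff)] = {
                "n_enriched": len(enriched),
                "n_overlap": len(shared),
                "overlap": shared,
                "p": float(p),
            }
        report["enrichment_overlap"] = overlaps
    if signature:
        groups = kmeans_risk_groups(usable.loc[signature, test], k=k_groups,
                                    seed=kmeans_seed)
        lr = km_logrank(groups, clinical)
        report["risk_groups"] = {s: int(g) for s, g in groups.sort_index().items()}
        report["logrank"] = {"statistic": lr.statistic, "df": lr.df, "p": lr.p}
    else:
        report["risk_groups"] = {}
        report["logrank"] = None
    return report
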