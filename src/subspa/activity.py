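"""Per-sample subpathway activity from merged gene + lncRNA expression.

The scoring scheme is a rank-exponential (FAIME-style) single-sample
statistic extended to lncRNA components. Within each sample the |N|
merged features are ranked ascending by expression (mid-ranks for
ties), each feature receives the weight

    w(r) = r * exp(sign * r / |N|)        (sign = +1 by default)

and the subpathway activity is the mean weight of the subpathway's
measured components minus the mean weight of all other measured
features (the complement). Activities are z-normalized per subpathway
across samples (sample standard deviation, n-1 denominator).

Both exponent signs are monotone non-decreasing in the rank over
r in [1, |N|], so order statistics downstream do not depend on the
choice; the positive sign is the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from subspa.errors import InputError
from subspa.mining import SubpathwayGraph
from subspa.pathway_io import validate_expression

logger = logging.getLogger(__name__)


@dataclass(eq=False)
class MergedExpression:
    """Gene rows stacked over lncRNA rows, restricted to common samples.

    The row index is the universe N of the weight formula.
    """

    data: pd.DataFrame
    gene_ids: list
    lnc_ids: list

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def samples(self) -> list:
        return list(self.data.columns)


@dataclass(eq=False)
class ActivityProfile:
    """Subpathways x samples activity matrices (raw sPA and z-scored).

    ``constant_rows`` lists subpathways whose raw activity did not vary
    across samples (their normalized row is all zero); ``skipped`` maps
    subpathways that could not be scored to the reason.
    """

    spa: pd.DataFrame
    spa_norm: pd.DataFrame
    row_mean: pd.Series
    row_sd: pd.Series
    constant_rows: list = field(default_factory=list)
    skipped: dict = field(default_factory=dict)
    unmeasured: dict = field(default_factory=dict)


def merge_profiles(gene_expr: pd.DataFrame, lnc_expr: pd.DataFrame) -> MergedExpression:
    """Concatenate gene and lncRNA matrices over their common samples."""
    validate_expression(gene_expr, "gene expression")
    validate_expression(lnc_expr, "lncRNA expression")
    common = [s for s in gene_expr.columns if s in set(lnc_expr.columns)]
    if not common:
        raise InputError("gene and lncRNA matrices share no samples")
    clash = set(gene_expr.index) & set(lnc_expr.index)
    if clash:
        raise InputError(f"feature id(s) {sorted(clash)[:5]} appear in both matrices")
    data = pd.concat([gene_expr[common], lnc_expr[common]], axis=0)
    return MergedExpression(
        data=data, gene_ids=list(gene_expr.index), lnc_ids=list(lnc_expr.index)
    )


def rank_weights(merged: MergedExpression, exponent_sign: int = +1) -> pd.DataFrame:
    """Rank-exponential weights w = r * exp(sign * r/|N|), per sample.

    Ranks are ascending in expression with mid-ranks for ties, so two
    features with identical expression in a sample always get identical
    weights and the score is invariant to their input order.
    """
    if exponent_sign not in (+1, -1):
        raise InputError(f"exponent_sign must be +1 or -1, got {exponent_sign}")
    if merged.n_features == 0:
        raise InputError("merged matrix has no features")
    ranks = merged.data.rank(axis=0, method="average")
    n = float(merged.n_features)
    return ranks * np.exp(exponent_sign * ranks / n)


def subpathway_activity(
    weights: pd.DataFrame,
    sub: SubpathwayGraph,
    min_components: int = 1,
) -> pd.Series | None:
    """sPA per sample: mean component weight minus mean complement weight.

    Subpathway components absent from the measured universe are ignored
    (their count is logged); if fewer than ``min_components`` remain the
    subpathway cannot be scored and ``None`` is returned. An empty
    complement (subpathway covering every measured feature) is an error.
    """
    measured = set(weights.index)
    wanted = sub.components
    comps = sorted(wanted & measured)
    n_unmeasured = len(wanted) - len(comps)
    if n_unmeasured:
        logger.info(
            "%s: %d of %d components not measured", sub.subpathway_id,
            n_unmeasured, len(wanted),
        )
    if len(comps) < max(min_components, 1):
        return None
    mask = weights.index.isin(wanted)
    if mask.all():
        raise InputError(
            f"{sub.subpathway_id}: complement is empty (subpathway covers all features)"
        )
    return weights.loc[comps].mean(axis=0) - weights.loc[~mask].mean(axis=0)


def normalize_activity(raw: pd.DataFrame) -> ActivityProfile:
    """Z-score each subpathway row across samples (n-1 denominator).

    Rows with zero variance are set to all-zero and flagged in
    ``constant_rows``; normalization over a single sample is undefined.
    """
    if raw.shape[1] < 2:
        raise InputError("normalization needs >= 2 samples")
    mean = raw.mean(axis=1)
    sd = raw.std(axis=1, ddof=1)
    constant = sd <= 0
    safe_sd = sd.where(~constant, 1.0)
    norm = raw.sub(mean, axis=0).div(safe_sd, axis=0)
    norm[constant] = 0.0
    constant_rows = list(raw.index[constant])
    if constant_rows:
        logger.warning("constant activity rows zeroed: %s", constant_rows)
    return ActivityProfile(
        spa=raw, spa_norm=norm, row_mean=mean, row_sd=sd, constant_rows=constant_rows
    )


def profile(
    merged: MergedExpression,
    subpathways: list,
    exponent_sign: int = +1,
    min_components: int = 1,
) -> ActivityProfile:
    """Batch driver: subpathways as rows, samples as columns.

    Unscoreable subpathways (no measured component) are excluded from
    the matrices and recorded in ``skipped``.
    """
    weights = rank_weights(merged, exponent_sign)
    rows, index, skipped, unmeasured = [], [], {}, {}
    measured = set(weights.index)
    for sub in subpathways:
        spa = subpathway_activity(weights, sub, min_components=min_components)
        if spa is None:
            skipped[sub.subpathway_id] = "no measured component"
            continue
        n_unmeasured = len(sub.components - measured)
        if n_unmeasured:
            unmeasured[sub.subpathway_id] = n_unmeasured
        rows.append(spa)
        index.append(sub.subpathway_id)
    if not rows:
        raise InputError("no subpathway could be scored against the merged matrix")
    raw = pd.DataFrame(rows, index=index, columns=merged.samples)
    prof = normalize_activity(raw)
    prof.skipped = skipped
    prof.unmeasured = unmeasured
    return prof
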