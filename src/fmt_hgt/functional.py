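"""COG functional grouping and PERMANOVA across timepoints.

COG single-letter categories are grouped into the four standard major
classes; a cluster annotated with several categories contributes one unit to
each (per-category accounting), and unannotated clusters form their own
"no classification" group. Functional composition across timepoints is
compared with PERMANOVA on Bray–Curtis dissimilarities of relative-abundance
vectors, with the permutation p using the +1 correction (minimum attainable
p = 1/(n_perm+1)).
"""

from __future__ import annotations

from itertools import permutations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

INFORMATION = set("ABJKL")
CELLULAR = set("DMNOTUVWYZ")
METABOLISM = set("CEFGHIPQ")
POORLY = set("RS")

COG_CLASS: dict[str, str] = {}
for _letters, _cls in (
    (INFORMATION, "information storage and processing"),
    (CELLULAR, "cellular processes and signaling"),
    (METABOLISM, "metabolism"),
    (POORLY, "poorly characterised"),
):
    for _l in _letters:
        COG_CLASS[_l] = _cls

NO_CLASSIFICATION = "no classification"


def classify_clusters(annotations: pd.DataFrame, clusters: Sequence[str]) -> pd.DataFrame:
    """Per-cluster (multi-valued) category and major-class assignment.

    Returns one row per (cluster, category); clusters with no annotation get
    a single row with empty category and class "no classification".
    """
    cats = dict(zip(annotations["cluster_id"], annotations["categories"].fillna("")))
    rows = []
    for cluster in clusters:
        letters = str(cats.get(cluster, "") or "")
        if not letters:
            rows.append({"cluster_id": cluster, "category": "", "major_class": NO_CLASSIFICATION})
            continue
        for letter in letters:
            if letter not in COG_CLASS:
                raise ValueError(f"unknown COG category letter {letter!r} for cluster {cluster}")
            rows.append({"cluster_id": cluster, "category": letter, "major_class": COG_CLASS[letter]})
    return pd.DataFrame(rows, columns=["cluster_id", "category", "major_class"])


def bray_curtis(x, y) -> float:
    """Bray–Curtis dissimilarity: 1 - 2 sum(min(x,y)) / (sum x + sum y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("Bray-Curtis requires nonnegative vectors")
    total = x.sum() + y.sum()
    if total == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / total)


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    """Pseudo-F from squared dissimilarities; d2 is the full n x n matrix."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    a = len(groups)
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(
    matrix: np.ndarray | pd.DataFrame,
    grouping: Sequence,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    method: Literal["bray_curtis", "precomputed"] = "bray_curtis",
    exhaustive: bool = False,
) -> dict:
    """One-way PERMANOVA on Bray–Curtis dissimilarities.

    ``matrix`` is samples x features (or a precomputed square distance
    matrix). Group labels are permuted; p = (1 + #{F* >= F}) / (1 + n_perm).
    With ``exhaustive=True`` every distinct label permutation is enumerated
    instead (feasible for small n) and p is the exact permutation p.
    """
    X = np.asarray(matrix, dtype=float)
    labels = np.asarray(list(grouping))
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("PERMANOVA requires at least two groups")
    if X.shape[0] != len(labels):
        raise ValueError("grouping length must match the number of rows")
    if method == "precomputed":
        dist = X
    else:
        dist = squareform(pdist(X, metric="braycurtis"))
    if not np.isfinite(dist).all():
        raise ValueError("distance matrix contains non-finite values (all-zero rows?)")
    if np.allclose(dist, 0):
        raise ValueError("degenerate distance matrix: all dissimilarities are zero")
    d2 = dist**2
    f_obs = _pseudo_f(d2, labels, groups)

    sizes = {g: int((labels == g).sum()) for g in groups}
    r2 = _r_squared(d2, labels, groups)

    if exhaustive:
        seen = set()
        hits = total = 0
        for perm in permutations(labels):
            if perm in seen:
                continue
            seen.add(perm)
            total += 1
            if _pseudo_f(d2, np.asarray(perm), groups) >= f_obs - 1e-12:
                hits += 1
        return {"pseudo_f": f_obs, "r2": r2, "p": hits / total,
                "n_perm": total, "group_sizes": sizes, "method": "exhaustive"}

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 0
    perm_labels = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(perm_labels)
        if _pseudo_f(d2, perm_labels, groups) >= f_obs - 1e-12:
            hits += 1
    return {"pseudo_f": f_obs, "r2": r2, "p": (1 + hits) / (1 + n_perm),
            "n_perm": n_perm, "group_sizes": sizes, "method": "permutation"}


def _r_squared(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    if ss_total == 0:
        return 0.0
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return float(1.0 - ss_within / ss_total)


def composition_rows(
    series: pd.DataFrame,
    classes: pd.DataFrame,
    level: Literal["class", "category"] = "class",
) -> pd.DataFrame:
    """Relative-abundance composition vectors, one row per HTGC x timepoint.

    ``series`` is the deduplicated abundance series (recipient_id, sex,
    cluster_id, timepoint, cpm); ``classes`` is the classify_clusters output.
    cpm is converted to relative abundance within each (sex, timepoint)
    cohort, then allocated to the cluster's categories (per-category
    accounting). Rows with zero abundance are dropped.
    """
    feature = "major_class" if level == "class" else "category"
    sub = series[series["cpm"] > 0].copy()
    if not len(sub):
        return pd.DataFrame()
    sub["rel"] = sub["cpm"] / sub.groupby(["sex", "timepoint"])["cpm"].transform("sum")
    merged = sub.merge(classes, on="cluster_id", how="left")
    merged[feature] = merged[feature].fillna(NO_CLASSIFICATION)
    wide = merged.pivot_table(
        index=["recipient_id", "sex", "cluster_id", "timepoint"],
        columns=feature,
        values="rel",
        aggfunc="sum",
        fill_value=0.0,
    ).reset_index()
    return wide


def compare_timepoints(
    series: pd.DataFrame,
    classes: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
    levels: Sequence[str] = ("class", "category"),
) -> pd.DataFrame:
    """PERMANOVA of functional composition across week 6/12/26, per sex, at
    the major-class and per-category levels. Timepoints with no observations
    are excluded. Returns one row per (sex, level)."""
    rows = []
    for level in levels:
        wide = composition_rows(series, classes, level=level)  # type: ignore[arg-type]
        if not len(wide):
            continue
        id_cols = ["recipient_id", "sex", "cluster_id", "timepoint"]
        feat_cols = [c for c in wide.columns if c not in id_cols]
        for sex, sub in wide.groupby("sex"):
            tp_counts = sub["timepoint"].value_counts()
            usable = tp_counts[tp_counts >= 2].index
            sub = sub[sub["timepoint"].isin(usable)]
            if sub["timepoint"].nunique() < 2:
                continue
            res = permanova(
                sub[feat_cols].to_numpy(), sub["timepoint"].to_numpy(),
                n_perm=n_perm, seed=seed,
            )
            rows.append(
                {
                    "sex": sex,
                    "level": level,
                    "pseudo_f": res["pseudo_f"],
                    "r2": res["r2"],
                    "p": res["p"],
                    "n_rows": len(sub),
                }
            )
    return pd.DataFrame(rows, columns=["sex", "level", "pseudo_f", "r2", "p", "n_rows"])
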