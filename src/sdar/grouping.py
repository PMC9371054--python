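"""Skill-group partitioning and LDA-coefficient relevance mapping.

Subjects are clustered into three groups (best / adequate / poor
performers) by k-means on a single classifier metric computed under the
Raw scenario.  Discriminative relevance of individual connectivity
links is read off the absolute LDA coefficients: normalized to [0, 1],
the three beta sub-band blocks merged element-wise by maximum (so the
map covers an unsplit mu block and one beta block, ``C*(C-1)`` values),
and summarized per group by column-wise maxima with a link threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from sklearn.cluster import KMeans

from .evaluation import lda_coefficients

__all__ = ["SkillPartition", "RelevanceMap", "kmeans_skill_groups",
           "relevance_from_lda", "group_relevance"]

GROUP_NAMES = ("GI", "GII", "GIII")


@dataclass
class SkillPartition:
    """Subjects assigned to ordered skill groups (GI best ... GIII worst)."""

    group_of: Dict[str, str]
    centroids: np.ndarray            # descending
    fitted_on: str = "raw"

    def members(self, group: str) -> List[str]:
        return [s for s, g in self.group_of.items() if g == group]


@dataclass
class RelevanceMap:
    """Normalized link relevance for one subject.

    ``per_band_weights`` has length ``4 * C(C-1)/2`` (band-major);
    ``merged_weights`` has length ``C(C-1)`` (mu block then max-merged
    beta block).
    """

    per_band_weights: np.ndarray
    merged_weights: np.ndarray
    pair_index: Sequence[Tuple[str, int, int]]
    link_threshold: float = 0.9


def kmeans_skill_groups(
    metric_per_subject: Dict[str, float],
    k: int = 3,
    seed: int = 0,
) -> SkillPartition:
    """Cluster subjects into ``k`` ordered skill groups by one metric.

    Runs k-means with multiple restarts on the 1-D metric values and
    relabels clusters by descending centroid, so GI holds the best
    performers.  Identical metrics across subjects (fewer distinct
    values than clusters) are rejected: a silent single-cluster result
    would corrupt every group-level summary downstream.
    """
    subjects = list(metric_per_subject)
    values = np.asarray([metric_per_subject[s] for s in subjects], float)
    if len(subjects) < k:
        raise ValueError(f"need at least {k} subjects, got {len(subjects)}")
    if np.unique(values).size < k:
        raise ValueError(
            "metric values are degenerate (fewer distinct values than "
            f"clusters): cannot form {k} skill groups")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw_labels = km.fit_predict(values[:, None])
    order = np.argsort(-km.cluster_centers_[:, 0], kind="stable")
    rank_of = {int(cluster): rank for rank, cluster in enumerate(order)}
    names = GROUP_NAMES if k == 3 else tuple(f"G{i+1}" for i in range(k))
    group_of = {s: names[rank_of[int(l)]] for s, l in zip(subjects, raw_labels)}
    centroids = km.cluster_centers_[order, 0]
    return SkillPartition(group_of=group_of, centroids=centroids,
                          fitted_on="raw")


def relevance_from_lda(model, pair_index: Sequence[Tuple[str, int, int]],
                       link_threshold: float = 0.9) -> RelevanceMap:
    """Relevance of each connectivity link from LDA coefficients.

    Takes the absolute coefficients (element-wise maximum across the
    class discriminants when more than two classes), min-max normalizes
    to [0, 1], then merges the three beta sub-band blocks by maximum.
    """
    coef = np.abs(lda_coefficients(model)).max(axis=0)
    n_feat = coef.size
    if len(pair_index) != n_feat:
        raise ValueError("pair_index length does not match coefficients")
    if n_feat % 4 != 0:
        raise ValueError("expected a 4-band feature vector")
    span = coef.max() - coef.min()
    if coef.max() == 0:
        warnings.warn("all-zero LDA coefficients; relevance map is zero",
                      RuntimeWarning)
        weights = np.zeros(n_feat)
    elif span == 0:
        weights = np.ones(n_feat)
    else:
        weights = (coef - coef.min()) / span
    n_pairs = n_feat // 4
    mu = weights[:n_pairs]
    beta = np.max(
        [weights[(b + 1) * n_pairs:(b + 2) * n_pairs] for b in range(3)],
        axis=0)
    merged = np.concatenate([mu, beta])
    return RelevanceMap(per_band_weights=weights, merged_weights=merged,
                        pair_index=list(pair_index),
                        link_threshold=link_threshold)


def group_relevance(
    maps: Dict[str, RelevanceMap],
    partition: SkillPartition,
    group: str,
    link_threshold: float = 0.9,
) -> Dict[str, object]:
    """Column-wise maxima of the group's stacked relevance vectors.

    Returns the per-link maxima and the set of links whose maximum
    exceeds ``link_threshold``.
    """
    members = [s for s in partition.members(group) if s in maps]
    if not members:
        raise ValueError(f"group {group!r} has no subjects with relevance maps")
    sizes = {maps[s].merged_weights.size for s in members}
    if len(sizes) != 1:
        raise ValueError("relevance maps have inconsistent dimensions")
    stacked = np.vstack([maps[s].merged_weights for s in members])
    maxima = stacked.max(axis=0)
    links = np.flatnonzero(maxima > link_threshold)
    return {
        "group": group,
        "subjects": members,
        "column_maxima": maxima,
        "links_above_threshold": links,
        "link_threshold": link_threshold,
    }


def plot_electrode_strength(positions: np.ndarray, strength: np.ndarray,
                            path: str, title: str = "") -> None:
    """Minimal top-view scalp scatter, electrodes colored by strength.

    Intended for quick visual inspection of relevance topographies;
    not a publication-grade interpolated topoplot.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    positions = np.asarray(positions)
    fig, ax = plt.subplots(figsize=(4, 4))
    sc = ax.scatter(positions[:, 0], positions[:, 1], c=strength,
                    cmap="viridis", s=120, edgecolors="k")
    circle = plt.Circle((0, 0), 1.0, fill=False, color="gray")
    ax.add_patch(circle)
    ax.set_aspect("equal")
    ax.set_axis_off()
    if title:
        ax.set_title(title)
    fig.colorbar(sc, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
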