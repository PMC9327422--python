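"""Cell-line validation of drug-response signatures.

Signatures derived from patient cohorts are tested in cell-line
proteomic/phosphoproteomic data by hierarchical clustering over the
signature features: a good signature separates drug-resistant cultures
from parental ones, and places early-resistance cultures (ligand-mediated)
closer to parental cells than late-resistance cultures (mutation-mediated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

GROUPS = ("parental", "early", "late", "resistant")


@dataclass
class CellLineDataset:
    """Feature x sample matrix of cell-line measurements with group labels.

    Groups label the resistance status of each culture: ``parental``
    (drug-naive), ``resistant`` (fully resistant), and optionally ``early``
    / ``late`` stages of acquired resistance.
    """

    values: pd.DataFrame  # index: feature ids, columns: sample ids
    groups: pd.Series  # index: sample ids -> group label

    def __post_init__(self) -> None:
        if not set(self.values.columns) == set(self.groups.index):
            raise ValueError("group labels must cover exactly the dataset samples")
        bad = set(self.groups) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    def subset_groups(self, keep: list[str]) -> "CellLineDataset":
        samples = [s for s in self.values.columns if self.groups[s] in keep]
        return CellLineDataset(
            values=self.values[samples], groups=self.groups[samples]
        )


@dataclass
class ClusterResult:
    """Dendrogram plus flat labels from cutting at ``k`` clusters."""

    linkage: np.ndarray
    labels: pd.Series  # sample id -> cluster label (1..k)
    samples: list[str]
    n_features_used: int
    n_features_dropped: int


def cluster_signature(
    data: CellLineDataset,
    signature,
    k: int = 2,
    linkage_method: str = "average",
) -> ClusterResult:
    """Cluster cell-line samples over signature features.

    Features are z-scored across samples; samples are clustered by
    average-linkage agglomerative clustering on Euclidean distance.
    Signature features absent from the data (e.g. transcripts when only
    proteins were measured) are dropped; fewer than two usable features is
    an error. Sample order is fixed by sorted sample id so the result does
    not depend on input column order.
    """
    import warnings

    wanted = _signature_feature_ids(signature)
    present = [f for f in wanted if f in data.values.index]
    dropped = len(wanted) - len(present)
    if dropped:
        warnings.warn(f"{dropped} signature features absent from cell-line data; dropped")
    if len(present) < 2:
        raise ValueError(
            f"need >= 2 signature features present in data, found {len(present)}"
        )
    samples = sorted(data.values.columns)
    sub = data.values.loc[present, samples]
    sd = sub.std(axis=1, ddof=0).replace(0.0, 1.0)
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    dist = pdist(z.T.to_numpy(), metric="euclidean")
    link = hierarchy.linkage(dist, method=linkage_method)
    flat = hierarchy.fcluster(link, t=k, criterion="maxclust")
    labels = pd.Series(flat, index=samples, name="cluster")
    return ClusterResult(
        linkage=link,
        labels=labels,
        samples=samples,
        n_features_used=len(present),
        n_features_dropped=dropped,
    )


def separation_score(cluster_labels, group_labels) -> float:
    """Adjusted Rand index between cluster assignment and known groups.

    1 for identical partitions (including the trivial single-cluster /
    single-group case), expectation 0 under random labeling.
    """
    a = np.asarray(cluster_labels)
    b = np.asarray(group_labels)
    if len(a) != len(b):
        raise ValueError("label vectors must have equal length")
    if len(set(a)) == 1 and len(set(b)) == 1:
        return 1.0
    return float(adjusted_rand_score(b, a))


@dataclass
class ProximityReport:
    """Mean cophenetic distances from parental to early/late groups."""

    d_parental_early: float
    d_parental_late: float
    early_closer: bool
    distances: dict = field(default_factory=dict)


def resistance_stage_proximity(data: CellLineDataset, signature, k: int = 2) -> ProximityReport:
    """Quantify whether early-resistance cultures sit nearer the parental
    cells than late-resistance cultures on the signature dendrogram.

    Uses mean cophenetic distance between group pairs from the
    :func:`cluster_signature` tree.
    """
    for g in ("parental", "early", "late"):
        if g not in set(data.groups):
            raise ValueError(f"group {g!r} missing from dataset")
    res = cluster_signature(data, signature, k=k)
    coph = squareform(hierarchy.cophenet(res.linkage))
    idx = {s: i for i, s in enumerate(res.samples)}

    def mean_dist(g1: str, g2: str) -> float:
        a = [idx[s] for s in res.samples if data.groups[s] == g1]
        b = [idx[s] for s in res.samples if data.groups[s] == g2]
        return float(np.mean([coph[i, j] for i in a for j in b]))

    d_pe = mean_dist("parental", "early")
    d_pl = mean_dist("parental", "late")
    return ProximityReport(
        d_parental_early=d_pe,
        d_parental_late=d_pl,
        early_closer=bool(d_pe < d_pl),
        distances={"parental-early": d_pe, "parental-late": d_pl,
                   "early-late": mean_dist("early", "late")},
    )


def to_newick(result: ClusterResult) -> str:
    """Serialize the dendrogram as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(result.linkage)

    def rec(node) -> str:
        if node.is_leaf():
            return result.samples[node.id]
        left, right = node.get_left(), node.get_right()
        ld = node.dist - left.dist
        rd = node.dist - right.dist
        return f"({rec(left)}:{ld:.6g},{rec(right)}:{rd:.6g})"

    return rec(tree) + ";"


def _signature_feature_ids(signature) -> list[str]:
    """Feature ids from a Signature, a list of (feature, modality, coef)
    tuples, or a plain list of ids."""
    if hasattr(signature, "features"):
        entries = signature.features
    else:
        entries = signature
    out = []
    for e in entries:
        if isinstance(e, str):
            out.append(e)
        else:
            out.append(e[0])
    # preserve order, drop duplicates
    seen = set()
    return [f for f in out if not (f in seen or seen.add(f))]
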