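"""Over-representation analysis of signatures and network nodes.

Gene-set enrichment is the upper-tail hypergeometric test: with a universe
of N genes of which K belong to a set, and n selected genes of which k hit
the set, p = P(X >= k) for X ~ Hypergeometric(N, K, n). P-values are
corrected across all tested sets by Benjamini-Hochberg; significance is
flagged at q < 0.01 by default.

Kinase over-representation treats each kinase's annotated substrate
phosphosites as a set within a site universe; since many sites carry no
kinase annotation at all, the fraction of unannotated selected sites is
reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection, KinaseSubstrateMap


@dataclass
class EnrichmentResult:
    """Per-set hypergeometric results, BH-adjusted, sorted by q then p."""

    table: pd.DataFrame  # columns: name, k, K, n, N, p, q, significant
    q_threshold: float = 0.01
    unannotated_fraction: float | None = None


def hypergeom_upper(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n); 1 when k = 0."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def randomized_null_pvalue(k: int, N: int, K: int, n: int, u: float) -> float:
    """Randomized (exact-null-uniform) version of the upper-tail
    hypergeometric p-value: P(X > k) + u * P(X = k) with u ~ U(0,1).

    The discrete p-value P(X >= k) is super-uniform under the null
    (P(p <= x) <= x), so its distribution cannot itself be tested against
    Uniform(0,1); the randomized version is exactly uniform and is the
    standard calibration diagnostic for discrete tests.
    """
    return float(stats.hypergeom.sf(k, N, K, n) + u * stats.hypergeom.pmf(k, N, K, n))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _finish(rows: list[dict], q_threshold: float) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["name", "k", "K", "n", "N", "p"])
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
        df["significant"] = df["q"] < q_threshold
        df = df.sort_values(["q", "p", "name"], kind="stable").reset_index(drop=True)
    else:
        df["q"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df


def enrich_sets(
    selected: list[str],
    sets: GeneSetCollection,
    universe: list[str],
    q_threshold: float = 0.01,
) -> EnrichmentResult:
    """Hypergeometric over-representation of ``selected`` genes in each
    gene set, against the measured universe.

    Selected members outside the universe are dropped with a warning;
    the universe is deduplicated. An empty selection yields an empty
    table, not an error.
    """
    uni = sorted(set(universe))
    uniset = set(uni)
    sel = sorted(set(selected))
    outside = [g for g in sel if g not in uniset]
    if outside:
        warnings.warn(f"{len(outside)} selected genes outside the universe; dropped")
        sel = [g for g in sel if g in uniset]
    N, n = len(uni), len(sel)
    rows = []
    if n:
        selset = set(sel)
        for name, members in sets:
            inset = set(members) & uniset
            K = len(inset)
            if K == 0:
                continue
            k = len(selset & inset)
            rows.append({"name": name, "k": k, "K": K, "n": n, "N": N,
                         "p": hypergeom_upper(k, N, K, n)})
    return EnrichmentResult(table=_finish(rows, q_threshold), q_threshold=q_threshold)


def enrich_kinases(
    selected_sites: list[str],
    ks: KinaseSubstrateMap,
    universe_sites: list[str],
    q_threshold: float = 0.01,
) -> EnrichmentResult:
    """Kinase over-representation among selected phosphosites.

    Each kinase's annotated substrate sites (restricted to the universe)
    form its set; unannotated sites count in the universe but match no
    kinase. Kinases with zero annotated sites in the universe are
    skipped. The fraction of selected sites with no kinase annotation is
    reported (sparse annotation limits the power of this test).
    """
    uni = sorted(set(universe_sites))
    uniset = set(uni)
    sel = sorted(set(selected_sites) & uniset)
    dropped = len(set(selected_sites)) - len(sel)
    if dropped:
        warnings.warn(f"{dropped} selected sites outside the site universe; dropped")
    N, n = len(uni), len(sel)
    annotated: dict[str, set] = {}
    for _i, row in ks.pairs.iterrows():
        if row["site"] in uniset:
            annotated.setdefault(row["kinase"], set()).add(row["site"])
    rows = []
    if n:
        selset = set(sel)
        for kinase in sorted(annotated):
            sites = annotated[kinase]
            K = len(sites)
            k = len(selset & sites)
            rows.append({"name": kinase, "k": k, "K": K, "n": n, "N": N,
                         "p": hypergeom_upper(k, N, K, n)})
    any_annotation = set().union(*annotated.values()) if annotated else set()
    unannot = (
        sum(1 for s in sel if s not in any_annotation) / n if n else float("nan")
    )
    return EnrichmentResult(
        table=_finish(rows, q_threshold),
        q_threshold=q_threshold,
        unannotated_fraction=unannot,
    )
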