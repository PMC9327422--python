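"""Drug/sample preparation: drug filtering, response binarization, and
cross-modality correlation summaries.

Drugs enter the modeling panel only if enough samples respond to them:
a drug is retained when at least ``max(ceil(min_fraction * n), min_count)``
of its ``n`` non-missing samples have AUC below the sensitivity threshold
(default 100). This yields a balanced response distribution for
regression. Spearman (average ranks for ties) is the correlation statistic
throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import DrugResponseTable, OmicsMatrix, site_parent_gene


@dataclass
class FilterConfig:
    """Sensitivity-based drug filter parameters."""

    auc_threshold: float = 100.0
    min_fraction: float = 0.10
    min_count: int = 2

    def __post_init__(self) -> None:
        if self.auc_threshold <= 0:
            raise ValueError("auc_threshold must be > 0")
        if not (0 < self.min_fraction < 1):
            raise ValueError("min_fraction must lie in (0, 1)")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


def required_sensitive_count(n_nonmissing: int, cfg: FilterConfig) -> int:
    """Sensitive-sample count a drug must reach to be retained."""
    return max(int(math.ceil(cfg.min_fraction * n_nonmissing)), cfg.min_count)


def filter_drugs(response: DrugResponseTable, cfg: FilterConfig | None = None) -> list[str]:
    """Drug ids (sorted) passing the sensitivity filter.

    ``n`` counts non-missing measurements per drug; drugs with zero
    non-missing values are excluded with a warning.
    """
    cfg = cfg or FilterConfig()
    if response.auc.empty:
        raise ValueError("response table is empty")
    retained = []
    for drug in response.drugs:
        row = response.auc.loc[drug]
        vals = row.dropna().to_numpy(dtype=float)
        if vals.size == 0:
            warnings.warn(f"drug {drug!r} has no non-missing AUC values; excluded")
            continue
        sensitive = int((vals < cfg.auc_threshold).sum())
        if sensitive >= required_sensitive_count(vals.size, cfg):
            retained.append(drug)
    return sorted(retained)


def binarize_response(auc, threshold: float = 100.0):
    """Binarize AUC: 1 = resistant (AUC >= threshold, ties resistant
    since sensitivity is defined strictly below threshold), 0 = sensitive.
    Missing values stay missing."""
    arr = pd.Series(np.asarray(auc, dtype=float))
    if isinstance(auc, pd.Series):
        arr.index = auc.index
    if np.isinf(arr.dropna()).any():
        raise ValueError("AUC values must be finite")
    out = arr.where(arr.isna(), (arr >= threshold).astype(float))
    return out if isinstance(auc, pd.Series) else out.to_numpy()


@dataclass
class CorrelationReport:
    """Spearman correlations between two modalities.

    ``per_feature`` has one row per matched feature (NaN where fewer than
    three complete pairs were available); ``pooled`` is the Spearman over
    all matched (feature, sample) pairs jointly.
    """

    per_feature: pd.DataFrame  # columns: feature_a, feature_b, spearman, n_pairs
    pooled: float
    pooled_n: int
    level: str


def _match_features(a: OmicsMatrix, b: OmicsMatrix) -> list[tuple[str, str]]:
    """Match features across modalities by gene id; phosphosites map to the
    parent protein via their id prefix."""

    def gene_key(m: OmicsMatrix, f: str) -> str:
        return site_parent_gene(f) if m.modality == "phosphosite" else f

    b_by_gene: dict[str, list[str]] = {}
    for f in b.features:
        b_by_gene.setdefault(gene_key(b, f), []).append(f)
    pairs = []
    for f in a.features:
        for g in b_by_gene.get(gene_key(a, f), []):
            pairs.append((f, g))
    return pairs


def modality_correlation(
    a: OmicsMatrix, b: OmicsMatrix, level: str = "pooled"
) -> CorrelationReport:
    """Spearman correlation between two omics matrices.

    ``level='per_feature'`` reports one correlation per matched feature
    across the shared samples; ``level='pooled'`` ranks all matched
    (feature, sample) pairs jointly, the statistic used for cohort-level
    mRNA-protein (~0.25) and site-protein (~0.15) coupling.
    """
    if level not in ("per_feature", "pooled"):
        raise ValueError("level must be 'per_feature' or 'pooled'")
    shared = [s for s in a.samples if s in set(b.samples)]
    if len(shared) < 3:
        raise ValueError("matrices share fewer than 3 samples")
    pairs = _match_features(a, b)
    rows = []
    xs, ys = [], []
    for fa, fb in pairs:
        va = a.values.loc[shared, fa].to_numpy(dtype=float)
        vb = b.values.loc[shared, fb].to_numpy(dtype=float)
        ok = ~(np.isnan(va) | np.isnan(vb))
        n_ok = int(ok.sum())
        if n_ok >= 3 and np.std(va[ok]) > 0 and np.std(vb[ok]) > 0:
            rho = float(stats.spearmanr(va[ok], vb[ok]).statistic)
        else:
            rho = float("nan")
        rows.append((fa, fb, rho, n_ok))
        xs.append(va[ok])
        ys.append(vb[ok])
    per_feature = pd.DataFrame(rows, columns=["feature_a", "feature_b", "spearman", "n_pairs"])
    if xs and sum(len(x) for x in xs) >= 3:
        all_x = np.concatenate(xs)
        all_y = np.concatenate(ys)
        pooled = float(stats.spearmanr(all_x, all_y).statistic)
        pooled_n = int(all_x.size)
    else:
        pooled, pooled_n = float("nan"), 0
    return CorrelationReport(per_feature=per_feature, pooled=pooled,
                             pooled_n=pooled_n, level=level)
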