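"""Sparse linear models of drug response under nested cross-validation.

For each drug the AUC vector ``y`` is regressed on standardized molecular
features ``X`` drawn from one or more modalities. Three penalized families
are supported, all with the elastic-net penalty

    P(beta) = lambda * [ (1 - a) * ||beta||_2^2 / 2 + a * ||beta||_1 ]

with unpenalized intercept. ``lasso`` fixes the mixing a = 1, ``elasticnet``
defaults to a = 0.5, and ``logistic`` models the binarized response
(resistant = 1) with a = 1 by default. Gaussian families minimize
(1/2n) * RSS + P(beta); logistic minimizes the average binomial deviance
plus the same penalty.

Model assessment is nested: an outer K-fold split (default K = 5, seeded;
stratified for logistic) measures held-out Spearman correlation between
predictions and observed response, while within each outer training set the
penalty level is chosen by leave-one-out cross-validation over a
50-point log-spaced path from the null-model threshold lambda_max down to
1e-3 * lambda_max, ties broken toward the sparser (larger-penalty) model.
Models whose refits select no features, or with an undefined fold score,
are excluded rather than scored.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet, LogisticRegression, enet_path

from .cohort import binarize_response
from .io_formats import MODALITIES, MultiOmicCohort, DrugResponseTable

FAMILIES = ("lasso", "elasticnet", "logistic")
DEFAULT_MIXING = {"lasso": 1.0, "elasticnet": 0.5, "logistic": 1.0}

#: the modality combinations the comparison sweeps: each modality alone,
#: transcript+protein, protein+phosphosite, and all four together
ALLOWED_COMBOS = (
    ("mutation",),
    ("transcript",),
    ("protein",),
    ("phosphosite",),
    ("transcript", "protein"),
    ("protein", "phosphosite"),
    ("mutation", "transcript", "protein", "phosphosite"),
)


class DegeneratePathError(ValueError):
    """The penalty path cannot be built (e.g. all-constant response)."""


class SingleClassError(ValueError):
    """Logistic fit requested on a single-class response."""


class EmptySignatureError(ValueError):
    """A full-data refit selected no features."""


@dataclass
class ModelSpec:
    """One (family, modality combination) model configuration."""

    family: str
    modalities: tuple[str, ...]
    mixing: float | None = None
    penalty_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        self.modalities = tuple(self.modalities)
        unknown = set(self.modalities) - set(MODALITIES)
        if unknown or not self.modalities:
            raise ValueError(f"invalid modalities {self.modalities}")
        if self.mixing is None:
            self.mixing = DEFAULT_MIXING[self.family]
        if self.family == "lasso" and self.mixing != 1.0:
            raise ValueError("lasso forces mixing a = 1")
        if not (0 < self.mixing <= 1):
            raise ValueError("mixing a must lie in (0, 1]")

    @property
    def label(self) -> str:
        return f"{self.family}:{'+'.join(self.modalities)}"


@dataclass
class CVConfig:
    """Nested cross-validation settings: K outer folds, leave-one-out
    inner penalty selection, Spearman held-out metric."""

    outer_k: int = 5
    seed: int = 0
    n_lambda: int = 50
    lambda_min_ratio: float = 1e-3

    def __post_init__(self) -> None:
        if self.outer_k < 2:
            raise ValueError("outer_k must be >= 2")


@dataclass
class FitResult:
    """A fitted model with nested-CV performance.

    ``excluded`` is set when any refit selected zero non-intercept features
    or a fold score was undefined; ``mean_score`` is present only for
    included models. ``coefficients`` and ``chosen_penalty`` come from the
    full-data refit (penalty selected by LOO on all samples).
    """

    coefficients: dict[str, float] = field(default_factory=dict)
    intercept: float = 0.0
    chosen_penalty: float | None = None
    fold_scores: list[float] = field(default_factory=list)
    fold_penalties: list[float] = field(default_factory=list)
    mean_score: float | None = None
    excluded: bool = False
    reason: str | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "coefficients": self.coefficients,
                    "intercept": self.intercept,
                    "chosen_penalty": self.chosen_penalty,
                    "fold_scores": self.fold_scores,
                    "fold_penalties": self.fold_penalties,
                    "mean_score": self.mean_score,
                    "excluded": self.excluded,
                    "reason": self.reason,
                },
                fh,
                indent=1,
            )


@dataclass
class Signature:
    """Nonzero features of a full-data refit for one drug."""

    drug: str
    spec: ModelSpec
    features: list[tuple[str, str, float]]  # (feature id, modality, coefficient)

    def __post_init__(self) -> None:
        if any(c == 0 for _f, _m, c in self.features):
            raise ValueError("signature coefficients must be nonzero")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "drug": self.drug,
                    "family": self.spec.family,
                    "modalities": list(self.spec.modalities),
                    "features": [list(f) for f in self.features],
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "Signature":
        with open(path) as fh:
            d = json.load(fh)
        spec = ModelSpec(family=d["family"], modalities=tuple(d["modalities"]))
        return cls(drug=d["drug"], spec=spec,
                   features=[tuple(f) for f in d["features"]])


# ---------------------------------------------------------------------------
# feature assembly


def assemble_features(
    cohort: MultiOmicCohort,
    modalities: tuple[str, ...],
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Concatenate and standardize the requested modalities into one
    feature matrix.

    Columns are named ``modality:feature`` so provenance survives model
    fitting. Each column is standardized to mean 0 and unit (population)
    variance over the modeled samples; constant columns are dropped with
    a warning.
    """
    for m in modalities:
        if m not in cohort:
            raise ValueError(f"modality {m!r} not present in cohort")
    if samples is None:
        samples = cohort.samples
    else:
        samples = [s for s in samples if s in set(cohort.samples)]
    if not samples:
        raise ValueError("empty sample intersection")
    blocks = []
    for m in modalities:
        block = cohort[m].values.loc[samples].copy()
        block.columns = [f"{m}:{f}" for f in block.columns]
        blocks.append(block)
    X = pd.concat(blocks, axis=1)
    sd = X.std(axis=0, ddof=0)
    constant = sd[sd == 0].index
    if len(constant):
        warnings.warn(f"dropping {len(constant)} constant feature columns")
        X = X.drop(columns=constant)
        sd = sd.drop(index=constant)
    return (X - X.mean(axis=0)) / sd


def split_column(col: str) -> tuple[str, str]:
    """Inverse of the ``modality:feature`` column naming."""
    modality, feature = col.split(":", 1)
    return modality, feature


# ---------------------------------------------------------------------------
# penalized fitting


def lambda_max(X: np.ndarray, y: np.ndarray, family: str, a: float) -> float:
    """Smallest penalty at which the fit is the null (intercept-only)
    model, from the KKT conditions at beta = 0."""
    n = len(y)
    if family == "logistic":
        pbar = y.mean()
        grad = 2.0 / n * np.abs(X.T @ (y - pbar))
    else:
        grad = np.abs(X.T @ (y - y.mean())) / n
    lmax = float(grad.max() / a)
    if lmax <= 0:
        raise DegeneratePathError("penalty path degenerate (constant response?)")
    return lmax


def default_path(lmax: float, n_lambda: int = 50, min_ratio: float = 1e-3) -> np.ndarray:
    return np.geomspace(lmax, lmax * min_ratio, n_lambda)


def fit_penalized(
    X: np.ndarray, y: np.ndarray, family: str, a: float, lam: float
) -> tuple[np.ndarray, float]:
    """Solve one penalized fit; returns (coefficients, intercept).

    Gaussian families use coordinate descent (lam = 0 falls back to least
    squares); logistic uses SAGA on the equivalent C = 2 / (n * lam)
    parameterization. Solutions satisfy the KKT conditions to ~1e-6.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if lam < 0:
        raise ValueError("penalty must be >= 0")
    if family == "logistic":
        classes = np.unique(y)
        if len(classes) < 2:
            raise SingleClassError("non-discretizable fold: single-class response")
        C = 2.0 / (n * lam) if lam > 0 else 1e12
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lr = LogisticRegression(
                C=C, l1_ratio=a, solver="saga", tol=1e-10, max_iter=200_000,
                random_state=0,
            ).fit(X, y)
        return lr.coef_[0].copy(), float(lr.intercept_[0])
    if lam == 0:
        Xi = np.column_stack([np.ones(n), X])
        beta, *_ = np.linalg.lstsq(Xi, y, rcond=None)
        return beta[1:], float(beta[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        en = ElasticNet(
            alpha=lam, l1_ratio=a, fit_intercept=True, tol=1e-12, max_iter=200_000
        ).fit(X, y)
    return en.coef_.copy(), float(en.intercept_)


def penalized_objective(
    X, y, family: str, a: float, lam: float, coef, intercept: float
) -> float:
    """The objective value the fit minimizes (for oracle comparisons)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    coef = np.asarray(coef, dtype=float)
    n = len(y)
    penalty = lam * ((1 - a) * (coef @ coef) / 2 + a * np.abs(coef).sum())
    eta = intercept + X @ coef
    if family == "logistic":
        # average binomial deviance: (2/n) sum [log(1 + e^eta) - y * eta]
        loss = 2.0 / n * float(np.sum(np.logaddexp(0.0, eta) - y * eta))
    else:
        loss = float(((y - eta) ** 2).sum()) / (2 * n)
    return loss + penalty


def kkt_residual(
    X, y, family: str, a: float, lam: float, coef, intercept: float
) -> float:
    """Max violation of the subgradient optimality conditions."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    coef = np.asarray(coef, dtype=float)
    n = len(y)
    eta = intercept + X @ coef
    if family == "logistic":
        p = 1.0 / (1.0 + np.exp(-eta))
        g = 2.0 / n * (X.T @ (p - y)) + lam * (1 - a) * coef
        g0 = 2.0 / n * float(np.sum(p - y))
    else:
        r = y - eta
        g = -(X.T @ r) / n + lam * (1 - a) * coef
        g0 = -float(r.mean())
    active = coef != 0
    res = np.where(
        active,
        np.abs(g + lam * a * np.sign(coef)),
        np.maximum(0.0, np.abs(g) - lam * a),
    )
    return float(max(res.max(initial=0.0), abs(g0)))


# ---------------------------------------------------------------------------
# leave-one-out penalty selection


def _loo_errors_gaussian(X, y, a, path) -> np.ndarray:
    """Mean LOO squared error per penalty on the path, via warm-started
    coordinate-descent paths on each leave-one-out training set."""
    n = len(y)
    errs = np.zeros((len(path), n))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xt, yt = X[mask], y[mask]
        xm = Xt.mean(axis=0)
        ym = yt.mean()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # selection-grade tolerance: the winning penalty is refit tightly
            _, coefs, _ = enet_path(
                Xt - xm, yt - ym, l1_ratio=a, alphas=path, tol=1e-5, max_iter=100_000
            )
        pred = (X[i] - xm) @ coefs + ym  # (n_lambda,)
        errs[:, i] = (pred - y[i]) ** 2
    return errs.mean(axis=1)


def _loo_errors_logistic(X, y, a, path, tol: float = 1e-6,
                         max_iter: int = 1500) -> np.ndarray:
    """Mean LOO binomial deviance per penalty.

    All n leave-one-out problems are solved jointly by accelerated
    proximal gradient (FISTA) on the average-deviance elastic-net
    objective, warm-started down the penalty path: the problems share X
    up to one excluded row, so their gradients differ only by a rank-one
    correction and vectorize. Splits whose training part collapses to a
    single class are skipped.
    """
    n, p = X.shape
    m = n - 1  # training size of each LOO problem
    usable = np.array([len(np.unique(y[np.arange(n) != i])) == 2 for i in range(n)])
    if not usable.any():
        raise SingleClassError("every leave-one-out split was single-class")
    # Lipschitz constant of the smooth part: (2/m) * (1/4) * ||X||_2^2
    sq_norm = float(np.linalg.norm(X, 2) ** 2)
    dev = np.full((len(path), n), np.nan)
    B = np.zeros((p, n))
    b0 = np.zeros(n)
    eps = 1e-12
    for k, lam in enumerate(path):
        L = 0.5 * sq_norm / m + lam * (1 - a) + 2.0 / m  # + intercept curvature
        step = 1.0 / L
        thresh = step * lam * a
        Z, z0 = B.copy(), b0.copy()
        t_mom = 1.0
        for it in range(max_iter):
            eta = X @ Z + z0  # (n samples, n problems)
            P = 1.0 / (1.0 + np.exp(-eta))
            R = P - y[:, None]
            np.fill_diagonal(R, 0.0)  # problem j excludes sample j
            grad_B = (2.0 / m) * (X.T @ R) + lam * (1 - a) * Z
            grad_b0 = (2.0 / m) * R.sum(axis=0)
            B_new = Z - step * grad_B
            B_new = np.sign(B_new) * np.maximum(np.abs(B_new) - thresh, 0.0)
            b0_new = z0 - step * grad_b0
            t_new = (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2)) / 2.0
            Z = B_new + (t_mom - 1.0) / t_new * (B_new - B)
            z0 = b0_new + (t_mom - 1.0) / t_new * (b0_new - b0)
            delta = max(
                np.abs(B_new - B).max(initial=0.0), np.abs(b0_new - b0).max()
            )
            B, b0, t_mom = B_new, b0_new, t_new
            if delta < tol * max(1.0, np.abs(B).max(initial=1.0)) and it > 2:
                break
        pj = 1.0 / (1.0 + np.exp(-(np.einsum("ij,ji->i", X, B) + b0)))
        pj = np.clip(pj, eps, 1 - eps)
        d = -2.0 * (y * np.log(pj) + (1 - y) * np.log(1 - pj))
        dev[k, usable] = d[usable]
    return np.nanmean(dev, axis=1)


def select_penalty_loo(
    X,
    y,
    family: str,
    a: float,
    path: np.ndarray | None = None,
    n_lambda: int = 50,
    min_ratio: float = 1e-3,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Penalty minimizing leave-one-out error over the path.

    Returns (lambda_star, path, loo_errors); ties break toward the larger
    penalty (sparser model) because the path is scanned in decreasing
    order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < 3:
        raise ValueError("need >= 3 training samples for LOO selection")
    if np.std(y) == 0:
        raise DegeneratePathError("penalty path degenerate: constant response")
    if path is None:
        if family == "logistic":
            # near-separable small-sample fits degenerate below ~1e-2*lmax
            min_ratio = max(min_ratio, 1e-2)
        path = default_path(lambda_max(X, y, family, a), n_lambda, min_ratio)
    path = np.sort(np.asarray(path, dtype=float))[::-1]
    if family == "logistic":
        errors = _loo_errors_logistic(X, y, a, path)
    else:
        errors = _loo_errors_gaussian(X, y, a, path)
    best = int(np.argmin(errors))  # first occurrence = largest penalty
    return float(path[best]), path, errors


# ---------------------------------------------------------------------------
# nested cross-validation


def _spearman(a, b) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(a, b).statistic
    return float(rho)


def _fold_seed(seed: int, tag: str) -> int:
    return (seed ^ zlib.crc32(tag.encode())) % (2**31)


def make_folds(
    n: int, k: int, seed: int, y_strata: np.ndarray | None = None
) -> list[np.ndarray]:
    """Seeded partition into k folds; optionally stratified by class so
    small binarized responses keep both classes in each training set."""
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    if y_strata is None:
        order = rng.permutation(n)
        for pos, idx in enumerate(order):
            folds[pos % k].append(int(idx))
    else:
        offset = 0
        for cls in np.unique(y_strata):
            members = np.flatnonzero(y_strata == cls)
            members = members[rng.permutation(len(members))]
            for pos, idx in enumerate(members):
                folds[(pos + offset) % k].append(int(idx))
            offset += len(members)
    return [np.array(sorted(f), dtype=int) for f in folds]


def evaluate_nested_cv(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    cv: CVConfig,
    fit_full: bool = True,
) -> FitResult:
    """Nested-CV assessment of one model.

    Outer folds are a seeded partition (stratified for logistic); within
    each outer training set the penalty is selected by LOO, the model is
    refit, and the held-out Spearman correlation between predictions and
    observations recorded (for logistic: between predicted probability of
    resistance and the observed label). If ``fit_full`` the penalty is also
    selected and refit on all samples to populate the coefficients.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{j}" for j in range(np.asarray(X).shape[1])
    ]
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    result = FitResult()
    if X.ndim != 2 or X.shape[0] != n:
        raise ValueError("X and y sample counts differ")
    if n < cv.outer_k:
        result.excluded = True
        result.reason = f"too few samples ({n}) for {cv.outer_k}-fold CV"
        return result
    a = spec.mixing
    strata = y if spec.family == "logistic" else None
    folds = make_folds(n, cv.outer_k, cv.seed, y_strata=strata)

    # every fold is evaluated (no early exit) so the defined fold scores
    # survive even when another fold triggers exclusion
    failures: list[str] = []
    for fold_idx, test in enumerate(folds):
        train = np.setdiff1d(np.arange(n), test)
        if len(test) < 2 or np.std(y[test]) == 0:
            failures.append(f"fold {fold_idx}: undefined score (too few or constant held-out y)")
            continue
        if spec.family == "logistic" and len(np.unique(y[train])) < 2:
            failures.append(f"fold {fold_idx}: single-class training set")
            continue
        try:
            lam, _, _ = select_penalty_loo(
                X[train], y[train], spec.family, a,
                path=spec.penalty_grid,
                n_lambda=cv.n_lambda, min_ratio=cv.lambda_min_ratio,
            )
            coef, b0 = fit_penalized(X[train], y[train], spec.family, a, lam)
        except (DegeneratePathError, SingleClassError) as exc:
            failures.append(f"fold {fold_idx}: {exc}")
            continue
        if np.count_nonzero(coef) == 0:
            failures.append(f"fold {fold_idx}: refit selected zero features")
            continue
        # for logistic the ranks of the linear predictor equal the ranks of
        # the predicted probability (monotone link), without saturation
        pred = b0 + X[test] @ coef
        score = _spearman(pred, y[test])
        if np.isnan(score):
            failures.append(f"fold {fold_idx}: undefined held-out correlation")
            continue
        result.fold_scores.append(score)
        result.fold_penalties.append(lam)

    if failures:
        result.excluded = True
        result.reason = "; ".join(failures)
        return result
    result.mean_score = float(np.mean(result.fold_scores))

    if fit_full:
        try:
            lam, _, _ = select_penalty_loo(
                X, y, spec.family, a,
                path=spec.penalty_grid,
                n_lambda=cv.n_lambda, min_ratio=cv.lambda_min_ratio,
            )
            coef, b0 = fit_penalized(X, y, spec.family, a, lam)
        except (DegeneratePathError, SingleClassError) as exc:
            result.excluded = True
            result.reason = f"full refit: {exc}"
            return result
        if np.count_nonzero(coef) == 0:
            result.excluded = True
            result.reason = "full refit selected zero features"
            return result
        result.chosen_penalty = lam
        result.intercept = b0
        result.coefficients = {
            names[j]: float(coef[j]) for j in np.flatnonzero(coef)
        }
    return result


def extract_signature(
    X: pd.DataFrame, y: np.ndarray, spec: ModelSpec, drug: str = "drug",
    cv: CVConfig | None = None,
) -> Signature:
    """Full-data signature: select the penalty by LOO on all samples,
    refit on all samples, return the nonzero features with modality tags."""
    cv = cv or CVConfig()
    lam, _, _ = select_penalty_loo(
        np.asarray(X, float), np.asarray(y, float), spec.family, spec.mixing,
        path=spec.penalty_grid, n_lambda=cv.n_lambda,
        min_ratio=cv.lambda_min_ratio,
    )
    coef, _b0 = fit_penalized(
        np.asarray(X, float), np.asarray(y, float), spec.family, spec.mixing, lam
    )
    nz = np.flatnonzero(coef)
    if nz.size == 0:
        raise EmptySignatureError(f"no features selected for {drug} at lambda={lam:g}")
    names = list(X.columns)
    features = []
    for j in nz:
        modality, feature = split_column(names[j])
        features.append((feature, modality, float(coef[j])))
    return Signature(drug=drug, spec=spec, features=features)


# ---------------------------------------------------------------------------
# model comparison sweep


def compare_models(
    cohort: MultiOmicCohort,
    response: DrugResponseTable,
    drugs: list[str],
    specs: list[ModelSpec],
    cv: CVConfig,
    auc_threshold: float = 100.0,
) -> pd.DataFrame:
    """One nested-CV evaluation per (drug, spec); excluded models appear
    flagged, never silently dropped.

    Samples missing the drug's AUC are dropped for that drug. Fold
    partitions are seeded per drug (shared across specs so families and
    modality combinations are compared on identical splits).
    """
    rows = []
    for drug in drugs:
        yrow = response.auc.loc[drug]
        samples = [s for s in cohort.samples if s in yrow.index and not np.isnan(yrow[s])]
        for spec in specs:
            fold_cv = CVConfig(
                outer_k=cv.outer_k,
                seed=_fold_seed(cv.seed, drug),
                n_lambda=cv.n_lambda,
                lambda_min_ratio=cv.lambda_min_ratio,
            )
            y = yrow[samples].to_numpy(dtype=float)
            if spec.family == "logistic":
                y = binarize_response(y, threshold=auc_threshold)
            try:
                X = assemble_features(cohort, spec.modalities, samples=samples)
                fit = evaluate_nested_cv(X, y, spec, fold_cv, fit_full=False)
            except (ValueError,) as exc:
                fit = FitResult(excluded=True, reason=str(exc))
            rows.append(
                {
                    "drug": drug,
                    "family": spec.family,
                    "modalities": "+".join(spec.modalities),
                    "mean_score": fit.mean_score,
                    "fold_scores": json.dumps(fit.fold_scores),
                    "excluded": fit.excluded,
                    "reason": fit.reason,
                    "n_samples": len(samples),
                }
            )
    return pd.DataFrame(rows)


def summarize_comparison(table: pd.DataFrame) -> dict[str, pd.Series]:
    """Median mean_score by family and by modality combination over
    included models (the comparison the performance figure reports)."""
    ok = table.loc[~table["excluded"]]
    return {
        "by_family": ok.groupby("family")["mean_score"].median(),
        "by_modalities": ok.groupby("modalities")["mean_score"].median(),
    }
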