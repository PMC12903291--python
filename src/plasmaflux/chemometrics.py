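"""Untargeted metabolome chemometrics: filtering, PCA, OPLS-DA, VIP, SDMs.

Implements the discriminant-analysis arm of a two-group plasma
metabolomics comparison: within-group missingness filtering, half-minimum
imputation, PCA overview, orthogonal projections to latent structures
discriminant analysis (OPLS-DA) with cross-validated Q2 and label
permutation validation, VIP scoring, and selection of significantly
differential metabolites (SDMs) by the joint VIP > 1 and t-test P < 0.05
rule.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA as _SkPCA
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "METABOLITE_CLASSES",
    "IntensityMatrix",
    "PcaResult",
    "OPLSDA",
    "OPLSDAResults",
    "PermutationResult",
    "filter_missing",
    "impute_missing",
    "pca",
    "fit_oplsda",
    "compute_vip",
    "permutation_test",
    "select_sdms",
    "class_summary",
]

#: Controlled vocabulary of metabolite classes used for class summaries.
METABOLITE_CLASSES = (
    "amino acids",
    "bile acids",
    "FFA",
    "LPA",
    "LPC",
    "LPE",
    "MG",
    "nucleotides",
    "organic acid",
    "PA",
    "PC",
    "PE",
    "sugars",
    "other",
)


@dataclass
class IntensityMatrix:
    """Sample x metabolite intensity matrix with group and class labels.

    ``values`` holds nonnegative intensities with NaN marking missing
    peaks; ``groups`` maps each sample to one of exactly two group labels;
    ``classes`` maps each metabolite to a class from
    :data:`METABOLITE_CLASSES`.  ``group_order`` fixes which label is the
    reference ("low") group for fold changes and y-encoding.
    """

    values: pd.DataFrame
    groups: pd.Series
    classes: pd.Series
    group_order: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.groups = pd.Series(self.groups).reindex(self.values.index)
        self.classes = pd.Series(self.classes).reindex(self.values.columns)
        levels = pd.unique(self.groups)
        if len(levels) != 2:
            raise ValueError(f"exactly two groups required, found {list(levels)}")
        if self.group_order is None:
            self.group_order = tuple(sorted(levels))
        if set(self.group_order) != set(levels):
            raise ValueError("group_order labels do not match the group column")
        counts = self.groups.value_counts()
        if counts.min() < 2:
            raise ValueError("each group needs >= 2 samples")
        unknown = set(self.classes.dropna()) - set(METABOLITE_CLASSES)
        if unknown:
            raise ValueError(f"unknown metabolite class label(s): {sorted(unknown)}")
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy() < 0).any():
                raise ValueError("intensities must be nonnegative")

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def is_complete(self) -> bool:
        return not self.values.isna().any().any()

    def y(self) -> np.ndarray:
        """Class labels encoded -1 (reference/low) and +1 (other/high)."""
        low, high = self.group_order
        return np.where(self.groups.to_numpy() == low, -1.0, 1.0)

    def subset(self, metabolites: Sequence[str]) -> "IntensityMatrix":
        return IntensityMatrix(
            self.values[list(metabolites)],
            self.groups,
            self.classes.reindex(list(metabolites)),
            self.group_order,
        )

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, matrix_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        """Write intensities (samples in rows, empty cell = missing) plus
        a JSON sidecar with groups, classes and group order."""
        matrix_path = Path(matrix_path)
        self.values.to_csv(matrix_path, sep="\t", na_rep="")
        sidecar = Path(sidecar_path) if sidecar_path else matrix_path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "groups": self.groups.to_dict(),
                    "classes": self.classes.to_dict(),
                    "group_order": list(self.group_order),
                },
                indent=2,
            )
        )

    @classmethod
    def from_tsv(cls, matrix_path: str | Path, sidecar_path: str | Path | None = None) -> "IntensityMatrix":
        matrix_path = Path(matrix_path)
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        sidecar = Path(sidecar_path) if sidecar_path else matrix_path.with_suffix(".json")
        meta = json.loads(sidecar.read_text())
        return cls(
            values,
            pd.Series(meta["groups"]),
            pd.Series(meta["classes"]),
            tuple(meta["group_order"]),
        )


# ---------------------------------------------------------------------------
# filtering / imputation
# ---------------------------------------------------------------------------

def filter_missing(
    matrix: IntensityMatrix,
    max_missing_frac: float = 0.5,
    mode: str = "all",
) -> IntensityMatrix:
    """Remove metabolites by within-group missingness.

    With ``mode="all"`` (default) a metabolite is removed iff its missing
    fraction strictly exceeds ``max_missing_frac`` in *every* group — a
    peak observed well in one group is biologically informative and kept.
    ``mode="any"`` removes it when any single group exceeds the threshold.
    Samples are never removed; removed ids are logged.
    """
    if not 0 <= max_missing_frac < 1:
        raise ValueError(f"max_missing_frac must be in [0, 1), got {max_missing_frac}")
    if mode not in ("all", "any"):
        raise ValueError(f"mode must be 'all' or 'any', got {mode!r}")
    frac = matrix.missing_mask.groupby(matrix.groups, observed=True).mean()
    exceeds = frac > max_missing_frac
    drop = exceeds.all(axis=0) if mode == "all" else exceeds.any(axis=0)
    removed = list(drop.index[drop])
    if removed:
        logger.info("filter_missing removed %d metabolite(s): %s", len(removed), removed)
    keep = [m for m in matrix.metabolite_ids if m not in set(removed)]
    return matrix.subset(keep)


def impute_missing(matrix: IntensityMatrix, method: str = "half_min") -> IntensityMatrix:
    """Replace missing intensities: half the observed per-metabolite
    minimum (default), the minimum itself, or zero."""
    if method not in ("half_min", "min", "zero"):
        raise ValueError(f"unknown imputation method {method!r}")
    values = matrix.values.copy()
    all_missing = values.columns[values.isna().all()]
    if len(all_missing):
        raise ValueError(
            f"metabolite(s) with no observed value: {list(all_missing)}; "
            "run filter_missing first"
        )
    if method == "zero":
        fill = pd.Series(0.0, index=values.columns)
    else:
        fill = values.min(axis=0, skipna=True)
        if method == "half_min":
            fill = fill / 2.0
    values = values.fillna(fill)
    return IntensityMatrix(values, matrix.groups, matrix.classes, matrix.group_order)


# ---------------------------------------------------------------------------
# scaling and PCA
# ---------------------------------------------------------------------------

def _scale_matrix(X: np.ndarray, scaling: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center and scale columns: 'uv' (unit variance), 'pareto', 'none'."""
    if scaling not in ("uv", "pareto", "none"):
        raise ValueError(f"unknown scaling {scaling!r}")
    center = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)  # constant columns pass through
    if scaling == "uv":
        scale = sd
    elif scaling == "pareto":
        scale = np.sqrt(sd)
    else:
        scale = np.ones_like(sd)
    return (X - center) / scale, center, scale


@dataclass
class PcaResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_fraction: np.ndarray


def pca(matrix: IntensityMatrix, n_components: int = 2, scaling: str = "uv") -> PcaResult:
    """Centered (and optionally scaled) PCA by SVD.

    Component sign is fixed so the largest-magnitude loading of each
    component is positive, making score plots reproducible.
    """
    if not matrix.is_complete:
        raise ValueError("PCA requires a complete matrix; impute first")
    max_nc = min(matrix.n_samples - 1, matrix.n_metabolites)
    if n_components > max_nc:
        raise ValueError(f"n_components={n_components} exceeds max {max_nc}")
    X, _, _ = _scale_matrix(matrix.values.to_numpy(), scaling)
    sk = _SkPCA(n_components=n_components, svd_solver="full")
    scores = sk.fit_transform(X)
    loadings = sk.components_.T  # metabolites x components, orthonormal columns
    for a in range(n_components):
        j = np.argmax(np.abs(loadings[:, a]))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
            scores[:, a] *= -1
    comp_names = [f"PC{a + 1}" for a in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.sample_ids, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=matrix.metabolite_ids, columns=comp_names),
        explained_variance_fraction=sk.explained_variance_ratio_.copy(),
    )


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------

def _opls_fit_arrays(
    X: np.ndarray, y: np.ndarray, n_orth: int
) -> dict[str, np.ndarray | float]:
    """Core OPLS on pre-scaled X and centered y (single response).

    Per orthogonal component: PLS weight w = X'y/|X'y|, score t = Xw,
    loading p = X't/t't; the y-orthogonal part of p (minus its projection
    on w) is the orthogonal weight; X is deflated by the orthogonal
    component.  A one-component PLS on the filtered X gives the predictive
    scores.
    """
    Xf = X.copy()
    W_o, T_o, P_o = [], [], []
    for _ in range(n_orth):
        w = Xf.T @ y
        w /= np.linalg.norm(w)
        t = Xf @ w
        p = Xf.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:  # no orthogonal variation left
            break
        w_o /= norm
        t_o = Xf @ w_o
        p_o = Xf.T @ t_o / (t_o @ t_o)
        Xf -= np.outer(t_o, p_o)
        W_o.append(w_o)
        T_o.append(t_o)
        P_o.append(p_o)

    w = Xf.T @ y
    w /= np.linalg.norm(w)
    t_p = Xf @ w
    p_p = Xf.T @ t_p / (t_p @ t_p)
    q = (y @ t_p) / (t_p @ t_p)

    ss_x = float((X**2).sum())
    ss_x_model = float((t_p @ t_p) * (p_p @ p_p)) + sum(
        float((t @ t) * (p @ p)) for t, p in zip(T_o, P_o)
    )
    return {
        "w": w,
        "t_p": t_p,
        "p_p": p_p,
        "q": q,
        "W_o": np.array(W_o).T if W_o else np.zeros((X.shape[1], 0)),
        "T_o": np.array(T_o).T if T_o else np.zeros((X.shape[0], 0)),
        "P_o": np.array(P_o).T if P_o else np.zeros((X.shape[1], 0)),
        "r2x": min(ss_x_model / ss_x, 1.0) if ss_x > 0 else 0.0,
    }


def _opls_predict(model: dict, Xnew: np.ndarray) -> np.ndarray:
    """Predict centered y for pre-scaled new samples."""
    Xf = Xnew.copy()
    W_o, P_o = model["W_o"], model["P_o"]
    for a in range(W_o.shape[1]):
        t_o = Xf @ W_o[:, a]
        Xf -= np.outer(t_o, P_o[:, a])
    return (Xf @ model["w"]) * model["q"]


@dataclass
class OPLSDAResults:
    """Fitted OPLS-DA model: scores, loadings, fit statistics and VIP.

    ``r2y`` is the fraction of (centered) class-label variance explained
    on the training data; ``q2`` its 1 - PRESS/SS analogue from stratified
    k-fold cross-validation in which the entire scaling + filter + fit is
    re-estimated per fold.  ``q2 <= r2y`` on the data the model was
    trained on; a large gap flags overfitting.
    """

    t_p: pd.Series
    weights: pd.Series
    loadings_p: pd.Series
    q: float
    t_orth: pd.DataFrame
    w_orth: pd.DataFrame
    p_orth: pd.DataFrame
    r2x: float
    r2y: float
    q2: float
    n_orth: int
    scaling: str
    cv_folds: int
    cv_seed: int
    group_order: tuple[str, str]
    _center: np.ndarray = field(repr=False, default=None)
    _scale: np.ndarray = field(repr=False, default=None)

    def vip(self) -> pd.Series:
        return compute_vip(self)

    def summary(self) -> str:
        low, high = self.group_order
        lines = [
            "OPLS-DA results",
            "=" * 46,
            f"groups: {low} (-1) vs {high} (+1)",
            f"scaling: {self.scaling}   orthogonal components: {self.n_orth}",
            f"R2X = {self.r2x:.4f}",
            f"R2Y = {self.r2y:.4f}",
            f"Q2  = {self.q2:.4f}  ({self.cv_folds}-fold stratified CV, seed {self.cv_seed})",
            "-" * 46,
            "top VIP metabolites:",
        ]
        top = self.vip().sort_values(ascending=False).head(10)
        for met, v in top.items():
            lines.append(f"  {met:<30}{v:>8.3f}")
        return "\n".join(lines)


class OPLSDA:
    """Two-group OPLS-DA model for an intensity matrix.

    Parameters
    ----------
    matrix : IntensityMatrix
        Complete (imputed) two-group matrix.
    n_orth : int
        Number of y-orthogonal components to strip (default 1, the
        standard for a binary discriminant model).
    scaling : {'uv', 'pareto', 'none'}
        Column scaling applied after mean-centering; re-estimated inside
        every cross-validation training fold.
    cv_folds, cv_seed :
        Stratified k-fold settings for Q2.
    """

    def __init__(
        self,
        matrix: IntensityMatrix,
        n_orth: int = 1,
        scaling: str = "uv",
        cv_folds: int = 7,
        cv_seed: int = 0,
    ) -> None:
        if not matrix.is_complete:
            raise ValueError("OPLS-DA requires a complete matrix; impute first")
        if matrix.n_samples < cv_folds:
            raise ValueError(
                f"cv_folds={cv_folds} exceeds n_samples={matrix.n_samples}"
            )
        if n_orth >= matrix.n_samples - 2:
            raise ValueError("n_orth must be < n_samples - 2")
        self.matrix = matrix
        self.n_orth = int(n_orth)
        self.scaling = scaling
        min_group = int(matrix.groups.value_counts().min())
        if cv_folds > min_group:
            # stratified CV needs at least one member of each class per fold
            logger.info(
                "cv_folds=%d capped at the smaller group size %d", cv_folds, min_group
            )
            cv_folds = min_group
        self.cv_folds = int(cv_folds)
        self.cv_seed = int(cv_seed)

    def _fit_arrays(self, X_raw: np.ndarray, y_raw: np.ndarray) -> tuple[dict, np.ndarray, np.ndarray, float]:
        Xs, center, scale = _scale_matrix(X_raw, self.scaling)
        y_mean = y_raw.mean()
        yc = y_raw - y_mean
        model = _opls_fit_arrays(Xs, yc, self.n_orth)
        return model, center, scale, y_mean

    def fit(self) -> OPLSDAResults:
        X_raw = self.matrix.values.to_numpy()
        y_raw = self.matrix.y()
        model, center, scale, y_mean = self._fit_arrays(X_raw, y_raw)
        yc = y_raw - y_mean
        y_hat = _opls_predict(model, (X_raw - center) / scale)
        ss_tot = float(yc @ yc)
        r2y = 1.0 - float((yc - y_hat) @ (yc - y_hat)) / ss_tot

        press = 0.0
        skf = StratifiedKFold(
            n_splits=self.cv_folds, shuffle=True, random_state=self.cv_seed
        )
        for train, test in skf.split(X_raw, y_raw):
            m, c, s, ym = self._fit_arrays(X_raw[train], y_raw[train])
            pred = _opls_predict(m, (X_raw[test] - c) / s) + ym
            press += float(((y_raw[test] - pred) ** 2).sum())
        # PRESS compared against deviation from the full-data mean
        q2 = 1.0 - press / float(((y_raw - y_mean) ** 2).sum())

        mets = self.matrix.metabolite_ids
        samples = self.matrix.sample_ids
        o_names = [f"o{a + 1}" for a in range(model["T_o"].shape[1])]
        return OPLSDAResults(
            t_p=pd.Series(model["t_p"], index=samples, name="t_p"),
            weights=pd.Series(model["w"], index=mets, name="w"),
            loadings_p=pd.Series(model["p_p"], index=mets, name="p_p"),
            q=float(model["q"]),
            t_orth=pd.DataFrame(model["T_o"], index=samples, columns=o_names),
            w_orth=pd.DataFrame(model["W_o"], index=mets, columns=o_names),
            p_orth=pd.DataFrame(model["P_o"], index=mets, columns=o_names),
            r2x=float(model["r2x"]),
            r2y=float(r2y),
            q2=float(q2),
            n_orth=self.n_orth,
            scaling=self.scaling,
            cv_folds=self.cv_folds,
            cv_seed=self.cv_seed,
            group_order=self.matrix.group_order,
            _center=center,
            _scale=scale,
        )


def fit_oplsda(
    matrix: IntensityMatrix,
    n_orth: int = 1,
    scaling: str = "uv",
    cv_folds: int = 7,
    cv_seed: int = 0,
) -> OPLSDAResults:
    """Convenience wrapper: ``OPLSDA(matrix, ...).fit()``."""
    return OPLSDA(matrix, n_orth=n_orth, scaling=scaling, cv_folds=cv_folds, cv_seed=cv_seed).fit()


def compute_vip(results: OPLSDAResults) -> pd.Series:
    """Variable importance in projection over the predictive component.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja/|w_a|)^2 / sum_a SSY_a ) with p the
    number of variables; for the single predictive component this reduces
    to sqrt(p) * |w_j| / |w|, and mean(VIP^2) = 1 exactly.
    """
    w = results.weights.to_numpy()
    p_var = w.size
    norm2 = float(w @ w)
    if norm2 == 0:
        raise ValueError("model has zero predictive weights; was it fitted?")
    vip = np.sqrt(p_var * (w**2) / norm2)
    return pd.Series(vip, index=results.weights.index, name="VIP")


@dataclass
class PermutationResult:
    """Label-permutation null distribution for R2Y and Q2."""

    n_permutations: int
    permuted_r2y: np.ndarray
    permuted_q2: np.ndarray
    observed_r2y: float
    observed_q2: float
    p_r2y: float
    p_q2: float
    seed: int


def permutation_test(
    matrix: IntensityMatrix,
    n_orth: int = 1,
    scaling: str = "uv",
    cv_folds: int = 7,
    cv_seed: int = 0,
    n_permutations: int = 200,
    seed: int = 0,
) -> PermutationResult:
    """Permutation validation of an OPLS-DA model.

    Group labels are shuffled and the full model (including the Q2
    cross-validation) refitted per permutation.  Empirical p-values use
    the add-one correction (1 + #{perm >= obs}) / (n + 1), which keeps
    them valid (conservative) under the null.
    """
    if n_permutations < 20:
        warnings.warn(
            f"n_permutations={n_permutations} < 20: empirical p resolution is poor",
            stacklevel=2,
        )
    observed = fit_oplsda(matrix, n_orth, scaling, cv_folds, cv_seed)
    rng = np.random.default_rng(seed)
    r2y_null = np.empty(n_permutations)
    q2_null = np.empty(n_permutations)
    groups = matrix.groups.to_numpy()
    for i in range(n_permutations):
        perm = pd.Series(rng.permutation(groups), index=matrix.sample_ids)
        shuffled = IntensityMatrix(
            matrix.values, perm, matrix.classes, matrix.group_order
        )
        res = fit_oplsda(shuffled, n_orth, scaling, cv_folds, cv_seed)
        r2y_null[i] = res.r2y
        q2_null[i] = res.q2
    p_r2y = (1 + int((r2y_null >= observed.r2y).sum())) / (n_permutations + 1)
    p_q2 = (1 + int((q2_null >= observed.q2).sum())) / (n_permutations + 1)
    return PermutationResult(
        n_permutations=n_permutations,
        permuted_r2y=r2y_null,
        permuted_q2=q2_null,
        observed_r2y=observed.r2y,
        observed_q2=observed.q2,
        p_r2y=p_r2y,
        p_q2=p_q2,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# SDM selection and class summary
# ---------------------------------------------------------------------------

def select_sdms(
    matrix: IntensityMatrix,
    vip: pd.Series,
    vip_threshold: float = 1.0,
    p_threshold: float = 0.05,
    log_scale: bool = True,
) -> pd.DataFrame:
    """Select significantly differential metabolites (SDMs).

    Per metabolite: a pooled two-sided t-test between groups on log2
    intensities (raw scale with ``log_scale=False``) and the log2 fold
    change high-over-low.  Selected iff VIP strictly > ``vip_threshold``
    AND p strictly < ``p_threshold``.  Returns a DataFrame indexed by
    metabolite, sorted by VIP descending, with columns
    ``vip, p_value, log2_fc, direction, selected``.
    """
    if list(vip.index) != matrix.metabolite_ids:
        if set(vip.index) != set(matrix.metabolite_ids):
            raise ValueError("VIP vector is not aligned with the matrix metabolites")
        vip = vip.reindex(matrix.metabolite_ids)
    if not matrix.is_complete:
        raise ValueError("select_sdms requires a complete matrix; impute first")
    low, high = matrix.group_order
    X = matrix.values.to_numpy()
    if log_scale:
        X = np.log2(np.maximum(X, np.finfo(float).tiny))
    mask_low = (matrix.groups == low).to_numpy()
    a, b = X[~mask_low], X[mask_low]  # high, low
    t, p = stats.ttest_ind(a, b, axis=0)
    log2_fc = a.mean(axis=0) - b.mean(axis=0)
    if not log_scale:
        with np.errstate(divide="ignore", invalid="ignore"):
            log2_fc = np.log2(a.mean(axis=0) / b.mean(axis=0))
    table = pd.DataFrame(
        {
            "vip": vip.to_numpy(),
            "p_value": p,
            "log2_fc": log2_fc,
            "direction": np.where(log2_fc > 0, "up", "down"),
            "selected": (vip.to_numpy() > vip_threshold) & (p < p_threshold),
        },
        index=matrix.metabolite_ids,
    )
    table.index.name = "metabolite"
    return table.sort_values("vip", ascending=False)


def class_summary(
    sdm_table: pd.DataFrame, matrix: IntensityMatrix
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class up/down SDM counts and the z-scored SDM submatrix.

    Returns ``(counts, zscores)``: counts indexed by metabolite class with
    columns up/down/total; zscores is the selected-metabolite submatrix
    z-scored per metabolite (mean 0, sd 1 across samples) with metabolites
    ordered by class — the heatmap substrate.  An empty selection yields
    empty frames.
    """
    selected = sdm_table.index[sdm_table["selected"]]
    if len(selected) == 0:
        return (
            pd.DataFrame(columns=["up", "down", "total"]),
            pd.DataFrame(index=matrix.sample_ids),
        )
    cls = matrix.classes.reindex(selected).fillna("other")
    dir_ = sdm_table.loc[selected, "direction"]
    counts = (
        pd.crosstab(cls, dir_)
        .reindex(columns=["up", "down"], fill_value=0)
        .astype(int)
    )
    counts["total"] = counts.sum(axis=1)
    counts.index.name = "class"

    order = cls.sort_values(kind="stable").index
    sub = matrix.values[order]
    z = (sub - sub.mean(axis=0)) / sub.std(axis=0, ddof=1)
    return counts, z
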