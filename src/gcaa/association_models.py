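"""Statistical battery linking evolutionary rate to composition and GC.

Per-gene-family Pearson correlations between gene GC percent and Ka,
principal-component regression of Ka on the 20 amino-acid composition
fractions (with the first component checked against GC content), ridge
regression with bootstrap selection of contributing amino acids, and the
pairwise correlations within the amino-acid feature table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold
from statsmodels.api import OLS, add_constant
from statsmodels.stats.multitest import multipletests

from .features import AA_ORDER, AAFeatureTable, default_feature_table

MIN_FAMILY_ROWS = 8  # "more than seven homologous genes"
COMPOSITION_COLS = [f"f_{aa}" for aa in AA_ORDER]


def correlate(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson R and two-sided p (t-distribution, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant input")
    res = stats.pearsonr(x, y)
    # never report p as exactly 0: clamp underflow to the smallest positive float
    return float(res.statistic), max(float(res.pvalue), np.nextafter(0.0, 1.0))


@dataclass
class GeneFamilyMatrix:
    """One gene family: homolog rows with composition, GC percent, and Ka.

    ``data`` columns: f_<aa> for the 20 composition fractions, gc_percent,
    ka (NaN = flagged missing; such rows are excluded from fits).
    """

    gene_name: str
    data: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in (*COMPOSITION_COLS, "gc_percent", "ka") if c not in self.data.columns]
        if missing:
            raise ValueError(f"family {self.gene_name}: missing columns {missing}")

    @property
    def fit_data(self) -> pd.DataFrame:
        return self.data.dropna(subset=["ka"])


def gene_gc_ka_table(
    families: Sequence[GeneFamilyMatrix],
    min_rows: int = MIN_FAMILY_ROWS,
) -> pd.DataFrame:
    """Per-family Pearson correlation of GC percent with Ka.

    Families with fewer than ``min_rows`` homologs with defined Ka are
    skipped with a warning. Benjamini–Hochberg q-values accompany the raw
    p-values.
    """
    if not families:
        raise ValueError("no families supplied")
    rows = []
    for fam in families:
        d = fam.fit_data
        if len(d) < min_rows:
            warnings.warn(
                f"family {fam.gene_name}: {len(d)} usable homologs < {min_rows}, skipped"
            )
            continue
        r, p = correlate(d["gc_percent"], d["ka"])
        rows.append({"gene_name": fam.gene_name, "n": len(d), "r": r, "p": p})
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    return table


@dataclass(frozen=True)
class PcrSummary:
    gene_name: str
    n_components: int
    r_squared: float
    component_coefficients: tuple[float, ...]
    component_pvalues: tuple[float, ...]
    pc1_loadings: tuple[float, ...]
    pc1_gc_correlation: float
    pc1_gc_pvalue: float
    pc1_positive_aas: frozenset[str]
    pc1_negative_aas: frozenset[str]


def pca_regression(
    family: GeneFamilyMatrix,
    n_components: int = 6,
    standardize: bool = False,
    loading_threshold: float | None = None,
) -> PcrSummary:
    """OLS of Ka on the leading principal components of composition.

    Compositions are centered (optionally standardized); components come
    from SVD with the sign convention that each component's largest-magnitude
    loading is positive. PC1 scores are correlated against gene GC percent.
    Amino acids enter the positive/negative PC1 sets when their |loading|
    exceeds ``loading_threshold`` (default 1/sqrt(20), the flat-loading
    magnitude).
    """
    d = family.fit_data
    if len(d) < n_components + 2:
        raise ValueError(
            f"family {family.gene_name}: {len(d)} rows < n_components + 2"
        )
    X = d[COMPOSITION_COLS].to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    if standardize:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    rank = np.linalg.matrix_rank(Xc)
    k = n_components
    if rank < n_components:
        warnings.warn(
            f"family {family.gene_name}: rank {rank} < {n_components}, fitting on rank"
        )
        k = rank
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = vt[:k]
    # sign convention: largest-|loading| entry positive per component
    for i in range(k):
        j = np.argmax(np.abs(loadings[i]))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
    scores = Xc @ loadings.T
    fit = OLS(d["ka"].to_numpy(dtype=float), add_constant(scores)).fit()
    pc1 = loadings[0]
    thr = loading_threshold if loading_threshold is not None else 1.0 / np.sqrt(len(AA_ORDER))
    pos = frozenset(aa for aa, w in zip(AA_ORDER, pc1) if w > thr)
    neg = frozenset(aa for aa, w in zip(AA_ORDER, pc1) if w < -thr)
    r_gc, p_gc = correlate(scores[:, 0], d["gc_percent"].to_numpy(dtype=float))
    return PcrSummary(
        gene_name=family.gene_name,
        n_components=k,
        r_squared=float(fit.rsquared),
        component_coefficients=tuple(float(c) for c in fit.params[1:]),
        component_pvalues=tuple(float(p) for p in fit.pvalues[1:]),
        pc1_loadings=tuple(float(w) for w in pc1),
        pc1_gc_correlation=r_gc,
        pc1_gc_pvalue=p_gc,
        pc1_positive_aas=pos,
        pc1_negative_aas=neg,
    )


@dataclass(frozen=True)
class RidgeSummary:
    gene_name: str
    alpha: float
    r_squared: float
    coefficients: tuple[float, ...]  # standardized scale, canonical aa order
    selected_positive: frozenset[str]
    selected_negative: frozenset[str]


def ridge_fit(
    family: GeneFamilyMatrix,
    alpha_grid: Sequence[float] | None = None,
    n_folds: int = 5,
    n_perm: int = 500,
    fwer: float = 0.05,
    seed: int = 0,
) -> RidgeSummary:
    """Ridge regression of Ka on standardized compositions.

    The penalty is chosen by k-fold cross-validated mean squared error over
    ``alpha_grid``. Amino acids are called contributing when their
    standardized coefficient magnitude exceeds the ``1 - fwer`` quantile of
    the max-|coefficient| null distribution obtained by refitting on
    permuted responses (a max-statistic permutation test, which controls the
    family-wise false-selection rate across the 20 predictors).
    """
    d = family.fit_data
    if len(d) < 10:
        raise ValueError(f"family {family.gene_name}: ridge needs >= 10 rows")
    if alpha_grid is None:
        alpha_grid = np.logspace(-4, 2, 25)
    X = d[COMPOSITION_COLS].to_numpy(dtype=float)
    y = d["ka"].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [aa for aa, k_ in zip(AA_ORDER, keep) if not k_]
        warnings.warn(f"family {family.gene_name}: constant predictors dropped: {dropped}")
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    rng = np.random.default_rng(seed)
    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    best_alpha, best_mse = None, np.inf
    for alpha in alpha_grid:
        mse = 0.0
        for tr, te in cv.split(Xs):
            model = Ridge(alpha=alpha).fit(Xs[tr], y[tr])
            resid = y[te] - model.predict(Xs[te])
            mse += float(resid @ resid)
        if mse < best_mse:
            best_alpha, best_mse = float(alpha), mse
    model = Ridge(alpha=best_alpha).fit(Xs, y)
    r2 = float(model.score(Xs, y))
    null_max = np.empty(n_perm)
    for b in range(n_perm):
        null_max[b] = np.max(
            np.abs(Ridge(alpha=best_alpha).fit(Xs, rng.permutation(y)).coef_)
        )
    threshold = float(np.quantile(null_max, 1 - fwer))
    kept_aas = [aa for aa, k_ in zip(AA_ORDER, keep) if k_]
    coefs = dict(zip(kept_aas, model.coef_))
    pos = frozenset(aa for aa, c in zip(kept_aas, model.coef_) if c > threshold)
    neg = frozenset(aa for aa, c in zip(kept_aas, model.coef_) if c < -threshold)
    full_coefs = tuple(float(coefs.get(aa, 0.0)) for aa in AA_ORDER)
    return RidgeSummary(
        gene_name=family.gene_name,
        alpha=best_alpha,
        r_squared=r2,
        coefficients=full_coefs,
        selected_positive=pos,
        selected_negative=neg,
    )


@dataclass(frozen=True)
class FeatureTableTests:
    correlations: pd.DataFrame  # columns: feature_a, feature_b, r, p
    cost_contrast_t: float
    cost_contrast_p: float
    mean_cost_gc_rich: float
    mean_cost_at_rich: float


def feature_table_tests(table: AAFeatureTable | None = None) -> FeatureTableTests:
    """All pairwise feature correlations plus the group cost contrast.

    The contrast is a Welch t-test of synthesis cost for GC-rich
    (gc_class == 2) versus AT-rich (gc_class == 0) amino acids.
    """
    if table is None:
        table = default_feature_table()
    feats = ("gc_class", "recruit_order", "cost", "mol_weight")
    rows = []
    for i, fa in enumerate(feats):
        for fb in feats[i + 1 :]:
            r, p = correlate(table.vector(fa), table.vector(fb))
            rows.append({"feature_a": fa, "feature_b": fb, "r": r, "p": p})
    rich = [table.value(aa, "cost") for aa in sorted(table.group("gc_rich"))]
    at = [table.value(aa, "cost") for aa in sorted(table.group("at_rich"))]
    res = stats.ttest_ind(rich, at, equal_var=False)
    return FeatureTableTests(
        correlations=pd.DataFrame(rows),
        cost_contrast_t=float(res.statistic),
        cost_contrast_p=float(res.pvalue),
        mean_cost_gc_rich=float(np.mean(rich)),
        mean_cost_at_rich=float(np.mean(at)),
    )
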