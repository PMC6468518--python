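"""Associate gene mutation status with intratumor heterogeneity.

Three layers, mirroring a pan-cancer driver-of-ITH discovery:

1. A binary sample × gene mutation matrix (presence/absence, which removes
   the bias a hypermutated gene would otherwise introduce through its
   mutation multiplicity).
2. Pathway-level association: genes are collapsed into 17 broad functional
   categories (epigenetic modifiers, genome integrity, RTK signaling, ...)
   and heterogeneity is regressed on all category indicators jointly, per
   cancer type, with Benjamini–Hochberg adjustment of the coefficient
   p-values within each model.
3. Gene-level driver discovery by LASSO: an L1 path over a descending
   penalty grid records the order in which genes enter the model (their
   relative importance), the penalty is chosen by cross-validated explained
   variance, and a model counts as significant when its R² exceeds zero by
   more than one standard deviation (estimated across CV folds).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources as _resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import lasso_path
from sklearn.model_selection import KFold
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from ithkit.variant_io import SampleVariantSet

logger = logging.getLogger(__name__)

#: The 17 pathway categories used for the category-level models.
PATHWAY_CATEGORIES = (
    "epigenetic modifiers",
    "transcription factors/regulators",
    "genome integrity",
    "RTK signaling",
    "cell cycle",
    "MAPK signaling",
    "PI(3)K signaling",
    "TGF-beta signaling",
    "Wnt/beta-catenin signaling",
    "proteolysis",
    "splicing",
    "HIPPO signaling",
    "metabolism",
    "NFE2L",
    "protein phosphatase",
    "ribosome",
    "TOR",
)


@dataclass
class MutationMatrix:
    """Binary sample × gene (or sample × category) presence/absence matrix."""

    data: pd.DataFrame                 # index: sample ids; columns: gene ids
    cancer_types: pd.Series            # index: sample ids

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate gene ids")
        vals = self.data.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("matrix entries must be binary")
        self.cancer_types = self.cancer_types.reindex(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, cancer_type: str) -> "MutationMatrix":
        mask = self.cancer_types == cancer_type
        return MutationMatrix(self.data.loc[mask], self.cancer_types[mask])


def build_mutation_matrix(
    sets: Iterable[SampleVariantSet],
    gene_universe: Sequence[str] | None = None,
    class_policy: str = "all",
) -> MutationMatrix:
    """Binarize per-sample variant calls into a sample × gene matrix.

    ``entry(s, g) = 1`` iff sample *s* carries at least one retained variant
    in gene *g*; mutation multiplicity is collapsed to 1. Variants with an
    empty gene symbol are skipped (their count is logged). ``class_policy``
    is ``"all"`` (every variant) or ``"snv"`` (SNVs only).
    """
    if class_policy not in ("all", "snv"):
        raise ValueError(f"unknown class_policy {class_policy!r}")
    sample_ids: list[str] = []
    ctypes: dict[str, str] = {}
    hits: dict[str, set[str]] = {}
    n_no_gene = 0
    for s in sets:
        sample_ids.append(s.sample_id)
        ctypes[s.sample_id] = s.cancer_type
        genes = hits.setdefault(s.sample_id, set())
        for v in s:
            if class_policy == "snv" and v.variant_class != "SNV":
                continue
            if not v.gene:
                n_no_gene += 1
                continue
            genes.add(v.gene)
    if n_no_gene:
        logger.info("skipped %d variant(s) without a gene symbol", n_no_gene)
    if gene_universe is None:
        universe = sorted(set().union(*hits.values())) if hits else []
    else:
        universe = list(dict.fromkeys(gene_universe))
    if not universe:
        raise ValueError("empty gene universe: no annotated variants retained")
    data = pd.DataFrame(
        [[1 if g in hits[s] else 0 for g in universe] for s in sample_ids],
        index=pd.Index(sample_ids, name="sample_id"),
        columns=universe,
        dtype=np.int8,
    )
    return MutationMatrix(data, pd.Series(ctypes, name="cancer_type"))


def load_category_map(path) -> dict[str, str]:
    """Load a gene→category table (TSV: ``gene<TAB>category``)."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["gene", "category"], header=None, dtype=str)
    # tolerate a header row
    if df.iloc[0]["gene"].lower() == "gene":
        df = df.iloc[1:]
    dup = df["gene"].duplicated()
    if dup.any():
        raise ValueError(f"gene(s) mapped to more than one category: "
                         f"{sorted(df['gene'][dup])[:5]}")
    return dict(zip(df["gene"], df["category"]))


def default_category_map() -> dict[str, str]:
    """The bundled 17-pathway gene membership table (editable TSV resource)."""
    ref = _resources.files("ithkit") / "resources" / "pathway_categories.tsv"
    with _resources.as_file(ref) as p:
        return load_category_map(p)


def collapse_to_categories(
    matrix: MutationMatrix,
    cmap: Mapping[str, str],
) -> MutationMatrix:
    """Collapse a gene matrix to categories by logical OR over member genes.

    ``entry(s, c) = 1`` iff any gene of category *c* is mutated in *s*.
    Genes absent from the map are dropped (their count is logged). Only
    categories with at least one mapped gene appear as columns.
    """
    if not cmap:
        raise ValueError("empty category map")
    mapped = [g for g in matrix.gene_ids if g in cmap]
    dropped = len(matrix.gene_ids) - len(mapped)
    if dropped:
        logger.info("dropped %d gene(s) absent from the category map", dropped)
    cats = sorted({cmap[g] for g in mapped})
    out = pd.DataFrame(0, index=matrix.data.index, columns=cats, dtype=np.int8)
    for g in mapped:
        c = cmap[g]
        out[c] = out[c] | matrix.data[g]
    return MutationMatrix(out, matrix.cancer_types)


@dataclass
class LinearModelResult:
    """Joint OLS of heterogeneity on category indicators for one cancer type."""

    cancer_type: str
    coefficients: dict[str, float | None]
    p_values: dict[str, float | None]
    adjusted_p: dict[str, float | None]
    r_squared: float
    model_p: float
    n: int
    dropped: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cats = list(self.coefficients)
        return pd.DataFrame({
            "cancer_type": self.cancer_type,
            "category": cats,
            "coefficient": [self.coefficients[c] for c in cats],
            "p_value": [self.p_values[c] for c in cats],
            "adjusted_p": [self.adjusted_p[c] for c in cats],
        })


def fit_category_model(
    cat_matrix: MutationMatrix,
    ith: pd.Series,
    cancer_type: str = "",
) -> LinearModelResult:
    """OLS of heterogeneity on all category indicators jointly.

    Samples with undefined heterogeneity are excluded. Constant (all-0 or
    all-1) columns are dropped with a warning and reported with undefined
    (None) coefficients — never zero. Benjamini–Hochberg adjustment is
    applied across the coefficient p-values of this one model.
    """
    ith = ith.reindex(cat_matrix.data.index)
    mask = ith.notna()
    X = cat_matrix.data.loc[mask].astype(float)
    y = ith[mask].astype(float)
    n = len(y)
    if n < X.shape[1] + 2:
        raise ValueError(
            f"need at least {X.shape[1] + 2} samples with defined ITH, got {n}"
        )
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        warnings.warn(
            f"dropping constant category column(s): {constant}", stacklevel=2
        )
    kept = [c for c in X.columns if c not in constant]
    model = sm.OLS(y.to_numpy(), sm.add_constant(X[kept].to_numpy())).fit()
    raw = dict(zip(kept, model.pvalues[1:]))
    adj = dict(zip(kept, multipletests(list(raw.values()), method="fdr_bh")[1])) \
        if kept else {}
    coefs = dict(zip(kept, model.params[1:]))
    all_cols = list(cat_matrix.data.columns)
    return LinearModelResult(
        cancer_type=cancer_type,
        coefficients={c: coefs.get(c) for c in all_cols},
        p_values={c: raw.get(c) for c in all_cols},
        adjusted_p={c: adj.get(c) for c in all_cols},
        r_squared=float(model.rsquared),
        model_p=float(model.f_pvalue),
        n=n,
        dropped=constant,
    )


@dataclass
class LassoResult:
    """LASSO driver fit: entry order, optimal-penalty coefficients, CV R²."""

    genes: list[str]                    # selected at the optimal penalty,
                                        # ordered by path entry
    entry_ranks: dict[str, int]         # 1-based, permutation of 1..k
    coefficients: dict[str, float]      # at the optimal penalty (standardized X)
    intercept: float
    r_squared: float                    # mean CV explained variance
    r_squared_sd: float                 # dispersion across folds
    significant: bool                   # r_squared − sd > 0
    penalty_grid: np.ndarray
    penalty: float
    feature_means: dict[str, float] = field(default_factory=dict)
    feature_sds: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene": self.genes,
            "entry_rank": [self.entry_ranks[g] for g in self.genes],
            "coefficient": [self.coefficients[g] for g in self.genes],
        })


def _penalty_grid(X: np.ndarray, y: np.ndarray, n_alphas: int = 100,
                  eps: float = 1e-3) -> np.ndarray:
    """Descending log-spaced grid from the smallest all-zero penalty down to
    ``eps`` times it."""
    n = X.shape[0]
    yc = y - y.mean()
    alpha_max = np.max(np.abs(X.T @ yc)) / n
    if alpha_max <= 0:
        alpha_max = 1e-3
    return np.logspace(np.log10(alpha_max), np.log10(alpha_max * eps), n_alphas)


def fit_lasso_drivers(
    matrix: MutationMatrix,
    ith: pd.Series,
    folds: int = 10,
    seed: int = 0,
    min_mutated: int = 2,
    n_alphas: int = 100,
) -> LassoResult:
    """L1-penalized regression of heterogeneity on standardized gene indicators.

    Genes mutated in fewer than ``min_mutated`` samples are dropped first
    (single-sample indicators produce unstable artifacts). The coefficient
    path is computed on a 100-point descending log grid; a gene's entry rank
    is the order in which its coefficient first becomes nonzero along the
    path (ties broken by larger absolute coefficient at entry, then gene
    name). The optimal penalty maximizes mean explained variance across
    seeded K-fold cross-validation; the R² standard deviation is the
    fold-wise dispersion at that penalty.
    """
    ith = ith.reindex(matrix.data.index)
    mask = ith.notna()
    df = matrix.data.loc[mask]
    y = ith[mask].to_numpy(dtype=float)
    n = len(y)
    if n < 2 * folds:
        raise ValueError(f"need at least {2 * folds} samples, got {n}")
    prevalent = [c for c in df.columns if df[c].sum() >= min_mutated
                 and df[c].nunique() > 1]
    if not prevalent:
        return LassoResult(
            genes=[], entry_ranks={}, coefficients={}, intercept=float(np.mean(y)),
            r_squared=0.0, r_squared_sd=0.0, significant=False,
            penalty_grid=np.array([]), penalty=np.nan,
        )
    Xraw = df[prevalent].to_numpy(dtype=float)
    mu, sd = Xraw.mean(axis=0), Xraw.std(axis=0)
    X = (Xraw - mu) / sd

    alphas = _penalty_grid(X, y, n_alphas=n_alphas)
    _, coefs, _ = lasso_path(X, y, alphas=alphas)

    # entry order along the path
    first_nz = np.full(len(prevalent), -1)
    entry_coef = np.zeros(len(prevalent))
    for j in range(len(prevalent)):
        nz = np.nonzero(coefs[j])[0]
        if nz.size:
            first_nz[j] = nz[0]
            entry_coef[j] = coefs[j, nz[0]]
    entered = [j for j in range(len(prevalent)) if first_nz[j] >= 0]
    entered.sort(key=lambda j: (first_nz[j], -abs(entry_coef[j]), prevalent[j]))
    ranks_all = {prevalent[j]: r + 1 for r, j in enumerate(entered)}

    # cross-validated explained variance along the same grid
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_r2 = np.empty((folds, len(alphas)))
    for i, (tr, te) in enumerate(kf.split(X)):
        _, ctr, _ = lasso_path(X[tr], y[tr], alphas=alphas)
        icept = y[tr].mean() - (X[tr].mean(axis=0)[None, :] @ ctr).ravel()
        pred = X[te] @ ctr + icept[None, :]
        sst = np.sum((y[te] - y[te].mean()) ** 2)
        sse = np.sum((y[te][:, None] - pred) ** 2, axis=0)
        fold_r2[i] = 1.0 - sse / sst if sst > 0 else 0.0
    mean_r2 = fold_r2.mean(axis=0)
    best = int(np.argmax(mean_r2))
    r2 = float(mean_r2[best])
    r2_sd = float(fold_r2[:, best].std(ddof=1))

    beta = coefs[:, best]
    intercept = float(y.mean() - X.mean(axis=0) @ beta)
    selected = [j for j in entered if beta[j] != 0]
    genes = [prevalent[j] for j in selected]
    return LassoResult(
        genes=genes,
        entry_ranks={g: r + 1 for r, g in
                     enumerate(sorted(genes, key=lambda g: ranks_all[g]))},
        coefficients={prevalent[j]: float(beta[j]) for j in selected},
        intercept=intercept,
        r_squared=r2,
        r_squared_sd=r2_sd,
        significant=(r2 - r2_sd) > 0,
        penalty_grid=alphas,
        penalty=float(alphas[best]),
        feature_means={g: float(m) for g, m in zip(prevalent, mu)},
        feature_sds={g: float(s) for g, s in zip(prevalent, sd)},
    )


def predict_ith(result: LassoResult, matrix: MutationMatrix) -> pd.Series:
    """Predicted heterogeneity from the optimal-penalty coefficients."""
    pred = np.full(len(matrix.data), result.intercept)
    for g, b in result.coefficients.items():
        x = matrix.data[g].to_numpy(dtype=float)
        z = (x - result.feature_means[g]) / result.feature_sds[g]
        pred = pred + b * z
    return pd.Series(pred, index=matrix.data.index, name="predicted_ith")


def evaluate_model(
    result: LassoResult,
    matrix: MutationMatrix,
    ith: pd.Series,
) -> tuple[pd.DataFrame, float | None, float | None]:
    """Predicted-vs-observed heterogeneity and their Pearson correlation.

    Returns ``(pairs, r, p)``; ``r`` is None for an empty model or a
    degenerate (constant) prediction.
    """
    ith = ith.reindex(matrix.data.index)
    pred = predict_ith(result, matrix)
    mask = ith.notna()
    pairs = pd.DataFrame({"observed": ith[mask], "predicted": pred[mask]})
    if not result.genes or pairs["predicted"].nunique() <= 1 or len(pairs) < 3:
        return pairs, None, None
    r, p = stats.pearsonr(pairs["predicted"], pairs["observed"])
    return pairs, float(r), float(p)
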