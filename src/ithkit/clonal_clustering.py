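"""Subclonal clustering of variant allele fractions across related samples.

Variants observed jointly in a set of related samples (e.g. timepoints of
one cell-line experiment) are grouped into clusters of shared allele
fraction — a proxy for subclones — with a maximum-likelihood finite binomial
mixture fitted by expectation–maximization:

    alt(v, s) ~ Binomial(depth(v, s), p[k(v), s])

where cluster ``k`` has one center ``p[k, s]`` per sample and mixture
weights shared across samples. The number of clusters is chosen by minimal
BIC over a candidate range. This is a deliberately simplified stand-in for
Dirichlet-process binomial clustering with copy-number priors (PyClone):
centers here are allele fractions, not cellular prevalences, which is the
object consumed downstream (per-sample cluster-mean VAF matrices and their
hierarchical clustering).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.special import gammaln, logsumexp

from ithkit.variant_io import SampleVariantSet

DEFAULT_MIN_READS = 50
_P_CLAMP = 1e-6


@dataclass
class ClusterInput:
    """Aligned alt/depth count matrices (variants × samples)."""

    variant_keys: list[tuple]
    sample_ids: list[str]
    alt: np.ndarray     # (V, S) int
    depth: np.ndarray   # (V, S) int; 0 marks "not observed in this sample"

    def __post_init__(self) -> None:
        if (self.alt > self.depth).any():
            raise ValueError("alt_count exceeds depth")
        if ((self.depth > 0).sum(axis=1) == 0).any():
            raise ValueError("every variant must be observed in >=1 sample")

    @property
    def n_variants(self) -> int:
        return len(self.variant_keys)


def prepare_cluster_input(
    sets: Sequence[SampleVariantSet],
    min_reads: int = DEFAULT_MIN_READS,
    count_mode: str = "depth",
) -> ClusterInput:
    """Align variants across samples and apply the read-support threshold.

    Variants are matched by (chrom, pos, ref, alt); a sample where a variant
    was not called gets depth 0 (unobserved). A variant is kept only if its
    support is ≥ ``min_reads`` in *every* sample where it was observed;
    ``count_mode`` selects whether support means total depth (default) or
    alt-supporting reads.
    """
    if count_mode not in ("depth", "alt"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    sample_ids = [s.sample_id for s in sets]
    per_sample = [{v.key: v for v in s} for s in sets]
    keys = sorted({k for d in per_sample for k in d})
    rows_alt, rows_depth, kept = [], [], []
    n_dropped = 0
    for key in keys:
        alt_row, depth_row, ok = [], [], True
        for d in per_sample:
            v = d.get(key)
            if v is None or v.depth is None:
                alt_row.append(0)
                depth_row.append(0)
                continue
            support = v.depth if count_mode == "depth" else v.alt_count
            if support < min_reads:
                ok = False
                break
            alt_row.append(v.alt_count)
            depth_row.append(v.depth)
        if ok and any(depth_row):
            kept.append(key)
            rows_alt.append(alt_row)
            rows_depth.append(depth_row)
        else:
            n_dropped += 1
    if not kept:
        raise ValueError(
            f"no variant passes the {min_reads}-read threshold "
            f"({n_dropped} dropped of {len(keys)})"
        )
    return ClusterInput(
        variant_keys=kept,
        sample_ids=sample_ids,
        alt=np.array(rows_alt, dtype=np.int64),
        depth=np.array(rows_depth, dtype=np.int64),
    )


@dataclass
class ClusterModel:
    """Fitted binomial mixture over variant allele fractions."""

    k: int
    centers: np.ndarray          # (K, S) allele-fraction centers
    weights: np.ndarray          # (K,) simplex
    assignments: np.ndarray      # (V,) hard cluster index, 0-based
    log_likelihood: float
    bic: float
    converged: bool
    sample_ids: list[str] = field(default_factory=list)
    variant_keys: list[tuple] = field(default_factory=list)
    bic_by_k: dict[int, float] = field(default_factory=dict)


def _binom_loglik_terms(alt: np.ndarray, depth: np.ndarray,
                        centers: np.ndarray) -> np.ndarray:
    """(V, K) log-likelihood of each variant under each cluster.

    Unobserved entries (depth 0) contribute 0. The binomial coefficient is
    constant across clusters but kept so the absolute likelihood (and BIC)
    is well defined.
    """
    p = np.clip(centers, _P_CLAMP, 1 - _P_CLAMP)          # (K, S)
    const = gammaln(depth + 1) - gammaln(alt + 1) - gammaln(depth - alt + 1)
    ll = (
        alt[:, None, :] * np.log(p)[None]
        + (depth - alt)[:, None, :] * np.log1p(-p)[None]
        + const[:, None, :]
    )                                                     # (V, K, S)
    ll = np.where(depth[:, None, :] > 0, ll, 0.0)
    return ll.sum(axis=2)


def _em_once(alt, depth, k, rng, tol, max_iter):
    v, s = alt.shape
    vaf = np.where(depth > 0, alt / np.maximum(depth, 1), np.nan)
    # initialize centers at k randomly chosen variants' observed VAF vectors
    idx = rng.choice(v, size=k, replace=(v < k))
    centers = np.nan_to_num(vaf[idx], nan=0.5)
    centers = np.clip(centers + rng.normal(0, 0.02, centers.shape), 0.01, 0.99)
    weights = np.full(k, 1.0 / k)
    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        log_prob = _binom_loglik_terms(alt, depth, centers) + np.log(weights)[None]
        norm = logsumexp(log_prob, axis=1)
        ll = float(norm.sum())
        if ll + 1e-8 < prev_ll:
            raise AssertionError("EM log-likelihood decreased")
        resp = np.exp(log_prob - norm[:, None])           # (V, K)
        weights = np.clip(resp.mean(axis=0), 1e-12, None)
        weights = weights / weights.sum()
        num = resp.T @ (alt * (depth > 0))                # (K, S)
        den = resp.T @ depth
        with np.errstate(invalid="ignore", divide="ignore"):
            new_centers = np.where(den > 0, num / np.maximum(den, 1e-12), centers)
        centers = np.clip(new_centers, 0.0, 1.0)
        if ll - prev_ll < tol * max(1.0, abs(ll)):
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
    log_prob = _binom_loglik_terms(alt, depth, centers) + np.log(
        np.clip(weights, 1e-300, None))[None]
    norm = logsumexp(log_prob, axis=1)
    return centers, weights, float(norm.sum()), np.argmax(log_prob, axis=1), converged


def fit_binomial_mixture(
    cluster_input: ClusterInput,
    k_range: Iterable[int] = range(1, 11),
    n_starts: int = 10,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> ClusterModel:
    """Fit the binomial mixture for each candidate K and pick minimal BIC.

    Each K is fitted from ``n_starts`` seeded random restarts, keeping the
    best log-likelihood. BIC = −2·logL + npar·ln(V) with
    npar = K·S + (K − 1) (one center per cluster per sample plus the free
    weights). Deterministic given the seed; a non-converged best fit is
    returned flagged rather than raised.
    """
    alt, depth = cluster_input.alt, cluster_input.depth
    v, s = alt.shape
    k_range = [k for k in k_range if 1 <= k <= v]
    if not k_range:
        raise ValueError("k_range empty after clamping to [1, n_variants]")
    rng = np.random.default_rng(seed)
    best_model: ClusterModel | None = None
    bic_by_k: dict[int, float] = {}
    for k in k_range:
        best_ll, best_fit = -np.inf, None
        for _ in range(n_starts):
            fit = _em_once(alt, depth, k, rng, tol, max_iter)
            if fit[2] > best_ll:
                best_ll, best_fit = fit[2], fit
        centers, weights, ll, assign, converged = best_fit
        npar = k * s + (k - 1)
        bic = -2.0 * ll + npar * np.log(v)
        bic_by_k[k] = bic
        if best_model is None or bic < best_model.bic:
            best_model = ClusterModel(
                k=k, centers=centers, weights=weights, assignments=assign,
                log_likelihood=ll, bic=bic, converged=converged,
                sample_ids=list(cluster_input.sample_ids),
                variant_keys=list(cluster_input.variant_keys),
            )
    best_model.bic_by_k = bic_by_k
    if not best_model.converged:
        warnings.warn(
            f"EM did not converge within {max_iter} iterations for K={best_model.k}; "
            "best-so-far fit returned"
        )
    return best_model


def cluster_mean_vaf(
    model: ClusterModel,
    cluster_input: ClusterInput,
) -> pd.DataFrame:
    """Cluster × sample matrix of mean observed variant allele fractions.

    Entry (c, s) averages alt/depth over the variants assigned to cluster c
    that are observed (depth > 0) in sample s; cells without any observed
    assigned variant are NaN (undefined), never 0.
    """
    alt, depth = cluster_input.alt, cluster_input.depth
    out = np.full((model.k, len(cluster_input.sample_ids)), np.nan)
    for c in range(model.k):
        members = model.assignments == c
        if not members.any():
            continue
        a, d = alt[members], depth[members]
        obs = d > 0
        with np.errstate(invalid="ignore"):
            vaf = np.where(obs, a / np.maximum(d, 1), np.nan)
        n_obs = obs.sum(axis=0)
        col = np.nansum(vaf, axis=0) / np.where(n_obs > 0, n_obs, np.nan)
        out[c] = col
    return pd.DataFrame(
        out,
        index=pd.Index([f"cluster_{c + 1}" for c in range(model.k)], name="cluster"),
        columns=cluster_input.sample_ids,
    )


def hierarchical_cluster_samples(
    matrix: pd.DataFrame,
) -> tuple[np.ndarray, list[str], str]:
    """Agglomerative (average-linkage) clustering of sample columns.

    Distance between two samples is Euclidean over the cells defined in
    both, rescaled by the fraction of shared defined cells so that sparsely
    shared pairs are not artificially close. Columns with no defined cell
    are excluded with a warning. Returns ``(linkage, leaf_order, newick)``.
    """
    cols = [c for c in matrix.columns if matrix[c].notna().any()]
    dropped = [c for c in matrix.columns if c not in cols]
    if dropped:
        warnings.warn(f"excluding all-undefined sample column(s): {dropped}")
    if len(cols) < 2:
        if len(cols) == 1:
            return np.empty((0, 4)), cols, f"{cols[0]};"
        raise ValueError("need at least one defined sample column")
    x = matrix[cols].to_numpy(dtype=float)
    k_total = x.shape[0]
    n = len(cols)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~np.isnan(x[:, i]) & ~np.isnan(x[:, j])
            if not shared.any():
                d = np.sqrt(k_total)  # no information: maximal-scale distance
            else:
                sq = np.sum((x[shared, i] - x[shared, j]) ** 2)
                d = np.sqrt(sq * k_total / shared.sum())
            dmat[i, j] = dmat[j, i] = d
    link = hierarchy.linkage(squareform(dmat, checks=False), method="average")
    leaves = hierarchy.leaves_list(hierarchy.optimal_leaf_ordering(
        link, squareform(dmat, checks=False)))
    leaf_order = [cols[i] for i in leaves]
    newick = _linkage_to_newick(link, cols)
    return link, leaf_order, newick


def _linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    from skbio import TreeNode

    tree = TreeNode.from_linkage_matrix(link, labels)
    return str(tree).strip()
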