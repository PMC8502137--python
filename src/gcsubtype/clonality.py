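"""Clonal-architecture inference from variant allele frequencies.

Copy-neutral, adequately covered SNVs (depth >= 20, total copy number in
2 +/- 0.25) are clustered with a binomial mixture model fit by EM.  The
number of mixture components (1..10) is chosen by BIC over multi-restart
fits, components lighter than 2% are pruned with re-estimation —
mirroring the automatic relevance determination of the variational
original — and the component structure is summarized as a clonal
pattern:

* monoclonal — one major clone, with or without one minor subclone;
* biclonal   — two major clones;
* complex    — anything richer.

A component is "major" when its mixture weight is at least
``major_clone_min_frac`` (default 0.15; the boundary between a clone and
a minor subclone is a convention, surfaced as a config knob).  Samples
with monoclonal/biclonal patterns form the oligoclonal group; complex
samples are multiclonal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .types import MutationRecord

log = logging.getLogger(__name__)

MIN_VARIANTS = 10
WEIGHT_PRUNE = 0.02
P_CLAMP = 1e-4


class InsufficientDataError(ValueError):
    """Too few copy-neutral variants to fit a mixture."""


@dataclass
class ClonalArchitecture:
    sample_id: str
    component_means: np.ndarray = field(default_factory=lambda: np.array([]))
    component_weights: np.ndarray = field(default_factory=lambda: np.array([]))
    assignments: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    n_variants_used: int = 0
    pattern: str | None = None
    group: str | None = None
    log_likelihood: float = np.nan
    insufficient: bool = False

    @property
    def n_components(self) -> int:
        return len(self.component_means)


def filter_clonality_variants(mutations: Sequence[MutationRecord], min_depth: int = 20,
                              cn_margin: float = 0.25) -> list[MutationRecord]:
    """Keep SNVs with depth >= ``min_depth`` and |local_cn - 2| <= ``cn_margin``."""
    return [
        m for m in mutations
        if m.is_snv and m.total_depth >= min_depth and abs(m.local_cn - 2.0) <= cn_margin
    ]


def _binom_loglik_matrix(alt: np.ndarray, depth: np.ndarray, means: np.ndarray,
                         coeff: np.ndarray | None = None) -> np.ndarray:
    """log Binom(alt | depth, p_c) for every variant x component."""
    if coeff is None:
        coeff = gammaln(depth + 1) - gammaln(alt + 1) - gammaln(depth - alt + 1)
    p = means[None, :]
    return coeff[:, None] + alt[:, None] * np.log(p) + (depth - alt)[:, None] * np.log1p(-p)


def _em_fit(alt: np.ndarray, depth: np.ndarray, means0: np.ndarray,
            max_iter: int = 300, tol: float = 1e-8,
            coeff: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """EM for a binomial mixture; returns (means, weights, loglik, history).

    The observed-data log-likelihood is recorded each iteration and is
    non-decreasing (a property of EM, asserted by the test suite).
    """
    if coeff is None:
        coeff = gammaln(depth + 1) - gammaln(alt + 1) - gammaln(depth - alt + 1)
    c = len(means0)
    means = np.clip(means0, P_CLAMP, 1 - P_CLAMP)
    weights = np.full(c, 1.0 / c)
    history: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        log_prob = _binom_loglik_matrix(alt, depth, means, coeff) + np.log(weights)[None, :]
        norm = logsumexp(log_prob, axis=1)
        loglik = float(norm.sum())
        history.append(loglik)
        resp = np.exp(log_prob - norm[:, None])
        weights = resp.mean(axis=0)
        means = np.clip((resp * alt[:, None]).sum(axis=0)
                        / np.maximum((resp * depth[:, None]).sum(axis=0), 1e-12),
                        P_CLAMP, 1 - P_CLAMP)
        if loglik - prev < tol * max(abs(loglik), 1.0) and len(history) > 1:
            break
        prev = loglik
    return means, weights, history[-1], history


def _init_means(vafs: np.ndarray, c: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding on raw VAFs (sorted for order invariance)."""
    centers = [float(rng.choice(vafs))]
    for _ in range(1, c):
        d2 = np.min([(vafs - m) ** 2 for m in centers], axis=0)
        total = d2.sum()
        if total <= 0:
            centers.append(centers[0])
            continue
        centers.append(float(rng.choice(vafs, p=d2 / total)))
    return np.sort(np.array(centers))


def fit_binomial_mixture(alt_depths: Sequence[int], total_depths: Sequence[int],
                         max_clusters: int = 10, seed: int = 0,
                         n_restarts: int = 10, sample_id: str = "",
                         history_sink: list | None = None) -> ClonalArchitecture:
    """Fit binomial mixtures for 1..``max_clusters`` components, pick by BIC.

    Per component count, the best of ``n_restarts`` seeded EM runs is
    kept; after model selection, components with weight < 2% are pruned
    and the remaining parameters re-estimated.  Deterministic given the
    seed; variants are sorted internally so input order is irrelevant.
    ``history_sink``, when given, collects every EM run's per-iteration
    log-likelihood trace (for monotonicity audits).
    """
    alt = np.asarray(alt_depths, dtype=float)
    depth = np.asarray(total_depths, dtype=float)
    if alt.shape != depth.shape or alt.ndim != 1:
        raise ValueError("alt_depths and total_depths must be equal-length 1-D")
    if len(alt) < MIN_VARIANTS:
        raise InsufficientDataError(
            f"need >= {MIN_VARIANTS} variants, got {len(alt)}")
    order = np.lexsort((alt, depth))
    alt_s, depth_s = alt[order], depth[order]
    coeff = gammaln(depth_s + 1) - gammaln(alt_s + 1) - gammaln(depth_s - alt_s + 1)
    vafs = alt_s / np.maximum(depth_s, 1)
    n = len(alt_s)
    best: tuple[float, np.ndarray, np.ndarray, float] | None = None
    n_worse = 0
    for c in range(1, max_clusters + 1):
        run_best: tuple[float, np.ndarray, np.ndarray] | None = None
        for r in range(n_restarts if c > 1 else 1):
            rng = np.random.default_rng([seed, c, r])
            means0 = _init_means(vafs, c, rng)
            means, weights, loglik, history = _em_fit(alt_s, depth_s, means0, coeff=coeff)
            if history_sink is not None:
                history_sink.append(history)
            if run_best is None or loglik > run_best[0]:
                run_best = (loglik, means, weights)
        loglik, means, weights = run_best
        n_params = 2 * c - 1
        bic = -2 * loglik + n_params * np.log(n)
        if best is None or bic < best[0]:
            best = (bic, means, weights, loglik)
            n_worse = 0
        else:
            # BIC deteriorating for two consecutive sizes: adding further
            # components will not recover (penalty grows, fit saturates)
            n_worse += 1
            if n_worse >= 2:
                break
    _, means, weights, loglik = best
    keep = weights >= WEIGHT_PRUNE
    if not keep.all() and keep.any():
        means, weights, loglik, _ = _em_fit(alt_s, depth_s, means[keep], coeff=coeff)
    log_prob = _binom_loglik_matrix(alt_s, depth_s, means, coeff) + np.log(weights)[None, :]
    assignments_sorted = np.argmax(log_prob, axis=1)
    assignments = np.empty(n, dtype=int)
    assignments[order] = assignments_sorted
    return ClonalArchitecture(
        sample_id=sample_id,
        component_means=means,
        component_weights=weights,
        assignments=assignments,
        n_variants_used=n,
        log_likelihood=loglik,
    )


def classify_pattern(architecture: ClonalArchitecture,
                     major_clone_min_frac: float = 0.15) -> str:
    """Map a fitted mixture to monoclonal / biclonal / complex."""
    if architecture.n_components == 0:
        raise ValueError("architecture has zero components")
    weights = architecture.component_weights
    n_major = int((weights >= major_clone_min_frac).sum())
    n_minor = len(weights) - n_major
    if n_major == 1 and n_minor <= 1:
        return "monoclonal"
    if n_major == 2 and n_minor == 0:
        return "biclonal"
    return "complex"


def classify_group(pattern: str) -> str:
    """Oligoclonal (monoclonal/biclonal) vs multiclonal (complex)."""
    if pattern in ("monoclonal", "biclonal"):
        return "oligoclonal"
    if pattern == "complex":
        return "multiclonal"
    raise ValueError(f"unknown pattern {pattern!r}")


def analyze_sample(mutations: Sequence[MutationRecord], sample_id: str,
                   min_depth: int = 20, cn_margin: float = 0.25,
                   max_clusters: int = 10, major_clone_min_frac: float = 0.15,
                   seed: int = 0) -> ClonalArchitecture:
    """Filter one sample's variants and infer its clonal architecture.

    Samples with too few copy-neutral variants are marked insufficient
    (excluded from the clonality layer, with a log entry) rather than
    raising.
    """
    subset = filter_clonality_variants(
        [m for m in mutations if m.sample_id == sample_id], min_depth, cn_margin)
    if len(subset) < MIN_VARIANTS:
        log.info("sample %s: %d copy-neutral variants (<%d); clonality not inferred",
                 sample_id, len(subset), MIN_VARIANTS)
        return ClonalArchitecture(sample_id=sample_id, insufficient=True,
                                  n_variants_used=len(subset))
    arch = fit_binomial_mixture(
        [m.alt_depth for m in subset], [m.total_depth for m in subset],
        max_clusters=max_clusters, seed=seed, sample_id=sample_id)
    arch.pattern = classify_pattern(arch, major_clone_min_frac)
    arch.group = classify_group(arch.pattern)
    return arch
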