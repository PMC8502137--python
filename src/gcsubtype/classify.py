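"""Integrative clustering and subtype characterization.

Every layer's unsupervised grouping, and the final integrative
subtyping, share one clustering engine: agglomerative clustering with
Ward linkage on Euclidean distances.  The integrative step wraps it in
resampling-based consensus clustering — repeated clustering of sample
subsamples aggregated into a co-clustering frequency matrix, which is
itself clustered to yield the four subtypes.  Setting ``n_resamples=1``
with ``subsample_frac=1.0`` reproduces the plain hierarchical variant.

Cluster labels are renumbered canonically: by descending cluster-mean
tumor mutation burden when a TMB vector is supplied (so subtypes 1 and 2
are the high-burden groups, matching the field's convention for this
classification), otherwise by descending cluster size with the first
sample index breaking ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from scipy import stats

log = logging.getLogger(__name__)

LAYER_COLUMNS = ("sig_cluster", "cnv_cluster", "nea_cluster", "clonality_group")


def _canonical_renumber(labels: np.ndarray, tmb: np.ndarray | None = None) -> np.ndarray:
    """Renumber arbitrary cluster labels to 1..k canonically."""
    uniq = pd.unique(labels)
    if tmb is not None:
        order = sorted(uniq, key=lambda c: -float(np.mean(tmb[labels == c])))
    else:
        order = sorted(
            uniq,
            key=lambda c: (-int(np.sum(labels == c)), int(np.argmax(labels == c))),
        )
    mapping = {old: new for new, old in enumerate(order, start=1)}
    return np.array([mapping[l] for l in labels], dtype=int)


def ward_cluster(matrix: np.ndarray, k: int, tmb: pd.Series | np.ndarray | None = None) -> np.ndarray:
    """Ward-linkage agglomerative clustering into ``k`` groups.

    Deterministic; returns canonical labels in 1..k (see module
    docstring for the renumbering rule).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or not np.isfinite(X).all():
        raise ValueError("ward_cluster requires a finite 2-D matrix")
    n = X.shape[0]
    if k > n or k < 1:
        raise ValueError(f"k={k} out of range for n={n}")
    if n == 1:
        return np.array([1])
    link = sch.linkage(X, method="ward")
    labels = sch.fcluster(link, t=k, criterion="maxclust")
    tmb_arr = None if tmb is None else np.asarray(tmb, dtype=float)
    return _canonical_renumber(labels, tmb_arr)


def encode_features(table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Encode a per-sample feature table for the Euclidean metric.

    Multi-level layer labels are one-hot encoded; binary flags and the
    clonality group become 0/1.  Every block is divided by the square
    root of its width so no single layer dominates the distance: each
    layer's one-hot expansion is one block, and the essential-SMG flags
    and essential-CNV flags each form one collective block (a cohort
    with twenty driver flags would otherwise swamp the four layer
    labels).  Returns (matrix, column names).
    """
    if table.isna().any().any():
        bad = table.columns[table.isna().any()].tolist()
        raise ValueError(f"feature table has missing values in {bad}")
    n_smg = sum(c.endswith("_mut") for c in table.columns)
    n_cnv = sum(c.endswith(("_amp", "_del")) for c in table.columns)
    blocks: list[np.ndarray] = []
    names: list[str] = []
    for col in table.columns:
        values = table[col]
        if col == "clonality_group":
            values = values.map({"oligoclonal": 0, "multiclonal": 1})
            if values.isna().any():
                raise ValueError("clonality_group must be oligoclonal/multiclonal")
        levels = sorted(pd.unique(values))
        if len(levels) <= 2 and set(levels) <= {0, 1}:
            if col.endswith("_mut"):
                width = n_smg
            elif col.endswith(("_amp", "_del")):
                width = n_cnv
            else:
                width = 1
            blocks.append(values.to_numpy(dtype=float)[:, None] / np.sqrt(width))
            names.append(col)
        else:
            width = len(levels)
            onehot = np.zeros((len(values), width))
            for j, level in enumerate(levels):
                onehot[values.to_numpy() == level, j] = 1.0
            blocks.append(onehot / np.sqrt(width))
            names.extend(f"{col}={level}" for level in levels)
    return np.hstack(blocks), names


@dataclass
class SubtypeAssignment:
    sample_id: str
    subtype: int
    membership: float  # mean consensus with own cluster, in [0,1]


def consensus_cluster(matrix: np.ndarray, k: int = 4, n_resamples: int = 1000,
                      subsample_frac: float = 0.8, seed: int = 0,
                      sample_ids: list[str] | None = None,
                      tmb: pd.Series | np.ndarray | None = None,
                      ) -> tuple[list[SubtypeAssignment], np.ndarray]:
    """Resampling-based consensus clustering.

    Repeats Ward clustering on row subsamples, accumulates the fraction
    of co-sampled runs in which each sample pair co-clusters, then
    clusters (1 - consensus) distances at ``k``.  Deterministic under a
    fixed seed.  Returns the assignments and the consensus matrix
    (symmetric, unit diagonal).
    """
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    m = int(round(subsample_frac * n))
    if m < k:
        raise ValueError(f"subsample size {m} < k={k}")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = np.random.default_rng(seed)
    together = np.zeros((n, n))
    co_sampled = np.zeros((n, n))
    for _ in range(n_resamples):
        idx = np.sort(rng.choice(n, size=m, replace=False)) if m < n else np.arange(n)
        labels = ward_cluster(X[idx], min(k, m))
        same = labels[:, None] == labels[None, :]
        co_sampled[np.ix_(idx, idx)] += 1
        together[np.ix_(idx, idx)] += same
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(co_sampled > 0, together / np.maximum(co_sampled, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    if n_resamples == 1 and m == n:
        final = ward_cluster(X, k, tmb=tmb)
    else:
        dist = 1.0 - consensus
        link = sch.linkage(ssd.squareform(dist, checks=False), method="ward")
        labels = sch.fcluster(link, t=k, criterion="maxclust")
        final = _canonical_renumber(labels, None if tmb is None else np.asarray(tmb, float))
    ids = sample_ids if sample_ids is not None else [f"S{i:03d}" for i in range(n)]
    assignments = []
    for i, sid in enumerate(ids):
        own = final == final[i]
        own[i] = False
        membership = float(consensus[i, own].mean()) if own.any() else 1.0
        assignments.append(SubtypeAssignment(sid, int(final[i]), membership))
    return assignments, consensus


# ---------------------------------------------------------------------------
# characterization statistics


def crosstab_test(labels: pd.Series, category: pd.Series) -> dict:
    """Chi-square test of a subtype x category crosstab, Fisher when any
    expected cell is below 5 (2x2 only; larger sparse tables fall back to
    chi-square with a warning)."""
    aligned = pd.concat([labels, category], axis=1, join="inner").dropna()
    table = pd.crosstab(aligned.iloc[:, 0], aligned.iloc[:, 1])
    observed = table.to_numpy()
    if observed.size == 0 or observed.shape[0] < 2 or observed.shape[1] < 2:
        return {"table": table, "test": "none", "p": np.nan}
    chi2, p, _, expected = stats.chi2_contingency(observed)
    test = "chi-square"
    if (expected < 5).any():
        if observed.shape == (2, 2):
            _, p = stats.fisher_exact(observed, alternative="two-sided")
            test = "fisher"
        else:
            log.warning("sparse %sx%s crosstab: expected cell < 5, chi-square kept",
                        *observed.shape)
    return {"table": table, "test": test, "p": float(p)}


def pairwise_mannwhitney(values: pd.Series, labels: pd.Series) -> pd.DataFrame:
    """Two-sided Mann-Whitney U between every pair of subtype groups."""
    aligned = pd.concat([values, labels], axis=1, join="inner").dropna()
    v, g = aligned.iloc[:, 0], aligned.iloc[:, 1]
    groups = sorted(g.unique())
    rows = []
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            va, vb = v[g == a], v[g == b]
            if len(va) == 0 or len(vb) == 0:
                continue
            try:
                stat, p = stats.mannwhitneyu(va, vb, alternative="two-sided")
            except ValueError:  # all values identical
                stat, p = np.nan, 1.0
            rows.append({"group_a": a, "group_b": b, "U": float(stat), "p": float(p)})
    return pd.DataFrame(rows)


def characterize_subtypes(assignments: list[SubtypeAssignment], clinical: pd.DataFrame,
                          features: pd.DataFrame, tmb: pd.Series,
                          tnb: pd.Series | None = None) -> dict:
    """Per-subtype alteration frequencies, clinical crosstabs, and
    pairwise burden comparisons.

    ``clinical`` is indexed by sample with ``lauren`` /
    ``first_metastasis`` columns where available; ``features`` holds the
    binary essential-alteration flags.
    """
    labels = pd.Series({a.sample_id: a.subtype for a in assignments}, name="subtype")
    present = labels.value_counts()
    empty = [s for s in range(1, labels.max() + 1) if s not in present.index]
    if empty:
        log.warning("subtype(s) %s have zero samples; excluded from report", empty)
    report: dict = {"subtype_sizes": {int(k): int(v) for k, v in present.sort_index().items()}}
    flag_cols = [c for c in features.columns if c not in LAYER_COLUMNS]
    freq = {}
    for subtype in sorted(present.index):
        members = labels.index[labels == subtype]
        sub = features.loc[features.index.intersection(members), flag_cols]
        freq[int(subtype)] = {c: float(sub[c].mean()) for c in flag_cols}
    report["alteration_frequencies"] = freq
    for col in ("lauren", "first_metastasis", "tcga_subtype"):
        if col in clinical.columns:
            res = crosstab_test(labels, clinical[col])
            report[f"{col}_crosstab"] = res["table"].to_dict()
            report[f"{col}_test"] = {"test": res["test"], "p": res["p"]}
    report["tmb_pairwise"] = pairwise_mannwhitney(tmb, labels).to_dict("records")
    if tnb is not None:
        report["tnb_pairwise"] = pairwise_mannwhitney(tnb, labels).to_dict("records")
    return report


def survival_compare(assignments: list[SubtypeAssignment], clinical: pd.DataFrame,
                     covariates: list[str] | None = None) -> dict:
    """Kaplan-Meier curves, k-group log-rank test, and Cox hazard ratios.

    The Cox model (Efron ties) treats subtype as a categorical covariate
    against the best-prognosis convention baseline (largest label) and
    adjusts for ``covariates`` (e.g. stage, TMB) when supplied.
    """
    from lifelines import CoxPHFitter, KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    labels = pd.Series({a.sample_id: a.subtype for a in assignments}, name="subtype")
    df = clinical.join(labels, how="inner").dropna(subset=["os_months", "os_event", "subtype"])
    for subtype, sub in df.groupby("subtype"):
        if sub["os_event"].sum() == 0:
            log.warning("subtype %s is fully censored; log-rank still computed", subtype)
    km = {}
    for subtype, sub in df.groupby("subtype"):
        fitter = KaplanMeierFitter()
        fitter.fit(sub["os_months"], sub["os_event"], label=f"subtype {subtype}")
        sf = fitter.survival_function_
        km[int(subtype)] = {
            "time": sf.index.to_list(),
            "survival": sf.iloc[:, 0].to_list(),
            "n": int(len(sub)),
            "events": int(sub["os_event"].sum()),
        }
    lr = multivariate_logrank_test(df["os_months"], df["subtype"], df["os_event"])
    out = {"km": km, "logrank_statistic": float(lr.test_statistic), "logrank_p": float(lr.p_value)}
    covariates = [c for c in (covariates or []) if c in df.columns]
    cox_df = df[["os_months", "os_event"] + covariates].copy()
    baseline = df["subtype"].max()
    for subtype in sorted(df["subtype"].unique()):
        if subtype != baseline:
            cox_df[f"subtype_{subtype}"] = (df["subtype"] == subtype).astype(float)
    if "stage" in covariates:
        cox_df["stage"] = df["stage"].map({"I": 1, "II": 2, "III": 3, "IV": 4})
    if df["os_event"].sum() > 0 and len(df) > len(cox_df.columns):
        cph = CoxPHFitter()
        try:
            cph.fit(cox_df.dropna(), duration_col="os_months", event_col="os_event")
            summary = cph.summary
            out["cox"] = {
                row: {
                    "hr": float(summary.loc[row, "exp(coef)"]),
                    "ci_low": float(summary.loc[row, "exp(coef) lower 95%"]),
                    "ci_high": float(summary.loc[row, "exp(coef) upper 95%"]),
                    "p": float(summary.loc[row, "p"]),
                }
                for row in summary.index
            }
            out["cox_baseline_subtype"] = int(baseline)
        except Exception as exc:  # degenerate designs on tiny cohorts
            log.warning("Cox fit failed: %s", exc)
            out["cox"] = None
    return out
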