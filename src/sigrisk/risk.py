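"""Prognostic index and risk-group stratification.

The prognostic index (PI) is the linear predictor of a Cox model,
``PI_s = sum_i beta_i * x_i[s]``, with coefficients either fitted by Cox
regression on the signature genes or supplied by the user as weights.
Samples are stratified into k risk groups either by quantile split of the
ordered PI (k = 2: median split) or by scanning all admissible cutpoints
and choosing the split whose log-rank p-value is minimal.

The minimum-p scan is a maximally-selected statistic and its naive p-value
is optimistically biased; :func:`split_pvalue_bias_check` provides a
permutation-based selection-adjusted p-value as an opt-in diagnostic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import ClinicalTable, ExpressionMatrix, GeneSignature
from .survival import (CoxFit, LogRankResult, ZeroVarianceError,
                       concordance_index, cox_fit, hazard_ratio, logrank_test)

logger = logging.getLogger(__name__)

__all__ = [
    "PrognosticIndex", "RiskGrouping",
    "compute_pi", "fit_or_weights", "assign_groups_quantile",
    "optimize_groups", "toggle_genes", "train_test_run", "stratified_run",
    "split_pvalue_bias_check", "default_min_group_size",
]


@dataclass
class PrognosticIndex:
    """Per-sample risk score: the Cox linear predictor for stored betas."""

    sample_ids: list
    pi: np.ndarray
    source: str                     # "cox_fit" or "user_weights"
    betas: np.ndarray
    gene_ids: list

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.betas = np.asarray(self.betas, dtype=float)


@dataclass
class RiskGrouping:
    """Assignment of samples to ordered risk groups.

    ``labels`` are 1..k in original sample order (1 = lowest risk) and are
    monotone in the PI.  ``split_points`` are the k-1 increasing PI
    thresholds between consecutive groups.
    """

    labels: np.ndarray
    split_points: np.ndarray
    method: str                     # "quantile" or "optimized"
    separation: LogRankResult
    min_group_size: int
    k: int
    scan: dict = field(default_factory=dict)   # optimization trace for plots
    notes: dict = field(default_factory=dict)

    def group_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k + 1)[1:]

    def assign_new(self, pi_values) -> np.ndarray:
        """Label new samples by the stored thresholds (train -> test)."""
        pi_values = np.asarray(pi_values, dtype=float)
        return 1 + np.searchsorted(self.split_points, pi_values, side="right")


def default_min_group_size(n: int) -> int:
    """Floor on group size for the optimized split: max(5, ceil(0.1 n)).

    An unconstrained minimum-p scan can isolate one-sample groups with
    spuriously extreme statistics; this floor keeps groups interpretable.
    """
    return max(5, int(np.ceil(0.1 * n)))


# ---------------------------------------------------------------------------
# Prognostic index
# ---------------------------------------------------------------------------

def compute_pi(expr: ExpressionMatrix, betas, source="cox_fit") -> PrognosticIndex:
    """Linear prognostic index PI = sum_i beta_i x_i per sample.

    ``betas`` may be an array aligned to ``expr.probe_ids`` or a mapping
    gene -> beta covering exactly the expression rows.
    """
    if isinstance(betas, dict):
        missing = [g for g in expr.probe_ids if g not in betas]
        extra = [g for g in betas if g not in set(expr.probe_ids)]
        if missing or extra:
            raise ValueError(
                "beta/gene mismatch: missing betas for "
                f"[{', '.join(map(str, missing))}]; extra betas for "
                f"[{', '.join(map(str, extra))}]")
        b = np.array([betas[g] for g in expr.probe_ids], dtype=float)
    else:
        b = np.asarray(betas, dtype=float)
        if b.shape != (len(expr.probe_ids),):
            raise ValueError(f"{b.size} betas for {len(expr.probe_ids)} genes")
    pi = b @ expr.values
    return PrognosticIndex(list(expr.sample_ids), pi, source, b,
                           list(expr.probe_ids))


def fit_or_weights(expr: ExpressionMatrix, clinical: ClinicalTable,
                   sig: GeneSignature, mode="cox", tie_method="efron"):
    """Obtain the beta coefficients: one multivariate Cox fit or user weights.

    ``mode='cox'`` fits all signature genes in a unique model on
    (time, event); zero-variance genes are dropped with a warning and the
    model refit on the remainder.  ``mode='user'`` returns the signature
    weights verbatim and no fit.  Returns ``(betas: dict, fit-or-None,
    expr-used)`` where ``expr-used`` excludes any dropped genes.
    """
    if expr.sample_ids != clinical.sample_ids:
        raise ValueError("expression and clinical samples are not aligned; "
                         "join them first")
    if mode == "user":
        if not sig.weighted:
            raise ValueError("mode='user' requires a weight on every "
                             "signature entry")
        order = {ident: w for ident, w in sig.entries}
        missing = [g for g in expr.probe_ids if g not in order]
        if missing:
            raise ValueError("no weight for gene(s): " + ", ".join(missing))
        betas = {g: float(order[g]) for g in expr.probe_ids}
        return betas, None, expr
    if mode != "cox":
        raise ValueError(f"unknown mode: {mode}")

    genes = list(expr.probe_ids)
    X = expr.values.T
    variances = X.var(axis=0)
    keep = variances > 0
    if not np.all(keep):
        dropped = [g for g, k in zip(genes, keep) if not k]
        warnings.warn("dropping zero-variance gene(s): " + ", ".join(dropped),
                      RuntimeWarning, stacklevel=2)
        genes = [g for g, k in zip(genes, keep) if k]
        X = X[:, keep]
        expr = ExpressionMatrix(genes, list(expr.sample_ids),
                                expr.values[keep], dict(expr.annotation))
    if not genes:
        raise ZeroVarianceError(list(expr.probe_ids))
    n_events = int(clinical.event.sum())
    if n_events < len(genes) + 1:
        warnings.warn(
            f"few events ({n_events}) for {len(genes)} genes; the Cox fit "
            "may be unstable", RuntimeWarning, stacklevel=2)
    fit = cox_fit(X, clinical.time, clinical.event, tie_method=tie_method,
                  names=genes)
    betas = {g: float(b) for g, b in zip(genes, fit.beta)}
    return betas, fit, expr


# ---------------------------------------------------------------------------
# Risk groups: quantile split
# ---------------------------------------------------------------------------

def _ordered(pi: PrognosticIndex):
    order = np.argsort(pi.pi, kind="stable")
    return order, pi.pi[order]


def _block_sizes(n: int, k: int) -> np.ndarray:
    """Contiguous block sizes differing by <= 1, remainder to low-risk side."""
    base, rem = divmod(n, k)
    return np.array([base + 1 if g < rem else base for g in range(k)])


def _grouping_from_boundaries(pi: PrognosticIndex, time, event, order,
                              pi_sorted, boundaries, method, min_group_size,
                              scan=None, notes=None) -> RiskGrouping:
    n = pi.pi.size
    k = len(boundaries) + 1
    labels_sorted = np.empty(n, dtype=int)
    edges = [0, *boundaries, n]
    for g in range(k):
        labels_sorted[edges[g]:edges[g + 1]] = g + 1
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    split_points = np.array([(pi_sorted[b - 1] + pi_sorted[b]) / 2.0
                             for b in boundaries])
    separation = logrank_test(time, event, labels)
    return RiskGrouping(labels, split_points, method, separation,
                        min_group_size, k, scan or {}, notes or {})


def assign_groups_quantile(pi: PrognosticIndex, time, event, k=2) -> RiskGrouping:
    """Split the ordered PI into k contiguous groups of (near-)equal size.

    For k = 2 and even n this is the median split.  With odd remainders the
    extra samples go to the lower-risk groups.  Ties in PI are kept in
    sorted order (stable), so labels remain monotone in the PI.
    """
    n = pi.pi.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} groups")
    order, pi_sorted = _ordered(pi)
    boundaries = np.cumsum(_block_sizes(n, k))[:-1].tolist()
    return _grouping_from_boundaries(pi, time, event, order, pi_sorted,
                                     boundaries, "quantile", 1)


# ---------------------------------------------------------------------------
# Risk groups: minimum-p-value split
# ---------------------------------------------------------------------------

def _logrank_scan(time, event, candidates):
    """Two-group log-rank chi-square for every candidate boundary.

    ``time``/``event`` must already be arranged in PI-ascending order; a
    candidate ``b`` splits positions [0, b) (low risk) from [b, n) (high).
    Vectorized over all candidates via suffix sums on the risk-set and
    death indicator matrices; agrees with :func:`sigrisk.survival.logrank_test`.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    candidates = np.asarray(candidates, dtype=int)
    ev_times = np.unique(time[event == 1])
    if ev_times.size == 0:
        return np.zeros(candidates.size), np.ones(candidates.size)
    atrisk = time[None, :] >= ev_times[:, None]
    death = (time[None, :] == ev_times[:, None]) & (event[None, :] == 1)
    # suffix sums: column b = totals over positions >= b (the high group)
    N1 = np.cumsum(atrisk[:, ::-1], axis=1)[:, ::-1].astype(float)
    O1 = np.cumsum(death[:, ::-1], axis=1)[:, ::-1].astype(float)
    N = atrisk.sum(axis=1).astype(float)[:, None]
    d = death.sum(axis=1).astype(float)[:, None]
    N1b, O1b = N1[:, candidates], O1[:, candidates]
    frac = N1b / N
    U = (O1b - d * frac).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        V = np.where(N > 1, d * frac * (1 - frac) * (N - d) / np.maximum(N - 1, 1), 0.0)
    Vs = V.sum(axis=0)
    chi2 = np.where(Vs > 0, U * U / np.where(Vs > 0, Vs, 1.0), 0.0)
    p = stats.chi2.sf(chi2, 1)
    p = np.where(chi2 > 0, p, 1.0)
    return chi2, p


def _admissible(pi_sorted, lo, hi):
    """Boundary positions in [lo, hi] that do not split tied PI values.

    A tied run is kept together on the lower-risk side, so a boundary is
    admissible only where the PI strictly increases.
    """
    b = np.arange(max(lo, 1), min(hi, pi_sorted.size - 1) + 1)
    return b[pi_sorted[b - 1] < pi_sorted[b]]


def optimize_groups(pi: PrognosticIndex, time, event, k=2,
                    min_group_size=None, max_cycles=100) -> RiskGrouping:
    """Choose risk-group boundaries minimizing the log-rank p-value.

    k = 2: exhaustive scan over all admissible split positions (each group
    at least ``min_group_size``).  k > 2: boundaries start at the quantile
    split and are refined one at a time, left to right, by the same
    two-group scan restricted to the samples of the two adjacent groups,
    until a full cycle moves nothing.  Tied p-values break to the earliest
    boundary position, making the result deterministic.
    """
    n = pi.pi.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if min_group_size is None:
        min_group_size = default_min_group_size(n)
    if n < k * min_group_size:
        raise ValueError(f"need n >= k*min_group_size = {k * min_group_size}, "
                         f"got {n}")
    order, pi_sorted = _ordered(pi)
    t_ord = np.asarray(time, dtype=float)[order]
    e_ord = np.asarray(event)[order]
    notes = {}

    if k == 2:
        cands = _admissible(pi_sorted, min_group_size, n - min_group_size)
        if cands.size == 0:
            raise ValueError("no admissible split point (PI ties or "
                             "min_group_size too large)")
        chi2, p = _logrank_scan(t_ord, e_ord, cands)
        best = int(np.argmin(p))
        boundaries = [int(cands[best])]
        scan = {"positions": cands, "p_values": p, "chi2": chi2,
                "chosen": boundaries[0]}
        return _grouping_from_boundaries(pi, time, event, order, pi_sorted,
                                         boundaries, "optimized",
                                         min_group_size, scan, notes)

    # k > 2: coordinate-wise refinement from the quantile initialization
    quantile_b = np.cumsum(_block_sizes(n, k))[:-1].tolist()
    boundaries = []
    prev = 0
    for i, b in enumerate(quantile_b):
        lo = prev + min_group_size
        hi = n - (k - 1 - i) * min_group_size
        cands = _admissible(pi_sorted, lo, hi)
        if cands.size == 0:
            raise ValueError("no admissible boundary configuration")
        boundaries.append(int(cands[np.argmin(np.abs(cands - b))]))
        prev = boundaries[-1]

    def boundary_p(i, b):
        lo_edge = boundaries[i - 1] if i > 0 else 0
        hi_edge = boundaries[i + 1] if i + 1 < len(boundaries) else n
        seg_t = t_ord[lo_edge:hi_edge]
        seg_e = e_ord[lo_edge:hi_edge]
        _, pvals = _logrank_scan(seg_t, seg_e, np.array([b - lo_edge]))
        return float(pvals[0])

    cycles = 0
    for cycles in range(1, max_cycles + 1):
        changed = False
        for i in range(len(boundaries)):
            lo_edge = boundaries[i - 1] if i > 0 else 0
            hi_edge = boundaries[i + 1] if i + 1 < len(boundaries) else n
            lo = lo_edge + min_group_size
            hi = hi_edge - min_group_size
            local = _admissible(pi_sorted, lo, hi)
            local = local[(local > lo_edge) & (local < hi_edge)]
            if local.size == 0:
                continue
            seg_t = t_ord[lo_edge:hi_edge]
            seg_e = e_ord[lo_edge:hi_edge]
            _, pvals = _logrank_scan(seg_t, seg_e, local - lo_edge)
            best = int(local[np.argmin(pvals)])
            if best != boundaries[i] and \
                    float(np.min(pvals)) < boundary_p(i, boundaries[i]) - 1e-15:
                boundaries[i] = best
                changed = True
        if not changed:
            break
    else:
        notes["max_cycles_hit"] = True
        logger.warning("boundary refinement hit the %d-cycle cap", max_cycles)
    notes["cycles"] = cycles
    scan = {"boundaries": list(boundaries)}
    return _grouping_from_boundaries(pi, time, event, order, pi_sorted,
                                     boundaries, "optimized", min_group_size,
                                     scan, notes)


# ---------------------------------------------------------------------------
# Signature toggling, train/test, stratified analysis
# ---------------------------------------------------------------------------

def toggle_genes(sig: GeneSignature, active) -> GeneSignature:
    """Restrict a signature to an active subset of its identifiers.

    Any fitted coefficients for the previous gene set are stale after this;
    callers must refit.
    """
    active = list(active)
    if not active:
        raise ValueError("active gene set is empty")
    known = set(sig.identifiers)
    unknown = [a for a in active if a not in known]
    if unknown:
        raise ValueError("not in signature: " + ", ".join(map(str, unknown)))
    active_set = set(active)
    entries = [(ident, w) for ident, w in sig.entries if ident in active_set]
    return GeneSignature(entries, id_space=sig.id_space)


def _evaluate(expr, clinical, betas, grouping_cfg, grouping=None):
    """PI -> groups -> (log-rank, HR if 2 groups, concordance)."""
    pi = compute_pi(expr, betas)
    if grouping is None:
        k = grouping_cfg.get("k", 2)
        if grouping_cfg.get("method", "quantile") == "optimized":
            grouping = optimize_groups(pi, clinical.time, clinical.event, k=k,
                                       min_group_size=grouping_cfg.get("min_group_size"))
        else:
            grouping = assign_groups_quantile(pi, clinical.time, clinical.event, k=k)
        labels = grouping.labels
        separation = grouping.separation
    else:  # apply existing thresholds (test set)
        labels = grouping.assign_new(pi.pi)
        separation = logrank_test(clinical.time, clinical.event, labels) \
            if len(np.unique(labels)) >= 2 else None
    res = {"pi": pi, "labels": labels, "grouping": grouping,
           "logrank": separation}
    if separation is not None and len(np.unique(labels)) == 2 \
            and clinical.event.sum() > 0:
        res["hazard_ratio"] = hazard_ratio(clinical.time, clinical.event, labels)
    try:
        res["concordance"] = concordance_index(pi.pi, clinical.time, clinical.event)
    except ValueError:
        res["concordance"] = None
    return res


def train_test_run(expr: ExpressionMatrix, clinical: ClinicalTable,
                   sig: GeneSignature, train_ids, test_ids,
                   mode="cox", grouping_cfg=None):
    """Fit on training samples only; evaluate train and test separately.

    Betas come from the training set, the PI is computed on both sets with
    those betas, and risk thresholds learned on the training PI are applied
    unchanged to the test set.
    """
    grouping_cfg = dict(grouping_cfg or {})
    train_ids, test_ids = list(train_ids), list(test_ids)
    if not test_ids:
        raise ValueError("test set is empty")
    if not train_ids:
        raise ValueError("train set is empty")
    overlap = set(train_ids) & set(test_ids)
    if overlap:
        raise ValueError("train/test overlap: " + ", ".join(sorted(map(str, overlap))))
    missing = [s for s in train_ids + test_ids if s not in set(expr.sample_ids)]
    if missing:
        raise ValueError("unknown sample ids: " + ", ".join(map(str, missing)))

    ex_tr, cl_tr = expr.subset_samples(train_ids), clinical.subset(train_ids)
    ex_te, cl_te = expr.subset_samples(test_ids), clinical.subset(test_ids)
    betas, fit, ex_tr = fit_or_weights(ex_tr, cl_tr, sig, mode=mode)
    if ex_tr.probe_ids != ex_te.probe_ids:  # genes dropped during the fit
        rows = [ex_te.probe_ids.index(g) for g in ex_tr.probe_ids]
        ex_te = ExpressionMatrix(list(ex_tr.probe_ids), list(ex_te.sample_ids),
                                 ex_te.values[rows], dict(ex_te.annotation))

    train_res = _evaluate(ex_tr, cl_tr, betas, grouping_cfg)
    test_res = _evaluate(ex_te, cl_te, betas, grouping_cfg,
                         grouping=train_res["grouping"])
    return {"fit": fit, "betas": betas, "train": train_res, "test": test_res}


def stratified_run(expr: ExpressionMatrix, clinical: ClinicalTable,
                   sig: GeneSignature, stratum_col: str,
                   mode="cox", grouping_cfg=None, min_stratum_n=20):
    """Run the full pipeline independently within each clinical stratum.

    Strata below ``min_stratum_n`` are skipped with a note.  Returns a dict
    with per-stratum results and a summary of log-rank p and concordance.
    """
    grouping_cfg = dict(grouping_cfg or {})
    if stratum_col not in clinical.covariates.columns:
        raise ValueError(f"no such covariate: {stratum_col!r}")
    col = clinical.covariates[stratum_col]
    results, skipped = {}, {}
    for level in sorted(col.dropna().unique(), key=str):
        ids = [s for s, v in zip(clinical.sample_ids, col) if v == level]
        if len(ids) < min_stratum_n:
            skipped[level] = f"only {len(ids)} samples (< {min_stratum_n})"
            continue
        ex, cl = expr.subset_samples(ids), clinical.subset(ids)
        betas, fit, ex = fit_or_weights(ex, cl, sig, mode=mode)
        res = _evaluate(ex, cl, betas, grouping_cfg)
        res["fit"] = fit
        results[level] = res
    if not results:
        raise ValueError("all strata below the minimum sample size")
    summary = []
    for level, res in results.items():
        summary.append({
            "stratum": level,
            "n": int(res["labels"].size),
            "logrank_p": res["logrank"].p_value if res["logrank"] else np.nan,
            "c_index": res["concordance"].c_index if res["concordance"] else np.nan,
        })
    return {"strata": results, "skipped": skipped, "summary": summary}


# ---------------------------------------------------------------------------
# Selection-bias diagnostic for the minimum-p split
# ---------------------------------------------------------------------------

def split_pvalue_bias_check(pi: PrognosticIndex, time, event,
                            n_perm=1000, seed=0, k=2,
                            min_group_size=None) -> dict:
    """Permutation-adjusted p-value for the minimum-p optimized split.

    Permutes (time, event) jointly against the PI ``n_perm`` times,
    re-runs the cutpoint scan, and reports the add-one-smoothed fraction of
    permuted minimum p-values at or below the observed minimum:
    ``(1 + #better) / (1 + n_perm)``.  This is an honest, selection-aware
    p-value for the optimized grouping.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a stable tail estimate")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    n = pi.pi.size
    if min_group_size is None:
        min_group_size = default_min_group_size(n)
    order, pi_sorted = _ordered(pi)
    cands = _admissible(pi_sorted, min_group_size, n - min_group_size)
    if cands.size == 0:
        raise ValueError("no admissible split point")

    def min_p(t, e):
        _, p = _logrank_scan(t[order], e[order], cands)
        return float(np.min(p))

    obs = min_p(time, event)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if min_p(time[perm], event[perm]) <= obs:
            count += 1
    adjusted = (1 + count) / (1 + n_perm)
    return {"observed_min_p": obs, "adjusted_p": float(adjusted),
            "n_perm": n_perm}
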