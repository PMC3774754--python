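"""Multi-cohort expression merging ("meta-base" construction).

Cohorts profiled on a common platform are combined into one matrix:
each cohort is quantile-normalized sample-wise, then for every shared
probeset each cohort's values are shifted so that all cohorts share a
common mean (the unweighted grand mean of the cohort means) while each
cohort's standard deviation is left untouched, and finally the columns
are concatenated over the intersection of probeset ids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, quantile_normalize

__all__ = ["MetaBase", "merge_cohorts"]


@dataclass
class MetaBase:
    """Merged expression matrix with a per-sample cohort map and audit trail.

    ``audit`` records, per (probeset, cohort), the pre- and post-merge mean
    and standard deviation, so the mean-equalization step can be verified.
    """

    expression: ExpressionMatrix
    cohort_of: dict            # sample_id -> cohort name
    audit: pd.DataFrame

    def cohort_labels(self) -> np.ndarray:
        return np.array([self.cohort_of[s] for s in self.expression.sample_ids])


def merge_cohorts(cohorts, qnorm=True) -> MetaBase:
    """Merge >= 2 cohorts into a meta-base.

    ``cohorts`` is a list of ``(name, ExpressionMatrix)`` pairs.  Only
    probesets present in every cohort are kept.  Each cohort needs at
    least 2 samples for its standard deviation to be defined.
    """
    cohorts = list(cohorts)
    if len(cohorts) < 2:
        raise ValueError("need at least 2 cohorts to merge")
    names = [name for name, _ in cohorts]
    if len(set(names)) != len(names):
        raise ValueError("cohort names must be unique")
    for name, ex in cohorts:
        if len(ex.sample_ids) < 2:
            raise ValueError(f"cohort {name!r} has a single sample; "
                             "standard deviation undefined")

    shared = set(cohorts[0][1].probe_ids)
    for _, ex in cohorts[1:]:
        shared &= set(ex.probe_ids)
    if not shared:
        raise ValueError("no probesets shared across all cohorts")
    # deterministic row order regardless of cohort input order
    shared = sorted(shared)

    blocks, audit_rows, cohort_of = [], [], {}
    for name, ex in cohorts:
        rows = [ex.probe_ids.index(p) for p in shared]
        vals = ex.values[rows].astype(float)
        if qnorm:
            vals = quantile_normalize(vals)
        blocks.append(vals)
        for s in ex.sample_ids:
            if s in cohort_of:
                raise ValueError(f"sample id {s!r} appears in two cohorts")
            cohort_of[s] = name

    pre_means = np.stack([b.mean(axis=1) for b in blocks])   # cohorts x probes
    target = pre_means.mean(axis=0)                          # grand mean of cohort means
    merged_blocks = []
    for (name, ex), block, mean_c in zip(cohorts, blocks, pre_means):
        shifted = block - mean_c[:, None] + target[:, None]
        merged_blocks.append(shifted)
        sd_pre = block.std(axis=1, ddof=1)
        sd_post = shifted.std(axis=1, ddof=1)
        for i, probe in enumerate(shared):
            audit_rows.append({
                "probeset": probe, "cohort": name,
                "mean_pre": mean_c[i],
                "mean_post": shifted[i].mean(),
                "sd_pre": sd_pre[i], "sd_post": sd_post[i],
                "target_mean": target[i],
            })

    sample_ids = [s for _, ex in cohorts for s in ex.sample_ids]
    merged = ExpressionMatrix(list(shared), sample_ids,
                              np.hstack(merged_blocks))
    audit = pd.DataFrame(audit_rows)
    return MetaBase(merged, cohort_of, audit)
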