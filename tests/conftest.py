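import numpy as np
import pytest

from sigrisk import SimConfig, simulate_dataset
from sigrisk.risk import PrognosticIndex


@pytest.fixture
def small_cohort():
    """150-sample cohort with 5 prognostic genes and known truth."""
    cfg = SimConfig(n=150, betas=(0.7, -0.5, 0.3, 0.0, 0.0), q_noise=5, seed=11)
    return simulate_dataset(cfg)


def make_pi(values):
    """Wrap raw scores in a PrognosticIndex for grouping functions."""
    values = np.asarray(values, dtype=float)
    return PrognosticIndex([f"s{i}" for i in range(values.size)], values,
                           "user_weights", np.array([1.0]), ["g"])


def random_censored(rng, n, cens_frac=0.3):
    """Exponential event times with independent exponential censoring."""
    T = rng.exponential(1.0, n)
    C = rng.exponential((1 - cens_frac) / cens_frac, n)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    return np.maximum(time, 1e-9), event


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive; loop-based)
# ---------------------------------------------------------------------------

def km_oracle(time, event):
    """Direct product over risk sets at each distinct event time."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    out = {}
    s = 1.0
    for t in sorted(set(time[event == 1])):
        n_at_risk = sum(1 for x in time if x >= t)
        d = sum(1 for x, e in zip(time, event) if x == t and e == 1)
        s *= 1.0 - d / n_at_risk
        out[t] = s
    return out


def logrank_oracle(time, event, group):
    """Explicit O-E/V computation of the k-sample log-rank chi-square."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    levels = sorted(set(group.tolist()))
    k = len(levels)
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in sorted(set(time[event == 1])):
        at = time >= t
        n = at.sum()
        d = int(((time == t) & (event == 1)).sum())
        for a, ga in enumerate(levels):
            na = (at & (group == ga)).sum()
            O[a] += ((time == t) & (event == 1) & (group == ga)).sum()
            E[a] += d * na / n
            if n > 1:
                for b, gb in enumerate(levels):
                    nb = (at & (group == gb)).sum()
                    delta = 1.0 if a == b else 0.0
                    V[a, b] += d * (n - d) / (n - 1) * (na / n) * (delta - nb / n)
    z = (O - E)[:-1]
    Vs = V[:-1, :-1]
    if k == 2:
        return float(z[0] ** 2 / Vs[0, 0]) if Vs[0, 0] > 0 else 0.0
    return float(z @ np.linalg.solve(Vs, z))


def concordance_oracle(score, time, event):
    """O(n^2) pairwise enumeration of Harrell's C."""
    n = len(score)
    num = 0.0
    pairs = 0
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                pairs += 1
                if score[i] > score[j]:
                    num += 1.0
                elif score[i] == score[j]:
                    num += 0.5
    return num / pairs, pairs


def mann_whitney_auc(pos, neg):
    """Rank-sum AUC of positives vs negatives, ties half-credit."""
    num = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                num += 1.0
            elif a == b:
                num += 0.5
    return num / (len(pos) * len(neg))
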