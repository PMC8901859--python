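"""Functional typing and spatial dispersion of neuron groups.

Neurons are classified by their responses to the weak (S1) and strong
(S4) stimuli into four types: #1 responds only to S4, #2 only to S1,
#3 to both, #4 to neither.  Whether a functional group is spatially
clustered is quantified by a nearest-neighbor-distance (NND) statistic
robust to unequal group sizes: for each neuron of a group, draw a
random k-subgroup of k other neurons, take the distance to the nearest
of them, and average over repeated draws until the running mean
converges.  The group's dispersion is the mean of these per-neuron
converged NNDs — smaller for clustered groups, larger for dispersed
ones, and comparable across groups of different sizes because k is
fixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .traces import ResponseTable

TYPE_LABELS = {1: "S4-only", 2: "S1-only", 3: "both", 4: "neither"}


def assign_types(
    table: ResponseTable,
    weak: str = "S1",
    strong: str = "S4",
    p_threshold: float = 0.0,
) -> np.ndarray:
    """Four-type functional classification from response probabilities.

    A neuron is "responsive" to a stimulus when its response probability
    exceeds ``p_threshold`` (default 0: any response across trials).
    Returns integer labels 1..4 per neuron.
    """
    p_weak = table.probability[weak].to_numpy()
    p_strong = table.probability[strong].to_numpy()
    r1 = p_weak > p_threshold
    r4 = p_strong > p_threshold
    out = np.full(p_weak.size, 4, dtype=int)
    out[r4 & ~r1] = 1
    out[r1 & ~r4] = 2
    out[r1 & r4] = 3
    return out


@dataclass
class NNDResult:
    """Converged random-k-subgroup NND estimates."""

    k: int
    per_neuron: pd.Series  # index: neuron position index; converged mean NND µm
    group_dispersion: dict  # group label -> mean of member NNDs
    reps_used: int  # maximum over neurons
    tol: float
    converged: bool
    per_neuron_reps: pd.Series | None = None


def _nested_min_chunk(
    dists: np.ndarray, ks: list[int], n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Min distance to a random k-subgroup, for each k, over ``n_reps``
    draws; subgroups are nested across k (first k of one random
    permutation), which makes the minima nonincreasing in k draw by
    draw."""
    m = dists.size
    kmax = max(ks)
    keys = rng.random((n_reps, m))
    rows = np.arange(n_reps)[:, None]
    part = np.argpartition(keys, kmax - 1, axis=1)[:, :kmax]
    order = np.argsort(keys[rows, part], axis=1)
    sel = part[rows, order]  # first kmax of a random permutation, in order
    prefmin = np.minimum.accumulate(dists[sel], axis=1)
    return prefmin[:, np.asarray(ks) - 1]  # (n_reps, len(ks))


def _converged_means(
    dists: np.ndarray,
    ks: list[int],
    tol: float,
    max_reps: int,
    window: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int, bool]:
    """Running means of the k-subgroup minima until, for every k, the
    relative change of the running mean stays below ``tol`` for
    ``window`` consecutive repetitions (capped at ``max_reps``)."""
    totals = np.zeros(len(ks))
    count = 0
    prev_mean = None
    while count < max_reps:
        n_new = min(window, max_reps - count)
        mins = _nested_min_chunk(dists, ks, n_new, rng)
        csum = totals[None, :] + np.cumsum(mins, axis=0)
        denom = (count + np.arange(1, n_new + 1))[:, None]
        means = csum / denom
        totals = csum[-1]
        count += n_new
        if prev_mean is not None:
            series = np.vstack([prev_mean, means])
            with np.errstate(divide="ignore", invalid="ignore"):
                rel = np.abs(np.diff(series, axis=0)) / np.where(
                    means == 0, 1.0, means
                )
            if n_new == window and np.all(rel < tol):
                return means[-1], count, True
        prev_mean = means[-1]
    return totals / count, count, False


def knn_subgroup_nnd(
    positions: np.ndarray,
    group_ids: np.ndarray | None = None,
    k: int = 5,
    tol: float = 1e-3,
    max_reps: int = 10000,
    window: int = 100,
    pool: str = "population",
    seed: int | np.random.Generator | None = None,
) -> NNDResult:
    """Random-k-subgroup NND dispersion per neuron and per group.

    For each neuron, k candidates are repeatedly drawn without
    replacement from the candidate pool — the whole recorded population
    minus the neuron itself (``pool="population"``, the default) or its
    own group (``pool="group"``) — and the distance to the nearest of
    the k is averaged until convergence (relative change of the running
    mean below ``tol`` for ``window`` consecutive draws, capped at
    ``max_reps``).
    """
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    if group_ids is None:
        group_ids = np.zeros(n, dtype=int)
    group_ids = np.asarray(group_ids)
    if group_ids.size != n:
        raise ValueError("group_ids must cover all neurons")
    if pool not in ("population", "group"):
        raise ValueError(f"unknown pool {pool!r}")
    D = cdist(positions, positions)
    rng = np.random.default_rng(seed)
    per = np.full(n, np.nan)
    per_reps = np.zeros(n, dtype=int)
    all_conv = True
    for i in range(n):
        if pool == "population":
            cand = np.delete(np.arange(n), i)
        else:
            cand = np.flatnonzero((group_ids == group_ids[i]))
            cand = cand[cand != i]
        if cand.size < k:
            raise ValueError(
                f"neuron {i}: candidate pool of {cand.size} smaller than k={k}"
            )
        if cand.size == k:
            per[i] = D[i, cand].min()  # single possible subgroup
            continue
        mean, reps, conv = _converged_means(D[i, cand], [k], tol, max_reps, window, rng)
        per[i] = mean[0]
        per_reps[i] = reps
        all_conv &= conv
    dispersion = {
        g: float(per[group_ids == g].mean()) for g in np.unique(group_ids)
    }
    return NNDResult(
        k=k,
        per_neuron=pd.Series(per),
        group_dispersion=dispersion,
        reps_used=int(per_reps.max()),
        tol=tol,
        converged=all_conv,
        per_neuron_reps=pd.Series(per_reps),
    )


def nnd_k_sweep(
    positions: np.ndarray,
    group_ids: np.ndarray | None = None,
    ks=range(5, 11),
    tol: float = 1e-3,
    max_reps: int = 10000,
    window: int = 100,
    pool: str = "population",
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Group dispersion across a range of subgroup sizes k.

    Draws are shared across k (nested subgroups), so each neuron's mean
    NND — and therefore each group's dispersion — is nonincreasing in k
    by construction, matching the order-statistics expectation that the
    minimum over more samples cannot grow.
    """
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    if group_ids is None:
        group_ids = np.zeros(n, dtype=int)
    group_ids = np.asarray(group_ids)
    ks = sorted(int(k) for k in ks)
    D = cdist(positions, positions)
    rng = np.random.default_rng(seed)
    per = np.full((n, len(ks)), np.nan)
    for i in range(n):
        if pool == "population":
            cand = np.delete(np.arange(n), i)
        else:
            cand = np.flatnonzero(group_ids == group_ids[i])
            cand = cand[cand != i]
        if cand.size < max(ks):
            raise ValueError(
                f"neuron {i}: candidate pool of {cand.size} smaller than k={max(ks)}"
            )
        means, _, _ = _converged_means(D[i, cand], ks, tol, max_reps, window, rng)
        per[i] = means
    rows = {}
    for g in np.unique(group_ids):
        vals = per[group_ids == g].mean(axis=0)
        assert np.all(np.diff(vals) <= 1e-12), "dispersion must be nonincreasing in k"
        rows[g] = vals
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(ks))


def exact_subgroup_nnd(dists: np.ndarray, k: int) -> float:
    """Exact expectation of the minimum distance over all C(m, k)
    k-subgroups of one neuron's candidate pool (order-statistics closed
    form): P(min = d_(j)) = C(m−1−j, k−1)/C(m, k) for sorted d."""
    d = np.sort(np.asarray(dists, dtype=float))
    m = d.size
    if k < 1 or k > m:
        raise ValueError("k out of range")
    tot = comb(m, k)
    return float(sum(comb(m - 1 - j, k - 1) * d[j] for j in range(m - k + 1)) / tot)
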