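"""Time-resolved detection of behavioural responses to stimulation.

Frames are aligned to pulse onsets and pooled across pulses of the same
class (short or long) and across worms of the same condition.  For every
feature and pulse-relative time bin the treatment and control value
distributions are compared by the Jensen-Shannon divergence (base 2, so in
[0, 1]) of their histograms on a shared grid; significance comes from a
permutation test that reshuffles worms (not frames, to respect within-worm
correlation), and p-values are corrected within strain by the
Benjamini-Hochberg step-up procedure at FDR 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from .io import PulseProtocol, ValidationError

#: default pulse-relative (start, stop) bins in seconds
DEFAULT_BINS = {
    "short": [(-5.0, 0.0), (0.0, 5.0), (5.0, 15.0)],
    "long": [(-30.0, 0.0), (0.0, 10.0), (10.0, 90.0), (90.0, 120.0)],
}

META_COLUMNS = ("worm_id", "strain", "condition", "time_s")


# ---------------------------------------------------------------------------
# alignment


def align_to_pulses(
    timestamps: np.ndarray,
    values: np.ndarray,
    pulses: list[tuple[float, float]],
    bins: list[tuple[float, float]],
    check_coverage: bool = True,
) -> dict[tuple[float, float], np.ndarray]:
    """Pool one worm's frame values into pulse-relative time bins.

    Values are concatenated across all pulses of the list; a frame enters at
    most one bin per pulse.  Raises if a pulse lies outside the recording.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    values = np.asarray(values, dtype=float)
    if check_coverage:
        uncovered = [
            p
            for p in pulses
            if p[0] < timestamps[0] or p[1] > timestamps[-1] + 1e-9
        ]
        if uncovered:
            raise ValidationError(
                f"pulses outside the recorded time range: {uncovered}"
            )
    out: dict[tuple[float, float], list[np.ndarray]] = {tuple(b): [] for b in bins}
    for start, _stop in pulses:
        rel = timestamps - start
        for lo, hi in bins:
            sel = (rel >= lo) & (rel < hi)
            out[(lo, hi)].append(values[sel])
    return {
        b: (np.concatenate(v) if v else np.array([])) for b, v in out.items()
    }


# ---------------------------------------------------------------------------
# histograms and divergence


def histogram_grid(
    pooled: np.ndarray, n_bins: int = 25, lo_pct: float = 1.0, hi_pct: float = 99.0
) -> np.ndarray:
    """Shared histogram edges spanning the pooled 1st-99th percentile range."""
    finite = pooled[np.isfinite(pooled)]
    if finite.size == 0:
        raise ValidationError("cannot build a histogram grid from no finite values")
    lo, hi = np.percentile(finite, [lo_pct, hi_pct])
    if hi <= lo:
        lo, hi = lo - 0.5, hi + 0.5
    return np.linspace(lo, hi, n_bins + 1)


def histogram(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Normalized histogram on a shared grid; out-of-range values clamp into
    the end bins so every finite value is counted."""
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return np.full(len(edges) - 1, np.nan)
    clipped = np.clip(finite, edges[0], edges[-1])
    counts, _ = np.histogram(clipped, bins=edges)
    return counts / counts.sum()


def jensen_shannon(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence with base-2 logarithm: JSD(p, q) =
    H((p+q)/2) - (H(p)+H(q))/2, in [0, 1]; 0 log 0 = 0."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValidationError("histograms must share the same grid")

    def _entropy(x: np.ndarray) -> float:
        nz = x[x > 0]
        return float(-(nz * np.log2(nz)).sum())

    m = 0.5 * (p + q)
    return _entropy(m) - 0.5 * (_entropy(p) + _entropy(q))


# ---------------------------------------------------------------------------
# permutation test


def permutation_test(
    treatment: list[np.ndarray],
    control: list[np.ndarray],
    n_perm: int = 1000,
    seed: int = 0,
    n_bins: int = 25,
) -> tuple[float, float]:
    """Worm-level permutation p-value for the JSD between two groups.

    ``treatment`` and ``control`` are per-worm value arrays.  The statistic
    is the JSD between the pooled histograms of the two groups on a grid
    fixed from all values; permutations reshuffle which worms carry the
    treatment label.  Returns (observed JSD, p).  With fewer than 20
    distinct assignments the null is enumerated exactly (with a warning).
    """
    treatment = [np.asarray(v, dtype=float) for v in treatment if len(v)]
    control = [np.asarray(v, dtype=float) for v in control if len(v)]
    if not treatment or not control:
        raise ValidationError("both groups need at least one worm with data")
    per_worm = treatment + control
    n_t, n_w = len(treatment), len(per_worm)
    edges = histogram_grid(np.concatenate(per_worm), n_bins=n_bins)
    counts = np.stack(
        [
            np.histogram(np.clip(v[np.isfinite(v)], edges[0], edges[-1]), bins=edges)[0]
            for v in per_worm
        ]
    ).astype(float)

    def _stat(t_idx: np.ndarray) -> float:
        mask = np.zeros(n_w, dtype=bool)
        mask[t_idx] = True
        ct = counts[mask].sum(axis=0)
        cc = counts[~mask].sum(axis=0)
        if ct.sum() == 0 or cc.sum() == 0:
            return np.nan
        return jensen_shannon(ct / ct.sum(), cc / cc.sum())

    observed = _stat(np.arange(n_t))
    if comb(n_w, n_t) < 20:
        warnings.warn(
            "fewer than 20 distinct worm assignments; enumerating the null exactly",
            stacklevel=2,
        )
        stats = [
            _stat(np.asarray(idx)) for idx in combinations(range(n_w), n_t)
        ]
        p = float(np.mean([s >= observed for s in stats]))
        return observed, p
    rng = np.random.default_rng(seed)
    masks = np.zeros((n_perm, n_w), dtype=bool)
    for i in range(n_perm):
        masks[i, rng.permutation(n_w)[:n_t]] = True
    ct = masks.astype(float) @ counts
    cc = counts.sum(axis=0) - ct
    stats = _jsd_rows(
        ct / ct.sum(axis=1, keepdims=True), cc / cc.sum(axis=1, keepdims=True)
    )
    exceed = int(np.sum(stats >= observed))
    return observed, (1 + exceed) / (1 + n_perm)


def _jsd_rows(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Row-wise base-2 Jensen-Shannon divergence of two stacks of histograms."""

    def _entropy_rows(x: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(x > 0, x * np.log2(np.where(x > 0, x, 1.0)), 0.0)
        return -term.sum(axis=1)

    m = 0.5 * (p + q)
    return _entropy_rows(m) - 0.5 * (_entropy_rows(p) + _entropy_rows(q))


# ---------------------------------------------------------------------------
# multiple testing


def benjamini_hochberg(
    p_values: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted q-values and rejections at
    FDR ``alpha``."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, q <= alpha


# ---------------------------------------------------------------------------
# experiment-level comparison


def _feature_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in META_COLUMNS]


def _pulse_classes(protocol: PulseProtocol) -> dict[str, list[tuple[float, float]]]:
    out = {}
    if protocol.short_pulses:
        out["short"] = protocol.short_pulses
    if protocol.long_pulses:
        out["long"] = protocol.long_pulses
    return out


def compare_conditions(
    df: pd.DataFrame,
    protocol: PulseProtocol,
    bins: dict[str, list[tuple[float, float]]] | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    n_bins: int = 25,
) -> pd.DataFrame:
    """JSD + permutation test for every (feature, pulse class, time bin).

    ``df`` holds per-frame feature values for one strain with columns
    ``worm_id, strain, condition, time_s`` plus one column per feature;
    ``condition`` must contain ``treatment`` and ``control``.  Returns one
    row per comparison with ``jsd``, ``p_value``, ``q_value`` and ``reject``
    (BH across all rows, i.e. within the strain).
    """
    bins = bins or DEFAULT_BINS
    features = _feature_columns(df)
    groups: dict[str, list[pd.DataFrame]] = {"treatment": [], "control": []}
    for (worm, cond), sub in df.groupby(["worm_id", "condition"], sort=True):
        if cond not in groups:
            raise ValidationError(f"unknown condition {cond!r}")
        groups[cond].append(sub)
    rows = []
    rng = np.random.default_rng(seed)
    for pulse_class, pulses in _pulse_classes(protocol).items():
        for lo, hi in bins[pulse_class]:
            for feat in features:
                pooled = {
                    cond: [
                        align_to_pulses(
                            sub["time_s"].to_numpy(),
                            sub[feat].to_numpy(),
                            pulses,
                            [(lo, hi)],
                        )[(lo, hi)]
                        for sub in subs
                    ]
                    for cond, subs in groups.items()
                }
                jsd, p = permutation_test(
                    pooled["treatment"],
                    pooled["control"],
                    n_perm=n_perm,
                    seed=int(rng.integers(2**31 - 1)),
                    n_bins=n_bins,
                )
                rows.append(
                    {
                        "feature": feat,
                        "pulse_class": pulse_class,
                        "bin_start": lo,
                        "bin_stop": hi,
                        "jsd": jsd,
                        "p_value": p,
                    }
                )
    result = pd.DataFrame(rows)
    q, reject = benjamini_hochberg(result["p_value"].to_numpy(), alpha=alpha)
    result["q_value"] = q
    result["reject"] = reject
    return result


# ---------------------------------------------------------------------------
# between-strain distances


@dataclass
class BinnedResponse:
    """Histograms of one strain/condition per (feature, pulse class, bin)."""

    strain: str
    condition: str
    histograms: dict[tuple[str, str, tuple[float, float]], np.ndarray]


def binned_responses(
    dfs_by_strain: dict[str, pd.DataFrame],
    protocol: PulseProtocol,
    condition: str,
    bins: dict[str, list[tuple[float, float]]] | None = None,
    n_bins: int = 25,
) -> dict[str, BinnedResponse]:
    """Per-strain pooled histograms on grids shared across strains."""
    bins = bins or DEFAULT_BINS
    features = None
    pooled: dict[str, dict] = {}
    for strain, df in dfs_by_strain.items():
        df = df[df["condition"] == condition]
        feats = _feature_columns(df)
        if features is None:
            features = feats
        missing = sorted(set(features) - set(feats))
        if missing:
            raise ValidationError(f"strain {strain!r} is missing features {missing}")
        pooled[strain] = {}
        for pulse_class, pulses in _pulse_classes(protocol).items():
            for b in bins[pulse_class]:
                for feat in features:
                    vals = align_to_pulses(
                        df["time_s"].to_numpy(), df[feat].to_numpy(), pulses, [b]
                    )[tuple(b)]
                    pooled[strain][(feat, pulse_class, tuple(b))] = vals
    keys = next(iter(pooled.values())).keys()
    out = {
        strain: BinnedResponse(strain=strain, condition=condition, histograms={})
        for strain in pooled
    }
    for key in keys:
        edges = histogram_grid(
            np.concatenate([pooled[s][key] for s in pooled]), n_bins=n_bins
        )
        for strain in pooled:
            out[strain].histograms[key] = histogram(pooled[strain][key], edges)
    return out


def strain_distance_matrix(
    responses: dict[str, BinnedResponse]
) -> tuple[list[str], np.ndarray]:
    """Symmetric matrix of median JSD across (feature, bin) histogram pairs."""
    strains = sorted(responses)
    keys = set(responses[strains[0]].histograms)
    for s in strains[1:]:
        missing = sorted(keys - set(responses[s].histograms))
        if missing:
            raise ValidationError(f"strain {s!r} is missing histograms {missing[:3]}")
    n = len(strains)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            divs = []
            for key in keys:
                hi = responses[strains[i]].histograms[key]
                hj = responses[strains[j]].histograms[key]
                if np.isnan(hi).any() or np.isnan(hj).any():
                    continue
                divs.append(jensen_shannon(hi, hj))
            mat[i, j] = mat[j, i] = float(np.median(divs)) if divs else np.nan
    return strains, mat


def cluster_map(matrix: np.ndarray, labels: list[str]) -> dict:
    """Average-linkage hierarchical clustering of a distance matrix.

    Returns the scipy linkage, the deterministic leaf order and the matrix
    reordered accordingly (ready for heatmap export).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] != matrix.shape[1] or not np.allclose(matrix, matrix.T):
        raise ValidationError("cluster_map needs a symmetric distance matrix")
    condensed = squareform(matrix, checks=False)
    linkage = average(condensed)
    order = leaves_list(linkage).tolist()
    return {
        "linkage": linkage,
        "order": order,
        "labels": [labels[i] for i in order],
        "matrix": matrix[np.ix_(order, order)],
    }
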