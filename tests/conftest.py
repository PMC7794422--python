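"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's sweep/cumsum algorithms:
interval operations are checked against per-base membership arrays, the
enrichment statistic against a stepwise python loop, and BH against the
quadratic-time step-up definition.
"""

from __future__ import annotations

import numpy as np
import pytest

from tadtargets import (
    GenomicInterval,
    Peak,
    PeakSet,
    PipelineConfig,
    SimulationConfig,
    run_pipeline,
    simulate_bundle,
    write_fixture_bundle,
)

CHROM_LEN = 100_000  # toy chromosome for the per-base oracles


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def bundle():
    """The default synthetic fixture (seed 1, default study conditions)."""
    return simulate_bundle(SimulationConfig())


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    d = tmp_path_factory.mktemp("fixture") / "bundle"
    write_fixture_bundle(bundle, d)
    return d


@pytest.fixture(scope="session")
def pipeline_result(bundle, bundle_dir, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("pipeline") / "out"
    config = PipelineConfig(bundle_dir=str(bundle_dir), outdir=str(outdir))
    report = run_pipeline(config, bundle=bundle)
    return report, outdir


# ---------------------------------------------------------------------------
# random instance generators
# ---------------------------------------------------------------------------

def random_intervals(rng, n_max=50, chrom="chr1", length=CHROM_LEN):
    n = int(rng.integers(0, n_max + 1))
    out = []
    for _ in range(n):
        start = int(rng.integers(0, length - 1))
        end = int(rng.integers(start + 1, min(start + 2_000, length) + 1))
        out.append(GenomicInterval(chrom, start, end))
    return out


def as_peakset(intervals, factor="tf", label="X"):
    return PeakSet(
        [Peak(iv) for iv in intervals], {"factor": factor, "label": label}
    )


# ---------------------------------------------------------------------------
# per-base interval oracles
# ---------------------------------------------------------------------------

def paint(intervals, length=CHROM_LEN):
    arr = np.zeros(length, dtype=bool)
    for iv in intervals:
        arr[iv.start:iv.end] = True
    return arr


def runs_to_intervals(mask, chrom="chr1"):
    out = []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(diff == 1)[0] + 1)
    ends = list(np.nonzero(diff == -1)[0] + 1)
    if mask[0]:
        starts = [0] + starts
    if mask[-1]:
        ends = ends + [len(mask)]
    for s, e in zip(starts, ends):
        out.append(GenomicInterval(chrom, int(s), int(e)))
    return out


def brute_merge(intervals, min_gap=0, length=CHROM_LEN):
    """Close uncovered gaps of length <= min_gap between covered runs."""
    if not intervals:
        return []
    mask = paint(intervals, length)
    covered = runs_to_intervals(mask)
    filled = mask.copy()
    for prev, cur in zip(covered, covered[1:]):
        if cur.start - prev.end <= min_gap:
            filled[prev.end:cur.start] = True
    return runs_to_intervals(filled)


def brute_consensus_regions(interval_sets, k, length=CHROM_LEN):
    depth = np.zeros(length, dtype=int)
    for ivs in interval_sets:
        depth += paint(ivs, length).astype(int)
    return runs_to_intervals(depth >= k)


def brute_cooccupancy_counts(a_ivs, b_ivs, min_overlap=1):
    def hits(xs, ys):
        n = 0
        for x in xs:
            best = 0
            for y in ys:
                best = max(best, min(x.end, y.end) - max(x.start, y.start))
            if best >= min_overlap:
                n += 1
        return n

    n_shared = hits(a_ivs, b_ivs)
    return (len(a_ivs) - n_shared, len(b_ivs) - hits(b_ivs, a_ivs), n_shared)


# ---------------------------------------------------------------------------
# other oracles
# ---------------------------------------------------------------------------

def brute_hockey_cutoff(signals):
    """Exhaustive slope scan on the min-max scaled rank/signal curve."""
    s = sorted(float(v) for v in signals)
    n = len(s)
    if s[0] == s[-1]:
        return float("inf")
    for i in range(n - 1):
        x_i, x_j = i / (n - 1), (i + 1) / (n - 1)
        y_i = (s[i] - s[0]) / (s[-1] - s[0])
        y_j = (s[i + 1] - s[0]) / (s[-1] - s[0])
        if (y_j - y_i) / (x_j - x_i) > 1.0:
            return s[i]
    return float("inf")


def brute_es(genes, scores, members, weight_p=1):
    """Stepwise running-sum enrichment score (max signed deviation)."""
    n = len(genes)
    hit = [g in members for g in genes]
    n_hit = sum(hit)
    w = [abs(s) ** weight_p if weight_p else 1.0 for s in scores]
    denom = sum(wi for wi, h in zip(w, hit) if h)
    running = 0.0
    hi, lo = float("-inf"), float("inf")
    for i in range(n):
        if hit[i]:
            running += (w[i] / denom) if denom > 0 else 1.0 / n_hit
        else:
            running -= 1.0 / (n - n_hit)
        hi, lo = max(hi, running), min(lo, running)
    # positive extreme wins ties (same convention as the implementation)
    return hi if hi >= -lo - 1e-9 else lo


def brute_bh(pvalues):
    """Quadratic-time step-up BH: adj_i = min over p_j >= p_i of m*p_j/rank_j."""
    p = list(map(float, pvalues))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    for pos, i in enumerate(order):
        best = min(
            m * p[order[j]] / (j + 1) for j in range(pos, m)
        )
        adj[i] = min(best, 1.0)
    return adj
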