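"""Shared fixtures: planted ensembles, dose-response panels, tiny helpers."""

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from bindmode import synthetic as syn

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def quinine_pattern():
    return dict(syn.QUININE_POSE7_PATTERN)


@pytest.fixture(scope="session")
def panel_numbers():
    return sorted(syn.PANEL_RESIDUES)


@pytest.fixture(scope="session")
def quinine_ensemble():
    """Single-group planted ensemble realizing the quinine binding pattern."""
    spec = syn.PlantSpec(
        patterns=[dict(syn.QUININE_POSE7_PATTERN)],
        group_sizes=[6],
        jitter_sd=0.2,
        displacement=8.0,
        seed=101,
    )
    return syn.gen_pose_ensemble(spec)


@pytest.fixture(scope="session")
def all_kinds_ensemble():
    """Planted ensemble exercising all five interaction kinds."""
    spec = syn.PlantSpec(
        patterns=[dict(syn.ALL_KINDS_PATTERN)],
        group_sizes=[5],
        jitter_sd=0.1,
        displacement=8.0,
        seed=202,
    )
    return syn.gen_pose_ensemble(spec)


@pytest.fixture(scope="session")
def three_group_ensemble():
    """Three planted pose-groups with identical patterns, for clustering."""
    spec = syn.PlantSpec(
        patterns=[dict(syn.QUININE_POSE7_PATTERN)] * 3,
        group_sizes=[8, 7, 5],
        jitter_sd=0.3,
        displacement=8.0,
        seed=303,
    )
    return syn.gen_pose_ensemble(spec)


@pytest.fixture(scope="session")
def quinine_panel_table():
    """Quinine-like 8-mutant dose-response table with ground truth."""
    return syn.gen_dose_response(syn.quinine_panel_spec(seed=404))


def brute_force_average_linkage(D):
    """Independent exhaustive UPGMA: recompute every cross-cluster mean
    from the original matrix at each step; ties to smallest member pair."""
    D = np.asarray(D, float)
    clusters = [frozenset([i]) for i in range(len(D))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = float(
                    np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
                )
                reps = tuple(sorted((min(clusters[a]), min(clusters[b]))))
                key = (d, reps)
                if (
                    best is None
                    or d < best[0][0] - 1e-12
                    or (abs(d - best[0][0]) <= 1e-12 and reps < best[0][1])
                ):
                    best = (key, a, b)
        (d, _), a, b = best
        merges.append((clusters[a], clusters[b], d))
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return merges


def brute_force_r2(D, labels):
    """R² from explicit loops over the squared-distance sums."""
    D = np.asarray(D, float)
    n = len(D)
    sst = sum(D[i, j] ** 2 for i in range(n) for j in range(n)) / (2 * n)
    ssw = 0.0
    for c in set(labels):
        idx = [i for i in range(n) if labels[i] == c]
        ssw += sum(D[i, j] ** 2 for i in idx for j in idx) / (2 * len(idx))
    return 1.0 - ssw / sst if sst > 0 else 1.0


@pytest.fixture(scope="session")
def brute_linkage():
    return brute_force_average_linkage


@pytest.fixture(scope="session")
def brute_r2():
    return brute_force_r2
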