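import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def naive_avalanche_scan(active, truncation_policy="discard"):
    """Independent per-bin scan oracle for avalanche extraction.

    Walks the binned raster bin by bin, opening an avalanche when any ROI
    is active and closing it at the first quiet bin; returns a list of
    (start, end, events_per_bin tuple, pattern frozenset).
    """
    n_rois, n_bins = active.shape
    out = []
    current = None
    for j in range(n_bins):
        rois = [r for r in range(n_rois) if active[r, j]]
        if rois:
            if current is None:
                current = [j, j, [], set()]
            current[1] = j
            current[2].append(len(rois))
            current[3].update(rois)
        elif current is not None:
            out.append(current)
            current = None
    if current is not None:
        out.append(current)
    result = []
    for start, end, counts, pattern in out:
        if truncation_policy == "discard" and (start == 0 or end == n_bins - 1):
            continue
        result.append((start, end, tuple(counts), frozenset(pattern)))
    return result


@pytest.fixture()
def scan_oracle():
    return naive_avalanche_scan
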