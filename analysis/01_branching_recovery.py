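#!/usr/bin/env python
"""How well does the avalanche branching-ratio estimator recover the true
branching parameter of a Galton--Watson process?

Simulates event rasters at sub-, near- and supercritical mean offspring
counts under two seeding regimes — sparse drive (avalanches start from a
single seed event, the regime resembling resting-state recordings) and
dense drive (avalanches start from many simultaneous seeds) — and compares
the estimate with the truth.

Finding: at criticality the estimator lands close to 1 regardless of
regime, which is what makes it usable for bin-length selection.  Away from
criticality it is informative only when avalanches start large: with
single-seed avalanches every in-avalanche bin is conditioned on containing
at least one event, so the successive-ratio statistic cannot see the decay
toward extinction and collapses to ~1 for any subcritical truth.

Writes results/estimator_recovery.csv.
"""

import warnings
from pathlib import Path

import pandas as pd

from flexms.avalanches import branching_ratio_overall, extract_avalanches
from flexms.synthetic import SyntheticSeriesSpec, simulate_branching_raster

OUT = Path(__file__).resolve().parent.parent / "results"

rows = []
for sigma_true in (0.5, 0.8, 1.0, 1.2):
    for drive_rate, regime in ((0.02, "sparse (single-seed)"), (8.0, "dense (multi-seed)")):
        spec = SyntheticSeriesSpec(
            n_rois=90, n_bins=150_000, sigma_true=sigma_true,
            drive_rate=drive_rate, seed=2026,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raster, _ = simulate_branching_raster(spec)
        aset = extract_avalanches(raster, "discard")
        try:
            sigma_hat = branching_ratio_overall(aset)
        except ValueError:
            sigma_hat = float("nan")
        rows.append({
            "sigma_true": sigma_true,
            "drive_rate": drive_rate,
            "regime": regime,
            "sigma_hat": round(sigma_hat, 4),
            "abs_error": round(abs(sigma_hat - sigma_true), 4),
            "n_avalanches": aset.n_avalanches,
            "n_used": aset.n_avalanches - aset.n_excluded_single_bin,
        })

table = pd.DataFrame(rows)
OUT.mkdir(exist_ok=True)
table.to_csv(OUT / "estimator_recovery.csv", index=False)
print(table.to_string(index=False))

critical = table[(table.sigma_true == 1.0) & (table.drive_rate == 0.02)].iloc[0]
print(
    f"\ncritical, sparse drive: sigma_hat = {critical.sigma_hat} "
    f"from {critical.n_used} multi-bin avalanches (|error| = {critical.abs_error})"
)
print("subcritical truths are recovered only in the dense-seeding regime;")
print("see docs/methods.md for why the sparse regime is blind to them.")
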