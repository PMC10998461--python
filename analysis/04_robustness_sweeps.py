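#!/usr/bin/env python
"""Robustness of the group comparison to the analysis knobs.

Re-runs the per-subject pipeline over a grid of z thresholds and bin
lengths (1 ... 5) on a small synthetic cohort whose patient recordings
carry a higher exogenous drive — hence larger functional repertoires —
than the control recordings, and checks that the direction of the
HC-vs-patient repertoire difference is stable across all settings.

A note on the threshold grid: in the synthetic generator, ground-truth
events are a class of their own, planted on top of an iid Gaussian
background whose own |z| > 3 excursions (rate 2 Phi(-3) ~ 0.0027 per
ROI-sample, i.e. ~0.7 spurious events per 3-sample bin over 90 ROIs)
vastly outnumber the planted ~0.1 events per bin.  Absolute thresholds
near 3 therefore probe the background, not the planted process — on real
recordings the suprathreshold excursions *are* the events, so no such
separation exists.  The sweep here uses thresholds above the background
tail (4.5 ... 6.0 SDs, with 10-SD planted deflections) so that the
statistic tracks the planted group effect at every setting.

Writes results/sweeps.csv (long format, one row per setting x subject).
"""

from pathlib import Path

import pandas as pd

from flexms.avalanches import AnalysisConfig
from flexms.pipeline import RunConfig, run_sweeps
from flexms.synthetic import SyntheticSeriesSpec, events_to_timeseries, simulate_branching_raster

OUT = Path(__file__).resolve().parent.parent / "results"

series, clinical_rows = {}, []
layout = [("HC", 0.012)] * 6 + [("RRMS", 0.045)] * 3 + [("SPMS", 0.028)] * 3
for i, (group, drive) in enumerate(layout):
    spec = SyntheticSeriesSpec(n_rois=90, n_bins=8000, sigma_true=1.0,
                               drive_rate=drive, samples_per_bin=3, seed=3000 + i)
    raster, _ = simulate_branching_raster(spec)
    s = events_to_timeseries(raster, spec)
    sid = f"S{i:02d}"
    s.subject_id = sid
    series[sid] = s
    clinical_rows.append({
        "subject_id": sid, "group": group, "edss": float("nan"), "fss": float("nan"),
        "sdmt": float("nan"), "bdi": float("nan"),
        "disease_duration_months": float("nan"), "repertoire_size": 0,
    })

config = RunConfig(analysis=AnalysisConfig(
    threshold_sweep=(4.5, 5.0, 5.5, 6.0), bin_candidates=(1, 2, 3, 4, 5)))
table = run_sweeps(config, series=series, clinical=pd.DataFrame(clinical_rows))
OUT.mkdir(exist_ok=True)
table.to_csv(OUT / "sweeps.csv", index=False)

clinical = pd.DataFrame(clinical_rows).set_index("subject_id")
table["is_hc"] = table["subject_id"].map(clinical["group"]) == "HC"
summary = (
    table.groupby(["z_threshold", "bin_length"])
    .apply(lambda g: g.loc[~g.is_hc, "repertoire_size"].mean()
           - g.loc[g.is_hc, "repertoire_size"].mean(), include_groups=False)
    .rename("patient_minus_hc_mean_repertoire")
    .reset_index()
)
print(summary.to_string(index=False))
signs = set(summary["patient_minus_hc_mean_repertoire"] > 0)
print(f"\n{len(summary)} settings; group-difference sign stable across all:",
      signs == {True})
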