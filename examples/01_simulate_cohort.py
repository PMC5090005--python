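"""Generate a small synthetic resting-state cohort and inspect its structure.

The generator plants a modular group connectome (strong within-module,
weak between-module weights), perturbs it per subject, and draws BOLD-like
ROI time series whose correlations approximate each subject's weight matrix.
"""

import numpy as np

import effconn as ec

spec = ec.CohortSpec(
    n_subjects=6, n_nodes=40, n_modules=4, n_timepoints=240,
    planted_nodes=(1, 4), planted_betas=(-300.0, -300.0), seed=7,
)
cohort = ec.simulate_cohort(spec)

ts = cohort.series[0]
print(f"{spec.n_subjects} subjects, series shape {ts.data.shape} (time x ROI), TR {ts.tr}s")

r = np.corrcoef(ts.data, rowvar=False)
mods = cohort.modules
same = mods[:, None] == mods[None, :]
off = ~np.eye(len(mods), dtype=bool)
print(f"mean empirical correlation within modules:  {r[same & off].mean():.3f}")
print(f"mean empirical correlation between modules: {r[~same].mean():.3f}")
print("-> the modular backbone survives into the sampled time series;")
print("   within-module pairs correlate far more strongly than between-module pairs.")
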