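"""Generate a small synthetic cohort and look at what it contains.

Builds a cohort of 4 patients and 3 controls performing the block task
(20 s rest / 20 s movement), writes every input the analysis consumes —
glove traces, EMG recordings, beta volumes, a label atlas, clinical
scores — and prints the cohort table.  Each subject directory also carries
a ground-truth sidecar, so you always know what an estimator *should*
recover.
"""

import tempfile
from pathlib import Path

import pandas as pd

from hemiscope import simulate_cohort

out = Path(tempfile.mkdtemp()) / "cohort"
simulate_cohort(out, n_patients=4, n_controls=3, seed=1, total_s=120.0,
                atlas_shape=(16, 16, 16))

cohort = pd.read_csv(out / "cohort.csv")
print(cohort.to_string(index=False))
print(f"\nper-subject files: {sorted(p.name for p in (out / 'S01').iterdir())}")
print("""
Each patient row carries clinical scores on their native scales (FM 0-66,
ARAT 0-57, %NHPT as percent of healthy norms); controls have none.  Lesion
sides alternate so downstream hemisphere flipping is exercised.
""")
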