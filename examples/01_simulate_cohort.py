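"""Simulate a small synthetic reach cohort and inspect the manifest.

Generates pose-track CSVs for 2 animals x 5 trials x 3 endpoint classes
(success, grasp fail, reach fail) plus a manifest and ground-truth
record, the same inputs a tracking pipeline would hand to the scorer.
"""

import tempfile
from pathlib import Path

from reachkdi import generate_cohort

out = Path(tempfile.mkdtemp(prefix="reachkdi_cohort_"))
manifest = generate_cohort(
    n_animals=2, trials_per_condition=5, scenario="endpoint_validity",
    seed=7, out_dir=out,
)

print(f"wrote {len(manifest)} trials to {out}")
print(manifest.table.groupby(["animal_id", "endpoint"]).size())
print(f"baseline successes (reference trials): {manifest.table.is_baseline_success.sum()}")
# Each animal contributes 5 successful baseline trials; those are the
# trials its subject-specific kinematic reference will be built from.
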