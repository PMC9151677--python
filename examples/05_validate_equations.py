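"""Validate equations with bias / precision / accuracy statistics.

Runs the end-to-end pipeline at a small scale and prints the metric table
(MPE, R^2, RMSE, MAPE, p15, p30, each with a combined bootstrap +
imputation 95% CI) for the two CT-based equations and the Cockcroft-Gault
and Ix comparators, in the validation and donor cohorts.
"""

import dataclasses
import tempfile
from pathlib import Path

from craftct import PipelineConfig, run_pipeline

config = PipelineConfig(
    n_patients=300,
    n_donors=120,
    seed=8,
    phantom_spacing_mm=3.0,
    imputation=dataclasses.replace(PipelineConfig().imputation, m=5),
    metrics=dataclasses.replace(PipelineConfig().metrics, n_bootstrap=300),
)
with tempfile.TemporaryDirectory() as out:
    run_pipeline(config, out)
    print(Path(out, "summary.txt").read_text())
print(
    "MPE near 0 means unbiased; RMSE in mmol/day measures accuracy;\n"
    "p15/p30 give the share of estimates within 15%/30% of the measured\n"
    "24-h excretion.  The CT-based equations should beat both comparators."
)
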