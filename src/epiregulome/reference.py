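"""Published study-design constants for the drug-resistant epilepsy cohorts.

Cohort sample sizes of the multi-pathology brain-tissue study the pipeline
is designed around: temporal lobe epilepsy with hippocampal sclerosis
(TLE-HS), focal cortical dysplasia types IIa and IIb, tuberous sclerosis
complex cortical tubers, and age-/tissue-matched control cortex and
hippocampus.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["EPILEPSY_STUDY_COHORTS", "total_samples"]

EPILEPSY_STUDY_COHORTS = pd.DataFrame(
    [
        ("control_cortex", "control", 14),
        ("control_hippocampus", "control", 13),
        ("TLE-HS", "disease", 64),
        ("FCD_IIa", "disease", 17),
        ("FCD_IIb", "disease", 33),
        ("TSC_cortical_tubers", "disease", 21),
    ],
    columns=["cohort", "group", "n_samples"],
)


def total_samples(table: pd.DataFrame | None = None) -> int:
    """Total sample count across the study cohorts."""
    t = EPILEPSY_STUDY_COHORTS if table is None else table
    return int(t["n_samples"].sum())
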