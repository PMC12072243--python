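"""Small published data tables used by the worked examples.

These are transcription-level inputs (a behavioural interaction-test
table and microscopy/recording tallies), shipped in code so the
bookkeeping operations can be exercised end to end without image or
recording files.
"""

from __future__ import annotations

import pandas as pd

# Social-interaction test after chronic social defeat: one row per mouse,
# (interaction time with the aggressor present, s; interaction ratio =
# time with aggressor / time with empty cage; published phenotype label).
_INTERACTION_ROWS = [
    ("001", 3.0, 0.06, "susceptible"),
    ("002", 15.0, 0.24, "susceptible"),
    ("003", 22.0, 0.43, "susceptible"),
    ("004", 13.0, 0.22, "susceptible"),
    ("005", 4.0, 0.07, "susceptible"),
    ("006", 18.5, 0.31, "susceptible"),
    ("007", 66.0, 1.10, "resilient"),
    ("008", 71.0, 1.28, "resilient"),
    ("009", 21.5, 0.28, "susceptible"),
    ("010", 73.0, 0.74, "resilient"),
    ("011", 28.5, 2.38, "resilient"),
    ("012", 40.5, 0.96, "intermediate"),
    ("013", 9.5, 0.28, "susceptible"),
    ("014", 42.0, 3.00, "resilient"),
    ("015", 10.0, 0.42, "susceptible"),
    ("016", 64.0, 0.79, "resilient"),
    ("017", 63.5, 0.69, "resilient"),
    ("018", 24.0, 1.66, "resilient"),
    ("019", 58.5, 1.18, "resilient"),
]


def interaction_table() -> pd.DataFrame:
    """Published social-interaction test results, one row per mouse."""
    return pd.DataFrame(
        _INTERACTION_ROWS,
        columns=["mouse_id", "interaction_time_s", "interaction_ratio",
                 "published_label"],
    )


# Dye-coupling bookkeeping: published tallies.
DYE_COUPLING_COUNTS = {
    # recordings with >= 1 coupled cell / total recordings
    "incidence": (19, 22),
    # same, in the presence of the gap-junction blocker carbenoxolone
    "incidence_carbenoxolone": (4, 7),
    # marker-positive fractions among coupled cells
    "marker_neun": (7, 37),
    "marker_olig2": (14, 26),
    "marker_3pgdh": (0, 45),
}

# Double recordings: synchronized neuron/non-neuron pairs over pairs tested.
PAIRED_RECORDING_COUNTS = {"synchronized_pairs": (5, 13)}

# Reported cohort sizes (cells) for the naive / susceptible / resilient
# comparison, used to dimension the synthetic three-group study.
COHORT_SIZES = {"naive": 63, "susceptible": 43, "resilient": 55}

# Reported passive properties (mean input resistance, MOhm) for the two
# recorded compartment types; used only as qualitative anchors in docs
# and tests (glial access resistance is far lower than neuronal).
INPUT_RESISTANCE_MOHM = {"neuron": 529.0, "non_neuron": 56.7}
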