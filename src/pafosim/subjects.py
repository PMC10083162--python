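"""Subject panels: the published 10-subject table and synthetic panels.

The printed subject table (sex, age, height, weight of the ten treadmill
subjects) is carried as a fixture for anthropometric worked examples; the
synthetic panel draws seeded subjects from the same height/mass ranges for
sweeps that need fresh subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: (subject, sex, age [years], height [m], weight [kg])
SUBJECT_TABLE_ROWS = [
    (1, "M", 20, 1.80, 74.84),
    (2, "F", 21, 1.63, 63.50),
    (3, "M", 19, 1.73, 58.97),
    (4, "M", 21, 1.78, 96.16),
    (5, "F", 20, 1.65, 55.79),
    (6, "M", 19, 1.68, 61.23),
    (7, "M", 19, 1.70, 68.04),
    (8, "F", 21, 1.73, 72.57),
    (9, "F", 20, 1.63, 52.16),
    (10, "M", 31, 1.77, 77.03),
]

HEIGHT_RANGE = (1.63, 1.80)
MASS_RANGE = (52.0, 96.0)
HEIGHT_MEAN_SD = (1.71, 0.06)
MASS_MEAN_SD = (68.0, 13.0)


@dataclass(frozen=True)
class SubjectSpec:
    """Inputs needed to simulate one subject."""

    subject_id: str
    height: float
    mass: float
    seed: int


def subject_table() -> pd.DataFrame:
    """The published ten-subject anthropometric table as a DataFrame."""
    return pd.DataFrame(
        SUBJECT_TABLE_ROWS,
        columns=["subject", "sex", "age", "height", "weight"],
    ).set_index("subject")


def table_subjects(seed: int = 0) -> list[SubjectSpec]:
    """Subject specs using the published heights and weights."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(len(SUBJECT_TABLE_ROWS))]
    return [SubjectSpec(f"S{row[0]}", row[3], row[4], seeds[i])
            for i, row in enumerate(SUBJECT_TABLE_ROWS)]


def synthetic_panel(n_subjects: int = 10, seed: int = 0) -> list[SubjectSpec]:
    """Seeded synthetic panel drawn from the published subject ranges."""
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_subjects)]
    out = []
    for i in range(n_subjects):
        h = float(np.clip(rng.normal(*HEIGHT_MEAN_SD), *HEIGHT_RANGE))
        m = float(np.clip(rng.normal(*MASS_MEAN_SD), *MASS_RANGE))
        out.append(SubjectSpec(f"syn{i + 1}", round(h, 3), round(m, 2),
                               seeds[i]))
    return out
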