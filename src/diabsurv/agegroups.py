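"""Age-group conventions shared across the package.

The analysis works on 5-year age bands with a wide first band covering
childhood and adolescence (0-19) and an open-ended last band (75+), the
grouping used throughout claims-based diabetes surveillance reporting.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

#: Canonical age-group labels, youngest first.
AGE_GROUP_LABELS: tuple[str, ...] = (
    "0-19",
    "20-24",
    "25-29",
    "30-34",
    "35-39",
    "40-44",
    "45-49",
    "50-54",
    "55-59",
    "60-64",
    "65-69",
    "70-74",
    "75+",
)

#: Labels restricted to adults (used by the comorbidity-curve analysis).
ADULT_AGE_GROUP_LABELS: tuple[str, ...] = AGE_GROUP_LABELS[1:]

_LABEL_RE = re.compile(r"^(\d+)-(\d+)$")
_OPEN_RE = re.compile(r"^(\d+)\+$")

# bin edges for np.digitize / pd.cut: [0,20), [20,25), ..., [70,75), [75,inf)
_EDGES = np.array([0, 20, 25, 30, 35, 40, 45, 50, 55, 60, 65, 70, 75, np.inf])


def age_to_group(age) -> pd.Categorical | str:
    """Map integer age(s) to the canonical age-group label(s).

    Accepts a scalar or an array-like; arrays come back as an ordered
    pandas Categorical so group-bys keep the age ordering.
    """
    if np.isscalar(age):
        if age < 0:
            raise ValueError(f"negative age: {age}")
        idx = int(np.digitize(age, _EDGES[1:-1]))
        return AGE_GROUP_LABELS[idx]
    arr = np.asarray(age)
    if (arr < 0).any():
        raise ValueError("negative ages present")
    idx = np.digitize(arr, _EDGES[1:-1])
    return pd.Categorical.from_codes(
        idx, categories=list(AGE_GROUP_LABELS), ordered=True
    )


def class_mean(label: str, open_end_mean: float = 80.0) -> float:
    """Class-mean age of one group label.

    Closed bands ``"a-b"`` (integer ages a..b inclusive) map to their
    midpoint ``(a + b) / 2`` ("20-24" -> 22.0); the open band ``"a+"``
    maps to ``open_end_mean`` (default 80 years).
    """
    m = _LABEL_RE.match(label)
    if m:
        a, b = int(m.group(1)), int(m.group(2))
        if b < a:
            raise ValueError(f"malformed age-group label: {label!r}")
        return (a + b) / 2.0
    if _OPEN_RE.match(label):
        return float(open_end_mean)
    raise ValueError(f"malformed age-group label: {label!r}")


def class_means(labels, open_end_mean: float = 80.0) -> np.ndarray:
    """Class-mean ages for a sequence of group labels (in order)."""
    return np.array([class_mean(lab, open_end_mean) for lab in labels])
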