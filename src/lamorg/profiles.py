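"""The windows x positions x features profile container.

``ProfileMatrix`` is the common currency between window extraction, radial
neighborhood profiling and all downstream distance / trajectory math.
Position 0 is the outer (boundary) end of the inner-outer axis; missing
samples (outside the mask or image) are NaN until imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ProfileMatrix:
    values: np.ndarray              # (n_windows, n_positions, n_features)
    meta: pd.DataFrame              # one row per window (section, timepoint, ...)
    feature_names: list[str]
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError("profile values must be 3-D (windows, positions, features)")
        if v.shape[0] != len(self.meta):
            raise ValueError("meta rows must match number of windows")
        if v.shape[2] != len(self.feature_names):
            raise ValueError("feature_names must match feature axis")
        self.values = v

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_positions(self) -> int:
        return self.values.shape[1]

    @property
    def n_features(self) -> int:
        return self.values.shape[2]

    def subset(self, idx: np.ndarray) -> "ProfileMatrix":
        idx = np.asarray(idx)
        return ProfileMatrix(
            self.values[idx],
            self.meta.iloc[idx].reset_index(drop=True),
            list(self.feature_names),
            dict(self.flags),
        )

    def copy(self) -> "ProfileMatrix":
        return ProfileMatrix(
            self.values.copy(), self.meta.copy(), list(self.feature_names), dict(self.flags)
        )
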