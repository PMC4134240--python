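"""Data-reduction rules applied before any statistics.

Three per-assay predicates, in pipeline order:

1. detection-limit censoring — a Ct at or beyond the instrument limit
   (40 cycles by default; only cycles strictly below the limit are
   informative) is treated as not detected;
2. annotation validity — assays whose identifier is dead in the target
   miRBase release are dropped, renamed ones are carried forward under
   their current id;
3. minimum paired detection — an assay must yield a computable paired
   ddCt in at least ``min_detected_pairs`` of the ``total_pairs`` sample
   pairs (9 of 18 by default) to enter the statistics.

Each filter is idempotent and never alters retained values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AnnotationMap, AnnotationStatus, validate_ct_table

__all__ = [
    "PruningConfig",
    "censor_detection_limit",
    "filter_annotation",
    "filter_min_pairs",
]


@dataclass(frozen=True)
class PruningConfig:
    """Thresholds for the reduction rules.

    ``min_detected_pairs`` defaults to 9 when ``total_pairs`` is 18 and to
    ``ceil(total_pairs / 2)`` otherwise, generalizing the 9-of-18 rule.
    """

    ct_detection_limit: float = 40.0
    total_pairs: int = 18
    min_detected_pairs: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.min_detected_pairs < 0:
            object.__setattr__(
                self,
                "min_detected_pairs",
                9 if self.total_pairs == 18 else math.ceil(self.total_pairs / 2),
            )
        if not (0 < self.min_detected_pairs <= self.total_pairs):
            raise ValueError(
                f"need 0 < min_detected_pairs <= total_pairs, got "
                f"{self.min_detected_pairs} / {self.total_pairs}"
            )
        if self.ct_detection_limit <= 0:
            raise ValueError("ct_detection_limit must be > 0")


def censor_detection_limit(table: pd.DataFrame, limit: float = 40.0) -> pd.DataFrame:
    """Censor every Ct at or above ``limit`` to missing.

    Only strictly smaller cycle numbers are kept, so a well reported at
    exactly the limit is treated as undetected. Record count is unchanged.
    """
    if limit <= 0:
        raise ValueError("detection limit must be > 0")
    out = table.copy()
    ct = out["ct"].to_numpy(dtype=float)
    out["ct"] = np.where(ct >= limit, np.nan, ct)
    return out


def filter_annotation(table: pd.DataFrame, amap: AnnotationMap) -> pd.DataFrame:
    """Keep assays valid under ``amap``, renaming where required.

    Records whose assay is dead or absent from the map are removed.
    A rename that collides with another assay measured in the same
    pair/tissue slot raises ``ValueError`` (two distinct array probes
    cannot legitimately fold into one current id within one sample).
    """
    resolved = table["assay_id"].map(amap.resolve)
    out = table.loc[resolved.notna()].copy()
    out["assay_id"] = resolved.loc[resolved.notna()]
    dup = out.duplicated(subset=["pair_id", "tissue_class", "assay_id"])
    if dup.any():
        row = out[dup].iloc[0]
        sources = sorted(
            a
            for a, e in amap.entries.items()
            if amap.resolve(a) == row["assay_id"]
        )
        raise ValueError(
            f"rename collision: assays {sources} all map to "
            f"{row['assay_id']!r} with records in pair {row['pair_id']!r} "
            f"({row['tissue_class']})"
        )
    return validate_ct_table(out.reset_index(drop=True))


def filter_min_pairs(matrix: pd.DataFrame, cfg: PruningConfig) -> pd.DataFrame:
    """Keep assays observed in at least ``cfg.min_detected_pairs`` pairs.

    "Observed in a pair" means the paired ddCt is computable, i.e. the
    matrix cell is non-missing. Pair columns and retained values are
    untouched.
    """
    if matrix.shape[1] != cfg.total_pairs:
        raise ValueError(
            f"matrix has {matrix.shape[1]} pair columns but the pruning "
            f"config expects total_pairs={cfg.total_pairs}"
        )
    n_obs = matrix.notna().sum(axis=1)
    return matrix.loc[n_obs >= cfg.min_detected_pairs]
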