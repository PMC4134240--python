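"""Endogenous-control selection and Ct -> dCt -> paired ddCt conversion.

Expression on a qPCR array is measured in Ct cycles, where abundance is
proportional to ``2**-Ct``. Normalization therefore happens in Ct space:

* the reference for a sample is the arithmetic mean of the chosen control
  assays' Ct values — exactly the Ct of the geometric mean of their
  expressions, since the geometric mean in expression space is the
  arithmetic mean in log (Ct) space;
* ``dCt = Ct(target) - Ct(reference)`` within one sample;
* ``ddCt = dCt(lesion) - dCt(control tissue)`` within one patient pair.

Negative ddCt means the target is more abundant in the lesion
(up-regulated); the linear-scale effect size is ``2**|ddCt|``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import TissueClass

__all__ = [
    "ControlSelection",
    "select_endogenous_controls",
    "compute_dct",
    "compute_ddct",
    "fold_change",
]

logger = logging.getLogger(__name__)

Direction = Literal["up", "down", "none"]


@dataclass(frozen=True)
class ControlSelection:
    """Outcome of stability ranking over the control candidates.

    ``stability_scores`` maps every scored candidate to the standard
    deviation of its Ct across all samples where it was detected (lower =
    more stable); ``chosen_ids`` are the ``k`` most stable candidates.
    """

    candidate_ids: tuple[str, ...]
    chosen_ids: tuple[str, ...]
    stability_scores: dict[str, float]


def select_endogenous_controls(
    table: pd.DataFrame, candidates: Sequence[str], k: int = 3
) -> ControlSelection:
    """Pick the ``k`` most stably expressed control candidates.

    Stability is the sample standard deviation of a candidate's Ct over
    every sample (both tissue classes) in which it was detected. Ties are
    broken by lower mean Ct, then lexicographic id, so the choice is
    deterministic.
    """
    if k > len(candidates):
        raise ValueError(f"cannot choose k={k} controls from {len(candidates)} candidates")
    sub = table[table["assay_id"].isin(candidates) & table["ct"].notna()]
    scores: dict[str, float] = {}
    means: dict[str, float] = {}
    for assay_id, grp in sub.groupby("assay_id"):
        if len(grp) >= 2:
            scores[assay_id] = float(grp["ct"].std(ddof=1))
            means[assay_id] = float(grp["ct"].mean())
    if len(scores) < k:
        raise ValueError(
            f"only {len(scores)} candidates detected in >= 2 samples; need {k}"
        )
    ranked = sorted(scores, key=lambda a: (scores[a], means[a], a))
    return ControlSelection(
        candidate_ids=tuple(candidates),
        chosen_ids=tuple(ranked[:k]),
        stability_scores=scores,
    )


def compute_dct(table: pd.DataFrame, controls: ControlSelection) -> pd.DataFrame:
    """Normalize each sample's Ct values against its control reference.

    Returns a long-form table ``pair_id, tissue_class, assay_id, dct``.
    The control assays themselves are excluded from the output. A sample
    in which any chosen control is undetected gets all-missing dct (the
    reference definition is kept uniform across samples); this is logged
    as a warning, not an error.
    """
    chosen = set(controls.chosen_ids)
    k = len(chosen)
    ctrl = table[table["assay_id"].isin(chosen) & table["ct"].notna()]
    ref = ctrl.groupby(["pair_id", "tissue_class"])["ct"].agg(["mean", "size"])

    out = table[~table["assay_id"].isin(chosen)].copy()
    out = out.rename(columns={"ct": "dct"})
    keys = pd.MultiIndex.from_frame(out[["pair_id", "tissue_class"]])
    ref_mean = ref["mean"].reindex(keys).to_numpy()
    ref_n = ref["size"].reindex(keys, fill_value=0).to_numpy()

    incomplete = ref_n < k
    if incomplete.any():
        bad = sorted({(p, t) for (p, t), m in zip(keys, incomplete) if m})
        logger.warning(
            "dropping dCt for %d sample(s) missing a chosen control: %s",
            len(bad),
            bad,
        )
    dct = out["dct"].to_numpy(dtype=float) - ref_mean
    dct[incomplete] = np.nan
    out["dct"] = dct
    return out.loc[:, ["pair_id", "tissue_class", "assay_id", "dct"]].reset_index(drop=True)


def compute_ddct(dct: pd.DataFrame) -> pd.DataFrame:
    """Pair lesion against control dCt per patient: ``ddCt = C_i - N_i``.

    Returns an assay x pair matrix with ``NaN`` where either side of a
    pair is missing. Raises if a pair carries duplicate measurements for
    one tissue class (violates the upstream table invariant).
    """
    dup = dct.duplicated(subset=["pair_id", "tissue_class", "assay_id"])
    if dup.any():
        row = dct[dup].iloc[0]
        raise ValueError(
            f"pair {row['pair_id']!r} has duplicate {row['tissue_class']} "
            f"measurements for assay {row['assay_id']!r}"
        )
    wide = dct.pivot(index="assay_id", columns=["tissue_class", "pair_id"], values="dct")
    pair_order = dct["pair_id"].unique()
    lesion = wide.get(TissueClass.LESION.value, pd.DataFrame(index=wide.index))
    control = wide.get(TissueClass.CONTROL.value, pd.DataFrame(index=wide.index))
    lesion = lesion.reindex(columns=pair_order)
    control = control.reindex(columns=pair_order)
    matrix = lesion - control
    matrix.index.name = "assay_id"
    matrix.columns.name = "pair_id"
    # keep the assay order of first appearance
    assay_order = dct["assay_id"].unique()
    return matrix.reindex(index=assay_order)


def fold_change(mean_ddct: float) -> tuple[float, Direction]:
    """Linear fold change and regulation direction implied by a mean ddCt.

    ``fold = 2**|mean_ddct|``; direction is ``up`` for negative ddCt
    (more abundant in the lesion), ``down`` for positive, ``none`` at
    exactly zero.
    """
    if not np.isfinite(mean_ddct):
        raise ValueError("mean ddCt must be finite")
    fold = float(2.0 ** abs(mean_ddct))
    if mean_ddct < 0:
        return fold, "up"
    if mean_ddct > 0:
        return fold, "down"
    return 1.0, "none"
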