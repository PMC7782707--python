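"""Differential cell-type proportion analysis between conditions.

Per cell type, the fraction of cells in each condition is computed over the
pooled cells of that condition, and the log2 ratio POP/control is thresholded
at |log2FC| > 0.5. A half-cell pseudocount (relative to the smaller
condition) keeps the ratio finite when a type is absent from one condition;
such one-sided records are flagged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from popsc.config import CONDITIONS, CONTROL, POP, PipelineConfig


def proportion_change(
    labels,
    conditions,
    cfg: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """Per-type condition fractions and their log2 fold change.

    Returns a DataFrame with cell_type, fraction_control, fraction_pop,
    log2fc, changed, one_sided. Fractions sum to 1 exactly within each
    condition.
    """
    labels = np.asarray(labels, dtype=object)
    conditions = np.asarray(conditions, dtype=object)
    if labels.shape != conditions.shape:
        raise ValueError("labels and conditions must align")
    totals = {c: int((conditions == c).sum()) for c in CONDITIONS}
    for c, n in totals.items():
        if n == 0:
            raise ValueError(f"condition {c!r} has zero cells")
    eps = 1.0 / (2.0 * min(totals.values()))
    rows = []
    for ctype in sorted(map(str, pd.unique(labels))):
        mask = labels == ctype
        f_ctrl = (mask & (conditions == CONTROL)).sum() / totals[CONTROL]
        f_pop = (mask & (conditions == POP)).sum() / totals[POP]
        log2fc = float(np.log2((f_pop + eps) / (f_ctrl + eps)))
        rows.append(
            (
                ctype, float(f_ctrl), float(f_pop), log2fc,
                bool(abs(log2fc) > cfg.prop_abs_log2fc),
                bool(f_ctrl == 0.0 or f_pop == 0.0),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["cell_type", "fraction_control", "fraction_pop", "log2fc",
                 "changed", "one_sided"],
    )
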