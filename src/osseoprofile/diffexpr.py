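"""Zero-FPKM filtering, signed fold changes, and >2-fold DE calling.

The differential-expression criterion is a plain fold-change threshold:
a transcript is called up at a timepoint when its implant/control expression
ratio exceeds the threshold, down when the reciprocal does.  Fold changes are
reported in the signed convention used for bone-healing expression tables —
a ratio r is written r when r >= 1 and -1/r when r < 1, so the magnitude is
always >= 1 and the sign encodes direction.  No variance model is fitted:
with a single animal per condition there is no dispersion to estimate.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io_tables import ExpressionTable, ValidationError

__all__ = [
    "DeCallSet",
    "filter_zero_fpkm",
    "signed_fold_change",
    "log2_fold",
    "fold_change_table",
    "gene_fold_change_table",
    "call_de",
    "overlap_sets",
    "round_report",
]

DEFAULT_THRESHOLD = 2.0
DEFAULT_PSEUDOCOUNT = 0.1


def filter_zero_fpkm(table: ExpressionTable) -> tuple[ExpressionTable, int]:
    """Drop transcripts whose FPKM is zero in *every* sample.

    A transcript detected in any single sample is retained, so genes expressed
    only under one condition survive the filter.  Returns the retained table
    and the number of excluded transcripts; counts always conserve:
    ``len(retained) + n_excluded == len(input)``.
    """
    all_zero = (table.values.to_numpy() == 0).all(axis=1)
    retained = table.subset(table.values.index[~all_zero])
    return retained, int(all_zero.sum())


def signed_fold_change(mean_implant, mean_control, pseudocount: float = DEFAULT_PSEUDOCOUNT):
    """Signed fold change of implant over control means.

    With r = (implant + eps) / (control + eps), returns r when r >= 1 and
    -1/r otherwise, so |result| >= 1 and equality of means gives +1.
    Accepts scalars or arrays.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    mi = np.asarray(mean_implant, dtype=float)
    mc = np.asarray(mean_control, dtype=float)
    if (mi < 0).any() or (mc < 0).any():
        raise ValueError("mean FPKM values must be non-negative")
    r = (mi + pseudocount) / (mc + pseudocount)
    out = np.where(r >= 1.0, r, -1.0 / r)
    if out.ndim == 0:
        return float(out)
    return out


def log2_fold(signed_fc):
    """log2 of a signed fold change: sign(fc) * log2(|fc|).

    Requires |fc| >= 1 (the signed convention); +-1 maps to 0.
    """
    fc = np.asarray(signed_fc, dtype=float)
    if (np.abs(fc) < 1.0 - 1e-12).any():
        raise ValueError("signed fold changes must have magnitude >= 1")
    out = np.sign(fc) * np.log2(np.maximum(np.abs(fc), 1.0))
    if out.ndim == 0:
        return float(out)
    return out


def round_report(x: float, ndigits: int = 2) -> float:
    """Half-even rounding used for all reported fold changes."""
    return round(float(x), ndigits)


def _condition_means(table: ExpressionTable, timepoint: str) -> tuple[pd.Series, pd.Series]:
    impl = table.sample_names(condition="implant", timepoint=timepoint)
    ctrl = table.sample_names(condition="control", timepoint=timepoint)
    if not impl or not ctrl:
        raise ValidationError(
            f"timepoint {timepoint!r} needs at least one implant and one control sample"
        )
    return table.values[impl].mean(axis=1), table.values[ctrl].mean(axis=1)


def fold_change_table(
    table: ExpressionTable, timepoint: str, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.DataFrame:
    """Per-transcript fold-change records at one timepoint.

    Returns a frame indexed by transcript_id with columns gene_id,
    mean_fpkm_implant, mean_fpkm_control, signed_fc, log2_fc.  Per-condition
    means are used; with a single sample per condition the mean degenerates
    to that sample's value.
    """
    mean_impl, mean_ctrl = _condition_means(table, timepoint)
    fc = signed_fold_change(mean_impl.to_numpy(), mean_ctrl.to_numpy(), pseudocount)
    return pd.DataFrame(
        {
            "gene_id": table.gene_ids,
            "timepoint": timepoint,
            "mean_fpkm_implant": mean_impl,
            "mean_fpkm_control": mean_ctrl,
            "signed_fc": fc,
            "log2_fc": log2_fold(fc),
        },
        index=table.values.index,
    )


def gene_fold_change_table(
    table: ExpressionTable, timepoint: str, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.DataFrame:
    """Gene-level fold changes from transcript FPKMs summed within gene.

    Gene expression is the sum of its transcripts' FPKM, so the gene-level
    mean per condition is the sum of transcript means.
    """
    mean_impl, mean_ctrl = _condition_means(table, timepoint)
    frame = pd.DataFrame(
        {"gene_id": table.gene_ids, "implant": mean_impl, "control": mean_ctrl}
    )
    sums = frame.groupby("gene_id").sum()
    fc = signed_fold_change(sums["implant"].to_numpy(), sums["control"].to_numpy(), pseudocount)
    return pd.DataFrame(
        {
            "timepoint": timepoint,
            "mean_fpkm_implant": sums["implant"],
            "mean_fpkm_control": sums["control"],
            "signed_fc": fc,
            "log2_fc": log2_fold(fc),
        },
        index=sums.index,
    )


@dataclasses.dataclass(frozen=True)
class DeCallSet:
    """Up/down calls at one timepoint under a strict |fold| > threshold rule."""

    timepoint: str
    threshold: float
    up: frozenset
    down: frozenset

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValidationError("a gene cannot be both up- and downregulated")

    @property
    def n_de(self) -> int:
        return len(self.up) + len(self.down)


def call_de(
    fold_changes: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    timepoint: str | None = None,
) -> DeCallSet:
    """Call DE from a fold-change frame (indexed by transcript or gene ID).

    ``up`` holds IDs with signed_fc > threshold, ``down`` those with
    signed_fc < -threshold; the comparison is strict, so a fold change equal
    to the threshold is called neither.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    fc = fold_changes["signed_fc"]
    tp = timepoint
    if tp is None:
        tps = fold_changes.get("timepoint")
        tp = str(tps.iloc[0]) if tps is not None and len(tps) else ""
    return DeCallSet(
        timepoint=tp,
        threshold=float(threshold),
        up=frozenset(fold_changes.index[fc > threshold]),
        down=frozenset(fold_changes.index[fc < -threshold]),
    )


def overlap_sets(de_1w: DeCallSet, de_4w: DeCallSet) -> tuple[frozenset, frozenset]:
    """Genes called in the same direction at both timepoints."""
    if de_1w.threshold != de_4w.threshold:
        raise ValueError("overlap requires call sets computed at the same threshold")
    return de_1w.up & de_4w.up, de_1w.down & de_4w.down
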