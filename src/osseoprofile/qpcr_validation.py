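"""Comparative-Ct (delta-delta-Ct) quantification and RNA-Seq concordance.

Relative quantification follows the comparative Ct method: for each target
gene and condition, the target's mean threshold cycle is normalised against a
reference (housekeeping) gene, ddCt is the treated-minus-control difference
of those normalised values, and the relative quantity is 2^(-ddCt).  The
reference gene is a required parameter — there is no universal housekeeping
choice for bone tissue.  No amplification-efficiency correction is applied
(both amplicons are assumed to double per cycle).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_tables import CtPlate, ValidationError

__all__ = [
    "DeltaDeltaCtResult",
    "ConcordanceRecord",
    "mean_ct",
    "delta_delta_ct",
    "concordance",
]

logger = logging.getLogger(__name__)


def mean_ct(wells: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample SD of a well group (SD = 0 when n = 1)."""
    wells = np.asarray(list(wells), dtype=float)
    if wells.size == 0:
        raise ValidationError("empty Ct well group")
    sd = float(np.std(wells, ddof=1)) if wells.size > 1 else 0.0
    return float(np.mean(wells)), sd


@dataclasses.dataclass(frozen=True)
class DeltaDeltaCtResult:
    gene_id: str
    timepoint: str
    mean_ct_target_treated: float
    mean_ct_ref_treated: float
    mean_ct_target_control: float
    mean_ct_ref_control: float
    delta_ct_treated: float
    delta_ct_control: float
    delta_delta_ct: float
    rel_quantity: float
    log2_rel_quantity: float


def delta_delta_ct(
    plate: CtPlate, gene_id: str, timepoint: str, reference_gene: str
) -> DeltaDeltaCtResult:
    """Comparative-Ct relative quantity of one target gene at one timepoint.

    dCt = mean_ct(target) - mean_ct(reference) per condition;
    ddCt = dCt_implant - dCt_control; relative quantity = 2^(-ddCt).
    Raises :class:`ValidationError` naming the missing (gene, condition)
    group if any of the four well groups is absent.
    """
    groups = {}
    for cond in ("implant", "control"):
        for gid, role in ((gene_id, "target"), (reference_gene, "reference")):
            wells = plate.group(gid, role, cond, timepoint)
            if wells.size == 0:
                raise ValidationError(
                    f"no {role} wells for ({gid}, {cond}, {timepoint})"
                )
            groups[(gid, cond)] = mean_ct(wells)[0]
    d_treated = groups[(gene_id, "implant")] - groups[(reference_gene, "implant")]
    d_control = groups[(gene_id, "control")] - groups[(reference_gene, "control")]
    ddct = d_treated - d_control
    return DeltaDeltaCtResult(
        gene_id=gene_id,
        timepoint=timepoint,
        mean_ct_target_treated=groups[(gene_id, "implant")],
        mean_ct_ref_treated=groups[(reference_gene, "implant")],
        mean_ct_target_control=groups[(gene_id, "control")],
        mean_ct_ref_control=groups[(reference_gene, "control")],
        delta_ct_treated=d_treated,
        delta_ct_control=d_control,
        delta_delta_ct=ddct,
        rel_quantity=2.0 ** (-ddct),
        log2_rel_quantity=-ddct,
    )


@dataclasses.dataclass(frozen=True)
class ConcordanceRecord:
    gene_id: str
    timepoint: str
    rnaseq_value: float
    qpcr_value: float
    scale: str
    direction_agree: bool


def _direction(value: float, scale: str) -> int:
    if scale == "linear":
        if value <= 0:
            raise ValueError(f"linear fold change must be > 0, got {value}")
        return (value > 1) - (value < 1)
    if scale == "log2":
        return (value > 0) - (value < 0)
    raise ValueError(f"unknown scale {scale!r} (expected 'linear' or 'log2')")


def concordance(
    rnaseq_values: Mapping[tuple[str, str], float],
    qpcr_values: Mapping[tuple[str, str], float] | Iterable[DeltaDeltaCtResult],
    rnaseq_scale: str = "log2",
    qpcr_scale: str = "log2",
) -> tuple[list[ConcordanceRecord], float]:
    """Direction agreement between RNA-Seq and qPCR fold changes.

    Both inputs are keyed by (gene_id, timepoint); qPCR values may also be
    given as :class:`DeltaDeltaCtResult` objects (their log2 relative quantity
    is used and ``qpcr_scale`` is ignored for them).  Each side's regulation
    direction is judged on its declared scale (linear: above/below 1; log2:
    sign); a no-change value only agrees with a no-change value.  Unmatched
    pairs are logged and skipped.  Returns the per-pair records and the
    overall agreement fraction.
    """
    if not isinstance(qpcr_values, Mapping):
        converted = {}
        for r in qpcr_values:
            converted[(r.gene_id, r.timepoint)] = r.log2_rel_quantity
        qpcr_values = converted
        qpcr_scale = "log2"

    records = []
    for key in sorted(rnaseq_values):
        if key not in qpcr_values:
            logger.warning("no qPCR value for %s; skipped", key)
            continue
        rv, qv = float(rnaseq_values[key]), float(qpcr_values[key])
        agree = _direction(rv, rnaseq_scale) == _direction(qv, qpcr_scale)
        records.append(
            ConcordanceRecord(
                gene_id=key[0],
                timepoint=key[1],
                rnaseq_value=rv,
                qpcr_value=qv,
                scale=qpcr_scale,
                direction_agree=agree,
            )
        )
    fraction = (
        sum(r.direction_agree for r in records) / len(records) if records else math.nan
    )
    return records, fraction
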