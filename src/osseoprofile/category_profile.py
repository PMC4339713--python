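"""Functional-category profiling of differentially expressed genes.

Genes are grouped into curated functional categories — cell proliferation,
extracellular matrix (ECM), growth factors, and osteogenesis with TGF-beta/BMP
and Wnt sub-pathways — and reported with their signed fold changes at both
timepoints.  Membership is an input table, not an algorithm: curated gene
lists are the norm for this kind of report, and the packaged reference table
(:func:`load_published_categories`) carries the curated lists for the beagle
peri-implant bone-healing dataset together with their published fold changes,
which the regression tests check against.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexpr import DEFAULT_THRESHOLD

__all__ = [
    "read_category_map",
    "load_published_categories",
    "load_published_qpcr",
    "build_category_table",
    "category_summary",
]

logger = logging.getLogger(__name__)

CATEGORY_COLUMNS = ["category", "sub_pathway", "gene_id"]


def read_category_map(path: str | Path) -> pd.DataFrame:
    """Read a category membership TSV (category, sub_pathway, gene_id).

    ``sub_pathway`` may be empty; a gene may appear under several categories
    (overlap is meaningful — e.g. a homeobox gene can sit in the osteogenesis
    core list and in both its sub-pathways).
    """
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(CATEGORY_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"category map lacks columns: {sorted(missing)}")
    return frame[CATEGORY_COLUMNS + [c for c in frame.columns if c not in CATEGORY_COLUMNS]]


def _load_packaged(name: str) -> pd.DataFrame:
    with resources.files("osseoprofile.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t", dtype=str).fillna("")


def load_published_categories() -> pd.DataFrame:
    """Curated category tables for the beagle peri-implant dataset.

    Columns: category, sub_pathway, gene_id, description, fc_1w, fc_4w
    (signed linear fold changes, implant over surgical-defect control).
    """
    frame = _load_packaged("published_categories.tsv")
    frame["fc_1w"] = frame["fc_1w"].astype(float)
    frame["fc_4w"] = frame["fc_4w"].astype(float)
    return frame


def load_published_qpcr() -> pd.DataFrame:
    """Published RNA-Seq vs real-time PCR validation values.

    Columns: gene_id, timepoint, rnaseq_log2, realtime_pcr.  The RNA-Seq
    column is the log2 of the linear fold change printed in the category
    tables; the real-time PCR column's scale is not declared at source and is
    treated as a parameter by :func:`osseoprofile.qpcr_validation.concordance`.
    """
    frame = _load_packaged("published_qpcr.tsv")
    frame["rnaseq_log2"] = frame["rnaseq_log2"].astype(float)
    frame["realtime_pcr"] = frame["realtime_pcr"].astype(float)
    return frame


def build_category_table(
    fold_changes: pd.DataFrame,
    category_map: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Tabulate mapped genes that are DE at one or more timepoints.

    ``fold_changes`` is indexed by gene_id with columns ``signed_fc_1w`` and
    ``signed_fc_4w`` (optionally ``description``).  A mapped gene is listed
    iff |signed_fc| > threshold at >= 1 timepoint; both timepoints' values are
    reported regardless of which passed.  Mapped genes absent from the
    expression data are logged and skipped.
    """
    rows = []
    for rec in category_map.itertuples(index=False):
        gene = rec.gene_id
        if gene not in fold_changes.index:
            logger.warning("category %s: gene %s absent from expression data; skipped",
                           rec.category, gene)
            continue
        fc1 = float(fold_changes.loc[gene, "signed_fc_1w"])
        fc4 = float(fold_changes.loc[gene, "signed_fc_4w"])
        if abs(fc1) > threshold or abs(fc4) > threshold:
            desc = ""
            if "description" in fold_changes.columns:
                desc = str(fold_changes.loc[gene, "description"])
            rows.append(
                {
                    "category": rec.category,
                    "sub_pathway": getattr(rec, "sub_pathway", ""),
                    "gene_id": gene,
                    "description": desc,
                    "signed_fc_1w": fc1,
                    "signed_fc_4w": fc4,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["category", "sub_pathway", "gene_id", "description",
                 "signed_fc_1w", "signed_fc_4w"],
    )


def category_summary(table: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Per-category up/down/below-threshold counts per timepoint.

    For every (category, timepoint), ``n_up + n_down + n_below`` equals the
    category's row count; a gene up at one timepoint and down at the other
    contributes to both respective counts.
    """
    rows = []
    for category, grp in table.groupby("category", sort=True):
        for tp, col in (("1w", "signed_fc_1w"), ("4w", "signed_fc_4w")):
            fc = grp[col].to_numpy(dtype=float)
            rows.append(
                {
                    "category": category,
                    "timepoint": tp,
                    "n_up": int(np.sum(fc > threshold)),
                    "n_down": int(np.sum(fc < -threshold)),
                    "n_below": int(np.sum(np.abs(fc) <= threshold)),
                }
            )
    return pd.DataFrame(rows, columns=["category", "timepoint", "n_up", "n_down", "n_below"])
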