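"""Readers, writers and validation for the pipeline's tabular formats.

Three inputs are handled: an FPKM expression table (TSV, one row per
transcript, one column per sample), a Biomart-style GO annotation export
(TSV, one row per gene/term pair), and a qPCR Ct plate (CSV, one row per
well).  Every reader validates structure before any computation and raises
:class:`ValidationError` (bad values) or :class:`SchemaError` (missing /
unparseable columns) with the offending row or cell named.
"""

from __future__ import annotations

import dataclasses
import json
import re
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "SchemaError",
    "ValidationError",
    "ExpressionTable",
    "AnnotationSet",
    "CtPlate",
    "read_expression_table",
    "write_expression_table",
    "read_annotation",
    "write_annotation",
    "read_ct_plate",
    "write_ct_plate",
    "write_results",
    "format_pvalue",
]


class SchemaError(ValueError):
    """A required column is missing or a column name cannot be interpreted."""


class ValidationError(ValueError):
    """A parsed value violates a structural invariant of its table."""


CONDITIONS = ("control", "implant")

_CONDITION_ALIASES = {
    "control": "control",
    "ctrl": "control",
    "implant": "implant",
    "impl": "implant",
}

_SAMPLE_RE = re.compile(r"^(?P<cond>[A-Za-z]+)_(?P<tp>\d+w)(?:_r?(?P<rep>\d+))?$")

GO_ACCESSION_RE = re.compile(r"^GO:\d{7}$")

GO_DOMAINS = ("biological_process", "cellular_component", "molecular_function")


def parse_sample_name(name: str) -> tuple[str, str, int]:
    """Split a sample column name into (condition, timepoint, replicate).

    Accepted forms: ``control_1w``, ``impl_4w_2``, ``implant_1w_r3``.
    Condition aliases ``ctrl``/``impl`` normalise to ``control``/``implant``.
    """
    m = _SAMPLE_RE.match(name)
    if m is None:
        raise SchemaError(
            f"sample column {name!r} does not match '<condition>_<timepoint>[_r<k>]'"
        )
    cond = _CONDITION_ALIASES.get(m.group("cond").lower())
    if cond is None:
        raise SchemaError(f"sample column {name!r}: unknown condition {m.group('cond')!r}")
    rep = int(m.group("rep")) if m.group("rep") else 1
    if rep < 1:
        raise SchemaError(f"sample column {name!r}: replicate index must be >= 1")
    return cond, m.group("tp"), rep


@dataclasses.dataclass
class ExpressionTable:
    """Transcripts x samples matrix of FPKM values with sample labels.

    ``values`` is indexed by transcript_id with one float column per sample;
    ``gene_ids`` maps transcript_id -> gene_id; ``samples`` is indexed by
    sample name with columns condition, timepoint, replicate.
    """

    values: pd.DataFrame
    gene_ids: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate transcript_id values: {dupes[:5]}")
        if not self.values.index.equals(self.gene_ids.index):
            raise ValidationError("gene_ids index does not match the value matrix")
        if list(self.values.columns) != list(self.samples.index):
            raise ValidationError("sample metadata does not match the value columns")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite FPKM at transcript {self.values.index[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r}"
            )
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative FPKM at transcript {self.values.index[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r}"
            )
        for col in ("condition", "timepoint", "replicate"):
            if col not in self.samples.columns:
                raise ValidationError(f"sample metadata lacks a {col!r} column")
        bad_cond = set(self.samples["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValidationError(f"unknown sample conditions: {sorted(bad_cond)}")

    @property
    def n_transcripts(self) -> int:
        return len(self.values)

    @property
    def transcript_ids(self) -> pd.Index:
        return self.values.index

    def timepoints(self) -> list[str]:
        return sorted(self.samples["timepoint"].unique())

    def sample_names(self, condition: str | None = None, timepoint: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.samples.index)
        if condition is not None:
            mask &= self.samples["condition"] == condition
        if timepoint is not None:
            mask &= self.samples["timepoint"] == timepoint
        return list(self.samples.index[mask])

    def subset(self, transcript_ids: Sequence[str] | pd.Index) -> "ExpressionTable":
        return ExpressionTable(
            values=self.values.loc[transcript_ids].copy(),
            gene_ids=self.gene_ids.loc[transcript_ids].copy(),
            samples=self.samples.copy(),
        )


def read_expression_table(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> ExpressionTable:
    """Read a TSV expression table.

    ``schema`` optionally maps file column names onto the canonical names
    (``transcript_id``, ``gene_id``, and sample names of the form
    ``<condition>_<timepoint>[_r<k>]``); by default the header is taken
    literally.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if schema:
        raw = raw.rename(columns=dict(schema))
    for required in ("transcript_id", "gene_id"):
        if required not in raw.columns:
            raise SchemaError(f"missing required column {required!r}")
    sample_cols = [c for c in raw.columns if c not in ("transcript_id", "gene_id")]
    if not sample_cols:
        raise SchemaError("no sample columns found")
    meta = {}
    for c in sample_cols:
        cond, tp, rep = parse_sample_name(c)
        meta[c] = {"condition": cond, "timepoint": tp, "replicate": rep}
    samples = pd.DataFrame.from_dict(meta, orient="index")
    samples.index.name = "sample"

    values = pd.DataFrame(index=raw["transcript_id"])
    values.index.name = "transcript_id"
    for c in sample_cols:
        parsed = pd.to_numeric(raw[c], errors="coerce")
        bad = parsed.isna() & raw[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"column {c!r}, data row {row + 1}: cannot parse FPKM value {raw[c].iloc[row]!r}"
            )
        neg = parsed < 0
        if neg.any():
            row = int(np.flatnonzero(neg)[0])
            raise ValidationError(
                f"column {c!r}, data row {row + 1}: negative FPKM {parsed.iloc[row]}"
            )
        values[c] = parsed.to_numpy(dtype=float)
    gene_ids = pd.Series(raw["gene_id"].to_numpy(), index=values.index, name="gene_id")
    return ExpressionTable(values=values, gene_ids=gene_ids, samples=samples)


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    out = table.values.copy()
    out.insert(0, "gene_id", table.gene_ids)
    out.to_csv(path, sep="\t", index=True)


# default header names follow the Ensembl Biomart export dialect
DEFAULT_ANNOTATION_SCHEMA: dict[str, str] = {
    "Gene stable ID": "gene_id",
    "Gene start (bp)": "start",
    "Gene end (bp)": "end",
    "Gene length (bp)": "length_bp",
    "GO term accession": "go_id",
    "GO term name": "go_name",
    "GO domain": "go_domain",
    # canonical names pass through
    "gene_id": "gene_id",
    "start": "start",
    "end": "end",
    "length_bp": "length_bp",
    "go_id": "go_id",
    "go_name": "go_name",
    "go_domain": "go_domain",
}


class AnnotationSet:
    """Gene lengths plus GO term assignments; the universe for enrichment.

    A gene may carry zero terms and still belongs to the sampling universe.
    """

    def __init__(
        self,
        lengths: pd.Series,
        annotations: pd.DataFrame,
        term_info: pd.DataFrame | None = None,
    ) -> None:
        lengths = lengths.astype(int).rename("length_bp")
        lengths.index.name = "gene_id"
        if lengths.index.has_duplicates:
            raise ValidationError("duplicate gene_id in annotation lengths")
        if (lengths < 1).any():
            bad = lengths.index[lengths < 1][0]
            raise ValidationError(f"gene {bad!r} has length < 1 bp")
        self.lengths = lengths.sort_index()

        annotations = annotations[["gene_id", "term"]].drop_duplicates()
        unknown = set(annotations["gene_id"]) - set(self.lengths.index)
        if unknown:
            raise ValidationError(f"annotated genes absent from length table: {sorted(unknown)[:5]}")
        for term in annotations["term"].unique():
            if not GO_ACCESSION_RE.match(term):
                raise ValidationError(f"malformed GO accession {term!r}")
        self.annotations = annotations.reset_index(drop=True)

        if term_info is None:
            term_info = pd.DataFrame(
                {"name": "", "domain": "biological_process"},
                index=pd.Index(sorted(annotations["term"].unique()), name="term"),
            )
        bad_domain = set(term_info["domain"]) - set(GO_DOMAINS)
        if bad_domain:
            raise ValidationError(f"unknown GO domains: {sorted(bad_domain)}")
        self.term_info = term_info

        self._gene_terms: dict[str, frozenset[str]] = {g: frozenset() for g in self.lengths.index}
        self._term_genes: dict[str, set[str]] = {}
        if len(self.annotations):
            for g, grp in self.annotations.groupby("gene_id")["term"]:
                self._gene_terms[g] = frozenset(grp)
            for t, grp in self.annotations.groupby("term")["gene_id"]:
                self._term_genes[t] = set(grp)

    @property
    def gene_ids(self) -> pd.Index:
        return self.lengths.index

    @property
    def n_genes(self) -> int:
        return len(self.lengths)

    @property
    def term_universe(self) -> list[str]:
        """GO terms attached to at least one gene, sorted."""
        return sorted(self._term_genes)

    def terms_of(self, gene_id: str) -> frozenset[str]:
        return self._gene_terms[gene_id]

    def genes_with(self, term: str) -> frozenset[str]:
        return frozenset(self._term_genes.get(term, set()))

    def has_term(self, gene_id: str, term: str) -> bool:
        return term in self._gene_terms.get(gene_id, frozenset())

    def domain_of(self, term: str) -> str:
        if term in self.term_info.index:
            return str(self.term_info.loc[term, "domain"])
        return "biological_process"

    def name_of(self, term: str) -> str:
        if term in self.term_info.index:
            return str(self.term_info.loc[term, "name"])
        return ""

    def set_term_members(self, term: str, members: Iterable[str]) -> None:
        """Replace the gene membership of one term (in place)."""
        members = set(members)
        unknown = members - set(self.lengths.index)
        if unknown:
            raise ValidationError(f"unknown genes for term {term!r}: {sorted(unknown)[:5]}")
        old = self._term_genes.get(term, set())
        for g in old - members:
            self._gene_terms[g] = self._gene_terms[g] - {term}
        for g in members - old:
            self._gene_terms[g] = self._gene_terms[g] | {term}
        if members:
            self._term_genes[term] = members
        else:
            self._term_genes.pop(term, None)
        keep = self.annotations["term"] != term
        extra = pd.DataFrame({"gene_id": sorted(members), "term": term})
        self.annotations = pd.concat(
            [self.annotations[keep], extra], ignore_index=True
        )

    def incidence(self, terms: Sequence[str] | None = None) -> tuple[list[str], list[str], sp.csr_matrix]:
        """Sparse gene x term membership matrix (genes and terms sorted)."""
        genes = list(self.lengths.index)
        if terms is None:
            terms = self.term_universe
        terms = list(terms)
        gpos = {g: i for i, g in enumerate(genes)}
        tpos = {t: j for j, t in enumerate(terms)}
        rows, cols = [], []
        for t in terms:
            j = tpos[t]
            for g in self._term_genes.get(t, ()):
                rows.append(gpos[g])
                cols.append(j)
        mat = sp.csr_matrix(
            (np.ones(len(rows), dtype=np.int32), (rows, cols)),
            shape=(len(genes), len(terms)),
        )
        return genes, terms, mat


def read_annotation(path: str | Path, schema: Mapping[str, str] | None = None) -> AnnotationSet:
    """Read a Biomart-style annotation export (one gene/GO-term pair per row).

    Rows sharing a gene collapse into one annotated gene; an empty GO cell
    contributes no term but keeps the gene in the universe.  Gene length is
    ``end - start + 1`` (1-based inclusive coordinates) unless an explicit
    length column is present.
    """
    mapping = dict(DEFAULT_ANNOTATION_SCHEMA)
    if schema:
        mapping.update(schema)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    raw = raw.rename(columns={c: mapping[c] for c in raw.columns if c in mapping})
    if "gene_id" not in raw.columns:
        raise SchemaError("annotation lacks a gene ID column")

    if "length_bp" in raw.columns:
        length = pd.to_numeric(raw["length_bp"], errors="coerce")
        if length.isna().any():
            row = int(np.flatnonzero(length.isna())[0])
            raise ValidationError(f"data row {row + 1}: non-numeric gene length")
    elif {"start", "end"} <= set(raw.columns):
        start = pd.to_numeric(raw["start"], errors="coerce")
        end = pd.to_numeric(raw["end"], errors="coerce")
        if start.isna().any() or end.isna().any():
            row = int(np.flatnonzero(start.isna() | end.isna())[0])
            raise ValidationError(f"data row {row + 1}: non-numeric gene coordinates")
        if (end < start).any():
            row = int(np.flatnonzero((end < start).to_numpy())[0])
            raise ValidationError(f"data row {row + 1}: gene end < start")
        length = end - start + 1
    else:
        raise SchemaError("annotation needs start/end columns or an explicit length column")

    lengths = (
        pd.DataFrame({"gene_id": raw["gene_id"], "length_bp": length})
        .groupby("gene_id")["length_bp"]
        .first()
    )

    has_term = raw.get("go_id")
    if has_term is None:
        ann = pd.DataFrame(columns=["gene_id", "term"])
        term_info = None
    else:
        mask = raw["go_id"].notna() & (raw["go_id"].str.strip() != "")
        ann = pd.DataFrame(
            {"gene_id": raw.loc[mask, "gene_id"], "term": raw.loc[mask, "go_id"].str.strip()}
        )
        names = raw.loc[mask, "go_name"] if "go_name" in raw.columns else ""
        domains = (
            raw.loc[mask, "go_domain"] if "go_domain" in raw.columns else "biological_process"
        )
        info = pd.DataFrame({"term": ann["term"], "name": names, "domain": domains})
        term_info = info.drop_duplicates("term").set_index("term")[["name", "domain"]]
        term_info["name"] = term_info["name"].fillna("")
        term_info["domain"] = term_info["domain"].fillna("biological_process")
    return AnnotationSet(lengths=lengths, annotations=ann, term_info=term_info)


def write_annotation(universe: AnnotationSet, path: str | Path) -> None:
    """Write an AnnotationSet back out in the Biomart header dialect."""
    rows = []
    for g in universe.gene_ids:
        length = int(universe.lengths.loc[g])
        terms = sorted(universe.terms_of(g))
        if not terms:
            rows.append((g, 1, length, "", "", ""))
        for t in terms:
            rows.append((g, 1, length, t, universe.name_of(t), universe.domain_of(t)))
    frame = pd.DataFrame(
        rows,
        columns=[
            "Gene stable ID",
            "Gene start (bp)",
            "Gene end (bp)",
            "GO term accession",
            "GO term name",
            "GO domain",
        ],
    )
    frame.to_csv(path, sep="\t", index=False)


CT_ROLES = ("target", "reference")


@dataclasses.dataclass
class CtPlate:
    """qPCR wells, one row per well, grouped by (gene, role, condition, timepoint)."""

    wells: pd.DataFrame
    ct_range: tuple[float, float] = (0.0, 45.0)

    def __post_init__(self) -> None:
        required = {"gene_id", "role", "condition", "timepoint", "well_ct"}
        missing = required - set(self.wells.columns)
        if missing:
            raise SchemaError(f"Ct plate lacks columns: {sorted(missing)}")
        if "replicate" not in self.wells.columns:
            self.wells = self.wells.copy()
            self.wells["replicate"] = (
                self.wells.groupby(["gene_id", "role", "condition", "timepoint"]).cumcount() + 1
            )
        bad_role = set(self.wells["role"]) - set(CT_ROLES)
        if bad_role:
            raise ValidationError(f"unknown well roles: {sorted(bad_role)}")
        bad_cond = set(self.wells["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValidationError(f"unknown well conditions: {sorted(bad_cond)}")
        ct = pd.to_numeric(self.wells["well_ct"], errors="coerce")
        if ct.isna().any():
            row = int(np.flatnonzero(ct.isna())[0])
            raise ValidationError(f"well row {row + 1}: non-numeric Ct")
        lo, hi = self.ct_range
        out = (ct < lo) | (ct > hi)
        if out.any():
            row = int(np.flatnonzero(out.to_numpy())[0])
            raise ValidationError(
                f"well row {row + 1}: Ct {ct.iloc[row]} outside plausible range [{lo}, {hi}]"
            )
        sizes = self.wells.groupby(["gene_id", "role", "condition", "timepoint"]).size()
        odd = sizes[sizes != 3]
        if len(odd):
            warnings.warn(
                f"{len(odd)} well group(s) without exactly 3 replicates "
                f"(e.g. {odd.index[0]}: {odd.iloc[0]} wells)",
                stacklevel=2,
            )

    def group(self, gene_id: str, role: str, condition: str, timepoint: str) -> np.ndarray:
        w = self.wells
        mask = (
            (w["gene_id"] == gene_id)
            & (w["role"] == role)
            & (w["condition"] == condition)
            & (w["timepoint"] == timepoint)
        )
        return pd.to_numeric(w.loc[mask, "well_ct"]).to_numpy(dtype=float)

    def groups(self) -> pd.core.groupby.DataFrameGroupBy:
        return self.wells.groupby(["gene_id", "condition", "timepoint"])


def read_ct_plate(path: str | Path, ct_range: tuple[float, float] = (0.0, 45.0)) -> CtPlate:
    wells = pd.read_csv(path)
    return CtPlate(wells=wells, ct_range=ct_range)


def write_ct_plate(plate: CtPlate, path: str | Path) -> None:
    plate.wells.to_csv(path, index=False)


def format_pvalue(p: float, n_draws: int | None, precision: int = 4) -> str:
    """Render a Monte-Carlo P-value; an estimate of exactly 0 becomes '<1/n_draws'."""
    if n_draws and p == 0.0:
        return f"<{1.0 / n_draws:g}"
    return f"{p:.{precision}f}"


def _enrichment_frame(results, p_precision: int) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "domain": r.domain,
                "term": r.term,
                "name": r.name,
                "n_genes": r.n_test_with_term,
                "F_test": f"{r.f_test:.4f}",
                "P": format_pvalue(r.p_value, r.n_draws, p_precision),
                "significant": r.significant,
            }
        )
    return pd.DataFrame(
        rows, columns=["domain", "term", "name", "n_genes", "F_test", "P", "significant"]
    )


def write_results(
    results,
    path: str | Path,
    format: str = "tsv",
    *,
    fold_precision: int = 2,
    p_precision: int = 4,
) -> None:
    """Write a pipeline product with deterministic column order and rendering.

    Fold-change-like columns are rendered with ``fold_precision`` decimals and
    P-value columns with ``p_precision``; a Monte-Carlo P of exactly 0 is
    rendered ``<1/n_draws``.  Dicts are written as JSON regardless of format.
    """
    path = Path(path)
    if isinstance(results, dict):
        with open(path, "w") as fh:
            json.dump(results, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return

    if isinstance(results, (list, tuple)) and results and hasattr(results[0], "p_value"):
        frame = _enrichment_frame(results, p_precision)
    elif isinstance(results, (list, tuple)) and not results:
        frame = pd.DataFrame(
            columns=["domain", "term", "name", "n_genes", "F_test", "P", "significant"]
        )
    elif isinstance(results, (list, tuple)) and dataclasses.is_dataclass(results[0]):
        frame = pd.DataFrame([dataclasses.asdict(r) for r in results])
    elif isinstance(results, pd.DataFrame):
        frame = results.copy()
        for col in frame.columns:
            if frame[col].dtype.kind == "f":
                if col.lower().startswith("p") or "p_value" in col.lower():
                    frame[col] = frame[col].map(lambda x: f"{x:.{p_precision}f}")
                else:
                    frame[col] = frame[col].map(lambda x: f"{x:.{fold_precision}f}")
    else:
        raise TypeError(f"cannot serialise result of type {type(results)!r}")

    if format == "tsv":
        frame.to_csv(path, sep="\t", index=False)
    elif format == "json":
        frame.to_json(path, orient="records", indent=2)
    else:
        raise ValueError(f"unknown output format {format!r}")
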