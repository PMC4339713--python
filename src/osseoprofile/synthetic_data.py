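"""Synthetic pipeline inputs with planted signal and a ground-truth ledger.

Every input the pipeline consumes — the FPKM expression table, the GO
annotation universe, and the qPCR Ct plate — can be generated here with the
statistical structure the analysis assumes, so every stage is testable
without any external download.  Alongside each dataset a
:class:`TruthLedger` records exactly what was planted (DE gene sets and
effect sizes per timepoint, enriched terms, true qPCR folds), which is
sufficient to score recovery exactly.

The default configuration mirrors the magnitudes of a single-animal
peri-implant bone-healing experiment: ~21,744 transcripts of which ~63% are
undetected (zero FPKM in every sample), on the order of 1,600-1,800 DE
transcripts per timepoint, and several hundred genes shared between the
1-week and 4-week DE sets.  Test suites use much smaller configurations.

Model choices: gene lengths and baseline FPKMs are log-normal, expression
noise is multiplicative log-normal (sigma expressed in log2 units), and Ct
well noise is additive Gaussian — the simplest standard models for each
quantity.  GO term assignment is Bernoulli per (gene, term) with a per-term
prevalence; a coupling coefficient optionally makes prevalence increase with
gene length (on the logit scale), which is the confound the
length-controlled enrichment test is designed to absorb.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io_tables import AnnotationSet, CtPlate, ExpressionTable

__all__ = [
    "SyntheticConfig",
    "TruthLedger",
    "generate_universe",
    "generate_expression",
    "generate_ct_plate",
]

TIMEPOINTS = ("1w", "4w")


@dataclasses.dataclass
class SyntheticConfig:
    """Parameters of the synthetic study; defaults emulate the full-scale run."""

    n_genes: int = 21_744
    n_transcripts_per_gene: int = 1
    zero_fraction: float = 13_690 / 21_744  # fraction of transcripts undetected
    # gene length distribution, log-normal (bp)
    length_meanlog: float = 9.9
    length_sdlog: float = 1.2
    # GO annotation
    n_terms: int = 2_000
    prevalence_low: float = 0.002  # per-term prevalence, log-uniform range
    prevalence_high: float = 0.1
    length_term_coupling: float = 0.0  # logit-scale slope on standardized log-length
    # planted differential expression
    n_up_1w: int = 773
    n_down_1w: int = 870
    n_up_4w: int = 937
    n_down_4w: int = 902
    overlap_up: int = 299
    overlap_down: int = 481
    effect_low: float = 1.2  # |log2 effect| range, uniform
    effect_high: float = 4.5
    # expression model
    baseline_meanlog: float = 2.0  # log FPKM
    baseline_sdlog: float = 1.5
    expression_sigma: float = 0.0  # per-sample log2-scale noise SD
    n_replicates: int = 1
    # planted term enrichment
    n_enriched_terms: int = 5
    enrichment_multiplier: float = 10.0
    enriched_target: tuple[str, str] = ("up", "1w")  # (direction, timepoint)
    # qPCR plate
    ct_sigma: float = 0.2  # cycles per well
    ct_reference_gene: str = "REF"
    ct_reference_mean: float = 20.0
    ct_target_baseline: float = 26.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_genes, self.n_transcripts_per_gene, self.n_terms,
            self.n_up_1w, self.n_down_1w, self.n_up_4w, self.n_down_4w,
            self.overlap_up, self.overlap_down, self.n_replicates,
            self.n_enriched_terms,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if not 0.0 <= self.zero_fraction <= 1.0:
            raise ValueError("zero_fraction must be in [0, 1]")
        if self.overlap_up > min(self.n_up_1w, self.n_up_4w):
            raise ValueError("overlap_up exceeds a per-timepoint planted count")
        if self.overlap_down > min(self.n_down_1w, self.n_down_4w):
            raise ValueError("overlap_down exceeds a per-timepoint planted count")
        if not 0 < self.prevalence_low <= self.prevalence_high < 1:
            raise ValueError("prevalence range must satisfy 0 < low <= high < 1")
        if self.effect_low > self.effect_high:
            raise ValueError("effect_low must be <= effect_high")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclasses.dataclass
class TruthLedger:
    """What was planted: sufficient to score recovery exactly."""

    up: dict[str, frozenset]  # timepoint -> planted upregulated genes
    down: dict[str, frozenset]
    effects: dict[str, dict[str, float]]  # gene -> timepoint -> true log2 effect
    zero_transcripts: frozenset
    enriched_terms: tuple[str, ...] = ()
    enriched_target: tuple[str, str] = ("up", "1w")
    ct_folds: dict[str, float] = dataclasses.field(default_factory=dict)  # "gene|tp" -> fold

    def to_json(self, path: str | Path) -> None:
        payload = {
            "up": {tp: sorted(v) for tp, v in self.up.items()},
            "down": {tp: sorted(v) for tp, v in self.down.items()},
            "effects": self.effects,
            "zero_transcripts": sorted(self.zero_transcripts),
            "enriched_terms": list(self.enriched_terms),
            "enriched_target": list(self.enriched_target),
            "ct_folds": self.ct_folds,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthLedger":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            up={tp: frozenset(v) for tp, v in payload["up"].items()},
            down={tp: frozenset(v) for tp, v in payload["down"].items()},
            effects=payload["effects"],
            zero_transcripts=frozenset(payload["zero_transcripts"]),
            enriched_terms=tuple(payload["enriched_terms"]),
            enriched_target=tuple(payload["enriched_target"]),
            ct_folds=payload["ct_folds"],
        )


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:06d}" for i in range(n)]


def _term_ids(n: int) -> list[str]:
    return [f"GO:{i + 1:07d}" for i in range(n)]


def generate_universe(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> AnnotationSet:
    """Annotated gene universe: log-normal lengths, Bernoulli term assignment.

    With a nonzero ``length_term_coupling`` the per-gene membership
    probability for every term is shifted on the logit scale by
    coupling * z(log length), making annotation prevalence increase with gene
    length; coupling 0 gives length-independent assignment.
    """
    if rng is None:
        rng = config.rng()
    genes = _gene_ids(config.n_genes)
    lengths = np.maximum(
        1, np.round(rng.lognormal(config.length_meanlog, config.length_sdlog, config.n_genes))
    ).astype(int)
    length_series = pd.Series(lengths, index=pd.Index(genes, name="gene_id"))

    terms = _term_ids(config.n_terms)
    log_len = np.log(lengths.astype(float))
    sd = log_len.std()
    z = (log_len - log_len.mean()) / sd if sd > 0 else np.zeros_like(log_len)

    prevalences = np.exp(
        rng.uniform(
            np.log(config.prevalence_low), np.log(config.prevalence_high), config.n_terms
        )
    )
    gene_arr = np.asarray(genes)
    frames = []
    for t, q in zip(terms, prevalences):
        p = expit(logit(q) + config.length_term_coupling * z)
        hit = rng.random(config.n_genes) < p
        if hit.any():
            frames.append(pd.DataFrame({"gene_id": gene_arr[hit], "term": t}))
    if frames:
        annotations = pd.concat(frames, ignore_index=True)
    else:
        annotations = pd.DataFrame(columns=["gene_id", "term"])

    domains = ["biological_process", "cellular_component", "molecular_function"]
    term_info = pd.DataFrame(
        {
            "name": [f"synthetic term {i + 1}" for i in range(config.n_terms)],
            "domain": [domains[i % 3] for i in range(config.n_terms)],
        },
        index=pd.Index(terms, name="term"),
    )
    return AnnotationSet(lengths=length_series, annotations=annotations, term_info=term_info)


def _plant_de_sets(
    nonzero_genes: list[str], config: SyntheticConfig, rng: np.random.Generator
) -> tuple[dict[str, set], dict[str, set]]:
    pools = {
        "up_both": config.overlap_up,
        "up_1w": config.n_up_1w - config.overlap_up,
        "up_4w": config.n_up_4w - config.overlap_up,
        "down_both": config.overlap_down,
        "down_1w": config.n_down_1w - config.overlap_down,
        "down_4w": config.n_down_4w - config.overlap_down,
    }
    total = sum(pools.values())
    if total > len(nonzero_genes):
        raise ValueError(
            f"infeasible config: {total} planted DE genes requested but only "
            f"{len(nonzero_genes)} genes have a detected transcript"
        )
    chosen = rng.choice(np.asarray(nonzero_genes), size=total, replace=False)
    out, start = {}, 0
    for name, n in pools.items():
        out[name] = set(chosen[start : start + n])
        start += n
    up = {"1w": out["up_both"] | out["up_1w"], "4w": out["up_both"] | out["up_4w"]}
    down = {"1w": out["down_both"] | out["down_1w"], "4w": out["down_both"] | out["down_4w"]}
    return up, down


def generate_expression(
    universe: AnnotationSet,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionTable, TruthLedger]:
    """Expression table with planted DE signal, plus its truth ledger.

    Baseline FPKMs are log-normal per transcript; a ``zero_fraction`` of
    transcripts is all-zero across every sample (undetected); planted genes'
    implant-side means are shifted by their true log2 effect at the planted
    timepoint(s).  When planted enriched terms are configured, those terms'
    membership is re-drawn among the planted target DE genes at
    ``enrichment_multiplier`` times the term's base prevalence — note this
    updates the annotation universe in place.
    """
    if rng is None:
        rng = config.rng()
    genes = list(universe.gene_ids)
    if config.n_genes != len(genes):
        raise ValueError("universe size does not match config.n_genes")

    transcripts, t_gene = [], []
    for g in genes:
        for k in range(config.n_transcripts_per_gene):
            transcripts.append(f"{g}.t{k + 1}")
            t_gene.append(g)
    n_tx = len(transcripts)

    baseline = rng.lognormal(config.baseline_meanlog, config.baseline_sdlog, n_tx)
    zero_mask = rng.random(n_tx) < config.zero_fraction

    gene_zero = pd.Series(zero_mask, index=t_gene).groupby(level=0).all()
    nonzero_genes = sorted(gene_zero.index[~gene_zero])
    up, down = _plant_de_sets(nonzero_genes, config, rng)

    effects: dict[str, dict[str, float]] = {}
    for tp in TIMEPOINTS:
        for g in sorted(up[tp]):
            effects.setdefault(g, {})[tp] = float(
                rng.uniform(config.effect_low, config.effect_high)
            )
        for g in sorted(down[tp]):
            effects.setdefault(g, {})[tp] = -float(
                rng.uniform(config.effect_low, config.effect_high)
            )

    effect_arr = {
        tp: np.array([effects.get(g, {}).get(tp, 0.0) for g in t_gene]) for tp in TIMEPOINTS
    }

    columns: dict[str, np.ndarray] = {}
    for tp in TIMEPOINTS:
        for cond in ("control", "implant"):
            mean = baseline * (2.0 ** effect_arr[tp] if cond == "implant" else 1.0)
            for r in range(1, config.n_replicates + 1):
                vals = mean.copy()
                if config.expression_sigma > 0:
                    vals = vals * 2.0 ** rng.normal(0.0, config.expression_sigma, n_tx)
                vals[zero_mask] = 0.0
                columns[f"{cond}_{tp}_r{r}"] = vals

    values = pd.DataFrame(columns, index=pd.Index(transcripts, name="transcript_id"))
    meta = {}
    for name in values.columns:
        cond, tp, rep = name.split("_")
        meta[name] = {"condition": cond, "timepoint": tp, "replicate": int(rep[1:])}
    samples = pd.DataFrame.from_dict(meta, orient="index")
    samples.index.name = "sample"
    table = ExpressionTable(
        values=values,
        gene_ids=pd.Series(t_gene, index=values.index, name="gene_id"),
        samples=samples,
    )

    enriched_terms: tuple[str, ...] = ()
    term_universe = universe.term_universe
    if config.n_enriched_terms > 0 and term_universe:
        direction, tp = config.enriched_target
        target = sorted((up if direction == "up" else down)[tp])
        n_pick = min(config.n_enriched_terms, len(term_universe))
        picked = sorted(
            rng.choice(np.asarray(term_universe), size=n_pick, replace=False).tolist()
        )
        for term in picked:
            members = set(universe.genes_with(term))
            base_prev = max(len(members) / universe.n_genes, 1.0 / universe.n_genes)
            p_target = min(1.0, config.enrichment_multiplier * base_prev)
            members -= set(target)
            hit = rng.random(len(target)) < p_target
            members |= {g for g, h in zip(target, hit) if h}
            universe.set_term_members(term, members)
        enriched_terms = tuple(picked)

    ledger = TruthLedger(
        up={tp: frozenset(v) for tp, v in up.items()},
        down={tp: frozenset(v) for tp, v in down.items()},
        effects=effects,
        zero_transcripts=frozenset(np.asarray(transcripts)[zero_mask].tolist()),
        enriched_terms=enriched_terms,
        enriched_target=config.enriched_target,
    )
    return table, ledger


def generate_ct_plate(
    folds: Mapping[tuple[str, str], float],
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> CtPlate:
    """Triplicate Ct plate encoding the given true (gene, timepoint) folds.

    The reference gene's expected Ct is constant across conditions; the
    target's control-side expected Ct is a fixed baseline and its implant-side
    expected Ct is baseline - log2(fold), so the comparative-Ct readout of a
    noiseless plate is exactly the planted fold.  Gaussian noise of
    ``ct_sigma`` cycles is added per well.
    """
    if rng is None:
        rng = config.rng()
    for key, f in folds.items():
        if not f > 0:
            raise ValueError(f"fold for {key} must be > 0")
    rows = []

    def emit(gene, role, cond, tp, expected):
        for r in range(1, 4):
            ct = expected + (rng.normal(0.0, config.ct_sigma) if config.ct_sigma > 0 else 0.0)
            rows.append(
                {
                    "gene_id": gene,
                    "role": role,
                    "condition": cond,
                    "timepoint": tp,
                    "well_ct": round(ct, 6),
                    "replicate": r,
                }
            )

    timepoints = sorted({tp for _, tp in folds})
    for tp in timepoints:
        for cond in ("control", "implant"):
            emit(config.ct_reference_gene, "reference", cond, tp, config.ct_reference_mean)
    for gene, tp in sorted(folds):
        fold = folds[(gene, tp)]
        emit(gene, "target", "control", tp, config.ct_target_baseline)
        emit(gene, "target", "implant", tp, config.ct_target_baseline - np.log2(fold))
    return CtPlate(wells=pd.DataFrame(rows))
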