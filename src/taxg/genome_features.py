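"""Comparative genome feature tables, feature regression and trait screens.

Covers the three desk analyses of a genome-based species description:
a per-genome feature table (size, G+C, rRNA/tRNA/CDS counts, median CDS
length), an ordinary-least-squares regression of CDS count on genome size
(closely related genomes show a strong positive correlation), and a
presence/absence screen for plant-growth-promoting genes driven by an
editable catalog of gene symbols and product-description patterns.
"""

from __future__ import annotations

import importlib.resources
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import AssemblyStats, GeneRecord, GenomeAssembly, assembly_stats

logger = logging.getLogger("taxg")


@dataclass
class GenomeFeatureRow:
    genome_id: str
    size_mbp: float
    gc_percent: float
    n_rrna: int | None
    n_trna: int | None
    n_cds: int | None
    median_cds_len: float | None


@dataclass
class RegressionResult:
    slope: float  # CDS per Mbp
    intercept: float
    r_squared: float


def lower_median(values: Sequence[int | float]) -> float:
    """Median with the lower of the two central values for even counts."""
    if not values:
        raise ValueError("no values")
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def feature_table(
    genomes: Sequence[GenomeAssembly],
    annotations: Mapping[str, Sequence[GeneRecord]],
) -> list[GenomeFeatureRow]:
    """Per-genome feature rows; genomes without annotations get null counts."""
    rows = []
    for genome in genomes:
        st: AssemblyStats = assembly_stats(genome)
        genes = annotations.get(genome.genome_id)
        if genes is None:
            logger.warning("genome %s: no annotation, counts omitted", genome.genome_id)
            rows.append(
                GenomeFeatureRow(
                    genome.genome_id, round(st.size_bp / 1e6, 2), st.gc_percent,
                    None, None, None, None,
                )
            )
            continue
        cds = [g for g in genes if g.feature_type == "CDS"]
        rows.append(
            GenomeFeatureRow(
                genome_id=genome.genome_id,
                size_mbp=round(st.size_bp / 1e6, 2),
                gc_percent=st.gc_percent,
                n_rrna=sum(1 for g in genes if g.feature_type == "rRNA"),
                n_trna=sum(1 for g in genes if g.feature_type == "tRNA"),
                n_cds=len(cds),
                median_cds_len=lower_median([g.length for g in cds]) if cds else None,
            )
        )
    return rows


def write_feature_table(rows: Sequence[GenomeFeatureRow], path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in rows]).to_csv(path, sep="\t", index=False)


def ols_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """OLS of y on x with R^2 = 1 - SS_res/SS_tot (0 for constant y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor")
    if np.ptp(y) == 0:
        slope, intercept = 0.0, float(y[0])
        return RegressionResult(slope, intercept, 0.0)
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


# ---------------------------------------------------------------------------
# Plant-growth-promoting trait screen
# ---------------------------------------------------------------------------


@dataclass
class TraitCatalogEntry:
    trait: str
    symbols: list[str]
    patterns: list[re.Pattern]


def _normalize_symbol(sym: str) -> str:
    return sym.lower().replace("-", "")


def load_trait_catalog(path: str | Path | None = None) -> list[TraitCatalogEntry]:
    """Load a trait catalog TSV (trait, symbols, product patterns).

    The bundled default covers phosphate solubilization/regulation genes
    (ppx-gppA, pstS, senX3), the tryptophan/auxin pathway (trpA/B/D/E/F,
    pdxI, aad), ethylene modulation (acc), antibiotic biosynthesis (fabG,
    bacC2, hdhA, auaJ, tcmO) and lytic enzymes (chitinase, glucoamylase).
    """
    if path is None:
        ref = importlib.resources.files("taxg") / "data" / "pgp_catalog.tsv"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    entries: list[TraitCatalogEntry] = []
    seen: set[str] = set()
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"catalog line needs 3 columns: {line!r}")
        trait, symbols, patterns = fields[0], fields[1], fields[2]
        if trait in seen:
            raise ValueError(f"duplicate catalog trait {trait!r}")
        seen.add(trait)
        compiled = []
        for pat in patterns.split(";"):
            pat = pat.strip()
            if not pat:
                continue
            try:
                compiled.append(re.compile(pat, re.IGNORECASE))
            except re.error as exc:
                raise ValueError(f"trait {trait!r}: bad pattern {pat!r}: {exc}") from exc
        entries.append(
            TraitCatalogEntry(
                trait=trait,
                symbols=[s.strip() for s in symbols.split(",") if s.strip()],
                patterns=compiled,
            )
        )
    return entries


@dataclass
class TraitMatrix:
    presence: pd.DataFrame  # traits x genomes, bool
    evidence: pd.DataFrame  # columns: trait, genome_id, gene_id, matched_on


def trait_screen(
    annotations: Mapping[str, Sequence[GeneRecord]],
    catalog: Sequence[TraitCatalogEntry] | None = None,
) -> TraitMatrix:
    """Presence/absence of catalog traits per genome, with gene evidence.

    A trait is present when any gene matches one of its symbols exactly
    (lowercased, hyphens stripped, tested against the record's gene symbol
    and gene id) or one of its product patterns.  Monotone: adding records
    can only turn cells present.
    """
    catalog = list(catalog) if catalog is not None else load_trait_catalog()
    genome_ids = sorted(annotations)
    presence = pd.DataFrame(
        False, index=[e.trait for e in catalog], columns=genome_ids
    )
    evid_rows = []
    for gid in genome_ids:
        for gene in annotations[gid]:
            gene_syms = {
                _normalize_symbol(gene.gene_symbol),
                _normalize_symbol(gene.gene_id.rsplit("|", 1)[-1]),
            }
            for entry in catalog:
                matched = None
                if any(_normalize_symbol(s) in gene_syms for s in entry.symbols):
                    matched = "symbol"
                else:
                    for pat in entry.patterns:
                        if gene.product and pat.search(gene.product):
                            matched = f"product:{pat.pattern}"
                            break
                if matched:
                    presence.loc[entry.trait, gid] = True
                    evid_rows.append(
                        {
                            "trait": entry.trait,
                            "genome_id": gid,
                            "gene_id": gene.gene_id,
                            "matched_on": matched,
                        }
                    )
    evidence = pd.DataFrame(
        evid_rows, columns=["trait", "genome_id", "gene_id", "matched_on"]
    )
    return TraitMatrix(presence=presence, evidence=evidence)


def write_trait_matrix(tm: TraitMatrix, path: str | Path, evidence_path: str | Path | None = None) -> None:
    """Trait matrix as +/- TSV; optional evidence TSV alongside."""
    out = tm.presence.map(lambda v: "+" if v else "-")
    out.index.name = "trait"
    out.to_csv(path, sep="\t")
    if evidence_path is not None:
        tm.evidence.to_csv(evidence_path, sep="\t", index=False)
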