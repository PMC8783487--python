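"""Pairwise orthologous groups (POGs) and core/pan functional partitioning.

Orthology is inferred by reciprocal top hits: every gene of each genome is
searched against every other genome (shared-k-mer prefilter, then global
protein alignment under BLOSUM62), a pair is reciprocal when each gene is
the other's highest-scoring hit, and POGs are the connected components of
the reciprocal-pair graph.  Short/partial genes that missed the reciprocal
stage are attached to POG centroids UCLUST-style at >= 95% identity over
the shorter sequence.  Genes in no cross-genome POG are strain-specific;
POGs with a member in every genome form the core genome.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .config import COG_CATEGORIES, UNASSIGNED_CATEGORY, PogConfig, SearchConfig
from .genome_io import GeneRecord

logger = logging.getLogger("taxg")


@dataclass
class SimilarityHit:
    query_gene: str
    subject_gene: str
    query_genome: str
    subject_genome: str
    identity_fraction: float  # matched columns / alignment columns
    score: float
    query_coverage: float


@dataclass
class ReciprocalPair:
    gene_a: str
    gene_b: str
    genome_a: str
    genome_b: str


@dataclass
class POG:
    pog_id: str
    members: dict[str, str]  # gene_id -> genome_id

    @property
    def presence_vector(self) -> Counter:
        return Counter(self.members.values())

    def genomes(self) -> set[str]:
        return set(self.members.values())


@dataclass
class PanGenomeSummary:
    n_pogs: int
    core_pog_ids: list[str]
    per_genome: pd.DataFrame  # columns: core, accessory, strain_specific, total
    core_gene_ids: set[str] = field(repr=False, default_factory=set)
    accessory_gene_ids: set[str] = field(repr=False, default_factory=set)
    strain_specific_gene_ids: set[str] = field(repr=False, default_factory=set)


def _protein_aligner(cfg: SearchConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(cfg.matrix)
    aligner.open_gap_score = cfg.gap_open
    aligner.extend_gap_score = cfg.gap_extend
    return aligner


def _alignment_identity(alignment) -> tuple[float, float, int]:
    """(identity_fraction, query_coverage, n_identities) for a global alignment.

    Identity is matched columns over all alignment columns; coverage is the
    fraction of query residues inside the terminal-gap-stripped region.
    """
    row_q, row_s = str(alignment[0]), str(alignment[1])
    start, end = 0, len(row_q)
    while start < end and (row_q[start] == "-" or row_s[start] == "-"):
        start += 1
    while end > start and (row_q[end - 1] == "-" or row_s[end - 1] == "-"):
        end -= 1
    if end == start:
        return 0.0, 0.0, 0
    matches = 0
    q_res = 0
    for cq, cs in zip(row_q[start:end], row_s[start:end]):
        if cq != "-":
            q_res += 1
        if cq == cs and cq != "-":
            matches += 1
    columns = end - start
    q_len = sum(1 for c in row_q if c != "-")
    return matches / columns, q_res / q_len if q_len else 0.0, matches


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _require_aa(genes: Iterable[GeneRecord]) -> None:
    for g in genes:
        if not g.aa_seq:
            raise ValueError(f"gene {g.gene_id!r} lacks an amino-acid sequence")


def all_vs_all_search(
    genomes: Mapping[str, Sequence[GeneRecord]],
    cfg: SearchConfig | None = None,
    prefilter: bool = True,
) -> list[SimilarityHit]:
    """All-vs-all cross-genome protein search.

    For each ordered genome pair, every query gene is compared against the
    other genome's genes; with ``prefilter=True`` only subjects sharing at
    least ``cfg.min_shared_kmers`` amino-acid k-mers with the query are
    aligned (``prefilter=False`` is the brute-force oracle mode).  Hits
    below the identity or query-coverage floors are dropped; per query,
    hits are sorted by score descending.
    """
    cfg = cfg or SearchConfig()
    for genes in genomes.values():
        _require_aa(genes)
    aligner = _protein_aligner(cfg)
    kmers: dict[str, set[str]] = {}
    if prefilter:
        for genes in genomes.values():
            for g in genes:
                kmers[g.gene_id] = _kmer_set(g.aa_seq, cfg.kmer_size)
    hits: list[SimilarityHit] = []
    genome_ids = sorted(genomes)
    for qg in genome_ids:
        for sg in genome_ids:
            if qg == sg:
                continue
            subjects = sorted(genomes[sg], key=lambda g: g.gene_id)
            for query in sorted(genomes[qg], key=lambda g: g.gene_id):
                q_hits: list[SimilarityHit] = []
                qk = kmers.get(query.gene_id)
                for subject in subjects:
                    if prefilter and len(qk & kmers[subject.gene_id]) < cfg.min_shared_kmers:
                        continue
                    aln = aligner.align(query.aa_seq, subject.aa_seq)[0]
                    identity, coverage, _ = _alignment_identity(aln)
                    if identity < cfg.min_identity or coverage < cfg.min_query_coverage:
                        continue
                    q_hits.append(
                        SimilarityHit(
                            query_gene=query.gene_id,
                            subject_gene=subject.gene_id,
                            query_genome=qg,
                            subject_genome=sg,
                            identity_fraction=identity,
                            score=float(aln.score),
                            query_coverage=coverage,
                        )
                    )
                q_hits.sort(
                    key=lambda h: (-h.score, -h.identity_fraction, h.subject_gene)
                )
                hits.extend(q_hits)
    return hits


def reciprocal_best_pairs(hits: Sequence[SimilarityHit]) -> list[ReciprocalPair]:
    """Bidirectional top hits per genome pair.

    Score ties break by higher identity fraction, then lexicographic
    subject gene id (the hit lists from :func:`all_vs_all_search` are
    already in that order).
    """
    top: dict[tuple[str, str, str], SimilarityHit] = {}
    for h in hits:
        key = (h.query_gene, h.query_genome, h.subject_genome)
        cur = top.get(key)
        if cur is None or (-h.score, -h.identity_fraction, h.subject_gene) < (
            -cur.score, -cur.identity_fraction, cur.subject_gene
        ):
            top[key] = h
    pairs: list[ReciprocalPair] = []
    for (q, qg, sg), h in sorted(top.items()):
        if qg >= sg:  # emit each unordered pair once, from the lower genome id
            continue
        back = top.get((h.subject_gene, sg, qg))
        if back is not None and back.subject_gene == q:
            pairs.append(ReciprocalPair(q, h.subject_gene, qg, sg))
    return pairs


def build_pogs(
    pairs: Sequence[ReciprocalPair], cfg: PogConfig | None = None
) -> list[POG]:
    """POGs from reciprocal pairs.

    ``single-linkage`` (default) takes connected components of the
    reciprocal-pair graph; ``pair-only`` keeps each pair as its own group.
    Ids are assigned deterministically from the smallest member gene id.
    """
    cfg = cfg or PogConfig()
    genome_of: dict[str, str] = {}
    for p in pairs:
        genome_of[p.gene_a] = p.genome_a
        genome_of[p.gene_b] = p.genome_b
    if cfg.merge_rule == "pair-only":
        components: list[set[str]] = [{p.gene_a, p.gene_b} for p in pairs]
    else:
        graph = nx.Graph()
        for p in pairs:
            graph.add_edge(p.gene_a, p.gene_b)
        components = [set(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: min(c))
    pogs = []
    for i, comp in enumerate(components, start=1):
        pogs.append(
            POG(
                pog_id=f"POG{i:05d}",
                members={g: genome_of[g] for g in sorted(comp)},
            )
        )
    return pogs


def attach_partial_genes(
    pogs: Sequence[POG],
    unassigned: Sequence[GeneRecord],
    identity_threshold: float = 0.95,
    gene_index: Mapping[str, GeneRecord] | None = None,
    cfg: SearchConfig | None = None,
) -> tuple[list[POG], list[GeneRecord]]:
    """UCLUST-style greedy attachment of leftover (typically partial) genes.

    Each POG is represented by its longest member (the centroid); genes are
    processed longest first and attached to the best centroid whose
    identity — counted over the shorter sequence's length — meets the
    threshold (inclusive).  Returns updated POGs and the still-unassigned
    remainder.
    """
    if not (0 < identity_threshold <= 1):
        raise ValueError("identity threshold must be in (0, 1]")
    cfg = cfg or SearchConfig()
    if gene_index is None:
        raise ValueError("gene_index mapping gene_id -> GeneRecord is required")
    aligner = _protein_aligner(cfg)
    pogs = [POG(p.pog_id, dict(p.members)) for p in pogs]
    centroids: list[tuple[str, str]] = []  # (aa_seq, pog_index)
    for idx, p in enumerate(pogs):
        longest = max(
            (gene_index[g] for g in p.members),
            key=lambda r: (len(r.aa_seq or ""), r.gene_id),
        )
        centroids.append((longest.aa_seq or "", idx))
    remaining: list[GeneRecord] = []
    for gene in sorted(unassigned, key=lambda g: (-len(g.aa_seq or ""), g.gene_id)):
        best: tuple[float, int] | None = None
        for seq, idx in centroids:
            if not seq or not gene.aa_seq:
                continue
            aln = aligner.align(gene.aa_seq, seq)[0]
            _, _, matches = _alignment_identity(aln)
            identity_short = matches / min(len(gene.aa_seq), len(seq))
            if identity_short >= identity_threshold and (
                best is None or identity_short > best[0]
            ):
                best = (identity_short, idx)
        if best is None:
            remaining.append(gene)
        else:
            pogs[best[1]].members[gene.gene_id] = gene.genome_id
    return pogs, remaining


def partition(
    pogs: Sequence[POG],
    all_genes: Mapping[str, Sequence[GeneRecord]],
    n_genomes: int | None = None,
) -> PanGenomeSummary:
    """Core / accessory / strain-specific partition of the gene universe.

    Core POGs have a member in every genome; strain-specific genes belong
    to no POG spanning >= 2 genomes; everything else is accessory.
    """
    genome_ids = sorted(all_genes)
    n_genomes = n_genomes or len(genome_ids)
    gene_to_pog: dict[str, POG] = {}
    for p in pogs:
        for g in p.members:
            if g in gene_to_pog:
                raise ValueError(f"gene {g!r} appears in more than one POG")
            gene_to_pog[g] = p
    core_ids = [
        p.pog_id for p in pogs if n_genomes >= 2 and len(p.genomes()) == n_genomes
    ]
    core_set = set(core_ids)
    core_genes: set[str] = set()
    accessory_genes: set[str] = set()
    specific_genes: set[str] = set()
    rows = []
    for gid in genome_ids:
        counts = {"core": 0, "accessory": 0, "strain_specific": 0}
        for gene in all_genes[gid]:
            p = gene_to_pog.get(gene.gene_id)
            if p is None or len(p.genomes()) < 2:
                counts["strain_specific"] += 1
                specific_genes.add(gene.gene_id)
            elif p.pog_id in core_set:
                counts["core"] += 1
                core_genes.add(gene.gene_id)
            else:
                counts["accessory"] += 1
                accessory_genes.add(gene.gene_id)
        counts["total"] = sum(counts.values())
        rows.append(pd.Series(counts, name=gid))
    return PanGenomeSummary(
        n_pogs=len(pogs),
        core_pog_ids=core_ids,
        per_genome=pd.DataFrame(rows),
        core_gene_ids=core_genes,
        accessory_gene_ids=accessory_genes,
        strain_specific_gene_ids=specific_genes,
    )


def category_frequencies(
    summary: PanGenomeSummary,
    all_genes: Mapping[str, Sequence[GeneRecord]],
    gene_to_category: Mapping[str, str],
) -> pd.DataFrame:
    """COG one-letter category counts for the core and pan partitions.

    Unmapped genes are counted under ``unassigned``; the returned frame has
    one row per category and columns ``core`` / ``pan``, plus an
    ``assigned_fraction`` attribute row is reported by the caller from the
    counts themselves.
    """
    for gene, cat in gene_to_category.items():
        if cat not in COG_CATEGORIES:
            raise ValueError(f"unknown COG category {cat!r} for gene {gene!r}")
    counts: dict[str, Counter] = {"core": Counter(), "pan": Counter()}
    for genes in all_genes.values():
        for gene in genes:
            cat = gene_to_category.get(gene.gene_id, UNASSIGNED_CATEGORY)
            counts["pan"][cat] += 1
            if gene.gene_id in summary.core_gene_ids:
                counts["core"][cat] += 1
    cats = sorted(set(counts["pan"]) | set(counts["core"]))
    df = pd.DataFrame(
        {
            "core": [counts["core"].get(c, 0) for c in cats],
            "pan": [counts["pan"].get(c, 0) for c in cats],
        },
        index=cats,
    )
    df.index.name = "category"
    return df


def assigned_fraction(freqs: pd.DataFrame, partition_name: str) -> float:
    """Fraction of genes in a partition carrying a defined COG category."""
    total = freqs[partition_name].sum()
    if total == 0:
        return 0.0
    unassigned = (
        freqs.loc[UNASSIGNED_CATEGORY, partition_name]
        if UNASSIGNED_CATEGORY in freqs.index
        else 0
    )
    return float((total - unassigned) / total)


def ortholog_matrix(pogs: Sequence[POG], genome_ids: Sequence[str]) -> pd.DataFrame:
    """Pairwise ortholog matrix: cell (i, j) counts POGs present in both
    genomes; the diagonal counts each genome's genes that sit in any POG."""
    genome_ids = list(genome_ids)
    n = len(genome_ids)
    gi = {g: i for i, g in enumerate(genome_ids)}
    mat = np.zeros((n, n), dtype=int)
    for p in pogs:
        present = sorted({g for g in p.genomes() if g in gi})
        for a in present:
            for b in present:
                if a != b:
                    mat[gi[a], gi[b]] += 1
        for gene, genome in p.members.items():
            if genome in gi:
                mat[gi[genome], gi[genome]] += 1
    return pd.DataFrame(mat, index=genome_ids, columns=genome_ids)


def write_ortholog_matrix(
    pogs: Sequence[POG], genome_ids: Sequence[str], path: str | Path
) -> pd.DataFrame:
    mat = ortholog_matrix(pogs, genome_ids)
    mat.to_csv(path, sep="\t")
    return mat


def write_pog_table(pogs: Sequence[POG], path: str | Path) -> None:
    """POG membership TSV: pog_id, genome_id, gene_id."""
    with open(path, "w") as fh:
        fh.write("pog_id\tgenome_id\tgene_id\n")
        for p in pogs:
            for gene, genome in sorted(p.members.items()):
                fh.write(f"{p.pog_id}\t{genome}\t{gene}\n")


def read_category_map(path: str | Path, gene_col: int = 0, cat_col: int = 1) -> dict[str, str]:
    """2-column TSV gene -> COG category (first letter taken when several)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) <= max(gene_col, cat_col):
                continue
            cat = fields[cat_col].strip()
            if cat:
                mapping[fields[gene_col]] = cat[0]
    return mapping
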