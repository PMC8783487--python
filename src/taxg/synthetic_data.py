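"""Synthetic genomes, pan-genomes and marker pairs with known ground truth.

Every generator draws from a single explicitly seeded ``numpy`` Generator,
so outputs are byte-reproducible.  The default evolution mode is
substitution-only, which keeps expected identities closed-form
(expected identity = 1 - p); indels can be switched on to exercise gap
handling but carry no closed-form expectation.  These simulations exist to
make the pipeline testable end-to-end, not to model real bacterial
evolution: there is no rate heterogeneity, no codon bias, no gene transfer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .genome_io import GeneRecord, GenomeAssembly, reverse_complement, translate

logger = logging.getLogger("taxg")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class EvolutionParams:
    """Per-site substitution probability, optional indels, and the seed."""

    substitution_prob: float = 0.0
    indel_rate: float = 0.0
    mean_indel_len: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.substitution_prob < 0.75):
            raise ValueError("substitution_prob must be in [0, 0.75)")
        if self.indel_rate < 0 or self.mean_indel_len <= 0:
            raise ValueError("indel parameters must be non-negative")


@dataclass
class PanGenomeTruth:
    """Ground truth of a simulated pan-genome."""

    families: dict[str, dict[str, str]]  # family_id -> {genome_id: gene_id}
    private: dict[str, list[str]]  # genome_id -> private gene ids
    divergence: float


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _random_codes(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A, C, G, T
    return rng.choice(4, size=length, p=probs).astype(np.uint8)


def random_genome(
    length: int,
    gc: float = 0.5,
    n_contigs: int = 1,
    seed: int = 0,
    genome_id: str | None = None,
) -> GenomeAssembly:
    """I.i.d. random genome with the requested G+C fraction.

    Contig lengths are near-equal; requires ``length >= n_contigs * 1020``
    so every contig can hold at least one ANI fragment.
    """
    if not (0 <= gc <= 1):
        raise ValueError("gc must be in [0, 1]")
    if n_contigs < 1 or length < n_contigs * 1020:
        raise ValueError(
            f"infeasible parameters: length {length} < {n_contigs} x 1020"
        )
    rng = np.random.default_rng(seed)
    base_len, extra = divmod(length, n_contigs)
    contigs = []
    for i in range(n_contigs):
        clen = base_len + (1 if i < extra else 0)
        contigs.append((f"c{i + 1}", _decode(_random_codes(rng, clen, gc))))
    return GenomeAssembly(
        genome_id=genome_id or f"sim{seed}", contigs=contigs, source="simulated"
    )


def _substitute(codes: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    out = codes.copy()
    mask = rng.random(len(codes)) < p
    shifts = rng.integers(1, 4, size=int(mask.sum()))
    out[mask] = (out[mask] + shifts) % 4
    return out


def mutate_genome(
    ancestor: GenomeAssembly, params: EvolutionParams
) -> tuple[GenomeAssembly, float]:
    """Evolve an assembly; returns (descendant, expected identity).

    Each site is substituted with probability p to a uniformly chosen
    different base; indels (if enabled) are applied after substitutions.
    Substitution-only evolution preserves length exactly and has expected
    identity 1 - p.
    """
    rng = np.random.default_rng(params.seed)
    p = params.substitution_prob
    contigs = []
    for cid, seq in ancestor.contigs:
        codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        acgt = np.isin(codes, _BASES)
        idx = {b: i for i, b in enumerate(_BASES)}
        mapped = np.array([idx.get(b, 0) for b in codes], dtype=np.uint8)
        mutated = _substitute(mapped, p, rng)
        new = codes.copy()
        new[acgt] = _BASES[mutated[acgt]]
        out = new.tobytes().decode()
        if params.indel_rate > 0:
            out = _apply_indels(out, params, rng)
        contigs.append((cid, out))
    descendant = GenomeAssembly(
        genome_id=f"{ancestor.genome_id}_mut",
        contigs=contigs,
        source=f"mutated p={p}",
    )
    return descendant, 1.0 - p


def _apply_indels(seq: str, params: EvolutionParams, rng: np.random.Generator) -> str:
    events = np.nonzero(rng.random(len(seq)) < params.indel_rate)[0]
    if len(events) == 0:
        return seq
    pieces: list[str] = []
    prev = 0
    for pos in events:
        pieces.append(seq[prev:pos])
        length = int(rng.geometric(1.0 / params.mean_indel_len))
        if rng.random() < 0.5:  # insertion
            pieces.append(_decode(_random_codes(rng, length, 0.5)))
            prev = pos
        else:  # deletion
            prev = min(len(seq), pos + length)
    pieces.append(seq[prev:])
    return "".join(pieces)


def simulate_genome_pair(
    length: int, gc: float = 0.5, p: float = 0.05, seed: int = 0
) -> tuple[GenomeAssembly, GenomeAssembly, float]:
    """Ancestor + substitution-only descendant; expected ANI = 100(1 - p)."""
    a = random_genome(length, gc=gc, seed=seed, genome_id=f"pairA_s{seed}")
    b, _ = mutate_genome(a, EvolutionParams(substitution_prob=p, seed=seed + 1))
    b.genome_id = f"pairB_s{seed}"
    return a, b, 100.0 * (1.0 - p)


def simulate_marker_pair(
    length: int, k_differences: int, seed: int = 0
) -> tuple[str, str, float]:
    """Marker pair with exactly k planted substitutions.

    Returns (seqA, seqB, exact similarity) with
    similarity = 100 (length - k) / length.
    """
    if not (0 <= k_differences <= length):
        raise ValueError("k_differences must be in [0, length]")
    rng = np.random.default_rng(seed)
    codes = _random_codes(rng, length, 0.5)
    positions = rng.choice(length, size=k_differences, replace=False)
    mutated = codes.copy()
    mutated[positions] = (mutated[positions] + rng.integers(1, 4, size=k_differences)) % 4
    return (
        _decode(codes),
        _decode(mutated),
        100.0 * (length - k_differences) / length,
    )


# ---------------------------------------------------------------------------
# Pan-genome simulation
# ---------------------------------------------------------------------------

_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


def _random_cds(rng: np.random.Generator, nt_len: int) -> str:
    """Random CDS: ATG start, no internal stops, TAA stop; length = nt_len."""
    n_codons = nt_len // 3
    middle = rng.choice(len(_NONSTOP_CODONS), size=n_codons - 2)
    return "ATG" + "".join(_NONSTOP_CODONS[i] for i in middle) + "TAA"


def _mutate_cds(seq: str, p: float, rng: np.random.Generator) -> str:
    """Substitution-only CDS mutation; internal stop codons are repaired by
    re-drawing one base, so translation of fixtures never errors."""
    idx = {b: i for i, b in enumerate(b"ACGT")}
    codes = np.array([idx[b] for b in seq.encode()], dtype=np.uint8)
    codes = _substitute(codes, p, rng)
    out = list(_decode(codes))
    for c in range(1, len(out) // 3 - 1):  # keep terminal stop, skip start codon
        codon = "".join(out[3 * c : 3 * c + 3])
        while codon in _STOPS:
            j = int(rng.integers(0, 3))
            codon = codon[:j] + "ACGT"[int(rng.integers(0, 4))] + codon[j + 1 :]
        out[3 * c : 3 * c + 3] = codon
    return "".join(out)


def simulate_pangenome(
    n_genomes: int = 4,
    n_core_families: int = 50,
    n_private_per_genome: int = 5,
    gene_len_range: tuple[int, int] = (300, 900),
    p: float = 0.05,
    seed: int = 0,
) -> tuple[dict[str, GenomeAssembly], dict[str, list[GeneRecord]], PanGenomeTruth]:
    """Multi-genome gene complement with known ortholog ground truth.

    Core families are ancestral random CDSs whose per-genome copies are
    independently mutated at nucleotide rate *p*; private genes are unique
    random CDSs.  Genes are embedded on random strands in spacer DNA, so
    annotation extraction and strand handling are exercised too.
    """
    if min(n_genomes, n_core_families) < 1 or n_private_per_genome < 0:
        raise ValueError("parameters must be positive")
    lo, hi = gene_len_range
    rng = np.random.default_rng(seed)
    genome_ids = [f"g{i + 1}" for i in range(n_genomes)]
    fam_lens = [int(rng.integers(lo // 3, hi // 3 + 1)) * 3 for _ in range(n_core_families)]
    ancestors = [_random_cds(rng, ln) for ln in fam_lens]
    families: dict[str, dict[str, str]] = {
        f"fam{i + 1:03d}": {} for i in range(n_core_families)
    }
    private: dict[str, list[str]] = {g: [] for g in genome_ids}
    genomes: dict[str, GenomeAssembly] = {}
    annotations: dict[str, list[GeneRecord]] = {}
    for gid in genome_ids:
        gene_seqs: list[tuple[str, str]] = []  # (gene_id, oriented nt_seq)
        for i, anc in enumerate(ancestors):
            gene_id = f"{gid}|fam{i + 1:03d}"
            gene_seqs.append((gene_id, _mutate_cds(anc, p, rng)))
            families[f"fam{i + 1:03d}"][gid] = gene_id
        for j in range(n_private_per_genome):
            gene_id = f"{gid}|priv{j + 1:02d}"
            ln = int(rng.integers(lo // 3, hi // 3 + 1)) * 3
            gene_seqs.append((gene_id, _random_cds(rng, ln)))
            private[gid].append(gene_id)
        parts: list[str] = []
        records: list[GeneRecord] = []
        pos = 0
        for gene_id, nt in gene_seqs:
            spacer = _decode(_random_codes(rng, int(rng.integers(100, 301)), 0.5))
            parts.append(spacer)
            pos += len(spacer)
            strand = "+" if rng.random() < 0.5 else "-"
            on_contig = nt if strand == "+" else reverse_complement(nt)
            parts.append(on_contig)
            records.append(
                GeneRecord(
                    gene_id=gene_id,
                    genome_id=gid,
                    contig_id="c1",
                    start=pos + 1,
                    end=pos + len(nt),
                    strand=strand,
                    nt_seq=nt,
                    aa_seq=translate(nt),
                    feature_type="CDS",
                )
            )
            pos += len(nt)
        parts.append(_decode(_random_codes(rng, int(rng.integers(100, 301)), 0.5)))
        genomes[gid] = GenomeAssembly(
            genome_id=gid, contigs=[("c1", "".join(parts))], source="simulated pan-genome"
        )
        annotations[gid] = records
    truth = PanGenomeTruth(families=families, private=private, divergence=p)
    return genomes, annotations, truth


def random_additive_tree(
    n_leaves: int, seed: int = 0, min_branch: float = 0.1, max_branch: float = 1.0
) -> tuple[TreeNode, pd.DataFrame]:
    """Random binary tree and its (additive) patristic tip-tip matrix."""
    if n_leaves < 3:
        raise ValueError("need >= 3 leaves")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=f"t{i + 1}") for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = float(rng.uniform(min_branch, max_branch))
        b.length = float(rng.uniform(min_branch, max_branch))
        parent = TreeNode(children=[a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = nodes[0]
    dm = tree.tip_tip_distances()
    labels = [str(i) for i in dm.ids]
    return tree, pd.DataFrame(dm.data, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# Fixture writers (used by the CLI `taxg simulate`)
# ---------------------------------------------------------------------------


def write_annotation_table(records: list[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcontig_id\tstart\tend\tstrand\tproduct\tfeature_type\n")
        for r in records:
            fh.write(
                f"{r.gene_id}\t{r.contig_id}\t{r.start}\t{r.end}\t{r.strand}"
                f"\t{r.product}\t{r.feature_type}\n"
            )


def write_pangenome_truth(truth: PanGenomeTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tfamily_id\tgenome_id\tgene_id\n")
        for fam, members in sorted(truth.families.items()):
            for gid, gene in sorted(members.items()):
                fh.write(f"core\t{fam}\t{gid}\t{gene}\n")
        for gid, genes in sorted(truth.private.items()):
            for gene in genes:
                fh.write(f"private\t-\t{gid}\t{gene}\n")
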