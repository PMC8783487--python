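"""Fragment-based ANI and digital DDH (formula-2) between genome pairs.

The homology kernel is a seed-and-extend local aligner: exact k-mer seeds
(default k = 13) on both strands, vectorised maximal-scoring ungapped
extension along each seed diagonal (match +2 / mismatch -3), and, when
seeds for one locus fall on several nearby diagonals (indels), a banded
re-alignment of the spanned region with edlib.  Overlapping HSPs are
deduplicated keeping the higher-identity one, and all tie-breaks are
lexicographic so results are byte-stable.

ANI follows the OrthoANI convention: both genomes are cut into 1,020-bp
fragments, every fragment is searched against the other genome's fragment
set, and the identity is averaged over reciprocal best-matching pairs that
clear the 35% identity / 70% coverage floors.

The dDDH distance is formula 2 of the genome-to-genome distance family:
d2 = 1 - (sum of identities / sum of HSP lengths) over the retained HSPs,
mapped to a DDH percentage by the monotone map in :class:`~taxg.config.DdhMapping`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd

from .config import AniConfig, DdhConfig, SpeciesThresholds, TaxgConfig
from .genome_io import GenomeAssembly, reverse_complement

logger = logging.getLogger("taxg")

_CODE_TABLE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_TABLE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    """2-bit encode; ambiguity codes (incl. N) become -1 (never match)."""
    return _CODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_values(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(positions, kmer integer values) for every valid k-window."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    pos = np.nonzero(valid)[0]
    vals = windows[pos].astype(np.int64) @ powers
    return pos, vals


@dataclass
class FragmentSet:
    """Non-overlapping fixed-length windows cut from an assembly."""

    genome_id: str
    fragments: list[tuple[str, str, str, int]]  # (fragment_id, seq, contig_id, offset)
    fragment_len: int
    n_discarded_trailing: int = 0
    n_discarded_ambiguous: int = 0

    def __len__(self) -> int:
        return len(self.fragments)

    def as_sequences(self) -> list[tuple[str, str]]:
        return [(fid, seq) for fid, seq, _, _ in self.fragments]


@dataclass
class HSP:
    """A locally aligned segment pair (coordinates 1-based inclusive)."""

    subject_id: str
    strand: str  # query strand relative to subject ('+' or '-')
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    identities: int
    aligned_len: int  # alignment columns excluding terminal gaps

    @property
    def identity_fraction(self) -> float:
        return self.identities / self.aligned_len if self.aligned_len else 0.0

    @property
    def score(self) -> int:
        return 2 * self.identities - 3 * (self.aligned_len - self.identities)


@dataclass
class AniResult:
    genome_a: str
    genome_b: str
    ani_percent: float | None
    n_reciprocal_pairs: int
    mean_ab: float | None  # per-direction mean identity (A->B), percent
    mean_ba: float | None
    undefined: bool = False


@dataclass
class DdhResult:
    genome_a: str
    genome_b: str
    d2: float
    ddh_percent: float
    sum_identities: int
    sum_aligned_len: int
    mapping_coefficients: dict = field(default_factory=dict)
    no_homology: bool = False


# ---------------------------------------------------------------------------
# Subject k-mer index
# ---------------------------------------------------------------------------


class KmerIndex:
    """Exact k-mer index over a set of named sequences.

    Sequences are concatenated with N spacers (which can never seed), so a
    single hash map serves any number of contigs or fragments.
    """

    def __init__(self, sequences: Sequence[tuple[str, str]], k: int = 13):
        self.k = k
        self.ids = [sid for sid, _ in sequences]
        self.lengths = np.array([len(s) for _, s in sequences], dtype=np.int64)
        spacer = "N" * k
        concat = spacer.join(seq for _, seq in sequences)
        self.codes = _encode(concat)
        starts = np.zeros(len(sequences), dtype=np.int64)
        off = 0
        for i, (_, seq) in enumerate(sequences):
            starts[i] = off
            off += len(seq) + k
        self.starts = starts
        pos, vals = _kmer_values(self.codes, k)
        order = np.argsort(vals, kind="stable")
        vals_sorted = vals[order]
        self._pos_sorted = pos[order]
        uniq, first = np.unique(vals_sorted, return_index=True)
        bounds = np.append(first, len(vals_sorted))
        self._table = {
            int(v): (int(bounds[i]), int(bounds[i + 1])) for i, v in enumerate(uniq)
        }

    def lookup(self, val: int) -> np.ndarray:
        span = self._table.get(val)
        if span is None:
            return np.empty(0, dtype=np.int64)
        return self._pos_sorted[span[0] : span[1]]

    def seq_index_of(self, gpos: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.starts, gpos, side="right") - 1


def _normalize_subject(subject) -> list[tuple[str, str]]:
    if isinstance(subject, GenomeAssembly):
        return list(subject.contigs)
    if isinstance(subject, FragmentSet):
        return subject.as_sequences()
    return list(subject)


# ---------------------------------------------------------------------------
# Seed-and-extend
# ---------------------------------------------------------------------------

_MATCH, _MISMATCH = 2, -3
_DIAG_BAND = 16  # seeds within this many diagonals are one (gapped) locus
_SEED_GAP = 120  # split loci when consecutive seeds are further apart than this


def _extend_scores(eq: np.ndarray) -> np.ndarray:
    return np.where(eq, _MATCH, _MISMATCH)


def _max_prefix(scores: np.ndarray) -> int:
    """Length of the maximal-scoring (strictly positive) prefix."""
    if len(scores) == 0:
        return 0
    cs = np.cumsum(scores)
    best = int(np.argmax(cs))
    return best + 1 if cs[best] > 0 else 0


def _cigar_walk(cigar: str, query: str, target: str) -> tuple[int, int, int, int, int, int]:
    """Walk an edlib CIGAR; returns (identities, columns, q_lead, q_trail, t_lead, t_trail).

    Leading/trailing gap ops are trimmed and reported as skipped prefix/suffix
    lengths on the respective sequence.
    """
    import re

    ops = [(int(n), op) for n, op in re.findall(r"(\d+)([=XIDM])", cigar)]
    # trim terminal indels (they are terminal gap columns)
    q_lead = t_lead = q_trail = t_trail = 0
    while ops and ops[0][1] in "ID":
        n, op = ops.pop(0)
        if op == "I":
            q_lead += n
        else:
            t_lead += n
    while ops and ops[-1][1] in "ID":
        n, op = ops.pop()
        if op == "I":
            q_trail += n
        else:
            t_trail += n
    qi, ti = q_lead, t_lead
    identities = 0
    columns = 0
    for n, op in ops:
        if op in "=XM":
            for j in range(n):
                if query[qi + j] == target[ti + j] and query[qi + j] in "ACGT":
                    identities += 1
            qi += n
            ti += n
            columns += n
        elif op == "I":
            qi += n
            columns += n
        elif op == "D":
            ti += n
            columns += n
    return identities, columns, q_lead, q_trail, t_lead, t_trail


def find_hsps(
    query: str,
    subject,
    min_identity: float = 0.35,
    min_len: int = 100,
    k: int = 13,
    index: KmerIndex | None = None,
) -> list[HSP]:
    """Seed-and-extend local alignment of *query* against *subject*.

    *subject* may be a :class:`GenomeAssembly`, a :class:`FragmentSet` or a
    list of ``(id, sequence)`` pairs; pass a prebuilt :class:`KmerIndex` to
    amortise indexing over many queries.  Returns HSPs with
    ``identity_fraction >= min_identity`` and ``aligned_len >= min_len``,
    sorted by score descending (ties by subject id, then subject start).
    """
    if not query:
        raise ValueError("empty query")
    if index is None:
        index = KmerIndex(_normalize_subject(subject), k=k)
    k = index.k
    hsps: list[HSP] = []
    qlen = len(query)
    for strand in "+-":
        qseq = query if strand == "+" else reverse_complement(query)
        qcodes = _encode(qseq)
        qpos, qvals = _kmer_values(qcodes, k)
        if len(qpos) == 0:
            continue
        qi_list: list[np.ndarray] = []
        sp_list: list[np.ndarray] = []
        lookup = index.lookup
        for i, v in zip(qpos.tolist(), qvals.tolist()):
            hitpos = lookup(v)
            if len(hitpos):
                qi_list.append(np.full(len(hitpos), i, dtype=np.int64))
                sp_list.append(hitpos)
        if not qi_list:
            continue
        qi = np.concatenate(qi_list)
        sp = np.concatenate(sp_list)
        seq_idx = index.seq_index_of(sp)
        diag = sp - qi
        order = np.lexsort((qi, diag, seq_idx))
        qi, sp, seq_idx, diag = qi[order], sp[order], seq_idx[order], diag[order]
        # cluster seeds into loci
        breaks = np.nonzero(
            (np.diff(seq_idx) != 0)
            | (np.abs(np.diff(diag)) > _DIAG_BAND)
            | (np.abs(np.diff(qi)) > _SEED_GAP)
        )[0]
        cluster_bounds = np.concatenate(([0], breaks + 1, [len(qi)]))
        for c0, c1 in zip(cluster_bounds[:-1], cluster_bounds[1:]):
            hsp = _extend_cluster(
                qseq, qcodes, index, int(seq_idx[c0]), qi[c0:c1], sp[c0:c1], k
            )
            if hsp is None:
                continue
            if hsp.aligned_len < min_len or hsp.identity_fraction < min_identity:
                continue
            if strand == "-":  # map query span back to forward coordinates
                qs, qe = hsp.query_start, hsp.query_end
                hsp.query_start = qlen - qe + 1
                hsp.query_end = qlen - qs + 1
                hsp.strand = "-"
            hsps.append(hsp)
    hsps = _dedup_hsps(hsps)
    hsps.sort(key=lambda h: (-h.score, h.subject_id, h.subject_start))
    return hsps


def _extend_cluster(
    qseq: str,
    qcodes: np.ndarray,
    index: KmerIndex,
    seq_i: int,
    qi: np.ndarray,
    sp: np.ndarray,
    k: int,
) -> HSP | None:
    sid = index.ids[seq_i]
    s_start = int(index.starts[seq_i])
    s_len = int(index.lengths[seq_i])
    diags = sp - qi
    if diags.min() == diags.max():
        # ungapped: maximal-scoring extension along the single diagonal
        d = int(diags[0])
        lo = max(0, s_start - d)
        hi = min(len(qcodes), s_start + s_len - d)
        seg_q = qcodes[lo:hi]
        seg_s = index.codes[lo + d : hi + d]
        eq = (seg_q == seg_s) & (seg_q >= 0)
        scores = _extend_scores(eq)
        a0 = int(qi.min()) - lo
        a1 = int(qi.max()) + k - lo
        left = _max_prefix(scores[:a0][::-1])
        right = _max_prefix(scores[a1:])
        start, end = a0 - left, a1 + right
        identities = int(eq[start:end].sum())
        aligned_len = end - start
        q0 = lo + start
        return HSP(
            subject_id=sid,
            strand="+",
            query_start=q0 + 1,
            query_end=q0 + aligned_len,
            subject_start=q0 + d - s_start + 1,
            subject_end=q0 + d - s_start + aligned_len,
            identities=identities,
            aligned_len=aligned_len,
        )
    # gapped: ungapped flank extension on the terminal diagonals, then a
    # banded re-alignment of the spanned region with edlib
    first = int(np.argmin(qi))
    last = int(np.argmax(qi))
    q0, q1 = int(qi[first]), int(qi[last]) + k
    g0, g1 = int(sp[first]), int(sp[last]) + k
    d_first, d_last = int(diags[first]), int(diags[last])
    # left flank along d_first
    lo = max(0, s_start - d_first)
    seg_q = qcodes[lo:q0]
    seg_s = index.codes[lo + d_first : q0 + d_first]
    eq = (seg_q == seg_s) & (seg_q >= 0)
    left = _max_prefix(_extend_scores(eq)[::-1])
    q0 -= left
    g0 -= left
    # right flank along d_last
    hi = min(len(qcodes), s_start + s_len - d_last)
    seg_q = qcodes[q1:hi]
    seg_s = index.codes[q1 + d_last : hi + d_last]
    eq = (seg_q == seg_s) & (seg_q >= 0)
    right = _max_prefix(_extend_scores(eq))
    q1 += right
    g1 += right
    sub_q = qseq[q0:q1]
    s0_local = g0 - s_start
    s1_local = g1 - s_start
    target = index.codes[g0:g1]
    sub_s = "".join("ACGT"[c] if c >= 0 else "N" for c in target.tolist())
    res = edlib.align(sub_q, sub_s, mode="NW", task="path")
    if res["cigar"] is None:
        return None
    ident, cols, q_lead, q_trail, t_lead, t_trail = _cigar_walk(
        res["cigar"], sub_q, sub_s
    )
    if cols == 0:
        return None
    return HSP(
        subject_id=sid,
        strand="+",
        query_start=q0 + q_lead + 1,
        query_end=q1 - q_trail,
        subject_start=s0_local + t_lead + 1,
        subject_end=s1_local - t_trail,
        identities=ident,
        aligned_len=cols,
    )


def _dedup_hsps(hsps: list[HSP]) -> list[HSP]:
    """Drop HSPs that substantially overlap a better one (same subject/strand)."""
    kept: list[HSP] = []
    for h in sorted(
        hsps, key=lambda h: (-h.score, -h.identity_fraction, h.subject_id, h.subject_start)
    ):
        redundant = False
        for g in kept:
            if g.subject_id != h.subject_id or g.strand != h.strand:
                continue
            q_ov = min(g.query_end, h.query_end) - max(g.query_start, h.query_start) + 1
            s_ov = (
                min(g.subject_end, h.subject_end)
                - max(g.subject_start, h.subject_start)
                + 1
            )
            if q_ov > 0.5 * (h.query_end - h.query_start + 1) and s_ov > 0:
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


# ---------------------------------------------------------------------------
# OrthoANI
# ---------------------------------------------------------------------------


def fragment_genome(genome: GenomeAssembly, fragment_len: int = 1020,
                    max_n_fraction: float = 0.20) -> FragmentSet:
    """Cut an assembly into consecutive non-overlapping windows.

    Trailing remainders shorter than *fragment_len* are discarded, as are
    fragments whose N fraction exceeds *max_n_fraction*.
    """
    if fragment_len < 100:
        raise ValueError("fragment_len must be >= 100")
    fragments = []
    n_trail = 0
    n_ambig = 0
    for cid, seq in genome.contigs:
        n_windows = len(seq) // fragment_len
        n_trail += len(seq) - n_windows * fragment_len
        for w in range(n_windows):
            off = w * fragment_len
            frag = seq[off : off + fragment_len]
            n_count = sum(frag.count(c) for c in "NRYSWKMBDHV")
            if n_count > max_n_fraction * fragment_len:
                n_ambig += 1
                continue
            fragments.append((f"{cid}:{off + 1}", frag, cid, off + 1))
    if not fragments:
        logger.warning(
            "genome %s shorter than fragment length %d: no fragments",
            genome.genome_id, fragment_len,
        )
    if n_ambig:
        logger.info("genome %s: dropped %d high-N fragments", genome.genome_id, n_ambig)
    return FragmentSet(
        genome_id=genome.genome_id,
        fragments=fragments,
        fragment_len=fragment_len,
        n_discarded_trailing=n_trail,
        n_discarded_ambiguous=n_ambig,
    )


def _best_hits(
    queries: FragmentSet, subjects: FragmentSet, cfg: AniConfig
) -> dict[str, tuple[str, float]]:
    """Best subject fragment per query fragment: {query_id: (subject_id, identity)}."""
    index = KmerIndex(subjects.as_sequences(), k=cfg.seed_k)
    min_len = int(np.ceil(cfg.min_coverage * cfg.fragment_len))
    best: dict[str, tuple[str, float]] = {}
    for fid, seq, _, _ in queries.fragments:
        hsps = find_hsps(
            seq, subjects, min_identity=cfg.min_identity, min_len=min_len, index=index
        )
        if hsps:
            top = hsps[0]
            best[fid] = (top.subject_id, top.identity_fraction)
    return best


def orthoani(
    a: GenomeAssembly, b: GenomeAssembly, cfg: AniConfig | None = None
) -> AniResult:
    """OrthoANI-style average nucleotide identity between two assemblies."""
    cfg = cfg or AniConfig()
    fa = fragment_genome(a, cfg.fragment_len, cfg.max_n_fraction)
    fb = fragment_genome(b, cfg.fragment_len, cfg.max_n_fraction)
    if len(fa) < 2 or len(fb) < 2:
        raise ValueError(
            f"ANI requires >= 2 fragments per genome "
            f"({a.genome_id}: {len(fa)}, {b.genome_id}: {len(fb)})"
        )
    best_ab = _best_hits(fa, fb, cfg)
    best_ba = _best_hits(fb, fa, cfg)
    idents_ab: list[float] = []
    idents_ba: list[float] = []
    n_pairs = 0
    for qa, (sb, id_ab) in sorted(best_ab.items()):
        back = best_ba.get(sb)
        if back is not None and back[0] == qa:
            n_pairs += 1
            idents_ab.append(id_ab)
            idents_ba.append(back[1])
    if n_pairs == 0:
        return AniResult(a.genome_id, b.genome_id, None, 0, None, None, undefined=True)
    mean_ab = float(np.mean(idents_ab))
    mean_ba = float(np.mean(idents_ba))
    ani = 100.0 * (mean_ab + mean_ba) / 2.0
    return AniResult(
        genome_a=a.genome_id,
        genome_b=b.genome_id,
        ani_percent=ani,
        n_reciprocal_pairs=n_pairs,
        mean_ab=100.0 * mean_ab,
        mean_ba=100.0 * mean_ba,
    )


# ---------------------------------------------------------------------------
# dDDH (formula-2 distance)
# ---------------------------------------------------------------------------


def _hsp_sums(query_frags: FragmentSet, subject: GenomeAssembly, cfg: DdhConfig) -> tuple[int, int]:
    index = KmerIndex(list(subject.contigs), k=cfg.seed_k)
    sum_id = 0
    sum_len = 0
    for _, seq, _, _ in query_frags.fragments:
        hsps = find_hsps(
            seq, subject, min_identity=cfg.min_identity, min_len=cfg.min_len, index=index
        )
        if hsps:
            top = hsps[0]
            sum_id += top.identities
            sum_len += top.aligned_len
    return sum_id, sum_len


def ddh_distance(
    a: GenomeAssembly, b: GenomeAssembly, cfg: DdhConfig | None = None
) -> DdhResult:
    """Formula-2 intergenomic distance and its digital DDH estimate.

    Both genomes are windowed and searched against the other assembly; the
    best HSP per window contributes its identities and length to
    ``d2 = 1 - sum(identities) / sum(aligned_len)``.
    """
    cfg = cfg or DdhConfig()
    fa = fragment_genome(a, cfg.fragment_len, max_n_fraction=1.0)
    fb = fragment_genome(b, cfg.fragment_len, max_n_fraction=1.0)
    if not fa.fragments:
        fa = FragmentSet(a.genome_id, [(c, s, c, 1) for c, s in a.contigs], cfg.fragment_len)
    if not fb.fragments:
        fb = FragmentSet(b.genome_id, [(c, s, c, 1) for c, s in b.contigs], cfg.fragment_len)
    id_ab, len_ab = _hsp_sums(fa, b, cfg)
    id_ba, len_ba = _hsp_sums(fb, a, cfg)
    sum_id = id_ab + id_ba
    sum_len = len_ab + len_ba
    coeffs = {"a": cfg.mapping.a, "b": cfg.mapping.b}
    if sum_len == 0:
        logger.warning("no homology detected between %s and %s", a.genome_id, b.genome_id)
        return DdhResult(a.genome_id, b.genome_id, 1.0, cfg.mapping(1.0), 0, 0,
                         mapping_coefficients=coeffs, no_homology=True)
    d2 = 1.0 - sum_id / sum_len
    return DdhResult(
        genome_a=a.genome_id,
        genome_b=b.genome_id,
        d2=d2,
        ddh_percent=cfg.mapping(d2),
        sum_identities=sum_id,
        sum_aligned_len=sum_len,
        mapping_coefficients=coeffs,
    )


# ---------------------------------------------------------------------------
# Distance matrices and the species-boundary classifier
# ---------------------------------------------------------------------------


def distance_matrix(
    genomes: Sequence[GenomeAssembly],
    metric: str = "ani_distance",
    cfg: TaxgConfig | None = None,
) -> pd.DataFrame:
    """Symmetric pairwise distance matrix (``ani_distance`` = 1 - ANI/100, or ``d2``)."""
    if len(genomes) < 2:
        raise ValueError("need >= 2 genomes")
    if metric not in ("ani_distance", "d2"):
        raise ValueError(f"unknown metric {metric!r}")
    cfg = cfg or TaxgConfig()
    labels = [g.genome_id for g in genomes]
    n = len(genomes)
    mat = np.zeros((n, n))
    undefined: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "ani_distance":
                res = orthoani(genomes[i], genomes[j], cfg.ani)
                if res.undefined:
                    undefined.append((labels[i], labels[j]))
                    continue
                d = 1.0 - res.ani_percent / 100.0
            else:
                res = ddh_distance(genomes[i], genomes[j], cfg.ddh)
                d = res.d2
            mat[i, j] = mat[j, i] = d
    if undefined:
        raise ValueError(f"undefined distances for pairs: {undefined}")
    return pd.DataFrame(mat, index=labels, columns=labels)


def write_distance_matrix(dm: pd.DataFrame, path: str | Path) -> None:
    dm.to_csv(path, sep="\t", float_format="%.10g")


def read_distance_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def classify_species_boundary(
    ani_percent: float | None = None,
    ddh_percent: float | None = None,
    thresholds: SpeciesThresholds | None = None,
) -> str:
    """'same' if either metric clears its species cutoff (ANI >= 95%, dDDH >= 70%)."""
    t = thresholds or SpeciesThresholds()
    if ani_percent is None and ddh_percent is None:
        raise ValueError("need at least one of ani_percent / ddh_percent")
    same = False
    if ani_percent is not None and ani_percent >= t.ani_percent:
        same = True
    if ddh_percent is not None and ddh_percent >= t.ddh_percent:
        same = True
    return "same" if same else "distinct"
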