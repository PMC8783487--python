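"""Published reference values for the *Nocardia alni* study group.

These are printed comparison tables from the species description of
*N. alni* ncl2^T (root-nodule isolate from *Alnus glutinosa*): pairwise
ANI / dDDH percentages between ncl2^T and its phylogenomic neighbours, and
per-genome assembly features.  They serve as *inputs* to the
species-boundary classifier and the feature regression; the package does
not recompute them from raw assemblies unless those assemblies are
supplied.
"""

from __future__ import annotations

#: (species, strain, dDDH percent, ANI percent) against strain ncl2^T.
NOCARDIA_RELATEDNESS: list[tuple[str, str, float, float]] = [
    ("N. aobensis", "NBRC 100429", 22.4, 77.9),
    ("N. casuarinae", "BMG 51109", 23.0, 78.9),
    ("N. cerradoensis", "NBRC 101014", 22.4, 77.8),
    ("N. jiangxiensis", "NBRC 101359", 24.6, 80.6),
    ("N. miyunensis", "NBRC 108239", 24.9, 80.7),
    ("N. nova", "NBRC 15556", 22.4, 77.9),
    ("N. pseudobrasiliensis", "DSM 44290", 22.4, 78.7),
    ("N. vaccinii", "NBRC 15922", 24.4, 80.2),
]

#: Genome features of ncl2^T and five reference type strains:
#: genome size (Mbp), G+C (%), rRNA, tRNA, CDS counts, median CDS length (bp).
NOCARDIA_GENOME_FEATURES: dict[str, dict[str, float]] = {
    "ncl2": {"size_mbp": 9.9, "gc": 67.0, "rrna": 12, "trna": 49, "cds": 8969, "median_cds": 831},
    "N. vaccinii": {"size_mbp": 9.2, "gc": 66.7, "rrna": 4, "trna": 49, "cds": 8502, "median_cds": 816},
    "N. miyunensis": {"size_mbp": 10.5, "gc": 66.9, "rrna": 4, "trna": 49, "cds": 9567, "median_cds": 831},
    "N. jiangxiensis": {"size_mbp": 10.4, "gc": 66.7, "rrna": 3, "trna": 49, "cds": 9695, "median_cds": 822},
    "N. casuarinae": {"size_mbp": 8.8, "gc": 68.9, "rrna": 9, "trna": 56, "cds": 7746, "median_cds": 819},
    "N. pseudobrasiliensis": {"size_mbp": 8.4, "gc": 67.3, "rrna": 8, "trna": 51, "cds": 7949, "median_cds": 822},
}


def genome_size_vs_cds() -> tuple[list[float], list[int]]:
    """(genome sizes in Mbp, CDS counts) across the six published genomes."""
    rows = NOCARDIA_GENOME_FEATURES.values()
    return [r["size_mbp"] for r in rows], [int(r["cds"]) for r in rows]
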