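"""Configuration objects for the taxg pipeline.

Every tunable threshold of the ANI / dDDH / pan-genome machinery lives here
as a frozen-by-convention dataclass with field-level defaults, so that runs
are reproducible from a single YAML file and nothing numeric hides inside
algorithm code.  ``load_config``/``dump_config`` round-trip the whole bundle.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

logger = logging.getLogger("taxg")

#: One-letter COG functional categories (Tatusov et al. scheme, incl. X mobilome).
COG_CATEGORIES = frozenset("JAKLBDYVTMNZWUXOCGEFHIPQRS")

#: Label used for genes without a functional category assignment.
UNASSIGNED_CATEGORY = "unassigned"


@dataclass
class AniConfig:
    """OrthoANI-style fragment ANI parameters.

    Defaults follow the OrthoANI convention: both genomes are cut into
    1,020-bp fragments, fragments are paired by reciprocal best hits, and
    pairs below 35% identity or 70% fragment coverage are discarded before
    averaging.
    """

    fragment_len: int = 1020
    min_identity: float = 0.35
    min_coverage: float = 0.70
    max_n_fraction: float = 0.20  # fragments with more N than this are dropped
    seed_k: int = 13


@dataclass
class DdhMapping:
    """Monotone map from the formula-2 intergenomic distance d2 to a DDH%.

    The estimate is a logistic in log distance,

        ddh_percent = 100 / (1 + exp(a + b * ln(d2))),

    with ``b > 0`` so the map is strictly decreasing in d2, pinned to 100%
    at d2 = 0.  The default coefficients are calibrated so that the
    genome-to-genome distance species boundary (DDH 70%) sits at
    d2 = 0.0259 and genomes near 80% ANI map to DDH in the mid-20s, the
    scale reported for draft *Nocardia* genomes.  Any alternative
    coefficient set (e.g. the published GLM of the original method) can be
    supplied here; only monotonicity is validated.
    """

    a: float = 3.2663
    b: float = 1.1258

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("DdhMapping requires b > 0 for a monotone decreasing map")

    def __call__(self, d2: float) -> float:
        if d2 < 0 or d2 > 1:
            raise ValueError(f"d2 must lie in [0, 1], got {d2}")
        if d2 == 0.0:
            return 100.0
        return 100.0 / (1.0 + math.exp(self.a + self.b * math.log(d2)))


@dataclass
class DdhConfig:
    """Digital DDH (formula-2 distance) parameters."""

    fragment_len: int = 1020  # query windows for the HSP search
    min_len: int = 100
    min_identity: float = 0.30
    seed_k: int = 13
    mapping: DdhMapping = field(default_factory=DdhMapping)


@dataclass
class SearchConfig:
    """Protein all-vs-all search parameters for the POG pipeline."""

    kmer_size: int = 5
    min_shared_kmers: int = 1
    min_identity: float = 0.30
    min_query_coverage: float = 0.50
    gap_open: float = -11.0
    gap_extend: float = -1.0
    matrix: str = "BLOSUM62"


@dataclass
class PogConfig:
    """POG construction parameters."""

    merge_rule: str = "single-linkage"  # or "pair-only"
    attach_identity: float = 0.95  # UCLUST-style partial-gene attachment floor

    def __post_init__(self) -> None:
        if self.merge_rule not in ("single-linkage", "pair-only"):
            raise ValueError(f"unknown merge rule {self.merge_rule!r}")


@dataclass
class SpeciesThresholds:
    """Species-boundary cutoffs: conspecific iff ANI >= 95-96% or dDDH >= 70%."""

    ani_percent: float = 95.0
    ddh_percent: float = 70.0


@dataclass
class TaxgConfig:
    """Top-level configuration bundle."""

    ani: AniConfig = field(default_factory=AniConfig)
    ddh: DdhConfig = field(default_factory=DdhConfig)
    search: SearchConfig = field(default_factory=SearchConfig)
    pog: PogConfig = field(default_factory=PogConfig)
    species: SpeciesThresholds = field(default_factory=SpeciesThresholds)


def _to_dict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    return obj


def dump_config(cfg: TaxgConfig, path: str | Path) -> None:
    """Serialize a configuration bundle to YAML."""
    Path(path).write_text(yaml.safe_dump(_to_dict(cfg), sort_keys=False))


def load_config(path: str | Path | None = None) -> TaxgConfig:
    """Load a configuration bundle from YAML; defaults when *path* is None."""
    if path is None:
        return TaxgConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    ddh_raw = dict(raw.get("ddh", {}))
    mapping = DdhMapping(**ddh_raw.pop("mapping", {}))
    return TaxgConfig(
        ani=AniConfig(**raw.get("ani", {})),
        ddh=DdhConfig(mapping=mapping, **ddh_raw),
        search=SearchConfig(**raw.get("search", {})),
        pog=PogConfig(**raw.get("pog", {})),
        species=SpeciesThresholds(**raw.get("species", {})),
    )
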