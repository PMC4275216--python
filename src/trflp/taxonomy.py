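"""OTU patterns and taxon affiliation of community T-RFs.

A clone library of ITS amplicons is digested with HhaI and MspI; each
distinct ordered pair of terminal-fragment lengths is one operational
taxonomic unit (OTU).  A pattern table maps OTUs to taxon names (from
sequence-similarity searches done once, outside this package, and
shipped as a plain-text fixture), so community T-RFs observed in
electropherograms can be affiliated with taxa: a query length resolves
to a taxon only when every OTU it matches (within a size tolerance)
agrees on one name at the requested rank.

HhaI is the discriminating enzyme in this system, so genus-level
abundance distributions are computed from HhaI profiles only.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .peaks import TRFProfile

__all__ = [
    "OTURecord",
    "PatternTable",
    "Affiliation",
    "collapse_to_otus",
    "affiliate_trf",
    "single_taxon_trfs",
    "genus_distribution",
    "distinct_trf_count",
]

logger = logging.getLogger(__name__)

RANKS = ("genus", "order", "phylum", "unresolved")
#: Table flag for OTUs whose representative sequencing failed; their
#: fragment lengths are real (they count toward distinct-T-RF totals) but
#: they can never resolve an affiliation.
INVALID_FLAG = "#"


@dataclass(frozen=True)
class OTURecord:
    """One OTU: an ordered (HhaI, MspI) T-RF pair with its best taxon call.

    ``None`` fragment lengths mean the enzyme produced no detectable
    terminal fragment for this OTU (e.g. an uncut amplicon).
    """

    otu_id: int
    hha_trf: Optional[int]
    msp_trf: Optional[int]
    taxon_name: str = "unresolved"
    taxon_rank: str = "unresolved"
    identity_pct: Optional[float] = None
    flag: str = ""
    count: int = 1

    def __post_init__(self) -> None:
        if self.hha_trf is None and self.msp_trf is None:
            raise ValueError(f"OTU {self.otu_id}: at least one T-RF must be present")
        if self.taxon_rank not in RANKS:
            raise ValueError(f"OTU {self.otu_id}: unknown rank {self.taxon_rank!r}")
        if self.identity_pct is not None and not 0 <= self.identity_pct <= 100:
            raise ValueError(f"OTU {self.otu_id}: identity_pct out of [0, 100]")

    def trf(self, enzyme: str) -> Optional[int]:
        if enzyme == "HhaI":
            return self.hha_trf
        if enzyme == "MspI":
            return self.msp_trf
        raise KeyError(f"unknown enzyme {enzyme!r}")

    @property
    def resolvable(self) -> bool:
        return self.flag != INVALID_FLAG and self.taxon_rank != "unresolved"


@dataclass(frozen=True)
class PatternTable:
    """Ordered collection of OTU records with distinct (HhaI, MspI) pairs."""

    records: tuple[OTURecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        pairs = [(r.hha_trf, r.msp_trf) for r in self.records]
        if len(set(pairs)) != len(pairs):
            dupes = [p for p, c in Counter(pairs).items() if c > 1]
            raise ValueError(f"duplicate dual-enzyme patterns: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records]).set_index("otu_id")


@dataclass(frozen=True)
class Affiliation:
    """Result of matching one community T-RF against a pattern table."""

    enzyme: str
    length_bp: float
    matches: tuple[OTURecord, ...]
    status: str  # "resolved" | "ambiguous" | "no_match"
    taxon: Optional[str] = None


def collapse_to_otus(patterns: Sequence[tuple]) -> PatternTable:
    """Group clone patterns into OTUs: one record per distinct ordered
    (HhaI, MspI) pair, counts summing to the library size.

    Records are ordered by count (descending), then by fragment lengths,
    so the ordering is deterministic and input-order invariant.
    """
    if len(patterns) == 0:
        raise ValueError("empty pattern sequence")
    counts = Counter((p[0], p[1]) for p in patterns)

    def sort_key(item):
        (hha, msp), count = item
        return (-count, hha if hha is not None else float("inf"),
                msp if msp is not None else float("inf"))

    records = tuple(
        OTURecord(otu_id=i + 1, hha_trf=hha, msp_trf=msp, count=count)
        for i, ((hha, msp), count) in enumerate(sorted(counts.items(), key=sort_key))
    )
    return PatternTable(records, provenance="collapsed clone library")


def _matching_records(
    enzyme: str, length_bp: float, table: PatternTable, tolerance_bp: float
) -> list[OTURecord]:
    out = []
    for rec in table:
        trf = rec.trf(enzyme)
        if trf is not None and abs(trf - length_bp) <= tolerance_bp:
            out.append(rec)
    return out


def affiliate_trf(
    enzyme: str,
    length_bp: float,
    table: PatternTable,
    tolerance_bp: float = 1.0,
    rank: str = "genus",
    min_identity: Optional[float] = None,
) -> Affiliation:
    """Affiliate a community T-RF with a taxon via the pattern table.

    Resolves only when all matched OTUs (i) are resolvable (not flagged
    invalid), (ii) carry a name at exactly the requested rank, (iii) meet
    ``min_identity`` when given, and (iv) agree on a single name.
    """
    if enzyme not in ("HhaI", "MspI"):
        raise KeyError(f"unknown enzyme {enzyme!r}")
    if tolerance_bp < 0:
        raise ValueError("tolerance_bp must be >= 0")
    matches = _matching_records(enzyme, length_bp, table, tolerance_bp)
    if not matches:
        return Affiliation(enzyme, length_bp, (), "no_match")

    def resolves(rec: OTURecord) -> bool:
        if not rec.resolvable or rec.taxon_rank != rank:
            return False
        if min_identity is not None and (
            rec.identity_pct is None or rec.identity_pct < min_identity
        ):
            return False
        return True

    names = {rec.taxon_name for rec in matches}
    if all(resolves(rec) for rec in matches) and len(names) == 1:
        return Affiliation(enzyme, length_bp, tuple(matches), "resolved", names.pop())
    return Affiliation(enzyme, length_bp, tuple(matches), "ambiguous")


def single_taxon_trfs(
    table: PatternTable,
    enzyme: str,
    rank: str = "genus",
    tolerance_bp: float = 0.0,
    min_identity: Optional[float] = None,
) -> set[int]:
    """Distinct T-RF lengths in the table that resolve to exactly one taxon."""
    lengths = {rec.trf(enzyme) for rec in table if rec.trf(enzyme) is not None}
    return {
        length
        for length in lengths
        if affiliate_trf(enzyme, length, table, tolerance_bp, rank, min_identity).status
        == "resolved"
    }


def genus_distribution(
    profile: "TRFProfile | Mapping[float, float]",
    table: PatternTable,
    tolerance_bp: float = 1.0,
    rank: str = "genus",
    enzyme: Optional[str] = None,
    min_identity: Optional[float] = None,
) -> dict[str, float]:
    """Taxon-level abundance distribution from an HhaI profile.

    Each bin's abundance is credited to its resolved taxon; ambiguous or
    unmatched bins accumulate under ``"unassigned"``.  Total abundance is
    conserved.  Only HhaI profiles are accepted — MspI fragments are not
    discriminating enough for taxon-level attribution in this system.
    """
    if isinstance(profile, TRFProfile):
        prof_enzyme = profile.enzyme
        bins = profile.bins
    else:
        prof_enzyme = enzyme
        bins = dict(profile)
    if prof_enzyme != "HhaI":
        raise ValueError(
            f"genus distributions are computed from HhaI profiles, got {prof_enzyme!r}"
        )
    if not bins:
        logger.warning("empty profile: returning empty distribution")
        return {}
    out: dict[str, float] = {}
    for size, abundance in bins.items():
        aff = affiliate_trf("HhaI", size, table, tolerance_bp, rank, min_identity)
        key = aff.taxon if aff.status == "resolved" else "unassigned"
        out[key] = out.get(key, 0.0) + abundance
    return out


def distinct_trf_count(table: PatternTable, enzyme: str) -> int:
    """Number of distinct present fragment lengths for one enzyme (absent
    markers excluded; invalid-sequencing OTUs still contribute their sizes)."""
    return len({rec.trf(enzyme) for rec in table if rec.trf(enzyme) is not None})
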