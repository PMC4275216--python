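"""Synthetic study generator: amplicons, electropherograms, clone
libraries, and chemistry tables.

Every input the analysis pipeline consumes can be generated here with a
fixed seed, so the whole pipeline is testable end to end without any
sequence downloads.  The generator emulates:

* ITS-like amplicons (~600 bp) with restriction sites planted so that
  in-silico digestion reproduces a chosen (HhaI, MspI) terminal-fragment
  pair exactly — a constructive inverse of the digestion step;
* fragment-analyzer peak tables with Gaussian size jitter, multiplicative
  height noise, and strictly sub-threshold spurious peaks (height drawn
  from [1, 49] FU, below the 50 FU floor) so threshold filtering is
  exercised deterministically;
* multinomial clone libraries (the study scale is ~226 clones);
* group-structured chemistry tables (Gaussian replicates around group
  means).

What it does NOT emulate: PCR amplification bias, primer artifacts,
chimeras, or capillary size-calling physics — synthetic fragment sizes
are the true digest lengths plus jitter.

A bundled 12-sample study design mirrors the field layout of the study
system: four plant ages at one site plus eight further sites, with four
planted chemical-content groups (High / Sub-high / Intermediate / Low)
whose analyte means follow the published per-group levels.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .digest import ENZYMES, dual_pattern, get_enzyme
from .peaks import HEIGHT_MIN, SIZE_MAX, SIZE_MIN, PeakTable
from .taxonomy import OTURecord, PatternTable

__all__ = [
    "TaxonSpec",
    "CommunitySpec",
    "NoiseSpec",
    "StudyDesign",
    "InfeasibleTargetError",
    "make_taxon_sequence",
    "simulate_electropherogram",
    "simulate_clone_library",
    "simulate_chemistry",
    "default_taxon_pool",
    "make_reference_design",
    "pool_pattern_table",
]

UNCUT = "uncut"
_BASES = "ACGT"

#: Default amplicon length (bp): the ITS1-5.8S-ITS2 product is ~600 bp.
DEFAULT_AMPLICON_LENGTH = 600
#: Default cumulative fluorescence per profile (arbitrary units).
DEFAULT_TOTAL_SIGNAL = 10_000.0


class InfeasibleTargetError(ValueError):
    """Raised when no sequence can realize the requested fragment targets."""


@dataclass(frozen=True)
class TaxonSpec:
    """A synthetic taxon: intended dual-enzyme T-RF pair and genus label."""

    name: str
    genus: str = "unidentified"
    target_hha: Union[int, str] = UNCUT
    target_msp: Union[int, str] = UNCUT
    amplicon_length: int = DEFAULT_AMPLICON_LENGTH

    def __post_init__(self) -> None:
        if self.amplicon_length <= 0:
            raise ValueError("amplicon_length must be positive")
        for target, enzyme in ((self.target_hha, "HhaI"), (self.target_msp, "MspI")):
            if target == UNCUT:
                continue
            if not isinstance(target, (int, np.integer)):
                raise ValueError(f"{enzyme} target must be an integer or 'uncut'")
            if not target < self.amplicon_length:
                raise ValueError(f"{enzyme} target must be < amplicon_length")

    def target(self, enzyme: str) -> Union[int, str]:
        return self.target_hha if enzyme == "HhaI" else self.target_msp

    def pattern(self) -> tuple:
        hha = None if self.target_hha == UNCUT else int(self.target_hha)
        msp = None if self.target_msp == UNCUT else int(self.target_msp)
        return (hha, msp)


@dataclass(frozen=True)
class CommunitySpec:
    """One sample: factor levels and taxon relative abundances (sum to 1)."""

    sample_id: str
    factors: dict = field(default_factory=dict)
    abundances: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        values = np.asarray(list(self.abundances.values()), dtype=float)
        if values.size == 0:
            raise ValueError("community has no taxa")
        if np.any(values < 0):
            raise ValueError("abundances must be >= 0")
        if abs(values.sum() - 1.0) > 1e-9:
            raise ValueError(f"abundances must sum to 1 (got {values.sum():.12g})")


@dataclass(frozen=True)
class NoiseSpec:
    """Electropherogram noise model.

    ``size_jitter_sd`` must stay below 0.5 bp so jittered peaks remain
    within their integer bin at the default alignment tolerance.
    ``n_noise_peaks`` spurious peaks are drawn strictly below the height
    floor so they are always removed by filtering.
    """

    total_signal: float = DEFAULT_TOTAL_SIGNAL
    size_jitter_sd: float = 0.1
    n_noise_peaks: int = 5
    height_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.total_signal, self.size_jitter_sd, self.height_cv) < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.n_noise_peaks < 0:
            raise ValueError("n_noise_peaks must be >= 0")
        if self.size_jitter_sd >= 0.5:
            raise ValueError("size_jitter_sd must be < 0.5 bp")


# ---------------------------------------------------------------------------
# sequence construction

def _planted_motif_starts(spec: TaxonSpec) -> dict[str, int | None]:
    """0-based motif start implied by each target length, or None if uncut."""
    starts: dict[str, int | None] = {}
    for name, enzyme in ENZYMES.items():
        target = spec.target(name)
        if target == UNCUT:
            starts[name] = None
            continue
        start = int(target) - enzyme.cut_offset
        if start < 0 or start + len(enzyme.motif) > spec.amplicon_length:
            raise InfeasibleTargetError(
                f"{name} target {target} cannot place motif inside a "
                f"{spec.amplicon_length} bp amplicon"
            )
        starts[name] = start
    return starts


def make_taxon_sequence(spec: TaxonSpec, seed: int) -> str:
    """Build an amplicon whose dual digest is exactly the spec's targets.

    Construction is rejection-free and left-to-right: planted motif bases
    are forced; every free base is drawn uniformly from the characters
    that do not complete a forbidden motif occurrence (an occurrence of
    an enzyme's motif 5' of that enzyme's planted site, or anywhere for
    an uncut enzyme) in any window whose other bases are already
    determined.  Same seed, same spec -> identical sequence.
    """
    starts = _planted_motif_starts(spec)
    n = spec.amplicon_length
    forced: dict[int, str] = {}
    for name, start in starts.items():
        if start is None:
            continue
        for k, ch in enumerate(ENZYMES[name].motif):
            pos = start + k
            if forced.get(pos, ch) != ch:
                raise InfeasibleTargetError(
                    f"planted {name} motif conflicts with the other enzyme's "
                    f"site at position {pos}"
                )
            forced[pos] = ch

    rng = np.random.default_rng(seed)
    seq: list[str] = []

    def known(pos: int) -> str | None:
        if pos < len(seq):
            return seq[pos]
        return forced.get(pos)

    def completes_forbidden(pos: int, base: str) -> bool:
        # any 4-window covering pos, fully determined once `base` is placed,
        # that spells a motif upstream of (or instead of) its planted site
        for name, enzyme in ENZYMES.items():
            motif = enzyme.motif
            m = len(motif)
            plant = starts[name]
            for s in range(max(0, pos - m + 1), pos + 1):
                if s + m > n:
                    continue
                if plant is not None and s >= plant:
                    continue  # at/after the planted site: not forbidden
                ok = True
                for k in range(m):
                    p = s + k
                    ch = base if p == pos else known(p)
                    if ch is None or ch != motif[k]:
                        ok = False
                        break
                if ok:
                    return True
        return False

    for pos in range(n):
        if pos in forced:
            base = forced[pos]
            if completes_forbidden(pos, base):
                raise InfeasibleTargetError(
                    f"planted motif base at {pos} forces a forbidden upstream site"
                )
            seq.append(base)
            continue
        allowed = [b for b in _BASES if not completes_forbidden(pos, b)]
        if not allowed:
            raise InfeasibleTargetError(
                f"no admissible base at position {pos} for targets "
                f"({spec.target_hha}, {spec.target_msp})"
            )
        seq.append(allowed[int(rng.integers(len(allowed)))])

    sequence = "".join(seq)
    if dual_pattern(sequence) != _expected_pattern(spec):
        raise AssertionError("internal error: constructed sequence fails its digest")
    return sequence


def _expected_pattern(spec: TaxonSpec):
    from .digest import DigestResult

    out = []
    for name in ("HhaI", "MspI"):
        target = spec.target(name)
        if target == UNCUT:
            out.append(DigestResult(name, None, None))
        else:
            out.append(DigestResult(name, int(target), int(target)))
    return tuple(out)


# ---------------------------------------------------------------------------
# electropherograms, clone libraries, chemistry

def _sample_rng(seed: int, *tokens: str) -> np.random.Generator:
    """Deterministic per-(sample, enzyme) stream derived from one seed."""
    return np.random.default_rng(
        [seed] + [zlib.crc32(t.encode()) for t in tokens]
    )


def _pool_dict(pool: Iterable[TaxonSpec]) -> dict[str, TaxonSpec]:
    if isinstance(pool, Mapping):
        return dict(pool)
    return {t.name: t for t in pool}


def simulate_electropherogram(
    community: CommunitySpec,
    pool: Iterable[TaxonSpec],
    enzyme: str,
    noise: NoiseSpec = NoiseSpec(),
) -> PeakTable:
    """One peak per present taxon, plus strictly sub-threshold noise peaks.

    Peak size = the taxon's target T-RF + Gaussian jitter (uncut taxa
    appear at full amplicon length, outside the scored window); expected
    peak height = abundance x total_signal with multiplicative noise of
    coefficient of variation ``height_cv``.  Deterministic per
    (seed, sample, enzyme).
    """
    enzyme_obj = get_enzyme(enzyme)
    pool_map = _pool_dict(pool)
    missing = [t for t in community.abundances if t not in pool_map]
    if missing:
        raise KeyError(f"taxa missing from pool: {missing}")
    rng = _sample_rng(noise.seed, community.sample_id, enzyme_obj.name)

    sizes: list[float] = []
    heights: list[float] = []
    for name in sorted(community.abundances):
        abundance = community.abundances[name]
        if abundance <= 0:
            continue
        spec = pool_map[name]
        target = spec.target(enzyme_obj.name)
        base_size = float(spec.amplicon_length if target == UNCUT else target)
        size = base_size + (
            rng.normal(0.0, noise.size_jitter_sd) if noise.size_jitter_sd > 0 else 0.0
        )
        height = abundance * noise.total_signal
        if noise.height_cv > 0:
            height *= 1.0 + noise.height_cv * rng.normal()
        sizes.append(max(size, 1.0))
        heights.append(max(height, 1.0))
    for _ in range(noise.n_noise_peaks):
        sizes.append(float(rng.uniform(SIZE_MIN, SIZE_MAX)))
        heights.append(float(rng.uniform(1.0, HEIGHT_MIN - 1.0)))
    return PeakTable(community.sample_id, enzyme_obj.name, np.array(sizes), np.array(heights))


def simulate_clone_library(
    community: CommunitySpec,
    pool: Iterable[TaxonSpec],
    n_clones: int,
    seed: int = 0,
) -> list[tuple]:
    """Multinomial clone sampling: n_clones dual-enzyme patterns drawn with
    probabilities equal to the community abundances."""
    if n_clones <= 0:
        raise ValueError("n_clones must be > 0")
    pool_map = _pool_dict(pool)
    names = sorted(t for t, a in community.abundances.items() if a > 0)
    if not names:
        raise ValueError("community is empty")
    missing = [t for t in names if t not in pool_map]
    if missing:
        raise KeyError(f"taxa missing from pool: {missing}")
    probs = np.array([community.abundances[t] for t in names], dtype=float)
    probs /= probs.sum()
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(names), size=n_clones, p=probs)
    return [pool_map[names[i]].pattern() for i in picks]


def simulate_chemistry(
    groups: Mapping[str, Mapping[str, tuple[float, float]]],
    design: Mapping[str, str],
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample Gaussian replicate draws around group analyte means.

    ``groups`` maps group label -> analyte -> (mean, SD); ``design`` maps
    sample -> group.  The returned table carries the empirical mean, SD
    (ddof=1) and n of the drawn replicates per sample and analyte.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    unknown = sorted(set(design.values()) - set(groups))
    if unknown:
        raise KeyError(f"unknown groups in design: {unknown}")
    for g, analytes in groups.items():
        for analyte, (mean, sd) in analytes.items():
            if sd < 0:
                raise ValueError(f"negative SD for {g}/{analyte}")
    rows = []
    for sample in design:
        rng = _sample_rng(seed, sample, "chem")
        for analyte, (mean, sd) in groups[design[sample]].items():
            draws = mean + sd * rng.standard_normal(n_replicates)
            rows.append(
                {
                    "sample_id": sample,
                    "analyte": analyte,
                    "mean": float(draws.mean()),
                    "sd": float(draws.std(ddof=1)),
                    "n": n_replicates,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bundled reference-style study design

def default_taxon_pool() -> dict[str, TaxonSpec]:
    """Nine taxa with realistic dual-enzyme targets (each HhaI size unique,
    so HhaI profiles can be attributed at genus level)."""
    specs = [
        TaxonSpec("pestalotiopsis", "Pestalotiopsis", 325, 148),
        TaxonSpec("marasmius", "Marasmius", 389, UNCUT),
        TaxonSpec("penicillium", "Penicillium", 174, 142),
        TaxonSpec("fusarium", "Fusarium", 153, 161),
        TaxonSpec("colletotrichum", "Colletotrichum", 170, 131),
        TaxonSpec("exserohilum", "Exserohilum", 139, 132),
        TaxonSpec("mycoleptodiscus", "Mycoleptodiscus", 359, 126),
        TaxonSpec("scopulariopsis", "Scopulariopsis", 345, 127),
        TaxonSpec("sebacina", "Sebacina", 222, 170),
    ]
    return {s.name: s for s in specs}


def pool_pattern_table(pool: Mapping[str, TaxonSpec]) -> PatternTable:
    """Pattern table derived from a taxon pool (for affiliating synthetic
    communities against their own generating taxa)."""
    records = []
    for i, name in enumerate(sorted(pool)):
        spec = pool[name]
        hha, msp = spec.pattern()
        records.append(
            OTURecord(
                otu_id=i + 1,
                hha_trf=hha,
                msp_trf=msp,
                taxon_name=spec.genus,
                taxon_rank="genus",
                identity_pct=99.0,
            )
        )
    return PatternTable(tuple(records), provenance="synthetic taxon pool")


#: Group-level community profiles: each chemical-content group has a
#: distinct endophyte assemblage (the High group dominated by
#: Pestalotiopsis, the Low group by Marasmius), mirroring the dominance
#: shifts seen between 4-year-old and low-content rhizomes.
GROUP_PROFILES: dict[str, dict[str, float]] = {
    "High": {
        "pestalotiopsis": 0.54, "marasmius": 0.06, "penicillium": 0.08,
        "fusarium": 0.10, "colletotrichum": 0.08, "exserohilum": 0.05,
        "mycoleptodiscus": 0.04, "sebacina": 0.05,
    },
    "Sub-high": {
        "pestalotiopsis": 0.30, "marasmius": 0.10, "penicillium": 0.12,
        "fusarium": 0.15, "colletotrichum": 0.15, "exserohilum": 0.08,
        "scopulariopsis": 0.10,
    },
    "Intermediate": {
        "pestalotiopsis": 0.18, "marasmius": 0.22, "penicillium": 0.14,
        "fusarium": 0.14, "colletotrichum": 0.12, "exserohilum": 0.06,
        "mycoleptodiscus": 0.06, "scopulariopsis": 0.04, "sebacina": 0.04,
    },
    "Low": {
        "marasmius": 0.55, "pestalotiopsis": 0.05, "penicillium": 0.10,
        "fusarium": 0.12, "colletotrichum": 0.10, "sebacina": 0.08,
    },
}

#: 12-sample layout: four ages at site LT plus eight further sites, with
#: the four content groups assigned as in the study system.
SAMPLE_GROUPS: dict[str, str] = {
    "LT-4-RZ": "High",
    "GZ-RZ": "Sub-high", "QJ-RZ": "Sub-high", "LT-3-RZ": "Sub-high",
    "GX-RZ": "Intermediate", "GY-RZ": "Intermediate", "KM-RZ": "Intermediate",
    "FJ-RZ": "Intermediate", "LT-2-RZ": "Intermediate",
    "HA-RZ": "Low", "HN-RZ": "Low", "LT-1-RZ": "Low",
}

#: Per-group analyte levels (volatile oil in mg/100 g, galangin in mg/g
#: of dried rhizome), at the published group means; the SD is a typical
#: replicate spread.
GROUP_CHEMISTRY: dict[str, dict[str, tuple[float, float]]] = {
    "High": {"volatile_oil": (14.65, 0.45), "galangin": (16.89, 0.45)},
    "Sub-high": {"volatile_oil": (10.17, 0.45), "galangin": (12.50, 0.45)},
    "Intermediate": {"volatile_oil": (7.54, 0.45), "galangin": (9.48, 0.45)},
    "Low": {"volatile_oil": (3.13, 0.45), "galangin": (5.37, 0.45)},
}


@dataclass(frozen=True)
class StudyDesign:
    """A complete synthetic study: communities, chemistry and taxon pool."""

    pool: dict[str, TaxonSpec]
    communities: tuple[CommunitySpec, ...]
    sample_groups: dict[str, str]
    group_chemistry: dict[str, dict[str, tuple[float, float]]]
    n_profile_replicates: int = 3
    n_clones: int = 226

    @property
    def sample_ids(self) -> list[str]:
        return [c.sample_id for c in self.communities]


def _perturb(profile: Mapping[str, float], rng: np.random.Generator, sigma: float) -> dict[str, float]:
    names = sorted(profile)
    logs = np.array([profile[n] for n in names])
    tweaked = logs * np.exp(sigma * rng.standard_normal(len(names)))
    tweaked /= tweaked.sum()
    return {n: float(v) for n, v in zip(names, tweaked)}


def make_reference_design(seed: int = 0, jitter_sigma: float = 0.15) -> StudyDesign:
    """The bundled 12-sample design with four planted content groups.

    Each sample's abundances are its group profile perturbed by a small
    seeded log-normal factor (sigma 0.15), so within-group communities
    stay far more similar than between-group ones.
    """
    pool = default_taxon_pool()
    communities = []
    for i, (sample, group) in enumerate(SAMPLE_GROUPS.items()):
        rng = _sample_rng(seed, sample, "community")
        abundances = _perturb(GROUP_PROFILES[group], rng, jitter_sigma)
        communities.append(
            CommunitySpec(
                sample_id=sample,
                factors={"chem_group": group, "site": sample.split("-")[0]},
                abundances=abundances,
            )
        )
    return StudyDesign(
        pool=pool,
        communities=tuple(communities),
        sample_groups=dict(SAMPLE_GROUPS),
        group_chemistry={g: dict(v) for g, v in GROUP_CHEMISTRY.items()},
    )
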