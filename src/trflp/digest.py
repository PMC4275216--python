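"""In-silico restriction digestion of 5'-labeled amplicons.

In T-RFLP the forward PCR primer carries a fluorescent label (FAM) on the
5' end of the forward strand, so after digestion only the fragment that
retains that labeled terminus is visible to the fragment analyzer.  The
terminal restriction fragment (T-RF) length is therefore the number of
bases from the labeled 5' terminus up to the first cut site on the
labeled strand.

Enzyme recognition and cut conventions are REBASE-standard data, carried
on the :class:`Enzyme` record and overridable:

* HhaI recognizes ``GCGC`` and cuts ``GCG^C`` (three motif bases retained
  on the labeled fragment).
* MspI recognizes ``CCGG`` and cuts ``C^CGG`` (one motif base retained).

Sequences must be plain uppercase ``A/C/G/T``; IUPAC ambiguity codes are
rejected rather than expanded (expansion semantics for a fragment-size
prediction are ill-defined, and synthetic amplicons are unambiguous).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

__all__ = [
    "Amplicon",
    "Enzyme",
    "DigestResult",
    "InvalidSequenceError",
    "HHAI",
    "MSPI",
    "ENZYMES",
    "find_recognition_sites",
    "terminal_fragment_length",
    "dual_pattern",
]

_VALID_BASES = frozenset("ACGT")


class InvalidSequenceError(ValueError):
    """Raised when a sequence contains characters outside {A, C, G, T}."""


@dataclass(frozen=True)
class Enzyme:
    """A restriction endonuclease with a non-degenerate recognition motif.

    ``cut_offset`` is the number of motif bases retained on the labeled
    (5') fragment, so a site starting at 0-based position ``s`` yields a
    T-RF of ``s + cut_offset`` bases.
    """

    name: str
    motif: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.motif or set(self.motif) - _VALID_BASES:
            raise ValueError(f"motif must be non-degenerate A/C/G/T: {self.motif!r}")
        if not 1 <= self.cut_offset < len(self.motif):
            raise ValueError(
                f"cut_offset must satisfy 1 <= offset < len(motif); got {self.cut_offset}"
            )


HHAI = Enzyme("HhaI", "GCGC", 3)
MSPI = Enzyme("MspI", "CCGG", 1)

#: Registry of the two enzymes used for mono-digestion profiling.
ENZYMES: dict[str, Enzyme] = {HHAI.name: HHAI, MSPI.name: MSPI}


def get_enzyme(enzyme: "Enzyme | str") -> Enzyme:
    """Resolve an enzyme name to an :class:`Enzyme`, or pass one through."""
    if isinstance(enzyme, Enzyme):
        return enzyme
    try:
        return ENZYMES[enzyme]
    except KeyError:
        raise KeyError(
            f"unknown enzyme {enzyme!r}; known: {sorted(ENZYMES)}"
        ) from None


@dataclass(frozen=True)
class Amplicon:
    """A labeled amplicon; the label is fixed to the 5' end of the forward strand."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        validate_sequence(self.sequence)


@dataclass(frozen=True)
class DigestResult:
    """Outcome of a mono-digestion of one labeled amplicon.

    ``trf_length is None`` flags an uncut amplicon (no recognition site);
    uncut products are never assigned a pseudo-length because the
    full-length product falls outside the scored size window anyway.
    """

    enzyme: str
    trf_length: Optional[int]
    cut_position: Optional[int]

    @property
    def uncut(self) -> bool:
        return self.trf_length is None


def validate_sequence(seq: str) -> None:
    """Reject empty sequences and any character outside {A, C, G, T}."""
    if not seq:
        raise InvalidSequenceError("empty sequence")
    for i, ch in enumerate(seq):
        if ch not in _VALID_BASES:
            raise InvalidSequenceError(
                f"invalid character {ch!r} at position {i}; only uppercase A/C/G/T allowed"
            )


def find_recognition_sites(seq: str, enzyme: "Enzyme | str") -> list[int]:
    """All 0-based start positions of the enzyme's motif, including overlaps."""
    enzyme = get_enzyme(enzyme)
    validate_sequence(seq)
    sites: list[int] = []
    start = seq.find(enzyme.motif)
    while start != -1:
        sites.append(start)
        start = seq.find(enzyme.motif, start + 1)  # step 1 so overlaps are reported
    return sites


def terminal_fragment_length(seq: str, enzyme: "Enzyme | str") -> DigestResult:
    """Length of the labeled terminal fragment, or an uncut flag.

    The T-RF runs from the labeled 5' terminus through the last base
    retained before the first cut, so its length equals the 0-based cut
    index (first-site start + cut offset).
    """
    enzyme = get_enzyme(enzyme)
    sites = find_recognition_sites(seq, enzyme)
    if not sites:
        return DigestResult(enzyme.name, None, None)
    cut = sites[0] + enzyme.cut_offset
    return DigestResult(enzyme.name, cut, cut)


def dual_pattern(seq: str) -> tuple[DigestResult, DigestResult]:
    """Independent HhaI and MspI mono-digestions of the same amplicon.

    Separate aliquots are digested with a single enzyme each; this is
    never a double digest, so the two results do not interact.
    """
    return (
        terminal_fragment_length(seq, HHAI),
        terminal_fragment_length(seq, MSPI),
    )
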