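"""File formats, bundled reference tables, configuration, and the
end-to-end pipeline driver.

All tabular formats are plain TSV with documented headers:

* peak tables: ``sample_id  enzyme  size_bp  height_fu``
* pattern tables: ``otu_id  hha_trf  msp_trf  taxon_name  rank  identity_pct  flag``
  (``-`` or empty = fragment absent / value missing)
* chemistry tables: ``sample_id  analyte  mean  sd  n`` (optional ``group``)

Two reference tables ship with the package (``trflp/data/``): the
dual-enzyme OTU/taxon affiliation table (25 OTUs) and the per-sample
active-chemical summaries (12 samples x 2 analytes) for *Alpinia
officinarum* rhizome fungal endophytes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import chemistry as chem
from . import community, ordination, peaks, taxonomy
from .digest import Amplicon, dual_pattern
from .peaks import PeakTable
from .taxonomy import OTURecord, PatternTable

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_peak_table",
    "write_peak_tables",
    "read_chem_table",
    "read_pattern_table",
    "write_pattern_table",
    "load_reference_patterns",
    "load_reference_chemistry",
    "StudyConfig",
    "PipelineReport",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

PEAK_COLUMNS = ("sample_id", "enzyme", "size_bp", "height_fu")
PATTERN_COLUMNS = ("otu_id", "hha_trf", "msp_trf", "taxon_name", "rank", "identity_pct", "flag")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[Amplicon]:
    """Read labeled amplicons; order and identifiers are preserved."""
    path = Path(path)
    text = path.read_text()
    stripped = text.strip()
    if not stripped:
        logger.warning("empty FASTA file %s", path)
        return []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise ValueError(f"{path}:{lineno}: expected FASTA header, got {line[:30]!r}")
            break
    records = list(SeqIO.parse(str(path), "fasta"))
    out = []
    for rec in records:
        try:
            out.append(Amplicon(rec.id, str(rec.seq).upper()))
        except ValueError as exc:
            raise ValueError(f"{path}: record {rec.id!r}: {exc}") from exc
    return out


def write_fasta(amplicons: Sequence[Amplicon], path) -> None:
    records = [
        SeqRecord(Seq(a.sequence), id=a.id, description="") for a in amplicons
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# TSV readers with typed validation

def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return table


def _numeric(table: pd.DataFrame, column: str, path, allow_missing: bool = False) -> pd.Series:
    raw = table[column]
    blank = raw.isna() | raw.str.strip().isin(("", "-"))
    converted = pd.to_numeric(raw.where(~blank), errors="coerce")
    bad = converted.isna() & ~blank
    if bad.any():
        row = int(bad.idxmax())
        raise ValueError(
            f"{path}: non-numeric value {raw[row]!r} in column {column!r}, row {row}"
        )
    if not allow_missing and blank.any():
        row = int(blank.idxmax())
        raise ValueError(f"{path}: missing value in column {column!r}, row {row}")
    return converted


def read_peak_table(path) -> list[PeakTable]:
    """Read a long-format peak TSV into one PeakTable per (sample, enzyme)."""
    table = _read_tsv(path, PEAK_COLUMNS)
    sizes = _numeric(table, "size_bp", path)
    heights = _numeric(table, "height_fu", path)
    table = table.assign(size_bp=sizes, height_fu=heights)
    out = []
    for (sample_id, enzyme), group in table.groupby(["sample_id", "enzyme"], sort=True):
        out.append(
            PeakTable(
                str(sample_id),
                str(enzyme),
                group["size_bp"].to_numpy(),
                group["height_fu"].to_numpy(),
            )
        )
    return out


def write_peak_tables(tables: Sequence[PeakTable], path) -> None:
    pd.concat([t.to_frame() for t in tables], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )


def read_chem_table(path) -> pd.DataFrame:
    """Read and validate a chemistry summary TSV."""
    table = _read_tsv(path, chem.CHEM_COLUMNS)
    for column in ("mean", "sd"):
        table[column] = _numeric(table, column, path)
    table["n"] = _numeric(table, "n", path).astype(int)
    return chem.validate_chem_table(table)


def read_pattern_table(path) -> PatternTable:
    """Read a dual-enzyme OTU pattern TSV."""
    table = _read_tsv(path, PATTERN_COLUMNS)
    otu_ids = _numeric(table, "otu_id", path).astype(int)
    hha = _numeric(table, "hha_trf", path, allow_missing=True)
    msp = _numeric(table, "msp_trf", path, allow_missing=True)
    identity = _numeric(table, "identity_pct", path, allow_missing=True)
    records = []
    for i in range(len(table)):
        flag = table["flag"].iloc[i]
        flag = "" if pd.isna(flag) else flag.strip()
        rank = table["rank"].iloc[i]
        rank = "unresolved" if pd.isna(rank) or not rank.strip() else rank.strip()
        name = table["taxon_name"].iloc[i]
        name = "unresolved" if pd.isna(name) or not name.strip() else name.strip()
        records.append(
            OTURecord(
                otu_id=int(otu_ids.iloc[i]),
                hha_trf=None if pd.isna(hha.iloc[i]) else int(hha.iloc[i]),
                msp_trf=None if pd.isna(msp.iloc[i]) else int(msp.iloc[i]),
                taxon_name=name,
                taxon_rank=rank,
                identity_pct=None if pd.isna(identity.iloc[i]) else float(identity.iloc[i]),
                flag=flag,
            )
        )
    return PatternTable(tuple(records), provenance=str(path))


def write_pattern_table(table: PatternTable, path) -> None:
    frame = table.to_frame().reset_index().rename(columns={"taxon_rank": "rank"})
    frame = frame[list(PATTERN_COLUMNS)]
    frame.to_csv(path, sep="\t", index=False)


def _data_path(name: str):
    return resources.files("trflp.data").joinpath(name)


def load_reference_patterns() -> PatternTable:
    """The bundled 25-OTU dual-enzyme affiliation table."""
    with resources.as_file(_data_path("alpinia_otu_patterns.tsv")) as path:
        return read_pattern_table(path)


def load_reference_chemistry() -> pd.DataFrame:
    """The bundled 12-sample volatile-oil / galangin summary table."""
    with resources.as_file(_data_path("alpinia_chemistry.tsv")) as path:
        return read_chem_table(path)


# ---------------------------------------------------------------------------
# configuration

_REP_SUFFIX = re.compile(r"\.rep\d+$")


@dataclass
class StudyConfig:
    """Declarative description of one pipeline run.

    Replicate samples are recognized by a ``.rep<k>`` suffix on the
    sample id (e.g. ``LT-4-RZ.rep2`` averages into ``LT-4-RZ``) unless an
    explicit ``replicate_map`` is given.
    """

    peaks_path: Optional[str] = None
    pattern_path: Optional[str] = None
    chem_path: Optional[str] = None
    fasta_path: Optional[str] = None
    outdir: str = "trflp_out"
    size_range: tuple[float, float] = (peaks.SIZE_MIN, peaks.SIZE_MAX)
    min_height: float = peaks.HEIGHT_MIN
    binning_tolerance_bp: float = 0.5
    matching_tolerance_bp: float = 1.0
    alpha: float = 0.05
    evenness_method: str = "pielou"
    presence_threshold: float = 0.0
    nmds_restarts: int = 20
    nmds_max_iter: int = 500
    nmds_tol: float = 1e-7
    reference_sample: Optional[str] = None
    replicate_map: Optional[dict] = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.size_range
        if not 0 < lo < hi:
            raise ValueError("size_range must satisfy 0 < low < high")
        if self.min_height < 0 or self.binning_tolerance_bp < 0 or self.matching_tolerance_bp < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["size_range"] = list(self.size_range)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "size_range" in data:
            data["size_range"] = tuple(data["size_range"])
        return cls(**data)


# ---------------------------------------------------------------------------
# end-to-end pipeline

@dataclass
class PipelineReport:
    """In-memory bundle of every pipeline product (also written as TSV)."""

    community_matrices: dict[str, pd.DataFrame]
    diversity: dict[str, pd.DataFrame]
    similarity: dict[tuple[str, str], community.SimilarityMatrix]
    nmds: dict[str, ordination.NMDSResult]
    genus_distributions: Optional[pd.DataFrame]
    chem_letters: dict[str, chem.LetterDisplay]
    chem_groups: dict[str, chem.GroupAssignment]
    fold_excess: dict[str, tuple[float, float]]
    outdir: Path


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r}: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: StudyConfig) -> PipelineReport:
    """Peak tables -> profiles -> diversity, similarity, NMDS, taxon
    distributions and chemistry groups; every product written as TSV.

    Deterministic under a fixed config seed; any stage failure aborts
    with a stage-tagged :class:`PipelineError`.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": dataclasses.asdict(config)}

    if config.peaks_path is None:
        raise PipelineError("stage 'input': no peak table configured")
    tables = _stage("read_peaks")(read_peak_table)(config.peaks_path)
    if not tables:
        raise PipelineError("stage 'input': peak table is empty")

    by_enzyme: dict[str, list[PeakTable]] = {}
    for t in tables:
        by_enzyme.setdefault(t.enzyme, []).append(t)

    community_matrices: dict[str, pd.DataFrame] = {}
    diversity: dict[str, pd.DataFrame] = {}
    similarity: dict[tuple[str, str], community.SimilarityMatrix] = {}
    nmds_results: dict[str, ordination.NMDSResult] = {}

    for enzyme, enz_tables in sorted(by_enzyme.items()):
        profiles = [
            peaks.normalize(
                peaks.filter_peaks(t, config.size_range, config.min_height)
            )
            for t in enz_tables
        ]
        matrix = _stage("bin_align")(peaks.bin_align)(profiles, config.binning_tolerance_bp)
        rep_map = config.replicate_map or {
            s: _REP_SUFFIX.sub("", s) for s in matrix.index
        }
        matrix = _stage("average_replicates")(peaks.average_replicates)(matrix, rep_map)
        community_matrices[enzyme] = matrix
        matrix.to_csv(outdir / f"community_matrix_{enzyme}.tsv", sep="\t")

        div = _stage("diversity")(community.diversity_table)(matrix, config.evenness_method)
        diversity[enzyme] = div
        div.to_csv(outdir / f"diversity_{enzyme}.tsv", sep="\t")

        for metric in ("bray_curtis", "jaccard"):
            sim = _stage("similarity")(community.pairwise_matrix)(matrix, metric)
            similarity[(metric, enzyme)] = sim
            sim.values.to_csv(outdir / f"similarity_{metric}_{enzyme}.tsv", sep="\t")

        res = _stage("nmds")(ordination.nmds)(
            similarity[("bray_curtis", enzyme)].as_dissimilarity().values,
            n_restarts=config.nmds_restarts,
            max_iter=config.nmds_max_iter,
            tol=config.nmds_tol,
            seed=config.seed,
        )
        nmds_results[enzyme] = res
        res.coordinates.to_csv(outdir / f"nmds_coords_{enzyme}.tsv", sep="\t")
        log.setdefault("nmds_stress", {})[enzyme] = res.stress

    genus_frame = None
    if config.pattern_path is not None and "HhaI" in community_matrices:
        pattern_table = _stage("read_patterns")(read_pattern_table)(config.pattern_path)
        matrix = community_matrices["HhaI"]
        rows = {}
        for sample in matrix.index:
            row = matrix.loc[sample]
            dist = taxonomy.genus_distribution(
                {float(b): float(v) for b, v in row.items() if v > 0},
                pattern_table,
                tolerance_bp=config.matching_tolerance_bp,
                enzyme="HhaI",
            )
            rows[sample] = dist
        genus_frame = pd.DataFrame(rows).T.fillna(0.0)
        genus_frame.index.name = "sample_id"
        genus_frame.to_csv(outdir / "genus_distribution.tsv", sep="\t")

    letters: dict[str, chem.LetterDisplay] = {}
    groups: dict[str, chem.GroupAssignment] = {}
    folds: dict[str, tuple[float, float]] = {}
    if config.chem_path is not None:
        table = _stage("read_chemistry")(read_chem_table)(config.chem_path)
        for analyte in sorted(table["analyte"].unique()):
            letters[analyte] = _stage("duncan")(chem.chem_letters)(table, analyte, config.alpha)
            groups[analyte] = chem.chem_groups(table, analyte, config.alpha)
            sub = table[table["analyte"] == analyte]
            reference = config.reference_sample or str(
                sub.loc[sub["mean"].idxmax(), "sample_id"]
            )
            folds[analyte] = chem.fold_excess(reference, table, analyte)
        letter_rows = [
            {"analyte": a, "sample_id": s, "letters": l, "group": groups[a].groups[s]}
            for a, disp in letters.items()
            for s, l in disp.letters.items()
        ]
        pd.DataFrame(letter_rows).to_csv(outdir / "chem_groups.tsv", sep="\t", index=False)
        log["fold_excess"] = {a: list(v) for a, v in folds.items()}

    from . import __version__

    log["version"] = __version__
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))

    return PipelineReport(
        community_matrices=community_matrices,
        diversity=diversity,
        similarity=similarity,
        nmds=nmds_results,
        genus_distributions=genus_frame,
        chem_letters=letters,
        chem_groups=groups,
        fold_excess=folds,
        outdir=outdir,
    )
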