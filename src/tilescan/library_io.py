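"""Data model and readers/writers for tiling-screen tables.

Conventions used throughout the package:

* CDS nucleotide coordinates are 1-based; ``cut_nt`` is the coding-strand
  base immediately 5' of the blunt Cas9 cut (3 bp 5' of the NGG PAM).
* Amino-acid intervals are 1-based inclusive; BED export is 0-based
  half-open with coordinates in amino-acid units.
* Nontargeting control guides live in the same table as targeting guides
  under the reserved gene name ``"NTC"`` and carry no cut coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

NTC_GENE = "NTC"
_VALID_BASES = frozenset("ACGT")

LIBRARY_COLUMNS = [
    "guide_id",
    "gene",
    "protospacer",
    "strand",
    "cut_nt",
    "cut_aa",
    "flag_tttt",
    "flag_yrich",
    "p_inframe",
]


def cut_aa_from_nt(cut_nt: int) -> int:
    """Amino acid (1-based) containing CDS nucleotide ``cut_nt`` (1-based)."""
    cut_nt = int(cut_nt)
    if cut_nt < 1:
        raise ValueError(f"cut_nt must be >= 1, got {cut_nt}")
    return (cut_nt - 1) // 3 + 1


@dataclass
class GuideRecord:
    """A single sgRNA.

    ``cut_nt``/``cut_aa``/``strand`` are ``None`` for nontargeting controls.
    """

    guide_id: str
    gene: str
    protospacer: str
    strand: str | None = None
    cut_nt: int | None = None
    cut_aa: int | None = None
    flag_tttt: bool = False
    flag_yrich: bool = False
    p_inframe: float | None = None

    def __post_init__(self) -> None:
        self.protospacer = str(self.protospacer).upper()
        if len(self.protospacer) != 20:
            raise ValueError(
                f"{self.guide_id}: protospacer must be 20 nt, "
                f"got {len(self.protospacer)}"
            )
        if not set(self.protospacer) <= _VALID_BASES:
            raise ValueError(f"{self.guide_id}: protospacer has non-ACGT characters")
        if self.is_ntc:
            if self.cut_nt is not None or self.cut_aa is not None:
                raise ValueError(f"{self.guide_id}: NTC guides carry no cut coordinates")
        elif self.cut_nt is not None:
            self.cut_nt = int(self.cut_nt)
            expected = cut_aa_from_nt(self.cut_nt)
            if self.cut_aa is None:
                self.cut_aa = expected
            elif int(self.cut_aa) != expected:
                raise ValueError(
                    f"{self.guide_id}: cut_aa {self.cut_aa} inconsistent with "
                    f"cut_nt {self.cut_nt} (expected {expected})"
                )
        if self.strand is not None and self.strand not in ("+", "-"):
            raise ValueError(f"{self.guide_id}: strand must be '+' or '-'")
        if self.p_inframe is not None:
            self.p_inframe = float(self.p_inframe)
            if not 0.0 <= self.p_inframe <= 1.0:
                raise ValueError(f"{self.guide_id}: p_inframe outside [0, 1]")

    @property
    def is_ntc(self) -> bool:
        return self.gene == NTC_GENE


def library_to_frame(records: Iterable[GuideRecord]) -> pd.DataFrame:
    """Tabulate guide records; index is guide_id."""
    rows = []
    for r in records:
        rows.append(
            {
                "guide_id": r.guide_id,
                "gene": r.gene,
                "protospacer": r.protospacer,
                "strand": r.strand,
                "cut_nt": r.cut_nt,
                "cut_aa": r.cut_aa,
                "flag_tttt": r.flag_tttt,
                "flag_yrich": r.flag_yrich,
                "p_inframe": r.p_inframe,
            }
        )
    frame = pd.DataFrame(rows, columns=LIBRARY_COLUMNS)
    frame["cut_nt"] = frame["cut_nt"].astype("Int64")
    frame["cut_aa"] = frame["cut_aa"].astype("Int64")
    return frame.set_index("guide_id", drop=False)


def frame_to_records(frame: pd.DataFrame) -> list[GuideRecord]:
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            GuideRecord(
                guide_id=row.guide_id,
                gene=row.gene,
                protospacer=row.protospacer,
                strand=None if pd.isna(row.strand) else row.strand,
                cut_nt=None if pd.isna(row.cut_nt) else int(row.cut_nt),
                cut_aa=None if pd.isna(row.cut_aa) else int(row.cut_aa),
                flag_tttt=bool(row.flag_tttt),
                flag_yrich=bool(row.flag_yrich),
                p_inframe=None if pd.isna(row.p_inframe) else float(row.p_inframe),
            )
        )
    return records


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def read_library_table(
    path: str | Path, cds_lengths: dict[str, int] | None = None
) -> list[GuideRecord]:
    """Read a guide library table (TSV/CSV).

    Required columns: guide_id, gene, protospacer. Optional: strand,
    cut_nt, cut_aa, p_inframe, flag_tttt, flag_yrich. Sequence-quality
    flags are computed from the protospacer when absent.
    """
    df = _read_table(path)
    required = {"guide_id", "gene", "protospacer"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"library table missing columns: {sorted(missing)}")
    dup = df["guide_id"][df["guide_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate guide_id values: {sorted(set(dup))[:5]}")

    from .library_design import flag_guide  # local import to avoid a cycle

    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        spacer = str(d["protospacer"]).upper()
        if "flag_tttt" in d and not pd.isna(d["flag_tttt"]):
            flags = {
                "flag_tttt": bool(d["flag_tttt"]),
                "flag_yrich": bool(d.get("flag_yrich", False)),
            }
        else:
            flags = flag_guide(spacer)
        cut_nt = d.get("cut_nt")
        cut_nt = None if cut_nt is None or pd.isna(cut_nt) else int(cut_nt)
        if cds_lengths is not None and cut_nt is not None:
            gene = d["gene"]
            if gene in cds_lengths and cut_nt > cds_lengths[gene]:
                raise ValueError(
                    f"{d['guide_id']}: cut_nt {cut_nt} exceeds CDS length "
                    f"{cds_lengths[gene]} of {gene}"
                )
        cut_aa = d.get("cut_aa")
        cut_aa = None if cut_aa is None or pd.isna(cut_aa) else int(cut_aa)
        p_inframe = d.get("p_inframe")
        p_inframe = None if p_inframe is None or pd.isna(p_inframe) else float(p_inframe)
        strand = d.get("strand")
        strand = None if strand is None or pd.isna(strand) else str(strand)
        records.append(
            GuideRecord(
                guide_id=str(d["guide_id"]),
                gene=str(d["gene"]),
                protospacer=spacer,
                strand=strand,
                cut_nt=cut_nt,
                cut_aa=cut_aa,
                p_inframe=p_inframe,
                **flags,
            )
        )
    return records


def write_library_table(records: Iterable[GuideRecord], path: str | Path) -> None:
    frame = library_to_frame(records)
    sep = "," if Path(path).suffix.lower() == ".csv" else "\t"
    frame.to_csv(path, sep=sep, index=False)


@dataclass
class CountMatrix:
    """Integer read counts, guides x samples, with sample metadata.

    ``counts`` is indexed by guide_id; ``samples`` is indexed by sample
    (column) name with columns cell_line, replicate, timepoint.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    missing_guides: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.samples.index) != set(self.counts.columns):
            raise ValueError("sample sheet does not match count columns")
        bad_tp = set(self.samples["timepoint"]) - {"initial", "final"}
        if bad_tp:
            raise ValueError(f"unknown timepoints: {sorted(bad_tp)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        for (line, rep), grp in self.samples.groupby(["cell_line", "replicate"]):
            tps = sorted(grp["timepoint"])
            if tps != ["final", "initial"]:
                raise ValueError(
                    f"({line}, rep {rep}) needs exactly one initial and one "
                    f"final sample, got {tps}"
                )

    @property
    def cell_lines(self) -> list[str]:
        return sorted(self.samples["cell_line"].unique())

    def replicates(self, cell_line: str) -> list[int]:
        sel = self.samples[self.samples["cell_line"] == cell_line]
        return sorted(sel["replicate"].unique())

    def sample_name(self, cell_line: str, replicate: int, timepoint: str) -> str:
        sel = self.samples[
            (self.samples["cell_line"] == cell_line)
            & (self.samples["replicate"] == replicate)
            & (self.samples["timepoint"] == timepoint)
        ]
        if len(sel) != 1:
            raise KeyError((cell_line, replicate, timepoint))
        return sel.index[0]


def read_count_matrix(
    path: str | Path,
    sample_sheet: str | Path | pd.DataFrame,
    library: Sequence[GuideRecord] | pd.DataFrame | None = None,
) -> CountMatrix:
    """Read a wide count table keyed by guide_id plus a sample sheet.

    The sample sheet maps count columns to (cell_line, replicate,
    timepoint); required columns: sample, cell_line, replicate, timepoint.
    Guides present in the counts but absent from the library are kept but
    reported in ``missing_guides`` (with a warning).
    """
    df = _read_table(path)
    if "guide_id" not in df.columns:
        raise ValueError("count table must have a guide_id column")
    df = df.set_index("guide_id")
    if isinstance(sample_sheet, (str, Path)):
        sheet = _read_table(sample_sheet)
    else:
        sheet = sample_sheet.copy()
    required = {"sample", "cell_line", "replicate", "timepoint"}
    if not required <= set(sheet.columns):
        raise ValueError(f"sample sheet missing columns: {sorted(required - set(sheet.columns))}")
    sheet = sheet.set_index("sample")
    unknown = set(df.columns) - set(sheet.index)
    if unknown:
        raise ValueError(f"count columns without sample metadata: {sorted(unknown)}")
    counts = df[list(sheet.index)]
    arr = counts.to_numpy()
    if not np.all(np.equal(np.mod(arr, 1), 0)):
        raise ValueError("counts must be integers")
    if (arr < 0).any():
        raise ValueError("negative counts")
    counts = counts.astype(np.int64)

    missing: list[str] = []
    if library is not None:
        if isinstance(library, pd.DataFrame):
            known = set(library["guide_id"])
        else:
            known = {r.guide_id for r in library}
        missing = sorted(set(counts.index) - known)
        if missing:
            warnings.warn(
                f"{len(missing)} guide(s) in counts are absent from the library",
                stacklevel=2,
            )
    return CountMatrix(counts=counts, samples=sheet, missing_guides=missing)


@dataclass
class AnnotationSet:
    """Per-gene annotation intervals (1-based inclusive amino acids)."""

    intervals: pd.DataFrame  # columns: gene, aa_start, aa_end, source

    SOURCES = ("pfam", "literature", "disorder")

    def __post_init__(self) -> None:
        required = {"gene", "aa_start", "aa_end", "source"}
        if not required <= set(self.intervals.columns):
            raise ValueError("annotation table needs gene, aa_start, aa_end, source")
        bad = set(self.intervals["source"]) - set(self.SOURCES)
        if bad:
            raise ValueError(f"unknown annotation sources: {sorted(bad)}")
        if (self.intervals["aa_start"] > self.intervals["aa_end"]).any():
            raise ValueError("annotation with aa_start > aa_end")
        if (self.intervals["aa_start"] < 1).any():
            raise ValueError("annotation coordinates must be >= 1")

    def for_gene(self, gene: str) -> pd.DataFrame:
        return self.intervals[self.intervals["gene"] == gene]


def read_annotations(path: str | Path) -> AnnotationSet:
    return AnnotationSet(_read_table(path))


@dataclass
class ConservationTrack:
    """Per-gene, per-CDS-nucleotide conservation scores (phyloP-style)."""

    scores: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for gene, arr in self.scores.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 1 or arr.size % 3 != 0:
                raise ValueError(
                    f"{gene}: track length {arr.size} not divisible by 3"
                )
            self.scores[gene] = arr

    def __getitem__(self, gene: str) -> np.ndarray:
        return self.scores[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.scores


def read_conservation_bedgraph(path: str | Path) -> ConservationTrack:
    """Read per-nucleotide scores from bedGraph (chrom = gene name,
    0-based half-open CDS nucleotide coordinates)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["gene", "start", "end", "score"],
    )
    tracks: dict[str, np.ndarray] = {}
    for gene, grp in df.groupby("gene"):
        length = int(grp["end"].max())
        if length % 3 != 0:
            raise ValueError(f"{gene}: track length {length} not divisible by 3")
        arr = np.zeros(length)
        for row in grp.itertuples(index=False):
            arr[int(row.start) : int(row.end)] = row.score
        tracks[str(gene)] = arr
    return ConservationTrack(tracks)


_REGION_COLUMNS = [
    "gene",
    "aa_start",
    "aa_end",
    "score",
    "method",
    "category",
    "sources",
    "mean_phylop",
    "conserved",
]


def regions_to_frame(regions: Iterable) -> pd.DataFrame:
    rows = []
    for r in regions:
        rows.append(
            {
                "gene": r.gene,
                "aa_start": int(r.aa_start),
                "aa_end": int(r.aa_end),
                "score": r.score,
                "method": r.method,
                "category": r.category,
                "sources": ";".join(sorted(r.sources)) if r.sources else None,
                "mean_phylop": r.mean_phylop,
                "conserved": r.conserved,
            }
        )
    frame = pd.DataFrame(rows, columns=_REGION_COLUMNS)
    return frame.sort_values(["gene", "aa_start"], kind="stable").reset_index(drop=True)


def write_regions(regions: Iterable, path: str | Path, format: str = "tsv") -> None:
    """Write called regions as TSV (1-based inclusive) or BED (0-based
    half-open, amino-acid units, score in column 5)."""
    frame = regions_to_frame(regions)
    path = Path(path)
    if format == "tsv":
        frame.to_csv(path, sep="\t", index=False)
    elif format == "bed":
        with open(path, "w") as fh:
            for row in frame.itertuples(index=False):
                fh.write(
                    f"{row.gene}\t{row.aa_start - 1}\t{row.aa_end}\t"
                    f"{row.method}\t{row.score:.6g}\n"
                )
    else:
        raise ValueError(f"unknown region format: {format!r}")


def read_regions(path: str | Path) -> list:
    """Read a TSV written by :func:`write_regions` back into Region objects."""
    from .region_analysis import Region  # local import to avoid a cycle

    frame = _read_table(path)
    regions = []
    for row in frame.itertuples(index=False):
        sources = getattr(row, "sources", None)
        if sources is None or pd.isna(sources):
            src = set()
        else:
            src = set(str(sources).split(";"))
        category = getattr(row, "category", None)
        mean_phylop = getattr(row, "mean_phylop", None)
        conserved = getattr(row, "conserved", None)
        regions.append(
            Region(
                gene=row.gene,
                aa_start=int(row.aa_start),
                aa_end=int(row.aa_end),
                score=float(row.score),
                method=row.method,
                sources=src,
                category=None if category is None or pd.isna(category) else category,
                mean_phylop=None
                if mean_phylop is None or pd.isna(mean_phylop)
                else float(mean_phylop),
                conserved=None
                if conserved is None or pd.isna(conserved)
                else bool(conserved),
            )
        )
    return regions


def read_cds_fasta(path: str | Path) -> dict[str, str]:
    """Read CDS sequences keyed by record id."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
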