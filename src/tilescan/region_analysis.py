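"""Annotation, conservation, and overlap bookkeeping for called regions.

All interval arithmetic is on 1-based inclusive amino-acid coordinates;
two regions overlap when they share at least ``min_aa`` residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .library_io import AnnotationSet, ConservationTrack

CATEGORY_PRECEDENCE = ("pfam", "literature", "disorder")


@dataclass
class Region:
    """A called essential interval in amino-acid coordinates."""

    gene: str
    aa_start: int
    aa_end: int
    score: float
    method: str = "tivex"
    sources: set[str] = field(default_factory=set)
    category: str | None = None
    mean_phylop: float | None = None
    conserved: bool | None = None

    def __post_init__(self) -> None:
        self.aa_start = int(self.aa_start)
        self.aa_end = int(self.aa_end)
        if self.aa_start < 1 or self.aa_start > self.aa_end:
            raise ValueError(
                f"{self.gene}: invalid interval [{self.aa_start}, {self.aa_end}]"
            )

    def __len__(self) -> int:
        return self.aa_end - self.aa_start + 1


def overlap_length(a: Region, b: Region) -> int:
    """Shared residues between two regions (0 when different genes)."""
    if a.gene != b.gene:
        return 0
    return max(0, min(a.aa_end, b.aa_end) - max(a.aa_start, b.aa_start) + 1)


def overlap_count(
    regions_a: list[Region], regions_b: list[Region], min_aa: int = 1
) -> dict:
    """How many regions in A overlap at least one region in B by >= min_aa.

    Returns ``{"n_a_overlapping_b": int, "pairs": [(i, j), ...]}`` with
    indices into the input lists.
    """
    pairs = []
    hit = set()
    for i, a in enumerate(regions_a):
        for j, b in enumerate(regions_b):
            if overlap_length(a, b) >= min_aa:
                pairs.append((i, j))
                hit.add(i)
    return {"n_a_overlapping_b": len(hit), "pairs": pairs}


def categorize(region: Region, annotations: AnnotationSet, min_aa: int = 1) -> set[str]:
    """Record every annotation source the region overlaps and set its
    display category by precedence pfam > literature > disorder > other."""
    sources: set[str] = set()
    for row in annotations.for_gene(region.gene).itertuples(index=False):
        inter = min(region.aa_end, int(row.aa_end)) - max(
            region.aa_start, int(row.aa_start)
        ) + 1
        if inter >= min_aa:
            sources.add(row.source)
    region.sources = sources
    region.category = next(
        (c for c in CATEGORY_PRECEDENCE if c in sources), "other"
    )
    return sources if sources else {"other"}


def conservation_score(
    region: Region, track: ConservationTrack, alpha: float = 0.05
) -> dict:
    """Average phyloP over the region's CDS nucleotides.

    The region covers CDS nucleotides 3*aa_start-2 .. 3*aa_end (1-based).
    phyloP is on a -log10 P scale, so the averaged score calls the region
    conserved when it reaches -log10(alpha).
    """
    if region.gene not in track:
        raise KeyError(f"no conservation track for {region.gene}")
    arr = track[region.gene]
    lo = 3 * region.aa_start - 3  # 0-based inclusive
    hi = 3 * region.aa_end  # 0-based exclusive
    if hi > arr.size:
        raise ValueError(
            f"{region.gene}: track length {arr.size} shorter than region end {hi}"
        )
    mean = float(np.mean(arr[lo:hi]))
    conserved = bool(mean >= -np.log10(alpha))
    region.mean_phylop = mean
    region.conserved = conserved
    return {"mean_phylop": mean, "conserved": conserved}


def coverage_fraction(regions_for_gene: list[Region], protein_length: int) -> float:
    """Fraction of the protein covered by the union of regions."""
    protein_length = int(protein_length)
    if protein_length < 1:
        raise ValueError("protein_length must be >= 1")
    if not regions_for_gene:
        return 0.0
    covered = np.zeros(protein_length, dtype=bool)
    for r in regions_for_gene:
        if r.aa_end > protein_length:
            raise ValueError(
                f"{r.gene}: region end {r.aa_end} exceeds protein length {protein_length}"
            )
        covered[r.aa_start - 1 : r.aa_end] = True
    return float(covered.mean())


def annotate_regions(
    regions: list[Region],
    annotations: AnnotationSet | None = None,
    track: ConservationTrack | None = None,
    alpha: float = 0.05,
) -> list[Region]:
    """Categorize and conservation-score regions in place (and return them)."""
    for r in regions:
        if annotations is not None:
            categorize(r, annotations)
        if track is not None and r.gene in track:
            conservation_score(r, track, alpha=alpha)
    return regions
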