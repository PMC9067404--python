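"""Tiling sgRNA enumeration from CDS sequences, spacing statistics, and
sequence-quality flags.

Cas9 (S. pyogenes) targets a 20-nt protospacer followed by an NGG PAM and
cuts bluntly 3 bp 5' of the PAM, i.e. between protospacer positions 17 and
18. ``cut_nt`` records the coding-strand base immediately 5' of the cut.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

from .library_io import GuideRecord, _VALID_BASES, cut_aa_from_nt

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_PYRIMIDINES = frozenset("CT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def flag_tttt(protospacer: str) -> bool:
    """True iff the protospacer contains a TTTT repeat (Pol III terminator
    risk; such guides are excluded from global analyses)."""
    return "TTTT" in protospacer


def flag_yrich(protospacer: str, window: int = 4, min_pyrimidines: int = 3) -> bool:
    """True iff >= ``min_pyrimidines`` of the final ``window`` protospacer
    bases (adjacent to the scaffold) are pyrimidines (C/T)."""
    tail = protospacer[-window:]
    return sum(b in _PYRIMIDINES for b in tail) >= min_pyrimidines


def flag_guide(
    protospacer: str, yrich_window: int = 4, yrich_min: int = 3
) -> dict[str, bool]:
    if len(protospacer) != 20:
        raise ValueError("protospacer must be 20 nt")
    return {
        "flag_tttt": flag_tttt(protospacer),
        "flag_yrich": flag_yrich(protospacer, yrich_window, yrich_min),
    }


def enumerate_guides(cds_sequence: str, gene_name: str) -> list[GuideRecord]:
    """All unique tiling sgRNAs for one CDS.

    Scans both strands for 20-mers followed by NGG whose cut site falls
    inside the CDS. Protospacers occurring more than once in the CDS
    (ambiguous position) are dropped entirely. Guide ids encode gene, cut
    site and strand.
    """
    seq = str(cds_sequence).upper()
    if not set(seq) <= _VALID_BASES:
        raise ValueError(f"{gene_name}: CDS contains non-ACGT characters")
    if len(seq) % 3 != 0:
        raise ValueError(f"{gene_name}: CDS length {len(seq)} not divisible by 3")
    L = len(seq)

    candidates: list[tuple[str, str, int]] = []  # (protospacer, strand, cut_nt)
    # plus strand: protospacer at p0..p0+19 (0-based), PAM at p0+20..p0+22
    for p0 in range(0, L - 22):
        if seq[p0 + 21] == "G" and seq[p0 + 22] == "G":
            candidates.append((seq[p0 : p0 + 20], "+", p0 + 17))
    # minus strand: coding-strand CCN at c0..c0+2 (0-based), protospacer is
    # the reverse complement of coding positions c0+3..c0+22 (0-based); the
    # blunt cut sits between coding bases c0+6 and c0+7 (1-based)
    for c0 in range(0, L - 22):
        if seq[c0] == "C" and seq[c0 + 1] == "C":
            candidates.append((reverse_complement(seq[c0 + 3 : c0 + 23]), "-", c0 + 6))

    counts: dict[str, int] = {}
    for spacer, _, _ in candidates:
        counts[spacer] = counts.get(spacer, 0) + 1

    records = []
    for spacer, strand, cut_nt in candidates:
        if counts[spacer] > 1:
            continue
        records.append(
            GuideRecord(
                guide_id=f"{gene_name}:{cut_nt}{strand}",
                gene=gene_name,
                protospacer=spacer,
                strand=strand,
                cut_nt=cut_nt,
                cut_aa=cut_aa_from_nt(cut_nt),
                **flag_guide(spacer),
            )
        )
    records.sort(key=lambda r: (r.cut_nt, r.strand))
    return records


def _protospacer_gene_map(all_cds_sequences: Mapping[str, str]) -> dict[str, set[str]]:
    hits: dict[str, set[str]] = {}
    for gene, seq in all_cds_sequences.items():
        seq = str(seq).upper()
        L = len(seq)
        for p0 in range(0, L - 22):
            if seq[p0 + 21] == "G" and seq[p0 + 22] == "G":
                hits.setdefault(seq[p0 : p0 + 20], set()).add(gene)
        for c0 in range(0, L - 22):
            if seq[c0] == "C" and seq[c0 + 1] == "C":
                hits.setdefault(
                    reverse_complement(seq[c0 + 3 : c0 + 23]), set()
                ).add(gene)
    return hits


def uniqueness_filter(
    guides: Sequence[GuideRecord],
    all_cds_sequences: Mapping[str, str],
    mode: str = "drop",
) -> tuple[list[GuideRecord], list[GuideRecord]]:
    """Screen guides for exact protospacer+PAM matches in other CDSs.

    Returns ``(kept, multi_target)``. With ``mode="drop"`` multi-target
    guides are removed; with ``mode="flag"`` they are kept in the first
    list as well (callers can inspect the second).
    """
    if not all_cds_sequences:
        raise ValueError("cannot assess uniqueness without CDS sequences")
    if mode not in ("drop", "flag"):
        raise ValueError(f"unknown mode {mode!r}")
    hits = _protospacer_gene_map(all_cds_sequences)
    kept, multi = [], []
    for g in guides:
        genes_hit = hits.get(g.protospacer, set())
        if len(genes_hit - {g.gene}) > 0:
            multi.append(g)
            if mode == "flag":
                kept.append(g)
        else:
            kept.append(g)
    return kept, multi


def spacing_stats(guides_for_gene: Iterable[GuideRecord]) -> dict[str, float]:
    """Median/maximum spacing (nt) between successive unique cut sites."""
    sites = sorted({g.cut_nt for g in guides_for_gene if g.cut_nt is not None})
    if len(sites) < 2:
        raise ValueError("spacing statistics need at least 2 distinct cut sites")
    gaps = np.diff(sites)
    return {
        "median_nt": float(np.median(gaps)),
        "max_nt": float(np.max(gaps)),
        "n_guides": len(sites),
    }
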