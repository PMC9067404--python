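"""Counts -> logFC -> median -> Z-score pipeline and gene-level calls.

Per replicate, each guide's log2 fold change compares its relative
abundance in the final versus initial population (library-size
normalized, pseudocount on both). The median logFC across replicates is
standardized per cell line against a baseline population (whole library
by default, NTC-only as option) to give a Z-score, and Z-scores are
averaged across cell lines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .library_io import NTC_GENE, CountMatrix


@dataclass
class GenotypeModel:
    """Editing-outcome model: probability that a single repaired allele
    carries an in-frame (non-frameshift) edit, and cell ploidy."""

    p_inframe_edit: float = 0.2
    ploidy: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_inframe_edit <= 1.0:
            raise ValueError("p_inframe_edit must be in [0, 1]")
        if int(self.ploidy) < 1:
            raise ValueError("ploidy must be >= 1")
        self.ploidy = int(self.ploidy)


def genotype_fractions(model: GenotypeModel | None = None, **kwargs) -> dict[str, float]:
    """Expected genotype mix after editing every allele independently.

    With in-frame repair probability p and ploidy k, a fraction (1-p)^k of
    cells carries frameshifts on all alleles; the rest retain at least one
    in-frame (but mutagenized) allele. For p=0.2 in diploid cells this is
    the 64% / 36% split that motivates tiling screens: in-frame alleles
    are only lethal when the edit lands in an essential region.
    """
    if model is None:
        model = GenotypeModel(**kwargs)
    all_fs = (1.0 - model.p_inframe_edit) ** model.ploidy
    return {"all_frameshift": all_fs, "at_least_one_inframe": 1.0 - all_fs}


@dataclass
class ScreenScores:
    """Per-guide scores at every stage of the pipeline.

    logfc has MultiIndex columns (cell_line, replicate); median_logfc and
    z have one column per cell line; mean_z averages z across cell lines.
    """

    guides: pd.DataFrame
    logfc: pd.DataFrame
    median_logfc: pd.DataFrame
    z: pd.DataFrame
    mean_z: pd.Series
    baseline: str = "library"

    @property
    def cell_lines(self) -> list[str]:
        return list(self.z.columns)

    def targeting(self) -> pd.DataFrame:
        return self.guides[self.guides["gene"] != NTC_GENE]

    def ntc_z(self) -> pd.DataFrame:
        return self.z.loc[self.guides["gene"] == NTC_GENE]


def normalize_and_logfc(cm: CountMatrix, pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-guide, per-replicate log2 fold change, library-size normalized.

    logfc = log2( ((final+c)/F_total) / ((initial+c)/I_total) ) with raw
    column totals F_total, I_total and pseudocount c.
    """
    cols = {}
    for line in cm.cell_lines:
        for rep in cm.replicates(line):
            ini = cm.counts[cm.sample_name(line, rep, "initial")].to_numpy(float)
            fin = cm.counts[cm.sample_name(line, rep, "final")].to_numpy(float)
            itot, ftot = ini.sum(), fin.sum()
            if itot == 0 or ftot == 0:
                raise ValueError(f"({line}, rep {rep}): empty sample")
            cols[(line, rep)] = np.log2(
                ((fin + pseudocount) / ftot) / ((ini + pseudocount) / itot)
            )
    frame = pd.DataFrame(cols, index=cm.counts.index)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["cell_line", "replicate"])
    return frame


def median_logfc(logfc: pd.DataFrame) -> pd.DataFrame:
    """Median logFC across replicates, one column per cell line."""
    return logfc.T.groupby(level="cell_line").median().T


def zscore(
    med: pd.DataFrame, guides: pd.DataFrame, baseline: str = "library"
) -> tuple[pd.DataFrame, pd.Series]:
    """Standardize per-cell-line median logFC against a baseline population.

    baseline="library" uses every scored guide; baseline="ntc" uses the
    nontargeting controls (their z then has mean 0, SD 1 by construction).
    """
    if baseline == "library":
        pop = med
    elif baseline == "ntc":
        ntc_ids = guides.index[guides["gene"] == NTC_GENE]
        ntc_ids = ntc_ids.intersection(med.index)
        if len(ntc_ids) == 0:
            raise ValueError("no NTC guides available for baseline='ntc'")
        pop = med.loc[ntc_ids]
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    mu = pop.mean(axis=0)
    sd = pop.std(axis=0, ddof=1)
    if (sd == 0).any() or sd.isna().any():
        bad = sd.index[(sd == 0) | sd.isna()].tolist()
        raise ValueError(f"zero baseline SD in cell line(s) {bad}")
    z = (med - mu) / sd
    return z, z.mean(axis=1)


def score_screen(
    cm: CountMatrix,
    guides: pd.DataFrame,
    baseline: str = "library",
    pseudocount: float = 0.5,
) -> ScreenScores:
    """Run the full counts -> logFC -> median -> Z pipeline."""
    lf = normalize_and_logfc(cm, pseudocount=pseudocount)
    guides = guides.loc[guides.index.intersection(lf.index)]
    lf = lf.loc[guides.index]
    med = median_logfc(lf)
    z, mean_z = zscore(med, guides, baseline=baseline)
    return ScreenScores(
        guides=guides, logfc=lf, median_logfc=med, z=z, mean_z=mean_z, baseline=baseline
    )


def filter_guides(
    scores: ScreenScores, drop: set[str] = frozenset({"tttt", "yrich"})
) -> tuple[ScreenScores, pd.DataFrame]:
    """Remove sequence-flagged guides from downstream analysis.

    Returns the filtered scores plus an audit table of removed guides.
    """
    unknown = set(drop) - {"tttt", "yrich"}
    if unknown:
        raise ValueError(f"unknown filter flags: {sorted(unknown)}")
    mask = pd.Series(False, index=scores.guides.index)
    if "tttt" in drop:
        mask |= scores.guides["flag_tttt"].astype(bool)
    if "yrich" in drop:
        mask |= scores.guides["flag_yrich"].astype(bool)
    if mask.all() and len(mask):
        raise ValueError("no guides remain after filtering")
    audit = scores.guides[mask].copy()
    keep = scores.guides.index[~mask]
    filtered = ScreenScores(
        guides=scores.guides.loc[keep],
        logfc=scores.logfc.loc[keep],
        median_logfc=scores.median_logfc.loc[keep],
        z=scores.z.loc[keep],
        mean_z=scores.mean_z.loc[keep],
        baseline=scores.baseline,
    )
    return filtered, audit


def call_gene_essentiality(
    scores: ScreenScores,
    z_cut: float = -1.0,
    min_fraction: float = 0.09,
    min_lines: int = 1,
) -> pd.DataFrame:
    """Gene-level essentiality from the per-line fraction of depleted guides.

    A cell line counts as a hit when more than ``min_fraction`` of a
    gene's guides have z < ``z_cut``; a gene is essential when at least
    ``min_lines`` lines hit.
    """
    targ = scores.targeting()
    if targ.empty:
        raise ValueError("no targeting guides to call genes on")
    z = scores.z.loc[targ.index]
    genes = targ["gene"]
    rows = []
    for gene, ids in z.groupby(genes).groups.items():
        zg = z.loc[ids]
        if len(zg) == 0:
            raise ValueError(f"{gene}: no scored guides")
        frac = (zg < z_cut).mean(axis=0)
        n_hit = int((frac > min_fraction).sum())
        row = {"gene": gene, "n_guides": len(zg), "n_lines_hit": n_hit,
               "essential": n_hit >= min_lines}
        for line in z.columns:
            row[f"fraction_{line}"] = float(frac[line])
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene").sort_index()


def compare_feature_bins(
    mean_z: pd.Series, bin_a: pd.Index | list, bin_b: pd.Index | list
) -> dict[str, float]:
    """Two-sided Mann-Whitney U comparing mean-Z values of two guide bins."""
    a = mean_z.loc[pd.Index(bin_a)]
    b = mean_z.loc[pd.Index(bin_b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("feature bins must be non-empty")
    if len(set(a.index) & set(b.index)) > 0:
        raise ValueError("feature bins must be disjoint")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "U": float(res.statistic),
        "p_value": float(res.pvalue),
        "median_a": float(a.median()),
        "median_b": float(b.median()),
    }


def cell_line_correlation(scores: ScreenScores) -> pd.DataFrame:
    """Pearson correlation of per-line Z-scores between cell lines,
    nontargeting controls excluded."""
    targ = scores.targeting()
    z = scores.z.loc[targ.index]
    if z.shape[1] < 2:
        raise ValueError("correlation needs at least 2 cell lines")
    r = np.corrcoef(z.to_numpy().T)
    return pd.DataFrame(r, index=z.columns, columns=z.columns)
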