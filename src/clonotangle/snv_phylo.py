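"""SNV-channel phylogenies.

Two distance constructions over site x sample genotype data:

* Identity-by-state (IBS) for DNA genotypes: per pair of samples, the mean
  over co-observed sites of the shared-allele fraction (2 - |g_i - g_j|) / 2
  for dosages g in {0, 1, 2}; the distance is 1 - IBS.  Missing data are
  handled pairwise-complete (no imputation).

* A depth-aware presence/absence divergence for RNA-derived variants: a site
  is callable in a cell when total read depth >= ``min_depth``; it is called
  variant-present when additionally alt / total >= ``alt_threshold``.  The
  divergence between two cells is the fraction of mutually callable sites at
  which presence differs.  This is a deliberate simplification of
  model-based read-count divergences: the interface takes the same inputs
  (alt / total read counts), so a likelihood-based estimator can drop in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .treecore import Dendrogram, DistanceMatrix, hclust, upgma

__all__ = ["GenotypeMatrix", "ibs_matrix", "rna_divergence", "build_snv_tree"]

MISSING = -1  # integer sentinel for missing dosage


@dataclass
class GenotypeMatrix:
    """Sites x samples allele dosage with optional per-cell read counts.

    ``dosage`` holds 0 / 1 / 2 with -1 for missing.  When ``alt_reads`` and
    ``total_reads`` are present they share the dosage shape, satisfy
    0 <= alt <= total, and dosage is missing wherever total = 0.
    """

    sites: list[str]
    samples: list[str]
    dosage: np.ndarray
    alt_reads: np.ndarray | None = None
    total_reads: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int16)
        shape = (len(self.sites), len(self.samples))
        if self.dosage.shape != shape:
            raise ValueError(f"dosage shape {self.dosage.shape} != {shape}")
        if not np.isin(self.dosage, (0, 1, 2, MISSING)).all():
            raise ValueError("dosage values must be 0/1/2 or -1 (missing)")
        if (self.alt_reads is None) != (self.total_reads is None):
            raise ValueError("alt_reads and total_reads must come together")
        if self.total_reads is not None:
            self.alt_reads = np.asarray(self.alt_reads, dtype=np.int64)
            self.total_reads = np.asarray(self.total_reads, dtype=np.int64)
            for name, arr in (("alt_reads", self.alt_reads),
                              ("total_reads", self.total_reads)):
                if arr.shape != shape:
                    raise ValueError(f"{name} shape {arr.shape} != {shape}")
                if (arr < 0).any():
                    raise ValueError(f"negative {name}")
            if (self.alt_reads > self.total_reads).any():
                raise ValueError("alt_reads exceeds total_reads")
            if (self.dosage[self.total_reads == 0] != MISSING).any():
                raise ValueError("dosage present where total_reads = 0")

    @property
    def has_reads(self) -> bool:
        return self.total_reads is not None

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.dosage, index=self.sites,
                     columns=self.samples).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, alt_path=None, total_path=None
                 ) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        alt = tot = None
        if alt_path is not None:
            alt = pd.read_csv(alt_path, sep="\t", index_col=0).to_numpy()
            tot = pd.read_csv(total_path, sep="\t", index_col=0).to_numpy()
        return cls(list(map(str, df.index)), list(map(str, df.columns)),
                   df.to_numpy(), alt, tot)


def ibs_matrix(gm: GenotypeMatrix) -> DistanceMatrix:
    """1 - mean identity-by-state over pairwise non-missing sites.

    Per co-observed site, IBS = (2 - |g_i - g_j|) / 2: identical dosages
    score 1, het vs hom scores 1/2, opposite homozygotes score 0.  A pair of
    samples with no co-observed site is an error (named in the message).
    """
    if len(gm.samples) < 2:
        raise ValueError("need at least 2 samples")
    g = gm.dosage.astype(float)
    g[gm.dosage == MISSING] = np.nan
    ns = len(gm.samples)
    d = np.zeros((ns, ns))
    bad_pairs = []
    for i in range(ns):
        for j in range(i + 1, ns):
            ok = ~np.isnan(g[:, i]) & ~np.isnan(g[:, j])
            if not ok.any():
                bad_pairs.append((gm.samples[i], gm.samples[j]))
                continue
            ibs = np.mean((2.0 - np.abs(g[ok, i] - g[ok, j])) / 2.0)
            d[i, j] = d[j, i] = 1.0 - ibs
    if bad_pairs:
        raise ValueError(f"sample pairs share no non-missing sites: "
                         f"{bad_pairs}")
    return DistanceMatrix(list(gm.samples), d)


def rna_divergence(gm: GenotypeMatrix, min_depth: int = 3,
                   alt_threshold: float = 0.2) -> DistanceMatrix:
    """Presence/absence divergence between cells from variant read counts.

    For each cell and site, the variant is present iff
    total >= ``min_depth`` and alt / total >= ``alt_threshold``.
    divergence(i, j) = fraction of sites callable (depth >= min_depth) in
    BOTH cells at which presence differs.  Pairs with no co-callable site
    are an error listing the offending pairs.
    """
    if not gm.has_reads:
        raise ValueError("rna_divergence requires alt/total read counts")
    tot = gm.total_reads
    alt = gm.alt_reads
    callable_ = tot >= min_depth
    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(tot > 0, alt / np.maximum(tot, 1), 0.0)
    present = callable_ & (vaf >= alt_threshold)
    ns = len(gm.samples)
    d = np.zeros((ns, ns))
    bad_pairs = []
    for i in range(ns):
        for j in range(i + 1, ns):
            ok = callable_[:, i] & callable_[:, j]
            if not ok.any():
                bad_pairs.append((gm.samples[i], gm.samples[j]))
                continue
            d[i, j] = d[j, i] = float(
                np.mean(present[ok, i] != present[ok, j]))
    if bad_pairs:
        raise ValueError(
            f"cell pairs share no site at depth >= {min_depth}: {bad_pairs}")
    return DistanceMatrix(list(gm.samples), d)


def build_snv_tree(dm: DistanceMatrix, linkage: str = "ward") -> Dendrogram:
    """Cluster an SNV-channel distance matrix into a dendrogram.

    ``linkage`` 'ward' (the RNA-channel default, R's ward.D), 'average' or
    'complete' go through :func:`clonotangle.treecore.hclust`; 'upgma'
    builds the classical ultrametric tree (IBS-channel default in the
    pipeline).
    """
    if linkage == "upgma":
        return upgma(dm)
    return hclust(dm, linkage)
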