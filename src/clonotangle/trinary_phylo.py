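"""Transcript-derived phylogenies from trinarized expression.

Each sample's counts are discretized against that sample's own global
distribution: a gene scores -1 if its count is strictly below MED - SD,
+1 if strictly above MED + SD, else 0, where MED and SD are the median and
standard deviation of all counts in the sample.  Pairwise distances between
the resulting 3-state characters use a Jukes-Cantor-type maximum-likelihood
correction for a 3-letter alphabet, and the tree is built by UPGMA.

The procedure is scale-agnostic: raw counts, normalized counts and (log)
microarray intensities all pass through unchanged, since thresholds are
derived per sample from the values as given.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .treecore import Dendrogram, DistanceMatrix, upgma

__all__ = [
    "TrinaryMatrix",
    "trinarize",
    "three_state_distance",
    "build_trinary_tree",
]

D_MAX_DEFAULT = 5.0


@dataclass
class TrinaryMatrix:
    """Genes x samples matrix over {-1, 0, +1} plus per-sample thresholds.

    ``med`` and ``sd`` record each sample's median and standard deviation of
    the original values; ``sd_mode`` records which SD denominator was used
    (``sample`` = n-1, ``population`` = n).
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray  # int8, shape (n_genes, n_samples)
    med: np.ndarray
    sd: np.ndarray
    sd_mode: str = "sample"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("shape mismatch")
        if not np.isin(self.values, (-1, 0, 1)).all():
            raise ValueError("trinary values must be in {-1, 0, +1}")

    def state_counts(self) -> pd.DataFrame:
        """Per-sample tally of {-1, 0, +1}; rows sum to the gene count."""
        out = {s: [int((self.values[:, j] == v).sum()) for v in (-1, 0, 1)]
               for j, s in enumerate(self.samples)}
        return pd.DataFrame(out, index=[-1, 0, 1]).T


def trinarize(counts: pd.DataFrame, sd_mode: str = "sample") -> TrinaryMatrix:
    """Discretize a genes x samples count table to {-1, 0, +1} per sample.

    Thresholds are strict: a value exactly equal to MED - SD or MED + SD maps
    to 0.  ``sd_mode`` chooses the SD denominator: ``sample`` (n-1, default)
    or ``population`` (n).  A constant sample (SD = 0) leaves every value
    equal to the median at 0 and pushes everything else to +/-1; this is
    degenerate and triggers a warning.
    """
    if sd_mode not in ("sample", "population"):
        raise ValueError("sd_mode must be 'sample' or 'population'")
    x = counts.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 genes per sample")
    if (x < 0).any():
        raise ValueError("negative counts")
    ddof = 1 if sd_mode == "sample" else 0
    med = np.median(x, axis=0)
    sd = np.std(x, axis=0, ddof=ddof)
    if (sd == 0).any():
        bad = [counts.columns[j] for j in np.flatnonzero(sd == 0)]
        warnings.warn(
            f"constant sample(s) {bad}: SD = 0, trinarization degenerates "
            "to a median split", stacklevel=2)
    vals = np.zeros(x.shape, dtype=np.int8)
    vals[x < med - sd] = -1
    vals[x > med + sd] = 1
    return TrinaryMatrix(
        genes=list(map(str, counts.index)),
        samples=list(map(str, counts.columns)),
        values=vals, med=med, sd=sd, sd_mode=sd_mode)


def three_state_distance(tm: TrinaryMatrix, model: str = "ml3",
                         d_max: float = D_MAX_DEFAULT) -> DistanceMatrix:
    """Pairwise distances between samples from their 3-state characters.

    ``ml3`` (default) is the maximum-likelihood distance under a symmetric
    3-state substitution model: with p the proportion of genes whose states
    differ, d = -(2/3) ln(1 - (3/2) p), capped at ``d_max`` when p >= 2/3
    (where the log diverges).  ``p`` gives the uncorrected p-distance.
    """
    if model not in ("ml3", "p"):
        raise ValueError("model must be 'ml3' or 'p'")
    v = tm.values
    n_genes = v.shape[0]
    if n_genes < 1:
        raise ValueError("need at least 1 gene")
    ns = len(tm.samples)
    d = np.zeros((ns, ns))
    for i in range(ns):
        diff = (v[:, i + 1:] != v[:, [i]]).mean(axis=0)
        if model == "p":
            vals = diff
        else:
            vals = np.where(
                diff < 2.0 / 3.0,
                -(2.0 / 3.0) * np.log(np.maximum(1.0 - 1.5 * diff, 1e-300)),
                d_max)
            vals = np.minimum(vals, d_max)
        d[i, i + 1:] = vals
        d[i + 1:, i] = vals
    return DistanceMatrix(list(tm.samples), d)


def build_trinary_tree(counts: pd.DataFrame, sd_mode: str = "sample",
                       model: str = "ml3",
                       d_max: float = D_MAX_DEFAULT) -> Dendrogram:
    """Full transcript channel: trinarize -> 3-state ML distance -> UPGMA."""
    return upgma(three_state_distance(trinarize(counts, sd_mode),
                                      model=model, d_max=d_max))
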