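"""Expression-inferred copy-number profiling and CNV-channel clustering.

``infer_cnv_profile`` is the moving-average core of expression-based CNV
inference: after filtering lowly expressed genes and normalizing library
sizes, each gene's log expression is centred on a reference mean and
smoothed along the chromosome, so that contiguous dosage changes emerge as
shifted blocks while gene-level transcriptional noise averages out.  No
HMM state calling is performed; the smoothed, denoised score profile itself
is the inferred-CNV signal handed to clustering.

The module also rasterizes DNA copy-number segments onto fixed-width bins
(``gcnv_tree``) and pseudo-bulks spatial spot counts into per-section
columns (``pseudobulk``), so that the genomic and transcriptomic CNV
channels both end in the same ward/Euclidean clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .treecore import Dendrogram, DistanceMatrix, hclust

__all__ = [
    "ICNVProfile",
    "pseudobulk",
    "infer_cnv_profile",
    "build_icnv_tree",
    "gcnv_tree",
]


@dataclass
class ICNVProfile:
    """Smoothed relative-CN scores, genes (genomically ordered) x samples."""

    genes: list[str]
    chrom: np.ndarray      # per retained gene
    start: np.ndarray
    samples: list[str]
    scores: np.ndarray     # (n_genes, n_samples)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.genes), len(self.samples)):
            raise ValueError("score shape mismatch")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite scores")
        order = np.lexsort((self.start, self.chrom))
        if not np.array_equal(order, np.arange(len(self.genes))):
            raise ValueError("genes not sorted by (chrom, start)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.genes,
                            columns=self.samples)


def pseudobulk(counts: pd.DataFrame,
               section_of: dict[str, str] | pd.Series) -> pd.DataFrame:
    """Sum spot columns into one column per section.

    ``section_of`` maps every spot (column of ``counts``) to its section
    name; output columns are the sections in first-appearance order.
    """
    section_of = dict(section_of)
    missing = [c for c in counts.columns if c not in section_of]
    if missing:
        raise ValueError(f"spots without a section assignment: {missing}")
    sections: list[str] = []
    for c in counts.columns:
        s = section_of[c]
        if s not in sections:
            sections.append(s)
    out = {s: counts.loc[:, [c for c in counts.columns
                             if section_of[c] == s]].sum(axis=1)
           for s in sections}
    return pd.DataFrame(out, index=counts.index)[sections]


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average down axis 0, window truncated at the ends."""
    n = x.shape[0]
    half = window // 2
    csum = np.vstack([np.zeros((1, x.shape[1])), np.cumsum(x, axis=0)])
    out = np.empty_like(x)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def infer_cnv_profile(counts: pd.DataFrame, annotation: pd.DataFrame,
                      reference_labels: list[str] | None = None,
                      cutoff: float = 0.1, window: int = 101,
                      cap_sd: float = 3.0,
                      denoise_sd: float = 1.0) -> ICNVProfile:
    """Infer a smoothed relative-CN score profile from expression counts.

    Stages, in order:

    1. drop genes with mean count < ``cutoff`` across samples;
    2. library-size normalize each sample to the median library size, then
       log2(x + 1);
    3. subtract the per-gene reference mean — the designated normal samples
       if ``reference_labels`` is given, else the mean over all samples;
    4. clamp values to +/- ``cap_sd`` x the global SD of the centred matrix;
    5. centred moving average of ``window`` genes within each chromosome
       (window truncated at chromosome ends);
    6. subtract each sample's median score;
    7. denoise: zero every value with \\|v\\| < ``denoise_sd`` x residual SD
       (the SD of the stage-6 matrix).

    ``annotation`` needs columns gene/chrom/start (end optional) covering
    every retained gene; genes are processed in (chrom, start) order.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    ann = annotation.set_index("gene") if "gene" in annotation.columns \
        else annotation
    keep = counts.mean(axis=1) >= cutoff
    counts = counts.loc[keep]
    if counts.shape[0] == 0:
        raise ValueError(f"no genes pass mean-count cutoff {cutoff}")
    missing = [g for g in counts.index if g not in ann.index]
    if missing:
        raise ValueError(f"genes missing from annotation: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    ann = ann.loc[counts.index]
    order = np.lexsort((ann["start"].to_numpy(), ann["chrom"].to_numpy()))
    counts = counts.iloc[order]
    ann = ann.iloc[order]
    chrom = ann["chrom"].to_numpy()
    start = ann["start"].to_numpy()

    x = counts.to_numpy(dtype=float)
    libsize = x.sum(axis=0)
    if (libsize == 0).any():
        raise ValueError("sample with zero total counts")
    x = x * (np.median(libsize) / libsize)
    x = np.log2(x + 1.0)

    if reference_labels:
        ref_idx = [counts.columns.get_loc(s) for s in reference_labels]
        ref_mean = x[:, ref_idx].mean(axis=1, keepdims=True)
    else:
        ref_mean = x.mean(axis=1, keepdims=True)
    x = x - ref_mean

    sd = x.std()
    if sd > 0:
        x = np.clip(x, -cap_sd * sd, cap_sd * sd)

    smoothed = np.empty_like(x)
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        smoothed[idx] = _moving_average(x[idx], window)

    smoothed = smoothed - np.median(smoothed, axis=0, keepdims=True)

    resid_sd = smoothed.std()
    if resid_sd > 0:
        smoothed = np.where(np.abs(smoothed) < denoise_sd * resid_sd,
                            0.0, smoothed)
    # re-centre so the per-sample median stays 0 after thresholding
    smoothed = smoothed - np.median(smoothed, axis=0, keepdims=True)

    return ICNVProfile(list(counts.index), chrom, start,
                       list(map(str, counts.columns)), smoothed)


def _ward_euclidean(labels: list[str], vectors: np.ndarray) -> Dendrogram:
    d = squareform(pdist(vectors, metric="euclidean"))
    return hclust(DistanceMatrix(labels, d), "ward")


def build_icnv_tree(profile: ICNVProfile) -> Dendrogram:
    """Ward.D clustering of Euclidean distances between score vectors."""
    return _ward_euclidean(list(profile.samples), profile.scores.T)


def gcnv_tree(segments: dict[str, "pd.DataFrame"], bin_bp: int,
              chrom_lengths: dict[str, int] | None = None) -> Dendrogram:
    """Cluster genomic CN segment sets into a ward/Euclidean dendrogram.

    ``segments`` maps unit name -> segment table (chrom, start, end,
    total_cn; 1-based inclusive coordinates).  Segments are rasterized to
    ``bin_bp``-wide bins by the midpoint rule (a bin takes the CN of the
    segment containing its midpoint); bins uncovered in any unit are dropped
    pairwise-complete before Euclidean distances are taken.
    """
    from .cnv_bins import bin_segments

    if chrom_lengths is None:
        chrom_lengths = {}
        for df in segments.values():
            for _, row in df.iterrows():
                c = str(row["chrom"])
                chrom_lengths[c] = max(chrom_lengths.get(c, 0),
                                       int(row["end"]))
    units = list(segments)
    binned = [bin_segments(segments[u], bin_bp, chrom_lengths).cn
              for u in units]
    mat = np.vstack(binned)  # units x bins, NaN = uncovered
    keep = ~np.isnan(mat).any(axis=0)
    if not keep.any():
        raise ValueError("no bin covered in every unit")
    return _ward_euclidean(units, mat[:, keep])
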