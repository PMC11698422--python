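"""Fixed-width binning of copy-number segments, discordant-call matrices,
and bootstrap-supported clustering.

Segment tables (one per sample: chrom, start, end, total_cn with 1-based
inclusive coordinates) are rasterized onto bins of ``bin_bp`` base pairs
tiling each chromosome from position 1.  A bin takes the copy number of the
segment containing its midpoint; bins not covered by any segment are
missing.  Bin-level calls are then thresholded against a diploid baseline
(deletion when CN <= ``del_cn`` = 1.5, amplification when CN >= ``amp_cn``
= 2.5, thresholds inclusive), bins that are missing anywhere or called
identically in every sample are dropped, and the remaining discordant-call
matrix is clustered with bootstrap resampling of bins to attach support
values to the internal nodes.

An import shim (:func:`read_battenberg_subclones`) maps the column layout of
Battenberg ``*_subclones.txt`` files (chr, startpos, endpos, nMaj1_A,
nMin1_A) onto the simplified schema, taking total CN as nMaj1_A + nMin1_A
and ignoring subclonal second states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .treecore import Dendrogram, DistanceMatrix, hclust, upgma

__all__ = [
    "BinnedCN",
    "CNCallMatrix",
    "genome_bins",
    "bin_segments",
    "call_bins",
    "discordant_matrix",
    "bootstrap_tree",
    "read_battenberg_subclones",
]

DEL_CN = 1.5
AMP_CN = 2.5


@dataclass
class BinnedCN:
    """Per-sample binned copy numbers; NaN marks uncovered bins."""

    bins: pd.DataFrame  # columns chrom, start, end (1-based inclusive)
    cn: np.ndarray

    def __post_init__(self) -> None:
        self.cn = np.asarray(self.cn, dtype=float)
        if len(self.cn) != len(self.bins):
            raise ValueError("cn length != number of bins")


@dataclass
class CNCallMatrix:
    """Discordant bins x samples calls in {-1, 0, +1}; plus provenance."""

    bins: pd.DataFrame
    samples: list[str]
    calls: np.ndarray  # int8
    bin_bp: int
    del_cn: float = DEL_CN
    amp_cn: float = AMP_CN

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.bins), len(self.samples)):
            raise ValueError("call matrix shape mismatch")

    @property
    def n_discordant(self) -> int:
        return len(self.bins)

    def to_frame(self) -> pd.DataFrame:
        idx = [f"{c}:{s}-{e}" for c, s, e in
               zip(self.bins["chrom"], self.bins["start"], self.bins["end"])]
        return pd.DataFrame(self.calls, index=idx, columns=self.samples)


def genome_bins(chrom_lengths: dict[str, int], bin_bp: int) -> pd.DataFrame:
    """Tile every chromosome from position 1 in ``bin_bp`` steps.

    The terminal bin of a chromosome is truncated at its length, so the bin
    count per chromosome is ceil(length / bin_bp).
    """
    if bin_bp < 1:
        raise ValueError("bin_bp must be positive")
    rows = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(1, length + 1, bin_bp)
        ends = np.minimum(starts + bin_bp - 1, length)
        rows.append(pd.DataFrame(
            {"chrom": str(chrom), "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def bin_segments(segments: pd.DataFrame, bin_bp: int,
                 chrom_lengths: dict[str, int]) -> BinnedCN:
    """Rasterize one sample's segments onto fixed-width bins.

    ``segments`` has columns chrom, start, end, total_cn with 1-based
    inclusive coordinates (Battenberg convention).  Internally a bin
    [start, start + bin_bp) is half-open; its midpoint start + bin_bp / 2
    decides which segment's CN it inherits.  Bins whose midpoint falls in no
    segment are NaN.  Overlapping segments within the sample are an error.
    """
    bins = genome_bins(chrom_lengths, bin_bp)
    cn = np.full(len(bins), np.nan)
    for chrom, seg in segments.groupby("chrom", sort=False):
        chrom = str(chrom)
        length = chrom_lengths.get(chrom)
        if length is None:
            raise ValueError(f"segment chromosome {chrom!r} has no length")
        seg = seg.sort_values("start")
        s = seg["start"].to_numpy(dtype=np.int64)
        e = seg["end"].to_numpy(dtype=np.int64)
        if (s < 1).any() or (e > length).any() or (e < s).any():
            bad = seg[(s < 1) | (e > length) | (e < s)]
            raise ValueError(
                f"segment outside chr{chrom}:1-{length}: "
                f"{bad[['start', 'end']].to_dict('records')}")
        overlap = s[1:] <= e[:-1]
        if overlap.any():
            pairs = [(int(s[i]), int(e[i]), int(s[i + 1]), int(e[i + 1]))
                     for i in np.flatnonzero(overlap)]
            raise ValueError(
                f"overlapping segments on {chrom}: {pairs}")
        mask = (bins["chrom"] == chrom).to_numpy()
        idx = np.flatnonzero(mask)
        mid = bins.loc[mask, "start"].to_numpy(dtype=float) + bin_bp / 2.0
        # position of each midpoint among segment starts
        k = np.searchsorted(s, mid, side="right") - 1
        inside = (k >= 0) & (mid <= e[np.clip(k, 0, len(e) - 1)])
        vals = seg["total_cn"].to_numpy(dtype=float)[np.clip(k, 0, None)]
        cn[idx[inside]] = vals[inside]
    return BinnedCN(bins, cn)


def call_bins(binned: BinnedCN, del_cn: float = DEL_CN,
              amp_cn: float = AMP_CN) -> np.ndarray:
    """Threshold binned CN against a diploid baseline.

    Call -1 (deletion) when CN <= ``del_cn``, +1 (amplification) when
    CN >= ``amp_cn`` (both inclusive), 0 otherwise; NaN (uncovered)
    propagates as NaN.
    """
    cn = binned.cn
    calls = np.full(cn.shape, np.nan)
    ok = ~np.isnan(cn)
    calls[ok] = 0.0
    calls[ok & (cn <= del_cn)] = -1.0
    calls[ok & (cn >= amp_cn)] = 1.0
    return calls


def discordant_matrix(calls_per_sample: dict[str, np.ndarray],
                      bins: pd.DataFrame, bin_bp: int,
                      del_cn: float = DEL_CN,
                      amp_cn: float = AMP_CN) -> CNCallMatrix:
    """Merge per-sample call vectors and keep only informative bins.

    Drops every bin that is missing in any sample and every bin whose calls
    are identical across all samples, leaving the discordant-call matrix.
    An all-concordant input yields zero rows and a warning (downstream
    clustering refuses such a matrix).
    """
    samples = list(calls_per_sample)
    mat = np.vstack([calls_per_sample[s] for s in samples]).T  # bins x samp
    if len(mat) != len(bins):
        raise ValueError("call vectors do not match the bin table")
    covered = ~np.isnan(mat).any(axis=1)
    varying = ~(mat == mat[:, [0]]).all(axis=1)
    keep = covered & varying
    if not keep.any():
        warnings.warn("no discordant bins: all covered bins are called "
                      "identically in every sample", stacklevel=2)
    return CNCallMatrix(bins.loc[keep].reset_index(drop=True), samples,
                        mat[keep].astype(np.int8), bin_bp, del_cn, amp_cn)


def _cluster_calls(mat: np.ndarray, samples: list[str], linkage: str,
                   distance: str) -> Dendrogram:
    """Cluster sample columns of a calls matrix (rows = bins)."""
    x = mat.T.astype(float)  # samples x bins
    if distance == "correlation":
        if np.any(x.std(axis=1) == 0):
            warnings.warn("zero-variance sample column under correlation "
                          "distance; falling back to Euclidean",
                          stacklevel=3)
            d = squareform(pdist(x, metric="euclidean"))
        else:
            d = squareform(pdist(x, metric="correlation"))
            d = np.clip(d, 0.0, None)
    elif distance == "euclidean":
        d = squareform(pdist(x, metric="euclidean"))
    else:
        raise ValueError(f"unknown distance {distance!r}")
    # round away ~1e-16 correlation residue so exact ties stay ties and the
    # lexicographic tie-break stays meaningful
    d = np.round(d, 12)
    np.fill_diagonal(d, 0.0)
    dm = DistanceMatrix(samples, d)
    return upgma(dm) if linkage == "upgma" else hclust(dm, linkage)


def _splits(t: Dendrogram) -> set[frozenset]:
    out = set()

    def walk(node) -> frozenset:
        if node.is_leaf:
            return frozenset([node.label])
        below = frozenset().union(*(walk(c) for c in node.children))
        out.add(below)
        return below

    walk(t.root)
    out.discard(frozenset(t.leaf_order))  # the root clade is trivial
    return out


def bootstrap_tree(m: CNCallMatrix, n_boot: int = 1000,
                   linkage: str = "average",
                   distance: str = "correlation",
                   seed: int = 0) -> Dendrogram:
    """Cluster the discordant-call matrix with bin-resampling support.

    The base tree clusters samples on the full matrix (default: correlation
    distance, average linkage).  ``n_boot`` bootstrap replicates resample
    the bins (rows) with replacement at the original row count and
    re-cluster; each internal node's support is the proportion of replicate
    trees containing the same leaf set.  ``n_boot = 0`` returns the base
    tree without support values.
    """
    if m.n_discordant < 2:
        raise ValueError("need >= 2 discordant bins to cluster")
    if len(m.samples) < 3:
        raise ValueError("need >= 3 samples to cluster")
    base = _cluster_calls(m.calls, m.samples, linkage, distance)
    if n_boot == 0:
        return base
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {s: 0 for s in _splits(base)}
    nrow = m.n_discordant
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # replicate fallbacks are expected
        for _ in range(n_boot):
            rows = rng.integers(0, nrow, size=nrow)
            rep = _cluster_calls(m.calls[rows], m.samples, linkage, distance)
            for s in _splits(rep):
                if s in counts:
                    counts[s] += 1
    for node in base.internal_nodes():
        below = frozenset(leaf.label for leaf in node.leaves())
        if below in counts:
            node.support = counts[below] / n_boot
        else:  # root clade: trivially present in every replicate
            node.support = 1.0
    return base


def read_battenberg_subclones(path) -> pd.DataFrame:
    """Map a Battenberg subclones table onto the simplified segment schema.

    Keeps chr/startpos/endpos and takes total CN = nMaj1_A + nMin1_A (the
    dominant clonal state); subclonal second states are ignored.
    """
    df = pd.read_csv(path, sep="\t")
    need = {"chr", "startpos", "endpos", "nMaj1_A", "nMin1_A"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"not a Battenberg subclones table; missing "
                         f"columns {sorted(missing)}")
    return pd.DataFrame({
        "chrom": df["chr"].astype(str),
        "start": df["startpos"].astype(np.int64),
        "end": df["endpos"].astype(np.int64),
        "total_cn": (df["nMaj1_A"] + df["nMin1_A"]).astype(float),
    })
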