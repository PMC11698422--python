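"""Ground-truth clone trees and paired DNA+RNA observations.

The simulator produces the three data regimes the package's builders are
exercised on:

* ``sidr_like`` — single cells from three strongly distinct populations
  (10 / 7 / 13 cells) with paired per-cell DNA genotypes + copy-number
  segments and RNA counts + variant read counts;
* ``bulk_a21_like`` — 7 multi-region bulk tumour samples drawn from one
  clone tree, each an impure mixture of clone and normal tissue;
* ``st_12section_like`` — 12 spatial sections (4 tumour-bearing, 8
  near-normal), emitted as spot-level counts plus a spot-to-section map so
  pseudo-bulking is exercised, with matched per-section bulk DNA.

A :class:`CloneTree` is a rooted binary topology over clones whose branches
carry copy-number events (contiguous gene spans gaining or losing one copy)
and single-nucleotide variant events (infinite-sites: each site mutates on
at most one branch, to heterozygous).  States accumulate root -> leaf from a
diploid, variant-free root.  Genes live on 22 autosomes with deterministic
uniform spacing so segment and annotation tables can be emitted.

Expression is coupled to dosage linearly: a gene's expected count is
base_expr x (CN / 2) x library size.  With every noise parameter at zero
the observation step is fully deterministic (expected values, rounded),
which is the backbone configuration in which every downstream builder must
recover the population partition exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .snv_phylo import GenotypeMatrix, MISSING
from .treecore import Node

logger = logging.getLogger(__name__)

__all__ = [
    "CloneTree",
    "SampleDesign",
    "NoiseConfig",
    "SimBundle",
    "simulate_clone_tree",
    "observe_dna",
    "observe_rna",
    "preset",
    "make_discordant_segment_bundle",
    "derive_seed",
]

N_CHROM = 22
GENE_SPAN_BP = 10_000  # genes tile each chromosome back to back


def derive_seed(master: int, stream: str) -> int:
    """Stable per-stream seed below 2**31 derived from a master seed."""
    h = hashlib.sha256(f"{master}:{stream}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

def gene_annotation(g: int) -> pd.DataFrame:
    """Deterministic gene -> (chrom, start, end) table for ``g`` genes.

    Genes are split as evenly as possible over 22 autosomes (zero-padded
    names chr01..chr22 so lexicographic order equals genomic order) and laid
    back to back, each spanning ``GENE_SPAN_BP`` bases.
    """
    per = int(np.ceil(g / N_CHROM))
    rows = []
    for i in range(g):
        c = i // per
        j = i % per
        start = 1 + j * GENE_SPAN_BP
        rows.append((f"g{i:05d}", f"chr{c + 1:02d}", start,
                     start + GENE_SPAN_BP - 1))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


# ---------------------------------------------------------------------------
# Clone tree simulation
# ---------------------------------------------------------------------------

@dataclass
class CloneTree:
    """Ground truth: clone topology plus per-clone CN and genotype states."""

    clones: list[str]
    topology: Node                      # leaves labelled by clone name
    branch_events: dict[str, dict]      # branch id -> {'cnv': [...], 'snv': [...]}
    clone_cn: pd.DataFrame              # genes x clones, integer CN (root = 2)
    clone_geno: pd.DataFrame            # sites x clones, dosage (root = 0)
    gene_annotation: pd.DataFrame
    site_gene: np.ndarray               # host gene index of each site

    @property
    def genes(self) -> list[str]:
        return list(self.clone_cn.index)

    @property
    def sites(self) -> list[str]:
        return list(self.clone_geno.index)

    def topology_newick(self) -> str:
        def fmt(node: Node, parent_h: float) -> str:
            if node.is_leaf:
                return f"{node.label}:{parent_h - node.height:.10g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{parent_h - node.height:.10g}"
        r = self.topology
        return "(" + ",".join(fmt(c, r.height) for c in r.children) + ");"


def _random_topology(clones: list[str], rng: np.random.Generator) -> Node:
    """Random rooted binary topology; node heights = subtree leaf count."""
    def build(group: list[str]) -> Node:
        if len(group) == 1:
            return Node(0.0, None, group[0])
        k = int(rng.integers(1, len(group)))
        left, right = group[:k], group[k:]
        node = Node(float(len(group)), [build(left), build(right)])
        return node
    order = list(rng.permutation(clones))
    return build(order)


def simulate_clone_tree(m: int, g: int, s: int,
                        cnv_rate: float = 2.0,
                        snv_rate: float = 10.0,
                        cnv_span: tuple[int, int] = (20, 80),
                        min_events_per_branch: int = 0,
                        trunk_cnv_rate: float = 0.0,
                        trunk_snv_rate: float = 0.0,
                        seed: int = 0) -> CloneTree:
    """Simulate a clone tree with per-branch CNV and SNV events.

    Event counts per branch are Poisson with means ``cnv_rate`` /
    ``snv_rate``, floored at ``min_events_per_branch`` (presets use floor 1
    so that every clone is distinguishable in every channel).  A CNV event
    gains or loses one copy over a contiguous run of genes confined to one
    chromosome, with length uniform in ``cnv_span`` (clipped at the
    chromosome end).  SNV events follow infinite sites: each event picks an
    unused site and sets it heterozygous for all descendants.  Copy numbers
    are floored at 0 (a clip is logged).

    ``trunk_cnv_rate`` / ``trunk_snv_rate`` put events on the trunk — the
    edge from the diploid, variant-free root cell to the most recent common
    ancestor of all clones — so every clone shares them; tumour-vs-normal
    regimes need a substantial trunk for tumour units to be mutually closer
    than to normal tissue.
    """
    if m < 2:
        raise ValueError("need at least 2 clones")
    if g < 50 or s < 20:
        raise ValueError("need g >= 50 genes and s >= 20 sites")
    rng = np.random.default_rng(seed)
    clones = [f"clone{chr(65 + i)}" for i in range(m)]
    ann = gene_annotation(g)
    chrom_of = ann["chrom"].to_numpy()
    site_gene = rng.integers(0, g, size=s)

    topo = _random_topology(clones, rng)
    free_sites = list(range(s))
    branch_events: dict[str, dict] = {}
    cn = {}
    geno = {}

    def apply_branch(branch: str, cn_state: np.ndarray,
                     geno_state: np.ndarray, rate_cnv: float,
                     rate_snv: float) -> tuple[np.ndarray, np.ndarray]:
        n_cnv = max(int(rng.poisson(rate_cnv)), min_events_per_branch)
        n_snv = max(int(rng.poisson(rate_snv)), min_events_per_branch)
        child_cn = cn_state.copy()
        child_geno = geno_state.copy()
        cnv_events = []
        for _ in range(n_cnv):
            lo = int(rng.integers(0, g))
            span = int(rng.integers(cnv_span[0], cnv_span[1] + 1))
            chrom = chrom_of[lo]
            hi = lo
            while hi + 1 < g and hi + 1 - lo < span \
                    and chrom_of[hi + 1] == chrom:
                hi += 1
            delta = int(rng.choice([-1, 1]))
            child_cn[lo:hi + 1] += delta
            cnv_events.append({"chrom": str(chrom), "start_gene": lo,
                               "end_gene": hi, "delta": delta})
        clipped = int((child_cn < 0).sum())
        if clipped:
            logger.warning("branch %s: %d gene CN values clipped at 0",
                           branch, clipped)
            child_cn = np.maximum(child_cn, 0)
        snv_events = []
        for _ in range(n_snv):
            if not free_sites:
                break
            site = free_sites.pop(int(rng.integers(0, len(free_sites))))
            child_geno[site] = 1
            snv_events.append(site)
        branch_events[branch] = {"cnv": cnv_events, "snv": snv_events}
        return child_cn, child_geno

    def descend(node: Node, cn_state: np.ndarray, geno_state: np.ndarray,
                path: str) -> None:
        for ci, child in enumerate([] if node.is_leaf else node.children):
            branch = f"{path}.{ci}"
            child_cn, child_geno = apply_branch(
                branch, cn_state, geno_state, cnv_rate, snv_rate)
            if child.is_leaf:
                cn[child.label] = child_cn
                geno[child.label] = child_geno
            else:
                descend(child, child_cn, child_geno, branch)

    root_cn = np.full(g, 2, dtype=np.int64)
    root_geno = np.zeros(s, dtype=np.int64)
    if trunk_cnv_rate > 0 or trunk_snv_rate > 0:
        root_cn, root_geno = apply_branch(
            "trunk", root_cn, root_geno, trunk_cnv_rate, trunk_snv_rate)
    descend(topo, root_cn, root_geno, "root")
    genes = list(ann["gene"])
    sites = [f"s{i:05d}" for i in range(s)]
    return CloneTree(
        clones=clones, topology=topo, branch_events=branch_events,
        clone_cn=pd.DataFrame({c: cn[c] for c in clones}, index=genes),
        clone_geno=pd.DataFrame({c: geno[c] for c in clones}, index=sites),
        gene_annotation=ann, site_gene=site_gene)


# ---------------------------------------------------------------------------
# Observation models
# ---------------------------------------------------------------------------

@dataclass
class SampleDesign:
    """Which clones each observed unit (cell / sample / section) contains.

    ``assignment`` maps unit -> clone name (single_cell mode) or
    unit -> {clone: fraction} with fractions summing to 1 (bulk / spatial).
    ``purity`` is the tumour fraction of each unit; the remaining
    1 - purity is diploid, variant-free normal tissue.
    """

    mode: str
    assignment: dict[str, object]
    purity: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("single_cell", "bulk", "spatial"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for u in self.units:
            p = self.purity.setdefault(u, 1.0)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"purity of {u} outside [0, 1]")
            if self.mode != "single_cell":
                frac = self.assignment[u]
                tot = sum(frac.values())
                if abs(tot - 1.0) > 1e-9:
                    raise ValueError(f"clone fractions of {u} sum to {tot}")

    @property
    def units(self) -> list[str]:
        return list(self.assignment)


@dataclass
class NoiseConfig:
    """Noise parameters for the observation step.

    ado_rate
        allelic dropout: each heterozygous single-cell genotype collapses to
        a homozygote (0 or 2, equiprobable) with this probability.
    fp_rate
        probability a reference-homozygous site is spuriously called het.
    nb_dispersion
        negative-binomial overdispersion a in Var = mu + a mu^2 for RNA
        counts; 0 selects the deterministic expected-value path.
    libsize_log_sd
        SD of log-normal per-unit library size factors.
    depth_mean
        mean variant-site read depth at diploid dosage and unit library
        size 1.
    cn_jitter_sd
        SD of the integer-rounded Gaussian jitter added to per-cell CN
        profiles (DNA channel, single-cell mode).
    seed
        RNG seed for the observation step.

    With every rate at zero the observation is fully deterministic:
    counts = round(expected), depth = round(expected), alt = round(
    depth x allele fraction).
    """

    ado_rate: float = 0.0
    fp_rate: float = 0.0
    nb_dispersion: float = 0.0
    libsize_log_sd: float = 0.0
    depth_mean: float = 30.0
    cn_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ado_rate", "fp_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")

    @property
    def is_zero(self) -> bool:
        return (self.ado_rate == 0 and self.fp_rate == 0
                and self.nb_dispersion == 0 and self.libsize_log_sd == 0
                and self.cn_jitter_sd == 0)


def _mixture_states(ct: CloneTree, design: SampleDesign
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-unit expected CN (genes x units) and allele dosage (sites x units)."""
    g = len(ct.genes)
    s = len(ct.sites)
    units = design.units
    cn = np.empty((g, len(units)))
    dos = np.empty((s, len(units)))
    for j, u in enumerate(units):
        p = design.purity[u]
        if design.mode == "single_cell":
            frac = {design.assignment[u]: 1.0}
        else:
            frac = design.assignment[u]
        cn_t = np.zeros(g)
        dos_t = np.zeros(s)
        for clone, f in frac.items():
            cn_t += f * ct.clone_cn[clone].to_numpy()
            dos_t += f * ct.clone_geno[clone].to_numpy()
        cn[:, j] = p * cn_t + (1 - p) * 2.0
        dos[:, j] = p * dos_t
    return cn, dos


def _segments_from_cn(cn_vec: np.ndarray, ann: pd.DataFrame) -> pd.DataFrame:
    """Run-length encode a per-gene CN vector into a segment table."""
    chrom = ann["chrom"].to_numpy()
    start = ann["start"].to_numpy()
    end = ann["end"].to_numpy()
    vals = np.round(cn_vec, 6)
    rows = []
    i = 0
    n = len(vals)
    while i < n:
        j = i
        while j + 1 < n and chrom[j + 1] == chrom[i] \
                and vals[j + 1] == vals[i]:
            j += 1
        rows.append((chrom[i], int(start[i]), int(end[j]), float(vals[i])))
        i = j + 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "total_cn"])


def observe_dna(ct: CloneTree, design: SampleDesign, noise: NoiseConfig,
                bulk_dosage_threshold: float = 0.1
                ) -> tuple[GenotypeMatrix, dict[str, pd.DataFrame]]:
    """DNA channel: per-unit genotypes and copy-number segment tables.

    Single-cell mode applies allelic dropout (het -> random homozygote at
    ``ado_rate``), false positives (ref -> het at ``fp_rate``) and
    integer-rounded Gaussian CN jitter.  Bulk / spatial modes emit the
    purity-weighted mixture: real-valued segment CN, and a variant is
    recorded (dosage 1) wherever the expected mixture dosage is >=
    ``bulk_dosage_threshold``.
    """
    rng = np.random.default_rng(derive_seed(noise.seed, "dna"))
    units = design.units
    cn, dos = _mixture_states(ct, design)
    ann = ct.gene_annotation
    segments: dict[str, pd.DataFrame] = {}

    if design.mode == "single_cell":
        dosage = np.rint(dos).astype(np.int64)
        if noise.ado_rate > 0:
            het = dosage == 1
            drop = het & (rng.random(dosage.shape) < noise.ado_rate)
            dosage[drop] = rng.choice([0, 2], size=int(drop.sum()))
        if noise.fp_rate > 0:
            ref = dosage == 0
            fp = ref & (rng.random(dosage.shape) < noise.fp_rate)
            dosage[fp] = 1
        cn_obs = cn.copy()
        if noise.cn_jitter_sd > 0:
            cn_obs = np.maximum(
                np.rint(cn + rng.normal(0, noise.cn_jitter_sd, cn.shape)), 0)
        for j, u in enumerate(units):
            segments[u] = _segments_from_cn(cn_obs[:, j], ann)
    else:
        dosage = (dos >= bulk_dosage_threshold).astype(np.int64)
        for j, u in enumerate(units):
            segments[u] = _segments_from_cn(cn[:, j], ann)

    gm = GenotypeMatrix(sites=ct.sites, samples=units,
                        dosage=dosage.astype(np.int16))
    return gm, segments


def observe_rna(ct: CloneTree, design: SampleDesign, noise: NoiseConfig,
                base_expr: np.ndarray
                ) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """RNA channel: gene counts and variant-site read counts per unit.

    count[g, u] has mean base_expr[g] x (CN[g, u] / 2) x libsize[u], drawn
    negative-binomially with Var = mu + a mu^2 (a = ``nb_dispersion``).
    Each site's total reads are Poisson with mean ``depth_mean`` scaled by
    the host gene's relative dosage and the unit library size; alt reads
    are binomial in the unit's allele fraction, with single-cell allelic
    dropout collapsing het fractions to 0 or 1 at ``ado_rate``.  At an
    all-zero noise configuration every quantity is its rounded expectation.
    """
    rng = np.random.default_rng(derive_seed(noise.seed, "rna"))
    units = design.units
    base_expr = np.asarray(base_expr, dtype=float)
    if base_expr.shape != (len(ct.genes),):
        raise ValueError("base_expr length != gene count")
    cn, dos = _mixture_states(ct, design)

    if noise.libsize_log_sd > 0:
        libsize = np.exp(rng.normal(0.0, noise.libsize_log_sd,
                                    size=len(units)))
    else:
        libsize = np.ones(len(units))

    mu = base_expr[:, None] * (cn / 2.0) * libsize[None, :]
    if noise.nb_dispersion == 0:
        counts = np.rint(mu)
    else:
        a = noise.nb_dispersion
        nsize = 1.0 / a
        counts = rng.negative_binomial(
            nsize, nsize / (nsize + np.maximum(mu, 1e-12))).astype(float)
        counts[mu == 0] = 0
    counts_df = pd.DataFrame(counts.astype(np.int64), index=ct.genes,
                             columns=units)

    # variant reads at each site, scaled by host-gene dosage
    gene_cn = cn[ct.site_gene, :]                      # sites x units
    depth_mu = noise.depth_mean * (gene_cn / 2.0) * libsize[None, :]
    af = dos / 2.0
    if design.mode == "single_cell" and noise.ado_rate > 0:
        het = np.isclose(af, 0.5)
        drop = het & (rng.random(af.shape) < noise.ado_rate)
        af = np.where(drop, rng.choice([0.0, 1.0], size=af.shape), af)
    if noise.is_zero:
        total = np.rint(depth_mu).astype(np.int64)
        alt = np.rint(total * af).astype(np.int64)
    else:
        total = rng.poisson(depth_mu)
        alt = rng.binomial(total, np.clip(af, 0.0, 1.0))
    dosage = np.rint(dos).astype(np.int16)
    dosage[total == 0] = MISSING
    reads = GenotypeMatrix(sites=ct.sites, samples=units, dosage=dosage,
                           alt_reads=alt, total_reads=total)
    return counts_df, reads


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

@dataclass
class SimBundle:
    """Everything one simulated experiment produced, plus its manifest."""

    name: str
    clone_tree: CloneTree
    design_dna: SampleDesign
    design_rna: SampleDesign
    genotypes: GenotypeMatrix
    segments: dict[str, pd.DataFrame]
    counts: pd.DataFrame
    reads: GenotypeMatrix
    unit_group: dict[str, str]          # unit -> population / section label
    section_of: dict[str, str] | None   # spot -> section (spatial only)
    manifest: dict

    def write(self, outdir) -> None:
        """Emit the TSV / Newick / JSON bundle to a directory."""
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(out / "counts.tsv", sep="\t")
        self.clone_tree.gene_annotation.to_csv(
            out / "genes.tsv", sep="\t", index=False)
        self.genotypes.to_tsv(out / "genotypes.tsv")
        self.reads.to_tsv(out / "rna_genotypes.tsv")
        pd.DataFrame(self.reads.alt_reads, index=self.reads.sites,
                     columns=self.reads.samples).to_csv(
            out / "alt_reads.tsv", sep="\t")
        pd.DataFrame(self.reads.total_reads, index=self.reads.sites,
                     columns=self.reads.samples).to_csv(
            out / "total_reads.tsv", sep="\t")
        seg_dir = out / "segments"
        seg_dir.mkdir(exist_ok=True)
        for u, seg in self.segments.items():
            seg.to_csv(seg_dir / f"{u}.tsv", sep="\t", index=False)
        (out / "clone_tree.nwk").write_text(
            self.clone_tree.topology_newick() + "\n")
        pd.Series(self.unit_group, name="group").rename_axis("unit").to_csv(
            out / "groups.tsv", sep="\t")
        if self.section_of:
            pd.Series(self.section_of, name="section").rename_axis(
                "spot").to_csv(out / "sections.tsv", sep="\t")
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n")


def _base_expression(g: int, rng: np.random.Generator) -> np.ndarray:
    """Log-normal per-gene mean expression (median 6, sigma 0.6)."""
    return np.exp(rng.normal(np.log(6.0), 0.6, size=g))


def preset(name: str, seed: int = 0,
           noise: NoiseConfig | None = None) -> SimBundle:
    """Build one of the three study-regime bundles.

    ``sidr_like``: 30 single cells (10 / 7 / 13) from 3 clones with at
    least one CNV and SNV event per branch; ``bulk_a21_like``: 7 bulk
    samples, one dominant clone each, purity 0.75; ``st_12section_like``:
    12 sections x 15 spots, 4 sections with tumour fraction 0.6 and 8
    near-normal (0.02), plus matched per-section bulk DNA.  ``noise``
    defaults to the all-zero configuration.
    """
    if noise is None:
        noise = NoiseConfig(seed=derive_seed(seed, "noise"))
    rng = np.random.default_rng(derive_seed(seed, f"preset:{name}"))

    if name == "sidr_like":
        ct = simulate_clone_tree(
            m=3, g=2200, s=240, cnv_rate=3.0, snv_rate=40.0,
            cnv_span=(40, 120), min_events_per_branch=1,
            seed=derive_seed(seed, "tree"))
        pops = {"cloneA": ("popA", 10), "cloneB": ("popB", 7),
                "cloneC": ("popC", 13)}
        assignment: dict[str, object] = {}
        groups: dict[str, str] = {}
        for clone, (popname, ncells) in pops.items():
            for i in range(ncells):
                cell = f"{popname}_{i + 1:02d}"
                assignment[cell] = clone
                groups[cell] = popname
        design = SampleDesign("single_cell", assignment)
        gm, segs = observe_dna(ct, design, noise)
        base = _base_expression(len(ct.genes), rng)
        counts, reads = observe_rna(ct, design, noise, base)
        section_of = None
        design_dna = design_rna = design
    elif name == "bulk_a21_like":
        ct = simulate_clone_tree(
            m=7, g=2200, s=240, cnv_rate=2.0, snv_rate=25.0,
            cnv_span=(40, 120), min_events_per_branch=1,
            seed=derive_seed(seed, "tree"))
        assignment = {f"S{i + 1}": {c: 1.0} for i, c in enumerate(ct.clones)}
        purity = {u: 0.75 for u in assignment}
        design = SampleDesign("bulk", assignment, purity)
        groups = {u: clone for u, frac in assignment.items()
                  for clone in frac}
        gm, segs = observe_dna(ct, design, noise)
        base = _base_expression(len(ct.genes), rng)
        counts, reads = observe_rna(ct, design, noise, base)
        section_of = None
        design_dna = design_rna = design
    elif name == "st_12section_like":
        ct = simulate_clone_tree(
            m=3, g=2200, s=240, cnv_rate=3.0, snv_rate=30.0,
            cnv_span=(40, 120), min_events_per_branch=1,
            trunk_cnv_rate=12.0, trunk_snv_rate=60.0,
            seed=derive_seed(seed, "tree"))
        sections = [f"sec{i + 1:02d}" for i in range(12)]
        tumour = set(sections[:4])
        sec_frac: dict[str, dict[str, float]] = {}
        groups = {}
        for k, sec in enumerate(sections):
            if sec in tumour:
                # each tumour section dominated by one clone
                dom = ct.clones[k % len(ct.clones)]
                frac = {c: (0.6 if c == dom else 0.2) for c in ct.clones}
                purity_s = 0.6
                groups[sec] = "tumour"
            else:
                frac = {c: 1.0 / len(ct.clones) for c in ct.clones}
                purity_s = 0.02
                groups[sec] = "normal"
            sec_frac[sec] = frac
        design_dna = SampleDesign(
            "bulk", {s: sec_frac[s] for s in sections},
            {s: (0.6 if s in tumour else 0.02) for s in sections})
        # spot-level RNA with a spot -> section map
        n_spots = 15
        spot_assign: dict[str, object] = {}
        spot_purity: dict[str, float] = {}
        section_of = {}
        for sec in sections:
            for i in range(n_spots):
                spot = f"{sec}_spot{i + 1:02d}"
                spot_assign[spot] = sec_frac[sec]
                spot_purity[spot] = design_dna.purity[sec]
                section_of[spot] = sec
        design_rna = SampleDesign("spatial", spot_assign, spot_purity)
        gm, segs = observe_dna(ct, design_dna, noise)
        base = _base_expression(len(ct.genes), rng)
        counts, reads = observe_rna(ct, design_rna, noise, base)
    else:
        raise ValueError(f"unknown preset {name!r}")

    manifest = {
        "preset": name, "seed": seed, "noise": asdict(noise),
        "n_units_dna": len(design_dna.units),
        "n_units_rna": len(design_rna.units),
        "n_genes": len(ct.genes), "n_sites": len(ct.sites),
        "clones": ct.clones,
    }
    return SimBundle(name=name, clone_tree=ct, design_dna=design_dna,
                     design_rna=design_rna, genotypes=gm, segments=segs,
                     counts=counts, reads=reads, unit_group=groups,
                     section_of=section_of, manifest=manifest)


# ---------------------------------------------------------------------------
# Engineered discordant-bin fixture
# ---------------------------------------------------------------------------

def make_discordant_segment_bundle(
        n_samples: int = 12, n_discordant: int = 28, bin_bp: int = 1200,
        ) -> tuple[dict[str, pd.DataFrame], dict[str, int]]:
    """Segment tables for ``n_samples`` samples engineered so that exactly
    ``n_discordant`` bins are discordant after thresholded calling.

    Two equal groups of samples share a diploid genome except at
    ``n_discordant`` isolated bins: the bins alternate between being
    amplified (CN 4) privately in group 1 and privately in group 2, so
    every discordant bin separates the same two groups with opposite
    orientation (no two bin patterns are affinely identical, which keeps
    correlation distance informative under any bootstrap resample).  One
    further bin is amplified in *all* samples to exercise the shared-call
    drop.  Returns (segments per sample, chromosome lengths).
    """
    if n_samples % 2:
        raise ValueError("n_samples must be even")
    half = n_samples // 2
    # one chromosome long enough for the discordant bins plus padding
    n_bins = 2 * n_discordant + 10
    chrom_len = {"chr01": n_bins * bin_bp}
    samples = [f"R{i + 1:02d}" for i in range(n_samples)]
    segs: dict[str, pd.DataFrame] = {}
    # discordant bins sit at every other bin: indices 2, 4, 6, ...
    event_bins = [2 * (k + 1) for k in range(n_discordant)]
    shared_bin = 0  # amplified everywhere -> dropped as concordant
    for si, samp in enumerate(samples):
        group = 0 if si < half else 1
        cn = np.full(n_bins, 2.0)
        cn[shared_bin] = 4.0
        for k, b in enumerate(event_bins):
            if k % 2 == group:
                cn[b] = 4.0
        rows = []
        start = 1
        for b in range(n_bins):
            rows.append(("chr01", start, start + bin_bp - 1, cn[b]))
            start += bin_bp
        segs[samp] = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "total_cn"])
    return segs, chrom_len
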