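"""Experiment orchestration: simulate -> build channel trees -> compare.

One :func:`run_experiment` call takes an :class:`ExperimentConfig` (preset
name, seed, channel list, per-module overrides), simulates the data bundle,
builds every requested channel dendrogram, compares every channel pair by
tanglegram entanglement (pre and post two-sided untangling), scores each
channel's partition against the ground-truth grouping by adjusted Rand
index, and writes trees, matrices, figures and a JSON report into one run
directory.  Everything is deterministic given the seed: each module draws
from its own RNG stream derived from the master seed by stable hashing, so
adding a channel does not perturb the others.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import icnv_lite, snv_phylo, synthetic_data, tangle, trinary_phylo
from .synthetic_data import NoiseConfig, SimBundle, derive_seed, preset
from .treecore import Dendrogram, write_newick

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "ConcordanceReport",
    "build_channel_trees",
    "run_experiment",
    "validate_inputs",
]

REPORT_SCHEMA_VERSION = 1
ALL_CHANNELS = ("gsnv", "isnv", "gcnv", "icnv", "trinary")

_KNOWN_KEYS = {"preset", "seed", "channels", "outdir", "noise",
               "L", "untangle_rounds", "gcnv_bin_bp", "icnv", "trinary",
               "rna_divergence"}


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment run."""

    preset: str = "sidr_like"
    seed: int = 0
    channels: tuple[str, ...] = ALL_CHANNELS
    outdir: str | None = None
    noise: dict = field(default_factory=dict)
    L: float = tangle.DEFAULT_L
    untangle_rounds: int = 25
    gcnv_bin_bp: int = 50_000
    icnv: dict = field(default_factory=dict)       # infer_cnv_profile kwargs
    trinary: dict = field(default_factory=dict)    # trinarize / distance kwargs
    rna_divergence: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "channels" in d:
            d["channels"] = tuple(d["channels"])
        return cls(**d)

    def resolve_channels(self) -> list[str]:
        bad = [c for c in self.channels if c not in ALL_CHANNELS]
        if bad:
            raise ValueError(f"unknown channels {bad}; choose from "
                             f"{ALL_CHANNELS}")
        return list(self.channels)


@dataclass
class ConcordanceReport:
    """Per-channel-pair entanglement and per-channel partition agreement."""

    schema_version: int
    config: dict
    channels: list[str]
    ari: dict[str, float]
    entanglement: dict[str, dict]       # "chan1-chan2" -> pre/post/rounds
    tree_files: dict[str, str]
    resolved_defaults: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"


def build_channel_trees(bundle: SimBundle, cfg: ExperimentConfig
                        ) -> dict[str, Dendrogram]:
    """Build the requested channel dendrograms from a simulated bundle.

    gsnv: identity-by-state on DNA genotypes, UPGMA.
    isnv: depth-gated presence divergence on RNA variant reads, ward.D.
    gcnv: segment rasterization, ward / Euclidean.
    icnv: expression-inferred CN profile, ward / Euclidean (spatial bundles
    are pseudo-bulked into sections first).
    trinary: MED +/- SD trinarization, 3-state ML distance, UPGMA.
    """
    trees: dict[str, Dendrogram] = {}
    counts = bundle.counts
    if bundle.section_of is not None:
        counts = icnv_lite.pseudobulk(counts, bundle.section_of)
    for chan in cfg.resolve_channels():
        if chan == "gsnv":
            dm = snv_phylo.ibs_matrix(bundle.genotypes)
            trees[chan] = snv_phylo.build_snv_tree(dm, "upgma")
        elif chan == "isnv":
            dm = snv_phylo.rna_divergence(bundle.reads,
                                          **cfg.rna_divergence)
            trees[chan] = snv_phylo.build_snv_tree(dm, "ward")
        elif chan == "gcnv":
            trees[chan] = icnv_lite.gcnv_tree(bundle.segments,
                                              cfg.gcnv_bin_bp)
        elif chan == "icnv":
            ann = bundle.clone_tree.gene_annotation
            profile = icnv_lite.infer_cnv_profile(counts, ann, **cfg.icnv)
            trees[chan] = icnv_lite.build_icnv_tree(profile)
        elif chan == "trinary":
            trees[chan] = trinary_phylo.build_trinary_tree(
                counts, **cfg.trinary)
    return trees


def _true_groups(bundle: SimBundle, units: list[str]) -> list[str]:
    out = []
    for u in units:
        if u in bundle.unit_group:
            out.append(bundle.unit_group[u])
        elif bundle.section_of and u in bundle.section_of:
            out.append(bundle.unit_group[bundle.section_of[u]])
        else:
            raise KeyError(f"no ground-truth group for unit {u}")
    return out


def run_experiment(cfg: ExperimentConfig) -> ConcordanceReport:
    """Simulate, build, compare, and (optionally) write a run directory."""
    noise = NoiseConfig(**{**cfg.noise,
                           "seed": derive_seed(cfg.seed, "noise")})
    bundle = preset(cfg.preset, seed=cfg.seed, noise=noise)
    trees = build_channel_trees(bundle, cfg)

    truth_cache: dict[str, list[str]] = {}
    ari: dict[str, float] = {}
    for chan, tree in trees.items():
        units = tree.leaf_order
        truth = _true_groups(bundle, units)
        k = len(set(truth))
        cut = tree.cut(k)
        ari[chan] = float(adjusted_rand_score(
            truth, [cut[u] for u in units]))

    ent: dict[str, dict] = {}
    for a, b in itertools.combinations(trees, 2):
        ta, tb = trees[a], trees[b]
        if not (ta.labels & tb.labels):
            logger.info("channels %s and %s share no labels; skipped", a, b)
            continue
        pre = tangle.entanglement(ta, tb, cfg.L)
        ua, ub, rounds = tangle.untangle_step2side(
            ta, tb, cfg.L, max_rounds=cfg.untangle_rounds)
        ent[f"{a}-{b}"] = {
            "pre": pre,
            "post": tangle.entanglement(ua, ub, cfg.L),
            "rounds": rounds,
            "shared_labels": len(ta.labels & tb.labels),
        }

    resolved = {
        "L": cfg.L, "gcnv_bin_bp": cfg.gcnv_bin_bp,
        "icnv_window": cfg.icnv.get("window", 101),
        "icnv_cutoff": cfg.icnv.get("cutoff", 0.1),
        "trinary_sd_mode": cfg.trinary.get("sd_mode", "sample"),
        "trinary_model": cfg.trinary.get("model", "ml3"),
        "rna_min_depth": cfg.rna_divergence.get("min_depth", 3),
        "rna_alt_threshold": cfg.rna_divergence.get("alt_threshold", 0.2),
        "noise": asdict(noise),
    }

    tree_files: dict[str, str] = {}
    if cfg.outdir is not None:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        bundle.write(out / "sim")
        for chan, tree in trees.items():
            p = out / f"tree_{chan}.nwk"
            p.write_text(write_newick(tree) + "\n")
            tree_files[chan] = str(p)
        for pair in ent:
            a, b = pair.split("-")
            tg = tangle.Tanglegram(trees[a], trees[b], cfg.L).untangled(
                cfg.untangle_rounds)
            groups = {u: bundle.unit_group.get(u, "")
                      for u in tg.shared_labels}
            tangle.render_tanglegram(tg, str(out / f"tangle_{pair}.svg"),
                                     groups=groups)

    report = ConcordanceReport(
        schema_version=REPORT_SCHEMA_VERSION,
        config={"preset": cfg.preset, "seed": cfg.seed,
                "channels": list(cfg.channels)},
        channels=list(trees), ari=ari, entanglement=ent,
        tree_files=tree_files, resolved_defaults=resolved)
    if cfg.outdir is not None:
        (Path(cfg.outdir) / "report.json").write_text(report.to_json())
    return report


def validate_inputs(paths: dict[str, str]) -> list[str]:
    """Schema-check a bundle of input files; returns diagnostics (empty =
    well-formed).

    Recognized keys: ``counts`` (genes x samples TSV), ``annotation``
    (gene/chrom/start/end TSV), ``genotypes`` (sites x samples TSV),
    ``segments`` (segment TSV or directory of them), ``tree`` (Newick),
    ``chrom_lengths`` (chrom/length TSV).
    """
    import pandas as pd
    from .treecore import NewickParseError, read_newick

    diags: list[str] = []

    counts = ann = None
    if "counts" in paths:
        counts = pd.read_csv(paths["counts"], sep="\t", index_col=0)
        if (counts.to_numpy() < 0).any():
            rows = np.flatnonzero((counts.to_numpy() < 0).any(axis=1))
            diags.append(f"counts: negative values at data line(s) "
                         f"{[int(r) + 2 for r in rows[:5]]}")
    if "annotation" in paths:
        ann = pd.read_csv(paths["annotation"], sep="\t")
        need = {"gene", "chrom", "start", "end"}
        if not need <= set(ann.columns):
            diags.append(f"annotation: missing columns "
                         f"{sorted(need - set(ann.columns))}")
        elif counts is not None:
            missing = [g for g in counts.index
                       if g not in set(ann["gene"])]
            if missing:
                diags.append(
                    f"annotation: counted gene(s) not annotated: "
                    f"{missing[:5]}")
    if "genotypes" in paths:
        gt = pd.read_csv(paths["genotypes"], sep="\t", index_col=0)
        bad = ~gt.isin((0, 1, 2, -1)).to_numpy()
        if bad.any():
            rows = np.flatnonzero(bad.any(axis=1))
            diags.append(f"genotypes: values outside {{0,1,2,-1}} at data "
                         f"line(s) {[int(r) + 2 for r in rows[:5]]}")
    if "segments" in paths:
        p = Path(paths["segments"])
        files = sorted(p.glob("*.tsv")) if p.is_dir() else [p]
        lengths = None
        if "chrom_lengths" in paths:
            cl = pd.read_csv(paths["chrom_lengths"], sep="\t")
            lengths = dict(zip(cl.iloc[:, 0].astype(str), cl.iloc[:, 1]))
        for f in files:
            seg = pd.read_csv(f, sep="\t")
            need = {"chrom", "start", "end", "total_cn"}
            if not need <= set(seg.columns):
                diags.append(f"{f.name}: missing columns "
                             f"{sorted(need - set(seg.columns))}")
                continue
            for i, row in seg.iterrows():
                if row["end"] < row["start"]:
                    diags.append(f"{f.name} line {i + 2}: end < start "
                                 f"({row['chrom']}:{row['start']}-"
                                 f"{row['end']})")
                if lengths is not None:
                    lim = lengths.get(str(row["chrom"]))
                    if lim is not None and row["end"] > lim:
                        diags.append(
                            f"{f.name} line {i + 2}: segment "
                            f"{row['chrom']}:{row['start']}-{row['end']} "
                            f"exceeds chromosome length {lim}")
    if "tree" in paths:
        try:
            read_newick(Path(paths["tree"]).read_text())
        except NewickParseError as exc:
            diags.append(f"tree: {exc}")
    return diags
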