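import numpy as np
import pandas as pd
import pytest

from clonotangle.synthetic_data import (CloneTree, NoiseConfig, SampleDesign,
                                        derive_seed, gene_annotation,
                                        observe_dna, observe_rna, preset,
                                        simulate_clone_tree)


class TestCloneTreeSimulation:
    def test_zero_rates_give_diploid_identical_clones(self):
        ct = simulate_clone_tree(m=2, g=60, s=25, cnv_rate=0.0,
                                 snv_rate=0.0, seed=0)
        assert (ct.clone_cn.to_numpy() == 2).all()
        assert (ct.clone_geno.to_numpy() == 0).all()

    def test_deterministic_under_seed(self):
        kw = dict(m=4, g=100, s=40, cnv_rate=2.0, snv_rate=8.0, seed=11)
        a, b = simulate_clone_tree(**kw), simulate_clone_tree(**kw)
        assert a.clone_cn.equals(b.clone_cn)
        assert a.clone_geno.equals(b.clone_geno)
        assert a.branch_events == b.branch_events

    def test_events_accumulate_root_to_leaf(self):
        """A branch gain of +1 raises exactly that gene span in the clones
        below it and nothing else."""
        ct = simulate_clone_tree(m=3, g=120, s=30, cnv_rate=1.0,
                                 snv_rate=5.0, min_events_per_branch=1,
                                 seed=5)
        recon = {c: np.full(120, 2, dtype=int) for c in ct.clones}

        def walk(node, path):
            ev = ct.branch_events.get(path)
            deltas = np.zeros(120, dtype=int)
            if ev:
                for e in ev["cnv"]:
                    deltas[e["start_gene"]:e["end_gene"] + 1] += e["delta"]
            if node.is_leaf:
                return {node.label: deltas}
            out = {}
            for ci, child in enumerate(node.children):
                for leaf, d in walk(child, f"{path}.{ci}").items():
                    out[leaf] = d + deltas
            return out

        trunk = np.zeros(120, dtype=int)
        if "trunk" in ct.branch_events:
            for e in ct.branch_events["trunk"]["cnv"]:
                trunk[e["start_gene"]:e["end_gene"] + 1] += e["delta"]
        acc = {}
        for ci, child in enumerate(ct.topology.children):
            acc.update(walk(child, f"root.{ci}"))
        for clone in ct.clones:
            expect = np.maximum(2 + trunk + acc[clone], 0)
            assert (ct.clone_cn[clone].to_numpy() == expect).all()

    def test_cnv_events_stay_on_one_chromosome(self):
        ct = simulate_clone_tree(m=4, g=220, s=30, cnv_rate=4.0,
                                 snv_rate=5.0, cnv_span=(30, 60), seed=9)
        chrom = ct.gene_annotation["chrom"].to_numpy()
        for ev in ct.branch_events.values():
            for e in ev["cnv"]:
                assert chrom[e["start_gene"]] == chrom[e["end_gene"]]

    def test_minimum_sizes_enforced(self):
        with pytest.raises(ValueError):
            simulate_clone_tree(m=1, g=100, s=30)
        with pytest.raises(ValueError):
            simulate_clone_tree(m=2, g=10, s=30)

    def test_annotation_orders_by_chrom_then_start(self):
        ann = gene_annotation(100)
        assert (ann.sort_values(["chrom", "start"]).index
                == ann.index).all()


class TestObserveDna:
    def _setup(self, seed=0):
        ct = simulate_clone_tree(m=3, g=100, s=1000, cnv_rate=1.0,
                                 snv_rate=300.0, min_events_per_branch=1,
                                 seed=seed)
        design = SampleDesign("single_cell",
                              {f"c{i}": ct.clones[i % 3] for i in range(6)})
        return ct, design

    def test_noise_free_cells_copy_clone_genotypes(self):
        ct, design = self._setup()
        gm, segs = observe_dna(ct, design, NoiseConfig())
        for j, u in enumerate(design.units):
            clone = design.assignment[u]
            assert (gm.dosage[:, j]
                    == ct.clone_geno[clone].to_numpy()).all()

    def test_zero_purity_bulk_is_diploid_and_variant_free(self):
        ct, _ = self._setup()
        design = SampleDesign(
            "bulk", {"b1": {c: 1 / 3 for c in ct.clones}}, {"b1": 0.0})
        gm, segs = observe_dna(ct, design, NoiseConfig())
        assert (gm.dosage == 0).all()
        assert (segs["b1"]["total_cn"] == 2.0).all()

    def test_ado_fraction_concentrates_at_rate(self):
        """Observed het dropout within 3 binomial SDs of ado_rate."""
        ct, design = self._setup(seed=3)
        noise = NoiseConfig(ado_rate=0.2, seed=3)
        gm, _ = observe_dna(ct, design, noise)
        het = ct.clone_geno.to_numpy()
        n_het = dropped = 0
        for j, u in enumerate(design.units):
            truth = ct.clone_geno[design.assignment[u]].to_numpy()
            mask = truth == 1
            n_het += int(mask.sum())
            dropped += int((gm.dosage[mask, j] != 1).sum())
        p = dropped / n_het
        sd = np.sqrt(0.2 * 0.8 / n_het)
        assert abs(p - 0.2) < 3 * sd

    def test_segments_tile_back_to_clone_cn(self):
        ct, design = self._setup()
        _, segs = observe_dna(ct, design, NoiseConfig())
        ann = ct.gene_annotation
        for u in design.units:
            clone = design.assignment[u]
            seg = segs[u]
            cn_back = np.empty(100)
            for _, row in seg.iterrows():
                sel = ((ann["chrom"] == row["chrom"])
                       & (ann["start"] >= row["start"])
                       & (ann["end"] <= row["end"])).to_numpy()
                cn_back[sel] = row["total_cn"]
            assert (cn_back == ct.clone_cn[clone].to_numpy()).all()


class TestObserveRna:
    def test_zero_base_expression_gives_all_zero_counts(self):
        ct = simulate_clone_tree(m=2, g=60, s=25, seed=0)
        design = SampleDesign("single_cell", {"c0": "cloneA"})
        counts, _ = observe_rna(ct, design, NoiseConfig(),
                                np.zeros(60))
        assert (counts.to_numpy() == 0).all()

    def test_counts_concentrate_on_base_expression(self):
        """Diploid, mild dispersion, 200 cells: means within 3 SE."""
        ct = simulate_clone_tree(m=2, g=60, s=25, cnv_rate=0.0,
                                 snv_rate=0.0, seed=1)
        design = SampleDesign("single_cell",
                              {f"c{i}": "cloneA" for i in range(200)})
        base = np.full(60, 50.0)
        a = 0.05
        counts, _ = observe_rna(ct, design,
                                NoiseConfig(nb_dispersion=a, seed=2), base)
        mean = counts.mean(axis=1).to_numpy()
        var_per = 50.0 + a * 50.0**2
        se = np.sqrt(var_per / 200)
        assert (np.abs(mean - 50.0) < 3 * se + 0.5).all()

    def test_cn4_vs_cn2_mean_ratio_near_two(self):
        ct = simulate_clone_tree(m=2, g=60, s=25, cnv_rate=0.0,
                                 snv_rate=0.0, seed=1)
        ct.clone_cn["cloneB"] = 4  # whole-genome doubling in one clone
        design = SampleDesign(
            "single_cell",
            {f"a{i}": "cloneA" for i in range(100)}
            | {f"b{i}": "cloneB" for i in range(100)})
        base = np.full(60, 40.0)
        counts, _ = observe_rna(ct, design,
                                NoiseConfig(nb_dispersion=0.05, seed=4),
                                base)
        ma = counts[[f"a{i}" for i in range(100)]].mean(axis=1)
        mb = counts[[f"b{i}" for i in range(100)]].mean(axis=1)
        ratio = (mb / ma).to_numpy()
        assert abs(ratio.mean() - 2.0) < 3 * ratio.std() / np.sqrt(60)

    def test_dosage_expression_slope_near_one(self):
        """log mean expression regressed on log(CN/2): slope in [0.8, 1.2]."""
        ct = simulate_clone_tree(m=2, g=200, s=25, cnv_rate=6.0,
                                 snv_rate=1.0, cnv_span=(20, 60), seed=6)
        design = SampleDesign("single_cell",
                              {f"c{i}": "cloneB" for i in range(200)})
        base = np.full(200, 30.0)
        counts, _ = observe_rna(
            ct, design, NoiseConfig(nb_dispersion=0.1, seed=7), base)
        cn = ct.clone_cn["cloneB"].to_numpy()
        ok = cn > 0
        x = np.log(cn[ok] / 2.0)
        y = np.log(counts.mean(axis=1).to_numpy()[ok])
        slope = np.polyfit(x, y, 1)[0]
        assert 0.8 <= slope <= 1.2


class TestPresets:
    def test_sidr_like_cell_counts(self):
        bundle = preset("sidr_like", seed=1)
        assert len(bundle.design_rna.units) == 30
        sizes = pd.Series(bundle.unit_group).value_counts()
        assert sorted(sizes) == [7, 10, 13]

    def test_bulk_preset_has_seven_units(self):
        bundle = preset("bulk_a21_like", seed=1)
        assert len(bundle.design_dna.units) == 7

    def test_spatial_preset_pseudobulks_to_twelve(self):
        bundle = preset("st_12section_like", seed=1)
        assert len(set(bundle.section_of.values())) == 12
        assert len(bundle.design_dna.units) == 12
        tallies = pd.Series(bundle.unit_group).value_counts()
        assert tallies["tumour"] == 4 and tallies["normal"] == 8

    def test_bundle_round_trips_to_disk(self, tmp_path):
        bundle = preset("sidr_like", seed=1)
        bundle.write(tmp_path / "out")
        counts = pd.read_csv(tmp_path / "out" / "counts.tsv", sep="\t",
                             index_col=0)
        assert counts.shape == bundle.counts.shape
        assert (tmp_path / "out" / "manifest.json").exists()
        assert (tmp_path / "out" / "clone_tree.nwk").read_text().count(
            "clone") == 3

    def test_derive_seed_stable_and_bounded(self):
        assert derive_seed(1, "x") == derive_seed(1, "x")
        assert derive_seed(1, "x") != derive_seed(2, "x")
        assert 0 <= derive_seed(12345, "rna") < 2**31


class TestNoiseConfigValidation:
    def test_rates_bounded(self):
        with pytest.raises(ValueError):
            NoiseConfig(ado_rate=1.0)
        with pytest.raises(ValueError):
            NoiseConfig(nb_dispersion=-0.1)

    def test_fraction_vectors_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            SampleDesign("bulk", {"b": {"cloneA": 0.5, "cloneB": 0.2}})
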