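"""Generator contracts: determinism, coverage, exact planted counts,
round-trips through the format readers."""

import numpy as np
import pytest

from crosstf import formats, synteny
from crosstf.synthgen import (
    SynthConfig,
    build_synteny,
    emit_dataset,
    generate,
    plant_peaks,
)

from conftest import small_config


class TestBuildSynteny:
    def test_coverage_within_tolerance(self):
        cfg = small_config(seed=1)
        scaffold = build_synteny(cfg)
        aligned = sum(size for _, _, size, _, _ in scaffold.aligned_blocks)
        total = sum(s for _, s in cfg.source_chroms)
        assert abs(aligned / total - cfg.syntenic_fraction) <= 0.02

    def test_block_sequences_copied_verbatim(self):
        cfg = small_config(seed=2)
        scaffold = build_synteny(cfg)
        for sc, ss, size, dc, ds in scaffold.aligned_blocks[:10]:
            assert np.array_equal(
                scaffold.source_seqs[sc][ss : ss + size],
                scaffold.target_seqs[dc][ds : ds + size],
            )

    def test_identity_configuration(self):
        cfg = SynthConfig(
            seed=0,
            source_chroms=(("m", 200_000),),
            target_chroms=(("h", 200_000),),
            syntenic_fraction=1.0,
            n_blocks=1,
            peaks_per_factor=10,
            factors=("O",),
            sc_fraction=(0.5,),
            syntenic_peak_fraction=(1.0,),
            dst_only_peaks_per_factor=5,
            esc_only_peaks_per_factor=0,
            cobind_fraction=0.0,
            n_genes=10,
        )
        scaffold = build_synteny(cfg)
        (chain,) = scaffold.chains
        assert chain.t_start == 0 and chain.t_end == 200_000
        assert chain.blocks == ((200_000, 0, 0),)
        index = synteny.ChainIndex(scaffold.chains)
        m = synteny.map_interval(
            formats.GenomicInterval("m", 12345, 23456), index
        )
        assert (m.target.start, m.target.end) == (12345, 23456)

    def test_chain_determinism(self, tmp_path):
        cfg = small_config(seed=3)
        for i in (1, 2):
            scaffold = build_synteny(cfg)
            formats.write_chain(scaffold.chains, tmp_path / f"c{i}.chain")
        assert (tmp_path / "c1.chain").read_bytes() == (
            tmp_path / "c2.chain"
        ).read_bytes()

    def test_infeasible_config_raises(self):
        with pytest.raises(ValueError):
            build_synteny(
                small_config(seed=0, n_blocks=500, syntenic_fraction=0.9)
            )


class TestPlantPeaks:
    def test_exact_class_counts(self):
        cfg = small_config(
            seed=4,
            peaks_per_factor=1000,
            factors=("O",),
            sc_fraction=(0.1,),
            syntenic_peak_fraction=(0.8,),
            source_chroms=(("mchr1", 4_000_000),),
            target_chroms=(("hchr1", 4_000_000),),
            n_blocks=20,
        )
        ds = generate(cfg, with_chromatin=False, with_motifs=False,
                      with_annotations=False)
        counts = ds.truth.klass.value_counts()
        assert counts["SC"] == 100
        assert counts["SC"] + counts["SU"] == 800
        assert counts.sum() == 1000

    def test_zero_sc_factor_yields_zero_sc_calls(self):
        cfg = small_config(
            seed=5, factors=("O",), sc_fraction=(0.0,),
            syntenic_peak_fraction=(0.7,),
        )
        ds = generate(cfg, with_chromatin=False, with_motifs=False,
                      with_annotations=False)
        index = synteny.ChainIndex(ds.scaffold.chains)
        calls = synteny.classify_peaks(
            ds.peaks.source["O"], ds.peaks.target["O"], index
        )
        assert sum(c.klass == "SC" for c in calls) == 0

    def test_strength_effect_zero_is_null(self):
        # with no planted strength effect, SC and SU q means agree within
        # 2 s.e. pooled over repeated generation
        diffs, ses = [], []
        for seed in range(20):
            cfg = small_config(
                seed=seed, strength_conservation_effect=0.0,
                factors=("O",), sc_fraction=(0.3,),
                syntenic_peak_fraction=(0.8,), peaks_per_factor=200,
            )
            ds = generate(cfg, with_chromatin=False, with_motifs=False,
                          with_annotations=False)
            t = ds.truth
            q = {p.name: p.neglog10_q for p in ds.peaks.source["O"]}
            sc = np.array([q[n] for n in t[t.klass == "SC"].name])
            su = np.array([q[n] for n in t[t.klass == "SU"].name])
            diffs.append(sc.mean() - su.mean())
            ses.append(
                np.sqrt(sc.var() / len(sc) + su.var() / len(su))
            )
        pooled = np.mean(diffs)
        pooled_se = np.sqrt(np.mean(np.square(ses)) / len(diffs))
        assert abs(pooled) < 2 * pooled_se + 1e-9

    def test_cobinding_sites_share_summits(self, small_dataset):
        ds = small_dataset
        from crosstf import cobind

        clusters = cobind.cluster_summits(ds.peaks.source)
        multi = [c for c in clusters if len(c.combination) >= 2]
        # a substantial planted co-binding fraction
        assert len(multi) >= 0.05 * sum(
            len(v) for v in ds.peaks.source.values()
        ) / len(ds.peaks.source)

    def test_straddle_sites_map_at_exactly_half(self):
        cfg = small_config(seed=6, straddle_fraction=0.1)
        ds = generate(cfg, with_chromatin=False, with_motifs=False,
                      with_annotations=False)
        tr = ds.truth[ds.truth.straddle]
        assert len(tr) > 0
        index = synteny.ChainIndex(ds.scaffold.chains)
        peaks = {
            p.name: p for f in cfg.factors for p in ds.peaks.source[f]
        }
        for name in tr.name:
            m = synteny.map_interval(peaks[name].interval, index)
            assert m.mapped_fraction == pytest.approx(0.5)

    def test_motif_rates_recovered(self, default_dataset):
        tr = default_dataset.truth
        cfg = default_dataset.cfg
        sc_rate = tr[tr.klass == "SC"].motif_src.mean()
        un_rate = tr[tr.klass != "SC"].motif_src.mean()
        assert abs(sc_rate - cfg.motif_rate_sc) < 0.03
        assert abs(un_rate - cfg.motif_rate_unc) < 0.03


class TestEmit:
    def test_round_trip_and_manifest(self, tmp_path, small_dataset):
        out = tmp_path / "ds"
        hashes = emit_dataset(small_dataset, out)
        assert (out / "manifest.json").exists()
        import json

        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["seed"] == small_dataset.cfg.seed
        # everything parses back cleanly
        chains = formats.read_chain(out / "source_to_target.chain")
        assert len(chains) == len(small_dataset.scaffold.chains)
        seqs, sizes = formats.read_genome(out / "source.fa")
        assert sizes == dict(small_dataset.cfg.source_chroms)
        for f in small_dataset.cfg.factors:
            peaks = formats.read_narrowpeak(
                out / "peaks" / f"{f}_{small_dataset.cfg.source_species}.narrowPeak"
            )
            assert len(peaks) == small_dataset.cfg.peaks_per_factor
        formats.read_ortholog_table(out / "orthologs.tsv")
        formats.read_bed_track(out / "repeats_source.bed")

    def test_refuses_non_empty_outdir(self, tmp_path, small_dataset):
        out = tmp_path / "ds"
        out.mkdir()
        (out / "junk").write_text("x")
        with pytest.raises(FileExistsError):
            emit_dataset(small_dataset, out)
        emit_dataset(small_dataset, out, force=True)

    def test_rerun_same_seed_identical_sha256(self, tmp_path):
        cfg = small_config(seed=9)
        h1 = emit_dataset(generate(cfg), tmp_path / "a")
        h2 = emit_dataset(generate(cfg), tmp_path / "b")
        assert h1 == h2

    def test_different_seed_differs(self, tmp_path):
        h1 = emit_dataset(generate(small_config(seed=10)), tmp_path / "a")
        h2 = emit_dataset(generate(small_config(seed=11)), tmp_path / "b")
        assert h1 != h2
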