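"""End-to-end orchestration of the cross-species binding comparison.

``run_all`` executes every analysis stage on a synthetic dataset (or a
pre-generated directory) and writes plain TSV/JSON outputs per stage plus
tidy per-figure-panel tables, deterministically for a fixed config.

Stage order: dataset generation -> co-binding -> TSS/target annotation ->
chromatin states (fit on the concatenated two-species corpus, decode,
enrich) -> synteny (classification, background, strength quartiles, summit
spectrum) -> repeats & persistence -> motif scanning -> conservation
classifier.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import annotate, chromstate, cobind, consmodel, motifs, synteny
from .formats import GenomicInterval, Peak
from .synthgen import SynthConfig, SyntheticDataset, emit_dataset, generate

__all__ = ["PipelineConfig", "run_all", "features_from_truth"]

STAGES = (
    "dataset",
    "cobind",
    "annotate",
    "chromstate",
    "synteny",
    "repeats_persistence",
    "motifs",
    "consmodel",
)

STAGE_DEPS = {
    "cobind": ("dataset",),
    "annotate": ("dataset",),
    "chromstate": ("dataset",),
    "synteny": ("dataset",),
    "repeats_persistence": ("dataset", "synteny"),
    "motifs": ("dataset", "synteny"),
    "consmodel": ("dataset", "synteny", "chromstate", "motifs"),
}


@dataclass
class PipelineConfig:
    synthetic: SynthConfig = field(default_factory=SynthConfig)
    outdir: str = "crosstf_out"
    stages: tuple[str, ...] = STAGES
    emit_files: bool = True
    # analysis parameters (desk-scale defaults)
    cobind_shuffles: int = 100
    background_shuffles: int = 200
    spectrum_shuffles: int = 50
    hmm_states: int | None = None  # default: synthetic.n_states
    hmm_max_iter: int = 30
    hmm_tol: float = 1e-4
    binarize_p: float = 1e-4
    motif_p: float = 1e-3
    kfold: int = 5
    min_match: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = raw.pop("synthetic", {})
        cfg = cls(**{k: tuple(v) if k == "stages" else v for k, v in raw.items()})
        cfg.synthetic = SynthConfig.from_dict(synth) if synth else SynthConfig()
        return cfg

    def to_dict(self) -> dict:
        # the output path is location metadata, not part of the analysis
        # identity, so it is excluded (keeps reports byte-identical across
        # working directories)
        d = dataclasses.asdict(self)
        d.pop("outdir", None)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=list).encode()
        ).hexdigest()[:16]


def _seed(cfg: PipelineConfig, stage: str) -> int:
    h = hashlib.sha256(f"{cfg.synthetic.seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def features_from_truth(truth: pd.DataFrame) -> list[consmodel.PeakTransitionFeatures]:
    """Classifier features straight from the generator's ground truth
    (planted states and motif flags); syntenic peaks only."""
    feats = []
    for row in truth.itertuples(index=False):
        if row.klass == "UN":
            continue
        feats.append(
            consmodel.PeakTransitionFeatures(
                name=row.name,
                klass=row.klass,
                state_src=int(row.state_src),
                state_dst=int(row.state_dst),
                motif_src=bool(row.motif_src),
                motif_dst=bool(row.motif_dst),
            )
        )
    return feats


def _combo_label(key, factors: Sequence[str]) -> str:
    if isinstance(key, frozenset):
        return "+".join(f for f in factors if f in key)
    return f"solo:{key[1]}"


class PipelineRun:
    """Holds in-memory stage products while files are written."""

    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.out = Path(cfg.outdir)
        self.results: dict = {}
        self.dataset: SyntheticDataset | None = None

    # -- helpers ------------------------------------------------------------
    def _write_tsv(self, name: str, df: pd.DataFrame) -> None:
        self.out.mkdir(parents=True, exist_ok=True)
        df.to_csv(self.out / name, sep="\t", index=False, float_format="%.6g")

    def _write_json(self, name: str, obj) -> None:
        self.out.mkdir(parents=True, exist_ok=True)
        (self.out / name).write_text(json.dumps(obj, indent=1, sort_keys=True))

    # -- stages -------------------------------------------------------------
    def stage_dataset(self) -> None:
        ds = generate(self.cfg.synthetic)
        self.dataset = ds
        if self.cfg.emit_files:
            emit_dataset(ds, self.out / "dataset", force=True)

    def stage_cobind(self) -> None:
        ds = self.dataset
        res = cobind.cobind_enrichment(
            ds.peaks.source,
            dict(ds.cfg.source_chroms),
            n_shuffles=self.cfg.cobind_shuffles,
            seed=_seed(self.cfg, "cobind"),
        )
        self.results["cobind"] = res
        factors = ds.cfg.factors
        rows = [
            {
                "combination": _combo_label(k, factors),
                "n_factors": len(k) if isinstance(k, frozenset) else 1,
                "observed": res.observed[k],
                "expected": res.expected[k],
                "log2_ratio": res.log2_ratio[k],
            }
            for k in sorted(
                res.observed, key=lambda k: -abs(res.log2_ratio[k])
            )
        ]
        self._write_tsv("cobind.tsv", pd.DataFrame(rows))

    def stage_annotate(self) -> None:
        ds = self.dataset
        ann = ds.annotations
        rows = []
        edges = list(annotate.DEFAULT_TSS_BINS)
        labels = ["0-5kb", "5-50kb", "50-500kb", ">500kb"]
        for species, peaks_by_f, tss in (
            (ds.cfg.source_species, ds.peaks.source, ann.tss_source),
            (ds.cfg.target_species, ds.peaks.target, ann.tss_target),
        ):
            for f, peaks in peaks_by_f.items():
                frac = annotate.tss_distance_distribution(peaks, tss, edges)
                for lab, x in zip(labels, frac):
                    rows.append(
                        {"species": species, "factor": f, "bin": lab, "fraction": x}
                    )
        self._write_tsv("tss_distance.tsv", pd.DataFrame(rows))

        src_targets = set()
        dst_targets = set()
        for f in ds.cfg.factors:
            src_targets |= annotate.assign_target_genes(
                ds.peaks.source[f], ann.tss_source
            )[0]
            dst_targets |= annotate.assign_target_genes(
                ds.peaks.target[f], ann.tss_target
            )[0]
        overlap = annotate.target_overlap_test(
            src_targets, dst_targets, ann.orthologs
        )
        self.results["target_overlap"] = overlap
        self._write_json("target_overlap.json", overlap)

    def stage_chromstate(self) -> None:
        ds = self.dataset
        K = self.cfg.hmm_states or ds.cfg.n_states
        bin_src = chromstate.binarize_counts(
            ds.chromatin.source, self.cfg.binarize_p
        )
        bin_dst = chromstate.binarize_counts(
            ds.chromatin.target, self.cfg.binarize_p
        )
        corpus = chromstate.concat_corpus(bin_src, bin_dst)
        hmm = chromstate.fit_hmm(
            corpus,
            n_states=K,
            seed=_seed(self.cfg, "hmm"),
            max_iter=self.cfg.hmm_max_iter,
            tol=self.cfg.hmm_tol,
        )
        segs = chromstate.decode_states(hmm, corpus)
        self.results["hmm"] = hmm
        self.results["segmentations"] = segs
        sub = self.out / "chromstate"
        sub.mkdir(parents=True, exist_ok=True)
        hmm.to_json(sub / "model.json")
        seg_src = segs[ds.cfg.source_species]
        seg_dst = segs[ds.cfg.target_species]
        seg_src.to_bed(sub / "segmentation_source.bed")
        seg_dst.to_bed(sub / "segmentation_target.bed")
        rows = []
        for species, seg, peaks_by_f in (
            (ds.cfg.source_species, seg_src, ds.peaks.source),
            (ds.cfg.target_species, seg_dst, ds.peaks.target),
        ):
            for f, peaks in peaks_by_f.items():
                states = chromstate.assign_peak_state(peaks, seg)
                enr = chromstate.state_enrichment(states, seg)
                for s in range(seg.n_states):
                    rows.append(
                        {
                            "species": species,
                            "factor": f,
                            "state": s + 1,
                            "peak_fraction": enr["peak_fraction"][s],
                            "genome_fraction": enr["genome_fraction"][s],
                            "log2_enrichment": enr["log2_enrichment"][s],
                        }
                    )
        self._write_tsv("state_enrichment.tsv", pd.DataFrame(rows))

    def stage_synteny(self) -> None:
        ds = self.dataset
        index = synteny.ChainIndex(ds.scaffold.chains)
        mcfg = synteny.MapperConfig(min_match=self.cfg.min_match)
        self.results["chain_index"] = index
        calls: dict[str, list[synteny.ConservationCall]] = {}
        call_rows = []
        rate_rows = []
        quart_rows = []
        for f in ds.cfg.factors:
            c = synteny.classify_peaks(
                ds.peaks.source[f], ds.peaks.target[f], index, mcfg
            )
            calls[f] = c
            counts = {k: sum(x.klass == k for x in c) for k in ("SC", "SU", "UN")}
            n = len(c)
            rate_rows.append(
                {
                    "factor": f,
                    "n_peaks": n,
                    "syntenic_rate": synteny.syntenic_rate(c),
                    "sc_fraction": counts["SC"] / n,
                    "su_fraction": counts["SU"] / n,
                    "un_fraction": counts["UN"] / n,
                }
            )
            for x in c:
                call_rows.append(
                    {
                        "factor": f,
                        "name": x.name,
                        "class": x.klass,
                        "target_locus": (
                            f"{x.mapped.target.chrom}:{x.mapped.target.start}-"
                            f"{x.mapped.target.end}"
                            if x.mapped
                            else ""
                        ),
                        "mapped_fraction": (
                            x.mapped.mapped_fraction if x.mapped else ""
                        ),
                        "partner": x.partner_peak or "",
                    }
                )
            q = synteny.conservation_by_strength_quartile(c, ds.peaks.source[f])
            for qi, pct in enumerate(q):
                quart_rows.append(
                    {"factor": f, "quartile": f"{qi * 25}-{(qi + 1) * 25}%",
                     "sc_percent": pct}
                )
        self.results["calls"] = calls
        self._write_tsv("conservation_calls.tsv", pd.DataFrame(call_rows))
        self._write_tsv("syntenic_rates.tsv", pd.DataFrame(rate_rows))
        self._write_tsv("strength_quartiles.tsv", pd.DataFrame(quart_rows))

        # pooled background conservation (all factors' peaks together)
        src_all = [p for f in ds.cfg.factors for p in ds.peaks.source[f]]
        dst_all = [p for f in ds.cfg.factors for p in ds.peaks.target[f]]
        bg = synteny.background_conservation(
            src_all,
            dst_all,
            index,
            dict(ds.cfg.source_chroms),
            dict(ds.cfg.target_chroms),
            n_shuffles=self.cfg.background_shuffles,
            seed=_seed(self.cfg, "background"),
            cfg=mcfg,
        )
        self.results["background"] = bg
        self._write_json(
            "background_conservation.json",
            {
                "mean_sc_rate": bg.mean,
                "ci_low": bg.ci_low,
                "ci_high": bg.ci_high,
                "n_shuffles": self.cfg.background_shuffles,
            },
        )

        spec_rows = []
        spectra = {}
        for f in ds.cfg.factors:
            syn_peaks = [
                p
                for p, c in zip(
                    sorted(ds.peaks.source[f], key=lambda p: p.name),
                    sorted(calls[f], key=lambda c: c.name),
                )
                if c.klass != "UN"
            ]
            spec = synteny.summit_distance_spectrum(
                syn_peaks,
                ds.peaks.target[f],
                index,
                dict(ds.cfg.target_chroms),
                n_shuffles=self.cfg.spectrum_shuffles,
                seed=_seed(self.cfg, "spectrum"),
                cfg=mcfg,
            )
            spectra[f] = spec
            for b in range(len(spec.observed)):
                lo = spec.bin_edges[b]
                hi = spec.bin_edges[b + 1]
                spec_rows.append(
                    {
                        "factor": f,
                        "bin": f"{int(lo)}-{'inf' if np.isinf(hi) else int(hi)}",
                        "observed": spec.observed[b],
                        "expected": spec.expected_mean[b],
                        "log2_ratio": spec.log2_ratio[b],
                    }
                )
        self.results["spectra"] = spectra
        self._write_tsv("summit_spectrum.tsv", pd.DataFrame(spec_rows))

    def stage_repeats_persistence(self) -> None:
        ds = self.dataset
        calls = self.results["calls"]
        rep = ds.annotations.repeats_source
        rows, fam_rows = [], []
        for f in ds.cfg.factors:
            klass = {c.name: c.klass for c in calls[f]}
            for cls in ("SC", "SU", "UN"):
                subset = [p for p in ds.peaks.source[f] if klass[p.name] == cls]
                if not subset:
                    continue
                overall, fams = annotate.repeat_association(subset, rep)
                rows.append(
                    {"factor": f, "class": cls, "repeat_fraction": overall}
                )
            overall, fams = annotate.repeat_association(ds.peaks.source[f], rep)
            for fam in annotate.REPEAT_FAMILIES:
                fam_rows.append(
                    {"factor": f, "family": fam, "fraction": fams.get(fam, 0.0)}
                )
        self._write_tsv("repeat_association.tsv", pd.DataFrame(rows))
        self._write_tsv("repeat_families.tsv", pd.DataFrame(fam_rows))

        pers_rows = []
        for f in ds.cfg.factors:
            pct = annotate.persistence_fraction(
                ds.peaks.source[f], ds.peaks.esc[f], calls[f]
            )
            for cls in ("SC", "SU", "UN"):
                pers_rows.append(
                    {
                        "factor": f,
                        "class": cls,
                        "persistent_percent": (
                            "" if pct[cls] is None else pct[cls]
                        ),
                    }
                )
        self.results["persistence"] = pers_rows
        self._write_tsv("persistence.tsv", pd.DataFrame(pers_rows))

    def stage_motifs(self) -> None:
        ds = self.dataset
        calls = self.results["calls"]
        src_genome = ds.source_genome()
        dst_genome = ds.target_genome()
        flag_rows = []
        frac_rows = []
        self.results["motif_flags"] = {}
        for f in ds.cfg.factors:
            pwm = motifs.pfm_to_pwm(ds.pfms[f])
            dist = motifs.score_distribution(pwm)
            peaks = ds.peaks.source[f]
            src_flags = motifs.peak_flags(
                peaks, src_genome, pwm, dist, self.cfg.motif_p
            )
            by_name = dict(zip([p.name for p in peaks], src_flags))
            mapped_flags = {}
            mapped_ivs, mapped_names = [], []
            for c in calls[f]:
                if c.mapped is not None:
                    mapped_ivs.append(c.mapped.target)
                    mapped_names.append(c.name)
            dst_flags = motifs.motif_occurrence_flags(
                mapped_ivs, dst_genome, pwm, dist, self.cfg.motif_p
            )
            mapped_flags = dict(zip(mapped_names, dst_flags))
            self.results["motif_flags"][f] = (by_name, mapped_flags)
            klass = {c.name: c.klass for c in calls[f]}
            for cls in ("SC", "SU", "UN"):
                names = [p.name for p in peaks if klass[p.name] == cls]
                if not names:
                    continue
                frac = float(np.mean([by_name[n] for n in names]))
                frac_rows.append(
                    {"factor": f, "class": cls, "motif_fraction": frac}
                )
            for p in peaks:
                flag_rows.append(
                    {
                        "factor": f,
                        "name": p.name,
                        "class": klass[p.name],
                        "motif_src": bool(by_name[p.name]),
                        "motif_dst": bool(mapped_flags.get(p.name, False)),
                    }
                )
        self._write_tsv("motif_flags.tsv", pd.DataFrame(flag_rows))
        self._write_tsv("motif_fractions.tsv", pd.DataFrame(frac_rows))

    def stage_consmodel(self) -> None:
        ds = self.dataset
        calls = self.results["calls"]
        segs = self.results["segmentations"]
        seg_src = segs[ds.cfg.source_species]
        seg_dst = segs[ds.cfg.target_species]
        K = seg_src.n_states
        feat_rows = []
        auc: dict = {}
        all_feats: list[consmodel.PeakTransitionFeatures] = []
        for f in ds.cfg.factors:
            peaks = {p.name: p for p in ds.peaks.source[f]}
            src_flags, dst_flags = self.results["motif_flags"][f]
            syn_calls = [c for c in calls[f] if c.klass != "UN"]
            src_states = chromstate.assign_peak_state(
                [peaks[c.name] for c in syn_calls], seg_src
            )
            mapped_peaks = [
                Peak(interval=c.mapped.target, name=c.name) for c in syn_calls
            ]
            dst_states = chromstate.assign_peak_state(mapped_peaks, seg_dst)
            feats = [
                consmodel.PeakTransitionFeatures(
                    name=c.name,
                    klass=c.klass,
                    state_src=int(ss),
                    state_dst=int(sd),
                    motif_src=bool(src_flags[c.name]),
                    motif_dst=bool(dst_flags[c.name]),
                )
                for c, ss, sd in zip(syn_calls, src_states, dst_states)
            ]
            all_feats.extend(feats)
            for x in feats:
                feat_rows.append(dataclasses.asdict(x) | {"factor": f})
            auc[f] = {
                "resubstitution": consmodel.evaluate(
                    feats, K, "resubstitution"
                )["auc"],
                f"kfold:{self.cfg.kfold}": consmodel.evaluate(
                    feats,
                    K,
                    f"kfold:{self.cfg.kfold}",
                    seed=_seed(self.cfg, "kfold"),
                )["auc"],
            }
        auc["pooled"] = {
            "resubstitution": consmodel.evaluate(
                all_feats, K, "resubstitution"
            )["auc"],
            f"kfold:{self.cfg.kfold}": consmodel.evaluate(
                all_feats, K, f"kfold:{self.cfg.kfold}",
                seed=_seed(self.cfg, "kfold"),
            )["auc"],
        }
        self.results["auc"] = auc
        self.results["features"] = all_feats
        self._write_tsv("features.tsv", pd.DataFrame(feat_rows))
        self._write_json("auc.json", auc)

        # transition matrices (pooled)
        sc = [x for x in all_feats if x.klass == "SC"]
        su = [x for x in all_feats if x.klass == "SU"]
        mat_sc = consmodel.state_transition_matrix(sc, K)
        mat_su = consmodel.state_transition_matrix(su, K)
        model = consmodel.nb_train(sc, su, K)
        self.results["matrices"] = (mat_sc, mat_su, model)
        np.savetxt(self.out / "state_transition_sc.tsv", mat_sc, delimiter="\t")
        np.savetxt(self.out / "state_transition_su.tsv", mat_su, delimiter="\t")
        np.savetxt(
            self.out / "state_transition_log2.tsv",
            model.state_log_odds,
            delimiter="\t",
        )

    # -- figure tables ------------------------------------------------------
    def make_figure_tables(self) -> None:
        fig = self.out / "figures"
        fig.mkdir(parents=True, exist_ok=True)

        def link(src: str, dst: str, transform=None) -> None:
            if not (self.out / src).exists():
                return
            df = pd.read_csv(self.out / src, sep="\t")
            if transform:
                df = transform(df)
            df.to_csv(fig / dst, sep="\t", index=False, float_format="%.6g")

        link("tss_distance.tsv", "fig1a.tsv")
        link("cobind.tsv", "fig1e.tsv")
        link(
            "state_enrichment.tsv",
            "fig2b.tsv",
            lambda d: d[["species", "factor", "state", "peak_fraction"]],
        )
        link(
            "state_enrichment.tsv",
            "fig2c.tsv",
            lambda d: d[["species", "factor", "state", "log2_enrichment"]],
        )
        if (self.out / "syntenic_rates.tsv").exists():
            rates = pd.read_csv(self.out / "syntenic_rates.tsv", sep="\t")
            f3b = rates[["factor", "syntenic_rate"]].copy()
            f3b["background_genome_rate"] = self.cfg.synthetic.syntenic_fraction
            f3b.to_csv(
                fig / "fig3b.tsv", sep="\t", index=False, float_format="%.6g"
            )
            rates[
                ["factor", "sc_fraction", "su_fraction", "un_fraction"]
            ].to_csv(fig / "fig3c.tsv", sep="\t", index=False, float_format="%.6g")
        link("strength_quartiles.tsv", "fig3d.tsv")
        link("repeat_association.tsv", "fig3e.tsv")
        link("repeat_families.tsv", "fig3f.tsv")
        link("persistence.tsv", "fig4d.tsv")
        if (self.out / "features.tsv").exists():
            mat_sc, mat_su, model = self.results["matrices"]
            K = len(mat_sc)
            rows = []
            for i in range(K):
                for j in range(K):
                    rows.append(
                        {
                            "state_target": i + 1,
                            "state_source": j + 1,
                            "sc_fraction": mat_sc[i, j],
                            "su_fraction": mat_su[i, j],
                            "log2_ratio": model.state_log_odds[i, j],
                        }
                    )
            pd.DataFrame(rows).to_csv(
                fig / "fig5a.tsv", sep="\t", index=False, float_format="%.6g"
            )
            pd.DataFrame(rows)[
                ["state_target", "state_source", "log2_ratio"]
            ].to_csv(fig / "fig5b.tsv", sep="\t", index=False, float_format="%.6g")
            link("motif_fractions.tsv", "fig5c.tsv")
            auc_rows = []
            for f, protos in self.results["auc"].items():
                for proto, modes in protos.items():
                    for mode, v in modes.items():
                        auc_rows.append(
                            {"factor": f, "protocol": proto, "mode": mode, "auc": v}
                        )
            pd.DataFrame(auc_rows).to_csv(
                fig / "fig5d.tsv", sep="\t", index=False, float_format="%.6g"
            )


def run_all(cfg: PipelineConfig) -> PipelineRun:
    """Run every enabled stage in order; returns the in-memory run object.

    Raises ``ValueError`` before running anything if an enabled stage's
    dependency is toggled off.
    """
    enabled = list(cfg.stages)
    for stage in enabled:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        for dep in STAGE_DEPS.get(stage, ()):
            if dep not in enabled:
                raise ValueError(
                    f"stage '{stage}' requires stage '{dep}'; enable it or "
                    f"drop '{stage}'"
                )
    run = PipelineRun(cfg)
    for stage in STAGES:
        if stage in enabled:
            getattr(run, f"stage_{stage}")()
    run.make_figure_tables()
    run._write_json(
        "report.json",
        {
            "version": __version__,
            "config_hash": cfg.config_hash(),
            "config": cfg.to_dict(),
            "stages": enabled,
        },
    )
    return run
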