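"""End-to-end orchestration: simulate -> classify -> anchor -> regions/orient
-> junctions -> copy number/CNV -> zygosity/paralog selection -> digest.

A pipeline run is configured by a plain mapping (usually loaded from YAML).
Two input modes exist:

* ``simulate`` mode — a ``simulate`` block holds the architecture parameters
  and a ``timepoints`` list names the ordered samples to generate (each
  ``pre_alt`` or ``alt``, with optional per-timepoint overrides such as
  ``alt_copies_per_end``).  The haploid reference, per-timepoint genomes,
  reads and truth files are produced and analysed in one pass.
* file mode — ``reference`` points at a FASTA and each timepoint at a FASTQ
  pair; marker sites, template FASTA, and target/control intervals are then
  supplied explicitly.

One global seed drives everything; each stage derives its own stream from
(seed, stage name) so stages are reproducible in isolation.  The report is a
pure function of (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .anchors import (
    build_seed_index,
    call_orientation,
    collect_candidate_regions,
    map_anchorable_mates,
    map_reads_for_depth,
)
from .core import ConfigurationError, GenomicInterval
from .digest import BUILTIN_ENZYMES
from .digest import digest as run_digest
from .junctions import scan_junction_reads, summarize_junctions
from .quant import (
    copy_number_ratio,
    depth_from_anchors,
    segment_profile,
    windowed_log2_ratio,
)
from .seqio import read_fasta, read_fastq_pair, write_fasta, write_fastq_pair, write_tsv
from .simulate import SimConfig, _build_chassis, build_alt_genome, build_pre_alt_genome, build_reference_genome, simulate_reads
from .telreads import category_counts, classification_table, classify_pairs, estimate_telomere_content
from .zygosity import SnpSite, call_zygosities, pileup_alleles, select_amplified_paralog

log = logging.getLogger("taltfinder")

_STAGE_DEFAULTS: dict[str, dict[str, Any]] = {
    "classify": {"threshold": 3},
    "anchor": {"k": 15, "max_mismatch_frac": 0.05, "max_occurrences": 64},
    "regions": {"window": 1000, "alpha": 0.01, "merge_gap_windows": 10},
    "orient": {"end_margin": 1000, "tau": 0.9, "min_informative": 20},
    "junctions": {"probe_len": 30, "max_spacer_units": 30, "dominance": 0.8},
    "quant": {"cnv_window": 1000, "min_segment": 5, "depth_scope": "loci"},
    "zygosity": {"min_depth": 5, "hom_cut": 0.9},
    "digest": {"enzymes": ["AluI", "MboI", "HinfI"]},
}

_TOP_KEYS = {"seed", "outdir", "simulate", "timepoints", "reference", "template",
             "sites", "target", "control", "genome_size", "n_ends", "stages"}


def _stage_seed(seed: int, stage: str) -> int:
    """Derived per-stage seed: stable, independent, below 2**31."""
    return (int(seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


class PipelineConfig(dict):
    """Validated pipeline configuration (a dict with helpers)."""

    def stage(self, name: str) -> dict[str, Any]:
        merged = dict(_STAGE_DEFAULTS[name])
        merged.update((self.get("stages") or {}).get(name, {}))
        return merged


def validate_config(source: str | Path | Mapping[str, Any]) -> PipelineConfig:
    """Load and validate a config; all problems are reported together."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    errors: list[str] = []
    for key in raw:
        if key not in _TOP_KEYS:
            log.warning("unknown config key %r ignored", key)
    cfg = PipelineConfig(raw)
    cfg.setdefault("seed", 0)
    if not isinstance(cfg["seed"], int):
        errors.append("seed must be an integer")
    stages = cfg.get("stages") or {}
    for name, block in stages.items():
        if name not in _STAGE_DEFAULTS:
            log.warning("unknown stage block %r ignored", name)
            continue
        for key, value in (block or {}).items():
            if key not in _STAGE_DEFAULTS[name]:
                log.warning("unknown parameter %s.%s ignored", name, key)
            elif isinstance(value, (int, float)) and not isinstance(value, bool):
                if key in ("window", "cnv_window", "end_margin", "probe_len",
                           "min_segment", "threshold", "k", "min_depth") and value <= 0:
                    errors.append(f"{name}.{key} must be positive (got {value})")
    if "reference" not in cfg:
        # simulate mode (the default: an empty config runs the default scenario)
        sim = cfg.get("simulate") or {}
        known = {f.name for f in dataclasses.fields(SimConfig)}
        for key in sim:
            if key not in known:
                log.warning("unknown simulate key %r ignored", key)
        try:
            _sim_config(cfg, overrides=None).validate()
        except (ConfigurationError, TypeError) as exc:
            errors.append(f"simulate block invalid: {exc}")
        tps = cfg.get("timepoints") or [{"label": "sample", "architecture": "alt"}]
        for tp in tps:
            if tp.get("architecture", "alt") not in ("pre_alt", "alt"):
                errors.append(f"timepoint {tp.get('label')}: bad architecture")
    else:
        for tp in cfg.get("timepoints") or []:
            for key in ("r1", "r2"):
                if key not in tp:
                    errors.append(f"timepoint {tp.get('label')}: missing {key}")
                elif not Path(tp[key]).exists():
                    errors.append(f"timepoint {tp.get('label')}: {tp[key]} does not exist")
    if errors:
        raise ConfigurationError("; ".join(errors))
    return cfg


def _sim_config(cfg: PipelineConfig, overrides: Mapping[str, Any] | None) -> SimConfig:
    base = {"seed": cfg.get("seed", 0)}
    base.update(cfg.get("simulate") or {})
    known = {f.name for f in dataclasses.fields(SimConfig)}
    base = {k: v for k, v in base.items() if k in known}
    if overrides:
        base.update({k: v for k, v in overrides.items() if k in known})
    return SimConfig(**base)


def _config_hash(cfg: Mapping[str, Any]) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(source: str | Path | Mapping[str, Any], outdir: str | Path | None = None) -> dict:
    """Execute every applicable stage in dependency order and write the report.

    Returns the report as a plain dict (also written to ``report.json``).
    Stage failures abort the run with the failing stage named.
    """
    cfg = validate_config(source)
    out = Path(outdir or cfg.get("outdir") or "taltfinder_run")
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    simulated = "reference" not in cfg

    report: dict[str, Any] = {
        "provenance": {
            "tool": "taltfinder",
            "version": __version__,
            "seed": seed,
            "config_hash": _config_hash(cfg),
        },
        "timepoints": [],
    }

    stage = "setup"
    try:
        # ---- reference, template, loci --------------------------------
        if simulated:
            base_sim = _sim_config(cfg, None)
            reference = build_reference_genome(base_sim)
            chassis = _build_chassis(base_sim)
            template_seq = chassis.template_a
            _, truth0 = build_pre_alt_genome(base_sim)
            target = truth0.template_locus_ref
            control = truth0.control_locus_ref
            sites = [
                SnpSite(c, p, a, b, "B") for c, p, a, b in truth0.marker_sites_ref
            ]
            write_fasta(reference, out / "reference.fa")
        else:
            reference = read_fasta(cfg["reference"])
            template_seq = (
                read_fasta(cfg["template"])[0].sequence if "template" in cfg else None
            )
            target = _interval_from(cfg.get("target"))
            control = _interval_from(cfg.get("control"))
            sites = _read_sites(cfg["sites"]) if "sites" in cfg else []

        stage = "index"
        anchor_par = cfg.stage("anchor")
        index = build_seed_index(reference, k=anchor_par["k"])
        quant_par = cfg.stage("quant")
        kmer_filter = None
        if quant_par["depth_scope"] == "loci" and target and control:
            kmer_filter = index.interval_kmers([target, control], margin=1000)

        series = []  # (zygosity calls, copy-number estimate) per timepoint
        depth_tracks = {}
        timepoints = cfg.get("timepoints") or [{"label": "sample", "architecture": "alt"}]

        for tp in timepoints:
            label = tp.get("label", "sample")
            stage = f"reads[{label}]"
            if simulated:
                sim = _sim_config(cfg, tp.get("overrides") or {k: v for k, v in tp.items() if k not in ("label", "architecture")})
                builder = build_pre_alt_genome if tp.get("architecture", "alt") == "pre_alt" else build_alt_genome
                genome, truth = builder(sim)
                pairs = simulate_reads(genome, sim)
                write_fastq_pair(pairs, str(out / f"{label}_1.fq"), str(out / f"{label}_2.fq"))
                truth.to_json(out / f"{label}_truth.json")
                truth.segments_bed(out / f"{label}_segments.bed")
                genome_size = sum(len(c) for c in genome)
                n_ends = truth.n_ends
            else:
                pairs = list(read_fastq_pair(tp["r1"], tp["r2"]))
                truth = None
                genome_size = int(cfg.get("genome_size") or sum(len(c) for c in reference))
                n_ends = int(cfg.get("n_ends") or 2 * len(reference))

            tp_report: dict[str, Any] = {"label": label, "n_pairs": len(pairs)}

            stage = f"classify[{label}]"
            cls_par = cfg.stage("classify")
            classified = classify_pairs(pairs, threshold=cls_par["threshold"])
            tp_report["pair_categories"] = category_counts(classified)
            est = estimate_telomere_content(classified, genome_size, n_ends)
            tp_report["telomere_content"] = {
                "telomeric_base_count": est.telomeric_base_count,
                "mean_depth": est.mean_depth,
                "length_per_end": est.length_per_end,
            }
            write_tsv(classification_table(classified), out / f"{label}_classify.tsv")
            log.info("%s: %s", label, tp_report["pair_categories"])

            stage = f"anchor[{label}]"
            single_hits = map_anchorable_mates(
                classified, index, max_mismatch_frac=anchor_par["max_mismatch_frac"]
            )
            tp_report["n_single_anchors"] = len(single_hits)

            stage = f"regions[{label}]"
            reg_par = cfg.stage("regions")
            regions = collect_candidate_regions(
                single_hits, index, window=reg_par["window"], alpha=reg_par["alpha"],
                merge_gap_windows=reg_par["merge_gap_windows"],
            )
            ori_par = cfg.stage("orient")
            for region in regions:
                call_orientation(
                    region, single_hits, end_margin=ori_par["end_margin"],
                    tau=ori_par["tau"], min_informative=ori_par["min_informative"],
                )
            tp_report["candidate_regions"] = [
                {
                    "contig": r.contig, "start": r.start, "end": r.end,
                    "anchor_count": r.anchor_count, "enrichment_p": r.enrichment_p,
                    "orientation": r.orientation.value, "counts": r.counts,
                }
                for r in regions[:10]
            ]

            if template_seq:
                stage = f"junctions[{label}]"
                jn_par = cfg.stage("junctions")
                flat = [(f"{p.id}/{m}", s) for p in pairs for m, s in ((1, p.mate1_seq), (2, p.mate2_seq))]
                calls = scan_junction_reads(
                    flat, template_seq, probe_len=jn_par["probe_len"],
                    max_spacer_units=jn_par["max_spacer_units"],
                )
                summary = summarize_junctions(calls, dominance=jn_par["dominance"])
                tp_report["junctions"] = {
                    "counts": summary.counts,
                    "dominant_class": summary.dominant_class,
                    "modal_spacer_units": summary.modal_spacer_units,
                    "spacer_histogram": {str(k): v for k, v in summary.spacer_histogram.items()},
                }

            if target and control:
                stage = f"depth[{label}]"
                rng = np.random.default_rng(_stage_seed(seed, f"depth:{label}"))
                flat = [(f"{p.id}/1", p.mate1_seq) for p in pairs]
                flat += [(f"{p.id}/2", p.mate2_seq) for p in pairs]
                depth_hits = map_reads_for_depth(
                    flat, index, rng,
                    max_mismatch_frac=anchor_par["max_mismatch_frac"],
                    kmer_filter=kmer_filter,
                )
                depth = depth_from_anchors(depth_hits, {c.name: len(c) for c in reference})
                depth_tracks[label] = depth
                cn = copy_number_ratio(depth, target, control)
                tp_report["copy_number"] = {
                    "mean_depth_target": cn.mean_depth_target,
                    "mean_depth_control": cn.mean_depth_control,
                    "ratio": cn.ratio,
                }

                if sites:
                    stage = f"zygosity[{label}]"
                    zyg_par = cfg.stage("zygosity")
                    seqs = dict(flat)
                    depths = pileup_alleles(depth_hits, seqs, sites)
                    zcalls = call_zygosities(
                        depths, min_depth=zyg_par["min_depth"], hom_cut=zyg_par["hom_cut"]
                    )
                    tp_report["zygosity"] = {
                        "n_sites": len(zcalls),
                        "calls": {
                            z: sum(1 for c in zcalls if c.call.value == z)
                            for z in ("HOM_REF", "HET", "HOM_ALT", "NOCALL")
                        },
                    }
                    series.append((zcalls, cn))

            report["timepoints"].append(tp_report)

        # ---- cross-sample stages --------------------------------------
        if len(series) >= 2:
            stage = "select_paralog"
            sel = select_amplified_paralog(series)
            report["paralog_selection"] = {
                "af_a": sel.af_a, "af_b": sel.af_b, "ratios": sel.ratios,
                "score_a": sel.score_a, "score_b": sel.score_b, "selected": sel.selected,
            }
        if len(depth_tracks) >= 2 and quant_par["depth_scope"] == "genome":
            stage = "cnv"
            labels = [tp.get("label", "sample") for tp in timepoints]
            prof = windowed_log2_ratio(
                depth_tracks[labels[-1]], depth_tracks[labels[0]],
                window=quant_par["cnv_window"],
            )
            segment_profile(prof, min_segment=quant_par["min_segment"])
            report["cnv"] = {
                contig: [
                    {"start_window": int(a), "end_window": int(b), "mean_log2": m}
                    for a, b, m in segs
                ]
                for contig, segs in prof.segments.items()
            }
        if template_seq:
            stage = "digest"
            dig_par = cfg.stage("digest")
            enzymes = [BUILTIN_ENZYMES[name] for name in dig_par["enzymes"]]
            result = run_digest(template_seq, enzymes)
            report["template_digest"] = {
                "enzymes": list(result.enzymes),
                "n_fragments": len(result.fragment_lengths),
                "fragment_lengths": list(result.fragment_lengths),
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report


def _interval_from(spec: Any) -> GenomicInterval | None:
    if spec is None:
        return None
    if isinstance(spec, GenomicInterval):
        return spec
    if isinstance(spec, str):  # "contig:start-end", 0-based half-open
        contig, rest = spec.split(":")
        start, end = rest.replace(",", "").split("-")
        return GenomicInterval(contig, int(start), int(end))
    return GenomicInterval(spec["contig"], int(spec["start"]), int(spec["end"]))


def _read_sites(path: str | Path) -> list[SnpSite]:
    from .seqio import read_tsv

    df = read_tsv(path)
    return [
        SnpSite(str(r.contig), int(r.position), str(r.ref_allele), str(r.alt_allele),
                str(getattr(r, "paralog_label", "none")))
        for r in df.itertuples()
    ]


def report_text(report: Mapping[str, Any]) -> str:
    """Human-readable rendering of a run report."""
    lines = [f"taltfinder {report['provenance']['version']} run "
             f"(seed {report['provenance']['seed']}, config {report['provenance']['config_hash']})"]
    for tp in report["timepoints"]:
        lines.append(f"\n[{tp['label']}] {tp['n_pairs']} read pairs")
        cats = tp.get("pair_categories", {})
        lines.append(f"  telomeric pairs: PAIR={cats.get('PAIR')} SINGLE={cats.get('SINGLE')} NONE={cats.get('NONE')}")
        tc = tp.get("telomere_content", {})
        if tc:
            lines.append(f"  telomere length/end: {tc['length_per_end']:.0f} bp at {tc['mean_depth']:.1f}x depth")
        for r in tp.get("candidate_regions", [])[:3]:
            lines.append(
                f"  region {r['contig']}:{r['start']}-{r['end']} anchors={r['anchor_count']} "
                f"p={r['enrichment_p']:.2e} orientation={r['orientation']}"
            )
        jn = tp.get("junctions")
        if jn and jn["dominant_class"]:
            lines.append(f"  junctions: {jn['dominant_class']} dominant, modal spacer {jn['modal_spacer_units']} units")
        cn = tp.get("copy_number")
        if cn:
            lines.append(f"  copy number ratio: {cn['ratio']:.2f}")
    sel = report.get("paralog_selection")
    if sel:
        lines.append(f"\nselected paralog: {sel['selected']} "
                     f"(AF_A {sel['af_a'][0]:.2f}->{sel['af_a'][-1]:.2f}, "
                     f"AF_B {sel['af_b'][0]:.2f}->{sel['af_b'][-1]:.2f})")
    dig = report.get("template_digest")
    if dig:
        lines.append(f"template digest ({'+'.join(dig['enzymes'])}): {dig['n_fragments']} fragments")
    return "\n".join(lines)
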