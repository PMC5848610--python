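"""End-to-end orchestration of the analysis stages from a structured config.

Each stage reads the standard input files, runs the corresponding library
functions and writes tab-separated tables / BED plus a machine-readable run
manifest (parameters, seed, input checksums). Reruns with the same config
and seed reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from promoter_architect import (
    annotate,
    binding_architecture as arch,
    expression_integration as expr,
    io_formats as io,
    motif_positional as mp,
    nome_ndr,
)
from promoter_architect.synthetic_data import SimConfig, generate

log = logging.getLogger("promoter_architect.pipeline")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


DEFAULTS: dict[str, Any] = {
    "half_width": 2000,
    "bin_size": 20,
    "motif": "AGGCCTAG",
    "n_scrambles": 10,
    "active_threshold": 0.0,
    "fdr_max": 0.05,
    "min_abs_fc": 1.5,
    "ndr_min_length": 140,
    "ndr_window": 100,
    "ndr_step": 20,
    "ndr_q_max": 0.05,
    "summit_offset_range": [140, 340],
    "metaplot_half_width": 1000,
    "seed": 0,
    "factor": "ZFX",
}


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


def resolve_params(config: Mapping[str, Any]) -> dict:
    params = dict(DEFAULTS)
    params.update({k: v for k, v in config.items() if k != "inputs"})
    return params


def _load_inputs(config: Mapping[str, Any]) -> dict:
    inputs = config.get("inputs", {})
    loaded: dict[str, Any] = {"paths": {}}
    readers = {
        "genome": io.read_fasta,
        "tss": io.read_tss,
        "cpg_islands": io.read_bed,
        "enhancers": io.read_bed,
        "insulators": io.read_bed,
        "methyl_calls": io.read_methyl_calls,
        "signal": io.read_bedgraph,
        "de_single": io.read_de_table,
        "de_double": io.read_de_table,
    }
    for key, reader in readers.items():
        if key in inputs:
            path = Path(inputs[key])
            if not path.exists():
                raise FileNotFoundError(f"input {key!r}: {path} does not exist")
            loaded[key] = reader(path)
            loaded["paths"][key] = str(path)
    loaded["peaks"] = {}
    for factor, path in inputs.get("peaks", {}).items():
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"peaks[{factor}]: {path} does not exist")
        loaded["peaks"][factor] = io.read_narrowpeak(path)
        loaded["paths"][f"peaks_{factor}"] = str(path)
    return loaded


def _write_profile(path, profile: mp.PositionalProfile) -> None:
    rows = [
        (int(lo), int(hi), int(c), f"{n:.6g}")
        for lo, hi, c, n in zip(
            profile.bin_edges[:-1], profile.bin_edges[1:], profile.counts, profile.normalized
        )
    ]
    io.write_table(path, rows, header=["bin_start", "bin_end", "count", "per_anchor"])


def _write_metaplot(path, plot: arch.Metaplot) -> None:
    rows = [(f"{o:g}", f"{v:.6g}") for o, v in zip(plot.offsets, plot.mean_signal)]
    io.write_table(path, rows, header=["offset", "mean_signal"])


def run_all(config: Mapping[str, Any], outdir) -> dict:
    """Run every stage; returns a summary dict (also written to summary.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = resolve_params(config)
    half = params["half_width"]
    factor = params["factor"]
    summary: dict[str, Any] = {}
    outputs: dict[str, str] = {}

    stage = "load"
    try:
        data = _load_inputs(config)
    except Exception as exc:
        raise StageError(stage, exc)

    tss = data.get("tss", [])
    peaks = data.get("peaks", {}).get(factor, [])
    genome = data.get("genome")
    expression = (
        {g.gene_id: g.expression for g in data["de_single"]}
        if "de_single" in data
        else None
    )

    # ---- annotation ------------------------------------------------------
    if tss and peaks:
        stage = "annotate"
        try:
            io.validate_chrom_namespace(peaks, tss)
            annotations = annotate.classify_peaks(
                peaks, tss, data.get("enhancers", ()), data.get("insulators", ()), half
            )
            path = outdir / "peak_annotation.tsv"
            io.write_table(
                path,
                [
                    (
                        a.peak.interval.chrom, a.peak.interval.start, a.peak.interval.end,
                        a.peak.interval.name or ".", a.category,
                        a.nearest_tss or ".",
                        a.signed_offset if a.signed_offset is not None else ".",
                    )
                    for a in annotations
                ],
                header=["chrom", "start", "end", "name", "category", "nearest_tss", "signed_offset"],
            )
            outputs["peak_annotation"] = str(path)
            counts = {c: 0 for c in annotate.CATEGORIES}
            for a in annotations:
                counts[a.category] += 1
            summary["peak_categories"] = counts

            statuses = annotate.classify_promoters(
                tss, data.get("cpg_islands", ()), data.get("peaks", {}),
                expression, params["active_threshold"], half,
            )
            path = outdir / "promoter_status.tsv"
            io.write_table(
                path,
                [
                    (
                        s.tss.gene_id, s.tss.chrom, s.tss.pos, s.tss.strand,
                        int(s.is_cpg_island),
                        ",".join(sorted(s.bound_by)) or ".",
                        "." if s.is_active is None else int(s.is_active),
                    )
                    for s in statuses
                ],
                header=["gene_id", "chrom", "pos", "strand", "is_cpg_island", "bound_by", "is_active"],
            )
            outputs["promoter_status"] = str(path)
            summary["n_bound_promoters"] = sum(1 for s in statuses if factor in s.bound_by)
        except Exception as exc:
            raise StageError(stage, exc)
    else:
        statuses = []
        annotations = []

    # ---- motif profiling -------------------------------------------------
    if tss and genome:
        stage = "motif_profile"
        try:
            motif = mp.Motif(params["motif"], label="consensus")
            status_map = {
                s.tss.gene_id: (s.is_cpg_island, factor in s.bound_by) for s in statuses
            } or None
            counts_df = mp.motifs_per_promoter(tss, genome, motif, half, status_map)
            path = outdir / "motifs_per_promoter.tsv"
            counts_df.to_csv(path, sep="\t", index=False)
            outputs["motifs_per_promoter"] = str(path)

            hits = mp.promoter_motif_hits(tss, genome, motif, half)
            all_hits = [h for hs in hits.values() for h in hs]
            profile = mp.profile_from_offsets(
                [h.tss_offset for h in all_hits], len(tss), half, params["bin_size"]
            )
            _write_profile(outdir / "motif_profile.tsv", profile)
            outputs["motif_profile"] = str(outdir / "motif_profile.tsv")
            summary["motif_modal_bin"] = list(profile.modal_bin())

            scrambles = mp.scramble_motif(motif, params["n_scrambles"], params["seed"])
            flat = []
            for sc in scrambles:
                sc_hits = mp.promoter_motif_hits(tss, genome, sc, half)
                sc_prof = mp.profile_from_offsets(
                    [h.tss_offset for hs in sc_hits.values() for h in hs],
                    len(tss), half, params["bin_size"],
                )
                expected = mp.expected_coarse_counts(tss, genome, sc, half)
                flat.append(mp.controlled_flatness_ratio(sc_prof, expected))
            summary["scramble_flatness_ratios"] = [round(f, 3) for f in flat]
            summary["true_motif_flatness_ratio"] = round(mp.flatness_ratio(profile), 3)
        except Exception as exc:
            raise StageError(stage, exc)

    # ---- summit architecture --------------------------------------------
    if tss and peaks:
        stage = "summit_profile"
        try:
            profile = mp.positional_profile(peaks, tss, half, params["bin_size"])
            _write_profile(outdir / "summit_profile.tsv", profile)
            outputs["summit_profile"] = str(outdir / "summit_profile.tsv")
            summary["summit_modal_bin"] = list(profile.modal_bin())

            single = arch.select_single_tss_promoters(tss, half)
            archs = arch.build_architectures(peaks, single, half)
            labels = arch.cluster_promoters(archs, "rule")
            summary["cluster_fractions"] = {
                k: round(v, 4) for k, v in arch.cluster_fractions(labels).items()
            }
            path = outdir / "promoter_clusters.tsv"
            io.write_table(
                path, sorted(labels.items()), header=["gene_id", "cluster"]
            )
            outputs["promoter_clusters"] = str(path)
        except Exception as exc:
            raise StageError(stage, exc)

    # ---- DE × binding ----------------------------------------------------
    if "de_single" in data and statuses:
        stage = "de_overlap"
        try:
            bound_genes = {s.tss.gene_id for s in statuses if factor in s.bound_by}
            down, up = expr.select_de_genes(
                data["de_single"], params["fdr_max"], params["min_abs_fc"]
            )
            res = expr.de_binding_overlap(down, up, bound_genes)
            summary["de_overlap"] = {
                "n_down": res.n_down, "n_up": res.n_up,
                "n_down_bound": res.n_down_bound, "n_up_bound": res.n_up_bound,
                "pct_down_bound": res.pct_down_bound, "pct_up_bound": res.pct_up_bound,
                "odds_ratio": round(res.odds_ratio, 4), "p_value": res.p_value,
            }
            path = outdir / "de_overlap.json"
            path.write_text(json.dumps(summary["de_overlap"], indent=2) + "\n")
            outputs["de_overlap"] = str(path)
            contrast = expr.expression_by_binding(
                statuses, expression, factor
            )
            summary["expression_contrast"] = {
                "median_bound": round(contrast.median_bound, 4),
                "median_unbound": round(contrast.median_unbound, 4),
                "p_value": contrast.p_value,
            }
            if "de_double" in data:
                d_down, _ = expr.select_de_genes(
                    data["de_double"], params["fdr_max"], params["min_abs_fc"]
                )
                comb = expr.combinatorial_kd_overlap([down], d_down, bound_genes)
                summary["additional_bound_down"] = comb.n_additional
        except Exception as exc:
            raise StageError(stage, exc)

    # ---- NDRs ------------------------------------------------------------
    if "methyl_calls" in data:
        stage = "call_ndrs"
        try:
            ndrs = nome_ndr.call_ndrs(
                data["methyl_calls"],
                min_length=params["ndr_min_length"],
                window=params["ndr_window"],
                step=params["ndr_step"],
                q_max=params["ndr_q_max"],
            )
            path = outdir / "ndrs.bed"
            io.write_bed(path, [n.interval for n in ndrs])
            outputs["ndrs"] = str(path)
            summary["n_ndrs"] = len(ndrs)
            if peaks and tss:
                by_gene = {t.gene_id: t for t in tss}
                tss_by_chrom: dict[str, list] = {}
                for t in tss:
                    tss_by_chrom.setdefault(t.chrom, []).append(t)
                offsets = [
                    annotate.nearest_tss_assignment(p, tss_by_chrom)[1] for p in peaks
                ]
                lo, hi = params["summit_offset_range"]
                summary["peak_ndr_overlap"] = round(
                    nome_ndr.peak_ndr_overlap(peaks, ndrs, offsets, (lo, hi)), 4
                )
        except Exception as exc:
            raise StageError(stage, exc)

    # ---- metaplots -------------------------------------------------------
    stage = "metaplot"
    try:
        mhalf = params["metaplot_half_width"]
        if "signal" in data and tss:
            plot = arch.metaplot(data["signal"], tss, mhalf, params["bin_size"])
            _write_metaplot(outdir / "signal_metaplot.tsv", plot)
            outputs["signal_metaplot"] = str(outdir / "signal_metaplot.tsv")
        if "methyl_calls" in data and tss:
            hcg, gch = nome_ndr.nome_metaplot(
                data["methyl_calls"], tss, mhalf, params["bin_size"]
            )
            _write_metaplot(outdir / "nome_metaplot_HCG.tsv", hcg)
            _write_metaplot(outdir / "nome_metaplot_GCH.tsv", gch)
            outputs["nome_metaplot_HCG"] = str(outdir / "nome_metaplot_HCG.tsv")
            outputs["nome_metaplot_GCH"] = str(outdir / "nome_metaplot_GCH.tsv")
    except Exception as exc:
        raise StageError(stage, exc)

    # ---- manifest --------------------------------------------------------
    manifest = {
        "parameters": {k: params[k] for k in sorted(params)},
        "seed": params["seed"],
        "inputs": {k: {"path": p, "sha256": _sha256(p)} for k, p in data["paths"].items()},
        "outputs": outputs,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary


def simulate(sim_overrides: Mapping[str, Any] | None, outdir, seed: int | None = None) -> dict:
    """Generate the synthetic bundle into ``outdir``; returns its paths."""
    kwargs = dict(sim_overrides or {})
    if seed is not None:
        kwargs["seed"] = seed
    cfg = SimConfig(**kwargs)
    bundle = generate(cfg, outdir)
    return bundle.paths
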