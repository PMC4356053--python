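"""Configuration-driven orchestration of the full analysis.

Stages run in dependency order (generate -> dmr -> profiles -> associations
-> motifs -> imaging -> report); each stage writes its outputs plus a JSON
manifest recording parameters, the derived stage seed and content hashes of
every file it wrote.  Manifests chain the previous stage's manifest hash, so
reruns with the same configuration are verifiably bit-identical and any
tampering with intermediate outputs is detectable.

A single global seed fans out to per-stage seeds by stable hashing of the
stage name, so adding a stage never perturbs the randomness of others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd
import yaml

from senesceq import association_stats as assoc
from senesceq import dmr_calling as dmrc
from senesceq import motif_enrichment as motifs_mod
from senesceq import signal_profiles as profiles_mod
from senesceq import synthetic_data as synth
from senesceq import telomere_imaging as imaging_mod
from senesceq.genome_regions import (
    GenomicInterval,
    RegionSet,
    standardize_region_length,
    write_bed,
)

STAGE_ORDER = ("generate", "dmr", "profiles", "associations", "motifs", "imaging", "report")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def stage_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineConfig:
    """Validated pipeline configuration (YAML-backed).

    Keys: ``seed`` (global), ``synthetic`` (generator overrides; the
    synthetic block is the default input source), ``inputs`` (paths to
    pre-existing files; every referenced path must exist at validation
    time) and per-stage parameter blocks (``dmr``, ``associations``,
    ``motifs``, ``imaging``).
    """

    def __init__(self, data: dict[str, Any] | None = None):
        data = data or {}
        self.seed = int(data.get("seed", 1))
        self.synthetic = dict(data.get("synthetic", {}))
        self.inputs = dict(data.get("inputs", {}))
        self.stage_params = {
            s: dict(data.get(s, {})) for s in ("dmr", "profiles", "associations", "motifs", "imaging")
        }
        for key, path in self.inputs.items():
            if not Path(path).exists():
                raise PipelineError(f"stage validation: input {key!r} missing: {path}")
        unknown = set(self.synthetic) - {
            f.name for f in dataclasses.fields(synth.SyntheticConfig)
        }
        if unknown:
            raise PipelineError(f"unknown synthetic config keys: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def synthetic_config(self) -> synth.SyntheticConfig:
        kwargs = {
            k: tuple(v) if isinstance(v, list) else v for k, v in self.synthetic.items()
        }
        return synth.SyntheticConfig(**kwargs)


def _write_manifest(
    stage_dir: Path, stage: str, seed: int, params: dict, prev_hash: str
) -> str:
    outputs = sorted(
        p for p in stage_dir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "stage": stage,
        "seed": seed,
        "params": params,
        "previous_manifest_sha256": prev_hash,
        "outputs": {str(p.relative_to(stage_dir)): _sha256(p) for p in outputs},
    }
    text = json.dumps(manifest, sort_keys=True, indent=1)
    (stage_dir / "manifest.json").write_text(text)
    return hashlib.sha256(text.encode()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict[str, Any]:
    """Run every stage; returns a summary of headline results.

    A stage failure raises :class:`PipelineError` naming the stage; outputs
    of completed stages are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state: dict[str, Any] = {}
    prev_hash = ""
    summary: dict[str, Any] = {"seed": config.seed}
    for stage in STAGE_ORDER:
        stage_dir = out / stage
        stage_dir.mkdir(exist_ok=True)
        seed = stage_seed(config.seed, stage)
        runner: Callable = _STAGES[stage]
        try:
            params = runner(config, stage_dir, seed, state, summary)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate with stage name
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        prev_hash = _write_manifest(stage_dir, stage, seed, params, prev_hash)
    (out / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=1))
    return summary


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_generate(config, stage_dir, seed, state, summary) -> dict:
    cfg = config.synthetic_config()
    bundle = synth.generate_genome_bundle(cfg, seed=seed, out_dir=stage_dir)
    state["bundle"] = bundle
    summary["genome_bp"] = bundle.genome.total_length
    return {"synthetic": dataclasses.asdict(cfg)}


def _stage_dmr(config, stage_dir, seed, state, summary) -> dict:
    bundle: synth.SyntheticBundle = state["bundle"]
    params = dict(config.stage_params["dmr"])
    hyper = dmrc.call_dmrs(
        bundle.fragments_late, bundle.fragments_early, direction="hyper", **params
    )
    hypo = dmrc.call_dmrs(
        bundle.fragments_early, bundle.fragments_late, direction="hypo", **params
    )
    state["hyper_dmrs"], state["hypo_dmrs"] = hyper, hypo
    dmrc.write_dmr_outputs(hyper, bundle.genome, stage_dir / "dmrs_hyper")
    dmrc.write_dmr_outputs(hypo, bundle.genome, stage_dir / "dmrs_hypo")
    for direction, called, truth in (
        ("hyper", hyper, bundle.truth.hyper_dmrs),
        ("hypo", hypo, bundle.truth.hypo_dmrs),
    ):
        ev = dmrc.evaluate_recovery(called, truth)
        summary[f"dmr_{direction}_called"] = ev["n_called"]
        summary[f"dmr_{direction}_recovery"] = ev["recovery"]
        summary[f"dmr_{direction}_false"] = ev["n_false"]
    return params


def _stage_profiles(config, stage_dir, seed, state, summary) -> dict:
    bundle: synth.SyntheticBundle = state["bundle"]
    bin_ = int(config.stage_params["profiles"].get("bin", 100))
    early = profiles_mod.rpkm_normalize(bundle.fragments_early, bin_)
    late = profiles_mod.rpkm_normalize(bundle.fragments_late, bin_)
    state["track_early"], state["track_late"] = early, late
    early.to_bedgraph(stage_dir / "rpkm_early.bedgraph")
    late.to_bedgraph(stage_dir / "rpkm_late.bedgraph")

    hyper_rs = dmrc.dmrs_to_regionset(state["hyper_dmrs"], bundle.genome, "hyper")
    for mark, frags in bundle.mark_fragments.items():
        track = profiles_mod.rpkm_normalize(frags, bin_)
        if len(hyper_rs):
            prof = profiles_mod.metaprofile(track, hyper_rs, half_window=1_000, step=bin_)
            prof.to_tsv(stage_dir / f"metaprofile_{mark}_around_hyper.tsv")

    io_test = profiles_mod.inside_outside_test(early, bundle.truth.lads)
    summary["lad_inside_outside_p"] = io_test["p_value"]
    summary["lad_mean_inside"] = io_test["mean_inside"]
    summary["lad_mean_outside"] = io_test["mean_outside"]

    border = profiles_mod.lad_border_profile(early, bundle.truth.lads)
    border.to_tsv(stage_dir / "lad_border_profile.tsv")

    sig = profiles_mod.select_significant_cpgs(bundle.probes)
    diff = profiles_mod.differential_signal_at_sites(
        early, late, pd.concat([sig["hyper"], sig["hypo"]], ignore_index=True)
    )
    diff.to_csv(stage_dir / "differential_at_cpgs.tsv", sep="\t", index=False)
    groups = profiles_mod.group_mean_differential(
        diff,
        {"hyper": sig["hyper"]["probe_id"], "hypo": sig["hypo"]["probe_id"]},
    )
    summary["differential_at_hyper_cpgs"] = groups["hyper"]
    summary["differential_at_hypo_cpgs"] = groups["hypo"]

    beta_prof = profiles_mod.neighborhood_beta_profile(bundle.probes, sig["hyper"])
    beta_prof.to_csv(stage_dir / "beta_profile_hyper.tsv", sep="\t", index=False)
    state["significant_cpgs"] = sig
    return {"bin": bin_}


def _stage_associations(config, stage_dir, seed, state, summary) -> dict:
    bundle: synth.SyntheticBundle = state["bundle"]
    params = dict(config.stage_params["associations"])
    n_random = int(params.get("n_random", 100))
    genome = bundle.genome
    rows = []
    for direction, dmrs in (("hyper", state["hyper_dmrs"]), ("hypo", state["hypo_dmrs"])):
        if not dmrs:
            continue
        rs = dmrc.dmrs_to_regionset(dmrs, genome, direction)
        enr = assoc.region_vs_domains_enrichment(
            rs, bundle.truth.lads, n_random=n_random, seed=seed
        )
        rows.append(
            {
                "regions": direction,
                "domains": "LADs",
                "observed_fraction": enr["observed_fraction"],
                "random_fraction": enr["random_fraction"],
                "p_value": enr["p_value"],
                "direction": enr["direction"],
            }
        )
        summary[f"{direction}_in_lads_fraction"] = enr["observed_fraction"]
        summary[f"{direction}_in_lads_p"] = enr["p_value"]
        summary[f"{direction}_in_lads_direction"] = enr["direction"]
    pd.DataFrame(rows).to_csv(stage_dir / "lad_enrichment.tsv", sep="\t", index=False)

    de = assoc.select_de_genes(bundle.genes)
    summary["n_up_genes"], summary["n_down_genes"] = len(de["up"]), len(de["down"])
    vic = int(params.get("gene_vicinity", 5_000))
    proj_rows = []
    for direction, dmrs in (("hyper", state["hyper_dmrs"]), ("hypo", state["hypo_dmrs"])):
        if not dmrs:
            continue
        rs = dmrc.dmrs_to_regionset(dmrs, genome, direction)
        for which, table in de.items():
            if not len(table):
                continue
            ref = RegionSet(
                genome,
                [
                    GenomicInterval(
                        r.chrom,
                        max(0, r.tss - vic),
                        min(genome.length_of(r.chrom), r.tss + vic),
                    )
                    for r in table.itertuples(index=False)
                ],
                name=f"{which}_vicinity",
            )
            res = assoc.projection_test(rs, ref, genome)
            proj_rows.append(
                {
                    "dmrs": direction,
                    "genes": which,
                    "n": res.n,
                    "k": res.k,
                    "p0": res.p0,
                    "p_value": res.p_value,
                    "direction": res.direction,
                }
            )
            summary[f"projection_{direction}_{which}_p"] = res.p_value
            summary[f"projection_{direction}_{which}_direction"] = res.direction
    pd.DataFrame(proj_rows).to_csv(stage_dir / "projection_tests.tsv", sep="\t", index=False)

    gl = assoc.gene_lad_association(bundle.genes, bundle.truth.lads, de)
    gl["profile"].to_csv(stage_dir / "expression_vs_lad_border.tsv", sep="\t", index=False)
    summary["gene_lad_fisher_p"] = gl["p_value"]

    universe = set(bundle.genes["gene_id"])
    inside = bundle.truth.lads
    sets = {
        "lad_genes": {
            r.gene_id
            for r in bundle.genes.itertuples(index=False)
            if inside.contains_points(r.chrom, np.array([r.tss]))[0]
        },
        "planted_up": set(bundle.truth.up_genes),
        "planted_down": set(bundle.truth.down_genes),
    }
    gse = assoc.gene_set_enrichment(set(de["up"]["gene_id"]), universe, sets)
    gse.to_csv(stage_dir / "gene_set_enrichment_up.tsv", sep="\t", index=False)
    return params


def _stage_motifs(config, stage_dir, seed, state, summary) -> dict:
    bundle: synth.SyntheticBundle = state["bundle"]
    params = dict(config.stage_params["motifs"])
    n_random = int(params.get("n_random", 100))
    fdr = float(params.get("fdr", 1e-4))
    genome = bundle.genome

    hyper_rs = dmrc.dmrs_to_regionset(state["hyper_dmrs"], genome, "hyper")
    std = RegionSet(
        genome,
        [standardize_region_length(iv, 40, genome) for iv in hyper_rs],
        name="hyper_40bp",
    )
    write_bed(std, stage_dir / "dmrs_hyper_40bp.bed")
    seqs = [bundle.sequence.fetch_interval(iv) for iv in std]
    dmr_table = motifs_mod.motif_enrichment_test(
        seqs, genome, std, bundle.motifs, bundle.sequence,
        n_random=n_random, seed=seed, fdr=fdr,
    )
    dmr_table.to_csv(stage_dir / "motif_enrichment_dmrs.tsv", sep="\t", index=False)
    top = dmr_table.iloc[0]
    summary["top_dmr_motif"] = str(top["motif_id"])
    summary["top_dmr_motif_adj_p"] = float(top["adj_p"])

    de = assoc.select_de_genes(bundle.genes)
    de_ids = set(de["up"]["gene_id"]) | set(de["down"]["gene_id"])
    de_genes = bundle.genes[bundle.genes["gene_id"].isin(de_ids)]
    prom_ivs = []
    prom_seqs = []
    for r in de_genes.itertuples(index=False):
        if r.strand == "+":
            lo, hi = max(0, r.tss - 1_000), r.tss
        else:
            lo, hi = r.tss, min(genome.length_of(r.chrom), r.tss + 1_000)
        prom_ivs.append(GenomicInterval(r.chrom, lo, hi, strand=r.strand))
        prom_seqs.append(bundle.sequence.fetch(r.chrom, lo, hi))
    prom_rs = RegionSet(genome, prom_ivs, name="de_promoters")
    prom_table = motifs_mod.motif_enrichment_test(
        prom_seqs, genome, prom_rs, bundle.motifs, bundle.sequence,
        n_random=n_random, seed=seed + 1, fdr=fdr,
    )
    prom_table.to_csv(stage_dir / "motif_enrichment_promoters.tsv", sep="\t", index=False)

    dmr_hits = set(dmr_table.loc[dmr_table["adj_p"] < 0.05, "motif_id"])
    prom_hits = set(prom_table.loc[prom_table["adj_p"] < 0.05, "motif_id"])
    if dmr_hits or prom_hits:
        overlap_p = assoc.list_overlap_test(dmr_hits, prom_hits, len(bundle.motifs))
        summary["motif_list_overlap_p"] = overlap_p
        summary["motif_lists_overlap"] = len(dmr_hits & prom_hits)
    return {"n_random": n_random, "fdr": fdr}


def _stage_imaging(config, stage_dir, seed, state, summary) -> dict:
    params = dict(config.stage_params["imaging"])
    n_nuclei = int(params.get("n_nuclei", 15))
    results = {}
    for i, passage in enumerate(("early", "late")):
        images, truth = synth.generate_nucleus_images(
            n_nuclei, passage, seed=seed + i, out_dir=stage_dir / passage
        )
        measurements = []
        for img in images:
            measurements.extend(imaging_mod.measure_image(img[0], img[1]))
        s = imaging_mod.telomere_summary(measurements)
        s["per_nucleus"].to_csv(
            stage_dir / f"nuclei_{passage}.tsv", sep="\t", index=False
        )
        results[passage] = s
        summary[f"{passage}_mean_area_px"] = s["mean_area"]
        summary[f"{passage}_mean_elongation"] = s["mean_elongation"]
        summary[f"{passage}_length_proxy"] = s["mean_length_proxy"]
        summary[f"{passage}_center_zone_fraction"] = s["zone_distribution"]["center"]
    return {"n_nuclei": n_nuclei}


def _stage_report(config, stage_dir, seed, state, summary) -> dict:
    (stage_dir / "report.json").write_text(json.dumps(summary, sort_keys=True, indent=1))
    return {}


_STAGES: dict[str, Callable] = {
    "generate": _stage_generate,
    "dmr": _stage_dmr,
    "profiles": _stage_profiles,
    "associations": _stage_associations,
    "motifs": _stage_motifs,
    "imaging": _stage_imaging,
    "report": _stage_report,
}
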