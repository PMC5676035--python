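"""End-to-end pooled-segregant QTL mapping runs.

Ties the stages together — simulate the cross, sequence the pools, scan
for linkage, fine-map each called QTL, and design allele-specific edits
— with a single seeded configuration, writing every artifact to an
output directory together with a manifest of paths and checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from bsaqtl.cross import (GenomeMap, PhenotypeModel, QtlEffect,
                          assign_phenotypes, sample_pool_reads, select_pools,
                          simulate_meiosis)
from bsaqtl.finemap import (design_marker_grid, markers_to_tsv, score_markers,
                            simulate_marker_calls)
from bsaqtl.linkage import build_linkage_track, call_qtls, qtl_calls_to_bed
from bsaqtl.poolfreq import filter_sites, track_to_tsv, write_pool_vcf

logger = logging.getLogger("bsaqtl")

__all__ = ["RunConfig", "run_end_to_end", "default_demo_config"]


@dataclass
class RunConfig:
    """Configuration for one reproducible end-to-end run."""

    seed: int = 0
    out_dir: str = "bsaqtl_run"
    # genome scale
    n_chromosomes: int = 4
    chrom_length_bp: int = 500_000
    snp_spacing_bp: int = 2_000
    morgans_per_chrom: float = 1.0
    full_yeast_genome: bool = False
    # cross and selection
    n_segregants: int = 574
    pool_size: int = 24
    baseline_ppm: float = 1.7
    noise_cv: float = 0.15
    combine_rule: str = "multiplicative"
    qtls: list[dict] = field(default_factory=list)  # chrom/pos/favored_parent/effect
    selection: str = "top_k"  # "top_k" | "cutoff" | "none"
    cutoff_ppm: float = 2.8
    # sequencing
    target_coverage: float = 100.0
    overdispersion: float = 0.0
    min_coverage: int = 20
    # scan
    alpha: float = 0.05
    smooth_method: str = "hmm"
    length_scale_bp: float = 20_000.0
    min_sites: int = 5
    merge_gap_bp: int = 20_000
    # fine mapping
    marker_spacing_min_bp: int = 5_000
    marker_spacing_max_bp: int = 15_000
    marker_missing_rate: float = 0.0

    def genome_map(self) -> GenomeMap:
        if self.full_yeast_genome:
            return GenomeMap.full_yeast(snp_spacing=self.snp_spacing_bp)
        return GenomeMap.regular(self.n_chromosomes, self.chrom_length_bp,
                                 self.snp_spacing_bp, self.morgans_per_chrom)

    def phenotype_model(self) -> PhenotypeModel:
        effects = tuple(QtlEffect(q["chrom"], int(q["pos"]), q["favored_parent"],
                                  float(q["effect"]), bool(q.get("dominant", False)))
                        for q in self.qtls)
        return PhenotypeModel(self.baseline_ppm, effects, self.noise_cv,
                              self.combine_rule)

    def config_hash(self) -> str:
        # out_dir does not affect scientific content, so reruns into
        # different directories hash identically
        payload = {k: v for k, v in dataclasses.asdict(self).items()
                   if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()
                              ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def default_demo_config(seed: int = 0, out_dir: str = "bsaqtl_demo") -> RunConfig:
    """Demo run: 4 planted QTLs, two favouring each parent, on the test-scale genome.

    Effect sizes follow the measured allele effects of the worked
    example (25-40 % per locus).
    """
    return RunConfig(
        seed=seed, out_dir=out_dir,
        qtls=[
            {"chrom": "chrI", "pos": 250_000, "favored_parent": "A", "effect": 0.35},
            {"chrom": "chrII", "pos": 150_000, "favored_parent": "A", "effect": 0.30},
            {"chrom": "chrIII", "pos": 350_000, "favored_parent": "B", "effect": 0.25},
            {"chrom": "chrIV", "pos": 200_000, "favored_parent": "B", "effect": 0.40},
        ],
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_end_to_end(config: RunConfig) -> dict:
    """Run simulate -> pool-seq -> scan -> fine-map and write all artifacts.

    Returns the manifest (also written as ``manifest.json``): paths and
    sha256 checksums of every artifact, the called QTLs, and per-QTL
    fine-mapping summaries.  Any stage failure raises with the stage
    name; artifacts written before the failure are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed_seq = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in seed_seq.spawn(5)]
    header = f"bsaqtl run seed={config.seed} config={config.config_hash()}"
    manifest: dict = {"seed": config.seed, "config_hash": config.config_hash(),
                      "stages": {}, "artifacts": {}}

    def record(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {"path": str(path), "sha256": _sha256(path)}

    stage = "simulate"
    try:
        gmap = config.genome_map()
        segregants = simulate_meiosis(gmap, config.n_segregants, rngs[0])
        segregants = assign_phenotypes(segregants, config.phenotype_model(),
                                       gmap, rngs[1])
        if config.selection == "cutoff":
            superior, random_pool = select_pools(
                segregants, config.pool_size, cutoff=config.cutoff_ppm,
                seed=rngs[2], target_coverage=config.target_coverage,
                overdispersion=config.overdispersion)
        elif config.selection == "none":
            # no selection: the scanned pool is the whole population, so the
            # track carries only read-sampling noise around 0.5 (a 24-member
            # unselected pool would add real haplotype-composition signal)
            from bsaqtl.cross import PoolSpec
            superior = PoolSpec(tuple(s.id for s in segregants), "unselected",
                                config.target_coverage, config.overdispersion)
            _, random_pool = select_pools(
                segregants, config.pool_size, top_k=config.pool_size,
                seed=rngs[2], target_coverage=config.target_coverage,
                overdispersion=config.overdispersion)
        else:
            superior, random_pool = select_pools(
                segregants, config.pool_size, top_k=config.pool_size,
                seed=rngs[2], target_coverage=config.target_coverage,
                overdispersion=config.overdispersion)
        sup_counts = sample_pool_reads(superior, segregants, gmap, rngs[3])
        rand_counts = sample_pool_reads(random_pool, segregants, gmap, rngs[4])

        pheno_path = out / "segregants.tsv"
        with open(pheno_path, "w") as fh:
            fh.write(f"# {header}\n" "segregant_id\tphenotype_ppm\tselected\n")
            sup_set = set(superior.members)
            for s in segregants:
                fh.write(f"{s.id}\t{s.phenotype:.6g}\t{int(s.id in sup_set)}\n")
        record("segregants", pheno_path)

        vcf_path = out / "pools.vcf"
        write_pool_vcf(vcf_path,
                       {"superior": sup_counts, "random": rand_counts},
                       contig_lengths={c.name: c.length_bp for c in gmap.chromosomes})
        record("pools_vcf", vcf_path)
        manifest["stages"][stage] = "ok"

        stage = "scan"
        sup_f, sup_report = filter_sites(sup_counts, config.min_coverage)
        rand_f, _ = filter_sites(rand_counts, config.min_coverage)
        track = build_linkage_track(sup_f, rand_f, method=config.smooth_method,
                                    length_scale_bp=config.length_scale_bp)
        track_path = out / "linkage_track.tsv"
        track_to_tsv(track, track_path, header_comment=header)
        record("linkage_track", track_path)
        calls = call_qtls(track, alpha=config.alpha, min_sites=config.min_sites,
                          merge_gap=config.merge_gap_bp)
        bed_path = out / "qtl_calls.bed"
        bed_path.write_text(qtl_calls_to_bed(calls))
        record("qtl_calls", bed_path)
        manifest["qtl_calls"] = [dataclasses.asdict(c) for c in calls]
        manifest["stages"][stage] = "ok"
        manifest["filter_report"] = dataclasses.asdict(sup_report)

        stage = "finemap"
        by_id = {s.id: s for s in segregants}
        pool_segs = [by_id[i] for i in superior.members]
        finemap_summaries = []
        rng_fm = np.random.default_rng(seed_seq.spawn(1)[0])
        for qi, call in enumerate(calls):
            markers = design_marker_grid(call, gmap,
                                         config.marker_spacing_min_bp,
                                         config.marker_spacing_max_bp)
            genotypes = simulate_marker_calls(pool_segs, markers, gmap,
                                              config.marker_missing_rate, rng_fm)
            result = score_markers(genotypes, alpha=config.alpha)
            fm_path = out / f"finemap_qtl{qi + 1}_{call.chrom}.tsv"
            markers_to_tsv(genotypes, fm_path)
            record(f"finemap_qtl{qi + 1}", fm_path)
            finemap_summaries.append({
                "chrom": call.chrom, "best_marker": result.best_marker,
                "interval": result.interval,
                "min_p": (None if result.best_marker is None else
                          float(result.table["p"].min()))})
        manifest["finemap"] = finemap_summaries
        manifest["stages"][stage] = "ok"
    except Exception as exc:
        manifest["stages"][stage] = f"failed: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    logger.info("run complete: %d QTL calls, manifest at %s",
                len(manifest["qtl_calls"]), manifest_path)
    return manifest
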