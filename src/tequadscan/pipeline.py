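"""End-to-end orchestration: scan -> null -> context -> profiles -> cohort -> motifs.

A run takes a genome FASTA plus an rmsk-style annotation table (or in-memory
equivalents), executes every analysis stage with one :class:`RunConfig`, and
writes a deterministic directory of TSV/BED outputs plus a machine-readable
JSON manifest holding the configuration, input checksums and per-stage
record counts.  Reruns with the same inputs and config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
import pandas as pd

from . import __version__
from .annotation import (
    RepeatAnnotation,
    read_fasta,
    read_rmsk_table,
    write_hits_bed,
    write_hits_tsv,
)
from .cohort import (
    ALU_AGE,
    L1_ACTIVE,
    SVA_AGE,
    age_trend,
    element_table,
    length_activity_contrast,
    percent_with_pqs,
)
from .context import FullLengthRule, assign_zones, resolve_family_key, zone_density
from .markov import expected_pqs_density
from .motifs import cluster_and_rank
from .profiles import build_profile, reference_density
from .scanner import ScanParams, scan_genome

__all__ = ["RunConfig", "run_all", "DEFAULT_CONSENSUS_LENGTHS"]

# consensus lengths used when annotations lack consensus coordinates and for
# choosing profile windows; keys are resolved family keys
DEFAULT_CONSENSUS_LENGTHS = {
    "L1": 6000,
    "Alu": 300,
    "SVA": 2000,
    "HERV_ltr": 400,
    "HERV_internal": 3000,
}


@dataclass
class RunConfig:
    """Every parameter of a pipeline run, fully serializable."""

    # scan
    min_run: int = 3
    min_runs: int = 4
    loop_min: int = 1
    loop_max: int = 7
    allow_g_loops: bool = True
    allow_n_loops: bool = True
    # context
    flank: int = 200
    # markov null
    markov_order: int = 2
    markov_window: int = 150
    null_replicates: int = 100
    null_sample_bp: int = 20_000
    # profiles
    consensus_lengths: dict = field(default_factory=lambda: dict(DEFAULT_CONSENSUS_LENGTHS))
    # cohort
    active_set: tuple = L1_ACTIVE
    n_permutations: int = 999
    # motifs
    motifs_top: int = 10
    seed: int = 0
    version: str = __version__

    def scan_params(self) -> ScanParams:
        return ScanParams(
            min_run=self.min_run,
            min_runs=self.min_runs,
            loop_min=self.loop_min,
            loop_max=self.loop_max,
            allow_g_loops=self.allow_g_loops,
            allow_n_loops=self.allow_n_loops,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, what: str, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# tequadscan v{config.version} {what} seed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_all(
    fasta: str | Path,
    rmsk: str | Path,
    outdir: str | Path,
    config: RunConfig | None = None,
) -> dict:
    """Run every stage on a genome + annotation table; returns the manifest."""
    config = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta, rmsk = Path(fasta), Path(rmsk)

    records = read_fasta(fasta, invalid="to_n")
    genome = {r.record_id: r.seq for r in records}
    annotations = read_rmsk_table(rmsk)
    manifest: dict = {
        "tool": "tequadscan",
        "version": config.version,
        "config": asdict(config),
        "inputs": {
            "fasta": {"path": str(fasta), "sha256": _sha256(fasta)},
            "rmsk": {"path": str(rmsk), "sha256": _sha256(rmsk)},
        },
        "stages": {},
    }
    params = config.scan_params()

    # --- scan ---------------------------------------------------------------
    hits = scan_genome(genome, params)
    write_hits_tsv(hits, outdir / "hits.tsv", params=dataclasses.asdict(params))
    write_hits_bed(hits, outdir / "hits.bed")
    manifest["stages"]["scan"] = {
        "n_hits": len(hits),
        "n_plus": sum(h.strand_label == "PQS3+" for h in hits),
        "n_minus": sum(h.strand_label == "PQS3-" for h in hits),
        "genome_bp": sum(len(s) for s in genome.values()),
    }

    # --- context ------------------------------------------------------------
    rule = FullLengthRule()
    assignments = assign_zones(hits, annotations, flank=config.flank)
    zdf = zone_density(
        assignments,
        annotations,
        flank=config.flank,
        rule=rule,
        chrom_lengths={c: len(s) for c, s in genome.items()},
    )
    _write_tsv(zdf, outdir / "zone_density.tsv", "zone densities", config)
    zone_rows = pd.DataFrame(
        [
            {
                "element_id": za.element_id,
                "zone": za.zone,
                "family": za.family_key or "",
                "chrom": za.hit.chrom,
                "start": za.hit.start,
                "end": za.hit.end,
                "strand_label": za.hit.strand_label,
            }
            for za in assignments
        ]
    )
    _write_tsv(zone_rows, outdir / "zones.tsv", "zone assignments", config)
    manifest["stages"]["context"] = {
        "n_assignments": len(assignments),
        "n_inside": sum(a.zone == "inside" for a in assignments),
    }

    # --- markov null (per family, on a capped sample of inside sequence) ----
    fam_anns: dict[str, list[RepeatAnnotation]] = {}
    for ann in annotations:
        key = resolve_family_key(ann)
        if key is not None:
            fam_anns.setdefault(key, []).append(ann)
    null_rows = []
    for fam in sorted(fam_anns):
        sample, total = [], 0
        for ann in fam_anns[fam]:
            seq = genome[ann.chrom][ann.geno_start : ann.geno_end]
            sample.append(seq)
            total += len(seq)
            if total >= config.null_sample_bp:
                break
        est = expected_pqs_density(
            "".join(sample)[: config.null_sample_bp],
            params,
            window_len=config.markov_window,
            n_replicates=config.null_replicates,
            seed=config.seed,
            order=config.markov_order,
        )
        null_rows.append(
            {
                "region": fam,
                "region_bp": min(total, config.null_sample_bp),
                "observed_per_kb": est.observed_pqs_per_kb,
                "expected_per_kb": est.expected_pqs_per_kb,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "n_replicates": est.n_replicates,
            }
        )
    _write_tsv(pd.DataFrame(null_rows), outdir / "null.tsv", "Markov null", config)
    manifest["stages"]["null"] = {"n_regions": len(null_rows)}

    # --- profiles -----------------------------------------------------------
    profile_frames = []
    for fam in sorted(fam_anns):
        clen = config.consensus_lengths.get(fam)
        if clen is None:
            continue
        prof = build_profile(assignments, annotations, fam, consensus_length=clen)
        n_inside_fam = prof.n_hits
        prof.reference_density = reference_density(
            manifest["stages"]["scan"]["n_hits"],
            manifest["stages"]["scan"]["genome_bp"],
            prof.window_len,
            max(prof.n_elements, 1),
        )
        profile_frames.append(prof.to_frame())
    profiles_df = (
        pd.concat(profile_frames, ignore_index=True) if profile_frames else pd.DataFrame()
    )
    _write_tsv(profiles_df, outdir / "profiles.tsv", "consensus profiles", config)
    manifest["stages"]["profiles"] = {"n_rows": len(profiles_df)}

    # --- cohort -------------------------------------------------------------
    elements = element_table(annotations, assignments, rule)
    _write_tsv(elements, outdir / "elements.tsv", "element table", config)
    pct = percent_with_pqs(elements, ("family",))
    _write_tsv(pct, outdir / "abundance_by_family.tsv", "family abundance", config)
    pct_sub = percent_with_pqs(elements, ("family", "rep_name", "chrom_class"))
    _write_tsv(pct_sub, outdir / "abundance_by_subfamily.tsv", "subfamily abundance", config)
    sva_tbl, sva_trend = age_trend(
        elements, SVA_AGE, n_permutations=config.n_permutations, seed=config.seed
    )
    alu_tbl, alu_trend = age_trend(
        elements, ALU_AGE, n_permutations=config.n_permutations, seed=config.seed
    )
    sva_tbl["family"], alu_tbl["family"] = "SVA", "Alu"
    _write_tsv(
        pd.concat([sva_tbl, alu_tbl], ignore_index=True),
        outdir / "age_trend.tsv",
        "age trends",
        config,
    )
    l1_tbl, l1_ratios = length_activity_contrast(elements, config.active_set, family="L1")
    _write_tsv(l1_tbl, outdir / "length_activity.tsv", "L1 length/activity", config)
    manifest["stages"]["cohort"] = {
        "n_elements": len(elements),
        "sva_trend": sva_trend,
        "alu_trend": alu_trend,
        "l1_ratios": l1_ratios,
    }

    # --- motifs -------------------------------------------------------------
    motif_rows = []
    inside_by_fam: dict[str, list] = {}
    seen = set()
    for za in assignments:
        if za.zone != "inside" or za.family_key is None:
            continue
        hid = (za.hit.chrom, za.hit.start, za.hit.end, za.hit.strand_label)
        if (za.family_key, hid) in seen:
            continue
        seen.add((za.family_key, hid))
        inside_by_fam.setdefault(za.family_key, []).append(za.hit)
    for fam in sorted(inside_by_fam):
        for rank, mc in enumerate(cluster_and_rank(inside_by_fam[fam], fam)):
            if rank >= config.motifs_top:
                break
            motif_rows.append(
                {
                    "family": fam,
                    "rank": rank + 1,
                    "signature_key": mc.signature_key,
                    "count": mc.count,
                    "representative": mc.representative,
                    "consensus_loops": ",".join(mc.consensus_loops),
                }
            )
    _write_tsv(pd.DataFrame(motif_rows), outdir / "motifs.tsv", "motif clusters", config)
    manifest["stages"]["motifs"] = {"n_rows": len(motif_rows)}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
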