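"""End-to-end orchestration: map normalization and smoothing, segmentation,
optional motif discovery, genome scanning, density tracks and the
association grid, with deterministic, manifest-stamped runs."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._util import format_motif, parse_motif
from .association import association_grid, rebin_density_to_map
from .density import density_track, rebin
from .discovery import (
    MotifRecord,
    build_consensus_set,
    differential_enrichment,
    enrichment_frame,
    enumerate_candidates,
)
from .motifs import (
    compute_qvalues,
    consensus_to_matrix,
    estimate_background,
    scan,
    write_occurrences_tsv,
)
from .recmap import (
    UNIT_RHO,
    AnchorSet,
    RecombinationMap,
    moving_median,
    normalize_to_cM,
    read_map,
    split_high_low,
    write_map,
)
from .synthetic import read_fasta

logger = logging.getLogger("recmotif")

DEFAULT_SCALES_KB = (1, 5, 25, 101, 501, 2501)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-loadable).

    ``motifs`` is a list of consensus strings (bracket shorthand accepted);
    when empty and ``discover`` is true, motifs come from the enumerative
    differential-enrichment discovery on the high/low split at each scale.
    """

    genome_fasta: str = ""
    map_csv: str = ""
    outdir: str = "recmotif_run"
    anchors: list[tuple] = field(default_factory=list)  # (chrom,start,end,cM)
    map_unit: str = "cM_per_Mb"
    motifs: list[str] = field(default_factory=list)
    discover: bool = False
    species: str = "sample"
    discovery_unit_lengths: tuple = (1, 2, 3)
    discovery_length_range: tuple = (8, 12)
    discovery_e_threshold: float = 0.01
    scales_kb: tuple = DEFAULT_SCALES_KB
    p_threshold: float = 1e-4
    dialect: str = "hard"
    pseudocount: float = 0.1
    granularity: float = 1e-3
    density_bin_kb: float = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.dialect not in ("hard", "soft"):
            raise ValueError("dialect must be 'hard' or 'soft'")
        if self.density_bin_kb <= 0:
            raise ValueError("density_bin_kb must be positive")
        if not self.scales_kb:
            raise ValueError("at least one smoothing scale is required")

    def to_dict(self) -> dict:
        d = {}
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            d[name] = list(v) if isinstance(v, tuple) else v
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _validate_scales(cfg: RunConfig, m: RecombinationMap) -> dict[float, int]:
    """Check every scale is an odd number of map bins before any compute."""
    windows = {}
    for scale in cfg.scales_kb:
        w_f = scale * 1000 / m.bin_size
        w = int(round(w_f))
        if abs(w_f - w) > 1e-9 or w < 1 or w % 2 == 0:
            raise ValueError(
                f"scale {scale} kb is not an odd multiple of the map bin "
                f"({m.bin_size} bp)"
            )
        windows[scale] = w
    return windows


def run_pipeline(
    cfg: RunConfig,
    genome: dict[str, str] | None = None,
    rec_map: RecombinationMap | None = None,
) -> dict:
    """Execute the full analysis and write every intermediate to the run dir.

    Stages: normalize (if the map is in rho units and anchors are given) ->
    moving-median smoothing at each scale -> per-scale high/low median split
    -> optional enumerative discovery + consensus construction -> PWM scan
    with q-scores per motif -> q-discounted density tracks -> association
    grid (per chromosome, pooled, every motif x scale).  Re-running the same
    config reproduces all CSV outputs bit-identically.

    Returns a dict with the grid, consensus set, artifact paths and manifest.
    """
    cfg.validate()
    t0 = time.time()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if genome is None:
        genome = read_fasta(cfg.genome_fasta)
    if rec_map is None:
        rec_map = read_map(cfg.map_csv, unit=cfg.map_unit)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    for chrom, length in rec_map.lengths.items():
        if chrom not in chrom_lengths:
            raise ValueError(f"map chromosome {chrom!r} absent from genome")
        if abs(chrom_lengths[chrom] - length) > rec_map.bin_size:
            raise ValueError(f"{chrom}: genome/map length mismatch")

    windows = _validate_scales(cfg, rec_map)

    if rec_map.unit == UNIT_RHO:
        if not cfg.anchors:
            raise ValueError("rho map given without genetic anchors")
        rec_map = normalize_to_cM(rec_map, AnchorSet([tuple(a) for a in cfg.anchors]))
        write_map(rec_map, outdir / "map_cM.csv")
        logger.info("normalize: %d chromosomes", len(rec_map.rates))

    smoothed: dict[float, RecombinationMap] = {}
    for scale, w in windows.items():
        sm = moving_median(rec_map, scale) if w > 1 else rec_map.copy()
        smoothed[scale] = sm
        write_map(sm, outdir / f"map_smoothed_{scale:g}kb.csv")
        logger.info("smooth: %g kb window (%d bins)", scale, w)

    labels_by_scale = {s: split_high_low(m) for s, m in smoothed.items()}
    for scale, labels in labels_by_scale.items():
        labels.to_bed().to_csv(
            outdir / f"labels_{scale:g}kb.bed", sep="\t", index=False, header=False
        )

    consensus_set = []
    if cfg.motifs:
        motif_strings = [parse_motif(m) for m in cfg.motifs]
    elif cfg.discover:
        candidates = enumerate_candidates(
            cfg.discovery_unit_lengths, cfg.discovery_length_range
        )
        records = []
        for scale, labels in labels_by_scale.items():
            results = differential_enrichment(genome, labels, candidates)
            enrichment_frame(results).to_csv(
                outdir / f"discovery_{scale:g}kb.tsv", sep="\t", index=False,
                float_format="%.6g",
            )
            records.extend(
                MotifRecord(cfg.species, scale, r.candidate, r.E_value)
                for r in results
            )
            logger.info("discover: scale %g kb, %d candidates", scale, len(results))
        consensus_set = build_consensus_set(
            records, e_threshold=cfg.discovery_e_threshold
        )
        motif_strings = [c.string for c in consensus_set]
        with open(outdir / "consensus_motifs.yaml", "w") as fh:
            yaml.safe_dump(
                [
                    {
                        "id": c.id,
                        "unit": c.unit,
                        "count": c.count,
                        "string": c.string,
                        "label": c.label,
                        "species": sorted(c.species),
                        "single_species": c.single_species,
                    }
                    for c in consensus_set
                ],
                fh,
                sort_keys=False,
            )
    else:
        raise ValueError("no motifs configured and discovery disabled")
    if not motif_strings:
        raise ValueError("motif set is empty")

    bg = estimate_background(genome)
    density_bin = int(round(cfg.density_bin_kb * 1000))
    densities = {}
    totals = {}
    for s in motif_strings:
        name = format_motif(s)
        matrix = consensus_to_matrix(s, dialect=cfg.dialect, name=name)
        occ = scan(
            genome, matrix, bg,
            p_threshold=cfg.p_threshold,
            pseudocount=cfg.pseudocount,
            granularity=cfg.granularity,
        )
        occ = compute_qvalues(occ)
        write_occurrences_tsv(occ, outdir / f"occurrences_{name}.tsv")
        track = density_track(occ, chrom_lengths, bin_size=density_bin, motif=name)
        track.write_csv(outdir / f"density_{name}_{cfg.density_bin_kb:g}kb.csv")
        totals[name] = float(track.total())
        if track.bin_size != rec_map.bin_size:
            if rec_map.bin_size % track.bin_size == 0:
                track = rebin_density_to_map(track, rec_map)
            else:
                raise ValueError("density bin incompatible with map bin")
        densities[name] = track
        logger.info("scan: %s, %d occurrences", name, len(occ))

    grid = association_grid(smoothed, densities)
    grid.to_csv(outdir / "association_grid.csv", index=False, float_format="%.6g")

    manifest = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "chromosomes": {c: int(n) for c, n in chrom_lengths.items()},
        "motifs": [format_motif(s) for s in motif_strings],
        "totals": totals,
        "background": bg.as_dict(),
        "elapsed_s": round(time.time() - t0, 3),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("associate: %d grid rows in %.1fs", len(grid), time.time() - t0)
    return {
        "grid": grid,
        "consensus_set": consensus_set,
        "densities": densities,
        "totals": totals,
        "smoothed": smoothed,
        "manifest": manifest,
        "outdir": outdir,
    }


def analyze_bundle(bundle, cfg: RunConfig) -> dict:
    """Run the pipeline directly on an in-memory fixture bundle."""
    return run_pipeline(cfg, genome=bundle.genome, rec_map=bundle.map)
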