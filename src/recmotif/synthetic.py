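"""Synthetic genomes and recombination landscapes with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without real data:

* a multi-chromosome genome drawn i.i.d. from an order-0 base composition;
* a per-kb recombination landscape in one of two qualitative shapes —
  ``mel_like`` (a plateau that decays gradually toward each chromosome end,
  the *D. melanogaster*-style centromere/telomere effect, here a logistic
  decay with length constant ``decay_scale``) and ``sim_like`` (a flat
  plateau with sharp suppression only within ``edge_drop_width`` of each
  end, the *D. simulans* style) — plus ``flat`` and ``custom``; raw per-bin
  rates carry multiplicative lognormal noise with coefficient of variation
  ``noise_cv``, mimicking noisy LD-based rate estimates;
* motif copies planted at per-bin Poisson counts with intensity
  ``a + b * rate`` per kb, coupling motif density to the landscape with
  slope ``b``; planted copies never overlap each other and the plus-strand
  genome substring at each truth interval equals the motif exactly.

A single global seed expands to fixed per-component seeds recorded in the
manifest; regeneration from a manifest is bit-identical.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._util import decode, encode, parse_motif, revcomp
from .recmap import UNIT_CM, RecombinationMap

__all__ = [
    "LandscapeSpec",
    "PlantSpec",
    "FixtureBundle",
    "simulate_landscape",
    "plant_motifs",
    "make_bundle",
    "make_fixture",
    "read_fixture",
]

BASES_ORDER = "ACGT"

# fixed offsets expanding the global seed into per-component streams
SEED_GENOME = 1
SEED_PLANT = 2
SEED_LANDSCAPE = 1000  # + chromosome index

EDGE_DROP_FACTOR = 50.0  # sim_like terminal rate = plateau / 50


@dataclass
class LandscapeSpec:
    """Parameters of one chromosome's simulated recombination landscape.

    shape : ``mel_like`` | ``sim_like`` | ``flat`` | ``custom``
    chrom_length : chromosome length in bp
    bin_size : bin width in bp (default 1000, i.e. per-kb rates)
    plateau_rate : mid-arm rate in cM/Mb (> 0)
    edge_drop_width : width in bp of the sim_like terminal suppression zone
    decay_scale : length constant in bp of the mel_like logistic decay
    noise_cv : coefficient of variation of multiplicative lognormal noise
    seed : integer stream seed
    custom_rates : noise-free per-bin rates when shape is ``custom``
    """

    shape: str = "flat"
    chrom_length: int = 1_000_000
    bin_size: int = 1000
    plateau_rate: float = 3.0
    edge_drop_width: int = 100_000
    decay_scale: float = 300_000.0
    noise_cv: float = 0.0
    seed: int = 0
    chrom_name: str = "chr1"
    custom_rates: np.ndarray | None = None

    def validate(self) -> None:
        if self.shape not in ("mel_like", "sim_like", "flat", "custom"):
            raise ValueError(f"unknown landscape shape {self.shape!r}")
        if self.plateau_rate <= 0:
            raise ValueError("plateau_rate must be > 0")
        if self.bin_size <= 0 or self.chrom_length <= 0:
            raise ValueError("bin_size and chrom_length must be > 0")
        if self.chrom_length < 10 * self.bin_size:
            raise ValueError("chromosome must span at least 10 bins")
        if self.edge_drop_width < 0:
            raise ValueError("edge_drop_width must be >= 0")
        if self.decay_scale <= 0:
            raise ValueError("decay_scale must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.shape == "custom" and self.custom_rates is None:
            raise ValueError("custom shape requires custom_rates")


@dataclass
class PlantSpec:
    """Motif-planting intensity, coupled to the landscape.

    The expected number of planted copies in a bin is
    ``(a + b * rate_bin) * bin_kb``: ``a`` copies per kb at rate zero plus
    ``b`` extra copies per kb per cM/Mb.  ``b = 0`` decouples occurrences
    from the landscape.
    """

    motif: str = "CACACACACACA"
    a: float = 0.2
    b: float = 0.0
    strand_policy: str = "plus_only"
    seed: int = 0

    def validate(self, max_rate: float) -> None:
        if not self.motif:
            raise ValueError("motif must be non-empty")
        parse_motif(self.motif)
        if self.a < 0:
            raise ValueError("base intensity a must be >= 0")
        if self.a + self.b * max_rate < 0:
            raise ValueError("intensity a + b*max(rate) must be >= 0")
        if self.strand_policy not in ("plus_only", "both"):
            raise ValueError(f"unknown strand policy {self.strand_policy!r}")


@dataclass
class FixtureBundle:
    """A generated genome, its raw map, the planted-occurrence truth and the
    full parameter manifest."""

    genome: dict[str, str]
    map: RecombinationMap
    truth: pd.DataFrame  # chrom, start, end, strand, motif
    manifest: dict

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def _noise_free_profile(spec: LandscapeSpec) -> np.ndarray:
    n = math.ceil(spec.chrom_length / spec.bin_size)
    centers = (np.arange(n) + 0.5) * spec.bin_size
    d_end = np.minimum(centers, spec.chrom_length - centers)  # bp to nearest end
    if spec.shape == "flat":
        return np.full(n, spec.plateau_rate)
    if spec.shape == "sim_like":
        rate = np.full(n, spec.plateau_rate)
        if spec.edge_drop_width > 0:
            rate[d_end < spec.edge_drop_width] = spec.plateau_rate / EDGE_DROP_FACTOR
        return rate
    if spec.shape == "mel_like":
        # logistic rise from the chromosome end, midpoint at 2 decay lengths
        z = (d_end - 2.0 * spec.decay_scale) / spec.decay_scale
        return spec.plateau_rate / (1.0 + np.exp(-z))
    rates = np.asarray(spec.custom_rates, dtype=float)
    if len(rates) != n:
        raise ValueError(f"custom_rates has {len(rates)} bins, expected {n}")
    if (rates[~np.isnan(rates)] < 0).any():
        raise ValueError("custom_rates must be >= 0")
    return rates.copy()


def simulate_landscape(spec: LandscapeSpec) -> RecombinationMap:
    """One chromosome's raw recombination map at ``bin_size`` resolution.

    The noise-free profile is set by ``shape``; multiplicative lognormal
    noise with mean 1 and coefficient of variation ``noise_cv`` is applied
    per bin.  Deterministic given the spec's seed.
    """
    spec.validate()
    rate = _noise_free_profile(spec)
    if spec.noise_cv > 0:
        rng = np.random.default_rng(spec.seed)
        sigma2 = math.log1p(spec.noise_cv**2)
        noise = rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=len(rate))
        rate = rate * noise
    return RecombinationMap(
        bin_size=spec.bin_size,
        unit=UNIT_CM,
        rates={spec.chrom_name: rate},
        lengths={spec.chrom_name: spec.chrom_length},
    )


def _merge_maps(maps: list[RecombinationMap]) -> RecombinationMap:
    rates, lengths = {}, {}
    bin_size = maps[0].bin_size
    for m in maps:
        if m.bin_size != bin_size:
            raise ValueError("chromosome maps disagree on bin size")
        rates.update(m.rates)
        lengths.update(m.lengths)
    return RecombinationMap(bin_size=bin_size, unit=UNIT_CM, rates=rates, lengths=lengths)


def plant_motifs(
    background: dict[str, float] | np.ndarray,
    m: RecombinationMap,
    plant: PlantSpec,
    genome_seed: int | None = None,
    saturation_limit: float = 0.2,
) -> FixtureBundle:
    """Draw a background genome over the map's coordinates and plant motifs.

    The genome is i.i.d. from the order-0 ``background``; per bin, the
    number of planted copies is Poisson with mean ``(a + b*rate) * bin_kb``
    (missing-rate bins contribute the base intensity ``a`` only), placed
    uniformly within the bin and rejected if they would overlap an earlier
    plant or run past the chromosome end.  Planting replaces the background
    bases, so the plus-strand substring at each truth interval equals the
    motif (reverse-complement for minus-strand plants under the ``both``
    strand policy).
    """
    if isinstance(background, dict):
        bg = np.array([background[b] for b in BASES_ORDER], dtype=float)
    else:
        bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or (bg < 0).any() or abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError("background must be 4 non-negative frequencies summing to 1")
    bg = bg / bg.sum()
    max_rate = max(
        (float(np.nanmax(v)) if np.isfinite(np.nanmax(v)) else 0.0)
        for v in m.rates.values()
    )
    plant.validate(max_rate)
    motif = parse_motif(plant.motif)
    L = len(motif)
    bin_kb = m.bin_size / 1000.0

    # saturation guard on the expected planted footprint
    exp_total = 0.0
    genome_len = 0
    for chrom, rate in m.rates.items():
        lam = (plant.a + plant.b * np.where(np.isnan(rate), 0.0, rate)) * bin_kb
        exp_total += float(np.clip(lam, 0, None).sum())
        genome_len += m.lengths[chrom]
    if exp_total * L > saturation_limit * genome_len:
        raise ValueError(
            f"expected planted footprint {exp_total * L:.0f} bp exceeds "
            f"{saturation_limit:.0%} of the genome ({genome_len} bp)"
        )

    g_rng = np.random.default_rng(plant.seed if genome_seed is None else genome_seed)
    p_rng = np.random.default_rng(plant.seed)
    motif_codes = encode(motif)
    motif_rc_codes = encode(revcomp(motif))

    genome: dict[str, str] = {}
    truth_rows = []
    for chrom in m.chromosomes:
        length = m.lengths[chrom]
        codes = g_rng.choice(4, size=length, p=bg).astype(np.uint8)
        rate = m.rates[chrom]
        lam = (plant.a + plant.b * np.where(np.isnan(rate), 0.0, rate)) * bin_kb
        lam = np.clip(lam, 0, None)
        counts = p_rng.poisson(lam)
        occupied = np.zeros(length, dtype=bool)
        for b in np.flatnonzero(counts):
            lo = b * m.bin_size
            hi = min(lo + m.bin_size, length)
            for _ in range(counts[b]):
                placed = False
                for _try in range(50):  # rejection sampling against overlaps
                    start = int(p_rng.integers(lo, hi))
                    if start + L > length:
                        continue
                    if occupied[start : start + L].any():
                        continue
                    if plant.strand_policy == "both" and p_rng.integers(2):
                        strand, mc = "-", motif_rc_codes
                    else:
                        strand, mc = "+", motif_codes
                    codes[start : start + L] = mc
                    occupied[start : start + L] = True
                    truth_rows.append((chrom, start, start + L, strand, motif))
                    placed = True
                    break
                if not placed:
                    # saturated bin: drop this copy rather than loop forever
                    continue
        genome[chrom] = decode(codes)
    truth = pd.DataFrame(
        truth_rows, columns=["chrom", "start", "end", "strand", "motif"]
    ).sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    manifest = {
        "background": dict(zip(BASES_ORDER, map(float, bg))),
        "plant": {
            "motif": plant.motif,
            "a": plant.a,
            "b": plant.b,
            "strand_policy": plant.strand_policy,
            "seed": int(plant.seed),
        },
        "genome_seed": int(plant.seed if genome_seed is None else genome_seed),
    }
    return FixtureBundle(genome=genome, map=m, truth=truth, manifest=manifest)


DEFAULT_MANIFEST = {
    "seed": 0,
    "background": {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25},
    "chromosomes": [
        {"name": "chr1", "length": 1_000_000, "shape": "sim_like"},
        {"name": "chr2", "length": 1_000_000, "shape": "sim_like"},
    ],
    "landscape": {
        "bin_size": 1000,
        "plateau_rate": 3.0,
        "edge_drop_width": 100_000,
        "decay_scale": 300_000.0,
        "noise_cv": 0.3,
    },
    "plant": {
        "motif": "[CA]6",
        "a": 0.2,
        "b": 0.5,
        "strand_policy": "plus_only",
    },
}


def _expanded_manifest(manifest: dict) -> dict:
    """Fill defaults and record the per-component seed expansion."""
    mf = {k: v for k, v in DEFAULT_MANIFEST.items()}
    mf.update({k: v for k, v in manifest.items() if k != "landscape" and k != "plant"})
    mf["landscape"] = {**DEFAULT_MANIFEST["landscape"], **manifest.get("landscape", {})}
    mf["plant"] = {**DEFAULT_MANIFEST["plant"], **manifest.get("plant", {})}
    seed = int(mf["seed"])
    mf["seeds"] = {
        "genome": seed + SEED_GENOME,
        "plant": seed + SEED_PLANT,
        "landscape": {
            c["name"]: seed + SEED_LANDSCAPE * (i + 1)
            for i, c in enumerate(mf["chromosomes"])
        },
    }
    return mf


def make_bundle(manifest: dict) -> FixtureBundle:
    """Build a full in-memory fixture bundle from a manifest dictionary.

    The manifest holds a global ``seed``, the ``background`` composition,
    per-chromosome entries (name, length, shape and optional landscape
    overrides) and shared ``landscape`` / ``plant`` parameter blocks; see
    ``DEFAULT_MANIFEST`` for the schema and defaults.
    """
    mf = _expanded_manifest(manifest)
    maps = []
    for i, chrom in enumerate(mf["chromosomes"]):
        params = {**mf["landscape"], **{k: v for k, v in chrom.items()
                                        if k not in ("name", "length")}}
        spec = LandscapeSpec(
            shape=params.get("shape", "flat"),
            chrom_length=int(chrom["length"]),
            bin_size=int(params["bin_size"]),
            plateau_rate=float(params["plateau_rate"]),
            edge_drop_width=int(params["edge_drop_width"]),
            decay_scale=float(params["decay_scale"]),
            noise_cv=float(params["noise_cv"]),
            seed=mf["seeds"]["landscape"][chrom["name"]],
            chrom_name=chrom["name"],
        )
        maps.append(simulate_landscape(spec))
    full_map = _merge_maps(maps)
    plant = PlantSpec(
        motif=mf["plant"]["motif"],
        a=float(mf["plant"]["a"]),
        b=float(mf["plant"]["b"]),
        strand_policy=mf["plant"]["strand_policy"],
        seed=mf["seeds"]["plant"],
    )
    bundle = plant_motifs(
        mf["background"], full_map, plant, genome_seed=mf["seeds"]["genome"]
    )
    bundle.manifest = mf
    return bundle


def _write_fasta(genome: dict[str, str], path: Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def make_fixture(manifest: dict, outdir, overwrite: bool = False) -> FixtureBundle:
    """Write a fixture bundle to disk: FASTA genome (60-column wrap), CSV
    map, BED6 truth occurrences and the expanded manifest as YAML.

    Refuses to write into an existing non-empty directory unless
    ``overwrite`` is set.  Identical manifests produce byte-identical files.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(f"{outdir} exists; pass overwrite=True to replace")
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = make_bundle(manifest)
    _write_fasta(bundle.genome, outdir / "genome.fa")
    bundle.map.to_frame().to_csv(
        outdir / "map.csv", index=False, float_format="%.10g"
    )
    bed = bundle.truth.copy()
    bed["score"] = 0
    bed[["chrom", "start", "end", "motif", "score", "strand"]].to_csv(
        outdir / "truth.bed", sep="\t", index=False, header=False
    )
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(bundle.manifest, fh, sort_keys=True)
    return bundle


def read_fixture(outdir) -> FixtureBundle:
    """Round-trip a written fixture back into memory."""
    from .recmap import read_map

    outdir = Path(outdir)
    genome = read_fasta(outdir / "genome.fa")
    m = read_map(outdir / "map.csv")
    truth = pd.read_csv(
        outdir / "truth.bed",
        sep="\t",
        names=["chrom", "start", "end", "motif", "score", "strand"],
    )[["chrom", "start", "end", "strand", "motif"]]
    with open(outdir / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    return FixtureBundle(genome=genome, map=m, truth=truth, manifest=manifest)


def manifest_hash(manifest: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(manifest, sort_keys=True).encode()
    ).hexdigest()[:16]
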