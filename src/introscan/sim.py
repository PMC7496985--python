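"""Synthetic two-species panels with planted introgression and trait effects.

The generator emulates the statistical structure of a strongly
differentiated pair of crop species (genome-wide FST near 0.9) plus a
semi-wild relative of species A:

* a fraction ``p_fixed`` of SNPs are fixed interspecific differences
  (species A fixed for one allele, species B for the other);
* the remaining SNPs are mostly private polymorphisms of one species,
  with a small shared-polymorphism fraction;
* the race group is modelled as drifted species A via a Balding–Nichols
  (beta) perturbation of the A allele frequencies;
* introgression is planted by replacing the calls of randomly chosen
  carrier accessions, inside a window, with fresh draws from the *donor*
  species' site frequencies (frequency replacement, not coalescent);
* trait values are species baseline + additive per-locus carrier effects
  + environment offset + Gaussian residual.

Everything is deterministic given the root seed: each consumer of
randomness draws from a named substream derived from
``(seed, crc32(label))``, so adding or reordering stages cannot silently
shift results.
"""

from __future__ import annotations

import dataclasses
import json
import os
import zlib
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .model import FIBRE_TRAITS, MISSING, GenotypeMatrix, SampleInfo, Window
from . import io as iolib

#: Direction labels: species A -> species B means A is the donor.
A_TO_B = "A->B"
B_TO_A = "B->A"
DIRECTIONS = (A_TO_B, B_TO_A)


def substream(seed: int, label: str) -> np.random.Generator:
    """Named random substream: Generator seeded by ``(seed, crc32(label))``."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])
    )


@dataclass(frozen=True)
class PlantedSegment:
    """A planted introgression: donor-ancestry carriers inside a window."""

    window: Window
    direction: str
    n_carriers: int

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if self.n_carriers < 1:
            raise ValueError("n_carriers must be >= 1")


@dataclass(frozen=True)
class LocusEffect:
    """Additive trait effect (in trait-SD units) of one planted segment."""

    segment: int
    trait: str
    effect: float


def _default_baselines() -> dict[str, tuple[float, float]]:
    # (species A mean, species B mean) in trait units: A is the high-yield
    # species, B the high-fibre-quality species.
    return {
        "LP": (42.0, 34.0), "SCW": (5.8, 5.0), "LW": (2.4, 1.7),
        "FL": (29.0, 33.0), "FS": (29.0, 34.0), "MV": (4.3, 4.0),
        "FU": (84.0, 86.0), "SFC": (12.0, 10.0), "FE": (6.5, 6.8),
    }


def _default_sd() -> dict[str, float]:
    return {
        "LP": 1.5, "SCW": 0.4, "LW": 0.2, "FL": 1.0, "FS": 1.2,
        "MV": 0.35, "FU": 1.0, "SFC": 1.2, "FE": 0.4,
    }


@dataclass
class TraitModel:
    """Additive multi-environment trait model.

    Baselines and SDs are in trait units; environment offsets, locus
    effects and the residual SD are expressed in trait-SD units.
    """

    baselines: dict[str, tuple[float, float]] = field(default_factory=_default_baselines)
    sd: dict[str, float] = field(default_factory=_default_sd)
    env_offsets: dict[str, float] = field(
        default_factory=lambda: {
            "E1": 0.0, "E2": 0.3, "E3": -0.2, "E4": 0.1, "E5": -0.4, "E6": 0.2,
        }
    )
    residual_sd: float = 1.0
    locus_effects: list[LocusEffect] = field(default_factory=list)

    @property
    def traits(self) -> list[str]:
        return list(self.baselines)

    @property
    def environments(self) -> list[str]:
        return list(self.env_offsets)


def default_maf_dist(rng: np.random.Generator, n: int) -> np.ndarray:
    """Low-skewed minor-allele frequencies: Beta(0.8, 4) clipped to [0.01, 0.5]."""
    return np.clip(rng.beta(0.8, 4.0, size=n), 0.01, 0.5)


@dataclass
class SimConfig:
    """Study conditions for one synthetic panel."""

    n_A: int = 60
    n_B: int = 30
    n_race: int = 10
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {c: 7_000_000 for c in ("A01", "A02", "A03", "D01", "D02")}
    )
    snp_density: float = 1.0e-3  # SNPs per bp
    p_fixed: float = 0.55  # fraction of sites that are fixed interspecific
    shared_frac: float = 0.11  # of non-fixed sites, fraction polymorphic in both
    maf_dist: Callable[[np.random.Generator, int], np.ndarray] = default_maf_dist
    # Balding-Nichols F for the race group vs species A; 0.5 yields a
    # realized A-vs-race FST near 0.21 (only A-polymorphic sites drift)
    race_drift: float = 0.5
    planted_segments: list[PlantedSegment] = field(default_factory=list)
    trait_model: TraitModel = field(default_factory=TraitModel)
    missing_rate: float = 0.02
    group_a: str = "Gh"
    group_b: str = "Gb"
    group_race: str = "Gh-race"
    seed: int = 0

    def validate(self) -> None:
        if self.n_A < 2 or self.n_B < 2:
            raise ValueError("need >= 2 samples in each species group")
        if not (0.0 <= self.p_fixed <= 1.0):
            raise ValueError("p_fixed must lie in [0, 1]")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must lie in [0, 1]")
        for seg in self.planted_segments:
            length = self.chrom_lengths.get(seg.window.chrom)
            if length is None or seg.window.end > length:
                raise ValueError(f"planted segment outside genome: {seg.window}")
            n_recipient = self.n_B if seg.direction == A_TO_B else self.n_A
            if seg.n_carriers > n_recipient:
                raise ValueError(
                    f"carrier count {seg.n_carriers} exceeds recipient group "
                    f"size {n_recipient} for {seg.window}"
                )


@dataclass
class RealizedSegment:
    index: int
    window: Window
    direction: str
    carriers: tuple[str, ...]


@dataclass
class SimTruth:
    """Ground truth emitted with a simulated panel."""

    segments: list[RealizedSegment]
    locus_effects: list[LocusEffect]
    fixed_mask: np.ndarray  # per-site: planted as a fixed interspecific difference
    seed: int

    def carriers_by_direction(self, direction: str) -> set[str]:
        out: set[str] = set()
        for seg in self.segments:
            if seg.direction == direction:
                out.update(seg.carriers)
        return out

    def summary(self) -> dict:
        return {
            "seed": self.seed,
            "n_segments": len(self.segments),
            "n_events_A_to_B": sum(1 for s in self.segments if s.direction == A_TO_B),
            "n_events_B_to_A": sum(1 for s in self.segments if s.direction == B_TO_A),
            "segments": [
                {
                    "index": s.index,
                    "chrom": s.window.chrom,
                    "start": s.window.start,
                    "end": s.window.end,
                    "direction": s.direction,
                    "carriers": sorted(s.carriers),
                }
                for s in self.segments
            ],
            "locus_effects": [dataclasses.asdict(e) for e in self.locus_effects],
        }


def _sample_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """n distinct sorted 1-based positions in [1, length]."""
    if n > length:
        raise ValueError("more sites requested than base pairs")
    pos = np.unique(rng.integers(1, length + 1, size=int(n * 1.2) + 8))
    while pos.size < n:
        extra = rng.integers(1, length + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def simulate_panel(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate a genotype panel plus ground truth, deterministically."""
    cfg.validate()
    rng_sites = substream(cfg.seed, "sites")
    rng_geno = substream(cfg.seed, "genotypes")
    rng_race = substream(cfg.seed, "race")
    rng_seg = substream(cfg.seed, "segments")
    rng_miss = substream(cfg.seed, "missing")

    ids_a = [f"{cfg.group_a}{i + 1:03d}" for i in range(cfg.n_A)]
    ids_b = [f"{cfg.group_b}{i + 1:03d}" for i in range(cfg.n_B)]
    ids_r = [f"{cfg.group_race}{i + 1:02d}" for i in range(cfg.n_race)]
    samples = (
        [SampleInfo(i, cfg.group_a) for i in ids_a]
        + [SampleInfo(i, cfg.group_b) for i in ids_b]
        + [SampleInfo(i, cfg.group_race) for i in ids_r]
    )

    chroms_list: list[np.ndarray] = []
    pos_list: list[np.ndarray] = []
    for chrom, length in cfg.chrom_lengths.items():
        n = max(1, int(round(length * cfg.snp_density)))
        p = _sample_positions(rng_sites, length, n)
        pos_list.append(p)
        chroms_list.append(np.full(n, chrom, dtype=object))
    chrom = np.concatenate(chroms_list)
    pos = np.concatenate(pos_list)
    n_sites = pos.size

    # Site classes and per-species allele frequencies
    u = rng_sites.random(n_sites)
    fixed = u < cfg.p_fixed
    rest = ~fixed
    v = rng_sites.random(n_sites)
    shared = rest & (v < cfg.shared_frac)
    private = rest & ~shared
    w = rng_sites.random(n_sites)
    private_a = private & (w < 0.5)
    private_b = private & ~private_a

    maf = cfg.maf_dist(rng_sites, n_sites)
    f_a = np.zeros(n_sites)
    f_b = np.zeros(n_sites)
    f_a[fixed], f_b[fixed] = 0.0, 1.0
    f_a[private_a] = maf[private_a]
    f_b[private_b] = maf[private_b]
    f_a[shared] = maf[shared]
    f_b[shared] = maf[shared]
    # ref/alt polarity is arbitrary: flip half the sites
    flip = rng_sites.random(n_sites) < 0.5
    f_a[flip] = 1.0 - f_a[flip]
    f_b[flip] = 1.0 - f_b[flip]

    # Race group: Balding-Nichols drift around species A frequencies
    f_r = f_a.copy()
    if cfg.n_race and cfg.race_drift > 0:
        seg_poly = (f_a > 0) & (f_a < 1)
        F = cfg.race_drift
        a_par = f_a[seg_poly] * (1 - F) / F
        b_par = (1 - f_a[seg_poly]) * (1 - F) / F
        f_r[seg_poly] = rng_race.beta(a_par, b_par)

    calls = np.empty((len(samples), n_sites), dtype=np.int8)
    calls[: cfg.n_A] = rng_geno.binomial(2, f_a, size=(cfg.n_A, n_sites))
    calls[cfg.n_A : cfg.n_A + cfg.n_B] = rng_geno.binomial(
        2, f_b, size=(cfg.n_B, n_sites)
    )
    if cfg.n_race:
        calls[cfg.n_A + cfg.n_B :] = rng_geno.binomial(
            2, f_r, size=(cfg.n_race, n_sites)
        )

    id_index = {s.id: i for i, s in enumerate(samples)}
    realized: list[RealizedSegment] = []
    for k, seg in enumerate(cfg.planted_segments):
        recipients = ids_b if seg.direction == A_TO_B else ids_a
        donor_freq = f_a if seg.direction == A_TO_B else f_b
        carriers = tuple(
            sorted(rng_seg.choice(recipients, size=seg.n_carriers, replace=False))
        )
        mask = (
            (chrom == seg.window.chrom)
            & (pos - 1 >= seg.window.start)
            & (pos - 1 < seg.window.end)
        )
        rows = np.array([id_index[c] for c in carriers], dtype=np.intp)
        calls[np.ix_(rows, np.flatnonzero(mask))] = rng_seg.binomial(
            2, donor_freq[mask], size=(rows.size, int(mask.sum()))
        )
        realized.append(RealizedSegment(k, seg.window, seg.direction, carriers))

    if cfg.missing_rate > 0:
        miss = rng_miss.random(calls.shape) < cfg.missing_rate
        calls[miss] = MISSING

    ref = np.full(n_sites, "A", dtype=object)
    alt = np.full(n_sites, "T", dtype=object)
    gm = GenotypeMatrix(samples, chrom, pos, ref, alt, calls)
    truth = SimTruth(
        segments=realized,
        locus_effects=list(cfg.trait_model.locus_effects),
        fixed_mask=fixed,
        seed=cfg.seed,
    )
    return gm, truth


def simulate_traits(
    truth: SimTruth, samples: list[SampleInfo], cfg: SimConfig
) -> pd.DataFrame:
    """Long-format trait table for every accession x trait x environment."""
    tm = cfg.trait_model
    known = {s.id for s in samples}
    for seg in truth.segments:
        missing = set(seg.carriers) - known
        if missing:
            raise KeyError(f"truth carriers not in accession list: {sorted(missing)}")
    rng = substream(cfg.seed, "traits")
    effect_by_trait: dict[str, list[LocusEffect]] = {}
    for eff in truth.locus_effects:
        effect_by_trait.setdefault(eff.trait, []).append(eff)
    seg_by_index = {s.index: s for s in truth.segments}

    recs: list[tuple[str, str, str, float]] = []
    for trait in tm.traits:
        sd = tm.sd[trait]
        mu_a, mu_b = tm.baselines[trait]
        base = np.array(
            [mu_b if s.group == cfg.group_b else mu_a for s in samples]
        )
        genetic = base.copy()
        for eff in effect_by_trait.get(trait, []):
            seg = seg_by_index.get(eff.segment)
            if seg is None:
                continue
            carrier = np.array([s.id in seg.carriers for s in samples])
            genetic = genetic + carrier * eff.effect * sd
        for env in tm.environments:
            shift = tm.env_offsets[env] * sd
            noise = rng.normal(0.0, tm.residual_sd * sd, size=len(samples))
            values = genetic + shift + noise
            recs.extend(
                (s.id, trait, env, float(v)) for s, v in zip(samples, values)
            )
    return pd.DataFrame(recs, columns=iolib.TRAIT_COLUMNS)


# -- presets ------------------------------------------------------------------

def _cotton_panel_segments() -> list[PlantedSegment]:
    """17 A->B and 7 B->A planted events, incl. one bidirectional window.

    Layout over 5 chromosomes x 7 one-Mb windows; same-direction events
    are never window-adjacent so each survives locus merging as its own
    event.  The bidirectional window sits on chromosome A01.
    """
    layout = {
        # per chromosome: window slot -> set of directions
        "A01": {0: {A_TO_B}, 2: {A_TO_B, B_TO_A}, 4: {A_TO_B}, 5: {B_TO_A}, 6: {A_TO_B}},
        "A02": {0: {A_TO_B}, 1: {B_TO_A}, 2: {A_TO_B}, 3: {B_TO_A}, 4: {A_TO_B}, 6: {A_TO_B}},
        "A03": {0: {A_TO_B}, 1: {B_TO_A}, 2: {A_TO_B}, 3: {B_TO_A}, 4: {A_TO_B}, 5: {B_TO_A}, 6: {A_TO_B}},
        "D01": {0: {A_TO_B}, 2: {A_TO_B}, 4: {A_TO_B}, 6: {A_TO_B}},
        "D02": {0: {A_TO_B}},
    }
    counts = {A_TO_B: [6, 8, 5, 7, 9, 6, 8, 7, 5, 9, 6, 7, 8, 5, 6, 9, 7],
              B_TO_A: [6, 8, 5, 7, 9, 6, 8]}
    taken = {A_TO_B: 0, B_TO_A: 0}
    segments: list[PlantedSegment] = []
    for chrom, slots in layout.items():
        for slot in sorted(slots):
            for direction in sorted(slots[slot]):
                n = counts[direction][taken[direction]]
                taken[direction] += 1
                w = Window(chrom, slot * 1_000_000, (slot + 1) * 1_000_000)
                segments.append(PlantedSegment(w, direction, n))
    assert taken[A_TO_B] == 17 and taken[B_TO_A] == 7
    return segments


def _cotton_panel_effects(segments: list[PlantedSegment]) -> list[LocusEffect]:
    """Donor-beneficial effects: A alleles raise yield in B, B alleles raise
    fibre quality in A (1 SD on two traits each, a few loci per direction).

    Effects are deliberately large ("major-effect" loci): with only a
    handful of carriers per event, smaller effects would be statistically
    invisible to per-locus contrasts at these panel sizes."""
    into_b = [i for i, s in enumerate(segments) if s.direction == A_TO_B]
    into_a = [i for i, s in enumerate(segments) if s.direction == B_TO_A]
    effects: list[LocusEffect] = []
    for i in into_b[:5]:
        effects.append(LocusEffect(i, "SCW", 1.0))
        effects.append(LocusEffect(i, "LW", 1.0))
    for i in into_a[:3]:
        effects.append(LocusEffect(i, "FL", 1.0))
        effects.append(LocusEffect(i, "FS", 1.0))
    return effects


def cotton_panel_config(seed: int = 0, **overrides) -> SimConfig:
    """Panel emulating the study conditions at desk scale.

    5 chromosomes x 7 Mb, 60 + 30 + 10 accessions, ~1 SNP/kb, 55% fixed
    interspecific sites, 17 planted A->B and 7 B->A events including one
    bidirectional window.
    """
    segments = _cotton_panel_segments()
    cfg = SimConfig(
        planted_segments=segments,
        trait_model=TraitModel(locus_effects=_cotton_panel_effects(segments)),
        seed=seed,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    cfg.validate()
    return cfg


def no_introgression_config(seed: int = 0, **overrides) -> SimConfig:
    """Cotton panel with no planted segments (null for false positives)."""
    cfg = cotton_panel_config(seed, **overrides)
    cfg.planted_segments = []
    cfg.trait_model = TraitModel()
    return cfg


def tiny_config(seed: int = 0) -> SimConfig:
    """Two 2-Mb chromosomes, <=1000 sites, one planted event per direction."""
    segments = [
        PlantedSegment(Window("A01", 0, 1_000_000), A_TO_B, 3),
        PlantedSegment(Window("D01", 0, 1_000_000), B_TO_A, 3),
    ]
    tm = TraitModel(
        env_offsets={"E1": 0.0, "E2": 0.3},
        locus_effects=[LocusEffect(0, "SCW", 0.8), LocusEffect(1, "FL", 0.8)],
    )
    return SimConfig(
        n_A=12,
        n_B=8,
        n_race=4,
        chrom_lengths={"A01": 2_000_000, "D01": 2_000_000},
        snp_density=2.5e-4,
        planted_segments=segments,
        trait_model=tm,
        seed=seed,
    )


PRESETS = {
    "tiny": tiny_config,
    "cotton": cotton_panel_config,
    "no-introgression": no_introgression_config,
}


def make_fixture(preset: str, outdir: str, seed: int = 0) -> dict[str, str]:
    """Write a complete fixture (VCF, groups, traits, truth JSON) to disk."""
    if preset not in PRESETS:
        raise KeyError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    os.makedirs(outdir, exist_ok=True)
    cfg = PRESETS[preset](seed)
    gm, truth = simulate_panel(cfg)
    traits = simulate_traits(truth, gm.samples, cfg)
    paths = {
        "vcf": os.path.join(outdir, "panel.vcf"),
        "groups": os.path.join(outdir, "groups.tsv"),
        "traits": os.path.join(outdir, "traits.csv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    iolib.write_vcf(gm, paths["vcf"])
    iolib.write_groups_table(gm, paths["groups"])
    iolib.write_trait_table(traits, paths["traits"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth.summary(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
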