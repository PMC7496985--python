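"""End-to-end orchestration: config, staged execution, run report.

Every stage is a pure function of (inputs, config, seed); the CLI in
:mod:`introscan.cli` is a thin wrapper around :func:`run_all` and the
individual stage helpers.  All tabular outputs are written with a fixed
float format so identical runs produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import association, introgression, io as iolib, popdiff, sim
from .model import GenotypeMatrix, Window, tile_windows

FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run."""

    # inputs: either a simulation preset or explicit file paths
    preset: str | None = "cotton"
    vcf: str | None = None
    groups: str | None = None
    traits: str | None = None
    qtl: str | None = None
    sweeps: str | None = None
    # group-role mapping
    group_a: str = "Gh"
    group_b: str = "Gb"
    group_race: str | None = "Gh-race"
    # stage parameters
    fst_window_size: int = 2_000_000
    fst_window_step: int = 50_000
    scan_window_size: int = 1_000_000
    min_fixed: int = 20
    knn: int = 5
    carrier_min_frac: float = 0.5
    merge_distance: int | None = None  # None -> LD-decay distance, fallback 5 Mb
    f3_block_size: int = 5_000_000
    z_threshold: float = 3.0
    maf_min: float = 0.05
    n_pcs: int = 3
    alpha: float = 0.05
    min_envs: int = 3
    scan_trait: str = "SCW"
    seed: int = 0
    outdir: str = "introscan-out"

    def validate(self) -> None:
        checks = [
            ("min_fixed", self.min_fixed >= 0),
            ("knn", self.knn >= 1),
            ("carrier_min_frac", 0.0 < self.carrier_min_frac <= 1.0),
            ("scan_window_size", self.scan_window_size > 0),
            ("fst_window_size", self.fst_window_size > 0),
            ("fst_window_step", self.fst_window_step > 0),
            ("maf_min", 0.0 <= self.maf_min < 0.5),
            ("n_pcs", self.n_pcs >= 0),
            ("alpha", 0.0 < self.alpha < 1.0),
            ("min_envs", self.min_envs >= 1),
            ("f3_block_size", self.f3_block_size > 0),
        ]
        for name, ok in checks:
            if not ok:
                raise ValueError(f"invalid config value for field '{name}'")
        if self.preset is None and (self.vcf is None or self.groups is None):
            raise ValueError(
                "invalid config: either 'preset' or both 'vcf' and 'groups' required"
            )
        if self.preset is not None and self.preset not in sim.PRESETS:
            raise ValueError(
                f"invalid config value for field 'preset': {self.preset!r}"
            )

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        cfg.validate()
        return cfg


def introgression_stage(
    gm: GenotypeMatrix,
    group_a: str = "Gh",
    group_b: str = "Gb",
    scan_window_size: int = 1_000_000,
    min_fixed: int = 20,
    knn: int = 5,
    carrier_min_frac: float = 0.5,
    merge_distance: float | None = None,
) -> dict:
    """Window scan, locus calling and event merging in one step.

    When ``merge_distance`` is None the LD-decay distance of the
    recipient (species B) panel is measured on sites polymorphic within
    that panel and used as the merge radius (fallback 5 Mb when the
    decay point is undefined).  Returns a dict with ``scan``, ``loci``,
    ``events``, ``merge_distance_bp`` and ``ld_decay_bp``.
    """
    lengths = _chrom_lengths(gm)
    scan = introgression.window_scan(
        gm,
        group_a,
        group_b,
        windows=tile_windows(lengths, scan_window_size),
        min_fixed=min_fixed,
        knn=knn,
    )
    loci = introgression.call_loci(scan, carrier_min_frac)
    ld_decay_bp = float("nan")
    if merge_distance is None:
        fb = popdiff.allele_counts(gm, group_b).freq()
        poly_b = np.flatnonzero((fb >= 0.05) & (fb <= 0.95))
        if poly_b.size:
            step = max(1, poly_b.size // 800)
            _, ld_decay_bp = popdiff.ld_decay(
                gm.subset(site_idx=poly_b[::step]),
                group_b,
                max_dist=2 * scan_window_size,
                bin_size=max(scan_window_size // 10, 1),
            )
        merge_distance = ld_decay_bp if np.isfinite(ld_decay_bp) else None
    events = introgression.call_events(loci, merge_distance)
    return {
        "scan": scan,
        "loci": loci,
        "events": events,
        "merge_distance_bp": merge_distance,
        "ld_decay_bp": ld_decay_bp,
    }


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def _chrom_lengths(gm: GenotypeMatrix) -> dict[str, int]:
    return {c: int(gm.pos[gm.chrom == c].max()) for c in gm.chromosomes()}


def load_inputs(cfg: RunConfig, outdir: str):
    """Load or simulate the panel; returns (gm, traits frame, truth|None)."""
    if cfg.vcf is not None:
        groups = iolib.read_groups_table(cfg.groups)
        gm, _ = iolib.read_vcf(cfg.vcf, groups)
        traits = iolib.read_trait_table(cfg.traits) if cfg.traits else None
        return gm, traits, None
    paths = sim.make_fixture(cfg.preset, outdir, seed=cfg.seed)
    groups = iolib.read_groups_table(paths["groups"])
    gm, _ = iolib.read_vcf(paths["vcf"], groups)
    traits = iolib.read_trait_table(paths["traits"])
    sim_cfg = sim.PRESETS[cfg.preset](cfg.seed)
    _, truth = sim.simulate_panel(sim_cfg)
    return gm, traits, truth


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage and write outputs + report under ``cfg.outdir``.

    Returns the report dictionary.
    """
    cfg.validate()
    outdir = cfg.outdir
    os.makedirs(outdir, exist_ok=True)
    t0 = time.time()
    timings: dict[str, float] = {}
    report: dict = {
        "config": {k: v for k, v in dataclasses.asdict(cfg).items()},
        "stages": {},
    }

    def tick(stage: str, start: float) -> None:
        timings[stage] = round(time.time() - start, 3)

    # -- load / simulate ------------------------------------------------------
    t = time.time()
    gm, traits, truth = load_inputs(cfg, outdir)
    report["stages"]["inputs"] = {
        "n_samples": gm.n_samples,
        "n_sites": gm.n_sites,
        "groups": {g: len(gm.group_ids(g)) for g in gm.groups},
    }
    tick("inputs", t)
    lengths = _chrom_lengths(gm)

    # -- fixed SNPs -----------------------------------------------------------
    t = time.time()
    counts_a = popdiff.allele_counts(gm, cfg.group_a)
    counts_b = popdiff.allele_counts(gm, cfg.group_b)
    fixed = popdiff.identify_fixed_snps(counts_a, counts_b)
    fixed_df = pd.DataFrame(
        {
            "chrom": gm.chrom[fixed.flagged],
            "start": gm.pos[fixed.flagged] - 1,
            "end": gm.pos[fixed.flagged],
            "label": [f"fix{i + 1}" for i in range(fixed.n_fixed)],
            "source": "fixed-snp",
        }
    )
    iolib.write_intervals_bed(fixed_df, os.path.join(outdir, "fixed_snps.bed"))
    report["stages"]["fixed_snps"] = {
        "n_fixed": fixed.n_fixed,
        "frac_of_sites": round(fixed.n_fixed / max(gm.n_sites, 1), 4),
    }
    tick("fixed_snps", t)

    # -- windowed FST and diversity ------------------------------------------
    t = time.time()
    fst_windows = tile_windows(lengths, cfg.fst_window_size, cfg.fst_window_step)
    pairs = [(cfg.group_a, cfg.group_b)]
    if cfg.group_race and cfg.group_race in gm.groups:
        pairs += [(cfg.group_a, cfg.group_race), (cfg.group_b, cfg.group_race)]
    gw: dict[str, dict] = {}
    for g1, g2 in pairs:
        est = popdiff.fst_wc_windowed(gm, g1, g2, fst_windows)
        _write_tsv(
            pd.DataFrame(
                {
                    "chrom": [e.window.chrom for e in est],
                    "start": [e.window.start for e in est],
                    "end": [e.window.end for e in est],
                    "n_snps": [e.n_snps for e in est],
                    "fst_wc": [e.fst for e in est],
                    "fst_hudson": [e.fst_hudson for e in est],
                }
            ),
            os.path.join(outdir, f"fst_windows_{g1}_vs_{g2}.tsv".replace("->", "")),
        )
        g = popdiff.fst_genomewide(gm, g1, g2)
        gw[f"{g1}_vs_{g2}"] = {
            "fst_wc": g.fst_wc,
            "fst_wc_mean": g.fst_wc_mean,
            "fst_hudson": g.fst_hudson,
            "n_snps": g.n_snps,
        }
    report["stages"]["fst"] = gw
    for grp, tag in ((cfg.group_a, "A"), (cfg.group_b, "B")):
        div = popdiff.diversity_windowed(
            gm, grp, tile_windows(lengths, cfg.scan_window_size)
        )
        _write_tsv(
            pd.DataFrame(
                {
                    "chrom": [d.window.chrom for d in div],
                    "start": [d.window.start for d in div],
                    "end": [d.window.end for d in div],
                    "n_variants": [d.n_variants for d in div],
                    "pi": [d.pi for d in div],
                    "density": [d.density for d in div],
                }
            ),
            os.path.join(outdir, f"diversity_{tag}.tsv"),
        )
    tick("fst_diversity", t)

    # -- f3 -------------------------------------------------------------------
    t = time.time()
    f3_rows = []
    if cfg.group_race and cfg.group_race in gm.groups:
        for target, s1, s2 in (
            (cfg.group_a, cfg.group_b, cfg.group_race),
            (cfg.group_b, cfg.group_a, cfg.group_race),
        ):
            r = introgression.f3_statistic(gm, target, s1, s2, cfg.f3_block_size)
            f3_rows.append(
                {
                    "target": r.target, "source1": r.source1, "source2": r.source2,
                    "f3": r.f3, "se": r.se, "z": r.z,
                    "n_blocks": r.n_blocks, "n_sites": r.n_sites,
                    "admixture_signal": r.is_admixture_signal(cfg.z_threshold),
                }
            )
        _write_tsv(pd.DataFrame(f3_rows), os.path.join(outdir, "f3.tsv"))
        report["stages"]["f3"] = f3_rows
    tick("f3", t)

    # -- scan, loci, events ---------------------------------------------------
    t = time.time()
    stage = introgression_stage(
        gm,
        cfg.group_a,
        cfg.group_b,
        scan_window_size=cfg.scan_window_size,
        min_fixed=cfg.min_fixed,
        knn=cfg.knn,
        carrier_min_frac=cfg.carrier_min_frac,
        merge_distance=cfg.merge_distance,
    )
    scan = stage["scan"]
    _write_tsv(
        pd.DataFrame(
            {
                "chrom": [r.window.chrom for r in scan],
                "start": [r.window.start for r in scan],
                "end": [r.window.end for r in scan],
                "n_snps": [r.n_snps for r in scan],
                "n_fixed": [r.n_fixed for r in scan],
                "assessable": [r.assessable for r in scan],
                "call": [r.call for r in scan],
                "intruders_into_A": [
                    ",".join(sorted(r.intruders_into_a)) for r in scan
                ],
                "intruders_into_B": [
                    ",".join(sorted(r.intruders_into_b)) for r in scan
                ],
            }
        ),
        os.path.join(outdir, "scan_windows.tsv"),
    )
    loci = stage["loci"]
    events = stage["events"]
    merge_dist = stage["merge_distance_bp"]
    ld_decay_bp = stage["ld_decay_bp"]
    loci_df = pd.DataFrame(
        {
            "chrom": [l.interval.chrom for l in loci],
            "start": [l.interval.start for l in loci],
            "end": [l.interval.end for l in loci],
            "direction": [l.direction for l in loci],
            "n_windows": [l.n_windows for l in loci],
            "n_carriers": [len(l.carriers) for l in loci],
            "mean_support": [l.mean_support for l in loci],
            "carriers": [",".join(sorted(l.carriers)) for l in loci],
        }
    )
    _write_tsv(loci_df, os.path.join(outdir, "loci.tsv"))
    events_df = pd.DataFrame(
        {
            "chrom": [e.interval.chrom for e in events],
            "start": [e.interval.start for e in events],
            "end": [e.interval.end for e in events],
            "id": [e.id for e in events],
            "direction": [e.direction for e in events],
            "n_loci": [len(e.loci) for e in events],
            "n_carriers": [len(e.carriers) for e in events],
            "carriers": [",".join(sorted(e.carriers)) for e in events],
        }
    )
    _write_tsv(events_df, os.path.join(outdir, "events.tsv"))
    indicator, counts = introgression.carrier_matrix(loci, gm.samples)
    indicator.index.name = "accession"
    indicator.reset_index().to_csv(
        os.path.join(outdir, "carrier_matrix.tsv"), sep="\t", index=False
    )
    n_into_b = sum(1 for e in events if e.direction == sim.A_TO_B)
    n_into_a = sum(1 for e in events if e.direction == sim.B_TO_A)
    a_ids = set(gm.group_ids(cfg.group_a))
    b_ids = set(gm.group_ids(cfg.group_b))
    carrier_a = {s for e in events if e.direction == sim.B_TO_A for s in e.carriers}
    carrier_b = {s for e in events if e.direction == sim.A_TO_B for s in e.carriers}
    report["stages"]["introgression"] = {
        "events_into_B": n_into_b,
        "events_into_A": n_into_a,
        "n_loci": len(loci),
        "merge_distance_bp": None if merge_dist is None else float(merge_dist),
        "ld_decay_bp": None if not np.isfinite(ld_decay_bp) else float(ld_decay_bp),
        "carriers_in_A": f"{len(carrier_a & a_ids)}/{len(a_ids)}",
        "carriers_in_B": f"{len(carrier_b & b_ids)}/{len(b_ids)}",
    }
    tick("scan", t)

    # -- masked FST contrast --------------------------------------------------
    t = time.time()
    if loci:
        mask = iolib.intervals_frame(
            [l.interval for l in loci],
            [f"locus{i + 1}" for i in range(len(loci))],
            "introgression",
        )
        masked = popdiff.fst_masked(gm, cfg.group_a, cfg.group_b, mask)
    else:
        g = popdiff.fst_genomewide(gm, cfg.group_a, cfg.group_b)
        masked = {
            "fst_with": g.fst_wc, "fst_without": g.fst_wc,
            "fst_hudson_with": g.fst_hudson, "fst_hudson_without": g.fst_hudson,
            "n_snps_with": g.n_snps, "n_snps_without": g.n_snps,
        }
    _write_tsv(
        pd.DataFrame([masked]), os.path.join(outdir, "fst_masked.tsv")
    )
    report["stages"]["fst_masked"] = masked
    tick("fst_masked", t)

    # -- association ----------------------------------------------------------
    t = time.time()
    if traits is not None and len(loci):
        blups = association.blup_table(traits)
        iolib.write_trait_table(blups, os.path.join(outdir, "blup.csv"))
        traits_all = pd.concat([traits, blups], ignore_index=True)
        trend_rows = []
        for panel, ids in ((cfg.group_a, a_ids), (cfg.group_b, b_ids)):
            panel_counts = counts[counts.index.isin(ids)]
            if panel_counts.nunique() < 2:
                continue
            for trait in sorted(traits["trait"].unique()):
                for env in sorted(traits["environment"].unique()):
                    try:
                        r = association.trend_test(panel_counts, traits, trait, env)
                    except ValueError:
                        continue
                    trend_rows.append(
                        {
                            "panel": panel, "trait": r.trait, "environment": env,
                            "slope": r.slope, "se": r.se, "t": r.t, "p": r.p,
                            "n": r.n, "degenerate": r.degenerate,
                        }
                    )
        trend_df = pd.DataFrame(trend_rows)
        _write_tsv(trend_df, os.path.join(outdir, "trend_tests.tsv"))
        effects = []
        stable: dict[str, list[str]] = {}
        for panel, ids in ((cfg.group_a, a_ids), (cfg.group_b, b_ids)):
            panel_loci = [
                c for c, l in zip(indicator.columns, loci)
                if (l.direction == sim.B_TO_A) == (panel == cfg.group_a)
            ]
            if not panel_loci:
                continue
            res = association.locus_effect_tests(
                indicator[panel_loci], traits, restrict_to=sorted(ids)
            )
            effects.extend(
                {
                    "panel": panel, "locus": r.locus, "trait": r.trait,
                    "environment": r.environment,
                    "mean_carrier": r.mean_carrier,
                    "mean_noncarrier": r.mean_noncarrier,
                    "n_carrier": r.n_carrier, "n_noncarrier": r.n_noncarrier,
                    "t": r.t, "p": r.p, "p_adj": r.p_adj,
                }
                for r in res
            )
            calls = association.classify_stable(res, cfg.min_envs, cfg.alpha)
            stable[panel] = sorted(c.locus for c in calls if c.stable)
        _write_tsv(pd.DataFrame(effects), os.path.join(outdir, "locus_effects.tsv"))
        with open(os.path.join(outdir, "stable_loci.json"), "w") as fh:
            json.dump(stable, fh, indent=1, sort_keys=True)
            fh.write("\n")
        report["stages"]["association"] = {
            "n_trend_tests": len(trend_rows),
            "n_trend_significant": int(
                sum(1 for r in trend_rows if r["p"] < cfg.alpha)
            )
            if trend_rows
            else 0,
            "stable_loci": stable,
        }
        # marker scan on the recipient-B panel, BLUP phenotype
        try:
            scan_df = association.marker_scan(
                gm, traits_all, cfg.scan_trait, "BLUP",
                group=cfg.group_b, maf_min=cfg.maf_min, n_pcs=cfg.n_pcs,
            )
        except ValueError as exc:
            report["stages"]["marker_scan"] = {"skipped": str(exc)}
        else:
            _write_tsv(
                scan_df.head(5000),
                os.path.join(outdir, f"marker_scan_{cfg.scan_trait}.tsv"),
            )
            report["stages"]["marker_scan"] = {
                "trait": cfg.scan_trait,
                "n_tested": int(len(scan_df)),
                "n_significant": int(scan_df["significant"].sum()) if len(scan_df) else 0,
                "top_logp": float(scan_df["logp"].iloc[0]) if len(scan_df) else None,
            }
    tick("association", t)

    # -- interval overlap -----------------------------------------------------
    t = time.time()
    if events and (cfg.qtl or cfg.sweeps):
        ev_frame = iolib.intervals_frame(
            [e.interval for e in events], [e.id for e in events], "introgression"
        )
        overlaps = []
        for path in (cfg.qtl, cfg.sweeps):
            if path:
                overlaps.append(association.interval_overlap(ev_frame, iolib.read_intervals(path)))
        ov = pd.concat(overlaps, ignore_index=True) if overlaps else pd.DataFrame()
        _write_tsv(ov, os.path.join(outdir, "overlap.tsv"))
        report["stages"]["overlap"] = {"n_overlaps": int(len(ov))}
    tick("overlap", t)

    # -- truth comparison (simulated inputs only) -----------------------------
    if truth is not None:
        report["stages"]["truth"] = {
            "planted_into_B": sum(
                1 for s in truth.segments if s.direction == sim.A_TO_B
            ),
            "planted_into_A": sum(
                1 for s in truth.segments if s.direction == sim.B_TO_A
            ),
        }

    report["wall_times_s"] = timings
    report["total_wall_time_s"] = round(time.time() - t0, 3)
    write_report(report, outdir)
    return report


def write_report(report: dict, outdir: str) -> None:
    """Machine-readable JSON plus a short human-readable summary."""
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    lines = ["introscan run report", "====================", ""]
    st = report["stages"]
    if "inputs" in st:
        lines.append(
            f"panel: {st['inputs']['n_samples']} samples x "
            f"{st['inputs']['n_sites']} SNPs; groups {st['inputs']['groups']}"
        )
    if "fixed_snps" in st:
        lines.append(f"fixed interspecific SNPs: {st['fixed_snps']['n_fixed']}")
    for pair, d in st.get("fst", {}).items():
        lines.append(f"genome-wide FST {pair}: {d['fst_wc']:.4f} (weighted WC)")
    for row in st.get("f3", []):
        lines.append(
            f"f3({row['target']}; {row['source1']}, {row['source2']}) = "
            f"{row['f3']:.5f}, Z = {row['z']:.2f}"
        )
    if "introgression" in st:
        d = st["introgression"]
        lines.append(
            f"introgression events: {d['events_into_B']} into B (A->B), "
            f"{d['events_into_A']} into A (B->A); {d['n_loci']} loci"
        )
        lines.append(
            f"carriers: {d['carriers_in_A']} of species A, "
            f"{d['carriers_in_B']} of species B"
        )
    if "fst_masked" in st:
        d = st["fst_masked"]
        lines.append(
            f"FST with introgression {d['fst_with']:.4f} -> "
            f"without {d['fst_without']:.4f}"
        )
    if "association" in st:
        lines.append(f"stable effective loci: {st['association']['stable_loci']}")
    with open(os.path.join(outdir, "report.txt"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
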